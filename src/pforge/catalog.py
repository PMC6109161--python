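"""Published attachment-site sequences and prophage coordinates.

Eleven prophages of human gut-associated *Bifidobacterium breve* and
*B. longum* strains integrate at three chromosomal loci: the *dnaJ2*
chaperone gene, a tmRNA gene, and a tRNA-Met gene.  The boundary
coordinates and the attL/attR common-core sequences reported for these
prophages are small enough to ship as data and serve as reference inputs
for the attachment-site routines.

Coordinates are 1-based inclusive as published; ``left > right`` marks a
reverse-orientation prophage.  For the tmRNA locus a single shared
attL/attR core sequence was reported; for Bl157phi1 attL and attR are
identical.
"""

from __future__ import annotations

from .attsite import ProphageRecord

#: Locus -> prophage -> {"attL": ..., "attR": ...} common-core sequences.
ATT_SITES: dict[str, dict[str, dict[str, str]]] = {
    "dnaJ2": {
        "Bb48phi1": {
            "attL": "TTCTTTAGCAAGTTAAAAGACGCACTGAGCTGAGA",
            "attR": "TTCTTCAGCAAGTTAAAGGATGCCTTGAGCTGATT",
        },
        "Bb83phi1": {
            "attL": "TTCTTTAGCAAGTTGAAGGACGCACTGAGCTGAGA",
            "attR": "TTCTTCAGCAAGTTAAAGGATGCCTTGAGCTGATT",
        },
        "Bb423phi1": {
            "attL": "TTCTTTAGCAAGTTGAAGGACGCGCTGAGCTGAGA",
            "attR": "TTCTTCGCAAGTTAAAGGATGCCTTGAGCTGATT",  # 34 bp: 1-nt deletion
        },
        "Bb439phi1": {
            "attL": "TTCTTTAGCAAGTTGAAGGACGCACTGAGCTGAGA",
            "attR": "TTCTTCAGCAAGTTAAAGGATGCCTTGAGCTGATT",
        },
        "Binf-1": {
            "attL": "TTCTTCAGCAAGTTAAAAGACGCACTGAGCTGAGA",
            "attR": "TTCTTCTGCAAGTTAAAAGACGCACTGAGCTGAGA",
        },
        "Bl30698phi1": {
            "attL": "TTCTTCAGCAAGTTGAAGGACGCGCTGAGCTGAGA",
            "attR": "TTCTTCGCAAGTTGAAGGACGCACTGAGCTGAGA",  # 34 bp: 1-nt deletion
        },
        "Bl157phi1": {
            "attL": "TTCTTCAGCAAGTTGAAGGACGCACTGAGCTGAGA",
            "attR": "TTCTTCAGCAAGTTGAAGGACGCACTGAGCTGAGA",
        },
    },
    "tmRNA": {
        "Bb447phi1/Bb1192phi1": {
            "attL": "GTGGAGTCGCGGGGAATCGAACCCCG",
            "attR": "GTGGAGTCGCGGGGAATCGAACCCCG",
        },
    },
    "tRNA-Met": {
        "Bb423phi2/689b-1": {
            "attL": "TGGTAGCGGGGCATGGATTTGAACCTTGGACCTCTGGGT",
            "attR": "TGGTAGCGGGGCATGGATTTGAACCATGGACCTCTGGGT",
        },
    },
}

#: Published prophage boundaries: name -> (host, left, right, size_nt, gc, locus).
PROPHAGES: dict[str, ProphageRecord] = {
    name: ProphageRecord(host_id=host, left=left, right=right,
                         locus_name=locus, name=name, gc=gc)
    for name, (host, left, right, gc, locus) in {
        "Bb48phi1": ("B. breve 082W4-8", 1_193_403, 1_232_804, 61.3, "dnaJ2"),
        "Bb83phi1": ("B. breve 180W8-3", 1_179_127, 1_219_381, 61.1, "dnaJ2"),
        "Bb423phi1": ("B. breve 139W4-23", 1_302_639, 1_342_715, 60.9, "dnaJ2"),
        "Bb439phi1": ("B. breve 017W4-39", 1_194_717, 1_234_971, 61.1, "dnaJ2"),
        "Binf-1": ("B. longum infantis ATCC 15697", 1_288_185, 1_330_866, 61.1, "dnaJ2"),
        "Bl30698phi1": ("B. longum longum CCUG 30698", 1_375_860, 1_336_483, 61.1, "dnaJ2"),
        "Bl157phi1": ("B. longum longum 157F", 1_246_936, 1_207_777, 60.9, "dnaJ2"),
        "Bb447phi1": ("B. breve 215W4-47a", 1_694_074, 1_735_438, 58.6, "tmRNA"),
        "Bb1192phi1": ("B. breve JCM 1192", 1_468_985, 1_509_872, 59.4, "tmRNA"),
        "Bb423phi2": ("B. breve 139W4-23", 420_545, 438_765, 61.4, "tRNA-Met"),
        "689b-1": ("B. breve 689b", 372_287, 390_546, 61.4, "tRNA-Met"),
    }.items()
}

#: Published genome sizes (nt) for the same prophages, for cross-checks.
PUBLISHED_SIZES: dict[str, int] = {
    "Bb48phi1": 39_402,
    "Bb83phi1": 40_255,
    "Bb423phi1": 40_077,
    "Bb439phi1": 40_255,
    "Binf-1": 42_682,
    "Bl30698phi1": 39_378,
    "Bl157phi1": 39_160,
    "Bb447phi1": 41_365,
    "Bb1192phi1": 40_888,
    "Bb423phi2": 18_221,
    "689b-1": 18_260,
}

#: The 11 bp asymmetric crossover motif of the Rin shufflon.
RIX_MOTIF = "TTCCCTAACCC"

#: The 8 bp junction motif of the tRNA-Met-prophage simple inversion locus.
SIMPLE_INVERSION_MOTIF = "CAGGGTTA"


def dnaj2_sites() -> list[str]:
    """All attL/attR core sequences of the dnaJ2-integrated prophages."""
    out = []
    for sites in ATT_SITES["dnaJ2"].values():
        out.extend([sites["attL"], sites["attR"]])
    return out
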