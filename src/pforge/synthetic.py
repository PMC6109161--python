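"""Seeded generators of synthetic inputs with known ground truth.

Every analysis stage in this package has a paired generator here that
plants a known structure — a lysogen with a duplicated attachment core
splitting a marker gene, a shufflon cassette, a Poisson coverage track
with an enriched prophage and a coverage-step terminus, a three-population
flow-event mixture, shotgun reads — and returns a :class:`TruthRecord`
describing exactly what was planted, so downstream results are checkable
without any external data.

Reproducibility: one top-level seed fans out to per-generator child
streams via ``SeedSequence([seed, crc32(generator_name)])``; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import STOP_CODONS, check_dna, revcomp, translate
from .attsite import integrate
from .errors import InputError
from .induction import CoverageTrack
from .shufflon import MINUS, PLUS, InversionState, ShufflonCassette, invert_between

BASES = np.array(list("ACGT"))

#: All sense codons (bacterial code), used to build stop-free ORF bodies.
_SENSE_CODONS = [
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


@dataclass(frozen=True)
class TruthRecord:
    """What a generator planted, for checking the consuming analysis."""

    generator: str
    seed: int
    params: dict[str, Any]
    expected: dict[str, Any] = field(default_factory=dict)

    def to_json(self, **kwargs) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not serializable: {type(o)}")

        return json.dumps(
            {
                "generator": self.generator,
                "seed": self.seed,
                "params": self.params,
                "expected": self.expected,
            },
            default=default,
            **kwargs,
        )


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Deterministic per-generator stream derived from the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _random_orf(rng: np.random.Generator, n_codons: int, stop: bool = True) -> str:
    """ATG + stop-free sense codons (+ terminal TAA when ``stop``)."""
    body = "".join(
        rng.choice(np.array(_SENSE_CODONS), size=max(0, n_codons - 1))
    )
    return "ATG" + body + ("TAA" if stop else "")


def _mutate_positions(
    rng: np.random.Generator, seq: str, positions: Sequence[int]
) -> str:
    out = list(seq)
    for p in positions:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


# ---------------------------------------------------------------------------
# lysogen with duplicated att core
# ---------------------------------------------------------------------------

def make_lysogen(
    seed: int,
    host_len: int = 4000,
    phage_len: int = 2000,
    core_len: int = 35,
    crossover_len: int = 7,
    flank_mismatches: int = 3,
) -> tuple[str, TruthRecord]:
    """A lysogen whose prophage splits a marker gene at its att core.

    The host carries a marker open reading frame whose 3' end is the attB
    core; the phage circle carries attP, identical to attB inside the
    planted crossover window and differing by ``flank_mismatches``
    substitutions on each side of it.  Integration (performed with
    :func:`pforge.attsite.integrate`) yields attL/attR differing at exactly
    ``2 x flank_mismatches`` positions, all outside the crossover.
    """
    if core_len < crossover_len + 2 * flank_mismatches:
        raise InputError(
            "core_len must be >= crossover_len + 2*flank_mismatches"
        )
    if phage_len < core_len + 100:
        raise InputError("phage_len too small for an att core plus interior")
    marker_codons = 60
    marker_len = 3 * marker_codons + 3
    if host_len < marker_len + 200:
        raise InputError("host_len too small for the marker gene plus flanks")
    rng = child_rng(seed, "lysogen")

    marker = _random_orf(rng, marker_codons)  # ends with TAA
    attB = marker[-core_len:]
    # crossover window inside the core, leaving room for flank mismatches
    offset = int(
        rng.integers(flank_mismatches, core_len - crossover_len - flank_mismatches + 1)
    )
    left_pos = rng.choice(offset, size=flank_mismatches, replace=False)
    right_pos = rng.choice(
        np.arange(offset + crossover_len, core_len), size=flank_mismatches,
        replace=False,
    )
    attP = _mutate_positions(rng, attB, [*left_pos, *right_pos])

    flank1 = _random_dna(rng, (host_len - marker_len) // 2)
    flank2 = _random_dna(rng, host_len - marker_len - len(flank1))
    host = flank1 + marker + flank2
    attB_start = len(flank1) + marker_len - core_len + 1  # 1-based

    interior = _random_dna(rng, phage_len - core_len)
    phage = attP + interior  # circle, attP first

    lysogen = integrate(
        host,
        (attB_start, attB_start + core_len - 1),
        phage,
        (1, core_len),
        (offset, crossover_len),
    )
    end = offset + crossover_len
    attL = attB[:end] + attP[end:]
    attR = attP[:end] + attB[end:]
    attL_start = attB_start
    attR_start = attL_start + core_len + len(interior)

    truth = TruthRecord(
        generator="make_lysogen",
        seed=seed,
        params=dict(
            host_len=host_len, phage_len=phage_len, core_len=core_len,
            crossover_len=crossover_len, flank_mismatches=flank_mismatches,
        ),
        expected=dict(
            host=host,
            phage=phage,
            attB=attB, attP=attP, attL=attL, attR=attR,
            crossover_offset=offset,
            crossover_len=crossover_len,
            crossover_seq=attB[offset:end],
            attB_interval=(attB_start, attB_start + core_len - 1),
            attL_interval=(attL_start, attL_start + core_len - 1),
            attR_interval=(attR_start, attR_start + core_len - 1),
            marker_interval=(len(flank1) + 1, len(flank1) + marker_len),
            marker_protein=translate(marker),
            total_att_mismatches=2 * flank_mismatches,
        ),
    )
    return lysogen, truth


# ---------------------------------------------------------------------------
# integration-dependent immunity locus
# ---------------------------------------------------------------------------

def make_immunity_locus(
    seed: int,
    extension_residues: int = 18,
    host_flank: int = 400,
    interior_len: int = 1200,
    rep_codons: int = 60,
    tagged: bool = True,
    read_through: bool = True,
) -> tuple[str, TruthRecord]:
    """A lysogen with an integration-dependent immunity architecture.

    The repressor gene ends the prophage interior and reads through attR:
    in the integrated frame the host side of attR supplies an immediate
    stop codon, while in the excised circular frame the gene reads through
    attP and gains ``extension_residues`` C-terminal residues (ending in
    an ssrA-like ...LAA when ``tagged``) before its stop.  attL/attR have
    phage and host flanks of different lengths, so the crossover offsets
    differ between the sites.
    """
    if extension_residues < 3:
        raise InputError("extension_residues must be >= 3 (room for the tag)")
    rng = child_rng(seed, "immunity")

    # PL + O as five sense codons: crossover ends on a codon boundary
    pl_o = "".join(rng.choice(np.array(_SENSE_CODONS), size=5))
    pl, core = pl_o[:8], pl_o[8:]  # |PL| = 8, |O| = 7
    bl = _random_dna(rng, 10)
    br = "TAA" + _random_dna(rng, 7)  # host side: immediate in-frame stop
    tag = "CTGGCAGCA" if tagged else "AAAAAGAGA"  # ...LAA vs ...KKR
    pr_codons = "".join(
        rng.choice(np.array(_SENSE_CODONS), size=extension_residues - 3)
    )
    pr = pr_codons + tag + "TAA"

    att_b = bl + core + br
    att_p = pl + core + pr
    att_l = bl + core + pr
    att_r = pl + core + br

    gene5 = _random_orf(rng, rep_codons, stop=not read_through)
    if not read_through:
        # control architecture: the gene terminates inside the prophage,
        # so the virion and prophage forms are identical
        gene5 += _random_dna(rng, 9)
    interior_head = _random_dna(rng, interior_len - len(gene5))
    interior = interior_head + gene5

    h1 = _random_dna(rng, host_flank)
    h2 = _random_dna(rng, host_flank)
    lysogen = h1 + att_l + interior + att_r + h2

    attL_iv = (len(h1) + 1, len(h1) + len(att_l))
    attR_start = len(h1) + len(att_l) + len(interior) + 1
    attR_iv = (attR_start, attR_start + len(att_r) - 1)
    rep_start = len(h1) + len(att_l) + len(interior_head) + 1

    prophage_protein = translate(gene5 + pl + core)
    virion_protein = translate(gene5 + pl + core + pr)
    truth = TruthRecord(
        generator="make_immunity_locus",
        seed=seed,
        params=dict(extension_residues=extension_residues, tagged=tagged,
                    rep_codons=rep_codons, interior_len=interior_len),
        expected=dict(
            attB=att_b, attP=att_p, attL=att_l, attR=att_r,
            attL_interval=attL_iv, attR_interval=attR_iv,
            crossover=(len(bl), len(pl), len(core)),  # offsets in attL/attR
            repressor_start=rep_start,
            prophage_protein=prophage_protein,
            virion_protein=virion_protein,
            extension=virion_protein[len(prophage_protein):],
            extension_len=extension_residues if read_through else 0,
            read_through=read_through,
        ),
    )
    return lysogen, truth


# ---------------------------------------------------------------------------
# shufflon cassette
# ---------------------------------------------------------------------------

def make_shufflon(
    seed: int,
    n_rv: int = 5,
    motif: str = "TTCCCTAACCC",
    layout: Sequence[tuple] | None = None,
    n_random_flips: int = 0,
    rc_codons: int = 168,
    rv_codon_range: tuple[int, int] = (95, 100),
) -> tuple[str, ShufflonCassette, TruthRecord]:
    """A shufflon locus with one active Rv and ``n_rv - 1`` stored variants.

    Default layout mirrors a full-length-RBP architecture: the in-gene rix
    and the gene-3' rix are direct (plus); every further Rv is stored
    reverse-complemented behind an inverted (minus) rix, so inversion
    against the in-gene rix swaps it intact onto the Rc head.  Segment
    reading frames are arranged so a correctly oriented Rv terminates the
    fused open reading frame exactly at its 3' boundary.

    ``n_random_flips`` applies that many random legal inversions so the
    returned locus need not be in the canonical arrangement.  A custom
    ``layout`` (items in cassette form) overrides the default.
    """
    if n_rv < 1:
        raise InputError("n_rv must be >= 1")
    motif = check_dna(motif, name="motif")
    if motif == revcomp(motif):
        raise InputError("rix motif must be asymmetric (non-palindromic)")
    rng = child_rng(seed, "shufflon")

    # Rc head: whole codons, stop-free, and stop-free through the rix
    while True:
        rc_head = _random_orf(rng, rc_codons, stop=False)
        if not _has_inframe_stop(rc_head + motif):
            break
    pad = (3 - (len(rc_head) + len(motif)) % 3) % 3

    segments: dict[str, str] = {}
    for i in range(1, n_rv + 1):
        n_codons = int(rng.integers(rv_codon_range[0], rv_codon_range[1] + 1))
        while True:
            pad_nt = _random_dna(rng, pad)
            body = "".join(rng.choice(np.array(_SENSE_CODONS), size=n_codons))
            seg = pad_nt + body + "TAA"
            # the reverse complement must not mimic a valid allele ending
            if seg[:3] in ("TTA", "CTA", "TCA"):
                continue
            if pad and _has_inframe_stop((rc_head + motif + seg)[: len(rc_head) + len(motif) + 3]):
                continue
            break
        segments[f"Rv{i}"] = seg

    if layout is None:
        items: list[tuple] = [("rix", PLUS), ("seg", "Rv1", PLUS), ("rix", PLUS)]
        for i in range(2, n_rv + 1):
            items.append(("seg", f"Rv{i}", MINUS))
            items.append(("rix", MINUS))
        items = tuple(items)
    else:
        items = tuple(layout)

    tail = _random_dna(rng, 30) + _random_orf(rng, 100) + _random_dna(rng, 30)
    cassette = ShufflonCassette(
        rc_head=rc_head,
        motif=min(motif, revcomp(motif)),
        items=items,
        segments=segments,
        roles={sid: "Rv" for sid in segments},
        tail=tail,
    )
    # the canonical motif may be the reverse complement of the requested
    # strand; re-orient items so the realized locus shows `motif` at plus
    # sites
    if cassette.motif != motif:
        flip = {PLUS: MINUS, MINUS: PLUS}
        items = tuple(
            ("rix", flip[it[1]]) if it[0] == "rix" else it for it in items
        )
        cassette = ShufflonCassette(
            rc_head=rc_head, motif=cassette.motif, items=items,
            segments=segments, roles=cassette.roles, tail=tail,
        )

    state = cassette.reference_state()
    applied = []
    for _ in range(n_random_flips):
        orients = state.rix_orientations()
        pairs = [
            (a, b)
            for a in range(len(orients))
            for b in range(a + 1, len(orients))
            if orients[a] != orients[b]
        ]
        if not pairs:
            break
        a, b = pairs[int(rng.integers(len(pairs)))]
        state = invert_between(state, a, b)
        applied.append((a, b))

    locus = state.sequence
    returned = ShufflonCassette(
        rc_head=rc_head, motif=cassette.motif, items=state.items,
        segments=segments, roles=cassette.roles, tail=tail,
    )

    rix_truth = _locate_rix(locus, cassette.motif)
    active = f"Rv1" if n_random_flips == 0 and layout is None else None
    expected: dict[str, Any] = dict(
        n_rv=n_rv,
        rix_sites=rix_truth,
        reference_items=cassette.items,
        applied_flips=applied,
    )
    if layout is None:
        expected["n_distinct_alleles"] = n_rv
        expected["allele_proteins"] = {
            sid: translate(rc_head + _plus_motif(cassette, state) + seg)
            for sid, seg in segments.items()
        }
    if active:
        expected["active_segment"] = active
    truth = TruthRecord(
        generator="make_shufflon",
        seed=seed,
        params=dict(n_rv=n_rv, motif=motif, n_random_flips=n_random_flips,
                    rc_codons=rc_codons, rv_codon_range=rv_codon_range),
        expected=expected,
    )
    return locus, returned, truth


def _plus_motif(cassette: ShufflonCassette, state: InversionState) -> str:
    in_gene = state.items[0]
    return cassette.motif if in_gene[1] == PLUS else revcomp(cassette.motif)


def _has_inframe_stop(seq: str) -> bool:
    return any(
        seq[p : p + 3] in STOP_CODONS for p in range(0, len(seq) - 2, 3)
    )


def _locate_rix(locus: str, motif: str) -> list[tuple[int, str]]:
    """All (position, orientation) occurrences of the motif in the locus."""
    out = []
    rc = revcomp(motif)
    for needle, orient in ((motif, PLUS), (rc, MINUS)):
        start = 0
        while (i := locus.find(needle, start)) != -1:
            out.append((i, orient))
            start = i + 1
    out.sort()
    return out


# ---------------------------------------------------------------------------
# coverage tracks
# ---------------------------------------------------------------------------

def make_coverage(
    seed: int,
    replicon_len: int = 20_000,
    prophage_interval: tuple[int, int] = (8_001, 12_000),
    lambda_host: float = 30.0,
    fold: float = 1.0,
    terminus_pos: int | None = None,
) -> tuple[CoverageTrack, TruthRecord]:
    """Poisson depth track with a fold-enriched prophage interval.

    Inside ``prophage_interval`` (1-based inclusive) the Poisson rate is
    ``lambda_host * fold``.  When ``terminus_pos`` is given, the rate is
    halved upstream of it, planting a coverage-step genome terminus with a
    true step ratio of 2.
    """
    if lambda_host <= 0:
        raise InputError("lambda_host must be positive")
    if fold < 1:
        raise InputError("fold must be >= 1")
    lo, hi = prophage_interval
    if not (1 <= lo <= hi <= replicon_len):
        raise InputError("prophage interval outside replicon")
    if terminus_pos is not None and not (1 <= terminus_pos <= replicon_len):
        raise InputError("terminus_pos outside replicon")
    rng = child_rng(seed, "coverage")
    lam = np.full(replicon_len, float(lambda_host))
    lam[lo - 1 : hi] *= fold
    if terminus_pos is not None:
        lam[: terminus_pos - 1] *= 0.5
    depth = rng.poisson(lam).astype(float)
    track = CoverageTrack(replicon_id=f"synthetic_seed{seed}", depth=depth)
    truth = TruthRecord(
        generator="make_coverage",
        seed=seed,
        params=dict(replicon_len=replicon_len,
                    prophage_interval=list(prophage_interval),
                    lambda_host=lambda_host, fold=fold,
                    terminus_pos=terminus_pos),
        expected=dict(fold=fold, terminus_pos=terminus_pos,
                      terminus_step_ratio=2.0 if terminus_pos else None),
    )
    return track, truth


# ---------------------------------------------------------------------------
# flow-cytometry event mixtures
# ---------------------------------------------------------------------------

#: Log-normal population parameters (log-median, log-sd) per channel,
#: positioned relative to the fixed debris/bead gate boxes.
_FLOW_POPS = {
    "debris": {"FSC-H": (20.0, 0.25), "SSC-H": (40.0, 0.25), "FL1-H": (5.0, 0.25)},
    "beads": {"FSC-H": (400.0, 0.15), "SSC-H": (1500.0, 0.12), "FL1-H": (40.0, 0.15)},
    "particles": {"FSC-H": (100.0, 0.5), "SSC-H": (300.0, 0.5), "FL1-H": (200.0, 0.4)},
}


def _sample_population(
    rng: np.random.Generator, name: str, n: int
) -> pd.DataFrame:
    cols = {}
    for ch, (median, sigma) in _FLOW_POPS[name].items():
        cols[ch] = np.exp(rng.normal(np.log(median), sigma, size=n))
    df = pd.DataFrame(cols)
    df["population"] = name
    return df


def make_flow_pair(
    seed: int,
    n_events: int = 100_000,
    fractions: tuple[float, float, float] = (0.75, 0.20, 0.05),
    effect: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthRecord]:
    """Treated/untreated flow event tables with a planted induction effect.

    ``fractions`` are the untreated (debris, beads, particles) mixture
    weights; the treated sample multiplies the particle weight by
    ``effect`` and renormalizes, modeling phage release against a fixed
    debris/bead background.  The expected gated-abundance fold is
    ``effect / (1 - p + p*effect)`` for particle fraction ``p``; the
    expected fluorescence fold is 1 (particle brightness is unchanged).
    """
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise InputError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise InputError("fractions must sum to 1")
    if effect <= 0:
        raise InputError("effect must be positive")
    rng = child_rng(seed, "flow")
    d, b, p = fractions
    norm = d + b + p * effect
    treated_fracs = (d / norm, b / norm, p * effect / norm)

    tables = []
    for fracs in (fractions, treated_fracs):
        counts = rng.multinomial(n_events, fracs)
        parts = [
            _sample_population(rng, name, n)
            for name, n in zip(("debris", "beads", "particles"), counts)
        ]
        df = pd.concat(parts, ignore_index=True)
        df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
        tables.append(df)
    untreated, treated = tables

    truth = TruthRecord(
        generator="make_flow_pair",
        seed=seed,
        params=dict(n_events=n_events, fractions=list(fractions), effect=effect),
        expected=dict(
            abundance_fold=effect / (1 - p + p * effect) if p > 0 else None,
            fluorescence_fold=1.0 if p > 0 else None,
        ),
    )
    return treated, untreated, truth


# ---------------------------------------------------------------------------
# shotgun reads
# ---------------------------------------------------------------------------

def make_reads(
    seed: int,
    templates: str | Mapping[str, str],
    depth: float = 50.0,
    read_len: int = 100,
    error_rate: float = 0.0,
    weights: Mapping[str, float] | None = None,
    n_reads: int | None = None,
) -> tuple[list[str], TruthRecord]:
    """Uniform shotgun reads from one or more circular templates.

    Start positions are uniform over each circular template; substitution
    errors occur independently at ``error_rate`` per base.  With multiple
    templates, reads are allotted by ``weights`` (default: proportional to
    template length).  ``n_reads`` overrides the depth-derived total.
    """
    if isinstance(templates, str):
        templates = {"template": templates}
    templates = {k: check_dna(v, name=k) for k, v in templates.items()}
    if not templates:
        raise InputError("no templates given")
    if depth <= 0:
        raise InputError("depth must be positive")
    if not 0 <= error_rate < 1:
        raise InputError("error_rate must be in [0, 1)")
    min_len = min(len(t) for t in templates.values())
    if read_len > min_len:
        raise InputError("read_len exceeds the shortest template")
    rng = child_rng(seed, "reads")

    names = sorted(templates)
    if weights is None:
        w = np.array([len(templates[n]) for n in names], dtype=float)
    else:
        w = np.array([weights[n] for n in names], dtype=float)
    w = w / w.sum()
    if n_reads is None:
        mean_len = np.mean([len(t) for t in templates.values()])
        n_reads = int(round(depth * mean_len / read_len))
    counts = rng.multinomial(n_reads, w)

    reads: list[str] = []
    per_template: dict[str, int] = {}
    for name, n in zip(names, counts):
        per_template[name] = int(n)
        tpl = templates[name]
        doubled = tpl + tpl
        starts = rng.integers(0, len(tpl), size=n)
        for s in starts:
            read = doubled[s : s + read_len]
            if error_rate > 0:
                errs = np.flatnonzero(rng.random(read_len) < error_rate)
                if errs.size:
                    read = _mutate_positions(rng, read, errs)
            reads.append(read)
    truth = TruthRecord(
        generator="make_reads",
        seed=seed,
        params=dict(depth=depth, read_len=read_len, error_rate=error_rate,
                    n_reads=n_reads),
        expected=dict(per_template_reads=per_template),
    )
    return reads, truth
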