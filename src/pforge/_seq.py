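"""Small DNA-string utilities shared across modules."""

from __future__ import annotations

from Bio.Seq import Seq

from .errors import InputError

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

STOP_CODONS = {"TAA", "TAG", "TGA"}


def check_dna(seq: str, *, name: str = "sequence", allow_empty: bool = False) -> str:
    """Uppercase ``seq`` and verify it only contains A/C/G/T/N."""
    if not isinstance(seq, str):
        raise InputError(f"{name} must be a string, got {type(seq).__name__}")
    seq = seq.upper()
    if not seq and not allow_empty:
        raise InputError(f"{name} is empty")
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise InputError(f"{name} contains non-DNA characters: {sorted(bad)}")
    return seq


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_strand(motif: str) -> str:
    """Lexicographically smaller of a motif and its reverse complement."""
    rc = revcomp(motif)
    return motif if motif <= rc else rc


def translate(seq: str, *, table: int = 11, to_stop: bool = True) -> str:
    """Translate a DNA string in frame 0 with the bacterial code.

    Trailing bases that do not fill a codon are ignored.
    """
    trimmed = seq[: len(seq) - len(seq) % 3]
    return str(Seq(trimmed).translate(table=table, to_stop=to_stop))


def gc_percent(seq: str) -> float:
    """GC% over unambiguous bases; N excluded from the denominator."""
    seq = check_dna(seq, name="seq")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise InputError("sequence has no unambiguous bases")
    return 100.0 * (seq.count("G") + seq.count("C")) / denom
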