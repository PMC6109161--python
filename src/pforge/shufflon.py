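"""The Rin shufflon: inversion-state enumeration and RBP allele calling.

Some prophages vary their tail receptor-binding protein (RBP) with a
shufflon: a constant 5' gene portion (*Rc*) is followed by a cassette of
variable 3'-end segments (*Rv*) delimited by short asymmetric crossover
sites (*rix*, canonically the 11 bp motif TTCCCTAACCC), next to a
tyrosine-family DNA invertase gene (*rin*).  Recombination between two
oppositely oriented rix sites reverse-complements the intervening block::

    ... R  >x>  R'  ...   ->   ... R  <x<  R'  ...     (R' = revcomp R)

which swaps a different Rv downstream of the in-gene rix and thereby fuses
a new C-terminus onto Rc.  This module discovers rix repeats, applies and
enumerates inversions, reconstructs the full-length Rc-Rv alleles, and
quantifies read support for alternative cassette orientations.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import STOP_CODONS, canonical_strand, check_dna, revcomp, translate
from .compare import Block, anchor_blocks
from .errors import (
    ConfigError,
    InputError,
    RecombinationError,
    StateSpaceOverflow,
)

PLUS = "+"
MINUS = "-"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RixSite:
    """One occurrence of the asymmetric rix crossover motif.

    ``motif`` is stored on its canonical strand (the lexicographically
    smaller of motif / reverse complement); ``orientation`` says which
    strand the occurrence lies on relative to that canonical form.
    """

    position: int  # 0-based offset in the locus
    orientation: str  # "+" or "-"
    motif: str

    def __post_init__(self) -> None:
        if len(self.motif) < 8:
            raise InputError("rix motif must be at least 8 bp")
        if self.motif == revcomp(self.motif):
            raise InputError("rix motif must be asymmetric (non-palindromic)")
        if self.orientation not in (PLUS, MINUS):
            raise InputError("orientation must be '+' or '-'")

    @property
    def occurrence(self) -> str:
        """The motif as it appears on the forward strand of the locus."""
        return self.motif if self.orientation == PLUS else revcomp(self.motif)


# state items: ("rix", orientation) | ("seg", segment_id, strand)
Item = tuple


@dataclass(frozen=True)
class ShufflonCassette:
    """Reference layout of a shufflon locus.

    ``rc_head`` is the constant 5' portion of the RBP gene up to (and
    excluding) the in-gene rix; ``items`` alternate rix sites and segments
    starting with the in-gene rix; ``tail`` is the downstream flank
    (typically holding the *rin* invertase gene).  Segment sequences are
    stored in reference orientation in ``segments``.
    """

    rc_head: str
    motif: str  # canonical strand
    items: tuple[Item, ...]
    segments: Mapping[str, str]
    roles: Mapping[str, str] = field(default_factory=dict)
    tail: str = ""

    def __post_init__(self) -> None:
        if self.motif == revcomp(self.motif):
            raise InputError("rix motif must be asymmetric")
        for it in self.items:
            if it[0] not in ("rix", "seg"):
                raise InputError(f"unknown cassette item {it!r}")
        segs = [it[1] for it in self.items if it[0] == "seg"]
        if len(segs) != len(set(segs)):
            raise InputError("segment ids must be unique")

    def reference_state(self) -> "InversionState":
        return InversionState(cassette=self, items=self.items)

    @property
    def n_rix(self) -> int:
        return sum(1 for it in self.items if it[0] == "rix")


@dataclass(frozen=True)
class InversionState:
    """One arrangement of a shufflon cassette."""

    cassette: ShufflonCassette
    items: tuple[Item, ...]

    @property
    def arrangement(self) -> tuple[str, ...]:
        """Signed segment order, e.g. ``('Rv1', '-Rv2', ...)``."""
        return tuple(
            (it[1] if it[2] == PLUS else "-" + it[1])
            for it in self.items
            if it[0] == "seg"
        )

    def rix_orientations(self) -> tuple[str, ...]:
        return tuple(it[1] for it in self.items if it[0] == "rix")

    @property
    def sequence(self) -> str:
        cas = self.cassette
        parts = [cas.rc_head]
        for it in self.items:
            if it[0] == "rix":
                parts.append(cas.motif if it[1] == PLUS else revcomp(cas.motif))
            else:
                seq = cas.segments[it[1]]
                parts.append(seq if it[2] == PLUS else revcomp(seq))
        parts.append(cas.tail)
        return "".join(parts)

    def __hash__(self) -> int:
        return hash(self.items)

    def __eq__(self, other) -> bool:
        return isinstance(other, InversionState) and self.items == other.items


# ---------------------------------------------------------------------------
# rix discovery
# ---------------------------------------------------------------------------

def find_rix_sites(locus: str, min_len: int = 11, min_count: int = 3) -> list[RixSite]:
    """Maximal exact repeats occurring ``min_count``+ times on either strand.

    Every occurrence (both strands counted together) is reported as a
    :class:`RixSite` tagged with its orientation relative to the canonical
    strand of the motif.  Palindromic motifs are excluded: orientation is
    undefined for them, and an invertase cannot use a symmetric crossover
    site directionally.  The empty list is a valid result.
    """
    locus = check_dna(locus, name="locus")
    if len(locus) < 2 * min_len:
        raise InputError("locus shorter than twice the minimum motif length")

    # seed: canonical k-mer occurrence lists at k = min_len
    occs: dict[str, list[tuple[int, int, str]]] = {}
    k = min_len
    for i in range(len(locus) - k + 1):
        km = locus[i : i + k]
        rc = revcomp(km)
        if km == rc:
            continue
        canon = km if km < rc else rc
        strand = PLUS if km == canon else MINUS
        occs.setdefault(canon, []).append((i, i + k, strand))

    families: dict[tuple, tuple[str, tuple[tuple[int, int, str], ...]]] = {}
    for canon, occ in occs.items():
        if len(occ) < min_count:
            continue
        occ = list(occ)
        motif = canon

        def step(side: str) -> bool:
            # extend all occurrences by one base on the canonical `side`
            chars = set()
            moved = []
            for s, e, strand in occ:
                grow_right = (side == "right") == (strand == PLUS)
                if grow_right:
                    if e >= len(locus):
                        return False
                    ch = locus[e]
                    if strand == MINUS:
                        ch = revcomp(ch)
                    moved.append((s, e + 1, strand))
                else:
                    if s <= 0:
                        return False
                    ch = locus[s - 1]
                    if strand == MINUS:
                        ch = revcomp(ch)
                    moved.append((s - 1, e, strand))
                chars.add(ch)
            if len(chars) != 1:
                return False
            occ[:] = moved
            nonlocal motif
            ch = chars.pop()
            motif = motif + ch if side == "right" else ch + motif
            return True

        while step("right"):
            pass
        while step("left"):
            pass
        if motif == revcomp(motif):
            continue
        key = (motif, tuple(sorted(occ)))
        families[key] = (motif, tuple(sorted(occ)))

    sites: list[RixSite] = []
    seen: set[tuple[int, str]] = set()
    for motif, occ in families.values():
        canon = canonical_strand(motif)
        for s, e, strand in occ:
            # re-derive orientation against the canonical strand of the
            # (possibly extended) motif
            found = locus[s:e]
            orient = PLUS if found == canon else MINUS
            if (s, canon) in seen:
                continue
            seen.add((s, canon))
            sites.append(RixSite(position=s, orientation=orient, motif=canon))
    sites.sort(key=lambda r: (r.position, r.motif))
    return sites


# ---------------------------------------------------------------------------
# inversion moves
# ---------------------------------------------------------------------------

def _rix_indices(items: Sequence[Item]) -> list[int]:
    return [i for i, it in enumerate(items) if it[0] == "rix"]


def invert_between(
    state: InversionState, rix_a: int, rix_b: int, allow_deletion: bool = False
) -> InversionState:
    """Recombine between the ``rix_a``-th and ``rix_b``-th rix sites.

    Indices count rix sites (0-based) left to right in the current state.
    The two sites must be oppositely oriented; the block between them is
    reverse-complemented in place (the bounding sites keep their
    orientations, contained sites flip).  Applying the same move twice is
    the identity.

    Recombination between two same-orientation sites would delete the
    intervening block; this is disallowed by default, modeling flip-only
    directionality, and performed only when ``allow_deletion`` is set.
    """
    idx = _rix_indices(state.items)
    try:
        ia, ib = idx[rix_a], idx[rix_b]
    except IndexError:
        raise InputError(
            f"rix index out of range (state has {len(idx)} rix sites)"
        ) from None
    if ia == ib:
        raise InputError("rix_a and rix_b must differ")
    if ia > ib:
        ia, ib = ib, ia
    oa, ob = state.items[ia][1], state.items[ib][1]
    if oa == ob:
        if not allow_deletion:
            raise RecombinationError(
                "recombination between direct (same-orientation) rix sites "
                "would delete the intervening block; only inversion between "
                "inverted sites is modeled"
            )
        new = state.items[: ia + 1] + state.items[ib + 1 :]
        return InversionState(cassette=state.cassette, items=new)

    flipped = []
    for it in reversed(state.items[ia + 1 : ib]):
        if it[0] == "rix":
            flipped.append(("rix", MINUS if it[1] == PLUS else PLUS))
        else:
            flipped.append(("seg", it[1], MINUS if it[2] == PLUS else PLUS))
    new = state.items[: ia + 1] + tuple(flipped) + state.items[ib:]
    return InversionState(cassette=state.cassette, items=new)


def enumerate_states(
    cassette: ShufflonCassette, max_states: int = 10_000
) -> list[InversionState]:
    """Breadth-first closure of all inversion moves from the reference state.

    States are deduplicated on their realized DNA sequence (tolerating
    duplicate segments) and returned in deterministic BFS discovery order,
    reference state first.  Exceeding ``max_states`` distinct states raises
    :class:`StateSpaceOverflow` rather than silently truncating.
    """
    if max_states < 1:
        raise InputError("max_states must be >= 1")
    ref = cassette.reference_state()
    seen: dict[str, InversionState] = {ref.sequence: ref}
    queue: deque[InversionState] = deque([ref])
    while queue:
        st = queue.popleft()
        orients = st.rix_orientations()
        for a in range(len(orients)):
            for b in range(a + 1, len(orients)):
                if orients[a] == orients[b]:
                    continue
                nxt = invert_between(st, a, b)
                key = nxt.sequence
                if key not in seen:
                    if len(seen) >= max_states:
                        raise StateSpaceOverflow(
                            f"inversion closure exceeds max_states={max_states}"
                        )
                    seen[key] = nxt
                    queue.append(nxt)
    return list(seen.values())


# ---------------------------------------------------------------------------
# allele reconstruction
# ---------------------------------------------------------------------------

def active_allele(state: InversionState) -> str | None:
    """Translate the currently fused full-length Rc-Rv allele, if valid.

    The RBP coding sequence is ``rc_head`` + the in-gene rix (retained
    once, it contributes junction codons) + whatever segment currently
    lies downstream.  The fusion is a *full-length* allele when its first
    in-frame stop codon terminates exactly at the 3' boundary of that
    segment (at the next rix site); a premature stop, a missing stop, or a
    stop read through into the next segment all return ``None``.  When no
    further rix follows, any in-frame stop is accepted (degenerate,
    Rc-only cassette).
    """
    items = state.items
    if not items or items[0][0] != "rix":
        raise InputError("state has no in-gene rix at the cassette start")
    cas = state.cassette
    rix0 = cas.motif if items[0][1] == PLUS else revcomp(cas.motif)

    downstream_parts = []
    seg_end_offset = None  # offset of the next rix, relative to fusion start
    offset = len(cas.rc_head) + len(rix0)
    for it in items[1:]:
        if it[0] == "rix":
            seg_end_offset = offset
            break
        seq = cas.segments[it[1]]
        part = seq if it[2] == PLUS else revcomp(seq)
        downstream_parts.append(part)
        offset += len(part)
    else:
        downstream_parts.append(cas.tail)
        offset += len(cas.tail)

    fused = cas.rc_head + rix0 + "".join(downstream_parts)
    # first in-frame stop
    stop_end = None
    for p in range(0, len(fused) - 2, 3):
        if fused[p : p + 3] in STOP_CODONS:
            stop_end = p + 3
            break
    if stop_end is None:
        return None
    if seg_end_offset is not None and stop_end != seg_end_offset:
        return None
    return translate(fused[: stop_end - 3], to_stop=False)


def count_distinct_alleles(
    cassette: ShufflonCassette, max_states: int = 10_000
) -> int:
    """Number of distinct full-length Rc-Rv proteins over all reachable states."""
    alleles = {
        prot
        for st in enumerate_states(cassette, max_states=max_states)
        if (prot := active_allele(st)) is not None
    }
    return len(alleles)


# ---------------------------------------------------------------------------
# locus comparison
# ---------------------------------------------------------------------------

def detect_inversions(
    seqA: str, seqB: str, anchor_k: int = 15
) -> list[tuple[tuple[int, int], tuple[int, int], str]]:
    """Collinear-block decomposition of two shufflon loci.

    Returns ``((a_start, a_end), (b_start, b_end), strand)`` per maximal
    block (0-based half-open), strand ``"-"`` marking inverted blocks whose
    junctions in an active shufflon coincide with rix positions.  An empty
    list means the sequences share no unique anchor k-mer.
    """
    blocks: list[Block] = anchor_blocks(seqA, seqB, k=anchor_k)
    return [
        ((b.a_start, b.a_end), (b.b_start, b.b_end), b.strand) for b in blocks
    ]


_PROT_ALIGNER: Align.PairwiseAligner | None = None


def _protein_aligner() -> Align.PairwiseAligner:
    # EMBOSS Needle-like defaults: BLOSUM62, gap open 10, extend 0.5
    global _PROT_ALIGNER
    if _PROT_ALIGNER is None:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -10.0
        aligner.extend_gap_score = -0.5
        _PROT_ALIGNER = aligner
    return _PROT_ALIGNER


def rv_identity_matrix(proteins: Sequence[str]) -> np.ndarray:
    """Pairwise global percent identity of Rv (or any) protein sequences.

    Needle convention: identical positions / alignment length (gaps
    included) x 100, computed from a BLOSUM62 global alignment with gap
    open 10 and extension 0.5.  The matrix is symmetric with a diagonal
    of 100.
    """
    if len(proteins) < 2:
        raise InputError("need at least two proteins")
    aligner = _protein_aligner()
    alphabet = set("ACDEFGHIKLMNPQRSTVWYBZX*")
    for i, p in enumerate(proteins):
        if not p:
            raise InputError(f"protein {i} is empty")
        if set(p) - alphabet:
            raise InputError(f"protein {i} has non-amino-acid characters")
    n = len(proteins)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            aln = aligner.align(proteins[i], proteins[j])[0]
            a, b = aln[0], aln[1]
            ident = sum(1 for x, y in zip(a, b) if x == y and x != "-")
            mat[i, j] = mat[j, i] = 100.0 * ident / len(a)
    return mat


# ---------------------------------------------------------------------------
# read support for cassette variants
# ---------------------------------------------------------------------------

def _diff_interval(a: str, b: str) -> tuple[int, int] | None:
    """(start, end) of the region where a and b differ, in a's coordinates."""
    if a == b:
        return None
    cp = 0
    while cp < min(len(a), len(b)) and a[cp] == b[cp]:
        cp += 1
    cs = 0
    while (
        cs < min(len(a), len(b)) - cp
        and a[len(a) - 1 - cs] == b[len(b) - 1 - cs]
    ):
        cs += 1
    return cp, len(a) - cs


def variant_read_support(
    reads: Sequence[str],
    variant_refs: Mapping[str, str],
    junction_flank: int = 15,
) -> dict[str, int]:
    """Assign reads to cassette orientation variants at their junctions.

    A read supports a variant iff its best (edit-distance) placement on
    that variant is strictly better than on every other variant *and* the
    placement spans at least one variant-discriminating junction with
    ``junction_flank`` matched bases on each side.  Ambiguous reads and
    reads not spanning any junction are excluded.  Reads are matched on
    both strands.
    """
    names = sorted(variant_refs)
    if len(names) < 2:
        raise InputError("need at least two variant references")
    refs = {n: check_dna(variant_refs[n], name=n) for n in names}
    if reads and junction_flank > min(len(r) for r in reads):
        raise InputError("junction_flank longer than the shortest read")

    junctions: dict[str, set[int]] = {n: set() for n in names}
    for i, n1 in enumerate(names):
        for n2 in names[i + 1 :]:
            iv = _diff_interval(refs[n1], refs[n2])
            if iv is None:
                raise InputError(
                    f"variants {n1!r} and {n2!r} are identical: no "
                    "discriminating junction exists"
                )
            junctions[n1].update(iv)
            iv2 = _diff_interval(refs[n2], refs[n1])
            junctions[n2].update(iv2)

    counts = {n: 0 for n in names}
    for read in reads:
        read = check_dna(read, name="read")
        best: list[tuple[int, str, tuple[int, int]]] = []
        for n in names:
            hits = []
            for q in (read, revcomp(read)):
                res = edlib.align(q, refs[n], mode="HW", task="locations")
                hits.append((res["editDistance"], res["locations"][0]))
            dist, loc = min(hits, key=lambda t: t[0])
            best.append((dist, n, (loc[0], loc[1] + 1)))  # half-open end
        best.sort(key=lambda t: t[0])
        if best[0][0] == best[1][0]:
            continue  # ambiguous
        dist, name, (s, e) = best[0]
        spans = any(
            s + junction_flank <= j <= e - junction_flank
            for j in junctions[name]
        )
        if spans:
            counts[name] += 1
    return counts
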