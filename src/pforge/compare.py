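"""Pairwise comparison of related prophage sequences.

Decomposes two sequences into collinear same-strand / inverted blocks by
chaining k-mers that are unique in both sequences, then reads off
structural differences: insertions (e.g. IS-element hops) and simple
inversions.  Insertion sequences can be further scanned for the hallmark
IS-element signature — terminal inverted repeats (TIRs) flanked by short
target-site duplications (TSDs).

Block coordinates are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import check_dna, revcomp
from .errors import InputError


@dataclass(frozen=True)
class Block:
    """A maximal collinear anchor chain shared by two sequences.

    ``strand`` is ``"+"`` (same strand) or ``"-"`` (inverted).  For an
    inverted block ``(b_start, b_end)`` still refers to forward-strand
    coordinates of sequence B.
    """

    a_start: int
    a_end: int
    b_start: int
    b_end: int
    strand: str
    n_anchors: int

    @property
    def a_len(self) -> int:
        return self.a_end - self.a_start


@dataclass(frozen=True)
class InsertionRecord:
    """A sequence present in A but absent from B between collinear blocks."""

    position_in_a: int  # 0-based start of the inserted sequence in A
    length: int
    sequence: str
    tir_length: int = 0
    tsd_length: int = 0


@dataclass(frozen=True)
class InvertedBlock:
    """An inverted block annotated with its junction sequences."""

    block: Block
    left_junction: str
    right_junction: str
    motif_matched: bool


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] = counts.get(seq[i : i + k], 0) + 1
    first: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if counts[km] == 1 and km not in first:
            first[km] = i
    return first


def anchor_blocks(seqA: str, seqB: str, k: int = 15) -> list[Block]:
    """Chain unique shared k-mers into maximal collinear blocks.

    A k-mer anchors if it occurs exactly once in A and exactly once in B
    counting both strands of B.  Anchors on one diagonal (same strand) or
    one anti-diagonal (inverted) chain into a block.  Blocks are returned
    ordered by their start in A; an empty list means no unique shared
    k-mer exists.
    """
    if k < 11:
        raise InputError("anchor k must be >= 11 to keep anchors specific")
    seqA = check_dna(seqA, name="seqA")
    seqB = check_dna(seqB, name="seqB")
    ua = _unique_kmers(seqA, k)
    # B uniqueness counts both strands together
    countsB: dict[str, int] = {}
    posB_fwd: dict[str, int] = {}
    for i in range(len(seqB) - k + 1):
        km = seqB[i : i + k]
        countsB[km] = countsB.get(km, 0) + 1
        posB_fwd.setdefault(km, i)

    anchors: list[tuple[int, int, str]] = []  # (posA, posB, strand)
    for km, ia in ua.items():
        rc = revcomp(km)
        n = countsB.get(km, 0) + (0 if rc == km else countsB.get(rc, 0))
        if n != 1:
            continue
        if km in countsB:
            anchors.append((ia, posB_fwd[km], "+"))
        else:
            anchors.append((ia, posB_fwd[rc], "-"))
    anchors.sort()
    if not anchors:
        return []

    blocks: list[Block] = []
    run: list[tuple[int, int, str]] = [anchors[0]]

    def flush(run: list[tuple[int, int, str]]) -> None:
        strand = run[0][2]
        a0, a1 = run[0][0], run[-1][0] + k
        if strand == "+":
            b0, b1 = run[0][1], run[-1][1] + k
        else:
            b0, b1 = run[-1][1], run[0][1] + k
        blocks.append(Block(a0, a1, b0, b1, strand, len(run)))

    for anc in anchors[1:]:
        prev = run[-1]
        da = anc[0] - prev[0]
        same_chain = (
            anc[2] == prev[2]
            and da > 0
            and ((anc[2] == "+" and anc[1] - prev[1] == da)
                 or (anc[2] == "-" and prev[1] - anc[1] == da))
        )
        if same_chain:
            run.append(anc)
        else:
            flush(run)
            run = [anc]
    flush(run)
    return blocks


def find_insertions(
    blocks: list[Block],
    seqA: str,
    seqB: str,
    min_len: int = 100,
    max_b_gap: int = 10,
) -> list[InsertionRecord]:
    """Inter-block gaps present in A but (nearly) absent in B.

    Consecutive same-strand blocks whose B coordinates are contiguous
    (|gap| <= ``max_b_gap``; a small negative gap arises when a target-site
    duplication or a chance match aligns on both sides of the junction)
    but whose A coordinates leave a gap of at least ``min_len`` mark an
    insertion in A.  The reported length is the net extra sequence in A,
    ``gap_a - gap_b``, which is invariant to how far flanking identity
    extends into the junction; a planted element without a target-site
    duplication is therefore recovered at its exact length, while one with
    a TSD is reported together with the duplicated bases.
    """
    seqA = check_dna(seqA, name="seqA")
    out: list[InsertionRecord] = []
    for prev, nxt in zip(blocks, blocks[1:]):
        if prev.strand != "+" or nxt.strand != "+":
            continue
        gap_a = nxt.a_start - prev.a_end
        gap_b = nxt.b_start - prev.b_end
        if gap_a - gap_b >= min_len and abs(gap_b) <= max_b_gap:
            out.append(
                InsertionRecord(
                    position_in_a=prev.a_end,
                    length=gap_a - gap_b,
                    sequence=seqA[prev.a_end : nxt.a_start - gap_b],
                )
            )
    return out


def is_element_signature(
    insertion: str,
    left_flank: str,
    right_flank: str,
    max_mismatch: int = 2,
) -> tuple[int, int]:
    """Terminal-inverted-repeat and target-site-duplication lengths.

    ``tir_length`` is the longest prefix of the insertion matching the
    reverse complement of its suffix with at most ``max_mismatch``
    mismatches, capped at half the insertion length.  ``tsd_length`` is the
    longest exact direct repeat immediately flanking the insertion
    (suffix of ``left_flank`` == prefix of ``right_flank``).
    """
    insertion = check_dna(insertion, name="insertion")
    left_flank = check_dna(left_flank, name="left_flank")
    right_flank = check_dna(right_flank, name="right_flank")
    if len(left_flank) < 10 or len(right_flank) < 10:
        raise InputError("flanks must be at least 10 bp")

    rc_suffix_head = revcomp(insertion)  # rc(insertion)[i] pairs insertion suffix
    tir = 0
    mism = 0
    for t in range(1, len(insertion) // 2 + 1):
        if insertion[t - 1] != rc_suffix_head[t - 1]:
            mism += 1
        if mism > max_mismatch:
            break
        tir = t

    tsd = 0
    for d in range(min(len(left_flank), len(right_flank)), 0, -1):
        if left_flank[-d:] == right_flank[:d]:
            tsd = d
            break
    return tir, tsd


def detect_simple_inversion(
    seqA: str,
    seqB: str,
    junction_motif: str | None = None,
    k: int = 15,
    junction_window: int = 20,
) -> list[InvertedBlock]:
    """Inverted blocks between two sequences, annotated with junctions.

    Each inverted block from :func:`anchor_blocks` is reported with the
    sequence around both of its A-coordinate junctions and, when
    ``junction_motif`` is given, whether the motif (either strand) occurs
    in either junction window.
    """
    seqA = check_dna(seqA, name="seqA")
    blocks = anchor_blocks(seqA, seqB, k=k)
    out: list[InvertedBlock] = []
    for b in blocks:
        if b.strand != "-":
            continue
        w = junction_window
        left = seqA[max(0, b.a_start - w) : b.a_start + w]
        right = seqA[max(0, b.a_end - w) : b.a_end + w]
        matched = False
        if junction_motif:
            motif = check_dna(junction_motif, name="junction_motif")
            for win in (left, right):
                if motif in win or revcomp(motif) in win:
                    matched = True
        out.append(InvertedBlock(block=b, left_junction=left,
                                 right_junction=right, motif_matched=matched))
    return out
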