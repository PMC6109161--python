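"""Attachment-site analysis for temperate-phage integration loci.

A tyrosine integrase recombines a phage attachment site (*attP*) with a
bacterial attachment site (*attB*) across a short common-core overlap *O*,
the strand-exchange (crossover) window.  In a lysogen the prophage is
flanked by the two hybrid sites::

    attB = B_left . O . B_right          attP = P_left . O . P_right
    attL = B_left . O . P_right          attR = P_left . O . B_right

This module aligns attL/attR pairs, infers conserved crossover windows from
a set of aligned sites, derives the theoretical attB/attP, and performs the
reversible in-silico excision/integration string surgery implied by the
algebra above.  Coordinates are 1-based inclusive at the API boundary
(matching how prophage boundaries are reported in genome records) and
0-based half-open internally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio import Align

from ._seq import check_dna, gc_percent
from .errors import AlignmentError, CrossoverError, InputError

GAP = "-"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AttSitePair:
    """A globally aligned attL/attR pair.

    ``alignment`` is the list of aligned column pairs; a gap is ``"-"``.
    ``core_length`` is the number of alignment columns, ``mismatches`` the
    substituted columns and ``indels`` the gapped columns, so that
    ``matches + mismatches + indels == core_length``.
    """

    attL: str
    attR: str
    alignment: tuple[tuple[str, str], ...]
    core_length: int
    mismatches: int
    indels: int
    max_gaps: int = 1
    gaps_exceeded: bool = False

    @property
    def matches(self) -> int:
        return self.core_length - self.mismatches - self.indels

    @property
    def total_differences(self) -> int:
        """Combined edit count (substitutions + indels)."""
        return self.mismatches + self.indels

    def aligned_rows(self) -> tuple[str, str]:
        return (
            "".join(a for a, _ in self.alignment),
            "".join(b for _, b in self.alignment),
        )


@dataclass(frozen=True)
class CrossoverWindow:
    """A maximal run of alignment columns identical across all sites."""

    start: int  # 0-based column index into the alignment
    length: int
    sequence: str

    @property
    def end(self) -> int:  # exclusive
        return self.start + self.length


@dataclass(frozen=True)
class AttSiteSet:
    """The four attachment sequences of one prophage plus its crossover."""

    attL: str
    attR: str
    attB: str
    attP: str
    crossover: CrossoverWindow


@dataclass(frozen=True)
class ProphageRecord:
    """Printed prophage boundaries on a host replicon.

    ``left`` and ``right`` are 1-based inclusive coordinates as published;
    ``left > right`` denotes a reverse-orientation prophage.
    """

    host_id: str
    left: int
    right: int
    locus_name: str = ""
    name: str = ""
    gc: float | None = None

    def __post_init__(self) -> None:
        if self.left <= 0 or self.right <= 0:
            raise InputError("prophage coordinates must be positive")

    @property
    def orientation(self) -> str:
        return "reverse" if self.left > self.right else "forward"

    @property
    def span(self) -> tuple[int, int]:
        """Forward-frame (low, high) 1-based inclusive coordinates."""
        return (min(self.left, self.right), max(self.left, self.right))


@dataclass(frozen=True)
class ExcisionResult:
    """Product of in-silico prophage excision.

    ``attP_interval`` is always ``(1, len(attP))``: the virion circle is
    returned rotated so that attP is its first segment.
    """

    host: str
    virion: str
    attB: str
    attP: str
    attB_interval: tuple[int, int]  # 1-based inclusive in `host`
    attP_interval: tuple[int, int]  # 1-based inclusive in `virion`
    crossover_in_attB: tuple[int, int]  # (0-based offset, length)
    crossover_in_attP: tuple[int, int]

    def __iter__(self):  # allow (host, virion) tuple unpacking
        return iter((self.host, self.virion))


# ---------------------------------------------------------------------------
# pairwise alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    # Unit edit costs with an infinitesimally heavier gap: among all
    # minimum-edit global alignments the one with fewest indels wins,
    # so equal-length homologs align gap-free (Hamming) whenever possible.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 0.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -1.0 - 1e-6
    aligner.extend_gap_score = -1.0 - 1e-6
    return aligner


_ALIGNER = _make_aligner()


def _nw_columns(a: str, b: str) -> tuple[tuple[str, str], ...]:
    """Minimum-edit global alignment of ``a`` and ``b`` as column pairs."""
    aln = _ALIGNER.align(a, b)[0]
    return tuple(zip(aln[0], aln[1]))


def align_att_pair(attL: str, attR: str, max_gaps: int = 1) -> AttSitePair:
    """Globally align an attL/attR pair at minimum edit cost.

    The alignment is reported with separate substitution and indel counts;
    an alignment requiring more than ``max_gaps`` gap columns is flagged via
    ``gaps_exceeded`` rather than silently accepted.
    """
    attL = check_dna(attL, name="attL")
    attR = check_dna(attR, name="attR")
    cols = _nw_columns(attL, attR)
    mismatches = sum(1 for a, b in cols if GAP not in (a, b) and a != b)
    indels = sum(1 for a, b in cols if GAP in (a, b))
    return AttSitePair(
        attL=attL,
        attR=attR,
        alignment=cols,
        core_length=len(cols),
        mismatches=mismatches,
        indels=indels,
        max_gaps=max_gaps,
        gaps_exceeded=indels > max_gaps,
    )


# ---------------------------------------------------------------------------
# multiple alignment + crossover inference
# ---------------------------------------------------------------------------

def _star_msa(sites: Sequence[str], max_gaps: int) -> list[str]:
    """Profile-free star alignment of near-identical sites.

    Each site is aligned pairwise to the longest site; gaps are merged into
    a common column space.  Adequate for attachment-site homologs, which
    differ by point substitutions and at most ``max_gaps`` short indels.
    """
    ref = max(sites, key=len)
    # per site: chars aligned to each ref base, plus insertions before each
    per_site: list[tuple[list[str], list[str]]] = []
    for s in sites:
        cols = _nw_columns(ref, s)
        n_gaps = sum(1 for a, b in cols if GAP in (a, b))
        if n_gaps > max_gaps:
            raise AlignmentError(
                f"site of length {len(s)} needs {n_gaps} gaps against the "
                f"{len(ref)} bp reference (max_gaps={max_gaps})"
            )
        aligned = [""] * len(ref)        # site char over ref base i
        inserts = [""] * (len(ref) + 1)  # site chars inserted before ref base i
        i = 0
        for a, b in cols:
            if a == GAP:
                inserts[i] += b
            else:
                aligned[i] = b
                i += 1
        per_site.append((aligned, inserts))

    ins_width = [max(len(ins[i]) for _, ins in per_site) for i in range(len(ref) + 1)]
    rows = []
    for aligned, inserts in per_site:
        row = []
        for i in range(len(ref)):
            row.append(inserts[i].ljust(ins_width[i], GAP))
            row.append(aligned[i])
        row.append(inserts[len(ref)].ljust(ins_width[len(ref)], GAP))
        rows.append("".join(row))
    return rows


def infer_crossover(
    sites: Sequence[str], max_gaps: int = 1
) -> list[CrossoverWindow]:
    """All maximal runs of columns identical across every aligned site.

    The strand-exchange window of an integration locus is contained in such
    a conserved run.  Windows are returned sorted by length (descending)
    then position; the list is empty when no column is conserved.
    """
    if len(sites) < 2:
        raise InputError("need at least two sites to infer a crossover")
    sites = [check_dna(s, name=f"site {i}") for i, s in enumerate(sites)]
    rows = _star_msa(sites, max_gaps=max_gaps)
    n_cols = len(rows[0])

    windows: list[CrossoverWindow] = []
    run_start: int | None = None
    for col in range(n_cols + 1):
        conserved = False
        if col < n_cols:
            chars = {row[col] for row in rows}
            conserved = len(chars) == 1 and GAP not in chars
        if conserved and run_start is None:
            run_start = col
        elif not conserved and run_start is not None:
            windows.append(
                CrossoverWindow(
                    start=run_start,
                    length=col - run_start,
                    sequence=rows[0][run_start:col],
                )
            )
            run_start = None
    windows.sort(key=lambda w: (-w.length, w.start))
    return windows


def select_crossover(
    windows: Sequence[CrossoverWindow], policy: str = "longest", index: int = 0
) -> CrossoverWindow:
    """Pick one window from :func:`infer_crossover` output.

    ``policy`` is ``longest`` (default), ``nearest-3prime`` (largest start)
    or ``index`` (positional, using ``index``).
    """
    if not windows:
        raise InputError("no conserved window to select")
    if policy == "longest":
        return windows[0]
    if policy == "nearest-3prime":
        return max(windows, key=lambda w: w.start)
    if policy == "index":
        return sorted(windows, key=lambda w: w.start)[index]
    raise InputError(f"unknown crossover policy {policy!r}")


# ---------------------------------------------------------------------------
# attB/attP derivation
# ---------------------------------------------------------------------------

def derive_attB_attP(pair: AttSitePair, crossover: CrossoverWindow) -> AttSiteSet:
    """Derive the theoretical attB and attP from an aligned attL/attR pair.

    Swapping the aligned rows after the crossover end reconstitutes the
    pre-integration sites: ``attB = attL[..O end] + attR[after O..]`` and
    ``attP = attR[..O end] + attL[after O..]``, each keeping a single copy
    of the common core O.
    """
    if crossover.start < 0 or crossover.end > pair.core_length:
        raise CrossoverError("crossover window lies outside the alignment")
    rowL, rowR = pair.aligned_rows()
    for col in range(crossover.start, crossover.end):
        if rowL[col] != rowR[col] or rowL[col] == GAP:
            raise CrossoverError(
                f"alignment column {col} inside the crossover is not identical"
            )
    attB = (rowL[: crossover.end] + rowR[crossover.end:]).replace(GAP, "")
    attP = (rowR[: crossover.end] + rowL[crossover.end:]).replace(GAP, "")
    return AttSiteSet(attL=pair.attL, attR=pair.attR, attB=attB, attP=attP,
                      crossover=crossover)


# ---------------------------------------------------------------------------
# excision / integration string surgery
# ---------------------------------------------------------------------------

def _norm_crossover(
    crossover: tuple[int, ...], site_a: str, site_b: str
) -> tuple[int, int, int]:
    """Normalize a crossover tuple to (offset_a, offset_b, length)."""
    if len(crossover) == 2:
        off_a, length = crossover
        off_b = off_a
    elif len(crossover) == 3:
        off_a, off_b, length = crossover
    else:
        raise InputError("crossover must be (offset, length) or (offA, offB, length)")
    if length <= 0:
        raise CrossoverError("crossover length must be positive")
    for off, site in ((off_a, site_a), (off_b, site_b)):
        if off < 0 or off + length > len(site):
            raise CrossoverError("crossover does not fit inside the attachment site")
    if site_a[off_a : off_a + length] != site_b[off_b : off_b + length]:
        raise CrossoverError("crossover sequence differs between the two sites")
    return off_a, off_b, length


def excise(
    genome: str,
    attL_interval: tuple[int, int],
    attR_interval: tuple[int, int],
    crossover: tuple[int, ...],
) -> ExcisionResult:
    """Excise a prophage from a lysogen by recombining attL with attR.

    ``attL_interval``/``attR_interval`` are 1-based inclusive coordinates of
    the hybrid sites on the forward strand, attL preceding attR.
    ``crossover`` gives the 0-based offset of the common core O within each
    site (a shared offset, or ``(offset_in_attL, offset_in_attR, length)``).

    Returns the restored host (carrying a single attB) and the virion circle
    rotated to start at attP; total nucleotide count is conserved.
    """
    genome = check_dna(genome, name="genome")
    (l1, l2), (r1, r2) = attL_interval, attR_interval
    if not (1 <= l1 <= l2 < r1 <= r2 <= len(genome)):
        raise InputError(
            "attL must precede attR and both must lie within the genome "
            f"(got attL={attL_interval}, attR={attR_interval})"
        )
    attL = genome[l1 - 1 : l2]
    attR = genome[r1 - 1 : r2]
    off_l, off_r, length = _norm_crossover(crossover, attL, attR)
    end_l, end_r = off_l + length, off_r + length

    interior = genome[l2 : r1 - 1]
    host = genome[: l1 - 1] + attL[:end_l] + attR[end_r:] + genome[r2:]
    virion = attR[:end_r] + attL[end_l:] + interior

    attB = attL[:end_l] + attR[end_r:]
    attP = attR[:end_r] + attL[end_l:]
    return ExcisionResult(
        host=host,
        virion=virion,
        attB=attB,
        attP=attP,
        attB_interval=(l1, l1 + len(attB) - 1),
        attP_interval=(1, len(attP)),
        crossover_in_attB=(off_l, length),
        crossover_in_attP=(off_r, length),
    )


def integrate(
    host: str,
    attB_interval: tuple[int, int],
    virion: str,
    attP_interval: tuple[int, int],
    crossover: tuple[int, ...],
) -> str:
    """Integrate a circular virion into a host chromosome at attB.

    ``attP_interval`` is 1-based inclusive on the (circular) virion; the
    crossover offsets refer to attB and attP respectively.  The product
    carries attL, the prophage interior, then attR; ``excise`` applied to
    the product returns the inputs byte-identically.
    """
    host = check_dna(host, name="host")
    virion = check_dna(virion, name="virion")
    b1, b2 = attB_interval
    if not (1 <= b1 <= b2 <= len(host)):
        raise InputError(f"attB interval {attB_interval} outside host")
    p1, p2 = attP_interval
    p_len = p2 - p1 + 1
    if p_len <= 0 or p_len > len(virion):
        raise InputError(f"attP interval {attP_interval} invalid for virion")
    attB = host[b1 - 1 : b2]
    rotated = virion[p1 - 1 :] + virion[: p1 - 1]  # attP now at offset 0
    attP = rotated[:p_len]
    interior = rotated[p_len:]

    off_b, off_p, length = _norm_crossover(crossover, attB, attP)
    end_b, end_p = off_b + length, off_p + length

    attL = attB[:end_b] + attP[end_p:]
    attR = attP[:end_p] + attB[end_b:]
    return host[: b1 - 1] + attL + interior + attR + host[b2:]


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------

def span_stats(
    record: ProphageRecord, seq: str | None = None
) -> tuple[int, float | None]:
    """Prophage span length (nt) and GC% of the provided sequence.

    Length is ``|right - left| + 1`` regardless of orientation.  GC% is
    computed over unambiguous bases only (N excluded) when ``seq`` is given.
    """
    low, high = record.span
    length = high - low + 1
    gc = gc_percent(seq) if seq is not None else None
    return length, gc


def compare_att_across_hosts(
    attP: str,
    attB_list: Iterable[tuple[str, str]],
    max_gaps: int = 1,
) -> list[tuple[str, int]]:
    """Rank candidate host attB sites by edit distance to a phage attP.

    Returns ``(host_id, edit_distance)`` ascending by distance, ties broken
    lexicographically by host id.  Sites needing more than ``max_gaps`` gaps
    against attP are rejected.
    """
    attP = check_dna(attP, name="attP")
    items = list(attB_list)
    if not items:
        raise InputError("attB_list is empty")
    ranked = []
    for host_id, attB in items:
        attB = check_dna(attB, name=f"attB[{host_id}]")
        cols = _nw_columns(attP, attB)
        gaps = sum(1 for a, b in cols if GAP in (a, b))
        if gaps > max_gaps:
            raise AlignmentError(
                f"attB of {host_id} needs {gaps} gaps vs attP (max_gaps={max_gaps})"
            )
        dist = gaps + sum(1 for a, b in cols if GAP not in (a, b) and a != b)
        ranked.append((host_id, dist))
    ranked.sort(key=lambda t: (t[1], t[0]))
    return ranked
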