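"""Prophage induction quantification from sequencing depth and growth data.

After mitomycin C induction, an excised, replicating prophage is
over-represented in supernatant sequencing relative to the host
chromosome; the fold enrichment of mean coverage measures replication.
On the packaged virion genome, the terminase cleavage site (cos / genome
terminus) shows up as a step discontinuity in coverage.  Growth
inhibition is summarized as the treated/untreated saturation-density
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InputError, UndefinedFoldError


@dataclass
class CoverageTrack:
    """Per-base sequencing depth over one replicon (1-based positions)."""

    replicon_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1 or self.depth.size == 0:
            raise InputError("depth must be a non-empty 1-D array")
        if np.any(self.depth < 0) or not np.all(np.isfinite(self.depth)):
            raise InputError("depths must be finite and non-negative")

    def __len__(self) -> int:
        return self.depth.size

    @classmethod
    def from_tsv(cls, path, replicon_id: str | None = None) -> "CoverageTrack":
        """Read a 3-column depth table (replicon, 1-based position, depth)."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["replicon", "pos", "depth"])
        if replicon_id is not None:
            df = df[df["replicon"] == replicon_id]
        elif df["replicon"].nunique() != 1:
            raise InputError("depth file has multiple replicons; pass replicon_id")
        rid = str(df["replicon"].iloc[0])
        n = int(df["pos"].max())
        depth = np.zeros(n)
        depth[df["pos"].to_numpy() - 1] = df["depth"].to_numpy()
        return cls(replicon_id=rid, depth=depth)


@dataclass(frozen=True)
class InductionReport:
    prophage_mean: float
    host_mean: float
    fold: float
    termini: tuple[tuple[int, float], ...] = field(default_factory=tuple)


def fold_enrichment(
    track: CoverageTrack,
    prophage_interval: tuple[int, int],
    host_mean_includes_prophage: bool = False,
) -> InductionReport:
    """Mean prophage coverage divided by mean host coverage.

    ``prophage_interval`` is 1-based inclusive.  By default the prophage
    interval is excluded from the host mean so that strong induction does
    not contaminate the denominator; set ``host_mean_includes_prophage``
    for a whole-replicon denominator instead.
    """
    lo, hi = prophage_interval
    if not (1 <= lo <= hi <= len(track)):
        raise InputError(f"interval {prophage_interval} outside replicon")
    depth = track.depth
    inside = depth[lo - 1 : hi]
    if host_mean_includes_prophage:
        host = depth
    else:
        host = np.concatenate([depth[: lo - 1], depth[hi:]])
    if host.size == 0:
        raise InputError("host region is empty")
    host_mean = float(host.mean())
    if host_mean == 0:
        raise UndefinedFoldError("host mean coverage is zero; fold undefined")
    prophage_mean = float(inside.mean())
    return InductionReport(
        prophage_mean=prophage_mean,
        host_mean=host_mean,
        fold=prophage_mean / host_mean,
    )


def detect_termini(
    track: CoverageTrack,
    window: int = 100,
    min_step: float = 1.5,
    circular: bool = True,
) -> list[tuple[int, float]]:
    """Coverage-step discontinuities on a (circular) virion-frame track.

    For each position p the step ratio is
    ``max(up/down, down/up)`` of the mean depths over the ``window`` bases
    upstream / downstream of p.  Positions with ratio >= ``min_step`` that
    are local maxima within ``window`` are reported as
    ``(1-based position, step_ratio)`` sorted by ratio descending, ties
    broken by leftmost position.  With ``circular`` (the natural frame for
    a genome assembled from packaged virion DNA) windows wrap around the
    origin, so calls shift with circular rotation of the track; without
    it, positions closer than ``window`` to either end are not evaluated.
    """
    if window < 10:
        raise InputError("window must be >= 10")
    n = len(track)
    if n < 4 * window:
        raise InputError("track shorter than 4x window")
    depth = track.depth
    if not np.any(depth > 0):
        raise InputError("all-zero coverage track")

    # circular window means via cumulative sums on a tiled track
    tiled = np.concatenate([depth[-window:], depth, depth[:window]])
    csum = np.concatenate([[0.0], np.cumsum(tiled)])
    # mean over [i, i+window) of tiled
    wmean = (csum[window:] - csum[:-window]) / window
    up = wmean[:n]        # mean over (p - window, p]
    down = wmean[window : window + n]  # mean over (p, p + window]

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            (up == 0) & (down == 0),
            1.0,
            np.maximum(
                np.divide(up, down, out=np.full(n, np.inf), where=down > 0),
                np.divide(down, up, out=np.full(n, np.inf), where=up > 0),
            ),
        )

    if not circular:
        ratio[:window] = 0.0
        ratio[n - window :] = 0.0

    candidates = np.flatnonzero(ratio >= min_step)
    calls: list[tuple[int, float]] = []
    for p in candidates:
        # local maximality within +/- window; leftmost tie wins
        if circular:
            idxs = np.arange(p - window, p + window + 1) % n
        else:
            idxs = np.arange(max(0, p - window), min(n, p + window + 1))
        neigh = ratio[idxs]
        if ratio[p] < neigh.max():
            continue
        ties = idxs[neigh == neigh.max()]
        if p != ties.min():
            continue
        calls.append((int(p) + 1, float(ratio[p])))
    calls.sort(key=lambda t: (-t[1], t[0]))
    return calls


def growth_inhibition(od_treated_final: float, od_untreated_final: float) -> float:
    """Treated / untreated maximum saturated culture density ratio."""
    if od_untreated_final <= 0:
        raise InputError("untreated OD must be positive")
    if od_treated_final < 0:
        raise InputError("treated OD must be non-negative")
    return od_treated_final / od_untreated_final


def growth_inhibition_table(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-strain mean and standard deviation of treated/untreated ratios.

    ``pairs`` needs columns ``strain``, ``treated``, ``untreated`` with one
    row per replicate pair.
    """
    for col in ("strain", "treated", "untreated"):
        if col not in pairs.columns:
            raise InputError(f"missing column {col!r}")
    df = pairs.copy()
    df["ratio"] = [
        growth_inhibition(t, u) for t, u in zip(df["treated"], df["untreated"])
    ]
    out = df.groupby("strain")["ratio"].agg(["mean", "std", "count"])
    return out.rename(columns={"count": "n"})
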