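"""Flow-cytometry gating and induction statistics.

Phage release into a culture supernatant is quantified by flow cytometry
of stained, PEG-precipitated particles: events falling inside fixed
three-dimensional rectangular gates for debris and for spiked bead
standards are removed, and the remaining ("gated") events report
phage-like particles.  Induction is summarized per treated/untreated
sample pair as the fold change in the gated/total event ratio and in the
median fluorescence of gated events; strain-type groups are compared with
a two-tailed t-test.

Event tables are pandas DataFrames with columns ``FSC-H``, ``SSC-H`` and
``FL1-H``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError, UndefinedFoldError

CHANNELS = ("FSC-H", "SSC-H", "FL1-H")

INF = math.inf


@dataclass(frozen=True)
class GateBox:
    """A 3-D rectangular gate; open ends use +/- inf.

    An event passes the gate when it lies strictly inside the open
    interval on all three channels simultaneously.
    """

    fsc: tuple[float, float]
    ssc: tuple[float, float]
    fl1: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.fsc, self.ssc, self.fl1):
            if not lo < hi:
                raise ConfigError(f"gate bounds must satisfy low < high, got ({lo}, {hi})")

    def contains(self, events: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(events), dtype=bool)
        for (lo, hi), ch in zip((self.fsc, self.ssc, self.fl1), CHANNELS):
            x = events[ch].to_numpy()
            mask &= (x > lo) & (x < hi)
        return mask


#: Debris gate: low scatter, low fluorescence.
DEBRIS_GATE = GateBox(fsc=(-INF, 50.0), ssc=(-INF, 100.0), fl1=(-INF, 15.0))
#: Bead-standard gate.
BEAD_GATE = GateBox(fsc=(150.0, 1000.0), ssc=(800.0, 2700.0), fl1=(15.0, 90.0))


def _check_events(events: pd.DataFrame, name: str = "events") -> pd.DataFrame:
    if len(events) == 0:
        raise InputError(f"{name} table is empty")
    missing = [c for c in CHANNELS if c not in events.columns]
    if missing:
        raise InputError(f"{name} table missing channels {missing}")
    vals = events[list(CHANNELS)].to_numpy()
    if not np.all(np.isfinite(vals)) or np.any(vals < 0):
        raise InputError(f"{name} channels must be finite and non-negative")
    return events


def apply_gates(
    events: pd.DataFrame,
    debris: GateBox = DEBRIS_GATE,
    beads: GateBox = BEAD_GATE,
) -> tuple[pd.DataFrame, int, int, int]:
    """Remove debris and bead events; keep the rest.

    Returns ``(gated_events, n_debris, n_beads, n_gated)``.  The three
    counts partition the input; an event inside both boxes counts as
    debris.
    """
    events = _check_events(events)
    in_debris = debris.contains(events)
    in_beads = beads.contains(events) & ~in_debris
    keep = ~in_debris & ~in_beads
    return (
        events.loc[keep],
        int(in_debris.sum()),
        int(in_beads.sum()),
        int(keep.sum()),
    )


def induction_metrics(
    treated: pd.DataFrame,
    untreated: pd.DataFrame,
    debris: GateBox = DEBRIS_GATE,
    beads: GateBox = BEAD_GATE,
) -> tuple[float, float]:
    """Fold changes in gated-event abundance and median fluorescence.

    ``abundance_fold`` is the gated/total event ratio of the treated sample
    divided by that of the untreated sample; ``fluorescence_fold`` is the
    ratio of median FL1-H over gated events.
    """
    gated_t, *_ , n_t = apply_gates(treated, debris, beads)
    gated_u, *_ , n_u = apply_gates(untreated, debris, beads)
    if n_u == 0:
        raise UndefinedFoldError("untreated sample has zero gated events")
    ratio_t = n_t / len(treated)
    ratio_u = n_u / len(untreated)
    abundance_fold = ratio_t / ratio_u
    med_u = float(gated_u["FL1-H"].median())
    if med_u == 0:
        raise UndefinedFoldError("untreated median fluorescence is zero")
    fluorescence_fold = float(gated_t["FL1-H"].median()) / med_u
    return abundance_fold, fluorescence_fold


def group_test(
    folds: dict[str, list[float]],
    reference: str,
    equal_var: bool = False,
) -> dict[str, float]:
    """Two-tailed t-test of each strain-type group against a reference.

    Welch (unequal variance) by default; set ``equal_var`` for the pooled
    test.  Degenerate comparisons where all values in both groups are
    identical return p = 1.0 rather than NaN.
    """
    if reference not in folds:
        raise InputError(f"reference group {reference!r} missing")
    ref = np.asarray(folds[reference], dtype=float)
    if ref.size < 2:
        raise InputError("reference group needs n >= 2")
    out: dict[str, float] = {}
    for name, values in folds.items():
        if name == reference:
            continue
        grp = np.asarray(values, dtype=float)
        if grp.size < 2:
            raise InputError(f"group {name!r} needs n >= 2")
        if np.ptp(grp) == 0 and np.ptp(ref) == 0:
            out[name] = 1.0 if grp[0] == ref[0] else 0.0
            continue
        res = stats.ttest_ind(grp, ref, equal_var=equal_var)
        p = float(res.pvalue)
        out[name] = p if np.isfinite(p) else 1.0
    return out
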