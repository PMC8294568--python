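"""Production-rate estimation and replicate quality control.

A donor's production rate for one (fiber, SCFA) pair is the two-point
slope of the replicate-averaged concentration between 2 h and 4 h, minus
the same slope in the no-spike-in control — giving net microbial
production attributable to the added fiber, in mM/h. Negative net rates
are retained (downstream z-scoring assumes the full real line).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mmpkit.data_io import SCFAS, Condition, ScfaSeries

logger = logging.getLogger(__name__)

FIBERS = (Condition.INULIN, Condition.PECTIN, Condition.CELLULOSE)


@dataclass(frozen=True)
class ProductionRate:
    """Control-subtracted SCFA production rate for one donor."""

    donor_id: str
    fiber: Condition
    scfa: str
    rate_mM_per_h: float
    window: tuple[float, float] = (2.0, 4.0)

    def __post_init__(self) -> None:
        if self.window[1] <= self.window[0]:
            raise ValueError(f"window end must exceed start: {self.window}")
        if not np.isfinite(self.rate_mM_per_h):
            raise ValueError("rate must be finite")


@dataclass
class ReplicateQc:
    """Replicate agreement summary.

    ``per_pair`` holds one row per (donor, condition, timepoint, scfa)
    group with >= 2 replicates: the pair CV in percent
    (100 * sd(n-1) / mean) and, as an alternative reading, the percentage
    difference (100 * |a-b| / mean). Zero-mean groups are flagged, not
    dropped. ``overall_cv`` is the unweighted mean of per-pair CVs.
    """

    per_pair: pd.DataFrame
    overall_cv: float
    overall_pct_diff: float
    n_flagged_zero_mean: int


def average_replicates(series_group: Sequence[ScfaSeries]) -> ScfaSeries:
    """Arithmetic mean of replicate trajectories, per timepoint.

    All series must share (donor, condition, SCFA). A timepoint missing
    from some wells is averaged over the wells that have it (warning
    logged). The returned series has replicate index cleared to 1.
    """
    if not series_group:
        raise ValueError("empty replicate group")
    first = series_group[0]
    for s in series_group[1:]:
        if (s.donor_id, s.condition, s.scfa) != (
            first.donor_id,
            first.condition,
            first.scfa,
        ):
            raise ValueError("replicate group mixes donors/conditions/SCFAs")
    timepoints = sorted({t for s in series_group for t in s.concentrations})
    out: dict[float, float] = {}
    for t in timepoints:
        vals = [s.concentrations[t] for s in series_group if t in s.concentrations]
        if len(vals) < len(series_group):
            logger.warning(
                "timepoint %g h present in %d/%d wells for %s/%s/%s; "
                "averaging available wells",
                t, len(vals), len(series_group),
                first.donor_id, first.condition.value, first.scfa,
            )
        out[t] = float(np.mean(vals))
    return ScfaSeries(first.donor_id, first.condition, first.scfa, 1, out)


def replicate_cv(all_series: Iterable[ScfaSeries]) -> ReplicateQc:
    """Per-pair and overall replicate coefficient of variation.

    Each (donor, condition, timepoint, SCFA) group with >= 2 replicate
    measurements contributes one CV; the overall statistic is their
    unweighted mean, matching a per-pair QC reading of replicate scatter.
    """
    groups: dict[tuple, list[float]] = {}
    for s in all_series:
        for t, c in s.concentrations.items():
            groups.setdefault((s.donor_id, s.condition.value, t, s.scfa), []).append(c)

    rows = []
    n_flagged = 0
    for (donor, cond, t, scfa), vals in sorted(groups.items()):
        if len(vals) < 2:
            continue
        arr = np.asarray(vals, dtype=float)
        mean = arr.mean()
        sd = arr.std(ddof=1)
        if mean == 0:
            n_flagged += 1
            cv = np.nan
            pct = np.nan
        else:
            cv = 100.0 * sd / mean
            # "percentage difference" alternative: range over mean
            pct = 100.0 * (arr.max() - arr.min()) / mean
        rows.append(
            {"donor": donor, "condition": cond, "timepoint_h": t, "scfa": scfa,
             "n": len(arr), "cv_pct": cv, "pct_diff": pct,
             "zero_mean": mean == 0}
        )
    if not rows:
        raise ValueError("no group has >= 2 replicates")
    df = pd.DataFrame(rows)
    return ReplicateQc(
        per_pair=df,
        overall_cv=float(np.nanmean(df["cv_pct"])),
        overall_pct_diff=float(np.nanmean(df["pct_diff"])),
        n_flagged_zero_mean=n_flagged,
    )


def production_rate(
    series: ScfaSeries,
    t_start: float = 2.0,
    t_end: float = 4.0,
    least_squares: bool = False,
) -> float:
    """Slope of the concentration trajectory over [t_start, t_end], mM/h.

    Default is the two-point slope (C(t_end) - C(t_start)) / (t_end - t_start)
    on replicate-averaged values. ``least_squares=True`` instead fits an
    ordinary least-squares line through every timepoint in the window.
    """
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if least_squares:
        ts = [t for t in series.concentrations if t_start <= t <= t_end]
        if len(ts) < 2:
            raise ValueError(f"need >= 2 timepoints in [{t_start}, {t_end}]")
        x = np.asarray(sorted(ts))
        y = np.asarray([series.concentrations[t] for t in sorted(ts)])
        return float(np.polyfit(x, y, 1)[0])
    for t in (t_start, t_end):
        if t not in series.concentrations:
            raise ValueError(
                f"missing timepoint {t} h for {series.donor_id}/"
                f"{series.condition.value}/{series.scfa}"
            )
    return (series.concentrations[t_end] - series.concentrations[t_start]) / (
        t_end - t_start
    )


def net_production_rate(
    fiber_rate: ProductionRate, control_rate: ProductionRate
) -> ProductionRate:
    """Fiber-condition rate minus the control rate (may be negative)."""
    if fiber_rate.donor_id != control_rate.donor_id:
        raise ValueError(
            f"donor mismatch: {fiber_rate.donor_id} vs {control_rate.donor_id}"
        )
    if fiber_rate.scfa != control_rate.scfa:
        raise ValueError(f"SCFA mismatch: {fiber_rate.scfa} vs {control_rate.scfa}")
    if control_rate.fiber != Condition.CONTROL:
        raise ValueError("second argument must be the control-condition rate")
    return ProductionRate(
        donor_id=fiber_rate.donor_id,
        fiber=fiber_rate.fiber,
        scfa=fiber_rate.scfa,
        rate_mM_per_h=fiber_rate.rate_mM_per_h - control_rate.rate_mM_per_h,
        window=fiber_rate.window,
    )


def rate_table(
    all_series: Iterable[ScfaSeries],
    t_start: float = 2.0,
    t_end: float = 4.0,
    fibers: Sequence[Condition] = (Condition.INULIN, Condition.PECTIN),
) -> pd.DataFrame:
    """Full pipeline: average replicates, slope, control-subtract.

    Returns a tidy frame (donor, fiber, scfa, rate_mM_per_h) with one row
    per donor x fiber x SCFA.
    """
    grouped: dict[tuple[str, Condition, str], list[ScfaSeries]] = {}
    for s in all_series:
        grouped.setdefault((s.donor_id, s.condition, s.scfa), []).append(s)

    slopes: dict[tuple[str, Condition, str], float] = {}
    for key, group in grouped.items():
        slopes[key] = production_rate(average_replicates(group), t_start, t_end)

    rows = []
    for (donor, cond, scfa), slope in sorted(
        slopes.items(), key=lambda kv: (kv[0][0], kv[0][1].value, kv[0][2])
    ):
        if cond not in fibers:
            continue
        ctrl_key = (donor, Condition.CONTROL, scfa)
        if ctrl_key not in slopes:
            raise ValueError(f"missing control series for donor {donor}, {scfa}")
        net = net_production_rate(
            ProductionRate(donor, cond, scfa, slope, (t_start, t_end)),
            ProductionRate(
                donor, Condition.CONTROL, scfa, slopes[ctrl_key], (t_start, t_end)
            ),
        )
        rows.append(
            {"donor": donor, "fiber": cond.value, "scfa": scfa,
             "rate_mM_per_h": net.rate_mM_per_h}
        )
    return pd.DataFrame(rows)
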