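"""Timepoint deltas and the Proportional Recovery Index (PRI).

For a rest / post-run (21k) / one-week-control T2 triplet,

    PRI = (T2_control - T2_21k) / (T2_rest - T2_21k)

PRI = 1 means complete return to baseline, PRI < 1 incomplete recovery,
PRI > 1 overcompensation, and PRI < 0 continued drift away from baseline.
Group summaries follow the reporting convention of the study tables:
delta columns are mean +/- SD of per-sample values, while the group PRI is
computed from the group-mean T2 triplet.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TimepointTriplet",
    "RecoveryMetrics",
    "compute_pri",
    "compute_deltas",
    "summarize_group",
    "recovery_table",
]

TIMEPOINTS = ("rest", "21k", "control")


@dataclass(frozen=True)
class TimepointTriplet:
    """T2 (ms) at the three study timepoints; finite and positive."""

    t2_rest: float
    t2_21k: float
    t2_control: float
    level: str = "per_sample"   # or "group_mean"

    def __post_init__(self) -> None:
        for name in ("t2_rest", "t2_21k", "t2_control"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


@dataclass(frozen=True)
class RecoveryMetrics:
    """Signed deltas (negative = T2 loss) and the PRI for one triplet."""

    delta_run_ms: float
    delta_run_pct: float
    delta_ctrl_ms: float
    delta_ctrl_pct: float
    pri: float


def compute_pri(t: TimepointTriplet) -> float:
    """PRI = (control - 21k) / (rest - 21k); NaN when rest == 21k.

    Full precision is returned; reports round to one decimal.
    """
    den = t.t2_rest - t.t2_21k
    if den == 0:
        warnings.warn("PRI undefined: rest and 21k T2 are equal")
        return float("nan")
    return (t.t2_control - t.t2_21k) / den


def compute_deltas(t: TimepointTriplet) -> tuple[float, float, float, float]:
    """Signed run and control deltas in ms and percent of rest."""
    d_run = t.t2_21k - t.t2_rest
    d_ctrl = t.t2_control - t.t2_rest
    return (
        d_run, 100.0 * d_run / t.t2_rest,
        d_ctrl, 100.0 * d_ctrl / t.t2_rest,
    )


def metrics_for(t: TimepointTriplet) -> RecoveryMetrics:
    d_run, d_run_pct, d_ctrl, d_ctrl_pct = compute_deltas(t)
    return RecoveryMetrics(d_run, d_run_pct, d_ctrl, d_ctrl_pct, compute_pri(t))


def summarize_group(samples: list, means: TimepointTriplet) -> dict:
    """Summarize one group: per-sample delta summaries + group-mean PRI.

    ``samples`` is a list of :class:`RecoveryMetrics` (one per sample);
    ``means`` is the group-mean T2 triplet from which the reported PRI is
    computed.  Delta columns are mean +/- SD over samples.
    """
    if len(samples) == 0:
        raise ValueError("cannot summarize an empty group")

    def _ms(vals):
        vals = np.asarray(vals, float)
        return float(np.mean(vals)), (
            float(np.std(vals, ddof=1)) if vals.size > 1 else float("nan")
        )

    run_ms = _ms([s.delta_run_ms for s in samples])
    run_pct = _ms([s.delta_run_pct for s in samples])
    ctrl_ms = _ms([s.delta_ctrl_ms for s in samples])
    ctrl_pct = _ms([s.delta_ctrl_pct for s in samples])
    return {
        "n": len(samples),
        "t2_rest_ms": means.t2_rest,
        "t2_21k_ms": means.t2_21k,
        "t2_control_ms": means.t2_control,
        "delta_run_ms": run_ms[0], "delta_run_ms_sd": run_ms[1],
        "delta_run_pct": run_pct[0], "delta_run_pct_sd": run_pct[1],
        "delta_ctrl_ms": ctrl_ms[0], "delta_ctrl_ms_sd": ctrl_ms[1],
        "delta_ctrl_pct": ctrl_pct[0], "delta_ctrl_pct_sd": ctrl_pct[1],
        "pri": compute_pri(means),
    }


def _complete_pivot(rois: pd.DataFrame, region: str) -> pd.DataFrame:
    """Per-sample wide table (rest/21k/control columns) for one region.

    A sample is one (participant, knee, slice); samples missing any
    timepoint are dropped (complete-case analysis).
    """
    sub = rois[rois["region"] == region]
    wide = sub.pivot_table(
        index=["participant", "knee", "slice", "sex"],
        columns="timepoint", values="mean_t2_ms", aggfunc="first",
    )
    missing = [tp for tp in TIMEPOINTS if tp not in wide.columns]
    if missing:
        return pd.DataFrame(columns=list(TIMEPOINTS))
    return wide[list(TIMEPOINTS)].dropna()


def recovery_table(
    rois: pd.DataFrame,
    regions: list,
    group_by: str | None = None,
) -> pd.DataFrame:
    """Recovery summary rows per region (optionally split by a grouping column).

    ``rois`` is the long-format ROI table (columns participant, knee, slice,
    timepoint, sex, region, mean_t2_ms, ...).  ``group_by`` may be ``"knee"``
    or ``"sex"`` for laterality/sex stratification.  Each output row carries
    group-mean T2 per timepoint with SD, per-sample delta summaries and the
    group-mean PRI.
    """
    rows = []
    for region in regions:
        wide = _complete_pivot(rois, region)
        if wide.empty:
            continue
        if group_by is None:
            groups = [("all", wide)]
        else:
            level = {"knee": "knee", "sex": "sex"}[group_by]
            groups = list(wide.groupby(level=level, sort=True))
        for gname, gw in groups:
            if gw.empty:
                continue
            means = TimepointTriplet(
                float(gw["rest"].mean()), float(gw["21k"].mean()),
                float(gw["control"].mean()), level="group_mean",
            )
            samples = [
                metrics_for(TimepointTriplet(r, k, c))
                for r, k, c in gw.itertuples(index=False)
            ]
            row = {"region": region, "group": gname}
            row.update(summarize_group(samples, means))
            row["t2_rest_sd"] = float(gw["rest"].std(ddof=1)) if len(gw) > 1 else np.nan
            row["t2_21k_sd"] = float(gw["21k"].std(ddof=1)) if len(gw) > 1 else np.nan
            row["t2_control_sd"] = (
                float(gw["control"].std(ddof=1)) if len(gw) > 1 else np.nan
            )
            rows.append(row)
    return pd.DataFrame(rows)
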