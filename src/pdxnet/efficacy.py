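"""RECIST efficacy and tolerability from caliper trial tables.

Tumor volume is ``V = length * width^2 / 2``; each animal's series is
expressed relative to day 0 (relative tumor volume, RTV).  Best response is
the best RECIST category achieved over the evaluation window:

* CR — nadir RTV at or below a near-complete-regression threshold
  (default 0.05; the printed rates do not depend on it),
* PR — nadir RTV <= 0.7 (at least 30% volume reduction),
* PD — maximum RTV >= 1.2 (at least 20% increase over baseline),
* SD — neither bound crossed.

CR/PR/SD take precedence over later progression ("best response").  Cohort
rates: ORR = (CR + PR) / n, CBR = (CR + PR + SD) / n, as nearest-integer
percentages.  Tolerability is the maximum relative body-weight loss from
day 0, flagged at a configurable threshold (default 5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pdxnet.cluster import round_percent

CATEGORIES = ["CR", "PR", "SD", "PD"]

CR_THRESHOLD = 0.05
PR_THRESHOLD = 0.7
PD_THRESHOLD = 1.2


@dataclass(frozen=True)
class ResponseCall:
    animal_id: str
    group: str
    rtv_series: pd.Series
    best_response: str
    nadir_rtv: float
    max_rtv: float


def tumor_volume(length, width):
    """``V = length * width^2 / 2`` in mm^3; swaps axes if width > length."""
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length <= 0) or np.any(width <= 0):
        raise ValueError("caliper dimensions must be positive")
    if np.any(width > length):
        warnings.warn("width > length encountered; axes swapped")
        length, width = np.maximum(length, width), np.minimum(length, width)
    v = length * width**2 / 2.0
    return float(v) if v.ndim == 0 else v


def relative_tumor_volume(volumes: pd.Series) -> pd.Series:
    """Per-day V_t / V_0 for a day-indexed volume series (day 0 required)."""
    if 0 not in volumes.index:
        raise ValueError("day 0 (randomization) measurement missing")
    v0 = float(volumes.loc[0])
    if v0 <= 0:
        raise ValueError("day 0 volume must be positive")
    return volumes / v0


def best_response(
    rtv: pd.Series,
    window: tuple[float, float] | None = None,
    cr_threshold: float = CR_THRESHOLD,
    pr_threshold: float = PR_THRESHOLD,
    pd_threshold: float = PD_THRESHOLD,
) -> tuple[str, float, float]:
    """Best RECIST category over the window, with nadir and maximum RTV.

    The category is the best achieved: a nadir at or below the PR bound is
    PR even if the tumor later regrows past the PD bound.
    """
    series = rtv
    if window is not None:
        lo, hi = window
        series = rtv.loc[(rtv.index >= lo) & (rtv.index <= hi)]
    if len(series) < 2:
        raise ValueError("evaluation window must contain at least 2 time points")
    nadir = float(series.min())
    peak = float(series.max())
    if nadir <= cr_threshold:
        category = "CR"
    elif nadir <= pr_threshold:
        category = "PR"
    elif peak >= pd_threshold:
        category = "PD"
    else:
        category = "SD"
    return category, nadir, peak


def response_calls(
    trial: pd.DataFrame,
    window: tuple[float, float] | None = None,
    cr_threshold: float = CR_THRESHOLD,
    pr_threshold: float = PR_THRESHOLD,
    pd_threshold: float = PD_THRESHOLD,
    metric: str = "volume",
) -> pd.DataFrame:
    """Per-animal RECIST calls from a long-format caliper table.

    ``metric`` selects the measured quantity the thresholds apply to:
    ``volume`` (default) or ``diameter`` (longest axis).
    """
    if metric not in ("volume", "diameter"):
        raise ValueError(f"unknown metric: {metric!r}")
    rows = []
    for animal, sub in trial.groupby("animal_id", sort=True):
        sub = sub.sort_values("day")
        if sub["day"].duplicated().any():
            raise ValueError(f"duplicate measurement days for animal {animal}")
        if metric == "volume":
            values = pd.Series(
                tumor_volume(sub["length_mm"].to_numpy(), sub["width_mm"].to_numpy()),
                index=sub["day"].to_numpy(),
            )
        else:
            values = pd.Series(sub["length_mm"].to_numpy(), index=sub["day"].to_numpy())
        rtv = relative_tumor_volume(values)
        category, nadir, peak = best_response(
            rtv, window, cr_threshold, pr_threshold, pd_threshold
        )
        rows.append(
            {
                "animal_id": animal,
                "group": sub["group"].iloc[0],
                "nadir_rtv": nadir,
                "max_rtv": peak,
                "best_response": category,
            }
        )
    return pd.DataFrame(rows).set_index("animal_id")


def summary_from_counts(cr: int, pr: int, sd: int, pd_: int) -> dict:
    """Group rates from category tallies; ORR/CBR as rounded percentages."""
    n = cr + pr + sd + pd_
    if n < 1:
        raise ValueError("group must be non-empty")
    return {
        "n": n,
        "CR": cr,
        "PR": pr,
        "SD": sd,
        "PD": pd_,
        "orr_pct": round_percent(100.0 * (cr + pr) / n),
        "cbr_pct": round_percent(100.0 * (cr + pr + sd) / n),
    }


def cohort_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-group response counts, ORR and CBR from per-animal calls."""
    if calls.empty:
        raise ValueError("no response calls given")
    rows = []
    for group, sub in calls.groupby("group", sort=True):
        tallies = sub["best_response"].value_counts()
        stats = summary_from_counts(
            int(tallies.get("CR", 0)),
            int(tallies.get("PR", 0)),
            int(tallies.get("SD", 0)),
            int(tallies.get("PD", 0)),
        )
        rows.append({"group": group, **stats})
    return pd.DataFrame(rows).set_index("group")


def tolerability(trial: pd.DataFrame, loss_threshold: float = 0.05) -> pd.DataFrame:
    """Per-animal maximum relative body-weight loss from day 0, with flag."""
    rows = []
    for animal, sub in trial.groupby("animal_id", sort=True):
        sub = sub.sort_values("day")
        weights = sub["body_weight_g"].to_numpy(dtype=float)
        if np.any(weights <= 0):
            raise ValueError(f"non-positive body weight for animal {animal}")
        if sub["day"].iloc[0] != 0:
            raise ValueError(f"day 0 weight missing for animal {animal}")
        w0 = weights[0]
        max_loss = max(0.0, float(np.max((w0 - weights) / w0)))
        rows.append(
            {
                "animal_id": animal,
                "group": sub["group"].iloc[0],
                "max_weight_loss_pct": 100.0 * max_loss,
                "tolerability_flag": max_loss >= loss_threshold,
            }
        )
    return pd.DataFrame(rows).set_index("animal_id")
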