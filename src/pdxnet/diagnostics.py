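"""Single-gene cutoff classification and exact binomial diagnostics.

A sample is called marker-positive when its expression value is at or above
a prespecified cutoff (default 12, the squamous-marker threshold).  Against
a truth labeling this yields a confusion table; sensitivity and specificity
are reported with exact Clopper-Pearson 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

DEFAULT_CUTOFF = 12.0


@dataclass(frozen=True)
class BinaryDiagnostics:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sens_ci"] = list(self.sens_ci)
        d["spec_ci"] = list(self.spec_ci)
        return d


def classify_by_cutoff(values, cutoff: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Boolean labels: value >= cutoff (the threshold itself is positive)."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression values must be finite")
    return values >= cutoff


def proportion_ci(x: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact Clopper-Pearson confidence interval for a binomial proportion.

    ``low`` is the alpha/2 quantile of Beta(x, n - x + 1) (0 when x = 0) and
    ``high`` the 1 - alpha/2 quantile of Beta(x + 1, n - x) (1 when x = n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= x <= n:
        raise ValueError("x must lie in [0, n]")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    alpha = 1.0 - level
    low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    high = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return low, high


def diagnostics_from_counts(
    tp: int, fp: int, tn: int, fn: int, level: float = 0.95
) -> BinaryDiagnostics:
    """Diagnostics straight from confusion counts (e.g. printed tallies)."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    pos, neg = tp + fn, tn + fp
    sensitivity = tp / pos if pos else float("nan")
    specificity = tn / neg if neg else float("nan")
    sens_ci = proportion_ci(tp, pos, level) if pos else (float("nan"),) * 2
    spec_ci = proportion_ci(tn, neg, level) if neg else (float("nan"),) * 2
    return BinaryDiagnostics(tp, fp, tn, fn, sensitivity, specificity, sens_ci, spec_ci)


def evaluate_marker(pred, truth, level: float = 0.95) -> BinaryDiagnostics:
    """Confusion counts and CI-backed sensitivity/specificity of a classifier.

    ``pred`` and ``truth`` are aligned boolean vectors (truth = condition
    present).  Proportions are kept at full precision; round only when
    reporting.
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    tn = int(np.sum(~pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return diagnostics_from_counts(tp, fp, tn, fn, level)
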