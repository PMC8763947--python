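"""Count normalization: median-of-ratios size factors and log2 transform.

Size factors follow the median-of-ratios construction: each sample's factor
is the median, over genes with strictly positive geometric mean across
samples, of the ratio of the sample's count to that geometric mean.  The
transform ``log2(count / size_factor + 1)`` puts values on the log2 scale
for large counts while keeping zeros at zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pdxnet.io import ExpressionMatrix


class SizeFactorError(ValueError):
    """Size factors could not be estimated."""


def estimate_size_factors(counts: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios size factors, one positive real per sample.

    Only genes with all-positive counts (strictly positive geometric mean)
    enter the per-sample median; with no such gene estimation fails.
    """
    if counts.scale != "raw_counts":
        raise ValueError("size factors are estimated from raw counts")
    values = counts.data.to_numpy(dtype=float)
    eligible = np.all(values > 0, axis=1)
    if not eligible.any():
        raise SizeFactorError(
            "no gene has strictly positive counts in every sample; "
            "cannot form median-of-ratios size factors"
        )
    logs = np.log(values[eligible])
    log_geo_mean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo_mean, axis=0))
    return pd.Series(factors, index=counts.data.columns, name="size_factor")


def log_transform(counts: ExpressionMatrix, size_factors: pd.Series) -> ExpressionMatrix:
    """``log2(count / size_factor + 1)`` per cell; monotone in the count."""
    if counts.scale != "raw_counts":
        raise ValueError("transform applies to raw counts")
    if list(size_factors.index) != list(counts.data.columns):
        raise ValueError("size factors do not match the matrix's samples")
    if np.any(size_factors.to_numpy() <= 0):
        raise ValueError("size factors must be strictly positive")
    values = counts.data.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    transformed = np.log2(values / size_factors.to_numpy()[None, :] + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(transformed, index=counts.data.index, columns=counts.data.columns),
        scale="log2_normalized",
    )


def normalize(counts: ExpressionMatrix) -> tuple[ExpressionMatrix, pd.Series]:
    """Convenience: estimate size factors and transform in one step."""
    sf = estimate_size_factors(counts)
    return log_transform(counts, sf), sf
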