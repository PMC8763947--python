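"""Median-of-ratios normalization and log2 transform of the cohort counts."""

from pathlib import Path

from pdxnet.io import ExpressionMatrix
from pdxnet.normalize import normalize

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"

counts = ExpressionMatrix.from_tsv(OUT / "expression_counts.tsv")
log2, size_factors = normalize(counts)
log2.to_tsv(OUT / "expression_log2.tsv")
size_factors.to_csv(OUT / "size_factors.csv", header=True)

print(f"size factors: min {size_factors.min():.3f}, median "
      f"{size_factors.median():.3f}, max {size_factors.max():.3f}")
print(f"log2 matrix written ({log2.n_genes} x {log2.n_samples}); "
      f"value range [{log2.data.min().min():.2f}, {log2.data.max().max():.2f}]")
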