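"""Marker-cutoff histology classification with exact binomial intervals.

Calls samples squamous-like when TP63 log2 expression >= 12 and scores the
calls against the generated histology labels; sensitivity and specificity
come with exact Clopper-Pearson 95% CIs.
"""

import json
from pathlib import Path

from pdxnet.diagnostics import classify_by_cutoff, evaluate_marker
from pdxnet.io import ExpressionMatrix, read_metadata

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"

log2 = ExpressionMatrix.from_tsv(OUT / "expression_log2.tsv", scale="log2_normalized")
meta = read_metadata(OUT / "metadata.tsv").loc[log2.sample_ids]

pred = classify_by_cutoff(log2.data.loc["TP63"], cutoff=12.0)
truth = (meta["histology"] == "A").to_numpy()
d = evaluate_marker(pred, truth)
(OUT / "marker_diagnostics.json").write_text(json.dumps(d.to_dict(), indent=2) + "\n")

print(f"confusion: tp={d.tp} fp={d.fp} tn={d.tn} fn={d.fn}")
print(f"sensitivity {d.sensitivity:.2f} CI [{d.sens_ci[0]:.2f}; {d.sens_ci[1]:.2f}]")
print(f"specificity {d.specificity:.2f} CI [{d.spec_ci[0]:.2f}; {d.spec_ci[1]:.2f}]")
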