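"""RECIST best responses, cohort ORR/CBR and tolerability from the trial."""

import json
from pathlib import Path

from pdxnet.efficacy import cohort_summary, response_calls, tolerability
from pdxnet.io import read_trial

OUT = Path(__file__).resolve().parent.parent / "results" / "analysis"

trial = read_trial(OUT / "trial.csv")
calls = response_calls(trial)
tol = tolerability(trial)
summary = cohort_summary(calls)

calls.join(tol[["max_weight_loss_pct", "tolerability_flag"]]).to_csv(
    OUT / "response_calls.csv"
)
(OUT / "cohort_summary.json").write_text(
    json.dumps(summary.reset_index().to_dict(orient="records"), indent=2) + "\n"
)

print(summary.to_string())
flagged = int(tol["tolerability_flag"].sum())
print(f"tolerability: {flagged}/{len(tol)} animals with >= 5% body-weight loss")
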