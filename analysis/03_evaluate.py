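#!/usr/bin/env python
"""Full evaluation of the fitted branches on both test sets.

Writes Table-style fixed-cutoff metrics with bootstrap 95% CIs, ROC / PR /
decision-curve / threshold-response / probability-density point lists, and
Hanley-McNeil power reports under results/. Requires 02_run_branches.py.
"""

import json
import pickle
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from dpetfusion.metrics import (  # noqa: E402
    decision_curve,
    hanley_mcneil,
    pr_curve,
    probability_density,
    report_with_cis,
    roc_points,
    threshold_response,
)

SEED = 1
BRANCHES = ("baseline", "radiomics", "deep", "ith", "decision_fusion", "feature_fusion")


def main() -> None:
    with open(ROOT / "scratch" / "pipeline_result.pkl", "rb") as fh:
        state = pickle.load(fh)
    result = state["result"]
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    rows = []
    curves_dir = results / "curves"
    curves_dir.mkdir(exist_ok=True)
    power = {}
    for part in ("test1", "test2"):
        labels = result.labels[part]
        for branch in BRANCHES:
            probs = result.predictions[branch][part]
            rep = report_with_cis(probs, labels, B=1000, seed=SEED)
            row = {"branch": branch, "partition": part}
            row.update({k: v for k, v in rep.as_dict().items() if not isinstance(v, tuple)})
            for metric, (lo, hi) in rep.ci.items():
                row[f"{metric}_lo"], row[f"{metric}_hi"] = round(lo, 3), round(hi, 3)
            rows.append(row)

            roc_points(probs, labels).to_csv(curves_dir / f"roc_{branch}_{part}.csv", index=False)
            pr, ap = pr_curve(probs, labels)
            pr.to_csv(curves_dir / f"pr_{branch}_{part}.csv", index=False)
            dc = decision_curve(probs, labels)
            dc.to_frame().to_csv(curves_dir / f"dca_{branch}_{part}.csv", index=False)
            threshold_response(probs, labels).to_csv(
                curves_dir / f"threshold_response_{branch}_{part}.csv", index=False
            )
            probability_density(probs, labels).to_csv(
                curves_dir / f"density_{branch}_{part}.csv", index=False
            )
            a = min(max(rep.auc, 0.01), 0.99)
            pw = hanley_mcneil(a, rep.n1, rep.n0)
            power[f"{branch}_{part}"] = {
                "auc": round(rep.auc, 3),
                "variance": pw.variance,
                "power_pct": round(100 * pw.power, 1),
                "dca_final_interval": dc.final_interval,
                "average_precision": round(ap, 3),
            }

    table = pd.DataFrame(rows)
    table.to_csv(results / "metrics_table.csv", index=False)
    (results / "power_and_dca.json").write_text(json.dumps(power, indent=2) + "\n")
    show = table[table.partition == "test1"][["branch", "AUC", "ACC", "SEN", "SPE", "PPV", "NPV"]]
    print("test set 1:")
    print(show.to_string(index=False))


if __name__ == "__main__":
    main()
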