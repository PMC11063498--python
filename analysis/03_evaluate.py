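"""Diagnostic accuracy of the two score variants for fetal acidemia.

ROC/AUC with DeLong confidence intervals and Youden-index cutoffs for the
DCS and RCT scores against umbilical-artery pH < 7.2, plus the sample-size
check of the one-sided AUC design (0.80 vs 0.50, power 0.90, 1:9).

Reads results/cohort/ and results/scores.csv; writes results/evaluation.json.

Run:  python analysis/03_evaluate.py
"""

import json
from pathlib import Path

import pandas as pd

from ipreface import auc_sample_size, read_cases, roc_analysis, youden_cutoff


def main() -> None:
    cases = read_cases("results/cohort/cases.csv", "results/cohort/events.csv")
    scores = pd.read_csv("results/scores.csv")
    outcome = {c.case_id: c.blood_gas.acidemia(7.2) for c in cases}

    blocks = {}
    for variant, sub in scores.groupby("variant"):
        y = [outcome[cid] for cid in sub["case_id"]]
        roc = roc_analysis(sub["score"].tolist(), y)
        cut = youden_cutoff(roc)
        blocks[variant] = {
            "auc": roc.auc, "ci": [roc.auc_ci_low, roc.auc_ci_high],
            "p_vs_0.5": roc.p_value, "cutoff": cut.cutoff,
            "sensitivity": cut.sensitivity, "specificity": cut.specificity,
            "ppv": cut.ppv, "npv": cut.npv,
        }
        print(f"{variant}: AUC {roc.auc:.2f} "
              f"(95% CI {roc.auc_ci_low:.2f}-{roc.auc_ci_high:.2f}), "
              f"cutoff {cut.cutoff:.0f} "
              f"(sens {cut.sensitivity:.0%}, spec {cut.specificity:.0%})")

    n_pos, n_neg, n_total = auc_sample_size(0.80, 0.90, 0.05, 9)
    blocks["design_sample_size"] = {"n_pos": n_pos, "n_neg": n_neg,
                                    "n_total": n_total}
    print(f"design sample size (AUC 0.80, power 0.90, 1-sided 5%, 1:9): "
          f"{n_pos}+{n_neg} = {n_total}")

    Path("results").mkdir(exist_ok=True)
    Path("results/evaluation.json").write_text(
        json.dumps(blocks, indent=1, sort_keys=True) + "\n")
    print("wrote results/evaluation.json")


if __name__ == "__main__":
    main()
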