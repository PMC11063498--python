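"""Composite study report: baseline cohort summary, both ROC analyses, and
the two-group comparison stratified at the RCT Youden cutoff.

Reads results/cohort/; writes results/report.json and prints the stratified
acid-base contrast (the respiratory-then-metabolic acidosis signature).

Run:  python analysis/04_report.py
"""

from pathlib import Path

from ipreface.cli import RunConfig, dump_report, run_full_analysis


def main() -> None:
    config = RunConfig(cases_path=Path("results/cohort/cases.csv"),
                       events_path=Path("results/cohort/events.csv"),
                       variant="both", outcome_threshold=7.2)
    report = run_full_analysis(config)
    dump_report(report, Path("results/report.json"))

    print(f"cohort: {report['n_cases']} cases")
    for variant in ("DCS", "RCT"):
        block = report["roc"][variant]
        print(f"{variant}: AUC {block['auc']:.2f} "
              f"(95% CI {block['auc_ci'][0]:.2f}-{block['auc_ci'][1]:.2f}), "
              f"Youden cutoff {block['youden_cutoff']['cutoff']:.0f}")
    comp = report.get("group_comparison")
    if comp:
        print(f"two groups stratified by {comp['stratified_by']}:")
        for row in comp["rows"]:
            lo, hi = row["group_summaries"]
            print(f"  {row['variable']:<28} {lo:>18} vs {hi:>18}  "
                  f"p={row['p_value']:.3g} ({row['test']})")
    print("wrote results/report.json")


if __name__ == "__main__":
    main()
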