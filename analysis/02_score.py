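"""Score the cohort: the deceleration-level sum over the 30-minute windows
ending at the cesarean decision (DCS) and at transducer removal (RCT).

Reads results/cohort/, writes results/scores.csv, and prints the per-variant
score distribution.

Run:  python analysis/02_score.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ipreface import FiveTierRuleTable, classify_level, read_cases, score_case


def main() -> None:
    table = FiveTierRuleTable.default()
    cases = read_cases("results/cohort/cases.csv", "results/cohort/events.csv")
    rows = []
    for case in cases:
        leveled = case.with_events(classify_level(e, table) for e in case.events)
        for variant in ("DCS", "RCT"):
            res = score_case(leveled, variant)
            rows.append({"case_id": case.case_id, "variant": variant,
                         "window_end_s": res.window.end_time,
                         "coverage_fraction": res.window.coverage_fraction,
                         "n_events_scored": res.n_events_scored,
                         "score": res.total})
    df = pd.DataFrame(rows)
    Path("results").mkdir(exist_ok=True)
    df.to_csv("results/scores.csv", index=False)
    for variant, sub in df.groupby("variant"):
        s = sub["score"]
        print(f"{variant}: median {s.median():.0f} "
              f"(IQR {s.quantile(.25):.0f}-{s.quantile(.75):.0f}, "
              f"range {s.min()}-{s.max()})")
    print(f"wrote {len(df)} rows to results/scores.csv")


if __name__ == "__main__":
    main()
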