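#!/usr/bin/env python
"""Group-level statistics on the detected event counts.

Mixed two-way ANOVA (group between subjects, 5-min window within subjects)
with partial eta squared, plus the per-window percent change of the treated
group relative to control, for both populations; and the cumulative-dose
arithmetic of the titrated seizure-susceptibility schedules.  Writes a tidy
summary to results/.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from catrans import (EventCountTable, cumulative_dose, mixed_anova,
                     percent_change, ptz_sst_schedule)

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def load_table(path: Path) -> EventCountTable:
    long = pd.read_csv(path)
    order = list(dict.fromkeys(long["window"]))
    wide = long.pivot(index="cell", columns="window", values="count")[order]
    gmap = long.drop_duplicates("cell").set_index("cell")["group"]
    return EventCountTable(wide.to_numpy(), list(wide.index),
                           [gmap[c] for c in wide.index], order)


def main() -> None:
    out = {}
    for pop in ("excitatory", "pv"):
        path = RESULTS / f"03_counts_{pop}.csv"
        if not path.exists():
            raise SystemExit("run analysis/03_detect_events.py first")
        table = load_table(path)
        res = mixed_anova(table)
        pc = percent_change(table, "control")
        out[pop] = {
            "F_group": res.F_group, "df": list(res.df), "p_group": res.p_value,
            "partial_eta_sq_group": res.partial_eta_sq_group,
            "partial_eta_sq_time": res.partial_eta_sq_time,
            "partial_eta_sq_interaction": res.partial_eta_sq_interaction,
            "percent_change_by_window": pc.round(1).to_dict(),
        }
        print(f"{pop}: F({res.df[0]}, {res.df[1]}) = {res.F_group:.2f}, "
              f"p = {res.p_value:.2e}, partial eta^2(group) = "
              f"{res.partial_eta_sq_group:.2f}")
        print(f"  % change vs control: "
              + ", ".join(f"{w}: {v:+.0f}%" for w, v in pc.round(0).items()))

    sched40 = ptz_sst_schedule(initial_dose=40.0)
    sched30 = ptz_sst_schedule(initial_dose=30.0)
    out["dose_examples"] = {
        "standard_arm_grade5_at_injection_3": cumulative_dose(sched40, 3),
        "standard_arm_grade5_at_injection_5": cumulative_dose(sched40, 5),
        "reduced_start_arm_grade5_at_injection_3": cumulative_dose(sched30, 3),
    }
    print("cumulative doses (mg/kg):", out["dose_examples"])

    (RESULTS / "04_group_statistics.json").write_text(json.dumps(out, indent=2))
    print(f"-> {RESULTS / '04_group_statistics.json'}")


if __name__ == "__main__":
    main()
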