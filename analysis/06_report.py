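#!/usr/bin/env python
"""Stage 6 — aggregate the calls into study-level summary tables.

Reads the stage-2 battery calls, tabulates scenarios by taxon group and
pooled groups with printed percentages, applies the two strict sensitivity
filters (>=20 tips; >=20% sampling), and writes the summary JSON whose every
percentage is recomputable from the adjacent counts.
"""

import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from neodiv.report import aggregate_counts, percent, sensitivity_filter
from neodiv.scenarios import ScenarioCall
from neodiv.simulate import SimConfig, simulate_study

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    calls_path = OUT / "battery_calls.csv"
    if not calls_path.exists():
        raise SystemExit("missing results/battery_calls.csv (run 02_fit_battery.py first)")
    calls_df = pd.read_csv(calls_path).set_index("clade_id")
    study = simulate_study(SimConfig(seed=SEED))
    records = [r for r in study.records if r.clade_id in calls_df.index]
    calls = {
        cid: ScenarioCall(row["scenario"], row["speciation_trend"], row["r_present"])
        for cid, row in calls_df.iterrows()
    }
    drivers = calls_df["driver"].to_dict()

    blocks = {}
    for name, recs in [
        ("full", records),
        ("min_tips_20", sensitivity_filter(records, "min_tips_20")),
        ("min_sampling_0.2", sensitivity_filter(records, "min_sampling_0.2")),
    ]:
        ids = {r.clade_id for r in recs}
        s = aggregate_counts({c: v for c, v in calls.items() if c in ids}, recs, drivers=drivers)
        blocks[name] = {
            "n": s.n_clades,
            "scenario_counts": s.by_scenario.to_dict(),
            "scenario_pct": {
                k: percent(int(v), s.n_clades) for k, v in s.by_scenario.items()
            },
            "driver_counts": s.by_driver.to_dict(),
            "scenario_by_pool": s.scenario_by_pool.to_dict(),
        }
    (OUT / "summary.json").write_text(json.dumps(blocks, indent=2))
    print(json.dumps(blocks, indent=2))


if __name__ == "__main__":
    main()
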