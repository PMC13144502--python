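#!/usr/bin/env python
"""Assemble the nine-facet validity scorecard for each tool.

Integrates the agreement, association, accuracy, misreporting, physiological
plausibility and stability results into one report per tool against DLW.
"""

from pathlib import Path

import pandas as pd

from nutrivalid.goldberg import classification_grid
from nutrivalid.scorecard import build_scorecard

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    participants = pd.read_csv(
        RESULTS / "synthetic" / "participants.csv"
    ).set_index("participant_id")
    intake = pd.read_csv(RESULTS / "synthetic" / "intake.csv")
    tdee = pd.read_csv(RESULTS / "dlw_results.csv").set_index(
        "participant_id"
    )["tdee_kcal_day"]
    norms = pd.read_csv(RESULTS / "energy_norms.csv")
    norms["ree_device_kcal"] = participants["ree_device_kcal"].reindex(
        norms["participant_id"]
    ).to_numpy()
    norms["pal_lifestyle"] = participants["pal_lifestyle"].reindex(
        norms["participant_id"]
    ).to_numpy()
    grid = classification_grid(norms, intake)

    for tool in sorted(intake["tool"].unique()):
        daily = intake[intake["tool"] == tool]
        tdei = daily.groupby("participant_id")["energy_kcal"].mean()
        report = build_scorecard(
            tdei=tdei,
            tdee=tdee,
            daily_intake=daily,
            ffm=participants["ffm_kg"],
            weight_change_kg=participants["weight_day8_kg"]
            - participants["weight_day1_kg"],
            goldberg_grid=grid,
            tool=tool,
        )
        out = RESULTS / f"scorecard_{tool}.csv"
        report.to_frame().to_csv(out, index=False)
        print(report.render())
        print(f"wrote {out}\n")


if __name__ == "__main__":
    main()
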