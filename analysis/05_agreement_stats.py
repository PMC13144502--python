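#!/usr/bin/env python
"""Method-comparison statistics for both tools against DLW.

Bland-Altman bias and limits of agreement, Pearson association, and the
normality-gated paired test, per tool; plus a reconstruction of the
published agreement tables from their printed summary inputs.
"""

from pathlib import Path

import pandas as pd

from nutrivalid import study
from nutrivalid.agreement import (
    bland_altman,
    paired_compare,
    pearson_assoc,
    summary_from_convention,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    intake = pd.read_csv(RESULTS / "synthetic" / "intake.csv")
    tdee = pd.read_csv(RESULTS / "dlw_results.csv").set_index(
        "participant_id"
    )["tdee_kcal_day"]

    rows = []
    for tool in sorted(intake["tool"].unique()):
        tdei = (
            intake[intake["tool"] == tool]
            .groupby("participant_id")["energy_kcal"]
            .mean()
        )
        ref = tdee.reindex(tdei.index)
        ba = bland_altman(tdei.to_numpy(), ref.to_numpy(), convention="n")
        assoc = pearson_assoc(tdei.to_numpy(), ref.to_numpy())
        test = paired_compare(tdei.to_numpy(), ref.to_numpy())
        rows.append(
            {
                "tool": tool,
                "bias": ba.bias,
                "sd_bias": ba.sd_bias,
                "se_bias": ba.se_bias,
                "loa_lower": ba.loa[0],
                "loa_upper": ba.loa[1],
                "se_loa": ba.se_loa,
                "r2": assoc["r2"],
                "signed_r2": assoc["signed_r2"],
                "test": test["test"],
                "p_adj": test["p_adj"],
            }
        )
        print(
            f"{tool} vs DLW: bias {ba.bias:+.1f} kcal/day, "
            f"LoA ({ba.loa[0]:.1f}, {ba.loa[1]:.1f}), "
            f"{test['test']} adj. p {test['p_adj']:.3g}"
        )
    pd.DataFrame(rows).to_csv(RESULTS / "agreement.csv", index=False)

    recon = []
    for name, row in study.BA_VS_DLW.items():
        rec = summary_from_convention(
            row["bias"], row["sd"], row["n"], row["convention"]
        )
        rec["pair"] = f"{name}_vs_dlw"
        recon.append(rec)
    for name, row in study.BA_APP_VS_RECALL.items():
        rec = summary_from_convention(
            row["bias"], row["sd"], row["n"], row["convention"]
        )
        rec["pair"] = f"app_vs_recall_{name}"
        recon.append(rec)
    pd.DataFrame(recon).to_csv(
        RESULTS / "published_reconstruction.csv", index=False
    )
    print(
        "published-summary reconstruction: "
        f"{len(recon)} rows -> {RESULTS / 'published_reconstruction.csv'}"
    )


if __name__ == "__main__":
    main()
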