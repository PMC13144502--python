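#!/usr/bin/env python
"""Energy-requirement norms and the three PAL variants.

Devine IBW, adjusted body weight, Mifflin-St Jeor and Harris-Benedict BMR
on ABW, and PAL as TDEE/aBMR, TDEE/REE, and the lifestyle input column.
"""

from pathlib import Path

import pandas as pd

from nutrivalid.energy import compute_energy_norms

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    participants = pd.read_csv(RESULTS / "synthetic" / "participants.csv")
    tdee = pd.read_csv(RESULTS / "dlw_results.csv").set_index(
        "participant_id"
    )["tdee_kcal_day"]

    norms = compute_energy_norms(participants, tdee=tdee)
    norms.to_csv(RESULTS / "energy_norms.csv", index=False)

    print(f"IBW {norms['ibw_kg'].mean():.1f} kg, ABW {norms['abw_kg'].mean():.1f} kg")
    print(
        f"aBMR (MSJ on ABW) {norms['abmr_kcal'].mean():.1f} +/- "
        f"{norms['abmr_kcal'].std():.1f} kcal/day (published cohort: 1449.6 +/- 114.9)"
    )
    print(f"HB on ABW {norms['bmr_hb_kcal'].mean():.1f} kcal/day")
    print(
        "PAL: TDEE/aBMR "
        f"{norms['pal_dlw_abmr'].mean():.3f}, TDEE/REE "
        f"{norms['pal_dlw_ree'].mean():.3f}, lifestyle "
        f"{norms['pal_lifestyle'].mean():.3f}"
    )
    print(f"wrote {RESULTS / 'energy_norms.csv'}")


if __name__ == "__main__":
    main()
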