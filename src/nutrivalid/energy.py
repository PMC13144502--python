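"""Energy-requirement prediction and physical activity level (PAL).

For adult females with obesity, basal metabolic rate predicted on actual
body weight overestimates true requirements because adipose tissue is less
metabolically active than lean tissue. The pipeline therefore predicts BMR
on an adjusted body weight (ABW) interpolated between the Devine ideal body
weight (IBW) and the actual weight:

    IBW = 50 + 2.3 * ((height_cm - 152.4) / 2.54)      [kg, females]
    ABW = IBW + 0.3 * (weight - IBW)

BMR comes from the Mifflin-St Jeor (default) or Harris-Benedict female
equations evaluated at ABW ("aBMR"). PAL is then estimated three ways:
TDEE/aBMR, TDEE/REE (device-measured resting energy expenditure), and a
self-reported lifestyle value carried through as an input column.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "ibw_devine",
    "adjusted_body_weight",
    "bmr_mifflin_female",
    "bmr_harris_benedict_female",
    "pal_set",
    "compute_energy_norms",
]

# revised classic Harris-Benedict female coefficients
HB_FEMALE = {"const": 655.0955, "weight": 9.5634, "height": 1.8496, "age": 4.6756}


def ibw_devine(height_m: float) -> float:
    """Devine ideal body weight (kg) for adult females from height in metres."""
    if height_m <= 0:
        raise ValueError(f"height must be positive, got {height_m}")
    return 50.0 + 2.3 * ((height_m * 100.0 - 152.4) / 2.54)


def adjusted_body_weight(weight_kg: float, ibw_kg: float) -> float:
    """ABW = IBW + 0.3*(weight - IBW); applied unchanged when weight < IBW."""
    if weight_kg <= 0 or ibw_kg <= 0:
        raise ValueError("weight and IBW must be positive")
    if weight_kg < ibw_kg:
        warnings.warn(
            f"weight {weight_kg:.1f} kg below IBW {ibw_kg:.1f} kg; "
            "adjusted body weight falls below IBW",
            stacklevel=2,
        )
    return ibw_kg + 0.3 * (weight_kg - ibw_kg)


def bmr_mifflin_female(weight_kg: float, height_cm: float, age_y: float) -> float:
    """Mifflin-St Jeor BMR (kcal/day), female form: 10W + 6.25H - 5A - 161.

    Pass the adjusted body weight as ``weight_kg`` to obtain aBMR.
    """
    if weight_kg <= 0 or height_cm <= 0 or age_y < 0:
        warnings.warn("Mifflin-St Jeor evaluated outside its domain", stacklevel=2)
    return 10.0 * weight_kg + 6.25 * height_cm - 5.0 * age_y - 161.0


def bmr_harris_benedict_female(
    weight_kg: float, height_cm: float, age_y: float
) -> float:
    """Revised classic Harris-Benedict BMR (kcal/day), female coefficients."""
    if weight_kg <= 0 or height_cm <= 0 or age_y < 0:
        warnings.warn("Harris-Benedict evaluated outside its domain", stacklevel=2)
    c = HB_FEMALE
    return (
        c["const"]
        + c["weight"] * weight_kg
        + c["height"] * height_cm
        - c["age"] * age_y
    )


def pal_set(
    tdee_kcal: float,
    abmr_kcal: float,
    ree_device_kcal: float | None = None,
    pal_lifestyle: float | None = None,
) -> dict[str, float]:
    """The three PAL variants for one participant.

    Returns a dict with keys ``pal_dlw_abmr`` (TDEE/aBMR), ``pal_dlw_ree``
    (TDEE/device REE) and ``pal_lifestyle``. A missing REE or lifestyle input
    yields NaN for the corresponding variant rather than a default.
    """
    if abmr_kcal <= 0:
        raise ValueError(f"aBMR must be positive, got {abmr_kcal}")
    out = {"pal_dlw_abmr": tdee_kcal / abmr_kcal}
    if ree_device_kcal is not None and not math.isnan(ree_device_kcal):
        if ree_device_kcal <= 0:
            raise ValueError(f"device REE must be positive, got {ree_device_kcal}")
        out["pal_dlw_ree"] = tdee_kcal / ree_device_kcal
    else:
        out["pal_dlw_ree"] = float("nan")
    out["pal_lifestyle"] = (
        float(pal_lifestyle) if pal_lifestyle is not None else float("nan")
    )
    return out


def compute_energy_norms(
    participants: pd.DataFrame,
    tdee: pd.Series | None = None,
    abmr_variant: str = "mifflin",
) -> pd.DataFrame:
    """Per-participant energy norms keyed by participant id.

    Parameters
    ----------
    participants : table with columns participant_id, age_y, height_m,
        weight_day1_kg and optionally ree_device_kcal, pal_lifestyle.
    tdee : optional Series of DLW TDEE (kcal/day) indexed by participant_id;
        when given, the three PAL columns are filled.
    abmr_variant : which equation on ABW defines aBMR, 'mifflin' (default)
        or 'harris_benedict'.
    """
    if abmr_variant not in ("mifflin", "harris_benedict"):
        raise ValueError(f"unknown aBMR variant {abmr_variant!r}")
    rows = []
    for _, p in participants.iterrows():
        ibw = ibw_devine(float(p["height_m"]))
        abw = adjusted_body_weight(float(p["weight_day1_kg"]), ibw)
        h_cm = float(p["height_m"]) * 100.0
        age = float(p["age_y"])
        msj = bmr_mifflin_female(abw, h_cm, age)
        hb = bmr_harris_benedict_female(abw, h_cm, age)
        abmr = msj if abmr_variant == "mifflin" else hb
        row = {
            "participant_id": p["participant_id"],
            "ibw_kg": ibw,
            "abw_kg": abw,
            "bmr_msj_kcal": msj,
            "bmr_hb_kcal": hb,
            "abmr_kcal": abmr,
        }
        if tdee is not None:
            t = float(tdee.loc[p["participant_id"]])
            pals = pal_set(
                t,
                abmr,
                float(p["ree_device_kcal"])
                if "ree_device_kcal" in p.index and pd.notna(p["ree_device_kcal"])
                else None,
                float(p["pal_lifestyle"])
                if "pal_lifestyle" in p.index and pd.notna(p["pal_lifestyle"])
                else None,
            )
            row["tdee_kcal"] = t
            row.update(pals)
        rows.append(row)
    out = pd.DataFrame(rows)
    return out
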