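"""Published summary statistics of the emulated validation study.

The synthetic cohort generator emulates a 7-day free-living validation of
an image-based dietary assessment app and a 24-h recall against doubly
labelled water in n=20 adult females with obesity. Only summary statistics
of that study are public (individual data live in its supplement); the
summaries below are the inputs to the pipeline's summary-arithmetic
recomputations (limits of agreement and standard errors from printed bias
and SD, unit conversions, Goldberg bound reconstruction) and the moments
the generator targets.

Each Bland-Altman entry carries the printed bias and SD of the paired
differences (first method minus reference), the pair count, the divisor
convention that reproduces the printed standard errors (the published
tables mix n and n-1), and the printed SEs and limits for comparison.
"""

from __future__ import annotations

#: cohort anthropometrics: mean and SD
COHORT = {
    "n": 20,
    "age_y": (37.9, 13.4),
    "height_m": (1.66, 0.06),
    "weight_kg": (108.4, 16.3),
    "bmi_kg_m2": (39.3, 5.4),
    "bmr_kcal": (1449.6, 114.9),
}

#: group energy estimates, kcal/day and kJ/day: mean and SD per method
ENERGY_KCAL = {
    "app": (2187.0, 1400.8),
    "recall": (1464.0, 554.1),
    "dlw": (3004.2, 480.5),
}
ENERGY_KJ = {
    "app": (9150.44, 5861.1),
    "recall": (6125.2, 2318.3),
    "dlw": (12569.7, 2010.4),
}

#: DLW quality-control ratios: mean and SD
QC_RATIOS = {"nd_no": (1.0398, 0.0067), "turnover": (1.3207, 0.0598)}

#: Bland-Altman summaries vs DLW (tool minus reference), kcal/day
BA_VS_DLW = {
    "app": {
        "bias": -817.3,
        "sd": 1474.5,
        "n": 20,
        "convention": "n",
        "se_bias": 329.7,
        "se_loa": 571.1,
        "loa": (-3707.3, 2072.8),
        "ci_bias": (-1507.3, -127.1),
    },
    "recall": {
        "bias": -1479.5,
        "sd": 635.5,
        "n": 20,
        "convention": "n-1",
        "se_bias": 145.8,
        "se_loa": 252.5,
        "loa": (-2725.0, -234.0),
        "ci_bias": (-1785.8, -1173.2),
    },
}

#: Bland-Altman summaries, app minus recall, by quantity
BA_APP_VS_RECALL = {
    "energy_kcal": {
        "bias": 641.7,
        "sd": 1358.9,
        "n": 20,
        "convention": "n-1",
        "se_bias": 311.8,
        "se_loa": 540.0,
        "loa": (-2021.7, 3305.1),
    },
    "energy_kj": {
        "bias": 2684.8,
        "sd": 5685.7,
        "n": 20,
        "convention": "n-1",
        "se_bias": 1304.4,
        "se_loa": 2259.3,
        "loa": (-8458.9, 13828.5),
        # entries derived from unrounded kcal values; wider print tolerance
        "unit_scale": 4.184,
    },
    "carb_g": {
        "bias": 60.8, "sd": 141.4, "n": 20, "convention": "n-1",
        "se_bias": 32.4, "se_loa": 56.2, "loa": (-216.3, 338.0),
    },
    "sugar_g": {
        "bias": 38.9, "sd": 106.6, "n": 20, "convention": "n-1",
        "se_bias": 24.5, "se_loa": 42.4, "loa": (-170.2, 247.9),
    },
    "fat_g": {
        "bias": 37.7, "sd": 83.8, "n": 20, "convention": "n-1",
        "se_bias": 19.2, "se_loa": 33.3, "loa": (-126.5, 201.9),
    },
    "satfat_g": {
        "bias": 21.6, "sd": 58.1, "n": 20, "convention": "n-1",
        "se_bias": 13.3, "se_loa": 23.1, "loa": (-92.3, 135.5),
    },
    "protein_g": {
        "bias": 8.0, "sd": 46.9, "n": 20, "convention": "n-1",
        "se_bias": 10.8, "se_loa": 18.6, "loa": (-83.9, 99.9),
    },
    "fibre_g": {
        "bias": 7.7, "sd": 16.4, "n": 20, "convention": "n-1",
        "se_bias": 3.8, "se_loa": 6.5, "loa": (-24.5, 39.8),
    },
    "occasions": {
        "bias": 2.1, "sd": 2.0, "n": 20, "convention": "n-1",
        "se_bias": 0.5, "se_loa": 0.8, "loa": (-1.9, 6.0),
    },
}

#: Goldberg classification of the best-performing grid cell
GOLDBERG = {
    "s_pct": 40.01,
    "cv_w_tdei_pct": 88.36,
    "cv_t_p_pct": 16.8,
    "n_for_bounds": 19,
    # geometric midpoint of the printed interval (mean PAL is not printed)
    "pal_ref": 2.081,
    "interval": (1.74, 2.49),
}

#: day-to-day stability of app-reported intake
ICC_STABILITY = {"icc": 0.00, "ci": (-0.083, 0.168)}
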