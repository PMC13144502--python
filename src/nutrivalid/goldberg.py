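"""Goldberg cut-off classification of dietary misreporting.

A participant's ratio of reported energy intake to an energy-requirement
denominator (aBMR or device REE) is compared against log-scale plausibility
bounds around a reference PAL:

    lower, upper = pal_ref * exp(-+ z * (S/100) / sqrt(n))

where the composite variability factor S pools the within-person CV of
reported intake over d assessment days, the within-person CV of the
requirement denominator, and the between-person CV of PAL:

    S = sqrt(cv_wTDEI^2 / d + cv_wB^2 + cv_tP^2)   [%]

Ratios below the lower bound are under-reports, above the upper bound
over-reports, otherwise plausible; ties at a bound count as plausible
(conservative toward accurate reporting). The classification is run over a
grid of denominator x PAL-variant x S-variant cells, and the cell with the
most plausible reporters is highlighted, mirroring common practice.

Black's generalised parameters for adult females (cv_wTDEI 26%, cv_tP
14.9%, cv_wB 8.5%) are the default alternative to study-specific CVs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "VariabilityParams",
    "BLACK_FEMALE_DEFAULTS",
    "s_factor",
    "goldberg_bounds",
    "classify",
    "study_variability",
    "classification_grid",
]


@dataclass(frozen=True)
class VariabilityParams:
    """Components of the Goldberg variability factor S.

    cv_w_tdei_pct : within-person CV of reported daily intake, %.
    cv_w_b_pct : within-person CV of the BMR/REE denominator, %.
    cv_t_p_pct : between-person CV of PAL, %.
    d_days : number of diet-assessment days.
    z : normal quantile for the confidence band (default 1.96).
    """

    cv_w_tdei_pct: float
    cv_w_b_pct: float
    cv_t_p_pct: float
    d_days: int = 7
    z: float = 1.96

    def __post_init__(self) -> None:
        if min(self.cv_w_tdei_pct, self.cv_w_b_pct, self.cv_t_p_pct) < 0:
            raise ValueError("all CVs must be non-negative")
        if self.d_days < 1:
            raise ValueError(f"d_days must be >= 1, got {self.d_days}")
        if self.z <= 0:
            raise ValueError(f"z must be positive, got {self.z}")


#: Black's recommended components for adult females
BLACK_FEMALE_DEFAULTS = VariabilityParams(
    cv_w_tdei_pct=26.0, cv_w_b_pct=8.5, cv_t_p_pct=14.9, d_days=7
)


def s_factor(v: VariabilityParams) -> float:
    """Composite variability factor S in % (Black's composition)."""
    return float(
        np.sqrt(
            v.cv_w_tdei_pct**2 / v.d_days + v.cv_w_b_pct**2 + v.cv_t_p_pct**2
        )
    )


def goldberg_bounds(
    pal_ref: float, s_pct: float, n: int, z: float = 1.96
) -> tuple[float, float]:
    """Log-scale symmetric plausibility bounds around the reference PAL."""
    if pal_ref <= 0:
        raise ValueError(f"reference PAL must be positive, got {pal_ref}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    half_width = z * (s_pct / 100.0) / np.sqrt(n)
    return (pal_ref * np.exp(-half_width), pal_ref * np.exp(half_width))


def classify(ei_ratio: float, bounds: tuple[float, float]) -> str:
    """'under' | 'plausible' | 'over'; ties at a bound are plausible."""
    if np.isnan(ei_ratio):
        return "unclassifiable"
    if ei_ratio <= 0:
        raise ValueError(f"intake ratio must be positive, got {ei_ratio}")
    lower, upper = bounds
    if ei_ratio < lower:
        return "under"
    if ei_ratio > upper:
        return "over"
    return "plausible"


def study_variability(
    intake: pd.DataFrame, pal: pd.Series, d_days: int | None = None,
    cv_w_b_pct: float = 8.5, z: float = 1.96,
) -> VariabilityParams:
    """Study-specific variability components from the data.

    cv_wTDEI is the pooled within-person CV of daily intake (root mean
    within-person variance over the grand mean); cv_tP is the
    between-person CV of the supplied PAL series. cv_wB keeps Black's
    literature value by default since the denominator is measured once.

    Parameters
    ----------
    intake : daily rows for one tool with participant_id, day, energy_kcal.
    pal : per-participant PAL values.
    """
    per = intake.groupby("participant_id")["energy_kcal"]
    within_var = per.var(ddof=1).mean()
    grand_mean = intake["energy_kcal"].mean()
    cv_w = 100.0 * np.sqrt(within_var) / grand_mean
    cv_tp = 100.0 * pal.std(ddof=1) / pal.mean()
    if d_days is None:
        d_days = int(intake.groupby("participant_id")["day"].nunique().median())
    return VariabilityParams(
        cv_w_tdei_pct=float(cv_w),
        cv_w_b_pct=cv_w_b_pct,
        cv_t_p_pct=float(cv_tp),
        d_days=d_days,
        z=z,
    )


def classify_cohort(
    tdei: pd.Series,
    denominator: pd.Series,
    pal_ref: float,
    s_pct: float,
    n_for_bounds: int | None = None,
    z: float = 1.96,
) -> pd.DataFrame:
    """Classify each participant's mean reported intake.

    tdei and denominator are aligned per-participant Series (kcal/day).
    Participants with a missing denominator are labelled unclassifiable.
    """
    ratio = tdei / denominator
    classifiable = int(ratio.notna().sum())
    n = n_for_bounds if n_for_bounds is not None else classifiable
    bounds = goldberg_bounds(pal_ref, s_pct, max(n, 1), z)
    labels = ratio.apply(lambda r: classify(r, bounds))
    return pd.DataFrame(
        {
            "participant_id": tdei.index,
            "ei_ratio": ratio.values,
            "lower_cut": bounds[0],
            "upper_cut": bounds[1],
            "label": labels.values,
        }
    )


def classification_grid(
    norms: pd.DataFrame,
    intake: pd.DataFrame,
    tools: tuple[str, ...] | None = None,
    n_for_bounds: int | None = None,
    cv_w_b_pct: float = 8.5,
    z: float = 1.96,
) -> pd.DataFrame:
    """Misreporting counts over the method grid.

    Grid axes: denominator in {abmr, ree} x PAL variant in {dlw_abmr,
    dlw_ree, lifestyle} x S variant in {study, black} x tool. Cells whose
    PAL or denominator column is entirely missing are skipped. Returns a
    tidy table of counts with a ``best`` flag on the cell(s) maximising
    plausible reporters per tool.

    Parameters
    ----------
    norms : per-participant table with participant_id, abmr_kcal,
        ree_device_kcal, pal_dlw_abmr, pal_dlw_ree, pal_lifestyle.
    intake : daily intake rows with tool, participant_id, day, energy_kcal.
    """
    if tools is None:
        tools = tuple(sorted(intake["tool"].unique()))
    norms = norms.set_index("participant_id")
    denom_cols = {"abmr": "abmr_kcal", "ree": "ree_device_kcal"}
    pal_cols = {
        "dlw_abmr": "pal_dlw_abmr",
        "dlw_ree": "pal_dlw_ree",
        "lifestyle": "pal_lifestyle",
    }
    rows = []
    for tool in tools:
        tool_daily = intake[intake["tool"] == tool]
        tdei = tool_daily.groupby("participant_id")["energy_kcal"].mean()
        tdei = tdei.reindex(norms.index)
        for den_name, den_col in denom_cols.items():
            if den_col not in norms.columns or norms[den_col].isna().all():
                continue
            for pal_name, pal_col in pal_cols.items():
                if pal_col not in norms.columns or norms[pal_col].isna().all():
                    continue
                pal_series = norms[pal_col].dropna()
                pal_ref = float(pal_series.mean())
                for s_mode in ("study", "black"):
                    if s_mode == "study":
                        v = study_variability(
                            tool_daily, pal_series, cv_w_b_pct=cv_w_b_pct, z=z
                        )
                    else:
                        v = VariabilityParams(
                            cv_w_tdei_pct=BLACK_FEMALE_DEFAULTS.cv_w_tdei_pct,
                            cv_w_b_pct=BLACK_FEMALE_DEFAULTS.cv_w_b_pct,
                            cv_t_p_pct=BLACK_FEMALE_DEFAULTS.cv_t_p_pct,
                            d_days=int(
                                tool_daily.groupby("participant_id")["day"]
                                .nunique()
                                .median()
                            ),
                            z=z,
                        )
                    s = s_factor(v)
                    labels = classify_cohort(
                        tdei,
                        norms[den_col],
                        pal_ref,
                        s,
                        n_for_bounds=n_for_bounds,
                        z=z,
                    )
                    counts = labels["label"].value_counts()
                    rows.append(
                        {
                            "tool": tool,
                            "denominator": den_name,
                            "pal_variant": pal_name,
                            "s_mode": s_mode,
                            "s_pct": s,
                            "pal_ref": pal_ref,
                            "lower_cut": float(labels["lower_cut"].iloc[0]),
                            "upper_cut": float(labels["upper_cut"].iloc[0]),
                            "n_under": int(counts.get("under", 0)),
                            "n_plausible": int(counts.get("plausible", 0)),
                            "n_over": int(counts.get("over", 0)),
                            "n_unclassifiable": int(
                                counts.get("unclassifiable", 0)
                            ),
                        }
                    )
    grid = pd.DataFrame(rows)
    if grid.empty:
        return grid
    best = grid.groupby("tool")["n_plausible"].transform("max")
    grid["best"] = grid["n_plausible"] == best
    return grid
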