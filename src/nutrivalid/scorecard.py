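"""Nine-facet comprehensive validity scorecard.

Assembles, for one dietary assessment tool against a reference method, the
nine complementary validity facets used to benchmark novel dietary
assessment tools:

1. agreement            Bland-Altman bias, CI and limits of agreement
2. strength             signed r-squared of TDEI vs reference TDEE, with p
3. accuracy             mean +/- SD absolute difference, mean percentage
                        difference (mean of per-participant ratios), adj. p
4. misreporting size    mean over- and under-estimation (kcal/day and %)
5. misreporting class   Goldberg plausible/over/under counts
6. homoeostatic control signed r-squared of TDEI vs fat-free mass
7. energy balance       signed r-squared of TDEI vs energy-storage change
8. compliance           signed r-squared of (TDEI - TDEE) vs weight change
9. diet stability       day-to-day ICC of reported intake

Percentage differences are means of per-participant percentages, not the
ratio of cohort means; facet 4's percentages are means of the individual
percentage differences within the over/under subset. Energy-storage change
(facet 7) is the week's weight change times a configurable energy density
of tissue (default 7700 kcal/kg), expressed per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import agreement as agr
from . import goldberg as gb

__all__ = [
    "ValidityReport",
    "percentage_difference",
    "misreport_magnitudes",
    "build_scorecard",
]

#: energy density of body-tissue change, kcal per kg
TISSUE_ENERGY_DENSITY_KCAL_PER_KG = 7700.0

#: sentinel used when one misreporting side has no participants
NO_OVERESTIMATION = "no overestimation"
NO_UNDERESTIMATION = "no underestimation"


def percentage_difference(
    tdei: np.ndarray, tdee: np.ndarray
) -> tuple[float, float]:
    """Mean and SD over participants of 100*(tdei_i - tdee_i)/tdee_i."""
    tdei = np.asarray(tdei, dtype=float)
    tdee = np.asarray(tdee, dtype=float)
    if np.any(tdee <= 0):
        raise ValueError("reference TDEE must be positive for all participants")
    pct = 100.0 * (tdei - tdee) / tdee
    sd = float(pct.std(ddof=1)) if pct.size > 1 else 0.0
    return float(pct.mean()), sd


def misreport_magnitudes(
    diffs: np.ndarray, tdee: np.ndarray
) -> dict[str, Any]:
    """Mean over- and under-estimation, each over its own participant subset.

    Returns kcal/day means of the positive and negative differences and the
    mean per-participant percentage difference within each subset. An empty
    side carries the sentinel string instead of a number.
    """
    diffs = np.asarray(diffs, dtype=float)
    tdee = np.asarray(tdee, dtype=float)
    if diffs.size == 0:
        raise ValueError("misreport magnitudes need at least one participant")
    pct = 100.0 * diffs / tdee
    over = diffs > 0
    under = diffs < 0
    out: dict[str, Any] = {}
    if over.any():
        out["over_kcal"] = float(diffs[over].mean())
        out["over_pct"] = float(pct[over].mean())
    else:
        out["over_kcal"] = NO_OVERESTIMATION
        out["over_pct"] = NO_OVERESTIMATION
    if under.any():
        out["under_kcal"] = float(diffs[under].mean())
        out["under_pct"] = float(pct[under].mean())
    else:
        out["under_kcal"] = NO_UNDERESTIMATION
        out["under_pct"] = NO_UNDERESTIMATION
    if not over.any() and not under.any():
        # all differences exactly zero
        out = {"over_kcal": 0.0, "over_pct": 0.0, "under_kcal": 0.0, "under_pct": 0.0}
    return out


@dataclass
class ValidityReport:
    """Nine-facet scorecard for one tool against one reference method."""

    tool: str
    reference: str
    facets: dict[str, dict[str, Any]] = field(default_factory=dict)

    FACET_NAMES = (
        "agreement",
        "strength",
        "accuracy",
        "misreporting_magnitude",
        "misreporting_goldberg",
        "homoeostatic_control",
        "energy_balance",
        "compliance",
        "diet_stability",
    )

    def to_frame(self) -> pd.DataFrame:
        """Long-format (facet, metric, value) table."""
        rows = []
        for facet, metrics in self.facets.items():
            for metric, value in metrics.items():
                rows.append(
                    {
                        "tool": self.tool,
                        "reference": self.reference,
                        "facet": facet,
                        "metric": metric,
                        "value": value,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ValidityReport":
        """Inverse of :meth:`to_frame` (CSV round-trip)."""
        tool = str(frame["tool"].iloc[0])
        reference = str(frame["reference"].iloc[0])
        facets: dict[str, dict[str, Any]] = {}
        for _, row in frame.iterrows():
            value = row["value"]
            if isinstance(value, str):
                try:
                    value = float(value)
                except ValueError:
                    pass
            facets.setdefault(str(row["facet"]), {})[str(row["metric"])] = value
        return cls(tool=tool, reference=reference, facets=facets)

    def render(self) -> str:
        """Human-readable scorecard."""
        lines = [f"Validity of {self.tool} against {self.reference}", "=" * 60]
        for i, facet in enumerate(self.FACET_NAMES, start=1):
            metrics = self.facets.get(facet)
            lines.append(f"({i}) {facet.replace('_', ' ')}")
            if metrics is None:
                lines.append("    not computable")
                continue
            for metric, value in metrics.items():
                if isinstance(value, float):
                    lines.append(f"    {metric}: {value:.4g}")
                else:
                    lines.append(f"    {metric}: {value}")
        return "\n".join(lines)


def _signed_assoc(x: np.ndarray, y: np.ndarray, bonferroni_k: int) -> dict[str, float]:
    res = agr.pearson_assoc(x, y)
    p = res["p"]
    return {
        "signed_r2": res["signed_r2"],
        "p_adj": min(1.0, bonferroni_k * p) if not math.isnan(p) else p,
    }


def build_scorecard(
    tdei: pd.Series,
    tdee: pd.Series,
    daily_intake: pd.DataFrame | None = None,
    ffm: pd.Series | None = None,
    weight_change_kg: pd.Series | None = None,
    goldberg_grid: pd.DataFrame | None = None,
    tool: str = "tool",
    reference: str = "DLW",
    ba_convention: str = "n",
    bonferroni_k: int = 3,
    tissue_energy_density: float = TISSUE_ENERGY_DENSITY_KCAL_PER_KG,
    study_days: int = 7,
) -> ValidityReport:
    """Assemble the nine facets for one tool.

    Parameters
    ----------
    tdei, tdee : per-participant mean reported intake and reference
        expenditure (kcal/day), aligned by participant id.
    daily_intake : day-level rows for this tool (participant_id, day,
        energy_kcal) for the stability ICC; omitted -> facet 9 not computed.
    ffm : fat-free mass (kg) per participant for facet 6.
    weight_change_kg : day-8 minus day-1 body weight for facets 7-8.
    goldberg_grid : output of :func:`nutrivalid.goldberg.classification_grid`;
        the best cell for this tool provides facet 5.
    """
    tdei, tdee = tdei.align(tdee, join="inner")
    a = tdei.to_numpy(dtype=float)
    b = tdee.to_numpy(dtype=float)
    report = ValidityReport(tool=tool, reference=reference)

    ba = agr.bland_altman(a, b, convention=ba_convention)
    report.facets["agreement"] = {
        "bias_kcal": ba.bias,
        "ci_lower": ba.ci_bias[0],
        "ci_upper": ba.ci_bias[1],
        "sd_bias": ba.sd_bias,
        "se_bias": ba.se_bias,
        "loa_lower": ba.loa[0],
        "loa_upper": ba.loa[1],
        "se_loa": ba.se_loa,
    }

    report.facets["strength"] = _signed_assoc(a, b, bonferroni_k)

    diffs = a - b
    pct_mean, pct_sd = percentage_difference(a, b)
    comp = agr.paired_compare(a, b, bonferroni_k=bonferroni_k)
    report.facets["accuracy"] = {
        "mean_diff_kcal": float(diffs.mean()),
        "sd_diff_kcal": float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0,
        "mean_pct_diff": pct_mean,
        "sd_pct_diff": pct_sd,
        "test": comp["test"],
        "p_adj": comp["p_adj"],
    }

    report.facets["misreporting_magnitude"] = misreport_magnitudes(diffs, b)

    if goldberg_grid is not None and not goldberg_grid.empty:
        cell = goldberg_grid[
            (goldberg_grid["tool"] == tool) & goldberg_grid["best"]
        ]
        if not cell.empty:
            cell = cell.iloc[0]
            report.facets["misreporting_goldberg"] = {
                "n_plausible": int(cell["n_plausible"]),
                "n_over": int(cell["n_over"]),
                "n_under": int(cell["n_under"]),
                "denominator": cell["denominator"],
                "pal_variant": cell["pal_variant"],
                "s_mode": cell["s_mode"],
                "s_pct": float(cell["s_pct"]),
            }

    if ffm is not None:
        ffm_aligned = ffm.reindex(tdei.index)
        report.facets["homoeostatic_control"] = _signed_assoc(
            a, ffm_aligned.to_numpy(dtype=float), bonferroni_k
        )

    if weight_change_kg is not None:
        dw = weight_change_kg.reindex(tdei.index).to_numpy(dtype=float)
        storage_kcal_day = dw * tissue_energy_density / study_days
        report.facets["energy_balance"] = _signed_assoc(
            a, storage_kcal_day, bonferroni_k
        )
        report.facets["compliance"] = _signed_assoc(diffs, dw, bonferroni_k)

    if daily_intake is not None:
        matrix = daily_intake.pivot_table(
            index="participant_id", columns="day", values="energy_kcal"
        )
        try:
            icc = agr.icc_two_way_random(matrix)
            report.facets["diet_stability"] = {
                "icc": icc.icc,
                "ci_lower": icc.ci[0],
                "ci_upper": icc.ci[1],
                "model": icc.model,
            }
        except ValueError:
            pass

    return report
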