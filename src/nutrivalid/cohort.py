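"""Seeded synthetic cohorts for the validation pipeline.

Emulates the data structure of a free-living DLW validation study in adult
females with obesity: anthropometrics and body composition, a two-point
urine isotope series per participant, and daily reported energy intake from
two dietary assessment tools (an image-based app and a 24-h recall), each
with its own systematic reporting bias and within/between-person noise.

The generator is the inverse of the analysis: isotope decay curves are
constructed by inverting the rCO2 and Weir equations at each participant's
true TDEE, so that at zero noise the DLW engine recovers the truth to
numerical precision. That forward-inverse identity anchors every recovery
test downstream.

Default parameter values are the study conditions being emulated (cohort
moments, reporting biases of -25% app-like and -50% recall-like, dilution
and elimination-rate ratios); see docs/methods.md for what is and is not
calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .dlw import DLWConfig, NATURAL_ABUNDANCE, WATER_MOLAR_MASS, tdee_weir

__all__ = [
    "ToolParams",
    "CohortParams",
    "generate_participants",
    "simulate_isotope_series",
    "simulate_reported_intake",
    "generate_cohort_bundle",
    "CohortBundle",
]


@dataclass(frozen=True)
class ToolParams:
    """Phenomenological reporting model of one dietary assessment tool.

    bias_frac : mean fractional reporting error (negative = underreporting).
    cv_within_pct : day-to-day within-person CV of reported intake, %.
    cv_between_pct : between-person CV of the person-level reporting factor, %.
    mean_occasions : Poisson mean of daily eating occasions.
    """

    name: str
    bias_frac: float
    cv_within_pct: float
    cv_between_pct: float
    mean_occasions: float


# app-like tool: bias and within-person CV at the study's reported values;
# recall-like tool: larger bias, tighter day-to-day spread
DEFAULT_TOOLS = (
    ToolParams("app", -0.25, 88.36, 50.0, 5.1),
    ToolParams("recall", -0.50, 30.0, 30.0, 3.0),
)


@dataclass(frozen=True)
class CohortParams:
    """Study conditions for the synthetic cohort.

    Anthropometric and TDEE moments default to the emulated cohort of n=20
    adult females with obesity. Normal draws are truncated at 2 SD below the
    mean (no upper bound) to avoid non-physiologic values.
    """

    n_participants: int = 20
    seed: int = 0
    weight_mean_kg: float = 108.4
    weight_sd_kg: float = 16.3
    height_mean_m: float = 1.66
    height_sd_m: float = 0.06
    age_mean_y: float = 37.9
    age_sd_y: float = 13.4
    tdee_mean_kcal: float = 3004.2
    tdee_sd_kcal: float = 480.5
    body_fat_frac_mean: float = 0.48
    body_fat_frac_sd: float = 0.04
    hydration_const: float = 0.732  # TBW = hydration_const * FFM
    n_days: int = 7
    rq: float = 0.85
    isotope_noise_sd_ppm: float = 0.3
    ndno_mean: float = 1.0398
    ndno_sd: float = 0.0067
    ko_kd_ratio: float = 1.3207  # water/CO2 turnover ratio k_O/k_d
    tools: tuple[ToolParams, ...] = DEFAULT_TOOLS
    macro_fracs: tuple[float, float, float] = (0.45, 0.35, 0.20)  # carb/fat/protein

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError(
                f"need at least 2 participants, got {self.n_participants}"
            )
        for name in (
            "weight_sd_kg",
            "height_sd_m",
            "age_sd_y",
            "tdee_sd_kcal",
            "body_fat_frac_sd",
            "ndno_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_days < 1:
            raise ValueError(f"n_days must be >= 1, got {self.n_days}")
        if not 0.7 <= self.rq <= 1.0:
            raise ValueError(f"RQ must lie in [0.7, 1.0], got {self.rq}")
        if self.isotope_noise_sd_ppm < 0:
            raise ValueError("isotope_noise_sd_ppm must be non-negative")

    def with_(self, **kwargs) -> "CohortParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class CohortBundle:
    """All tables of one synthetic cohort, plus the generating truth."""

    participants: pd.DataFrame
    truth: pd.DataFrame
    isotope_samples: pd.DataFrame
    doses: pd.DataFrame
    intake: pd.DataFrame
    params: CohortParams = field(repr=False, default=None)


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal truncated at [mean - 2*sd, inf); degenerate sd returns means."""
    if sd == 0:
        return np.full(size, mean, dtype=float)
    return stats.truncnorm.rvs(-2.0, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_unit_mean(
    rng: np.random.Generator, cv_pct: float, size
) -> np.ndarray:
    """Multiplicative lognormal factor with mean 1 and the given CV (%)."""
    cv = cv_pct / 100.0
    if cv == 0:
        return np.ones(size, dtype=float)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def generate_participants(
    params: CohortParams,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the cohort's anthropometrics and latent truth.

    Returns ``(participants, truth)``. ``participants`` mirrors the study's
    anthropometrics sheet (id, age, height, weight day 1 and day 8, FM, FFM,
    device REE, lifestyle PAL, smoking/activity labels). ``truth`` carries
    the generating quantities (true TDEE, TBW, body-composition) used by the
    isotope and intake simulators and by recovery tests.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    ids = [f"P{i + 1:03d}" for i in range(n)]
    age = _trunc_normal(rng, params.age_mean_y, params.age_sd_y, n)
    # adults only: clip at 18 y (cohort inclusion criterion)
    age = np.maximum(age, 18.0)
    height = _trunc_normal(rng, params.height_mean_m, params.height_sd_m, n)
    weight = _trunc_normal(rng, params.weight_mean_kg, params.weight_sd_kg, n)
    fat_frac = np.clip(
        _trunc_normal(rng, params.body_fat_frac_mean, params.body_fat_frac_sd, n),
        0.15,
        0.60,
    )
    fm = fat_frac * weight
    ffm = weight - fm
    tbw = params.hydration_const * ffm
    tdee = _trunc_normal(rng, params.tdee_mean_kcal, params.tdee_sd_kcal, n)
    # weight change over the study week: small, centred on zero
    dw = rng.normal(0.0, 0.6, n) if params.weight_sd_kg > 0 else np.zeros(n)
    # device REE: proportional to FFM with a multiplicative 5% spread,
    # anchored so the cohort mean sits near typical measured REE
    ree = (370.0 + 21.6 * ffm) * _lognormal_unit_mean(
        rng, 5.0 if params.weight_sd_kg > 0 else 0.0, n
    )
    pal_lifestyle = np.clip(
        rng.normal(1.5, 0.15, n) if params.weight_sd_kg > 0 else np.full(n, 1.5),
        1.2,
        2.2,
    )
    smoking = rng.random(n) < 0.30
    activity = rng.choice(
        ["none", "1-2h", "2-6h", ">6h"], size=n, p=[0.50, 0.05, 0.35, 0.10]
    )
    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "sex": "female",
            "age_y": age,
            "height_m": height,
            "weight_day1_kg": weight,
            "weight_day8_kg": weight + dw,
            "fm_kg": fm,
            "ffm_kg": ffm,
            "ree_device_kcal": ree,
            "pal_lifestyle": pal_lifestyle,
            "smoking": smoking,
            "activity": activity,
        }
    )
    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "true_tdee_kcal": tdee,
            "true_tbw_kg": tbw,
            "true_fm_kg": fm,
            "true_ffm_kg": ffm,
            "weight_kg": weight,
        }
    )
    return participants, truth


def simulate_isotope_series(
    truth: pd.DataFrame,
    params: CohortParams,
    sample_times_h: tuple[float, ...] = (0.0, 4.0, 5.0, 168.0),
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-point urine isotope series per participant.

    Doses follow the study protocol (1.8 g/kg TBW of 10 atom% H2(18)O and
    0.12 g/kg TBW of 99.9 atom% 2H2O). Dilution spaces are set from true TBW
    with N_d/N_o drawn around the study's QC ratio; elimination rates are
    obtained by inverting the rCO2 equation at the participant's true TDEE
    under the engine's own pooling convention, with k_O/k_d at the study's
    turnover ratio. Plateau samples (4 h, 5 h) are placed on the decay curve
    so their arithmetic mean equals the exact plateau enrichment. Additive
    Gaussian noise (ppm) perturbs post-dose samples.

    Returns ``(samples, doses)`` in the schemas run_dlw consumes.
    """
    times = sorted(sample_times_h)
    if times[0] != 0.0:
        raise ValueError("sample times must include the pre-dose time 0")
    plateau_times = [t for t in times if 3.0 <= t <= 6.0]
    if len(plateau_times) < 1:
        raise ValueError("sample times must include a plateau sample in [3, 6] h")
    t_final = times[-1]
    if t_final <= max(plateau_times):
        raise ValueError(
            f"final sample time {t_final} h must exceed the plateau window"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    engine = DLWConfig(rq=params.rq)
    dose_af = {"18O": 0.10, "2H": 0.999}
    dose_per_kg_tbw = {"18O": 1.8, "2H": 0.12}

    sample_rows, dose_rows = [], []
    for _, row in truth.iterrows():
        pid = row["participant_id"]
        tbw = float(row["true_tbw_kg"])
        tdee = float(row["true_tdee_kcal"])
        n_o = tbw * 1000.0 / WATER_MOLAR_MASS
        ndno = (
            rng.normal(params.ndno_mean, params.ndno_sd)
            if params.ndno_sd > 0 and params.isotope_noise_sd_ppm > 0
            else params.ndno_mean
        )
        n_by_tracer = {"18O": n_o, "2H": ndno * n_o}
        n_pool = (n_o + n_by_tracer["2H"] / engine.ndno_reference) / 2.0
        rco2_l = tdee / (1.106 + 3.94 / params.rq)
        # invert rCO2 = 0.4664*N*(1.007 k_O - 1.043 k_d)*22.26 with k_O = rho*k_d
        g = rco2_l / (0.4664 * n_pool * 22.26)
        rho = params.ko_kd_ratio
        k_d = g / (1.007 * rho - 1.043)
        k = {"18O": rho * k_d, "2H": k_d}
        t_mid = float(np.mean(plateau_times))
        for tracer in ("18O", "2H"):
            dose_g = dose_per_kg_tbw[tracer] * tbw
            n_water = dose_g / WATER_MOLAR_MASS
            excess_mol = n_water * (dose_af[tracer] - NATURAL_ABUNDANCE[tracer])
            e_plateau = excess_mol / n_by_tracer[tracer] * 1e6  # ppm
            # plateau samples sit on the decay curve scaled so their
            # arithmetic mean equals e_plateau; later samples decay from
            # e_plateau itself, anchoring the two-point estimate exactly
            post_times = [t for t in times if t > 0]
            rel = np.exp([-k[tracer] * (t - t_mid) / 24.0 for t in post_times])
            plat_rel = [r for t, r in zip(post_times, rel) if 3.0 <= t <= 6.0]
            scale = e_plateau / float(np.mean(plat_rel))
            for t, r in zip(post_times, rel):
                excess = scale * r if 3.0 <= t <= 6.0 else e_plateau * r
                if params.isotope_noise_sd_ppm > 0:
                    excess = max(
                        excess + rng.normal(0.0, params.isotope_noise_sd_ppm),
                        1e-9,
                    )
                sample_rows.append(
                    {
                        "participant_id": pid,
                        "time_h": t,
                        "tracer": tracer,
                        "excess_ppm": excess,
                    }
                )
            sample_rows.append(
                {
                    "participant_id": pid,
                    "time_h": 0.0,
                    "tracer": tracer,
                    "excess_ppm": 0.0,
                }
            )
            dose_rows.append(
                {
                    "participant_id": pid,
                    "tracer": tracer,
                    "dose_g": dose_g,
                    "dose_atom_fraction": dose_af[tracer],
                }
            )
    samples = pd.DataFrame(sample_rows).sort_values(
        ["participant_id", "tracer", "time_h"], ignore_index=True
    )
    return samples, pd.DataFrame(dose_rows)


def simulate_reported_intake(
    truth: pd.DataFrame,
    params: CohortParams,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Daily reported intake per tool.

    Day-level energy = true TDEE * (1 + bias_frac) * B_i * W_id with B_i a
    person-level and W_id a day-level lognormal factor, both of mean 1 —
    multiplicative noise keeps intake positive and right-skewed. Eating
    occasions are Poisson; macronutrient grams follow a fixed energy split
    (4/9/4 kcal per g of carbohydrate/fat/protein), with sugars at 40% of
    carbohydrate and fibre at 14 g per 1000 kcal.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 2)
    carb_f, fat_f, prot_f = params.macro_fracs
    rows = []
    for tool in params.tools:
        for _, row in truth.iterrows():
            pid = row["participant_id"]
            tdee = float(row["true_tdee_kcal"])
            person = float(_lognormal_unit_mean(rng, tool.cv_between_pct, 1)[0])
            days = _lognormal_unit_mean(rng, tool.cv_within_pct, params.n_days)
            occ = rng.poisson(tool.mean_occasions, params.n_days)
            for d in range(params.n_days):
                kcal = max(tdee * (1.0 + tool.bias_frac) * person * days[d], 0.0)
                carb_g = kcal * carb_f / 4.0
                rows.append(
                    {
                        "tool": tool.name,
                        "participant_id": pid,
                        "day": d + 1,
                        "energy_kcal": kcal,
                        "carb_g": carb_g,
                        "sugar_g": 0.40 * carb_g,
                        "fat_g": kcal * fat_f / 9.0,
                        "satfat_g": 0.35 * kcal * fat_f / 9.0,
                        "protein_g": kcal * prot_f / 4.0,
                        "fibre_g": 14.0 * kcal / 1000.0,
                        "occasions": int(occ[d]),
                    }
                )
    return pd.DataFrame(rows)


def generate_cohort_bundle(params: CohortParams) -> CohortBundle:
    """Full synthetic study: participants, isotope series, and intake logs."""
    participants, truth = generate_participants(params)
    samples, doses = simulate_isotope_series(truth, params)
    intake = simulate_reported_intake(truth, params)
    return CohortBundle(
        participants=participants,
        truth=truth,
        isotope_samples=samples,
        doses=doses,
        intake=intake,
        params=params,
    )
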