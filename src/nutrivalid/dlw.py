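"""Two-point doubly labelled water (DLW) engine.

Computes CO2 production and total daily energy expenditure (TDEE) from a
urine isotope sample sheet: one pre-dose baseline, a post-dose plateau pair
(nominally 4 h and 5 h), and a final sample about 7 days later, for each of
the two tracers (2H and 18O).

Model
-----
Excess enrichment of each tracer decays mono-exponentially from plateau.
The elimination rates k_O and k_d (per day), together with the body-water
pool N (mol), give CO2 production

    rCO2 = 0.4664 * N * (1.007*k_O - 1.043*k_d) * 22.26   [L/day]

(the constants 1.007 and 1.043 correct for isotope exchange/fractionation,
0.4664 converts water turnover to CO2 turnover, and 22.26 L/mol converts
moles of CO2 to litres). Energy expenditure follows from the Weir equation
under an assumed respiratory quotient RQ:

    TDEE = rCO2 * (1.106 + 3.94/RQ)   [kcal/day]

Dilution spaces are obtained from the dose bookkeeping

    N = n_water(dose) * (dose atom fraction - natural abundance) / excess,

one pool per tracer; the pool used in rCO2 is a configurable combination of
the two (default: mean of N_o and N_d/1.041, a standard two-point
convention). The ratio N_d/N_o is a quality-control metric expected in a
narrow band around 1.04.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DoseSpec",
    "DLWResult",
    "DLWConfig",
    "elimination_rate",
    "dilution_space",
    "rco2",
    "tdee_weir",
    "run_dlw",
]

#: molar mass of water, g/mol (used for both dose water and body water)
WATER_MOLAR_MASS = 18.015
#: natural atom-fraction abundances of the rare isotopes (VSMOW)
NATURAL_ABUNDANCE = {"18O": 0.0020052, "2H": 0.00015576}
#: VSMOW isotope ratios, for delta-per-mil -> ppm conversion helpers
VSMOW_RATIO = {"18O": 2005.20e-6, "2H": 155.76e-6}

KCAL_PER_KJ = 1.0 / 4.184

#: default QC band for the dilution-space ratio N_d/N_o
NDNO_QC_BAND = (1.00, 1.07)
#: reference dilution-space ratio used when pooling N_o and N_d
NDNO_REFERENCE = 1.041

TRACERS = ("18O", "2H")


class DLWDataError(ValueError):
    """Raised when a participant's sample sheet is incomplete or invalid."""


@dataclass(frozen=True)
class DoseSpec:
    """Administered dose of one tracer for one participant.

    Parameters
    ----------
    dose_g : grams of labelled water administered.
    atom_fraction : isotopic atom fraction of the dose water, in (0, 1].
    """

    dose_g: float
    atom_fraction: float

    def __post_init__(self) -> None:
        if self.dose_g <= 0:
            raise ValueError(f"dose mass must be positive, got {self.dose_g}")
        if not 0 < self.atom_fraction <= 1:
            raise ValueError(
                f"dose atom fraction must be in (0, 1], got {self.atom_fraction}"
            )


@dataclass
class DLWResult:
    """Per-participant output of the two-point DLW computation."""

    participant_id: str
    k_o: float  # per day
    k_d: float  # per day
    n_o: float  # mol
    n_d: float  # mol
    n_pool: float  # mol, pool used in rCO2
    ratio_nd_no: float
    ratio_kd_ko: float
    ratio_ko_kd: float
    rco2_l_day: float
    tdee_kcal_day: float
    tdee_kj_day: float
    qc_flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class DLWConfig:
    """Tunable conventions of the two-point method.

    rq : respiratory quotient assumed in the Weir equation (mixed diet 0.85).
    ndno_reference : divisor applied to N_d before pooling with N_o.
    ndno_qc_band : acceptable range for N_d/N_o before a QC flag is raised.
    plateau_window_h : samples in this time window count as plateau.
    """

    rq: float = 0.85
    ndno_reference: float = NDNO_REFERENCE
    ndno_qc_band: tuple[float, float] = NDNO_QC_BAND
    plateau_window_h: tuple[float, float] = (3.0, 6.0)

    def __post_init__(self) -> None:
        if not 0.7 <= self.rq <= 1.0:
            raise ValueError(f"RQ must lie in [0.7, 1.0], got {self.rq}")


def elimination_rate(
    excess_initial: float, excess_final: float, delta_t_days: float
) -> float:
    """Exponential elimination rate k (per day) between two excess enrichments.

    k = (ln excess_initial - ln excess_final) / delta_t. A final excess above
    the initial yields a negative k; callers flag it rather than erroring.
    """
    if excess_initial <= 0 or excess_final <= 0:
        raise DLWDataError(
            "elimination rate requires positive excess enrichments, got "
            f"initial={excess_initial}, final={excess_final}"
        )
    if delta_t_days <= 0:
        raise DLWDataError(f"delta_t must be positive, got {delta_t_days}")
    return (np.log(excess_initial) - np.log(excess_final)) / delta_t_days


def dilution_space(
    dose: DoseSpec, excess_at_plateau_ppm: float, tracer: str
) -> float:
    """Body-water dilution space N (mol) from dose dilution.

    The moles of excess tracer delivered (dose water moles times atom-fraction
    excess over natural abundance) divided by the plateau excess (atom
    fraction, here carried in ppm) gives the apparent pool size in moles of
    water. The per-molecule atom-site count cancels because dose and body
    water share it.
    """
    if excess_at_plateau_ppm <= 0:
        raise DLWDataError(
            f"plateau excess must be positive, got {excess_at_plateau_ppm}"
        )
    if tracer not in NATURAL_ABUNDANCE:
        raise ValueError(f"unknown tracer {tracer!r}; expected one of {TRACERS}")
    n_water = dose.dose_g / WATER_MOLAR_MASS
    excess_mol = n_water * (dose.atom_fraction - NATURAL_ABUNDANCE[tracer])
    return excess_mol / (excess_at_plateau_ppm * 1e-6)


def rco2(n_pool: float, k_o: float, k_d: float) -> float:
    """CO2 production in L/day from the pool size and elimination rates.

    rCO2 = 0.4664 * N * (1.007*k_O - 1.043*k_d) * 22.26. A negative value is
    returned as-is (the caller attaches a QC flag); it arises when the 2H
    turnover exceeds its physiologic share of the 18O turnover.
    """
    if n_pool < 0:
        raise ValueError(f"pool size must be non-negative, got {n_pool}")
    return 0.4664 * n_pool * (1.007 * k_o - 1.043 * k_d) * 22.26


def tdee_weir(rco2_l_day: float, rq: float = 0.85) -> float:
    """Weir equation: kcal/day from CO2 production under an assumed RQ."""
    if rq <= 0:
        raise ValueError(f"RQ must be positive, got {rq}")
    return rco2_l_day * (1.106 + 3.94 / rq)


def _tracer_kinetics(
    sub: pd.DataFrame, pid: str, tracer: str, config: DLWConfig
) -> tuple[float, float, float]:
    """Return (k per day, plateau excess ppm, plateau midpoint hours)."""
    lo, hi = config.plateau_window_h
    baseline = sub[sub["time_h"] == 0]
    plateau = sub[(sub["time_h"] >= lo) & (sub["time_h"] <= hi)]
    final = sub[sub["time_h"] > hi]
    missing = []
    if baseline.empty:
        missing.append("pre-dose baseline (time 0)")
    if plateau.empty:
        missing.append(f"plateau sample in [{lo}, {hi}] h")
    if final.empty:
        missing.append(f"final sample after {hi} h")
    if missing:
        raise DLWDataError(
            f"participant {pid}, tracer {tracer}: missing " + "; ".join(missing)
        )
    base = float(baseline["excess_ppm"].mean())
    plateau_excess = float(plateau["excess_ppm"].mean()) - base
    t_mid_h = float(plateau["time_h"].mean())
    final_row = final.loc[final["time_h"].idxmax()]
    final_excess = float(final_row["excess_ppm"]) - base
    if plateau_excess <= 0 or final_excess <= 0:
        raise DLWDataError(
            f"participant {pid}, tracer {tracer}: non-positive excess after "
            f"baseline subtraction (plateau={plateau_excess:.4g}, "
            f"final={final_excess:.4g})"
        )
    dt_days = (float(final_row["time_h"]) - t_mid_h) / 24.0
    k = elimination_rate(plateau_excess, final_excess, dt_days)
    return k, plateau_excess, t_mid_h


def run_dlw(
    samples: pd.DataFrame,
    doses: pd.DataFrame,
    config: DLWConfig | None = None,
) -> pd.DataFrame:
    """Run the two-point DLW computation for every participant.

    Parameters
    ----------
    samples : long table with columns participant_id, time_h, tracer
        ('18O'/'2H'), excess_ppm (excess isotopic abundance above the
        pre-dose baseline, in ppm of atom fraction; units only need to be
        self-consistent between dose bookkeeping and samples).
    doses : one row per participant and tracer with columns participant_id,
        tracer, dose_g, dose_atom_fraction.
    config : DLWConfig conventions; defaults are the standard two-point ones.

    Returns
    -------
    DataFrame with one row per participant: elimination rates, dilution
    spaces, pooled N, QC ratios, rCO2 (L/day), TDEE (kcal/day and kJ/day),
    and a semicolon-joined ``qc_flags`` column.
    """
    if config is None:
        config = DLWConfig()
    required = {"participant_id", "time_h", "tracer", "excess_ppm"}
    if not required.issubset(samples.columns):
        raise DLWDataError(
            f"sample sheet missing columns: {sorted(required - set(samples.columns))}"
        )
    results = []
    for pid, grp in samples.groupby("participant_id", sort=True):
        res = _run_one(str(pid), grp, doses, config)
        results.append(res)
    rows = []
    for r in results:
        d = r.__dict__.copy()
        d["qc_flags"] = ";".join(d["qc_flags"])
        rows.append(d)
    return pd.DataFrame(rows)


def _run_one(
    pid: str, grp: pd.DataFrame, doses: pd.DataFrame, config: DLWConfig
) -> DLWResult:
    kin: dict[str, tuple[float, float, float]] = {}
    space: dict[str, float] = {}
    for tracer in TRACERS:
        sub = grp[grp["tracer"] == tracer]
        if sub.empty:
            raise DLWDataError(f"participant {pid}: no samples for tracer {tracer}")
        kin[tracer] = _tracer_kinetics(sub, pid, tracer, config)
        dose_row = doses[
            (doses["participant_id"] == pid) & (doses["tracer"] == tracer)
        ]
        if dose_row.empty:
            raise DLWDataError(f"participant {pid}: no dose row for tracer {tracer}")
        dose = DoseSpec(
            dose_g=float(dose_row["dose_g"].iloc[0]),
            atom_fraction=float(dose_row["dose_atom_fraction"].iloc[0]),
        )
        space[tracer] = dilution_space(dose, kin[tracer][1], tracer)

    k_o, k_d = kin["18O"][0], kin["2H"][0]
    n_o, n_d = space["18O"], space["2H"]
    flags: list[str] = []
    if k_o <= 0 or k_d <= 0:
        flags.append("non_positive_elimination_rate")
    if k_o <= k_d:
        flags.append("k_o_not_above_k_d")
    ratio_nd_no = n_d / n_o
    lo, hi = config.ndno_qc_band
    if not lo <= ratio_nd_no <= hi:
        flags.append("ndno_ratio_outside_qc_band")
    n_pool = (n_o + n_d / config.ndno_reference) / 2.0
    r = rco2(n_pool, k_o, k_d)
    if r < 0:
        flags.append("negative_rco2")
    tdee = tdee_weir(r, config.rq)
    return DLWResult(
        participant_id=pid,
        k_o=k_o,
        k_d=k_d,
        n_o=n_o,
        n_d=n_d,
        n_pool=n_pool,
        ratio_nd_no=ratio_nd_no,
        ratio_kd_ko=k_d / k_o,
        ratio_ko_kd=k_o / k_d,
        rco2_l_day=r,
        tdee_kcal_day=tdee,
        tdee_kj_day=tdee * 4.184,
        qc_flags=flags,
    )
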