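"""CSV schemas, unit conversion, and cohort loading.

All tables are flat UTF-8 comma-separated files with a header row. Units
are normalised once at the boundary: heights to metres, energies to
kcal/day (a column named ``energy_kj`` is converted on read). Row-level
validation failures are reported with participant id and row number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .cohort import CohortBundle
from .dlw import VSMOW_RATIO

__all__ = [
    "kcal_kj",
    "delta_permil_to_ppm",
    "read_cohort",
    "write_cohort",
    "CohortValidationError",
]

KJ_PER_KCAL = 4.184

PARTICIPANT_REQUIRED = [
    "participant_id",
    "age_y",
    "height_m",
    "weight_day1_kg",
]
ISOTOPE_REQUIRED = ["participant_id", "time_h", "tracer", "excess_ppm"]
DOSE_REQUIRED = ["participant_id", "tracer", "dose_g", "dose_atom_fraction"]
INTAKE_REQUIRED = ["tool", "participant_id", "day", "energy_kcal"]


class CohortValidationError(ValueError):
    """Raised when an input sheet fails schema or row-level validation."""


def kcal_kj(value: float, direction: str = "kcal_to_kj") -> float:
    """Convert between kcal and kJ, by the exact factor 4.184."""
    if direction == "kcal_to_kj":
        return value * KJ_PER_KCAL
    if direction == "kj_to_kcal":
        return value / KJ_PER_KCAL
    raise ValueError(f"unknown direction {direction!r}")


def delta_permil_to_ppm(delta_excess_permil: float, tracer: str) -> float:
    """Excess delta (per mil vs VSMOW) to ppm excess atom fraction.

    Uses the small-excess approximation atom fraction ~= isotope ratio,
    adequate for tracer work at the enrichments used here.
    """
    if tracer not in VSMOW_RATIO:
        raise ValueError(f"unknown tracer {tracer!r}")
    return delta_excess_permil / 1000.0 * VSMOW_RATIO[tracer] * 1e6


def _check_columns(df: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"{name} sheet missing columns: {missing}")


def _validate_participants(df: pd.DataFrame) -> None:
    for idx, row in df.iterrows():
        pid = row.get("participant_id", "?")
        if row["weight_day1_kg"] <= 0:
            raise CohortValidationError(
                f"participants row {idx} (participant {pid}): "
                f"non-positive weight {row['weight_day1_kg']}"
            )
        if not 1.2 < row["height_m"] < 2.2:
            raise CohortValidationError(
                f"participants row {idx} (participant {pid}): "
                f"height {row['height_m']} m outside (1.2, 2.2)"
            )


def read_cohort(
    participants_path: str | Path,
    isotope_path: str | Path | None = None,
    dose_path: str | Path | None = None,
    intake_path: str | Path | None = None,
) -> CohortBundle:
    """Load the cohort sheets into a bundle, validating schemas and rows.

    An intake sheet carrying ``energy_kj`` instead of ``energy_kcal`` is
    converted to kcal on read.
    """
    participants = pd.read_csv(participants_path)
    _check_columns(participants, PARTICIPANT_REQUIRED, "participants")
    _validate_participants(participants)

    samples = doses = intake = None
    if isotope_path is not None:
        samples = pd.read_csv(isotope_path)
        _check_columns(samples, ISOTOPE_REQUIRED, "isotope samples")
    if dose_path is not None:
        doses = pd.read_csv(dose_path)
        _check_columns(doses, DOSE_REQUIRED, "doses")
    if intake_path is not None:
        intake = pd.read_csv(intake_path)
        if "energy_kj" in intake.columns and "energy_kcal" not in intake.columns:
            intake["energy_kcal"] = intake["energy_kj"] / KJ_PER_KCAL
            intake = intake.drop(columns=["energy_kj"])
        _check_columns(intake, INTAKE_REQUIRED, "intake")
        bad = intake[intake["energy_kcal"] < 0]
        if not bad.empty:
            idx = bad.index[0]
            raise CohortValidationError(
                f"intake row {idx} (participant "
                f"{bad['participant_id'].iloc[0]}): negative energy"
            )
    return CohortBundle(
        participants=participants,
        truth=None,
        isotope_samples=samples,
        doses=doses,
        intake=intake,
    )


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundle's tables as CSVs; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tables = {
        "participants": bundle.participants,
        "truth": bundle.truth,
        "isotope_samples": bundle.isotope_samples,
        "doses": bundle.doses,
        "intake": bundle.intake,
    }
    for name, df in tables.items():
        if df is None:
            continue
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
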