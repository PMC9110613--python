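"""File formats and configuration.

The exchange format for measurements is a flat CSV table, one row per
acquisition, with a versioned comment header::

    # tridose timepoint table v1
    cohort_id,patient_id,cycle_id,injected_MBq,voi,t_hours,odr_mGy_per_s,slot

Times are stored in hours (clinical convention); all internal computation
is in seconds.  Dose tables and fit records are written as CSV/JSON;
population templates as two-column CSV (t_hours, mGy/s per MBq).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .fitting import Slot, TimePointMeasurement
from .kinetics import LU177_HALF_LIFE_DAYS
from .sparse import CycleRecord, PatientRecord, PopulationTemplate

__all__ = [
    "TIMEPOINT_COLUMNS",
    "TIMEPOINT_HEADER",
    "SchemaError",
    "WorkflowConfig",
    "read_timepoints_csv",
    "write_timepoints_csv",
    "patients_to_frame",
    "frame_to_patients",
    "write_template_csv",
    "read_template_csv",
    "write_json",
]

TIMEPOINT_HEADER = "# tridose timepoint table v1"
TIMEPOINT_COLUMNS = [
    "cohort_id",
    "patient_id",
    "cycle_id",
    "injected_MBq",
    "voi",
    "t_hours",
    "odr_mGy_per_s",
    "slot",
]


class SchemaError(ValueError):
    """A table does not match the documented schema."""


@dataclass
class WorkflowConfig:
    """All tunables of the adaptive workflow, with documented defaults.

    Round-trips losslessly through YAML.
    """

    tol_first_point_mgy_per_s: float = 1e-5  # first-point fit tolerance
    template_grid_step_hours: float = 0.1  # population-template resolution
    template_span_hours: float = 600.0  # curve support, matches the boundary
    donor_policy: str = "nearest"  # M1 donor choice: nearest | next_first
    reference_cycle: int = 0  # 0 = earliest cycle with >= 3 points
    half_life_days: float = LU177_HALF_LIFE_DAYS  # physical half-life override
    k2_over_k3: float = 10.0  # structural washout/clearance rate ratio
    omega2_over_omega3: float = 2.0  # structural washout/clearance amplitude ratio
    seed: int = 0  # multi-start seed
    cohort_id: str = "cohort"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @property
    def lam(self) -> float:
        from .kinetics import lu177_lambda

        return lu177_lambda(self.half_life_days)


def patients_to_frame(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for pat in patients:
        for cyc in pat.cycles:
            for voi, points in sorted(cyc.measurements.items()):
                for p in points:
                    rows.append(
                        {
                            "cohort_id": pat.cohort_id,
                            "patient_id": pat.patient_id,
                            "cycle_id": cyc.cycle_id,
                            "injected_MBq": cyc.injected_activity_mbq,
                            "voi": voi,
                            "t_hours": p.t_hours,
                            "odr_mGy_per_s": p.odr,
                            "slot": p.nominal_slot.value,
                        }
                    )
    return pd.DataFrame(rows, columns=TIMEPOINT_COLUMNS)


def frame_to_patients(df: pd.DataFrame) -> list[PatientRecord]:
    missing = set(TIMEPOINT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"missing columns: {sorted(missing)}")
    patients: list[PatientRecord] = []
    for (cohort, pid), pat_df in df.groupby(["cohort_id", "patient_id"], sort=True):
        cycles = []
        for cyc_id, cyc_df in pat_df.groupby("cycle_id", sort=True):
            activities = cyc_df["injected_MBq"].unique()
            if len(activities) != 1:
                raise SchemaError(
                    f"patient {pid} cycle {cyc_id}: inconsistent injected_MBq"
                )
            rec = CycleRecord(
                cycle_id=int(cyc_id), injected_activity_mbq=float(activities[0])
            )
            for row in cyc_df.itertuples():
                rec.measurements.setdefault(str(row.voi), []).append(
                    TimePointMeasurement(
                        t_hours=float(row.t_hours),
                        odr=float(row.odr_mGy_per_s),
                        voi_label=str(row.voi),
                        cycle_id=int(cyc_id),
                        nominal_slot=Slot(str(row.slot)),
                    )
                )
            cycles.append(rec)
        patients.append(
            PatientRecord(patient_id=str(pid), cycles=cycles, cohort_id=str(cohort))
        )
    return patients


def write_timepoints_csv(path: str | Path, patients: Sequence[PatientRecord]) -> None:
    df = patients_to_frame(patients)
    with open(path, "w") as fh:
        fh.write(TIMEPOINT_HEADER + "\n")
        # repr gives the shortest exact decimal: the round-trip is lossless
        df.to_csv(fh, index=False, float_format=lambda x: repr(float(x)))


def read_timepoints_csv(path: str | Path) -> list[PatientRecord]:
    """Parse a time-point table; malformed rows raise with line numbers."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"{path.name}: {exc}") from exc
    missing = set(TIMEPOINT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path.name}: missing columns {sorted(missing)}")
    bad = df[
        ~np.isfinite(pd.to_numeric(df["t_hours"], errors="coerce"))
        | ~np.isfinite(pd.to_numeric(df["odr_mGy_per_s"], errors="coerce"))
        | (pd.to_numeric(df["t_hours"], errors="coerce") <= 0)
        | (pd.to_numeric(df["odr_mGy_per_s"], errors="coerce") < 0)
    ]
    if not bad.empty:
        lines = ", ".join(str(i + 3) for i in bad.index[:5])  # header + comment
        raise SchemaError(f"{path.name}: malformed rows near lines {lines}")
    return frame_to_patients(df)


def write_template_csv(path: str | Path, template: PopulationTemplate) -> None:
    pd.DataFrame(
        {
            "t_hours": template.time_grid_hours,
            "mGy_per_s_per_MBq": template.mean_curve,
        }
    ).to_csv(path, index=False)


def read_template_csv(
    path: str | Path, voi_label: str = "", n_contributors: int = 0
) -> PopulationTemplate:
    df = pd.read_csv(path)
    return PopulationTemplate(
        time_grid_hours=df["t_hours"].to_numpy(),
        mean_curve=df["mGy_per_s_per_MBq"].to_numpy(),
        n_contributors=n_contributors,
        voi_label=voi_label,
    )


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(path: str | Path, payload) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
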