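"""Quantitative-SPECT plumbing: calibration, dead time, dose-rate maps, VOI means.

This module carries voxel data from reconstructed counts to an organ dose
rate (ODR): counts are converted to activity with an experimentally
determined camera sensitivity (cps/MBq), count rates are corrected for
detector dead time with a paralyzable model, unit (per-MBq) dose-rate maps
are scaled to the total activity in the field of view, and the ODR of a
volume of interest is the arithmetic mean of dose-rate voxels inside its
mask.

Monte Carlo particle transport is out of scope here; a local-deposition
dose-rate operator is provided as an explicitly non-Monte-Carlo stand-in
(it models no cross-dose) for desk-scale pipelines and phantoms.

Units are tracked on every volume and mismatches raise instead of silently
coercing.  Grids follow the (z, y, x) array convention with spacing and
origin in millimetres.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.special import lambertw

__all__ = [
    "ScalarVolume",
    "VoiMask",
    "CalibrationConfig",
    "UnitError",
    "GeometryError",
    "EmptyVoiError",
    "SaturationError",
    "counts_to_activity",
    "deadtime_correct",
    "deadtime_forward",
    "scale_dose_rate_map",
    "compute_odr",
    "local_deposition_map",
    "read_volume",
    "write_volume",
]

VALID_UNITS = ("counts", "MBq/mL", "mGy/s", "mGy/s per MBq")

#: Mean energy deposited locally per 177Lu decay (J): the mean beta energy,
#: ~147 keV.  Photon energy escapes the voxel and is deliberately ignored
#: by the local-deposition operator.
LU177_MEAN_BETA_ENERGY_J = 147.0e3 * 1.602176634e-19


class UnitError(ValueError):
    """Volume carries the wrong unit for this operation."""


class GeometryError(ValueError):
    """Two grids are incompatible and no resampling rule applies."""


class EmptyVoiError(ValueError):
    """A VOI mask selects no voxels."""


class SaturationError(ValueError):
    """Observed count rate beyond the peak of the paralyzable response."""


@dataclass
class ScalarVolume:
    """A 3-D scalar grid with geometry and a tracked physical unit."""

    values: np.ndarray
    spacing: tuple[float, float, float]  # mm, (z, y, x)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)  # mm
    unit: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError("volume must be 3-D")
        if any(not (s > 0) for s in self.spacing):
            raise GeometryError(f"spacing must be > 0 on all axes: {self.spacing}")
        if any(not math.isfinite(o) for o in self.origin):
            raise GeometryError("origin must be finite")
        if self.unit not in VALID_UNITS:
            raise UnitError(f"unknown unit {self.unit!r}; expected one of {VALID_UNITS}")

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in mL (spacing product, mm^3 -> mL)."""
        return float(np.prod(self.spacing)) / 1000.0

    def same_grid(self, other: "ScalarVolume | VoiMask") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class VoiMask:
    """A binary volume of interest on its own grid (never interpolated)."""

    values: np.ndarray
    label: str
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise GeometryError("mask must be 3-D")
        if any(not (s > 0) for s in self.spacing):
            raise GeometryError(f"spacing must be > 0 on all axes: {self.spacing}")
        if any(not math.isfinite(o) for o in self.origin):
            raise GeometryError("origin must be finite")
        if not self.values.any():
            raise EmptyVoiError(f"mask {self.label!r} selects no voxels")

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class CalibrationConfig:
    """Camera calibration: sensitivity, dead time, acquisition duration."""

    sensitivity_cps_per_mbq: float
    deadtime_tau_s: float = 0.0
    acquisition_duration_s: float = 1.0

    def __post_init__(self) -> None:
        if self.sensitivity_cps_per_mbq <= 0:
            raise ValueError("sensitivity must be > 0")
        if self.deadtime_tau_s < 0:
            raise ValueError("dead time must be >= 0")
        if self.acquisition_duration_s <= 0:
            raise ValueError("acquisition duration must be > 0")


def counts_to_activity(
    volume: ScalarVolume, cal: CalibrationConfig
) -> tuple[ScalarVolume, float]:
    """Convert a counts volume to activity concentration (MBq/mL).

    Voxel activity = (counts / duration) / sensitivity; the concentration is
    that activity divided by the voxel volume.  Returns the concentration
    volume and the total activity (MBq) in the field of view.
    """
    if volume.unit != "counts":
        raise UnitError(f"expected a counts volume, got unit {volume.unit!r}")
    activity_mbq = volume.values / cal.acquisition_duration_s / cal.sensitivity_cps_per_mbq
    total_mbq = float(activity_mbq.sum())
    conc = ScalarVolume(
        values=activity_mbq / volume.voxel_volume_ml,
        spacing=volume.spacing,
        origin=volume.origin,
        unit="MBq/mL",
    )
    return conc, total_mbq


def deadtime_forward(true_rate: float | np.ndarray, tau: float) -> float | np.ndarray:
    """Paralyzable detector response: observed rate m = n * exp(-tau * n)."""
    n = np.asarray(true_rate, dtype=float)
    out = n * np.exp(-tau * n)
    return out if out.ndim else float(out)


def deadtime_correct(observed_rate: float, tau: float) -> float:
    """Invert the paralyzable dead-time model for the true count rate.

    Solves ``m = n exp(-tau n)`` for n on the principal (sub-saturation)
    branch via the Lambert W function: ``n = -W0(-tau m) / tau``.  The
    correction is the identity at tau = 0 and always satisfies n >= m.
    Rates beyond the peak of the paralyzable response (tau*m > 1/e) have no
    solution and raise :class:`SaturationError`.
    """
    if observed_rate < 0:
        raise ValueError("observed rate must be >= 0")
    if tau < 0:
        raise ValueError("dead time must be >= 0")
    if tau == 0.0 or observed_rate == 0.0:
        return float(observed_rate)
    x = tau * observed_rate
    if x > math.exp(-1.0):
        raise SaturationError(
            f"observed rate {observed_rate:g} cps exceeds the paralyzable peak "
            f"for tau = {tau:g} s"
        )
    n = -lambertw(-x, k=0).real / tau
    return float(n)


def scale_dose_rate_map(unit_map: ScalarVolume, total_activity_mbq: float) -> ScalarVolume:
    """Scale a per-MBq dose-rate map to the imaged total activity."""
    if unit_map.unit != "mGy/s per MBq":
        raise UnitError(f"expected a per-MBq dose-rate map, got unit {unit_map.unit!r}")
    if total_activity_mbq < 0:
        raise ValueError("total activity must be >= 0")
    return ScalarVolume(
        values=unit_map.values * total_activity_mbq,
        spacing=unit_map.spacing,
        origin=unit_map.origin,
        unit="mGy/s",
    )


def _resample_to_mask_grid(volume: ScalarVolume, mask: VoiMask) -> ScalarVolume:
    """Trilinear resampling of a dose-rate map onto a mask grid.

    The dose map is interpolated; the mask is never interpolated.  Voxel
    centres of the mask grid are mapped into the volume's index space via
    physical coordinates (origin + index * spacing).
    """
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(volume.values)
    img.SetSpacing(tuple(volume.spacing[::-1]))  # sitk uses (x, y, z)
    img.SetOrigin(tuple(volume.origin[::-1]))
    ref = sitk.Image([int(s) for s in mask.values.shape[::-1]], sitk.sitkFloat64)
    ref.SetSpacing(tuple(mask.spacing[::-1]))
    ref.SetOrigin(tuple(mask.origin[::-1]))
    out = sitk.Resample(img, ref, sitk.Transform(), sitk.sitkLinear, 0.0)
    return ScalarVolume(
        values=sitk.GetArrayFromImage(out),
        spacing=mask.spacing,
        origin=mask.origin,
        unit=volume.unit,
    )


def compute_odr(dose_map: ScalarVolume, mask: VoiMask, resample: bool = True) -> float:
    """Organ dose rate: mean of dose-rate voxels inside the VOI (mGy/s).

    If map and mask grids differ, the map is resampled trilinearly onto the
    mask grid first (``resample=True``); with ``resample=False`` a grid
    mismatch raises :class:`GeometryError`.
    """
    if dose_map.unit != "mGy/s":
        raise UnitError(f"expected a dose-rate map, got unit {dose_map.unit!r}")
    if not dose_map.same_grid(mask):
        if not resample:
            raise GeometryError("dose map and mask are on different grids")
        dose_map = _resample_to_mask_grid(dose_map, mask)
    return float(dose_map.values[mask.values].mean())


def local_deposition_map(
    activity: ScalarVolume,
    mean_energy_per_decay_j: float = LU177_MEAN_BETA_ENERGY_J,
    density_g_per_ml: float = 1.0,
) -> ScalarVolume:
    """Local-deposition dose-rate map, normalized per MBq of total activity.

    Every decay deposits its mean (beta) energy in the voxel where it
    occurs: voxel dose rate = concentration (MBq/mL) x 1e6 Bq/MBq x energy
    (J) / voxel mass (kg).  This is NOT a Monte Carlo transport result — no
    cross-dose between voxels is modelled — and the returned map is tagged
    per-MBq so that :func:`scale_dose_rate_map` restores absolute units.
    """
    if activity.unit != "MBq/mL":
        raise UnitError(f"expected an activity map, got unit {activity.unit!r}")
    if mean_energy_per_decay_j <= 0:
        raise ValueError("mean energy per decay must be > 0")
    if density_g_per_ml <= 0:
        raise ValueError("density must be > 0")
    if np.any(activity.values < 0):
        raise ValueError("activity must be non-negative")
    mass_per_ml_kg = density_g_per_ml * 1e-3
    gray_per_s = activity.values * 1e6 * mean_energy_per_decay_j / mass_per_ml_kg
    total_mbq = float(activity.values.sum()) * activity.voxel_volume_ml
    per_mbq = gray_per_s * 1e3 / total_mbq if total_mbq > 0 else np.zeros_like(gray_per_s)
    return ScalarVolume(
        values=per_mbq,
        spacing=activity.spacing,
        origin=activity.origin,
        unit="mGy/s per MBq",
    )


# --- file I/O ----------------------------------------------------------------


def write_volume(path: str | Path, volume: ScalarVolume | VoiMask) -> None:
    """Write a volume as NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd).

    Geometry (spacing/origin) round-trips exactly; the unit/label is not
    stored in the header and must travel alongside.
    """
    path = Path(path)
    arr = np.asarray(volume.values, dtype=float)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(volume.spacing[::-1]) + [1.0])
        affine[:3, 3] = volume.origin[::-1]
        # nibabel stores (x, y, z); our arrays are (z, y, x)
        nib.save(nib.Nifti1Image(arr.T, affine), str(path))
    elif suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(arr)
        img.SetSpacing(tuple(float(s) for s in volume.spacing[::-1]))
        img.SetOrigin(tuple(float(o) for o in volume.origin[::-1]))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unsupported volume format: {path.name}")


def read_volume(
    path: str | Path, unit: str = "counts", as_mask: bool = False, label: str = ""
) -> ScalarVolume | VoiMask:
    """Read a NIfTI or MetaImage volume into a ScalarVolume (or VoiMask)."""
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=float).T
        affine = img.affine
        spacing = tuple(float(abs(affine[i, i])) for i in (2, 1, 0))
        origin = tuple(float(affine[i, 3]) for i in (2, 1, 0))
    elif suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img).astype(float)
        spacing = tuple(float(s) for s in img.GetSpacing()[::-1])
        origin = tuple(float(o) for o in img.GetOrigin()[::-1])
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    if as_mask:
        return VoiMask(values=arr > 0.5, label=label, spacing=spacing, origin=origin)
    return ScalarVolume(values=arr, spacing=spacing, origin=origin, unit=unit)
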