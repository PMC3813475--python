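"""PRFS (proton resonance frequency shift) thermometry reconstruction.

The water proton resonance shifts by roughly −0.01 ppm per °C, so heating
appears as a phase change in spoiled gradient-echo images:

    Δφ = 2π · γ · B0 · α_prf · TE · ΔT

Reconstruction proceeds by (1) wrapped phase difference against a non-heated
reference acquisition, (2) temporal unwrapping, (3) B0-drift correction by
subtracting the mean phase of a small reference ROI placed in motion-free,
non-heated tissue, and (4) linear conversion to temperature.  The display
semantics of the monitoring interface are modeled too: four isothermal color
corridors rendered only inside a square monitoring ROI, and a lethal zone
defined by a fixed temperature threshold (default 55 °C) at the final ("peak
temperature") acquisition triplet, evaluated on the slice with the largest
thermal impact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dose import LethalZone, area_mm2

TWO_PI = 2.0 * np.pi

#: Corridor temperature bounds in °C.  Half-open: [40,55) [55,70) [70,85),
#: and ≥85 for the hottest corridor (a boundary value of 85.0 is assigned to
#: the upper corridor).
CORRIDOR_EDGES = (40.0, 55.0, 70.0, 85.0)
CORRIDOR_LABELS = {0: "none", 1: "40-54", 2: "55-69", 3: "70-85", 4: "85-100"}
#: Display palette for the four corridors (dark blue, light blue, yellow, red).
CORRIDOR_COLORS = ("#00008b", "#87cefa", "#ffff00", "#ff0000")


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo acquisition and PRFS conversion constants.

    Defaults mirror the monitoring sequence this package models: TE 12 ms,
    TR 970 ms, flip 65°, BW 260 Hz/px, 1.5 T, 128×128 matrix over a 320 mm
    FOV, three 3 mm slices with 6 mm gaps, fat suppressed.  The PRF
    coefficient −0.01 ppm/°C is the water literature standard; it is not a
    vendor-published value and is configurable.
    """

    echo_time: float = 0.012  # s
    repetition_time: float = 0.970  # s
    flip_angle: float = 65.0  # deg
    field_strength: float = 1.5  # T
    gyromagnetic_ratio: float = 42.576e6  # Hz/T
    prf_coefficient: float = -0.01e-6  # fractional shift per °C (−0.01 ppm/°C)
    matrix: int = 128
    fov: float = 320.0  # mm
    slice_thickness: float = 3.0  # mm
    slice_gap: float = 6.0  # mm
    baseline_temp: float = 37.0  # °C
    bandwidth: float = 260.0  # Hz/pixel

    def __post_init__(self) -> None:
        if self.echo_time <= 0:
            raise ValueError("echo_time must be > 0")
        if self.field_strength <= 0:
            raise ValueError("field_strength must be > 0")
        if self.matrix <= 0 or self.fov <= 0:
            raise ValueError("matrix and fov must be > 0")

    @property
    def voxel_size(self) -> float:
        """In-plane voxel size in mm (square voxels)."""
        return self.fov / self.matrix

    @property
    def slice_pitch(self) -> float:
        """Slice-center to slice-center distance in mm."""
        return self.slice_thickness + self.slice_gap

    @property
    def phase_per_degC(self) -> float:
        """Phase change in rad per °C of heating (negative for water PRFS)."""
        return (
            TWO_PI
            * self.gyromagnetic_ratio
            * self.field_strength
            * self.prf_coefficient
            * self.echo_time
        )


@dataclass
class ComplexImageSeries:
    """Magnitude + wrapped phase GRE images over time.

    Arrays are shaped ``(n_times, n_slices, ny, nx)``; phase is wrapped to
    (−π, π].  ``reference_index`` marks the non-heated baseline acquisition.
    """

    magnitude: np.ndarray
    phase: np.ndarray
    reference_index: int = 0
    times: Optional[np.ndarray] = None  # s, aligned with axis 0

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase shapes differ")
        if not (0 <= self.reference_index < self.magnitude.shape[0]):
            raise ValueError("reference_index out of range")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape[0] != self.magnitude.shape[0]:
                raise ValueError("times length must match time axis")

    @property
    def n_times(self) -> int:
        return self.magnitude.shape[0]


@dataclass(frozen=True)
class SquareROI:
    """Square region of interest given by a (row, col) center and side length."""

    center: tuple[int, int]
    side: int

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("side must be positive")

    @property
    def n_voxels(self) -> int:
        return self.side * self.side

    def slices(self) -> tuple[slice, slice]:
        r0 = self.center[0] - self.side // 2
        c0 = self.center[1] - self.side // 2
        return slice(r0, r0 + self.side), slice(c0, c0 + self.side)

    def in_bounds(self, shape: tuple[int, int]) -> bool:
        rs, cs = self.slices()
        return rs.start >= 0 and cs.start >= 0 and rs.stop <= shape[-2] and cs.stop <= shape[-1]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape[-2:], dtype=bool)
        rs, cs = self.slices()
        m[rs, cs] = True
        return m

    def overlaps(self, other: "SquareROI") -> bool:
        rs, cs = self.slices()
        ors, ocs = other.slices()
        return rs.start < ors.stop and ors.start < rs.stop and cs.start < ocs.stop and ocs.start < cs.stop


class MonitoringROI(SquareROI):
    """The square thermal-display ROI (400 or 900 voxels: side 20 or 30)."""


@dataclass(frozen=True)
class DriftReferenceROI(SquareROI):
    """Small ROI (default 6×6 = 36 voxels) in motion-free, non-heated tissue
    used to estimate the spatially uniform B0 drift phase."""

    side: int = 6
    slice_index: int = 1  # slice whose ROI mean defines the correction


@dataclass
class TemperatureMap:
    """Reconstructed temperature in °C with a validity mask.

    Voxels whose reference magnitude falls below ~3× the noise floor carry no
    meaningful phase and are flagged invalid rather than assigned temperatures.
    """

    temp: np.ndarray  # (n_slices, ny, nx) or (nt, n_slices, ny, nx)
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.temp = np.asarray(self.temp, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.temp.shape != self.valid.shape:
            raise ValueError("temp and valid shapes differ")


def wrap_phase(phi: np.ndarray | float) -> np.ndarray | float:
    """Wrap phase to the interval (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(phi, dtype=float), TWO_PI)


def phase_difference(series: ComplexImageSeries, t_index: int) -> np.ndarray:
    """Wrapped phase difference (actual − reference) at one time point."""
    if t_index < series.reference_index:
        raise ValueError(
            f"t_index {t_index} precedes reference_index {series.reference_index}"
        )
    return wrap_phase(series.phase[t_index] - series.phase[series.reference_index])


def unwrap_temporal(
    wrapped_diffs: np.ndarray, suspect_fraction: float = 0.9
) -> tuple[np.ndarray, np.ndarray]:
    """Temporally unwrap a series of wrapped phase differences.

    Assumes the true per-step phase change stays below π per voxel (heating is
    slow relative to the acquisition cadence).  Returns ``(unwrapped, flags)``
    where ``flags`` marks voxels whose apparent per-step change reached
    ``suspect_fraction·π`` at any time — best-effort results there.
    """
    wrapped_diffs = np.asarray(wrapped_diffs, dtype=float)
    unwrapped = np.unwrap(wrapped_diffs, axis=0)
    if wrapped_diffs.shape[0] > 1:
        steps = np.abs(np.diff(unwrapped, axis=0))
        flags = np.any(steps >= suspect_fraction * np.pi, axis=0)
    else:
        flags = np.zeros(wrapped_diffs.shape[1:], dtype=bool)
    return unwrapped, flags


def b0_correct(
    diff_map: np.ndarray,
    roi: DriftReferenceROI,
    monitoring_roi: Optional[MonitoringROI] = None,
) -> np.ndarray:
    """Remove the spatially uniform B0-drift phase from a difference map.

    Subtracts the mean phase difference over the drift-reference ROI (taken on
    ``roi.slice_index`` for multi-slice maps) from every voxel, so the
    corrected map's ROI mean is exactly zero.  A spatially uniform drift of
    any size is removed exactly; noise leaves only the ROI's noise mean.
    """
    diff_map = np.asarray(diff_map, dtype=float)
    if not roi.in_bounds(diff_map.shape):
        raise ValueError("drift-reference ROI out of image bounds")
    if monitoring_roi is not None and roi.overlaps(monitoring_roi):
        warnings.warn(
            "drift-reference ROI overlaps the monitoring ROI; the correction "
            "may absorb real heating",
            stacklevel=2,
        )
    rs, cs = roi.slices()
    if diff_map.ndim == 2:
        offset = diff_map[rs, cs].mean()
    else:
        offset = diff_map[..., roi.slice_index, rs, cs].mean()
    return diff_map - offset


def phase_to_temperature(
    corrected_diff: np.ndarray,
    acq: AcquisitionParams,
    valid: Optional[np.ndarray] = None,
) -> TemperatureMap:
    """Convert a drift-corrected phase difference to absolute temperature.

    ΔT = Δφ / (2π·γ·B0·α_prf·TE); the sign of the PRF coefficient makes
    heating positive.  Temperature = baseline + ΔT.
    """
    scale = acq.phase_per_degC
    if scale == 0:
        raise ValueError("TE, B0 and prf_coefficient must all be nonzero")
    corrected_diff = np.asarray(corrected_diff, dtype=float)
    temp = acq.baseline_temp + corrected_diff / scale
    if valid is None:
        valid = np.ones_like(temp, dtype=bool)
    return TemperatureMap(temp=temp, valid=np.broadcast_to(valid, temp.shape).copy())


def reconstruct_temperature(
    series: ComplexImageSeries,
    acq: AcquisitionParams,
    drift_roi: DriftReferenceROI,
    noise_floor: Optional[float] = None,
    monitoring_roi: Optional[MonitoringROI] = None,
) -> TemperatureMap:
    """Full reconstruction: difference → temporal unwrap → B0 → temperature.

    Returns a map shaped like the input series (time on axis 0).  When
    ``noise_floor`` is given, voxels whose reference magnitude is below
    3×noise_floor are flagged invalid.
    """
    wrapped = np.stack(
        [phase_difference(series, t) for t in range(series.reference_index, series.n_times)]
    )
    unwrapped, _ = unwrap_temporal(wrapped)
    corrected = np.stack(
        [b0_correct(unwrapped[i], drift_roi, monitoring_roi) for i in range(unwrapped.shape[0])]
    )
    if noise_floor is not None:
        valid2d = series.magnitude[series.reference_index] >= 3.0 * noise_floor
        valid = np.broadcast_to(valid2d, corrected.shape)
    else:
        valid = np.ones_like(corrected, dtype=bool)
    return phase_to_temperature(corrected, acq, valid=valid)


def corridor_map(temp_map: TemperatureMap, roi: MonitoringROI) -> np.ndarray:
    """Label the four isothermal corridors inside the monitoring ROI.

    Labels: 0 none, 1: 40–54 °C, 2: 55–69 °C, 3: 70–85 °C, 4: ≥85 °C.  Voxels
    outside the ROI are never labeled — hot tissue beyond the ROI border is
    "thermometrically blind", exactly as on the clinical display.  Invalid
    voxels stay unlabeled.
    """
    temp = temp_map.temp
    if not roi.in_bounds(temp.shape):
        raise ValueError("monitoring ROI out of image bounds")
    labels = np.zeros(temp.shape, dtype=np.int8)
    for lab, lo in enumerate(CORRIDOR_EDGES, start=1):
        labels[temp >= lo] = lab
    labels[~temp_map.valid] = 0
    roi_mask = np.broadcast_to(roi.mask(temp.shape), temp.shape)
    labels[~roi_mask] = 0
    return labels


def select_peak_slice(masks_or_areas: Sequence[np.ndarray] | np.ndarray) -> int:
    """Pick the slice with the largest thermal impact; ties → lowest index.

    Accepts per-slice binary masks (stacked or listed) or a vector of areas.
    """
    arr = np.asarray(masks_or_areas)
    if arr.ndim == 1:
        areas = arr.astype(float)
    else:
        areas = arr.reshape(arr.shape[0], -1).astype(bool).sum(axis=1).astype(float)
    return int(np.argmax(areas))


def lethal_zone_prfs(
    temp_map: TemperatureMap,
    roi: MonitoringROI,
    threshold: float = 55.0,
    voxel_spacing: float | Sequence[float] = 2.5,
) -> LethalZone:
    """Lethal zone at the peak-temperature map: temp ≥ threshold inside the ROI.

    The threshold is inclusive (a voxel at exactly 55.0 °C is lethal).  Area is
    reported for the slice with the largest zone.
    """
    temp = temp_map.temp
    if temp.ndim == 2:
        temp = temp[None]
        valid = temp_map.valid[None]
    else:
        valid = temp_map.valid
    if not roi.in_bounds(temp.shape):
        raise ValueError("monitoring ROI out of image bounds")
    roi_mask = np.broadcast_to(roi.mask(temp.shape), temp.shape)
    mask = (temp >= threshold) & valid & roi_mask
    s = select_peak_slice(mask)
    return LethalZone(
        mask=mask,
        area_mm2=area_mm2(mask[s], voxel_spacing),
        slice_index=s,
        threshold=threshold,
        modality="prfs",
    )
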