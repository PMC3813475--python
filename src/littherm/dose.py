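"""Thermal damage models and lethal-zone measurement.

Two lethality criteria used in thermal-ablation monitoring are implemented:

* the Arrhenius damage integral ``Ω(τ) = ∫₀^τ A·exp(−Ea/(R·T(t))) dt`` with the
  conventional irreversibility threshold Ω ≥ 1, and
* the peak-temperature model, which declares a voxel lethal when its maximum
  temperature over the procedure crosses a fixed threshold.

Both operate on per-voxel temperature histories in °C sampled on the stored
acquisition cadence.  Area measurement (voxel count × in-plane voxel area, in
mm²) is shared by the ground-truth and both reconstruction arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

GAS_CONSTANT = 8.314462618
"""Molar gas constant R in J/(mol·K)."""

KELVIN_OFFSET = 273.15

#: Default liver Arrhenius parameters.  The activation energy is the published
#: liver value (2.577e5 J/mol); the frequency factor was calibrated with
#: ``scripts/calibrate_damage.py`` so that on the standard one-fiber regimen the
#: Ω = 1 boundary coincides with a peak temperature near 52–53 °C, the
#: operating point of the clinical protocol this package models.
DEFAULT_FREQUENCY_FACTOR = 2.34e38
DEFAULT_ACTIVATION_ENERGY = 2.577e5


@dataclass(frozen=True)
class DamageModelParams:
    """First-order Arrhenius injury-kinetics parameters.

    Attributes
    ----------
    frequency_factor:
        Pre-exponential factor A in 1/s.
    activation_energy:
        Activation energy Ea in J/mol.
    gas_constant:
        Molar gas constant in J/(mol·K); exposed for completeness.
    omega_lethal:
        Damage value taken as irreversible (dimensionless, conventionally 1).
    """

    frequency_factor: float = DEFAULT_FREQUENCY_FACTOR
    activation_energy: float = DEFAULT_ACTIVATION_ENERGY
    gas_constant: float = GAS_CONSTANT
    omega_lethal: float = 1.0

    def __post_init__(self) -> None:
        if self.frequency_factor <= 0 or self.activation_energy <= 0:
            raise ValueError("frequency_factor and activation_energy must be > 0")
        if self.gas_constant <= 0:
            raise ValueError("gas_constant must be > 0")

    def rate(self, temp_c: np.ndarray | float) -> np.ndarray | float:
        """Instantaneous damage rate A·exp(−Ea/(R·T_K)) at temperature in °C."""
        t_k = np.asarray(temp_c, dtype=float) + KELVIN_OFFSET
        return self.frequency_factor * np.exp(
            -self.activation_energy / (self.gas_constant * t_k)
        )


@dataclass
class LethalZone:
    """Binary prediction (or truth) of lethally heated tissue on one slice.

    ``mask`` keeps the full per-slice stack so callers can inspect all slices;
    ``area_mm2`` and ``slice_index`` refer to the selected (largest) slice, the
    quantity compared against necrosis in the 2D analysis.
    """

    mask: np.ndarray  # (n_slices, ny, nx) bool
    area_mm2: float
    slice_index: int
    threshold: float
    modality: str  # "prfs" | "t1" | "truth"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.area_mm2 < 0:
            raise ValueError("area must be non-negative")


def arrhenius_omega(
    temps: np.ndarray,
    times: Sequence[float],
    params: Optional[DamageModelParams] = None,
    rule: str = "left",
) -> np.ndarray:
    """Integrate the Arrhenius damage integral over a temperature history.

    Parameters
    ----------
    temps:
        Temperature history in °C with time on the first axis,
        shape ``(nt, ...)``.
    times:
        Sample times in seconds, strictly increasing, length ``nt``.
    params:
        Damage kinetics; defaults to the calibrated liver constants.
    rule:
        ``"left"`` (default) evaluates the rate at the left sample of each
        interval, matching the discrete acquisition cadence; ``"trapezoid"``
        averages the endpoint rates.

    Returns
    -------
    Ω map of shape ``temps.shape[1:]`` (dimensionless, ≥ 0).
    """
    params = params or DamageModelParams()
    temps = np.asarray(temps, dtype=float)
    times = np.asarray(times, dtype=float)
    if temps.ndim < 1 or temps.shape[0] != times.shape[0]:
        raise ValueError("temps first axis must match times length")
    if times.size == 0:
        raise ValueError("empty time vector")
    if np.any(np.diff(times) <= 0):
        raise ValueError("time vector must be strictly increasing")
    if times.size == 1:
        return np.zeros(temps.shape[1:], dtype=float)

    dt = np.diff(times)
    rates = params.rate(temps)
    if rule == "left":
        contrib = rates[:-1]
    elif rule == "trapezoid":
        contrib = 0.5 * (rates[:-1] + rates[1:])
    else:
        raise ValueError(f"unknown integration rule {rule!r}")
    # tensordot over the time axis keeps this a single BLAS-style pass
    omega = np.tensordot(dt, contrib, axes=(0, 0))
    return np.asarray(omega, dtype=float)


def peak_temperature_model(
    temps: np.ndarray, threshold: Optional[float] = None
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Per-voxel maximum temperature and, optionally, a threshold mask.

    ``temps`` has time on the first axis.  Returns ``(peak_map, mask)`` where
    ``mask`` is ``peak >= threshold`` or None when no threshold is supplied.
    """
    temps = np.asarray(temps, dtype=float)
    if temps.size == 0:
        raise ValueError("empty temperature series")
    peak = temps.max(axis=0)
    mask = None if threshold is None else peak >= threshold
    return peak, mask


def area_mm2(mask: np.ndarray, voxel_spacing: float | Sequence[float]) -> float:
    """In-plane area of a binary mask: voxel count × voxel area.

    ``voxel_spacing`` is the in-plane spacing in mm, a scalar for square voxels
    or a ``(dy, dx)`` pair.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool and not np.all(np.isin(mask, (0, 1))):
        raise ValueError("mask must be binary")
    spacing = np.atleast_1d(np.asarray(voxel_spacing, dtype=float))
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive")
    voxel_area = spacing[0] * (spacing[1] if spacing.size > 1 else spacing[0])
    return float(np.count_nonzero(mask) * voxel_area)


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
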