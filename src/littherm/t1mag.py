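"""Qualitative T1-magnitude thermometry: signal-loss detection.

Tissue T1 lengthens with temperature, so a T1-weighted FLASH image darkens
where tissue heats.  In clinical practice only a signal drop of roughly 25 %
is reliably visible as blackening of the grey scale, and the margin of the
signal-loss zone is read as the boundary of lethal impact.  This module turns
that reading into an algorithm: fractional signal drop against a pre-heating
reference, thresholding at the visibility level, and morphological cleanup
mimicking a reader outlining one coherent blackened zone per slice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .dose import LethalZone, area_mm2
from .prfs import select_peak_slice


@dataclass
class MagnitudeSeries:
    """T1-weighted magnitude images over time, shape ``(nt, n_slices, ny, nx)``."""

    signal: np.ndarray
    reference_index: int = 0
    times: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(self.signal < 0):
            raise ValueError("magnitude signal must be non-negative")
        if not (0 <= self.reference_index < self.signal.shape[0]):
            raise ValueError("reference_index out of range")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)

    @property
    def n_times(self) -> int:
        return self.signal.shape[0]


@dataclass
class SignalDropMap:
    """Fractional signal drop 1 − S(t)/S(ref), clipped to [0, 1].

    Noise-driven signal increases are clipped to zero: they are not cooling in
    this qualitative model.  ``valid`` is False where the reference signal sits
    at or below the noise floor (the ratio is meaningless there).
    """

    drop: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.drop = np.asarray(self.drop, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.drop.shape != self.valid.shape:
            raise ValueError("drop and valid shapes differ")


def signal_drop(
    series: MagnitudeSeries, t_index: int, noise_floor: float = 0.0
) -> SignalDropMap:
    """Per-voxel fractional drop of the magnitude signal at ``t_index``."""
    if t_index < series.reference_index:
        raise ValueError(
            f"t_index {t_index} precedes reference_index {series.reference_index}"
        )
    ref = series.signal[series.reference_index]
    cur = series.signal[t_index]
    valid = ref > max(noise_floor, np.finfo(float).tiny)
    with np.errstate(divide="ignore", invalid="ignore"):
        drop = 1.0 - np.where(valid, cur / np.where(valid, ref, 1.0), 0.0)
    drop = np.clip(drop, 0.0, 1.0)
    drop[~valid] = 0.0
    return SignalDropMap(drop=drop, valid=valid)


def _clean_slice(
    mask2d: np.ndarray,
    min_blob_voxels: int,
    seed_points: Optional[Sequence[tuple[int, int]]],
) -> np.ndarray:
    """Keep one coherent blob per slice: drop specks below ``min_blob_voxels``,
    then keep the component containing an applicator seed (fallback: largest)."""
    labels, n = ndimage.label(mask2d)
    if n == 0:
        return np.zeros_like(mask2d, dtype=bool)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = None
    if seed_points:
        for r, c in seed_points:
            if 0 <= r < mask2d.shape[0] and 0 <= c < mask2d.shape[1]:
                lab = labels[r, c]
                if lab > 0 and sizes[lab - 1] >= min_blob_voxels:
                    keep = lab
                    break
    if keep is None:
        order = np.argsort(sizes)[::-1]
        if sizes[order[0]] < min_blob_voxels:
            return np.zeros_like(mask2d, dtype=bool)
        keep = int(order[0]) + 1
    return labels == keep


def lethal_zone_t1(
    drop_map: SignalDropMap,
    threshold: float = 0.25,
    voxel_spacing: float | Sequence[float] = 2.5,
    min_blob_voxels: int = 2,
    seed_points: Optional[Sequence[tuple[int, int]]] = None,
) -> LethalZone:
    """Segment the predicted-lethal zone at the signal-drop visibility level.

    ``mask = drop ≥ threshold`` followed by per-slice cleanup; the applicator
    positions (in-plane voxel coordinates), when known, anchor which connected
    component is the ablation zone.  Area is reported for the largest slice.
    """
    drop = drop_map.drop
    squeeze = drop.ndim == 2
    if squeeze:
        drop = drop[None]
        valid = drop_map.valid[None]
    else:
        valid = drop_map.valid
    raw = (drop >= threshold) & valid
    mask = np.stack(
        [_clean_slice(raw[s], min_blob_voxels, seed_points) for s in range(raw.shape[0])]
    )
    s = select_peak_slice(mask)
    return LethalZone(
        mask=mask,
        area_mm2=area_mm2(mask[s], voxel_spacing),
        slice_index=s,
        threshold=threshold,
        modality="t1",
    )
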