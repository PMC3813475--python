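"""On-disk case layout: NIfTI volumes + JSON sidecar + CSV manifests.

A simulated case directory contains::

    caseNNN/
      prfs_mag.nii.gz    4D magnitude      (x, y, slice, time)
      prfs_phase.nii.gz  4D wrapped phase  (x, y, slice, time)
      t1_mag.nii.gz      4D T1-w magnitude (x, y, slice, time)
      truth_necrosis.nii.gz  3D binary mask (x, y, slice)
      sidecar.json       acquisition, regimen, ROI anchors, seed, times

In-memory arrays are time-major ``(nt, n_slices, ny, nx)`` with row-major
in-plane axes; on disk the conventional NIfTI (x, y, z, t) order is used and
the affine carries the voxel spacing (in-plane mm, slice pitch).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Optional

import nibabel as nib
import numpy as np

from .phantom import SimulatedCase, CohortConfig
from .prfs import AcquisitionParams, ComplexImageSeries
from .t1mag import MagnitudeSeries


def _affine(voxel_spacing: tuple[float, float], slice_pitch: float) -> np.ndarray:
    dy, dx = voxel_spacing
    return np.diag([dx, dy, slice_pitch, 1.0])


def write_nifti(
    path: Path | str,
    arr: np.ndarray,
    voxel_spacing: tuple[float, float],
    slice_pitch: float,
) -> None:
    """Write a (nt, ns, ny, nx) or (ns, ny, nx) array as NIfTI (x, y, z[, t])."""
    arr = np.asarray(arr)
    if arr.ndim == 4:
        data = np.transpose(arr, (3, 2, 1, 0))
    elif arr.ndim == 3:
        data = np.transpose(arr, (2, 1, 0))
    else:
        raise ValueError("expected a 3D or 4D array")
    img = nib.Nifti1Image(data.astype(np.float32), _affine(voxel_spacing, slice_pitch))
    nib.save(img, str(path))


def read_nifti(path: Path | str) -> np.ndarray:
    """Read a NIfTI volume back into the time-major in-memory convention."""
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    if data.ndim == 4:
        return np.transpose(data, (3, 2, 1, 0))
    if data.ndim == 3:
        return np.transpose(data, (2, 1, 0))
    raise ValueError("expected a 3D or 4D NIfTI")


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def dump_json(path: Path | str, payload: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2, sort_keys=True))


def write_case(case_dir: Path | str, case: SimulatedCase, config: CohortConfig) -> Path:
    """Write one simulated case (volumes + sidecar) to ``case_dir``."""
    case_dir = Path(case_dir)
    case_dir.mkdir(parents=True, exist_ok=True)
    spacing = case.temperature.voxel_spacing
    pitch = case.temperature.slice_thickness + case.temperature.slice_gap
    write_nifti(case_dir / "prfs_mag.nii.gz", case.prfs_series.magnitude, spacing, pitch)
    write_nifti(case_dir / "prfs_phase.nii.gz", case.prfs_series.phase, spacing, pitch)
    write_nifti(case_dir / "t1_mag.nii.gz", case.t1_series.signal, spacing, pitch)
    write_nifti(
        case_dir / "truth_necrosis.nii.gz",
        case.truth.necrosis_mask.astype(np.uint8),
        spacing,
        pitch,
    )
    sidecar = {
        "case_id": case.case_id,
        "seed": case.seed,
        "times_s": case.temperature.times,
        "voxel_spacing_mm": spacing,
        "slice_thickness_mm": case.temperature.slice_thickness,
        "slice_gap_mm": case.temperature.slice_gap,
        "acq_gre": config.acq_gre,
        "acq_t1": config.acq_t1,
        "t1_signal": config.t1_signal,
        "regimen": config.regimen,
        "noise_sd": config.noise_sd,
        "tumor_diameter_cm": case.tumor_diameter_cm,
        "applicator_count": case.applicator_count,
        "applicator_voxels": case.applicator_voxels(),
        "tumor_center_voxel": case.anatomy.tumor_center,
        "drift_roi_center_voxel": case.anatomy.drift_roi_center,
        "necrosis_area_mm2_per_slice": case.truth.necrosis_area,
    }
    dump_json(case_dir / "sidecar.json", sidecar)
    return case_dir


def read_sidecar(case_dir: Path | str) -> dict:
    return json.loads((Path(case_dir) / "sidecar.json").read_text())


def load_acquisition(sidecar: dict, key: str = "acq_gre") -> AcquisitionParams:
    return AcquisitionParams(**sidecar[key])


def load_complex_series(case_dir: Path | str) -> tuple[ComplexImageSeries, dict]:
    """Load the PRFS complex series and its sidecar from a case directory."""
    case_dir = Path(case_dir)
    sidecar = read_sidecar(case_dir)
    mag = read_nifti(case_dir / "prfs_mag.nii.gz")
    phase = read_nifti(case_dir / "prfs_phase.nii.gz")
    series = ComplexImageSeries(
        magnitude=mag,
        phase=phase,
        reference_index=0,
        times=np.asarray(sidecar["times_s"], dtype=float),
    )
    return series, sidecar


def load_magnitude_series(case_dir: Path | str) -> tuple[MagnitudeSeries, dict]:
    """Load the T1-magnitude series and its sidecar from a case directory."""
    case_dir = Path(case_dir)
    sidecar = read_sidecar(case_dir)
    sig = read_nifti(case_dir / "t1_mag.nii.gz")
    series = MagnitudeSeries(
        signal=np.clip(sig, 0.0, None),
        reference_index=0,
        times=np.asarray(sidecar["times_s"], dtype=float),
    )
    return series, sidecar


def load_truth_mask(case_dir: Path | str) -> np.ndarray:
    return read_nifti(Path(case_dir) / "truth_necrosis.nii.gz").astype(bool)


def list_case_dirs(root: Path | str) -> list[Path]:
    return sorted(p for p in Path(root).iterdir() if (p / "sidecar.json").exists())
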