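"""Cohort-level orchestration: simulate → reconstruct both arms → score.

The in-memory path (`analyze_case`, `run_cohort`) is what the statistics and
the acceptance checks run on; the CLI layers disk IO on top of the same
functions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as lio
from .dose import LethalZone
from .phantom import (
    Anatomy,
    CohortConfig,
    SimulatedCase,
    generate_cohort,
)
from .prfs import (
    DriftReferenceROI,
    MonitoringROI,
    SquareROI,
    TemperatureMap,
    lethal_zone_prfs,
    reconstruct_temperature,
)
from .qc import snr_dual, temperature_sd
from .stats import CaseRecord, CohortSummary, run_cohort_analysis
from .t1mag import lethal_zone_t1, signal_drop


@dataclass(frozen=True)
class AnalysisParams:
    """Reader-side parameters of the monitoring analysis."""

    roi_side: int = 20  # monitoring ROI side in voxels (400 voxels)
    lethal_threshold_c: float = 55.0
    drop_threshold: float = 0.25
    min_blob_voxels: int = 2


def _quiet_liver_roi(anatomy: Anatomy, side: int = 6) -> SquareROI:
    """A small ROI in non-heated liver, left-lateral of the tumor."""
    ny, nx = anatomy.m0.shape
    return SquareROI(center=(ny // 2, nx // 2 - int(0.3 * nx)), side=side)


def _necrosis_area_for_slice(case: SimulatedCase, slice_index: int) -> float:
    """Necrosis area measured on the modality's discriminative slice; if that
    slice shows no necrosis, the reader measures the largest necrotic slice."""
    area = float(case.truth.necrosis_area[slice_index])
    if area == 0.0:
        area = float(case.truth.necrosis_area.max())
    return area


def analyze_case(
    case: SimulatedCase,
    config: CohortConfig,
    params: AnalysisParams = AnalysisParams(),
) -> tuple[list[CaseRecord], dict]:
    """Score one case with both modalities; returns records plus QC metrics."""
    anatomy = case.anatomy
    monitor_roi = MonitoringROI(center=anatomy.tumor_center, side=params.roi_side)
    drift_roi = DriftReferenceROI(center=anatomy.drift_roi_center)
    spacing = case.temperature.voxel_spacing

    # --- PRFS arm -----------------------------------------------------------
    temp = reconstruct_temperature(
        case.prfs_series,
        config.acq_gre,
        drift_roi,
        noise_floor=config.noise_sd,
        monitoring_roi=monitor_roi,
    )
    peak_map = TemperatureMap(temp=temp.temp[-1], valid=temp.valid[-1])
    zone_prfs = lethal_zone_prfs(
        peak_map, monitor_roi, threshold=params.lethal_threshold_c, voxel_spacing=spacing
    )

    # --- T1-magnitude arm ---------------------------------------------------
    drop = signal_drop(
        case.t1_series, case.t1_series.n_times - 1, noise_floor=3.0 * config.noise_sd
    )
    zone_t1 = lethal_zone_t1(
        drop,
        threshold=params.drop_threshold,
        voxel_spacing=spacing,
        min_blob_voxels=params.min_blob_voxels,
        seed_points=case.applicator_voxels(),
    )

    records = [
        CaseRecord(
            case_id=case.case_id,
            modality="prfs",
            estimated_area_mm2=zone_prfs.area_mm2,
            necrosis_area_mm2=_necrosis_area_for_slice(case, zone_prfs.slice_index),
            tumor_diameter_cm=case.tumor_diameter_cm,
            applicator_count=case.applicator_count,
        ),
        CaseRecord(
            case_id=case.case_id,
            modality="t1",
            estimated_area_mm2=zone_t1.area_mm2,
            necrosis_area_mm2=_necrosis_area_for_slice(case, zone_t1.slice_index),
            tumor_diameter_cm=case.tumor_diameter_cm,
            applicator_count=case.applicator_count,
        ),
    ]

    # --- QC on the PRFS magnitude / temperature maps ------------------------
    liver_roi = _quiet_liver_roi(anatomy)
    qc = {
        "snr": snr_dual(
            case.prfs_series.magnitude[0], case.prfs_series.magnitude[1], liver_roi
        ),
        "temp_sd_c": temperature_sd(temp.temp[-1], liver_roi),
    }
    return records, qc


def run_cohort(
    config: Optional[CohortConfig] = None,
    n_cases: int = 34,
    seed: int = 0,
    params: AnalysisParams = AnalysisParams(),
    cases: Optional[Sequence[SimulatedCase]] = None,
) -> tuple[pd.DataFrame, CohortSummary]:
    """Simulate (or reuse) a cohort and run the full matched analysis.

    Returns the per-case record table (one row per case × modality, with QC
    columns) and the cohort summary.
    """
    config = config or CohortConfig()
    if cases is None:
        cases = generate_cohort(config, n_cases=n_cases, seed=seed)
    rows = []
    records: list[CaseRecord] = []
    for case in cases:
        recs, qc = analyze_case(case, config, params)
        records.extend(recs)
        for r in recs:
            rows.append(
                {
                    "case_id": r.case_id,
                    "modality": r.modality,
                    "estimated_area_mm2": r.estimated_area_mm2,
                    "necrosis_area_mm2": r.necrosis_area_mm2,
                    "ratio": r.ratio,
                    "predictive_error_pct": r.predictive_error_pct,
                    "tumor_diameter_cm": r.tumor_diameter_cm,
                    "applicators": r.applicator_count,
                    "snr": qc["snr"],
                    "temp_sd_c": qc["temp_sd_c"],
                }
            )
    summary = run_cohort_analysis(records)
    return pd.DataFrame(rows), summary


def records_from_frame(df: pd.DataFrame) -> list[CaseRecord]:
    """Build CaseRecords from a cases table (CLI `analyze` input format)."""
    required = {"case_id", "modality", "estimated_area_mm2", "necrosis_area_mm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cases table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        out.append(
            CaseRecord(
                case_id=str(row["case_id"]),
                modality=str(row["modality"]),
                estimated_area_mm2=float(row["estimated_area_mm2"]),
                necrosis_area_mm2=float(row["necrosis_area_mm2"]),
                tumor_diameter_cm=float(row.get("tumor_diameter_cm", float("nan"))),
                applicator_count=int(row.get("applicators", 0)),
            )
        )
    return out


def write_report(
    out_dir: Path | str,
    df: pd.DataFrame,
    summary: CohortSummary,
    make_figures: bool = True,
) -> None:
    """Write summary.json, per_case.csv and the two comparison figures."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lio.dump_json(out_dir / "summary.json", summary.to_dict())
    df.to_csv(out_dir / "per_case.csv", index=False)
    if make_figures and not df.empty:
        _figures(out_dir, df)


def _figures(out_dir: Path, df: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    groups = [
        df.loc[df.modality == m, "predictive_error_pct"].to_numpy()
        for m in ("prfs", "t1")
    ]
    ax.boxplot(groups, tick_labels=["PRFS", "T1 magnitude"])
    ax.set_ylabel("predictive error (%)")
    ax.set_title("Necrosis prediction error by modality")
    fig.tight_layout()
    fig.savefig(out_dir / "predictive_error_box.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 4))
    piv = df.pivot_table(index="case_id", columns="modality", values="ratio")
    x = np.arange(len(piv))
    width = 0.4
    ax.bar(x - width / 2, 100 * piv["prfs"], width, label="PRFS", color="#333366")
    ax.bar(x + width / 2, 100 * piv["t1"], width, label="T1 magnitude", color="#aaaacc")
    ax.axhline(100.0, color="k", lw=0.8, ls="--")
    ax.set_ylabel("estimated / necrosis (%)")
    ax.set_xlabel("case")
    ax.set_xticks([])
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "ratio_bars.png", dpi=120)
    plt.close(fig)


def config_digest(config: CohortConfig, params: AnalysisParams, seed: int) -> str:
    payload = lio._jsonable(
        {"config": config, "analysis": params, "seed": seed}
    )
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()[:16]
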