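"""Cohort comparison statistics for thermometry accuracy.

Each case contributes the predicted lethal-zone area of one monitoring
modality and the ground-truth necrosis area.  The accuracy statistic is the
predictive error: the estimated area as a percentage of the necrosis area
(necrosis = 100 %), with underestimation positive,

    ratio = estimated / necrosis,   error% = (1 − ratio) · 100.

Cohorts are compared nonparametrically: Spearman rank correlation between
estimated and true areas within each modality (two-sided, exact permutation p
for n ≤ 8), and Mann-Whitney U between modalities on the area ratios and on
the necrosis extents (exact enumeration p for small tie-free samples, normal
approximation with tie and continuity corrections otherwise).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

SPEARMAN_EXACT_MAX_N = 8
MANNWHITNEY_EXACT_MAX_N = 14


@dataclass
class CaseRecord:
    """Per-case accuracy record for one modality."""

    case_id: str
    modality: str  # "prfs" | "t1"
    estimated_area_mm2: float
    necrosis_area_mm2: float
    tumor_diameter_cm: float = float("nan")
    applicator_count: int = 0

    @property
    def ratio(self) -> float:
        if self.necrosis_area_mm2 <= 0:
            return float("nan")
        return self.estimated_area_mm2 / self.necrosis_area_mm2

    @property
    def predictive_error_pct(self) -> float:
        """Positive = underestimation, negative = overestimation."""
        return (1.0 - self.ratio) * 100.0


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")


def predictive_error(
    estimated_area: float, necrosis_area: float
) -> tuple[float, float]:
    """Area ratio and signed predictive error in % (necrosis = 100 %).

    Examples: estimated 78 vs necrosis 100 → ratio 0.78, underestimation 22 %;
    estimated 103 vs 100 → overestimation 3 % (error −3).
    """
    if necrosis_area <= 0:
        raise ValueError("necrosis_area must be > 0 for a predictive error")
    ratio = estimated_area / necrosis_area
    return ratio, (1.0 - ratio) * 100.0


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with a two-sided p-value.

    Average ranks for ties.  For n ≤ 8 the p-value is the exact permutation
    probability of |rho| at least as large as observed (all n! pairings);
    larger samples use the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("rank correlation undefined for a constant vector")
    rx, ry = _rank(x), _rank(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= SPEARMAN_EXACT_MAX_N:
        perms = np.array(list(itertools.permutations(range(n))))
        ry_c = ry - ry.mean()
        rx_c = rx - rx.mean()
        denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        rhos = (ry_c[perms] @ rx_c) / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        method = "spearman-exact-permutation"
    else:
        p = float(sps.spearmanr(x, y).pvalue)
        method = "spearman-t-approx"
    return TestResult(statistic=rho, p_value=p, method=method, n1=n)


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test between two independent samples.

    Exact null distribution when n1+n2 ≤ 14 and no ties are present;
    otherwise the normal approximation with tie correction and continuity
    correction.  Ties receive average ranks.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    exact = (a.size + b.size) <= MANNWHITNEY_EXACT_MAX_N and not has_ties
    res = sps.mannwhitneyu(
        a,
        b,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        method="mannwhitney-exact" if exact else "mannwhitney-normal-approx",
        n1=int(a.size),
        n2=int(b.size),
    )


@dataclass
class ModalitySummary:
    modality: str
    n: int
    median_ratio: float
    ratio_range: tuple[float, float]
    median_error_pct: float
    error_range_pct: tuple[float, float]
    spearman: TestResult


@dataclass
class CohortSummary:
    """Cohort-level comparison of the two monitoring modalities."""

    prfs: ModalitySummary
    t1: ModalitySummary
    mw_ratio: TestResult  # between-arm test on estimated/necrosis ratios
    mw_necrosis: TestResult  # between-arm test on true necrosis extents

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _summarize(modality: str, records: list[CaseRecord]) -> ModalitySummary:
    ratios = np.array([r.ratio for r in records])
    errors = np.array([r.predictive_error_pct for r in records])
    est = np.array([r.estimated_area_mm2 for r in records])
    nec = np.array([r.necrosis_area_mm2 for r in records])
    try:
        spearman = spearman_rho(est, nec)
    except ValueError:
        # degenerate column (constant areas or < 3 cases): flagged, not fatal
        spearman = TestResult(
            statistic=float("nan"),
            p_value=float("nan"),
            method="spearman-undefined",
            n1=len(records),
        )
    return ModalitySummary(
        modality=modality,
        n=len(records),
        median_ratio=float(np.median(ratios)),
        ratio_range=(float(ratios.min()), float(ratios.max())),
        median_error_pct=float(np.median(errors)),
        error_range_pct=(float(errors.min()), float(errors.max())),
        spearman=spearman,
    )


def run_cohort_analysis(records: Sequence[CaseRecord]) -> CohortSummary:
    """Full matched-cohort analysis over per-case records of both modalities.

    Computes per-modality medians/ranges of the area ratio and predictive
    error, Spearman correlation of estimated vs necrosis areas per modality,
    and between-modality Mann-Whitney tests on the ratios and on the necrosis
    extents.
    """
    by_mod: dict[str, list[CaseRecord]] = {}
    for r in records:
        by_mod.setdefault(r.modality, []).append(r)
    if "prfs" not in by_mod or "t1" not in by_mod:
        raise ValueError("records must contain both 'prfs' and 't1' modalities")
    prfs = _summarize("prfs", by_mod["prfs"])
    t1 = _summarize("t1", by_mod["t1"])
    ratios_p = [r.ratio for r in by_mod["prfs"]]
    ratios_t = [r.ratio for r in by_mod["t1"]]
    nec_p = [r.necrosis_area_mm2 for r in by_mod["prfs"]]
    nec_t = [r.necrosis_area_mm2 for r in by_mod["t1"]]
    return CohortSummary(
        prfs=prfs,
        t1=t1,
        mw_ratio=mann_whitney_u(ratios_p, ratios_t),
        mw_necrosis=mann_whitney_u(nec_p, nec_t),
    )
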