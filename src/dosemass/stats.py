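"""Cohort-level statistics: paired deltas, Wilcoxon tests, DVH-vs-DMH
regression with zero crossing, and Spearman correlation tables.

Conventions: deltas are always DIBH - FB; relative deltas are normalized to
the FB value and reported in percent; cohort relative deltas are the mean of
per-patient relative deltas (a delta-of-means variant is emitted alongside
for transparency); SDs are sample SDs (ddof=1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatisticsError

EXACT_WILCOXON_MAX_N = 25


# ---------------------------------------------------------------------------
# Paired deltas
# ---------------------------------------------------------------------------

def paired_delta(fb_value: float, dibh_value: float) -> Tuple[float, float]:
    """(DIBH - FB, relative delta in % of FB).

    The relative delta is NaN (flagged, not raised) when the FB value is 0.
    """
    if not np.isfinite(fb_value):
        raise StatisticsError("FB value must be finite")
    delta = dibh_value - fb_value
    relative = delta * 100.0 / fb_value if fb_value != 0 else float("nan")
    return float(delta), float(relative)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _signed_rank_statistic(diffs: np.ndarray) -> Tuple[float, np.ndarray]:
    ranks = sps.rankdata(np.abs(diffs))  # midranks for ties
    w_plus = float(ranks[diffs > 0].sum())
    return w_plus, ranks


def _exact_two_sided_p(w_plus: float, ranks: np.ndarray) -> float:
    """Exact p by dynamic programming over all 2^n sign assignments.

    Midranks are doubled so the DP runs on integers; counts are exact
    (python ints), so this matches full enumeration bit-for-bit.
    """
    r2 = np.round(2.0 * ranks).astype(int)
    total = int(r2.sum())
    counts = [0] * (total + 1)
    counts[0] = 1
    for r in r2:
        nxt = counts[:]
        for value in range(total - r + 1):
            if counts[value]:
                nxt[value + r] += counts[value]
        counts = nxt
    w2 = int(round(2.0 * w_plus))
    lo = min(w2, total - w2)
    hi = total - lo
    n_low = sum(counts[: lo + 1])
    n_high = sum(counts[hi:])
    return min(1.0, (n_low + n_high) / float(2 ** len(ranks)))


def wilcoxon_signed_rank(pairs: Sequence[Tuple[float, float]]) -> float:
    """Two-sided Wilcoxon signed-rank p for (FB, DIBH) pairs.

    Zero differences are dropped (Wilcoxon convention).  The exact null
    distribution is used for n <= 25 non-tied pairs; otherwise the normal
    approximation with tie correction (no continuity correction).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise StatisticsError("pairs must be (n, 2)")
    diffs = arr[:, 1] - arr[:, 0]
    diffs = diffs[diffs != 0.0]
    n = diffs.size
    if n == 0:
        raise StatisticsError("all pairs tied: Wilcoxon test undefined")
    w_plus, ranks = _signed_rank_statistic(diffs)
    if n <= EXACT_WILCOXON_MAX_N:
        return _exact_two_sided_p(w_plus, ranks)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:
        raise StatisticsError("zero variance: Wilcoxon test undefined")
    z = (w_plus - mean) / math.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Regression with zero crossing
# ---------------------------------------------------------------------------

@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    x_at_y0: float  # NaN when the slope is 0 (flagged, not raised)
    crossing_defined: bool
    n: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "x_at_y0": self.x_at_y0,
            "crossing_defined": self.crossing_defined,
            "n": self.n,
        }


def regression_zero_crossing(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x and the x where the fit crosses 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise StatisticsError("regression needs >= 3 finite points")
    if np.ptp(x) == 0:
        raise StatisticsError("x is constant: regression undefined")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    if slope == 0.0:
        return RegressionResult(0.0, float(intercept), r_squared, float("nan"), False, x.size)
    return RegressionResult(
        float(slope), float(intercept), float(r_squared), float(-intercept / slope), True, x.size
    )


# ---------------------------------------------------------------------------
# Spearman correlations
# ---------------------------------------------------------------------------

def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def spearman_correlations(
    factors: Dict[str, Sequence[float]] | pd.DataFrame,
    deltas: Dict[str, Sequence[float]] | pd.DataFrame,
) -> pd.DataFrame:
    """Spearman r (+p, significance stars) for every factor x delta pair.

    Rows are delta metrics, columns are factors (correlation-table layout).
    Constant columns give NaN r with an ``undefined`` marker instead of an
    exception.
    """
    factors = pd.DataFrame(factors)
    deltas = pd.DataFrame(deltas)
    if len(factors) != len(deltas):
        raise StatisticsError("factors and deltas must cover the same patients")
    if len(factors) < 5:
        raise StatisticsError("Spearman correlations need n >= 5")
    records = {}
    for dname in deltas.columns:
        row = {}
        for fname in factors.columns:
            x = np.asarray(factors[fname], dtype=float)
            y = np.asarray(deltas[dname], dtype=float)
            keep = np.isfinite(x) & np.isfinite(y)
            if keep.sum() < 5 or np.ptp(x[keep]) == 0 or np.ptp(y[keep]) == 0:
                row[fname] = {"r": float("nan"), "p": float("nan"), "stars": "", "undefined": True}
                continue
            r, p = sps.spearmanr(x[keep], y[keep])
            row[fname] = {"r": float(r), "p": float(p), "stars": _stars(p), "undefined": False}
        records[dname] = row
    table = pd.DataFrame(records).T
    table.index.name = "delta_metric"
    return table


def correlation_table_flat(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format view of :func:`spearman_correlations` output for CSV."""
    rows = []
    for dname, row in table.iterrows():
        for fname, cell in row.items():
            rows.append(
                {
                    "delta_metric": dname,
                    "factor": fname,
                    "r": cell["r"],
                    "p": cell["p"],
                    "significance": cell["stars"],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class PatientMetrics:
    """Per-patient scalar metrics for both phases plus anatomical factors.

    ``dose_metrics[phase][structure]`` are flat dicts of named scalars
    (e.g. ``dmean_dvh_gy``, ``v20_rel_pct``); ``expansion`` holds the
    lung / V20-region expansion summaries when registration ran.
    """

    patient_id: str
    dose_metrics: Dict[str, Dict[str, Dict[str, float]]]
    anatomy: Dict[str, float] = field(default_factory=dict)
    expansion: Dict[str, dict] = field(default_factory=dict)
    adverse: bool = False

    def scalar(self, phase: str, structure: str, key: str) -> float:
        return self.dose_metrics[phase][structure][key]

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "dose_metrics": self.dose_metrics,
            "anatomy": self.anatomy,
            "expansion": self.expansion,
            "adverse": self.adverse,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "PatientMetrics":
        return cls(
            patient_id=payload["patient_id"],
            dose_metrics=payload["dose_metrics"],
            anatomy=payload.get("anatomy", {}),
            expansion=payload.get("expansion", {}),
            adverse=payload.get("adverse", False),
        )


@dataclass
class CohortResult:
    summary: pd.DataFrame
    tests: Dict[str, float]
    regressions: Dict[str, RegressionResult]
    correlations: Optional[pd.DataFrame]
    per_patient: pd.DataFrame


def _mean_sd(values: np.ndarray) -> Tuple[float, float]:
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    return float(np.mean(values)), sd


#: (row label, structure, scalar key) pairs summarized phase-by-phase.
SUMMARY_ROWS = [
    ("ptv_volume_cm3", "ptv", "volume_cm3"),
    ("lung_volume_cm3", "left_lung", "volume_cm3"),
    ("lung_mass_g", "left_lung", "mass_g"),
    ("lung_density_g_cm3", "left_lung", "mean_density_g_cm3"),
    ("lung_dmean_dvh_gy", "left_lung", "dmean_dvh_gy"),
    ("lung_dmean_dmh_gy", "left_lung", "dmean_dmh_gy"),
    ("lung_v20_rel_pct", "left_lung", "v20_rel_pct"),
    ("lung_v20_abs_cm3", "left_lung", "v20_abs_cm3"),
    ("lung_m20_rel_pct", "left_lung", "m20_rel_pct"),
    ("lung_m20_abs_g", "left_lung", "m20_abs_g"),
    ("heart_dmean_dvh_gy", "heart", "dmean_dvh_gy"),
    ("heart_v20_rel_pct", "heart", "v20_rel_pct"),
    ("heart_v40_rel_pct", "heart", "v40_rel_pct"),
]


def build_summary(patients: List[PatientMetrics]) -> CohortResult:
    """Aggregate per-patient metrics into the cohort tables.

    Emits the phase summary (mean +- SD for FB, DIBH, delta and relative
    delta), Wilcoxon p per metric, the DVH-vs-DMH regressions with zero
    crossings, and (for n >= 5) the Spearman correlation table.
    """
    if len(patients) < 2:
        raise StatisticsError("cohort needs >= 2 patients")

    long_rows = []
    for pm in patients:
        row: Dict[str, float] = {"patient_id": pm.patient_id, "adverse": pm.adverse}
        for label, structure, key in SUMMARY_ROWS:
            try:
                fb = pm.scalar("fb", structure, key)
                dibh = pm.scalar("dibh", structure, key)
            except KeyError:
                continue
            if fb is None or dibh is None:
                continue
            delta, rel = paired_delta(fb, dibh)
            row[f"{label}_fb"] = fb
            row[f"{label}_dibh"] = dibh
            row[f"{label}_delta"] = delta
            row[f"{label}_delta_rel_pct"] = rel
        for key, value in pm.anatomy.items():
            row[f"anatomy_{key}"] = value
        for struct, exp in pm.expansion.items():
            for key, value in exp.items():
                if isinstance(value, (int, float)):
                    row[f"expansion_{struct}_{key}"] = value
        long_rows.append(row)
    per_patient = pd.DataFrame(long_rows).set_index("patient_id")

    summary_rows = []
    tests: Dict[str, float] = {}
    for label, _, _ in SUMMARY_ROWS:
        if f"{label}_fb" not in per_patient.columns:
            continue
        fb = per_patient[f"{label}_fb"].to_numpy(dtype=float)
        dibh = per_patient[f"{label}_dibh"].to_numpy(dtype=float)
        delta = per_patient[f"{label}_delta"].to_numpy(dtype=float)
        rel = per_patient[f"{label}_delta_rel_pct"].to_numpy(dtype=float)
        fb_m, fb_s = _mean_sd(fb)
        di_m, di_s = _mean_sd(dibh)
        de_m, de_s = _mean_sd(delta)
        re_m, re_s = _mean_sd(rel)
        try:
            p = wilcoxon_signed_rank(np.column_stack([fb, dibh]))
        except StatisticsError:
            p = float("nan")
        tests[label] = p
        summary_rows.append(
            {
                "metric": label,
                "fb_mean": fb_m,
                "fb_sd": fb_s,
                "dibh_mean": di_m,
                "dibh_sd": di_s,
                "delta_mean": de_m,
                "delta_sd": de_s,
                "delta_rel_mean_pct": re_m,
                "delta_rel_sd_pct": re_s,
                "delta_rel_of_means_pct": (di_m - fb_m) * 100.0 / fb_m if fb_m else float("nan"),
                "wilcoxon_p": p,
            }
        )
    summary = pd.DataFrame(summary_rows).set_index("metric")

    regressions: Dict[str, RegressionResult] = {}
    for name, xcol, ycol in [
        ("dmean_dvh_vs_dmh", "lung_dmean_dvh_gy_delta_rel_pct", "lung_dmean_dmh_gy_delta_rel_pct"),
        ("v20_vs_m20", "lung_v20_rel_pct_delta_rel_pct", "lung_m20_rel_pct_delta_rel_pct"),
    ]:
        if xcol in per_patient.columns and ycol in per_patient.columns:
            try:
                regressions[name] = regression_zero_crossing(per_patient[xcol], per_patient[ycol])
            except StatisticsError:
                pass

    correlations = None
    factor_cols = [c for c in per_patient.columns if c.startswith(("anatomy_", "expansion_"))]
    delta_cols = [
        c
        for c in per_patient.columns
        if c.endswith("_delta_rel_pct") and c.startswith(("lung_dmean", "lung_v20_rel", "lung_m20_rel", "heart_dmean"))
    ]
    if len(per_patient) >= 5 and factor_cols and delta_cols:
        correlations = spearman_correlations(
            per_patient[factor_cols], per_patient[delta_cols]
        )

    return CohortResult(
        summary=summary,
        tests=tests,
        regressions=regressions,
        correlations=correlations,
        per_patient=per_patient,
    )
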