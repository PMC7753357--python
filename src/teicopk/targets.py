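"""PK/PD target attainment: PTA, CFR and optimal-dose search.

Efficacy is judged two ways, mirroring the study design:

* trough targets — a regimen is optimal when the cohort MEAN trough
  reaches 10 mg/L (moderate infection) or 15 mg/L (severe infection);
* AUC24/MIC targets — steady-state AUC24 = daily dose / CL per subject,
  PTA at each MIC is the fraction of subjects with AUC24/MIC at or above
  the ratio target (125 moderate, 345 severe), and CFR is the
  MIC-frequency-weighted average of PTAs; CFR >= 90% qualifies a dose.

Loading regimens are optimized against trough targets only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .cohort import VirtualCohort
from .regimens import (
    DEFAULT_SCR_CUT,
    DEFAULT_WT_BINS,
    RegimenPolicy,
    cohort_troughs,
)

__all__ = [
    "MICDistribution",
    "TargetSpec",
    "pta",
    "cfr",
    "cohort_auc24",
    "optimal_dose_trough",
    "optimal_dose_cfr",
    "dose_table",
    "example_mrsa_mic_distribution",
    "DEFAULT_DOSE_GRID",
]

DEFAULT_DOSE_GRID = tuple(range(4, 26))  # mg/kg, integer scan
_TOL = 1e-9  # comparison tolerance for ">= threshold" at the optimum


@dataclass(frozen=True)
class MICDistribution:
    """Discrete MIC strata (mg/L) with relative frequencies.

    Frequencies are normalized to sum to one on construction (with a
    warning when they do not already).
    """

    mics: np.ndarray
    frequencies: np.ndarray

    def __init__(self, mics, frequencies):
        mics = np.asarray(mics, dtype=float)
        freqs = np.asarray(frequencies, dtype=float)
        if mics.size == 0 or mics.size != freqs.size:
            raise ValueError("mics and frequencies must be equal-length, non-empty")
        if np.any(mics <= 0) or np.any(np.diff(mics) <= 0):
            raise ValueError("mics must be positive and strictly increasing")
        if np.any(freqs < 0):
            raise ValueError("frequencies must be non-negative")
        total = freqs.sum()
        if total <= 0:
            raise ValueError("frequencies must have positive mass")
        if not np.isclose(total, 1.0):
            warnings.warn("MIC frequencies do not sum to 1; normalizing", stacklevel=2)
        object.__setattr__(self, "mics", mics)
        object.__setattr__(self, "frequencies", freqs / total)

    @staticmethod
    def from_csv(path) -> "MICDistribution":
        df = pd.read_csv(path, comment="#")
        return MICDistribution(df["mic_mg_per_L"], df["frequency"])


def example_mrsa_mic_distribution() -> MICDistribution:
    """Bundled synthetic example MRSA teicoplanin MIC distribution.

    A stand-in snapshot constructed to resemble the qualitative shape of
    surveillance distributions for teicoplanin against S. aureus (mode at
    0.5 mg/L, wild type below 2 mg/L); it is NOT surveillance data, and
    any CFR computed from it is conditional on this choice.
    """
    with resources.files("teicopk").joinpath(
        "data/mic_mrsa_synthetic_example.csv"
    ).open() as fh:
        return MICDistribution.from_csv(fh)


@dataclass(frozen=True)
class TargetSpec:
    """A trough (mg/L) or AUC24/MIC (unitless ratio) efficacy target."""

    kind: str  # "trough" | "auc_ratio"
    threshold: float
    eval_time: float | None = None  # trough targets only

    def __post_init__(self) -> None:
        if self.kind not in ("trough", "auc_ratio"):
            raise ValueError(f"unknown target kind {self.kind!r}")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


def pta(auc24_values, mic: float, ratio_target: float) -> float:
    """Fraction of subjects with AUC24/MIC at or above the ratio target."""
    auc = np.asarray(auc24_values, dtype=float)
    if auc.size == 0:
        raise ValueError("auc24_values must be non-empty")
    if mic <= 0:
        raise ValueError("MIC must be positive")
    return float(np.mean(auc / mic >= ratio_target))


def cfr(auc24_values, dist: MICDistribution, ratio_target: float) -> float:
    """MIC-frequency-weighted average of PTAs (cumulative fraction of response)."""
    ptas = np.array([pta(auc24_values, m, ratio_target) for m in dist.mics])
    return float(np.dot(dist.frequencies, ptas))


def cohort_auc24(cohort: VirtualCohort, dose_per_kg_day: float) -> np.ndarray:
    """Steady-state AUC24 (mg*h/L) per subject: daily dose / CL."""
    return dose_per_kg_day * cohort.wt / cohort.cl


def optimal_dose_trough(
    cohort: VirtualCohort,
    regimen_kind: str,
    target: TargetSpec,
    dose_grid=DEFAULT_DOSE_GRID,
) -> int | None:
    """Smallest grid dose (mg/kg) whose cohort-mean trough meets the target.

    Returns ``None`` when no grid dose qualifies.
    """
    if target.kind != "trough":
        raise ValueError("optimal_dose_trough needs a trough target")
    grid = list(dose_grid)
    if not grid:
        raise ValueError("dose grid must be non-empty")
    for dose in grid:
        policy = RegimenPolicy(regimen_kind, float(dose))
        mean = float(np.mean(cohort_troughs(cohort, policy, target.eval_time)))
        if mean >= target.threshold - _TOL:
            return int(dose)
    return None


def optimal_dose_cfr(
    cohort: VirtualCohort,
    ratio_target: float,
    dist: MICDistribution,
    dose_grid=DEFAULT_DOSE_GRID,
    cfr_min: float = 0.90,
) -> int | None:
    """Smallest once-daily dose (mg/kg/day) with CFR at or above ``cfr_min``."""
    grid = list(dose_grid)
    if not grid:
        raise ValueError("dose grid must be non-empty")
    for dose in grid:
        if cfr(cohort_auc24(cohort, float(dose)), dist, ratio_target) >= cfr_min - _TOL:
            return int(dose)
    return None


def dose_table(
    cohort: VirtualCohort,
    mic_dist: MICDistribution | None = None,
    wt_bins=DEFAULT_WT_BINS,
    scr_cut: float = DEFAULT_SCR_CUT,
    dose_grid=DEFAULT_DOSE_GRID,
    trough_targets=(10.0, 15.0),
    ratio_targets=(125.0, 345.0),
    cfr_min: float = 0.90,
) -> pd.DataFrame:
    """Optimal-dose report per weight x creatinine subgroup plus overall.

    Columns: per trough target the optimal loading (q12h x3, 48-h trough)
    and maintenance (q24h, 96-h trough) doses; per AUC24/MIC ratio target
    the optimal once-daily dose by CFR (only when a MIC distribution is
    supplied).  Cells where no grid dose qualifies hold NaN.
    """
    from .regimens import _bin_labels  # shared bin labelling

    wt = cohort.wt
    scr = cohort.data["scr"].to_numpy()
    edges = np.concatenate([[-np.inf], np.asarray(wt_bins, float), [np.inf]])
    labels = _bin_labels(wt_bins)
    wt_idx = np.digitize(wt, edges[1:-1])

    cells: list[tuple[str, str, np.ndarray]] = []
    for bi, label in enumerate(labels):
        cells.append((label, f"<{scr_cut:g}", (wt_idx == bi) & (scr < scr_cut)))
        cells.append((label, f">={scr_cut:g}", (wt_idx == bi) & (scr >= scr_cut)))
    cells.append(("overall", "all", np.ones(len(cohort), dtype=bool)))

    rows = []
    for wt_label, scr_label, mask in cells:
        row: dict = {"wt_bin": wt_label, "scr_group": scr_label, "n": int(mask.sum())}
        if mask.sum() == 0:
            rows.append(row)
            continue
        sub = cohort.subset(mask)
        for thr in trough_targets:
            t = TargetSpec("trough", thr)
            row[f"loading_cmin{thr:g}"] = optimal_dose_trough(sub, "loading", t, dose_grid)
            row[f"maintenance_cmin{thr:g}"] = optimal_dose_trough(
                sub, "maintenance", t, dose_grid
            )
        if mic_dist is not None:
            for rt in ratio_targets:
                row[f"maintenance_cfr{rt:g}"] = optimal_dose_cfr(
                    sub, rt, mic_dist, dose_grid, cfr_min
                )
        rows.append(row)
    return pd.DataFrame(rows)
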