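"""Weight-based dosing regimens and cohort trough simulation.

Loading regimens are 3 doses q12h with the trough read 48 h after the
first dose (24 h after the last loading dose starts); maintenance
regimens are once-daily doses from t = 0 with the steady-state-ish trough
read at 96 h, immediately before what would be the fifth dose.  Troughs
are computed with the closed-form infusion model vectorized across the
cohort, each subject keeping its own fixed covariates and random effects
(common random numbers across doses in a scan).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import VirtualCohort
from .pk_core import DoseEvent, Regimen

__all__ = [
    "RegimenPolicy",
    "TroughSummary",
    "build_regimen",
    "cohort_troughs",
    "simulate_troughs",
    "toxicity_fraction",
    "subgroup_summaries",
    "DEFAULT_WT_BINS",
    "DEFAULT_SCR_CUT",
]

DEFAULT_WT_BINS = (10.0, 20.0, 30.0)  # kg cut points -> <10, [10,20), [20,30), >=30
DEFAULT_SCR_CUT = 44.0  # umol/L


@dataclass(frozen=True)
class RegimenPolicy:
    """A weight-based loading or maintenance dosing policy."""

    kind: str  # "loading" | "maintenance"
    dose_per_kg: float
    interval: float | None = None  # h; defaults 12 (loading) / 24 (maintenance)
    n_doses: int | None = None  # defaults 3 (loading) / 4 (maintenance)
    infusion_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("loading", "maintenance"):
            raise ValueError(f"unknown regimen kind {self.kind!r}")
        if self.dose_per_kg <= 0:
            raise ValueError("dose_per_kg must be positive")
        if self.interval is None:
            object.__setattr__(self, "interval", 12.0 if self.kind == "loading" else 24.0)
        if self.n_doses is None:
            object.__setattr__(self, "n_doses", 3 if self.kind == "loading" else 4)
        if self.interval <= 0 or self.n_doses < 1:
            raise ValueError("interval must be positive and n_doses >= 1")

    @property
    def default_eval_time(self) -> float:
        """Trough read-out: 48 h (loading) or 96 h (maintenance)."""
        return 48.0 if self.kind == "loading" else 96.0

    @staticmethod
    def loading(dose_per_kg: float, **kw) -> "RegimenPolicy":
        return RegimenPolicy("loading", dose_per_kg, **kw)

    @staticmethod
    def maintenance(dose_per_kg: float, **kw) -> "RegimenPolicy":
        return RegimenPolicy("maintenance", dose_per_kg, **kw)


def build_regimen(policy: RegimenPolicy, wt: float) -> Regimen:
    """Concrete dose events for one subject of weight ``wt`` kg."""
    if wt <= 0:
        raise ValueError("weight must be positive")
    amount = policy.dose_per_kg * wt
    return Regimen(
        tuple(
            DoseEvent(i * policy.interval, amount, policy.infusion_duration)
            for i in range(policy.n_doses)
        )
    )


@dataclass(frozen=True)
class TroughSummary:
    """Per-subject troughs with the summaries the dose tables report."""

    troughs: np.ndarray
    eval_time: float

    @property
    def n(self) -> int:
        return self.troughs.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.troughs))

    @property
    def sd(self) -> float:
        return float(np.std(self.troughs, ddof=1)) if self.n > 1 else 0.0

    @property
    def frac_ge_10(self) -> float:
        return float(np.mean(self.troughs >= 10.0))

    @property
    def frac_ge_15(self) -> float:
        return float(np.mean(self.troughs >= 15.0))

    @property
    def frac_gt_60(self) -> float:
        return float(np.mean(self.troughs > 60.0))


def cohort_troughs(
    cohort: VirtualCohort, policy: RegimenPolicy, eval_time: float | None = None
) -> np.ndarray:
    """Trough concentration per cohort member, vectorized.

    Identical (to floating-point round-off) to looping
    :func:`teicopk.pk_core.conc_profile` subject by subject.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    t_eval = policy.default_eval_time if eval_time is None else float(eval_time)
    cl = cohort.cl
    v = cohort.v
    k = cl / v
    amounts = policy.dose_per_kg * cohort.wt  # (n,)
    dur = policy.infusion_duration
    total = np.zeros_like(cl)
    for i in range(policy.n_doses):
        t0 = i * policy.interval
        tau = t_eval - t0
        if tau < 0:
            continue
        rate = amounts / dur
        if tau < dur:
            total += (rate / cl) * (1.0 - np.exp(-k * tau))
        else:
            ceoi = (rate / cl) * (1.0 - np.exp(-k * dur))
            total += ceoi * np.exp(-k * (tau - dur))
    return total


def simulate_troughs(
    cohort: VirtualCohort, policy: RegimenPolicy, eval_time: float | None = None
) -> TroughSummary:
    """Trough distribution summary for a cohort under one policy."""
    t_eval = policy.default_eval_time if eval_time is None else float(eval_time)
    return TroughSummary(cohort_troughs(cohort, policy, t_eval), t_eval)


def toxicity_fraction(summary: TroughSummary, threshold: float = 60.0) -> float:
    """Fraction of troughs strictly above the potentially toxic threshold."""
    if summary.n == 0:
        raise ValueError("empty trough summary")
    return float(np.mean(summary.troughs > threshold))


def subgroup_summaries(
    cohort: VirtualCohort,
    policy: RegimenPolicy,
    wt_bins=DEFAULT_WT_BINS,
    scr_cut: float = DEFAULT_SCR_CUT,
    eval_time: float | None = None,
) -> pd.DataFrame:
    """Trough summaries per weight-bin x creatinine-group cell.

    Weight bins are left-closed intervals defined by ``wt_bins`` cut
    points; the creatinine split is ``< scr_cut`` vs ``>= scr_cut``.
    Returns a tidy frame (one row per cell) with n, mean, sd and the
    target-attainment fractions; empty cells keep n = 0 and NaN stats.
    """
    t_eval = policy.default_eval_time if eval_time is None else float(eval_time)
    troughs = cohort_troughs(cohort, policy, t_eval)
    wt = cohort.wt
    scr = cohort.data["scr"].to_numpy()
    edges = np.concatenate([[-np.inf], np.asarray(wt_bins, float), [np.inf]])
    labels = _bin_labels(wt_bins)
    wt_idx = np.digitize(wt, edges[1:-1])
    rows = []
    for bi, label in enumerate(labels):
        for scr_label, scr_mask in (
            (f"<{scr_cut:g}", scr < scr_cut),
            (f">={scr_cut:g}", scr >= scr_cut),
        ):
            mask = (wt_idx == bi) & scr_mask
            cell = troughs[mask]
            if cell.size:
                s = TroughSummary(cell, t_eval)
                rows.append(
                    dict(
                        wt_bin=label,
                        scr_group=scr_label,
                        n=s.n,
                        mean=s.mean,
                        sd=s.sd,
                        frac_ge_10=s.frac_ge_10,
                        frac_ge_15=s.frac_ge_15,
                        frac_gt_60=s.frac_gt_60,
                    )
                )
            else:
                rows.append(
                    dict(
                        wt_bin=label,
                        scr_group=scr_label,
                        n=0,
                        mean=np.nan,
                        sd=np.nan,
                        frac_ge_10=np.nan,
                        frac_ge_15=np.nan,
                        frac_gt_60=np.nan,
                    )
                )
    return pd.DataFrame(rows)


def _bin_labels(wt_bins) -> list[str]:
    cuts = [f"{c:g}" for c in wt_bins]
    labels = [f"<{cuts[0]}"]
    labels += [f"[{a},{b})" for a, b in zip(cuts[:-1], cuts[1:])]
    labels.append(f">={cuts[-1]}")
    return labels
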