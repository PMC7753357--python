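"""Virtual pediatric cohorts and synthetic sparse-TDM datasets.

The study population (159 Chinese children, sparse therapeutic-drug-
monitoring sampling) is emulated from its published summary statistics:
weight, serum creatinine and age are drawn from truncated log-normal
marginals moment-matched to the reported mean/SD and clipped to the
reported ranges; sex is Bernoulli.  Subject-level random effects are
log-normal per the final model, residual error exponential (7% CV), and
concentrations below the assay's lower limit of quantification (2.5 mg/L)
are recorded at that limit, as in the original data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import warnings

import numpy as np
import pandas as pd

from .covariates import OmegaSet, SigmaSet, ThetaSet, individual_cl, individual_vd
from .pk_core import DoseEvent, PKParameters, Regimen, conc_profile

__all__ = [
    "CovariateDistribution",
    "CovariateSpec",
    "VirtualCohort",
    "EtaScheme",
    "sample_covariates",
    "sample_random_effects",
    "make_cohort",
    "TroughSampling",
    "FixedTimesSampling",
    "StandardRegimenPolicy",
    "simulate_tdm_dataset",
    "LLOQ_DEFAULT",
]

LLOQ_DEFAULT = 2.5  # mg/L, assay lower limit of quantification


@dataclass(frozen=True)
class CovariateDistribution:
    """Truncated log-normal descriptor for one continuous covariate."""

    mean: float
    sd: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if not self.minimum < self.maximum:
            raise ValueError("minimum must be below maximum")
        if not (self.minimum <= self.mean <= self.maximum):
            raise ValueError("mean must lie inside [minimum, maximum]")


@dataclass(frozen=True)
class CovariateSpec:
    """Study-population covariate distributions (defaults = the pediatric cohort summaries)."""

    wt: CovariateDistribution = field(
        default_factory=lambda: CovariateDistribution(16.7, 10.1, 2.9, 69.0)
    )
    scr: CovariateDistribution = field(
        default_factory=lambda: CovariateDistribution(29.1, 17.3, 10.0, 139.0)
    )
    age: CovariateDistribution = field(
        default_factory=lambda: CovariateDistribution(4.1, 3.4, 0.2, 14.0)
    )
    male_fraction: float = 0.547

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale (mu, sigma) of an untruncated log-normal with these moments."""
    var = sd * sd
    sigma2 = np.log1p(var / (mean * mean))
    mu = np.log(mean) - 0.5 * sigma2
    return mu, float(np.sqrt(sigma2))


def _truncated_lognormal_moment(mu: float, sig: float, lo: float, hi: float, k: int) -> float:
    """k-th moment of a log-normal truncated to [lo, hi]."""
    from scipy.stats import norm

    a = (np.log(lo) - mu) / sig
    b = (np.log(hi) - mu) / sig
    mass = norm.cdf(b) - norm.cdf(a)
    return float(
        np.exp(k * mu + 0.5 * k * k * sig * sig)
        * (norm.cdf(b - k * sig) - norm.cdf(a - k * sig))
        / mass
    )


def _matched_truncated_params(dist: CovariateDistribution) -> tuple[float, float]:
    """(mu, sigma) such that the TRUNCATED log-normal has the target moments.

    Truncation (age especially, where the upper bound cuts a visible tail)
    would otherwise deflate the realized SD below the population value.
    """
    from scipy.optimize import least_squares

    mu0, sig0 = _lognormal_params(dist.mean, dist.sd)

    def resid(x):
        mu, logsig = x
        sig = np.exp(logsig)
        m1 = _truncated_lognormal_moment(mu, sig, dist.minimum, dist.maximum, 1)
        m2 = _truncated_lognormal_moment(mu, sig, dist.minimum, dist.maximum, 2)
        sd = np.sqrt(max(m2 - m1 * m1, 1e-12))
        return [m1 / dist.mean - 1.0, sd / dist.sd - 1.0]

    sol = least_squares(resid, [mu0, np.log(sig0)], xtol=1e-12, ftol=1e-12)
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _sample_truncated_lognormal(
    rng: np.random.Generator, dist: CovariateDistribution, n: int
) -> np.ndarray:
    """Rejection-sample a truncation-corrected log-normal on [min, max]."""
    mu, sig = _matched_truncated_params(dist)
    out = np.empty(0)
    while out.size < n:
        draw = rng.lognormal(mu, sig, size=max(2 * (n - out.size), 16))
        keep = draw[(draw >= dist.minimum) & (draw <= dist.maximum)]
        out = np.concatenate([out, keep])
    return out[:n]


def sample_covariates(n: int, spec: CovariateSpec | None = None, seed=None) -> pd.DataFrame:
    """Draw ``n`` virtual children (columns id, wt, scr, age, sex)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    spec = spec or CovariateSpec()
    rng = np.random.default_rng(seed)
    wt = _sample_truncated_lognormal(rng, spec.wt, n)
    scr = _sample_truncated_lognormal(rng, spec.scr, n)
    age = _sample_truncated_lognormal(rng, spec.age, n)
    sex = np.where(rng.random(n) < spec.male_fraction, "male", "female")
    return pd.DataFrame(
        {"id": np.arange(1, n + 1), "wt": wt, "scr": scr, "age": age, "sex": sex}
    )


def sample_random_effects(
    n: int, omega: OmegaSet | None = None, seed=None, correlation: float = 0.0
) -> np.ndarray:
    """N(0, omega^2) draws, shape (n, 2) = (eta_cl, eta_v).

    Independent by default; ``correlation`` imposes the given correlation
    between the two effects (marginal SDs unchanged).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if not -1.0 <= correlation <= 1.0:
        raise ValueError("correlation must be in [-1, 1]")
    omega = omega or OmegaSet()
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    etas = np.empty((n, 2))
    etas[:, 0] = omega.omega_cl * z[:, 0]
    etas[:, 1] = omega.omega_v * (
        correlation * z[:, 0] + np.sqrt(1.0 - correlation**2) * z[:, 1]
    )
    return etas


@dataclass(frozen=True)
class EtaScheme:
    """How virtual children acquire their subject-level PK deviations.

    ``"estimates"`` (default) emulates resampling per-patient parameter
    ESTIMATES from a sparse, trough-only study: the log-scale SDs are the
    population omegas scaled by one minus the eta-shrinkage of such a
    design, and the two deviations are fully correlated — a trough-only
    design identifies only the exposure combination of CL and V, so
    individual estimate pairs are collinear and carry no spread in
    k = CL/V.  ``"model"`` draws independent full-omega deviations from
    the population model itself (the data-generating truth; use this when
    simulating datasets for estimation studies).
    """

    kind: str = "estimates"
    shrinkage_cl: float = 0.269
    shrinkage_v: float = 0.198
    correlation: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("estimates", "model"):
            raise ValueError(f"unknown eta scheme {self.kind!r}")
        if not (0.0 <= self.shrinkage_cl < 1.0 and 0.0 <= self.shrinkage_v < 1.0):
            raise ValueError("shrinkages must be in [0, 1)")

    def effective(self, omega: OmegaSet) -> tuple[OmegaSet, float]:
        """(marginal SDs, correlation) actually used for sampling."""
        if self.kind == "model":
            return omega, 0.0
        return (
            OmegaSet(
                omega.omega_cl * (1.0 - self.shrinkage_cl),
                omega.omega_v * (1.0 - self.shrinkage_v),
            ),
            self.correlation,
        )


@dataclass(frozen=True)
class VirtualCohort:
    """Covariates plus fixed random effects and derived CL/Vd per subject."""

    data: pd.DataFrame  # id, wt, scr, age, sex, eta_cl, eta_v, cl, v
    theta: ThetaSet

    def __len__(self) -> int:
        return len(self.data)

    @property
    def cl(self) -> np.ndarray:
        return self.data["cl"].to_numpy()

    @property
    def v(self) -> np.ndarray:
        return self.data["v"].to_numpy()

    @property
    def wt(self) -> np.ndarray:
        return self.data["wt"].to_numpy()

    def subset(self, mask) -> "VirtualCohort":
        return VirtualCohort(self.data.loc[mask].reset_index(drop=True), self.theta)


def make_cohort(
    n: int,
    spec: CovariateSpec | None = None,
    theta: ThetaSet | None = None,
    omega: OmegaSet | None = None,
    seed=None,
    scheme: EtaScheme | None = None,
) -> VirtualCohort:
    """Assemble a virtual cohort: covariates, etas and individual CL/Vd.

    A single seed drives both the covariate and the random-effect draws so
    the full cohort is reproducible from one integer.  ``scheme`` selects
    how subject deviations are sampled (see :class:`EtaScheme`); the
    default emulates resampling of per-patient parameter estimates.
    """
    theta = theta or ThetaSet()
    scheme = scheme or EtaScheme()
    eff_omega, corr = scheme.effective(omega or OmegaSet())
    ss = np.random.SeedSequence(seed)
    s_cov, s_eta = ss.spawn(2)
    cov = sample_covariates(n, spec, s_cov)
    etas = sample_random_effects(n, eff_omega, s_eta, correlation=corr)
    df = cov.copy()
    df["eta_cl"] = etas[:, 0]
    df["eta_v"] = etas[:, 1]
    df["cl"] = individual_cl(df["wt"], df["scr"], theta, df["eta_cl"])
    df["v"] = individual_vd(df["wt"], theta, df["eta_v"])
    return VirtualCohort(df, theta)


@dataclass(frozen=True)
class StandardRegimenPolicy:
    """Study dosing: 10 mg/kg q12h x3 loading, then once-daily maintenance."""

    loading_per_kg: float = 10.0
    maintenance_per_kg: float = 10.0
    n_maintenance: int = 5
    infusion_duration: float = 0.5

    def regimen(self, wt: float) -> Regimen:
        events = [
            DoseEvent(t, self.loading_per_kg * wt, self.infusion_duration)
            for t in (0.0, 12.0, 24.0)
        ]
        for i in range(self.n_maintenance):
            events.append(
                DoseEvent(
                    48.0 + 24.0 * i,
                    self.maintenance_per_kg * wt,
                    self.infusion_duration,
                )
            )
        return Regimen(tuple(events))


@dataclass(frozen=True)
class TroughSampling:
    """Sparse TDM sampling: 1-2 pre-dose troughs per child, mean 1.5.

    Each subject contributes one trough drawn 0.5 h before a randomly
    chosen late dose, plus a second with probability ``p_extra``.
    """

    p_extra: float = 0.5
    predose_offset: float = 0.5
    first_eligible_dose: int = 3  # index into the regimen's events

    def times(self, regimen: Regimen, rng: np.random.Generator) -> np.ndarray:
        starts = np.array([e.time for e in regimen])
        eligible = starts[self.first_eligible_dose :]
        if eligible.size == 0:
            return np.empty(0)
        n = 1 + int(rng.random() < self.p_extra)
        n = min(n, eligible.size)
        picks = rng.choice(eligible.size, size=n, replace=False)
        return np.sort(eligible[picks] - self.predose_offset)


@dataclass(frozen=True)
class FixedTimesSampling:
    """Deterministic rich sampling at fixed times (for estimation studies)."""

    sample_times: tuple[float, ...]

    def times(self, regimen: Regimen, rng: np.random.Generator) -> np.ndarray:
        return np.asarray(self.sample_times, dtype=float)


def simulate_tdm_dataset(
    cohort: VirtualCohort,
    regimen_policy=None,
    sampling_policy=None,
    sigma: SigmaSet | None = None,
    lloq: float = LLOQ_DEFAULT,
    seed=None,
) -> pd.DataFrame:
    """Simulate a NONMEM-style event-record dataset from a virtual cohort.

    Returns a DataFrame with columns ID, TIME, AMT, RATE, DV, EVID, MDV,
    WT, SCR, AGE, SEX, LLOQFL (SEX coded 1 = male, 0 = female).  Dose rows
    have EVID 1 / MDV 1 and missing DV; observations carry the residual-
    perturbed prediction, floored at ``lloq`` with LLOQFL set.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be non-empty")
    regimen_policy = regimen_policy or StandardRegimenPolicy()
    sampling_policy = sampling_policy or TroughSampling()
    sigma = sigma or SigmaSet()
    rng = np.random.default_rng(seed)

    rows = []
    for rec in cohort.data.itertuples(index=False):
        regimen = regimen_policy.regimen(rec.wt)
        params = PKParameters(rec.cl, rec.v)
        sex_code = 1 if rec.sex == "male" else 0
        base = dict(WT=rec.wt, SCR=rec.scr, AGE=rec.age, SEX=sex_code)
        for ev in regimen:
            rows.append(
                dict(
                    ID=rec.id,
                    TIME=ev.time,
                    AMT=ev.amount,
                    RATE=ev.amount / ev.duration,
                    DV=np.nan,
                    EVID=1,
                    MDV=1,
                    LLOQFL=0,
                    **base,
                )
            )
        times = np.asarray(sampling_policy.times(regimen, rng), dtype=float)
        first_dose = regimen.events[0].time if len(regimen) else 0.0
        valid = times >= first_dose
        if not np.all(valid):
            warnings.warn(
                f"subject {rec.id}: dropped {np.sum(~valid)} sample(s) before "
                "the first dose",
                stacklevel=2,
            )
            times = times[valid]
        if times.size == 0:
            continue
        pred = conc_profile(params, regimen, times)
        dv = _apply_residual(pred, sigma, rng)
        floored = dv < lloq
        dv = np.where(floored, lloq, dv)
        for t, y, fl in zip(times, dv, floored):
            rows.append(
                dict(
                    ID=rec.id,
                    TIME=float(t),
                    AMT=np.nan,
                    RATE=np.nan,
                    DV=float(y),
                    EVID=0,
                    MDV=0,
                    LLOQFL=int(fl),
                    **base,
                )
            )
    df = pd.DataFrame(rows)
    cols = ["ID", "TIME", "AMT", "RATE", "DV", "EVID", "MDV", "WT", "SCR", "AGE", "SEX", "LLOQFL"]
    df = df[cols].sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False])
    return df.reset_index(drop=True)


def _apply_residual(pred: np.ndarray, sigma: SigmaSet, rng: np.random.Generator) -> np.ndarray:
    if sigma.sigma == 0:
        return pred.copy()
    eps = rng.standard_normal(pred.shape)
    if sigma.model == "exponential":
        return pred * np.exp(sigma.sigma * eps)
    if sigma.model == "additive":
        return pred + sigma.sigma * eps
    return pred * (1.0 + sigma.sigma * eps)  # proportional
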