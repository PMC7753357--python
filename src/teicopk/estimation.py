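"""Approximate nonlinear mixed-effects estimation and model validation.

The population model is estimated by maximizing a Laplace approximation to
the marginal likelihood: for each subject the joint -2 log-likelihood
``g(eta) = -2 log p(y | eta) - 2 log p(eta)`` is minimized over the
subject's random effects by a damped Newton search (finite-difference
derivatives, gradient tolerance 1e-8), and the marginal contribution is

    -2 log L_i  ~=  g_i(eta_hat) + log det(H_i / 2) - q log(2*pi)

with ``H_i`` the Hessian of ``g_i`` at the mode and ``q`` the number of
active random-effect dimensions.  The sum over subjects plays the role of
an objective function value (OFV) for nested-model comparison; absolute
values are approximation-specific and are never compared across software.

Covariate search follows the classic stepwise procedure: forward addition
keeps a covariate when it drops the OFV by more than 3.84 (chi-square,
df 1, p < 0.05); backward deletion removes it from the full model unless
its removal raises the OFV by at least 10.83 (p < 0.001).

External validation uses relative prediction errors of the population
(eta = 0) predictions: PE = (pred - obs)/obs * 100%, APE = |PE|, with
acceptance bands of +-15% for observations at or above 10 mg/L and +-20%
below.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .covariates import OmegaSet, SigmaSet, ThetaSet

__all__ = [
    "CovariateCandidate",
    "StructuralModel",
    "final_model_structure",
    "base_model_structure",
    "FitResult",
    "SelectionResult",
    "neg2ll",
    "fit_poppk",
    "stepwise_selection",
    "prediction_errors",
    "validation_summary",
    "ValidationSummary",
]

_BOLUS_DURATION = 1e-6
_FD_STEP = 1e-4
_GRAD_TOL = 1e-8
_INNER_MAXIT = 100
_OMEGA_ACTIVE = 1e-8  # below this an eta dimension is fixed at zero

_DEFAULT_REFS = {"wt": 16.71, "scr": 29.075, "age": 4.1}
_CAND_INITS = {"linear": 0.1, "power": 0.1, "exponential": 1.0}


# ---------------------------------------------------------------------------
# structural (covariate) model


@dataclass(frozen=True)
class CovariateCandidate:
    """One covariate effect: which covariate, on CL or V, in which form.

    Forms (x = covariate / reference): linear ``1 + beta*x``, power
    ``x**beta``, exponential ``beta**x`` (beta > 0).  The final study model
    is linear weight + exponential creatinine on CL and exponential weight
    on V.
    """

    covariate: str  # "wt" | "scr" | "age"
    parameter: str  # "cl" | "v"
    form: str  # "linear" | "power" | "exponential"
    init: float | None = None

    def __post_init__(self) -> None:
        if self.parameter not in ("cl", "v"):
            raise ValueError("parameter must be 'cl' or 'v'")
        if self.form not in ("linear", "power", "exponential"):
            raise ValueError(f"unknown covariate form {self.form!r}")
        if self.init is None:
            object.__setattr__(self, "init", _CAND_INITS[self.form])

    @property
    def name(self) -> str:
        return f"{self.covariate}_{self.parameter}_{self.form}"


@dataclass(frozen=True)
class StructuralModel:
    """Typical-value model: scales theta_cl/theta_v by covariate factors."""

    candidates: tuple[CovariateCandidate, ...] = ()
    refs: dict = field(default_factory=lambda: dict(_DEFAULT_REFS))

    @property
    def param_names(self) -> list[str]:
        return ["theta_cl", "theta_v"] + [c.name for c in self.candidates]

    def default_values(self) -> dict:
        vals = {"theta_cl": ThetaSet().theta_cl, "theta_v": ThetaSet().theta_v}
        for c in self.candidates:
            vals[c.name] = c.init
        return vals

    def typical_cl_v(self, values: dict, cov: dict) -> tuple[np.ndarray, np.ndarray]:
        """Per-subject typical CL and V; returns (cl, v) or factors <= 0 as nan."""
        cl = np.full_like(cov["wt"], values["theta_cl"], dtype=float)
        v = np.full_like(cov["wt"], values["theta_v"], dtype=float)
        for c in self.candidates:
            x = cov[c.covariate] / self.refs[c.covariate]
            beta = values[c.name]
            if c.form == "linear":
                factor = 1.0 + beta * x
            elif c.form == "power":
                factor = x**beta
            else:  # exponential base-power
                if beta <= 0:
                    return np.full_like(cl, np.nan), np.full_like(v, np.nan)
                factor = beta**x
            if np.any(factor <= 0):
                return np.full_like(cl, np.nan), np.full_like(v, np.nan)
            if c.parameter == "cl":
                cl = cl * factor
            else:
                v = v * factor
        return cl, v


def final_model_structure(theta: ThetaSet | None = None) -> tuple[StructuralModel, dict]:
    """The study's final covariate model and its parameter values."""
    theta = theta or ThetaSet()
    structure = StructuralModel(
        candidates=(
            CovariateCandidate("wt", "cl", "linear", theta.theta1_wt_cl),
            CovariateCandidate("scr", "cl", "exponential", theta.theta2_scr_cl),
            CovariateCandidate("wt", "v", "exponential", theta.theta3_wt_v),
        ),
        refs={"wt": theta.ref_wt, "scr": theta.ref_scr, "age": _DEFAULT_REFS["age"]},
    )
    values = {
        "theta_cl": theta.theta_cl,
        "theta_v": theta.theta_v,
        "wt_cl_linear": theta.theta1_wt_cl,
        "scr_cl_exponential": theta.theta2_scr_cl,
        "wt_v_exponential": theta.theta3_wt_v,
    }
    return structure, values


def base_model_structure() -> StructuralModel:
    """Covariate-free model: CL = theta_cl * e^eta1, V = theta_v * e^eta2."""
    return StructuralModel()


def _theta_from_values(values: dict, refs: dict) -> ThetaSet | None:
    try:
        return ThetaSet(
            theta_cl=values["theta_cl"],
            theta_v=values["theta_v"],
            theta1_wt_cl=values["wt_cl_linear"],
            theta2_scr_cl=values["scr_cl_exponential"],
            theta3_wt_v=values["wt_v_exponential"],
            ref_wt=refs["wt"],
            ref_scr=refs["scr"],
        )
    except (KeyError, ValueError):
        return None


# ---------------------------------------------------------------------------
# dataset encoding


class _EncodedDataset:
    """Flat numpy view of a NONMEM-style event table for fast likelihoods."""

    def __init__(self, df: pd.DataFrame):
        df = df.reset_index(drop=True)
        ids = df["ID"].to_numpy()
        self.subject_ids = pd.unique(ids)
        self.n_subj = len(self.subject_ids)
        id_index = {sid: i for i, sid in enumerate(self.subject_ids)}

        obs = df[df["EVID"] == 0]
        doses = df[df["EVID"] == 1]
        if len(obs) == 0:
            raise ValueError("dataset has no observation records")
        no_obs = set(self.subject_ids) - set(obs["ID"])
        if no_obs:
            warnings.warn(
                f"subjects without observations contribute nothing: {sorted(no_obs)}",
                stacklevel=3,
            )
        no_dose = set(obs["ID"]) - set(doses["ID"])
        if no_dose:
            raise ValueError(f"subjects with observations but no dose: {sorted(no_dose)}")

        self.obs_subj = np.array([id_index[i] for i in obs["ID"]])
        self.obs_time = obs["TIME"].to_numpy(dtype=float)
        self.obs_dv = obs["DV"].to_numpy(dtype=float)
        self.n_obs = len(obs)
        if np.any(~np.isfinite(self.obs_dv)) or np.any(self.obs_dv <= 0):
            raise ValueError("observed concentrations must be positive and finite")

        # per-subject covariates from the first record
        first = df.groupby("ID", sort=False).first()
        order = [id_index[i] for i in first.index]
        self.cov = {}
        for col, key in (("WT", "wt"), ("SCR", "scr"), ("AGE", "age")):
            if col in df.columns:
                arr = np.empty(self.n_subj)
                arr[order] = first[col].to_numpy(dtype=float)
                self.cov[key] = arr

        # (observation, dose) pairs with dose start at or before the observation
        p_obs, p_t0, p_amt, p_rate, p_dur = [], [], [], [], []
        dose_by_id = {
            sid: (
                grp["TIME"].to_numpy(dtype=float),
                grp["AMT"].to_numpy(dtype=float),
                grp["RATE"].to_numpy(dtype=float) if "RATE" in grp else np.zeros(len(grp)),
            )
            for sid, grp in doses.groupby("ID", sort=False)
        }
        obs_ids = obs["ID"].to_numpy()
        for j in range(self.n_obs):
            t0s, amts, rates = dose_by_id[obs_ids[j]]
            for t0, amt, rate in zip(t0s, amts, rates):
                if t0 <= self.obs_time[j]:
                    rate = rate if np.isfinite(rate) and rate > 0 else 0.0
                    p_obs.append(j)
                    p_t0.append(t0)
                    p_amt.append(amt)
                    p_rate.append(rate)
                    p_dur.append(amt / rate if rate > 0 else 0.0)
        self.pair_obs = np.asarray(p_obs, dtype=int)
        self.pair_t0 = np.asarray(p_t0, dtype=float)
        self.pair_amt = np.asarray(p_amt, dtype=float)
        self.pair_rate = np.asarray(p_rate, dtype=float)
        self.pair_dur = np.asarray(p_dur, dtype=float)
        self.pair_tau = self.obs_time[self.pair_obs] - self.pair_t0
        self.pair_subj = self.obs_subj[self.pair_obs]

    def predictions(self, cl: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Concentration at every observation for per-subject CL, V arrays."""
        k = cl / v
        k_p = k[self.pair_subj]
        cl_p = cl[self.pair_subj]
        v_p = v[self.pair_subj]
        is_bolus = self.pair_dur < _BOLUS_DURATION
        tau_on = np.minimum(self.pair_tau, self.pair_dur)
        tau_off = np.maximum(self.pair_tau - self.pair_dur, 0.0)
        with np.errstate(over="ignore"):
            inf_contrib = (
                np.where(is_bolus, 0.0, self.pair_rate)
                / cl_p
                * -np.expm1(-k_p * tau_on)
                * np.exp(-k_p * tau_off)
            )
            bolus_contrib = self.pair_amt / v_p * np.exp(-k_p * self.pair_tau)
        contrib = np.where(is_bolus, bolus_contrib, inf_contrib)
        return np.bincount(self.pair_obs, weights=contrib, minlength=self.n_obs)


# ---------------------------------------------------------------------------
# Laplace engine


class _LaplaceEngine:
    def __init__(self, enc: _EncodedDataset, structure: StructuralModel, sigma: SigmaSet):
        self.enc = enc
        self.structure = structure
        self.sigma_model = sigma.model
        for c in structure.candidates:
            if c.covariate not in enc.cov:
                raise ValueError(f"covariate {c.covariate!r} missing from dataset")

    # conditional -2 log p(y | eta), per subject
    def _conditional(self, cl_t, v_t, eta, sigma) -> np.ndarray:
        enc = self.enc
        cl = cl_t * np.exp(eta[:, 0])
        v = v_t * np.exp(eta[:, 1])
        f = enc.predictions(cl, v)
        y = enc.obs_dv
        bad = np.zeros(enc.n_subj, dtype=bool)
        if sigma <= 0:
            raise ValueError("sigma must be positive for likelihood evaluation")
        if self.sigma_model == "additive":
            l_obs = ((y - f) / sigma) ** 2 + math.log(2 * math.pi * sigma**2)
        elif self.sigma_model == "proportional":
            s = sigma * np.abs(f)
            ok = s > 0
            l_obs = np.where(
                ok, ((y - f) / np.where(ok, s, 1.0)) ** 2 + np.log(2 * np.pi * np.where(ok, s, 1.0) ** 2), np.inf
            )
        else:  # exponential: y log-normal around log f (includes the 1/y Jacobian)
            ok = f > 0
            logf = np.log(np.where(ok, f, 1.0))
            l_obs = np.where(
                ok,
                ((np.log(y) - logf) / sigma) ** 2
                + math.log(2 * math.pi * sigma**2)
                + 2.0 * np.log(y),
                np.inf,
            )
        out = np.bincount(enc.obs_subj, weights=np.where(np.isfinite(l_obs), l_obs, 0.0), minlength=enc.n_subj)
        inf_subj = np.bincount(enc.obs_subj, weights=(~np.isfinite(l_obs)).astype(float), minlength=enc.n_subj) > 0
        out[inf_subj | bad] = np.inf
        return out

    def neg2ll(self, values: dict, omega: OmegaSet, sigma: float, eta0=None):
        """Laplace -2 log marginal likelihood.

        Returns (total, per_subject, eta_modes, ok_flag).
        """
        enc = self.enc
        cl_t, v_t = self.structure.typical_cl_v(values, enc.cov)
        if np.any(~np.isfinite(cl_t)) or np.any(~np.isfinite(v_t)) or np.any(cl_t <= 0) or np.any(v_t <= 0):
            return np.inf, None, eta0, False
        omegas = np.array([omega.omega_cl, omega.omega_v])
        active = np.where(omegas > _OMEGA_ACTIVE)[0]
        q = active.size

        pen_const = float(np.sum(np.log(2 * np.pi * omegas[active] ** 2)))

        def g(eta: np.ndarray) -> np.ndarray:
            cond = self._conditional(cl_t, v_t, eta, sigma)
            pen = np.zeros(enc.n_subj)
            for d in active:
                pen += eta[:, d] ** 2 / omegas[d] ** 2
            return cond + pen + pen_const

        eta = np.zeros((enc.n_subj, 2)) if eta0 is None else eta0.copy()
        eta[:, [d for d in (0, 1) if d not in active]] = 0.0

        if q == 0:
            per = self._conditional(cl_t, v_t, eta, sigma)
            total = float(np.sum(per))
            return total, per, eta, np.isfinite(total)

        eta, g0, hess, ok = _newton_modes(g, eta, active)
        if not np.all(np.isfinite(g0)):
            return np.inf, None, eta, False
        # log det of H/2 per subject
        if q == 1:
            det = hess[:, 0, 0] / 2.0
        else:
            h = hess / 2.0
            det = h[:, 0, 0] * h[:, 1, 1] - h[:, 0, 1] ** 2
        bad_det = det <= 0
        if np.any(bad_det):
            det = np.where(bad_det, np.abs(det) + 1e-10, det)
            ok = False
        per = g0 + np.log(det) - q * math.log(2 * math.pi)
        total = float(np.sum(per))
        return total, per, eta, ok and np.isfinite(total)


def _newton_modes(g, eta, active):
    """Vectorized damped-Newton minimization of per-subject objectives.

    ``g`` maps an (n, 2) eta array to an (n,) objective vector; only the
    ``active`` columns are searched.  Returns (eta, g(eta), Hessian of g
    restricted to active dims as (n, q, q), converged_flag).
    """
    n = eta.shape[0]
    q = len(active)
    h = _FD_STEP
    g0 = g(eta)
    if not np.all(np.isfinite(g0)):
        # fall back: subjects with non-finite start keep eta as-is
        pass
    hess = np.zeros((n, q, q))
    converged = False
    for _ in range(_INNER_MAXIT):
        grad = np.zeros((n, q))
        for a, d in enumerate(active):
            ep = eta.copy()
            ep[:, d] += h
            em = eta.copy()
            em[:, d] -= h
            gp, gm = g(ep), g(em)
            grad[:, a] = (gp - gm) / (2 * h)
            hess[:, a, a] = (gp - 2 * g0 + gm) / (h * h)
        if q == 2:
            epp = eta.copy()
            epp[:, active] += h
            emm = eta.copy()
            emm[:, active] -= h
            epm = eta.copy()
            epm[:, active[0]] += h
            epm[:, active[1]] -= h
            emp = eta.copy()
            emp[:, active[0]] -= h
            emp[:, active[1]] += h
            cross = (g(epp) + g(emm) - g(epm) - g(emp)) / (4 * h * h)
            hess[:, 0, 1] = cross
            hess[:, 1, 0] = cross
        gmax = np.max(np.abs(grad), axis=1)
        if np.all(gmax[np.isfinite(g0)] < _GRAD_TOL):
            converged = True
            break
        # per-subject regularized Newton step
        step = np.zeros((n, q))
        if q == 1:
            hh = np.maximum(hess[:, 0, 0], 1e-8)
            step[:, 0] = -grad[:, 0] / hh
        else:
            a11 = hess[:, 0, 0]
            a22 = hess[:, 1, 1]
            a12 = hess[:, 0, 1]
            det = a11 * a22 - a12 * a12
            ridge = np.where((det <= 1e-12) | (a11 <= 0) | (a22 <= 0), np.abs(a11) + np.abs(a22) + 1.0, 0.0)
            a11r = a11 + ridge
            a22r = a22 + ridge
            detr = a11r * a22r - a12 * a12
            step[:, 0] = -(a22r * grad[:, 0] - a12 * grad[:, 1]) / detr
            step[:, 1] = -(a11r * grad[:, 1] - a12 * grad[:, 0]) / detr
        step = np.clip(step, -5.0, 5.0)
        # backtracking line search, vectorized over subjects
        scale = np.ones(n)
        improved = np.zeros(n, dtype=bool)
        trial = eta.copy()
        for _ls in range(25):
            cand = eta.copy()
            upd = ~improved
            for a, d in enumerate(active):
                cand[:, d] = np.where(upd, eta[:, d] + scale * step[:, a], trial[:, d])
            gc = g(cand)
            better = upd & (gc < g0)
            trial[better] = cand[better]
            g0 = np.where(better, gc, g0)
            improved |= better
            scale = np.where(improved, scale, scale * 0.5)
            if np.all(improved):
                break
        eta = trial
        if not np.any(improved):
            break
    return eta, g0, hess, converged


# ---------------------------------------------------------------------------
# public estimation API


def neg2ll(
    dataset: pd.DataFrame,
    theta: ThetaSet | None = None,
    omega: OmegaSet | None = None,
    sigma: SigmaSet | None = None,
) -> float:
    """Laplace -2 log marginal likelihood of the final covariate model."""
    theta = theta or ThetaSet()
    omega = omega or OmegaSet()
    sigma = sigma or SigmaSet()
    enc = _EncodedDataset(dataset)
    structure, values = final_model_structure(theta)
    engine = _LaplaceEngine(enc, structure, sigma)
    total, per, _, ok = engine.neg2ll(values, omega, sigma.sigma)
    if not np.isfinite(total):
        bad = "unknown"
        if per is not None:
            idx = np.where(~np.isfinite(per))[0]
            if idx.size:
                bad = enc.subject_ids[idx[0]]
        raise ValueError(f"non-finite likelihood contribution (subject {bad})")
    return total


@dataclass
class FitResult:
    """Estimated parameters, objective value, and empirical-Bayes modes."""

    params: dict
    omega: OmegaSet
    sigma: SigmaSet
    ofv: float
    converged: bool
    eta: np.ndarray  # (n_subj, 2) conditional modes
    subject_ids: np.ndarray
    structure: StructuralModel
    n_evals: int
    theta: ThetaSet | None = None


_LOG_SCALE = {"theta_cl", "theta_v", "omega_cl", "omega_v", "sigma"}


def _to_internal(name: str, value: float, structure: StructuralModel) -> float:
    if name in _LOG_SCALE or name.endswith("_exponential"):
        return math.log(value)
    return value


def _from_internal(name: str, x: float, structure: StructuralModel) -> float:
    if name in _LOG_SCALE or name.endswith("_exponential"):
        return math.exp(x)
    return x


def fit_poppk(
    dataset: pd.DataFrame,
    init: dict | None = None,
    structure: StructuralModel | None = None,
    estimate=None,
    sigma_model: str = "exponential",
    maxiter: int | None = None,
) -> FitResult:
    """Fit the population model by Nelder-Mead on the Laplace objective.

    ``init`` maps parameter names (structural parameters plus ``omega_cl``,
    ``omega_v``, ``sigma``) to starting values; missing entries take the
    study defaults.  ``estimate`` restricts which parameters move (default:
    all).  Deterministic given dataset and starting values; on
    non-convergence the best iterate is returned with ``converged=False``.
    """
    if structure is None:
        structure, struct_defaults = final_model_structure()
    else:
        struct_defaults = structure.default_values()
    values = dict(struct_defaults)
    values.update(
        {"omega_cl": OmegaSet().omega_cl, "omega_v": OmegaSet().omega_v, "sigma": SigmaSet().sigma}
    )
    if init:
        values.update(init)
    names = structure.param_names + ["omega_cl", "omega_v", "sigma"]
    free = list(names) if estimate is None else [n for n in names if n in set(estimate)]
    if not free:
        raise ValueError("no free parameters to estimate")

    enc = _EncodedDataset(dataset)
    if enc.n_obs < len(free):
        warnings.warn(
            f"only {enc.n_obs} observations for {len(free)} parameters; "
            "the design may not be identifiable",
            stacklevel=2,
        )
    engine = _LaplaceEngine(enc, structure, SigmaSet(sigma_model, values["sigma"]))

    eta_warm = {"eta": np.zeros((enc.n_subj, 2))}
    n_evals = {"n": 0}

    def objective(x: np.ndarray) -> float:
        n_evals["n"] += 1
        vals = dict(values)
        for name, xi in zip(free, x):
            vals[name] = _from_internal(name, float(xi), structure)
        om = OmegaSet(vals["omega_cl"], vals["omega_v"])
        total, _, eta, ok = engine.neg2ll(
            {k: vals[k] for k in structure.param_names},
            om,
            vals["sigma"],
            eta0=eta_warm["eta"],
        )
        if not np.isfinite(total):
            return 1e12
        eta_warm["eta"] = eta
        return total

    x0 = np.array([_to_internal(n, values[n], structure) for n in free])
    res = minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options=dict(
            xatol=1e-4,
            fatol=1e-3,
            maxiter=maxiter or 400 * len(free),
            maxfev=maxiter or 400 * len(free),
        ),
    )
    best = dict(values)
    for name, xi in zip(free, res.x):
        best[name] = _from_internal(name, float(xi), structure)
    omega = OmegaSet(best["omega_cl"], best["omega_v"])
    sigma = SigmaSet(sigma_model, best["sigma"])
    total, _, eta, ok = engine.neg2ll(
        {k: best[k] for k in structure.param_names}, omega, sigma.sigma, eta0=eta_warm["eta"]
    )
    params = {k: best[k] for k in structure.param_names}
    return FitResult(
        params=params,
        omega=omega,
        sigma=sigma,
        ofv=float(total),
        converged=bool(res.success and np.isfinite(total)),
        eta=eta,
        subject_ids=enc.subject_ids,
        structure=structure,
        n_evals=n_evals["n"],
        theta=_theta_from_values(params, structure.refs),
    )


@dataclass
class SelectionResult:
    """Outcome of stepwise covariate selection with the full decision trace."""

    selected: list[CovariateCandidate]
    trace: list[dict]
    final_fit: FitResult


def stepwise_selection(
    dataset: pd.DataFrame,
    candidates: list[CovariateCandidate],
    base_structure: StructuralModel | None = None,
    init: dict | None = None,
    forward_dofv: float = 3.84,
    backward_dofv: float = 10.83,
    **fit_kw,
) -> SelectionResult:
    """Forward-addition / backward-deletion covariate search on the OFV.

    Forward: at each round the candidate with the largest OFV drop is added
    if that drop exceeds ``forward_dofv``.  Backward: from the resulting
    full model, each covariate is removed unless removal raises the OFV by
    at least ``backward_dofv``.  A failed fit skips the candidate (logged
    in the trace).
    """
    base = base_structure or base_model_structure()
    trace: list[dict] = []

    def fit_with(cands: list[CovariateCandidate]) -> FitResult:
        structure = StructuralModel(base.candidates + tuple(cands), refs=base.refs)
        return fit_poppk(dataset, init=init, structure=structure, **fit_kw)

    current: list[CovariateCandidate] = []
    fit_cur = fit_with(current)
    if not candidates:
        return SelectionResult([], trace, fit_cur)

    # forward addition
    remaining = list(candidates)
    while remaining:
        best = None
        for cand in remaining:
            try:
                fit_c = fit_with(current + [cand])
            except Exception as exc:  # noqa: BLE001 - candidate skipped, logged
                trace.append(dict(step="forward", candidate=cand.name, error=str(exc)))
                continue
            delta = fit_cur.ofv - fit_c.ofv
            trace.append(
                dict(step="forward", candidate=cand.name, ofv=fit_c.ofv, delta_ofv=delta,
                     accepted=delta > forward_dofv)
            )
            if delta > forward_dofv and (best is None or delta > best[0]):
                best = (delta, cand, fit_c)
        if best is None:
            break
        _, cand, fit_cur = best
        current.append(cand)
        remaining.remove(cand)

    # backward deletion from the full model
    changed = True
    while changed and current:
        changed = False
        for cand in list(current):
            reduced = [c for c in current if c is not cand]
            try:
                fit_r = fit_with(reduced)
            except Exception as exc:  # noqa: BLE001
                trace.append(dict(step="backward", candidate=cand.name, error=str(exc)))
                continue
            increase = fit_r.ofv - fit_cur.ofv
            keep = increase >= backward_dofv
            trace.append(
                dict(step="backward", candidate=cand.name, ofv=fit_r.ofv,
                     delta_ofv=increase, retained=keep)
            )
            if not keep:
                current = reduced
                fit_cur = fit_r
                changed = True
                break
    return SelectionResult(current, trace, fit_cur)


# ---------------------------------------------------------------------------
# external-validation metrics


def prediction_errors(predicted, observed):
    """Relative prediction error PE (%) and its absolute value APE (%)."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if np.any(obs <= 0):
        raise ValueError("observed concentrations must be positive")
    pe = (pred - obs) / obs * 100.0
    ape = np.abs(pe)
    if pe.ndim == 0:
        return float(pe), float(ape)
    return pe, ape


@dataclass
class ValidationSummary:
    """Population-prediction error summary with band-membership fractions."""

    table: pd.DataFrame  # ID, TIME, observed, predicted, pe, ape, band, within
    mean_pe: float
    mean_ape: float
    frac_within_ge10: float  # obs >= 10 mg/L, +-15% band
    frac_within_lt10: float  # obs < 10 mg/L, +-20% band
    n_ge10: int
    n_lt10: int


def validation_summary(
    dataset: pd.DataFrame,
    theta: ThetaSet | None = None,
    structure: StructuralModel | None = None,
    values: dict | None = None,
) -> ValidationSummary:
    """Score population (eta = 0) predictions against observations.

    Observations at or above 10 mg/L are judged on the +-15% PE band,
    those below 10 mg/L on +-20% (the boundary value 10 uses +-15%).
    """
    enc = _EncodedDataset(dataset)
    if structure is None:
        structure, values = final_model_structure(theta)
    elif values is None:
        values = structure.default_values()
    cl_t, v_t = structure.typical_cl_v(values, enc.cov)
    pred = enc.predictions(cl_t, v_t)
    pe, ape = prediction_errors(pred, enc.obs_dv)
    pe = np.atleast_1d(pe)
    ape = np.atleast_1d(ape)
    ge10 = enc.obs_dv >= 10.0
    within = np.where(ge10, ape <= 15.0, ape <= 20.0)
    table = pd.DataFrame(
        {
            "ID": enc.subject_ids[enc.obs_subj],
            "TIME": enc.obs_time,
            "observed": enc.obs_dv,
            "predicted": pred,
            "pe": pe,
            "ape": ape,
            "band": np.where(ge10, "+-15%", "+-20%"),
            "within": within,
        }
    )
    n_ge10 = int(ge10.sum())
    n_lt10 = int((~ge10).sum())
    return ValidationSummary(
        table=table,
        mean_pe=float(np.mean(pe)),
        mean_ape=float(np.mean(ape)),
        frac_within_ge10=float(np.mean(within[ge10])) if n_ge10 else float("nan"),
        frac_within_lt10=float(np.mean(within[~ge10])) if n_lt10 else float("nan"),
        n_ge10=n_ge10,
        n_lt10=n_lt10,
    )
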