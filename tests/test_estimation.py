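"""Laplace likelihood, population fitting and validation metrics."""

import math

import numpy as np
import pandas as pd
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy.special import logsumexp

from conftest import build_event_df, model_observations
from teicopk.cohort import EtaScheme, FixedTimesSampling, make_cohort, simulate_tdm_dataset
from teicopk.covariates import OmegaSet, SigmaSet, ThetaSet, individual_cl, individual_vd
from teicopk.estimation import (
    fit_poppk,
    neg2ll,
    prediction_errors,
    validation_summary,
)
from teicopk.pk_core import DoseEvent, PKParameters, Regimen, conc_profile


def toy_subjects(sigma=0.15):
    """Two sparse subjects with observations generated from the model."""
    spec = {
        1: dict(wt=12.0, scr=25.0, eta=(0.35, -0.2),
                doses=[(0.0, 120.0, 0.5), (12.0, 120.0, 0.5)],
                times=[6.0, 11.5, 23.5], eps=[0.1, -0.15, 0.05]),
        2: dict(wt=30.0, scr=50.0, eta=(-0.4, 0.3),
                doses=[(0.0, 300.0, 0.5)],
                times=[2.0, 24.0], eps=[-0.1, 0.2]),
    }
    subjects = {}
    for sid, d in spec.items():
        obs = model_observations(d["wt"], d["scr"], d["eta"], d["doses"], d["times"],
                                 sigma=sigma, eps=d["eps"])
        subjects[sid] = dict(wt=d["wt"], scr=d["scr"], doses=d["doses"], obs=obs)
    return subjects


def quadrature_neg2ll(subjects, theta, omega, sigma, n_nodes=50):
    """Independent oracle: Gauss-Hermite integration over both etas."""
    x, w = hermegauss(n_nodes)
    logw = np.log(w) - logsumexp(np.log(w))
    total = 0.0
    for d in subjects.values():
        reg = Regimen(tuple(DoseEvent(t, a, dur) for t, a, dur in d["doses"]))
        logl = np.empty((n_nodes, n_nodes))
        for i, xi in enumerate(x):
            for j, xj in enumerate(x):
                cl = individual_cl(d["wt"], d["scr"], theta, omega.omega_cl * xi)
                v = individual_vd(d["wt"], theta, omega.omega_v * xj)
                ll = 0.0
                for t, y in d["obs"]:
                    f = max(float(conc_profile(PKParameters(cl, v), reg, [t])[0]), 1e-300)
                    ll += (
                        -0.5 * ((math.log(y) - math.log(f)) / sigma.sigma) ** 2
                        - math.log(y * sigma.sigma)
                        - 0.5 * math.log(2 * math.pi)
                    )
                logl[i, j] = ll
        total += -2.0 * logsumexp(logl + logw[:, None] + logw[None, :])
    return total


class TestNeg2ll:
    def test_omega_zero_equals_fixed_effects_closed_form(self):
        subjects = toy_subjects()
        df = build_event_df(subjects)
        sigma = SigmaSet("additive", 0.5)
        closed = 0.0
        for d in subjects.values():
            cl = individual_cl(d["wt"], d["scr"])
            v = individual_vd(d["wt"])
            reg = Regimen(tuple(DoseEvent(t, a, dur) for t, a, dur in d["doses"]))
            for t, y in d["obs"]:
                f = float(conc_profile(PKParameters(cl, v), reg, [t])[0])
                closed += ((y - f) / sigma.sigma) ** 2 + math.log(2 * math.pi * sigma.sigma**2)
        assert neg2ll(df, omega=OmegaSet(0.0, 0.0), sigma=sigma) == pytest.approx(closed)

    def test_matches_quadrature_oracle(self):
        subjects = toy_subjects()
        df = build_event_df(subjects)
        theta, omega, sigma = ThetaSet(), OmegaSet(0.4, 0.35), SigmaSet("exponential", 0.15)
        oracle = quadrature_neg2ll(subjects, theta, omega, sigma)
        lap = neg2ll(df, theta, omega, sigma)
        assert lap == pytest.approx(oracle, rel=0.01)

    def test_duplicated_subject_doubles_contribution(self):
        subjects = toy_subjects()
        one = {1: subjects[1]}
        two = {1: subjects[1], 2: subjects[1]}
        v1 = neg2ll(build_event_df(one))
        v2 = neg2ll(build_event_df(two))
        assert v2 == pytest.approx(2 * v1, rel=1e-6)


class TestFitPoppk:
    def test_exact_data_limit_recovers_thetas(self):
        # dense noise-free data at eta=0: thetas recovered within 1%
        subjects = {}
        for sid, (wt, scr) in enumerate([(8.0, 20.0), (16.7, 29.1), (30.0, 50.0), (50.0, 80.0)], 1):
            doses = [(0.0, 10 * wt, 0.5), (12.0, 10 * wt, 0.5), (24.0, 10 * wt, 0.5)]
            times = [1.0, 3.0, 6.0, 12.5, 18.0, 24.5, 30.0, 48.0]
            obs = model_observations(wt, scr, (0.0, 0.0), doses, times)
            subjects[sid] = dict(wt=wt, scr=scr, doses=doses, obs=obs)
        df = build_event_df(subjects)
        fit = fit_poppk(
            df,
            init={"theta_cl": 0.09, "theta_v": 1.8, "omega_cl": 1e-12, "omega_v": 1e-12,
                  "sigma": 0.05},
            estimate=["theta_cl", "theta_v"],
        )
        assert fit.params["theta_cl"] == pytest.approx(0.0694, rel=0.01)
        assert fit.params["theta_v"] == pytest.approx(1.39, rel=0.01)

    def test_refit_from_optimum_is_stationary(self):
        coh = make_cohort(30, seed=21, scheme=EtaScheme("model"))
        df = simulate_tdm_dataset(
            coh, sampling_policy=FixedTimesSampling((6.0, 23.5, 47.5, 95.5)),
            lloq=0.0, seed=22,
        )
        free = ["theta_cl", "theta_v", "omega_cl", "omega_v", "sigma"]
        fit1 = fit_poppk(df, estimate=free)
        fit2 = fit_poppk(df, init={k: fit1.params.get(k, getattr(fit1.omega, k, None))
                                   for k in ("theta_cl", "theta_v")}
                         | {"omega_cl": fit1.omega.omega_cl, "omega_v": fit1.omega.omega_v,
                            "sigma": fit1.sigma.sigma},
                         estimate=free)
        assert fit2.ofv <= fit1.ofv + 1e-3
        assert fit1.ofv - fit2.ofv < 0.5

    def test_recovery_bias_over_replicates(self):
        # reduced-scale bias check on repeated simulated studies
        rel_cl, rel_v = [], []
        for rep in range(4):
            coh = make_cohort(60, seed=100 + rep, scheme=EtaScheme("model"))
            df = simulate_tdm_dataset(
                coh,
                sampling_policy=FixedTimesSampling((1.0, 6.0, 13.0, 30.0, 60.0, 95.5)),
                lloq=0.0,
                seed=200 + rep,
            )
            fit = fit_poppk(df, estimate=["theta_cl", "theta_v", "omega_cl", "omega_v", "sigma"])
            rel_cl.append(fit.params["theta_cl"] / 0.0694 - 1)
            rel_v.append(fit.params["theta_v"] / 1.39 - 1)
        assert abs(np.mean(rel_cl)) < 0.10
        assert abs(np.mean(rel_v)) < 0.15


class TestPredictionErrors:
    def test_perfect_prediction(self):
        pe, ape = prediction_errors(10.0, 10.0)
        assert (pe, ape) == (0.0, 0.0)

    def test_direct_arithmetic(self):
        assert prediction_errors(11.0, 10.0) == (10.0, 10.0)

    def test_sign_symmetry(self):
        pe, ape = prediction_errors(9.0, 10.0)
        assert (pe, ape) == (-10.0, 10.0)

    def test_nonpositive_observation_rejected(self):
        with pytest.raises(ValueError):
            prediction_errors(5.0, 0.0)


class TestValidationSummary:
    def _df_from_pairs(self, pairs):
        # one subject per (pred, obs) pair: dose sized so that the typical
        # prediction at 24 h equals `pred` exactly (dose linearity)
        subjects = {}
        for sid, (pred, obs) in enumerate(pairs, 1):
            wt, scr = 16.71, 29.075
            unit = model_observations(wt, scr, (0.0, 0.0), [(0.0, 100.0, 0.5)], [24.0])[0][1]
            amt = 100.0 * pred / unit
            subjects[sid] = dict(wt=wt, scr=scr, doses=[(0.0, amt, 0.5)], obs=[(24.0, obs)])
        return build_event_df(subjects)

    def test_hand_computed_triple(self):
        df = self._df_from_pairs([(11.0, 10.0), (8.0, 10.0), (9.5, 9.0)])
        s = validation_summary(df)
        assert s.mean_pe == pytest.approx((10.0 - 20.0 + 50.0 / 9.0) / 3.0, abs=1e-9)
        assert s.mean_pe == pytest.approx(-1.48, abs=0.01)
        assert s.mean_ape == pytest.approx(11.85, abs=0.01)
        assert s.n_ge10 == 2 and s.frac_within_ge10 == pytest.approx(0.5)
        assert s.n_lt10 == 1 and s.frac_within_lt10 == pytest.approx(1.0)

    def test_boundary_observation_uses_15_percent_band(self):
        # obs exactly 10 with a 16% error: outside the >=10 band
        df = self._df_from_pairs([(11.6, 10.0)])
        s = validation_summary(df)
        assert s.n_ge10 == 1
        assert s.frac_within_ge10 == 0.0

    def test_noise_free_cohort_has_exactly_zero_errors(self):
        coh = make_cohort(25, seed=31, omega=OmegaSet(0.0, 0.0), scheme=EtaScheme("model"))
        df = simulate_tdm_dataset(
            coh, sampling_policy=FixedTimesSampling((47.5, 95.5)),
            sigma=SigmaSet("exponential", 0.0), lloq=0.0, seed=32,
        )
        s = validation_summary(df)
        assert s.mean_pe == pytest.approx(0.0, abs=1e-9)
        assert s.mean_ape == pytest.approx(0.0, abs=1e-9)
        assert all(s.table["within"])
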