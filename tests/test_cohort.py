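"""Virtual-cohort generation and synthetic sparse-TDM datasets."""

import numpy as np
import pandas as pd
import pytest

from teicopk.cohort import (
    CovariateDistribution,
    CovariateSpec,
    EtaScheme,
    FixedTimesSampling,
    VirtualCohort,
    make_cohort,
    sample_covariates,
    sample_random_effects,
    simulate_tdm_dataset,
)
from teicopk.covariates import OmegaSet, SigmaSet, ThetaSet


class TestSampleCovariates:
    def test_empty_cohort(self):
        assert len(sample_covariates(0, seed=1)) == 0

    def test_moments_and_ranges_match_population(self):
        df = sample_covariates(5000, seed=3)
        spec = CovariateSpec()
        assert df["wt"].mean() == pytest.approx(16.7, abs=0.5)
        assert df["wt"].std() == pytest.approx(10.1, abs=1.5)
        for col, dist in (("wt", spec.wt), ("scr", spec.scr), ("age", spec.age)):
            assert df[col].between(dist.minimum, dist.maximum).all()
            assert df[col].mean() == pytest.approx(dist.mean, rel=0.10)
            assert df[col].std() == pytest.approx(dist.sd, rel=0.10)
        assert (df["sex"] == "male").mean() == pytest.approx(0.547, abs=0.03)

    def test_same_seed_is_bit_identical(self):
        a = sample_covariates(200, seed=11)
        b = sample_covariates(200, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_infeasible_spec_rejected(self):
        with pytest.raises(ValueError):
            CovariateDistribution(mean=1.0, sd=1.0, minimum=2.0, maximum=5.0)


class TestSampleRandomEffects:
    def test_zero_omega_gives_zero_etas(self):
        etas = sample_random_effects(50, OmegaSet(0.0, 0.0), seed=1)
        assert np.all(etas == 0.0)

    def test_default_sds_recovered(self):
        etas = sample_random_effects(100_000, seed=5)
        assert etas[:, 0].std() == pytest.approx(0.659, abs=0.01)
        assert etas[:, 1].std() == pytest.approx(0.610, abs=0.01)
        # independent by default
        assert abs(np.corrcoef(etas[:, 0], etas[:, 1])[0, 1]) < 0.02

    def test_correlation_parameter(self):
        etas = sample_random_effects(100_000, seed=5, correlation=1.0)
        assert np.corrcoef(etas[:, 0], etas[:, 1])[0, 1] == pytest.approx(1.0)
        assert etas[:, 1].std() == pytest.approx(0.610, abs=0.01)

    def test_reproducible(self):
        np.testing.assert_array_equal(
            sample_random_effects(100, seed=9), sample_random_effects(100, seed=9)
        )


class TestEtaScheme:
    def test_estimate_scheme_shrinks_and_correlates(self):
        eff, corr = EtaScheme().effective(OmegaSet())
        assert eff.omega_cl == pytest.approx(0.659 * (1 - 0.269))
        assert eff.omega_v == pytest.approx(0.610 * (1 - 0.198))
        assert corr == 1.0

    def test_model_scheme_is_untouched(self):
        eff, corr = EtaScheme("model").effective(OmegaSet())
        assert (eff.omega_cl, eff.omega_v, corr) == (0.659, 0.610, 0.0)

    def test_cohort_parameters_are_derived_from_etas(self):
        coh = make_cohort(20, seed=4)
        from teicopk.covariates import individual_cl, individual_vd

        df = coh.data
        np.testing.assert_allclose(
            df["cl"], individual_cl(df["wt"], df["scr"], ThetaSet(), df["eta_cl"])
        )
        np.testing.assert_allclose(df["v"], individual_vd(df["wt"], ThetaSet(), df["eta_v"]))


class TestSimulateTDM:
    def _tiny_cohort(self, cl=0.234, v=2.43):
        df = pd.DataFrame(
            dict(id=[1], wt=[16.7], scr=[29.0], age=[4.0], sex=["male"],
                 eta_cl=[0.0], eta_v=[0.0], cl=[cl], v=[v])
        )
        return VirtualCohort(df, ThetaSet())

    def test_noise_free_dv_equals_model_prediction(self):
        coh = self._tiny_cohort()
        tdm = simulate_tdm_dataset(
            coh,
            sampling_policy=FixedTimesSampling((47.5, 95.5)),
            sigma=SigmaSet("exponential", 0.0),
            lloq=0.0,
            seed=1,
        )
        obs = tdm[tdm.EVID == 0]
        from teicopk.cohort import StandardRegimenPolicy
        from teicopk.pk_core import PKParameters, conc_profile

        reg = StandardRegimenPolicy().regimen(16.7)
        expected = conc_profile(PKParameters(0.234, 2.43), reg, obs["TIME"].to_numpy())
        np.testing.assert_allclose(obs["DV"].to_numpy(), expected, rtol=1e-12)

    def test_low_trough_floored_at_lloq(self):
        # high-clearance child whose true trough is far below 2.5 mg/L
        coh = self._tiny_cohort(cl=2.0, v=2.43)
        tdm = simulate_tdm_dataset(
            coh,
            sampling_policy=FixedTimesSampling((95.5,)),
            sigma=SigmaSet("exponential", 0.0),
            seed=1,
        )
        obs = tdm[tdm.EVID == 0]
        assert (obs["DV"] == 2.5).all()
        assert (obs["LLOQFL"] == 1).all()

    def test_sparse_sampling_count_near_expectation(self):
        coh = make_cohort(159, seed=8, scheme=EtaScheme("model"))
        tdm = simulate_tdm_dataset(coh, seed=9)
        n_obs = int((tdm.EVID == 0).sum())
        # 159 children x mean 1.5 samples => ~239 observations
        assert 210 <= n_obs <= 268

    def test_each_subject_has_dose_rows_and_flags_consistent(self):
        coh = make_cohort(20, seed=2)
        tdm = simulate_tdm_dataset(coh, seed=3)
        for _, grp in tdm.groupby("ID"):
            assert (grp.EVID == 1).sum() >= 1
            first_dose = grp.loc[grp.EVID == 1, "TIME"].min()
            assert (grp.loc[grp.EVID == 0, "TIME"] >= first_dose).all()
        obs = tdm[tdm.EVID == 0]
        assert (obs.loc[obs.LLOQFL == 1, "DV"] >= 2.5 - 1e-12).all()

    def test_empty_cohort_rejected(self):
        empty = VirtualCohort(
            pd.DataFrame(columns=["id", "wt", "scr", "age", "sex", "eta_cl", "eta_v", "cl", "v"]),
            ThetaSet(),
        )
        with pytest.raises(ValueError):
            simulate_tdm_dataset(empty, seed=1)
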