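import numpy as np
import pandas as pd
import pytest

import soilheat as sh
from soilheat.design import DesignSpec, build_model_matrix, enumerate_units, units_to_frame
from soilheat.jsdm import (
    JSDMSpec,
    JointSpeciesModel,
    PosteriorDraws,
    classify_support,
    prevalence_filter,
    psrf,
)


class TestPrevalenceFilter:
    def test_quarter_of_120_units_gives_cutoff_30(self):
        rng = np.random.default_rng(0)
        Y = pd.DataFrame(rng.poisson(0.5, size=(120, 12)))
        _, cutoff = prevalence_filter(Y, 0.25)
        assert cutoff == 30

    def test_ubiquitous_species_always_retained(self):
        Y = pd.DataFrame({"a": np.ones(40), "b": np.zeros(40)})
        filtered, _ = prevalence_filter(Y, 0.9)
        assert list(filtered.columns) == ["a"]

    def test_toy_matrix_matches_direct_count(self):
        rng = np.random.default_rng(1)
        Y = pd.DataFrame(rng.poisson(0.4, size=(8, 10)))
        filtered, cutoff = prevalence_filter(Y, 0.25)
        assert cutoff == 2
        expected = [c for c in Y.columns if int((Y[c] > 0).sum()) >= 2]
        assert list(filtered.columns) == expected

    def test_threshold_bounds(self):
        Y = pd.DataFrame(np.ones((4, 2)))
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                prevalence_filter(Y, bad)


class TestPSRF:
    def test_identical_chains_give_exactly_one(self):
        rng = np.random.default_rng(2)
        one = rng.normal(size=(1, 200, 3))
        chains = np.repeat(one, 4, axis=0)
        r = psrf(chains)
        assert np.allclose(r, 1.0, atol=1e-9)

    def test_same_distribution_stays_below_1_1(self):
        rng = np.random.default_rng(3)
        chains = rng.normal(size=(4, 500, 5))
        assert psrf(chains).max() < 1.1

    def test_separated_means_exceed_1_2(self):
        rng = np.random.default_rng(4)
        chains = rng.normal(size=(2, 300, 1))
        chains[1] += 10.0
        assert psrf(chains).min() > 1.2

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            psrf(np.zeros((1, 100, 2)))


class TestSupportClassification:
    def _draws(self, values):
        arr = np.asarray(values, float).reshape(2, -1, 1)
        return PosteriorDraws(arr, ["beta[sp,term]"])

    def test_all_positive_draws(self):
        d = self._draws(np.ones(1000))
        assert classify_support(d).iloc[0] == "positive"

    def test_960_of_1000_is_positive_at_95(self):
        vals = np.concatenate([np.ones(960), -np.ones(40)])
        assert classify_support(self._draws(vals)).iloc[0] == "positive"
        vals = np.concatenate([np.ones(949), -np.ones(51)])
        assert classify_support(self._draws(vals)).iloc[0] == "neutral"

    def test_even_split_is_neutral(self):
        vals = np.concatenate([np.ones(500), -np.ones(500)])
        assert classify_support(self._draws(vals)).iloc[0] == "neutral"


def _small_design(n_plots=5, seasons=("spring", "summer")):
    spec = DesignSpec(seasons=seasons, plots_per_site_season=n_plots, harvests=("H1",))
    units = units_to_frame(enumerate_units(spec))
    return units, build_model_matrix(units, groups="block")


def _simulate_counts(mm, beta, sigma=0.3, seed=0):
    rng = np.random.default_rng(seed)
    eta = mm.matrix @ beta + rng.normal(0, sigma, size=(mm.shape[0], beta.shape[1]))
    return pd.DataFrame(rng.poisson(np.exp(eta)), index=mm.frame.index,
                        columns=[f"sp{j}" for j in range(beta.shape[1])])


class TestJointSpeciesModel:
    def test_bookkeeping_4_chains_x_250_gives_1000_draws(self):
        units, mm = _small_design(n_plots=2, seasons=("spring",))
        beta = np.zeros((mm.shape[1], 2))
        beta[0] = 1.0
        Y = _simulate_counts(mm, beta, seed=5)
        res = JointSpeciesModel(Y, mm, family="lognormal_poisson").fit(
            chains=4, samples=250, transient=20, seed=1
        )
        assert res.draws.n_chains == 4
        assert res.draws.n_samples == 250
        assert res.draws.n_total == 1000

    def test_planted_treatment_effect_recovered(self):
        units, mm = _small_design(n_plots=8, seasons=("spring", "summer", "autumn"))
        p = mm.shape[1]
        S = 5
        beta = np.zeros((p, S))
        beta[0] = np.log(20.0)
        t_idx = mm.columns.index("treatment[extreme_heat]")
        beta[t_idx, 2] = 1.5
        Y = _simulate_counts(mm, beta, seed=6)
        res = JointSpeciesModel(Y, mm, family="lognormal_poisson").fit(
            chains=2, samples=200, transient=200, seed=2
        )
        est = res.beta_mean.loc["sp2", "treatment[extreme_heat]"]
        assert est == pytest.approx(1.5, abs=0.5)
        cls, _ = res.support(0.95)
        assert cls.loc["sp2", "treatment[extreme_heat]"] == "positive"

    def test_hurdle_presence_invariant_to_abundance_rescaling(self):
        units, mm = _small_design(n_plots=3)
        rng = np.random.default_rng(7)
        Y = pd.DataFrame(
            rng.poisson(2.0, size=(mm.shape[0], 3)), index=mm.frame.index, columns=list("abc")
        )
        r1 = JointSpeciesModel(Y, mm, family="hurdle_probit").fit(chains=2, samples=50, transient=20, seed=3)
        r2 = JointSpeciesModel(Y * 10, mm, family="hurdle_probit").fit(chains=2, samples=50, transient=20, seed=3)
        np.testing.assert_allclose(r1.draws.array, r2.draws.array)

    def test_hurdle_lognormal_runs_and_zscales(self):
        units, mm = _small_design(n_plots=4)
        rng = np.random.default_rng(8)
        Y = pd.DataFrame(
            rng.poisson(5.0, size=(mm.shape[0], 4)) * rng.integers(0, 2, size=(mm.shape[0], 4)),
            index=mm.frame.index, columns=list("abcd"),
        )
        res = JointSpeciesModel(Y, mm, family="hurdle_lognormal").fit(chains=2, samples=60, transient=40, seed=4)
        assert res.draws.n_total == 120
        assert np.isfinite(res.beta_mean.to_numpy()).all()

    def test_traits_must_align_with_species(self):
        units, mm = _small_design(n_plots=2)
        Y = pd.DataFrame(np.ones((mm.shape[0], 2)), index=mm.frame.index, columns=["a", "b"])
        traits = pd.DataFrame({"t": [1.0]}, index=["a"])
        with pytest.raises(KeyError):
            JointSpeciesModel(Y, mm, traits=traits)

    def test_check_convergence_raises_on_bad_chains(self):
        units, mm = _small_design(n_plots=2, seasons=("spring",))
        beta = np.zeros((mm.shape[1], 2))
        Y = _simulate_counts(mm, beta, seed=9)
        res = JointSpeciesModel(Y, mm, family="lognormal_poisson").fit(
            chains=2, samples=250, transient=100, seed=5
        )
        # doctor the draws into two separated chains
        res.draws.array[1] += 50.0
        with pytest.raises(RuntimeError, match="R-hat"):
            res.check_convergence(threshold=1.2)


@pytest.fixture(scope="module")
def fitted():
    spec = DesignSpec(plots_per_site_season=6, harvests=("H1",))
    units = units_to_frame(enumerate_units(spec))
    mm = build_model_matrix(units, groups="block")
    rng = np.random.default_rng(10)
    p, S = mm.shape[1], 4
    beta = np.zeros((p, S))
    beta[0] = np.log(15.0)
    t_idx = mm.columns.index("treatment[extreme_heat]")
    beta[t_idx] = 2.0  # dominant heat effect for every species
    Y = _simulate_counts(mm, beta, seed=11)
    return JointSpeciesModel(Y, mm, family="lognormal_poisson").fit(
        chains=2, samples=150, transient=150, seed=6
    )


class TestVariancePartition:
    def test_proportions_sum_to_one(self, fitted):
        vp = fitted.variance_partition()
        np.testing.assert_allclose(vp.sum(axis=1), 1.0, atol=1e-9)
        assert (vp.to_numpy() >= 0).all()

    def test_dominant_treatment_effect_dominates_partition(self, fitted):
        vp = fitted.variance_partition()
        assert (vp["treatment"] > 0.5).all()

    def test_single_group_takes_everything(self, fitted):
        cols = [c for c in fitted.model.term_names if c != "Intercept"]
        vp = fitted.variance_partition({"all_fixed": cols})
        # block variance still gets its own share; fixed share + random = 1
        assert set(vp.columns) == {"all_fixed", "random"}
        np.testing.assert_allclose(vp.sum(axis=1), 1.0, atol=1e-9)

    def test_overlapping_groups_rejected(self, fitted):
        with pytest.raises(ValueError, match="overlap"):
            fitted.variance_partition(
                {"a": ["treatment[extreme_heat]"], "b": ["treatment[extreme_heat]"]}
            )


class TestJSDMSpecValidation:
    def test_family_and_plan_validation(self):
        with pytest.raises(ValueError):
            JSDMSpec(family="poisson")
        with pytest.raises(ValueError):
            JSDMSpec(chains=0)
        spec = JSDMSpec()
        assert spec.chains * spec.samples == 1000
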