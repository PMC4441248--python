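import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp
from sklearn.base import clone

from msydemog.abcfit import (
    ABCModelChoice,
    ABCPosterior,
    build_summary,
    local_linear_adjust,
    logtan,
    logtan_inverse,
    model_choice_logistic,
    model_posterior_rejection,
    parameter_recovery_suite,
    power_analysis,
    reject,
    sfs_columns,
)
from msydemog.coalescent import simulate_batch
from msydemog.demography import UniformPrior, model_spec, sample_prior


def xi_frame(X, models=None):
    df = pd.DataFrame(X, columns=[f"xi_{i+1}" for i in range(np.shape(X)[1])])
    if models is not None:
        df.insert(0, "model", models)
    return df


class TestBuildSummary:
    def test_mask_drops_empty_observed_categories(self):
        table = xi_frame(np.ones((10, 3)))
        obs, sims, scaler = build_summary([5, 0, 2], table)
        assert list(scaler.mask) == [0, 2]
        assert obs.shape == (2,)
        assert sims.shape == (10, 2)

    def test_identity_mask_when_all_observed(self):
        table = xi_frame(np.arange(30).reshape(10, 3))
        obs, sims, scaler = build_summary([1, 1, 1], table)
        assert list(scaler.mask) == [0, 1, 2]

    def test_mad_scaling_and_zero_mad_guard(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        table = xi_frame(X)
        obs, sims, scaler = build_summary([2, 3], table)
        assert scaler.scale[1] == 1.0  # zero-MAD category untouched
        assert sims[:, 0] == pytest.approx(np.arange(10.0) / scaler.scale[0])

    def test_empty_observed_rejected(self):
        with pytest.raises(ValueError):
            build_summary([0, 0, 0], xi_frame(np.ones((5, 3))))


class TestRejection:
    def test_full_acceptance_returns_simulation_proportions(self, rng):
        models = np.array(["A"] * 60 + ["B"] * 40)
        sims = rng.normal(size=(100, 4))
        res = reject(np.zeros(4), sims, 100, rng)
        probs = model_posterior_rejection(models[res.indices])
        assert probs["A"] == pytest.approx(0.6)
        assert probs["B"] == pytest.approx(0.4)

    def test_exact_match_accepted_at_zero_distance(self, rng):
        sims = rng.normal(size=(50, 3))
        res = reject(sims[17], sims, 5, rng)
        assert 17 in res.indices
        assert res.distances.min() == 0.0

    def test_duplicated_table_keeps_same_distance_multiset(self, rng):
        sims = rng.normal(size=(40, 3))
        obs = rng.normal(size=3)
        r1 = reject(obs, sims, 10, 0)
        r2 = reject(obs, np.vstack([sims, sims]), 20, 0)
        assert np.allclose(np.sort(np.repeat(r1.distances, 2)), np.sort(r2.distances))

    def test_invalid_n_accept(self, rng):
        sims = rng.normal(size=(10, 2))
        with pytest.raises(ValueError):
            reject(np.zeros(2), sims, 0)
        with pytest.raises(ValueError):
            reject(np.zeros(2), sims, 11)

    def test_full_acceptance_recovers_prior(self, m1_table_small):
        # with every row accepted the "posterior" must be the prior itself
        spec = model_spec("M1")
        table = m1_table_small
        obs = table[sfs_columns(table)].iloc[0].to_numpy(float)
        o, s, _ = build_summary(obs, table)
        res = reject(o, s, len(table), 0)
        accepted_n = table["N"].to_numpy()[res.indices]
        fresh = np.array(
            [sample_prior(spec, np.random.default_rng(i)).values["N"] for i in range(600)]
        )
        assert ks_2samp(accepted_n, fresh).pvalue > 0.01


class TestModelChoice:
    def test_symmetric_models_near_half(self, rng):
        X = rng.normal(size=(2000, 4))
        models = np.array(["A", "B"] * 1000)
        probs = model_choice_logistic(np.zeros(4), X, models, 400, rng)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert abs(probs["A"] - 0.5) < 0.15

    def test_agrees_with_rejection_on_symmetric_problem(self, rng):
        X = rng.normal(size=(2000, 4))
        models = np.array(["A", "B"] * 1000)
        for _ in range(10):
            obs = rng.normal(size=4) * 0.3
            pl = model_choice_logistic(obs, X, models, 400, rng)
            res = reject(obs, X, 400, rng)
            pr = model_posterior_rejection(models[res.indices]).reindex(
                ["A", "B"], fill_value=0
            )
            assert abs(pl["A"] - pr["A"]) < 0.12

    def test_separated_models_are_resolved(self, rng):
        X = np.vstack([rng.normal(0, 1, (500, 3)), rng.normal(8, 1, (500, 3))])
        models = np.array(["near"] * 500 + ["far"] * 500)
        with pytest.warns(UserWarning, match="absent"):
            # so well separated that only "near" survives rejection
            probs = model_choice_logistic(np.zeros(3) + 0.1, X, models, 200, rng)
        assert probs["near"] > 0.95

    def test_absent_model_reported_zero_with_warning(self, rng):
        X = np.vstack([rng.normal(0, 0.1, (50, 2)), rng.normal(50, 0.1, (50, 2))])
        models = np.array(["A"] * 50 + ["B"] * 50)
        with pytest.warns(UserWarning, match="absent"):
            probs = model_choice_logistic(np.zeros(2), X, models, 20, rng)
        assert probs["B"] == 0.0
        assert probs["A"] == 1.0


class TestLogtan:
    PRIOR = UniformPrior(20.0, 20_000.0)

    def test_midpoint_maps_to_zero(self):
        mid = (self.PRIOR.lower + self.PRIOR.upper) / 2
        assert logtan(mid, self.PRIOR) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(min_value=20.001, max_value=19_999.999))
    def test_round_trip(self, x):
        assert logtan_inverse(logtan(x, self.PRIOR), self.PRIOR) == pytest.approx(
            x, abs=1e-6, rel=1e-9
        )

    def test_monotone_and_limits(self):
        xs = np.linspace(20.01, 19_999.99, 500)
        ys = logtan(xs, self.PRIOR)
        assert (np.diff(ys) > 0).all()
        with pytest.warns(UserWarning, match="clamping"):
            lo = logtan(20.0, self.PRIOR)
        assert lo < -10

    def test_inverse_always_inside_support(self, rng):
        y = rng.normal(scale=50, size=1000)
        x = logtan_inverse(y, self.PRIOR)
        assert (x > self.PRIOR.lower).all() and (x < self.PRIOR.upper).all()


class TestLocalLinearAdjust:
    def test_uninformative_summaries_leave_posterior_unadjusted(self, rng):
        prior = UniformPrior(0.0, 100.0)
        n = 500
        params = pd.DataFrame({"p": rng.uniform(1, 99, n)})
        sims = rng.normal(size=(n, 3))  # independent of the parameter
        d = np.sqrt((sims**2).sum(axis=1))
        post = local_linear_adjust(params, sims, d, d.max(), np.zeros(3), {"p": prior})
        p = post["p"]
        assert p.adjusted
        assert abs(p.r2) < 0.05
        # adjustment is a no-op in distribution: medians agree loosely
        assert abs(p.median - np.median(params["p"])) < 10

    def test_noiseless_linear_map_recovers_generating_value(self, rng):
        prior = UniformPrior(100.0, 200.0)
        n = 400
        x = rng.uniform(101, 199, n)
        sims = np.column_stack([x, 0.01 * x**2])  # summaries carry x exactly
        obs = np.array([150.0, 0.01 * 150.0**2])
        d = np.sqrt(((sims - obs) ** 2).sum(axis=1))
        keep = np.argsort(d)[:200]
        post = local_linear_adjust(
            pd.DataFrame({"p": x[keep]}), sims[keep], d[keep], d[keep].max(), obs,
            {"p": prior},
        )
        p = post["p"]
        assert p.r2 > 0.99
        assert p.median == pytest.approx(150.0, abs=0.5)
        assert p.ci_high - p.ci_low < 5.0

    def test_adjusted_samples_respect_prior_support(self, m1_table_small):
        spec = model_spec("M1")
        table = m1_table_small
        obs = table[sfs_columns(table)].iloc[3].to_numpy(float)
        o, s, _ = build_summary(obs, table)
        res = reject(o, s, 100, 0)
        post = local_linear_adjust(
            table.iloc[res.indices][["N"]], s[res.indices], res.distances,
            res.tolerance, o, {"N": spec.priors["N"]},
        )
        p = post["N"]
        assert (p.sample > 20).all() and (p.sample < 20_000).all()
        assert spec.priors["N"].lower <= p.ci_low <= p.ci_high <= spec.priors["N"].upper

    def test_t1_recomposed_from_t2_and_lex(self, rng):
        priors = {"T2": UniformPrior(0.0, 30.0), "LEX": UniformPrior(5.0, 634.0)}
        n = 300
        params = pd.DataFrame(
            {"T2": rng.uniform(0.1, 29.9, n), "LEX": rng.uniform(6, 630, n)}
        )
        sims = rng.normal(size=(n, 2))
        d = np.sqrt((sims**2).sum(axis=1))
        post = local_linear_adjust(params, sims, d, d.max(), np.zeros(2), priors)
        assert "T1" in post
        assert np.allclose(post["T1"].sample, post["T2"].sample + post["LEX"].sample)
        assert post["T1"].sample.max() < 664.0

    def test_singular_design_falls_back_to_rejection(self, rng):
        prior = UniformPrior(0.0, 10.0)
        params = pd.DataFrame({"p": rng.uniform(1, 9, 50)})
        sims = np.zeros((50, 2))  # constant summaries: singular design
        d = np.zeros(50)
        post = local_linear_adjust(params, sims, d, 0.0, np.zeros(2), {"p": prior})
        assert not post["p"].adjusted
        assert math.isnan(post["p"].r2)


class TestPowerAndCoverage:
    """Contract checks at miniature sizes; the paper-scale run lives in the
    acceptance suite."""

    @pytest.fixture(scope="class")
    def small_pair(self):
        m1 = model_spec("M1", N=UniformPrior(500.0, 2000.0))
        m4 = model_spec("M4", NA=UniformPrior(50.0, 200.0),
                        NC=UniformPrior(5000.0, 20_000.0))
        ss = np.random.SeedSequence(77)
        c1, c2 = ss.spawn(2)
        table = pd.concat(
            [simulate_batch(m1, 400, 20, c1), simulate_batch(m4, 400, 20, c2)],
            ignore_index=True,
        )
        return [m1, m4], table

    def test_confusion_matrix_is_a_stochastic_matrix(self, small_pair):
        specs, table = small_pair
        conf = power_analysis(specs, table, 25, 40, 20, 31)
        assert conf.shape == (2, 2)
        assert ((conf.to_numpy() >= 0) & (conf.to_numpy() <= 1)).all()
        assert conf.sum(axis=1).to_numpy() == pytest.approx([1.0, 1.0])

    def test_recovery_suite_reports_coverage_per_parameter(self, m1_table_small):
        spec = model_spec("M1")
        out = parameter_recovery_suite(spec, m1_table_small, 25, 60, 20, 5)
        assert list(out["parameter"]) == ["N"]
        assert 0.0 <= out["coverage"].iloc[0] <= 1.0

    def test_t1_posterior_stays_wide(self, rng):
        # single-locus data barely constrains the onset time of change: the
        # T1 interval must remain a large fraction of its prior interval
        spec = model_spec("M4")
        table = simulate_batch(spec, 1500, 20, 202)
        obs = table[sfs_columns(table)].iloc[7].to_numpy(float)
        o, s, _ = build_summary(obs, table)
        res = reject(o, s, 150, 0)
        post = local_linear_adjust(
            table.iloc[res.indices][list(spec.parameter_names)],
            s[res.indices], res.distances, res.tolerance, o, spec.priors,
        )
        prior_t1 = np.array(
            [
                sample_prior(spec, np.random.default_rng(i)).t1
                for i in range(2000)
            ]
        )
        prior_width = np.quantile(prior_t1, 0.975) - np.quantile(prior_t1, 0.025)
        post_width = post["T1"].ci_high - post["T1"].ci_low
        assert post_width / prior_width > 0.5


class TestEstimators:
    def test_model_choice_estimator_api(self, rng):
        X = np.vstack([rng.poisson(3, (300, 5)), rng.poisson(12, (300, 5))])
        y = np.array(["M1"] * 300 + ["M4"] * 300)
        est = ABCModelChoice(n_keep=0.2, random_state=0)
        assert clone(est).get_params() == est.get_params()
        est.fit(X, y)
        probs = est.predict_proba(np.full(5, 12.0))
        assert probs.shape == (1, 2)
        assert probs.iloc[0].sum() == pytest.approx(1.0, abs=1e-9)
        assert est.predict(np.full(5, 12.0))[0] == "M4"
        rej = ABCModelChoice(n_keep=0.2, method="rejection").fit(X, y)
        assert rej.predict(np.full(5, 3.0))[0] == "M1"

    def test_posterior_estimator_api(self, m1_table_small):
        spec = model_spec("M1")
        table = m1_table_small
        est = ABCPosterior(priors={"N": spec.priors["N"]}, n_accept=100)
        est.fit(table[sfs_columns(table)], table[["N"]])
        post = est.posterior(table[sfs_columns(table)].iloc[5])
        assert set(post) == {"N"}
        assert 20 <= post["N"].ci_low <= post["N"].ci_high <= 20_000

    def test_unfitted_raises(self):
        with pytest.raises(Exception):
            ABCModelChoice().predict_proba(np.ones(3))
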