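"""Unit tests for correlations, the Bayesian association model and BFs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normdev import association as assoc
from normdev import synthetic


class TestCorrelationMatrix:
    def test_self_and_mirror_correlations(self, rng):
        x = rng.normal(size=100)
        df = pd.DataFrame({"a": x, "b": x, "c": -x})
        cm = assoc.correlation_matrix(df)
        assert cm.r[0, 0] == pytest.approx(1.0)
        assert cm.r[0, 1] == pytest.approx(1.0)
        assert cm.r[0, 2] == pytest.approx(-1.0)

    def test_matches_direct_covariance_formula(self, rng):
        for _ in range(20):
            x, y = rng.normal(size=(2, 60))
            cm = assoc.correlation_matrix(pd.DataFrame({"x": x, "y": y}))
            oracle = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
            assert cm.r[0, 1] == pytest.approx(oracle, abs=1e-12)

    def test_star_thresholds(self):
        assert assoc._stars(0.04) == "*"
        assert assoc._stars(0.009) == "**"
        assert assoc._stars(0.0009) == "***"
        assert assoc._stars(0.2) == ""

    def test_symmetry_and_unit_diagonal(self, rng):
        df = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        cm = assoc.correlation_matrix(df)
        assert np.allclose(cm.r, cm.r.T)
        assert np.allclose(np.diag(cm.r), 1.0)
        assert np.all(np.abs(cm.r) <= 1.0)

    def test_constant_column_rejected(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=30), "b": np.ones(30)})
        with pytest.raises(ValueError, match="constant"):
            assoc.correlation_matrix(df)


class TestStandardize:
    def test_mean_zero_sd_one(self, rng):
        (out,) = assoc.standardize_predictors(rng.uniform(5, 10, 200))
        assert abs(out.mean()) < 1e-12
        assert out.std() == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        x = rng.normal(size=100)
        (a,) = assoc.standardize_predictors(x)
        (b,) = assoc.standardize_predictors(3.0 * x + 7.0)
        assert np.allclose(a, b)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            assoc.standardize_predictors(np.ones(10))


def _simulate(n, b_dom, rng, sigma=1.0):
    age = rng.normal(size=n)
    sex = rng.integers(0, 2, n).astype(float)
    dom = rng.normal(size=n)
    age_std, dom_std = assoc.standardize_predictors(age, dom)
    z = 0.1 * age_std + 0.05 * sex + b_dom * dom_std + rng.normal(0, sigma, n)
    return z, age_std, sex, dom_std


class TestBayesianLM:
    def test_prior_only_posterior_equals_prior(self):
        empty = np.empty(0)
        model = assoc.fit_bayesian_lm(empty, empty, empty, empty, prior_sd=1.0)
        assert model.posterior_mean("domain") == pytest.approx(0.0)
        assert model.posterior_sd("domain") == pytest.approx(1.0, rel=1e-6)
        assert assoc.savage_dickey_bf(model) == pytest.approx(1.0, rel=1e-6)

    def test_recovers_large_effect(self):
        # average over replicates so the check tests bias, not a single
        # simulation's sampling noise (SE of the mean ~ 0.01)
        means = []
        for rep in range(10):
            z, a, s, d = _simulate(1000, 0.5, np.random.default_rng(300 + rep))
            model = assoc.fit_bayesian_lm(z, a, s, d)
            means.append(model.posterior_mean("domain"))
        assert np.mean(means) == pytest.approx(0.5, abs=0.05)

    def test_analytic_and_sampling_posteriors_agree(self, rng):
        z, a, s, d = _simulate(500, 0.2, rng)
        model = assoc.fit_bayesian_lm(z, a, s, d)
        draws = model.sample(8000, seed=3)[:, model._idx("domain")]
        assert draws.mean() == pytest.approx(model.posterior_mean("domain"), abs=0.02 * model.posterior_sd("domain") + 0.02 * abs(model.posterior_mean("domain")))
        assert draws.std() == pytest.approx(model.posterior_sd("domain"), rel=0.05)

    def test_credible_interval_brackets_posterior_mean(self, rng):
        z, a, s, d = _simulate(400, -0.1, rng)
        model = assoc.fit_bayesian_lm(z, a, s, d)
        lo, hi = model.credible_interval(0.95)
        assert lo < model.posterior_mean("domain") < hi
        assert model.posterior_cdf(lo) == pytest.approx(0.025, abs=1e-6)

    def test_rank_deficient_predictors_rejected(self, rng):
        z, a, s, _ = _simulate(100, 0.0, rng)
        with pytest.raises(ValueError, match="rank"):
            assoc.fit_bayesian_lm(z, a, s, a)  # domain duplicates age

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="equal length"):
            assoc.fit_bayesian_lm(np.ones(5), np.ones(4), np.ones(5), np.ones(5))


class TestSavageDickey:
    def test_sampling_estimate_close_to_analytic(self, rng):
        z, a, s, d = _simulate(1000, 0.0, rng)
        model = assoc.fit_bayesian_lm(z, a, s, d)
        bf_a = assoc.savage_dickey_bf(model, method="analytic")
        bf_s = assoc.savage_dickey_bf(model, method="samples", n_draws=30000, seed=1)
        assert bf_s == pytest.approx(bf_a, rel=0.05)

    def test_too_few_draws_rejected(self, rng):
        z, a, s, d = _simulate(200, 0.0, rng)
        model = assoc.fit_bayesian_lm(z, a, s, d)
        with pytest.raises(ValueError, match="1000"):
            assoc.savage_dickey_bf(model, method="samples", draws=np.zeros(100))

    def test_bf_decreases_with_effect_size(self, rng):
        bfs = []
        for b in (0.0, 0.1, 0.2, 0.4):
            z, a, s, d = _simulate(800, b, np.random.default_rng(55))
            model = assoc.fit_bayesian_lm(z, a, s, d)
            bfs.append(assoc.savage_dickey_bf(model))
        assert bfs == sorted(bfs, reverse=True)


class TestClassifyBF:
    @pytest.mark.parametrize(
        "bf, label",
        [
            (0.005, "extreme (alternative)"),
            (0.05, "strong (alternative)"),
            (0.2, "moderate (alternative)"),
            (0.5, "anecdotal (alternative)"),
            (1.0, "evidence in either direction"),
            (2.0, "anecdotal (null)"),
            (5.0, "moderate (null)"),
            (15.0, "strong (null)"),
            (50.0, "very strong (null)"),
            (200.0, "extreme (null)"),
        ],
    )
    def test_band_probes(self, bf, label):
        assert assoc.classify_bf(bf) == label

    def test_boundary_conventions(self):
        # alternative side: [lower, upper); null side: (lower, upper]
        assert assoc.classify_bf(0.3) == "anecdotal (alternative)"
        assert assoc.classify_bf(0.1) == "moderate (alternative)"
        assert assoc.classify_bf(3.0) == "anecdotal (null)"
        assert assoc.classify_bf(30.0) == "strong (null)"

    @settings(deadline=None, max_examples=200)
    @given(st.floats(min_value=1e-300, max_value=1e300))
    def test_every_positive_bf_gets_exactly_one_label(self, bf):
        label = assoc.classify_bf(bf)
        assert isinstance(label, str) and label

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            assoc.classify_bf(0.0)
        with pytest.raises(ValueError):
            assoc.classify_bf(np.inf)


@pytest.fixture(scope="module")
def grid_inputs():
    coh = synthetic.generate_cohort(300, seed=31)
    rng = np.random.default_rng(0)
    deviations = pd.DataFrame(
        {f"{f}_dev": rng.normal(size=300) for f in synthetic.BRAIN_FEATURES}
    )
    domains = coh.latents[[f"dom_{j + 1}" for j in range(7)]].copy()
    domains.columns = [f"IC{j + 1}" for j in range(7)]
    domains["general"] = domains.mean(axis=1)
    return coh, deviations, domains


class TestAssociationGrid:
    def test_grid_cardinality_and_columns(self, grid_inputs):
        coh, deviations, domains = grid_inputs
        grid = assoc.run_association_grid(
            deviations,
            domains,
            coh.latents["dev_COG"].to_numpy(),
            coh.table["age"].to_numpy(),
            coh.table["sex"].to_numpy(),
        )
        assert len(grid) == 54
        assert set(grid["feature"]) == {f"{f}_dev" for f in synthetic.BRAIN_FEATURES}
        assert grid.groupby("feature").size().eq(9).all()
        assert (grid["BF01"] > 0).all()
        for row in grid.itertuples():
            assert row.label == assoc.classify_bf(row.BF01)

    def test_row_order_invariance(self, grid_inputs):
        coh, deviations, domains = grid_inputs
        args = (
            coh.latents["dev_COG"].to_numpy(),
            coh.table["age"].to_numpy(),
            coh.table["sex"].to_numpy(),
        )
        grid1 = assoc.run_association_grid(deviations, domains, *args)
        perm = np.random.default_rng(5).permutation(len(deviations))
        grid2 = assoc.run_association_grid(
            deviations.iloc[perm].reset_index(drop=True),
            domains.iloc[perm].reset_index(drop=True),
            args[0][perm],
            args[1][perm],
            args[2][perm],
        )
        pd.testing.assert_frame_equal(grid1, grid2)

    def test_misaligned_subject_ids_rejected(self, grid_inputs):
        coh, deviations, domains = grid_inputs
        dev = deviations.copy()
        dev["subject_id"] = coh.table["subject_id"].to_numpy()
        dom = domains.copy()
        dom["subject_id"] = coh.table["subject_id"].to_numpy()[::-1]
        with pytest.raises(ValueError, match="misaligned"):
            assoc.run_association_grid(
                dev,
                dom,
                coh.latents["dev_COG"].to_numpy(),
                coh.table["age"].to_numpy(),
                coh.table["sex"].to_numpy(),
            )
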