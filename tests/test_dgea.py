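"""Per-feature linear models, variance moderation and selection rules."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from icaflow.dgea import (
    ModeratedLinearModel,
    bh_adjust,
    build_design,
    ebayes_moderate,
    fit_linear_models,
    hierarchical_order,
    select_differential,
    select_strong_effects,
)
from icaflow.io import DataError, FeatureAnnotation
from icaflow.simulate import SimulationConfig, simulate_dataset

from conftest import make_matrix, make_samples


def small_design_matrix(rng=None, m=8):
    distances = [0, 50, 0, 25, 0, 80, 0, 40][:m]
    genders = (["male", "male", "female", "female"] * m)[:m]
    samples = make_samples(m, distances=distances, genders=genders, paired=True)
    return samples, build_design(samples)


class TestDesign:
    def test_paired_mixed_design_is_full_rank(self):
        samples = make_samples(4, distances=[0, 50, 0, 50],
                               genders=["male", "male", "female", "female"],
                               paired=True)
        X = build_design(samples)
        assert X.shape == (4, 3)
        assert np.linalg.matrix_rank(X.to_numpy()) == 3
        assert list(X["intercept"]) == [1.0] * 4

    def test_single_gender_cohort_is_fatal(self):
        samples = make_samples(4, distances=[0, 50, 0, 25],
                               genders=["male"] * 4, paired=True)
        with pytest.raises(DataError, match="gender"):
            build_design(samples)

    def test_row_order_follows_samples(self):
        samples, X = small_design_matrix()
        perm = [3, 1, 0, 2, 5, 4, 7, 6]
        Xp = build_design([samples[i] for i in perm])
        assert np.array_equal(Xp.to_numpy(), X.to_numpy()[perm])


class TestOls:
    def test_exact_linear_feature_recovered(self):
        samples, X = small_design_matrix()
        d = X["distance"].to_numpy()
        expr = make_matrix(np.vstack([2.0 * d]), distances=d,
                           genders=[s.gender for s in samples], paired=True)
        expr.samples = samples
        fit = fit_linear_models(expr, X)
        assert fit.coef[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        samples, X = small_design_matrix()
        Y = rng.normal(size=(8, 12))
        model = ModeratedLinearModel(prior_df=0).fit(X.to_numpy(), Y)
        Xm = X.to_numpy()
        oracle = np.linalg.solve(Xm.T @ Xm, Xm.T @ Y).T
        assert np.max(np.abs(model.coef_ - oracle)) < 1e-10

    def test_constant_shift_changes_only_intercept(self, rng):
        samples, X = small_design_matrix()
        Y = rng.normal(size=(8, 3))
        a = ModeratedLinearModel(prior_df=0).fit(X.to_numpy(), Y)
        b = ModeratedLinearModel(prior_df=0).fit(X.to_numpy(), Y + 5.0)
        assert np.allclose(b.coef_[:, 0] - a.coef_[:, 0], 5.0)
        assert np.allclose(b.coef_[:, 1:], a.coef_[:, 1:])

    def test_rank_deficient_design_is_fatal(self, rng):
        X = np.ones((6, 3))
        with pytest.raises(DataError, match="rank"):
            ModeratedLinearModel().fit(X, rng.normal(size=(6, 20)))


class TestModeration:
    def test_prior_recovery_on_simulated_variances(self):
        cfg = SimulationConfig(n_genes=5000, seed=42, k_modes=0, subject_sd=0.0,
                               pi_diff=0.0, pi_gender=0.0)
        expr, _, _ = simulate_dataset(cfg)
        fit = ebayes_moderate(fit_linear_models(expr, build_design(expr.samples)))
        assert fit.d0 == pytest.approx(cfg.d0, rel=0.20)
        assert fit.s0_squared == pytest.approx(cfg.s0_squared, rel=0.10)

    def test_zero_prior_df_reproduces_ordinary_t(self, rng):
        samples, X = small_design_matrix()
        Y = rng.normal(size=(8, 50))
        expr = make_matrix(Y.T, distances=list(X["distance"]),
                           genders=[s.gender for s in samples], paired=True)
        expr.samples = samples
        fit0 = fit_linear_models(expr, X)
        mod = ebayes_moderate(fit0, prior_df=0.0)
        se = np.sqrt(np.outer(fit0.sigma2, fit0.unscaled_var))
        assert np.allclose(mod.t_mod, fit0.coef / se)

    def test_identical_variances_are_a_fixed_point(self):
        samples, X = small_design_matrix()
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(8, 30))
        expr = make_matrix(Y.T, distances=list(X["distance"]),
                           genders=[s.gender for s in samples], paired=True)
        expr.samples = samples
        fit = fit_linear_models(expr, X)
        fit.sigma2[:] = 0.3
        for d0 in (1.0, 7.0):
            mod = ebayes_moderate(fit, prior_df=d0)
            assert np.allclose(mod.posterior_var, 0.3)

    def test_matches_bioconductor_limma(self, tmp_path):
        """Moderated t and (d0, s0^2) agree with limma's eBayes."""
        cfg = SimulationConfig(n_genes=200, seed=11, k_modes=0, subject_sd=0.0)
        expr, _, _ = simulate_dataset(cfg)
        design = build_design(expr.samples)
        fit = ebayes_moderate(fit_linear_models(expr, design))
        pd.DataFrame(expr.values, index=expr.feature_ids,
                     columns=expr.sample_ids).to_csv(tmp_path / "y.tsv", sep="\t")
        design.to_csv(tmp_path / "x.tsv", sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            y <- as.matrix(read.delim("{tmp_path}/y.tsv", row.names=1, check.names=FALSE))
            x <- as.matrix(read.delim("{tmp_path}/x.tsv", row.names=1, check.names=FALSE))
            eb <- eBayes(lmFit(y, x))
            write.table(data.frame(t_gender=eb$t[,"gender"], t_distance=eb$t[,"distance"]),
                        "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)
            cat(eb$df.prior, eb$s2.prior, file="{tmp_path}/prior.txt")
        """)
        (tmp_path / "oracle.R").write_text(script)
        res = subprocess.run(["Rscript", str(tmp_path / "oracle.R")],
                             capture_output=True, text=True)
        assert res.returncode == 0, res.stderr
        out = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        d0_r, s0_r = map(float, (tmp_path / "prior.txt").read_text().split())
        assert fit.d0 == pytest.approx(d0_r, rel=1e-5)
        assert fit.s0_squared == pytest.approx(s0_r, rel=1e-5)
        assert np.max(np.abs(out["t_distance"].to_numpy() - fit.t_mod[:, 2])) < 1e-8
        assert np.max(np.abs(out["t_gender"].to_numpy() - fit.t_mod[:, 1])) < 1e-8


class TestBhAdjust:
    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_is_fatal(self):
        with pytest.raises(DataError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    def test_matches_statsmodels_and_dominates_input(self, ps):
        mine = bh_adjust(ps)
        theirs = multipletests(ps, method="fdr_bh")[1]
        assert np.allclose(mine, theirs, atol=1e-12)
        assert np.all(mine >= np.asarray(ps) - 1e-15)


class TestSelection:
    def _moderated(self, seed=0, **kw):
        expr, ann, truth = simulate_dataset(SimulationConfig(seed=seed, **kw))
        fit = ebayes_moderate(fit_linear_models(expr, build_design(expr.samples)))
        return expr, ann, truth, fit

    def test_null_selection_rate_is_controlled(self):
        expr, ann, truth, fit = self._moderated(seed=3, pi_diff=0.0, pi_gender=0.0,
                                                k_modes=0, subject_sd=0.0)
        diff = select_differential(fit, "distance", ann, alpha=0.05)
        # BH controls FDR, so under the global null few features are selected
        se = 3 * np.sqrt(0.05 * 0.95 / expr.n_features)
        assert diff.counts["features"] / expr.n_features <= 0.05 + se

    def test_alpha_zero_selects_nothing(self):
        _, ann, _, fit = self._moderated(seed=1)
        assert len(select_differential(fit, "distance", ann, alpha=0.0).table) == 0

    def test_direction_is_sign_of_beta(self):
        _, ann, _, fit = self._moderated(seed=2)
        diff = select_differential(fit, "distance", ann)
        t = diff.table
        assert (t.loc[t["beta"] < 0, "direction"] == "down").all()
        assert (t.loc[t["beta"] > 0, "direction"] == "up").all()

    def test_down_fraction_near_planted_split(self):
        _, ann, truth, fit = self._moderated(seed=4)
        diff = select_differential(fit, "distance", ann)
        assert diff.counts["pct_down"] == pytest.approx(63.0, abs=12.0)

    def test_unknown_coefficient_is_fatal(self):
        _, ann, _, fit = self._moderated(seed=1)
        with pytest.raises(DataError):
            select_differential(fit, "age", ann)


class TestStrongEffects:
    def _diff_from_betas(self, betas):
        table = pd.DataFrame({
            "feature_id": [f"F{i}" for i in range(len(betas))],
            "gene_id": [f"G{i}" for i in range(len(betas))],
            "beta": betas,
            "t_mod": betas, "p": 0.001, "adj_p": 0.001,
            "direction": ["down" if b < 0 else "up" for b in betas],
        })
        from icaflow.dgea import DifferentialList
        return DifferentialList("distance", table, 0.05)

    def test_constant_betas_select_nothing(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert select_strong_effects(self._diff_from_betas([1, 1, 1, 1])) == []

    @pytest.mark.parametrize("convention", ["signed", "absolute"])
    def test_single_spike_below_two_sigma_threshold(self, convention):
        # mean 2, SD ~4.47 under both conventions: threshold 10.94 > |10|
        got = select_strong_effects(self._diff_from_betas([0, 0, 0, 0, 10]),
                                    convention)
        assert got == []

    def test_extreme_negative_effect_selected_under_signed_convention(self):
        got = select_strong_effects(self._diff_from_betas([0.1, -0.1, 0.2, -8.0]))
        assert got == ["F3"]


class TestHierarchicalOrder:
    def test_identical_features_are_adjacent_leaves(self, rng):
        vals = rng.normal(size=(4, 6))
        vals[2] = vals[0]
        expr = make_matrix(vals)
        rows, _ = hierarchical_order(expr, ["F0", "F1", "F2", "F3"],
                                     standardize=False)
        assert abs(rows.index("F0") - rows.index("F2")) == 1

    def test_close_pair_merges_before_far_point(self):
        # rows at 0, 1 and 11 on a line: (F0,F1) cluster, F2 apart
        expr = make_matrix([[0, 0], [1, 1], [11, 11]])
        rows, _ = hierarchical_order(expr, ["F0", "F1", "F2"], standardize=False)
        assert rows.index("F2") in (0, 2)

    def test_leaf_orders_are_permutations(self, rng):
        expr = make_matrix(rng.normal(size=(10, 7)))
        rows, cols = hierarchical_order(expr, expr.feature_ids)
        assert sorted(rows) == sorted(expr.feature_ids)
        assert sorted(cols) == sorted(expr.sample_ids)
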