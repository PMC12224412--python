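"""Partial Spearman, group tests, FDR and factorial models."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lexrsa.rsa_inference import (
    RSAConfig,
    between_group_test,
    fdr_bh,
    fit_factorial,
    partial_spearman,
    run_rsa,
    signed_rank_test,
    tukey_posthoc,
)


class TestPartialSpearman:
    def test_no_confounds_equals_scipy_spearman(self, rng):
        for _ in range(200):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            ours = partial_spearman(x, y)
            ref = stats.spearmanr(x, y).statistic
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_identical_vectors_give_one(self, rng):
        x = rng.normal(size=10)
        assert partial_spearman(x, x) == pytest.approx(1.0)
        c = rng.normal(size=10)
        assert partial_spearman(x, x, [c]) == pytest.approx(1.0)

    def test_confound_equal_to_model_degenerate(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="zero-variance"):
            partial_spearman(x, y, [y])

    def test_manual_linear_algebra_oracle(self):
        # 8-element vectors, one confound: explicit ranks, OLS, Pearson
        x = np.array([3.0, 9.0, 1.0, 7.0, 5.0, 8.0, 2.0, 6.0])
        y = np.array([2.0, 8.0, 3.0, 9.0, 4.0, 7.0, 1.0, 5.0])
        z = np.array([1.0, 6.0, 2.0, 8.0, 3.0, 7.0, 4.0, 5.0])
        rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
        Z = np.column_stack([np.ones(8), rz])
        hat = Z @ np.linalg.inv(Z.T @ Z) @ Z.T
        ex, ey = rx - hat @ rx, ry - hat @ ry
        expected = float(
            (ex @ ey) / np.sqrt((ex @ ex) * (ey @ ey))
        )
        assert partial_spearman(x, y, [z]) == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_partial_corr(self, rng):
        import pingouin as pg

        x, y = rng.normal(size=30), rng.normal(size=30)
        c1, c2 = rng.normal(size=30), rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": y, "c1": c1, "c2": c2})
        ref = pg.partial_corr(
            df, x="x", y="y", covar=["c1", "c2"], method="spearman"
        )["r"].iloc[0]
        assert partial_spearman(x, y, [c1, c2]) == pytest.approx(ref, abs=1e-6)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            partial_spearman(np.ones(5), np.ones(4))


def exact_signed_rank_p(values):
    """Full 2^n sign-flip enumeration of the signed-rank null."""
    v = np.asarray(values, float)
    v = v[v != 0]
    n = v.size
    ranks = stats.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    total = ranks.sum()
    stat_obs = min(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if min(w, total - w) <= stat_obs + 1e-12:
            count += 1
    return count / 2**n


class TestSignedRank:
    def test_all_positive_five_values(self):
        assert signed_rank_test(np.array([1, 2, 3, 4, 5])) == pytest.approx(
            0.0625
        )

    def test_exact_branch_equals_enumeration(self, rng):
        for n in (5, 8, 10, 12):
            for _ in range(5):
                v = rng.normal(0.3, 1.0, size=n)
                assert signed_rank_test(v) == pytest.approx(
                    exact_signed_rank_p(v), abs=1e-10
                )

    def test_symmetric_sample_not_significant(self):
        v = np.array([-2.0, 2.0, -1.0, 1.0, -3.0, 3.0])
        assert signed_rank_test(v) > 0.5

    def test_zeros_dropped(self):
        v = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        assert signed_rank_test(v) == pytest.approx(0.0625)

    def test_too_few_nonzero_rejected(self):
        with pytest.raises(ValueError):
            signed_rank_test(np.array([0.0, 0.0, 1.0, 2.0]))

    def test_null_calibration(self, rng):
        rejections = 0
        reps = 2000
        for _ in range(reps):
            v = rng.normal(size=20)
            rejections += signed_rank_test(v) < 0.05
        assert 0.035 <= rejections / reps <= 0.065


class TestBetweenGroup:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = between_group_test(a, a.copy())
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            between_group_test(np.ones(3), np.ones(4))

    def test_agrees_with_permutation_test(self, rng):
        a = rng.normal(0.0, 1.0, size=20)
        b = rng.normal(0.7, 1.0, size=22)
        _, p = between_group_test(a, b)
        ref = stats.permutation_test(
            (a, b),
            lambda x, y: np.mean(x) - np.mean(y),
            n_resamples=4000,
            alternative="two-sided",
            rng=rng,
        ).pvalue
        assert p == pytest.approx(ref, abs=0.02)

    def test_ranksum_variant(self, rng):
        a, b = rng.normal(size=10), rng.normal(1.5, 1.0, size=10)
        stat, p = between_group_test(a, b, method="ranksum")
        ref = stats.ranksums(a, b)
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


class TestFdrBH:
    def test_worked_vector(self):
        q = fdr_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_equal_ps(self):
        assert fdr_bh(np.array([0.2]))[0] == pytest.approx(0.2)
        np.testing.assert_allclose(fdr_bh(np.full(5, 0.3)), 0.3)

    def test_monotone_and_dominates_p(self, rng):
        p = rng.uniform(size=30)
        q = fdr_bh(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.5]))


def balanced_table(rng, effect_group=0.0, effect_model=0.0, n_per_cell=4):
    rows = []
    for g in ("ctl", "dys"):
        for m in ("Sem", "Orth"):
            for s in range(n_per_cell):
                rho = (
                    effect_group * (g == "ctl")
                    + effect_model * (m == "Sem")
                    + rng.normal(0, 0.1)
                )
                rows.append({"group": g, "model": m, "rho": rho})
    return pd.DataFrame(rows)


class TestFitFactorial:
    def test_pure_group_effect_gives_zero_model_F(self, rng):
        # noiseless response depending only on group
        # identical within-cell values across models: model cell means
        # coincide exactly, so SS_model = 0 while residual SS > 0
        wiggle = [0.05, -0.02, -0.03]
        rows = [
            {"group": g, "model": m, "rho": (1.0 if g == "ctl" else 0.0) + w}
            for g in ("ctl", "dys")
            for m in ("Sem", "Orth")
            for w in wiggle
        ]
        df = pd.DataFrame(rows)
        res = {r.term: r for r in fit_factorial(df, "rho", ["group", "model"])}
        assert res["C(model)"].F == pytest.approx(0.0, abs=1e-10)
        assert res["C(group)"].F > 100

    def test_constant_response_rejected(self):
        df = pd.DataFrame(
            {"group": ["a", "a", "b", "b"], "model": ["x", "y", "x", "y"],
             "rho": [1.0] * 4}
        )
        with pytest.raises(ValueError, match="constant"):
            fit_factorial(df, "rho", ["group", "model"])

    def test_hand_projection_oracle_16_rows(self, rng):
        df = balanced_table(rng, effect_group=0.3, effect_model=0.2)
        res = fit_factorial(
            df, "rho", ["group", "model"],
            interactions=[("group", "model")],
        )
        # explicit projection computation: RSS drops between nested models
        y = df["rho"].to_numpy()
        g = (df["group"] == "ctl").to_numpy(float)
        m = (df["model"] == "Sem").to_numpy(float)
        one = np.ones_like(y)

        def rss(cols):
            X = np.column_stack(cols)
            b, *_ = np.linalg.lstsq(X, y, rcond=None)
            return ((y - X @ b) ** 2).sum()

        rss_full = rss([one, g, m, g * m])
        df_resid = len(y) - 4
        # Type II: main effects adjusted for the other main effect only,
        # the interaction adjusted for both mains
        expected = {
            "C(group)": (rss([one, m]) - rss([one, g, m])),
            "C(model)": (rss([one, g]) - rss([one, g, m])),
            "C(group):C(model)": (rss([one, g, m]) - rss_full),
        }
        for r in res:
            F_hand = expected[r.term] / (rss_full / df_resid)
            assert r.F == pytest.approx(F_hand, rel=1e-6)
            assert r.df_den == df_resid

    def test_ancova_with_covariate_runs(self, rng):
        df = balanced_table(rng, effect_group=0.2, n_per_cell=6)
        df["fluency"] = rng.normal(450, 60, size=len(df))
        res = fit_factorial(
            df, "rho", ["group", "model"], covariates=["fluency"],
            interactions=[("group", "model")],
        )
        terms = {r.term for r in res}
        assert "fluency" in terms and "C(group):C(model)" in terms

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"group": ["a"] * 4, "rho": [1.0, 2.0, 3.0, 4.0]})
        with pytest.raises(ValueError, match="levels"):
            fit_factorial(df, "rho", ["group"])


class TestTukey:
    def test_equal_cell_means_give_p_one(self):
        vals = np.array([1.0, 2.0, 1.0, 2.0])
        cells = np.array(["a", "a", "b", "b"])
        res = tukey_posthoc(vals, cells)
        assert res["p_adj"].iloc[0] == pytest.approx(1.0)

    def test_two_cells_equal_unadjusted_t(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(0.8, 1.0, size=8)
        res = tukey_posthoc(
            np.concatenate([a, b]), np.array(["a"] * 8 + ["b"] * 8)
        )
        _, p_t = stats.ttest_ind(a, b, equal_var=True)
        assert res["p_adj"].iloc[0] == pytest.approx(p_t, abs=1e-9)

    def test_matches_statsmodels_tukeyhsd(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        vals = np.concatenate(
            [rng.normal(mu, 1.0, size=6) for mu in (0.0, 0.2, 1.5, 0.1)]
        )
        cells = np.repeat(["c1", "c2", "c3", "c4"], 6)
        ours = tukey_posthoc(vals, cells)
        ref = pairwise_tukeyhsd(vals, cells)
        np.testing.assert_allclose(
            ours["p_adj"].to_numpy(), ref.pvalues, atol=1e-6
        )

    def test_outlier_cell_has_smallest_ps(self, rng):
        vals = np.concatenate(
            [rng.normal(0.0, 0.3, size=5) for _ in range(3)]
            + [rng.normal(5.0, 0.3, size=5)]
        )
        cells = np.repeat(["a", "b", "c", "d"], 5)
        res = tukey_posthoc(vals, cells)
        with_d = res[(res["cell_a"] == "d") | (res["cell_b"] == "d")]
        without_d = res[(res["cell_a"] != "d") & (res["cell_b"] != "d")]
        assert with_d["p_adj"].max() < without_d["p_adj"].min()

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            tukey_posthoc(np.ones(3), np.array(["a"] * 3))


class TestRunRSA:
    @pytest.fixture
    def small_dataset(self):
        from lexrsa.synthetic_data import SimulationConfig, make_dataset

        cfg = SimulationConfig(
            n_words=12,
            n_subjects=6,
            latent_dim=8,
            seed=21,
            group_weights={"control": (0.8, 0.2), "dyslexic": (0.3, 0.7)},
        )
        return make_dataset(cfg)

    def test_output_tables_shapes_and_q_dominates_p(self, small_dataset):
        from lexrsa.stimulus_models import frequency_rdm, length_rdm

        ds = small_dataset
        models = {"SemModel": ds.sem_model, "OrthModel": ds.orth_model}
        confounds = [frequency_rdm(ds.words), length_rdm(ds.words)]
        rsa_results, group_results = run_rsa(
            ds.patterns, ds.groups, models, confounds
        )
        assert len(rsa_results) == 12 * 2  # subjects x models
        assert set(rsa_results["model"]) == {"SemModel", "OrthModel"}
        within = group_results[group_results["kind"] == "within"]
        assert len(within) == 4  # 2 groups x 2 models
        between = group_results[group_results["kind"] == "between"]
        assert len(between) == 2
        assert (group_results["q"] >= group_results["p"] - 1e-12).all()

    def test_pooled_fdr_family(self, small_dataset):
        from lexrsa.stimulus_models import frequency_rdm, length_rdm

        ds = small_dataset
        models = {"SemModel": ds.sem_model, "OrthModel": ds.orth_model}
        confounds = [frequency_rdm(ds.words), length_rdm(ds.words)]
        _, gr = run_rsa(
            ds.patterns, ds.groups, models, confounds,
            RSAConfig(fdr_family="pooled"),
        )
        assert not gr["q"].isna().any()

    def test_neural_equal_to_model_gives_rho_one(self, rng):
        # when the neural RDM vector equals the model RDM vector the
        # confound-partialled correlation is exactly 1
        from lexrsa.stimulus_models import frequency_rdm

        v = rng.normal(size=66)
        c = rng.normal(size=66)
        assert partial_spearman(v, v.copy(), [c]) == pytest.approx(1.0)
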