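"""CMD, permutation tests, BH-FDR, longitudinal IQR, twin heritability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from normcharts import simulate
from normcharts.cohort import (
    CentileDeviation,
    case_control_tests,
    cmd_reference,
    cmd_score,
    cohens_d,
    longitudinal_iqr,
    permutation_median_test,
    twin_correlation,
    twin_h2,
    welch_anova_bootstrap,
    welch_f,
)
from statsmodels.stats.multitest import multipletests


def diagonal_cn(rng, sds=(0.2, 0.1), n=400):
    return rng.normal(0.5, sds, size=(n, len(sds)))


class TestCMD:
    def test_diagonal_hand_example(self, rng):
        ref = cmd_reference(diagonal_cn(rng, n=100_000))
        res = cmd_score(ref, ref.mean + np.array([0.2, -0.2]))
        # components |0.2|/0.2 = 1 and |-0.2|/0.1 = 2, cmd = 3
        np.testing.assert_allclose(sorted(res.component_scores), [1.0, 2.0],
                                   atol=0.02)
        assert res.cmd == pytest.approx(3.0, abs=0.03)

    def test_zero_at_cn_mean(self, rng):
        ref = cmd_reference(diagonal_cn(rng))
        assert cmd_score(ref, ref.mean).cmd == 0.0

    def test_axes_orthonormal_and_trace_preserved(self, rng):
        X = rng.normal(0.5, 0.1, (200, 4)) @ rng.normal(size=(4, 4))
        ref = cmd_reference(X)
        np.testing.assert_allclose(ref.axes @ ref.axes.T, np.eye(4),
                                   atol=1e-10)
        assert np.sum(ref.sds ** 2) == pytest.approx(
            np.trace(np.cov(X, rowvar=False)), rel=1e-10)

    def test_matches_eigen_oracle(self, rng):
        X = rng.normal(0.5, 0.15, (300, 4))
        X[:, 1] += 0.5 * X[:, 0]
        ref = cmd_reference(X)
        x = X[0]
        # brute-force oracle via explicit eigendecomposition
        cov = np.cov(X, rowvar=False)
        evals, evecs = np.linalg.eigh(cov)
        d = np.abs(evecs.T @ (x - X.mean(axis=0))) / np.sqrt(evals)
        assert cmd_score(ref, x).cmd == pytest.approx(np.sum(d), rel=1e-10)

    def test_rotation_invariance(self, rng):
        X = rng.normal(0.5, 0.15, (250, 4))
        Q = np.linalg.qr(rng.normal(size=(4, 4)))[0]
        subj = X[7]
        a = cmd_score(cmd_reference(X), subj).cmd
        b = cmd_score(cmd_reference(X @ Q), subj @ Q).cmd
        assert a == pytest.approx(b, abs=1e-8)

    def test_euclidean_variant(self, rng):
        ref = cmd_reference(diagonal_cn(rng, n=100_000))
        res = cmd_score(ref, ref.mean + np.array([0.2, -0.2]),
                        euclidean=True)
        assert res.cmd == pytest.approx(np.sqrt(5.0), abs=0.03)

    def test_rank_deficient_axes_dropped(self, rng):
        X = rng.normal(0.5, 0.1, (50, 2))
        X = np.column_stack([X, X[:, 0]])  # third column duplicates first
        with pytest.warns(UserWarning, match="near-zero-variance"):
            ref = cmd_reference(X)
        assert len(ref.sds) == 2

    def test_transformer_api(self, rng):
        X = diagonal_cn(rng)
        est = CentileDeviation().fit(X)
        out = est.transform(X[:5])
        assert out.shape == (5,)
        assert np.all(out >= 0)

    def test_input_validation(self, rng):
        with pytest.raises(ValueError, match="10"):
            cmd_reference(np.ones((5, 3)))
        ref = cmd_reference(diagonal_cn(rng))
        with pytest.raises(ValueError, match="dimension"):
            cmd_score(ref, np.ones(5))


class TestPermutationAndBH:
    def test_bh_worked_example(self):
        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_null_pvalues_super_uniform(self, rng):
        # stochastic dominance of null permutation p-values over U(0,1)
        reps, hits = 300, 0
        for _ in range(reps):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            _, p = permutation_median_test(x, y, 199, rng)
            hits += p <= 0.05
        se = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps <= 0.05 + 3 * se

    def test_detects_shift(self, rng):
        x = rng.normal(1.0, 1.0, 100)
        y = rng.normal(0.0, 1.0, 100)
        t, p = permutation_median_test(x, y, 499, rng)
        assert t > 0 and p < 0.01

    def test_cohens_d_recovery(self, rng):
        delta = simulate.z_shift_for_cohens_d(0.8)
        ref = stats.norm.cdf(rng.normal(size=500))
        case = stats.norm.cdf(rng.normal(size=500) + delta)
        assert cohens_d(case, ref) == pytest.approx(0.8, abs=0.15)

    def test_welch_f_against_pingouin(self, rng):
        import pingouin as pg

        groups = [rng.normal(m, s, n) for m, s, n in
                  [(0, 1, 40), (0.4, 2, 60), (-0.2, 0.5, 30)]]
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [40, 60, 30]),
        })
        expected = pg.welch_anova(data=df, dv="y", between="g")["F"].iloc[0]
        assert welch_f(groups) == pytest.approx(expected, rel=1e-9)

    def test_omnibus_null_and_alternative(self, rng):
        null = welch_anova_bootstrap(
            rng.normal(size=150), np.repeat(["a", "b", "c"], 50),
            n_boot=300, seed=5)
        assert null["p"] > 0.01
        alt = welch_anova_bootstrap(
            np.concatenate([rng.normal(size=50), rng.normal(2, 1, 50)]),
            np.repeat(["a", "b"], 50), n_boot=300, seed=5)
        assert alt["p"] < 0.02

    def test_case_control_table_layout(self, rng):
        n = 120
        df = pd.DataFrame({
            "centile": rng.uniform(size=3 * n),
            "dx": np.tile(np.repeat(["CN", "A", "B"], n // 2), 2)[:3 * n],
            "sex": np.repeat(["F", "M"], 3 * n // 2),
        })
        res = case_control_tests(df, n_perm=199, seed=3)
        pair = res[res["group"] != "(omnibus)"]
        assert {"median_diff", "cohens_d", "p", "q"} <= set(pair.columns)
        assert set(pair["sex"]) == {"F", "M"}
        assert ((pair["q"] >= pair["p"] - 1e-12)).all()

    def test_min_permutations(self, rng):
        df = pd.DataFrame({"centile": rng.uniform(size=20),
                           "dx": ["CN"] * 10 + ["A"] * 10,
                           "sex": ["F"] * 20})
        with pytest.raises(ValueError, match="99"):
            case_control_tests(df, n_perm=50)


class TestLongitudinalIQR:
    def test_constant_centiles_zero(self):
        df = pd.DataFrame({"participant_id": ["s1"] * 3,
                           "centile": [0.5, 0.5, 0.5]})
        iqr, _ = longitudinal_iqr(df)
        assert iqr["s1"] == 0.0

    def test_hand_computed_linear_interpolation(self):
        df = pd.DataFrame({"participant_id": ["s1"] * 4,
                           "centile": [0.2, 0.4, 0.6, 0.8]})
        iqr, _ = longitudinal_iqr(df)
        assert iqr["s1"] == pytest.approx(0.3)

    def test_single_session_excluded(self):
        df = pd.DataFrame({"participant_id": ["a", "a", "b"],
                           "centile": [0.2, 0.4, 0.9]})
        iqr, n_excl = longitudinal_iqr(df)
        assert n_excl == 1 and list(iqr.index) == ["a"]

    def test_session_order_invariance(self, rng):
        vals = rng.uniform(size=6)
        a = pd.DataFrame({"participant_id": "s", "centile": vals})
        b = pd.DataFrame({"participant_id": "s",
                          "centile": rng.permutation(vals)})
        assert longitudinal_iqr(a)[0]["s"] == longitudinal_iqr(b)[0]["s"]

    def test_drifting_exceeds_stable(self, gmv_truth, fitted_chart):
        from normcharts.scoring import centile_score

        stable = simulate.make_longitudinal(
            gmv_truth, n_subjects=60, sessions=4, drift_per_year=0.0, seed=8)
        drift = simulate.make_longitudinal(
            gmv_truth, n_subjects=60, sessions=4, drift_per_year=0.05, seed=8)
        out = {}
        for name, tab in [("stable", stable), ("drift", drift)]:
            cent = centile_score(fitted_chart, tab, mode="population")
            tab2 = tab.assign(centile=cent["centile"].to_numpy())
            out[name] = longitudinal_iqr(tab2)[0].median()
        assert out["drift"] > out["stable"]


class TestTwinH2:
    def test_falconer_formula_exact(self, rng):
        mz = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], 400)
        dz = rng.multivariate_normal([0, 0], [[1, 0.4], [0.4, 1]], 400)
        res = twin_h2(mz, dz, B=50, seed=1)
        # h2 is exactly twice the difference of the measured correlations
        assert res["h2"] == pytest.approx(
            np.clip(2 * (res["r_mz"] - res["r_dz"]), 0, 1), abs=1e-12)
        assert res["h2"] == pytest.approx(0.8, abs=0.12)
        assert res["ci_low"] <= res["h2"] <= res["ci_high"]

    def test_equal_correlations_zero(self, rng):
        pairs = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], 300)
        res = twin_h2(pairs, pairs.copy(), B=20, seed=2)
        assert res["h2"] == 0.0

    def test_double_entry_correlation_oracle(self):
        pairs = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 3.0], [0.5, 1.5]])
        a = np.r_[pairs[:, 0], pairs[:, 1]]
        b = np.r_[pairs[:, 1], pairs[:, 0]]
        assert twin_correlation(pairs) == pytest.approx(
            np.corrcoef(a, b)[0, 1], abs=1e-14)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            twin_h2(np.ones((20, 2)), np.ones((20, 2)))
        with pytest.raises(ValueError, match="10 pairs"):
            twin_h2(np.random.default_rng(0).normal(size=(5, 2)),
                    np.random.default_rng(1).normal(size=(20, 2)))

    def test_ace_limits_in_generator(self, gmv_truth):
        tw = simulate.make_twins(gmv_truth, 800, ace=(1.0, 0.0, 0.0), seed=4)
        mz = tw[tw.zygosity == "MZ"][["centile_1", "centile_2"]].to_numpy()
        dz = tw[tw.zygosity == "DZ"][["centile_1", "centile_2"]].to_numpy()
        r_mz, r_dz = twin_correlation(mz), twin_correlation(dz)
        assert r_mz > 0.93
        assert r_dz == pytest.approx(0.5, abs=0.08)
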