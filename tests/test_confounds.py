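"""Statistical kernels for the confound screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import fcclassify as fc


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert fc.pearson_test(x, x)[0] == pytest.approx(1.0)
        assert fc.pearson_test(x, -x)[0] == pytest.approx(-1.0)

    def test_closed_form_example(self):
        # oracle: r = sum(dx dy)/sqrt(sum dx^2 sum dy^2) = 10/sqrt(148),
        # p from t = r sqrt((n-2)/(1-r^2)) on 3 df
        r, p = fc.pearson_test([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(10 / np.sqrt(148), abs=1e-12)
        assert p == pytest.approx(0.087707, abs=1e-5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fc.pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(0)
        ps = [fc.pearson_test(rng.normal(size=20), rng.normal(size=20))[1]
              for _ in range(2000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestTTest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        t, df, p = fc.independent_ttest(a, a.copy())
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_demographic_summary_row(self):
        # published-style age row: pooled t on (mean, sd, n) per group
        t, df, p = fc.independent_ttest(
            summary=((37.16, 12.197, 192), (35.65, 8.934, 173)))
        assert df == 363
        assert 0.17 <= p <= 0.19

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.01, size=10)
        b = rng.normal(1, 0.01, size=10)
        assert fc.independent_ttest(a, b)[2] < 1e-3

    def test_degenerate_equal_constant_groups(self):
        t, _, p = fc.independent_ttest(np.full(4, 2.0), np.full(5, 2.0))
        assert (t, p) == (0.0, 1.0)

    def test_welch_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(1, 3, size=20)
        t, _, p = fc.independent_ttest(a, b, variant="welch")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


def _bh_bruteforce(p):
    """Literal step-up definition: q_(i) = min_{j >= i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q[order[rank - 1]] = min(running, 1.0)
    return q


class TestBH:
    def test_single_p_unchanged(self):
        assert fc.bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_stepup_arithmetic_example(self):
        np.testing.assert_allclose(fc.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(fc.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_equals_bruteforce_stepup(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=rng.integers(1, 25))
        np.testing.assert_allclose(fc.bh_fdr(p), _bh_bruteforce(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fc.bh_fdr([0.5, 1.5])


class TestTwoProportion:
    def test_equal_proportions(self):
        z, p = fc.two_proportion_test(30, 100, 15, 50)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pooled_formula_example(self):
        z, p = fc.two_proportion_test(90, 100, 70, 100)
        assert z == pytest.approx(3.535534, abs=1e-5)
        assert p == pytest.approx(4.0695e-4, rel=1e-3)

    def test_antisymmetric_in_groups(self):
        z1, p1 = fc.two_proportion_test(80, 100, 60, 90)
        z2, p2 = fc.two_proportion_test(60, 90, 80, 100)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_z_squared_equals_uncorrected_chisquare(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(5, 60)), int(rng.integers(5, 60))
        x1, x2 = int(rng.integers(1, n1)), int(rng.integers(1, n2))
        if x1 == n1 and x2 == n2:
            x1 -= 1
        z, _ = fc.two_proportion_test(x1, n1, x2, n2)
        table = [[x1, n1 - x1], [x2, n2 - x2]]
        chi2 = stats.chi2_contingency(table, correction=False).statistic
        assert z ** 2 == pytest.approx(chi2, rel=1e-9)

    def test_degenerate_pooled_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            z, p = fc.two_proportion_test(0, 10, 0, 10)
        assert p == 1.0


class TestScreen:
    @staticmethod
    def _manifest(n_pat, n_ctl, rng):
        rows = []
        for i in range(n_pat + n_ctl):
            patient = i < n_pat
            rows.append({
                "subject_id": f"s{i}",
                "group": "patient" if patient else "control",
                "duration": rng.uniform(1, 20) if patient else np.nan,
                "ymrs": rng.uniform(0, 10) if patient else np.nan,
                "madrs": rng.uniform(0, 30) if patient else np.nan,
                "med_antipsychotic": bool(rng.random() < 0.5) if patient else np.nan,
                "med_antidepressant": bool(rng.random() < 0.4) if patient else np.nan,
                "med_mood_stabilizer": bool(rng.random() < 0.6) if patient else np.nan,
                "sex": "F" if rng.random() < 0.5 else "M",
                "mean_fd": rng.gamma(6.25, 0.0144),
            })
        return pd.DataFrame(rows)

    def test_null_panel_rarely_rejects(self):
        total = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            manifest = self._manifest(30, 30, rng)
            feats = pd.DataFrame(
                rng.normal(size=(60, 5)),
                columns=[f"e{k}" for k in range(5)],
                index=pd.Index(manifest["subject_id"], name="subject_id"))
            report = fc.confound_screen(feats, manifest)
            total += int((report.table["q"] < 0.05).sum())
        assert total <= 10  # at most ~1 false positive per panel on average

    def test_planted_fd_association_flagged(self):
        rng = np.random.default_rng(3)
        manifest = self._manifest(40, 40, rng)
        fd = manifest["mean_fd"].to_numpy()
        feats = pd.DataFrame({
            "e_fd": fd + rng.normal(0, 0.005, size=80),
            "e_noise": rng.normal(size=80),
        }, index=pd.Index(manifest["subject_id"], name="subject_id"))
        report = fc.confound_screen(feats, manifest)
        hit = report.table.query("feature == 'e_fd' and covariate == 'mean_fd'")
        assert float(hit["q"].iloc[0]) < 1e-3

    def test_empty_feature_set_gives_empty_report(self):
        rng = np.random.default_rng(0)
        manifest = self._manifest(5, 5, rng)
        feats = pd.DataFrame(index=pd.Index(manifest["subject_id"],
                                            name="subject_id"))
        report = fc.confound_screen(feats, manifest)
        assert len(report.table) == 0
        assert "p" in report.fd_group_test

    def test_fd_group_contrast_reported(self):
        rng = np.random.default_rng(1)
        manifest = self._manifest(30, 30, rng)
        feats = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"],
                             index=pd.Index(manifest["subject_id"],
                                            name="subject_id"))
        report = fc.confound_screen(feats, manifest)
        assert 0.0 <= report.fd_group_test["p"] <= 1.0
        assert report.fd_group_test["patient_mean"] > 0
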