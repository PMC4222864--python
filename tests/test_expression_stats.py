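import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from oracles import biweight_oracle

from retroprobe import expression_stats as es
from retroprobe import fixtures
from retroprobe.models import (
    BiweightParams,
    Chemistry,
    ExpressionMatrix,
    PlatformManifest,
    ProbeRecord,
    REAnnotationRow,
    Scale,
)

SEQ = "ACGTACGTACGTACGTACGTACGTA"


def _matrix(values, samples=None, factors=None):
    df = pd.DataFrame(values)
    if samples:
        df.columns = samples
    fdf = factors if factors is not None else pd.DataFrame(index=df.columns)
    return ExpressionMatrix(df, Scale.LOG2, fdf)


class TestTukeyBiweight:
    def test_constant_vector(self):
        assert es.tukey_biweight([5, 5, 5]) == 5.0

    def test_symmetric_vector_equals_median(self):
        assert es.tukey_biweight([1, 2, 3]) == pytest.approx(2.0)

    def test_outlier_downweighted_to_zero(self):
        # frozen from the straight-line formula oracle
        assert es.tukey_biweight([10, 10.2, 9.8, 10.1, 50]) == pytest.approx(
            10.062209173591306, abs=1e-12)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            n = int(rng.integers(1, 20))
            x = rng.normal(8, 2, size=n)
            assert es.tukey_biweight(x) == pytest.approx(biweight_oracle(x), abs=1e-12)

    def test_point_beyond_cutoff_has_zero_influence(self, rng):
        x = np.array([10.0, 10.2, 9.8, 10.1, 50.0])
        moved = x.copy()
        moved[-1] = 500.0  # still |u| >= 1 -> weight exactly 0
        assert es.tukey_biweight(x) == es.tukey_biweight(moved)

    def test_equals_mean_for_tight_data(self, rng):
        x = 100 + rng.normal(scale=1e-6, size=9)
        assert es.tukey_biweight(x) == pytest.approx(x.mean(), rel=1e-9)

    def test_single_value_returned(self):
        assert es.tukey_biweight([7.5]) == 7.5

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            es.tukey_biweight([])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=30))
    def test_estimate_bounded_by_data_range(self, xs):
        t = es.tukey_biweight(xs)
        assert min(xs) - 1e-9 <= t <= max(xs) + 1e-9


class TestQuantileNormalize:
    def test_two_array_oracle_example(self):
        m = _matrix({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = es.quantile_normalize(m).values
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_sorted_vectors_identical_after(self, rng):
        m = _matrix({f"s{j}": rng.normal(8, 2, 50) for j in range(4)})
        out = es.quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_within_array_ranks_preserved(self, rng):
        m = _matrix({f"s{j}": rng.normal(8, 2, 50) for j in range(3)})
        out = es.quantile_normalize(m).values.to_numpy()
        X = m.values.to_numpy()
        for j in range(3):
            assert (np.argsort(X[:, j], kind="stable")
                    == np.argsort(out[:, j], kind="stable")).all()

    def test_idempotent(self, rng):
        m = _matrix({f"s{j}": rng.normal(8, 2, 30) for j in range(3)})
        once = es.quantile_normalize(m)
        twice = es.quantile_normalize(once)
        np.testing.assert_allclose(once.values.to_numpy(), twice.values.to_numpy())

    def test_single_array_unchanged(self):
        m = _matrix({"a": [3.0, 1.0, 2.0]})
        np.testing.assert_allclose(es.quantile_normalize(m).values["a"], [3, 1, 2])

    def test_already_identical_arrays_unchanged(self):
        m = _matrix({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        np.testing.assert_allclose(es.quantile_normalize(m).values.to_numpy(),
                                   m.values.to_numpy())

    def test_ties_receive_mean_of_spanned_quantiles(self):
        m = _matrix({"a": [1.0, 1.0, 5.0], "b": [2.0, 4.0, 6.0]})
        out = es.quantile_normalize(m).values
        mean_sorted = np.sort(m.values.to_numpy(), axis=0).mean(axis=1)
        expected_tie = mean_sorted[:2].mean()
        assert out["a"].tolist()[:2] == [expected_tie, expected_tie]


class TestBackgroundCorrection:
    def test_output_positive_and_order_preserving(self, rng):
        obs, _ = fixtures.generate_convolution_array(2000, rng=rng)
        m = ExpressionMatrix(pd.DataFrame({"s": obs}), Scale.LINEAR,
                             pd.DataFrame(index=["s"]))
        corr = es.background_correct(m).values["s"].to_numpy()
        assert (corr > 0).all()
        order = np.argsort(obs, kind="stable")
        assert (np.diff(corr[order]) >= -1e-9).all()

    def test_recovers_signal_better_than_raw(self, rng):
        obs, signal = fixtures.generate_convolution_array(5000, rng=rng)
        m = ExpressionMatrix(pd.DataFrame({"s": obs}), Scale.LINEAR,
                             pd.DataFrame(index=["s"]))
        corr = es.background_correct(m).values["s"].to_numpy()
        assert np.mean(np.abs(corr - signal)) < np.mean(np.abs(obs - signal))

    def test_additive_noise_is_shrunk_out(self, rng):
        """With a constant signal plus Gaussian noise, correction removes the
        noise offset and contracts the noise spread."""
        obs = 400.0 + rng.normal(100, 15, size=3000)
        m = ExpressionMatrix(pd.DataFrame({"s": obs}), Scale.LINEAR,
                             pd.DataFrame(index=["s"]))
        corr = es.background_correct(m).values["s"].to_numpy()
        assert (corr < obs).all()
        assert corr.std() <= obs.std()

    def test_zero_variance_array_rejected(self):
        m = ExpressionMatrix(pd.DataFrame({"s": [5.0] * 10}), Scale.LINEAR,
                             pd.DataFrame(index=["s"]))
        with pytest.raises(ValueError, match="no-bgcorrect"):
            es.background_correct(m)

    def test_log2_matrix_rejected(self):
        m = _matrix({"s": [1.0, 2.0]})
        with pytest.raises(ValueError, match="linear"):
            es.background_correct(m)


class TestSummarizeProbeset:
    def _manifest(self, composition):
        probes = [ProbeRecord(f"{ps}_p{i}", ps, SEQ)
                  for ps, n in composition.items() for i in range(n)]
        return PlatformManifest("t", Chemistry.ANTISENSE_CRNA, probes)

    def test_singleton_probeset_identical_to_probe(self, rng):
        manifest = self._manifest({"ps1": 1})
        m = _matrix({"s1": [4.2], "s2": [5.1]})
        m.values.index = ["ps1_p0"]
        out = es.summarize_probeset(m, manifest)
        np.testing.assert_allclose(out.loc["ps1"], [4.2, 5.1])

    def test_identical_probes_identical_value(self):
        manifest = self._manifest({"ps1": 3})
        m = _matrix({"s1": [7.0, 7.0, 7.0]})
        m.values.index = [f"ps1_p{i}" for i in range(3)]
        assert es.summarize_probeset(m, manifest).loc["ps1", "s1"] == 7.0

    def test_outlier_probe_ignored(self, rng):
        manifest = self._manifest({"ps1": 6})
        clean = rng.normal(8, 0.05, size=5)
        vals = np.append(clean, 14.0)
        m = _matrix({"s1": vals})
        m.values.index = [f"ps1_p{i}" for i in range(6)]
        out = es.summarize_probeset(m, manifest).loc["ps1", "s1"]
        assert out == pytest.approx(clean.mean(), abs=0.05)

    def test_probeset_missing_from_matrix_warns_and_omits(self):
        manifest = self._manifest({"ps1": 1, "ps2": 1})
        m = _matrix({"s1": [4.2]})
        m.values.index = ["ps1_p0"]
        with pytest.warns(UserWarning, match="ps2"):
            out = es.summarize_probeset(m, manifest)
        assert list(out.index) == ["ps1"]


class TestAnovaSelect:
    def test_matches_statsmodels_sequential_anova(self, rng):
        """Cross-check F and p against statsmodels anova_lm (type I SS)."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf
        m = fixtures.generate_anova_matrix(
            5, 3, 3, effect=1.0, batch_offsets={"e1": 0.0, "e2": 1.5}, rng=rng)
        results = es.anova_select(m, "tissue", ["experiment"], alpha=0.01)
        for r in results:
            df = m.sample_factors.copy()
            df["y"] = m.values.loc[r.probe_id]
            fit = smf.ols("y ~ C(experiment) + C(tissue)", data=df).fit()
            tab = sm.stats.anova_lm(fit, typ=1)
            assert r.f_statistic == pytest.approx(tab.loc["C(tissue)", "F"], rel=1e-8)
            assert r.p_value == pytest.approx(tab.loc["C(tissue)", "PR(>F)"], rel=1e-8)

    def test_null_type_one_error_near_alpha(self):
        m = fixtures.generate_anova_matrix(1000, 3, 3, effect=0.0,
                                           rng=np.random.default_rng(7))
        frac = np.mean([r.retained for r in es.anova_select(m, "tissue", [], 0.01)])
        band = 1.96 * np.sqrt(0.01 * 0.99 / 1000)
        assert abs(frac - 0.01) <= band

    def test_batch_elimination_restores_power(self):
        rng = np.random.default_rng(11)
        m = fixtures.generate_anova_matrix(
            200, 3, 3, effect=3.0, batch_offsets={"e1": 0.0, "e2": 5.0}, rng=rng)
        kept_blocked = np.mean([r.retained for r in
                                es.anova_select(m, "tissue", ["experiment"], 0.01)])
        kept_raw = np.mean([r.retained for r in es.anova_select(m, "tissue", [], 0.01)])
        assert kept_blocked > 0.95
        assert kept_blocked > kept_raw

    def test_confounded_design_rejected(self, rng):
        m = fixtures.generate_anova_matrix(3, 3, 3, rng=rng)
        m.sample_factors["copy"] = m.sample_factors["tissue"]
        with pytest.raises(ValueError, match="aliased"):
            es.anova_select(m, "tissue", ["copy"], 0.01)

    def test_single_level_factor_rejected(self, rng):
        m = fixtures.generate_anova_matrix(3, 3, 3, rng=rng)
        m.sample_factors["const"] = "x"
        with pytest.raises(ValueError, match="levels"):
            es.anova_select(m, "const", [], 0.01)

    def test_fdr_flag_never_keeps_more(self, rng):
        m = fixtures.generate_anova_matrix(300, 3, 3, effect=1.0, rng=rng)
        raw = sum(r.retained for r in es.anova_select(m, "tissue", [], 0.05))
        fdr = sum(r.retained for r in es.anova_select(m, "tissue", [], 0.05, fdr=True))
        assert fdr <= raw


class TestConcordance:
    def _setup(self, rng, discordant=False):
        tissues = ["heart", "liver", "spleen"]
        samples, factors = [], []
        for t in tissues:
            for i in range(4):
                samples.append(f"{t}_{i}")
                factors.append({"tissue": t})
        fdf = pd.DataFrame(factors, index=samples)
        base = 8 + rng.normal(scale=0.1, size=len(samples))
        eff = np.array([2.0 if t.startswith("heart") else 0.0 for t in samples])
        rows = {}
        for i in range(4):
            rows[f"ps_p{i}"] = base + eff + rng.normal(scale=0.05, size=len(samples))
        if discordant:
            rows["ps_re"] = base - eff + rng.normal(scale=0.05, size=len(samples))
        else:
            rows["ps_re"] = rows["ps_p0"].copy()  # duplicated member probe
        df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
        m = ExpressionMatrix(df, Scale.LOG2, fdf)
        probes = [ProbeRecord(p, "ps", SEQ) for p in rows]
        manifest = PlatformManifest("t", Chemistry.ANTISENSE_CRNA, probes)
        re_rows = [REAnnotationRow(pid="ps_re", probeset="ps", plen=25, numhits=1,
                                   sid="chr1", sstart=100, send=125, nident=25,
                                   repeat="RLTR1A", repclass="LTR/ERV1",
                                   rstart=50, rend=450)]
        return m, manifest, re_rows

    def test_duplicated_probe_is_concordant(self, rng):
        m, manifest, re_rows = self._setup(rng, discordant=False)
        out = es.probe_vs_probeset_concordance(m, manifest, re_rows, "tissue")
        assert out.iloc[0]["concordant"]

    def test_opposite_tissue_effect_is_discordant(self, rng):
        m, manifest, re_rows = self._setup(rng, discordant=True)
        out = es.probe_vs_probeset_concordance(m, manifest, re_rows, "tissue")
        assert not out.iloc[0]["concordant"]

    def test_fraction_concordant_reported(self, rng):
        m, manifest, re_rows = self._setup(rng)
        out = es.probe_vs_probeset_concordance(m, manifest, re_rows, "tissue")
        assert out.attrs["fraction_concordant"] == 1.0

    def test_probeset_with_too_few_members_skipped(self, rng):
        m, manifest, re_rows = self._setup(rng)
        small = PlatformManifest("t", Chemistry.ANTISENSE_CRNA, [
            ProbeRecord("ps_re", "ps", SEQ), ProbeRecord("ps_p0", "ps", SEQ)])
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = es.probe_vs_probeset_concordance(m, small, re_rows, "tissue")
        assert out.empty


class TestNearestGeneRegression:
    def test_perfectly_coregulated_pair(self):
        re_m, gs, rows, fac = fixtures.generate_regression_fixture(
            0.5, 10, 6, np.random.default_rng(3))
        re_m = gs.copy()
        re_m.index = [f"RE{i + 1}" for i in range(10)]
        out = es.nearest_gene_regression(re_m, gs, rows, fac, "tissue", "heart")
        assert out.loc["all", "r2"] == pytest.approx(1.0)
        assert out.loc["all", "slope"] == pytest.approx(1.0)

    def test_independent_values_give_near_zero_r2(self):
        re_m, gs, rows, fac = fixtures.generate_regression_fixture(
            0.0, 100, 5, np.random.default_rng(5))
        out = es.nearest_gene_regression(re_m, gs, rows, fac, "tissue", "heart")
        assert out.loc["all", "r2"] < 0.02

    def test_absent_gene_points_omitted_and_counted(self):
        re_m, gs, rows, fac = fixtures.generate_regression_fixture(
            0.3, 10, 5, np.random.default_rng(5))
        gs_missing = gs.drop(index=["G1", "G2"])
        out = es.nearest_gene_regression(re_m, gs_missing, rows, fac, "tissue", "heart")
        assert out.attrs["omitted_points"] == 2
        assert out.loc["all", "n_points"] == 40

    def test_nearer_gene_prefers_five_prime_on_tie(self):
        row = REAnnotationRow(
            pid="re", probeset="ps", plen=25, numhits=1,
            sid="chr1", sstart=5000, send=5025, nident=25,
            repeat="r", repclass="LTR/ERV1", rstart=4900, rend=5300,
            five_id="L", five_start=1000, five_stop=4000,
            three_id="R", three_start=6025, three_stop=8000,
        )
        assert es._nearer_gene(row) == "L"  # both gaps are 1000

    def test_classwise_fits_reported(self):
        re_m, gs, rows, fac = fixtures.generate_regression_fixture(
            0.3, 30, 5, np.random.default_rng(5), repclass="SINE/B2")
        out = es.nearest_gene_regression(re_m, gs, rows, fac, "tissue", "heart")
        assert "SINE" in out.index and out.loc["SINE", "n_points"] == 150


class TestHierarchicalCluster:
    def test_duplicated_groups_split_into_two_clusters(self, rng):
        sig_a = rng.normal(size=30)
        sig_b = rng.normal(size=30)
        df = pd.DataFrame({
            "a1": sig_a, "a2": sig_a + rng.normal(scale=0.01, size=30),
            "b1": sig_b, "b2": sig_b + rng.normal(scale=0.01, size=30),
        }).T
        order, Z = es.hierarchical_cluster(df, axis="rows")
        from scipy.cluster.hierarchy import fcluster
        labels = dict(zip(sorted(df.index), fcluster(Z, 2, criterion="maxclust")))
        assert labels["a1"] == labels["a2"] != labels["b1"]
        assert labels["b1"] == labels["b2"]

    def test_planted_tissue_signatures_group_samples_by_tissue(self, rng):
        tissues = ["heart", "liver", "spleen"]
        samples = [f"{t}_r{i}" for t in tissues for i in range(4)]
        X = rng.normal(8, 0.3, size=(30, len(samples)))
        for k, t in enumerate(tissues):  # ten signature probes per tissue
            for j, s in enumerate(samples):
                if s.startswith(t):
                    X[10 * k:10 * (k + 1), j] += 3.0
        df = pd.DataFrame(X, index=[f"p{i}" for i in range(30)], columns=samples)
        order, Z = es.hierarchical_cluster(df, axis="columns")
        from scipy.cluster.hierarchy import fcluster
        labels = dict(zip(sorted(samples), fcluster(Z, 3, criterion="maxclust")))
        for s1 in labels:
            for s2 in labels:
                same_tissue = s1.split("_")[0] == s2.split("_")[0]
                assert (labels[s1] == labels[s2]) == same_tissue

    def test_column_permutation_invariance(self, rng):
        df = pd.DataFrame(rng.normal(size=(8, 12)),
                          index=[f"r{i}" for i in range(8)])
        order1, _ = es.hierarchical_cluster(df, axis="rows")
        perm = df[rng.permutation(df.columns)]
        order2, _ = es.hierarchical_cluster(perm, axis="rows")
        assert order1 == order2

    def test_constant_row_warns(self, rng):
        df = pd.DataFrame(rng.normal(size=(4, 10)))
        df.iloc[0] = 3.0
        with pytest.warns(UserWarning, match="constant"):
            es.hierarchical_cluster(df, axis="rows")
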