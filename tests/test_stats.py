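import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, nbinom

from exosmallrna import stats


GROUPS4 = {"c1": "cell", "c2": "cell", "e1": "exosome", "e2": "exosome"}


class TestFilterFeatures:
    def frame(self, cell, exo):
        return pd.DataFrame({"c1": [cell], "c2": [0], "e1": [exo], "e2": [0]})

    @pytest.mark.parametrize(
        "cell,exo,kept",
        [(15, 0, True), (14, 4, False), (0, 5, True), (14, 5, True), (15, 5, True)],
    )
    def test_or_rule_boundaries(self, cell, exo, kept):
        out = stats.filter_features(self.frame(cell, exo), GROUPS4)
        assert (len(out) == 1) is kept

    def test_missing_labels_error(self):
        with pytest.raises(ValueError):
            stats.filter_features(self.frame(20, 0), {"c1": "cell"})


class TestTMM:
    def test_identical_columns(self):
        m = pd.DataFrame({"a": [10, 20, 30, 5], "b": [10, 20, 30, 5]})
        assert np.allclose(stats.tmm_factors(m), [1.0, 1.0])

    def test_pure_depth_difference_absorbed(self, rng):
        a = rng.poisson(50, 300)
        m = pd.DataFrame({"a": a, "b": a * 2})
        f = stats.tmm_factors(m)
        assert np.allclose(f, [1.0, 1.0], atol=0.01)

    def test_geometric_mean_one(self, rng):
        m = pd.DataFrame(rng.poisson(40, size=(200, 4)), columns=list("abcd"))
        f = stats.tmm_factors(m)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_reference_implementation(self, rng, tmp_path):
        """Factors agree within 2% with the published TMM algorithm run
        independently (edgeR::calcNormFactors) on an asymmetric simulation."""
        mu = rng.gamma(2, 25, 200)
        up = mu.copy()
        up[:10] *= 8  # 5% of features 8-fold up in sample b
        m = pd.DataFrame({
            "a": rng.poisson(mu), "b": rng.poisson(up),
            "c": rng.poisson(mu), "d": rng.poisson(mu),
        })
        counts_path = tmp_path / "counts.tsv"
        m.to_csv(counts_path, sep="\t")
        script = tmp_path / "tmm.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(edgeR))
            x <- as.matrix(read.delim('{counts_path}', row.names=1))
            cat(calcNormFactors(x, method='TMM'), sep='\\n')
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        reference = np.array([float(v) for v in out.stdout.split()])
        mine = stats.tmm_factors(m).to_numpy()
        assert np.allclose(mine, reference, rtol=0.02)


class TestLogImpute:
    def test_hand_example(self):
        m = pd.DataFrame({"s": [0.0, 4.0, 8.0]})
        norm = stats.log_impute(m)
        # min nonzero 4 -> floor 2
        assert np.allclose(norm.log_values["s"], np.log([2.0, 4.0, 8.0]))
        assert norm.imputed["s"].tolist() == [True, False, False]
        assert norm.floors["s"] == 2.0

    def test_no_zeros_plain_log(self):
        m = pd.DataFrame({"s": [1.0, 10.0]})
        assert np.allclose(stats.log_impute(m).log_values["s"], np.log([1.0, 10.0]))

    def test_per_sample_floors_independent(self):
        m = pd.DataFrame({"a": [0.0, 4.0, 8.0], "b": [10.0, 0.0, 40.0]})
        norm = stats.log_impute(m)
        assert norm.log_values.loc[0, "a"] == pytest.approx(np.log(2.0))
        assert norm.log_values.loc[1, "b"] == pytest.approx(np.log(5.0))

    def test_all_zero_sample_errors(self):
        with pytest.raises(ValueError):
            stats.log_impute(pd.DataFrame({"s": [0.0, 0.0]}))


class TestCorrelation:
    def test_duplicate_columns_r1(self):
        m = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        assert stats.correlation_matrix(m).loc["a", "b"] == pytest.approx(1.0)

    def test_negated_column(self):
        a = np.array([1.0, 2, 3, 4])
        m = pd.DataFrame({"a": a, "b": -a})
        assert stats.correlation_matrix(m).loc["a", "b"] == pytest.approx(-1.0)

    def test_four_point_hand_example(self):
        x = np.array([1.0, 2, 3, 5])
        y = np.array([2.0, 1, 4, 6])
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        r = stats.correlation_matrix(pd.DataFrame({"x": x, "y": y}))
        assert r.loc["x", "y"] == pytest.approx(expected)
        assert r.loc["x", "x"] == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        m = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        transformed = m * pd.Series({"a": 2.0, "b": 0.5, "c": 7.0}) + 3.0
        assert np.allclose(stats.correlation_matrix(m), stats.correlation_matrix(transformed))

    def test_zero_variance_gives_nan(self):
        m = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        assert np.isnan(stats.correlation_matrix(m).loc["a", "b"])


class TestCluster:
    def test_identical_samples_merge_at_zero(self, rng):
        base = rng.normal(size=20)
        m = pd.DataFrame({"a": base, "b": base, "c": rng.normal(size=20)})
        result = stats.cluster(m)
        assert result.sample_linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_correlated_pair_merges_first(self, rng):
        base = rng.normal(size=50)
        m = pd.DataFrame({
            "a": base + rng.normal(0, 0.01, 50),
            "b": base + rng.normal(0, 0.01, 50),
            "c": rng.normal(size=50),
        })
        result = stats.cluster(m)
        first = sorted(result.sample_linkage[0, :2].astype(int))
        labels = [result.sample_labels[i] for i in first]
        assert labels == ["a", "b"]

    def test_tissue_pure_subtrees(self, rng):
        """Six exosome samples, three per tissue, with a tissue effect large
        enough that each tissue forms its own subtree."""
        n = 80
        base = rng.normal(5, 1, n)
        effect = np.zeros(n)
        effect[:20] = 3.0
        cols = {}
        for i in range(3):
            cols[f"ASC{i}"] = base + effect + rng.normal(0, 0.3, n)
        for i in range(3):
            cols[f"BMSC{i}"] = base - effect + rng.normal(0, 0.3, n)
        result = stats.cluster(pd.DataFrame(cols))
        # leaf sets of the two children of the root, from the linkage matrix
        link = result.sample_linkage
        n = len(result.sample_labels)

        def leaves(node):
            if node < n:
                return {result.sample_labels[node]}
            left, right = link[node - n, 0], link[node - n, 1]
            return leaves(int(left)) | leaves(int(right))

        sides = [leaves(int(link[-1, 0])), leaves(int(link[-1, 1]))]
        assert {"ASC0", "ASC1", "ASC2"} in sides
        assert {"BMSC0", "BMSC1", "BMSC2"} in sides

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            stats.cluster(pd.DataFrame({"a": [1.0]}))


class TestCommonDispersion:
    def test_poisson_counts_near_zero(self, rng):
        mu = rng.gamma(2, 40, 2000)
        counts = pd.DataFrame({s: rng.poisson(mu) for s in GROUPS4})
        phi = stats.estimate_common_dispersion(counts, GROUPS4)
        assert phi < 0.01

    def test_recovers_true_dispersion(self, rng):
        phi_true = 0.2
        r = 1 / phi_true
        mu = rng.gamma(2, 40, 2000)
        counts = pd.DataFrame(
            {s: rng.negative_binomial(r, r / (r + mu)) for s in GROUPS4}
        )
        phi = stats.estimate_common_dispersion(counts, GROUPS4)
        assert 0.15 <= phi <= 0.25

    def test_single_feature_no_crash(self):
        counts = pd.DataFrame({"c1": [5], "c2": [5], "e1": [5], "e2": [5]})
        phi = stats.estimate_common_dispersion(counts, GROUPS4)
        assert np.isfinite(phi) and phi >= 0

    def test_no_replication_warns_zero(self):
        counts = pd.DataFrame({"c1": [5, 8], "e1": [5, 9]})
        phi = stats.estimate_common_dispersion(counts, {"c1": "cell", "e1": "exosome"})
        assert phi == 0.0


def enumerate_exact_pvalue(a, b, phi):
    """Brute-force doubletail p-value for a 1-vs-1 comparison."""
    t = a + b
    if phi == 0:
        probs = np.array([binom_pmf(x, t) for x in range(t + 1)])
    else:
        r = 1 / phi
        mu = t / 2

        def pmf(x):
            return nbinom.pmf(x, r, r / (r + mu)) * nbinom.pmf(t - x, r, r / (r + mu))

        probs = np.array([pmf(x) for x in range(t + 1)])
    obs = probs[a]
    return min(1.0, probs[probs <= obs * (1 + 1e-10)].sum() / probs.sum())


def binom_pmf(x, t):
    from scipy.stats import binom as _b

    return _b.pmf(x, t, 0.5)


class TestExactTest:
    GROUPS2 = {"a": "g1", "b": "g2"}

    def counts(self, a, b):
        return pd.DataFrame({"a": a, "b": b})

    def test_identical_totals_p_one(self):
        res = stats.exact_test_nb(self.counts([10], [10]), self.GROUPS2, 0.1)
        assert res.p_value.iloc[0] == pytest.approx(1.0)
        assert res.logFC.iloc[0] == pytest.approx(0.0)

    def test_phi_zero_equals_binomial(self):
        # equal library sizes: (9,1) in one feature, (1,9) in the other
        counts = self.counts([9, 1], [1, 9])
        res = stats.exact_test_nb(counts, self.GROUPS2, 0.0)
        expected = binomtest(9, 10, 0.5).pvalue
        assert res.p_value.iloc[0] == pytest.approx(expected, rel=1e-9)
        assert res.p_value.iloc[1] == pytest.approx(expected, rel=1e-9)

    def test_small_totals_match_enumeration(self):
        cases = [(a, b) for a in range(0, 16) for b in range(0, 16) if 0 < a + b <= 30]
        counts = self.counts([a for a, _ in cases], [b for _, b in cases])
        # pad to equalize library sizes so pseudo-counts stay integral
        total_a = counts["a"].sum()
        total_b = counts["b"].sum()
        pad = max(total_a, total_b)
        counts.loc[len(counts)] = [pad - total_a + 10, pad - total_b + 10]
        res = stats.exact_test_nb(counts, self.GROUPS2, 0.5)
        for i, (a, b) in enumerate(cases):
            assert res.p_value.iloc[i] == pytest.approx(
                enumerate_exact_pvalue(a, b, 0.5), rel=1e-9
            ), (a, b)

    def test_type_i_error_null_simulation(self, rng):
        """At most 6% of null features rejected at alpha = 0.05."""
        phi = 0.1
        r = 1 / phi
        mu = rng.gamma(2, 30, 5000)
        counts = pd.DataFrame(
            {s: rng.negative_binomial(r, r / (r + mu)) for s in GROUPS4}
        )
        res = stats.exact_test_nb(counts, GROUPS4, phi)
        assert (res.p_value < 0.05).mean() <= 0.06

    def test_negative_phi_errors(self):
        with pytest.raises(ValueError):
            stats.exact_test_nb(self.counts([1], [1]), self.GROUPS2, -0.1)


class TestBhFdr:
    def hand_bh(self, p):
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        prev = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            rank = m - rank_from_end
            prev = min(prev, p[idx] * m / rank)
            adj[idx] = prev
        return adj

    def test_textbook_step_up(self):
        assert np.allclose(stats.bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p(self):
        assert stats.bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_hand_implementation(self, rng):
        p = rng.uniform(size=200)
        assert np.allclose(stats.bh_fdr(p), self.hand_bh(p))

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            stats.bh_fdr([1.5])
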