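import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

from enviroscore.validation_stats import (
    contingency,
    correlation_matrix,
    distribution_summary,
    weighted_kappa,
    weighted_kappa_from_table,
)

GRADES = list("ABCDE")


# --- independent brute-force kappa oracle (plain loops over the table) ----

def kappa_oracle(labels_a, labels_b, scheme, categories=GRADES):
    k = len(categories)
    idx = {c: i for i, c in enumerate(categories)}
    n = len(labels_a)
    counts = [[0] * k for _ in range(k)]
    for x, y in zip(labels_a, labels_b):
        counts[idx[x]][idx[y]] += 1
    row = [sum(counts[i]) / n for i in range(k)]
    col = [sum(counts[i][j] for i in range(k)) / n for j in range(k)]

    def w(i, j):
        if scheme == "linear":
            return abs(i - j) / (k - 1)
        if scheme == "quadratic":
            return ((i - j) / (k - 1)) ** 2
        return 0.0 if i == j else 1.0

    num = sum(w(i, j) * counts[i][j] / n for i in range(k) for j in range(k))
    den = sum(w(i, j) * row[i] * col[j] for i in range(k) for j in range(k))
    return 1.0 - num / den


class TestDistributionSummary:
    def test_small_examples(self):
        out = distribution_summary({"g": [1, 2, 3, 4, 5], "one": [7.0]})
        by_name = {s.group: s for s in out}
        assert by_name["g"].median == 3 and by_name["g"].iqr == 2
        assert by_name["one"].median == 7 and by_name["one"].iqr == 0

    def test_sorted_by_descending_median(self):
        out = distribution_summary({"lo": [1, 2], "hi": [10, 20], "mid": [5]})
        assert [s.group for s in out] == ["hi", "mid", "lo"]

    def test_matches_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(0, 1, size=20)
        (s,) = distribution_summary({"g": vals})

        def quantile(sorted_v, q):
            # linear interpolation between order statistics
            h = (len(sorted_v) - 1) * q
            lo = int(np.floor(h))
            hi = min(lo + 1, len(sorted_v) - 1)
            return sorted_v[lo] + (h - lo) * (sorted_v[hi] - sorted_v[lo])

        sv = sorted(vals)
        assert s.median == pytest.approx(quantile(sv, 0.5), rel=1e-12)
        assert s.iqr == pytest.approx(quantile(sv, 0.75) - quantile(sv, 0.25), rel=1e-12)

    def test_empty_group_named(self):
        with pytest.raises(ValueError, match="bad"):
            distribution_summary({"bad": []})


class TestContingency:
    def test_perfect_agreement_is_diagonal(self):
        labels = ["A", "B", "C", "D", "E", "A"]
        tab = contingency(labels, labels)
        assert tab.n == 6
        assert np.trace(tab.counts) == 6

    def test_small_enumeration(self):
        tab = contingency(["A", "A", "B"], ["A", "B", "B"], categories=["A", "B"])
        assert tab.counts.tolist() == [[1, 1], [0, 1]]

    def test_row_percent_sums_to_100(self):
        rng = np.random.default_rng(0)
        a = rng.choice(GRADES, 40).tolist()
        b = rng.choice(GRADES, 40).tolist()
        tab = contingency(a, b)
        sums = tab.row_percent.sum(axis=1)
        nonempty = tab.counts.sum(axis=1) > 0
        assert np.allclose(sums[nonempty], 100.0)

    def test_length_mismatch_and_unknown_label(self):
        with pytest.raises(ValueError, match="length"):
            contingency(["A"], ["A", "B"])
        with pytest.raises(ValueError, match="'Z'"):
            contingency(["Z"], ["A"])


class TestWeightedKappa:
    def test_identical_sequences_score_one(self):
        a = ["A", "C", "E", "B", "B", "D"]
        res = weighted_kappa(a, a)
        assert res.kappa == pytest.approx(1.0)
        assert res.n == 6

    def test_uniform_two_by_two_table_is_chance(self):
        # counts [[1,1],[1,1]]: observed agreement equals chance agreement
        kappa = weighted_kappa_from_table(np.array([[1, 1], [1, 1]]), scheme="linear")
        assert kappa == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("scheme", ["linear", "quadratic", "unweighted"])
    def test_matches_bruteforce_formula_oracle(self, scheme):
        a = ["A", "B", "B", "C", "E", "D", "A", "C", "E", "B"]
        b = ["A", "C", "B", "C", "D", "D", "B", "C", "E", "A"]
        res = weighted_kappa(a, b, scheme=scheme)
        assert res.kappa == pytest.approx(kappa_oracle(a, b, scheme), rel=1e-12)

    @pytest.mark.parametrize("scheme,sk_weights", [("linear", "linear"), ("quadratic", "quadratic")])
    def test_cross_checked_against_sklearn(self, scheme, sk_weights):
        rng = np.random.default_rng(12)
        a = rng.choice(GRADES, 60).tolist()
        b = [x if rng.random() < 0.6 else rng.choice(GRADES) for x in a]
        ours = weighted_kappa(a, b, scheme=scheme).kappa
        theirs = cohen_kappa_score(a, b, labels=GRADES, weights=sk_weights)
        assert ours == pytest.approx(theirs, rel=1e-10)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        a = rng.choice(GRADES, 30).tolist()
        b = rng.choice(GRADES, 30).tolist()
        assert weighted_kappa(a, b).kappa == pytest.approx(weighted_kappa(b, a).kappa)

    def test_unweighted_equals_linear_on_two_categories(self):
        rng = np.random.default_rng(9)
        a = rng.choice(["A", "B"], 25).tolist()
        b = rng.choice(["A", "B"], 25).tolist()
        lin = weighted_kappa(a, b, scheme="linear", categories=["A", "B"]).kappa
        unw = weighted_kappa(a, b, scheme="unweighted", categories=["A", "B"]).kappa
        assert lin == pytest.approx(unw)

    def test_table_route_equals_sequence_route(self):
        rng = np.random.default_rng(21)
        a = rng.choice(GRADES, 50).tolist()
        b = rng.choice(GRADES, 50).tolist()
        tab = contingency(a, b)
        assert weighted_kappa_from_table(tab.counts) == pytest.approx(
            weighted_kappa(a, b).kappa
        )

    def test_p_values_agree_between_methods(self):
        rng = np.random.default_rng(7)
        a = rng.choice(GRADES, 40).tolist()
        b = [x if rng.random() < 0.7 else rng.choice(GRADES) for x in a]
        asym = weighted_kappa(a, b, p_value=True).p_value
        perm = weighted_kappa(
            a, b, p_value=True, p_value_method="permutation",
            n_permutations=2000, rng=np.random.default_rng(0),
        ).p_value
        assert 0 < asym <= 1 and 0 < perm <= 1
        # both should call this strong agreement significant
        assert asym < 0.01 and perm < 0.01

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            weighted_kappa(["A"], ["A", "B"])
        with pytest.raises(ValueError, match="scheme"):
            weighted_kappa(["A", "B"], ["A", "B"], scheme="cubic")


class TestCorrelationMatrix:
    def test_exact_linear_relations(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "y": 2 * x + 1, "z": -x})
        mat = correlation_matrix(df, "pearson")
        frame = mat.to_frame()
        assert frame.loc["x", "y"] == pytest.approx(1.0)
        assert frame.loc["x", "z"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(mat.values), 1.0)
        assert np.allclose(mat.values, mat.values.T)

    @pytest.mark.parametrize("method", ["pearson", "spearman"])
    def test_matches_scipy_oracle(self, method):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("abcd"))
        mat = correlation_matrix(df, method).to_frame()
        fn = sps.pearsonr if method == "pearson" else sps.spearmanr
        for u in "abcd":
            for v in "abcd":
                expected = fn(df[u], df[v])[0] if u != v else 1.0
                assert mat.loc[u, v] == pytest.approx(expected, rel=1e-10)

    def test_invariance_under_transformations(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(size=12), "y": rng.normal(size=12)})
        base_p = correlation_matrix(df, "pearson").to_frame().loc["x", "y"]
        affine = df.assign(x=3.0 * df["x"] + 7.0)
        assert correlation_matrix(affine, "pearson").to_frame().loc["x", "y"] == pytest.approx(base_p)
        base_s = correlation_matrix(df, "spearman").to_frame().loc["x", "y"]
        warped = df.assign(x=np.exp(df["x"]))  # strictly monotone
        assert correlation_matrix(warped, "spearman").to_frame().loc["x", "y"] == pytest.approx(base_s)

    def test_constant_variable_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            correlation_matrix(df)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="3 rows"):
            correlation_matrix(pd.DataFrame({"x": [1.0, 2.0], "y": [3.0, 4.0]}))
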