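"""Paired statistics, clustering, and block segmentation (vs brute force)."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gamma as gamma_fn

from sheetflow.phenotype import (
    ZeroVarianceError,
    bic_for_boundaries,
    block_split_bic,
    build_phenotype_matrix,
    cluster_tree,
    confidence_interval,
    paired_t_statistic,
)


class TestPairedT:
    def test_identical_values_zero(self):
        assert paired_t_statistic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_unit_differences(self):
        # d = {1,2,3}: mean 2, sd 1, SE 1/√3 → t = 2√3
        assert paired_t_statistic([1, 2, 3], [0, 0, 0]) == pytest.approx(2 * np.sqrt(3))

    def test_constant_nonzero_difference_errors(self):
        with pytest.raises(ZeroVarianceError):
            paired_t_statistic([2, 2, 2, 2], [1, 1, 1, 1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=8),
        st.integers(0, 10_000),
    )
    def test_antisymmetry(self, a, seed):
        rng = np.random.default_rng(seed)
        b = rng.normal(0, 1, len(a))
        x = np.asarray(a)
        try:
            t_ab = paired_t_statistic(x, b)
        except ZeroVarianceError:
            return
        assert paired_t_statistic(b, x) == pytest.approx(-t_ab)


class TestPhenotypeMatrix:
    def _table(self, values):
        rows = []
        for (rep, line, metric), v in values.items():
            rows.append({"replicate": rep, "cell_line": line, "metric": metric, "value": v})
        return pd.DataFrame(rows)

    def test_line_equal_to_control_gives_zero_column(self):
        vals = {}
        for rep in range(4):
            for line in ("ctrl", "mut"):
                vals[(rep, line, "speed")] = 1.0 + rep
        m = build_phenotype_matrix(self._table(vals), control="ctrl")
        assert m.loc["speed", "mut"] == 0.0

    def test_expected_t_matches_noncentral_t_mean(self):
        # known shift δ with noise σ: E[t] = c_ν·δ√n/σ where c_ν is the exact
        # noncentral-t mean factor √(ν/2)·Γ((ν−1)/2)/Γ(ν/2)
        rng = np.random.default_rng(42)
        delta, sigma, n = 0.8, 1.0, 10
        nu = n - 1
        c = np.sqrt(nu / 2) * gamma_fn((nu - 1) / 2) / gamma_fn(nu / 2)
        expected = c * delta * np.sqrt(n) / sigma
        ts = []
        for _ in range(1000):
            d = delta + rng.normal(0, sigma, n)
            ts.append(d.mean() / (d.std(ddof=1) / np.sqrt(n)))
        assert np.mean(ts) == pytest.approx(expected, rel=0.05)

    def test_unpaired_replicate_dropped(self, caplog):
        vals = {
            (0, "ctrl", "speed"): 1.0, (0, "mut", "speed"): 2.0,
            (1, "ctrl", "speed"): 1.5, (1, "mut", "speed"): 2.1,
            (2, "ctrl", "speed"): 0.9, (2, "mut", "speed"): 2.4,
            (3, "mut", "speed"): 9.9,  # replicate 3 has no control measurement
        }
        m = build_phenotype_matrix(self._table(vals), control="ctrl")
        direct = paired_t_statistic([2.0, 2.1, 2.4], [1.0, 1.5, 0.9])
        assert m.loc["speed", "mut"] == pytest.approx(direct)

    def test_alternative_reference(self):
        vals = {}
        for rep in range(3):
            vals[(rep, "ctrl", "m")] = 0.0
            vals[(rep, "a", "m")] = 1.0 + 0.1 * rep
            vals[(rep, "b", "m")] = 5.0 + 0.2 * rep
        m = build_phenotype_matrix(self._table(vals), control="ctrl", reference="a")
        assert "a" not in m.columns
        assert m.loc["m", "b"] > 0


class TestClusterTree:
    def test_correlated_profiles_merge_first(self):
        # profiles (1,2,3) and (2,4,6) are perfectly correlated (distance 0);
        # (3,2,1) is anti-correlated with both (distance 2)
        m = pd.DataFrame(
            {"l1": [1.0, 2.0, 3.0], "l2": [2.0, 4.0, 6.0], "l3": [3.0, 2.0, 1.0]},
            index=["a", "b", "c"],
        )
        tree = cluster_tree(m, axis="lines")
        Z = tree.linkage_matrix
        assert Z[0, 2] == pytest.approx(0.0, abs=1e-12)  # first merge at distance 0
        assert Z[-1, 2] == pytest.approx(2.0, abs=1e-9)
        first = {tree.labels[int(Z[0, 0])], tree.labels[int(Z[0, 1])]}
        assert first == {"l1", "l2"}

    def test_two_perfect_pairs_adjacent_in_leaf_order(self):
        X = np.array([
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],   # pair of row 0
            [4.0, 3.0, 2.0, 1.0],
            [8.0, 6.0, 4.0, 2.0],   # pair of row 2
        ])
        m = pd.DataFrame(X.T, columns=["p", "q", "r", "s"])
        tree = cluster_tree(m, axis="lines")
        Z = tree.linkage_matrix
        assert np.sum(np.isclose(Z[:, 2], 0.0)) == 2
        order = tree.leaf_order
        assert abs(order.index("p") - order.index("q")) == 1
        assert abs(order.index("r") - order.index("s")) == 1

    def test_zero_variance_profile_named_in_error(self):
        m = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        with pytest.raises(ZeroVarianceError, match="x"):
            cluster_tree(m, axis="lines")

    def test_tree_invariant_under_affine_rescaling(self):
        rng = np.random.default_rng(3)
        X = rng.normal(0, 1, (5, 6))
        m1 = pd.DataFrame(X.T, columns=list("abcde"))
        X2 = X.copy()
        X2[2] = 10.0 * X2[2] + 3.0  # affine rescale of one profile
        m2 = pd.DataFrame(X2.T, columns=list("abcde"))
        t1 = cluster_tree(m1, axis="lines")
        t2 = cluster_tree(m2, axis="lines")
        assert np.allclose(t1.linkage_matrix[:, 2], t2.linkage_matrix[:, 2], atol=1e-9)
        assert t1.leaf_order == t2.leaf_order


class TestBlockSplit:
    def _bruteforce_best(self, corr):
        n = corr.shape[0]
        best = (np.inf, ())
        for k in range(n):
            for bounds in itertools.combinations(range(1, n), k):
                bic = bic_for_boundaries(corr, bounds)
                if bic < best[0]:
                    best = (bic, bounds)
        return best[1]

    def test_identity_matrix_single_block(self):
        assert np.all(block_split_bic(np.eye(4)) == 0)

    def test_exact_two_block_matrix(self):
        corr = np.full((6, 6), -0.9)
        corr[:3, :3] = 0.9
        corr[3:, 3:] = 0.9
        np.fill_diagonal(corr, 1.0)
        labels = block_split_bic(corr)
        assert np.array_equal(labels, [0, 0, 0, 1, 1, 1])
        assert self._bruteforce_best(corr) == (3,)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greedy_matches_bruteforce_on_random_block_matrices(self, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(2, 4, size=2)
        n = sizes.sum()
        corr = rng.normal(-0.5, 0.1, (n, n))
        start = 0
        for s in sizes:
            corr[start : start + s, start : start + s] = rng.normal(0.8, 0.05, (s, s))
            start += s
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        greedy = block_split_bic(corr)
        brute = self._bruteforce_best(corr)
        lab = np.zeros(n, int)
        for b in sorted(brute):
            lab[b:] += 1
        assert np.array_equal(greedy, lab)

    def test_labels_contiguous_and_complete(self):
        rng = np.random.default_rng(9)
        corr = rng.uniform(-1, 1, (8, 8))
        corr = (corr + corr.T) / 2
        np.fill_diagonal(corr, 1.0)
        labels = block_split_bic(corr)
        assert len(labels) == 8
        assert np.all(np.diff(labels) >= 0)  # contiguous in leaf order
        assert set(labels) == set(range(labels.max() + 1))


class TestConfidenceInterval:
    def test_constant_values_degenerate_interval(self):
        assert confidence_interval([1.0, 1.0, 1.0]) == (1.0, 1.0, 1.0)

    def test_two_values_uses_t_critical(self):
        m, lo, hi = confidence_interval([0.0, 2.0])
        assert m == 1.0
        assert lo == pytest.approx(1 - 12.706, abs=0.01)
        assert hi == pytest.approx(1 + 12.706, abs=0.01)

    def test_width_shrinks_as_sqrt_n(self):
        rng = np.random.default_rng(0)
        widths = {}
        for n in (10, 40):
            w = []
            for _ in range(400):
                x = rng.normal(0, 1, n)
                _, lo, hi = confidence_interval(x)
                w.append(hi - lo)
            widths[n] = np.mean(w)
        # t-critical ratio ≈ 1.09, √4 = 2 → expected ratio ≈ 2·(2.26/2.02)⁻¹...
        # compare against the exact expectation ratio instead of the asymptote
        from scipy import stats

        exact = (stats.t.ppf(0.975, 9) / np.sqrt(10)) / (stats.t.ppf(0.975, 39) / np.sqrt(40))
        assert widths[10] / widths[40] == pytest.approx(exact, rel=0.15)

    def test_single_value_errors(self):
        with pytest.raises(ValueError):
            confidence_interval([1.0])
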