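"""Community statistics: chi-square, Chao dissimilarity, NMDS, ANOSIM."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from skbio import DistanceMatrix

from trnldiet.community import (
    CommunityStatsError,
    anosim,
    anosim_exact,
    anosim_r,
    chao_dissimilarity,
    dissimilarity_matrix,
    jaccard_dissimilarity,
    nmds,
    pearson_chisq,
    _nmds_single,
)

counts = st.lists(st.integers(min_value=0, max_value=50), min_size=2, max_size=8)


def chisq_oracle(t):
    """Straight-from-formula Pearson statistic and df."""
    t = np.asarray(t, float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    e = row @ col / t.sum()
    x2 = ((t - e) ** 2 / e).sum()
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    return x2, df


class TestPearsonChisq:
    def test_identical_columns_give_zero(self):
        x2, _, p = pearson_chisq(pd.DataFrame([[5, 5], [3, 3], [2, 2]]))
        assert x2 == pytest.approx(0)
        assert p == pytest.approx(1)

    def test_2x2_closed_form(self):
        x2, df, _ = pearson_chisq(pd.DataFrame([[10, 0], [0, 10]]))
        assert x2 == pytest.approx(20)
        assert df == 1

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            t = rng.integers(1, 40, size=(rng.integers(2, 6), rng.integers(2, 4)))
            x2, df, _ = pearson_chisq(pd.DataFrame(t))
            ox2, odf = chisq_oracle(t)
            assert x2 == pytest.approx(ox2, abs=1e-10)
            assert df == odf

    def test_zero_margins_dropped_with_warning(self):
        t = pd.DataFrame([[5, 3], [0, 0], [2, 8]])
        with pytest.warns(UserWarning, match="zero-margin"):
            x2, df, _ = pearson_chisq(t)
        assert df == 1


def chao_oracle(x, y):
    """Independent straight-from-formula Chao-Jaccard dissimilarity."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n, m = x.sum(), y.sum()
    shared = [i for i in range(len(x)) if x[i] > 0 and y[i] > 0]
    if not shared:
        return 1.0

    def u_of(a, b, tot_a, tot_b):
        u = sum(a[i] / tot_a for i in shared)
        f1 = sum(1 for i in shared if b[i] == 1)
        f2 = sum(1 for i in shared if b[i] == 2)
        f2 = f2 if f2 > 0 else 1
        u += (tot_b - 1) / tot_b * f1 / (2 * f2) * sum(
            a[i] / tot_a for i in shared if b[i] == 1
        )
        return min(u, 1.0)

    u = u_of(x, y, n, m)
    v = u_of(y, x, m, n)
    if u == 0 or v == 0:
        return 1.0
    return 1 - u * v / (u + v - u * v)


class TestChao:
    def test_identical_samples_zero(self):
        x = [4, 3, 2, 0]
        assert chao_dissimilarity(x, x) == pytest.approx(0)

    def test_disjoint_supports_one(self):
        assert chao_dissimilarity([5, 0, 2, 0], [0, 3, 0, 4]) == 1.0

    def test_correction_and_no_correction_paths_match_oracle(self):
        # y holds a shared singleton -> correction path triggered
        x, y = [4, 3, 0], [2, 0, 5]
        assert chao_dissimilarity(x, y) == pytest.approx(chao_oracle(x, y), abs=1e-12)
        x2, y2 = [4, 3, 1], [1, 2, 5]
        assert chao_dissimilarity(x2, y2) == pytest.approx(chao_oracle(x2, y2), abs=1e-12)
        # all shared species abundant -> no correction
        x3, y3 = [40, 30, 0], [20, 10, 5]
        assert chao_dissimilarity(x3, y3) == pytest.approx(chao_oracle(x3, y3), abs=1e-12)

    @given(counts, counts)
    def test_matches_oracle_and_symmetry(self, x, y):
        k = min(len(x), len(y))
        x, y = x[:k], y[:k]
        if sum(x) == 0 or sum(y) == 0:
            with pytest.raises(CommunityStatsError):
                chao_dissimilarity(x, y)
            return
        d = chao_dissimilarity(x, y)
        assert d == pytest.approx(chao_oracle(x, y), abs=1e-12)
        assert d == pytest.approx(chao_dissimilarity(y, x), abs=1e-12)
        assert 0 <= d <= 1

    def test_invariant_to_species_absent_from_both(self):
        x, y = [4, 3, 1], [1, 2, 5]
        assert chao_dissimilarity(x + [0, 0], y + [0, 0]) == pytest.approx(
            chao_dissimilarity(x, y)
        )

    def test_empty_sample_signals(self):
        with pytest.raises(CommunityStatsError, match="empty"):
            chao_dissimilarity([0, 0], [1, 2])

    def test_jaccard_presence_counterpart(self):
        assert jaccard_dissimilarity([3, 0, 1], [1, 1, 0]) == pytest.approx(1 - 1 / 3)


class TestNmds:
    @staticmethod
    def _euclidean_toy():
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.2]])
        from scipy.spatial.distance import pdist, squareform

        return DistanceMatrix(squareform(pdist(pts)), [f"p{i}" for i in range(4)])

    def test_perfect_recovery_low_stress(self):
        res = nmds(self._euclidean_toy(), k=2, seed=0)
        assert res.stress < 0.01
        assert np.allclose(res.coordinates.mean(axis=0), 0, atol=1e-8)

    def test_stress_trace_non_increasing(self):
        D = self._euclidean_toy()
        rng = np.random.default_rng(1)
        for _ in range(5):
            x0 = rng.normal(size=(4, 2))
            _, _, trace, _ = _nmds_single(D.condensed_form(), x0, 200, 1e-6)
            assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 4))
        from scipy.spatial.distance import pdist, squareform

        D = DistanceMatrix(squareform(pdist(pts)), [f"p{i}" for i in range(10)])
        r1 = nmds(D, seed=42)
        r2 = nmds(D, seed=42)
        assert r1.stress == r2.stress
        assert np.array_equal(r1.coordinates.to_numpy(), r2.coordinates.to_numpy())

    def test_separated_groups_ordinate_apart(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0, 0.3, size=(8, 5))
        b = rng.normal(4, 0.3, size=(8, 5))
        pts = np.vstack([a, b])
        from scipy.spatial.distance import pdist, squareform

        ids = [f"p{i}" for i in range(16)]
        D = DistanceMatrix(squareform(pdist(pts)), ids)
        grouping = {i: ("A" if int(i[1:]) < 8 else "B") for i in ids}
        assert anosim_r(D, grouping) > 0.9


class TestAnosim:
    @staticmethod
    def _matrix(n, rng):
        d = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals = rng.uniform(0.1, 1.0, size=len(iu[0]))
        d[iu] = vals
        d += d.T
        return DistanceMatrix(d, [f"s{i}" for i in range(n)])

    def test_perfect_separation_gives_r_one(self):
        n = 6
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            same = (i < 3) == (j < 3)
            d[i, j] = d[j, i] = 0.2 if same else 0.9
        D = DistanceMatrix(d, [f"s{i}" for i in range(n)])
        grouping = {f"s{i}": "A" if i < 3 else "B" for i in range(n)}
        assert anosim_r(D, grouping) == pytest.approx(1.0)

    def test_permutation_p_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        D = self._matrix(6, rng)
        grouping = {f"s{i}": "A" if i < 3 else "B" for i in range(6)}
        r_exact, p_exact = anosim_exact(D, grouping)
        res = anosim(D, grouping, n_perm=999, seed=3)
        assert res.R == pytest.approx(r_exact)
        # 20 distinct assignments; add-one MC estimate within sampling error
        se = np.sqrt(p_exact * (1 - p_exact) / 999)
        assert abs(res.p - p_exact) < max(4 * se, 0.03)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(8)
        rs = []
        for _ in range(60):
            D = self._matrix(10, rng)
            labels = rng.permutation(["A"] * 5 + ["B"] * 5)
            grouping = {f"s{i}": labels[i] for i in range(10)}
            rs.append(anosim_r(D, grouping))
        assert abs(np.mean(rs)) < 0.05

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        D = self._matrix(8, rng)
        grouping = {f"s{i}": "A" if i < 4 else "B" for i in range(8)}
        D2 = DistanceMatrix(np.sqrt(D.data), list(D.ids))
        assert anosim_r(D, grouping) == pytest.approx(anosim_r(D2, grouping))

    def test_agrees_with_skbio_r(self):
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(10)
        D = self._matrix(12, rng)
        labels = ["A"] * 6 + ["B"] * 6
        grouping = dict(zip(D.ids, labels))
        ours = anosim_r(D, grouping)
        theirs = skbio_anosim(D, labels, permutations=0)
        assert ours == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_p_in_unit_interval_and_addone(self):
        rng = np.random.default_rng(11)
        D = self._matrix(8, rng)
        grouping = {f"s{i}": "A" if i < 4 else "B" for i in range(8)}
        res = anosim(D, grouping, n_perm=99, seed=0)
        assert 1 / 100 <= res.p <= 1


class TestDissimilarityMatrix:
    def test_chao_matrix_properties(self):
        m = pd.DataFrame(
            {"A": [5, 1, 0], "B": [2, 3, 1], "C": [0, 2, 6]},
            index=["s1", "s2", "s3"],
        )
        D = dissimilarity_matrix(m, metric="chao")
        assert np.allclose(np.diag(D.data), 0)
        assert np.allclose(D.data, D.data.T)
        assert ((D.data >= 0) & (D.data <= 1)).all()

    def test_jaccard_mode_uses_presence_only(self):
        m1 = pd.DataFrame({"A": [5, 0], "B": [2, 3]}, index=["s1", "s2"])
        m2 = pd.DataFrame({"A": [1, 0], "B": [9, 1]}, index=["s1", "s2"])
        assert np.allclose(
            dissimilarity_matrix(m1, "jaccard").data,
            dissimilarity_matrix(m2, "jaccard").data,
        )
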