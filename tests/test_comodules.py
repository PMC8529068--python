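import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trinetomics import (bicor, bicor_matrix, cluster_modules, eigenprofile,
                         pick_soft_threshold, scale_free_fit, signed_adjacency,
                         tom_dissimilarity, ModulePartition, UNASSIGNED)


class TestBicor:
    def test_self_and_negated(self, rng):
        x = rng.standard_normal(50)
        assert bicor(x, x) == pytest.approx(1.0)
        assert bicor(x, -x) == pytest.approx(-1.0)

    def test_close_to_pearson_on_gaussian(self, rng):
        x = rng.standard_normal(1000)
        y = 0.6 * x + 0.8 * rng.standard_normal(1000)
        assert abs(bicor(x, y) - np.corrcoef(x, y)[0, 1]) < 0.05

    def test_symmetric_and_shift_scale_invariant(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        assert bicor(x, y) == pytest.approx(bicor(y, x))
        assert bicor(3.0 * x + 7.0, y) == pytest.approx(bicor(x, y), abs=1e-12)

    def test_downweights_single_outlier(self, rng):
        x = rng.standard_normal(100)
        y = x + 0.1 * rng.standard_normal(100)
        y_out = y.copy()
        y_out[0] += 50.0                         # one gross outlier
        assert bicor(x, y_out) > np.corrcoef(x, y_out)[0, 1]

    def test_constant_vector_falls_back_to_pearson(self, rng):
        # MAD = 0 for a vector with > half identical values; falls back, stays finite
        x = np.r_[np.zeros(30), rng.standard_normal(10)]
        y = rng.standard_normal(40)
        assert np.isfinite(bicor(x, y))

    def test_matrix_agrees_with_pairwise(self, rng):
        data = rng.standard_normal((30, 4))
        c = bicor_matrix(data)
        for i in range(4):
            for j in range(4):
                assert c[i, j] == pytest.approx(bicor(data[:, i], data[:, j]), abs=1e-10)


class TestSignedAdjacency:
    def test_closed_forms(self):
        c = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert signed_adjacency(c, 13)[0, 1] == pytest.approx(1.0)
        c = np.array([[1.0, -1.0], [-1.0, 1.0]])
        assert signed_adjacency(c, 13)[0, 1] == pytest.approx(0.0)
        c = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert signed_adjacency(c, 13)[0, 1] == pytest.approx(2.0**-13)

    def test_rejects_bad_beta(self):
        with pytest.raises(ValueError):
            signed_adjacency(np.eye(2), 0)

    @given(st.integers(1, 20))
    @settings(max_examples=10, deadline=None)
    def test_entries_in_unit_interval(self, beta):
        rng = np.random.default_rng(beta)
        x = rng.standard_normal((20, 6))
        c = np.corrcoef(x, rowvar=False)
        a = signed_adjacency(c, beta)
        assert (a >= 0).all() and (a <= 1).all()
        np.testing.assert_allclose(a, a.T)


class TestSoftThreshold:
    def test_power_law_degree_sequence_fits_well(self):
        # frequency(k) ~ k^-2 exactly: a perfect log-log line
        ks = np.concatenate([np.full(int(round(1000 * k**-2.0)), float(k))
                             for k in range(1, 11)])
        r2, slope = scale_free_fit(ks)
        assert r2 >= 0.95
        assert slope < 0

    def test_degenerate_falls_back_to_grid_max(self, rng):
        c = np.eye(8)                         # no correlation at all
        scan = pick_soft_threshold(c, beta_grid=[2, 6, 13])
        assert scan.chosen == 13

    def test_target_zero_picks_smallest_beta(self, rng):
        x = rng.standard_normal((50, 15))
        c = np.corrcoef(x, rowvar=False)
        scan = pick_soft_threshold(c, beta_grid=[3, 7, 13], r2_target=0.0)
        if (scan.table["r_squared"] > 0).any():
            assert scan.chosen == 3

    def test_mean_connectivity_decreases_in_beta(self, rng):
        x = rng.standard_normal((60, 20))
        c = np.corrcoef(x, rowvar=False)
        scan = pick_soft_threshold(c, beta_grid=list(range(1, 15)))
        mk = scan.table["mean_connectivity"].to_numpy()
        assert (np.diff(mk) <= 1e-12).all()


class TestTom:
    def test_shared_everything_gives_zero(self):
        a = np.ones((5, 5))
        d = tom_dissimilarity(a)
        np.testing.assert_allclose(d, 0.0, atol=1e-12)

    def test_isolated_pair_gives_one(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 0.0               # no edge, no shared neighbours
        d = tom_dissimilarity(a)
        assert d[0, 1] == pytest.approx(1.0)

    def test_four_node_toy_matches_hand_formula(self):
        a = np.array([
            [1.0, 0.8, 0.4, 0.0],
            [0.8, 1.0, 0.5, 0.1],
            [0.4, 0.5, 1.0, 0.6],
            [0.0, 0.1, 0.6, 1.0],
        ])
        d = tom_dissimilarity(a)
        off = a - np.eye(4)
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                l = sum(off[i, u] * off[u, j] for u in range(4) if u not in (i, j))
                k_i, k_j = off[i].sum(), off[j].sum()
                expected = 1 - (l + off[i, j]) / (min(k_i, k_j) + 1 - off[i, j])
                assert d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_symmetric_zero_diag_unit_range(self, rng):
        x = rng.standard_normal((30, 10))
        a = signed_adjacency(np.corrcoef(x, rowvar=False), 6)
        d = tom_dissimilarity(a)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)
        assert (d >= 0).all() and (d <= 1).all()


def _block_dissimilarity(sizes, d_within=0.1, d_between=0.9):
    n = sum(sizes)
    d = np.full((n, n), d_between)
    start = 0
    for s in sizes:
        d[start:start + s, start:start + s] = d_within
        start += s
    np.fill_diagonal(d, 0.0)
    return d


class TestClusterModules:
    def test_two_planted_blocks_recovered_exactly(self):
        d = _block_dissimilarity([10, 10])
        part = cluster_modules(d, deep_split=4, min_size=3)
        labels = list(part.labels.values())
        assert len(part.module_sizes()) == 2
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_identical_dissimilarity_merges_to_one_module(self):
        d = np.full((8, 8), 0.5)
        np.fill_diagonal(d, 0.0)
        part = cluster_modules(d, min_size=3)
        assert len(part.module_sizes()) == 1

    def test_blocks_below_min_size_unassigned(self):
        d = _block_dissimilarity([2, 2, 2])
        part = cluster_modules(d, min_size=3)
        assert all(l == UNASSIGNED for l in part.labels.values())

    def test_raising_min_size_never_adds_modules(self):
        d = _block_dissimilarity([3, 5, 10])
        counts = [len(cluster_modules(d, min_size=m).module_sizes()) for m in (3, 4, 6, 11)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))

    def test_reassignment_adopts_correlated_features(self, rng):
        # 2 blocks of 8 + one extra feature correlated with block 1
        base = rng.standard_normal((60, 1))
        block1 = base + 0.3 * rng.standard_normal((60, 8))
        base2 = rng.standard_normal((60, 1))
        block2 = base2 + 0.3 * rng.standard_normal((60, 8))
        extra = base + 1.0 * rng.standard_normal((60, 1))
        data = pd.DataFrame(np.hstack([block1, block2, extra]),
                            columns=[f"f{i}" for i in range(17)])
        c = bicor_matrix(data.to_numpy())
        d = tom_dissimilarity(signed_adjacency(c, 6))
        part = cluster_modules(d, feature_ids=data.columns, min_size=5, data=data)
        assert part.labels["f16"] == part.labels["f0"] != UNASSIGNED

    def test_partition_enforces_min_size(self):
        with pytest.raises(ValueError):
            ModulePartition({"a": "M1", "b": "M1"}, min_size=3)


class TestEigenprofile:
    def test_identical_members_give_common_profile(self, rng):
        profile = rng.standard_normal(25)
        data = pd.DataFrame({f"f{i}": profile for i in range(4)})
        part = ModulePartition({f"f{i}": "M1" for i in range(4)}, min_size=3)
        eig = eigenprofile(data, part)
        assert eig.variance_explained["M1"] == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eig.scores["M1"], z, atol=1e-8)

    def test_anticorrelated_pair_fully_explained_and_oriented(self, rng):
        x = rng.standard_normal(30)
        data = pd.DataFrame({"a": x, "b": -2.0 * x + 1.0})
        part = ModulePartition({"a": "M1", "b": "M1"}, min_size=2)
        eig = eigenprofile(data, part)
        assert eig.variance_explained["M1"] == pytest.approx(1.0)
        mean_profile = ((data - data.mean()) / data.std(ddof=0)).mean(axis=1)
        assert np.corrcoef(eig.scores["M1"], mean_profile)[0, 1] >= 0

    def test_matches_svd_oracle(self, rng):
        data = pd.DataFrame(rng.standard_normal((20, 5)),
                            columns=[f"f{i}" for i in range(5)])
        part = ModulePartition({f"f{i}": "M1" for i in range(5)}, min_size=3)
        eig = eigenprofile(data, part)
        xs = (data - data.mean()) / data.std(ddof=0)
        u, s, _ = np.linalg.svd(xs.to_numpy(), full_matrices=False)
        oracle = u[:, 0] * s[0]
        oracle /= oracle.std()
        agree = min(np.abs(eig.scores["M1"].to_numpy() - oracle).max(),
                    np.abs(eig.scores["M1"].to_numpy() + oracle).max())
        assert agree < 1e-8

    def test_single_member_module_errors(self, rng):
        data = pd.DataFrame({"a": rng.standard_normal(10)})
        part = ModulePartition({"a": "M1"}, min_size=1)
        with pytest.raises(ValueError):
            eigenprofile(data, part)
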