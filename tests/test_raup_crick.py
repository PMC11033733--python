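import itertools

import numpy as np
import pytest

from assemblage.io_core import BinaryMatrix, FeatureTable
from assemblage.raup_crick import beta_rc, presence_and_weights, simulate_null_communities

from conftest import random_binary


def exact_beta_rc_richness2(weights, obs_shared):
    """Exhaustive oracle for two communities of richness 2.

    Enumerates all unordered 2-subsets with their sequential
    sampling-without-replacement probabilities (proportional to weights).
    """
    w = np.asarray(weights, dtype=float)
    n = w.size
    total = w.sum()
    subsets = {}
    for a, b in itertools.permutations(range(n), 2):
        p = (w[a] / total) * (w[b] / (total - w[a]))
        key = frozenset((a, b))
        subsets[key] = subsets.get(key, 0.0) + p
    gt = ties = 0.0
    for sa, pa in subsets.items():
        for sb, pb in subsets.items():
            shared = len(sa & sb)
            if shared > obs_shared:
                gt += pa * pb
            elif shared == obs_shared:
                ties += pa * pb
    return 2.0 * (gt + 0.5 * ties) - 1.0


class TestBetaRC:
    def test_identical_samples_near_minus_one(self):
        # two identical rich samples; a witness sample keeps the 50-taxon
        # pool occupied so the null can scatter
        n_taxa = 50
        e = np.zeros((n_taxa, 3), dtype=np.uint8)
        e[:10, 0] = 1
        e[:10, 1] = 1
        e[:, 2] = 1
        m = BinaryMatrix(e, [f"t{i}" for i in range(n_taxa)], ["a", "b", "w"])
        rc = beta_rc(m, n_reps=999, seed=1)
        assert rc.values[0, 1] < -0.95

    def test_disjoint_high_richness_near_plus_one(self):
        # disjoint pairs approach +1 once null pairs almost surely overlap
        n_taxa = 100
        e = np.zeros((n_taxa, 3), dtype=np.uint8)
        e[:40, 0] = 1
        e[40:80, 1] = 1
        e[:, 2] = 1
        m = BinaryMatrix(e, [f"t{i}" for i in range(n_taxa)], ["a", "b", "w"])
        rc = beta_rc(m, n_reps=999, seed=2)
        assert rc.values[0, 1] > 0.95

    def test_null_pairs_centered(self, rng):
        base = random_binary(rng, 40, 10, p=0.35)
        w_by_id = dict(zip(base.taxon_ids, base.entries.sum(axis=1).astype(float)))
        sets = simulate_null_communities(base, 20, seed=3)
        vals = []
        for i, s in enumerate(sets):
            weights = np.array([w_by_id[t] for t in s.taxon_ids])
            rc = beta_rc(s, n_reps=299, seed=50 + i, pool_weights=weights)
            iu = np.triu_indices(rc.values.shape[0], k=1)
            vals.extend(rc.values[iu].tolist())
        vals = np.asarray(vals)
        assert abs(np.nanmean(vals)) < 0.1

    def test_symmetry_bounds_masked_diagonal(self, rng):
        m = random_binary(rng, 15, 8)
        rc = beta_rc(m, n_reps=199, seed=4)
        v = rc.values
        assert np.isnan(np.diag(v)).all()
        off = v[~np.eye(v.shape[0], dtype=bool)]
        assert np.nanmax(off) <= 1.0 and np.nanmin(off) >= -1.0
        np.testing.assert_allclose(v, v.T, equal_nan=True)

    def test_taxon_relabeling_invariance(self, rng):
        m = random_binary(rng, 12, 9)
        perm = rng.permutation(12)
        m2 = BinaryMatrix(
            m.entries[perm], [m.taxon_ids[i] for i in perm], list(m.sample_ids)
        )
        a = beta_rc(m, n_reps=3000, seed=5).values
        b = beta_rc(m2, n_reps=3000, seed=6).values
        iu = np.triu_indices(a.shape[0], k=1)
        np.testing.assert_allclose(a[iu], b[iu], atol=0.12)

    def test_monotone_in_shared(self):
        # same richness, decreasing shared -> beta_rc never decreases
        n_taxa = 20
        uniform = np.ones(n_taxa)
        vals = []
        for shared in (6, 4, 2, 0):
            e = np.zeros((n_taxa, 2), dtype=np.uint8)
            e[:8, 0] = 1
            e[8 - shared : 16 - shared, 1] = 1
            ft = FeatureTable(
                e.T.astype(np.int64),
                ["a", "b"],
                [f"t{i}" for i in range(n_taxa)],
            )
            rc = beta_rc(ft, n_reps=4000, seed=7, pool_weights=uniform)
            vals.append(rc.values[0, 1])
        assert all(vals[i] <= vals[i + 1] + 0.03 for i in range(len(vals) - 1))

    def test_exact_enumeration_small(self):
        # 5-taxon pool, richness (2,2): exact null enumerable
        n_taxa = 5
        e = np.zeros((n_taxa, 2), dtype=np.uint8)
        e[[0, 1], 0] = 1
        e[[1, 2], 1] = 1  # shared = 1
        ft = FeatureTable(e.T.astype(np.int64), ["a", "b"], [f"t{i}" for i in range(5)])
        w = np.array([3.0, 1.0, 2.0, 1.0, 1.0])
        exact = exact_beta_rc_richness2(w, obs_shared=1)
        rc = beta_rc(ft, n_reps=20000, seed=8, pool_weights=w)
        assert rc.values[0, 1] == pytest.approx(exact, abs=0.03)


class TestSimulateNullCommunities:
    def test_richness_conserved(self, rng):
        m = random_binary(rng, 20, 8)
        for s in simulate_null_communities(m, 10, seed=9):
            np.testing.assert_array_equal(
                s.entries.sum(axis=0), m.entries.sum(axis=0)
            )

    def test_occupancy_rank_preserved(self, rng):
        m = random_binary(rng, 25, 12, p=0.4)
        sets = simulate_null_communities(m, 500, seed=10)
        idx = {t: i for i, t in enumerate(m.taxon_ids)}
        realized = np.zeros(m.n_taxa)
        for s in sets:
            for t, occ in zip(s.taxon_ids, s.entries.sum(axis=1)):
                realized[idx[t]] += occ
        expected = m.entries.sum(axis=1).astype(float)
        r = np.corrcoef(expected, realized)[0, 1]
        assert r > 0.9

    def test_seed_reproducibility(self, rng):
        m = random_binary(rng, 10, 6)
        a = simulate_null_communities(m, 3, seed=11)
        b = simulate_null_communities(m, 3, seed=11)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.entries, y.entries)


class TestPresenceAndWeights:
    def test_zero_weight_present_taxon_floored(self, rng):
        m = random_binary(rng, 5, 4)
        w = np.ones(5)
        w[0] = 0.0
        with pytest.warns(UserWarning, match="flooring"):
            _, _, _, w_out = presence_and_weights(m, w)
        assert (w_out > 0).all()

    def test_regional_pool_keeps_absent_taxa(self):
        counts = np.array([[1, 0, 0], [2, 0, 0]])
        ft = FeatureTable(counts, ["a", "b"], ["t1", "t2", "t3"])
        presence, sample_ids, taxon_ids, w = presence_and_weights(
            ft, np.array([5.0, 3.0, 2.0])
        )
        assert taxon_ids == ["t1", "t2", "t3"]
        assert presence.shape == (2, 3)
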