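"""SILA ordinal dissimilarity and affinity-propagation clustering."""

import itertools

import numpy as np
import pytest
from scipy.stats import wasserstein_distance

from esilung import PatternProfile, affinity_propagation, sila, sila_matrix
from esilung.cohort import REGIONS, generate_profile
from esilung.exceptions import DomainError, MalformedInputError


def single_region_profile(fractions, region="LU"):
    return PatternProfile(regions=[region], fractions=np.array([fractions]),
                          volume_weights=np.array([1.0]))


def random_profile(rng, n_regions=6):
    fr = rng.dirichlet(np.ones(4), size=n_regions)
    vw = rng.dirichlet(np.ones(n_regions))
    return PatternProfile(regions=list(REGIONS[:n_regions]), fractions=fr,
                          volume_weights=vw)


class TestSila:
    def test_identity(self):
        rng = np.random.default_rng(0)
        p = random_profile(rng)
        assert sila(p, p) == 0.0

    def test_extreme_profiles_reach_three(self):
        p = single_region_profile([1, 0, 0, 0])
        q = single_region_profile([0, 0, 0, 1])
        assert sila(p, q) == pytest.approx(3.0)

    def test_matches_wasserstein_oracle(self):
        """Per region, the ordinal CDF distance equals the 1-Wasserstein
        distance between the two class distributions on grades 0..3."""
        rng = np.random.default_rng(1)
        grades = np.arange(4)
        for _ in range(50):
            p = single_region_profile(rng.dirichlet(np.ones(4)))
            q = single_region_profile(rng.dirichlet(np.ones(4)))
            oracle = wasserstein_distance(grades, grades,
                                          p.fractions[0], q.fractions[0])
            assert sila(p, q) == pytest.approx(oracle, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p, q = random_profile(rng), random_profile(rng)
            assert sila(p, q) == pytest.approx(sila(q, p), abs=1e-12)

    def test_triangle_inequality(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            # shared weights so the pseudometric axioms apply cleanly
            vw = rng.dirichlet(np.ones(6))
            ps = [PatternProfile(regions=list(REGIONS),
                                 fractions=rng.dirichlet(np.ones(4), size=6),
                                 volume_weights=vw) for _ in range(3)]
            a, b, c = (sila(ps[0], ps[1]), sila(ps[1], ps[2]),
                       sila(ps[0], ps[2]))
            assert c <= a + b + 1e-12

    def test_mismatched_regions_rejected(self):
        p = single_region_profile([1, 0, 0, 0], region="LU")
        q = single_region_profile([1, 0, 0, 0], region="RL")
        with pytest.raises(DomainError):
            sila(p, q)

    def test_extended_profile_renormalizes_with_warning(self):
        fr = np.array([[0.4, 0.2, 0.1, 0.1, 0.1, 0.05, 0.05]] * 6)
        with pytest.warns(UserWarning):
            p = PatternProfile.from_extended_fractions(
                list(REGIONS), fr, np.full(6, 1 / 6))
        assert np.allclose(p.fractions.sum(axis=1), 1.0)


class TestSilaMatrix:
    def test_identical_profiles_zero_matrix(self):
        rng = np.random.default_rng(4)
        p = random_profile(rng)
        m = sila_matrix([p, p, p])
        assert np.all(m == 0)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(5)
        profiles = [random_profile(rng) for _ in range(8)]
        m = sila_matrix(profiles)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)
        assert np.all(m >= 0)


def planted_profiles(rng, centers, n_per, spread=0.02):
    """Tight groups of profiles around given severity centres."""
    out, tiers = [], []
    for tier, c in enumerate(centers):
        for _ in range(n_per):
            out.append(generate_profile(
                float(np.clip(c + rng.normal(0, spread), 0, 1)), rng))
            tiers.append(tier)
    return out, np.array(tiers)


def two_medoid_oracle(dissim):
    """Exhaustive best 2-medoid assignment."""
    n = dissim.shape[0]
    best = None
    for i, j in itertools.combinations(range(n), 2):
        cost = np.minimum(dissim[:, i], dissim[:, j]).sum()
        labels = (dissim[:, j] < dissim[:, i]).astype(int)
        if best is None or cost < best[0]:
            best = (cost, labels)
    return best[1]


class TestAffinityPropagation:
    def test_single_subject(self):
        res = affinity_propagation(np.zeros((1, 1)))
        assert res.labels.tolist() == [0]
        assert res.exemplars.tolist() == [0]
        assert res.converged

    def test_two_planted_groups_match_medoid_oracle(self):
        rng = np.random.default_rng(6)
        profiles, tiers = planted_profiles(rng, [0.1, 0.9], 10)
        d = sila_matrix(profiles)
        res = affinity_propagation(d, seed=0)
        assert res.converged
        assert res.n_clusters == 2
        oracle = two_medoid_oracle(d)
        # same partition up to relabelling
        agree = (res.labels == oracle).mean()
        assert agree in (0.0, 1.0)
        # and the partition recovers the planting
        assert len(set(zip(res.labels, tiers))) == 2

    def test_three_tiers_ordered_by_severe_fraction(self):
        rng = np.random.default_rng(7)
        profiles, tiers = planted_profiles(rng, [0.08, 0.45, 0.9], 12,
                                           spread=0.03)
        d = sila_matrix(profiles)
        res = affinity_propagation(d, seed=0)
        assert res.n_clusters == 3
        severe = np.array([p.fractions[:, 3].mean() for p in profiles])
        means = sorted(severe[res.labels == k].mean()
                       for k in range(res.n_clusters))
        assert means[0] < means[1] < means[2]

    def test_permutation_invariance_up_to_relabelling(self):
        rng = np.random.default_rng(8)
        profiles, _ = planted_profiles(rng, [0.15, 0.85], 6)
        d = sila_matrix(profiles)
        res = affinity_propagation(d, seed=0)
        perm = rng.permutation(len(profiles))
        res_p = affinity_propagation(d[np.ix_(perm, perm)], seed=0)
        # partitions must coincide after undoing the permutation
        lab1 = res.labels[perm]
        lab2 = res_p.labels
        mapping = {}
        for a, b in zip(lab2, lab1):
            mapping.setdefault(a, b)
            assert mapping[a] == b

    def test_cross_check_against_sklearn(self):
        from sklearn.cluster import AffinityPropagation

        rng = np.random.default_rng(9)
        profiles, _ = planted_profiles(rng, [0.1, 0.5, 0.9], 8)
        d = sila_matrix(profiles)
        res = affinity_propagation(d, damping=0.7, seed=0)
        sk = AffinityPropagation(affinity="precomputed", damping=0.7,
                                 max_iter=500, convergence_iter=50,
                                 random_state=0).fit(-d)
        assert res.n_clusters == len(sk.cluster_centers_indices_)
        mapping = {}
        for a, b in zip(res.labels, sk.labels_):
            mapping.setdefault(a, b)
            assert mapping[a] == b

    def test_bad_inputs_rejected(self):
        with pytest.raises(MalformedInputError):
            affinity_propagation(np.zeros((2, 3)))
        with pytest.raises(DomainError):
            affinity_propagation(np.zeros((3, 3)), damping=0.3)
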