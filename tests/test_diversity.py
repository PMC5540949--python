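"""Alpha/beta diversity, rarefaction curves, UPGMA, ordination, AMOVA/HOMOVA."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from ampliforge.diversity import (
    ALPHA_INDICES,
    BETA_MEASURES,
    DistanceMatrix,
    alpha_diversity,
    amova,
    beta_distance,
    homova,
    nmds,
    pcoa,
    rank_abundance,
    rarefaction_curve,
    upgma_tree,
)
from ampliforge.otu_inference import Otu, OtuTable


def make_table(counts):
    counts = np.asarray(counts)
    return OtuTable(
        samples=tuple(f"S{i+1}" for i in range(counts.shape[0])),
        otus=tuple(Otu(f"OTU_{j+1}", "ACGT", 0) for j in range(counts.shape[1])),
        counts=counts,
    )


def euclid_dm(points, labels=None):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    labels = labels or tuple(f"S{i+1}" for i in range(len(points)))
    return DistanceMatrix(labels=tuple(labels), d=d)


class TestAlpha:
    def test_shannon_uniform(self):
        assert alpha_diversity([10, 10, 10, 10], "shannon") == pytest.approx(np.log(4))

    def test_chao_hand_value(self):
        # Sobs=6, 3 singletons, 1 doubleton: 6 + 3*2/(2*2) = 7.5
        assert alpha_diversity([1, 1, 1, 2, 5, 9], "chao") == pytest.approx(7.5)

    def test_simpson_hand_value(self):
        assert alpha_diversity([5, 5], "simpson") == pytest.approx(40 / 90)

    def test_sobs_ignores_zeros(self):
        assert alpha_diversity([3, 0, 1], "sobs") == 2

    def test_jackknife_hand_value(self):
        # Sobs=3, n1=2, N=10: 3 + 2*9/10 = 4.8
        assert alpha_diversity([1, 1, 8], "jackknife") == pytest.approx(4.8)

    def test_single_otu_sample(self):
        assert alpha_diversity([7], "shannon") == 0.0
        assert alpha_diversity([7], "simpson") == 1.0
        assert alpha_diversity([7], "sobs") == 1.0
        assert alpha_diversity([7], "chao") == 1.0

    @pytest.mark.parametrize("index", ALPHA_INDICES)
    def test_all_indices_finite(self, index, rng):
        counts = rng.integers(0, 30, size=40)
        counts[0] = 1
        assert np.isfinite(alpha_diversity(counts, index))

    def test_unknown_index_rejected(self):
        with pytest.raises(ValueError):
            alpha_diversity([1, 2], "gini")


class TestRarefactionCurve:
    def test_endpoint_is_sobs_and_depth1_is_one(self):
        curve = rarefaction_curve([5, 3, 2], step=1, n_resamples=50, seed=0)
        depths = [d for d, _ in curve]
        values = dict(curve)
        assert values[10] == 3.0
        assert values[1] == 1.0

    def test_monotone_in_depth(self, rng):
        counts = rng.integers(0, 40, size=15) + 1
        curve = rarefaction_curve(counts, step=20, n_resamples=200, seed=1)
        vals = [v for _, v in curve]
        assert all(b >= a - 0.15 for a, b in zip(vals, vals[1:]))

    def test_hypergeometric_expectation_at_depth_2(self):
        # [50,50] at depth 2: E[sobs] = 2 - 2*C(50,2)/C(100,2) = 1 + 50/99
        curve = dict(rarefaction_curve([50, 50], step=2, n_resamples=10000, seed=3))
        expected = 1 + 50 / 99
        assert curve[2] == pytest.approx(expected, abs=3 * 0.5 / np.sqrt(10000))


class TestRankAbundance:
    def test_sorted_normalized(self):
        assert rank_abundance([10, 30, 60]) == [(1, 0.6), (2, 0.3), (3, 0.1)]

    def test_ties_stable_and_zeros_excluded(self):
        out = rank_abundance([20, 0, 20, 10])
        assert [r for r, _ in out] == [1, 2, 3]
        assert [a for _, a in out] == pytest.approx([0.4, 0.4, 0.2])


class TestBeta:
    def test_braycurtis_hand_value(self):
        dm = beta_distance(make_table([[2, 2, 0], [1, 3, 0]]), "braycurtis")
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_jclass_hand_value(self):
        dm = beta_distance(make_table([[1, 1, 1, 0], [0, 1, 1, 1]]), "jclass")
        assert dm.d[0, 1] == pytest.approx(0.5)

    def test_identical_samples_zero(self):
        for m in BETA_MEASURES:
            dm = beta_distance(make_table([[5, 3, 2], [5, 3, 2]]), m)
            assert dm.d[0, 1] == pytest.approx(0.0, abs=1e-12), m

    def test_disjoint_samples_one(self):
        t = make_table([[5, 5, 0, 0], [0, 0, 3, 7]])
        for m in ("jclass", "thetayc", "braycurtis"):
            assert beta_distance(t, m).d[0, 1] == pytest.approx(1.0), m

    @pytest.mark.parametrize("measure", BETA_MEASURES)
    def test_symmetry_range_diagonal(self, measure, rng):
        t = make_table(rng.integers(0, 20, size=(5, 12)) + (rng.random((5, 12)) < 0.5))
        dm = beta_distance(t, measure)
        assert np.allclose(dm.d, dm.d.T)
        assert np.allclose(np.diag(dm.d), 0)
        assert (dm.d >= -1e-12).all() and (dm.d <= 1 + 1e-12).all()


class TestUpgma:
    def test_three_leaf_hand_computed(self):
        d = np.array([[0, 0.2, 0.6], [0.2, 0, 0.6], [0.6, 0.6, 0]])
        tree = upgma_tree(DistanceMatrix(labels=("A", "B", "C"), d=d))
        tips = {t.name: t for t in tree.tips()}
        cherry = tree.lca([tips["A"], tips["B"]])
        assert {t.name for t in cherry.tips()} == {"A", "B"}
        assert tips["A"].length == pytest.approx(0.1)
        # root height 0.3: C hangs at 0.3, cherry node at 0.1 with branch 0.2
        assert tips["C"].length == pytest.approx(0.3)
        assert cherry.length == pytest.approx(0.2)

    def test_two_leaf_cherry(self):
        d = np.array([[0, 0.8], [0.8, 0]])
        tree = upgma_tree(DistanceMatrix(labels=("A", "B"), d=d))
        assert all(t.length == pytest.approx(0.4) for t in tree.tips())

    def test_ultrametric_input_reconstructed(self):
        # generating tree: ((A,B):h2,(C,D):h2) with A-B at 0.1, C-D at 0.2, across 0.6
        d = np.zeros((4, 4))
        pairs = {(0, 1): 0.1, (2, 3): 0.2}
        for i in range(4):
            for j in range(i + 1, 4):
                d[i, j] = d[j, i] = pairs.get((i, j), 0.6)
        tree = upgma_tree(DistanceMatrix(labels=("A", "B", "C", "D"), d=d))
        tips = {t.name: t for t in tree.tips()}
        for grp, h in ((("A", "B"), 0.05), (("C", "D"), 0.1)):
            node = tree.lca([tips[g] for g in grp])
            assert {t.name for t in node.tips()} == set(grp)
            assert tips[grp[0]].length == pytest.approx(h)
        # ultrametric: all root-to-tip distances equal
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        assert np.ptp(list(depths.values())) < 1e-12


class TestOrdination:
    def test_pcoa_recovers_line(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        dm = euclid_dm(x[:, None])
        res = pcoa(dm)
        axis1 = res.coordinates[:, 0]
        # axis 1 recovers the line up to sign/translation; other eigenvalues ~ 0
        r = np.corrcoef(axis1, x)[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-9)
        assert res.eigenvalues[0] > 0
        if res.eigenvalues.size > 1:
            assert res.eigenvalues[1:].max() < 1e-9

    def test_pcoa_preserves_euclidean_distances(self, rng):
        pts = rng.normal(size=(6, 3))
        dm = euclid_dm(pts)
        res = pcoa(dm)
        d_re = squareform(pdist(res.coordinates))
        assert np.allclose(d_re, dm.d, atol=1e-8)

    def test_pcoa_identical_samples_collapse(self):
        d = np.zeros((3, 3))
        d[0, 2] = d[2, 0] = d[1, 2] = d[2, 1] = 1.0
        res = pcoa(DistanceMatrix(labels=("A", "B", "C"), d=d))
        assert np.allclose(res.coordinates[0], res.coordinates[1], atol=1e-9)

    def test_nmds_low_stress_on_2d_structure(self, rng):
        pts = rng.normal(size=(10, 2))
        res = nmds(euclid_dm(pts), seed=4)
        assert res.stress < 0.05

    def test_nmds_deterministic_and_more_starts_no_worse(self, rng):
        pts = rng.normal(size=(8, 4))
        dm = euclid_dm(pts)
        r1 = nmds(dm, n_starts=1, seed=5)
        r1b = nmds(dm, n_starts=1, seed=5)
        assert np.allclose(r1.coordinates, r1b.coordinates)
        r8 = nmds(dm, n_starts=8, seed=5)
        assert r8.stress <= r1.stress + 1e-9

    def test_stress_rotation_invariant(self, rng):
        from ampliforge.diversity import kruskal_stress

        pts = rng.normal(size=(7, 2))
        dm = euclid_dm(pts)
        res = nmds(dm, seed=6)
        theta = 1.1
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        assert kruskal_stress(dm.d, res.coordinates @ R) == pytest.approx(
            res.stress, abs=1e-9
        )


class TestGroupTests:
    def _clouds(self, rng, n_per=4, sep=0.9, noise=0.05, k=2):
        pts = []
        groups = {}
        for g in range(k):
            center = np.zeros(3)
            center[0] = g * sep
            for i in range(n_per):
                pts.append(center + rng.normal(scale=noise, size=3))
                groups[f"S{g}_{i}"] = f"g{g}"
        labels = list(groups)
        return euclid_dm(np.array(pts), labels=labels), groups

    def test_amova_detects_separation(self, rng):
        dm, groups = self._clouds(rng, n_per=4, k=3)
        res = amova(dm, groups, n_perm=999, seed=0)
        assert res.p_value <= 0.01
        assert res.statistic > 10

    def test_amova_matches_permanova_statistic(self, rng):
        """Independent oracle: the pseudo-F equals scikit-bio's PERMANOVA."""
        from skbio import DistanceMatrix as SkDM
        from skbio.stats.distance import permanova

        dm, groups = self._clouds(rng, n_per=5, sep=0.3, noise=0.2, k=2)
        res = amova(dm, groups, n_perm=9, seed=0)
        sk = permanova(
            SkDM(dm.d, ids=dm.labels),
            grouping=[groups[l] for l in dm.labels],
            permutations=9,
        )
        assert res.statistic == pytest.approx(sk["test statistic"], rel=1e-9)

    def test_amova_null_calibration_small(self, rng):
        """Type-I error near nominal under random labels (small version)."""
        hits = 0
        n_rep = 50
        for rep in range(n_rep):
            pts = rng.normal(size=(8, 3))
            dm = euclid_dm(pts)
            labs = list(dm.labels)
            groups = {l: ("a" if i < 4 else "b") for i, l in enumerate(labs)}
            if amova(dm, groups, n_perm=199, seed=rep).p_value <= 0.05:
                hits += 1
        assert 0 <= hits / n_rep <= 0.14

    def test_homova_zero_when_dispersions_equal(self):
        # two groups with identical within-group distance structure
        d = np.zeros((4, 4))
        d[0, 1] = d[1, 0] = 0.2
        d[2, 3] = d[3, 2] = 0.2
        for i in (0, 1):
            for j in (2, 3):
                d[i, j] = d[j, i] = 0.9
        dm = DistanceMatrix(labels=("a1", "a2", "b1", "b2"), d=d)
        groups = {"a1": "a", "a2": "a", "b1": "b", "b2": "b"}
        assert homova(dm, groups, n_perm=99, seed=0).statistic == pytest.approx(0.0)

    def test_homova_detects_unequal_dispersion(self, rng):
        hits = 0
        n_rep = 30
        for rep in range(n_rep):
            r = np.random.default_rng(rep)
            pts = np.vstack(
                [r.normal(scale=0.05, size=(6, 3)), r.normal(scale=0.5, size=(6, 3))]
            )
            dm = euclid_dm(pts)
            groups = {l: ("a" if i < 6 else "b") for i, l in enumerate(dm.labels)}
            if homova(dm, groups, n_perm=199, seed=rep).p_value <= 0.05:
                hits += 1
        assert hits / n_rep >= 0.9

    def test_group_of_one_rejected(self, rng):
        dm = euclid_dm(rng.normal(size=(3, 2)))
        groups = dict(zip(dm.labels, ["a", "a", "b"]))
        with pytest.raises(ValueError):
            amova(dm, groups, n_perm=9)
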