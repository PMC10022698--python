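"""Neighbor joining, frequency PCA, and admixture EM."""

import itertools

import dendropy
import numpy as np
import pytest

from indelkit.genotype_model import FrequencyTable, LocusMeta
from indelkit.population_distance import DistanceMatrix
from indelkit.structure_inference import (
    AdmixtureFit,
    admixture_em,
    align_components,
    neighbor_joining,
    newick_string,
    pca_frequencies,
    write_newick,
)
from indelkit.synthetic_data import sample_admixed_population, sample_hwe_population


def random_additive_matrix(n_leaves: int, rng: np.random.Generator):
    """Pairwise distances of a random binary tree with random positive
    branch lengths — built by random agglomeration, independent of the NJ
    code under test."""
    labels = [f"t{i}" for i in range(n_leaves)]
    dm = np.zeros((n_leaves, n_leaves))
    # each active node: dict leaf_index -> distance to the node's junction
    nodes = [{i: 0.0} for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        la, lb = rng.uniform(0.1, 1.0, size=2)
        a, b = nodes[j], nodes[i]
        for x, dx in a.items():
            for y, dy in b.items():
                d = dx + la + dy + lb
                dm[x, y] = dm[y, x] = d
        merged = {x: dx + la for x, dx in a.items()}
        merged.update({y: dy + lb for y, dy in b.items()})
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(merged)
    return labels, dm


class TestNeighborJoining:
    def test_three_leaf_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        tree = neighbor_joining(dm)
        pend = {child.label: bl for child, bl in tree.root.children}
        assert pend == pytest.approx({"A": 0.5, "B": 1.5, "C": 2.5})
        assert newick_string(tree).endswith(";")

    def test_fewer_than_three_leaves_rejected(self):
        dm = DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float))
        with pytest.raises(ValueError, match=">= 3"):
            neighbor_joining(dm)

    def test_ultrametric_four_leaf_split(self):
        # ((A,B),(C,D)): within-pair distance 2, across 6
        ids = ["A", "B", "C", "D"]
        m = np.full((4, 4), 6.0)
        m[0, 1] = m[1, 0] = 2.0
        m[2, 3] = m[3, 2] = 2.0
        np.fill_diagonal(m, 0.0)
        tree = neighbor_joining(DistanceMatrix(ids, m))
        labels, pl = tree.path_lengths()
        idx = {l: i for i, l in enumerate(labels)}
        np.testing.assert_allclose(
            [[pl[idx[a], idx[b]] for b in ids] for a in ids], m, atol=1e-9)

    def test_exact_recovery_of_random_additive_matrices(self):
        """NJ reproduces the generating tree metric for 100 random trees
        with 4-10 leaves."""
        rng = np.random.default_rng(17)
        for rep in range(100):
            n = int(rng.integers(4, 11))
            labels, m = random_additive_matrix(n, rng)
            tree = neighbor_joining(DistanceMatrix(labels, m))
            got_labels, pl = tree.path_lengths()
            idx = {l: i for i, l in enumerate(got_labels)}
            perm = [idx[l] for l in labels]
            np.testing.assert_allclose(pl[np.ix_(perm, perm)], m, atol=1e-9)


class TestNewick:
    def test_round_trip_through_dendropy(self, tmp_path):
        rng = np.random.default_rng(3)
        labels, m = random_additive_matrix(6, rng)
        tree = neighbor_joining(DistanceMatrix(labels, m))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        dt = dendropy.Tree.get(path=str(path), schema="newick")
        assert sorted(t.label for t in dt.taxon_namespace) == sorted(labels)
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                j = labels.index(b)
                assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                    m[i, j], abs=1e-6)

    def test_metacharacter_labels_are_quoted(self):
        dm = DistanceMatrix(["X Y", "B", "C"],
                            np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
        s = newick_string(neighbor_joining(dm))
        assert "'X Y'" in s


def _table(rows, sizes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    k, L = rows.shape
    return FrequencyTable([f"p{i}" for i in range(k)],
                          [LocusMeta(f"l{j}") for j in range(L)],
                          rows, np.asarray(sizes or [100] * k))


class TestPca:
    def test_identical_populations_rejected_as_constant(self):
        with pytest.raises(ValueError, match="constant"):
            pca_frequencies(_table([[0.3, 0.7], [0.3, 0.7]]))

    def test_rank_one_gradient_loads_on_pc1(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.8, 20)
        direction = rng.normal(size=20) * 0.05
        rows = [np.clip(base + t * direction, 0, 1) for t in (-1.0, 0.0, 1.0)]
        res = pca_frequencies(_table(rows))
        assert res.explained_fraction[0] == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_identity_and_fraction_sum(self):
        rng = np.random.default_rng(8)
        table = _table(rng.uniform(0.05, 0.95, size=(6, 20)), [50] * 6)
        res = pca_frequencies(table)  # full rank = 5 components
        assert res.explained_fraction.shape == (5,)
        assert np.all(np.diff(res.explained_fraction) <= 1e-12)
        assert res.explained_fraction.sum() == pytest.approx(1.0, abs=1e-10)
        centered = table.freq - table.freq.mean(axis=0)
        recon = res.scores @ res.loadings.T
        np.testing.assert_allclose(recon, centered, atol=1e-10)

    def test_component_count_validation(self):
        rng = np.random.default_rng(1)
        table = _table(rng.uniform(0.1, 0.9, size=(4, 10)))
        with pytest.raises(ValueError, match="n_components"):
            pca_frequencies(table, n_components=4)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(2)
        table = _table(rng.uniform(0.1, 0.9, size=(5, 12)))
        a = pca_frequencies(table)
        b = pca_frequencies(table)
        np.testing.assert_array_equal(a.scores, b.scores)
        for c in range(a.loadings.shape[1]):
            assert a.loadings[np.argmax(np.abs(a.loadings[:, c])), c] > 0


def _two_pop_freqs(n_loci=40, delta=0.8, rng=None):
    rng = rng or np.random.default_rng(0)
    f1 = np.full(n_loci, (1 + delta) / 2)
    f2 = np.full(n_loci, (1 - delta) / 2)
    return np.vstack([f1, f2])


class TestAdmixtureEm:
    def test_k1_is_allele_frequency_mle(self):
        gm = sample_hwe_population(np.array([0.2, 0.5, 0.8]), 100, seed=6)
        fit = admixture_em(gm, 1, seed=0, n_restarts=1)
        np.testing.assert_allclose(fit.q, 1.0)
        np.testing.assert_allclose(
            fit.f[0], gm.dosage.mean(axis=0) / 2, atol=1e-6)

    def test_loglik_monotone_and_q_rows_normalized(self):
        f = _two_pop_freqs()
        q = np.vstack([np.tile([1.0, 0.0], (30, 1)),
                       np.tile([0.0, 1.0], (30, 1))])
        gm = sample_admixed_population(q, f, seed=5)
        fit = admixture_em(gm, 2, seed=3, n_restarts=2, max_iter=200)
        diffs = np.diff(fit.loglik_trace)
        assert np.all(diffs >= -1e-7)
        np.testing.assert_allclose(fit.q.sum(axis=1), 1.0, atol=1e-9)
        assert np.all((fit.f >= 1e-6) & (fit.f <= 1 - 1e-6))

    def test_unadmixed_two_population_recovery(self):
        # assignment certainty scales with panel information: 100 strongly
        # divergent loci make per-individual ancestry near-deterministic
        f = _two_pop_freqs(n_loci=100)
        q_true = np.vstack([np.tile([1.0, 0.0], (40, 1)),
                            np.tile([0.0, 1.0], (40, 1))])
        gm = sample_admixed_population(q_true, f, seed=11)
        fit = admixture_em(gm, 2, seed=2, n_restarts=3, max_iter=300)
        ref = AdmixtureFit(q_true, f, np.zeros(1), 2, 0, True)
        perm = align_components(ref, fit)
        assert fit.q[:, perm].max(axis=1).mean() > 0.95

    def test_half_admixed_recovery(self):
        rng = np.random.default_rng(4)
        f = np.vstack([rng.uniform(0.75, 0.95, 60),
                       rng.uniform(0.05, 0.25, 60)])
        q_true = np.vstack([
            np.tile([1.0, 0.0], (30, 1)),
            np.tile([0.0, 1.0], (30, 1)),
            np.tile([0.5, 0.5], (30, 1)),
        ])
        gm = sample_admixed_population(q_true, f, seed=12)
        fit = admixture_em(gm, 2, seed=5, n_restarts=3, max_iter=400)
        ref = AdmixtureFit(q_true, f, np.zeros(1), 2, 0, True)
        perm = align_components(ref, fit)
        assert np.abs(fit.q[:, perm] - q_true).mean() < 0.1

    def test_k_larger_than_sample_rejected(self):
        gm = sample_hwe_population(np.array([0.5]), 3, seed=0)
        with pytest.raises(ValueError, match="exceed"):
            admixture_em(gm, 4)


class TestAlignComponents:
    def _fit(self, q):
        return AdmixtureFit(np.asarray(q, float), np.zeros((q.shape[1], 1)),
                            np.zeros(1), q.shape[1], 0, True)

    def test_self_alignment_is_identity(self):
        rng = np.random.default_rng(9)
        q = rng.dirichlet(np.ones(3), size=40)
        fit = self._fit(q)
        np.testing.assert_array_equal(align_components(fit, fit), [0, 1, 2])

    def test_column_swap_recovered(self):
        rng = np.random.default_rng(10)
        q = rng.dirichlet(np.ones(3), size=40)
        perm = np.array([2, 0, 1])
        swapped = self._fit(q[:, perm])
        got = align_components(self._fit(q), swapped)
        np.testing.assert_allclose(q[:, perm][:, got], q, atol=1e-12)

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(11)
        k = 4
        qa = rng.dirichlet(np.ones(k), size=60)
        qb = rng.dirichlet(np.ones(k), size=60)
        fa, fb = self._fit(qa), self._fit(qb)
        got = align_components(fa, fb)

        def score(perm):
            return sum(np.corrcoef(qa[:, i], qb[:, perm[i]])[0, 1]
                       for i in range(k))

        best = max(itertools.permutations(range(k)), key=score)
        assert score(tuple(got)) == pytest.approx(score(best), abs=1e-12)

    def test_mismatched_k_rejected(self):
        qa = np.ones((5, 2)) / 2
        qb = np.ones((5, 3)) / 3
        with pytest.raises(ValueError, match="different K"):
            align_components(self._fit(qa), self._fit(qb))
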