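"""Family tools: clustering, star alignment, majority consensus,
neighbor joining and bootstrap support."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from skbio import TreeNode

from retrosite._seq import random_dna
from retrosite.families import (
    CopyAlignment,
    bootstrap_support,
    cluster_copies,
    majority_consensus,
    neighbor_joining,
    p_distance_matrix,
    pairwise_identity,
    star_align,
    tree_splits,
)
from retrosite.simulate import apply_divergence


class TestClustering:
    def test_two_diverged_families_separate_cleanly(self):
        """Copies from two consensi 25% apart (5% within-family noise)
        form exactly two clusters with no misassignment at cutoff
        0.85."""
        rng = np.random.default_rng(0)
        consA = random_dna(rng, 400)
        consB = apply_divergence(consA, 0.25, 0.0, 1)
        seqs, truth = [], []
        for i in range(40):
            src, fam = (consA, 0) if i % 2 == 0 else (consB, 1)
            seqs.append(apply_divergence(src, 0.05, 0.0, 100 + i))
            truth.append(fam)
        labels = cluster_copies(seqs, identity_cutoff=0.85)
        assert len(set(labels)) == 2
        mapping = {}
        for lab, t in zip(labels, truth):
            mapping.setdefault(lab, t)
            assert mapping[lab] == t

    def test_identical_copies_one_cluster(self):
        seqs = ["ACGTACGTAC" * 12] * 5
        assert len(set(cluster_copies(seqs, 0.9))) == 1

    def test_unit_cutoff_on_diverged_copies_gives_singletons(self):
        rng = np.random.default_rng(1)
        base = random_dna(rng, 300)
        seqs = [apply_divergence(base, 0.1, 0.0, i) for i in range(4)]
        assert len(set(cluster_copies(seqs, 1.0))) == 4

    def test_short_copies_are_flagged_singletons(self):
        seqs = ["ACGT" * 100, "ACGT" * 100, "ACGT" * 10]
        labels = cluster_copies(seqs, 0.9, min_overlap=100)
        assert labels[0] == labels[1]
        assert labels[2] != labels[0]

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        consA = random_dna(rng, 300)
        consB = apply_divergence(consA, 0.3, 0.0, 3)
        seqs = [apply_divergence(c, 0.04, 0.0, i) for i, c in enumerate([consA] * 4 + [consB] * 4)]
        labels = cluster_copies(seqs, 0.85)
        perm = [5, 2, 7, 0, 3, 6, 1, 4]
        labels_perm = cluster_copies([seqs[i] for i in perm], 0.85)
        # same partition up to relabelling
        pairs = {(i < 4) == (j < 4) for i, j in zip(range(8), range(8))}
        part1 = {frozenset(i for i in range(8) if labels[i] == l) for l in set(labels)}
        part2_named = {
            frozenset(perm[k] for k in range(8) if labels_perm[k] == l)
            for l in set(labels_perm)
        }
        assert part1 == part2_named


class TestStarAlignAndConsensus:
    def test_identical_copies_give_gapless_matrix(self):
        ref = "ACGTACGTACGTACGTACGT" * 3
        aln = star_align([ref, ref, ref], ref)
        assert all("-" not in row for row in aln.rows)
        assert majority_consensus(aln) == ref

    def test_single_insertion_creates_gap_block(self):
        rng = np.random.default_rng(3)
        ref = random_dna(rng, 120)
        withins = ref[:60] + "GGG" + ref[60:]
        aln = star_align([ref, withins, ref], ref)
        assert aln.n_columns == 123
        gap_cols = [i for i in range(123) if aln.rows[0][i] == "-"]
        assert len(gap_cols) == 3
        assert aln.rows[1].replace("-", "") == withins

    def test_two_of_three_majority(self):
        aln = CopyAlignment(["a", "b", "c"], ["ACGT", "ACGA", "ACGT"])
        assert majority_consensus(aln) == "ACGT"

    def test_gap_majority_column_dropped(self):
        aln = CopyAlignment(["a", "b", "c", "d"], ["A-CT", "A-CT", "AGCT", "A-CT"])
        assert majority_consensus(aln) == "ACT"

    def test_consensus_recovers_ancestor_from_diverged_copies(self):
        """20 copies at 10% divergence: the majority consensus matches
        the true ancestor at >= 99% identity."""
        rng = np.random.default_rng(4)
        truth = random_dna(rng, 800)
        copies = [apply_divergence(truth, 0.10, 0.0, 500 + i) for i in range(20)]
        aln = star_align(copies, copies[0])
        cons = majority_consensus(aln)
        ident, cols = pairwise_identity(cons, truth)
        assert cols >= 790
        assert ident >= 0.99

    def test_consensus_idempotence(self):
        rng = np.random.default_rng(5)
        seq = random_dna(rng, 200)
        aln = CopyAlignment([f"r{i}" for i in range(5)], [seq] * 5)
        c1 = majority_consensus(aln)
        aln2 = CopyAlignment(["a", "b"], [c1, c1])
        assert majority_consensus(aln2) == c1


def _tip_distances(tree: TreeNode, labels):
    dm = tree.tip_tip_distances(endpoints=list(labels))
    return {frozenset((a, b)): dm[a, b] for a in labels for b in labels if a != b}


class TestNeighborJoining:
    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):1,(C:3,D:1)) gives this additive matrix
        labels = ["A", "B", "C", "D"]
        mat = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        tree = neighbor_joining(labels, mat)
        assert tree_splits(tree) == {frozenset({"A", "B"})}
        d = _tip_distances(tree, labels)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    assert d[frozenset((a, b))] == pytest.approx(mat[i, j], abs=1e-9)

    def test_three_taxa_closed_form(self):
        labels = ["A", "B", "C"]
        mat = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = neighbor_joining(labels, mat)
        d = _tip_distances(tree, labels)
        assert d[frozenset(("A", "B"))] == pytest.approx(2, abs=1e-9)
        assert d[frozenset(("A", "C"))] == pytest.approx(3, abs=1e-9)
        assert d[frozenset(("B", "C"))] == pytest.approx(3, abs=1e-9)

    def test_negative_branch_lengths_clamped(self):
        labels = ["A", "B", "C", "D"]
        mat = np.array(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]], dtype=float
        )
        tree = neighbor_joining(labels, mat)
        for node in tree.traverse():
            assert node.length is None or node.length >= 0


class TestBootstrap:
    def test_separated_families_get_high_support(self):
        """Two clearly separated simulated families: the family split is
        supported in >= 95 of 100 replicates."""
        rng = np.random.default_rng(6)
        ancA = random_dna(rng, 600)
        ancB = apply_divergence(ancA, 0.3, 0.0, 7)
        rows, ids = [], []
        for i in range(3):
            rows.append(apply_divergence(ancA, 0.03, 0.0, 10 + i))
            ids.append(f"A{i}")
        for i in range(3):
            rows.append(apply_divergence(ancB, 0.03, 0.0, 20 + i))
            ids.append(f"B{i}")
        aln = CopyAlignment(ids, rows)
        tree, support = bootstrap_support(aln, n_reps=100, seed=8)
        family_split = min(
            frozenset({"A0", "A1", "A2"}),
            frozenset({"B0", "B1", "B2"}),
            key=lambda s: tuple(sorted(s)),
        )
        assert support[family_split] >= 95
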