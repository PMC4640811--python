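"""Synthetic-genome generator: layout, divergence, insertion geometry,
truth bookkeeping and reversibility."""

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retrosite._seq import random_dna
from retrosite.models import CleavageGeometry, TargetGeneModel
from retrosite.simulate import (
    FamilySpec,
    apply_divergence,
    build_target_arrays,
    insert_elements,
    reverse_edits,
)


def _model(rng, length=190):
    return TargetGeneModel("t", random_dna(rng, length))


class TestBuildTargetArrays:
    def test_single_array_layout_arithmetic(self, rng):
        model = _model(rng)
        genome, loci = build_target_arrays(model, 1, 3, spacer_len_dist=200, seed=1)
        (contig,) = genome
        assert len(genome[contig]) == 3 * 190 + 2 * 200
        assert [(l.start, l.end) for l in loci] == [(0, 190), (390, 580), (780, 970)]

    def test_single_gene_contig(self, rng):
        model = _model(rng)
        genome, loci = build_target_arrays(model, 1, 1, seed=2)
        (contig,) = genome
        assert genome[contig] == model.sequence
        assert loci[0].as_1based() == (1, 190)

    def test_loci_reextract_exactly(self, rng):
        """Spacer divergence applies only to spacers: every emitted locus
        re-extracts at 100% identity (exact string search oracle)."""
        model = _model(rng)
        genome, loci = build_target_arrays(
            model, 2, 5, spacer_len_dist=(150, 250), spacer_divergence=0.3, seed=7
        )
        for l in loci:
            assert genome[l.contig][l.start : l.end] == model.sequence
        total = sum(genome[c].count(model.sequence) for c in genome)
        assert total == len(loci)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError):
            TargetGeneModel("bad", "")


class TestApplyDivergence:
    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=200), st.integers(0, 100))
    def test_zero_rates_identity(self, seq, seed):
        assert apply_divergence(seq, 0.0, 0.0, seed) == seq

    def test_substitution_rate_within_binomial_band(self):
        seq = "ACGT" * 2500
        mutated = apply_divergence(seq, 0.10, 0.0, 3)
        assert len(mutated) == len(seq)
        hamming = sum(1 for a, b in zip(seq, mutated) if a != b)
        # 99% binomial interval for n=10000, p=0.1
        assert 0.08 <= hamming / 10000 <= 0.12

    def test_indels_only_no_substitution_columns(self):
        # sparse indels: a minimum-edit alignment then shows pure I/D ops
        # (at high density an adjacent I+D pair would be rewritten as a
        # cheaper substitution by the oracle, so sparsity matters here)
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 2000)
        mutated = apply_divergence(seq, 0.0, 0.005, 11)
        assert len(mutated) != len(seq) or mutated != seq
        res = edlib.align(seq, mutated, mode="NW", task="path")
        assert "X" not in res["cigar"]

    def test_deterministic_under_seed(self):
        seq = "ACGT" * 100
        assert apply_divergence(seq, 0.2, 0.05, 42) == apply_divergence(seq, 0.2, 0.05, 42)


def _insert_one(rng, top_offset, **kw):
    model = _model(rng)
    genome, loci = build_target_arrays(model, 1, 1, seed=1)
    # pad the contig so flanks exist around the single gene
    pad5, pad3 = random_dna(rng, 100), random_dna(rng, 100)
    contig = next(iter(genome))
    genome = {contig: pad5 + genome[contig] + pad3}
    for l in loci:
        l.start += 100
        l.end += 100
    spec = FamilySpec(
        "f", random_dna(rng, 400), CleavageGeometry(38, top_offset), n_copies=1, **kw
    )
    mutated, truths = insert_elements(genome, loci, [spec], model, seed=5)
    return model, genome[contig], mutated[contig], truths[0], spec


class TestInsertElements:
    def test_tsd_duplicates_twenty_bases(self, rng):
        model, orig, mut, t, spec = _insert_one(rng, +20)
        assert t.tsd_len == 20 and t.deletion_len == 0
        left = mut[t.start - 20 : t.start]
        right = mut[t.end : t.end + 20]
        assert left == right == model.sequence[38:58]
        assert mut[t.start : t.end] == spec.consensus

    def test_blunt_is_pure_concatenation(self, rng):
        model, orig, mut, t, spec = _insert_one(rng, 0)
        assert t.tsd_len == 0 and t.deletion_len == 0
        assert mut == orig[: t.start] + spec.consensus + orig[t.start :]
        # upstream ends with target nt 38, downstream begins at nt 39
        assert mut[t.start - 38 : t.start] == model.sequence[:38]
        assert mut[t.end : t.end + 30] == model.sequence[38:68]

    def test_deletion_removes_target_5prime(self, rng):
        model, orig, mut, t, spec = _insert_one(rng, -38)
        assert t.deletion_len == 38 and t.tsd_len == 0
        assert mut[t.end : t.end + 30] == model.sequence[38:68]
        # the first 38 target bases are gone from the locus
        assert model.sequence[:38] not in mut

    def test_oversized_deletion_rejected(self, rng):
        with pytest.raises(ValueError):
            _insert_one(rng, -39)

    def test_truth_exclusivity_and_on_target_positions(self, rng):
        model = _model(rng)
        genome, loci = build_target_arrays(model, 2, 10, seed=3)
        spec = FamilySpec(
            "f",
            random_dna(rng, 500),
            CleavageGeometry(38, 20),
            n_copies=12,
            divergence=0.05,
            truncation_prob=0.4,
        )
        mutated, truths = insert_elements(genome, loci, [spec], model, seed=8)
        assert len(truths) == 12
        for t in truths:
            assert not (t.tsd_len > 0 and t.deletion_len > 0)
            assert t.on_target and t.locus_index is not None

    def test_fixed_seed_byte_identical(self, rng):
        model = _model(rng)
        genome, loci = build_target_arrays(model, 1, 6, seed=4)
        spec = FamilySpec(
            "f",
            random_dna(rng, 300),
            CleavageGeometry(38, 0),
            n_copies=4,
            divergence=0.1,
            indel_rate=0.01,
        )
        m1, t1 = insert_elements(genome, loci, [spec], model, seed=77)
        m2, t2 = insert_elements(genome, loci, [spec], model, seed=77)
        assert m1 == m2
        assert [(t.start, t.end, t.tsd_len) for t in t1] == [
            (t.start, t.end, t.tsd_len) for t in t2
        ]


class TestRoundTrip:
    @pytest.mark.parametrize("config_seed", range(100))
    def test_reverse_edits_restores_original(self, config_seed):
        """Removing every recorded edit (block + duplicated bases,
        restoring deleted bases) reconstructs the pre-insertion genome
        exactly, across random configurations including truncation,
        divergence, off-target and nested insertions."""
        rng = np.random.default_rng(1_000_000 + config_seed)
        model = TargetGeneModel("t", random_dna(rng, 190))
        genome, loci = build_target_arrays(
            model,
            int(rng.integers(1, 3)),
            int(rng.integers(2, 6)),
            spacer_len_dist=(80, 160),
            seed=int(rng.integers(0, 2**31)),
        )
        top_offset = int(rng.choice([20, 0, -38, 7, -5]))
        spec = FamilySpec(
            "f",
            random_dna(rng, int(rng.integers(200, 500))),
            CleavageGeometry(38, top_offset),
            n_copies=int(rng.integers(1, 5)),
            truncation_prob=float(rng.random() * 0.5),
            divergence=float(rng.random() * 0.1),
            indel_rate=float(rng.random() * 0.02),
            off_target_rate=float(rng.random() * 0.4),
            nesting_rate=float(rng.random() * 0.4),
        )
        mutated, truths = insert_elements(
            genome, loci, [spec], model, seed=int(rng.integers(0, 2**31))
        )
        assert reverse_edits(mutated, truths) == genome
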