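"""Junction flanks: extraction conventions, classification, TSD and
target-deletion inference."""

import numpy as np
import pytest

from retrosite._seq import random_dna, revcomp
from retrosite.detect import CopyHit, ElementFamily, detect_copies
from retrosite.junctions import (
    TARGET_GENE,
    UNSEQUENCED,
    InsertionCall,
    JunctionParams,
    analyze_junctions,
    classify_flank,
    extract_flanks,
    infer_tsd_and_deletion,
)
from retrosite.models import CleavageGeometry, TargetGeneModel
from retrosite.simulate import FamilySpec, build_target_arrays, insert_elements
from tests.conftest import DIAGNOSTIC_21MER


def _copy(contig, start, end, strand="+", qstart=0, qend=0, clen=0):
    return CopyHit(
        family="fam",
        contig=contig,
        start=start,
        end=end,
        strand=strand,
        score=0,
        identity=1.0,
        qstart=qstart,
        qend=qend or clen,
        has_intact_3prime=True,
        truncated_5prime_by=qstart,
        consensus_len=clen,
    )


class TestExtractFlanks:
    def test_plus_strand_flanks_are_literal_substrings(self):
        rng = np.random.default_rng(0)
        g = random_dna(rng, 500)
        j5, j3 = extract_flanks(_copy("seq", 200, 300), g, flank_len=60)
        assert j5.seq == g[140:200]
        assert j3.seq == g[300:360]

    def test_minus_strand_flanks_reverse_complemented(self):
        rng = np.random.default_rng(1)
        g = random_dna(rng, 500)
        j5, j3 = extract_flanks(_copy("seq", 200, 300, strand="-"), g, flank_len=60)
        assert j5.seq == revcomp(g[300:360])
        assert j3.seq == revcomp(g[140:200])

    def test_contig_end_clamps_flank(self):
        rng = np.random.default_rng(2)
        g = random_dna(rng, 310)
        j5, j3 = extract_flanks(_copy("seq", 200, 300), g, flank_len=60)
        assert len(j3.seq) == 10

    def test_empty_and_n_rich_flanks_flagged_unsequenced(self):
        g = "A" * 100 + "N" * 20 + "C" * 100
        j5, j3 = extract_flanks(_copy("seq", 100, 120), "ACGT" * 30 + g, flank_len=60)
        # construct directly: copy at contig start has an empty 5' flank
        j5b, _ = extract_flanks(_copy("seq", 0, 50), g, flank_len=60)
        assert j5b.classification == UNSEQUENCED


class TestClassifyFlank:
    def test_diagnostic_target_fragment_places_at_position_39(self, target_model):
        """The 21-mer target fragment seen downstream of an element maps
        with its start at model position 39."""
        j5, _ = extract_flanks(
            _copy("seq", 100, 200), "A" * 79 + DIAGNOSTIC_21MER + "C" * 200
        )
        junction = classify_flank(j5, target_model, [])
        assert junction.classification == TARGET_GENE
        assert junction.target_start == 39
        assert junction.target_end == 59

    def test_random_flank_is_other(self, rng, target_model):
        j = classify_flank(
            __import__("retrosite.junctions", fromlist=["Junction"]).Junction(
                "3p", random_dna(rng, 60)
            ),
            target_model,
            [],
        )
        assert j.classification == "other"

    def test_element_flank_classified_with_family_name(self, rng, target_model):
        cons = random_dna(rng, 500)
        from retrosite.junctions import Junction

        j = classify_flank(
            Junction("3p", cons[10:70]), target_model, [ElementFamily("famX", cons)]
        )
        assert j.classification == "element:famX"


def _simulated_call(rng, top_offset, seed=5):
    model = TargetGeneModel("t", random_dna(rng, 190))
    genome, loci = build_target_arrays(model, 1, 3, (200, 250), seed=seed)
    # pad so even the first gene has an upstream flank
    contig = next(iter(genome))
    genome = {contig: random_dna(rng, 100) + genome[contig]}
    for l in loci:
        l.start += 100
        l.end += 100
    cons = random_dna(rng, 600)
    spec = FamilySpec("fam", cons, CleavageGeometry(38, top_offset), n_copies=1)
    mutated, truths = insert_elements(genome, loci, [spec], model, seed=seed)
    fam = ElementFamily("fam", cons)
    copies = detect_copies([fam], mutated)
    assert len(copies) == 1
    calls = analyze_junctions(copies, mutated, model, [fam])
    return calls[0], truths[0], model


class TestInferTsdAndDeletion:
    def test_reptile_type_twenty_bp_tsd(self, rng):
        call, truth, _ = _simulated_call(rng, +20)
        assert call.tsd_len == 20
        assert call.deletion_len == 0
        assert call.inferred_geometry.top_offset == 20

    def test_arthropod_type_blunt(self, rng):
        call, truth, _ = _simulated_call(rng, 0)
        assert call.tsd_len == 0
        assert call.deletion_len == 0
        assert call.inferred_geometry.top_offset == 0

    def test_oomycete_type_deletion_of_38(self, rng):
        call, truth, _ = _simulated_call(rng, -38)
        assert call.deletion_len == 38
        assert call.tsd_len == 0
        assert call.inferred_geometry.top_offset == -38
        assert call.junction_3p.target_start == 39

    def test_tsd_bounded_by_tsd_max(self, rng):
        call, _, model = _simulated_call(rng, +20)
        params = JunctionParams(tsd_max=10)
        infer_tsd_and_deletion(call, model, params)
        assert call.tsd_len <= 10

    def test_tsd_symmetric_under_locus_reverse_complement(self, rng):
        """Reverse-complementing the whole locus leaves the inferred TSD
        unchanged (the copy is then detected on the minus strand)."""
        model = TargetGeneModel("t", random_dna(rng, 190))
        genome, loci = build_target_arrays(model, 1, 3, (200, 250), seed=12)
        cons = random_dna(rng, 600)
        spec = FamilySpec("fam", cons, CleavageGeometry(38, 20), n_copies=1)
        mutated, _ = insert_elements(genome, loci, [spec], model, seed=12)
        fam = ElementFamily("fam", cons)
        for g in (mutated, {c: revcomp(s) for c, s in mutated.items()}):
            copies = detect_copies([fam], g)
            call = analyze_junctions(copies, g, model, [fam])[0]
            assert call.tsd_len == 20

    def test_unsequenced_flank_blocks_geometry(self, rng, target_model):
        from retrosite.junctions import Junction

        call = InsertionCall(
            _copy("seq", 100, 200),
            Junction("5p", "", classification=UNSEQUENCED),
            Junction("3p", target_model.sequence[38:98]),
        )
        infer_tsd_and_deletion(call, target_model)
        assert call.inferred_geometry is None
        assert call.geometry_warning == "unsequenced flank"
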