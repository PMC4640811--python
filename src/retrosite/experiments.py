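"""Parameter-recovery experiments: simulate a genome under a known
cleavage geometry, run the full analysis, and summarise what the
pipeline inferred.

These drive the package's validation: under the reptile-type geometry
(top-strand cut 20 nt downstream of the bottom cut) the pipeline must
read back 20-bp TSDs; under the arthropod-type blunt geometry, no TSD;
under the oomycete-type geometry (top cut 38 nt upstream), disrupted
target loci missing their 5'-terminal 38 nt, with the downstream target
fragment starting at model position 39.

Default problem size: ~220 target genes in 11 tandem arrays plus a
700-kb random background contig (~1.1 Mb mutated genome), 200 on-target
full-length insertions of a 1.5-kb element at 5% substitution
divergence.  These sizes keep a full three-geometry recovery run within
a few minutes on one CPU while leaving enough copies for stable modal
statistics.  5'-truncation is off by default here (it is a detection
concern, exercised by the anchor-scan and sensitivity tests): the exact
boundary of a truncated copy is ambiguous by one or two bases whenever
the flanking target happens to match the consensus at the truncation
point, which blurs per-call geometry exactness without changing the
modal answer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import random_dna
from .census import CensusParams, InventoryRecord, census_target_genes
from .detect import DetectionParams, ElementFamily, detect_copies
from .junctions import TARGET_GENE, InsertionCall, JunctionParams, analyze_junctions
from .models import CleavageGeometry, TargetGeneModel
from .simulate import FamilySpec, InsertionTruth, build_target_arrays, insert_elements

REPTILE_TOP_OFFSET = 20
ARTHROPOD_TOP_OFFSET = 0
OOMYCETE_TOP_OFFSET = -38


@dataclass
class ExperimentResult:
    model: TargetGeneModel
    family: ElementFamily
    genome: dict[str, str]
    truths: list[InsertionTruth]
    n_gene_loci: int
    calls: list[InsertionCall]
    census: list[InventoryRecord]

    # --- junction summaries -------------------------------------------------
    def geometry_calls(self) -> list[InsertionCall]:
        """Calls with an inferred geometry from an intact, sequenced 3'
        terminus."""
        return [
            c
            for c in self.calls
            if c.copy.has_intact_3prime and c.inferred_geometry is not None
        ]

    def modal_tsd_len(self) -> int:
        counts = Counter(c.tsd_len for c in self.geometry_calls())
        return counts.most_common(1)[0][0]

    def modal_deletion_len(self) -> int:
        counts = Counter(c.deletion_len for c in self.geometry_calls())
        return counts.most_common(1)[0][0]

    def tsd_exact_fraction(self, expected_top_offset: int) -> float:
        calls = self.geometry_calls()
        ok = sum(1 for c in calls if c.top_offset == expected_top_offset)
        return ok / len(calls) if calls else 0.0

    def modal_target_start_3p(self) -> int:
        starts = [
            c.junction_3p.target_start
            for c in self.calls
            if c.junction_3p.classification == TARGET_GENE
            and c.junction_3p.target_start is not None
        ]
        return Counter(starts).most_common(1)[0][0]

    def target_start_exact_fraction(self, expected: int) -> float:
        starts = [
            c.junction_3p.target_start
            for c in self.calls
            if c.junction_3p.classification == TARGET_GENE
            and c.junction_3p.target_start is not None
        ]
        ok = sum(1 for s in starts if s == expected)
        return ok / len(starts) if starts else 0.0

    # --- census summaries ---------------------------------------------------
    def disrupted_missing(self) -> list[int]:
        return [r.missing_5prime for r in self.census if r.status == "disrupted"]

    def modal_missing_5prime(self) -> int:
        return Counter(self.disrupted_missing()).most_common(1)[0][0]

    def missing_exact_fraction(self, expected: int) -> float:
        vals = self.disrupted_missing()
        ok = sum(1 for v in vals if v == expected)
        return ok / len(vals) if vals else 0.0


def geometry_recovery_experiment(
    top_offset: int,
    seed: int,
    n_insertions: int = 200,
    divergence: float = 0.05,
    indel_rate: float = 0.001,
    truncation_prob: float = 0.0,
    element_len: int = 1500,
    target_len: int = 190,
    n_arrays: int = 11,
    genes_per_array: int = 20,
    background_len: int = 700_000,
    off_target_rate: float = 0.0,
    nesting_rate: float = 0.0,
    detection: DetectionParams | None = None,
    junction: JunctionParams | None = None,
    census: CensusParams | None = None,
) -> ExperimentResult:
    """Simulate insertions under one cleavage geometry and analyse them.

    All randomness derives from *seed*; the same seed gives a
    byte-identical genome, truth list and analysis.
    """
    rng = np.random.default_rng(seed)
    model = TargetGeneModel("target", random_dna(rng, target_len))
    consensus = random_dna(rng, element_len)
    genome, loci = build_target_arrays(
        model,
        n_arrays=n_arrays,
        genes_per_array=genes_per_array,
        spacer_len_dist=(200, 300),
        spacer_divergence=0.25,
        seed=int(rng.integers(0, 2**31)),
    )
    if background_len > 0:
        genome["background"] = random_dna(rng, background_len)
    spec = FamilySpec(
        name="fam1",
        consensus=consensus,
        geometry=CleavageGeometry(model.insertion_site, top_offset),
        n_copies=n_insertions,
        truncation_prob=truncation_prob,
        divergence=divergence,
        indel_rate=indel_rate,
        off_target_rate=off_target_rate,
        nesting_rate=nesting_rate,
    )
    mutated, truths = insert_elements(
        genome, loci, [spec], model, seed=int(rng.integers(0, 2**31))
    )
    family = ElementFamily("fam1", consensus)
    det = detection or DetectionParams()
    copies = detect_copies([family], mutated, det)
    calls = analyze_junctions(
        copies, mutated, model, [family], junction or JunctionParams()
    )
    records = census_target_genes(mutated, model, copies, census or CensusParams())
    return ExperimentResult(
        model=model,
        family=family,
        genome=mutated,
        truths=truths,
        n_gene_loci=len(loci),
        calls=calls,
        census=records,
    )
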