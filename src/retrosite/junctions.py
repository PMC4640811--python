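"""Junction flanks: extraction, classification and cleavage-geometry
inference.

For every detected copy the two flanking sequences (element-sense 5' and
3') are extracted and classified as target gene, another element, other,
or unsequenced.  Geometry is then inferred per copy:

* the target site duplication is the longest common block ending the 5'
  flank and starting the 3' flank (sequence evidence);
* when both flanks align to the target model, the gap between the model
  coordinate where the 5'-flank match ends and where the 3'-flank match
  begins gives the target deletion length directly — a negative gap is a
  duplication and is re-reported as a TSD;
* when only the 3' flank maps to the target (starting at model position
  s > 1) and the 5' flank is non-target with no sequence TSD, the
  target's first s-1 bases are absent at the locus and are reported as a
  deletion — the inference used for 5'-target-deleting families, whose
  upstream target fragment is simply missing.

The inferred ``top_offset`` (TSD length, 0, or minus the deletion
length) is directly comparable with the generator's cleavage geometry.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from ._seq import revcomp
from .align import DEFAULT_SCORING, LocalHit, ScoringScheme, best_local_hit
from .detect import CopyHit, ElementFamily
from .models import CleavageGeometry, TargetGeneModel

TARGET_GENE = "target_gene"
OTHER = "other"
UNSEQUENCED = "unsequenced"

_N_RUN = re.compile(r"N{5,}")


@dataclass
class JunctionParams:
    """Flank classification and TSD-inference parameters.

    The default profile (identity 0.85 over >= 15 matches) is the strict
    profile used for clean target-gene fragments.  ``weak_specificity()``
    relaxes it to 0.75 / 12 so that the short degenerate target fragments
    seen at the junctions of weakly specific families still score as
    target-like.
    """

    flank_len: int = 60
    id_threshold: float = 0.85
    min_match: int = 15
    tsd_max: int = 30
    # Minimum length for a TSD called on sequence evidence alone: a
    # 1-base terminal identity occurs at 25% of junctions by chance, so
    # short blocks only count when corroborated by target mapping.
    tsd_min_seq: int = 4
    tsd_mismatch_tol: int = 0
    # A copy whose alignment leaves a few consensus 5' bases unaligned
    # almost surely has diverged element bases sitting just outside the
    # alignment (genuine truncations are far larger); up to this many
    # genome bases at the 5' boundary are treated as element, not flank.
    boundary_slack: int = 10
    n_run: int = 5
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    @classmethod
    def weak_specificity(cls) -> "JunctionParams":
        return cls(id_threshold=0.75, min_match=12)


@dataclass
class Junction:
    """One element-terminus flank.

    ``target_start``/``target_end`` are 1-based model coordinates aligned
    to the first/last aligned base of the flank *in flank orientation*
    (set only for target_gene classifications).
    """

    side: str  # "5p" | "3p", element sense
    seq: str
    classification: str | None = None
    target_start: int | None = None
    target_end: int | None = None
    match_identity: float | None = None
    match_strand: str | None = None
    match_score: int = 0

    @property
    def unsequenced(self) -> bool:
        return self.classification == UNSEQUENCED


@dataclass
class InsertionCall:
    """A detected copy with classified junctions and inferred geometry."""

    copy: CopyHit
    junction_5p: Junction
    junction_3p: Junction
    tsd_len: int = 0
    deletion_len: int = 0
    inferred_geometry: CleavageGeometry | None = None
    geometry_warning: str | None = None

    @property
    def top_offset(self) -> int | None:
        return self.inferred_geometry.top_offset if self.inferred_geometry else None


def _flag_unsequenced(j: Junction, n_run: int) -> None:
    if not j.seq or re.search("N{%d,}" % n_run, j.seq):
        j.classification = UNSEQUENCED


def extract_flanks(
    copy: CopyHit,
    genome: dict[str, str] | str,
    flank_len: int = 60,
    n_run: int = 5,
    boundary_slack: int = 10,
) -> tuple[Junction, Junction]:
    """Extract the element-sense 5' and 3' flanks of a copy.

    Minus-strand copies are reverse-complemented so both flanks read in
    element sense; flanks are clamped at contig ends and flagged
    unsequenced when empty or containing an N run of ``n_run`` or more.
    When a small 5' remainder of the consensus (<= ``boundary_slack``)
    is unaligned, that many genome bases at the 5' boundary are assumed
    to be diverged element sequence and excluded from the 5' flank.
    """
    if isinstance(genome, str):
        genome = {"seq": genome}
    seq = genome[copy.contig]
    if not 0 <= copy.start <= copy.end <= len(seq):
        raise ValueError("copy interval outside contig bounds")
    pad = copy.qstart if 0 < copy.qstart <= boundary_slack else 0
    if copy.strand == "+":
        eff_start = max(0, copy.start - pad)
        upstream = seq[max(0, eff_start - flank_len) : eff_start]
        downstream = seq[copy.end : copy.end + flank_len]
    else:
        eff_end = min(len(seq), copy.end + pad)
        upstream = seq[max(0, copy.start - flank_len) : copy.start]
        downstream = seq[eff_end : eff_end + flank_len]
    if copy.strand == "+":
        j5 = Junction("5p", upstream)
        j3 = Junction("3p", downstream)
    else:
        j5 = Junction("5p", revcomp(downstream))
        j3 = Junction("3p", revcomp(upstream))
    _flag_unsequenced(j5, n_run)
    _flag_unsequenced(j3, n_run)
    return j5, j3


def classify_flank(
    junction: Junction,
    target_model: TargetGeneModel,
    families: list[ElementFamily],
    params: JunctionParams | None = None,
) -> Junction:
    """Classify a flank as target gene, element:<family>, or other.

    The flank is aligned (both strands) against the target model and
    against every family consensus.  A classification requires identity
    >= ``id_threshold`` with >= ``min_match`` matching bases; the target
    gene takes precedence over elements on score ties.  Unsequenced
    flanks are never reclassified.
    """
    params = params or JunctionParams()
    if junction.unsequenced:
        return junction
    t_hit = best_local_hit(junction.seq, target_model.sequence, params.scoring)
    e_best: LocalHit | None = None
    e_name = None
    for fam in families:
        h = best_local_hit(junction.seq, fam.consensus, params.scoring)
        if e_best is None or h.score > e_best.score:
            e_best = h
            e_name = fam.name

    def passes(h: LocalHit) -> bool:
        return (
            h.n_matches >= params.min_match and h.identity >= params.id_threshold
        )

    t_ok = passes(t_hit)
    e_ok = e_best is not None and passes(e_best)
    if t_ok and (not e_ok or t_hit.score >= e_best.score):
        junction.classification = TARGET_GENE
        if t_hit.strand == "+":
            junction.target_start = t_hit.subject_start + 1
            junction.target_end = t_hit.subject_end
        else:
            junction.target_start = t_hit.subject_end
            junction.target_end = t_hit.subject_start + 1
        junction.match_identity = t_hit.identity
        junction.match_strand = t_hit.strand
        junction.match_score = t_hit.score
    elif e_ok:
        junction.classification = f"element:{e_name}"
        junction.match_identity = e_best.identity
        junction.match_strand = e_best.strand
        junction.match_score = e_best.score
    else:
        junction.classification = OTHER
        junction.match_identity = max(t_hit.identity, 0.0)
        junction.match_score = t_hit.score
    return junction


def _sequence_tsd(f5: str, f3: str, tsd_max: int, mismatch_tol: int) -> int:
    """Longest block (<= tsd_max) that both ends the 5' flank and starts
    the 3' flank, allowing up to ``mismatch_tol`` mismatches."""
    best = 0
    kmax = min(tsd_max, len(f5), len(f3))
    for k in range(1, kmax + 1):
        mm = sum(1 for x, y in zip(f5[-k:], f3[:k]) if x != y or x == "N")
        if mm <= mismatch_tol:
            best = k
    return best


def infer_tsd_and_deletion(
    call: InsertionCall,
    target_model: TargetGeneModel,
    params: JunctionParams | None = None,
) -> InsertionCall:
    """Infer TSD length, target deletion length and cleavage geometry for
    one call (both flanks must be extracted and classified)."""
    params = params or JunctionParams()
    j5, j3 = call.junction_5p, call.junction_3p
    call.tsd_len = 0
    call.deletion_len = 0
    call.inferred_geometry = None
    call.geometry_warning = None
    if j5.unsequenced or j3.unsequenced:
        call.geometry_warning = "unsequenced flank"
        return call
    seq_tsd = _sequence_tsd(j5.seq, j3.seq, params.tsd_max, params.tsd_mismatch_tol)
    if seq_tsd < params.tsd_min_seq:
        seq_tsd = 0
    both_target = (
        j5.classification == TARGET_GENE
        and j3.classification == TARGET_GENE
        and j5.match_strand == "+"
        and j3.match_strand == "+"
    )
    if both_target:
        gap = (j3.target_start - 1) - j5.target_end
        if gap < -params.tsd_max:
            call.geometry_warning = (
                "3' flank maps upstream of 5' flank end by more than tsd_max"
            )
            call.tsd_len = seq_tsd
            if seq_tsd:
                call.inferred_geometry = CleavageGeometry(None, seq_tsd)
            return call
        if gap < 0:
            call.tsd_len = -gap
        else:
            call.deletion_len = gap
        call.inferred_geometry = CleavageGeometry(
            j3.target_start - 1, -gap if gap > 0 else call.tsd_len
        )
        return call
    if (
        j3.classification == TARGET_GENE
        and j3.match_strand == "+"
        and j3.target_start is not None
        and j3.target_start > 1
        and seq_tsd == 0
        and j5.classification not in (None, UNSEQUENCED, TARGET_GENE)
    ):
        # upstream target fragment absent: 5'-target deletion
        call.deletion_len = j3.target_start - 1
        call.inferred_geometry = CleavageGeometry(
            j3.target_start - 1, -call.deletion_len
        )
        return call
    if seq_tsd:
        call.tsd_len = seq_tsd
        bottom = (
            j3.target_start - 1
            if j3.classification == TARGET_GENE
            and j3.match_strand == "+"
            and j3.target_start is not None
            else None
        )
        call.inferred_geometry = CleavageGeometry(bottom, seq_tsd)
        return call
    if j3.classification == TARGET_GENE and j3.match_strand == "+":
        # blunt junction placed on the target
        call.inferred_geometry = CleavageGeometry(
            (j3.target_start or 1) - 1, 0
        )
    return call


def analyze_junctions(
    copies: list[CopyHit],
    genome: dict[str, str] | str,
    target_model: TargetGeneModel,
    families: list[ElementFamily],
    params: JunctionParams | None = None,
) -> list[InsertionCall]:
    """Flank extraction + classification + geometry inference for every
    detected copy."""
    params = params or JunctionParams()
    calls = []
    for copy in copies:
        j5, j3 = extract_flanks(
            copy, genome, params.flank_len, params.n_run, params.boundary_slack
        )
        classify_flank(j5, target_model, families, params)
        classify_flank(j3, target_model, families, params)
        call = InsertionCall(copy, j5, j3)
        infer_tsd_and_deletion(call, target_model, params)
        calls.append(call)
    return calls
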