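"""Census of target-gene copies: intact, disrupted, or fragment.

A genome is scanned with two diagnostic queries derived from the target
model — the 5'-terminal ~100 nt and the post-insertion-site remainder —
and every matching locus is classified:

* ``intact``: the functional 5' region (first 50 nt for U2) is present
  without interruption.  Presence of this region is the package's proxy
  for a functional gene copy; an insertion placed downstream of it (e.g.
  a duplication geometry that leaves the first 58 nt upstream of the
  element) does not cost the locus its intact status.
* ``disrupted``: the locus begins at or after the insertion site (nt 39
  for U2) and an element 3' terminus is immediately adjacent upstream.
  This is the diagnostic signature of 5'-target-deleting integration:
  the gene remainder directly abuts the element's 3' UTR.
* ``fragment``: any residual partial match (including 5' gene stubs left
  upstream of blunt or duplication-type insertions, which abut element
  5' ends and are deliberately not counted as disrupted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import ScoringScheme, seed_extend_scan, smith_waterman
from .detect import CopyHit
from .junctions import InsertionCall
from .models import TargetGeneModel


@dataclass
class CensusParams:
    five_prime_query_len: int = 100
    adjacency_gap: int = 5
    min_score: int = 30
    id_threshold: float = 0.8
    k: int = 11
    band: int = 32
    array_gap: int = 2000  # loci closer than this group into one array
    scoring: ScoringScheme = field(default_factory=ScoringScheme)


@dataclass
class InventoryRecord:
    """One target-gene locus (0-based half-open interval)."""

    contig: str
    start: int
    end: int
    strand: str
    status: str  # intact | disrupted | fragment
    missing_5prime: int
    identity: float
    adjacent_element: tuple[str, str] | None = None  # (family, "5p"|"3p")
    array_id: int | None = None


def _element_termini(copies: list[CopyHit]):
    """(contig, genome position, family, side) for every element terminus;
    side is the element-sense end ("3p" or "5p") facing that position."""
    out = []
    for c in copies:
        if c.strand == "+":
            out.append((c.contig, c.end, c.family, "3p"))
            out.append((c.contig, c.start, c.family, "5p"))
        else:
            out.append((c.contig, c.start, c.family, "3p"))
            out.append((c.contig, c.end, c.family, "5p"))
    return out


def _trim_pairs_inside_elements(
    pairs: list[tuple[int, int]],
    strand: str,
    ws: int,
    we: int,
    intervals: list[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Drop leading/trailing aligned columns whose genome position falls
    inside a detected element copy.  Local alignment happily extends a
    base or two across the element/target junction whenever the element
    terminus happens to match the target model; without this trim the
    inferred missing-5' extent of a disrupted locus would be biased by
    exactly those chance matches."""
    if not intervals:
        return pairs

    def inside(sj: int) -> bool:
        g = ws + sj if strand == "+" else we - 1 - sj
        import bisect

        i = bisect.bisect_right(intervals, (g, float("inf"))) - 1
        return i >= 0 and intervals[i][0] <= g < intervals[i][1]

    lo, hi = 0, len(pairs)
    while lo < hi and inside(pairs[lo][1]):
        lo += 1
    while hi > lo and inside(pairs[hi - 1][1]):
        hi -= 1
    return pairs[lo:hi]


def _merge_intervals(loci):
    loci = sorted(loci)
    merged = []
    for contig, s, e, strand in loci:
        if merged and merged[-1][0] == contig and merged[-1][3] == strand and s <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (contig, prev[1], max(prev[2], e), strand)
        else:
            merged.append((contig, s, e, strand))
    return merged


def census_target_genes(
    genome: dict[str, str] | str,
    target_model: TargetGeneModel,
    element_calls: list[InsertionCall] | list[CopyHit] | None = None,
    params: CensusParams | None = None,
) -> list[InventoryRecord]:
    """Find and classify every target-gene locus in *genome*.

    ``element_calls`` (insertion calls or raw copy hits) provide the
    element termini used for the disrupted-gene adjacency test; with no
    calls every non-intact locus is a fragment.
    """
    params = params or CensusParams()
    if isinstance(genome, str):
        genome = {"seq": genome}
    copies: list[CopyHit] = []
    for item in element_calls or []:
        copies.append(item.copy if isinstance(item, InsertionCall) else item)
    termini = _element_termini(copies)
    # Extend each interval over the (short) unaligned consensus 3' tail of
    # copies whose terminus diverged out of the alignment, so that chance
    # matches of those element bases to the target model are still trimmed.
    element_intervals: dict[str, list[tuple[int, int]]] = {}
    for c in copies:
        tail = min(max(c.consensus_len - c.qend, 0), 10)
        s, e = c.start, c.end
        if c.strand == "+":
            e += tail
        else:
            s -= tail
        element_intervals.setdefault(c.contig, []).append((s, e))
    for v in element_intervals.values():
        v.sort()

    model_seq = target_model.sequence
    q5 = model_seq[: params.five_prime_query_len]
    q_rest = model_seq[target_model.insertion_site :]
    candidates = []
    for query in (q5, q_rest):
        for h in seed_extend_scan(
            query,
            genome,
            k=params.k,
            band=params.band,
            min_score=params.min_score,
            scoring=params.scoring,
        ):
            candidates.append((h.contig, h.subject_start, h.subject_end, h.strand))
    records: list[InventoryRecord] = []
    for contig, s, e, strand in _merge_intervals(candidates):
        seq = genome[contig]
        margin = len(model_seq)
        ws = max(0, s - margin)
        we = min(len(seq), e + margin)
        window = seq[ws:we]
        if strand == "-":
            from ._seq import revcomp

            window = revcomp(window)
        hit = smith_waterman(model_seq, window, params.scoring)
        if hit.is_empty() or hit.identity < params.id_threshold:
            continue
        pairs = _trim_pairs_inside_elements(
            hit.pairs, strand, ws, we, element_intervals.get(contig, [])
        )
        if not pairs:
            continue
        missing = pairs[0][0]
        sj_lo, sj_hi = pairs[0][1], pairs[-1][1] + 1
        if strand == "+":
            ls, le = ws + sj_lo, ws + sj_hi
        else:
            ls, le = we - sj_hi, we - sj_lo
        func = target_model.functional_5prime_len
        func_cols = {qi for qi, _ in pairs if qi < func}
        intact = missing == 0 and len(func_cols) == func
        status = "fragment"
        adjacent = None
        # position of the locus 5' boundary on the genome
        five_prime_boundary = ls if strand == "+" else le
        for tcontig, tpos, fam, side in termini:
            if tcontig != contig:
                continue
            if abs(tpos - five_prime_boundary) <= params.adjacency_gap:
                adjacent = (fam, side)
                if side == "3p":
                    break
        if intact:
            status = "intact"
        elif (
            missing >= target_model.insertion_site
            and adjacent is not None
            and adjacent[1] == "3p"
        ):
            status = "disrupted"
        records.append(
            InventoryRecord(
                contig=contig,
                start=ls,
                end=le,
                strand=strand,
                status=status,
                missing_5prime=missing,
                identity=hit.identity,
                adjacent_element=adjacent,
            )
        )
    records.sort(key=lambda r: (r.contig, r.start))
    # assign array ids to runs of nearby loci
    aid = -1
    prev = None
    for r in records:
        if (
            prev is None
            or r.contig != prev.contig
            or r.start - prev.end > params.array_gap
        ):
            aid += 1
        r.array_id = aid
        prev = r
    return records


def census_counts(records: list[InventoryRecord]) -> dict[str, int]:
    out = {"intact": 0, "disrupted": 0, "fragment": 0}
    for r in records:
        out[r.status] += 1
    return out


def bootstrap_target_model(
    genome: dict[str, str] | str,
    seed_model: TargetGeneModel,
    params: CensusParams | None = None,
) -> TargetGeneModel:
    """Re-derive the target model from the genome itself: majority
    consensus of the intact loci found with a (possibly cross-species)
    seed model.  Falls back to the seed model when fewer than two intact
    loci are found."""
    from ._seq import revcomp
    from .families import CopyAlignment, majority_consensus, star_align

    if isinstance(genome, str):
        genome = {"seq": genome}
    records = census_target_genes(genome, seed_model, None, params)
    seqs = []
    for r in records:
        if r.status != "intact":
            continue
        s = genome[r.contig][r.start : r.end]
        if r.strand == "-":
            s = revcomp(s)
        seqs.append(s)
    if len(seqs) < 2:
        return seed_model
    aln = star_align(seqs, seed_model.sequence)
    consensus = majority_consensus(aln)
    return TargetGeneModel(
        name=f"{seed_model.name}_bootstrapped",
        sequence=consensus,
        functional_5prime_len=seed_model.functional_5prime_len,
        insertion_site=seed_model.insertion_site,
    )
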