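"""Genome-wide detection of element copies.

Two search modes mirror how site-specific retroelement copies are found
in practice:

* :func:`detect_copies` scans with each family's full consensus, chains
  collinear fragments of one copy, and resolves loci hit by several
  families to the best-identity family.  The consensus-coordinate span of
  the chained alignment gives the 5'-truncation of a copy and whether its
  3' terminus is intact.
* :func:`anchor_3prime_scan` scans with the 3'-terminal anchor (70 bp by
  default) only.  Because most copies of a non-LTR element are 5'
  truncated while the 3' end is always attached to the target, harvesting
  3' termini recovers copies that full-length detection misses, and every
  junction analysis starts from an intact, sequenced 3' terminus.

Coordinates are 0-based half-open; minus-strand hits are reported in
element-sense (consensus) coordinates with ``strand == "-"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import check_dna
from .align import DEFAULT_SCORING, LocalHit, ScoringScheme, seed_extend_scan


@dataclass(frozen=True)
class ElementFamily:
    """Named consensus with the 3'-terminal anchor length used for
    junction harvesting."""

    name: str
    consensus: str
    anchor_3prime_len: int = 70

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("family consensus must be non-empty")
        check_dna(self.consensus, f"consensus of {self.name}")
        object.__setattr__(self, "consensus", self.consensus.upper())
        if self.anchor_3prime_len > len(self.consensus):
            raise ValueError("anchor length exceeds consensus length")

    @property
    def anchor(self) -> str:
        return self.consensus[-self.anchor_3prime_len :]


@dataclass
class DetectionParams:
    k: int = 11
    band: int = 32
    min_score: int = 30
    chain_gap: int = 50  # max unaligned nt between chained fragments
    chain_overlap_tol: int = 10
    scoring: ScoringScheme = field(default_factory=ScoringScheme)


@dataclass
class CopyHit:
    """One detected element copy (or 3'-terminus record).

    ``truncated_5prime_by`` counts consensus 5' bases absent from the
    alignment; ``has_intact_3prime`` is True iff the alignment covers the
    final consensus base.  ``host_copy`` is set when the copy lies inside
    another detected copy (a nested insertion).
    """

    family: str
    contig: str
    start: int
    end: int
    strand: str
    score: int
    identity: float
    qstart: int
    qend: int
    has_intact_3prime: bool
    truncated_5prime_by: int
    consensus_len: int = 0
    copy_id: int = -1
    host_copy: int | None = None

    @property
    def three_prime_pos(self) -> int:
        """Genome coordinate of the element 3' terminus boundary
        (insertion point of the downstream flank in element sense)."""
        return self.end if self.strand == "+" else self.start

    @property
    def five_prime_pos(self) -> int:
        return self.start if self.strand == "+" else self.end


def _trim_hit_ends(
    hit: LocalHit,
    q_codes,
    g_codes,
    qlen: int,
    run: int = 6,
) -> LocalHit:
    """Trim unreliable alignment ends back to an anchored run of *run*
    consecutive matching columns.

    A local alignment of a 5'-truncated copy freely extends a few columns
    past the true element boundary whenever flanking target bases happen
    to match the consensus; those chance extensions corrupt junction
    coordinates.  Ends that reach a consensus terminus (query_start == 0
    or query_end == qlen) are genuine and left untouched.
    """
    pairs = hit.pairs
    if not pairs:
        return hit
    minus = hit.strand == "-"
    step = -1 if minus else 1

    def is_match(qi: int, sj: int) -> bool:
        qa, sb = int(q_codes[qi]), int(g_codes[sj])
        if qa >= 4 or sb >= 4:
            return False
        return qa + sb == 3 if minus else qa == sb

    flags = [is_match(qi, sj) for qi, sj in pairs]

    def anchored(indices) -> int | None:
        cnt = 0
        prev = None
        for idx in indices:
            consec = (
                prev is not None
                and pairs[idx][0] == pairs[prev][0] + (1 if idx > prev else -1)
                and pairs[idx][1] == pairs[prev][1] + (step if idx > prev else -step)
            )
            if flags[idx]:
                cnt = cnt + 1 if (cnt and consec) else 1
                if cnt == run:
                    return idx
            else:
                cnt = 0
            prev = idx
        return None

    i0, i1 = 0, len(pairs) - 1
    if hit.query_start > 0:
        end_of_run = anchored(range(len(pairs)))
        if end_of_run is not None:
            i0 = end_of_run - run + 1
    if hit.query_end < qlen:
        start_of_run = anchored(range(len(pairs) - 1, -1, -1))
        if start_of_run is not None:
            i1 = start_of_run + run - 1
    if i0 == 0 and i1 == len(pairs) - 1:
        return hit
    if i1 < i0:
        return hit
    kept = pairs[i0 : i1 + 1]
    qstart, qend = kept[0][0], kept[-1][0] + 1
    if minus:
        sstart, send = kept[-1][1], kept[0][1] + 1
    else:
        sstart, send = kept[0][1], kept[-1][1] + 1
    n_matches = sum(flags[i0 : i1 + 1])
    n_columns = (qend - qstart) + (send - sstart) - len(kept)
    return LocalHit(
        query_start=qstart,
        query_end=qend,
        subject_start=sstart,
        subject_end=send,
        strand=hit.strand,
        score=hit.score,
        n_matches=n_matches,
        n_columns=n_columns,
        contig=hit.contig,
        pairs=kept,
    )


def _chainable(prev: LocalHit, nxt: LocalHit, params: DetectionParams) -> bool:
    """Collinearity test for two subject-sorted hits of one family/strand."""
    sgap = nxt.subject_start - prev.subject_end
    if not -params.chain_overlap_tol <= sgap <= params.chain_gap:
        return False
    if prev.strand == "+":
        qgap = nxt.query_start - prev.query_end
    else:  # query coordinates decrease along the subject on the minus strand
        qgap = prev.query_start - nxt.query_end
    return -params.chain_overlap_tol <= qgap <= params.chain_gap


def _chain_hits(hits: list[LocalHit], params: DetectionParams) -> list[LocalHit]:
    """Greedily chain collinear fragments of one copy."""
    by_key: dict[tuple[str, str], list[LocalHit]] = {}
    for h in hits:
        by_key.setdefault((h.contig or "", h.strand), []).append(h)
    chained: list[LocalHit] = []
    for key in sorted(by_key):
        group = sorted(by_key[key], key=lambda h: h.subject_start)
        cur = group[0]
        for nxt in group[1:]:
            if _chainable(cur, nxt, params):
                cur = LocalHit(
                    query_start=min(cur.query_start, nxt.query_start),
                    query_end=max(cur.query_end, nxt.query_end),
                    subject_start=cur.subject_start,
                    subject_end=nxt.subject_end,
                    strand=cur.strand,
                    score=cur.score + nxt.score,
                    n_matches=cur.n_matches + nxt.n_matches,
                    n_columns=cur.n_columns + nxt.n_columns,
                    contig=cur.contig,
                )
            else:
                chained.append(cur)
                cur = nxt
        chained.append(cur)
    return chained


def _resolve_families(copies: list[CopyHit]) -> list[CopyHit]:
    """Where copies of different families overlap on the genome, keep the
    best-identity (then best-score) family."""
    copies = sorted(copies, key=lambda c: (c.contig, c.start, c.end))
    kept: list[CopyHit] = []
    for c in copies:
        drop = False
        for p in reversed(kept):
            if p.contig != c.contig or p.end <= c.start:
                break
            if p.family == c.family:
                continue
            overlap = min(p.end, c.end) - max(p.start, c.start)
            if overlap > 0.5 * min(p.end - p.start, c.end - c.start):
                if (c.identity, c.score) > (p.identity, p.score):
                    kept.remove(p)
                else:
                    drop = True
                break
        if not drop:
            kept.append(c)
    return kept


def _annotate_nesting(copies: list[CopyHit]) -> None:
    """Mark copies flanked on both sides by collinear fragments of another
    copy (the host was split by the insertion)."""
    tol = 15
    for c in copies:
        for left in copies:
            if left is c or left.contig != c.contig:
                continue
            if abs(left.end - c.start) > tol:
                continue
            for right in copies:
                if right is c or right is left or right.contig != c.contig:
                    continue
                if abs(right.start - c.end) > tol:
                    continue
                if right.family == left.family and right.strand == left.strand:
                    c.host_copy = left.copy_id
                    break
            if c.host_copy is not None:
                break


def _to_copy(hit: LocalHit, family: ElementFamily) -> CopyHit:
    return CopyHit(
        family=family.name,
        contig=hit.contig or "seq",
        start=hit.subject_start,
        end=hit.subject_end,
        strand=hit.strand,
        score=hit.score,
        identity=hit.identity,
        qstart=hit.query_start,
        qend=hit.query_end,
        has_intact_3prime=hit.query_end == len(family.consensus),
        truncated_5prime_by=hit.query_start,
        consensus_len=len(family.consensus),
    )


def detect_copies(
    families: list[ElementFamily],
    genome: dict[str, str] | str,
    params: DetectionParams | None = None,
) -> list[CopyHit]:
    """Detect element copies with full-consensus scans.

    Collinear fragments within ``chain_gap`` are chained into one copy;
    loci hit by several families resolve to the best identity.
    """
    if not families:
        raise ValueError("at least one family required")
    params = params or DetectionParams()
    if isinstance(genome, str):
        genome = {"seq": genome}
    from ._seq import encode

    g_codes = {name: encode(seq) for name, seq in genome.items()}
    copies: list[CopyHit] = []
    for fam in families:
        hits = seed_extend_scan(
            fam.consensus,
            genome,
            k=params.k,
            band=params.band,
            min_score=params.min_score,
            scoring=params.scoring,
        )
        q_codes = encode(fam.consensus)
        hits = [
            _trim_hit_ends(h, q_codes, g_codes[h.contig or "seq"], len(fam.consensus))
            for h in hits
        ]
        copies.extend(_to_copy(h, fam) for h in _chain_hits(hits, params))
    copies = _resolve_families(copies)
    copies.sort(key=lambda c: (c.contig, c.start, c.end, c.family))
    for i, c in enumerate(copies):
        c.copy_id = i
    _annotate_nesting(copies)
    return copies


def anchor_3prime_scan(
    family: ElementFamily,
    genome: dict[str, str] | str,
    params: DetectionParams | None = None,
) -> list[CopyHit]:
    """Locate element 3' termini with the 3'-terminal anchor only.

    One record per located terminus, including termini of 5'-truncated
    copies; ``truncated_5prime_by`` is the consensus 5' extent absent from
    the anchor alignment (a lower bound on the true copy extent).
    """
    from ._seq import encode

    params = params or DetectionParams()
    if isinstance(genome, str):
        genome = {"seq": genome}
    anchor = family.anchor
    offset = len(family.consensus) - len(anchor)
    hits = seed_extend_scan(
        anchor,
        genome,
        k=params.k,
        band=params.band,
        min_score=params.min_score,
        scoring=params.scoring,
    )
    a_codes = encode(anchor)
    g_codes = {name: encode(seq) for name, seq in genome.items()}
    hits = [
        _trim_hit_ends(h, a_codes, g_codes[h.contig or "seq"], len(anchor))
        for h in hits
    ]
    copies = []
    for i, h in enumerate(hits):
        c = CopyHit(
            family=family.name,
            contig=h.contig or "seq",
            start=h.subject_start,
            end=h.subject_end,
            strand=h.strand,
            score=h.score,
            identity=h.identity,
            qstart=offset + h.query_start,
            qend=offset + h.query_end,
            has_intact_3prime=h.query_end == len(anchor),
            truncated_5prime_by=offset + h.query_start,
            consensus_len=len(family.consensus),
            copy_id=i,
        )
        copies.append(c)
    return copies
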