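"""Synthetic genomes with target-gene arrays and element insertions of
known truth.

The generator emulates the genomic signatures of site-specific non-LTR
retroelements integrating into a short multicopy gene (the U2 snRNA
case):

* tandem arrays of near-exact target genes separated by divergent random
  spacers;
* insertions at a fixed target coordinate with a family-specific cleavage
  geometry — blunt junctions, target site duplications (top-strand cut
  downstream of the bottom cut), or 5' target deletions (top-strand cut
  upstream);
* 5'-truncated copies, per-copy substitution/indel divergence, nested
  element-into-element insertions, and a configurable off-target rate.

Every edit is recorded in an :class:`InsertionTruth`, giving the ground
truth for parameter-recovery tests.  On-target insertions are placed in a
fixed orientation relative to the target gene (the element 3' end joined
at the bottom-strand cut), which is the orientation the target-primed
reverse transcription mechanism enforces; off-target insertions land on
either strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from ._seq import check_dna, decode, encode, random_dna, revcomp
from .models import CleavageGeometry, GeneLocus, TargetGeneModel

SpacerLenDist = Callable[[np.random.Generator], int] | int | tuple[int, int]


@dataclass
class FamilySpec:
    """Simulation parameters for one element family.

    ``truncation_len_dist`` draws a 5'-truncation length given (rng,
    consensus length); the default is uniform over [0, 0.8 * length].
    ``antisense_prob`` applies to off-target insertions only.
    """

    name: str
    consensus: str
    geometry: CleavageGeometry
    n_copies: int
    truncation_prob: float = 0.0
    truncation_len_dist: Callable[[np.random.Generator, int], int] | None = None
    divergence: float = 0.0
    indel_rate: float = 0.0
    off_target_rate: float = 0.0
    nesting_rate: float = 0.0
    antisense_prob: float = 0.5

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError("consensus must be non-empty")
        check_dna(self.consensus, f"consensus of {self.name}")
        self.consensus = self.consensus.upper()
        if self.n_copies < 0:
            raise ValueError("n_copies must be >= 0")
        for attr in (
            "truncation_prob",
            "divergence",
            "indel_rate",
            "off_target_rate",
            "nesting_rate",
            "antisense_prob",
        ):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{attr} must be in [0, 1], got {v}")


@dataclass
class InsertionTruth:
    """Ground truth for one inserted element copy.

    ``start``/``end`` delimit the inserted block (0-based half-open) in
    the final mutated genome; for a duplication geometry the duplicated
    target bases sit immediately 5' of ``start``.  ``deleted_seq`` stores
    the target bases removed by a negative top-strand offset so edits can
    be reversed exactly.
    """

    copy_id: int
    family: str
    contig: str
    start: int
    end: int
    strand: str
    tsd_len: int
    deletion_len: int
    truncated_5prime_by: int
    on_target: bool
    nested_in: int | None = None
    locus_index: int | None = None
    deleted_seq: str = ""

    @property
    def position(self) -> int:
        """0-based point of the bottom-strand cut in final genome
        coordinates (= start of the inserted block)."""
        return self.start

    @property
    def top_offset(self) -> int:
        return self.tsd_len if self.tsd_len else -self.deletion_len


def apply_divergence(
    sequence: str,
    substitution_rate: float,
    indel_rate: float,
    seed: int | np.random.Generator,
) -> str:
    """Mutate a sequence with independent per-site substitutions and
    single-base indels (insertion/deletion equally likely).

    Deterministic under a fixed seed; expected substitution count is
    ``substitution_rate * len(sequence)``.
    """
    if not 0.0 <= substitution_rate < 1.0 or not 0.0 <= indel_rate < 1.0:
        raise ValueError("rates must be in [0, 1)")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    codes = encode(sequence)
    n = codes.shape[0]
    if substitution_rate > 0.0 and n:
        mask = (rng.random(n) < substitution_rate) & (codes < 4)
        shift = rng.integers(1, 4, size=n)
        codes = np.where(mask, (codes + shift) % 4, codes).astype(np.int8)
    if indel_rate > 0.0 and n:
        events = np.nonzero(rng.random(n) < indel_rate)[0]
        if events.size:
            is_ins = rng.random(events.size) < 0.5
            ins_base = rng.integers(0, 4, size=events.size)
            parts: list[np.ndarray] = []
            last = 0
            for e, (i, ins) in enumerate(zip(events, is_ins)):
                if ins:  # keep base i, add a random base after it
                    parts.append(codes[last : i + 1])
                    parts.append(np.array([ins_base[e]], dtype=np.int8))
                else:  # delete base i
                    parts.append(codes[last:i])
                last = i + 1
            parts.append(codes[last:])
            codes = np.concatenate(parts)
    return decode(codes)


def _draw_spacer_len(dist: SpacerLenDist, rng: np.random.Generator) -> int:
    if callable(dist):
        return int(dist(rng))
    if isinstance(dist, tuple):
        lo, hi = dist
        return int(rng.integers(lo, hi + 1))
    return int(dist)


def build_target_arrays(
    model: TargetGeneModel,
    n_arrays: int,
    genes_per_array: int,
    spacer_len_dist: SpacerLenDist = 250,
    spacer_divergence: float = 0.25,
    seed: int = 0,
    contig_prefix: str = "array",
) -> tuple[dict[str, str], list[GeneLocus]]:
    """Emit tandem target-gene arrays with divergent spacers.

    Each array is one contig of ``genes_per_array`` exact copies of the
    model sequence separated by spacers.  Spacers within an array derive
    from one ancestral random sequence mutated at ``spacer_divergence``
    per instance, emulating intergenic sequence that is recognisably
    related yet strongly diverged; genes themselves are exact.
    """
    if n_arrays < 1 or genes_per_array < 1:
        raise ValueError("n_arrays and genes_per_array must be >= 1")
    rng = np.random.default_rng(seed)
    genome: dict[str, str] = {}
    loci: list[GeneLocus] = []
    width = max(3, len(str(n_arrays)))
    for a in range(n_arrays):
        contig = f"{contig_prefix}_{a + 1:0{width}d}"
        ancestral_spacer = random_dna(rng, _draw_spacer_len(spacer_len_dist, rng))
        parts: list[str] = []
        pos = 0
        for g in range(genes_per_array):
            parts.append(model.sequence)
            loci.append(GeneLocus(contig, pos, pos + len(model.sequence)))
            pos += len(model.sequence)
            if g + 1 < genes_per_array:
                spacer = ancestral_spacer
                if len(spacer) > 0:
                    target_len = _draw_spacer_len(spacer_len_dist, rng)
                    if target_len != len(spacer):
                        spacer = (spacer * (target_len // len(spacer) + 1))[:target_len]
                    spacer = apply_divergence(spacer, spacer_divergence, 0.0, rng)
                parts.append(spacer)
                pos += len(spacer)
        genome[contig] = "".join(parts)
    return genome, loci


def _shift_point(x: int, cut: int, block_start: int, delta: int) -> int:
    """Map a pre-insertion coordinate through an edit that replaced
    ``genome[block_start_pre:cut]`` region semantics: positions >= cut
    shift by delta; positions inside a deleted zone collapse to its
    start."""
    if x >= cut:
        return x + delta
    if x > block_start:  # inside a deleted zone (only when top_offset < 0)
        return block_start
    return x


@dataclass
class _Contig:
    seq: str


def insert_elements(
    genome: dict[str, str],
    gene_loci: Sequence[GeneLocus],
    specs: Sequence[FamilySpec],
    model: TargetGeneModel,
    seed: int = 0,
    upstream_spillover: bool = False,
) -> tuple[dict[str, str], list[InsertionTruth]]:
    """Insert element copies into a genome, returning the mutated genome
    and a full truth record per copy.

    On-target copies go to unoccupied gene loci at the model's insertion
    site with the family geometry; off-target copies land at uniform
    random positions; nested copies land inside previously placed copies.
    All recorded coordinates (truths and a private copy of the loci) are
    kept current as later insertions shift the genome.
    """
    rng = np.random.default_rng(seed)
    site = model.insertion_site
    for spec in specs:
        off = spec.geometry.top_offset
        if off < 0 and -off > site and not upstream_spillover:
            raise ValueError(
                f"geometry of {spec.name} deletes {-off} nt but only {site} "
                "target bases lie 5' of the bottom cut "
                "(pass upstream_spillover=True to allow)"
            )
    contigs = {name: _Contig(seq) for name, seq in genome.items()}
    loci = [GeneLocus(l.contig, l.start, l.end) for l in gene_loci]
    occupied = [False] * len(loci)
    truths: list[InsertionTruth] = []
    copy_id = 0

    def do_insert(
        contig: str,
        cut: int,
        off: int,
        block: str,
        *,
        family: str,
        strand: str,
        trunc: int,
        on_target: bool,
        nested_in: int | None,
        locus_index: int | None,
    ) -> InsertionTruth:
        nonlocal copy_id
        seq = contigs[contig].seq
        a = cut + off
        deleted = seq[a:cut] if off < 0 else ""
        contigs[contig].seq = seq[:a] + block + seq[cut:]
        delta = len(block) + off
        block_start = a  # deleted zone is [a, cut) when off < 0
        for t in truths:
            if t.contig != contig:
                continue
            t.start = _shift_point(t.start, cut, block_start, delta)
            t.end = _shift_point(t.end, cut, block_start, delta)
        for l in loci:
            if l.contig != contig:
                continue
            l.start = _shift_point(l.start, cut, block_start, delta)
            l.end = _shift_point(l.end, cut, block_start, delta)
        truth = InsertionTruth(
            copy_id=copy_id,
            family=family,
            contig=contig,
            start=a if off <= 0 else a,
            end=a + len(block),
            strand=strand,
            tsd_len=max(off, 0),
            deletion_len=max(-off, 0),
            truncated_5prime_by=trunc,
            on_target=on_target,
            nested_in=nested_in,
            locus_index=locus_index,
            deleted_seq=deleted,
        )
        truths.append(truth)
        copy_id += 1
        return truth

    def make_block(spec: FamilySpec) -> tuple[str, int]:
        trunc = 0
        elem = spec.consensus
        if spec.truncation_prob > 0.0 and rng.random() < spec.truncation_prob:
            if spec.truncation_len_dist is not None:
                trunc = int(spec.truncation_len_dist(rng, len(elem)))
            else:
                trunc = int(rng.integers(0, int(0.8 * len(elem)) + 1))
            trunc = min(trunc, len(elem) - 1)
            elem = elem[trunc:]
        if spec.divergence > 0.0 or spec.indel_rate > 0.0:
            elem = apply_divergence(elem, spec.divergence, spec.indel_rate, rng)
        return elem, trunc

    contig_names = sorted(contigs)
    for spec in specs:
        off = spec.geometry.top_offset
        for _ in range(spec.n_copies):
            block, trunc = make_block(spec)
            r = rng.random()
            if r < spec.off_target_rate:
                strand = "-" if rng.random() < spec.antisense_prob else "+"
                if strand == "-":
                    block = revcomp(block)
                lengths = np.array(
                    [len(contigs[c].seq) for c in contig_names], dtype=float
                )
                contig = contig_names[
                    int(rng.choice(len(contig_names), p=lengths / lengths.sum()))
                ]
                # the duplicated (off > 0) or deleted (off < 0) target
                # bases must exist within the contig
                lo = max(0, -off)
                hi = len(contigs[contig].seq) - max(off, 0)
                cut = int(rng.integers(lo, hi + 1))
                do_insert(
                    contig,
                    cut,
                    off,
                    block,
                    family=spec.name,
                    strand=strand,
                    trunc=trunc,
                    on_target=False,
                    nested_in=None,
                    locus_index=None,
                )
                continue
            free = [i for i, occ in enumerate(occupied) if not occ]
            nest = truths and (
                rng.random() < spec.nesting_rate or not free
            )
            if nest:
                if not truths:
                    raise ValueError("nested insertion requested before any copy")
                host = truths[int(rng.integers(0, len(truths)))]
                # land well inside the host so both junctions of the
                # nested copy read element sequence
                margin = 70
                lo = host.start + max(margin, -off)
                hi = host.end - margin
                if hi <= lo:
                    lo, hi = host.start + max(0, -off), host.end
                hi = min(hi, len(contigs[host.contig].seq) - max(off, 0))
                cut = int(rng.integers(lo, max(lo, hi) + 1))
                strand = "-" if rng.random() < spec.antisense_prob else "+"
                if strand == "-":
                    block = revcomp(block)
                do_insert(
                    host.contig,
                    cut,
                    off,
                    block,
                    family=spec.name,
                    strand=strand,
                    trunc=trunc,
                    on_target=False,
                    nested_in=host.copy_id,
                    locus_index=None,
                )
                continue
            if not free:
                raise ValueError(
                    "no unoccupied gene locus for an on-target insertion "
                    "(increase loci or enable nesting)"
                )
            li = free[int(rng.integers(0, len(free)))]
            locus = loci[li]
            occupied[li] = True
            cut = locus.start + site
            do_insert(
                locus.contig,
                cut,
                off,
                block,
                family=spec.name,
                strand="+",
                trunc=trunc,
                on_target=True,
                nested_in=None,
                locus_index=li,
            )
    mutated = {name: c.seq for name, c in contigs.items()}
    return mutated, truths


def reverse_edits(
    genome: dict[str, str], truths: Sequence[InsertionTruth]
) -> dict[str, str]:
    """Undo every recorded insertion (in reverse order of application),
    restoring duplicated and deleted target bases.  Round-trips exactly to
    the pre-insertion genome."""
    seqs = dict(genome)
    pending = sorted(truths, key=lambda t: t.copy_id)
    coords = {t.copy_id: [t.start, t.end] for t in pending}
    for t in reversed(pending):
        start, end = coords[t.copy_id]
        seq = seqs[t.contig]
        a = start - t.tsd_len
        seqs[t.contig] = seq[:a] + t.deleted_seq + seq[end:]
        delta = (end - a) - len(t.deleted_seq)
        for u in pending:
            if u.copy_id >= t.copy_id or u.contig != t.contig:
                continue
            c = coords[u.copy_id]
            if c[0] >= end:
                c[0] -= delta
            if c[1] >= end:
                c[1] -= delta
    return seqs


# ---------------------------------------------------------------------------
# serialization

TRUTH_COLUMNS = [
    "contig",
    "start",
    "end",
    "family",
    "strand",
    "tsd_len",
    "deletion_len",
    "truncated_5prime_by",
    "on_target",
    "copy_id",
    "nested_in",
    "locus_index",
]


def truths_to_frame(truths: Sequence[InsertionTruth]):
    """Truth list as a BED-like DataFrame (0-based half-open)."""
    import pandas as pd

    rows = [
        {
            "contig": t.contig,
            "start": t.start,
            "end": t.end,
            "family": t.family,
            "strand": t.strand,
            "tsd_len": t.tsd_len,
            "deletion_len": t.deletion_len,
            "truncated_5prime_by": t.truncated_5prime_by,
            "on_target": int(t.on_target),
            "copy_id": t.copy_id,
            "nested_in": -1 if t.nested_in is None else t.nested_in,
            "locus_index": -1 if t.locus_index is None else t.locus_index,
        }
        for t in truths
    ]
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)
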