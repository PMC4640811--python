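"""Family-level tools: copy clustering, majority-rule consensus, and a
distance-based tree with bootstrap support.

Consensus building follows the classical repeat-curation recipe: copies
are aligned (star alignment onto a reference copy), and the consensus is
the per-column majority base.  Clustering is single-linkage on pairwise
identity; the tree is neighbor joining on p-distances, intended as a
light-weight family-grouping aid rather than a publishable phylogeny.

Pairwise identities for clustering are computed with edlib (banded exact
edit distance, infix mode so a 5'-truncated copy aligns inside a
full-length one); neighbor joining is delegated to scikit-bio.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .align import DEFAULT_SCORING, ScoringScheme, smith_waterman

GAP = "-"


@dataclass
class CopyAlignment:
    """Aligned copies: equal-length rows over ACGTN plus the gap symbol.

    Each row degaps to a subsequence of its source copy (star alignment
    keeps only the locally aligned part of each copy).
    """

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def pairwise_identity(a: str, b: str) -> tuple[float, int]:
    """Identity and aligned-column count of the best semi-global
    alignment of the shorter sequence inside the longer one."""
    if len(a) > len(b):
        a, b = b, a
    res = edlib.align(a, b, mode="HW", task="path")
    cigar = res["cigar"] or ""
    matches = cols = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            n = int(num)
            num = ""
            cols += n
            if ch == "=":
                matches += n
    return (matches / cols if cols else 0.0), cols


def cluster_copies(
    sequences: list[str],
    identity_cutoff: float = 0.85,
    min_overlap: int = 100,
) -> list[int]:
    """Single-linkage clustering of copy sequences by pairwise identity.

    Returns one integer label per input (labels numbered by first
    occurrence, so the result is deterministic and order-independent up
    to relabelling).  Copies shorter than ``min_overlap`` become flagged
    singletons (they cannot satisfy the overlap requirement).
    """
    if not sequences:
        raise ValueError("at least one copy required")
    n = len(sequences)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for i in range(n):
        if len(sequences[i]) < min_overlap:
            continue
        for j in range(i + 1, n):
            if len(sequences[j]) < min_overlap:
                continue
            ident, cols = pairwise_identity(sequences[i], sequences[j])
            if cols >= min_overlap and ident >= identity_cutoff:
                union(i, j)
    roots = [find(i) for i in range(n)]
    relabel: dict[int, int] = {}
    labels = []
    for r in roots:
        if r not in relabel:
            relabel[r] = len(relabel)
        labels.append(relabel[r])
    return labels


def star_align(
    copies: list[str],
    reference: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    ids: list[str] | None = None,
) -> CopyAlignment:
    """Align each copy to *reference* and project onto a shared
    coordinate system (reference positions plus per-position insertion
    columns sized to the longest insertion seen).

    Copies with no positive-scoring alignment to the reference are
    excluded.  The reference itself is not a row.
    """
    if ids is None:
        ids = [f"copy_{i}" for i in range(len(copies))]
    per_copy = []  # (id, cover: dict ref_pos -> char, ins: dict ref_pos -> str, span)
    ins_len: dict[int, int] = {}
    for cid, seq in zip(ids, copies):
        hit = smith_waterman(seq, reference, scoring)
        if hit.is_empty():
            continue
        cover: dict[int, str] = {}
        ins: dict[int, str] = {}
        qi_prev = hit.query_start - 1
        sj_prev = hit.subject_start - 1
        for qi, sj in hit.pairs:
            # query bases between pairs are insertions after ref pos sj_prev
            if qi - qi_prev > 1:
                ins[sj_prev] = ins.get(sj_prev, "") + seq[qi_prev + 1 : qi]
            for s in range(sj_prev + 1, sj):
                cover[s] = GAP  # deletion in the copy
            cover[sj] = seq[qi]
            qi_prev, sj_prev = qi, sj
        if hit.query_end - 1 > qi_prev:
            ins[sj_prev] = ins.get(sj_prev, "") + seq[qi_prev + 1 : hit.query_end]
        for pos, s in ins.items():
            ins_len[pos] = max(ins_len.get(pos, 0), len(s))
        per_copy.append((cid, cover, ins, (hit.subject_start, hit.subject_end)))
    columns: list[tuple[int, int]] = []  # (ref_pos, -1) for ref col, (ref_pos, k) for ins col k
    columns.append((-1, 0))  # slot for insertions before the first ref position
    for pos in range(len(reference)):
        columns.append((pos, -1))
        for k in range(ins_len.get(pos, 0)):
            columns.append((pos, k))
    for k in range(ins_len.get(-1, 0)):
        columns.insert(1 + k, (-1, 1 + k))
    out_ids, rows = [], []
    for cid, cover, ins, _span in per_copy:
        row = []
        for pos, k in columns:
            if k == -1:
                row.append(cover.get(pos, GAP))
            else:
                s = ins.get(pos, "")
                row.append(s[k] if k < len(s) else GAP)
        out_ids.append(cid)
        rows.append("".join(row))
    aln = CopyAlignment(out_ids, rows)
    return _drop_allgap_columns(aln)


def _drop_allgap_columns(aln: CopyAlignment) -> CopyAlignment:
    if not aln.rows:
        return aln
    keep = [
        i
        for i in range(aln.n_columns)
        if any(r[i] != GAP for r in aln.rows)
    ]
    rows = ["".join(r[i] for i in keep) for r in aln.rows]
    return CopyAlignment(aln.ids, rows)


def majority_consensus(aln: CopyAlignment) -> str:
    """Majority-rule consensus: per column, the most frequent non-gap
    base; a column is emitted only when at least half its rows are
    non-gap.  Ties break alphabetically (A < C < G < T), documented and
    deterministic."""
    if len(aln.rows) < 2:
        raise ValueError("majority consensus requires at least two rows")
    out = []
    n = len(aln.rows)
    for i in range(aln.n_columns):
        counts: dict[str, int] = {}
        for r in aln.rows:
            c = r[i]
            if c != GAP:
                counts[c] = counts.get(c, 0) + 1
        non_gap = sum(counts.values())
        if non_gap * 2 < n or non_gap == 0:
            continue
        best = min(counts, key=lambda c: (-counts[c], c))
        out.append(best)
    return "".join(out)


def p_distance_matrix(aln: CopyAlignment) -> tuple[list[str], np.ndarray]:
    """Pairwise p-distances (mismatches / shared non-gap columns).

    Pairs with no shared columns get distance 1.0.  p-distances may
    violate the triangle inequality; callers treating them as metric
    should check :func:`triangle_violations`.
    """
    n = len(aln.rows)
    mat = np.zeros((n, n))
    arr = np.array([list(r) for r in aln.rows])
    gap = arr == GAP
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gap[i] & ~gap[j]
            cols = int(shared.sum())
            if cols == 0:
                d = 1.0
            else:
                d = float((arr[i][shared] != arr[j][shared]).sum()) / cols
            mat[i, j] = mat[j, i] = d
    return list(aln.ids), mat


def triangle_violations(mat: np.ndarray, tol: float = 1e-9) -> int:
    n = mat.shape[0]
    count = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if mat[i, j] > mat[i, k] + mat[k, j] + tol:
                    count += 1
    return count


def neighbor_joining(labels: list[str], matrix: np.ndarray) -> TreeNode:
    """Neighbor-joining tree (scikit-bio); negative branch lengths are
    clamped to zero.  On an additive matrix the recovered tree reproduces
    the generating tree exactly."""
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 labels")
    dm = DistanceMatrix(matrix, ids=list(labels))
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return tree


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the leaf set, each canonicalized to
    the lexicographically smaller side."""
    leaves = frozenset(t.name for t in tree.tips())
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        splits.add(min(side, other, key=lambda s: tuple(sorted(s))))
    return splits


def bootstrap_support(
    aln: CopyAlignment,
    n_reps: int = 100,
    seed: int = 0,
) -> tuple[TreeNode, dict[frozenset[str], float]]:
    """NJ tree of the alignment plus per-split bootstrap support.

    Columns are resampled with replacement ``n_reps`` times; support is
    the percentage of replicate NJ trees containing each split of the
    full-alignment tree.  Support values are attached to the internal
    nodes of the returned tree as names.
    """
    labels, mat = p_distance_matrix(aln)
    tree = neighbor_joining(labels, mat)
    target = tree_splits(tree)
    counts = {s: 0 for s in target}
    rng = np.random.default_rng(seed)
    ncol = aln.n_columns
    for _ in range(n_reps):
        idx = rng.integers(0, ncol, size=ncol)
        rows = ["".join(r[i] for i in idx) for r in aln.rows]
        rlabels, rmat = p_distance_matrix(CopyAlignment(list(aln.ids), rows))
        rtree = neighbor_joining(rlabels, rmat)
        for s in tree_splits(rtree):
            if s in counts:
                counts[s] += 1
    support = {s: 100.0 * c / n_reps for s, c in counts.items()}
    leaves = frozenset(aln.ids)
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = min(side, leaves - side, key=lambda s: tuple(sorted(s)))
        if key in support:
            node.name = f"{support[key]:.0f}"
    return tree, support
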