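"""End-to-end orchestration: detect copies, analyse junctions, census the
target gene, tabulate specificity, and score a run against simulation
truth.

The specificity table follows the shape of a per-family flank-category
count: for every family, its copies' 3' flanks (and analogously 5'
flanks) are counted as target gene / element / other, and the
specificity fraction is target / (target + element + other).  Copies
whose element 3' terminus is truncated or unsequenced never enter the 3'
table denominator — junctions can only be read off an intact, sequenced
terminus.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import ScoringScheme
from .census import CensusParams, InventoryRecord, census_counts, census_target_genes
from .detect import CopyHit, DetectionParams, ElementFamily, detect_copies
from .junctions import (
    TARGET_GENE,
    UNSEQUENCED,
    InsertionCall,
    JunctionParams,
    analyze_junctions,
)
from .models import TargetGeneModel
from .simulate import InsertionTruth


@dataclass
class RunConfig:
    """All analysis parameters in one document (echoed into the output
    directory for reproducibility)."""

    seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    junction: JunctionParams = field(default_factory=JunctionParams)
    census: CensusParams = field(default_factory=CensusParams)
    cluster_identity_cutoff: float = 0.85
    bootstrap_reps: int = 100
    build_tree: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, klass in (
            ("detection", DetectionParams),
            ("junction", JunctionParams),
            ("census", CensusParams),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if isinstance(sub.get("scoring"), dict):
                    sub["scoring"] = ScoringScheme(**sub["scoring"])
                d[key] = klass(**sub)
        return cls(**d)


@dataclass
class SpecificityTable:
    """Per-family counts of flank classifications for one junction side."""

    side: str  # "5p" | "3p"
    rows: dict[str, dict[str, int]]

    @staticmethod
    def _empty_row() -> dict[str, int]:
        return {TARGET_GENE: 0, "element": 0, "other": 0, UNSEQUENCED: 0, "excluded": 0}

    def specificity_fraction(self, family: str) -> float | None:
        r = self.rows[family]
        denom = r[TARGET_GENE] + r["element"] + r["other"]
        return r[TARGET_GENE] / denom if denom else None

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for fam in sorted(self.rows):
            r = self.rows[fam]
            frac = self.specificity_fraction(fam)
            recs.append(
                {
                    "family": fam,
                    "target_gene": r[TARGET_GENE],
                    "element": r["element"],
                    "other": r["other"],
                    "unsequenced": r[UNSEQUENCED],
                    "excluded": r["excluded"],
                    "specificity_fraction": float("nan") if frac is None else frac,
                }
            )
        return pd.DataFrame(
            recs,
            columns=[
                "family",
                "target_gene",
                "element",
                "other",
                "unsequenced",
                "excluded",
                "specificity_fraction",
            ],
        )


def build_specificity_tables(
    calls: list[InsertionCall], families: list[ElementFamily]
) -> tuple[SpecificityTable, SpecificityTable]:
    """3' and 5' specificity tables.

    3' table: copies without an intact, sequenced element 3' terminus are
    excluded from the denominator (counted in ``excluded``).  5' table:
    analogous, over non-5'-truncated copies.
    """
    t3 = SpecificityTable("3p", {f.name: SpecificityTable._empty_row() for f in families})
    t5 = SpecificityTable("5p", {f.name: SpecificityTable._empty_row() for f in families})
    for call in calls:
        fam = call.copy.family
        if fam not in t3.rows:
            t3.rows[fam] = SpecificityTable._empty_row()
            t5.rows[fam] = SpecificityTable._empty_row()
        j3 = call.junction_3p
        if not call.copy.has_intact_3prime:
            t3.rows[fam]["excluded"] += 1
        elif j3.classification == UNSEQUENCED:
            t3.rows[fam][UNSEQUENCED] += 1
        elif j3.classification == TARGET_GENE:
            t3.rows[fam][TARGET_GENE] += 1
        elif j3.classification and j3.classification.startswith("element:"):
            t3.rows[fam]["element"] += 1
        else:
            t3.rows[fam]["other"] += 1
        j5 = call.junction_5p
        if call.copy.truncated_5prime_by > 0:
            t5.rows[fam]["excluded"] += 1
        elif j5.classification == UNSEQUENCED:
            t5.rows[fam][UNSEQUENCED] += 1
        elif j5.classification == TARGET_GENE:
            t5.rows[fam][TARGET_GENE] += 1
        elif j5.classification and j5.classification.startswith("element:"):
            t5.rows[fam]["element"] += 1
        else:
            t5.rows[fam]["other"] += 1
    return t5, t3


@dataclass
class PipelineResult:
    copies: list[CopyHit]
    calls: list[InsertionCall]
    census: list[InventoryRecord]
    table_5p: SpecificityTable
    table_3p: SpecificityTable
    consensus: dict[str, str] = field(default_factory=dict)
    tree_newick: str | None = None

    def census_counts(self) -> dict[str, int]:
        return census_counts(self.census)


def run_pipeline(
    genome: dict[str, str] | str,
    families: list[ElementFamily],
    target_model: TargetGeneModel,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Detect, classify, census and tabulate.  Deterministic given the
    config; optionally writes all report files into *outdir*."""
    config = config or RunConfig()
    if isinstance(genome, str):
        genome = {"seq": genome}
    if not genome or any(not s for s in genome.values()):
        raise ValueError("empty genome")
    if not families:
        raise ValueError("at least one element family required")
    copies = detect_copies(families, genome, config.detection)
    calls = analyze_junctions(copies, genome, target_model, families, config.junction)
    census = census_target_genes(genome, target_model, copies, config.census)
    table_5p, table_3p = build_specificity_tables(calls, families)
    result = PipelineResult(copies, calls, census, table_5p, table_3p)
    if config.build_tree and len(families) >= 1 and copies:
        from ._seq import revcomp
        from .families import (
            CopyAlignment,
            bootstrap_support,
            cluster_copies,
            majority_consensus,
            star_align,
        )

        seqs = []
        for c in copies:
            s = genome[c.contig][c.start : c.end]
            seqs.append(revcomp(s) if c.strand == "-" else s)
        labels = cluster_copies(seqs, config.cluster_identity_cutoff)
        for lab in sorted(set(labels)):
            members = [s for s, l in zip(seqs, labels) if l == lab]
            if len(members) >= 2:
                ref = max(members, key=len)
                aln = star_align(members, ref)
                if len(aln.rows) >= 2:
                    result.consensus[f"cluster_{lab}"] = majority_consensus(aln)
        if len(result.consensus) >= 3:
            refs = sorted(result.consensus)
            ref_longest = max(result.consensus.values(), key=len)
            aln = star_align(
                [result.consensus[r] for r in refs], ref_longest, ids=refs
            )
            if len(aln.rows) >= 3:
                tree, _ = bootstrap_support(
                    aln, config.bootstrap_reps, seed=config.seed
                )
                result.tree_newick = str(tree).strip()
    if outdir is not None:
        write_outputs(result, Path(outdir), config)
    return result


# ---------------------------------------------------------------------------
# report writers (1-based closed coordinates in TSV reports, 0-based in BED)


def calls_to_frame(calls: list[InsertionCall]) -> pd.DataFrame:
    rows = []
    for call in calls:
        c = call.copy
        rows.append(
            {
                "family": c.family,
                "contig": c.contig,
                "start": c.start + 1,
                "end": c.end,
                "strand": c.strand,
                "identity": round(c.identity, 4),
                "truncated_5prime_by": c.truncated_5prime_by,
                "intact_3prime": int(c.has_intact_3prime),
                "class_5p": call.junction_5p.classification or "",
                "class_3p": call.junction_3p.classification or "",
                "target_start_3p": call.junction_3p.target_start or 0,
                "tsd_len": call.tsd_len,
                "deletion_len": call.deletion_len,
                "top_offset": "" if call.top_offset is None else call.top_offset,
            }
        )
    return pd.DataFrame(rows)


def census_to_frame(records: list[InventoryRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "contig": r.contig,
                "start": r.start + 1,
                "end": r.end,
                "strand": r.strand,
                "status": r.status,
                "missing_5prime": r.missing_5prime,
                "identity": round(r.identity, 4),
                "adjacent_family": r.adjacent_element[0] if r.adjacent_element else "",
                "adjacent_side": r.adjacent_element[1] if r.adjacent_element else "",
                "array_id": r.array_id,
            }
        )
    return pd.DataFrame(rows)


def copies_to_bed(copies: list[CopyHit]) -> pd.DataFrame:
    rows = []
    for c in copies:
        rows.append(
            {
                "contig": c.contig,
                "start": c.start,
                "end": c.end,
                "name": c.family,
                "score": c.score,
                "strand": c.strand,
                "identity": round(c.identity, 4),
                "truncated_5prime_by": c.truncated_5prime_by,
                "intact_3prime": int(c.has_intact_3prime),
            }
        )
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, outdir: Path, config: RunConfig) -> None:
    import yaml

    outdir.mkdir(parents=True, exist_ok=True)
    calls_to_frame(result.calls).to_csv(outdir / "insertions.tsv", sep="\t", index=False)
    census_to_frame(result.census).to_csv(outdir / "census.tsv", sep="\t", index=False)
    copies_to_bed(result.copies).to_csv(outdir / "copies.bed", sep="\t", index=False, header=False)
    result.table_3p.to_frame().to_csv(outdir / "specificity_3p.tsv", sep="\t", index=False)
    result.table_5p.to_frame().to_csv(outdir / "specificity_5p.tsv", sep="\t", index=False)
    summary = {"census": result.census_counts(), "n_copies": len(result.copies)}
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    with open(outdir / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    if result.consensus:
        with open(outdir / "consensus.fasta", "w") as fh:
            for name in sorted(result.consensus):
                fh.write(f">{name}\n{result.consensus[name]}\n")
    if result.tree_newick:
        (outdir / "tree.nwk").write_text(result.tree_newick + "\n")


# ---------------------------------------------------------------------------
# truth scoring


def _match_calls_to_truths(
    copies: list[CopyHit], truths: list[InsertionTruth], tol: int = 20
) -> dict[int, int]:
    """Map truth copy_id -> detected copy_id by boundary agreement."""
    mapping: dict[int, int] = {}
    by_contig: dict[str, list[CopyHit]] = {}
    for c in copies:
        by_contig.setdefault(c.contig, []).append(c)
    for t in truths:
        best = None
        for c in by_contig.get(t.contig, []):
            if abs(c.start - t.start) <= tol and abs(c.end - t.end) <= tol:
                if best is None or abs(c.start - t.start) < abs(best.start - t.start):
                    best = c
        if best is not None:
            mapping[t.copy_id] = best.copy_id
    return mapping


def score_against_truth(
    result: PipelineResult,
    truths: list[InsertionTruth],
    n_gene_loci: int | None = None,
    boundary_tol: int = 20,
) -> dict:
    """Recovery metrics of one simulated run: detection sensitivity,
    per-call geometry accuracy, census consistency and clustering ARI
    (machine-readable, JSON-safe)."""
    from sklearn.metrics import adjusted_rand_score

    copies_by_id = {c.copy_id: c for c in result.copies}
    calls_by_id = {call.copy.copy_id: call for call in result.calls}
    mapping = _match_calls_to_truths(result.copies, truths, boundary_tol)
    sensitivity = len(mapping) / len(truths) if truths else 1.0
    geom_total = geom_exact = 0
    truth_fams, det_fams = [], []
    for t in truths:
        cid = mapping.get(t.copy_id)
        if cid is None:
            continue
        truth_fams.append(t.family)
        det_fams.append(copies_by_id[cid].family)
        call = calls_by_id.get(cid)
        if call is None or call.top_offset is None:
            continue
        geom_total += 1
        if call.top_offset == t.top_offset:
            geom_exact += 1
    geometry_accuracy = geom_exact / geom_total if geom_total else float("nan")
    ari = (
        adjusted_rand_score(truth_fams, det_fams) if len(set(truth_fams)) > 0 else 1.0
    )
    out = {
        "n_truths": len(truths),
        "n_detected": len(result.copies),
        "sensitivity": sensitivity,
        "geometry_calls": geom_total,
        "geometry_accuracy": geometry_accuracy,
        "clustering_ari": float(ari),
        "census": result.census_counts(),
    }
    if n_gene_loci is not None:
        counts = result.census_counts()
        out["census_conservation"] = (
            counts["intact"] + counts["disrupted"]
        ) / n_gene_loci
    return out
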