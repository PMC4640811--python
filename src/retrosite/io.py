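"""FASTA and table I/O (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .detect import ElementFamily
from .models import TargetGeneModel
from .simulate import TRUTH_COLUMNS, InsertionTruth


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_families(path: str | Path, anchor_3prime_len: int = 70) -> list[ElementFamily]:
    return [
        ElementFamily(name, seq, anchor_3prime_len)
        for name, seq in read_fasta(path).items()
    ]


def read_target_model(
    path: str | Path,
    functional_5prime_len: int = 50,
    insertion_site: int = 38,
) -> TargetGeneModel:
    seqs = read_fasta(path)
    if len(seqs) != 1:
        raise ValueError("target model FASTA must contain exactly one record")
    ((name, seq),) = seqs.items()
    return TargetGeneModel(name, seq, functional_5prime_len, insertion_site)


def write_truths(truths: list[InsertionTruth], path: str | Path) -> None:
    from .simulate import truths_to_frame

    truths_to_frame(truths).to_csv(path, sep="\t", index=False)


def read_truths(path: str | Path) -> list[InsertionTruth]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            InsertionTruth(
                copy_id=int(row.copy_id),
                family=str(row.family),
                contig=str(row.contig),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                tsd_len=int(row.tsd_len),
                deletion_len=int(row.deletion_len),
                truncated_5prime_by=int(row.truncated_5prime_by),
                on_target=bool(row.on_target),
                nested_in=None if row.nested_in == -1 else int(row.nested_in),
                locus_index=None if row.locus_index == -1 else int(row.locus_index),
            )
        )
    return out
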