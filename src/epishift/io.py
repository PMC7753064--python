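"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED4/BED6 (tab-separated, no header), a TSV gene-model table with
comma-separated exon boundary lists, diffReps-like per-mark region tables,
DMP tables, FPKM expression matrices with a tumor/normal pairing table,
PPI edge lists, survival tables and GMT gene-set files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .integrate import ExpressionTable, MarkAlteration, MethylPosition
from .intervals import GeneModel, GenomicInterval
from .survival import SurvivalRecord


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED3/4/6; column 4, when present, becomes the payload."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3 or not fields[0]:
                raise ValueError(f"{path}:{ln}: not a BED record")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            payload = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, strand=strand, payload=payload))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from exc
    return out


def write_bed(ivs: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            payload = "" if iv.payload is None else f"\t{iv.payload}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{payload}\n")


def _opt(v) -> int | None:
    return None if pd.isna(v) or v == "" else int(v)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for r in df.itertuples():
        starts = [int(x) for x in str(r.exon_starts).split(",") if x]
        ends = [int(x) for x in str(r.exon_ends).split(",") if x]
        utr5 = (_opt(r.utr5_start), _opt(r.utr5_end)) if _opt(r.utr5_start) is not None else None
        utr3 = (_opt(r.utr3_start), _opt(r.utr3_end)) if _opt(r.utr3_start) is not None else None
        genes.append(
            GeneModel(
                gene_id=str(r.gene_id),
                chrom=str(r.chrom),
                strand=str(r.strand),
                tx_start=int(r.tx_start),
                tx_end=int(r.tx_end),
                exons=tuple(zip(starts, ends)),
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes


def read_mark_table(path: str | Path, mark: str) -> list[MarkAlteration]:
    """diffReps-like TSV: chrom, start, end, direction, log2FC, padj."""
    df = pd.read_csv(path, sep="\t")
    return [
        MarkAlteration(
            mark=mark,
            region=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            direction=str(r.direction),
            stat=float(r.log2FC),
            q=float(r.padj),
        )
        for r in df.itertuples()
    ]


def read_dmp_table(path: str | Path) -> list[MethylPosition]:
    df = pd.read_csv(path, sep="\t")
    return [
        MethylPosition(
            cpg_id=str(r.cpg_id),
            chrom=str(r.chrom),
            pos=int(r.pos),
            delta_beta=float(r.delta_beta),
            q=float(r.q),
            in_cgi=bool(r.in_cgi),
        )
        for r in df.itertuples()
    ]


def read_expression(fpkm_path: str | Path, pairing_path: str | Path) -> ExpressionTable:
    fpkm = pd.read_csv(fpkm_path, sep="\t", index_col=0)
    pairing = pd.read_csv(pairing_path, sep="\t")
    pairs = [(str(r.tumor), str(r.normal)) for r in pairing.itertuples()]
    return ExpressionTable(fpkm=fpkm, pairs=pairs)


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(r[0]), str(r[1])) for r in df.itertuples(index=False)]


def read_survival(
    survival_path: str | Path, expression_path: str | Path
) -> list[SurvivalRecord]:
    surv = pd.read_csv(survival_path, sep="\t")
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    records = []
    for r in surv.itertuples():
        records.append(
            SurvivalRecord(
                sample_id=str(r.sample_id),
                time=float(r.time),
                event=int(r.event),
                subtype=str(r.subtype),
                expression=expr.loc[str(r.sample_id)].to_dict(),
            )
        )
    return records


def read_gmt(path: str | Path) -> list[tuple[str, str, frozenset[str]]]:
    """GMT lines: term_id <tab> name <tab> gene1 <tab> gene2 ..."""
    out = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            out.append((fields[0], fields[1], frozenset(fields[2:])))
    return out
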