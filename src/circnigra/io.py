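"""Readers and writers for the standard formats used across the pipeline.

All coordinates are converted to internal 0-based half-open at parse time
(GTF is 1-based closed on disk, BED already half-open, SAM POS 1-based).
FASTA/FASTQ go through Biopython; SAM reading goes through pysam (see
editidx.pileup_from_sam); tables are pandas TSVs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Iterator, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .circdetect import BackspliceJunction, CircCountMatrix
from .synthgen import AluElement, GeneModel, GenomeModel, SampleMeta

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality string); malformed records raise."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33)
                       for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq).upper(), qual


def write_fastq(path, reads: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple[str, int, int, str, float, str]]:
    """BED6 records as (chrom, start, end, name, score, strand), half-open."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            name = f[3] if len(f) > 3 else f"feature{ln}"
            score = float(f[4]) if len(f) > 4 and f[4] != "." else 0.0
            strand = f[5] if len(f) > 5 else "+"
            out.append((f[0], start, end, name, score, strand))
    return out


def read_alu_bed(path) -> list[AluElement]:
    return [AluElement(name, chrom, s, e, strand)
            for chrom, s, e, name, _score, strand in read_bed(path)]


def write_alu_bed(path, alus: Iterable[AluElement]) -> None:
    with open(path, "w") as fh:
        for a in alus:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.alu_id}\t0\t{a.strand}\n")


# ---------------------------------------------------------------------------
# GTF (gene/exon features with a gene_id attribute)
# ---------------------------------------------------------------------------

def read_gtf(path) -> list[GeneModel]:
    """Parse gene models from exon features (1-based closed -> half-open)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    info: dict[str, tuple[str, str]] = {}
    attrs_extra: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{ln}: malformed GTF line")
            chrom, _src, feature, start, end, _score, strand, _frame, attr = f[:9]
            if feature != "exon":
                continue
            gid = None
            extra = {}
            for part in attr.strip().strip(";").split(";"):
                part = part.strip()
                if not part:
                    continue
                key, _, val = part.partition(" ")
                val = val.strip().strip('"')
                if key == "gene_id":
                    gid = val
                else:
                    extra[key] = val
            if gid is None:
                raise ValueError(f"{path}:{ln}: exon without gene_id")
            try:
                s, e = int(start) - 1, int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            exons.setdefault(gid, []).append((s, e))
            info[gid] = (chrom, strand)
            attrs_extra.setdefault(gid, {}).update(extra)
    genes = []
    for gid in exons:
        chrom, strand = info[gid]
        ex = sorted(exons[gid])
        extra = attrs_extra.get(gid, {})
        circ_idx = extra.get("circ_exon_index")
        genes.append(GeneModel(
            gene_id=gid, chrom=chrom, strand=strand, exons=ex,
            circ_exon_index=int(circ_idx) if circ_idx is not None else None,
            base_expression=float(extra.get("base_expression", 1.0)),
            circ_fraction=float(extra.get("circ_fraction", 0.0)),
        ))
    return sorted(genes, key=lambda g: (g.chrom, g.span[0]))


def write_gtf(path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            lo, hi = g.span
            base = (f'gene_id "{g.gene_id}";'
                    f' base_expression "{g.base_expression:.6g}";'
                    f' circ_fraction "{g.circ_fraction:.6g}";')
            if g.circ_exon_index is not None:
                base += f' circ_exon_index "{g.circ_exon_index}";'
            fh.write(f"{g.chrom}\tcircnigra\tgene\t{lo + 1}\t{hi}\t.\t"
                     f"{g.strand}\t.\t{base}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tcircnigra\texon\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t.\t{base}\n")


# ---------------------------------------------------------------------------
# sample metadata and generic tables
# ---------------------------------------------------------------------------

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(path, df: pd.DataFrame, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_meta(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "region", "condition", "age", "sex"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata lacks columns: {sorted(missing)}")
    return meta.set_index("sample_id", drop=False)


def write_meta(path, samples: Iterable[SampleMeta]) -> None:
    rows = [{"sample_id": s.sample_id, "region": s.region,
             "condition": s.condition, "age": s.age, "sex": s.sex}
            for s in samples]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def meta_to_samples(meta: pd.DataFrame) -> list[SampleMeta]:
    return [SampleMeta(sample_id=str(r["sample_id"]), region=r["region"],
                       condition=r["condition"], age=float(r["age"]),
                       sex=r["sex"])
            for _i, r in meta.iterrows()]


# ---------------------------------------------------------------------------
# junction count tables (BED6-compatible first six columns)
# ---------------------------------------------------------------------------

def write_counts_tsv(path, matrix: CircCountMatrix) -> None:
    samples = list(matrix.counts.columns)
    with open(path, "w") as fh:
        fh.write("#mapped_totals\t" + "\t".join(
            f"{s}={int(matrix.mapped_totals[s])}" for s in samples) + "\n")
        fh.write("\t".join(["chrom", "start", "end", "name", "score",
                            "strand"] + samples) + "\n")
        for j in matrix.junctions:
            row = matrix.counts.loc[j.key]
            fh.write("\t".join(
                [j.chrom, str(j.start), str(j.end), j.key,
                 str(int(row.sum())), j.strand]
                + [str(int(row[s])) for s in samples]) + "\n")


def read_counts_tsv(path) -> CircCountMatrix:
    mapped: dict[str, int] = {}
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#mapped_totals"):
            raise ValueError(f"{path}: missing #mapped_totals header")
        for part in first.split("\t")[1:]:
            sid, _, val = part.partition("=")
            mapped[sid] = int(val)
        df = pd.read_csv(fh, sep="\t")
    samples = [c for c in df.columns
               if c not in ("chrom", "start", "end", "name", "score", "strand")]
    junctions = [BackspliceJunction(r["chrom"], int(r["start"]), int(r["end"]),
                                    r["strand"])
                 for _i, r in df.iterrows()]
    counts = df[samples].copy()
    counts.index = [j.key for j in junctions]
    return CircCountMatrix(
        junctions=junctions, counts=counts,
        mapped_totals=pd.Series(mapped).reindex(samples),
    )
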