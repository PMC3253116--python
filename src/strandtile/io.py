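"""Readers and writers for the formats the pipeline exchanges.

FASTA goes through Biopython, GFF3 through gffutils (in-memory DB on read;
1-based closed coordinates converted to the internal 0-based half-open
convention), tables through pandas.  Per-gene expression tables can also be
ingested from spreadsheet files whose column layout mirrors the published
per-gene sense/antisense supplementary tables.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core_model import (
    GeneModel,
    Genome,
    GenomeSequence,
    IntensityMatrix,
    ProbeMap,
    SampleInfo,
)


# ---------------------------------------------------------------- FASTA

def read_genome_fasta(path: str | Path) -> Genome:
    chroms = [
        GenomeSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    return Genome(chroms)


def write_genome_fasta(genome: Genome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(c.sequence), id=c.chrom_id, description="")
        for c in genome
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------- GFF3

def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene + mRNA + exon + CDS features, converting to 1-based closed."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.utr3_end is not None:
                attrs += f";utr3_end={g.utr3_end}"
            fh.write(
                f"{g.chrom}\tstrandtile\tgene\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tstrandtile\tmRNA\t{g.cds_start + 1}\t{g.cds_end}\t.\t"
                f"{g.strand}\t.\tID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            exons = g.exons or ((g.cds_start, g.cds_end),)
            for i, (s, e) in enumerate(exons, 1):
                for ftype in ("exon", "CDS"):
                    fh.write(
                        f"{g.chrom}\tstrandtile\t{ftype}\t{s + 1}\t{e}\t.\t"
                        f"{g.strand}\t.\tID={g.gene_id}.1.{ftype}{i};"
                        f"Parent={g.gene_id}.1\n"
                    )


def read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons = []
        for mrna in db.children(gene, featuretype="mRNA"):
            for exon in db.children(mrna, featuretype="exon"):
                exons.append((exon.start - 1, exon.end))
        exons.sort()
        if exons == [(gene.start - 1, gene.end)]:
            exons = []  # trivial single exon spanning the CDS
        utr3_end = gene.attributes.get("utr3_end")
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                cds_start=gene.start - 1,
                cds_end=gene.end,
                exons=tuple(exons),
                utr3_end=int(utr3_end[0]) if utr3_end else None,
            )
        )
    return genes


# ---------------------------------------------------------------- tables

def write_probe_tsv(probes: ProbeMap, path: str | Path) -> None:
    probes.to_frame().to_csv(path, sep="\t", index=False)


def read_probe_tsv(path: str | Path) -> ProbeMap:
    return ProbeMap.from_frame(pd.read_csv(path, sep="\t"))


def write_intensity_tsv(matrix: IntensityMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    meta = pd.DataFrame(
        [(s.sample, s.condition, s.channel) for s in matrix.samples.values()],
        columns=["sample", "condition", "channel"],
    )
    with open(path, "w") as fh:
        for row in meta.itertuples(index=False):
            fh.write(f"#sample\t{row.sample}\t{row.condition}\t{row.channel}\n")
        df.to_csv(fh, sep="\t")


def read_intensity_tsv(path: str | Path) -> IntensityMatrix:
    samples: list[SampleInfo] = []
    body_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#sample\t"):
                _, name, condition, channel = line.rstrip("\n").split("\t")
                samples.append(SampleInfo(name, condition, channel))
            else:
                body_lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(body_lines)), sep="\t", index_col="probe_id")
    return IntensityMatrix(df, samples)


def write_segments_bed(segments, path: str | Path) -> None:
    """BED6: name = segment id, score = mean intensity scaled to [0,1000]."""
    rows = []
    means = [s.mean_intensity for s in segments]
    lo = min(means, default=0.0)
    hi = max(means, default=1.0)
    span = (hi - lo) or 1.0
    for i, s in enumerate(segments):
        score = int(round(1000 * (s.mean_intensity - lo) / span))
        rows.append(
            f"{s.chrom}\t{s.genomic_start}\t{s.genomic_end}\tseg_{i:05d}\t"
            f"{score}\t{s.strand}"
        )
    Path(path).write_text("\n".join(rows) + ("\n" if rows else ""))


# ----------------------------------------------- per-gene expression tables

SENSE_SUFFIX = "_sense"
ANTISENSE_SUFFIX = "_antisense"


def write_gene_expression_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Wide per-gene table: index gene_id, columns <sample>_sense / <sample>_antisense."""
    out = table.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_gene_expression_table(path: str | Path) -> pd.DataFrame:
    """Read a wide per-gene sense/antisense table from TSV/CSV or XLS(X).

    The expected layout mirrors the published per-gene supplementary tables:
    one row per gene, one pair of columns per sample named
    ``<sample>_sense`` / ``<sample>_antisense`` (case-insensitive; spaces
    accepted in place of underscores).
    """
    path = Path(path)
    if path.suffix.lower() in (".xls", ".xlsx"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path, sep="\t" if path.suffix.lower() != ".csv" else ",")
    df.columns = [str(c).strip().lower().replace(" ", "_") for c in df.columns]
    gene_col = next(
        (c for c in df.columns if c in ("gene_id", "gene", "systematic_name", "orf")),
        df.columns[0],
    )
    df = df.set_index(gene_col)
    keep = [
        c
        for c in df.columns
        if c.endswith(SENSE_SUFFIX) or c.endswith(ANTISENSE_SUFFIX)
    ]
    return df[keep].astype(float)


def sample_view(table: pd.DataFrame, sample: str) -> pd.DataFrame:
    """Extract one sample's (sense_avg, antisense_avg) frame from a wide table."""
    sense = table[f"{sample}{SENSE_SUFFIX}"]
    anti = table[f"{sample}{ANTISENSE_SUFFIX}"]
    return pd.DataFrame({"sense_avg": sense, "antisense_avg": anti})
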