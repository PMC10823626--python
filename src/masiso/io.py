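"""Readers and writers for the standard formats the workflow touches.

GTF is written 1-based inclusive and read back through gffutils; FASTA and
FASTQ go through Biopython; BED12 blocks map to exon chains (0-based
half-open). Internal coordinates are always 0-based half-open.
"""

from __future__ import annotations

import os
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import Annotation, GenomeSequence, TranscriptModel


class FormatError(ValueError):
    """Malformed record, reported with its line number."""


# --------------------------------------------------------------- FASTA/FASTQ

def write_fasta(path: str | os.PathLike, records: list[GenomeSequence] | list[tuple[str, str]],
                wrap: int = 60) -> None:
    seqs = []
    for rec in records:
        if isinstance(rec, GenomeSequence):
            name, seq = rec.contig_id, rec.sequence
        else:
            name, seq = rec
        seqs.append(SeqRecord(Seq(seq), id=name, description=""))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=wrap)
    writer.write_file(seqs)


def read_fasta(path: str | os.PathLike) -> list[GenomeSequence]:
    return [GenomeSequence(r.id, str(r.seq).upper())
            for r in SeqIO.parse(str(path), "fasta")]


def write_fastq(path: str | os.PathLike, reads: list[tuple[str, str]],
                quality: int = 30) -> None:
    """Write reads with a uniform Phred quality (HiFi proxy)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


def read_fastx(path: str | os.PathLike) -> list[tuple[str, str]]:
    fmt = "fastq" if str(path).endswith(("fastq", "fq")) else "fasta"
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), fmt)]


# ----------------------------------------------------------------------- GTF

def write_gtf(path: str | os.PathLike, annotation: Annotation,
              source: str = "masiso") -> None:
    """Emit gene/transcript/exon features, 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        for gene in sorted(annotation.genes.values(),
                           key=lambda g: (g.contig_id, g.start, g.gene_id)):
            attrs = f'gene_id "{gene.gene_id}";'
            fh.write("\t".join([gene.contig_id, source, "gene",
                                str(gene.start + 1), str(gene.end), ".",
                                gene.strand, ".", attrs]) + "\n")
            for t in sorted(annotation.transcripts_of_gene(gene.gene_id),
                            key=lambda t: t.transcript_id):
                attrs = (f'gene_id "{gene.gene_id}"; '
                         f'transcript_id "{t.transcript_id}"; '
                         f'spike_class "{t.spike_class}";')
                fh.write("\t".join([t.contig_id, source, "transcript",
                                    str(t.start + 1), str(t.end), ".",
                                    t.strand, ".", attrs]) + "\n")
                for s, e in t.exons:
                    fh.write("\t".join([t.contig_id, source, "exon",
                                        str(s + 1), str(e), ".",
                                        t.strand, ".", attrs]) + "\n")


def read_gtf(path: str | os.PathLike) -> Annotation:
    """Read a GTF back into an Annotation (coordinates converted to 0-based)."""
    db = gffutils.create_db(str(path), ":memory:", force=True,
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    transcripts = []
    for tf in db.features_of_type("transcript"):
        exons = sorted((e.start - 1, e.end)
                       for e in db.children(tf, featuretype="exon"))
        spike = tf.attributes.get("spike_class", ["background"])[0]
        transcripts.append(TranscriptModel(
            transcript_id=tf.attributes["transcript_id"][0],
            gene_id=tf.attributes["gene_id"][0],
            contig_id=tf.seqid,
            strand=tf.strand,
            exons=tuple(exons),
            spike_class=spike,
        ))
    return Annotation(transcripts)


# --------------------------------------------------------------------- BED12

def write_bed12(path: str | os.PathLike,
                chains: list[tuple[str, TranscriptModel]] | list[TranscriptModel]) -> None:
    """Write exon chains as BED12 (0-based half-open, blocks relative to start)."""
    with open(path, "w") as fh:
        for item in chains:
            name, t = item if isinstance(item, tuple) else (item.transcript_id, item)
            start, end = t.start, t.end
            sizes = ",".join(str(e - s) for s, e in t.exons) + ","
            starts = ",".join(str(s - start) for s, e in t.exons) + ","
            fh.write("\t".join([
                t.contig_id, str(start), str(end), name, "0", t.strand,
                str(start), str(end), "0,0,0", str(len(t.exons)), sizes, starts,
            ]) + "\n")


def read_bed12(path: str | os.PathLike) -> list[TranscriptModel]:
    """Parse BED12 lines into exon-chain transcript models.

    The BED name field becomes both transcript_id and gene_id (callers may
    re-gene them); malformed lines raise FormatError with the line number.
    """
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED fields")
            try:
                contig, start, end = fields[0], int(fields[1]), int(fields[2])
                name, strand = fields[3], fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(f"{path}:{lineno}: block count mismatch")
            exons = tuple((start + o, start + o + s)
                          for o, s in zip(offsets, sizes))
            if exons[-1][1] != end:
                raise FormatError(f"{path}:{lineno}: blocks do not span chromEnd")
            models.append(TranscriptModel(name, name, contig, strand, exons))
    return models


# ----------------------------------------------------------------------- TSV

def write_tsv(path: str | os.PathLike, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_expression_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Short-read expression table with columns transcript_id, tpm."""
    df = pd.read_csv(path, sep="\t")
    missing = {"transcript_id", "tpm"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def ensure_dir(path: str | os.PathLike) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
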