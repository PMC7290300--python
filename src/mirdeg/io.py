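"""Readers/writers for the text formats the pipeline exchanges.

FASTA/FASTQ go through Biopython's SeqIO (gzip-transparent on input).
GFF3 output is 1-based inclusive; BED6 is 0-based half-open, per the
respective conventions.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .srna import Cluster, SmallRnaTag
from .synthetic import TruthSet


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> dict[str, str]:
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | Path, descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    records = [
        SeqRecord(Seq(s), id=name, description=descriptions.get(name, ""))
        for name, s in seqs.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fastq(path: str | Path) -> list[str]:
    with _open_text(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "read") -> None:
    """Write reads with constant Phred-40 quality ('I')."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads, 1):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_tags_fasta(tags: Sequence[SmallRnaTag], path: str | Path) -> None:
    """Collapsed tags as FASTA with count/rpm annotations in the header."""
    with open(path, "w") as fh:
        for i, t in enumerate(tags, 1):
            fh.write(f">tag_{i} count={t.raw_count} rpm={t.rpm:.3f}\n{t.sequence}\n")


def write_clusters_bed(clusters: Sequence[Cluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(clusters, 1):
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\tcluster_{i}\t"
                f"{c.total_rpm:.1f}\t{c.strand}\n"
            )


def write_cluster_histograms(clusters: Sequence[Cluster], path: str | Path) -> None:
    rows = []
    for i, c in enumerate(clusters, 1):
        for length, rpm in sorted(c.length_histogram().items()):
            rows.append(dict(cluster=f"cluster_{i}", length=length, rpm=rpm))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth_gff3(truth: TruthSet, path: str | Path) -> None:
    """MIR gene truth (gene/exon/intron/precursor/mature/star) as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in truth.mir_genes:
            def line(ftype: str, span: tuple[int, int], attrs: str) -> str:
                return (
                    f"{g.chrom}\tmirdeg\t{ftype}\t{span[0] + 1}\t{span[1]}\t.\t"
                    f"{g.strand}\t.\t{attrs}\n"
                )

            fh.write(line("MIR_gene", g.pri_span, f"ID={g.gene_id}"))
            for i, e in enumerate(g.exon_spans, 1):
                fh.write(line("exon", e, f"ID={g.gene_id}.exon{i};Parent={g.gene_id}"))
            for i, iv in enumerate(g.intron_spans, 1):
                fh.write(line("intron", iv, f"ID={g.gene_id}.intron{i};Parent={g.gene_id}"))
            fh.write(line("miRNA_primary_transcript", g.precursor_span, f"ID={g.gene_id}.prec;Parent={g.gene_id}"))
            for m in g.matures:
                fh.write(line("miRNA", m.genomic_span, f"ID={m.mirna_id};Parent={g.gene_id}.prec"))
                fh.write(line("miRNA_star", m.star_genomic_span, f"ID={m.mirna_id}.star;Parent={g.gene_id}.prec"))


def write_qpcr_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_qpcr_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
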