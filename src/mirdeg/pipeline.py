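"""End-to-end convenience wrappers chaining the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from . import degradome, discovery, srna
from .fold import FoldingEngine
from .synthetic import TruthSet


@dataclass
class SrnaResult:
    tags: list[srna.SmallRnaTag]
    clusters: list[srna.Cluster]
    unplaced: list[srna.SmallRnaTag]
    stats: dict[str, int]


def run_srna_pipeline(
    reads: Sequence[str],
    adapter: str,
    genome: Mapping[str, str],
    library_id: str,
    min_overlap: int = srna.MIN_OVERLAP_DEFAULT,
    max_mismatch_rate: float = 0.1,
    max_gap: int = srna.MAX_GAP_DEFAULT,
) -> SrnaResult:
    """Trim, filter, collapse/normalize, map and cluster one sRNA library."""
    retained, stats = srna.trim_and_filter(reads, adapter, min_overlap, max_mismatch_rate)
    tags = srna.collapse_normalize(retained, library_id)
    clusters, unplaced = srna.map_and_cluster(tags, genome, max_gap=max_gap)
    return SrnaResult(tags, clusters, unplaced, stats)


def discover_mirnas(
    result: SrnaResult,
    genome: Mapping[str, str],
    catalog: Mapping[str, str],
    folder: FoldingEngine | None = None,
    min_reads: int = discovery.MIN_READS_DEFAULT,
) -> list[discovery.MirnaCall]:
    tag_seqs = {t.sequence for t in result.tags}
    return discovery.discover_from_clusters(
        result.clusters, genome, catalog, folder, tag_seqs, min_reads=min_reads
    )


def confirm_targets(
    calls: Sequence[discovery.MirnaCall] | Mapping[str, str],
    pare_reads: Sequence[str],
    adapter: str,
    transcriptome: Mapping[str, str],
    max_score: int = degradome.DEFAULT_MAX_SCORE,
    max_rank: int = degradome.DEFAULT_MAX_RANK,
) -> tuple[list[degradome.TargetCall], degradome.Pileup]:
    """Degradome confirmation of miRNA targets for a set of miRNA calls."""
    if isinstance(calls, Mapping):
        mirnas = dict(calls)
    else:
        mirnas = {c.mirna_id: c.mature_seq for c in calls}
    tags = degradome.process_pare_reads(pare_reads, adapter)
    pileup = degradome.build_pileup(tags, transcriptome)
    accepted, _ = degradome.call_targets(
        mirnas, pileup, transcriptome, max_score=max_score, max_rank=max_rank
    )
    return accepted, pileup


def mir_locus_length_mode(
    clusters: Sequence[srna.Cluster], truth: TruthSet
) -> int:
    """Pooled modal tag length over clusters intersecting planted MIR loci."""
    loci = truth.mir_locus_spans()
    pooled: dict[int, float] = {}
    for c in clusters:
        hit = any(
            c.chrom == chrom and c.strand == strand and c.start < end and c.end > start
            for chrom, strand, start, end in loci
        )
        if not hit:
            continue
        for length, rpm in c.length_histogram().items():
            pooled[length] = pooled.get(length, 0.0) + rpm
    return srna.modal_length(pooled)
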