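"""Synthetic ground truth for the miRNA discovery / degradome pipeline.

Generates a miniature genome with planted MIR genes, a transcriptome with
planted miRNA target sites, and read libraries (sRNA-seq, degradome/PARE)
plus RT-qPCR Ct tables carrying the statistical structure the downstream
analysis assumes:

* each MIR gene's precursor is a perfect inverted repeat, so its hairpin
  contains the mature miRNA on one stem arm with the miRNA* on the other
  arm under the canonical 2-nt 3' overhang duplex geometry;
* one gene yields two distinct mature miRNAs from opposite arms of the same
  precursor, and some MIR genes carry U2-type (GT...AG) introns with the
  precursor in the second exon;
* sRNA libraries are dominated by 21-nt miRNA reads, with miRNA* at a small
  fraction of miRNA abundance and a configurable background of random
  genomic 18-26-mers, all with a 3' sequencing adapter appended;
* degradome tags are 26-27-mers whose 5' ends sit at the slicer position —
  the target residue paired to miRNA nucleotide 10 counted from the miRNA
  5' end (cleavage between the residues paired to nucleotides 10 and 11);
* the experimental design is a drought series (control 70% SWC, 30% SWC
  mild, 20% SWC severe, rewatering; 3 biological replicates) in which
  planted miRNAs are downregulated and their targets upregulated.

Library read counts are sampled per feature as independent Poisson draws
with means proportional to absolute transcript abundance at a fixed nominal
depth, so planted condition effects act directly on expected read counts.
Replicate-level biological noise is a lognormal factor (sd in log2 units).

All generators are deterministic for a fixed (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._seq import random_seq, revcomp

# fixed 33-nt synthetic 3' adapter (no biological meaning)
ADAPTER = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"

DROUGHT_CONDITIONS = ("control_70SWC", "drought_30SWC", "drought_20SWC", "rewatering")
# drought response defaults: miRNAs go down, targets go up (reciprocally).
# Magnitudes are generator choices mimicking the qualitative pattern only.
MIRNA_DROUGHT_FACTORS = {
    "control_70SWC": 1.0,
    "drought_30SWC": 0.5,
    "drought_20SWC": 0.25,
    "rewatering": 0.6,
}
TARGET_DROUGHT_FACTORS = {c: 1.0 / f for c, f in MIRNA_DROUGHT_FACTORS.items()}


# ---------------------------------------------------------------------------
# configuration and truth types


@dataclass(frozen=True)
class GeneratorConfig:
    n_mir: int = 6
    genome_size: int = 50_000
    n_chrom: int = 2
    mirna_len: int = 21
    adapter: str = ADAPTER
    two_arm: bool = True  # first gene yields two miRNAs from opposite arms
    n_intron_genes: int = 2
    intron_len: int = 80
    exon1_len: int = 120
    loop_len: int = 10
    pad5: int = 8  # bases 5' of the mature on its arm
    pad3: int = 15  # bases 3' of the mature on its arm
    two_arm_pad3: int = 30  # longer arm for the two-miRNA precursor
    prec_flank: int = 40  # exonic flank around the precursor
    bg_fraction: float = 0.3  # background share of a control library
    bg_locus_fraction: float = 0.98  # background drawn from discrete noise loci
    n_noise_loci: int = 30
    noise_locus_len: int = 500
    star_fraction: float = 0.1  # miRNA* abundance relative to its miRNA
    # 3'-end length-variant probabilities (offset vs mature length)
    variant_probs: tuple[tuple[int, float], ...] = ((0, 0.84), (-1, 0.07), (1, 0.06), (-2, 0.03))
    depth: int = 30_000
    noise_sd: float = 0.1  # replicate-level lognormal noise, log2 units
    replicates: int = 3
    conditions: tuple[str, ...] = DROUGHT_CONDITIONS
    mirna_factors: tuple[tuple[str, float], ...] = tuple(MIRNA_DROUGHT_FACTORS.items())
    target_factors: tuple[tuple[str, float], ...] = tuple(TARGET_DROUGHT_FACTORS.items())
    transcript_len: int = 600
    site_pos: int = 250  # 0-based start of the planted target site
    n_background_transcripts: int = 2
    pare_signal: int = 60
    pare_background_per_transcript: float = 20.0
    pare_tag_lens: tuple[int, ...] = (26, 27)
    qpcr_noise_sd: float = 0.1
    base_ct_range: tuple[float, float] = (24.0, 30.0)
    reference_gene: str = "ARF1-like"
    max_compliance: int = 7  # planted duplexes are perfect (score 0) <= this


@dataclass(frozen=True)
class MatureMirna:
    mirna_id: str
    sequence: str
    arm: str  # "5p" or "3p"
    prec_span: tuple[int, int]  # 0-based half-open, precursor coordinates
    star_sequence: str
    star_prec_span: tuple[int, int]
    genomic_span: tuple[int, int]
    star_genomic_span: tuple[int, int]


@dataclass(frozen=True)
class MirGeneTruth:
    gene_id: str
    chrom: str
    strand: str
    pri_span: tuple[int, int]  # genomic, 0-based half-open
    exon_spans: tuple[tuple[int, int], ...]
    intron_spans: tuple[tuple[int, int], ...]
    precursor_span: tuple[int, int]
    precursor_seq: str  # transcribed (sense) orientation
    pri_seq: str  # spliced pri-miRNA, sense orientation
    gene_seq: str  # unspliced, sense orientation
    precursor_exon_index: int  # 0-based index of the precursor-bearing exon
    matures: tuple[MatureMirna, ...]


@dataclass(frozen=True)
class TargetLink:
    mirna_id: str
    transcript_id: str
    slicer_pos: int  # 1-based transcript position paired to miRNA nt 10


@dataclass(frozen=True)
class ExperimentDesign:
    conditions: tuple[str, ...]
    replicates: int
    mirna_effects: Mapping[str, Mapping[str, float]]  # mirna_id -> condition -> factor
    target_effects: Mapping[str, Mapping[str, float]]  # transcript_id -> condition -> factor
    depth: int
    noise_sd: float
    reference_gene: str

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("design needs >= 2 replicates per condition")
        for effects in (self.mirna_effects, self.target_effects):
            for per_cond in effects.values():
                if any(f <= 0 for f in per_cond.values()):
                    raise ValueError("effect factors must be > 0")


@dataclass(frozen=True)
class TruthSet:
    genome: Mapping[str, str]
    transcripts: Mapping[str, str]
    mir_genes: tuple[MirGeneTruth, ...]
    target_links: tuple[TargetLink, ...]
    design: ExperimentDesign
    config: GeneratorConfig
    base_abundance: Mapping[str, float]  # mirna_id -> relative abundance
    noise_loci: tuple[tuple[str, int, int], ...] = ()  # background sRNA hotspots

    def mature_sequences(self) -> dict[str, str]:
        return {m.mirna_id: m.sequence for g in self.mir_genes for m in g.matures}

    def star_sequences(self) -> dict[str, str]:
        return {m.mirna_id: m.star_sequence for g in self.mir_genes for m in g.matures}

    def mir_locus_spans(self) -> list[tuple[str, str, int, int]]:
        return [(g.chrom, g.strand, *g.pri_span) for g in self.mir_genes]


# ---------------------------------------------------------------------------
# truth construction


def _duplex_star_span(mature_span: tuple[int, int], n: int) -> tuple[int, int]:
    """Star span for a mature span on a perfect inverted-repeat precursor.

    With pairing i <-> n-1-i, the star is the partner interval shifted 3' by
    2 nt, which realises 2-nt 3' overhangs at both ends of the duplex.
    """
    a, b = mature_span
    k = b - a
    return (n - k - a + 2, n - a + 2)


def _plant_stem_wobbles(prec: list[str], span: tuple[int, int], n: int) -> None:
    """Break the exact inverted-repeat symmetry opposite one mature span.

    Two stem positions pairing inside the mature are converted to G:U
    wobbles (or, when the mature base allows neither, plain mismatches) by
    mutating the partner base. Real precursor stems are imperfect, and
    without this every mature would map to both hairpin arms and be
    discarded as a multi-mapper.
    """
    a, b = span
    candidates = [i for i in range(a + 3, b - 3) if prec[i] in "GT"]
    if len(candidates) >= 2:
        picks = [candidates[0], candidates[-1]]
        if picks[1] - picks[0] < 4 and len(candidates) > 2:
            picks[1] = candidates[len(candidates) // 2]
    else:
        picks = [a + 5, b - 6]
    for i in picks:
        j = n - 1 - i
        base = prec[i]
        if base == "G":
            prec[j] = "T"  # G:U wobble
        elif base == "T":
            prec[j] = "G"  # U:G wobble
        else:
            prec[j] = {"A": "C", "C": "A"}[base]  # mismatch


def _build_precursor(rng: np.random.Generator, cfg: GeneratorConfig, two_arm: bool):
    k = cfg.mirna_len
    pad3 = cfg.two_arm_pad3 if two_arm else cfg.pad3
    arm_len = cfg.pad5 + k + pad3
    if k > arm_len or cfg.pad5 < 2:
        raise ValueError("miRNA length exceeds precursor arm capacity")
    arm5 = random_seq(rng, arm_len)
    loop = random_seq(rng, cfg.loop_len)
    prec = arm5 + loop + revcomp(arm5)
    n = len(prec)
    spans = [(cfg.pad5, cfg.pad5 + k)]
    if two_arm:
        c = arm_len + cfg.loop_len + 4
        star1_start = _duplex_star_span(spans[0], n)[0]
        if c + k + 2 > star1_start:
            raise ValueError("two-arm precursor arms too short for a second miRNA")
        spans.append((c, c + k))
    mutable = list(prec)
    for span in spans:
        # partner region of each mature is disjoint from every other mature,
        # so mutating it never rewrites another planted sequence
        pa, pb = n - span[1], n - span[0]
        for oa, ob in spans:
            if (oa, ob) != span and not (pb <= oa or pa >= ob):
                raise ValueError("mature spans and partner regions collide")
        _plant_stem_wobbles(mutable, span, n)
    return "".join(mutable), spans


def _genomic_span(gene_span: tuple[int, int], gene_len: int, offset: int, strand: str):
    a, b = gene_span
    if strand == "+":
        return (offset + a, offset + b)
    return (offset + gene_len - b, offset + gene_len - a)


def generate_truth(config: GeneratorConfig | None = None, seed: int = 0) -> TruthSet:
    """Build a deterministic TruthSet satisfying all planted invariants."""
    cfg = config or GeneratorConfig()
    ss = np.random.SeedSequence([int(seed), 9001])
    rng_gene, rng_genome, rng_tx, rng_ab, rng_noise = [
        np.random.default_rng(s) for s in ss.spawn(5)
    ]

    # -- genes (sequences + precursor-relative truth) ------------------------
    proto = []  # (gene_id, strand, gene_seq, pri_seq, exon/intron spans in gene coords, prec offset, prec, mature spans)
    for i in range(cfg.n_mir):
        two_arm = cfg.two_arm and i == 0
        has_intron = (not two_arm) and len([p for p in proto if p["introns"]]) < cfg.n_intron_genes
        prec, mspans = _build_precursor(rng_gene, cfg, two_arm)
        exon_with_prec = (
            random_seq(rng_gene, cfg.prec_flank) + prec + random_seq(rng_gene, cfg.prec_flank)
        )
        prec_off_in_exon = cfg.prec_flank
        if has_intron:
            exon1 = random_seq(rng_gene, cfg.exon1_len)
            intron = "GT" + random_seq(rng_gene, cfg.intron_len - 4) + "AG"
            gene_seq = exon1 + intron + exon_with_prec
            exons = [(0, len(exon1)), (len(exon1) + len(intron), len(gene_seq))]
            introns = [(len(exon1), len(exon1) + len(intron))]
            prec_exon_idx = 1
            prec_off = exons[1][0] + prec_off_in_exon
            pri_seq = exon1 + exon_with_prec
        else:
            gene_seq = exon_with_prec
            exons = [(0, len(gene_seq))]
            introns = []
            prec_exon_idx = 0
            prec_off = prec_off_in_exon
            pri_seq = gene_seq
        proto.append(
            dict(
                gene_id=f"MIR{i + 1}",
                strand="+" if i % 2 == 0 else "-",
                gene_seq=gene_seq,
                pri_seq=pri_seq,
                exons=exons,
                introns=introns,
                prec_exon_idx=prec_exon_idx,
                prec_off=prec_off,
                prec=prec,
                mspans=mspans,
                two_arm=two_arm,
            )
        )

    # -- chromosome assembly -------------------------------------------------
    per_chrom: list[list[dict]] = [[] for _ in range(cfg.n_chrom)]
    for i, p in enumerate(proto):
        per_chrom[i % cfg.n_chrom].append(p)
    genome: dict[str, str] = {}
    mir_genes: list[MirGeneTruth] = []
    chrom_target = cfg.genome_size // cfg.n_chrom
    for ci, genes_here in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        gene_total = sum(len(p["gene_seq"]) for p in genes_here)
        spacer = max(200, (chrom_target - gene_total) // (len(genes_here) + 1)) if genes_here else chrom_target
        parts: list[str] = []
        pos = 0
        for p in genes_here:
            sp = random_seq(rng_genome, spacer)
            parts.append(sp)
            pos += len(sp)
            glen = len(p["gene_seq"])
            segment = p["gene_seq"] if p["strand"] == "+" else revcomp(p["gene_seq"])
            parts.append(segment)
            offset = pos
            pos += glen

            gspan = lambda s: _genomic_span(s, glen, offset, p["strand"])  # noqa: E731
            prec_span_gene = (p["prec_off"], p["prec_off"] + len(p["prec"]))
            matures = []
            for j, (ma, mb) in enumerate(p["mspans"]):
                arm = "5p" if mb <= (len(p["prec"]) - cfg.loop_len) // 2 + 1 else "3p"
                sa, sb = _duplex_star_span((ma, mb), len(p["prec"]))
                mid = f"syn-miR{p['gene_id'][3:]}-{arm}" if len(p["mspans"]) > 1 else f"syn-miR{p['gene_id'][3:]}"
                matures.append(
                    MatureMirna(
                        mirna_id=mid,
                        sequence=p["prec"][ma:mb],
                        arm=arm,
                        prec_span=(ma, mb),
                        star_sequence=p["prec"][sa:sb],
                        star_prec_span=(sa, sb),
                        genomic_span=gspan((p["prec_off"] + ma, p["prec_off"] + mb)),
                        star_genomic_span=gspan((p["prec_off"] + sa, p["prec_off"] + sb)),
                    )
                )
            mir_genes.append(
                MirGeneTruth(
                    gene_id=p["gene_id"],
                    chrom=chrom,
                    strand=p["strand"],
                    pri_span=gspan((0, glen)),
                    exon_spans=tuple(sorted(gspan(e) for e in p["exons"])),
                    intron_spans=tuple(sorted(gspan(iv) for iv in p["introns"])),
                    precursor_span=gspan(prec_span_gene),
                    precursor_seq=p["prec"],
                    pri_seq=p["pri_seq"],
                    gene_seq=p["gene_seq"],
                    precursor_exon_index=p["prec_exon_idx"],
                    matures=tuple(matures),
                )
            )
        parts.append(random_seq(rng_genome, max(200, chrom_target - pos)))
        genome[chrom] = "".join(parts)
    mir_genes.sort(key=lambda g: g.gene_id)

    # -- transcripts with planted slicer sites -------------------------------
    transcripts: dict[str, str] = {}
    links: list[TargetLink] = []
    k = cfg.mirna_len
    for g in mir_genes:
        for m in g.matures:
            tid = f"target_{m.mirna_id}"
            site = revcomp(m.sequence)
            tail = cfg.transcript_len - cfg.site_pos - k
            tx = random_seq(rng_tx, cfg.site_pos) + site + random_seq(rng_tx, tail)
            transcripts[tid] = tx
            # residue paired to miRNA nt 10 for a site starting at site_pos (0-based)
            links.append(TargetLink(m.mirna_id, tid, cfg.site_pos + k - 9))
    for b in range(cfg.n_background_transcripts):
        transcripts[f"bgtx_{b + 1}"] = random_seq(rng_tx, cfg.transcript_len)

    # -- design + abundances -------------------------------------------------
    mirna_ids = [m.mirna_id for g in mir_genes for m in g.matures]
    mf = dict(cfg.mirna_factors)
    tf = dict(cfg.target_factors)
    design = ExperimentDesign(
        conditions=cfg.conditions,
        replicates=cfg.replicates,
        mirna_effects={mid: dict(mf) for mid in mirna_ids},
        target_effects={f"target_{mid}": dict(tf) for mid in mirna_ids},
        depth=cfg.depth,
        noise_sd=cfg.noise_sd,
        reference_gene=cfg.reference_gene,
    )
    base_abundance = {mid: float(rng_ab.uniform(0.5, 2.0)) for mid in mirna_ids}

    # discrete background-sRNA hotspots (rRNA/degradation-like loci); most
    # non-miRNA reads come from these so intergenic space stays sparse
    chrom_ids = sorted(genome)
    noise_loci = []
    for _ in range(cfg.n_noise_loci):
        chrom = chrom_ids[int(rng_noise.integers(0, len(chrom_ids)))]
        limit = max(1, len(genome[chrom]) - cfg.noise_locus_len)
        start = int(rng_noise.integers(0, limit))
        noise_loci.append((chrom, start, start + cfg.noise_locus_len))

    truth = TruthSet(
        genome=genome,
        transcripts=transcripts,
        mir_genes=tuple(mir_genes),
        target_links=tuple(links),
        design=design,
        config=cfg,
        base_abundance=base_abundance,
        noise_loci=tuple(noise_loci),
    )
    validate_truth(truth)
    return truth


def validate_truth(truth: TruthSet) -> None:
    """String-level checks of the planted invariants; raises on violation."""
    for g in truth.mir_genes:
        chrom_seq = truth.genome[g.chrom]
        a, b = g.precursor_span
        genomic = chrom_seq[a:b]
        sense = genomic if g.strand == "+" else revcomp(genomic)
        if sense != g.precursor_seq:
            raise AssertionError(f"{g.gene_id}: precursor not at its genomic span")
        n = len(g.precursor_seq)
        for m in g.matures:
            if g.precursor_seq[slice(*m.prec_span)] != m.sequence:
                raise AssertionError(f"{m.mirna_id}: mature not at precursor span")
            if g.precursor_seq[slice(*m.star_prec_span)] != m.star_sequence:
                raise AssertionError(f"{m.mirna_id}: star not at precursor span")
            if _duplex_star_span(m.prec_span, n) != m.star_prec_span:
                raise AssertionError(f"{m.mirna_id}: star span violates 2-nt overhang rule")
        for ia, ib in g.intron_spans:
            if ib - ia < 60:
                raise AssertionError(f"{g.gene_id}: intron shorter than 60 nt")
            intron = chrom_seq[ia:ib] if g.strand == "+" else revcomp(chrom_seq[ia:ib])
            if not (intron.startswith("GT") and intron.endswith("AG")):
                raise AssertionError(f"{g.gene_id}: intron is not GT...AG")
    matures = truth.mature_sequences()
    for link in truth.target_links:
        tx = truth.transcripts[link.transcript_id]
        mseq = matures[link.mirna_id]
        k = len(mseq)
        start = tx.find(revcomp(mseq))
        if start < 0:
            raise AssertionError(f"{link.mirna_id}: planted site missing from transcript")
        if link.slicer_pos != start + k - 9:
            raise AssertionError(
                f"{link.mirna_id}: slicer position not paired to miRNA nt 10"
            )


# ---------------------------------------------------------------------------
# read-library simulation


def _library_rng(seed: int, *extras: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, extras)]))


def simulate_srna_library(
    truth: TruthSet, condition: str, replicate: int, seed: int = 0
) -> list[str]:
    """Simulate one adapter-ligated sRNA library as a list of read sequences.

    Per-feature counts are Poisson with mean = nominal depth x relative
    abundance x condition effect x lognormal replicate noise. Mature reads
    carry small 3'-end length variants taken from the precursor context, so
    the insert length distribution is centred on the mature length (21 nt by
    default); miRNA* is emitted at ``star_fraction`` of its miRNA; background
    reads are uniform random genomic 18-26-mers.
    """
    design = truth.design
    if condition not in design.conditions:
        raise ValueError(f"unknown condition {condition!r}")
    cfg = truth.config
    rng = _library_rng(seed, design.conditions.index(condition), replicate)
    if design.depth <= 0:
        return []

    total_base = sum(truth.base_abundance.values())
    unit = design.depth * (1.0 - cfg.bg_fraction) / (total_base * (1.0 + cfg.star_fraction))
    reads: list[str] = []

    prec_by_mirna = {
        m.mirna_id: (g.precursor_seq, m.prec_span)
        for g in truth.mir_genes
        for m in g.matures
    }
    star_by_mirna = truth.star_sequences()
    for mid in sorted(truth.base_abundance):
        eff = design.mirna_effects[mid][condition]
        noise = 2.0 ** rng.normal(0.0, design.noise_sd)
        mean = unit * truth.base_abundance[mid] * eff * noise
        prec, (ma, mb) = prec_by_mirna[mid]
        for off, prob in cfg.variant_probs:
            hi = mb + off
            if hi <= ma or hi > len(prec):
                continue
            n = rng.poisson(mean * prob)
            if n:
                reads.extend([prec[ma:hi] + cfg.adapter] * int(n))
        n_star = rng.poisson(mean * cfg.star_fraction)
        if n_star:
            reads.extend([star_by_mirna[mid] + cfg.adapter] * int(n_star))

    n_bg = int(rng.poisson(design.depth * cfg.bg_fraction))
    chroms = sorted(truth.genome)
    lens = np.array([len(truth.genome[c]) for c in chroms], dtype=float)
    probs = lens / lens.sum()
    loci = truth.noise_loci
    for _ in range(n_bg):
        ln = int(rng.integers(18, 27))
        if loci and rng.random() < cfg.bg_locus_fraction:
            chrom, lo, hi = loci[int(rng.integers(0, len(loci)))]
            seq = truth.genome[chrom]
            start = int(rng.integers(lo, min(hi, len(seq) - ln)))
        else:
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            seq = truth.genome[chrom]
            start = int(rng.integers(0, len(seq) - ln))
        frag = seq[start : start + ln]
        if rng.random() < 0.5:
            frag = revcomp(frag)
        reads.append(frag + cfg.adapter)
    return reads


def simulate_pare_library(
    truth: TruthSet,
    seed: int = 0,
    signal: int | None = None,
    background: float | None = None,
) -> tuple[list[str], list[TargetLink]]:
    """Simulate degradome/PARE tags (adapter-ligated 26-27-mers).

    For each target link, ``signal`` tags start exactly at the slicer
    position; background tags are uniform over every transcript. Links whose
    slicer position leaves fewer than 14 nt to the transcript 3' end are
    skipped and returned in the flagged list (tags are truncated when at
    least 14 nt remain).
    """
    if not truth.target_links:
        raise ValueError("truth set has no target links")
    cfg = truth.config
    sig = cfg.pare_signal if signal is None else signal
    bg = cfg.pare_background_per_transcript if background is None else background
    rng = _library_rng(seed, 777)
    reads: list[str] = []
    skipped: list[TargetLink] = []
    for link in truth.target_links:
        tx = truth.transcripts[link.transcript_id]
        avail = len(tx) - (link.slicer_pos - 1)
        if avail <= 13:
            skipped.append(link)
            continue
        for _ in range(sig):
            ln = int(rng.choice(cfg.pare_tag_lens))
            tag = tx[link.slicer_pos - 1 : link.slicer_pos - 1 + min(ln, avail)]
            reads.append(tag + cfg.adapter)
    min_len = min(cfg.pare_tag_lens)
    for tid in sorted(truth.transcripts):
        tx = truth.transcripts[tid]
        n = int(rng.poisson(bg))
        for _ in range(n):
            ln = int(rng.choice(cfg.pare_tag_lens))
            start = int(rng.integers(0, max(1, len(tx) - min_len)))
            reads.append(tx[start : start + ln] + cfg.adapter)
    return reads, skipped


def simulate_qpcr(
    truth: TruthSet,
    design: ExperimentDesign | None = None,
    seed: int = 0,
    noise_sd: float | None = None,
) -> pd.DataFrame:
    """Simulate an RT-qPCR Ct table for target genes plus the reference gene.

    Ct = base_ct - log2(expression) + N(0, sd); the reference gene has
    condition-invariant expression, targets follow their planted condition
    effects. Columns: sample, gene, condition, replicate, ct.
    """
    design = design or truth.design
    cfg = truth.config
    sd = cfg.qpcr_noise_sd if noise_sd is None else noise_sd
    rng = _library_rng(seed, 555)
    genes = sorted(design.target_effects) + [design.reference_gene]
    base_ct = {g: float(rng.uniform(*cfg.base_ct_range)) for g in genes}
    rows = []
    for cond in design.conditions:
        for rep in range(1, design.replicates + 1):
            for gene in genes:
                if gene == design.reference_gene:
                    expr = 1.0
                else:
                    expr = design.target_effects[gene][cond]
                if expr <= 0:
                    raise ValueError("expression must be positive")
                ct = base_ct[gene] - math.log2(expr) + float(rng.normal(0.0, sd))
                rows.append(
                    dict(sample=f"{cond}_r{rep}", gene=gene, condition=cond, replicate=rep, ct=ct)
                )
    return pd.DataFrame(rows)
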