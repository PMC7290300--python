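"""Novel-miRNA discovery from sRNA clusters.

Candidate precursors are excised around each cluster's dominant tag, folded
(ViennaRNA MFE by default, lowest free energy kept), and validated: the
dominant tag must sit entirely on one arm of the hairpin stem, a miRNA* must
be derivable as the duplex partner with 2-nt 3' overhangs, and the duplex
may carry at most 4 unpaired miRNA bases with no bulge longer than 2 nt
(community plant-miRNA annotation practice; config-exposed). Candidates are
then classified against a catalog of known mature miRNAs (known = identical,
homologue = 1-2 mismatches, novel otherwise), grouped into families
(sequence similarity + shared target), and MIR gene exon-intron structure is
reconstructed by spliced alignment of pri-miRNA sequences against the genome
requiring U2-type GT...AG introns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib

from . import srna
from ._seq import normalize, revcomp
from .fold import FoldingEngine, default_folder, pair_table

MAX_UNPAIRED_DEFAULT = 4
MAX_BULGE_DEFAULT = 2
MIN_READS_DEFAULT = 20
FLANK_DEFAULT = 200


# ---------------------------------------------------------------------------
# candidate excision


@dataclass(frozen=True)
class PrecursorWindow:
    chrom: str
    strand: str
    start: int  # genomic, 0-based half-open
    end: int
    seq: str  # transcribed orientation (reverse-complemented for '-')


def excise_candidates(
    cluster: srna.Cluster,
    genome: Mapping[str, str],
    flank: int = FLANK_DEFAULT,
    seed: srna.Placement | None = None,
) -> list[PrecursorWindow]:
    """Windows extending the cluster's dominant-tag span by ``flank``.

    The window is clipped at chromosome ends and oriented by cluster strand
    (minus-strand windows are reverse-complemented so the returned sequence
    is the transcribed one). ``seed`` substitutes another member placement
    for the dominant tag (used when one cluster holds several loci).
    """
    if cluster.chrom not in genome:
        raise KeyError(f"unknown chromosome {cluster.chrom!r}")
    chrom_seq = normalize(genome[cluster.chrom])
    dom = seed if seed is not None else cluster.dominant
    start = max(0, dom.start - flank)
    end = min(len(chrom_seq), dom.end + flank)
    window = chrom_seq[start:end]
    if cluster.strand == "-":
        window = revcomp(window)
    return [PrecursorWindow(cluster.chrom, cluster.strand, start, end, window)]


def _cluster_seeds(
    cluster: srna.Cluster, min_reads: int, separation: int = 200
) -> list[srna.Placement]:
    """Abundance-ranked member placements at least ``separation`` nt apart.

    Background chaining can fuse independent loci into one cluster; each
    well-separated abundant tag seeds its own precursor candidate.
    """
    seeds: list[srna.Placement] = []
    for p in sorted(
        cluster.members, key=lambda p: (-p.tag.rpm, p.start, p.tag.sequence)
    ):
        if p.multi or p.tag.raw_count < min_reads:
            continue
        if all(abs(p.start - s.start) >= separation for s in seeds):
            seeds.append(p)
    return seeds


# ---------------------------------------------------------------------------
# hairpin validation


@dataclass(frozen=True)
class HairpinCandidate:
    precursor_seq: str
    structure: str  # dot-bracket, same length as precursor_seq
    dg: float
    mature_span: tuple[int, int]  # 0-based half-open on the precursor
    star_span: tuple[int, int]
    n_unpaired_in_duplex: int
    overhang_ok: bool


class Rejection(Exception):
    """A candidate failed a validation rule (not an engine failure)."""

    def __init__(self, reason: str) -> None:
        super().__init__(reason)
        self.reason = reason


def _arm_check(pt: list[int], span: tuple[int, int]) -> list[int]:
    """Paired positions of span; raise unless all partners lie on one side."""
    a, b = span
    paired = [i for i in range(a, b) if pt[i] >= 0]
    if not paired:
        raise Rejection("mature region entirely unpaired")
    left = all(pt[i] < a for i in paired)
    right = all(pt[i] >= b for i in paired)
    if not (left or right):
        raise Rejection("mature region overlaps the hairpin loop")
    return paired


def derive_star(
    structure: str,
    mature_span: tuple[int, int],
    max_unpaired: int = MAX_UNPAIRED_DEFAULT,
    max_bulge: int = MAX_BULGE_DEFAULT,
) -> tuple[tuple[int, int], int]:
    """Derive the miRNA* span for a mature span on a folded precursor.

    The star is the base-pair partner region shifted to give 2-nt 3'
    overhangs at both duplex ends. Raises :class:`Rejection` if the mature
    overlaps the loop, has more than ``max_unpaired`` unpaired bases, or the
    duplex contains a bulge/internal loop side longer than ``max_bulge``.
    Returns (star_span, n_unpaired).
    """
    pt = pair_table(structure)
    a, b = mature_span
    paired = _arm_check(pt, (a, b))
    n_unpaired = (b - a) - len(paired)
    if n_unpaired > max_unpaired:
        raise Rejection(f"{n_unpaired} unpaired mature bases > {max_unpaired}")
    for i1, i2 in zip(paired, paired[1:]):
        gap_m = i2 - i1 - 1
        gap_t = abs(pt[i1] - pt[i2]) - 1
        # a bulge is one-sided: symmetric internal loops are limited only by
        # the total-unpaired rule above
        if abs(gap_m - gap_t) > max_bulge:
            raise Rejection("duplex bulge longer than allowed")
    i_first, i_last = paired[0], paired[-1]
    # extrapolate through unpaired terminal mature bases, then apply the
    # 2-nt 3' overhang shift (partner index decreases along the mature)
    star_start = pt[i_last] - ((b - 1) - i_last) + 2
    star_end = pt[i_first] + (i_first - a) + 3
    if star_start < 0 or star_end > len(structure) or star_start >= star_end:
        raise Rejection("derived star span falls outside the precursor")
    if not (star_end <= a or star_start >= b):
        raise Rejection("derived star span overlaps the mature span")
    return (star_start, star_end), n_unpaired


def fold_select(
    window_seq: str,
    mature_seq: str,
    folder: FoldingEngine | None = None,
    max_unpaired: int = MAX_UNPAIRED_DEFAULT,
    max_bulge: int = MAX_BULGE_DEFAULT,
    refine: bool = True,
) -> HairpinCandidate:
    """Fold a candidate window and validate the hairpin around ``mature_seq``.

    The window's minimum-free-energy structure is obtained from the folding
    engine; the candidate is rejected (``Rejection``) if the mature sequence
    is absent, the structure has dG >= 0, the mature does not lie fully on
    one stem arm, or the miRNA/miRNA* duplex fails the unpaired/bulge rules.
    With ``refine`` the precursor is excised as the mature..star extent plus
    the intervening loop and re-folded, so the stored structure belongs to
    the excised precursor itself. Engine failures propagate as
    :class:`~mirdeg.fold.FoldingError`, distinct from rejections.
    """
    folder = folder or default_folder()
    window_seq = normalize(window_seq)
    mature_seq = normalize(mature_seq)
    if len(window_seq) < 50:
        raise Rejection("window shorter than 50 nt")
    pos = window_seq.find(mature_seq)
    if pos < 0:
        raise Rejection("mature sequence not in window")
    structure, dg = folder.fold(window_seq)
    if dg >= 0:
        raise Rejection("no stable structure (dG >= 0)")
    span = (pos, pos + len(mature_seq))
    star_span, n_unp = derive_star(structure, span, max_unpaired, max_bulge)
    if not refine:
        return HairpinCandidate(window_seq, structure, dg, span, star_span, n_unp, True)

    lo = min(span[0], star_span[0])
    hi = max(span[1], star_span[1])
    precursor = window_seq[lo:hi]
    p_struct, p_dg = folder.fold(precursor)
    if p_dg >= 0:
        raise Rejection("excised precursor unstable (dG >= 0)")
    p_span = (span[0] - lo, span[1] - lo)
    p_star, p_unp = derive_star(p_struct, p_span, max_unpaired, max_bulge)
    return HairpinCandidate(precursor, p_struct, p_dg, p_span, p_star, p_unp, True)


# ---------------------------------------------------------------------------
# novelty and families


@dataclass(frozen=True)
class MirnaCall:
    mirna_id: str
    mature_seq: str
    precursor_id: str
    hairpin: HairpinCandidate
    star_seq: str
    star_observed_in_reads: bool
    status: str  # known | homologue | novel
    best_hit: str | None
    mismatches: int | None
    family: str | None = None
    cluster: srna.Cluster | None = None


def classify_novelty(
    mature: str, catalog: Mapping[str, str]
) -> tuple[str, str | None, int | None]:
    """Best full-length ungapped catalog hit and the derived novelty status.

    Catalog entries within +-2 nt of the query length are compared by
    sliding the shorter sequence along the longer one and keeping the best
    window (minimum mismatches). 0 mismatches -> known, 1-2 -> homologue,
    otherwise novel.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    q = normalize(mature)
    best_id: str | None = None
    best_mm: int | None = None
    for cid in sorted(catalog):
        ref = normalize(catalog[cid])
        if abs(len(ref) - len(q)) > 2:
            continue
        short, long_ = (q, ref) if len(q) <= len(ref) else (ref, q)
        mm = min(
            sum(a != b for a, b in zip(short, long_[off : off + len(short)]))
            for off in range(len(long_) - len(short) + 1)
        )
        if best_mm is None or mm < best_mm:
            best_id, best_mm = cid, mm
    if best_mm is None:
        return "novel", None, None
    status = "known" if best_mm == 0 else ("homologue" if best_mm <= 2 else "novel")
    return status, best_id, best_mm


def group_families(
    calls: Sequence[MirnaCall],
    targets: Mapping[str, set[str]],
    max_edit: int = 3,
) -> dict[str, str]:
    """Union-find family grouping: edit distance <= 3 AND >= 1 shared target.

    ``targets`` maps miRNA id -> set of target transcript ids (may be empty).
    Returns mirna_id -> family id (the lexicographically smallest member id).
    """
    ids = [c.mirna_id for c in calls]
    seqs = {c.mirna_id: normalize(c.mature_seq) for c in calls}
    parent = {i: i for i in ids}

    def find(i: str) -> str:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            shared = targets.get(a, set()) & targets.get(b, set())
            if not shared:
                continue
            dist = edlib.align(seqs[a], seqs[b], task="distance", mode="NW")["editDistance"]
            if dist <= max_edit:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)
    return {i: find(i) for i in ids}


# ---------------------------------------------------------------------------
# spliced pri-miRNA alignment (MIR gene structure)


@dataclass(frozen=True)
class GeneModel:
    pri_id: str
    chrom: str
    strand: str
    exon_spans: tuple[tuple[int, int], ...]  # genomic, 0-based half-open, ordered
    intron_spans: tuple[tuple[int, int], ...]
    precursor_exon_index: int | None = None


class SplicedAlignError(Exception):
    def __init__(self, reason: str, diagnostics: list[str] | None = None) -> None:
        super().__init__(reason)
        self.diagnostics = diagnostics or []


def _lce(a: str, i: int, b: str, j: int) -> int:
    n = 0
    while i + n < len(a) and j + n < len(b) and a[i + n] == b[j + n]:
        n += 1
    return n


def _chain(
    pri: str, g: str, p0: int, gpos: int, min_exon: int, min_intron: int, diags: list[str]
) -> list[tuple[int, int]] | None:
    """Exact colinear exon chain of pri[p0:] in g starting at gpos."""
    ext = _lce(pri, p0, g, gpos)
    if p0 + ext >= len(pri):
        return [(gpos, gpos + ext)]
    if ext < min_exon:
        return None
    for back in range(0, min(11, ext - min_exon + 1)):
        exon_len = ext - back
        q = p0 + exon_len
        intron_start = gpos + exon_len
        if g[intron_start : intron_start + 2] != "GT":
            if back == 0:
                diags.append(
                    f"intron after pri position {q} starts with "
                    f"{g[intron_start:intron_start + 2]!r}, not GT (non-U2)"
                )
            continue
        seed = pri[q : q + min_exon]
        if len(seed) < min_exon:
            continue
        j = g.find(seed, intron_start + min_intron)
        while j >= 0:
            if g[j - 2 : j] == "AG":
                rest = _chain(pri, g, q, j, min_exon, min_intron, diags)
                if rest is not None:
                    return [(gpos, intron_start)] + rest
            else:
                diags.append(f"candidate intron before genome position {j} does not end AG")
            j = g.find(seed, j + 1)
    return None


def spliced_align_pri(
    pri: str,
    genome: Mapping[str, str],
    pri_id: str = "pri",
    min_exon: int = 20,
    min_intron: int = 60,
    precursor_seq: str | None = None,
) -> GeneModel:
    """Reconstruct a MIR gene model by exact spliced alignment of a pri-miRNA.

    Finds a colinear chain of exact exon blocks (>= ``min_exon`` nt) on one
    genomic strand whose gaps are introns >= ``min_intron`` nt beginning GT
    and ending AG. The full pri sequence must be covered; otherwise a
    :class:`SplicedAlignError` carrying diagnostics is raised (a planted
    non-GT..AG intron therefore surfaces as a non-U2 diagnostic, not a model).
    """
    pri = normalize(pri)
    if len(pri) < 100:
        raise ValueError("pri-miRNA shorter than 100 nt")
    diags: list[str] = []
    for chrom in sorted(genome):
        chrom_seq = normalize(genome[chrom])
        for strand in ("+", "-"):
            g = chrom_seq if strand == "+" else revcomp(chrom_seq)
            seed = pri[:min_exon]
            start = g.find(seed)
            while start >= 0:
                chain = _chain(pri, g, 0, start, min_exon, min_intron, diags)
                if chain is not None:
                    n = len(chrom_seq)
                    if strand == "+":
                        exons = [(a, b) for a, b in chain]
                    else:
                        exons = sorted((n - b, n - a) for a, b in chain)
                    introns = [
                        (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
                    ]
                    prec_idx = None
                    if precursor_seq is not None:
                        off = pri.find(normalize(precursor_seq))
                        if off >= 0:
                            covered = 0
                            # index in transcript (pri) order, i.e. "second
                            # exon" means the second exon of the spliced pri
                            for idx, (a, b) in enumerate(chain):
                                if covered <= off < covered + (b - a):
                                    prec_idx = idx
                                    break
                                covered += b - a
                    return GeneModel(
                        pri_id, chrom, strand, tuple(exons), tuple(introns), prec_idx
                    )
                start = g.find(seed, start + 1)
    raise SplicedAlignError("no full-coverage exon chain found", diags)


# ---------------------------------------------------------------------------
# cluster-level discovery pipeline


def discover_from_clusters(
    clusters: Sequence[srna.Cluster],
    genome: Mapping[str, str],
    catalog: Mapping[str, str],
    folder: FoldingEngine | None = None,
    tag_sequences: set[str] | None = None,
    min_reads: int = MIN_READS_DEFAULT,
    flank: int = FLANK_DEFAULT,
    second_arm_fraction: float = 0.1,
    max_unpaired: int = MAX_UNPAIRED_DEFAULT,
    max_bulge: int = MAX_BULGE_DEFAULT,
) -> list[MirnaCall]:
    """Run excision -> folding -> duplex validation -> novelty on clusters.

    Every well-separated cluster member that is uniquely mapped and carries
    >= ``min_reads`` reads seeds a candidate. Within an accepted hairpin, a
    second abundant tag (>= ``second_arm_fraction`` of the seed) lying fully
    on the opposite arm yields a second call against the same precursor —
    the two-miRNAs-one-precursor case. ``tag_sequences`` (all observed tag
    sequences) drives the miRNA*-observed flag.
    """
    folder = folder or default_folder()
    tag_sequences = tag_sequences or set()
    calls: list[MirnaCall] = []
    called_matures: set[str] = set()
    n_prec = 0
    for cluster in clusters:
        for dom in _cluster_seeds(cluster, min_reads):
            if dom.tag.sequence in called_matures:
                continue
            window = excise_candidates(cluster, genome, flank, seed=dom)[0]
            try:
                cand0 = fold_select(
                    window.seq, dom.tag.sequence, folder, max_unpaired, max_bulge,
                    refine=False,
                )
            except Rejection:
                continue
            # opposite-arm scan (on the unrefined window so the other arm is
            # still present) for a second mature from the same precursor
            pt = pair_table(cand0.structure)
            seen = {dom.tag.sequence, cand0.precursor_seq[slice(*cand0.star_span)]}
            threshold = dom.tag.raw_count * second_arm_fraction
            a, b = cand0.mature_span
            second: tuple[str, tuple[int, int], tuple[int, int]] | None = None
            for p in sorted(cluster.members, key=lambda p: -p.tag.rpm):
                seq = p.tag.sequence
                if seq in seen or p.tag.raw_count < max(min_reads, threshold):
                    continue
                pos = window.seq.find(seq)
                if pos < 0:
                    continue
                span2 = (pos, pos + len(seq))
                if not (span2[0] >= b or span2[1] <= a):
                    continue
                try:
                    paired = _arm_check(pt, span2)
                except Rejection:
                    continue
                # opposite arm: partners point 3' on the 5' arm and 5' on the
                # 3' arm, so the direction sign must differ from the seed's
                dom_paired = [i for i in range(a, b) if pt[i] >= 0]
                if (pt[paired[0]] > paired[0]) == (pt[dom_paired[0]] > dom_paired[0]):
                    continue
                try:
                    star2, _ = derive_star(cand0.structure, span2, max_unpaired, max_bulge)
                except Rejection:
                    continue
                second = (seq, span2, star2)
                break

            # excise the precursor covering every mature/star duplex, re-fold,
            # and re-derive all spans on the excised precursor's own structure
            spans = [cand0.mature_span, cand0.star_span]
            if second is not None:
                spans += [second[1], second[2]]
            lo = min(s[0] for s in spans)
            hi = max(s[1] for s in spans)
            precursor = window.seq[lo:hi]
            p_struct, p_dg = folder.fold(precursor)
            if p_dg >= 0:
                continue
            try:
                m_span = (cand0.mature_span[0] - lo, cand0.mature_span[1] - lo)
                m_star, m_unp = derive_star(p_struct, m_span, max_unpaired, max_bulge)
            except Rejection:
                continue
            n_prec += 1
            prec_id = f"prec{n_prec}_{cluster.chrom}_{dom.start}"
            made = [
                (
                    dom.tag.sequence,
                    HairpinCandidate(precursor, p_struct, p_dg, m_span, m_star, m_unp, True),
                )
            ]
            if second is not None:
                try:
                    s_span = (second[1][0] - lo, second[1][1] - lo)
                    s_star, s_unp = derive_star(p_struct, s_span, max_unpaired, max_bulge)
                    made.append(
                        (
                            second[0],
                            HairpinCandidate(
                                precursor, p_struct, p_dg, s_span, s_star, s_unp, True
                            ),
                        )
                    )
                except Rejection:
                    pass
            for mature_seq, hp in made:
                called_matures.add(mature_seq)
                star_seq = hp.precursor_seq[slice(*hp.star_span)]
                status, hit, mm = classify_novelty(mature_seq, catalog)
                calls.append(
                    MirnaCall(
                        mirna_id=f"{prec_id}:{mature_seq[:6]}",
                        mature_seq=mature_seq,
                        precursor_id=prec_id,
                        hairpin=hp,
                        star_seq=star_seq,
                        star_observed_in_reads=star_seq in tag_sequences,
                        status=status,
                        best_hit=hit,
                        mismatches=mm,
                        cluster=cluster,
                    )
                )
    return calls
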