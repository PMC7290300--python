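"""Small-RNA read processing: adapter trimming, length filtering, collapsing
to unique tags with RPM normalisation, genome placement and locus clustering.

The processing rules mirror standard sRNA-seq practice: 3' adapters are
removed requiring a minimum overlap of 19 nt, and only reads longer than
13 nt whose adapter was identified are retained. Retained reads are collapsed
to unique tags; RPM (reads per million retained reads) is the normalisation
unit throughout. Tags are placed at every exact genomic match and same-strand
placements closer than ``max_gap`` are chained into clusters — the loci whose
per-length read distributions identify miRNA candidates.

Coordinates are 0-based half-open internally; reports use 1-based inclusive.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._seq import normalize, revcomp

MIN_OVERLAP_DEFAULT = 19
MIN_INSERT_LEN = 13  # retained reads must be strictly longer than this
MAX_GAP_DEFAULT = 100


# ---------------------------------------------------------------------------
# trimming and filtering


def _find_adapter(read: str, adapter: str, min_overlap: int, max_mismatch_rate: float) -> int:
    """Leftmost start of a 3' adapter occurrence in ``read``, or -1.

    An occurrence at position p compares read[p:p+ov] with adapter[:ov],
    ov = min(len(adapter), len(read)-p) >= min_overlap, allowing at most
    floor(max_mismatch_rate * ov) mismatches.
    """
    la, lr = len(adapter), len(read)
    for p in range(0, lr - min_overlap + 1):
        ov = min(la, lr - p)
        if ov < min_overlap:
            break
        allowed = int(max_mismatch_rate * ov)
        mism = 0
        for a, b in zip(read[p : p + ov], adapter[:ov]):
            if a != b:
                mism += 1
                if mism > allowed:
                    break
        else:
            return p
    return -1


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    max_mismatch_rate: float = 0.1,
) -> tuple[str, bool]:
    """Remove a 3' adapter from ``read``; return (insert, adapter_found).

    The leftmost suffix-of-read / prefix-of-adapter match of length
    >= ``min_overlap`` (mismatch fraction <= ``max_mismatch_rate``) and
    everything 3' of it are removed. Trimming is iterated to a fixed point so
    that re-trimming an already trimmed insert never removes more sequence.
    Set ``max_mismatch_rate=0`` for exact matching. Total function: a read
    with no identifiable adapter is returned unchanged with flag False.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not read:
        raise ValueError("read must be non-empty")
    cur = read
    found = False
    while cur:
        p = _find_adapter(cur, adapter, min_overlap, max_mismatch_rate)
        if p < 0:
            break
        cur = cur[:p]
        found = True
    return cur, found


def filter_reads(inserts: Iterable[tuple[str, bool]]) -> list[str]:
    """Retain inserts with an identified adapter and length > 13 nt."""
    return [seq for seq, ok in inserts if ok and len(seq) > MIN_INSERT_LEN]


def trim_and_filter(
    reads: Iterable[str],
    adapter: str,
    min_overlap: int = MIN_OVERLAP_DEFAULT,
    max_mismatch_rate: float = 0.1,
) -> tuple[list[str], dict[str, int]]:
    """Trim then length/adapter-filter a library; returns (retained, accounting).

    The accounting dict reconciles input = retained + filtered.
    """
    trimmed = [trim_adapter(r, adapter, min_overlap, max_mismatch_rate) for r in reads]
    retained = filter_reads(trimmed)
    stats = {
        "input": len(trimmed),
        "retained": len(retained),
        "filtered": len(trimmed) - len(retained),
    }
    return retained, stats


# ---------------------------------------------------------------------------
# collapsing / normalisation


@dataclass(frozen=True)
class SmallRnaTag:
    """A collapsed unique read: the atom of the sRNA pipeline."""

    sequence: str
    raw_count: int
    rpm: float
    library_id: str


def collapse_normalize(inserts: Sequence[str], library_id: str) -> list[SmallRnaTag]:
    """Collapse one library's retained inserts to unique tags with RPM.

    rpm = raw_count * 1e6 / total retained reads, so RPM sums to 1e6 over the
    library. Tags are returned by descending raw count (ties lexicographic)
    for deterministic downstream behaviour. Empty input yields an empty list.
    """
    counts = Counter(normalize(s) for s in inserts)
    total = sum(counts.values())
    tags = [
        SmallRnaTag(seq, c, c * 1e6 / total, library_id)
        for seq, c in counts.items()
    ]
    tags.sort(key=lambda t: (-t.raw_count, t.sequence))
    return tags


# ---------------------------------------------------------------------------
# genome placement and clustering


@dataclass(frozen=True)
class Placement:
    tag: SmallRnaTag
    chrom: str
    strand: str
    start: int  # 0-based
    end: int  # half-open
    multi: bool = False


@dataclass
class Cluster:
    """A strand-specific genomic locus of chained tag placements."""

    chrom: str
    strand: str
    start: int
    end: int
    members: list[Placement] = field(default_factory=list)

    @property
    def total_rpm(self) -> float:
        return sum(p.tag.rpm for p in self.members)

    @property
    def dominant(self) -> Placement:
        """Highest-RPM member; deterministic tie-break by position/sequence."""
        return max(self.members, key=lambda p: (p.tag.rpm, -p.start, p.tag.sequence))

    def length_histogram(self) -> dict[int, float]:
        hist: dict[int, float] = {}
        for p in self.members:
            n = len(p.tag.sequence)
            hist[n] = hist.get(n, 0.0) + p.tag.rpm
        return hist


def _occurrences(haystack: str, needle: str, max_mismatches: int) -> list[int]:
    if max_mismatches == 0:
        out, i = [], haystack.find(needle)
        while i >= 0:
            out.append(i)
            i = haystack.find(needle, i + 1)
        return out
    # naive scan, used only for small genomes / nonzero mismatch settings
    out = []
    n, m = len(haystack), len(needle)
    for i in range(n - m + 1):
        mism = 0
        for a, b in zip(haystack[i : i + m], needle):
            if a != b:
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            out.append(i)
    return out


def place_tags(
    tags: Sequence[SmallRnaTag],
    genome: Mapping[str, str],
    max_mismatches: int = 0,
) -> tuple[list[Placement], list[SmallRnaTag]]:
    """Place each tag at every genomic match on either strand.

    Returns (placements, unplaced). Tags with more than one placement are
    flagged ``multi`` at every placement; tags absent from the genome go to
    the unplaced bin rather than being dropped silently.
    """
    placements: list[Placement] = []
    unplaced: list[SmallRnaTag] = []
    chroms = {c: normalize(s) for c, s in genome.items()}
    for tag in tags:
        hits: list[tuple[str, str, int]] = []
        rc = revcomp(tag.sequence)
        for chrom, seq in chroms.items():
            for i in _occurrences(seq, tag.sequence, max_mismatches):
                hits.append((chrom, "+", i))
            for i in _occurrences(seq, rc, max_mismatches):
                hits.append((chrom, "-", i))
        if not hits:
            unplaced.append(tag)
            continue
        multi = len(hits) > 1
        for chrom, strand, i in hits:
            placements.append(
                Placement(tag, chrom, strand, i, i + len(tag.sequence), multi)
            )
    return placements, unplaced


def chain_placements(placements: Sequence[Placement], max_gap: int = MAX_GAP_DEFAULT) -> list[Cluster]:
    """Chain same-chromosome, same-strand placements with gap <= max_gap.

    The gap between consecutive placements (sorted by start) is
    next.start - current cluster end; overlaps count as gap <= 0.
    """
    groups: dict[tuple[str, str], list[Placement]] = {}
    for p in placements:
        groups.setdefault((p.chrom, p.strand), []).append(p)
    clusters: list[Cluster] = []
    for (chrom, strand), ps in sorted(groups.items()):
        ps.sort(key=lambda p: (p.start, p.end))
        cur: Cluster | None = None
        for p in ps:
            if cur is not None and p.start - cur.end <= max_gap:
                cur.members.append(p)
                cur.end = max(cur.end, p.end)
            else:
                cur = Cluster(chrom, strand, p.start, p.end, [p])
                clusters.append(cur)
    return clusters


def map_and_cluster(
    tags: Sequence[SmallRnaTag],
    genome: Mapping[str, str],
    max_mismatches: int = 0,
    max_gap: int = MAX_GAP_DEFAULT,
) -> tuple[list[Cluster], list[SmallRnaTag]]:
    """Place collapsed tags on the genome and chain them into loci."""
    placements, unplaced = place_tags(tags, genome, max_mismatches)
    return chain_placements(placements, max_gap), unplaced


# ---------------------------------------------------------------------------
# length distributions


def length_distribution(cluster: Cluster) -> dict[int, float]:
    """Per-cluster read-length histogram (length -> summed RPM)."""
    if not cluster.members:
        raise ValueError("empty cluster has no length distribution")
    return cluster.length_histogram()


def modal_length(hist: Mapping[int, float]) -> int:
    """RPM-weighted modal length; ties resolved to the smaller length."""
    if not hist:
        raise ValueError("empty histogram")
    best = max(hist.values())
    return min(n for n, v in hist.items() if v == best)
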