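"""Degradome (PARE) analysis: 5'-end pileups, cleavage-site ranking, the
0-18 compliance-scored miRNA:target duplex aligner, and target calling.

Slicer-cleaved targets leave a sharp degradome 5'-end peak at the cut site,
which lies between the target residues paired to miRNA nucleotides 10 and 11
(counted from the miRNA 5' end). A target is called when a top-ranked peak
("cutting power" = normalized 5'-end read count) coincides with that
position and the miRNA:site duplex scores no worse than ``max_score`` on the
compliance scale.

Compliance score: an integer penalty in [0, 18]; 0 means perfect
complementarity. Per miRNA position the penalties are mismatch +2, G:U
wobble +1, bulge (either strand) +2, all doubled in the seed-proximal
region (miRNA positions 2-13); the summed penalty is capped at 18. Lower is
better, so ranking "by lowest compliance score" puts perfect duplexes first.
``DuplexAlignment.inverted_score`` (18 - S) is available for reports that
prefer the opposite polarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import srna
from ._seq import is_watson_crick, is_wobble, normalize

SCORE_CAP = 18
SEED_RANGE = (2, 13)  # miRNA positions with doubled penalties, 1-based inclusive
PENALTY_MISMATCH = 2
PENALTY_WOBBLE = 1
PENALTY_BULGE = 2
DEFAULT_BAND = 3
DEFAULT_MAX_SCORE = 7
DEFAULT_MAX_RANK = 3

_INF = float("inf")


# ---------------------------------------------------------------------------
# PARE read processing (shared trim/filter code path with the sRNA pipeline)


def process_pare_reads(
    reads: Iterable[str],
    adapter: str,
    min_overlap: int = srna.MIN_OVERLAP_DEFAULT,
    max_mismatch_rate: float = 0.1,
) -> list[str]:
    """Trim adapters and drop tags without an adapter or <= 13 nt."""
    retained, _ = srna.trim_and_filter(reads, adapter, min_overlap, max_mismatch_rate)
    return retained


# ---------------------------------------------------------------------------
# pileups and cleavage-site ranking


@dataclass
class Pileup:
    """Per-transcript degradome 5'-end count vectors.

    ``raw[tx][pos]`` counts tag 5' ends at 1-based transcript position
    ``pos``; normalized counts are per million mapped tags (multi-placed
    tags are counted in every pileup but once in the mapped-tag total).
    """

    raw: dict[str, dict[int, int]] = field(default_factory=dict)
    multi_flag: dict[str, set[int]] = field(default_factory=dict)
    n_mapped: int = 0
    n_unmapped: int = 0

    def normalized(self, transcript_id: str) -> dict[int, float]:
        scale = 1e6 / self.n_mapped if self.n_mapped else 0.0
        return {p: c * scale for p, c in self.raw.get(transcript_id, {}).items()}


def build_pileup(tags: Iterable[str], transcriptome: Mapping[str, str]) -> Pileup:
    """Place clean tags at every exact transcript match; count 5' ends."""
    txs = {tid: normalize(s) for tid, s in transcriptome.items()}
    pile = Pileup()
    for tag in tags:
        tag = normalize(tag)
        hits: list[tuple[str, int]] = []
        for tid, seq in txs.items():
            i = seq.find(tag)
            while i >= 0:
                hits.append((tid, i + 1))
                i = seq.find(tag, i + 1)
        if not hits:
            pile.n_unmapped += 1
            continue
        pile.n_mapped += 1
        multi = len(hits) > 1
        for tid, pos in hits:
            d = pile.raw.setdefault(tid, {})
            d[pos] = d.get(pos, 0) + 1
            if multi:
                pile.multi_flag.setdefault(tid, set()).add(pos)
    return pile


@dataclass(frozen=True)
class DegradomePeak:
    transcript_id: str
    position: int  # 1-based 5'-most residue of the degradome tag
    raw: int
    normalized: float
    rank: int


def rank_sites(pileup: Pileup, transcript_id: str) -> list[DegradomePeak]:
    """Rank a transcript's nonzero positions by cutting power.

    Descending normalized count; ties by higher raw count, then by the
    5'-most (smallest) position. Ranks are 1..k.
    """
    raw = pileup.raw.get(transcript_id, {})
    norm = pileup.normalized(transcript_id)
    order = sorted(raw, key=lambda p: (-norm[p], -raw[p], p))
    return [
        DegradomePeak(transcript_id, p, raw[p], norm[p], i + 1)
        for i, p in enumerate(order)
    ]


# ---------------------------------------------------------------------------
# compliance-scored duplex alignment


@dataclass(frozen=True)
class DuplexAlignment:
    """A miRNA:target-site alignment with per-position states and score.

    ``states[i]`` (keys 1..L, miRNA positions from the 5' end) is one of
    match / wobble / mismatch / bulge-miRNA; target-side bulges are listed
    in ``target_bulges`` as (adjacent miRNA position, window position).
    ``partner[i]`` maps a paired miRNA position to the 1-based position
    within the target window (5'->3' on the transcript), or None for a
    bulged miRNA base.
    """

    mirna: str
    window: str
    states: Mapping[int, str]
    partner: Mapping[int, int | None]
    target_bulges: tuple[tuple[int, int], ...]
    score: int
    raw_penalty: int

    @property
    def inverted_score(self) -> int:
        return SCORE_CAP - self.score


def _weight(pos: int) -> int:
    return 2 if SEED_RANGE[0] <= pos <= SEED_RANGE[1] else 1


def _pair_penalty(m: str, t: str) -> tuple[int, str]:
    if is_watson_crick(m, t):
        return 0, "match"
    if is_wobble(m, t):
        return PENALTY_WOBBLE, "wobble"
    return PENALTY_MISMATCH, "mismatch"


def score_duplex(
    mirna: str,
    window: str,
    band: int = DEFAULT_BAND,
    cap: int = SCORE_CAP,
) -> DuplexAlignment:
    """Optimal (minimum-penalty) gapped duplex of a miRNA and a target window.

    The miRNA (5'->3') is aligned antiparallel against the window (the
    window sequence is given 5'->3' in transcript orientation) by a banded
    global dynamic program (band +-``band`` around the diagonal). The
    summed positional penalty is capped at ``cap`` (18) to give the
    compliance score; the uncapped value is kept as ``raw_penalty``.
    """
    x = normalize(mirna)
    w = normalize(window)
    if not x or not w:
        raise ValueError("miRNA and window must be non-empty")
    if abs(len(w) - len(x)) > band:
        raise ValueError(
            f"window length {len(w)} outside miRNA length {len(x)} +- {band}"
        )
    y = w[::-1]  # pair miRNA position i with reversed-window position i
    L, M = len(x), len(y)

    D = [[_INF] * (M + 1) for _ in range(L + 1)]
    D[0][0] = 0.0
    for i in range(0, L + 1):
        lo, hi = max(0, i - band), min(M, i + band)
        for j in range(lo, hi + 1):
            if i == 0 and j == 0:
                continue
            best = _INF
            if i > 0 and j > 0:
                pen, _ = _pair_penalty(x[i - 1], y[j - 1])
                best = min(best, D[i - 1][j - 1] + pen * _weight(i))
            if i > 0 and abs(i - 1 - j) <= band:
                best = min(best, D[i - 1][j] + PENALTY_BULGE * _weight(i))
            if j > 0 and abs(i - (j - 1)) <= band:
                best = min(best, D[i][j - 1] + PENALTY_BULGE * _weight(max(i, 1)))
            D[i][j] = best

    # traceback (prefer diagonal, then miRNA bulge, then target bulge)
    states: dict[int, str] = {}
    partner: dict[int, int | None] = {}
    bulges: list[tuple[int, int]] = []
    i, j = L, M
    while i > 0 or j > 0:
        cur = D[i][j]
        if i > 0 and j > 0:
            pen, st = _pair_penalty(x[i - 1], y[j - 1])
            if D[i - 1][j - 1] + pen * _weight(i) == cur:
                states[i] = st
                partner[i] = M - j + 1  # window coordinate, 1-based 5'->3'
                i, j = i - 1, j - 1
                continue
        if i > 0 and abs(i - 1 - j) <= band and D[i - 1][j] + PENALTY_BULGE * _weight(i) == cur:
            states[i] = "bulge-miRNA"
            partner[i] = None
            i -= 1
            continue
        states_pos = max(i, 1)
        bulges.append((states_pos, M - j + 1))
        j -= 1

    raw_pen = int(D[L][M])
    return DuplexAlignment(
        mirna=x,
        window=w,
        states=states,
        partner=partner,
        target_bulges=tuple(reversed(bulges)),
        score=min(raw_pen, cap),
        raw_penalty=raw_pen,
    )


# ---------------------------------------------------------------------------
# target calling


@dataclass(frozen=True)
class TargetCall:
    mirna_id: str
    transcript_id: str
    cleavage_pos: int  # 1-based; residue paired to miRNA nt 10
    peak: DegradomePeak
    duplex: DuplexAlignment
    window_start: int  # 0-based window start on the transcript
    accepted: bool
    reason: str = ""


def _candidate_for_peak(
    mirna: str, tx: str, peak_pos: int, band: int
) -> tuple[DuplexAlignment, int] | None:
    """Best duplex whose residue paired to miRNA nt 10 is the peak position."""
    L = len(mirna)
    base = peak_pos - L + 9  # 0-based window start for the ungapped geometry
    best: tuple[DuplexAlignment, int] | None = None
    for a_off in range(-band, 1):
        for b_off in range(-band, band + 1):
            a = base + a_off
            b = base + L + b_off
            if a < 0 or b > len(tx) or abs((b - a) - L) > band:
                continue
            try:
                aln = score_duplex(mirna, tx[a:b], band=band)
            except ValueError:
                continue
            p10 = aln.partner.get(10)
            if p10 is None or a + p10 != peak_pos:
                continue
            if best is None or aln.score < best[0].score:
                best = (aln, a)
    return best


def call_targets(
    mirnas: Mapping[str, str],
    pileup: Pileup,
    transcriptome: Mapping[str, str],
    max_score: int = DEFAULT_MAX_SCORE,
    max_rank: int = DEFAULT_MAX_RANK,
    band: int = DEFAULT_BAND,
) -> tuple[list[TargetCall], list[TargetCall]]:
    """Call slicer targets where a top-ranked peak sits at the 10/11 position.

    For every miRNA x transcript, peaks of rank <= ``max_rank`` are tested:
    the call is accepted when the peak position equals the target residue
    paired to miRNA nucleotide 10 (cleavage between the residues paired to
    nucleotides 10 and 11) in a duplex with compliance score <= ``max_score``.
    Returns (accepted calls, near-miss diagnostics).
    """
    accepted: list[TargetCall] = []
    near: list[TargetCall] = []
    txs = {tid: normalize(s) for tid, s in transcriptome.items()}
    for tid, tx in sorted(txs.items()):
        peaks = rank_sites(pileup, tid)
        for peak in peaks:
            if peak.rank > max_rank:
                break
            for mid in sorted(mirnas):
                cand = _candidate_for_peak(normalize(mirnas[mid]), tx, peak.position, band)
                if cand is None:
                    continue
                aln, wstart = cand
                ok = aln.score <= max_score
                call = TargetCall(
                    mirna_id=mid,
                    transcript_id=tid,
                    cleavage_pos=peak.position,
                    peak=peak,
                    duplex=aln,
                    window_start=wstart,
                    accepted=ok,
                    reason="" if ok else f"compliance score {aln.score} > {max_score}",
                )
                (accepted if ok else near).append(call)
    return accepted, near


def calls_table(calls: Sequence[TargetCall]) -> pd.DataFrame:
    rows = [
        dict(
            mirna=c.mirna_id,
            transcript=c.transcript_id,
            position=c.cleavage_pos,
            raw=c.peak.raw,
            normalized=c.peak.normalized,
            rank=c.peak.rank,
            score=c.duplex.score,
            accepted=c.accepted,
        )
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=["mirna", "transcript", "position", "raw", "normalized", "rank", "score", "accepted"],
    )


def export_tplot(
    transcript_id: str,
    transcript_seq: str,
    pileup: Pileup,
    call: TargetCall | None = None,
) -> pd.DataFrame:
    """Dense per-position T-plot table: (position, raw, normalized, is_called_site)."""
    if call is not None and call.transcript_id != transcript_id:
        raise ValueError("call refers to a different transcript")
    raw = pileup.raw.get(transcript_id, {})
    norm = pileup.normalized(transcript_id)
    n = len(transcript_seq)
    called = call.cleavage_pos if call is not None else None
    return pd.DataFrame(
        {
            "position": range(1, n + 1),
            "raw": [raw.get(p, 0) for p in range(1, n + 1)],
            "normalized": [norm.get(p, 0.0) for p in range(1, n + 1)],
            "is_called_site": [p == called for p in range(1, n + 1)],
        }
    )


def plot_tplot(table: pd.DataFrame, ax=None):
    """Render a T-plot (normalized 5'-end reads vs transcript position)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 2.5))
    ax.vlines(table["position"], 0, table["normalized"], color="0.6", lw=1)
    hit = table[table["is_called_site"]]
    if not hit.empty:
        ax.vlines(hit["position"], 0, hit["normalized"], color="red", lw=2)
    ax.set_xlabel("transcript position (nt)")
    ax.set_ylabel("normalized reads")
    return ax
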