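"""Tests for degradome pileups, cleavage-site ranking, the compliance-scored
duplex aligner (against an exhaustive alignment oracle), and target calling."""

import functools

import numpy as np
import pytest

from mirdeg import degradome
from mirdeg._seq import is_watson_crick, is_wobble, revcomp
from mirdeg.degradome import (
    SCORE_CAP,
    build_pileup,
    call_targets,
    export_tplot,
    process_pare_reads,
    rank_sites,
    score_duplex,
)
from mirdeg.synthetic import ADAPTER


# ---------------------------------------------------------------------------
# exhaustive alignment oracle (unbanded recursion, same penalty model)


def _weight(pos: int) -> int:
    return 2 if 2 <= pos <= 13 else 1


def oracle_score(mirna: str, window: str, cap: int = SCORE_CAP) -> int:
    x, y = mirna, window[::-1]

    @functools.lru_cache(maxsize=None)
    def go(i: int, j: int) -> float:
        if i == 0 and j == 0:
            return 0.0
        best = float("inf")
        if i > 0 and j > 0:
            a, b = x[i - 1], y[j - 1]
            pen = 0 if is_watson_crick(a, b) else (1 if is_wobble(a, b) else 2)
            best = min(best, go(i - 1, j - 1) + pen * _weight(i))
        if i > 0:
            best = min(best, go(i - 1, j) + 2 * _weight(i))
        if j > 0:
            best = min(best, go(i, j - 1) + 2 * _weight(max(i, 1)))
        return best

    return min(int(go(len(x), len(y))), cap)


def _random_mirna(rng, n=21):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------


class TestProcessPareReads:
    def test_full_length_tag_recovered(self):
        tag = "ACGTTGCAGGTCCATGCATGCATGCA"  # 26 nt
        assert process_pare_reads([tag + ADAPTER], ADAPTER) == [tag]

    def test_short_tag_discarded(self):
        assert process_pare_reads(["ACGTACGTACGT" + ADAPTER], ADAPTER) == []

    def test_no_adapter_discarded(self):
        assert process_pare_reads(["ACGTTGCAGGTCCATGCATGCATGCA"], ADAPTER) == []


class TestPileup:
    TX = {"tx1": "ACGT" * 50, "tx2": "TTGCA" * 40}

    def test_five_prime_end_counting_and_normalization(self):
        tx = {"tx1": "A" * 99 + "CTGCTGATTGCCGGATCAATCGAGCAA" + "A" * 99}
        tag = tx["tx1"][99:125]
        other = tx["tx1"][10:36]
        pile = build_pileup([tag, tag, tag, other], tx)
        assert pile.raw["tx1"][100] == 3
        assert pile.n_mapped == 4 and pile.n_unmapped == 0
        assert pile.normalized("tx1")[100] == pytest.approx(3e6 / 4)

    def test_multi_transcript_tag_counted_in_each_and_flagged(self):
        shared = "GATTACAGATTACAGATTACAGATTAC"
        tx = {"a": "C" * 30 + shared + "C" * 30, "b": "G" * 10 + shared + "G" * 50}
        pile = build_pileup([shared], tx)
        assert pile.raw["a"][31] == 1 and pile.raw["b"][11] == 1
        assert 31 in pile.multi_flag["a"] and 11 in pile.multi_flag["b"]
        assert pile.n_mapped == 1  # counted once in the reconciliation total

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_placement_oracle(self, seed):
        rng = np.random.default_rng(seed)
        tx = {f"t{i}": "".join(rng.choice(list("ACGT"), size=150)) for i in range(4)}
        tags = []
        for _ in range(40):
            tid = f"t{rng.integers(0, 4)}"
            start = int(rng.integers(0, 124))
            tags.append(tx[tid][start : start + 26])
        tags.append("A" * 26)  # likely unmappable
        pile = build_pileup(tags, tx)
        # oracle: independent nested scan
        expected = {}
        unmapped = 0
        for tag in tags:
            hits = [
                (tid, i + 1)
                for tid, seq in tx.items()
                for i in range(len(seq) - len(tag) + 1)
                if seq[i : i + len(tag)] == tag
            ]
            if not hits:
                unmapped += 1
            for tid, pos in hits:
                expected.setdefault(tid, {})
                expected[tid][pos] = expected[tid].get(pos, 0) + 1
        assert pile.raw == expected
        assert pile.n_unmapped == unmapped
        assert pile.n_mapped + pile.n_unmapped == len(tags)


class TestRankSites:
    def _pileup(self, counts, total=100):
        p = degradome.Pileup(raw={"tx": dict(counts)}, n_mapped=total)
        return p

    def test_highest_count_is_rank_one(self):
        peaks = rank_sites(self._pileup({100: 50, 200: 10}), "tx")
        assert peaks[0].position == 100 and peaks[0].rank == 1
        assert [p.rank for p in peaks] == [1, 2]

    def test_tie_breaks_to_five_prime_most(self):
        peaks = rank_sites(self._pileup({150: 7, 90: 7}), "tx")
        assert peaks[0].position == 90

    def test_empty_pileup(self):
        assert rank_sites(degradome.Pileup(), "tx") == []


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            m = _random_mirna(rng)
            aln = score_duplex(m, revcomp(m))
            assert aln.score == 0
            assert all(s == "match" for s in aln.states.values())

    def test_fully_mismatched_duplex_caps_at_18(self):
        rng = np.random.default_rng(1)
        m = _random_mirna(rng)
        anti = "".join({"A": "T", "T": "A", "G": "C", "C": "G"}[c] for c in revcomp(m))
        aln = score_duplex(m, anti)
        assert aln.score == SCORE_CAP and aln.raw_penalty > SCORE_CAP

    def test_single_wobble_outside_seed_scores_one(self):
        rng = np.random.default_rng(2)
        m = list(_random_mirna(rng))
        m[14] = "G"  # miRNA position 15
        m = "".join(m)
        w = list(revcomp(m))
        w[len(m) - 15] = "T"  # G:U against position 15
        w = "".join(w)
        aln = score_duplex(m, w)
        assert aln.score == 1 == oracle_score(m, w)
        assert aln.states[15] == "wobble"

    def test_seed_region_penalties_doubled(self):
        rng = np.random.default_rng(3)
        m = _random_mirna(rng)
        w = revcomp(m)

        def mutate(pos):  # miRNA position -> mismatched window
            out = list(w)
            i = len(m) - pos
            out[i] = {"A": "C", "C": "A", "G": "A", "T": "C"}[out[i]]
            return "".join(out)

        assert score_duplex(m, mutate(5)).score == 4  # seed-proximal, 2x
        assert score_duplex(m, mutate(18)).score == 2

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError):
            score_duplex("ACGT" * 5 + "A", "ACXT" + "A" * 17)

    def test_window_length_outside_band_rejected(self):
        with pytest.raises(ValueError):
            score_duplex("A" * 21, "T" * 28)

    @pytest.mark.parametrize("seed", range(20))
    def test_banded_dp_matches_exhaustive_oracle(self, seed):
        """Banded DP equals unbanded exhaustive alignment on <=25-nt windows."""
        rng = np.random.default_rng(seed)
        m = _random_mirna(rng, int(rng.integers(18, 23)))
        w = list(revcomp(m))
        for _ in range(int(rng.integers(0, 6))):  # point mutations
            i = int(rng.integers(0, len(w)))
            w[i] = str(rng.choice(list("ACGT")))
        for _ in range(int(rng.integers(0, 3))):  # small indels, stay in band
            if len(w) < len(m) + 3 and rng.random() < 0.5:
                w.insert(int(rng.integers(0, len(w))), str(rng.choice(list("ACGT"))))
            elif len(w) > len(m) - 3:
                del w[int(rng.integers(0, len(w)))]
        w = "".join(w)
        assert score_duplex(m, w).score == oracle_score(m, w)

    @pytest.mark.parametrize("seed", range(10))
    def test_score_monotone_under_single_substitutions(self, seed):
        rng = np.random.default_rng(seed)
        m = _random_mirna(rng)
        w = list(revcomp(m))
        for _ in range(int(rng.integers(0, 4))):
            i = int(rng.integers(0, len(w)))
            w[i] = str(rng.choice(list("ACGT")))
        base = score_duplex(m, "".join(w))
        matched = [i for i, s in base.states.items() if s == "match" and base.partner[i]]
        for i in matched[:6]:
            wi = base.partner[i] - 1  # 0-based window index paired to i
            for alt in "ACGT":
                if alt == w[wi]:
                    continue
                mutated = w.copy()
                mutated[wi] = alt
                assert score_duplex(m, "".join(mutated)).score >= base.score

    def test_symmetric_across_transcripts(self):
        rng = np.random.default_rng(7)
        m = _random_mirna(rng)
        w = revcomp(m)
        assert score_duplex(m, w).score == score_duplex(m, str(w)).score


class TestCallTargets:
    def _setup(self, rng, offset=0, mutate_mirna=0):
        m = _random_mirna(rng)
        site = revcomp(m)
        tx = {"tx": "".join(rng.choice(list("ACGT"), size=100)) + site
              + "".join(rng.choice(list("ACGT"), size=100))}
        slicer = 100 + 21 - 9  # residue paired to miRNA nt 10, 1-based
        pile = degradome.Pileup(raw={"tx": {slicer + offset: 40}}, n_mapped=40)
        if mutate_mirna:
            m = "".join(
                {"A": "C", "C": "A", "G": "A", "T": "C"}[c] if i < mutate_mirna else c
                for i, c in enumerate(m)
            )
        return m, tx, pile, slicer

    def test_planted_site_accepted_at_rank_one(self):
        m, tx, pile, slicer = self._setup(np.random.default_rng(0))
        accepted, _ = call_targets({"mir": m}, pile, tx)
        assert len(accepted) == 1
        call = accepted[0]
        assert call.cleavage_pos == slicer and call.peak.rank == 1
        assert call.duplex.score == 0

    def test_peak_three_nt_away_rejected(self):
        m, tx, pile, _ = self._setup(np.random.default_rng(1), offset=3)
        accepted, _ = call_targets({"mir": m}, pile, tx)
        assert accepted == []

    def test_score_above_cutoff_rejected_with_diagnostic(self):
        # 10 disrupted 5' positions: no in-band alignment stays under the cutoff
        m, tx, pile, _ = self._setup(np.random.default_rng(2), mutate_mirna=10)
        accepted, near = call_targets({"mir": m}, pile, tx, max_score=7)
        assert accepted == []
        assert any("compliance score" in c.reason for c in near)


class TestTplot:
    def test_dense_table_with_called_site_flag(self):
        rng = np.random.default_rng(5)
        m = _random_mirna(rng)
        tx_seq = "".join(rng.choice(list("ACGT"), size=100)) + revcomp(m) \
            + "".join(rng.choice(list("ACGT"), size=79))
        tags = [tx_seq[111:137]] * 5 + [tx_seq[20:46]] * 2
        pile = build_pileup(tags, {"tx": tx_seq})
        accepted, _ = call_targets({"mir": m}, pile, {"tx": tx_seq})
        table = export_tplot("tx", tx_seq, pile, accepted[0])
        assert len(table) == len(tx_seq)  # dense: every position present
        assert table.loc[table.position == 112, "is_called_site"].item()
        assert int(table.raw.sum()) == pile.n_mapped == 7

    def test_transcript_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call = TestCallTargets()
            m, tx, pile, _ = call._setup(np.random.default_rng(3))
            acc, _ = call_targets({"mir": m}, pile, tx)
            export_tplot("other", "ACGT" * 10, pile, acc[0])
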