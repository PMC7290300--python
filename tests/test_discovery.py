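"""Tests for precursor excision, hairpin/star validation, novelty and family
classification, and spliced pri-miRNA alignment."""

import pytest

from mirdeg import discovery, synthetic
from mirdeg._seq import revcomp
from mirdeg.discovery import (
    GeneModel,
    Rejection,
    SplicedAlignError,
    classify_novelty,
    derive_star,
    excise_candidates,
    fold_select,
    group_families,
    spliced_align_pri,
)
from mirdeg.fold import MaxPairFolder, ViennaFolder, default_folder
from mirdeg.srna import Cluster, Placement, SmallRnaTag
from mirdeg.synthetic import GeneratorConfig, generate_truth


def _cluster(genome_len=2000, start=1000, strand="+"):
    tag = SmallRnaTag("A" * 21, 30, 1000.0, "lib")
    p = Placement(tag, "c1", strand, start, start + 21)
    return Cluster("c1", strand, start, start + 21, [p])


class TestExcision:
    def test_flank_extension(self):
        genome = {"c1": "ACGT" * 500}
        (w,) = excise_candidates(_cluster(start=1000), genome, flank=200)
        assert (w.start, w.end) == (800, 1221)

    def test_clipped_at_chromosome_start(self):
        genome = {"c1": "ACGT" * 500}
        (w,) = excise_candidates(_cluster(start=50), genome, flank=200)
        assert w.start == 0 and w.end == 271

    def test_minus_strand_reverse_complemented(self):
        genome = {"c1": "ACGT" * 500}
        (plus,) = excise_candidates(_cluster(start=1000, strand="+"), genome)
        (minus,) = excise_candidates(_cluster(start=1000, strand="-"), genome)
        assert minus.seq == revcomp(plus.seq)

    def test_unknown_chromosome(self):
        with pytest.raises(KeyError):
            excise_candidates(_cluster(), {"other": "ACGT" * 100})


PERFECT_ARM = "GCTAGCTAGGATCCTTAGCAACGGATCGAT"  # 30 nt


class TestFoldSelect:
    @pytest.mark.parametrize("folder", [ViennaFolder(), MaxPairFolder()])
    def test_perfect_inverted_repeat_accepted(self, folder):
        hairpin = PERFECT_ARM + "GAAACAAA" + revcomp(PERFECT_ARM)
        mature = PERFECT_ARM[4:25]
        cand = fold_select(hairpin, mature, folder, refine=False)
        assert cand.dg < 0
        assert cand.precursor_seq[slice(*cand.mature_span)] == mature
        assert cand.n_unpaired_in_duplex <= 4

    def test_homopolymer_rejected(self):
        with pytest.raises(Rejection):
            fold_select("A" * 80, "A" * 21, default_folder())

    def test_short_window_rejected(self):
        with pytest.raises(Rejection):
            fold_select("ACGT" * 10, "ACGT" * 3, default_folder())

    def test_planted_precursors_recovered_across_seeds(self):
        """50 generator precursors: mature recovered on a stem arm in each."""
        folder = default_folder()
        cfg = GeneratorConfig(n_mir=5, genome_size=15_000, depth=1_000)
        n_checked = 0
        for seed in range(10):
            t = generate_truth(cfg, seed=seed)
            for g in t.mir_genes:
                chrom = t.genome[g.chrom]
                a, b = g.precursor_span
                lo, hi = max(0, a - 50), min(len(chrom), b + 50)
                window = chrom[lo:hi] if g.strand == "+" else revcomp(chrom[lo:hi])
                for m in g.matures:
                    cand = fold_select(window, m.sequence, folder)
                    assert m.sequence in cand.precursor_seq
                    n_checked += 1
        assert n_checked >= 50


def _stem_structure(n_pair=20, loop=10):
    return "(" * n_pair + "." * loop + ")" * n_pair


class TestDeriveStar:
    def test_perfect_stem_star_with_two_nt_overhangs(self):
        structure = _stem_structure()  # pairs i <-> 49-i
        span, unpaired = derive_star(structure, (2, 18))
        assert span == (34, 50) and unpaired == 0

    def test_five_unpaired_mature_bases_rejected(self):
        s = list(_stem_structure(22, 6))
        for i in range(5, 10):  # unpair 5 duplex positions symmetrically
            s[i] = "."
            s[49 - i] = "."
        with pytest.raises(Rejection, match="unpaired"):
            derive_star("".join(s), (2, 20))

    def test_four_unpaired_accepted(self):
        s = list(_stem_structure(22, 6))
        for i in range(5, 9):
            s[i] = "."
            s[49 - i] = "."
        _, unpaired = derive_star("".join(s), (2, 20))
        assert unpaired == 4

    def test_mature_overlapping_loop_rejected(self):
        # span (15, 35) straddles the loop: partners fall inside the span
        with pytest.raises(Rejection, match="loop"):
            derive_star(_stem_structure(), (15, 35))
        # span reaching into the loop without straddling fails the unpaired rule
        with pytest.raises(Rejection, match="unpaired"):
            derive_star(_stem_structure(), (12, 30))

    def test_large_bulge_rejected(self):
        # 3-nt bulge on the mature side between paired positions
        s = "(" * 8 + "..." + "(" * 8 + "." * 6 + ")" * 16
        with pytest.raises(Rejection, match="bulge"):
            derive_star(s, (2, 16))


class TestNovelty:
    CATALOG = {
        "mir-a": "TGACAGAAGAGAGTGAGCACA",
        "mir-b": "GGAATGTTGTCTGGCTCGAGG",
    }

    def test_identical_is_known(self):
        assert classify_novelty("TGACAGAAGAGAGTGAGCACA", self.CATALOG)[0] == "known"

    def test_two_mismatches_is_homologue(self):
        q = "TGACAGAAGAGAGTGAGCACA"
        q = "AC" + q[2:]  # two substitutions vs mir-a
        status, hit, mm = classify_novelty(q, self.CATALOG)
        assert (status, hit, mm) == ("homologue", "mir-a", 2)

    def test_distant_query_is_novel(self):
        status, _, mm = classify_novelty("CCCCCCCAAAAAAATTTTTTT", self.CATALOG)
        assert status == "novel" and mm > 2

    def test_length_offset_handled_by_sliding(self):
        q = "TGACAGAAGAGAGTGAGCACA"
        status, hit, mm = classify_novelty("A" + q + "G", self.CATALOG)  # +2 nt
        assert (status, hit, mm) == ("known", "mir-a", 0)

    def test_empty_catalog_rejected(self):
        with pytest.raises(ValueError):
            classify_novelty("ACGT" * 5 + "A", {})


def _call(mid, seq):
    return discovery.MirnaCall(
        mirna_id=mid, mature_seq=seq, precursor_id="p", hairpin=None,
        star_seq="", star_observed_in_reads=False, status="novel",
        best_hit=None, mismatches=None,
    )


class TestFamilies:
    A = "TGACAGAAGAGAGTGAGCACA"
    B = "TGACAGAAGAGAGTGAGCAGG"  # edit distance 2 from A

    def test_similar_with_shared_target_grouped(self):
        fams = group_families(
            [_call("a", self.A), _call("b", self.B)],
            {"a": {"tx1"}, "b": {"tx1", "tx2"}},
        )
        assert fams["a"] == fams["b"]

    def test_identical_with_shared_target_grouped(self):
        fams = group_families(
            [_call("a", self.A), _call("b", self.A)], {"a": {"tx1"}, "b": {"tx1"}}
        )
        assert fams["a"] == fams["b"]

    def test_similar_without_shared_target_separate(self):
        fams = group_families(
            [_call("a", self.A), _call("b", self.B)], {"a": {"tx1"}, "b": {"tx2"}}
        )
        assert fams["a"] != fams["b"]

    def test_shared_target_but_dissimilar_separate(self):
        fams = group_families(
            [_call("a", self.A), _call("b", "CCCCCCCAAAAAAATTTTTTT")],
            {"a": {"tx1"}, "b": {"tx1"}},
        )
        assert fams["a"] != fams["b"]


class TestSplicedAlign:
    def test_planted_genes_recover_exact_structure(self):
        """20 seeded MIR genes align back to their exact exon/intron spans."""
        n_checked = 0
        cfg = GeneratorConfig(n_mir=4, genome_size=20_000, depth=1_000)
        for seed in (11, 12, 13, 14, 15):
            t = generate_truth(cfg, seed=seed)
            for g in t.mir_genes:
                gm = spliced_align_pri(
                    g.pri_seq, t.genome, g.gene_id, precursor_seq=g.precursor_seq
                )
                assert isinstance(gm, GeneModel)
                assert (gm.chrom, gm.strand) == (g.chrom, g.strand)
                assert gm.exon_spans == g.exon_spans
                assert gm.intron_spans == g.intron_spans
                assert gm.precursor_exon_index == g.precursor_exon_index
                n_checked += 1
        assert n_checked == 20

    def test_intronless_pri_is_single_exon(self, truth):
        g = next(g for g in truth.mir_genes if not g.intron_spans)
        gm = spliced_align_pri(g.pri_seq, truth.genome, g.gene_id)
        assert len(gm.exon_spans) == 1 and not gm.intron_spans

    def test_gc_ag_intron_rejected_as_non_u2(self, truth):
        g = next(g for g in truth.mir_genes if g.intron_spans and g.strand == "+")
        chrom = truth.genome[g.chrom]
        ia, _ = g.intron_spans[0]
        mutated = chrom[:ia] + "GC" + chrom[ia + 2 :]
        with pytest.raises(SplicedAlignError) as err:
            spliced_align_pri(g.pri_seq, {**truth.genome, g.chrom: mutated}, g.gene_id)
        assert any("non-U2" in d for d in err.value.diagnostics)

    def test_short_pri_rejected(self, truth):
        with pytest.raises(ValueError):
            spliced_align_pri("ACGT" * 10, truth.genome)


class TestRefoldInvariant:
    def test_accepted_candidates_refold_identically(self, truth, control_result):
        from mirdeg.pipeline import discover_mirnas

        folder = default_folder()
        calls = discover_mirnas(control_result, truth.genome, TestNovelty.CATALOG)
        assert calls
        for c in calls:
            structure, dg = folder.fold(c.hairpin.precursor_seq)
            assert structure == c.hairpin.structure
            assert dg == pytest.approx(c.hairpin.dg)
            assert c.mature_seq in c.hairpin.precursor_seq
            assert c.star_seq in c.hairpin.precursor_seq
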