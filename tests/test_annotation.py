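"""Transcript parsing, coordinate arithmetic and NMD feature annotation."""

import numpy as np
import pytest
from Bio.Seq import Seq

from nmdeff import (
    TranscriptModel,
    annotate_nmd_features,
    build_gene_sets,
    parse_transcript_models,
    select_target_control_pairs,
)
from nmdeff.features import NMDFeatureProfile, PairThresholds, find_uorfs


def build_locus(exon_seqs, strand="+", intron_len=50, cds_start=0, cds_end=None, chrom="chrT"):
    """Lay spliced exon sequences on a toy genome; return (model, genome)."""
    spliced = "".join(exon_seqs)
    cds_end = cds_end if cds_end is not None else len(spliced)
    intron = "T" * intron_len
    locus, offsets = "", []
    for i, es in enumerate(exon_seqs):
        if i:
            locus += intron
        offsets.append(len(locus))
        locus += es
    if strand == "+":
        genome = {chrom: locus}
        exons = [(off, off + len(es)) for off, es in zip(offsets, exon_seqs)]
    else:
        genome = {chrom: str(Seq(locus).reverse_complement())}
        L = len(locus)
        exons = [
            (L - off - len(es), L - off) for off, es in zip(offsets, exon_seqs)
        ]
    model = TranscriptModel("tx1", "g1", chrom, strand, exons, cds_start, cds_end)
    return model, genome


class TestParsing:
    def test_round_trip_coordinates_both_strands(self, toy_annotation):
        """genomic->transcript->genomic is the identity on every exonic nt."""
        _, models, _ = toy_annotation
        assert any(m.strand == "-" for m in models)
        for m in models:
            for s, e in m.exons:
                for g in range(s, e):
                    assert m.transcript_to_genomic(m.genomic_to_transcript(g)) == g

    def test_parsed_models_match_generator_truth(self, toy_annotation):
        bundle, models, profiles = toy_annotation
        truth = bundle.truth.set_index("transcript_id")
        assert len(models) == len(truth)
        for m in models:
            t = truth.loc[m.transcript_id]
            p = profiles[m.transcript_id]
            assert p.has_3utr_ejc == bool(t.expect_3utr_ejc)
            assert p.n_qualifying_uorfs == int(t.expect_n_uorfs)
            # all generated CDS are complete ORFs
            cds = m.cds_sequence(bundle.genome)
            assert cds[:3] == "ATG" and cds[-3:] == "TAA" and len(cds) % 3 == 0

    def test_transcript_without_cds_is_skipped_with_warning(self, tmp_path, caplog):
        gtf = tmp_path / "a.gtf"
        fa = tmp_path / "a.fa"
        fa.write_text(">chr1\n" + "ACGT" * 30 + "\n")
        gtf.write_text(
            'chr1\tx\texon\t1\t30\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\tCDS\t1\t30\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
            'chr1\tx\texon\t41\t80\t.\t+\t.\tgene_id "g2"; transcript_id "t2";\n'
        )
        import logging

        with caplog.at_level(logging.WARNING):
            models = parse_transcript_models(str(gtf), str(fa))
        assert [m.transcript_id for m in models] == ["t1"]
        assert any("t2" in r.message for r in caplog.records)

    def test_missing_chromosome_raises_with_name(self, tmp_path):
        gtf = tmp_path / "a.gtf"
        fa = tmp_path / "a.fa"
        fa.write_text(">chr1\nACGTACGT\n")
        gtf.write_text(
            'chrZ\tx\texon\t1\t6\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chrZ\tx\tCDS\t1\t6\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(ValueError, match="chrZ"):
            parse_transcript_models(str(gtf), str(fa))


class TestFeatures:
    def test_minimal_uorf_counts(self):
        # ATG + 8 codons + TAA = 30 nt, ends before the CDS: one qualifying uORF
        utr5 = "CCC" + "ATG" + "GGC" * 8 + "TAA" + "CC"
        assert find_uorfs(utr5) == [(3, 30)]

    def test_short_uorf_not_counted(self):
        utr5 = "CCC" + "ATG" + "GGC" * 7 + "TAA" + "CC"  # 27 nt
        assert find_uorfs(utr5) == []
        assert find_uorfs(utr5, min_length_nt=27) == [(3, 27)]

    def test_uorf_without_stop_before_cds_not_counted(self):
        # AUG whose frame reaches the CDS without a stop: overlaps the CDS
        utr5 = "CCC" + "ATG" + "GGC" * 12
        assert find_uorfs(utr5) == []

    @pytest.mark.parametrize("distance,expected", [(40, False), (50, False), (60, True)])
    def test_3utr_junction_distance_rule(self, distance, expected):
        """An EJC triggers only when strictly more than 50 nt past the stop."""
        cds = "ATG" + "GGC" * 20 + "TAA"
        utr3a, utr3b = "C" * distance, "G" * 40
        model, genome = build_locus(
            [cds + utr3a, utr3b], cds_start=0, cds_end=len(cds)
        )
        prof = annotate_nmd_features(model, genome)
        assert prof.ejc_distances_nt == [distance]
        assert prof.has_3utr_ejc is expected

    def test_strand_symmetry(self):
        """Reverse-complementing the locus and flipping strand preserves features."""
        utr5 = "CCC" + "ATG" + "GGC" * 8 + "TAA" + "CCCGGG"
        cds = "ATG" + "GCTAAGGAC" * 7 + "TAA"
        utr3 = "GCGCGC" * 20
        parts = [utr5 + cds + utr3[:60], utr3[60:]]
        plus_model, plus_genome = build_locus(
            parts, strand="+", cds_start=len(utr5), cds_end=len(utr5) + len(cds)
        )
        minus_model, minus_genome = build_locus(
            parts, strand="-", cds_start=len(utr5), cds_end=len(utr5) + len(cds)
        )
        p_plus = annotate_nmd_features(plus_model, plus_genome)
        p_minus = annotate_nmd_features(minus_model, minus_genome)
        assert p_plus.uorfs == p_minus.uorfs
        assert p_plus.ejc_distances_nt == p_minus.ejc_distances_nt
        assert p_plus.utr3_gc == p_minus.utr3_gc

    def test_empty_3utr(self):
        cds = "ATG" + "GGC" * 30 + "TAA"
        model, genome = build_locus([cds[:50], cds[50:]], cds_start=0, cds_end=len(cds))
        prof = annotate_nmd_features(model, genome)
        assert prof.utr3_gc is None and prof.has_3utr_ejc is False


class TestGeneSets:
    LISTS = {
        "tani": {"A", "B", "C"},
        "colombo": {"B", "C", "D"},
        "karousis": {"C", "E"},
    }

    def test_consensus_and_all(self):
        sets = build_gene_sets(self.LISTS)
        assert sets["consensus"] == {"B", "C"}
        assert sets["all"] == {"A", "B", "C", "D", "E"}
        assert "A" in sets["all"] and "A" not in sets["consensus"]

    def test_random_controls_exclude_study_genes(self):
        profiles = {}
        gene_of_tx = {}
        for i in range(30):
            g, tid = f"R{i}", f"R{i}.t"
            gene_of_tx[tid] = g
            profiles[tid] = NMDFeatureProfile(
                tid, has_3utr_ejc=(i % 2 == 0), n_qualifying_uorfs=0
            )
        # also give study genes profiles: they must still be excluded
        for g in ["A", "B", "C", "D", "E"]:
            gene_of_tx[g + ".t"] = g
            profiles[g + ".t"] = NMDFeatureProfile(g + ".t", has_3utr_ejc=True)
        sets = build_gene_sets(
            self.LISTS, profiles, gene_of_tx, n_random=10, rng_seed=3
        )
        assert not sets["random_with_features"] & sets["all"]
        assert not sets["random_without_features"] & sets["all"]
        assert not sets["random_with_features"] & sets["random_without_features"]

    def test_pool_too_small_raises(self):
        profiles = {"X.t": NMDFeatureProfile("X.t", has_3utr_ejc=True)}
        with pytest.raises(ValueError, match="eligible"):
            build_gene_sets(self.LISTS, profiles, {"X.t": "X"}, n_random=5)

    def test_fewer_than_two_lists_rejected(self):
        with pytest.raises(ValueError):
            build_gene_sets({"tani": {"A"}})


def _gene_with_two_transcripts(ejc_target=True, gc_fill="G"):
    utr5 = "C" * 60
    cds = "ATG" + "GGC" * 40 + "TAA"
    utr3 = (gc_fill * 2 + "TT") * 30
    t_parts = [utr5 + cds + utr3[:60], utr3[60:]]
    target, genome_t = build_locus(
        t_parts, cds_start=len(utr5), cds_end=len(utr5) + len(cds), chrom="chrT"
    )
    target.transcript_id, target.gene_id = "g1.t1", "g1"
    c_parts = [utr5 + cds[:60], cds[60:] + utr3]
    control, genome_c = build_locus(
        c_parts, cds_start=len(utr5), cds_end=len(utr5) + len(cds), chrom="chrC"
    )
    control.transcript_id, control.gene_id = "g1.t2", "g1"
    genome = {**genome_t, **genome_c}
    return target, control, genome


class TestPairSelection:
    def _setup(self):
        target, control, genome = _gene_with_two_transcripts()
        profiles = {
            t.transcript_id: annotate_nmd_features(t, genome) for t in (target, control)
        }
        assert profiles["g1.t1"].has_3utr_ejc and not profiles["g1.t2"].has_nmd_features
        return target, control, genome, profiles

    def test_pair_emitted_when_all_criteria_met(self):
        target, control, genome, profiles = self._setup()
        pair = select_target_control_pairs(
            [target, control], profiles,
            median_logtpm={"g1.t1": 1.5, "g1.t2": 3.2},
            median_tpm={"g1.t1": 4.0, "g1.t2": 10.0},
            genome=genome,
        )
        assert pair is not None
        assert pair.target_id == "g1.t1" and pair.control_id == "g1.t2"
        assert pair.expression_ratio == pytest.approx(0.4)

    def test_ratio_above_limit_rejected(self):
        target, control, genome, profiles = self._setup()
        pair = select_target_control_pairs(
            [target, control], profiles,
            median_logtpm={"g1.t1": 1.5, "g1.t2": 3.2},
            median_tpm={"g1.t1": 9.5, "g1.t2": 10.0},
            genome=genome,
        )
        assert pair is None

    def test_highest_utr3_gc_target_wins(self):
        target, control, genome, profiles = self._setup()
        # clone the target with lower 3'UTR GC
        low_gc = TranscriptModel(
            "g1.t0", "g1", target.chrom, target.strand, list(target.exons),
            target.cds_start, target.cds_end,
        )
        profiles = dict(profiles)
        profiles["g1.t0"] = NMDFeatureProfile(
            "g1.t0", has_3utr_ejc=True, ejc_distances_nt=[60], utr3_gc=0.55
        )
        profiles["g1.t1"] = NMDFeatureProfile(
            "g1.t1", has_3utr_ejc=True, ejc_distances_nt=[60], utr3_gc=0.62
        )
        pair = select_target_control_pairs(
            [low_gc, target, control], profiles,
            median_logtpm={"g1.t0": 2.0, "g1.t1": 1.5, "g1.t2": 3.2},
            median_tpm={"g1.t0": 4.0, "g1.t1": 4.0, "g1.t2": 10.0},
            genome=genome,
        )
        assert pair.target_id == "g1.t1"

    def test_wildtype_cellline_ratio_filter(self):
        target, control, genome, profiles = self._setup()
        kwargs = dict(
            profiles=profiles,
            median_logtpm={"g1.t1": 1.5, "g1.t2": 3.2},
            median_tpm={"g1.t1": 4.0, "g1.t2": 10.0},
            genome=genome,
        )
        ok = select_target_control_pairs(
            [target, control], wildtype_cellline_ratios={"g1.t1": 0.8}, **kwargs
        )
        assert ok is not None and ok.wildtype_cellline_ratio == 0.8
        bad = select_target_control_pairs(
            [target, control], wildtype_cellline_ratios={"g1.t1": 0.95}, **kwargs
        )
        assert bad is None
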