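"""PTC prediction (vs naive mutate-and-translate) and NMD-rule classification
(vs exhaustive position arithmetic)."""

import numpy as np
import pytest
from Bio.Seq import Seq

from nmdeff import (
    NMDClass,
    NMDRuleSet,
    PTCVariant,
    VariantOutsideCdsError,
    classify_ptc_nmd,
    predict_ptc,
)
from nmdeff.features import NMDFeatureProfile

from test_annotation import build_locus


def make_coding_locus(n_codons=120, strand="+", exon_split=None, seed=0):
    rng = np.random.default_rng(seed)
    safe = ["GCT", "GCC", "TGC", "GAC", "GAA", "TTC", "GGT", "CAC", "CTG"]
    utr5 = "C" * 30
    cds = "ATG" + "".join(rng.choice(safe) for _ in range(n_codons - 2)) + "TAA"
    utr3 = "".join(rng.choice(list("ACGT")) for _ in range(100))
    spliced = utr5 + cds + utr3
    cut = exon_split or [len(spliced) // 2]
    bounds = [0] + sorted(cut) + [len(spliced)]
    parts = [spliced[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    model, genome = build_locus(
        parts, strand=strand, cds_start=len(utr5), cds_end=len(utr5) + len(cds)
    )
    return model, genome, spliced


def variant_at(model, genome, t_pos, ref_len, alt_tx):
    """Build a plus-strand-allele variant whose transcript-strand edit at
    ``t_pos`` replaces ``ref_len`` bases with ``alt_tx`` (transcript strand)."""
    seq = model.spliced_sequence(genome)
    ref_tx = seq[t_pos : t_pos + ref_len]
    if model.strand == "+":
        pos = model.transcript_to_genomic(t_pos)
        ref, alt = ref_tx, alt_tx
    else:
        g_last = model.transcript_to_genomic(t_pos)
        pos = g_last - ref_len + 1
        ref = str(Seq(ref_tx).reverse_complement())
        alt = str(Seq(alt_tx).reverse_complement())
    return PTCVariant(
        variant_id=f"v:{t_pos}", chrom=model.chrom, pos=pos, ref=ref, alt=alt,
        variant_class="frameshift_indel" if len(alt_tx) != ref_len else "nonsense",
    )


def oracle_translate_ptc(model, genome, t_pos, ref_len, alt_tx):
    """Independent oracle: splice, edit, translate the full CDS-onward sequence
    with Biopython, report the first stop codon index (mutated frame)."""
    seq = model.spliced_sequence(genome)
    mutated = seq[:t_pos] + alt_tx + seq[t_pos + ref_len :]
    tail = mutated[model.cds_start :]
    tail = tail[: 3 * (len(tail) // 3)]
    prot = str(Seq(tail).translate())
    star = prot.find("*")
    return None if star == -1 else star


class TestPredictPtc:
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_nonsense_snv_maps_to_its_codon(self, strand):
        model, genome, _ = make_coding_locus(strand=strand)
        # codon 100 of the CDS: replace first base to make TGA from GCT etc.
        seq = model.spliced_sequence(genome)
        t_pos = model.cds_start + 3 * 100
        codon = seq[t_pos : t_pos + 3]
        stop = {"G": "TGA", "T": "TAA"}.get(codon[0], "TAG")
        var = variant_at(model, genome, t_pos, 3, stop)
        var.variant_class = "nonsense"
        pred = predict_ptc(var, model, genome)
        assert pred.ptc_cds_pos_nt == 3 * 100
        assert pred.ptc_genomic_pos == model.transcript_to_genomic(t_pos)

    @pytest.mark.parametrize("strand", ["+", "-"])
    @pytest.mark.parametrize("edit", [("del1", 1, ""), ("del2", 2, ""), ("ins1", 0, "G"), ("ins2", 1, "GCC" "C")])
    def test_indels_match_mutate_and_translate_oracle(self, strand, edit):
        """Frameshift/in-frame indels across positions agree with the naive
        full-sequence translation oracle."""
        _, ref_len, alt = edit
        model, genome, _ = make_coding_locus(strand=strand, seed=3)
        checked = 0
        for codon_i in range(2, 110, 9):
            t_pos = model.cds_start + 3 * codon_i + 1
            var = variant_at(model, genome, t_pos, ref_len, alt)
            pred = predict_ptc(var, model, genome)
            stop_codon = oracle_translate_ptc(model, genome, t_pos, ref_len, alt)
            delta = len(alt) - ref_len
            checked += 1
            if delta % 3 == 0:
                ref_stop = model.cds_length // 3 - 1
                premature = stop_codon is not None and 3 * stop_codon < 3 * ref_stop + delta
                if not premature:
                    assert pred.ptc_cds_pos_nt is None
                    continue
            if stop_codon is None:
                assert pred.ptc_cds_pos_nt is None
                continue
            # map oracle (mutated) position back to reference coordinates
            m = 3 * stop_codon
            expect_ref = m - delta if m >= (t_pos - model.cds_start) + len(alt) else m
            assert pred.ptc_cds_pos_nt == expect_ref
        assert checked >= 5

    def test_frameshift_with_stop_15_codons_downstream(self):
        """Constructed deletion whose shifted frame stops 15 codons later."""
        utr5 = "C" * 12
        k_stop = 16  # variant codon 1 + 15
        # all-G CDS; plant T/A so that the -1 frame reads TGA at codon 16
        cds = list("G" * 180)
        cds[0:3] = "ATG"
        cds[3 * k_stop + 1] = "T"
        cds[3 * k_stop + 3] = "A"
        cds[-3:] = "TAA"
        cds = "".join(cds)
        spliced = utr5 + cds + "C" * 60
        model, genome = build_locus(
            [spliced[:80], spliced[80:]], cds_start=len(utr5), cds_end=len(utr5) + len(cds)
        )
        t_pos = model.cds_start + 4  # delete one base in codon 1
        var = variant_at(model, genome, t_pos, 1, "")
        pred = predict_ptc(var, model, genome)
        oracle = oracle_translate_ptc(model, genome, t_pos, 1, "")
        assert oracle == k_stop
        assert pred.ptc_cds_pos_nt == 3 * k_stop + 1  # reference coords: +1 deleted base
        assert pred.ptc_exon_index is not None

    def test_inframe_deletion_without_stop_gives_no_ptc(self):
        model, genome, _ = make_coding_locus(seed=5)
        t_pos = model.cds_start + 31
        var = variant_at(model, genome, t_pos, 3, "")
        pred = predict_ptc(var, model, genome)
        assert pred.ptc_cds_pos_nt is None

    def test_variant_outside_cds_raises_distinct_error(self):
        model, genome, _ = make_coding_locus()
        var = variant_at(model, genome, 5, 1, "G")  # in the 5'UTR
        with pytest.raises(VariantOutsideCdsError):
            predict_ptc(var, model, genome)


# ---------------------------------------------------------------------------
# classification vs brute force
# ---------------------------------------------------------------------------

def brute_force_classify(t_pos, exon_lengths, has_3utr_ejc, rules):
    """Exhaustive position arithmetic, written independently of the library."""
    if t_pos < rules.start_proximal_nt:
        return "evading"
    cum = np.cumsum(exon_lengths)
    exon = int(np.searchsorted(cum, t_pos, side="right"))
    n = len(exon_lengths)
    in_last = exon == n - 1
    in_55 = exon == n - 2 and (cum[n - 2] - t_pos) <= rules.penultimate_tail_nt
    if in_last or in_55:
        if rules.utr3_ejc_override and has_3utr_ejc:
            return "triggering"
        return "evading"
    if rules.evading_min_exon_nt is not None and exon_lengths[exon] >= rules.evading_min_exon_nt:
        return "evading"
    if (
        rules.triggering_max_exon_nt is not None
        and exon_lengths[exon] > rules.triggering_max_exon_nt
    ):
        return "buffer"
    return "triggering"


FIXTURE_EXONS = [
    [300, 120, 200],
    [100, 700, 90, 400],
    [250, 1200, 60],
    [150, 80],
    [600, 550, 1050, 200],
]


class TestClassify:
    @pytest.mark.parametrize("exon_lengths", FIXTURE_EXONS)
    @pytest.mark.parametrize("ruleset", ["ase", "dnds"])
    @pytest.mark.parametrize("has_ejc", [False, True])
    def test_agrees_with_brute_force_on_every_position(self, exon_lengths, ruleset, has_ejc):
        total = sum(exon_lengths)
        exons = []
        start = 0
        for l in exon_lengths:
            exons.append((start, start + l))
            start += l + 50
        from nmdeff import TranscriptModel

        model = TranscriptModel("t", "g", "chr1", "+", exons, 0, total - total % 3)
        profile = NMDFeatureProfile("t", has_3utr_ejc=has_ejc)
        rules = NMDRuleSet.dnds() if ruleset == "dnds" else NMDRuleSet.ase_default()
        for t_pos in range(total):
            ptc = PTCVariant("v", "chr1", 0, "A", "T", "nonsense",
                             ptc_transcript_pos=t_pos)
            got = classify_ptc_nmd(ptc, model, profile, rules).value
            want = brute_force_classify(t_pos, exon_lengths, has_ejc, rules)
            assert got == want, (t_pos, got, want)

    def test_documented_rule_examples(self):
        from nmdeff import TranscriptModel

        # 3 exons of 300 nt each
        model = TranscriptModel(
            "t", "g", "chr1", "+", [(0, 300), (400, 700), (800, 1100)], 0, 900
        )
        no_ejc = NMDFeatureProfile("t", has_3utr_ejc=False)
        with_ejc = NMDFeatureProfile("t", has_3utr_ejc=True)
        rules = NMDRuleSet.ase_default()

        def cls(t_pos, profile, r=rules):
            ptc = PTCVariant("v", "chr1", 0, "A", "T", "nonsense", ptc_transcript_pos=t_pos)
            return classify_ptc_nmd(ptc, model, profile, r)

        assert cls(700, no_ejc) is NMDClass.EVADING  # last exon
        assert cls(700, with_ejc) is NMDClass.TRIGGERING  # 3'UTR EJC override
        assert cls(100, no_ejc) is NMDClass.EVADING  # start-proximal
        assert cls(560, no_ejc) is NMDClass.EVADING  # last 55 nt of penultimate exon
        assert cls(540, no_ejc) is NMDClass.TRIGGERING  # 60 nt from the junction
        # dnds buffer: PTC in a 700 nt internal exon, 300 nt from the start
        model2 = TranscriptModel(
            "t2", "g", "chr1", "+", [(0, 260), (300, 1000), (1100, 1400)], 0, 1200
        )
        ptc = PTCVariant("v", "chr1", 0, "A", "T", "nonsense", ptc_transcript_pos=300)
        assert classify_ptc_nmd(ptc, model2, NMDFeatureProfile("t2"), NMDRuleSet.dnds()) \
            is NMDClass.BUFFER

    def test_ruleset_validation(self):
        with pytest.raises(ValueError):
            NMDRuleSet(triggering_max_exon_nt=1000, evading_min_exon_nt=500)
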