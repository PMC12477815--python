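"""Premature termination codon (PTC) prediction and NMD-rule classification.

A PTC triggers NMD unless it falls in a canonical escape zone: the last exon,
the final stretch of the penultimate exon (the "55 nt rule": the terminating
ribosome displaces the last EJC), or the start-proximal region of the
transcript (translation reinitiation).  A splice junction in the 3'UTR
deposits an extra EJC downstream of any stop, flipping last-exon / 55 nt
escape calls back to triggering.

Two rule presets are provided: the default used for allele-specific
quantification (start-proximal cutoff 200 nt) and a stricter variant used for
selection analyses (cutoff 250 nt, plus long-exon evasion >= 1000 nt, a
500-1000 nt buffer zone, and a <= 500 nt exon requirement for triggering).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from Bio.Seq import Seq

from .features import NMDFeatureProfile, STOP_CODONS
from .transcripts import TranscriptModel


class NMDClass(str, Enum):
    TRIGGERING = "triggering"
    EVADING = "evading"
    BUFFER = "buffer"
    NONE = "none"


class VariantOutsideCdsError(ValueError):
    """The variant does not overlap the transcript CDS (distinct from 'no PTC')."""


@dataclass
class NMDRuleSet:
    """Configurable PTC classification rules (all distances in nt).

    ``start_proximal_nt`` is measured from the transcript start in spliced
    transcript coordinates.  ``penultimate_tail_nt`` is inclusive (a PTC
    exactly 55 nt from the junction evades).  The exon-length rules
    (``triggering_max_exon_nt`` / ``evading_min_exon_nt``) are only active in
    the ``dnds`` preset.
    """

    name: str = "ase_default"
    start_proximal_nt: int = 200
    penultimate_tail_nt: int = 55
    triggering_max_exon_nt: int | None = None
    evading_min_exon_nt: int | None = None
    utr3_ejc_override: bool = True

    def __post_init__(self):
        if (
            self.triggering_max_exon_nt is not None
            and self.evading_min_exon_nt is not None
            and not self.triggering_max_exon_nt < self.evading_min_exon_nt
        ):
            raise ValueError("triggering_max_exon_nt must be < evading_min_exon_nt")

    @classmethod
    def ase_default(cls) -> "NMDRuleSet":
        return cls(name="ase_default", start_proximal_nt=200)

    @classmethod
    def dnds(cls) -> "NMDRuleSet":
        return cls(
            name="dnds",
            start_proximal_nt=250,
            triggering_max_exon_nt=500,
            evading_min_exon_nt=1000,
        )


@dataclass
class PTCVariant:
    """A variant with its predicted PTC and allele-specific RNA counts.

    ``pos`` is the 0-based genomic position of the first reference base,
    ``ref``/``alt`` are plus-strand alleles (VCF-style anchored for indels).
    ``ptc_transcript_pos`` is the spliced-transcript offset of the first base
    of the predicted stop codon; ``ptc_cds_pos_nt`` the same offset relative
    to the CDS start.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # nonsense | frameshift_indel | inframe_indel | synonymous | missense
    transcript_id: str = ""
    ptc_transcript_pos: int | None = None
    ptc_cds_pos_nt: int | None = None
    ptc_exon_index: int | None = None
    ptc_genomic_pos: int | None = None
    nmd_class: NMDClass = NMDClass.NONE
    population_maf: float = 0.0
    gene_loeuf_percentile: float = 0.5
    filter_status: str = "PASS"
    wt_count: int = 0
    mut_count: int = 0


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def _edit_in_transcript_coords(variant, transcript: TranscriptModel):
    """(t_pos, ref_t, alt_t): the edit expressed on the spliced transcript strand."""
    if transcript.strand == "+":
        t_pos = transcript.genomic_to_transcript(variant.pos)
        return t_pos, variant.ref.upper(), variant.alt.upper()
    # minus strand: the last genomic base of ref is the transcript-first base
    g_last = variant.pos + len(variant.ref) - 1
    t_pos = transcript.genomic_to_transcript(g_last)
    return t_pos, _revcomp(variant.ref.upper()), _revcomp(variant.alt.upper())


def predict_ptc(variant: PTCVariant, transcript: TranscriptModel, genome) -> PTCVariant:
    """Predict the (premature) termination codon produced by a coding variant.

    Nonsense SNVs place the PTC at the mutated codon.  Frameshift indels are
    resolved by rebuilding the mutated spliced sequence and scanning the
    shifted reading frame from the variant codon for the first stop, which may
    fall downstream of the reference stop (including in the 3'UTR); the stop
    position is mapped back through the exon structure to a genomic location.
    In-frame indels yield a PTC only if they introduce a new stop upstream of
    the reference one.  Variants not overlapping the CDS raise
    :class:`VariantOutsideCdsError`.
    """
    seq = transcript.spliced_sequence(genome)
    t_pos, ref_t, alt_t = _edit_in_transcript_coords(variant, transcript)
    if not (transcript.cds_start <= t_pos < transcript.cds_end):
        raise VariantOutsideCdsError(
            f"{variant.variant_id} at transcript offset {t_pos} is outside the CDS"
        )
    if seq[t_pos : t_pos + len(ref_t)] != ref_t:
        raise ValueError(
            f"{variant.variant_id}: reference allele mismatch at transcript offset {t_pos}"
        )

    mutated = seq[:t_pos] + alt_t + seq[t_pos + len(ref_t) :]
    delta = len(alt_t) - len(ref_t)
    cds_pos = t_pos - transcript.cds_start
    codon0 = cds_pos // 3
    ref_stop_codon = transcript.cds_length // 3 - 1  # natural stop, ref coords

    # scan mutated sequence codon-by-codon from the variant codon to the 3' end
    mut_cds_onward = mutated[transcript.cds_start :]
    hit = None  # codon index in the mutated frame
    for k in range(codon0, len(mut_cds_onward) // 3):
        if mut_cds_onward[3 * k : 3 * k + 3] in STOP_CODONS:
            hit = k
            break

    result = None
    if delta == 0:  # SNV / MNV
        if hit is not None and hit < ref_stop_codon:
            result = 3 * hit
    elif delta % 3 == 0:  # in-frame indel: premature only if before shifted natural stop
        if hit is not None and 3 * hit < 3 * ref_stop_codon + delta:
            result = 3 * hit
    else:  # frameshift: any stop in the shifted frame is the predicted PTC
        if hit is not None:
            result = 3 * hit

    out = PTCVariant(**{**variant.__dict__})
    out.transcript_id = transcript.transcript_id
    if result is None:
        out.ptc_transcript_pos = None
        out.ptc_cds_pos_nt = None
        out.ptc_exon_index = None
        out.ptc_genomic_pos = None
        return out

    # map the stop position in mutated coordinates back to reference coordinates
    m_tpos = transcript.cds_start + result
    if m_tpos >= t_pos + len(alt_t):
        ref_tpos = m_tpos - delta
    elif m_tpos >= t_pos:
        ref_tpos = t_pos  # inside the inserted allele: anchor position
    else:
        ref_tpos = m_tpos
    ref_tpos = min(ref_tpos, transcript.transcript_length - 1)
    out.ptc_transcript_pos = ref_tpos
    out.ptc_cds_pos_nt = ref_tpos - transcript.cds_start
    out.ptc_exon_index = transcript.exon_index_of(ref_tpos)
    out.ptc_genomic_pos = transcript.transcript_to_genomic(ref_tpos)
    return out


def classify_ptc_nmd(
    ptc: PTCVariant,
    transcript: TranscriptModel,
    profile: NMDFeatureProfile,
    rules: NMDRuleSet | None = None,
) -> NMDClass:
    """Classify a predicted PTC as NMD-triggering, -evading or buffer-zone.

    Precedence: start-proximal evasion first; then last-exon and penultimate
    55 nt evasion (both flipped to triggering when the transcript carries a
    3'UTR EJC and ``rules.utr3_ejc_override``); then, for internal PTCs, the
    exon-length rules of the ``dnds`` preset (evading for exons >=
    ``evading_min_exon_nt``, buffer for lengths strictly between the two
    cutoffs, triggering only for exons <= ``triggering_max_exon_nt``).
    """
    rules = rules or NMDRuleSet.ase_default()
    if ptc.ptc_transcript_pos is None:
        return NMDClass.NONE
    t_pos = ptc.ptc_transcript_pos

    if t_pos < rules.start_proximal_nt:
        return NMDClass.EVADING

    exon_idx = transcript.exon_index_of(t_pos)
    last = transcript.n_exons - 1
    flip = rules.utr3_ejc_override and profile.has_3utr_ejc

    if exon_idx == last:
        return NMDClass.TRIGGERING if flip else NMDClass.EVADING
    if exon_idx == last - 1:
        junction = transcript.junction_positions()[exon_idx]
        if junction - t_pos <= rules.penultimate_tail_nt:
            return NMDClass.TRIGGERING if flip else NMDClass.EVADING

    if rules.evading_min_exon_nt is not None or rules.triggering_max_exon_nt is not None:
        exon_len = transcript.exon_lengths[exon_idx]
        if rules.evading_min_exon_nt is not None and exon_len >= rules.evading_min_exon_nt:
            return NMDClass.EVADING
        if (
            rules.triggering_max_exon_nt is not None
            and exon_len > rules.triggering_max_exon_nt
        ):
            return NMDClass.BUFFER
    return NMDClass.TRIGGERING
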