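"""NMD-triggering feature annotation and target/control transcript pairing.

Two sequence features mark a transcript as a likely endogenous NMD substrate:

* a qualifying upstream ORF (uORF) in the 5'UTR — AUG-initiated, terminating
  strictly before the CDS, of at least a minimum length (default 30 nt
  including the stop codon);
* an exon-exon junction (EJC deposition site) in the 3'UTR located strictly
  more than 50 nt downstream of the termination codon.

3'UTR GC content is recorded as well; among competing target transcripts the
one with the highest 3'UTR GC wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .transcripts import TranscriptModel

STOP_CODONS = {"TAA", "TAG", "TGA"}

#: strict ">" — a junction exactly 50 nt downstream does not trigger
EJC_MIN_DISTANCE_NT = 50
DEFAULT_MIN_UORF_NT = 30


@dataclass
class NMDFeatureProfile:
    """Per-transcript NMD-feature annotation."""

    transcript_id: str
    uorfs: list[tuple[int, int]] = field(default_factory=list)  # (start, length) in 5'UTR
    n_qualifying_uorfs: int = 0
    has_3utr_ejc: bool = False
    ejc_distances_nt: list[int] = field(default_factory=list)
    utr3_gc: float | None = None  # None when the 3'UTR is empty

    @property
    def has_nmd_features(self) -> bool:
        return self.has_3utr_ejc or self.n_qualifying_uorfs > 0


def find_uorfs(utr5: str, min_length_nt: int = DEFAULT_MIN_UORF_NT) -> list[tuple[int, int]]:
    """Qualifying uORFs in a 5'UTR sequence.

    Every AUG opens its own candidate ORF (overlapping uORFs count
    individually).  An ORF qualifies if an in-frame stop codon occurs with its
    last base still inside the 5'UTR — i.e. the uORF does not overlap the CDS —
    and its length (start through stop codon, inclusive) is >= ``min_length_nt``.
    """
    utr5 = utr5.upper()
    out = []
    n = len(utr5)
    for i in range(n - 2):
        if utr5[i : i + 3] != "ATG":
            continue
        for j in range(i + 3, n - 2, 3):
            if utr5[j : j + 3] in STOP_CODONS:
                length = j + 3 - i
                if length >= min_length_nt:
                    out.append((i, length))
                break
    return out


def annotate_nmd_features(
    transcript: TranscriptModel,
    genome,
    min_uorf_nt: int = DEFAULT_MIN_UORF_NT,
    ejc_min_distance_nt: int = EJC_MIN_DISTANCE_NT,
) -> NMDFeatureProfile:
    """Annotate uORFs, 3'UTR junctions and 3'UTR GC for one transcript.

    Junction distances are measured from the first nt after the stop codon
    (transcript offset ``cds_end``) to each downstream exon-exon junction; a
    junction counts as an NMD-triggering EJC only if strictly more than
    ``ejc_min_distance_nt`` downstream.
    """
    seq = transcript.spliced_sequence(genome)
    utr5 = seq[: transcript.cds_start]
    utr3 = seq[transcript.cds_end :]

    uorfs = find_uorfs(utr5, min_length_nt=min_uorf_nt)

    distances = [
        j - transcript.cds_end
        for j in transcript.junction_positions()
        if j > transcript.cds_end
    ]
    has_ejc = any(d > ejc_min_distance_nt for d in distances)

    if utr3:
        gc = sum(1 for b in utr3 if b in "GC") / len(utr3)
    else:
        gc = None

    return NMDFeatureProfile(
        transcript_id=transcript.transcript_id,
        uorfs=uorfs,
        n_qualifying_uorfs=len(uorfs),
        has_3utr_ejc=has_ejc,
        ejc_distances_nt=distances,
        utr3_gc=gc,
    )


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------

def build_gene_sets(
    study_gene_lists: dict[str, set[str]],
    feature_profiles: dict[str, NMDFeatureProfile] | None = None,
    gene_of_transcript: dict[str, str] | None = None,
    all_genes: set[str] | None = None,
    n_random: int = 50,
    rng_seed: int = 0,
) -> dict[str, set[str]]:
    """Combine per-study NMD-target gene lists into the derived sets.

    Returns the per-study sets plus:

    * ``consensus`` — genes reported in at least 2 independent studies;
    * ``all`` — union over all studies;
    * ``random_with_features`` / ``random_without_features`` — control sets of
      ``n_random`` genes absent from every study list, restricted to genes
      whose transcripts do / do not carry NMD-triggering features (requires
      ``feature_profiles`` and ``gene_of_transcript``).
    """
    if len(study_gene_lists) < 2:
        raise ValueError("at least 2 study gene lists are required")
    sets: dict[str, set[str]] = {k: set(v) for k, v in study_gene_lists.items()}
    union: set[str] = set().union(*sets.values())
    counts: dict[str, int] = {}
    for s in sets.values():
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    sets["consensus"] = {g for g, c in counts.items() if c >= 2}
    sets["all"] = union

    if feature_profiles is not None and gene_of_transcript is not None:
        genes_with, genes_without = set(), set()
        for tid, prof in feature_profiles.items():
            g = gene_of_transcript[tid]
            (genes_with if prof.has_nmd_features else genes_without).add(g)
        genes_without -= genes_with
        pool_with = sorted((genes_with - union) & (all_genes or genes_with))
        pool_without = sorted((genes_without - union) & (all_genes or genes_without))
        rng = np.random.default_rng(rng_seed)
        for name, pool in (
            ("random_with_features", pool_with),
            ("random_without_features", pool_without),
        ):
            if n_random > len(pool):
                raise ValueError(
                    f"{name}: requested {n_random} genes but only {len(pool)} eligible"
                )
            sets[name] = set(rng.choice(pool, size=n_random, replace=False))
    return sets


# ---------------------------------------------------------------------------
# target / control pairing
# ---------------------------------------------------------------------------

@dataclass
class TargetControlPair:
    """An NMD-target transcript paired with a same-gene featureless control."""

    gene_id: str
    target_id: str
    control_id: str
    target_median_logtpm: float
    control_median_logtpm: float
    expression_ratio: float
    target_utr3_gc: float | None
    wildtype_cellline_ratio: float | None = None


@dataclass
class PairThresholds:
    """Selection thresholds for target/control pairing.

    ``log(TPM)`` thresholds use natural log by default (``log_base=e``);
    ``log_base`` may be set to 2 for log2-scaled summaries.
    """

    target_min_logtpm: float = 1.0
    control_min_logtpm: float = 3.0
    max_expression_ratio: float = 0.9  # inclusive
    min_uorfs: int = 2
    log_base: float = math.e
    max_wildtype_ratio: float = 0.9


def _has_start_stop(transcript: TranscriptModel, genome) -> bool:
    cds = transcript.cds_sequence(genome)
    return (
        len(cds) >= 6
        and cds[:3] == "ATG"
        and cds[-3:] in STOP_CODONS
        and len(cds) % 3 == 0
    )


def select_target_control_pairs(
    transcripts: list[TranscriptModel],
    profiles: dict[str, NMDFeatureProfile],
    median_logtpm: dict[str, float],
    median_tpm: dict[str, float],
    genome,
    thresholds: PairThresholds | None = None,
    wildtype_cellline_ratios: dict[str, float] | None = None,
) -> TargetControlPair | None:
    """Select the NMD target/control transcript pair for one gene.

    Target: start+stop codon, median log(TPM) >= 1, and either a 3'UTR EJC or
    >= 2 qualifying uORFs; ties broken by highest 3'UTR GC, then transcript id.
    Control: start+stop codon, median log(TPM) >= 3, no NMD features; the most
    expressed qualifying control is used.  The pair is emitted only when the
    target/control TPM ratio is <= 0.9 (and, when supplied, the wild-type
    cell-line expression ratio is <= 0.9).
    """
    th = thresholds or PairThresholds()

    targets, controls = [], []
    for tx in transcripts:
        prof = profiles[tx.transcript_id]
        if not _has_start_stop(tx, genome):
            continue
        ltpm = median_logtpm.get(tx.transcript_id, -np.inf)
        if prof.has_3utr_ejc or prof.n_qualifying_uorfs >= th.min_uorfs:
            if ltpm >= th.target_min_logtpm:
                targets.append(tx)
        elif not prof.has_nmd_features and ltpm >= th.control_min_logtpm:
            controls.append(tx)
    if not targets or not controls:
        return None

    # highest 3'UTR GC wins; deterministic lexicographic tie-break
    def gc_key(tx):
        gc = profiles[tx.transcript_id].utr3_gc
        return (-(gc if gc is not None else -1.0), tx.transcript_id)

    target = min(targets, key=gc_key)
    control = max(controls, key=lambda t: median_logtpm[t.transcript_id])

    t_tpm = median_tpm[target.transcript_id]
    c_tpm = median_tpm[control.transcript_id]
    if c_tpm <= 0:
        return None
    ratio = t_tpm / c_tpm
    if ratio > th.max_expression_ratio:
        return None
    wt_ratio = None
    if wildtype_cellline_ratios is not None:
        wt_ratio = wildtype_cellline_ratios.get(target.transcript_id)
        if wt_ratio is not None and wt_ratio > th.max_wildtype_ratio:
            return None

    return TargetControlPair(
        gene_id=target.gene_id,
        target_id=target.transcript_id,
        control_id=control.transcript_id,
        target_median_logtpm=median_logtpm[target.transcript_id],
        control_median_logtpm=median_logtpm[control.transcript_id],
        expression_ratio=ratio,
        target_utr3_gc=profiles[target.transcript_id].utr3_gc,
        wildtype_cellline_ratio=wt_ratio,
    )
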