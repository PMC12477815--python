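"""Allele-specific-expression (ASE) iNMDeff estimation.

Germline PTC variants contribute two design rows each (wild-type and mutant
allele counts); the NB regression with gene fixed effects yields iNMDeff as
the sign-flipped mutant-allele coefficient.  The gene (not the variant) is
the blocking factor, so variants sharing a gene share one effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glm import INMDeffEstimate, derive_seed, fit_nb_glm

VARIANT_SETS = ("triggering", "evading", "synonymous")
MIN_VARIANTS = 3
MAX_VARIANTS = 100
MIN_COVERAGE_SNV = 5
MIN_COVERAGE_INDEL = 2
MAX_MAF = 0.20  # exclude strictly greater
DEFAULT_LOEUF_CUTOFF = 0.10  # most constrained decile excluded

_INDEL_CLASSES = {"frameshift_indel", "inframe_indel"}


@dataclass
class AseFilterConfig:
    min_coverage_snv: int = MIN_COVERAGE_SNV
    min_coverage_indel: int = MIN_COVERAGE_INDEL
    max_maf: float = MAX_MAF
    loeuf_cutoff: float = DEFAULT_LOEUF_CUTOFF
    min_variants: int = MIN_VARIANTS
    max_variants: int = MAX_VARIANTS
    gtex_mode: bool = False  # drop variants observed in a single tissue


@dataclass
class AuxiliaryLists:
    """Side inputs to the ASE cascade (all optional)."""

    positive_selection_genes: set[str] = field(default_factory=set)
    nmd_all_genes: set[str] = field(default_factory=set)
    single_exon_transcripts: set[str] = field(default_factory=set)
    noncoding_transcripts: set[str] = field(default_factory=set)
    excluded_variants: set[str] = field(default_factory=set)  # somatic co-occurrence


def filter_ase_variants(
    variants: pd.DataFrame,
    individual_id: str,
    variant_set: str,
    config: AseFilterConfig | None = None,
    auxiliary: AuxiliaryLists | None = None,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-individual ASE filtering cascade; returns the NB design table.

    ``variants`` is one row per variant with columns ``variant_id``,
    ``gene_id``, ``transcript_id``, ``variant_class``, ``nmd_class``,
    ``filter_status``, ``heterozygous`` (bool), ``population_maf``,
    ``gene_loeuf_percentile``, ``wt_count``, ``mut_count``, and — in GTex
    mode — ``n_tissues_observed``.

    Keeps PASS heterozygous variants with total coverage >= 5 (SNV classes)
    or >= 2 (indels) and MAF <= 20%; drops single-exon / non-coding
    transcripts, positively selected genes, the most constrained LOEUF bin,
    and variants co-occurring with somatic truncating events.  The triggering
    set keeps triggering PTCs only (frameshifts must have a predicted PTC),
    the evading set evading PTCs only, and the synonymous set drops variants
    in any NMD-All gene.  Fewer than 3 survivors yields an empty table; more
    than 100 are subsampled with a seeded generator.
    """
    if variant_set not in VARIANT_SETS:
        raise ValueError(f"unknown variant set {variant_set!r}; choose from {VARIANT_SETS}")
    cfg = config or AseFilterConfig()
    aux = auxiliary or AuxiliaryLists()
    v = variants.copy()

    v = v[v["filter_status"] == "PASS"]
    if "heterozygous" in v.columns:
        v = v[v["heterozygous"].astype(bool)]
    cov = v["wt_count"] + v["mut_count"]
    is_indel = v["variant_class"].isin(_INDEL_CLASSES)
    v = v[
        (is_indel & (cov >= cfg.min_coverage_indel))
        | (~is_indel & (cov >= cfg.min_coverage_snv))
    ]
    v = v[v["population_maf"] <= cfg.max_maf]
    if "transcript_id" in v.columns:
        v = v[~v["transcript_id"].isin(aux.single_exon_transcripts)]
        v = v[~v["transcript_id"].isin(aux.noncoding_transcripts)]
    v = v[~v["gene_id"].isin(aux.positive_selection_genes)]
    v = v[v["gene_loeuf_percentile"] > cfg.loeuf_cutoff]
    v = v[~v["variant_id"].isin(aux.excluded_variants)]
    if cfg.gtex_mode and "n_tissues_observed" in v.columns:
        v = v[v["n_tissues_observed"] > 1]

    if variant_set == "triggering":
        v = v[v["nmd_class"] == "triggering"]
        has_ptc = v["ptc_cds_pos_nt"].notna() if "ptc_cds_pos_nt" in v.columns else True
        v = v[~(v["variant_class"].eq("frameshift_indel") & ~has_ptc)]
    elif variant_set == "evading":
        v = v[v["nmd_class"] == "evading"]
    else:
        v = v[v["variant_class"] == "synonymous"]
        v = v[~v["gene_id"].isin(aux.nmd_all_genes)]

    if len(v) < cfg.min_variants:
        return _empty_design()
    if len(v) > cfg.max_variants:
        rng = np.random.default_rng(derive_seed(rng_seed, individual_id))
        idx = rng.choice(len(v), size=cfg.max_variants, replace=False)
        v = v.iloc[np.sort(idx)]

    rows = []
    for row in v.itertuples(index=False):
        for count, is_mut in ((row.wt_count, 0), (row.mut_count, 1)):
            rows.append(
                {
                    "variant_id": row.variant_id,
                    "raw_count": int(count),
                    "is_nmd_target": is_mut,
                    "gene_label": row.gene_id,
                }
            )
    return pd.DataFrame(rows)


def _empty_design() -> pd.DataFrame:
    return pd.DataFrame(columns=["variant_id", "raw_count", "is_nmd_target", "gene_label"])


def estimate_inmdeff_ase(
    individual_id: str,
    variant_set: str,
    rows: pd.DataFrame,
    theta: float | None = None,
) -> INMDeffEstimate | None:
    """NB regression of allele counts; iNMDeff = -(mutant-allele coefficient).

    exp(-inmdeff) is the modeled mutant/wild-type allele ratio.  Returns
    ``None`` on an empty design table.  A degenerate all-zero mutant arm
    surfaces as ``converged=False`` or an extreme finite estimate.
    """
    if rows.empty:
        return None
    n_variants = int(rows["is_nmd_target"].sum())
    fit = fit_nb_glm(rows, theta=theta, length_covariate=False)
    return INMDeffEstimate(
        individual_id=individual_id,
        nmd_set=variant_set,
        inmdeff=-fit.beta1,
        standard_error=fit.beta1_se,
        n_units=n_variants,
        dispersion=fit.theta,
        converged=fit.converged,
    )
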