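"""Endogenous-target-gene (ETG) iNMDeff estimation.

For one individual and one NMD gene set, the filtered target/control
transcript pairs are pooled into a design table (one row per transcript) and
the NB regression of :mod:`nmdeff.glm` is fit; iNMDeff is the sign-flipped
coefficient of the NMD-target indicator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .features import TargetControlPair
from .glm import INMDeffEstimate, derive_seed, fit_nb_glm

MIN_PAIRS = 2
MAX_PAIRS = 50
PREVALENCE_MIN_LOG2_COUNT = 1.0  # log2(raw) >= 1, i.e. raw >= 2
PREVALENCE_MIN_FRACTION = 0.5
CONSENSUS_SET = "consensus"


def filter_etg_pairs(
    pairs: list[TargetControlPair] | pd.DataFrame,
    cohort_counts: pd.DataFrame,
    individual_id: str,
    tissue_of_sample: pd.Series | dict | None = None,
    transcript_lengths: dict[str, int] | pd.Series | None = None,
    coding_transcripts: set[str] | None = None,
    excluded_transcripts: set[str] | None = None,
    nmd_set: str = "all",
    max_pairs: int = MAX_PAIRS,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Per-individual ETG filtering cascade; returns the NB design table.

    Filters, in order: cohort prevalence (a pair is dropped when *both*
    members have log2(raw count) >= 1 in fewer than 50% of the individual's
    tissue cohort — the whole cohort when no tissue labels are supplied);
    non-coding transcripts; transcripts in the per-individual exclusion set
    (overlapping truncating variants or copy-number alterations).  Fewer than
    2 surviving pairs yields an empty table (no estimate).  All sets except
    the consensus set are capped at ``max_pairs`` by seeded subsampling.

    ``cohort_counts`` is a transcripts x samples raw-count matrix.
    """
    if individual_id not in cohort_counts.columns:
        raise KeyError(f"unknown individual {individual_id!r}")
    if not isinstance(pairs, pd.DataFrame):
        pairs = pd.DataFrame(
            [
                {"gene_id": p.gene_id, "target_id": p.target_id, "control_id": p.control_id}
                for p in pairs
            ]
        )

    if tissue_of_sample is not None:
        tissue_of_sample = pd.Series(tissue_of_sample)
        cohort = tissue_of_sample.index[
            tissue_of_sample == tissue_of_sample[individual_id]
        ]
        cohort = [c for c in cohort if c in cohort_counts.columns]
    else:
        cohort = list(cohort_counts.columns)
    sub = cohort_counts.loc[:, cohort]
    # log2(raw count) >= 1 <=> raw count >= 2
    prevalent = (
        (sub >= 2.0 ** PREVALENCE_MIN_LOG2_COUNT)
        .mean(axis=1)
        .ge(PREVALENCE_MIN_FRACTION)
    )

    def tx_ok(tid: str) -> bool:
        if tid not in cohort_counts.index:
            return False
        if coding_transcripts is not None and tid not in coding_transcripts:
            return False
        if excluded_transcripts and tid in excluded_transcripts:
            return False
        return True

    keep = []
    for row in pairs.itertuples(index=False):
        if not (tx_ok(row.target_id) and tx_ok(row.control_id)):
            continue
        if not (prevalent.get(row.target_id, False) or prevalent.get(row.control_id, False)):
            continue
        keep.append(row)
    if len(keep) < MIN_PAIRS:
        return _empty_design()

    if nmd_set != CONSENSUS_SET and len(keep) > max_pairs:
        rng = np.random.default_rng(derive_seed(rng_seed, individual_id))
        idx = rng.choice(len(keep), size=max_pairs, replace=False)
        keep = [keep[i] for i in sorted(idx)]

    rows = []
    for row in keep:
        for tid, is_target in ((row.control_id, 0), (row.target_id, 1)):
            rec = {
                "transcript_id": tid,
                "raw_count": int(cohort_counts.at[tid, individual_id]),
                "is_nmd_target": is_target,
                "gene_label": row.gene_id,
            }
            if transcript_lengths is not None:
                rec["transcript_length_nt"] = int(transcript_lengths[tid])
            rows.append(rec)
    return pd.DataFrame(rows)


def _empty_design() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["transcript_id", "raw_count", "is_nmd_target", "gene_label"]
    )


def estimate_inmdeff_etg(
    individual_id: str,
    nmd_set: str,
    filtered_rows: pd.DataFrame,
    theta: float | None = None,
) -> INMDeffEstimate | None:
    """Fit the ETG NB regression and return the sign-flipped coefficient.

    Returns ``None`` on an empty design table (individual not estimable).
    exp(-inmdeff) is the modeled target/control expression ratio; values
    above 1 indicate lower NMD efficiency.
    """
    if filtered_rows.empty:
        return None
    n_pairs = int(filtered_rows["is_nmd_target"].sum())
    fit = fit_nb_glm(filtered_rows, theta=theta)
    return INMDeffEstimate(
        individual_id=individual_id,
        nmd_set=nmd_set,
        inmdeff=-fit.beta1,
        standard_error=fit.beta1_se,
        n_units=n_pairs,
        dispersion=fit.theta,
        converged=fit.converged,
    )
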