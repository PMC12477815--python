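"""Somatic copy-number signatures by sparse PCA and their iNMDeff associations.

The gene-level GISTIC-style dosage matrix is split into a duplicated
gain/loss representation (amplification rows keep scores >= 0, deletion rows
keep scores <= 0), so a single sparse component can capture an arm-level gain
without mixing in deletions.  Sparse PCA (elastic-net penalised, deterministic
LARS solver) is tuned by an autocorrelation criterion: a component driven by
an arm-level event has near-identical loadings on neighbouring genes, so the
lag-1 Pearson correlation of its genomically ordered loading vector
approaches 1.

Downstream: per-signature linear-model association with iNMDeff (discovery on
the allele-based estimates, validation on the transcript-based estimates),
gene-wise focal-amplification median iNMDeff tracks, and a two-criterion
candidate-gene prioritisation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.decomposition import SparsePCA

from .randomization import benjamini_hochberg

logger = logging.getLogger(__name__)


@dataclass
class GainLossMatrix:
    """Duplicated amplification/deletion dosage matrix.

    ``values`` is (2 * n_genes) x n_samples: the first block holds
    amplification rows (negative scores zeroed), the second deletion rows
    (positive scores zeroed); ``amp(g) + del(g)`` reconstructs the input
    score exactly.  ``gene_meta`` carries chrom/start for genomic ordering.
    """

    values: pd.DataFrame
    gene_meta: pd.DataFrame  # index: duplicated row ids; columns: gene, chrom, start, kind
    genomic_order: np.ndarray  # row positions sorted by (chrom, start, kind)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def build_gain_loss_matrix(
    gistic: pd.DataFrame,
    gene_coords: pd.DataFrame,
) -> GainLossMatrix:
    """Split a gene x sample GISTIC score table into gain/loss rows.

    ``gene_coords`` must be indexed by gene with ``chrom`` and ``start``
    columns; genes without coordinates are dropped with a warning.
    """
    known = gistic.index.intersection(gene_coords.index)
    missing = gistic.index.difference(gene_coords.index)
    if len(missing):
        logger.warning("%d genes without coordinates dropped", len(missing))
    g = gistic.loc[known]

    amp = g.clip(lower=0.0)
    dele = g.clip(upper=0.0)
    amp.index = [f"{i}__amp" for i in known]
    dele.index = [f"{i}__del" for i in known]
    values = pd.concat([amp, dele])

    meta = pd.DataFrame(
        {
            "gene": list(known) * 2,
            "chrom": list(gene_coords.loc[known, "chrom"]) * 2,
            "start": list(gene_coords.loc[known, "start"]) * 2,
            "kind": ["amp"] * len(known) + ["del"] * len(known),
        },
        index=values.index,
    )
    # amp block then del block, each in genomic order: an arm-level event is a
    # contiguous run in exactly one block, so lag-1 autocorrelation is preserved
    order = np.lexsort(
        (meta["start"].to_numpy(), meta["chrom"].to_numpy(), meta["kind"].to_numpy())
    )
    return GainLossMatrix(values=values, gene_meta=meta, genomic_order=order)


def autocorrelation_score(loadings: np.ndarray, genomic_order: np.ndarray | None = None) -> float:
    """Lag-1 Pearson autocorrelation of a genomically ordered loading vector.

    Returns 0 for constant vectors (correlation undefined).
    """
    v = np.asarray(loadings, dtype=float)
    if genomic_order is not None:
        v = v[genomic_order]
    if v.size < 3:
        raise ValueError("need at least 3 loadings")
    a, b = v[:-1], v[1:]
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class CnaPcSignature:
    pc_index: int
    loadings: np.ndarray  # over the duplicated gene axis (matrix row order)
    sample_scores: np.ndarray
    effective: bool
    autocorrelation: float
    explained_variance: float


def fit_sparse_pca(
    matrix: GainLossMatrix,
    alpha: float,
    k: int,
    ridge_alpha: float = 0.01,
    max_iter: int = 500,
) -> list[CnaPcSignature]:
    """Fit sparse PCA and return per-component signatures.

    Observations are samples, variables the duplicated gene rows.  The LARS
    solver with SVD warm start is deterministic, so fixed inputs give fixed
    loadings.  Components are ordered by explained variance of their sample
    scores; ``effective`` marks components with any nonzero loading.
    """
    X = matrix.values.to_numpy(dtype=float).T  # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    spca = SparsePCA(
        n_components=min(k, *X.shape),
        alpha=alpha,
        ridge_alpha=ridge_alpha,
        method="lars",
        max_iter=max_iter,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        scores = spca.fit_transform(X)
    comps = spca.components_  # (k, n_features)
    var = scores.var(axis=0, ddof=0)
    order = np.argsort(-var)
    out = []
    for rank, j in enumerate(order):
        load = comps[j]
        eff = bool(np.any(load != 0))
        ac = autocorrelation_score(load, matrix.genomic_order) if eff else 0.0
        out.append(
            CnaPcSignature(
                pc_index=rank,
                loadings=load,
                sample_scores=scores[:, j],
                effective=eff,
                autocorrelation=ac,
                explained_variance=float(var[j]),
            )
        )
    return out


@dataclass
class SparsePcaTuning:
    alpha: float
    k: int
    score: float
    n_effective: int
    reached_threshold: bool
    grid: pd.DataFrame = field(default=None, repr=False)


def tune_sparse_pca(
    matrix: GainLossMatrix,
    alpha_grid: list[float],
    k_grid: list[int],
    closeness_threshold: float = 0.9,
    leading: bool = True,
) -> tuple[SparsePcaTuning, list[CnaPcSignature]]:
    """Grid-tune (alpha, k) by the autocorrelation criterion.

    For each grid point the tuning score is the median lag-1 autocorrelation
    over the leading ceil(1%) of effective components (highest-variance
    components, where arm-level structure concentrates; set
    ``leading=False`` for the trailing subset).  The global score maximiser
    is selected; if no grid point reaches ``closeness_threshold`` the best
    one is returned with a warning.
    """
    if not alpha_grid or not k_grid:
        raise ValueError("empty tuning grid")
    records = []
    best = None
    for alpha in alpha_grid:
        for k in k_grid:
            sigs = fit_sparse_pca(matrix, alpha=alpha, k=k)
            eff = [s for s in sigs if s.effective]
            if eff:
                m = max(1, math.ceil(0.01 * len(eff)))
                subset = eff[:m] if leading else eff[-m:]
                score = float(np.median([s.autocorrelation for s in subset]))
            else:
                score = -np.inf
            records.append(
                {"alpha": alpha, "k": k, "score": score, "n_effective": len(eff)}
            )
            if best is None or score > best[0]:
                best = (score, alpha, k, sigs, len(eff))
    score, alpha, k, sigs, n_eff = best
    reached = score >= closeness_threshold
    if not reached:
        logger.warning(
            "no grid point reached autocorrelation %.2f (best %.3f at alpha=%g, k=%d)",
            closeness_threshold, score, alpha, k,
        )
    tuning = SparsePcaTuning(
        alpha=alpha, k=k, score=score, n_effective=n_eff,
        reached_threshold=reached, grid=pd.DataFrame(records),
    )
    return tuning, sigs


# ---------------------------------------------------------------------------
# associations and gene-wise scores
# ---------------------------------------------------------------------------

def _lm_beta(y: np.ndarray, x: np.ndarray, covariates: pd.DataFrame | None):
    X = pd.DataFrame({"score": x})
    if covariates is not None:
        X = pd.concat([X, covariates.reset_index(drop=True)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(y, X.to_numpy(dtype=float)).fit()
    j = 1  # score column follows the constant
    return float(fit.params[j]), float(fit.bse[j]), float(fit.pvalues[j])


def associate_signatures(
    signature_scores: pd.DataFrame,
    inmdeff_ase: pd.Series,
    inmdeff_etg: pd.Series,
    covariates: pd.DataFrame | None = None,
    fdr_threshold: float = 0.10,
) -> pd.DataFrame:
    """Discovery (ASE) -> validation (ETG) association of signatures with iNMDeff.

    ``signature_scores`` is samples x signatures.  Per signature a linear
    model iNMDeff ~ score (+ covariates) is fit on the ASE estimates; BH-FDR
    over signatures selects discoveries, which are re-tested on the ETG
    estimates (BH-FDR over the discovered subset).  A signature is replicated
    iff both FDRs pass the threshold and the effect signs agree.
    """
    out = []
    samples_ase = signature_scores.index.intersection(inmdeff_ase.index)
    samples_etg = signature_scores.index.intersection(inmdeff_etg.index)
    n_par = 2 + (0 if covariates is None else covariates.shape[1])
    for col in signature_scores.columns:
        rec = {"signature": col}
        for label, samples, resp in (
            ("ase", samples_ase, inmdeff_ase),
            ("etg", samples_etg, inmdeff_etg),
        ):
            if len(samples) <= n_par:
                rec[f"{label}_beta"] = np.nan
                rec[f"{label}_p"] = np.nan
                rec[f"{label}_skipped"] = "fewer samples than parameters"
                continue
            cov = covariates.loc[samples] if covariates is not None else None
            b, se, p = _lm_beta(
                resp.loc[samples].to_numpy(dtype=float),
                signature_scores.loc[samples, col].to_numpy(dtype=float),
                cov,
            )
            rec[f"{label}_beta"], rec[f"{label}_se"], rec[f"{label}_p"] = b, se, p
        out.append(rec)
    df = pd.DataFrame(out).set_index("signature")

    ok_ase = df["ase_p"].notna()
    df["ase_fdr"] = np.nan
    if ok_ase.any():
        df.loc[ok_ase, "ase_fdr"] = benjamini_hochberg(df.loc[ok_ase, "ase_p"])
    discovered = df.index[(df["ase_fdr"] <= fdr_threshold).fillna(False)]
    df["etg_fdr"] = np.nan
    ok_etg = df.index.isin(discovered) & df["etg_p"].notna()
    if ok_etg.any():
        df.loc[ok_etg, "etg_fdr"] = benjamini_hochberg(df.loc[ok_etg, "etg_p"])
    df["replicated"] = (
        (df["ase_fdr"] <= fdr_threshold)
        & (df["etg_fdr"] <= fdr_threshold)
        & (np.sign(df["ase_beta"]) == np.sign(df["etg_beta"]))
    ).fillna(False)
    return df


@dataclass
class FocalityDefinition:
    """Focal = contiguous altered run spanning < ``max_fraction`` of its chromosome."""

    score_threshold: float = 0.3
    max_fraction: float = 0.25


def genewise_focal_inmdeff(
    cna: pd.DataFrame,
    gene_coords: pd.DataFrame,
    inmdeff: pd.Series,
    focality: FocalityDefinition | None = None,
) -> pd.Series:
    """Median iNMDeff of focal-amplification carriers, per gene.

    ``cna`` is genes x samples.  For each sample, contiguous genomically
    ordered runs of genes with score > threshold are called events; an event
    is focal when it spans less than ``max_fraction`` of the genes on its
    chromosome.  Genes with no focal carriers get NaN.
    """
    foc = focality or FocalityDefinition()
    ordered = gene_coords.loc[cna.index].sort_values(["chrom", "start"]).index
    result = pd.Series(np.nan, index=cna.index, dtype=float)
    carriers: dict[str, list[float]] = {g: [] for g in cna.index}
    chroms = gene_coords.loc[ordered, "chrom"].to_numpy()
    mat = cna.loc[ordered]
    for sample in cna.columns:
        if sample not in inmdeff.index:
            continue
        altered = (mat[sample] > foc.score_threshold).to_numpy()
        i = 0
        n = len(altered)
        while i < n:
            if not altered[i]:
                i += 1
                continue
            j = i
            while j < n and altered[j] and chroms[j] == chroms[i]:
                j += 1
            chrom_size = int((chroms == chroms[i]).sum())
            if (j - i) < foc.max_fraction * chrom_size:
                for g in ordered[i:j]:
                    carriers[g].append(float(inmdeff[sample]))
            i = j
    for g, vals in carriers.items():
        if vals:
            result[g] = float(np.median(vals))
    return result


def prioritize_candidates(
    expression: pd.DataFrame,
    inmdeff: pd.Series,
    cna: pd.DataFrame,
    expr_inmdeff_threshold: float = -0.3,
    expr_cna_threshold: float = 0.3,
) -> list[str]:
    """Two-criterion candidate genes: expression anti-correlates with iNMDeff
    and correlates with the gene's CNA dosage.

    ``expression`` and ``cna`` are genes x samples, sample-aligned with
    ``inmdeff``.
    """
    samples = expression.columns.intersection(cna.columns).intersection(inmdeff.index)
    y = inmdeff.loc[samples].to_numpy(dtype=float)
    out = []
    for g in expression.index:
        e = expression.loc[g, samples].to_numpy(dtype=float)
        if e.std() == 0 or y.std() == 0:
            continue
        r_ei = np.corrcoef(e, y)[0, 1]
        if g not in cna.index:
            continue
        c = cna.loc[g, samples].to_numpy(dtype=float)
        if c.std() == 0:
            continue
        r_ec = np.corrcoef(e, c)[0, 1]
        if r_ei < expr_inmdeff_threshold and r_ec > expr_cna_threshold:
            out.append(g)
    return out
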