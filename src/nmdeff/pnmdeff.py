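"""Per-PTC NMD efficiency (pNMDeff) and variability tests.

pNMDeff = -log2(MUT/WT RNA counts): 0 means no degradation of the mutant
allele, 1 means the mutant allele is expressed at half the wild-type level,
and complete degradation approaches +infinity (MUT = 0 with WT > 0).  Loci
with WT = 0 are undefined and excluded by the caller.

Inter- and intra-individual variability of pNMDeff is assessed against a
baseline obtained by permuting pNMDeff values over the whole record table
(a single exchangeable null): the observed statistic (mean Spearman
correlation of sampled PTC pairs, or mean within-group variance) is compared
with the permutation distribution, and an excess variance (randomized minus
observed) quantifies the structure removed by the permutation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr


def compute_pnmdeff(wt_count: float, mut_count: float) -> float:
    """-log2(mut/wt); +inf when the mutant allele is fully degraded.

    Raises ``ValueError`` when ``wt_count`` is 0 (undefined; the locus must
    be excluded upstream).
    """
    if wt_count <= 0:
        raise ValueError("pNMDeff undefined for wt_count = 0")
    if mut_count < 0:
        raise ValueError("negative count")
    if mut_count == 0:
        return math.inf
    return -math.log2(mut_count / wt_count)


@dataclass
class PnmdeffFilterConfig:
    max_vaf: float = 0.20
    min_median_tpm: float = 5.0
    max_expression_cv: float = 0.5
    loeuf_cutoff: float = 0.10


def apply_pnmdeff_filters(
    records: pd.DataFrame,
    config: PnmdeffFilterConfig | None = None,
    positive_selection_genes: set[str] | None = None,
) -> pd.DataFrame:
    """Apply the pNMDeff exclusion cascade to a per-PTC record table.

    Expected columns (absent columns skip the corresponding filter):
    ``has_downstream_ptc``, ``cooccurring_truncating`` (bool),
    ``single_exon_no_3utr_ejc`` (bool), ``gene_loeuf_percentile``,
    ``gene_id``, ``homozygous`` (bool), ``dna_vaf``, ``median_tpm``,
    ``expression_cv``.
    """
    cfg = config or PnmdeffFilterConfig()
    r = records
    if "has_downstream_ptc" in r.columns:
        r = r[r["has_downstream_ptc"].astype(bool)]
    if "cooccurring_truncating" in r.columns:
        r = r[~r["cooccurring_truncating"].astype(bool)]
    if "single_exon_no_3utr_ejc" in r.columns:
        r = r[~r["single_exon_no_3utr_ejc"].astype(bool)]
    if "gene_loeuf_percentile" in r.columns:
        r = r[r["gene_loeuf_percentile"] > cfg.loeuf_cutoff]
    if positive_selection_genes and "gene_id" in r.columns:
        r = r[~r["gene_id"].isin(positive_selection_genes)]
    if "homozygous" in r.columns:
        r = r[~r["homozygous"].astype(bool)]
    if "dna_vaf" in r.columns:
        r = r[r["dna_vaf"] <= cfg.max_vaf]
    if "median_tpm" in r.columns:
        r = r[r["median_tpm"] >= cfg.min_median_tpm]
    if "expression_cv" in r.columns:
        r = r[r["expression_cv"] <= cfg.max_expression_cv]
    return r.copy()


@dataclass
class VariabilityResult:
    mode: str  # inter | intra
    metric: str  # spearman | variance
    observed: float
    randomized_mean: float
    randomized_sd: float
    randomized_quantiles: dict = field(default_factory=dict)
    n_iterations: int = 0
    excess_variance: float | None = None
    p_value: float | None = None
    testable: bool = True
    reason: str = ""


def _group_col(mode: str) -> tuple[str, str]:
    # intra: PTCs within an individual; inter: individuals sharing a PTC
    if mode == "intra":
        return "individual_id", "variant_id"
    if mode == "inter":
        return "variant_id", "individual_id"
    raise ValueError(f"unknown mode {mode!r}")


def _pair_spearman(values: np.ndarray, groups: np.ndarray, rng) -> float:
    """Spearman correlation of one sampled pair per group (>=2 members)."""
    a, b = [], []
    order = rng.permutation(len(values))
    first: dict = {}
    second: dict = {}
    for i in order:
        g = groups[i]
        if g not in first:
            first[g] = values[i]
        elif g not in second:
            second[g] = values[i]
    for g in second:
        a.append(first[g])
        b.append(second[g])
    if len(a) < 3:
        return np.nan
    rho = spearmanr(a, b).statistic
    return float(rho)


def _variance_layout(groups: np.ndarray, min_size: int):
    """Column order, reduceat boundaries and group sizes for fast group variances."""
    codes, _ = pd.factorize(groups)
    order = np.argsort(codes, kind="stable")
    sizes = np.bincount(codes)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    keep = sizes >= min_size
    return order, starts, sizes, keep


def _mean_group_variance(matrix: np.ndarray, starts, sizes, keep) -> np.ndarray:
    """Mean within-group sample variance per row of a (n_iter, n) value matrix."""
    s1 = np.add.reduceat(matrix, starts, axis=1)
    s2 = np.add.reduceat(matrix**2, starts, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (s2 - s1**2 / sizes) / np.maximum(sizes - 1, 1)
    return var[:, keep].mean(axis=1)


def variability_test(
    records: pd.DataFrame,
    mode: str,
    metric: str,
    n_iter: int = 1000,
    seed: int = 0,
    drop_infinite: bool = True,
) -> VariabilityResult:
    """Inter/intra-individual pNMDeff variability with a permutation baseline.

    ``records`` needs columns ``individual_id``, ``variant_id``, ``pnmdeff``.
    For ``metric='spearman'`` each iteration samples two PTCs per individual
    (intra) or two individuals per shared PTC (inter) and records the Spearman
    correlation of the pair values across groups; the statistic is the mean
    over iterations.  For ``metric='variance'`` the statistic is the mean
    within-group variance over groups with >= 3 members.  The baseline
    repeats the computation with pNMDeff permuted over all records, and
    ``excess_variance`` (variance metric) is randomized minus observed.  The
    permutation-tail p-value uses the (count + 1) / n_iter formula: lower tail
    for variance (structure reduces within-group variance), upper tail for
    correlation.
    """
    if metric not in ("spearman", "variance"):
        raise ValueError(f"unknown metric {metric!r}")
    group_col, _ = _group_col(mode)
    r = records
    vals = r["pnmdeff"].to_numpy(dtype=float)
    if drop_infinite:
        ok = np.isfinite(vals)
        r, vals = r[ok], vals[ok]
    groups = r[group_col].to_numpy()

    min_size = 3 if metric == "variance" else 2
    sizes = pd.Series(groups).value_counts()
    if (sizes >= min_size).sum() < 2:
        return VariabilityResult(
            mode, metric, np.nan, np.nan, np.nan, {}, n_iter,
            testable=False, reason="insufficient sharing structure",
        )

    rng = np.random.default_rng(seed)
    if metric == "variance":
        order, starts, sizes, keep = _variance_layout(groups, min_size)
        observed = float(
            _mean_group_variance(vals[order][None, :], starts, sizes, keep)[0]
        )
        n = len(vals)
        # a random permutation sliced into the fixed group layout is exactly a
        # random reassignment of values to (individual, PTC) slots
        perms = vals[np.argsort(rng.random((n_iter, n)), axis=1)]
        null = _mean_group_variance(perms, starts, sizes, keep)
        p = (np.sum(null <= observed) + 1) / n_iter
        excess = float(np.mean(null) - observed)
    else:
        obs_draws = np.array(
            [_pair_spearman(vals, groups, rng) for _ in range(n_iter)]
        )
        observed = float(np.nanmean(obs_draws))
        null = np.empty(n_iter)
        for i in range(n_iter):
            perm = rng.permutation(vals)
            null[i] = _pair_spearman(perm, groups, rng)
        p = (np.sum(null >= observed) + 1) / n_iter
        excess = None

    qs = {q: float(np.nanquantile(null, q)) for q in (0.025, 0.5, 0.975)}
    return VariabilityResult(
        mode=mode,
        metric=metric,
        observed=observed,
        randomized_mean=float(np.nanmean(null)),
        randomized_sd=float(np.nanstd(null)),
        randomized_quantiles=qs,
        n_iterations=n_iter,
        excess_variance=excess,
        p_value=float(min(p, 1.0)),
    )
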