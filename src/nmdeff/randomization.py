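"""Tissue-level randomization statistics for iNMDeff.

Two permutation tests summarize how iNMDeff varies across tissues:

* ITNVD (inter-tissue iNMDeff variability deviation): the SD over tissues of
  the tissue median iNMDeff, compared with its null median under random
  reassignment of samples to tissues (sizes preserved);
* TND (tissue iNMDeff deviation): one tissue's observed median against the
  median of its randomized medians; positive values mean the tissue is more
  NMD-efficient than chance.

p-values follow (count + 1) / n_iter with strict inequality (ties do not
count as exceedances), so the attainable floor is 1/n_iter — 5e-4 at the
default 2000 iterations.  Also provided: the empirical-FDR ratio used to
calibrate replicated association counts against randomized runs, and an OLS
variance decomposition (per-covariate drop in R^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_N_ITER = 2000


@dataclass
class RandomizationResult:
    statistic_name: str  # ITNVD | TND
    observed: float
    deviation: float  # observed - null median
    p_value: float
    n_iter: int
    seed: int
    tissue: str | None = None
    null_median: float = np.nan
    null_mean: float = np.nan
    null_sd: float = np.nan
    null_distribution: np.ndarray | None = field(default=None, repr=False)


def _permuted_matrix(values: np.ndarray, n_iter: int, rng) -> np.ndarray:
    """(n_iter, n) matrix of independent permutations of ``values``."""
    n = values.shape[0]
    keys = rng.random((n_iter, n))
    idx = np.argsort(keys, axis=1)
    return values[idx]


def _tissue_layout(tissues: np.ndarray):
    names, inverse = np.unique(tissues, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    sizes = np.bincount(inverse)
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    return names, order, bounds


def itnvd_test(
    inmdeff: np.ndarray | pd.Series,
    tissues: np.ndarray | pd.Series,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> RandomizationResult:
    """Inter-tissue variability deviation test.

    Observed statistic: SD over tissues of the tissue-median iNMDeff.  Null:
    sample-to-tissue assignments permuted (tissue sizes preserved) ``n_iter``
    times.  ITNVD = observed - median(null); p = (#{null > observed} + 1) /
    n_iter.
    """
    values = np.asarray(inmdeff, dtype=float)
    tissues = np.asarray(tissues)
    names, order, bounds = _tissue_layout(tissues)
    if len(names) < 2:
        raise ValueError("ITNVD requires at least 2 tissues")

    def stat(vec_matrix: np.ndarray) -> np.ndarray:
        # vec_matrix rows are sample vectors already ordered by tissue blocks
        medians = np.stack(
            [
                np.median(vec_matrix[:, bounds[i] : bounds[i + 1]], axis=1)
                for i in range(len(names))
            ],
            axis=1,
        )
        return medians.std(axis=1, ddof=0)

    ordered = values[order]
    observed = float(stat(ordered[None, :])[0])
    rng = np.random.default_rng(seed)
    # permuting values, then slicing fixed-size blocks, is exactly a random
    # reassignment of samples to tissues with tissue sizes preserved
    null = np.asarray(stat(_permuted_matrix(values, n_iter, rng)))
    null_median = float(np.median(null))
    p = (int(np.sum(null > observed)) + 1) / n_iter
    return RandomizationResult(
        statistic_name="ITNVD",
        observed=observed,
        deviation=observed - null_median,
        p_value=p,
        n_iter=n_iter,
        seed=seed,
        null_median=null_median,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        null_distribution=null,
    )


def tnd_test(
    inmdeff: np.ndarray | pd.Series,
    tissues: np.ndarray | pd.Series,
    tissue: str,
    n_iter: int = DEFAULT_N_ITER,
    seed: int = 0,
) -> RandomizationResult:
    """Tissue deviation test for one tissue.

    Per iteration the randomized tissue median is the median of a size-
    preserving random subset of all samples.  TND = observed median - median
    of randomized medians.  The p-value is one-sided in the direction of the
    deviation: upper tail (#{null > observed}) for TND >= 0, lower tail for
    TND < 0, each with the (count + 1) / n_iter formula.
    """
    values = np.asarray(inmdeff, dtype=float)
    tissues = np.asarray(tissues)
    mask = tissues == tissue
    n_t = int(mask.sum())
    if n_t == 0:
        raise ValueError(f"tissue {tissue!r} absent")
    observed = float(np.median(values[mask]))
    rng = np.random.default_rng(seed)
    perm = _permuted_matrix(values, n_iter, rng)
    null = np.median(perm[:, :n_t], axis=1)
    null_median = float(np.median(null))
    deviation = observed - null_median
    if deviation >= 0:
        p = (int(np.sum(null > observed)) + 1) / n_iter
    else:
        p = (int(np.sum(null < observed)) + 1) / n_iter
    return RandomizationResult(
        statistic_name="TND",
        tissue=tissue,
        observed=observed,
        deviation=deviation,
        p_value=p,
        n_iter=n_iter,
        seed=seed,
        null_median=null_median,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        null_distribution=null,
    )


def empirical_fdr(
    observed_hits: int,
    observed_tests: int,
    randomized_hits: int,
    randomized_tests: int,
) -> float:
    """Empirical FDR: randomized hit rate divided by observed hit rate.

    E.g. 3 randomized vs 10 observed replicated hits at equal test totals
    gives 0.30.  Raises ``ValueError`` when ``observed_hits`` is 0 (the
    calibration is undefined without observed hits).
    """
    if observed_tests <= 0 or randomized_tests <= 0:
        raise ValueError("test totals must be positive")
    if observed_hits <= 0:
        raise ValueError("empirical FDR undefined with zero observed hits")
    return (randomized_hits / randomized_tests) / (observed_hits / observed_tests)


def empirical_fdr_details(
    observed_hits: int,
    observed_tests: int,
    randomized_hits: int,
    randomized_tests: int,
) -> dict:
    """Empirical FDR plus the raw inverse ratio, for auditing."""
    fdr = empirical_fdr(observed_hits, observed_tests, randomized_hits, randomized_tests)
    return {
        "empirical_fdr": fdr,
        "observed_rate": observed_hits / observed_tests,
        "randomized_rate": randomized_hits / randomized_tests,
        "inverse_ratio": np.inf if fdr == 0 else 1.0 / fdr,
    }


def variance_decomposition(
    data: pd.DataFrame,
    response: str,
    covariates: list[str],
) -> pd.DataFrame:
    """Per-covariate drop in OLS R^2 (leave-one-covariate-out).

    Categorical covariates (object/category dtype) are dummy-encoded.  Raises
    ``ValueError`` naming the offending pair when two covariates are
    collinear after encoding.
    """
    y = data[response].to_numpy(dtype=float)

    def encode(cols: list[str]) -> pd.DataFrame:
        X = pd.DataFrame(index=data.index)
        for c in cols:
            col = data[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                d = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
                X = pd.concat([X, d], axis=1)
            else:
                X[c] = col.to_numpy(dtype=float)
        return sm.add_constant(X, has_constant="add")

    X_full = encode(covariates)
    rank = np.linalg.matrix_rank(X_full.to_numpy())
    if rank < X_full.shape[1]:
        for i, a in enumerate(covariates):
            for b in covariates[i + 1 :]:
                Xa = encode([a, b])
                if np.linalg.matrix_rank(Xa.to_numpy()) < Xa.shape[1]:
                    raise ValueError(f"collinear covariates: {a!r} and {b!r}")
        raise ValueError("design matrix rank deficient")

    full_r2 = sm.OLS(y, X_full).fit().rsquared
    rows = [{"covariate": "(full model)", "r_squared": full_r2, "delta_r2": np.nan}]
    for c in covariates:
        reduced = [x for x in covariates if x != c]
        r2 = sm.OLS(y, encode(reduced)).fit().rsquared if reduced else 0.0
        rows.append({"covariate": c, "r_squared": r2, "delta_r2": full_r2 - r2})
    return pd.DataFrame(rows)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted q-values (thin wrapper over statsmodels multipletests)."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
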