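"""Statistical layer for count matrices of small-RNA features.

Covers the between-sample workflow used for the cell-versus-exosome
comparison:

* abundance filtering (>=15 reads over cell samples OR >=5 over exosome
  samples),
* trimmed-mean-of-M-values (TMM) normalization factors,
* zero imputation at half the per-sample minimum nonzero normalized value
  (an estimate of the lower limit of detection), followed by a log
  transform,
* Pearson correlation between samples; hierarchical clustering with
  standardized-euclidean gene distances and correlation-based sample
  distances,
* a two-group negative-binomial exact test with a common (shared)
  dispersion estimated by conditional maximum likelihood on
  equalized library sizes, and Benjamini-Hochberg FDR.

Count input is a pandas DataFrame (features x samples); group membership
is a mapping sample -> "cell" | "exosome" (or any two labels for the
exact test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import binom, nbinom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Filtering


def filter_features(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    cell_min: int = 15,
    exo_min: int = 5,
) -> pd.DataFrame:
    """Keep features with >=cell_min reads over cell samples OR >=exo_min over exosomes."""
    missing = [s for s in counts.columns if s not in groups]
    if missing:
        raise ValueError(f"samples without group labels: {missing}")
    cell_cols = [s for s in counts.columns if groups[s] == "cell"]
    exo_cols = [s for s in counts.columns if groups[s] == "exosome"]
    keep = (counts[cell_cols].sum(axis=1) >= cell_min) | (
        counts[exo_cols].sum(axis=1) >= exo_min
    )
    return counts.loc[keep]


# ---------------------------------------------------------------------------
# TMM normalization


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """TMM factor of one sample against the reference column."""
    mask = (obs > 0) & (ref > 0)
    if not mask.any():
        logger.warning("sample shares no expressed features with the reference; factor 1")
        return 1.0
    o, r = obs[mask], ref[mask]
    m = np.log2((o / lib_obs) / (r / lib_ref))
    a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # delta-method (binomial) weights on log-ratios
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)

    n = len(m)
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    # ranks, average for ties (matches the reference rank-trim behaviour)
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    The reference sample is the column whose 75th percentile of
    library-scaled counts is closest to the mean of those percentiles.
    Each factor is a doubly trimmed (30% on M, 5% on A), precision-weighted
    mean of the log2 count ratios against the reference.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("zero-sum library")
    scaled75 = (counts / lib).quantile(0.75, axis=0)
    ref_name = (scaled75 - scaled75.mean()).abs().idxmin()
    ref = counts[ref_name].to_numpy(dtype=float)

    factors = {}
    for sample in counts.columns:
        if sample == ref_name:
            factors[sample] = 1.0
            continue
        factors[sample] = _tmm_pair(
            counts[sample].to_numpy(dtype=float), ref, lib[sample], lib[ref_name],
            logratio_trim, abs_trim,
        )
    f = pd.Series(factors)[counts.columns]
    return f / np.exp(np.log(f).mean())


# ---------------------------------------------------------------------------
# Normalization + imputation


@dataclass
class NormalizedMatrix:
    """Log-scale normalized values with per-sample imputation floors."""

    log_values: pd.DataFrame
    floors: pd.Series
    imputed: pd.DataFrame  # boolean mask of imputed cells
    norm_factors: pd.Series


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts scaled by effective library size, per million."""
    lib = counts.sum(axis=0).astype(float)
    if factors is None:
        factors = pd.Series(1.0, index=counts.columns)
    eff = lib * factors
    return counts / eff * 1e6


def log_impute(normalized: pd.DataFrame, factors: pd.Series | None = None) -> NormalizedMatrix:
    """Log-transform, imputing zeros at half each sample's minimum nonzero value.

    The imputed floor estimates the sample's lower limit of detection.
    Natural log; a sample with no nonzero value is an error.
    """
    if (normalized < 0).any().any():
        raise ValueError("normalized values must be non-negative")
    log_values = normalized.copy().astype(float)
    floors = {}
    imputed = normalized == 0
    for sample in normalized.columns:
        col = normalized[sample]
        nonzero = col[col > 0]
        if nonzero.empty:
            raise ValueError(f"sample {sample} is all zero; cannot impute")
        floor = nonzero.min() / 2.0
        floors[sample] = floor
        log_values[sample] = np.log(col.where(col > 0, floor))
    if factors is None:
        factors = pd.Series(1.0, index=normalized.columns)
    return NormalizedMatrix(log_values, pd.Series(floors), imputed, factors)


# ---------------------------------------------------------------------------
# Correlation and clustering


def correlation_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson r between sample columns; zero-variance samples give NaN."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least two features")
    variances = matrix.var(axis=0)
    for sample in matrix.columns[variances == 0]:
        logger.warning("sample %s has zero variance; correlations undefined", sample)
    return matrix.corr(method="pearson")


def _linkage_to_newick(linkage: np.ndarray, labels: Sequence[str]) -> str:
    n = len(labels)

    def node(i: int) -> str:
        if i < n:
            return labels[i]
        left, right, height, _ = linkage[i - n]
        return f"({node(int(left))},{node(int(right))}):{height:.6g}"

    return node(2 * n - 2) + ";" if n > 1 else labels[0] + ";"


@dataclass
class ClusterResult:
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    gene_labels: list[str]
    sample_labels: list[str]

    @property
    def gene_newick(self) -> str:
        return _linkage_to_newick(self.gene_linkage, self.gene_labels)

    @property
    def sample_newick(self) -> str:
        return _linkage_to_newick(self.sample_linkage, self.sample_labels)


def cluster(matrix: pd.DataFrame) -> ClusterResult:
    """Average-linkage clustering of genes and samples.

    Genes: euclidean distance on per-gene standardized (z-scored) values.
    Samples: distance 1 - Pearson r.  Rows/columns are sorted by label
    first so equal-distance merge order is deterministic.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least a 2x2 matrix to cluster")
    matrix = matrix.sort_index(axis=0).sort_index(axis=1)
    values = matrix.to_numpy(dtype=float)
    sd = values.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    gene_link = average(pdist(z, metric="euclidean"))

    r = np.corrcoef(values.T)
    sample_dist = squareform(1.0 - r, checks=False)
    sample_link = average(sample_dist)
    return ClusterResult(
        gene_link, sample_link, list(matrix.index.astype(str)), list(matrix.columns.astype(str))
    )


# ---------------------------------------------------------------------------
# Common dispersion (conditional maximum likelihood on equal library sizes)


def _equalize(counts: pd.DataFrame, lib_sizes: pd.Series) -> pd.DataFrame:
    """Pseudo-counts scaled to the geometric-mean library size."""
    common = np.exp(np.log(lib_sizes.astype(float)).mean())
    return counts * (common / lib_sizes)


def _cond_loglik(pseudo: np.ndarray, group_idx: list[np.ndarray], phi: float) -> float:
    """Summed conditional log-likelihood of phi over features and groups.

    For a group of n equal-sized libraries with feature counts y_i, the
    likelihood conditional on z = sum(y) depends on the dispersion only
    through  sum_i lgamma(y_i + r) - n lgamma(r) + lgamma(n r) - lgamma(z + n r),
    with r = 1/phi.
    """
    r = 1.0 / phi
    total = 0.0
    for idx in group_idx:
        y = pseudo[:, idx]
        n_feat, n = y.shape
        if n < 2:
            continue
        z = y.sum(axis=1)
        total += float(
            np.sum(gammaln(y + r))
            - n_feat * n * gammaln(r)
            + np.sum(gammaln(n * r) - gammaln(z + n * r))
        )
    return total


def estimate_common_dispersion(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    factors: pd.Series | None = None,
    phi_max: float = 4.0,
) -> float:
    """Shared NB dispersion maximizing the conditional log-likelihood.

    Library sizes (times optional normalization factors) are equalized to
    their geometric mean first.  The optimum is located on a log-spaced
    bracket grid and refined by bounded scalar minimization (tolerance
    1e-6).  With no within-group replication anywhere the dispersion is
    unidentifiable and 0 is returned with a warning.
    """
    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors
    samples = list(counts.columns)
    labels = sorted({groups[s] for s in samples})
    group_idx = [
        np.array([i for i, s in enumerate(samples) if groups[s] == g]) for g in labels
    ]
    if all(len(idx) < 2 for idx in group_idx):
        logger.warning("no replicated group: common dispersion set to 0")
        return 0.0
    pseudo = _equalize(counts, lib).to_numpy(dtype=float)
    pseudo = pseudo[pseudo.sum(axis=1) > 0]
    if pseudo.size == 0:
        logger.warning("no expressed features: common dispersion set to 0")
        return 0.0

    grid = np.geomspace(1e-6, phi_max, 41)
    ll = [_cond_loglik(pseudo, group_idx, phi) for phi in grid]
    best = int(np.argmax(ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda p: -_cond_loglik(pseudo, group_idx, p),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-6},
    )
    return float(res.x)


# ---------------------------------------------------------------------------
# NB exact test


def _exact_nb_pvalue(a: float, b: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact NB p-value for group sums (a, b), doubletail convention.

    Conditional on t = a + b, the first group's sum is compared with the
    distribution p(x) * q(t - x) where p, q are the group sums' NB (or
    binomial when phi = 0) distributions under the null of equal means;
    the p-value sums all outcomes at most as probable as the observed one.
    """
    a, b = round(a), round(b)
    t = a + b
    if t == 0:
        return 1.0
    x = np.arange(t + 1)
    if phi <= 0:
        probs = binom.pmf(x, t, n1 / (n1 + n2))
    else:
        mu1 = t * n1 / (n1 + n2)
        mu2 = t * n2 / (n1 + n2)
        r1, r2 = n1 / phi, n2 / phi
        probs = nbinom.pmf(x, r1, r1 / (r1 + mu1)) * nbinom.pmf(t - x, r2, r2 / (r2 + mu2))
    total = probs.sum()
    if total <= 0:
        return 1.0
    observed = probs[a]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-10)].sum() / total))


def exact_test_nb(
    counts: pd.DataFrame,
    groups: Mapping[str, str],
    phi: float,
    factors: pd.Series | None = None,
    prior_count: float = 0.125,
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Per-feature exact NB test between two groups of samples.

    Library sizes (optionally TMM-adjusted via ``factors``; pass None to
    normalize by total library sizes, as done for high-level RNA classes)
    are equalized to their geometric mean; group sums of the resulting
    pseudo-counts are compared conditionally on their total.

    Returns a DataFrame with columns logFC (log2, second group over the
    reference group, with a small prior count), p_value, fdr and
    direction.  Group order is alphabetical unless ``reference_group``
    names the baseline.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    samples = list(counts.columns)
    labels = sorted({groups[s] for s in samples})
    if len(labels) != 2:
        raise ValueError("exact test needs exactly two groups")
    if reference_group is not None:
        if reference_group not in labels:
            raise ValueError(f"unknown reference group {reference_group}")
        labels = [reference_group, next(g for g in labels if g != reference_group)]
    g1 = [s for s in samples if groups[s] == labels[0]]
    g2 = [s for s in samples if groups[s] == labels[1]]
    n1, n2 = len(g1), len(g2)

    lib = counts.sum(axis=0).astype(float)
    if factors is not None:
        lib = lib * factors
    pseudo = _equalize(counts, lib)
    s1 = pseudo[g1].sum(axis=1)
    s2 = pseudo[g2].sum(axis=1)

    logfc = np.log2((s2 / n2 + prior_count) / (s1 / n1 + prior_count))
    pvals = np.array(
        [_exact_nb_pvalue(a, b, n1, n2, phi) for a, b in zip(s1.to_numpy(), s2.to_numpy())]
    )
    fdr = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "p_value": pvals,
            "fdr": fdr,
            "direction": np.where(logfc > 0, f"up_in_{labels[1]}", f"up_in_{labels[0]}"),
        },
        index=counts.index,
    )


def bh_fdr(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
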