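"""Differential-expression benchmarks: Welch t-test and an NB exact test.

Both selectors declare a gene differential when its raw two-sided
p-value falls below ``alpha`` (default 0.05, no multiple-testing
correction — the selection rule is deliberately liberal because the
genes feed a downstream classifier, not an inference table).

The count-based test is a classic negative-binomial conditional exact
test with a single common dispersion: library sizes are equalized by
quantile-mapping each sample's counts to the geometric-mean effective
library size, group totals are formed, and the two-sided p-value sums
the conditional probabilities of all splits of the observed total that
are no more probable than the observed one. Conditionally on the
total, the split follows a negative hypergeometric law that depends
only on the group sizes and the dispersion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp

from .preprocess import CountMatrix

DE_COLUMNS = ["gene_id", "statistic", "p_value", "direction", "is_deg"]


def _split_samples(labels: pd.Series, positive_class: str) -> tuple[list, list]:
    classes = labels.unique()
    if len(classes) != 2:
        raise ValueError(f"expected exactly two classes, got {list(classes)}")
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not in labels")
    pos = labels.index[labels == positive_class].tolist()
    neg = labels.index[labels != positive_class].tolist()
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each class needs at least 2 samples")
    return pos, neg


def ttest_de(
    log_expr: pd.DataFrame,
    labels: pd.Series,
    alpha: float = 0.05,
    positive_class: str = "HFE",
) -> pd.DataFrame:
    """Per-gene Welch (unequal-variance) two-sample t-test on log2-CPM.

    Returns a frame with ``gene_id, statistic, p_value, direction,
    is_deg``. Degenerate genes with zero variance in both groups get
    p = 1 when the group means agree and p = 0 otherwise (the limiting
    convention of the t statistic).
    """
    pos, neg = _split_samples(labels, positive_class)
    a = log_expr[pos].to_numpy(dtype=float)
    b = log_expr[neg].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    t = np.where(degenerate, np.where(diff == 0, 0.0, np.sign(diff) * np.inf), t)
    p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
    return pd.DataFrame(
        {
            "gene_id": log_expr.index,
            "statistic": t,
            "p_value": p,
            "direction": np.sign(diff).astype(int),
            "is_deg": p < alpha,
        }
    ).reset_index(drop=True)


def estimate_common_dispersion(
    counts: CountMatrix,
    factors: pd.Series,
    labels: pd.Series,
    min_dispersion: float = 1e-6,
) -> float:
    """Common NB dispersion by the method of moments.

    Counts are scaled to the geometric-mean effective library size;
    per gene, the within-class sample variance is matched to
    ``mu + phi * mu**2`` and the common value is the 10%-trimmed mean
    of the per-gene solutions over genes with scaled mean >= 5 (the
    trim keeps a minority of atypically dispersed genes from dragging
    the common value). Clamped below at ``min_dispersion``.
    """
    eff = counts.library_sizes.astype(float) * factors.reindex(counts.sample_ids)
    common = float(np.exp(np.mean(np.log(eff))))
    z = counts.values.to_numpy(dtype=float) * (common / eff.to_numpy())[None, :]
    groups = [labels.index[labels == c].tolist() for c in labels.unique()]
    cols = {s: i for i, s in enumerate(counts.sample_ids)}
    within_var = np.zeros(z.shape[0])
    for g in groups:
        idx = [cols[s] for s in g]
        within_var += z[:, idx].var(axis=1, ddof=1) * (len(idx) - 1)
    dof = sum(len(g) - 1 for g in groups)
    within_var /= dof
    mu = z.mean(axis=1)
    ok = mu >= 5.0
    if not ok.any():
        ok = mu > 0
    if not ok.any():
        return min_dispersion
    per_gene = (within_var[ok] - mu[ok]) / mu[ok] ** 2
    return max(float(stats.trim_mean(per_gene, 0.1)), min_dispersion)


def _quantile_adjust(
    z: np.ndarray, eff: np.ndarray, common: float, phi: float
) -> np.ndarray:
    """Map counts to pseudo-counts at a common library size.

    Each observed count is carried through the mid-CDF of its
    sample-specific NB distribution and back through the quantile
    function at the common library size, preserving rank information
    while removing depth differences.
    """
    r = 1.0 / phi
    p_g = z.sum(axis=1) / eff.sum()
    pseudo = np.zeros_like(z, dtype=float)
    for j in range(z.shape[1]):
        mu_j = np.maximum(p_g * eff[j], 1e-12)
        mu_c = np.maximum(p_g * common, 1e-12)
        pj = r / (r + mu_j)
        pc = r / (r + mu_c)
        c = z[:, j]
        mid = 0.5 * (stats.nbinom.cdf(c - 1, r, pj) + stats.nbinom.cdf(c, r, pj))
        mid = np.clip(mid, 1e-15, 1.0 - 1e-15)
        pseudo[:, j] = stats.nbinom.ppf(mid, r, pc)
    return pseudo


def nb_exact_pvalue(total_a: int, total_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional exact p-value for a split of group totals.

    Group totals of ``n`` iid NB(mu, phi) counts are NB with shape
    ``n / phi``; conditionally on the grand total the split probability
    is free of ``mu``. The p-value sums conditional probabilities of
    every split at most as probable as the observed one.
    """
    t = int(total_a + total_b)
    if t == 0:
        return 1.0
    r_a, r_b = n_a / phi, n_b / phi
    a = np.arange(t + 1)
    # log Gamma(a + r) - log Gamma(r) as a cumulative sum of log(r + i):
    # stable even for tiny dispersions where r dwarfs the counts
    i = np.arange(t, dtype=float)
    ca = np.concatenate([[0.0], np.cumsum(np.log(r_a + i))])
    cb = np.concatenate([[0.0], np.cumsum(np.log(r_b + i))])
    logw = ca[a] + cb[t - a] - gammaln(a + 1.0) - gammaln(t - a + 1.0)
    logw -= logsumexp(logw)
    obs = logw[int(total_a)]
    keep = logw <= obs + 1e-9
    return float(min(np.exp(logsumexp(logw[keep])), 1.0))


def nb_exact_de(
    counts: CountMatrix,
    factors: pd.Series,
    labels: pd.Series,
    alpha: float = 0.05,
    positive_class: str = "HFE",
    dispersion: float | None = None,
) -> pd.DataFrame:
    """NB conditional exact test per gene on library-size-equalized counts.

    ``dispersion`` overrides the method-of-moments common estimate.
    All-zero genes get p = 1. The p-value is invariant to swapping the
    two group labels.
    """
    pos, neg = _split_samples(labels, positive_class)
    labels = labels.reindex(counts.sample_ids)
    if labels.isna().any():
        raise ValueError("labels must cover every sample")
    if dispersion is None:
        dispersion = estimate_common_dispersion(counts, factors, labels)
    eff = (
        counts.library_sizes.astype(float) * factors.reindex(counts.sample_ids)
    ).to_numpy()
    common = float(np.exp(np.mean(np.log(eff))))
    z = counts.values.to_numpy(dtype=float)
    pseudo = _quantile_adjust(z, eff, common, dispersion)

    cols = {s: i for i, s in enumerate(counts.sample_ids)}
    ia = [cols[s] for s in pos]
    ib = [cols[s] for s in neg]
    tot_a = np.rint(pseudo[:, ia].sum(axis=1)).astype(np.int64)
    tot_b = np.rint(pseudo[:, ib].sum(axis=1)).astype(np.int64)

    pvals = np.array(
        [
            nb_exact_pvalue(tot_a[g], tot_b[g], len(ia), len(ib), dispersion)
            for g in range(z.shape[0])
        ]
    )
    # statistic: normalized per-sample mean difference of pseudo-counts
    diff = tot_a / len(ia) - tot_b / len(ib)
    return pd.DataFrame(
        {
            "gene_id": counts.gene_ids,
            "statistic": diff,
            "p_value": pvals,
            "direction": np.sign(diff).astype(int),
            "is_deg": pvals < alpha,
        }
    ).reset_index(drop=True)
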