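"""Count normalization: TMM factors, CPM, and the expression filter.

The between-sample normalization is TMM (trimmed mean of M-values): a
per-sample scaling factor computed from doubly trimmed log expression
ratios against a reference sample, precision-weighted, and rescaled so
the factors have geometric mean one. Downstream stages consume
``log2(CPM + 1)`` where CPM uses the TMM-adjusted effective library
size.

Genes are kept when they reach at least 1 CPM in at least half of the
samples (``ceil(n/2)`` for odd ``n``). Factors are computed on the
unfiltered matrix, the common convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class CountMatrix:
    """Gene x sample non-negative integer counts for one tissue."""

    values: pd.DataFrame
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.values.sum(axis=0) <= 0).any():
            bad = self.values.columns[self.values.sum(axis=0) <= 0].tolist()
            raise ValueError(f"samples with zero total counts: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def library_sizes(self) -> pd.Series:
        return self.values.sum(axis=0)

    @classmethod
    def read_tsv(cls, path: str | Path, tissue: str = "") -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df, tissue=tissue or Path(path).stem)


@dataclass
class NormalizedMatrix:
    """TMM-adjusted CPM and log expression, plus the filter outcome.

    ``cpm`` and ``log_expr`` cover all genes; ``retained_genes`` lists
    those passing the expression filter, in original order.
    """

    cpm: pd.DataFrame
    log_expr: pd.DataFrame
    tmm_factors: pd.Series
    retained_genes: list[str]
    tissue: str = ""

    @property
    def filtered_log_expr(self) -> pd.DataFrame:
        return self.log_expr.loc[self.retained_genes]

    @property
    def filtered_cpm(self) -> pd.DataFrame:
        return self.cpm.loc[self.retained_genes]


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Per-sample TMM scaling factors (geometric mean one).

    The reference is the sample whose upper-quartile count fraction is
    closest to the mean across samples, unless ``ref_sample`` names one.
    For each sample, M-values (log2 expression ratio vs the reference)
    and A-values (average log2 abundance) are computed over genes
    nonzero in both; the upper and lower ``trim_m`` of M and ``trim_a``
    of A are discarded and the factor is 2 to the precision-weighted
    mean of the surviving M-values, weights being inverse asymptotic
    binomial variances.
    """
    y = counts.values.to_numpy(dtype=float)
    lib = y.sum(axis=0)
    samples = counts.sample_ids
    if len(samples) < 2:
        raise ValueError("TMM needs at least 2 samples")

    if ref_sample is None:
        uq = np.array([np.quantile(y[:, j], 0.75) / lib[j] for j in range(len(samples))])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref = samples.index(ref_sample)

    factors = np.ones(len(samples))
    yr, nr = y[:, ref], lib[ref]
    for j in range(len(samples)):
        if j == ref:
            continue
        ys, ns = y[:, j], lib[j]
        ok = (ys > 0) & (yr > 0)
        if not ok.any():
            raise ValueError(
                f"sample {samples[j]!r} shares no expressed genes with the "
                f"reference {samples[ref]!r}"
            )
        ps, pr = ys[ok] / ns, yr[ok] / nr
        m = np.log2(ps / pr)
        a = 0.5 * np.log2(ps * pr)
        # delta-method variance of M for binomial sampling
        w = (ns - ys[ok]) / (ns * ys[ok]) + (nr - yr[ok]) / (nr * yr[ok])

        n = m.size
        lo_m = int(np.floor(n * trim_m)) + 1
        hi_m = n + 1 - lo_m
        lo_a = int(np.floor(n * trim_a)) + 1
        hi_a = n + 1 - lo_a
        rank_m = _rank(m)
        rank_a = _rank(a)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if keep.any():
            f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        else:
            f = 0.0
        if not np.isfinite(f) or abs(f) < 1e-10:
            f = 0.0
        factors[j] = 2.0 ** f

    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=samples, name="tmm_factor")


def _rank(x: np.ndarray) -> np.ndarray:
    """Average ranks, 1-based (ties share the mean rank)."""
    from scipy.stats import rankdata

    return rankdata(x)


def cpm(counts: CountMatrix, factors: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million over the effective (TMM-adjusted) library size."""
    lib = counts.library_sizes.astype(float)
    if factors is None:
        eff = lib
    else:
        f = factors.reindex(counts.sample_ids)
        if f.isna().any() or (f <= 0).any():
            raise ValueError("factors must be positive and cover every sample")
        eff = lib * f
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    return counts.values.div(eff, axis=1) * 1e6


def filter_expressed(cpm_matrix: pd.DataFrame, min_cpm: float = 1.0) -> list[str]:
    """Genes with >= ``min_cpm`` in at least half of the samples.

    "Half" is ``ceil(n/2)``; order of the input is preserved. Idempotent.
    """
    n = cpm_matrix.shape[1]
    threshold = int(np.ceil(n / 2))
    n_ok = (cpm_matrix >= min_cpm).sum(axis=1)
    return cpm_matrix.index[n_ok >= threshold].tolist()


def normalize(counts: CountMatrix) -> NormalizedMatrix:
    """TMM -> CPM -> log2(CPM + 1) -> expression filter, in one step."""
    factors = tmm_factors(counts)
    cpm_matrix = cpm(counts, factors)
    retained = filter_expressed(cpm_matrix)
    log_expr = np.log2(cpm_matrix + 1.0)
    return NormalizedMatrix(
        cpm=cpm_matrix,
        log_expr=log_expr,
        tmm_factors=factors,
        retained_genes=retained,
        tissue=counts.tissue,
    )
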