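"""Expression filtering, TMM normalization and log-CPM computation.

TMM (trimmed mean of M-values) estimates a scaling factor per sample from
doubly trimmed, precision-weighted gene-wise log-ratios against a reference
sample, so that composition differences between libraries do not distort
between-sample comparisons.  log-CPM uses the familiar prior-count convention
log2((count + 0.5) / (effective library size + 1) * 1e6).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, ParameterError


@dataclass
class NormalizedExpression:
    """TMM-normalized log2-CPM matrix plus the factors that produced it.

    Attributes
    ----------
    logcpm : DataFrame
        Genes x samples log2 counts-per-million.
    tmm_factors : Series
        Per-sample scaling factors; geometric mean 1.
    library_sizes : Series
        Raw per-sample library sizes (column sums of the counts).
    """

    logcpm: pd.DataFrame
    tmm_factors: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        if np.any(self.tmm_factors.to_numpy() <= 0):
            raise ParameterError("TMM factors must be positive")
        if not np.all(np.isfinite(self.logcpm.to_numpy())):
            raise ParameterError("logcpm must be finite")

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.library_sizes * self.tmm_factors

    @property
    def gene_ids(self) -> list[str]:
        return list(self.logcpm.index.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.logcpm.columns.astype(str))

    def subset_samples(self, sample_ids) -> "NormalizedExpression":
        ids = list(sample_ids)
        return NormalizedExpression(
            self.logcpm[ids].copy(),
            self.tmm_factors.loc[ids],
            self.library_sizes.loc[ids],
        )


def filter_by_expression(
    counts: CountMatrix, cpm_threshold: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep genes with CPM above ``cpm_threshold`` in at least ``min_samples`` samples.

    CPM is computed on raw library sizes with no prior count.  The exon-level
    preset (threshold 0.125 in >= 10 samples) is expressed through the same
    parameters.  Idempotent: re-filtering a filtered matrix retains every gene,
    since dropping genes can only increase the CPM of those that remain.
    """
    if counts.n_genes == 0:
        return counts
    if min_samples > counts.n_samples:
        raise ParameterError(
            f"min_samples={min_samples} exceeds the {counts.n_samples} available samples"
        )
    if cpm_threshold < 0:
        raise ParameterError("cpm_threshold must be non-negative")
    cpm = counts.cpm().to_numpy()
    keep = (cpm > cpm_threshold).sum(axis=1) >= min_samples
    return CountMatrix(counts.counts.loc[keep].copy())


def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    abs_trim: float,
) -> float:
    """Two-sample TMM factor: weighted trimmed mean of M values vs the reference."""
    pos = (obs > 0) & (ref > 0)
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    # inverse approximate variances of M (delta method on binomial counts)
    w = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (
        lib_ref * ref[pos]
    )
    finite = np.isfinite(M) & np.isfinite(A)
    M, A, w = M[finite], A[finite], w[finite]
    n = M.size
    if n == 0:
        return 1.0
    if np.max(np.abs(M)) < 1e-6:  # columns are exact scalings of each other
        return 1.0
    # double trim by rank on M and on A
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = np.argsort(np.argsort(M, kind="stable"), kind="stable") + 1
    rank_a = np.argsort(np.argsort(A, kind="stable"), kind="stable") + 1
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    counts: CountMatrix, logratio_trim: float = 0.3, abs_trim: float = 0.05
) -> pd.Series:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose 75th-percentile CPM is closest to
    the mean 75th percentile across samples.  Genes with a zero count in
    either member of a pair are excluded from that pair's M/A values; the
    remaining log-ratios are trimmed by rank at ``logratio_trim`` on M and
    ``abs_trim`` on A and averaged with inverse-variance weights.
    """
    mat = counts.counts.to_numpy(dtype=float)
    libs = counts.library_sizes.to_numpy(dtype=float)
    if np.any(libs <= 0):
        bad = counts.sample_ids[int(np.argmax(libs <= 0))]
        raise ParameterError(f"sample {bad!r} has an all-zero library")
    q75 = np.percentile(mat, 75, axis=0) / libs
    ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.array(
        [
            1.0
            if j == ref_idx
            else _tmm_pair_factor(
                mat[:, j], mat[:, ref_idx], libs[j], libs[ref_idx], logratio_trim, abs_trim
            )
            for j in range(mat.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return pd.Series(f, index=counts.counts.columns, name="tmm_factor")


def log_cpm(
    counts: CountMatrix, factors: pd.Series | None = None, prior_count: float = 0.5
) -> NormalizedExpression:
    """log2 counts-per-million with a prior count, on effective library sizes.

    logcpm[g, i] = log2((count + prior_count) / (lib_i * factor_i + 1) * 1e6).
    """
    if factors is None:
        factors = pd.Series(1.0, index=counts.counts.columns, name="tmm_factor")
    factors = factors.loc[counts.counts.columns]
    if np.any(factors.to_numpy() <= 0):
        raise ParameterError("factors must be positive")
    if prior_count < 0:
        raise ParameterError("prior_count must be non-negative")
    eff = counts.library_sizes * factors
    logcpm = np.log2(
        (counts.counts + prior_count) / (eff + 1.0) * 1e6
    )
    return NormalizedExpression(
        logcpm=logcpm, tmm_factors=factors, library_sizes=counts.library_sizes.copy()
    )


def normalize(
    counts: CountMatrix,
    cpm_threshold: float = 1.0,
    min_samples: int = 3,
    prior_count: float = 0.5,
) -> NormalizedExpression:
    """Filter on expression, compute TMM factors and return log-CPM."""
    kept = filter_by_expression(counts, cpm_threshold, min_samples)
    factors = tmm_factors(kept)
    return log_cpm(kept, factors, prior_count)
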