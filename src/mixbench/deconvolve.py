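"""Reference-based linear-mixture deconvolution of bulk expression.

A mixed sample is modelled as Y = (1 - p) N + p T on the concentration (CPM)
scale, where N and T are the expression profiles of the two pure sources and
p is the proportion of the tumour-like source T.  Given reference profiles
from pure samples, the proportion has a closed-form least-squares estimate
and the T profile can be recovered algebraically.  Genes with similar
expression in both sources carry no information about p, so an informative-
gene filter on the pure-sample fold-change is applied first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ParameterError

logger = logging.getLogger(__name__)


@dataclass
class DeconvolutionResult:
    """Estimates for one mixed sample: proportion and deconvolved T profile."""

    sample_id: str
    p_hat: float
    T_hat: pd.Series
    n_clipped: int = 0
    corr_truth: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hat <= 1.0:
            raise ParameterError("p_hat must lie in [0, 1]")
        if np.any(self.T_hat.to_numpy() < 0):
            raise ParameterError("T_hat must be non-negative")


def informative_gene_filter(
    pure_mean_N: pd.Series,
    pure_mean_T: pd.Series,
    fc_hi: float = 2.0,
    fc_lo: float = 0.5,
) -> pd.Series:
    """Boolean mask of genes whose pure-sample fold-change T/N is informative.

    Keeps genes with T/N > ``fc_hi`` or T/N < ``fc_lo``; genes with similar
    levels in both sources would only dilute the proportion estimate.  Genes
    with a zero mean in either source are excluded first (and counted in the
    log) since their ratio is undefined.
    """
    if fc_lo >= fc_hi:
        raise ParameterError("fc_lo must be below fc_hi")
    N = pd.Series(pure_mean_N).astype(float)
    T = pd.Series(pure_mean_T).astype(float)
    if not N.index.equals(T.index):
        raise ParameterError("gene universes of N and T differ")
    nonzero = (N > 0) & (T > 0)
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("informative_gene_filter: %d zero-mean genes excluded", dropped)
    ratio = T.where(nonzero) / N.where(nonzero)
    mask = ((ratio > fc_hi) | (ratio < fc_lo)) & nonzero
    return mask.fillna(False)


def estimate_proportion(
    mixed: pd.Series,
    ref_N: pd.Series,
    ref_T: pd.Series,
    mask: pd.Series | None = None,
) -> float:
    """Least-squares proportion of source T in a mixed sample.

    Minimizes sum_g (mixed_g - (1-p) N_g - p T_g)^2 over the masked genes;
    the minimizer p = <T - N, mixed - N> / ||T - N||^2 is clipped to [0, 1].
    """
    mixed = pd.Series(mixed).astype(float)
    N = pd.Series(ref_N).astype(float).loc[mixed.index]
    T = pd.Series(ref_T).astype(float).loc[mixed.index]
    if mask is not None:
        mask = pd.Series(mask).reindex(mixed.index, fill_value=False)
        if not mask.any():
            raise ParameterError("gene mask is empty")
        mixed, N, T = mixed[mask], N[mask], T[mask]
    d = (T - N).to_numpy()
    denom = float(d @ d)
    if denom == 0.0:
        raise ParameterError("references identical on the masked genes; p is unidentifiable")
    p = float(d @ (mixed - N).to_numpy()) / denom
    return float(np.clip(p, 0.0, 1.0))


def deconvolve_expression(
    mixed: pd.Series, p_hat: float, ref_N: pd.Series
) -> tuple[pd.Series, int]:
    """Recover the T profile: T_hat = (mixed - (1 - p) N) / p, clipped at 0.

    Returns (T_hat, number of genes clipped to zero).  Requires p_hat > 0.
    """
    if p_hat <= 0:
        raise ParameterError("p_hat must be positive to deconvolve the T component")
    mixed = pd.Series(mixed).astype(float)
    N = pd.Series(ref_N).astype(float).loc[mixed.index]
    raw = (mixed - (1.0 - p_hat) * N) / p_hat
    n_clipped = int((raw < 0).sum())
    if n_clipped:
        logger.info("deconvolve_expression: %d negative values clipped to 0", n_clipped)
    return raw.clip(lower=0.0).rename("T_hat"), n_clipped


def deconvolve_sample(
    sample_id: str,
    mixed: pd.Series,
    ref_N: pd.Series,
    ref_T: pd.Series,
    mask: pd.Series | None = None,
) -> DeconvolutionResult:
    """Estimate the proportion and T profile of one mixed sample."""
    p_hat = estimate_proportion(mixed, ref_N, ref_T, mask)
    if p_hat > 0:
        T_hat, n_clipped = deconvolve_expression(mixed, p_hat, ref_N)
    else:
        T_hat, n_clipped = pd.Series(np.nan, index=mixed.index, name="T_hat"), 0
    return DeconvolutionResult(sample_id, p_hat, T_hat, n_clipped)


def evaluate_deconvolution(
    results: list[DeconvolutionResult],
    truth_proportions: list[float],
    truth_profile: pd.Series,
) -> pd.DataFrame:
    """Score estimates against the design truth, one row per mixed sample.

    Columns: p_hat, truth, error (p_hat - truth), and the Pearson correlation
    of the deconvolved T profile with the pure T profile.  The correlation is
    missing when either profile is constant.  Summary row ``_summary`` holds
    max |error| and min correlation.
    """
    if len(results) != len(truth_proportions):
        raise ParameterError("results and truth_proportions lengths differ")
    truth_profile = pd.Series(truth_profile).astype(float)
    rows = []
    for res, truth in zip(results, truth_proportions):
        t_hat = res.T_hat.dropna()
        tp = truth_profile.loc[t_hat.index]
        if t_hat.std() == 0 or tp.std() == 0 or len(t_hat) < 2:
            corr = np.nan
            logger.warning("correlation undefined for sample %s", res.sample_id)
        else:
            corr = float(stats.pearsonr(t_hat.to_numpy(), tp.to_numpy())[0])
        res.corr_truth = corr
        rows.append(
            {
                "sample_id": res.sample_id,
                "p_hat": res.p_hat,
                "truth": truth,
                "error": res.p_hat - truth,
                "corr_T": corr,
            }
        )
    table = pd.DataFrame(rows).set_index("sample_id")
    summary = pd.DataFrame(
        {
            "p_hat": [np.nan],
            "truth": [np.nan],
            "error": [table["error"].abs().max()],
            "corr_T": [table["corr_T"].min()],
        },
        index=pd.Index(["_summary"], name="sample_id"),
    )
    return pd.concat([table, summary])
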