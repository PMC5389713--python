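"""Reference differential-expression test and FDR adjustment.

The benchmark harness needs at least one built-in DE method so it runs
end-to-end without external tools.  The reference method is a deliberately
simple moderated t-test on log-CPM: gene-wise pooled variances are shrunk
toward their mean with a configurable prior degrees of freedom, mimicking the
empirical-Bayes moderation used throughout the field without re-implementing
any particular package.  Results from external tools are ingested through the
same tabular schema.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ParameterError
from .preprocess import NormalizedExpression


@dataclass
class DEResult:
    """Per-gene differential-expression calls for one two-group comparison.

    ``table`` columns: logFC, p_value, fdr, significant; indexed by gene_id.
    """

    table: pd.DataFrame
    method_label: str = "moderated-t"
    fdr_cutoff: float = 0.05

    def __post_init__(self) -> None:
        required = {"logFC", "p_value", "fdr"}
        missing = required - set(self.table.columns)
        if missing:
            raise ParameterError(f"DE table missing columns: {sorted(missing)}")
        p = self.table["p_value"].to_numpy()
        if np.any((p < 0) | (p > 1)):
            raise ParameterError("p-values must lie in [0, 1]")
        if "significant" not in self.table.columns:
            self.table = self.table.assign(significant=self.table["fdr"] < self.fdr_cutoff)

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    def significant_set(self, fdr_cutoff: float | None = None) -> set[str]:
        cutoff = self.fdr_cutoff if fdr_cutoff is None else fdr_cutoff
        return set(self.table.index[self.table["fdr"] < cutoff].astype(str))

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out["method_label"] = self.method_label
        out.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, fdr_cutoff: float = 0.05) -> "DEResult":
        df = pd.read_csv(path, sep="\t", index_col=0)
        label = str(df["method_label"].iloc[0]) if "method_label" in df.columns else "external"
        df = df.drop(columns=[c for c in ("method_label",) if c in df.columns])
        if "fdr" not in df.columns:
            df["fdr"] = bh_adjust(df["p_value"].to_numpy())
        return cls(df, method_label=label, fdr_cutoff=fdr_cutoff)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    q_(i) = min_{j >= i} (p_(j) * n / j), capped at 1, in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ParameterError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def moderated_two_group_test(
    expr: NormalizedExpression,
    group1: Sequence[str],
    group2: Sequence[str],
    prior_df: float = 4.0,
    fdr_cutoff: float = 0.05,
    method_label: str = "moderated-t",
) -> DEResult:
    """Moderated t-test on log-CPM between two sample groups.

    Per gene: logFC = mean(group1) - mean(group2); the pooled variance s2_g
    (df_g = n1 + n2 - 2) is shrunk toward the across-gene mean s0^2 as

        s2_post = (prior_df * s0^2 + df_g * s2_g) / (prior_df + df_g),

    and the t statistic logFC / sqrt(s2_post * (1/n1 + 1/n2)) is referred to
    a t distribution on df_g + prior_df degrees of freedom (two-sided).
    ``prior_df = 0`` recovers the ordinary pooled t-test.
    """
    g1, g2 = list(group1), list(group2)
    if set(g1) & set(g2):
        raise ParameterError("groups overlap")
    if len(g1) < 2 or len(g2) < 2:
        raise ParameterError("each group needs at least 2 samples")
    if prior_df < 0:
        raise ParameterError("prior_df must be non-negative")
    missing = (set(g1) | set(g2)) - set(expr.sample_ids)
    if missing:
        raise ParameterError(f"unknown sample ids: {sorted(missing)}")

    z1 = expr.logcpm[g1].to_numpy(dtype=float)
    z2 = expr.logcpm[g2].to_numpy(dtype=float)
    n1, n2 = z1.shape[1], z2.shape[1]
    logfc = z1.mean(axis=1) - z2.mean(axis=1)
    df_g = n1 + n2 - 2
    ss = ((z1 - z1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (z2 - z2.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_g
    s0_sq = float(np.mean(s2))
    if prior_df > 0:
        s2_post = (prior_df * s0_sq + df_g * s2) / (prior_df + df_g)
    else:
        s2_post = s2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df=df_g + prior_df)
    p = np.clip(p, 0.0, 1.0)
    fdr = bh_adjust(p)
    table = pd.DataFrame(
        {"logFC": logfc, "p_value": p, "fdr": fdr, "significant": fdr < fdr_cutoff},
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    return DEResult(table, method_label=method_label, fdr_cutoff=fdr_cutoff)
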