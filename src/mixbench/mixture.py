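"""Gene-wise non-linear mixture model of a two-source titration experiment.

For a sample with mixing proportion ``p`` of source A, the log2-CPM of gene g
is modelled as

    logCPM_gi = log2(p_i * X_g + (1 - p_i) * Y_g) + eps_gi,

with eps_gi independent, mean zero and gene-specific standard deviation
phi_g.  X_g and Y_g are the gene's concentrations in the two pure sources;
their log-ratio M_g = log2(X_g / Y_g) is the expression log-fold-change
between the pure samples.  Because the mean is linear in (X, Y) on the raw
scale but the noise is on the log scale, the model is a genuinely non-linear
least-squares problem, solved here per gene by a vectorized Gauss-Newton
iteration with step halving, parameterized in (log2 X, log2 Y) to keep the
concentrations positive without constraints.

The fitted model predicts the log-fold-change between any two mixture groups
with proportions p and q:

    delta_g(p, q) = log2((p Xhat_g + (1-p) Yhat_g) / (q Xhat_g + (1-q) Yhat_g)),

which serves as built-in truth when benchmarking differential-expression
methods on mixture data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, MixtureDesign, ParameterError
from .preprocess import NormalizedExpression, normalize


class DesignError(ValueError):
    """The sample design cannot identify the model (too few distinct proportions)."""


@dataclass
class ContrastPrediction:
    """Model-predicted log-fold-changes between two mixture groups."""

    p: float
    q: float
    delta: pd.Series  # per-gene predicted log2-FC; NaN where the fit did not converge

    def __neg__(self) -> "ContrastPrediction":
        return ContrastPrediction(self.q, self.p, -self.delta)


class MixtureModel:
    """Non-linear dose-response model of log2-CPM across a mixture series.

    Parameters
    ----------
    logcpm : DataFrame
        Genes x samples matrix of (TMM-normalized) log2-CPM values.
    proportions : array-like
        Mixing proportion of source A for each sample (column), in [0, 1].

    Use :meth:`from_counts` to build the model directly from a count matrix
    and a design table, with filtering and TMM normalization applied.
    """

    def __init__(self, logcpm: pd.DataFrame, proportions: Sequence[float]):
        self.logcpm = logcpm
        self.proportions = np.asarray(proportions, dtype=float)
        if self.proportions.shape != (logcpm.shape[1],):
            raise ParameterError("one proportion per sample is required")
        if np.any(self.proportions < 0) or np.any(self.proportions > 1):
            raise ParameterError("proportions must lie in [0, 1]")
        if logcpm.shape[1] < 3:
            raise DesignError("at least 3 samples are required")
        if np.unique(self.proportions).size < 2:
            raise DesignError(
                "the model is unidentifiable with fewer than 2 distinct proportions"
            )
        if not np.all(np.isfinite(logcpm.to_numpy())):
            raise ParameterError("logcpm must be finite")

    # ------------------------------------------------------------------ #
    @classmethod
    def from_counts(
        cls,
        counts: CountMatrix,
        design: MixtureDesign,
        exclude_samples: Sequence[str] = (),
        cpm_threshold: float = 1.0,
        min_samples: int = 3,
        prior_count: float = 0.5,
    ) -> "MixtureModel":
        """Normalize counts and align them with the design's proportions.

        ``exclude_samples`` removes samples (e.g. those used in a pairwise
        comparison) *before* normalization and fitting, so predictions for
        that comparison are not over-fitted to its own samples.
        """
        keep = [s for s in design.sample_ids if s not in set(exclude_samples)]
        sub_design = design.subset(keep)
        sub_counts = counts.subset_samples(keep)
        expr = normalize(sub_counts, cpm_threshold, min_samples, prior_count)
        return cls.from_normalized(expr, sub_design)

    @classmethod
    def from_normalized(
        cls, expr: NormalizedExpression, design: MixtureDesign
    ) -> "MixtureModel":
        ids = [s for s in expr.sample_ids if s in set(design.sample_ids)]
        if len(ids) < len(expr.sample_ids):
            expr = expr.subset_samples(ids)
        prop = design.samples.set_index("sample_id")["proportion"].loc[ids].to_numpy()
        return cls(expr.logcpm, prop)

    # ------------------------------------------------------------------ #
    def _initial_values(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Start values (log2 X0, log2 Y0) per gene.

        Linear regression of 2^logcpm on (p, 1-p) without intercept — exact
        when the data are noise-free — clipped to positive; genes for which
        either coefficient is non-positive fall back to the mean logcpm of
        the highest- and lowest-proportion samples.
        """
        p = self.proportions
        w = np.exp2(z)  # genes x samples, raw-CPM scale
        D = np.column_stack([p, 1.0 - p])
        coef, *_ = np.linalg.lstsq(D, w.T, rcond=None)  # 2 x genes
        X0, Y0 = coef[0], coef[1]
        hi = p == p.max()
        lo = p == p.min()
        fb_a = z[:, hi].mean(axis=1)
        fb_b = z[:, lo].mean(axis=1)
        bad = ~(np.isfinite(X0) & np.isfinite(Y0) & (X0 > 0) & (Y0 > 0))
        a = np.where(bad, fb_a, np.log2(np.where(X0 > 0, X0, 1.0)))
        b = np.where(bad, fb_b, np.log2(np.where(Y0 > 0, Y0, 1.0)))
        return a, b

    @staticmethod
    def _sse(z: np.ndarray, p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        mu = np.log2(p[None, :] * np.exp2(a)[:, None] + (1.0 - p)[None, :] * np.exp2(b)[:, None])
        r = z - mu
        return np.einsum("gi,gi->g", r, r)

    def fit(self, max_iter: int = 50, tol: float = 1e-8, max_halvings: int = 20) -> "MixtureResults":
        """Fit (X_g, Y_g) per gene by Gauss-Newton least squares.

        Minimizes sum_i (logCPM_gi - log2(p_i X + (1-p_i) Y))^2 over
        (a, b) = (log2 X, log2 Y) for all genes simultaneously.  Each
        iteration solves the 2x2 normal equations per gene in closed form and
        halves the step until the SSE does not increase.  Convergence is a
        relative SSE decrease below ``tol``; genes that do not converge are
        flagged and keep their best iterate.
        """
        z = self.logcpm.to_numpy(dtype=float)
        p = self.proportions
        G, n = z.shape
        a, b = self._initial_values(z)
        sse = self._sse(z, p, a, b)
        n_iter = np.zeros(G, dtype=int)
        converged = np.zeros(G, dtype=bool)
        active = np.ones(G, dtype=bool)

        for it in range(1, max_iter + 1):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            aa, bb = a[idx], b[idx]
            X = np.exp2(aa)[:, None]
            Y = np.exp2(bb)[:, None]
            S = p[None, :] * X + (1.0 - p)[None, :] * Y
            mu = np.log2(S)
            r = z[idx] - mu
            # Jacobian of mu wrt (a, b): d mu/da = pX/S, d mu/db = (1-p)Y/S
            Ja = p[None, :] * X / S
            Jb = (1.0 - p)[None, :] * Y / S
            g1 = np.einsum("gi,gi->g", Ja, r)
            g2 = np.einsum("gi,gi->g", Jb, r)
            h11 = np.einsum("gi,gi->g", Ja, Ja)
            h22 = np.einsum("gi,gi->g", Jb, Jb)
            h12 = np.einsum("gi,gi->g", Ja, Jb)
            det = h11 * h22 - h12 * h12
            det = np.where(np.abs(det) < 1e-300, 1e-300, det)
            da = (h22 * g1 - h12 * g2) / det
            db = (h11 * g2 - h12 * g1) / det
            # guard against wild steps from near-singular normal equations
            step_cap = 30.0
            scale = np.maximum(1.0, np.maximum(np.abs(da), np.abs(db)) / step_cap)
            da /= scale
            db /= scale

            old = sse[idx]
            best_a, best_b, best_sse = aa.copy(), bb.copy(), old.copy()
            pending = np.ones(idx.size, dtype=bool)
            halve = np.zeros(idx.size)
            for _ in range(max_halvings + 1):
                if not pending.any():
                    break
                trial_a = aa[pending] + da[pending] * np.exp2(-halve[pending])
                trial_b = bb[pending] + db[pending] * np.exp2(-halve[pending])
                trial_sse = self._sse(z[idx[pending]], p, trial_a, trial_b)
                improved = trial_sse <= best_sse[pending]
                sub = np.flatnonzero(pending)
                ok = sub[improved]
                best_a[ok] = trial_a[improved]
                best_b[ok] = trial_b[improved]
                best_sse[ok] = trial_sse[improved]
                pending[ok] = False
                halve[sub[~improved]] += 1.0

            a[idx], b[idx] = best_a, best_b
            sse[idx] = best_sse
            n_iter[idx] = it
            rel = (old - best_sse) / np.maximum(old, 1e-300)
            done = rel < tol
            converged[idx[done]] = True
            active[idx] = ~done

        df_resid = max(n - 2, 1)
        phi_hat = np.sqrt(sse / df_resid)
        return MixtureResults(
            model=self,
            log2X=a,
            log2Y=b,
            sse=sse,
            phi_hat=phi_hat,
            converged=converged,
            n_iter=n_iter,
            df_resid=n - 2,
        )


@dataclass
class MixtureResults:
    """Per-gene estimates from :meth:`MixtureModel.fit`.

    ``Xhat``/``Yhat`` are the estimated source concentrations (CPM scale),
    ``M`` their log2 ratio, ``phi_hat`` the residual log2-scale standard
    deviation sqrt(RSS / (n - 2)).
    """

    model: MixtureModel
    log2X: np.ndarray
    log2Y: np.ndarray
    sse: np.ndarray
    phi_hat: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray
    df_resid: int

    @property
    def gene_ids(self) -> list[str]:
        return list(self.model.logcpm.index.astype(str))

    @property
    def samples_used(self) -> list[str]:
        return list(self.model.logcpm.columns.astype(str))

    @property
    def Xhat(self) -> np.ndarray:
        return np.exp2(self.log2X)

    @property
    def Yhat(self) -> np.ndarray:
        return np.exp2(self.log2Y)

    @property
    def M(self) -> np.ndarray:
        """Estimated log2 fold-change between the pure sources, log2X - log2Y."""
        return self.log2X - self.log2Y

    # ------------------------------------------------------------------ #
    def predicted_logfc(self, p: float, q: float) -> ContrastPrediction:
        """Predicted log2-FC between mixture groups with proportions p and q."""
        if not (0.0 <= p <= 1.0) or not (0.0 <= q <= 1.0):
            raise ParameterError("p and q must lie in [0, 1]")
        num = p * self.Xhat + (1.0 - p) * self.Yhat
        den = q * self.Xhat + (1.0 - q) * self.Yhat
        delta = np.log2(num / den)
        delta = np.where(self.converged, delta, np.nan)
        return ContrastPrediction(p, q, pd.Series(delta, index=self.gene_ids, name="delta"))

    def summary(self, top: int = 10) -> str:
        """Plain-text summary of the fit."""
        G = len(self.gene_ids)
        lines = [
            "Mixture dose-response model (gene-wise non-linear least squares)",
            "=" * 64,
            f"genes: {G}    samples: {len(self.samples_used)}    "
            f"proportions: {sorted({float(p) for p in np.round(self.model.proportions, 4)})}",
            f"converged: {int(self.converged.sum())}/{G}    "
            f"median iterations: {int(np.median(self.n_iter))}",
            f"median phi_hat: {np.median(self.phi_hat):.4f}    "
            f"median |M|: {np.median(np.abs(self.M)):.4f}",
            "-" * 64,
        ]
        head = self.to_frame().head(top)
        lines.append(head.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "Xhat": self.Xhat,
                "Yhat": self.Yhat,
                "M": self.M,
                "phi_hat": self.phi_hat,
                "converged": self.converged,
                "n_iter": self.n_iter,
            },
            index=pd.Index(self.gene_ids, name="gene_id"),
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------- #
# Functional wrappers

def fit_mixture(
    expr: NormalizedExpression,
    design: MixtureDesign,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> MixtureResults:
    """Fit the mixture model to a normalized expression matrix."""
    return MixtureModel.from_normalized(expr, design).fit(max_iter=max_iter, tol=tol)


def leave_out_fit(
    expr: NormalizedExpression,
    design: MixtureDesign,
    comparison: tuple[Sequence[str], Sequence[str]],
    max_iter: int = 50,
    tol: float = 1e-8,
) -> MixtureResults:
    """Fit the model excluding the samples of a pairwise comparison.

    Removing the compared samples before fitting keeps the model's predicted
    log-FCs independent of the data being benchmarked against them.
    """
    excluded = set(comparison[0]) | set(comparison[1])
    keep = [s for s in expr.sample_ids if s not in excluded]
    sub_design = design.subset([s for s in design.sample_ids if s in set(keep)])
    if np.unique(sub_design.proportions).size < 2:
        raise DesignError("excluding the comparison leaves fewer than 2 distinct proportions")
    return fit_mixture(expr.subset_samples(keep), sub_design, max_iter=max_iter, tol=tol)


def predicted_logfc(fit: MixtureResults, p: float, q: float) -> ContrastPrediction:
    """Module-level alias for :meth:`MixtureResults.predicted_logfc`."""
    return fit.predicted_logfc(p, q)


def rmse_logfc(estimated: pd.Series, predicted: ContrastPrediction) -> tuple[float, int]:
    """Root-mean-square error between estimated and model-predicted log-FCs.

    RMSE = sqrt(mean over shared genes of (logFC_g - delta_g)^2).  Genes with
    a missing prediction (non-converged fit) or absent from either side are
    excluded pairwise.  Returns (rmse, number of genes excluded).
    """
    est = pd.Series(estimated).astype(float)
    joined = pd.concat([est.rename("est"), predicted.delta.rename("pred")], axis=1, join="inner")
    total = len(joined)
    valid = joined.dropna()
    if len(valid) == 0:
        raise ParameterError("no genes shared between estimated and predicted log-FCs")
    excluded = (len(est) - len(valid)) if total else len(est)
    err = valid["est"] - valid["pred"]
    return float(np.sqrt(np.mean(err.to_numpy() ** 2))), int(excluded)
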