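"""Core data containers: reference truth, sample design and count matrices.

These are light dataclass wrappers around pandas/numpy objects.  They validate
their invariants on construction so downstream stages can assume them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

GOOD = "good"
DEGRADED = "degraded"

#: mixing proportions of source A used throughout the default design
DEFAULT_PROPORTIONS = (1.0, 0.75, 0.5, 0.25, 0.0)


class ParameterError(ValueError):
    """A parameter fails its precondition (non-finite, out of range, ...)."""


@dataclass
class ReferenceTranscriptome:
    """Ground-truth per-gene concentrations of the two reference sources.

    Attributes
    ----------
    gene_ids : list of str
        Gene identifiers.
    X, Y : ndarray
        Expected concentration (CPM scale, strictly positive) of each gene in
        source A and source B respectively.
    phi : ndarray
        Per-gene log2-scale residual standard deviation (>= 0).
    dispersion : ndarray
        Per-gene negative-binomial dispersion, variance = mu + dispersion*mu^2
        (>= 0; 0 means Poisson).
    de_lfc_threshold : float
        |log2(X/Y)| at or above which a gene is considered differentially
        expressed between the sources.
    """

    gene_ids: list[str]
    X: np.ndarray
    Y: np.ndarray
    phi: np.ndarray
    dispersion: np.ndarray
    de_lfc_threshold: float = 1.0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.dispersion = np.asarray(self.dispersion, dtype=float)
        n = len(self.gene_ids)
        for name in ("X", "Y", "phi", "dispersion"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ParameterError(f"{name} must have length {n}, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ParameterError(f"{name} contains non-finite values")
        if np.any(self.X <= 0) or np.any(self.Y <= 0):
            raise ParameterError("X and Y must be strictly positive")
        if np.any(self.phi < 0) or np.any(self.dispersion < 0):
            raise ParameterError("phi and dispersion must be non-negative")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def R(self) -> np.ndarray:
        """Per-gene concentration ratio X/Y between the sources."""
        return self.X / self.Y

    @property
    def is_de(self) -> np.ndarray:
        """True for genes whose |log2 ratio| reaches the DE threshold."""
        return np.abs(np.log2(self.R)) >= self.de_lfc_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "X": self.X,
                "Y": self.Y,
                "R": self.R,
                "phi": self.phi,
                "dispersion": self.dispersion,
                "is_de": self.is_de,
            }
        ).set_index("gene_id")

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, de_lfc_threshold: float = 1.0) -> "ReferenceTranscriptome":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            gene_ids=list(df.index.astype(str)),
            X=df["X"].to_numpy(),
            Y=df["Y"].to_numpy(),
            phi=df["phi"].to_numpy(),
            dispersion=df["dispersion"].to_numpy(),
            de_lfc_threshold=de_lfc_threshold,
        )


@dataclass
class MixtureDesign:
    """Sample sheet of a mixture experiment.

    ``samples`` has one row per RNA sample with columns ``sample_id``,
    ``proportion`` (of source A, in [0,1]), ``replicate`` (1-based),
    ``quality`` ('good' or 'degraded') and ``protocol``.
    """

    samples: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "proportion", "replicate", "quality", "protocol"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ParameterError(f"design table missing columns: {sorted(missing)}")
        p = self.samples["proportion"].to_numpy(dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ParameterError("proportions must lie in [0, 1]")
        if not self.samples["quality"].isin([GOOD, DEGRADED]).all():
            raise ParameterError(f"quality must be '{GOOD}' or '{DEGRADED}'")
        triples = self.samples[["proportion", "replicate", "quality"]]
        if triples.duplicated().any():
            raise ParameterError("(proportion, replicate, quality) triples must be unique")
        if self.samples["sample_id"].duplicated().any():
            raise ParameterError("sample ids must be unique")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples["sample_id"])

    @property
    def proportions(self) -> np.ndarray:
        return self.samples["proportion"].to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, sample_ids: Sequence[str]) -> "MixtureDesign":
        wanted = set(sample_ids)
        unknown = wanted - set(self.sample_ids)
        if unknown:
            raise ParameterError(f"unknown sample ids: {sorted(unknown)}")
        sub = self.samples[self.samples["sample_id"].isin(wanted)].reset_index(drop=True)
        return MixtureDesign(sub)

    def good_only(self) -> "MixtureDesign":
        return MixtureDesign(
            self.samples[self.samples["quality"] == GOOD].reset_index(drop=True)
        )

    def group(self, proportion: float, quality: str = GOOD) -> list[str]:
        """Sample ids at one mixing proportion and quality."""
        m = (np.isclose(self.samples["proportion"], proportion)
             & (self.samples["quality"] == quality))
        return list(self.samples.loc[m, "sample_id"])

    def substituted(self, replicate: int = 2) -> "MixtureDesign":
        """Replace the good samples of one replicate with their degraded twins.

        Emulates re-running an analysis on the set where a replicate's RNA has
        been degraded: drops good samples of ``replicate`` at proportions for
        which a degraded duplicate exists, keeping everything else.
        """
        df = self.samples
        degr = df[df["quality"] == DEGRADED]
        drop = (
            (df["quality"] == GOOD)
            & (df["replicate"] == replicate)
            & df["proportion"].isin(degr["proportion"])
        )
        out = df[~drop].reset_index(drop=True)
        return MixtureDesign(out)

    def to_tsv(self, path) -> None:
        self.samples.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "MixtureDesign":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative integer read counts."""

    counts: pd.DataFrame
    library_sizes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise ParameterError("counts must be non-negative")
        if not np.allclose(vals, np.round(vals)):
            raise ParameterError("counts must be integral")
        colsums = self.counts.sum(axis=0)
        if self.library_sizes is None:
            self.library_sizes = colsums.astype(float)
        else:
            self.library_sizes = pd.Series(self.library_sizes, index=self.counts.columns, dtype=float)
            if not np.allclose(self.library_sizes.to_numpy(), colsums.to_numpy()):
                raise ParameterError("library_sizes must equal column sums")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index.astype(str))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns.astype(str))

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def cpm(self) -> pd.DataFrame:
        """Counts per million on raw library sizes, no prior count."""
        return self.counts / self.library_sizes * 1e6

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts[list(sample_ids)].copy())

    def subset_genes(self, gene_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)].copy())

    def to_tsv(self, path) -> None:
        self.counts.rename_axis("gene_id").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)
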