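"""Simulation of two-source mixture experiments.

The generator emulates a titration design: two reference transcriptomes mixed
at proportions 1, 0.75, 0.5, 0.25 and 0 of source A, in triplicate, with the
second replicate duplicated as a degraded (higher-dispersion) aliquot.  Counts
are negative binomial with gene-specific dispersion so that the gene-wise
variability is strongly gene-specific (low empirical-Bayes prior degrees of
freedom), the regime observed in real mixture control data.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import (
    DEFAULT_PROPORTIONS,
    DEGRADED,
    GOOD,
    CountMatrix,
    MixtureDesign,
    ParameterError,
    ReferenceTranscriptome,
)

LN2 = math.log(2.0)


def simulate_reference_profiles(
    n_genes: int,
    de_fraction: float = 0.1,
    lfc_sd: float = 2.0,
    *,
    abundance_meanlog: float = 4.0,
    abundance_sdlog: float = 1.8,
    de_lfc_threshold: float = 1.0,
    dispersion_mean: float = 0.05,
    dispersion_prior_df: float = 5.0,
    seed: int = 0,
) -> ReferenceTranscriptome:
    """Draw ground-truth per-gene concentrations for the two sources.

    Exactly ``round(n_genes * de_fraction)`` genes are differentially
    expressed: their log2 ratio log2(X/Y) is drawn from Normal(0, lfc_sd^2)
    truncated away from ``(-de_lfc_threshold, de_lfc_threshold)``.  All other
    genes have equal concentration in both sources (ratio 1).  Source-A
    abundances X are log-normal on the CPM scale, reproducing the wide dynamic
    range of real transcriptomes; Y = X / ratio.

    Gene-wise NB dispersions follow a scaled inverse-chi-square with
    ``dispersion_prior_df`` degrees of freedom around ``dispersion_mean``, so
    that variability is gene-specific rather than common (prior df ~5 mimics
    biological noise; df -> infinity would mimic purely technical noise).
    """
    params = dict(
        de_fraction=de_fraction, lfc_sd=lfc_sd,
        abundance_meanlog=abundance_meanlog, abundance_sdlog=abundance_sdlog,
        de_lfc_threshold=de_lfc_threshold, dispersion_mean=dispersion_mean,
        dispersion_prior_df=dispersion_prior_df,
    )
    for name, val in params.items():
        if not np.isfinite(val):
            raise ParameterError(f"{name} must be finite, got {val!r}")
    if n_genes < 1:
        raise ParameterError("n_genes must be >= 1")
    if not 0.0 <= de_fraction <= 1.0:
        raise ParameterError("de_fraction must lie in [0, 1]")
    if lfc_sd <= 0:
        raise ParameterError("lfc_sd must be positive")

    rng = np.random.default_rng(seed)
    gene_ids = [f"gene{i:06d}" for i in range(n_genes)]

    X = rng.lognormal(mean=abundance_meanlog * LN2, sigma=abundance_sdlog * LN2, size=n_genes)

    n_de = int(round(n_genes * de_fraction))
    lfc = np.zeros(n_genes)
    todo = np.arange(n_de)
    while todo.size:  # rejection sampling of the truncated normal
        draw = rng.normal(0.0, lfc_sd, size=todo.size)
        ok = np.abs(draw) >= de_lfc_threshold
        lfc[todo[ok]] = draw[ok]
        todo = todo[~ok]
    Y = X / np.exp2(lfc)

    if dispersion_mean > 0 and dispersion_prior_df > 0:
        dispersion = dispersion_mean * dispersion_prior_df / rng.chisquare(
            dispersion_prior_df, size=n_genes
        )
    else:
        dispersion = np.full(n_genes, float(dispersion_mean))
    # log2-scale residual sd implied by the NB dispersion at high counts
    phi = np.sqrt(dispersion) / LN2

    return ReferenceTranscriptome(
        gene_ids=gene_ids, X=X, Y=Y, phi=phi, dispersion=dispersion,
        de_lfc_threshold=de_lfc_threshold,
    )


def make_default_design(
    n_replicates: int = 3,
    degraded_replicate: int = 2,
    proportions: tuple[float, ...] = DEFAULT_PROPORTIONS,
    protocol: str = "mRNA",
) -> MixtureDesign:
    """Build the titration sample sheet.

    Every proportion is sequenced in ``n_replicates`` good replicates, and the
    ``degraded_replicate``-th replicate is additionally split into a degraded
    duplicate at every proportion.  Defaults give 15 good + 5 degraded = 20
    samples.
    """
    if n_replicates < 1:
        raise ParameterError("n_replicates must be >= 1")
    if not 1 <= degraded_replicate <= n_replicates:
        raise ParameterError("degraded_replicate must be in 1..n_replicates")
    rows = []
    for p in proportions:
        label = f"{int(round(p * 100)):03d}"
        for rep in range(1, n_replicates + 1):
            rows.append((f"{label}_R{rep}", p, rep, GOOD, protocol))
        rows.append((f"{label}_R{degraded_replicate}D", p, degraded_replicate, DEGRADED, protocol))
    df = pd.DataFrame(rows, columns=["sample_id", "proportion", "replicate", "quality", "protocol"])
    return MixtureDesign(df)


def expected_cpm(ref: ReferenceTranscriptome, proportion: float) -> np.ndarray:
    """Expected CPM profile of a mixture sample: normalized p*X + (1-p)*Y."""
    mix = proportion * ref.X + (1.0 - proportion) * ref.Y
    return mix / mix.sum() * 1e6


def simulate_mixture_counts(
    ref: ReferenceTranscriptome,
    design: MixtureDesign,
    lib_size_mean: float = 2e7,
    lib_size_cv: float = 0.1,
    degradation_dispersion_multiplier: float = 4.0,
    seed: int = 0,
) -> CountMatrix:
    """Draw a count matrix for every sample in the design.

    For sample i with mixing proportion p_i the expected count of gene g is
    ``lib_i * (p_i X_g + (1-p_i) Y_g) / sum_g(p_i X_g + (1-p_i) Y_g)``; counts
    are NB with variance mu + dispersion*mu^2, the dispersion multiplied by
    ``degradation_dispersion_multiplier`` for degraded samples.  Each sample
    draws from its own deterministic RNG sub-stream (spawn-keyed on its row
    index), so altering one sample's parameters never perturbs another's
    counts and a multiplier of 1 makes degraded columns distributionally
    identical to good replicates.
    """
    if ref.n_genes == 0 or design.n_samples == 0:
        raise ParameterError("reference and design must be non-empty")
    if lib_size_mean <= 0:
        raise ParameterError("lib_size_mean must be positive")
    if lib_size_cv < 0:
        raise ParameterError("lib_size_cv must be non-negative")
    if degradation_dispersion_multiplier < 1:
        raise ParameterError("degradation_dispersion_multiplier must be >= 1")
    if not np.any(ref.X > 0) and not np.any(ref.Y > 0):
        raise ParameterError("reference is all zero")

    cols = {}
    for i, row in design.samples.reset_index(drop=True).iterrows():
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        p = float(row["proportion"])
        mix = p * ref.X + (1.0 - p) * ref.Y
        frac = mix / mix.sum()
        if lib_size_cv > 0:
            sigma = math.sqrt(math.log1p(lib_size_cv**2))
            lib = lib_size_mean * math.exp(
                rng.normal(-0.5 * sigma**2, sigma)
            )
        else:
            lib = lib_size_mean
        mu = lib * frac
        disp = ref.dispersion * (
            degradation_dispersion_multiplier if row["quality"] == DEGRADED else 1.0
        )
        counts = np.empty(ref.n_genes, dtype=np.int64)
        poisson = disp <= 0
        if poisson.any():
            counts[poisson] = rng.poisson(mu[poisson])
        nb = ~poisson
        if nb.any():
            size = 1.0 / disp[nb]  # NB shape; variance = mu + mu^2/size
            prob = size / (size + mu[nb])
            counts[nb] = rng.negative_binomial(size, prob)
        cols[row["sample_id"]] = counts
    df = pd.DataFrame(cols, index=ref.gene_ids)
    return CountMatrix(df)
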