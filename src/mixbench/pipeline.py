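"""End-to-end pipeline: simulate -> normalize -> fit -> benchmark -> deconvolve.

Stages exchange plain TSV files so any stage can be re-run from saved
intermediates; a JSON manifest records the seed, parameters and a SHA-256
checksum of every output for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .benchmark import run_benchmark
from .datatypes import CountMatrix, MixtureDesign, ParameterError
from .deconvolve import (
    deconvolve_sample,
    evaluate_deconvolution,
    informative_gene_filter,
)
from .mixture import MixtureModel
from .preprocess import filter_by_expression, log_cpm, tmm_factors
from .simulate import make_default_design, simulate_mixture_counts, simulate_reference_profiles

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    de_fraction: float = 0.1
    lfc_sd: float = 2.0
    de_lfc_threshold: float = 1.0
    abundance_meanlog: float = 4.0
    abundance_sdlog: float = 1.8
    dispersion_mean: float = 0.05
    dispersion_prior_df: float = 5.0
    n_replicates: int = 3
    degraded_replicate: int = 2
    lib_size_mean: float = 2e6
    lib_size_cv: float = 0.1
    degradation_dispersion_multiplier: float = 4.0
    seed: int = 0


@dataclass
class PreprocessConfig:
    cpm_threshold: float = 1.0
    min_samples: int = 3
    prior_count: float = 0.5


@dataclass
class FitConfig:
    max_iter: int = 50
    tol: float = 1e-8


@dataclass
class BenchmarkConfig:
    comparisons: list = field(
        default_factory=lambda: [[1.0, 0.0], [0.75, 0.25], [0.5, 0.25], [0.75, 0.5]]
    )
    anchor: list = field(default_factory=lambda: [1.0, 0.0])
    fdr_cutoff: float = 0.05


@dataclass
class DeconvolutionConfig:
    fc_hi: float = 2.0
    fc_lo: float = 0.5


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    counts: str | None = None
    design: str | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    deconvolution: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        blocks = {
            "simulation": SimulationConfig,
            "preprocessing": PreprocessConfig,
            "fit": FitConfig,
            "benchmark": BenchmarkConfig,
            "deconvolution": DeconvolutionConfig,
        }
        known = set(blocks) | {"counts", "design"}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {"counts": raw.get("counts"), "design": raw.get("design")}
        for key, cfg_cls in blocks.items():
            sub = raw.get(key, {})
            valid = {f.name for f in cfg_cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
            bad = set(sub) - valid
            if bad:
                raise ParameterError(f"unknown keys in config block {key!r}: {sorted(bad)}")
            kwargs[key] = cfg_cls(**sub)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute every stage and return the manifest (also written to disk).

    Stages: simulate (or load counts/design) -> expression filter -> TMM +
    log-CPM -> mixture fit (full, degraded-substituted and leave-out) ->
    reference DE per comparison -> benchmark metrics -> deconvolution.
    Any stage failure aborts with the stage name; outputs written so far are
    preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            "counts": config.counts,
            "design": config.design,
            "simulation": asdict(config.simulation),
            "preprocessing": asdict(config.preprocessing),
            "fit": asdict(config.fit),
            "benchmark": asdict(config.benchmark),
            "deconvolution": asdict(config.deconvolution),
        },
        "stages": [],
        "outputs": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s: %s", stage, info)

    def save(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["outputs"][name] = _sha256(path)
        return path

    stage = "simulate"
    try:
        sim = config.simulation
        if config.counts and config.design:
            counts = CountMatrix.from_tsv(config.counts)
            design = MixtureDesign.from_tsv(config.design)
            ref = None
            record(stage, source="loaded", n_genes=counts.n_genes, n_samples=counts.n_samples)
        else:
            ref = simulate_reference_profiles(
                sim.n_genes,
                sim.de_fraction,
                sim.lfc_sd,
                abundance_meanlog=sim.abundance_meanlog,
                abundance_sdlog=sim.abundance_sdlog,
                de_lfc_threshold=sim.de_lfc_threshold,
                dispersion_mean=sim.dispersion_mean,
                dispersion_prior_df=sim.dispersion_prior_df,
                seed=sim.seed,
            )
            design = make_default_design(sim.n_replicates, sim.degraded_replicate)
            counts = simulate_mixture_counts(
                ref,
                design,
                lib_size_mean=sim.lib_size_mean,
                lib_size_cv=sim.lib_size_cv,
                degradation_dispersion_multiplier=sim.degradation_dispersion_multiplier,
                seed=sim.seed,
            )
            save("truth.tsv", ref.to_tsv)
            record(stage, source="simulated", n_genes=counts.n_genes,
                   n_samples=counts.n_samples, seed=sim.seed)
        save("counts.tsv", counts.to_tsv)
        save("design.tsv", design.to_tsv)

        stage = "normalize"
        pre = config.preprocessing
        good_design = design.good_only()
        good_counts = counts.subset_samples(good_design.sample_ids)
        kept = filter_by_expression(good_counts, pre.cpm_threshold, pre.min_samples)
        factors = tmm_factors(kept)
        expr = log_cpm(kept, factors, pre.prior_count)
        save("tmm_factors.tsv",
             lambda p: factors.rename_axis("sample_id").to_csv(p, sep="\t"))
        save("logcpm.tsv", lambda p: expr.logcpm.rename_axis("gene_id").to_csv(p, sep="\t"))
        record(stage, genes_in=good_counts.n_genes, genes_kept=kept.n_genes,
               cpm_filter="raw library sizes, no prior count")

        stage = "fit"
        fit = MixtureModel.from_normalized(expr, good_design).fit(
            max_iter=config.fit.max_iter, tol=config.fit.tol
        )
        save("mixture_fit.tsv", fit.to_tsv)
        record(stage, converged=int(fit.converged.sum()), genes=len(fit.gene_ids))

        stage = "benchmark"
        bm = config.benchmark
        report = run_benchmark(
            counts,
            design,
            comparisons=[tuple(c) for c in bm.comparisons],
            fdr_cutoff=bm.fdr_cutoff,
            anchor=tuple(bm.anchor),
            cpm_threshold=pre.cpm_threshold,
            min_samples=pre.min_samples,
        )
        save("benchmark_metrics.tsv",
             lambda p: report.metrics.to_csv(p, sep="\t", index=False))
        save("benchmark_report.json",
             lambda p: Path(p).write_text(json.dumps(report.to_json_dict(), indent=2)))
        record(stage, comparisons=len(bm.comparisons), fdr_cutoff=bm.fdr_cutoff)

        stage = "deconvolve"
        dc = config.deconvolution
        cpm = counts.cpm()
        pure_T = good_design.group(1.0)
        pure_N = good_design.group(0.0)
        ref_T = cpm[pure_T].mean(axis=1)
        ref_N = cpm[pure_N].mean(axis=1)
        mask = informative_gene_filter(ref_N, ref_T, dc.fc_hi, dc.fc_lo)
        mixed_ids, truths = [], []
        for p in sorted({round(float(x), 4) for x in good_design.proportions} - {0.0, 1.0}, reverse=True):
            for sid in good_design.group(p):
                mixed_ids.append(sid)
                truths.append(p)
        results = [deconvolve_sample(sid, cpm[sid], ref_N, ref_T, mask) for sid in mixed_ids]
        table = evaluate_deconvolution(results, truths, ref_T)
        save("deconvolution.tsv", lambda p: table.to_csv(p, sep="\t"))
        record(stage, informative_genes=int(mask.sum()), mixed_samples=len(mixed_ids))
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
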