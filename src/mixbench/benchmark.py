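"""Benchmark metrics over pairs of mixture comparisons.

A mixture design has no per-gene true positives known a priori, but the same
genes must differ between any two distinct mixture proportions, so methods
can be scored against themselves: *sensitivity* is the number of genes called
significant in a comparison; *recovery* is the fraction of the anchor
comparison's (pure vs pure) significant genes that a subtler comparison also
calls; *inconsistency* is the fraction of the subtler comparison's calls
absent from the anchor's.  RMSE scores each method's log-FCs against the
mixture model's leave-out predictions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .datatypes import CountMatrix, MixtureDesign, ParameterError
from .de import DEResult, moderated_two_group_test
from .mixture import leave_out_fit, rmse_logfc
from .preprocess import NormalizedExpression, normalize

logger = logging.getLogger(__name__)

#: a DE method: (expr, group1_ids, group2_ids) -> DEResult
DEMethod = Callable[[NormalizedExpression, Sequence[str], Sequence[str]], DEResult]


def sensitivity(result: DEResult, fdr_cutoff: float = 0.05) -> int:
    """Number of genes with FDR strictly below the cutoff."""
    return int((result.table["fdr"] < fdr_cutoff).sum())


def _shared_sets(
    a: DEResult, b: DEResult, fdr_cutoff: float
) -> tuple[set[str], set[str]]:
    universe = set(a.gene_ids.astype(str)) & set(b.gene_ids.astype(str))
    dropped = len(set(a.gene_ids.astype(str)) | set(b.gene_ids.astype(str))) - len(universe)
    if dropped:
        logger.info("benchmark: %d genes outside the shared universe dropped", dropped)
    return (
        a.significant_set(fdr_cutoff) & universe,
        b.significant_set(fdr_cutoff) & universe,
    )


def recovery_rate(
    anchor: DEResult, subtle: DEResult, fdr_cutoff: float = 0.05
) -> float | None:
    """Fraction of the anchor's significant genes also significant in ``subtle``.

    Undefined (None) when the anchor has no significant genes.
    """
    s_anchor, s_subtle = _shared_sets(anchor, subtle, fdr_cutoff)
    if not s_anchor:
        logger.warning("recovery undefined: anchor has no significant genes")
        return None
    return len(s_anchor & s_subtle) / len(s_anchor)


def inconsistency_rate(
    anchor: DEResult, subtle: DEResult, fdr_cutoff: float = 0.05
) -> float | None:
    """Fraction of the subtle comparison's significant genes missing from the anchor.

    Undefined (None) when the subtle comparison has no significant genes,
    matching the convention of excluding comparisons with no discoveries.
    """
    s_anchor, s_subtle = _shared_sets(anchor, subtle, fdr_cutoff)
    if not s_subtle:
        logger.warning("inconsistency undefined: subtle comparison has no significant genes")
        return None
    return len(s_subtle - s_anchor) / len(s_subtle)


def overlap_sets(
    results: Sequence[DEResult], fdr_cutoff: float = 0.05
) -> dict[tuple[bool, ...], int]:
    """Venn-region membership counts of the significant sets.

    Keys are inclusion patterns (one boolean per result, at least one True);
    values are the number of genes significant in exactly that subset of
    methods.  Region counts sum to the size of the union.
    """
    if not 2 <= len(results) <= 5:
        raise ParameterError("overlap_sets supports 2 to 5 result sets")
    universe = set(results[0].gene_ids.astype(str))
    for r in results[1:]:
        universe &= set(r.gene_ids.astype(str))
    sets = [r.significant_set(fdr_cutoff) & universe for r in results]
    regions: dict[tuple[bool, ...], int] = {}
    for pattern in itertools.product([True, False], repeat=len(sets)):
        if not any(pattern):
            continue
        members = universe
        for s, inside in zip(sets, pattern):
            members = members & s if inside else members - s
        regions[pattern] = len(members)
    return regions


@dataclass
class BenchmarkReport:
    """Collected benchmark metrics.

    ``metrics`` rows: method, comparison, sensitivity, recovery,
    inconsistency, rmse, rmse_genes, n_excluded.  ``overlaps`` maps a
    comparison label to Venn-region counts across methods.
    """

    metrics: pd.DataFrame
    overlaps: dict[str, dict[tuple[bool, ...], int]] = field(default_factory=dict)
    fdr_cutoff: float = 0.05
    anchor: str = ""
    n_genes: int = 0

    def to_json_dict(self) -> dict:
        return {
            "fdr_cutoff": self.fdr_cutoff,
            "anchor": self.anchor,
            "n_genes": self.n_genes,
            "metrics": self.metrics.to_dict(orient="records"),
            "overlaps": {
                comp: {"".join("1" if b else "0" for b in k): v for k, v in regions.items()}
                for comp, regions in self.overlaps.items()
            },
        }


def comparison_label(p: float, q: float) -> str:
    return f"{int(round(p * 100)):03d}v{int(round(q * 100)):03d}"


def run_benchmark(
    counts: CountMatrix,
    design: MixtureDesign,
    comparisons: Sequence[tuple[float, float]] = ((1.0, 0.0), (0.75, 0.25), (0.5, 0.25), (0.75, 0.5)),
    methods: Mapping[str, DEMethod] | None = None,
    fdr_cutoff: float = 0.05,
    anchor: tuple[float, float] = (1.0, 0.0),
    cpm_threshold: float = 1.0,
    min_samples: int = 3,
    good_only: bool = True,
    compute_rmse: bool = True,
) -> BenchmarkReport:
    """Run DE methods over the listed comparisons and score them.

    Each comparison is a pair of mixing proportions (p, q); its two groups are
    the (good) samples at those proportions.  For every method the report
    carries sensitivity, recovery and inconsistency against the anchor
    comparison (default pure vs pure, the comparison expected to yield the
    most discoveries), and the RMSE of the method's log-FCs against the
    mixture model's predictions fitted with the compared samples left out.
    """
    if methods is None:
        methods = {"moderated-t": lambda e, g1, g2: moderated_two_group_test(e, g1, g2)}
    work_design = design.good_only() if good_only else design
    work_counts = counts.subset_samples(work_design.sample_ids)
    expr = normalize(work_counts, cpm_threshold, min_samples)
    logger.info(
        "benchmark: %d/%d genes retained after CPM > %g in >= %d samples",
        expr.logcpm.shape[0], counts.n_genes, cpm_threshold, min_samples,
    )

    if anchor not in [tuple(c) for c in comparisons]:
        comparisons = [tuple(anchor)] + [tuple(c) for c in comparisons]

    results: dict[tuple[str, str], DEResult] = {}
    rows = []
    for method_name, method in methods.items():
        for p, q in comparisons:
            label = comparison_label(p, q)
            g1 = work_design.group(p)
            g2 = work_design.group(q)
            if len(g1) < 2 or len(g2) < 2:
                logger.warning("comparison %s: missing samples, skipped", label)
                continue
            try:
                res = method(expr, g1, g2)
            except Exception as exc:  # a failed method is recorded, not fatal
                logger.warning("method %s failed on %s: %s", method_name, label, exc)
                continue
            results[(method_name, label)] = res
            rmse = n_excl = rmse_genes = None
            if compute_rmse:
                lo_fit = leave_out_fit(expr, work_design, (g1, g2))
                pred = lo_fit.predicted_logfc(p, q)
                rmse, n_excl = rmse_logfc(res.table["logFC"], pred)
                rmse_genes = len(pred.delta.dropna())
            rows.append(
                {
                    "method": method_name,
                    "comparison": label,
                    "sensitivity": sensitivity(res, fdr_cutoff),
                    "rmse": rmse,
                    "rmse_excluded": n_excl,
                }
            )

    anchor_label = comparison_label(*anchor)
    for row in rows:
        key = (row["method"], anchor_label)
        anc = results.get(key)
        res = results.get((row["method"], row["comparison"]))
        if anc is None or res is None or row["comparison"] == anchor_label:
            row["recovery"] = 1.0 if row["comparison"] == anchor_label else None
            row["inconsistency"] = 0.0 if row["comparison"] == anchor_label else None
            continue
        row["recovery"] = recovery_rate(anc, res, fdr_cutoff)
        row["inconsistency"] = inconsistency_rate(anc, res, fdr_cutoff)

    overlaps = {}
    if len(methods) >= 2:
        for _, label in {(None, comparison_label(p, q)) for p, q in comparisons}:
            rs = [results[(m, label)] for m in methods if (m, label) in results]
            if 2 <= len(rs) <= 5:
                overlaps[label] = overlap_sets(rs, fdr_cutoff)

    metrics = pd.DataFrame(rows)
    return BenchmarkReport(
        metrics=metrics,
        overlaps=overlaps,
        fdr_cutoff=fdr_cutoff,
        anchor=anchor_label,
        n_genes=expr.logcpm.shape[0],
    )
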