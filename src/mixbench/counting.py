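"""Assignment of 5'-reduced read positions to exon/intron/intergenic features.

Each aligned read is reduced to the genomic position of its first transcribed
base — the leftmost coordinate on the plus strand, the rightmost (end - 1) on
the minus strand — and assigned to the single annotation interval covering
that position.  The annotation must partition the classes without overlap, so
every read lands in exactly one feature or is counted as unassigned.
Coordinates are BED-style: 0-based, half-open.

Also provides the conservative derived counts used for gene-level intron and
intergenic signal: reads overlapping both an exon and an intron count only
toward the exon (intron = gene body - exon counts), and reads overlapping a
gene and its preceding intergenic region count only toward the gene
(intergenic = amalgamated region - gene body counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import ParameterError

FEATURE_CLASSES = ("exon", "intron", "intergenic")


class AnnotationError(ValueError):
    """The annotation violates the non-overlap requirement."""


@dataclass
class GenomicAnnotation:
    """Non-overlapping classified intervals.

    ``intervals`` columns: chrom, start, end (0-based half-open),
    feature_class (exon/intron/intergenic), name (gene or region id), strand.
    """

    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "feature_class", "name", "strand"}
        missing = required - set(self.intervals.columns)
        if missing:
            raise ParameterError(f"annotation missing columns: {sorted(missing)}")
        bad = self.intervals["start"] >= self.intervals["end"]
        if bad.any():
            row = self.intervals[bad].iloc[0]
            raise ParameterError(f"interval with start >= end: {row['chrom']}:{row['start']}-{row['end']}")
        unknown = ~self.intervals["feature_class"].isin(FEATURE_CLASSES)
        if unknown.any():
            raise ParameterError(
                f"unknown feature class {self.intervals.loc[unknown, 'feature_class'].iloc[0]!r}"
            )
        self._validate_non_overlap()
        self._index = {
            chrom: grp.sort_values("start").reset_index(drop=True)
            for chrom, grp in self.intervals.groupby("chrom", sort=False)
        }

    def _validate_non_overlap(self) -> None:
        for chrom, grp in self.intervals.groupby("chrom", sort=False):
            srt = grp.sort_values("start")
            starts = srt["start"].to_numpy()
            ends = srt["end"].to_numpy()
            clash = np.flatnonzero(starts[1:] < ends[:-1])
            if clash.size:
                i = clash[0]
                a = srt.iloc[i]
                b = srt.iloc[i + 1]
                raise AnnotationError(
                    f"overlapping intervals on {chrom}: "
                    f"{a['name']} [{a['start']},{a['end']}) and {b['name']} [{b['start']},{b['end']})"
                )

    @classmethod
    def from_bed(cls, path, feature_class_from: str = "name") -> "GenomicAnnotation":
        """Read BED6; the feature class is parsed from the name field.

        Names of the form ``<id>:<class>`` (e.g. ``GENE1:exon``) carry the
        class; a bare name whose value is a class is taken as the class
        itself.
        """
        df = read_bed6(path)
        classes, names = [], []
        for name in df["name"]:
            if ":" in name:
                base, cls_ = name.rsplit(":", 1)
            elif name in FEATURE_CLASSES:
                base, cls_ = name, name
            else:
                raise ParameterError(
                    f"cannot parse feature class from BED name {name!r}; use '<id>:<class>'"
                )
            names.append(base)
            classes.append(cls_)
        df = df.assign(name=names, feature_class=classes)
        return cls(df[["chrom", "start", "end", "feature_class", "name", "strand"]])


@dataclass
class ReadPositions:
    """Aligned read coordinates: chrom, start, end (0-based half-open), strand."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand"}
        missing = required - set(self.records.columns)
        if missing:
            raise ParameterError(f"reads missing columns: {sorted(missing)}")
        if (self.records["start"] >= self.records["end"]).any():
            raise ParameterError("read with start >= end")
        if not self.records["strand"].isin(["+", "-"]).all():
            raise ParameterError("read strand must be '+' or '-'")

    @property
    def five_prime(self) -> np.ndarray:
        """5' position per read: start on '+', end - 1 on '-'."""
        plus = (self.records["strand"] == "+").to_numpy()
        return np.where(
            plus, self.records["start"].to_numpy(), self.records["end"].to_numpy() - 1
        )

    @classmethod
    def from_bed(cls, path) -> "ReadPositions":
        df = read_bed6(path)
        return cls(df[["chrom", "start", "end", "strand"]])


def read_bed6(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str, "strand": str},
    )
    return df


def assign_reads_5prime(
    reads: ReadPositions, annotation: GenomicAnnotation
) -> tuple[pd.Series, pd.Series]:
    """Count reads per feature by the 5' position rule.

    Returns ``(per_feature, per_class)``: counts indexed by feature name and
    by class (exon / intron / intergenic / unassigned).  Every read
    contributes exactly once, so the class counts sum to the number of reads.
    """
    feat_counts: dict[str, int] = {
        name: 0 for name in annotation.intervals["name"].unique()
    }
    class_counts = {c: 0 for c in FEATURE_CLASSES}
    class_counts["unassigned"] = 0

    pos5 = reads.five_prime
    chroms = reads.records["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        mask = chroms == chrom
        positions = pos5[mask]
        grp = annotation._index.get(chrom)
        if grp is None:
            class_counts["unassigned"] += int(mask.sum())
            continue
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        names = grp["name"].to_numpy()
        classes = grp["feature_class"].to_numpy()
        # rightmost interval starting at or before the position
        idx = np.searchsorted(starts, positions, side="right") - 1
        hit = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        for j, ok in zip(idx, hit):
            if ok:
                feat_counts[names[j]] += 1
                class_counts[classes[j]] += 1
            else:
                class_counts["unassigned"] += 1

    per_feature = pd.Series(feat_counts, name="count").sort_index()
    per_class = pd.Series(class_counts, name="count")
    return per_feature, per_class


def conservative_intron_counts(
    gene_body_counts: pd.Series, exon_counts: pd.Series
) -> pd.Series:
    """Gene-level intron counts as gene-body minus exon counts.

    Reads overlapping both an intron and an exon are assigned to the exon, so
    the difference counts only reads wholly attributable to intronic signal.
    """
    body = pd.Series(gene_body_counts).astype(np.int64)
    exon = pd.Series(exon_counts).astype(np.int64)
    if set(body.index) != set(exon.index):
        raise ParameterError("gene universes of body and exon counts differ")
    exon = exon.loc[body.index]
    bad = exon > body
    if bad.any():
        raise ParameterError(
            f"exon count exceeds gene-body count for gene {body.index[bad][0]!r}"
        )
    return (body - exon).rename("intron_count")


def conservative_intergenic_counts(
    amalgamated_counts: pd.Series,
    gene_body_counts: pd.Series,
    region_to_gene: Mapping[str, str],
) -> pd.Series:
    """Intergenic counts as amalgamated-region minus mapped gene-body counts.

    Each amalgamated region spans a gene body plus the intergenic region
    preceding it; subtracting the gene-body count leaves a conservative
    estimate of reads in the intergenic stretch alone.
    """
    amal = pd.Series(amalgamated_counts).astype(np.int64)
    body = pd.Series(gene_body_counts).astype(np.int64)
    out = {}
    for region, count in amal.items():
        gene = region_to_gene.get(region)
        if gene is None or gene not in body.index:
            raise ParameterError(f"region {region!r} is not mapped to a known gene")
        diff = int(count) - int(body[gene])
        if diff < 0:
            raise ParameterError(
                f"region {region!r}: amalgamated count {count} below gene-body count {body[gene]}"
            )
        out[region] = diff
    return pd.Series(out, name="intergenic_count").sort_index()
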