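"""Known-miRNA quantification, expression filtering, inheritance analysis
and miR/miR* arm-usage ratios.

Counting rule: a read is assigned to (family, mature) when any of its hits
lies on the same strand as an annotated mature miRNA and its 5' end falls
within ``shift_tolerance`` nt of the annotated 5' end (likewise for star
strands).  A multi-mapped read counts once per family, not once per locus,
so paralog-rich families are not inflated; per-MIR-gene counts are reported
separately for arm-usage analysis.

Expression filter: a family is called expressed when it is detected (count
> 0) in at least ``min_libraries`` of the libraries AND its summed count
reaches ``min_total``.  Normalisation for fold-change analysis is reads per
million perfect-match reads of the library; a zero parental count yields an
explicit "undetected_in_one" call rather than an infinite ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import AnnotationFeature
from .mapping import AlignedRead

__all__ = [
    "ExpressionFilter",
    "FoldChangeRecord",
    "StarRatioRecord",
    "count_families",
    "gene_counts",
    "is_expressed",
    "expressed_families",
    "abundance",
    "fold_change_analysis",
    "star_ratio_analysis",
]


@dataclass
class ExpressionFilter:
    min_libraries: int = 3
    min_total: int = 10
    n_libraries: int = 5

    def __post_init__(self):
        if not (1 <= self.min_libraries <= self.n_libraries):
            raise ValueError("need 1 <= min_libraries <= n_libraries")


@dataclass
class FoldChangeRecord:
    family: str
    rpm: dict[str, float]  # normalized abundance per library (reads/million)
    parental_ratio: float | None  # P1 / P2
    bulk_ratio: float | None  # bulk1 / bulk2
    call: str  # inherited_high_P1 | inherited_high_P2 | not_inherited | undetected_in_one


@dataclass
class StarRatioRecord:
    name: str  # family or MIR gene
    library: str
    mature: int
    star: int
    ratio: float | None  # mature/star, None when star == 0
    arm_switch: bool  # star >= mature

    def __post_init__(self):
        if self.mature < 0 or self.star < 0:
            raise ValueError("negative counts")


def _strand_features(
    annotations: list[AnnotationFeature],
) -> list[tuple[AnnotationFeature, str]]:
    out = []
    for f in annotations:
        if f.kind in ("MIR_mature", "MIR_star"):
            if not f.family:
                raise ValueError(f"MIR feature {f.name!r} lacks a family label")
            out.append((f, "mature" if f.kind == "MIR_mature" else "star"))
    return out


def _read_assignments(
    read: AlignedRead,
    by_chrom: dict[str, list[tuple[AnnotationFeature, str]]],
    shift_tolerance: int,
) -> set[tuple[str, str, str]]:
    """(family, strand, gene name) labels a mapped read picks up via its hits."""
    labels: set[tuple[str, str, str]] = set()
    for h in read.hits:
        for f, strand_kind in by_chrom.get(h.chrom, ()):
            if f.strand != h.strand:
                continue
            if not f.overlaps(h.chrom, h.start, h.end):
                continue
            five_prime_hit = h.start if h.strand == "+" else h.end
            five_prime_feat = f.start if f.strand == "+" else f.end
            if abs(five_prime_hit - five_prime_feat) <= shift_tolerance:
                labels.add((f.family, strand_kind, f.name))
    return labels


def count_families(
    aligned: dict[str, list[AlignedRead]],
    annotations: list[AnnotationFeature],
    shift_tolerance: int = 2,
) -> pd.DataFrame:
    """Family x strand count matrix with one column per library.

    ``aligned`` maps library label -> aligned reads.  Every annotated family
    appears in the matrix even at zero counts.  The 5'-shift tolerance lets
    reads longer than the annotated mature (e.g. a 22-nt species over a
    20-nt annotation) still count.
    """
    feats = _strand_features(annotations)
    by_chrom: dict[str, list[tuple[AnnotationFeature, str]]] = {}
    for f, sk in feats:
        by_chrom.setdefault(f.chrom, []).append((f, sk))
    families = sorted({f.family for f, _ in feats})
    libs = list(aligned)
    index = pd.MultiIndex.from_product(
        [families, ["mature", "star"]], names=["family", "strand"]
    )
    mat = pd.DataFrame(0, index=index, columns=libs)
    for lib, reads in aligned.items():
        for a in reads:
            if not a.mapped:
                continue
            labels = _read_assignments(a, by_chrom, shift_tolerance)
            # once per (family, strand) even when several members are hit
            for fam, strand in {(f, s) for f, s, _ in labels}:
                mat.loc[(fam, strand), lib] += 1
    return mat


def gene_counts(
    aligned: dict[str, list[AlignedRead]],
    annotations: list[AnnotationFeature],
    shift_tolerance: int = 2,
) -> pd.DataFrame:
    """Per-MIR-gene counts (finer granularity than families), long format."""
    feats = _strand_features(annotations)
    by_chrom: dict[str, list[tuple[AnnotationFeature, str]]] = {}
    for f, sk in feats:
        by_chrom.setdefault(f.chrom, []).append((f, sk))
    rows: dict[tuple[str, str, str, str], int] = {}
    for lib, reads in aligned.items():
        for a in reads:
            if not a.mapped:
                continue
            for fam, strand, gene in _read_assignments(a, by_chrom, shift_tolerance):
                key = (fam, gene, strand, lib)
                rows[key] = rows.get(key, 0) + 1
    df = pd.DataFrame(
        [dict(family=f, gene=g, strand=s, library=l, count=c) for (f, g, s, l), c in rows.items()]
    )
    if df.empty:
        df = pd.DataFrame(columns=["family", "gene", "strand", "library", "count"])
    return df.sort_values(["family", "gene", "strand", "library"]).reset_index(drop=True)


def is_expressed(counts, expr_filter: ExpressionFilter = ExpressionFilter()) -> bool:
    """Expression call for one family row of per-library counts."""
    counts = np.asarray(counts)
    if counts.size != expr_filter.n_libraries:
        raise ValueError(
            f"expected {expr_filter.n_libraries} library counts, got {counts.size}"
        )
    return (
        int((counts > 0).sum()) >= expr_filter.min_libraries
        and int(counts.sum()) >= expr_filter.min_total
    )


def expressed_families(
    matrix: pd.DataFrame, expr_filter: ExpressionFilter = ExpressionFilter()
) -> list[str]:
    """Families passing the filter on their summed mature+star counts."""
    fam_totals = matrix.groupby(level="family").sum()
    return sorted(
        fam for fam, row in fam_totals.iterrows() if is_expressed(row.values, expr_filter)
    )


def abundance(matrix: pd.DataFrame, library_totals: dict[str, int]) -> pd.DataFrame:
    """Per-family, per-library fraction of the library's perfect matches."""
    out = matrix.astype(float).copy()
    for lib in out.columns:
        total = library_totals[lib]
        if total <= 0:
            raise ValueError(f"library {lib!r} has no perfect-match reads")
        out[lib] = out[lib] / total
    return out


def _ratio(a: float, b: float) -> float:
    if b == 0:
        return float("inf") if a > 0 else float("nan")
    return a / b


def fold_change_analysis(
    matrix: pd.DataFrame,
    library_totals: dict[str, int],
    parent1: str,
    parent2: str,
    bulk1: str,
    bulk2: str,
    cutoff: float = 2.0,
) -> list[FoldChangeRecord]:
    """Inheritance calls from parental and bulk fold changes.

    Family-level read counts (mature + star summed, as in the family
    count table) are normalised per library.  inherited_high_P1: both
    normalized ratios >= cutoff; inherited_high_P2: both <= 1/cutoff; a
    family undetected in either parent is excluded from calls (mirroring
    how families absent from one parental library are left out of
    fold-change plots).  Summing both strands keeps the call about
    transcriptional output: an arm-usage switch alone does not fake a
    fold change in family expression.
    """
    if cutoff <= 1:
        raise ValueError("cutoff must exceed 1")
    records = []
    fam_totals = matrix.groupby(level="family").sum()
    for family, row in fam_totals.iterrows():
        rpm = {
            lib: 1e6 * row[lib] / library_totals[lib]
            for lib in (parent1, parent2, bulk1, bulk2)
        }
        if row[parent1] == 0 or row[parent2] == 0:
            records.append(FoldChangeRecord(family, rpm, None, None, "undetected_in_one"))
            continue
        pr = _ratio(rpm[parent1], rpm[parent2])
        br = _ratio(rpm[bulk1], rpm[bulk2])
        if pr >= cutoff and br >= cutoff:
            call = "inherited_high_P1"
        elif pr <= 1 / cutoff and br <= 1 / cutoff:
            call = "inherited_high_P2"
        else:
            call = "not_inherited"
        records.append(FoldChangeRecord(family, rpm, pr, br, call))
    records.sort(key=lambda r: r.family)
    return records


def star_ratio_analysis(matrix: pd.DataFrame) -> list[StarRatioRecord]:
    """Per-library mature:star ratios with arm-switch flags.

    The ratio is undefined (None) when no star reads were seen; the
    arm-switch flag marks libraries where the star strand is at least as
    abundant as the mature strand.
    """
    records = []
    for family in matrix.index.get_level_values("family").unique():
        for lib in matrix.columns:
            m = int(matrix.loc[(family, "mature"), lib])
            s = int(matrix.loc[(family, "star"), lib])
            ratio = m / s if s > 0 else None
            records.append(StarRatioRecord(family, lib, m, s, ratio, s >= m))
    records.sort(key=lambda r: (r.name, r.library))
    return records
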