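"""Size distributions, genomic-element attribution, repeat filtering and
25-nt hotspot detection.

Element attribution is read-centric: each mapped read is assigned exactly
one element kind, the highest-priority feature kind overlapped by any of its
hits (default priority MIR > rRNA > tRNA > repeat > exon > intron > gene >
other).  Hotspot detection is locus-centric: every reported hit of every
25-nt read contributes coverage, and a hotspot is a maximal run of bases
each covered by strictly more than ``min_coverage`` reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_formats import AnnotationFeature
from .library_stats import ReadCluster
from .mapping import AlignedRead

__all__ = [
    "DEFAULT_PRIORITY",
    "HotspotConfig",
    "HotspotInterval",
    "size_distribution",
    "attribute_elements",
    "filter_repeats",
    "coverage_arrays",
    "detect_hotspots",
    "hotspot_table",
]

DEFAULT_PRIORITY = (
    "MIR",
    "rRNA",
    "tRNA",
    "repeat",
    "exon",
    "intron",
    "gene",
    "other",
)

# annotation kinds folded into the "MIR" attribution class
_MIR_KINDS = {"MIR_hairpin", "MIR_mature", "MIR_star"}


@dataclass
class HotspotConfig:
    target_length: int = 25
    min_coverage: int = 1000  # strict: a base needs MORE than this many reads
    merge_gap: int = 0

    def __post_init__(self):
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


@dataclass
class HotspotInterval:
    chrom: str
    start: int
    end: int
    peak_coverage: int
    mean_coverage: float
    annotated: bool = False  # overlaps an rRNA/tRNA feature in the GFF3

    @property
    def length(self) -> int:
        return self.end - self.start


def size_distribution(aligned: list[AlignedRead]) -> pd.DataFrame:
    """Read-length histogram (18..25 nt) with per-length fractions."""
    counts = {length: 0 for length in range(18, 26)}
    total = 0
    for a in aligned:
        if a.mapped:
            counts[a.inferred_length] += 1
            total += 1
    return pd.DataFrame(
        {
            "length": list(counts),
            "count": list(counts.values()),
            "fraction": [c / total if total else 0.0 for c in counts.values()],
        }
    )


def _feature_trees(features: list[AnnotationFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    return trees


def _attribution_class(kind: str) -> str:
    return "MIR" if kind in _MIR_KINDS else kind


def attribute_elements(
    aligned: list[AlignedRead],
    features: list[AnnotationFeature],
    priority: tuple[str, ...] = DEFAULT_PRIORITY,
) -> pd.DataFrame:
    """Assign each mapped read to one element kind, by priority across hits.

    Returns a table kind -> count whose counts sum to the number of mapped
    reads ("other" collects reads overlapping nothing, i.e. intergenic).
    """
    rank = {kind: i for i, kind in enumerate(priority)}
    if "other" not in rank:
        raise ValueError("priority list must contain 'other'")
    for kind in ("MIR", "rRNA", "tRNA", "repeat"):
        if kind not in rank:
            raise ValueError(f"priority list missing required kind {kind!r}")
    trees = _feature_trees(features)
    counts = {kind: 0 for kind in priority}
    other_rank = rank["other"]
    for a in aligned:
        if not a.mapped:
            continue
        best = other_rank
        for h in a.hits:
            tree = trees.get(h.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(h.start, h.end):
                r = rank.get(_attribution_class(iv.data.kind))
                if r is not None and r < best:
                    best = r
        counts[priority[best]] += 1
    return pd.DataFrame({"kind": list(counts), "count": list(counts.values())})


def filter_repeats(
    clusters: list[ReadCluster], features: list[AnnotationFeature]
) -> tuple[list[ReadCluster], list[ReadCluster]]:
    """Split clusters into (kept, removed): removed iff ANY hit overlaps a
    repeat feature.  The kept set feeds de novo miRNA calling."""
    trees = _feature_trees([f for f in features if f.kind == "repeat"])
    kept, removed = [], []
    for c in clusters:
        hit_repeat = any(
            trees.get(h.chrom) is not None and trees[h.chrom].overlaps(h.start, h.end)
            for h in c.hits
        )
        (removed if hit_repeat else kept).append(c)
    return kept, removed


def coverage_arrays(
    aligned: list[AlignedRead],
    chrom_lengths: dict[str, int],
    target_length: int = 25,
) -> dict[str, np.ndarray]:
    """Per-base coverage by reads of exactly ``target_length`` nt.

    Multi-mapped reads contribute at every reported hit (coverage is
    locus-centric).
    """
    cov = {c: np.zeros(n + 1, dtype=np.int64) for c, n in chrom_lengths.items()}
    for a in aligned:
        if a.inferred_length != target_length:
            continue
        for h in a.hits:
            d = cov[h.chrom]
            d[h.start] += 1
            d[h.end] -= 1
    return {c: np.cumsum(d[:-1]) for c, d in cov.items()}


def detect_hotspots(
    coverage: dict[str, np.ndarray],
    config: HotspotConfig = HotspotConfig(),
    annotations: list[AnnotationFeature] | None = None,
) -> list[HotspotInterval]:
    """Maximal runs of consecutive bases with coverage > min_coverage.

    Each hotspot is labelled annotated/unannotated by overlap with rRNA/tRNA
    features of the supplied annotation set (hotspots over loci missing from
    the annotation are exactly the interesting ones).
    """
    rna_trees = _feature_trees(
        [f for f in (annotations or []) if f.kind in ("rRNA", "tRNA")]
    )
    out: list[HotspotInterval] = []
    for chrom in sorted(coverage):
        cov = coverage[chrom]
        above = cov > config.min_coverage
        if not above.any():
            continue
        # segment boundaries of the boolean mask
        edges = np.flatnonzero(np.diff(above.astype(np.int8)))
        bounds = np.concatenate([[0], edges + 1, [len(above)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            if not above[lo]:
                continue
            seg = cov[lo:hi]
            tree = rna_trees.get(chrom)
            annotated = bool(tree and tree.overlaps(int(lo), int(hi)))
            out.append(
                HotspotInterval(
                    chrom,
                    int(lo),
                    int(hi),
                    int(seg.max()),
                    float(seg.mean()),
                    annotated,
                )
            )
    return out


def hotspot_table(hotspots: list[HotspotInterval]) -> pd.DataFrame:
    """BED-compatible hotspot table (chrom/start/end/name/score + extras)."""
    rows = [
        dict(
            chrom=h.chrom,
            start=h.start,
            end=h.end,
            name=f"hotspot_{i + 1}",
            score=h.peak_coverage,
            mean_coverage=round(h.mean_coverage, 2),
            annotated="annotated" if h.annotated else "unannotated",
        )
        for i, h in enumerate(sorted(hotspots, key=lambda h: (h.chrom, h.start)))
    ]
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "mean_coverage", "annotated"],
    )
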