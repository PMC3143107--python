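"""Identical-read clustering and per-library sequencing statistics.

A cluster is two or more reads with identical insert sequences (100%
identity); reads seen once are singlets, and the non-redundant set is the
number of distinct sequences (singlets + clusters).  Statistics follow the
same arithmetic as the published per-library table: the identity
``n_nonredundant = n_singlets + n_clusters`` must always hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .mapping import AlignedRead, AlignmentHit

__all__ = ["ReadCluster", "LibraryStats", "cluster_reads", "compute_stats", "stats_table"]


@dataclass
class ReadCluster:
    """All reads sharing one exact insert sequence.

    Identical inserts necessarily share the same hit list, so the cluster
    carries the hits of its first read.
    """

    sequence: str
    count: int
    libraries: dict[str, int] = field(default_factory=dict)
    hits: list[AlignmentHit] = field(default_factory=list)
    multimapped: bool = False

    def __post_init__(self):
        if self.libraries and self.count != sum(self.libraries.values()):
            raise ValueError("cluster count != sum of per-library counts")


@dataclass
class LibraryStats:
    library: str
    n_raw: int
    n_perfect: int
    n_singlets: int
    n_clusters: int
    n_nonredundant: int

    def __post_init__(self):
        if self.n_nonredundant != self.n_singlets + self.n_clusters:
            raise ValueError(
                f"{self.library}: non-redundant {self.n_nonredundant} != "
                f"singlets {self.n_singlets} + clusters {self.n_clusters}"
            )

    @property
    def pct_perfect(self) -> float:
        return 100.0 * self.n_perfect / self.n_raw if self.n_raw else 0.0

    @property
    def pct_singlets(self) -> float:
        return 100.0 * self.n_singlets / self.n_perfect if self.n_perfect else 0.0

    @property
    def pct_nonredundant(self) -> float:
        return 100.0 * self.n_nonredundant / self.n_perfect if self.n_perfect else 0.0


def cluster_reads(aligned: list[AlignedRead]) -> list[ReadCluster]:
    """Group mapped reads by exact insert sequence.

    Order is deterministic: count descending, then sequence.  Reads from
    several libraries may be pooled; per-library counts are retained.
    """
    groups: dict[str, ReadCluster] = {}
    for a in aligned:
        if not a.mapped:
            continue
        c = groups.get(a.insert)
        if c is None:
            groups[a.insert] = ReadCluster(
                a.insert, 1, {a.library: 1}, a.hits, a.multimapped
            )
        else:
            c.count += 1
            c.libraries[a.library] = c.libraries.get(a.library, 0) + 1
    out = list(groups.values())
    out.sort(key=lambda c: (-c.count, c.sequence))
    return out


def compute_stats(
    library: str, n_raw: int, aligned: list[AlignedRead], clusters: list[ReadCluster]
) -> LibraryStats:
    """Per-library statistics; raises on any internal inconsistency."""
    n_perfect = sum(1 for a in aligned if a.mapped)
    n_singlets = sum(1 for c in clusters if c.count == 1)
    n_multi = sum(1 for c in clusters if c.count >= 2)
    if n_singlets + sum(c.count for c in clusters if c.count >= 2) != n_perfect:
        raise ValueError(f"{library}: cluster counts do not cover perfect matches")
    return LibraryStats(
        library=library,
        n_raw=n_raw,
        n_perfect=n_perfect,
        n_singlets=n_singlets,
        n_clusters=n_multi,
        n_nonredundant=n_singlets + n_multi,
    )


def stats_table(stats: list[LibraryStats]) -> pd.DataFrame:
    """Table with one row per library plus a Total row."""
    rows = []
    for s in stats:
        rows.append(
            dict(
                library=s.library,
                n_raw=s.n_raw,
                n_perfect=s.n_perfect,
                pct_perfect=round(s.pct_perfect),
                n_singlets=s.n_singlets,
                pct_singlets=round(s.pct_singlets),
                n_clusters=s.n_clusters,
                n_nonredundant=s.n_nonredundant,
                pct_nonredundant=round(s.pct_nonredundant),
            )
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        total = df.drop(columns=["library"]).sum()
        tot = LibraryStats(
            "Total",
            int(total["n_raw"]),
            int(total["n_perfect"]),
            int(total["n_singlets"]),
            int(total["n_clusters"]),
            int(total["n_nonredundant"]),
        )
        df.loc[len(df)] = dict(
            library="Total",
            n_raw=tot.n_raw,
            n_perfect=tot.n_perfect,
            pct_perfect=round(tot.pct_perfect),
            n_singlets=tot.n_singlets,
            pct_singlets=round(tot.pct_singlets),
            n_clusters=tot.n_clusters,
            n_nonredundant=tot.n_nonredundant,
            pct_nonredundant=round(tot.pct_nonredundant),
        )
    return df
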