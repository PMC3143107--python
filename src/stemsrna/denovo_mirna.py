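"""Rule-based de novo miRNA calling.

Clusters that survived repeat filtering and do not touch known MIR loci
seed candidate hairpin windows (110 nt, the span of the novel MIR genes in
the reference table).  Each window is folded with a Nussinov
maximum-base-pairing DP (Watson-Crick + G:U, minimum loop 3) and evaluated
against explicit plant miRNA annotation criteria:

* mature and star on opposite arms of one stem-loop;
* the star is the duplex partner predicted with a 2-nt 3' overhang
  (tolerance +/-1) and at most 2 nt of bulge asymmetry;
* at most 4 unpaired mature positions within the duplex;
* a clean read signature: mature + star reads make up >= 90% of the
  window's reads and >= 75% of mature reads share one 5' end.

This deterministic filter stands in for a probabilistic hairpin score: the
criteria themselves are the published annotation standard, so candidates
are reported as pass/fail per criterion rather than ranked by likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import AnnotationFeature, NamedSequence, revcomp
from .library_stats import ReadCluster

__all__ = [
    "PairingStructure",
    "CandidateWindow",
    "HairpinCandidate",
    "DenovoConfig",
    "fold_hairpin",
    "excise_windows",
    "evaluate_candidate",
    "call_denovo",
    "candidate_features",
    "denovo_table",
]

# allowed pairs: Watson-Crick plus G:U wobble (DNA alphabet, T for U)
_PAIRABLE = {
    "A": "T",
    "C": "G",
    "G": "CT",
    "T": "AG",
}
MIN_LOOP = 3  # j - i > 3 for a pair (i, j)


@dataclass
class PairingStructure:
    """A nested (pseudoknot-free) pairing of one sequence."""

    sequence: str
    pairs: list[tuple[int, int]]
    partner: list[int] = field(default_factory=list)  # -1 = unpaired

    def __post_init__(self):
        if not self.partner:
            self.partner = [-1] * len(self.sequence)
            for i, j in self.pairs:
                self.partner[i] = j
                self.partner[j] = i

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def dotbracket(self) -> str:
        s = ["."] * len(self.sequence)
        for i, j in self.pairs:
            s[i], s[j] = "(", ")"
        return "".join(s)


def _can_pair(a: str, b: str) -> bool:
    return b in _PAIRABLE.get(a, "")


def fold_hairpin(seq: str) -> PairingStructure:
    """Maximum base pairing structure (Nussinov DP).

    Deterministic traceback: at each subproblem, pairing the leftmost base
    is preferred when it attains the optimum, with the smallest partner.
    """
    n = len(seq)
    dp = [[0] * n for _ in range(n)]
    # partners[i] = positions k > i+MIN_LOOP that can pair with i
    partners = [
        [k for k in range(i + MIN_LOOP + 1, n) if _can_pair(seq[i], seq[k])]
        for i in range(n)
    ]
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1][j]
            row = dp[i + 1]
            for k in partners[i]:
                if k > j:
                    break
                cand = 1 + (row[k - 1] if k - 1 > i else 0) + (dp[k + 1][j] if k + 1 <= j else 0)
                if cand > best:
                    best = cand
            dp[i][j] = best
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if j - i <= MIN_LOOP:
            continue
        target = dp[i][j]
        chosen = None
        for k in partners[i]:
            if k > j:
                break
            cand = 1 + (dp[i + 1][k - 1] if k - 1 > i else 0) + (dp[k + 1][j] if k + 1 <= j else 0)
            if cand == target:
                chosen = k
                break
        if chosen is None:
            stack.append((i + 1, j))
        else:
            pairs.append((i, chosen))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
    pairs.sort()
    return PairingStructure(seq, pairs)


@dataclass
class DenovoConfig:
    window: int = 110
    flank: int = 20  # distance from window edge to the seeding read
    min_reads: int = 5  # cluster depth needed to seed a window
    locus_merge_gap: int = 50  # clusters closer than this share a locus
    max_unpaired_mature: int = 4
    max_bulge_asymmetry: int = 2
    min_signature: float = 0.9
    min_shared_5p: float = 0.75
    shift_tolerance: int = 2


@dataclass
class CandidateWindow:
    chrom: str
    start: int
    end: int
    strand: str
    locus: str
    seed_cluster: ReadCluster


@dataclass
class HairpinCandidate:
    window: CandidateWindow
    structure: PairingStructure
    mature_seq: str
    mature_local: tuple[int, int]  # half-open, window-local 5'->3'
    mature_arm: str  # '5p' | '3p' | '?'
    star_seq: str | None
    star_local: tuple[int, int] | None
    flags: dict[str, bool]
    signature_fraction: float
    mature_reads: int
    star_reads: int
    total_reads: int

    @property
    def verdict(self) -> bool:
        return all(self.flags.values())


def _cluster_anchor(c: ReadCluster):
    return c.hits[0] if c.hits else None


def excise_windows(
    clusters: list[ReadCluster],
    genome: dict[str, str],
    annotations: list[AnnotationFeature],
    config: DenovoConfig = DenovoConfig(),
) -> list[CandidateWindow]:
    """Candidate 110-nt windows from qualifying read loci.

    Qualifying clusters (depth >= min_reads, no hit on a known MIR locus)
    are merged into loci; per locus the most abundant cluster seeds two
    windows, one placing the read on the 5' arm and one on the 3' arm.
    Windows clipped by a chromosome end are dropped.
    """
    mir = [f for f in annotations if f.kind in ("MIR_hairpin", "MIR_mature", "MIR_star")]
    qualifying = []
    for c in clusters:
        if c.count < config.min_reads or not c.hits:
            continue
        if any(f.overlaps(h.chrom, h.start, h.end) for h in c.hits for f in mir):
            continue
        qualifying.append(c)
    # merge into loci on (chrom, strand) of the anchor hit
    keyed = sorted(
        qualifying,
        key=lambda c: (c.hits[0].chrom, c.hits[0].strand, c.hits[0].start),
    )
    loci: list[list[ReadCluster]] = []
    for c in keyed:
        h = c.hits[0]
        if loci:
            ph = loci[-1][-1].hits[0]
            last_end = max(x.hits[0].end for x in loci[-1])
            if (
                ph.chrom == h.chrom
                and ph.strand == h.strand
                and h.start <= last_end + config.locus_merge_gap
            ):
                loci[-1].append(c)
                continue
        loci.append([c])
    windows = []
    for members in loci:
        rep = max(members, key=lambda c: (c.count, c.sequence))
        h = rep.hits[0]
        locus_id = f"{h.chrom}:{h.start}:{h.strand}"
        chrom_len = len(genome[h.chrom])
        if h.strand == "+":
            w5 = (h.start - config.flank, h.start - config.flank + config.window)
            w3 = (h.end + config.flank - config.window, h.end + config.flank)
        else:
            # the read 5' end sits at h.end on the minus strand
            w5 = (h.end + config.flank - config.window, h.end + config.flank)
            w3 = (h.start - config.flank, h.start - config.flank + config.window)
        for ws, we in (w5, w3):
            if ws < 0 or we > chrom_len:
                continue
            windows.append(CandidateWindow(h.chrom, ws, we, h.strand, locus_id, rep))
    return windows


def _local(hit, win: CandidateWindow) -> tuple[int, int]:
    """Window-local half-open coordinates of a hit, oriented 5'->3'."""
    if win.strand == "+":
        return hit.start - win.start, hit.end - win.start
    return win.end - hit.end, win.end - hit.start


def _window_seq(genome: dict[str, str], win: CandidateWindow) -> str:
    s = genome[win.chrom][win.start : win.end]
    return s if win.strand == "+" else revcomp(s)


def _find_partner(partner: list[int], pos: int, tol: int = 1) -> int | None:
    for d in (0, -1, 1) if tol else (0,):
        p = pos + d
        if 0 <= p < len(partner) and partner[p] != -1:
            return partner[p]
    return None


def evaluate_candidate(
    win: CandidateWindow,
    structure: PairingStructure,
    window_clusters: list[ReadCluster],
    config: DenovoConfig = DenovoConfig(),
) -> HairpinCandidate:
    """Apply the annotation criteria to one folded window.

    ``window_clusters`` are all clusters (any depth) with a hit inside the
    window on its strand; the most abundant one is the mature candidate.
    """
    n = win.end - win.start
    local = []
    for c in window_clusters:
        for h in c.hits:
            if h.chrom == win.chrom and h.strand == win.strand and h.start >= win.start and h.end <= win.end:
                local.append((c, _local(h, win)))
                break
    total = sum(c.count for c, _ in local)
    mature_c, (ma, mb) = max(local, key=lambda t: (t[0].count, t[0].sequence))
    L = mb - ma
    partner = structure.partner

    # predicted star: 5' end pairs opposite mature[-3], 3' end two beyond
    # the partner of mature[0] (the canonical 2-nt 3' overhangs)
    c5 = _find_partner(partner, mb - 3)
    c3 = _find_partner(partner, ma)
    star_local = None
    star_seq = None
    overhang_ok = False
    if c5 is not None and c3 is not None:
        ss, se = c5, c3 + 2 + 1  # half-open
        if 0 <= ss < se <= n:
            star_local = (ss, se)
            star_seq = structure.sequence[ss:se]
            overhang_ok = abs((se - ss) - L) <= config.max_bulge_asymmetry

    # duplex pairing quality: mature positions minus its own 2-nt overhang
    unpaired = sum(1 for p in range(ma, mb - 2) if partner[p] == -1)
    mismatches_ok = unpaired <= config.max_unpaired_mature

    opposite = False
    if star_local is not None:
        ss, se = star_local
        disjoint = se <= ma or mb <= ss
        # only duplex positions count: the mature 2-nt 3' overhang is
        # unpaired by definition and may stick to flank bases
        partners_in_star = [partner[p] for p in range(ma, mb - 2) if partner[p] != -1]
        inside = all(ss - 2 <= q <= se + 1 for q in partners_in_star) if partners_in_star else False
        opposite = disjoint and inside

    # read signature over the window
    def _near_5p(interval, ref_start):
        return abs(interval[0] - ref_start) <= config.shift_tolerance

    mature_reads = sum(c.count for c, iv in local if _near_5p(iv, ma))
    star_reads = 0
    if star_local is not None:
        star_reads = sum(
            c.count for c, iv in local if not _near_5p(iv, ma) and _near_5p(iv, star_local[0])
        )
    signature = (mature_reads + star_reads) / total if total else 0.0
    # 5' homogeneity among reads assigned to the mature arm
    mature_groups: dict[int, int] = {}
    for c, iv in local:
        if _near_5p(iv, ma):
            mature_groups[iv[0]] = mature_groups.get(iv[0], 0) + c.count
    shared_5p = max(mature_groups.values()) / mature_reads if mature_reads else 0.0
    signature_ok = signature >= config.min_signature and shared_5p >= config.min_shared_5p

    arm = "?"
    if star_local is not None:
        arm = "5p" if (ma + mb) / 2 < sum(star_local) / 2 else "3p"

    return HairpinCandidate(
        window=win,
        structure=structure,
        mature_seq=mature_c.sequence,
        mature_local=(ma, mb),
        mature_arm=arm,
        star_seq=star_seq,
        star_local=star_local,
        flags=dict(
            on_opposite_arms=opposite,
            duplex_overhang_ok=overhang_ok,
            duplex_mismatches_ok=mismatches_ok,
            signature_ok=signature_ok,
        ),
        signature_fraction=signature,
        mature_reads=mature_reads,
        star_reads=star_reads,
        total_reads=total,
    )


def call_denovo(
    kept_clusters: list[ReadCluster],
    all_clusters: list[ReadCluster],
    genome: list[NamedSequence],
    annotations: list[AnnotationFeature],
    config: DenovoConfig = DenovoConfig(),
) -> tuple[list[HairpinCandidate], list[HairpinCandidate]]:
    """Run excision, folding and evaluation; returns (called, all candidates).

    Candidates from overlapping windows are deduplicated, keeping the one
    with the best signature fraction (verdict-true first).
    """
    gseqs = {g.id: g.seq for g in genome}
    windows = excise_windows(kept_clusters, gseqs, annotations, config)
    candidates = []
    for win in windows:
        seq = _window_seq(gseqs, win)
        structure = fold_hairpin(seq)
        wc = [
            c
            for c in all_clusters
            if any(
                h.chrom == win.chrom
                and h.strand == win.strand
                and h.start >= win.start
                and h.end <= win.end
                for h in c.hits
            )
        ]
        if not wc:
            continue
        candidates.append(evaluate_candidate(win, structure, wc, config))
    # dedupe overlapping windows
    candidates.sort(
        key=lambda c: (not c.verdict, -c.signature_fraction, c.window.chrom, c.window.start)
    )
    chosen: list[HairpinCandidate] = []
    for cand in candidates:
        w = cand.window
        if any(
            w.chrom == k.window.chrom
            and w.strand == k.window.strand
            and w.start < k.window.end
            and k.window.start < w.end
            for k in chosen
        ):
            continue
        chosen.append(cand)
    chosen.sort(key=lambda c: (c.window.chrom, c.window.start))
    called = [c for c in chosen if c.verdict]
    return called, chosen


def candidate_features(called: list[HairpinCandidate], prefix: str = "novel") -> list[AnnotationFeature]:
    """Annotation features for called candidates, for re-quantification."""
    feats = []
    for i, cand in enumerate(called, 1):
        w = cand.window
        fam = f"{prefix}-{i}"

        def _genomic(local):
            if w.strand == "+":
                return w.start + local[0], w.start + local[1]
            return w.end - local[1], w.end - local[0]

        feats.append(
            AnnotationFeature(w.chrom, w.start, w.end, w.strand, "MIR_hairpin", fam, fam)
        )
        ms, me = _genomic(cand.mature_local)
        feats.append(AnnotationFeature(w.chrom, ms, me, w.strand, "MIR_mature", fam, fam))
        if cand.star_local is not None:
            ss, se = _genomic(cand.star_local)
            feats.append(AnnotationFeature(w.chrom, ss, se, w.strand, "MIR_star", fam, fam))
    return feats


def denovo_table(called: list[HairpinCandidate], prefix: str = "novel") -> pd.DataFrame:
    """Report table for called candidates (position printed 1-based closed)."""
    rows = []
    for i, cand in enumerate(called, 1):
        w = cand.window
        rows.append(
            dict(
                mir_gene=f"{prefix}-{i}",
                position=f"{w.chrom}: {w.start + 1}..{w.end}",
                strand=w.strand,
                mature_size=len(cand.mature_seq),
                mature_seq=cand.mature_seq,
                star_seq=cand.star_seq or "",
                star_size=len(cand.star_seq) if cand.star_seq else 0,
                mature_reads=cand.mature_reads,
                star_reads=cand.star_reads,
                signature=round(cand.signature_fraction, 3),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "mir_gene",
            "position",
            "strand",
            "mature_size",
            "mature_seq",
            "star_seq",
            "star_size",
            "mature_reads",
            "star_reads",
            "signature",
        ],
    )
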