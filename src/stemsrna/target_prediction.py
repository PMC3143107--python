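"""miRNA target-site scoring and transcriptome scanning.

The scoring scheme penalises each duplex alignment column: Watson-Crick
pair 0, G:U wobble 0.5, gap 2, anything else 1, with penalties doubled
within the first 13 bases counted from the miRNA 5' end; a transcript is a
potential target when the best full-miRNA alignment scores at most 8.

Site search is an exhaustive semi-global dynamic program over every
transcript position (the miRNA must be fully aligned, transcript ends are
free, at most 3 gaps), run against the transcript strand so that the
reported site is the region whose reverse complement pairs with the miRNA.
No heuristic prescreen is used: every transcript is scanned in full.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io_formats import NamedSequence

__all__ = [
    "ScoringScheme",
    "TargetSite",
    "score_duplex",
    "find_sites",
    "scan_transcriptome",
]

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_GU = {("G", "T"), ("T", "G")}  # DNA alphabet: T stands for U


@dataclass
class ScoringScheme:
    match: float = 0.0
    gu_pair: float = 0.5
    gap: float = 2.0
    mismatch: float = 1.0
    boosted_region: int = 13  # miRNA positions counted from the 5' end
    boost_factor: float = 2.0
    max_score: float = 8.0
    max_gaps: int = 3
    # 'mirna_pos': the boost window is the first 13 miRNA bases (default);
    # 'column': the first 13 alignment columns
    boost_by: str = "mirna_pos"

    def __post_init__(self):
        for name in ("gu_pair", "gap", "mismatch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} penalty must be >= 0")
        if self.boost_by not in ("mirna_pos", "column"):
            raise ValueError("boost_by must be 'mirna_pos' or 'column'")


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    start: int  # transcript coordinates, 0-based half-open
    end: int
    score: float
    alignment: list[tuple[str, str]]  # columns (miRNA base | '-', site base | '-')
    cleavage_pos: int | None  # transcript base opposite miRNA position 10

    @property
    def mirna_str(self) -> str:
        return "".join(m for m, _ in self.alignment)

    @property
    def site_str(self) -> str:
        return "".join(t for _, t in self.alignment)


def _column_penalty(m: str, t: str, scheme: ScoringScheme) -> float:
    if m == "-" or t == "-":
        return scheme.gap
    if (m, t) in _WC:
        return scheme.match
    if (m, t) in _GU:
        return scheme.gu_pair
    return scheme.mismatch


def score_duplex(
    mirna: str, alignment: list[tuple[str, str]], scheme: ScoringScheme = ScoringScheme()
) -> float:
    """Score an explicit duplex alignment.

    Columns run in miRNA 5'->3' order; the second element of each column is
    the transcript base that faces the miRNA base (pairing is judged by
    complementarity, so a perfectly complementary duplex scores 0).  Gap
    columns consuming no miRNA base inherit the boost status of the
    preceding miRNA position (position 1 for a leading gap).
    """
    consumed = "".join(m for m, _ in alignment if m != "-")
    if consumed != mirna:
        raise ValueError("alignment does not cover the miRNA exactly")
    score = 0.0
    pos = 0  # 1-based count of consumed miRNA bases
    for col_idx, (m, t) in enumerate(alignment, start=1):
        if m != "-":
            pos += 1
        if scheme.boost_by == "mirna_pos":
            ref = pos if m != "-" else max(pos, 1)
        else:
            ref = col_idx
        penalty = _column_penalty(m, t, scheme)
        if ref <= scheme.boosted_region:
            penalty *= scheme.boost_factor
        score += penalty
    return score


def find_sites(
    mirna: NamedSequence | str,
    transcript: NamedSequence,
    scheme: ScoringScheme = ScoringScheme(),
) -> list[TargetSite]:
    """All non-overlapping sites on a transcript with score <= max_score.

    The DP aligns the miRNA (5'->3') against the reversed transcript, which
    is the antiparallel duplex geometry: the miRNA 5' end faces the site's
    3' end.  States carry the number of gaps used (bounded by max_gaps);
    boosting follows miRNA positions.
    """
    if isinstance(mirna, str):
        mirna = NamedSequence("miRNA", mirna)
    M = mirna.seq
    R = transcript.seq[::-1]  # reversed transcript
    n, m = len(R), len(M)
    if n < m:
        return []
    G = scheme.max_gaps
    INF = float("inf")

    def boost(pos_1based: int) -> float:
        return scheme.boost_factor if pos_1based <= scheme.boosted_region else 1.0

    # dp[i][g] for the current column x: best score aligning M[:i] ending
    # exactly at R position x (free start).  back pointers for traceback.
    best_sites: list[tuple[float, int, int, list[tuple[str, str]]]] = []
    # full matrix DP per start is too slow; do one pass over x with
    # dp[x][i][g]; transcript is short enough at analysis scale.
    dp = [[[INF] * (G + 1) for _ in range(m + 1)] for _ in range(n + 1)]
    back: dict[tuple[int, int, int], tuple[int, int, int, str]] = {}
    for x in range(n + 1):
        for g in range(G + 1):
            dp[x][0][g] = 0.0 if g == 0 else INF  # free start in transcript
    for x in range(n + 1):
        for i in range(1, m + 1):
            for g in range(G + 1):
                cand = INF
                choice = None
                if x >= 1:
                    # consume both (pair/mismatch column)
                    pen = _column_penalty(M[i - 1], R[x - 1], scheme) * boost(i)
                    cand = dp[x - 1][i - 1][g] + pen
                    choice = (x - 1, i - 1, g, "D")
                # gap in transcript: consume miRNA base only
                if g > 0 and dp[x][i - 1][g - 1] + scheme.gap * boost(i) < cand:
                    cand = dp[x][i - 1][g - 1] + scheme.gap * boost(i)
                    choice = (x, i - 1, g - 1, "M")
                # gap in miRNA: consume transcript base only (boost of the
                # adjacent -- already consumed -- miRNA position)
                if x >= 1 and g > 0 and dp[x - 1][i][g - 1] + scheme.gap * boost(max(i, 1)) < cand:
                    cand = dp[x - 1][i][g - 1] + scheme.gap * boost(max(i, 1))
                    choice = (x - 1, i, g - 1, "T")
                dp[x][i][g] = cand
                if choice is not None:
                    back[(x, i, g)] = choice
    # candidate ends: best g for each x with full miRNA consumed
    ends = []
    for x in range(1, n + 1):
        g_best = min(range(G + 1), key=lambda g: dp[x][m][g])
        sc = dp[x][m][g_best]
        if sc <= scheme.max_score:
            ends.append((sc, x, g_best))
    ends.sort(key=lambda t: (t[0], t[1]))
    # traceback + greedy non-overlap selection (best score first)
    taken: list[tuple[int, int]] = []
    sites: list[TargetSite] = []
    for sc, x_end, g_end in ends:
        cols_rev: list[tuple[str, str]] = []
        x, i, g = x_end, m, g_end
        cleav_x = None
        while i > 0:
            px, pi, pg, op = back[(x, i, g)]
            if op == "D":
                cols_rev.append((M[i - 1], R[x - 1]))
                if i == 10:
                    cleav_x = x
            elif op == "M":
                cols_rev.append((M[i - 1], "-"))
            else:
                cols_rev.append(("-", R[x - 1]))
            x, i, g = px, pi, pg
        x_start = x
        # convert reversed-transcript span back to transcript coordinates
        t_start, t_end = n - x_end, n - x_start
        if any(t_start < e and s < t_end for s, e in taken):
            continue
        taken.append((t_start, t_end))
        cleavage = n - cleav_x if cleav_x is not None else None
        alignment = cols_rev[::-1]
        sites.append(
            TargetSite(
                mirna.id, transcript.id, t_start, t_end, sc, alignment, cleavage
            )
        )
    sites.sort(key=lambda s: (s.score, s.start))
    return sites


def scan_transcriptome(
    mirnas: list[NamedSequence],
    transcripts: list[NamedSequence],
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[pd.DataFrame, list[TargetSite]]:
    """Scan every miRNA against every transcript; table sorted by
    (miRNA, score).  miRNAs with no site at or below the threshold are
    simply absent from the table."""
    all_sites: list[TargetSite] = []
    for mi in mirnas:
        for tr in transcripts:
            if len(tr.seq) < len(mi.seq):
                continue
            all_sites.extend(find_sites(mi, tr, scheme))
    all_sites.sort(key=lambda s: (s.mirna_id, s.score, s.transcript_id, s.start))
    rows = [
        dict(
            mirna=s.mirna_id,
            transcript=s.transcript_id,
            start=s.start,
            end=s.end,
            score=s.score,
            cleavage_pos=s.cleavage_pos if s.cleavage_pos is not None else -1,
            mirna_alignment=s.mirna_str,
            site_alignment=s.site_str,
        )
        for s in all_sites
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "mirna",
            "transcript",
            "start",
            "end",
            "score",
            "cleavage_pos",
            "mirna_alignment",
            "site_alignment",
        ],
    )
    return df, all_sites
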