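"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by direct enumeration or scanning,
without touching the optimised implementation paths it checks.
"""

from stemsrna.io_formats import revcomp

# ---------------------------------------------------------------------------
# mapping: naive longest-prefix perfect-match scan of every position/strand
# ---------------------------------------------------------------------------


def naive_map(genome_seqs: dict, decoded: str, min_len: int = 18):
    """Return (inferred_length, [(chrom, start, end, strand), ...])."""
    for L in range(len(decoded), min_len - 1, -1):
        prefix = decoded[:L]
        rc = revcomp(prefix)
        hits = []
        for chrom, seq in genome_seqs.items():
            i = seq.find(prefix)
            while i != -1:
                hits.append((chrom, i, i + L, "+"))
                i = seq.find(prefix, i + 1)
            i = seq.find(rc)
            while i != -1:
                hits.append((chrom, i, i + L, "-"))
                i = seq.find(rc, i + 1)
        if hits:
            hits.sort()
            return L, hits
    return 0, []


# ---------------------------------------------------------------------------
# hotspots: per-base threshold scan
# ---------------------------------------------------------------------------


def naive_hotspots(cov, min_coverage: int):
    """Maximal runs with coverage strictly above min_coverage."""
    out = []
    start = None
    for i, v in enumerate(list(cov) + [0]):
        if v > min_coverage and start is None:
            start = i
        elif v <= min_coverage and start is not None:
            out.append((start, i))
            start = None
    return out


# ---------------------------------------------------------------------------
# folding: exhaustive enumeration of nested structures (no memoisation)
# ---------------------------------------------------------------------------

_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "G")}


def max_pairs_exhaustive(seq: str, min_loop: int = 3) -> int:
    def rec(i, j):
        if j - i <= min_loop:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) in _PAIRS:
                cand = 1 + rec(i + 1, k - 1) + rec(k + 1, j)
                if cand > best:
                    best = cand
        return best

    return rec(0, len(seq) - 1) if seq else 0


# ---------------------------------------------------------------------------
# target scoring: enumerate every alignment with a bounded gap count
# ---------------------------------------------------------------------------


def best_duplex_score_exhaustive(mirna: str, transcript: str, scheme) -> float:
    """Minimum duplex score over all semi-global alignments of the full
    miRNA against the transcript, with at most scheme.max_gaps gaps.

    Enumerates alignments column by column against the reversed transcript
    (the antiparallel duplex orientation used by the scanner).
    """
    from stemsrna.target_prediction import _column_penalty

    R = transcript[::-1]
    m, n = len(mirna), len(R)
    best = [float("inf")]

    def boost(pos):
        return scheme.boost_factor if pos <= scheme.boosted_region else 1.0

    def rec(i, x, gaps, score):
        if score >= best[0]:
            return
        if i == m:
            best[0] = score
            return
        if x < n:  # pair/mismatch column
            pen = _column_penalty(mirna[i], R[x], scheme) * boost(i + 1)
            rec(i + 1, x + 1, gaps, score + pen)
        if gaps < scheme.max_gaps:
            # gap in transcript (consume miRNA base)
            rec(i + 1, x, gaps + 1, score + scheme.gap * boost(i + 1))
            # gap in miRNA (consume transcript base); adjacent-position boost
            if x < n and i > 0:
                rec(i, x + 1, gaps + 1, score + scheme.gap * boost(max(i, 1)))

    for start in range(n - 1, -1, -1):
        rec(0, start, 0, 0.0)
    return best[0]
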