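"""Perfect-match prefix mapping of colorspace reads.

Reads are decoded to base space first: since only perfect matches are kept,
a colorspace aligner buys nothing (any color error breaks the perfect-match
filter), so an exact k-mer index over both strands suffices.  For each read
the mapper finds the longest prefix (18..read length) of the decoded
sequence with at least one exact genomic hit; all hits at that length are
reported, capped at 10 with a multimapped flag, in deterministic
(chrom, start, strand) order.  The SOLiD-3 25-nt read limit means adapters
never enter the insert, so the longest-prefix length IS the inferred insert
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io_formats import ColorRead, NamedSequence, revcomp

__all__ = [
    "GenomeIndex",
    "AlignmentHit",
    "AlignedRead",
    "build_index",
    "map_read",
    "map_library",
    "MIN_INSERT",
    "MAX_HITS",
]

MIN_INSERT = 18  # smallest small-RNA insert considered (18-25 nt class)
MAX_HITS = 10  # cap on reported loci per read


@dataclass(frozen=True)
class AlignmentHit:
    chrom: str
    start: int
    end: int
    strand: str

    @property
    def matched_length(self) -> int:
        return self.end - self.start


@dataclass
class AlignedRead:
    """A read with its decoded insert and up to MAX_HITS perfect hits."""

    id: str
    library: str
    insert: str  # decoded prefix of inferred length ('' when unmapped)
    inferred_length: int  # 0 when unmapped
    hits: list[AlignmentHit] = field(default_factory=list)
    multimapped: bool = False

    @property
    def mapped(self) -> bool:
        return bool(self.hits)


class GenomeIndex:
    """Exact k-mer lookup over both strands of a genome.

    Minus-strand entries are keyed by the reverse complement of the genomic
    k-mer and store the plus-strand position of that k-mer, so a read prefix
    looked up directly yields hits on either strand in plus coordinates.
    """

    def __init__(self, seqs: dict[str, str], k: int):
        if k < 12:
            raise ValueError(f"k={k} too small: k-mer collisions blow up below 12")
        self.k = k
        self.seqs = seqs
        lookup: dict[str, list[tuple[str, int, str]]] = {}
        for chrom, seq in seqs.items():
            if len(seq) < k:
                continue
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                lookup.setdefault(kmer, []).append((chrom, i, "+"))
                lookup.setdefault(revcomp(kmer), []).append((chrom, i, "-"))
        self.lookup = lookup


def build_index(genome: list[NamedSequence] | NamedSequence, k: int = 18) -> GenomeIndex:
    if isinstance(genome, NamedSequence):
        genome = [genome]
    seqs = {rec.id: rec.seq for rec in genome}
    if all(len(s) < k for s in seqs.values()):
        raise ValueError(f"no sequence is at least k={k} long")
    return GenomeIndex(seqs, k)


def _extend(index: GenomeIndex, decoded: str, chrom: str, pos: int, strand: str) -> int:
    """Longest read prefix length matching at an anchored k-mer hit."""
    seq = index.seqs[chrom]
    k = index.k
    n = len(decoded)
    length = k
    if strand == "+":
        while length < n and pos + length < len(seq) and seq[pos + length] == decoded[length]:
            length += 1
    else:
        # read[0:k] == revcomp(seq[pos:pos+k]); growing the prefix walks left
        comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
        while length < n and pos + k - length - 1 >= 0 and seq[pos + k - length - 1] == comp[decoded[length]]:
            length += 1
    return length


def map_read(index: GenomeIndex, read: ColorRead) -> AlignedRead:
    """Map one colorspace read by longest-prefix perfect match.

    Unmapped (no perfect hit of length >= 18 on either strand) is a normal
    outcome, returned with an empty hit list.
    """
    decoded = read.decode()
    k = index.k
    if len(decoded) < k:
        return AlignedRead(read.id, read.library, "", 0)
    anchors = index.lookup.get(decoded[:k])
    if not anchors:
        return AlignedRead(read.id, read.library, "", 0)
    best = 0
    scored: list[tuple[int, str, int, str]] = []
    for chrom, pos, strand in anchors:
        length = _extend(index, decoded, chrom, pos, strand)
        scored.append((length, chrom, pos, strand))
        if length > best:
            best = length
    if best < MIN_INSERT:
        return AlignedRead(read.id, read.library, "", 0)
    hits = []
    for length, chrom, pos, strand in scored:
        if length != best:
            continue
        if strand == "+":
            hits.append(AlignmentHit(chrom, pos, pos + best, "+"))
        else:
            hits.append(AlignmentHit(chrom, pos + k - best, pos + k, "-"))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    multimapped = len(hits) > MAX_HITS
    return AlignedRead(
        read.id, read.library, decoded[:best], best, hits[:MAX_HITS], multimapped
    )


def map_library(
    index: GenomeIndex, reads: list[ColorRead]
) -> tuple[list[AlignedRead], float]:
    """Map a library; returns aligned reads (order-stable, unmapped included)
    and the perfect-match fraction mapped/raw."""
    aligned = [map_read(index, r) for r in reads]
    n_mapped = sum(1 for a in aligned if a.mapped)
    frac = n_mapped / len(aligned) if aligned else 0.0
    return aligned, frac
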