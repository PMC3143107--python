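"""Readers and writers for the plain-text formats the pipeline consumes and
emits, plus the SOLiD colorspace codec.

Conventions
-----------
* All sequences are stored in the DNA alphabet; ``U`` is normalised to ``T``
  at ingest and everything is upper-cased.
* Internal coordinates are 0-based half-open everywhere.  GFF3 (1-based,
  closed) is converted at the boundary, in both directions.
* The csfasta dialect is the SOLiD one: a header line ``>id`` followed by a
  single call line consisting of the primer base and the color string,
  e.g. ``T0123...``.  Quality files are ignored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "NamedSequence",
    "AnnotationFeature",
    "ColorRead",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_csfasta",
    "write_csfasta",
    "encode_colorspace",
    "decode_colorspace",
    "revcomp",
    "write_tables",
]

_DNA = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# SOLiD di-base code.  With A,C,G,T encoded as 0..3 the color of a di-base
# (x, y) is code(x) XOR code(y): 0 = identical, 1 = A<->C / G<->T,
# 2 = A<->G / C<->T, 3 = A<->T / C<->G.
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_BASE = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class NamedSequence:
    """A named nucleotide sequence (genome, transcript, mature miRNA...)."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.seq) - _DNA
        if bad:
            raise ValueError(
                f"illegal characters {sorted(bad)} in record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


#: canonical feature kinds used throughout the pipeline
FEATURE_KINDS = (
    "repeat",
    "rRNA",
    "tRNA",
    "MIR_hairpin",
    "MIR_mature",
    "MIR_star",
    "gene",
    "exon",
    "intron",
    "other",
)

# documented mapping from GFF3 type column -> internal kind
GFF3_TYPE_TO_KIND = {
    "repeat_region": "repeat",
    "repeat": "repeat",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "MIR_hairpin": "MIR_hairpin",
    "pre_miRNA": "MIR_hairpin",
    "miRNA_primary_transcript": "MIR_hairpin",
    "MIR_mature": "MIR_mature",
    "miRNA": "MIR_mature",
    "MIR_star": "MIR_star",
    "miRNA_star": "MIR_star",
    "gene": "gene",
    "exon": "exon",
    "intron": "intron",
}

# preferred GFF3 type emitted for each internal kind
KIND_TO_GFF3_TYPE = {
    "repeat": "repeat_region",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "MIR_hairpin": "MIR_hairpin",
    "MIR_mature": "MIR_mature",
    "MIR_star": "MIR_star",
    "gene": "gene",
    "exon": "exon",
    "intron": "intron",
    "other": "region",
}


@dataclass
class AnnotationFeature:
    """A genomic feature, 0-based half-open.

    ``family`` carries the miRNA family label (e.g. ``miR172``) for MIR
    features; it is empty for everything else.
    """

    chrom: str
    start: int
    end: int
    strand: str
    kind: str
    name: str
    family: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name!r}: invalid interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.name!r}: bad strand {self.strand!r}")
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"feature {self.name!r}: unknown kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class ColorRead:
    """One SOLiD colorspace read: primer base plus color calls."""

    id: str
    primer_base: str
    colors: str
    library: str

    def __post_init__(self):
        if self.primer_base not in _BASE_CODE:
            raise ValueError(f"read {self.id!r}: bad primer base {self.primer_base!r}")
        bad = set(self.colors) - set("0123")
        if bad:
            raise ValueError(f"read {self.id!r}: illegal color symbols {sorted(bad)}")

    def decode(self) -> str:
        return decode_colorspace(self.primer_base, self.colors)


# ---------------------------------------------------------------------------
# colorspace codec
# ---------------------------------------------------------------------------

def encode_colorspace(bases: str, primer_base: str) -> str:
    """Encode a base-space sequence into SOLiD colors.

    The first color is the transition primer_base -> bases[0]; the output has
    exactly ``len(bases)`` colors.  ``N`` is rejected (the perfect-match
    pipeline never sees ambiguous reads).
    """
    if not bases:
        raise ValueError("cannot encode an empty sequence")
    if primer_base not in _BASE_CODE:
        raise ValueError(f"bad primer base {primer_base!r}")
    out = []
    prev = _BASE_CODE[primer_base]
    for b in bases:
        if b not in _BASE_CODE:
            raise ValueError(f"cannot encode base {b!r} (N is not allowed)")
        cur = _BASE_CODE[b]
        out.append(str(prev ^ cur))
        prev = cur
    return "".join(out)


def decode_colorspace(primer_base: str, colors: str) -> str:
    """Decode SOLiD colors back to bases; the primer base is not included."""
    if primer_base not in _BASE_CODE:
        raise ValueError(f"bad primer base {primer_base!r}")
    out = []
    prev = _BASE_CODE[primer_base]
    for c in colors:
        if c not in "0123":
            raise ValueError(f"illegal color symbol {c!r}")
        prev ^= int(c)
        out.append(_CODE_BASE[prev])
    return "".join(out)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[NamedSequence]:
    """Read a FASTA file into NamedSequence records.

    U is normalised to T and case is folded to upper.  Illegal characters
    raise a ValueError naming the offending record.
    """
    records: list[NamedSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("U", "T")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        try:
            records.append(NamedSequence(rec.id, seq))
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[NamedSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path) -> list[AnnotationFeature]:
    """Read GFF3 (1-based closed on disk) into 0-based half-open features.

    Unknown feature types map to kind ``other`` with a warning; reversed
    coordinates raise.
    """
    from gffutils.iterators import DataIterator

    feats: list[AnnotationFeature] = []
    for f in DataIterator(str(path)):
        if f.end < f.start:
            raise ValueError(
                f"{path}: feature on {f.seqid} has end {f.end} < start {f.start}"
            )
        kind = GFF3_TYPE_TO_KIND.get(f.featuretype)
        if kind is None:
            warnings.warn(
                f"{path}: unknown GFF3 type {f.featuretype!r}, storing as 'other'"
            )
            kind = "other"
        name = f.attributes.get("Name", [f.id or ""])[0]
        family = f.attributes.get("family", [None])[0]
        feats.append(
            AnnotationFeature(
                chrom=f.seqid,
                start=f.start - 1,  # 1-based closed -> 0-based half-open
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                kind=kind,
                name=name,
                family=family,
            )
        )
    return feats


def write_gff3(features: Sequence[AnnotationFeature], path, source: str = "stemsrna") -> None:
    """Write features back to GFF3 (converting to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = f"Name={f.name}"
            if f.family:
                attrs += f";family={f.family}"
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        source,
                        KIND_TO_GFF3_TYPE[f.kind],
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# csfasta
# ---------------------------------------------------------------------------

def read_csfasta(path, library: str) -> list[ColorRead]:
    """Read a SOLiD csfasta file; every read is tagged with ``library``."""
    reads: list[ColorRead] = []
    header = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                header = line[1:].strip()
                if not header:
                    raise ValueError(f"{path}:{lineno}: empty csfasta header")
            else:
                if header is None:
                    raise ValueError(f"{path}:{lineno}: call line before any header")
                primer, colors = line[0], line[1:]
                try:
                    reads.append(ColorRead(header, primer, colors, library))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: {exc}") from exc
                header = None
    return reads


def write_csfasta(reads: Iterable[ColorRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.id}\n{r.primer_base}{r.colors}\n")


# ---------------------------------------------------------------------------
# tabular outputs
# ---------------------------------------------------------------------------

def write_tables(tables: dict, out_dir) -> list[Path]:
    """Write a dict of name -> DataFrame as TSV files under ``out_dir``.

    Row order must already be deterministic (each producer sorts by its
    documented keys); writing is therefore byte-stable across reruns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in sorted(tables.items()):
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, lineterminator="\n")
        written.append(p)
    return written
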