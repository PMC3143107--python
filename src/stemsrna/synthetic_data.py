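"""Synthetic data generator for the full pipeline.

Builds a toy genome carrying every element class the analysis cares about
(repeat blocks, annotated MIR hairpins, two unannotated novel hairpins,
rRNA/tRNA arrays deliberately omitted from the emitted GFF3, protein-coding
genes with introns) and simulates five barcoded SOLiD libraries with the
statistical structure the study design assumes: ~75% repeat-derived reads,
a dominant 22-nt miR172-analog inside a host-gene intron, >=25-nt rRNA/tRNA
fragments truncated to the 25-nt read limit, planted genotype fold
differences that the bulks inherit from their parent, and genotype-dependent
miR395 arm usage (~6:1 vs ~1:1 mature:star).

All randomness flows from a single integer seed; identical configs produce
byte-identical output files.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .denovo_mirna import fold_hairpin
from .io_formats import (
    AnnotationFeature,
    ColorRead,
    NamedSequence,
    encode_colorspace,
    revcomp,
    write_csfasta,
    write_fasta,
    write_gff3,
)

__all__ = [
    "SimConfig",
    "GenotypeProfile",
    "PhenotypeRecord",
    "PhenotypeModel",
    "MirLocus",
    "SimTruth",
    "default_profiles",
    "build_genome",
    "build_transcripts",
    "simulate_library",
    "make_mix",
    "simulate_phenotypes",
    "select_bulk_segregants",
    "emit_dataset",
    "LIBRARY_BARCODES",
]

_BASES = np.array(list("ACGT"))

#: barcode layout of the five libraries
LIBRARY_BARCODES = {
    "Mix": "bc01",
    "BTx623-like": "bc02",
    "Rio-like": "bc03",
    "LBEF-bulk": "bc04",
    "HBLF-bulk": "bc05",
}

# length distribution of siRNA-like (repeat/background) inserts, 18..24 nt;
# 22 nt is made dominant, with an elevated 24-nt shoulder, so that together
# with the 25-nt rRNA/tRNA fragments the library-level size profile shows
# the characteristic 22 and >=24 peaks
_SIRNA_LENGTHS = np.arange(18, 25)
_SIRNA_WEIGHTS = np.array([3, 4, 6, 8, 14, 12, 10], dtype=float)
_SIRNA_WEIGHTS /= _SIRNA_WEIGHTS.sum()


@dataclass
class SimConfig:
    seed: int = 1
    genome_length: int = 30_000
    n_reads: int = 20_000  # per library
    read_length: int = 25
    window: int = 110  # planted hairpin window length
    n_repeat_families: int = 2
    repeat_copies: int = 4
    repeat_length: int = 300
    rna_array_length: int = 100
    mature_jitter: float = 0.08  # P(+-1 nt 5'-end shift) for miRNA reads
    hairpin_noise: float = 0.05  # fraction of family reads from random hairpin positions
    placement_margin: int = 40
    max_tries: int = 2000

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.genome_length < 5000:
            raise ValueError("genome_length too small to host the planted features")


@dataclass
class GenotypeProfile:
    """Expected read composition of one genotype's library."""

    label: str
    family_abundance: dict[str, float]
    arm_usage: dict[str, float] = field(default_factory=dict)  # mature:star ratio
    default_arm_ratio: float = 6.0
    repeat_fraction: float = 0.75
    hotspot_fraction: float = 0.10

    def __post_init__(self):
        for name, v in (("repeat_fraction", self.repeat_fraction), ("hotspot_fraction", self.hotspot_fraction)):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        total = self.repeat_fraction + self.hotspot_fraction + sum(self.family_abundance.values())
        if total > 1 + 1e-9:
            raise ValueError(f"{self.label}: class fractions sum to {total:.3f} > 1")

    def arm_ratio(self, family: str) -> float:
        return self.arm_usage.get(family, self.default_arm_ratio)


@dataclass
class PhenotypeRecord:
    plant_id: str
    brix: float
    leaves: int

    def __post_init__(self):
        if self.brix < 0 or self.leaves < 1:
            raise ValueError("invalid phenotype values")


@dataclass
class PhenotypeModel:
    """Two-component additive model: one major F2 locus (1:2:1) moves both
    Brix and leaf number, plus correlated environmental noise."""

    brix_base: float = 5.0
    brix_add: float = 4.0
    brix_sd: float = 1.5
    leaves_base: float = 8.0
    leaves_add: float = 3.0
    leaves_sd: float = 1.2
    noise_corr: float = 0.3


@dataclass
class MirLocus:
    family: str
    name: str
    chrom: str
    window_start: int
    window_end: int
    mature_start: int
    mature_read_len: int  # length of the sequenced species
    annotated_len: int  # length recorded in the GFF3 (may differ)
    star_start: int
    star_len: int
    mature_seq: str
    star_seq: str
    novel: bool

    @property
    def mature_end(self) -> int:
        return self.mature_start + self.mature_read_len

    @property
    def star_end(self) -> int:
        return self.star_start + self.star_len


@dataclass
class SimTruth:
    """Everything planted, including what the emitted GFF3 hides."""

    genome: NamedSequence
    features: list[AnnotationFeature]  # the emitted annotation
    hidden_rna: list[AnnotationFeature]  # rRNA/tRNA arrays, truth only
    mir: dict[str, MirLocus]
    repeat_intervals: list[tuple[int, int]]
    transcripts: list[NamedSequence]
    engineered_sites: list[dict]
    config: SimConfig

    def summary(self) -> dict:
        return dict(
            genome_length=len(self.genome.seq),
            n_features=len(self.features),
            families=sorted(self.mir),
            novel=[f for f, m in self.mir.items() if m.novel],
            hidden_rna=[(f.kind, f.start, f.end) for f in self.hidden_rna],
            n_repeats=len(self.repeat_intervals),
        )


# (family, gene name, sequenced mature length, annotated mature length, abundance planted?)
_KNOWN_FAMILIES = [
    ("miR172", "MIR172c-like", 22, 20),  # 22-nt species over a 20-nt annotation
    ("miR169", "MIR169-1", 21, 21),
    ("miR395", "MIR395-1", 21, 21),
    ("miR160", "MIR160-1", 21, 21),
    ("miR164", "MIR164-1", 21, 21),
    ("miR319", "MIR319-1", 21, 21),
    ("miR399", "MIR399-1", 21, 21),  # annotated but silent in every library
    ("miR437", "MIR437-1", 21, 21),  # annotated but silent
]
_NOVEL_FAMILIES = [("miR-N1", "novelA", 21), ("miR-N2", "novelB", 21)]

_INHERITED = ("miR172", "miR169", "miR395")


def default_profiles() -> dict[str, GenotypeProfile]:
    """The four genotype profiles of the study design.

    Inherited families are planted at 3-fold parental differences (the
    analysis calls anything >= 2-fold); trending families at 1.4-fold; the
    bulks inherit the parental value of inherited families and sit midway
    for the rest.  miR395 arm usage is 6:1 in the grain-type genotype and
    1:1 in the sweet-type genotype.
    """
    btx = {
        "miR172": 0.060,
        "miR169": 0.030,
        "miR395": 0.010,
        "miR160": 0.007,
        "miR164": 0.007,
        "miR319": 0.007,
        "miR-N1": 0.005,
        "miR-N2": 0.005,
    }
    rio = {
        "miR172": 0.020,
        "miR169": 0.010,
        "miR395": 0.030,
        "miR160": 0.005,
        "miR164": 0.005,
        "miR319": 0.005,
        "miR-N1": 0.005,
        "miR-N2": 0.005,
    }
    mid = {k: (btx[k] + rio[k]) / 2 for k in btx}
    lbef = {k: (btx[k] if k in _INHERITED else mid[k]) for k in btx}
    hblf = {k: (rio[k] if k in _INHERITED else mid[k]) for k in btx}
    return {
        "BTx623-like": GenotypeProfile("BTx623-like", btx),
        "Rio-like": GenotypeProfile("Rio-like", rio, arm_usage={"miR395": 1.0}),
        "LBEF-bulk": GenotypeProfile("LBEF-bulk", lbef),
        "HBLF-bulk": GenotypeProfile("HBLF-bulk", hblf, arm_usage={"miR395": 1.0}),
    }


def _random_seq(rng, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _make_hairpin(rng, mature_len: int, window: int):
    """Design a 110-nt window folding into a recoverable hairpin.

    Layout: 20-nt 5' flank, mature, 12-nt loop, star, 3' flank.  The star is
    the wobbled reverse complement of the mature core with a 2-nt 3'
    overhang; two G:U pairs are forced at stem positions ~1/3 and ~2/3 so no
    18-nt stretch of the mature is perfectly reverse-complemented elsewhere
    in the window (which would let mature reads map to the star arm).
    The design is accepted only if the max-pairing folder recovers >=90% of
    the planted stem and the canonical star prediction.
    """
    flank5 = 20
    loop_len = 12
    for _ in range(100):
        mature = list(_random_seq(rng, mature_len))
        w1, w2 = mature_len // 3, (2 * mature_len) // 3
        for p in (w1, w2):
            mature[p] = "G" if rng.random() < 0.5 else "T"
        mature = "".join(mature)
        core = mature[: mature_len - 2]
        star_core = list(revcomp(core))
        # inject the wobbles: star position opposite mature position p
        for p in (w1, w2):
            if p < mature_len - 2:
                star_core[mature_len - 3 - p] = "T" if mature[p] == "G" else "G"
        star = "".join(star_core) + _random_seq(rng, 2)
        loop = _random_seq(rng, loop_len)
        used = flank5 + mature_len + loop_len + len(star)
        flank3 = _random_seq(rng, window - used)
        seq = _random_seq(rng, flank5) + mature + loop + star + flank3
        ma = flank5
        mb = ma + mature_len
        ss = mb + loop_len
        se = ss + len(star)
        # designed stem pairs: mature[k] with star_core[L-3-k]
        designed = [
            (ma + k, ss + mature_len - 3 - k) for k in range(mature_len - 2)
        ]
        st = fold_hairpin(seq)
        recovered = sum(1 for i, j in designed if st.partner[i] == j)
        if recovered < 0.9 * len(designed):
            continue
        if st.partner[mb - 3] != ss or st.partner[ma] != se - 3:
            continue
        return seq, ma, ss, len(star), mature, "".join(star)
    raise RuntimeError("could not design a recoverable hairpin (rng exhausted)")


class _Placer:
    def __init__(self, rng, genome_length: int, margin: int, max_tries: int):
        self.rng = rng
        self.L = genome_length
        self.margin = margin
        self.max_tries = max_tries
        self.taken: list[tuple[int, int]] = []

    def place(self, length: int) -> int:
        for _ in range(self.max_tries):
            start = int(self.rng.integers(0, self.L - length))
            lo, hi = start - self.margin, start + length + self.margin
            if all(hi <= s or e <= lo for s, e in self.taken):
                self.taken.append((start, start + length))
                return start
        raise RuntimeError(
            "could not place all planted features; increase genome_length"
        )


def build_genome(config: SimConfig = SimConfig()):
    """Construct the toy genome.

    Returns (genome, emitted features, truth).  The rRNA/tRNA arrays appear
    only in the truth record, emulating genes missing from the annotation.
    """
    for attempt in range(5):
        rng = np.random.default_rng([config.seed, 101, attempt])
        try:
            return _build_genome_once(config, rng)
        except RuntimeError:
            if attempt == 4:
                raise
    raise AssertionError("unreachable")


def _build_genome_once(config: SimConfig, rng):
    chrom = "chr1"
    genome = list(_random_seq(rng, config.genome_length))
    placer = _Placer(rng, config.genome_length, config.placement_margin, config.max_tries)
    features: list[AnnotationFeature] = []
    hidden: list[AnnotationFeature] = []
    mir: dict[str, MirLocus] = {}
    repeat_intervals: list[tuple[int, int]] = []

    def paste(seq: str, start: int):
        genome[start : start + len(seq)] = list(seq)

    # --- repeat blocks: identical copies so repeat reads multimap
    for fam_i in range(config.n_repeat_families):
        unit = _random_seq(rng, config.repeat_length)
        for copy_i in range(config.repeat_copies):
            start = placer.place(config.repeat_length)
            paste(unit, start)
            repeat_intervals.append((start, start + config.repeat_length))
            features.append(
                AnnotationFeature(
                    chrom,
                    start,
                    start + config.repeat_length,
                    "+",
                    "repeat",
                    f"repeat{fam_i + 1}.{copy_i + 1}",
                )
            )

    # --- known MIR hairpins; the miR172 analog goes inside a host intron
    def plant_hairpin(family, name, mature_len, annotated_len, novel, host=None):
        seq, ma, ss, star_len, mature_seq, star_seq = _make_hairpin(
            rng, mature_len, config.window
        )
        if host is None:
            start = placer.place(config.window)
        else:
            start = host
        paste(seq, start)
        locus = MirLocus(
            family=family,
            name=name,
            chrom=chrom,
            window_start=start,
            window_end=start + config.window,
            mature_start=start + ma,
            mature_read_len=mature_len,
            annotated_len=annotated_len,
            star_start=start + ss,
            star_len=star_len,
            mature_seq=mature_seq,
            star_seq=star_seq,
            novel=novel,
        )
        mir[family] = locus
        if not novel:
            features.append(
                AnnotationFeature(
                    chrom, start, start + config.window, "+", "MIR_hairpin", name, family
                )
            )
            features.append(
                AnnotationFeature(
                    chrom,
                    locus.mature_start,
                    locus.mature_start + annotated_len,
                    "+",
                    "MIR_mature",
                    f"{name}-mature",
                    family,
                )
            )
            features.append(
                AnnotationFeature(
                    chrom,
                    locus.star_start,
                    locus.star_end,
                    "+",
                    "MIR_star",
                    f"{name}-star",
                    family,
                )
            )
        return locus

    # host gene: exon1-intron1-exon2-intron2(contains the hairpin)-exon3
    ex, in1, in2pad = 100, 150, 60
    host_len = ex + in1 + ex + (in2pad + config.window + in2pad) + ex
    host_start = placer.place(host_len)
    gene_name = "hostGene1"
    bounds = [
        ("exon", host_start, host_start + ex),
        ("intron", host_start + ex, host_start + ex + in1),
        ("exon", host_start + ex + in1, host_start + 2 * ex + in1),
        (
            "intron",
            host_start + 2 * ex + in1,
            host_start + 2 * ex + in1 + in2pad + config.window + in2pad,
        ),
        (
            "exon",
            host_start + 2 * ex + in1 + in2pad + config.window + in2pad,
            host_start + host_len,
        ),
    ]
    features.append(
        AnnotationFeature(chrom, host_start, host_start + host_len, "+", "gene", gene_name)
    )
    for i, (kind, s, e) in enumerate(bounds, 1):
        features.append(AnnotationFeature(chrom, s, e, "+", kind, f"{gene_name}.{kind}{i}"))
    hairpin_start = host_start + 2 * ex + in1 + in2pad

    first = True
    for family, name, mlen, alen in _KNOWN_FAMILIES:
        plant_hairpin(family, name, mlen, alen, novel=False, host=hairpin_start if first else None)
        first = False

    # a second, miRNA-free gene for attribution variety
    g2 = placer.place(420)
    features.append(AnnotationFeature(chrom, g2, g2 + 420, "+", "gene", "gene2"))
    features.append(AnnotationFeature(chrom, g2, g2 + 150, "+", "exon", "gene2.exon1"))
    features.append(AnnotationFeature(chrom, g2 + 150, g2 + 270, "+", "intron", "gene2.intron1"))
    features.append(AnnotationFeature(chrom, g2 + 270, g2 + 420, "+", "exon", "gene2.exon2"))

    # --- novel hairpins: truth only, never annotated
    for family, name, mlen in _NOVEL_FAMILIES:
        plant_hairpin(family, name, mlen, mlen, novel=True)

    # --- rRNA/tRNA arrays: present in the genome, absent from the GFF3
    for kind in ("rRNA", "tRNA"):
        start = placer.place(config.rna_array_length)
        paste(_random_seq(rng, config.rna_array_length), start)
        hidden.append(
            AnnotationFeature(
                chrom, start, start + config.rna_array_length, "+", kind, f"{kind}-array"
            )
        )

    genome_seq = "".join(genome)
    # planted mature/star sequences must be unique in the genome, or reads
    # would leak between loci
    for locus in mir.values():
        for s in (locus.mature_seq, locus.star_seq):
            if genome_seq.count(s) != 1 or revcomp(s) in genome_seq:
                raise RuntimeError("planted miRNA sequence collides; regenerating")

    genome_rec = NamedSequence(chrom, genome_seq)
    truth = SimTruth(
        genome=genome_rec,
        features=features,
        hidden_rna=hidden,
        mir=mir,
        repeat_intervals=repeat_intervals,
        transcripts=[],
        engineered_sites=[],
        config=config,
    )
    truth.transcripts, truth.engineered_sites = build_transcripts(truth, rng)
    return genome_rec, features, truth


def build_transcripts(truth: SimTruth, rng) -> tuple[list[NamedSequence], list[dict]]:
    """Synthetic transcripts for target scanning.

    One transcript carries an engineered site for the first novel miRNA: the
    exact reverse complement of its mature with a single mismatch opposite
    miRNA position 15 (outside the boosted region), i.e. an expected duplex
    score of 1.  The remaining transcripts are random background.
    """
    transcripts = []
    engineered = []
    novels = [m for m in truth.mir.values() if m.novel]
    if novels:
        m = novels[0]
        site = list(revcomp(m.mature_seq))
        # mismatch opposite miRNA position 15 (1-based from the 5' end)
        pos = len(m.mature_seq) - 15
        mir_base = m.mature_seq[14]
        forbidden = {"A": "T", "C": "G", "G": "CT", "T": "AG"}[mir_base]
        choices = [b for b in "ACGT" if b not in forbidden]
        site[pos] = choices[int(rng.integers(0, len(choices)))]
        site = "".join(site)
        upstream = _random_seq(rng, 150)
        downstream = _random_seq(rng, 130)
        seq = upstream + site + downstream
        transcripts.append(NamedSequence("transcript-target1", seq))
        engineered.append(
            dict(
                transcript="transcript-target1",
                mirna_family=m.family,
                site_start=len(upstream),
                site_end=len(upstream) + len(site),
                expected_score=1.0,
            )
        )
    for i in range(2):
        transcripts.append(NamedSequence(f"transcript-bg{i + 1}", _random_seq(rng, 300)))
    return transcripts, engineered


def _sample_lengths(rng, n: int) -> np.ndarray:
    return rng.choice(_SIRNA_LENGTHS, size=n, p=_SIRNA_WEIGHTS)


def simulate_library(
    truth: SimTruth,
    profile: GenotypeProfile,
    n_reads: int,
    seed: int,
    library: str,
) -> tuple[list[ColorRead], list[dict]]:
    """Simulate one barcoded library.

    Returns (reads, labels); ``labels[i]`` records the true source class of
    ``reads[i]``.  Every read is an exact substring of the genome (or its
    reverse complement) encoded into colorspace, so the perfect-match
    mapper's assumption holds by construction.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    cfg = truth.config
    rng = np.random.default_rng([seed, 7])
    genome = truth.genome.seq
    families = [f for f in profile.family_abundance if f in truth.mir]
    classes = (
        [("repeat", profile.repeat_fraction), ("hotspot", profile.hotspot_fraction)]
        + [(f, profile.family_abundance[f]) for f in families]
    )
    background = 1.0 - sum(p for _, p in classes)
    classes.append(("background", max(background, 0.0)))
    probs = np.array([p for _, p in classes])
    counts = rng.multinomial(n_reads, probs / probs.sum())

    avoid = (
        truth.repeat_intervals
        + [(m.window_start, m.window_end) for m in truth.mir.values()]
        + [(f.start, f.end) for f in truth.hidden_rna]
    )

    def emit(seq: str, label: dict, out):
        out.append((seq, label))

    out: list[tuple[str, dict]] = []
    for (cname, _), count in zip(classes, counts):
        if cname == "repeat":
            lengths = _sample_lengths(rng, count)
            for ell in lengths:
                s, e = truth.repeat_intervals[int(rng.integers(0, len(truth.repeat_intervals)))]
                start = int(rng.integers(s, e - int(ell) + 1))
                frag = genome[start : start + int(ell)]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                emit(frag, dict(source="repeat"), out)
        elif cname == "hotspot":
            for _ in range(count):
                f = truth.hidden_rna[int(rng.integers(0, len(truth.hidden_rna)))]
                start = int(rng.integers(f.start, f.end - cfg.read_length + 1))
                emit(
                    genome[start : start + cfg.read_length],
                    dict(source="hotspot", kind=f.kind),
                    out,
                )
        elif cname == "background":
            lengths = _sample_lengths(rng, count)
            for ell in lengths:
                for _ in range(200):
                    start = int(rng.integers(0, len(genome) - int(ell)))
                    end = start + int(ell)
                    if all(end <= s or e <= start for s, e in avoid):
                        break
                frag = genome[start:end]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                emit(frag, dict(source="background"), out)
        else:  # a miRNA family
            locus = truth.mir[cname]
            ratio = profile.arm_ratio(cname)
            p_mature = ratio / (1.0 + ratio)
            for _ in range(count):
                u = rng.random()
                if u < cfg.hairpin_noise:
                    ell = int(rng.integers(18, 25))
                    start = int(
                        rng.integers(locus.window_start, locus.window_end - ell + 1)
                    )
                    emit(
                        genome[start : start + ell],
                        dict(source="hairpin_noise", family=cname),
                        out,
                    )
                    continue
                if rng.random() < p_mature:
                    start, ell, strand_kind = locus.mature_start, locus.mature_read_len, "mature"
                else:
                    start, ell, strand_kind = locus.star_start, locus.star_len, "star"
                if rng.random() < cfg.mature_jitter:
                    start += 1 if rng.random() < 0.5 else -1
                emit(
                    genome[start : start + ell],
                    dict(source="miRNA", family=cname, strand=strand_kind),
                    out,
                )

    order = rng.permutation(len(out))
    reads, labels = [], []
    for new_i, idx in enumerate(order):
        seq, label = out[idx]
        reads.append(
            ColorRead(f"{library}_{new_i:06d}", "T", encode_colorspace(seq, "T"), library)
        )
        labels.append(label)
    return reads, labels


def make_mix(
    libraries: list[list[ColorRead]], n_reads: int, seed: int, library: str = "bc01"
) -> list[ColorRead]:
    """Equal-proportion mix: n_reads/4 reads sampled without replacement
    from each of the four libraries (earlier libraries absorb the remainder),
    relabeled to the mix barcode."""
    if len(libraries) != 4 or any(not lib for lib in libraries):
        raise ValueError("need four non-empty libraries")
    rng = np.random.default_rng([seed, 13])
    quotas = [n_reads // 4 + (1 if i < n_reads % 4 else 0) for i in range(4)]
    for lib, q in zip(libraries, quotas):
        if len(lib) < q:
            raise ValueError("a source library is smaller than its mix quota")
    mixed: list[ColorRead] = []
    for lib, q in zip(libraries, quotas):
        idx = rng.choice(len(lib), size=q, replace=False)
        for i in sorted(idx):
            r = lib[i]
            mixed.append(ColorRead(f"{library}_{len(mixed):06d}", r.primer_base, r.colors, library))
    return mixed


def simulate_phenotypes(
    n: int = 553, model: PhenotypeModel = PhenotypeModel(), seed: int = 1
) -> list[PhenotypeRecord]:
    """Brix and leaf-count phenotypes for an F2 population."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng([seed, 23])
    g = rng.binomial(2, 0.5, size=n)
    cov = np.array(
        [
            [model.brix_sd**2, model.noise_corr * model.brix_sd * model.leaves_sd],
            [model.noise_corr * model.brix_sd * model.leaves_sd, model.leaves_sd**2],
        ]
    )
    if model.brix_sd == 0 and model.leaves_sd == 0:
        noise = np.zeros((n, 2))
    else:
        noise = rng.multivariate_normal([0, 0], cov, size=n, method="cholesky")
    records = []
    for i in range(n):
        brix = max(0.0, model.brix_base + model.brix_add * g[i] + noise[i, 0])
        leaves = max(1, round(model.leaves_base + model.leaves_add * g[i] + noise[i, 1]))
        records.append(PhenotypeRecord(f"F2-{i + 1:04d}", float(brix), int(leaves)))
    return records


def select_bulk_segregants(
    records: list[PhenotypeRecord],
    brix_low: float = 5.0,
    leaves_low: int = 9,
    brix_high: float = 13.0,
    leaves_high: int = 14,
) -> tuple[list[PhenotypeRecord], list[PhenotypeRecord]]:
    """Bulked-segregant selection of phenotypic extremes.

    Low bulk: Brix <= brix_low AND leaves <= leaves_low; high bulk: Brix >=
    brix_high AND leaves >= leaves_high.
    """
    if not records:
        raise ValueError("no phenotype records")
    low = [r for r in records if r.brix <= brix_low and r.leaves <= leaves_low]
    high = [r for r in records if r.brix >= brix_high and r.leaves >= leaves_high]
    if not low or not high:
        warnings.warn("a selection bulk is empty under the given thresholds")
    return low, high


def emit_dataset(
    config: SimConfig,
    out_dir,
    profiles: dict[str, GenotypeProfile] | None = None,
) -> dict:
    """Simulate everything and write it under ``out_dir``.

    Emits genome.fasta, annotations.gff3, transcripts.fasta, one csfasta per
    barcoded library, phenotypes.tsv and truth.json.  Returns a dict with
    the in-memory objects for immediate pipeline use.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    profiles = profiles or default_profiles()
    genome, features, truth = build_genome(config)

    phenos = simulate_phenotypes(seed=config.seed)
    low, high = select_bulk_segregants(phenos)

    libs: dict[str, list[ColorRead]] = {}
    labels: dict[str, list[dict]] = {}
    parent_order = ["BTx623-like", "Rio-like", "LBEF-bulk", "HBLF-bulk"]
    for i, label in enumerate(parent_order):
        bc = LIBRARY_BARCODES[label]
        reads, lab = simulate_library(
            truth, profiles[label], config.n_reads, config.seed * 1000 + i, bc
        )
        libs[bc] = reads
        labels[bc] = lab
    libs["bc01"] = make_mix(
        [libs[LIBRARY_BARCODES[p]] for p in parent_order], config.n_reads, config.seed
    )

    write_fasta([genome], out_dir / "genome.fasta")
    write_gff3(features, out_dir / "annotations.gff3")
    write_fasta(truth.transcripts, out_dir / "transcripts.fasta")
    for bc in sorted(libs):
        write_csfasta(libs[bc], out_dir / f"{bc}.csfasta")
    with open(out_dir / "phenotypes.tsv", "w") as fh:
        fh.write("plant_id\tbrix\tleaves\n")
        for r in phenos:
            fh.write(f"{r.plant_id}\t{r.brix:.2f}\t{r.leaves}\n")
    with open(out_dir / "truth.json", "w") as fh:
        payload = truth.summary()
        payload["config"] = asdict(config)
        payload["bulk_sizes"] = dict(low=len(low), high=len(high))
        payload["mir_loci"] = {f: asdict(m) for f, m in truth.mir.items()}
        json.dump(payload, fh, indent=1, sort_keys=True)
    return dict(
        genome=genome,
        features=features,
        truth=truth,
        libraries=libs,
        labels=labels,
        phenotypes=phenos,
        bulks=(low, high),
    )
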