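"""End-to-end orchestration: decode -> map -> cluster/stats -> profile and
hotspots -> known-miRNA quantification -> repeat filter -> de novo calling
-> novel re-quantification -> target scan.

Every stage is a pure function of its inputs plus the config, so identical
config and seed give byte-identical output tables.  Any stage failure
aborts with the stage name attached.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genome_profile, library_stats, mirna_quant
from .denovo_mirna import DenovoConfig, call_denovo, candidate_features, denovo_table
from .genome_profile import HotspotConfig
from .io_formats import (
    NamedSequence,
    read_csfasta,
    read_fasta,
    read_gff3,
    write_tables,
)
from .mapping import AlignedRead, build_index, map_library
from .mirna_quant import ExpressionFilter
from .target_prediction import ScoringScheme, scan_transcriptome

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "simulate", "hits_table"]

log = logging.getLogger("stemsrna")

#: library roles in the study design
PARENT1, PARENT2, BULK1, BULK2, MIX = "bc02", "bc03", "bc04", "bc05", "bc01"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    genome: str
    annotations: str
    libraries: dict[str, str]  # barcode -> csfasta path
    transcripts: str | None = None
    out_dir: str = "results"
    seed: int = 1
    k: int = 18
    shift_tolerance: int = 2
    fold_cutoff: float = 2.0
    hotspot: HotspotConfig = field(default_factory=HotspotConfig)
    expression: ExpressionFilter = field(default_factory=ExpressionFilter)
    denovo: DenovoConfig = field(default_factory=DenovoConfig)
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def validate(self) -> None:
        for label, p in [("genome", self.genome), ("annotations", self.annotations)] + [
            (f"library {bc}", p) for bc, p in self.libraries.items()
        ]:
            if not Path(p).is_file():
                raise FileNotFoundError(f"{label} file not found: {p}")
        if self.transcripts and not Path(self.transcripts).is_file():
            raise FileNotFoundError(f"transcripts file not found: {self.transcripts}")
        if not self.libraries:
            raise ValueError("no libraries configured")

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_data_dir(cls, data_dir, out_dir="results", **kw) -> "PipelineConfig":
        """Config pointing at a simulated dataset directory."""
        d = Path(data_dir)
        libs = {p.stem: str(p) for p in sorted(d.glob("bc*.csfasta"))}
        tr = d / "transcripts.fasta"
        return cls(
            genome=str(d / "genome.fasta"),
            annotations=str(d / "annotations.gff3"),
            libraries=libs,
            transcripts=str(tr) if tr.is_file() else None,
            out_dir=str(out_dir),
            **kw,
        )


def hits_table(aligned: dict[str, list[AlignedRead]]) -> pd.DataFrame:
    """Internal hits table (one row per reported hit)."""
    rows = []
    for lib in sorted(aligned):
        for a in aligned[lib]:
            for h in a.hits:
                rows.append(
                    dict(
                        read_id=a.id,
                        library=lib,
                        chrom=h.chrom,
                        start=h.start,
                        end=h.end,
                        strand=h.strand,
                        length=a.inferred_length,
                        n_hits=len(a.hits),
                        multimapped=a.multimapped,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "library",
            "chrom",
            "start",
            "end",
            "strand",
            "length",
            "n_hits",
            "multimapped",
        ],
    )


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-tag with stage name
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig, write: bool = True) -> dict:
    """Run every stage and (optionally) write the result tables.

    Returns a bundle dict holding all intermediate and final objects.
    """
    config.validate()

    @_stage("load")
    def _load():
        genome = read_fasta(config.genome)
        features = read_gff3(config.annotations)
        libs = {
            bc: read_csfasta(path, bc) for bc, path in sorted(config.libraries.items())
        }
        transcripts = read_fasta(config.transcripts) if config.transcripts else []
        return genome, features, libs, transcripts

    genome, features, libs, transcripts = _load()
    log.info("loaded %d libraries, %d features", len(libs), len(features))

    @_stage("map")
    def _map():
        index = build_index(genome, k=config.k)
        aligned = {}
        fractions = {}
        for bc, reads in libs.items():
            aligned[bc], fractions[bc] = map_library(index, reads)
            log.info("mapped %s: %d reads, %.1f%% perfect", bc, len(reads), 100 * fractions[bc])
        return aligned, fractions

    aligned, mapped_fractions = _map()

    @_stage("stats")
    def _stats():
        per_lib_clusters = {}
        stats = []
        for bc, al in aligned.items():
            per_lib_clusters[bc] = library_stats.cluster_reads(al)
            stats.append(
                library_stats.compute_stats(bc, len(libs[bc]), al, per_lib_clusters[bc])
            )
        return per_lib_clusters, stats

    per_lib_clusters, stats = _stats()

    @_stage("profile")
    def _profile():
        size_tables = []
        element_tables = []
        for bc, al in aligned.items():
            sd = genome_profile.size_distribution(al)
            sd.insert(0, "library", bc)
            size_tables.append(sd)
            eb = genome_profile.attribute_elements(al, features)
            eb.insert(0, "library", bc)
            element_tables.append(eb)
        chrom_lengths = {g.id: len(g.seq) for g in genome}
        pooled = [a for al in aligned.values() for a in al]
        cov = genome_profile.coverage_arrays(
            pooled, chrom_lengths, config.hotspot.target_length
        )
        hotspots = genome_profile.detect_hotspots(cov, config.hotspot, features)
        return (
            pd.concat(size_tables, ignore_index=True),
            pd.concat(element_tables, ignore_index=True),
            hotspots,
        )

    size_dist, element_breakdown, hotspots = _profile()
    log.info("found %d hotspot(s)", len(hotspots))

    library_totals = {s.library: s.n_perfect for s in stats}

    @_stage("quant")
    def _quant():
        matrix = mirna_quant.count_families(aligned, features, config.shift_tolerance)
        expressed = mirna_quant.expressed_families(matrix, config.expression)
        fold = mirna_quant.fold_change_analysis(
            matrix, library_totals, PARENT1, PARENT2, BULK1, BULK2, config.fold_cutoff
        )
        stars = mirna_quant.star_ratio_analysis(matrix)
        genes = mirna_quant.gene_counts(aligned, features, config.shift_tolerance)
        return matrix, expressed, fold, stars, genes

    matrix, expressed, fold_changes, star_ratios, per_gene = _quant()
    log.info("%d known families pass the expression filter", len(expressed))

    @_stage("denovo")
    def _denovo():
        pooled = [a for al in aligned.values() for a in al]
        all_clusters = library_stats.cluster_reads(pooled)
        kept, removed = genome_profile.filter_repeats(all_clusters, features)
        called, candidates = call_denovo(kept, all_clusters, genome, features, config.denovo)
        return all_clusters, kept, removed, called, candidates

    all_clusters, kept_clusters, removed_clusters, called, candidates = _denovo()
    log.info(
        "de novo: %d/%d clusters kept after repeat filter, %d candidate(s) called",
        len(kept_clusters),
        len(all_clusters),
        len(called),
    )

    @_stage("requant")
    def _requant():
        novel_features = candidate_features(called)
        if not novel_features:
            return novel_features, None, [], []
        novel_matrix = mirna_quant.count_families(
            aligned, novel_features, config.shift_tolerance
        )
        novel_expressed = mirna_quant.expressed_families(novel_matrix, config.expression)
        novel_fold = mirna_quant.fold_change_analysis(
            novel_matrix, library_totals, PARENT1, PARENT2, BULK1, BULK2, config.fold_cutoff
        )
        return novel_features, novel_matrix, novel_expressed, novel_fold

    novel_features, novel_matrix, novel_expressed, novel_fold = _requant()

    @_stage("targets")
    def _targets():
        mirnas = [
            NamedSequence(f"novel-{i + 1}", c.mature_seq) for i, c in enumerate(called)
        ]
        if not mirnas or not transcripts:
            return pd.DataFrame(), []
        return scan_transcriptome(mirnas, transcripts, config.scoring)

    target_table, target_sites = _targets()

    bundle = dict(
        genome=genome,
        features=features,
        aligned=aligned,
        mapped_fractions=mapped_fractions,
        clusters=per_lib_clusters,
        stats=stats,
        size_distribution=size_dist,
        element_breakdown=element_breakdown,
        hotspots=hotspots,
        family_matrix=matrix,
        expressed=expressed,
        fold_changes=fold_changes,
        star_ratios=star_ratios,
        per_gene_counts=per_gene,
        kept_clusters=kept_clusters,
        removed_clusters=removed_clusters,
        called=called,
        candidates=candidates,
        novel_matrix=novel_matrix,
        novel_expressed=novel_expressed,
        novel_fold=novel_fold,
        target_table=target_table,
        target_sites=target_sites,
        library_totals=library_totals,
    )
    if write:
        _write_bundle(bundle, config)
    return bundle


def _matrix_frame(matrix: pd.DataFrame) -> pd.DataFrame:
    df = matrix.reset_index()
    return df.sort_values(["family", "strand"]).reset_index(drop=True)


def _fold_frame(records) -> pd.DataFrame:
    rows = []
    for r in records:
        row = dict(family=r.family, call=r.call)
        row.update({f"rpm_{k}": round(v, 3) for k, v in r.rpm.items()})
        row["parental_ratio"] = round(r.parental_ratio, 4) if r.parental_ratio is not None else ""
        row["bulk_ratio"] = round(r.bulk_ratio, 4) if r.bulk_ratio is not None else ""
        rows.append(row)
    return pd.DataFrame(rows)


def _star_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                name=r.name,
                library=r.library,
                mature=r.mature,
                star=r.star,
                ratio=round(r.ratio, 4) if r.ratio is not None else "",
                arm_switch=r.arm_switch,
            )
            for r in records
        ]
    )


def _write_bundle(bundle: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    tables = {
        "library_stats": library_stats.stats_table(bundle["stats"]),
        "size_distribution": bundle["size_distribution"],
        "element_breakdown": bundle["element_breakdown"],
        "hotspots": genome_profile.hotspot_table(bundle["hotspots"]),
        "family_counts": _matrix_frame(bundle["family_matrix"]),
        "fold_changes": _fold_frame(bundle["fold_changes"]),
        "star_ratios": _star_frame(bundle["star_ratios"]),
        "per_gene_counts": bundle["per_gene_counts"],
        "novel_mirnas": denovo_table(bundle["called"]),
        "targets": bundle["target_table"],
        "hits": hits_table(bundle["aligned"]),
    }
    if bundle["novel_matrix"] is not None:
        tables["novel_family_counts"] = _matrix_frame(bundle["novel_matrix"])
        tables["novel_fold_changes"] = _fold_frame(bundle["novel_fold"])
    write_tables(tables, out)
    config.to_yaml(out / "pipeline_config.yaml")


def simulate(config=None, out_dir="simdata"):
    """Generate a complete synthetic dataset on disk (wraps synthetic_data)."""
    from .synthetic_data import SimConfig, emit_dataset

    if config is None:
        config = SimConfig()
    return emit_dataset(config, out_dir)
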