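import numpy as np
import pytest
from scipy import stats as sps

from stemsrna.io_formats import revcomp
from stemsrna.synthetic_data import (
    GenotypeProfile,
    PhenotypeModel,
    PhenotypeRecord,
    SimConfig,
    build_genome,
    default_profiles,
    make_mix,
    select_bulk_segregants,
    simulate_library,
    simulate_phenotypes,
)


class TestBuildGenome:
    def test_planted_mature_sequences_unique_in_genome(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        g = truth.genome.seq
        for locus in truth.mir.values():
            assert g.count(locus.mature_seq) == 1
            assert revcomp(locus.mature_seq) not in g

    def test_intronic_hairpin_inside_host_intron(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        locus = truth.mir["miR172"]
        introns = [f for f in truth.features if f.kind == "intron"]
        assert any(
            f.start <= locus.window_start and locus.window_end <= f.end for f in introns
        )

    def test_rna_arrays_absent_from_emitted_gff3(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        assert truth.hidden_rna
        assert all(f.kind not in ("rRNA", "tRNA") for f in truth.features)

    def test_novel_hairpins_not_annotated(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        novels = [m for m in truth.mir.values() if m.novel]
        assert len(novels) == 2
        mir_feats = [f for f in truth.features if f.kind.startswith("MIR")]
        for m in novels:
            assert not any(
                f.start < m.window_end and m.window_start < f.end for f in mir_feats
            )

    def test_too_small_genome_raises(self):
        with pytest.raises(ValueError):
            SimConfig(genome_length=1000)


class TestDeterminism:
    def test_identical_seed_gives_byte_identical_files(self, tmp_path):
        from stemsrna.pipeline import simulate

        cfg = SimConfig(seed=5, n_reads=1500)
        simulate(cfg, tmp_path / "a")
        simulate(cfg, tmp_path / "b")
        for name in ("genome.fasta", "annotations.gff3", "bc01.csfasta", "bc05.csfasta", "truth.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestSimulateLibrary:
    def test_reads_are_genome_substrings(self, sim_dataset):
        _, data = sim_dataset
        g = data["truth"].genome.seq
        for r in data["libraries"]["bc03"][:400]:
            d = r.decode()
            assert d in g or revcomp(d) in g

    def test_arm_usage_six_to_one_recovered(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        profile = default_profiles()["BTx623-like"]
        reads, labels = simulate_library(truth, profile, 60000, 991, "bcX")
        m = sum(1 for l in labels if l.get("family") == "miR395" and l.get("strand") == "mature")
        s = sum(1 for l in labels if l.get("family") == "miR395" and l.get("strand") == "star")
        ci = sps.binomtest(m, m + s, 6 / 7).proportion_ci(0.99)
        assert ci.low <= 6 / 7 <= ci.high
        assert m / s > 3  # far from 1:1

    def test_arm_usage_one_to_one_symmetric(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        profile = default_profiles()["Rio-like"]
        reads, labels = simulate_library(truth, profile, 60000, 992, "bcX")
        m = sum(1 for l in labels if l.get("family") == "miR395" and l.get("strand") == "mature")
        s = sum(1 for l in labels if l.get("family") == "miR395" and l.get("strand") == "star")
        ci = sps.binomtest(m, m + s, 0.5).proportion_ci(0.99)
        assert ci.low <= 0.5 <= ci.high

    def test_zero_repeat_fraction_emits_no_repeat_reads(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        profile = GenotypeProfile("norep", {"miR172": 0.06}, repeat_fraction=0.0, hotspot_fraction=0.0)
        _, labels = simulate_library(truth, profile, 2000, 993, "bcX")
        assert not any(l["source"] == "repeat" for l in labels)

    def test_repeat_fraction_recovered_at_depth(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        profile = default_profiles()["BTx623-like"]
        _, labels = simulate_library(truth, profile, 200000, 994, "bcX")
        share = sum(1 for l in labels if l["source"] == "repeat") / len(labels)
        assert abs(share - 0.75) < 0.02

    def test_zero_reads_rejected(self, sim_dataset):
        _, data = sim_dataset
        with pytest.raises(ValueError):
            simulate_library(data["truth"], default_profiles()["Rio-like"], 0, 1, "bcX")


class TestMakeMix:
    def test_equal_quotas(self, sim_dataset):
        _, data = sim_dataset
        libs = [data["libraries"][bc] for bc in ("bc02", "bc03", "bc04", "bc05")]
        mixed = make_mix(libs, 8000, 3)
        assert len(mixed) == 8000
        assert all(r.library == "bc01" for r in mixed)

    def test_remainder_rule(self, sim_dataset):
        _, data = sim_dataset
        libs = [data["libraries"][bc][:5] for bc in ("bc02", "bc03", "bc04", "bc05")]
        mixed = make_mix(libs, 10, 3)
        assert len(mixed) == 10  # quotas 3,3,2,2

    def test_small_source_library_rejected(self, sim_dataset):
        _, data = sim_dataset
        libs = [data["libraries"][bc][:3] for bc in ("bc02", "bc03", "bc04", "bc05")]
        with pytest.raises(ValueError):
            make_mix(libs, 100, 3)

    def test_mix_composition_matches_source_mean(self, sim_dataset):
        """Chi-square goodness of fit of mix class proportions vs the mean
        of the four source libraries."""
        _, data = sim_dataset
        from collections import Counter

        # labels are per source library; identify mixed reads by sequence
        seq_class = {}
        for bc in ("bc02", "bc03", "bc04", "bc05"):
            for r, l in zip(data["libraries"][bc], data["labels"][bc]):
                seq_class[(bc, r.colors)] = l["source"]
        pooled = Counter()
        for bc in ("bc02", "bc03", "bc04", "bc05"):
            pooled.update(l["source"] for l in data["labels"][bc])
        mix_counts = Counter()
        for r in data["libraries"]["bc01"]:
            # colors are near-unique; find the source class by any library
            for bc in ("bc02", "bc03", "bc04", "bc05"):
                cls = seq_class.get((bc, r.colors))
                if cls:
                    mix_counts[cls] += 1
                    break
        classes = sorted(pooled)
        n_mix = sum(mix_counts.values())
        expected = np.array([pooled[c] / sum(pooled.values()) * n_mix for c in classes])
        observed = np.array([mix_counts[c] for c in classes])
        p = sps.chisquare(observed, expected).pvalue
        assert p > 0.001


class TestPhenotypes:
    def test_population_size(self):
        recs = simulate_phenotypes(553, seed=1)
        assert len(recs) == 553

    def test_zero_variance_gives_identical_records(self):
        model = PhenotypeModel(brix_add=0, leaves_add=0, brix_sd=0, leaves_sd=0)
        recs = simulate_phenotypes(50, model, seed=2)
        assert len({(r.brix, r.leaves) for r in recs}) == 1

    def test_noise_correlation_recovered(self):
        model = PhenotypeModel(brix_add=0, leaves_add=0, noise_corr=0.5, leaves_base=30)
        recs = simulate_phenotypes(2000, model, seed=3)
        brix = np.array([r.brix for r in recs])
        leaves = np.array([r.leaves for r in recs])
        assert abs(np.corrcoef(brix, leaves)[0, 1] - 0.5) < 0.1

    def test_brix_leaves_positively_correlated_at_defaults(self):
        recs = simulate_phenotypes(553, seed=4)
        brix = np.array([r.brix for r in recs])
        leaves = np.array([r.leaves for r in recs])
        assert np.corrcoef(brix, leaves)[0, 1] > 0.5


class TestBulkSelection:
    def test_threshold_rules(self):
        low = PhenotypeRecord("p1", 4.0, 8)
        high = PhenotypeRecord("p2", 14.0, 15)
        neither = PhenotypeRecord("p3", 9.0, 11)
        lo, hi = select_bulk_segregants([low, high, neither])
        assert lo == [low] and hi == [high]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            select_bulk_segregants([])

    def test_empty_bulk_warns(self):
        recs = [PhenotypeRecord("p", 9.0, 11)]
        with pytest.warns(UserWarning):
            select_bulk_segregants(recs)
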