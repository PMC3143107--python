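import numpy as np
import pytest

from stemsrna.denovo_mirna import (
    DenovoConfig,
    evaluate_candidate,
    excise_windows,
    fold_hairpin,
)
from stemsrna.io_formats import AnnotationFeature
from stemsrna.library_stats import ReadCluster
from stemsrna.mapping import AlignmentHit

from oracles import max_pairs_exhaustive


class TestFoldHairpin:
    def test_simple_stem_loop(self):
        st = fold_hairpin("GGGAAACCC")
        assert st.n_pairs == 3
        assert st.dotbracket() == "(((...)))"

    def test_unpairable_sequence(self):
        assert fold_hairpin("AAAAAA").n_pairs == 0

    def test_min_loop_enforced(self):
        for i, j in fold_hairpin("GCGCGCGCGCGCGCGC").pairs:
            assert j - i > 3

    def test_structure_is_nested_and_consistent(self):
        st = fold_hairpin("GGGCCAAATTTGGCCC" * 2)
        seen = set()
        for i, j in st.pairs:
            assert i < j and st.partner[i] == j and st.partner[j] == i
            assert not (i in seen or j in seen)
            seen.update((i, j))
        for (i1, j1) in st.pairs:
            for (i2, j2) in st.pairs:
                if i1 < i2:  # nested or disjoint, never crossing
                    assert j2 < j1 or i2 > j1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 26))
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        assert fold_hairpin(seq).n_pairs == max_pairs_exhaustive(seq)

    def test_deterministic_traceback(self):
        seq = "GCAUAGCUAGGCUAGCAUGCGCAUA".replace("U", "T")
        assert fold_hairpin(seq).pairs == fold_hairpin(seq).pairs

    def test_planted_stems_recovered(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        g = truth.genome.seq
        for locus in truth.mir.values():
            window = g[locus.window_start : locus.window_end]
            st = fold_hairpin(window)
            ma = locus.mature_start - locus.window_start
            L = locus.mature_read_len
            ss = locus.star_start - locus.window_start
            designed = [(ma + k, ss + L - 3 - k) for k in range(L - 2)]
            recovered = sum(1 for i, j in designed if st.partner[i] == j)
            assert recovered >= 0.9 * len(designed)


def _cluster(seq, count, start, lib="bc02", strand="+"):
    return ReadCluster(
        seq, count, {lib: count}, [AlignmentHit("chr1", start, start + len(seq), strand)]
    )


class TestExciseWindows:
    def test_cluster_on_known_mir_excluded(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        g = {truth.genome.id: truth.genome.seq}
        locus = truth.mir["miR172"]
        c = _cluster(locus.mature_seq[:22], 50, locus.mature_start)
        assert excise_windows([c], g, truth.features) == []

    def test_low_depth_cluster_excluded(self, sim_dataset):
        _, data = sim_dataset
        truth = data["truth"]
        g = {truth.genome.id: truth.genome.seq}
        c = _cluster("A" * 21, 4, 9000)
        assert excise_windows([c], g, truth.features, DenovoConfig(min_reads=5)) == []

    def test_window_near_chromosome_start_dropped(self):
        g = {"chr1": "ACGT" * 100}
        c = _cluster("ACGTACGTACGTACGTACGTA", 10, 20)
        wins = excise_windows([c], g, [], DenovoConfig())
        # the 5'-arm window would start at 0 exactly; the 3'-arm window
        # would end at 20+21+20-110 < 0 and must be dropped
        assert all(w.start >= 0 and w.end <= 400 for w in wins)
        assert len(wins) == 1

    def test_planted_novel_cluster_yields_true_window(self, pipeline_bundle):
        _, bundle, data = pipeline_bundle
        truth = data["truth"]
        g = {truth.genome.id: truth.genome.seq}
        wins = excise_windows(bundle["kept_clusters"], g, bundle["features"])
        for locus in (m for m in truth.mir.values() if m.novel):
            assert any(
                w.start == locus.window_start and w.end == locus.window_end for w in wins
            )


class TestEvaluateCandidate:
    def _planted_candidate(self, data, family):
        truth = data["truth"]
        locus = truth.mir[family]
        from stemsrna.denovo_mirna import CandidateWindow

        seq = truth.genome.seq[locus.window_start : locus.window_end]
        return locus, CandidateWindow(
            "chr1", locus.window_start, locus.window_end, "+", "L", None
        ), fold_hairpin(seq)

    def test_planted_hairpin_with_clean_signature_passes(self, sim_dataset):
        _, data = sim_dataset
        locus, win, st = self._planted_candidate(data, "miR-N1")
        clusters = [
            _cluster(locus.mature_seq, 80, locus.mature_start),
            _cluster(locus.star_seq, 15, locus.star_start),
            _cluster("G" * 20, 3, locus.window_start + 5),
        ]
        cand = evaluate_candidate(win, st, clusters)
        assert cand.verdict, cand.flags
        assert cand.mature_seq == locus.mature_seq
        assert cand.star_seq == locus.star_seq

    def test_uniform_reads_fail_signature(self, sim_dataset):
        _, data = sim_dataset
        locus, win, st = self._planted_candidate(data, "miR-N1")
        g = data["truth"].genome.seq
        clusters = [
            _cluster(g[p : p + 21], 10, p)
            for p in range(locus.window_start, locus.window_end - 21, 7)
        ]
        cand = evaluate_candidate(win, st, clusters)
        assert not cand.flags["signature_ok"]
        assert not cand.verdict

    def test_unpaired_mature_fails_duplex_criterion(self, sim_dataset):
        _, data = sim_dataset
        locus, win, st = self._planted_candidate(data, "miR-N1")
        # force the mature onto the unpaired 3' flank of the window
        flank_start = locus.star_end + 10
        clusters = [_cluster(data["truth"].genome.seq[flank_start : flank_start + 21], 50, flank_start)]
        cand = evaluate_candidate(win, st, clusters)
        assert not cand.verdict


class TestCallDenovo:
    def test_planted_novels_called_no_false_positives(self, pipeline_bundle):
        _, bundle, data = pipeline_bundle
        truth = data["truth"]
        called = sorted((c.window.start, c.window.end) for c in bundle["called"])
        expected = sorted(
            (m.window_start, m.window_end) for m in truth.mir.values() if m.novel
        )
        assert called == expected

    def test_called_candidates_avoid_repeats_and_known_mirs(self, pipeline_bundle):
        _, bundle, _ = pipeline_bundle
        blocked = [
            f
            for f in bundle["features"]
            if f.kind in ("repeat", "MIR_hairpin", "MIR_mature", "MIR_star")
        ]
        for c in bundle["called"]:
            w = c.window
            assert not any(f.overlaps(w.chrom, w.start, w.end) for f in blocked)

    def test_called_novels_pass_expression_filter(self, pipeline_bundle):
        _, bundle, _ = pipeline_bundle
        assert bundle["novel_expressed"] == ["novel-1", "novel-2"]
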