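"""Local-ancestry HMM, site calls, tract selection, partitioned trees."""

import numpy as np
import pytest

from phylodisc.ancestry import (AncestryTrack, call_sites, call_tracts,
                                infer_dosage, intersect_candidates,
                                partition_trees)
from phylodisc.simnet import simulate_admixed_panel
from phylodisc.sitepat import WindowStat
from phylodisc.winphylo import WindowSpec, make_windows


@pytest.fixture(scope="module")
def diverged_panel():
    gm, truth = simulate_admixed_panel(np.inf, 0.2, 10, 1e-5, seed=51,
                                       n_sites=2500, chrom_length=2_500_000,
                                       n_source=8, n_admixed=3)
    return gm, truth


@pytest.fixture(scope="module")
def diverged_tracks(diverged_panel):
    gm, _ = diverged_panel
    return infer_dosage(gm, "adm", "src1", "src2", g=[8.0, 10.0, 12.0],
                        recomb_rate=1e-5, seed=1)


def _track(dosages, pos=None):
    dosages = np.asarray(dosages, dtype=float)
    pos = np.arange(len(dosages)) if pos is None else np.asarray(pos)
    return AncestryTrack(individual="x", chrom=np.full(len(dosages), "chr1"),
                         pos=pos, dosage=dosages, g_values=(10.0,),
                         n_runs=1)


class TestCallSites:
    def test_strictly_above_threshold_is_called(self):
        tr = _track([1.6, 1.5, 0.2, 2.0])
        assert call_sites(tr).tolist() == [0, 3]

    def test_boundary_value_not_called(self):
        tr = _track([1.5])
        assert call_sites(tr).size == 0

    def test_empty_track_empty_set(self):
        tr = _track([])
        assert call_sites(tr).size == 0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        tr = _track(rng.uniform(0, 2, 500))
        lo = set(call_sites(tr, threshold=1.2).tolist())
        hi = set(call_sites(tr, threshold=1.7).tolist())
        assert hi <= lo

    def test_source_one_calls_use_complementary_dosage(self):
        tr = _track([0.2, 1.8])
        assert call_sites(tr, source=1).tolist() == [0]


class TestInferDosage:
    def test_source1_individuals_have_near_zero_dosage(self, diverged_panel):
        gm, _ = diverged_panel
        # relabel one src1 individual as "admixed" and infer its dosage
        pm = dict(gm.pop_map)
        probe = "src1-0"
        pm[probe] = "probe"
        gm2 = type(gm)(chrom=gm.chrom, pos=gm.pos, genotypes=gm.genotypes,
                       individuals=list(gm.individuals), pop_map=pm)
        [tr] = infer_dosage(gm2, "probe", "src1", "src2",
                            g=[10.0], recomb_rate=1e-5, n_runs=1, seed=3)
        assert tr.dosage.max() < 0.5

    def test_recall_precision_on_diverged_panels(self, diverged_panel,
                                                 diverged_tracks):
        gm, truth = diverged_panel
        for k, tr in enumerate(diverged_tracks):
            pred = tr.dosage > 1.5
            true = truth.dosage[:, k] == 2
            tp = (pred & true).sum()
            assert tp / max(true.sum(), 1) >= 0.8
            assert tp / max(pred.sum(), 1) >= 0.8

    def test_identical_g_values_equal_single_run(self, diverged_panel):
        gm, _ = diverged_panel
        [a] = infer_dosage(gm, "adm", "src1", "src2", g=[10.0, 10.0, 10.0],
                           recomb_rate=1e-5, n_runs=3, seed=4)[:1]
        [b] = infer_dosage(gm, "adm", "src1", "src2", g=[10.0],
                           recomb_rate=1e-5, n_runs=1, seed=5)[:1]
        assert np.allclose(a.dosage, b.dosage)

    def test_posterior_normalised(self, diverged_tracks):
        for tr in diverged_tracks:
            assert tr.dosage.min() >= 0.0
            assert tr.dosage.max() <= 2.0

    def test_indistinguishable_panels_rejected(self):
        gm, _ = simulate_admixed_panel(0.0001, 0.2, 10, 1e-5, seed=52,
                                       n_sites=50, n_source=4, n_admixed=1)
        # force the two panels to identical genotypes
        gm.genotypes[:, 4:8] = gm.genotypes[:, 0:4]
        with pytest.raises(ValueError):
            infer_dosage(gm, "adm", "src1", "src2", g=[10.0],
                         recomb_rate=1e-5, n_runs=1, seed=6)

    def test_invalid_g_rejected(self, diverged_panel):
        gm, _ = diverged_panel
        with pytest.raises(ValueError):
            infer_dosage(gm, "adm", "src1", "src2", g=[0.0],
                         recomb_rate=1e-5, n_runs=1, seed=7)


class TestCallTracts:
    def test_top_one_percent_of_thousand_windows(self):
        rng = np.random.default_rng(8)
        pos = np.arange(10_000) * 100
        tr = _track(rng.uniform(0, 2, 10_000), pos=pos)
        wins = make_windows({"chr1": 1_000_000}, 1000)
        ts = call_tracts([tr], wins, fraction=0.01)
        assert len(ts.windows) == 1000
        assert len(ts.selected) == 10

    def test_all_zero_selection_flagged_degenerate(self):
        tr = _track(np.zeros(100), pos=np.arange(100) * 100)
        wins = make_windows({"chr1": 10_000}, 1000)
        ts = call_tracts([tr], wins, fraction=0.2)
        assert ts.degenerate
        assert len(ts.selected) == 2  # ceil(0.2 * 10), lowest coordinates
        assert [s.window.start for s in ts.selected] == [0, 1000]

    def test_selected_windows_overlap_true_tracts(self, diverged_panel,
                                                  diverged_tracks):
        """Permutation oracle: observed overlap of selected windows with
        true tracts beats randomly placed selections (p < 0.05).

        The >1.5 dosage rule detects homozygous-source regions, so the
        truth set is the windows containing sites of true dosage 2; long
        tracts (low recombination) keep that truth sparse on the grid.
        """
        gm, truth = simulate_admixed_panel(
            np.inf, 0.3, 10, 2e-7, seed=60, n_sites=2500,
            chrom_length=2_500_000, n_source=8, n_admixed=1)
        tracks = infer_dosage(gm, "adm", "src1", "src2", g=[10.0],
                              recomb_rate=2e-7, n_runs=1, seed=10)
        wins = make_windows({"chr1": 2_500_000}, 10_000)
        ts = call_tracts(tracks, wins, fraction=0.05)
        hom_pos = gm.pos[truth.dosage[:, 0] == 2]
        true_windows = {w for w in wins
                        if ((hom_pos >= w.start) & (hom_pos < w.end)).any()}
        assert 0 < len(true_windows) < len(wins) // 2
        obs = sum(1 for s in ts.selected if s.window in true_windows)
        rng = np.random.default_rng(9)
        k = len(ts.selected)
        null = np.array([
            sum(1 for w in rng.choice(len(wins), k, replace=False)
                if wins[w] in true_windows)
            for _ in range(400)])
        p = (1 + (null >= obs).sum()) / 401
        assert p < 0.05


class TestIntersect:
    def _ts(self, wins, chosen):
        stats = [WindowStat(w, "dosage_sum", float(i in chosen))
                 for i, w in enumerate(wins)]
        from phylodisc.ancestry import TractSet
        return TractSet(windows=stats,
                        selected=[stats[i] for i in chosen],
                        fraction=0.1, source=2)

    def test_disjoint_selections_empty(self):
        wins = make_windows({"chr1": 50_000}, 10_000)
        ts = self._ts(wins, [0, 1])
        fd = [WindowStat(wins[i], "fd", 1.0) for i in (3, 4)]
        assert intersect_candidates(ts, fd) == []

    def test_identical_selections_preserved(self):
        wins = make_windows({"chr1": 50_000}, 10_000)
        ts = self._ts(wins, [1, 2])
        fd = [WindowStat(wins[i], "fd", 1.0) for i in (1, 2)]
        assert intersect_candidates(ts, fd) == [wins[1], wins[2]]

    def test_mismatched_grids_refused(self):
        wins = make_windows({"chr1": 50_000}, 10_000)
        other = make_windows({"chr1": 50_000}, 5_000)
        ts = self._ts(wins, [0])
        fd = [WindowStat(other[0], "fd", 1.0)]
        with pytest.raises(ValueError):
            intersect_candidates(ts, fd)


class TestPartitionTrees:
    def test_refuses_empty_partition(self, diverged_panel):
        gm, _ = diverged_panel
        with pytest.raises(ValueError):
            partition_trees(gm, [], "src1")
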