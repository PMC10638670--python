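"""Polarisation, D statistics, f4/f-branch, F_d, FST, heterozygosity."""

import math

import numpy as np
import pytest

from phylodisc.sitepat import (PolarizedFreqs, enumerate_trios, f4_ratio,
                               f_branch, fd_windows, heterozygosity_windows,
                               hudson_fst, patterson_d, polarize,
                               top_fraction, WindowStat)
from phylodisc.trees import tree_from_newick
from phylodisc.winphylo import WindowSpec, make_windows
from conftest import toy_matrix


def pf_from(freqs: dict, pos=None, chrom="chr1", outgroup="O"):
    pops = list(freqs)
    arr = np.column_stack([np.asarray(freqs[p], dtype=float) for p in pops])
    n = arr.shape[0]
    pos = np.arange(n) if pos is None else np.asarray(pos)
    return PolarizedFreqs(chrom=np.full(n, chrom), pos=pos, pops=pops,
                          freqs=arr, outgroup=outgroup)


class TestPolarize:
    def test_outgroup_fixed_ref_keeps_alt_frequency(self):
        gm = toy_matrix([[2, 1, 0], [0, 2, 0]],
                        {"A": "A", "B": "B", "O": "O"}, outgroup="O")
        pf = polarize(gm)
        assert pf.pop("A").tolist() == [1.0, 0.0]
        assert pf.pop("B").tolist() == [0.5, 1.0]

    def test_outgroup_fixed_alt_flips(self):
        gm = toy_matrix([[2, 0, 2]], {"A": "A", "B": "B", "O": "O"},
                        outgroup="O")
        pf = polarize(gm)
        assert pf.pop("A")[0] == 0.0
        assert pf.pop("B")[0] == 1.0

    def test_polymorphic_or_missing_outgroup_dropped(self):
        gm = toy_matrix([[2, 0, 1], [2, 0, -1], [2, 0, 0]],
                        {"A": "A", "B": "B", "O": "O"}, outgroup="O")
        pf = polarize(gm)
        assert pf.n_sites == 1

    def test_hand_enumerated_table(self):
        # 5 sites, 2 outgroup individuals
        gm = toy_matrix(
            [[2, 2, 0, 0],    # kept, derived A=1
             [0, 2, 2, 2],    # outgroup fixed alt -> flip: A=1, B=0
             [1, 0, 0, 2],    # outgroup polymorphic across inds -> drop
             [2, 1, 0, 0],    # kept: A=1, B=0.5
             [0, 0, 2, 2]],   # flip: A=1, B=1
            {"A": "A", "B": "B", "O1": "O", "O2": "O"}, outgroup="O")
        pf = polarize(gm)
        assert pf.n_sites == 4
        assert pf.pop("A").tolist() == [1.0, 1.0, 1.0, 1.0]
        assert pf.pop("B").tolist() == [1.0, 0.0, 0.5, 1.0]


class TestPattersonD:
    def test_trivial_abba_baba_ratio(self):
        # 30 pure ABBA sites and 10 pure BABA sites -> D = 0.5
        p1 = [0.0] * 30 + [1.0] * 10
        p2 = [1.0] * 30 + [0.0] * 10
        p3 = [1.0] * 40
        pf = pf_from({"P1": p1, "P2": p2, "P3": p3},
                     pos=np.arange(40) * 50)
        r = patterson_d(pf, "P1", "P2", "P3", block_size=500)
        assert r.d == pytest.approx((30 - 10) / (30 + 10))

    def test_equal_p1_p2_gives_exactly_zero(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 200)
        p3 = rng.uniform(0, 1, 200)
        pf = pf_from({"P1": p, "P2": p.copy(), "P3": p3})
        r = patterson_d(pf, "P1", "P2", "P3", block_size=10)
        assert r.d == 0.0

    def test_antisymmetric_under_p1_p2_swap(self):
        rng = np.random.default_rng(1)
        pf = pf_from({"P1": rng.uniform(0, 1, 300),
                      "P2": rng.uniform(0, 1, 300),
                      "P3": rng.uniform(0, 1, 300)})
        a = patterson_d(pf, "P1", "P2", "P3", block_size=15)
        b = patterson_d(pf, "P2", "P1", "P3", block_size=15)
        assert a.d == pytest.approx(-b.d, abs=1e-12)

    def test_zero_denominator_flagged_undefined(self):
        pf = pf_from({"P1": [0.0] * 5, "P2": [0.0] * 5, "P3": [0.0] * 5})
        r = patterson_d(pf, "P1", "P2", "P3")
        assert not r.defined

    def test_jackknife_se_tracks_multinomial_se(self):
        """On i.i.d. sites the block jackknife SE must approach the
        analytic multinomial SE of D (ratio within [0.8, 1.25])."""
        rng = np.random.default_rng(5)
        n = 100_000
        # each site independently ABBA (p=0.3), BABA (p=0.2) or neither
        u = rng.random(n)
        abba = (u < 0.3).astype(float)
        baba = ((u >= 0.3) & (u < 0.5)).astype(float)
        pf = pf_from({"P1": baba, "P2": abba, "P3": abba + baba})
        r = patterson_d(pf, "P1", "P2", "P3", block_size=2000)
        # analytic: D = (A-B)/(A+B) for multinomial counts
        pA, pB = 0.3, 0.2
        m = n * (pA + pB)
        d = (pA - pB) / (pA + pB)
        se_analytic = math.sqrt((1 - d ** 2) / m)
        assert 0.8 <= r.se / se_analytic <= 1.25


class TestEnumerateTrios:
    LADDER = "((((A:1,B:2):1,C:3):1,D:4):1,O:5);"

    def test_ladder_orderings_match_manual_reading(self):
        sp = tree_from_newick(self.LADDER)
        trios = dict(enumerate_trios(sp, ["A", "B", "C", "D"]))
        assert set(trios) == {("A", "B", "C"), ("A", "B", "D"),
                              ("A", "C", "D"), ("B", "C", "D")}

    def test_combinatorial_count_for_sixteen_taxa(self):
        taxa = [f"T{i:02d}" for i in range(16)]
        nwk = taxa[0]
        for t in taxa[1:]:
            nwk = f"({nwk},{t})"
        sp = tree_from_newick(nwk + ";")
        trios = enumerate_trios(sp, taxa)
        assert len(trios) == 560  # C(16,3)

    def test_root_spanning_triple_puts_lone_taxon_outside(self):
        sp = tree_from_newick("(((A:1,B:1):1,C:2):1,(D:2,E:2):1);")
        trios = dict(enumerate_trios(sp, ["A", "D", "E"]))
        assert ("D", "E", "A") in trios


class TestF4Ratio:
    def test_donor_identical_to_b_gives_ratio_one(self):
        rng = np.random.default_rng(2)
        pc = rng.uniform(0, 1, 100)
        pb = pc.copy()   # B == C (B carries the full donor signal)
        pa = np.zeros(100)
        pf = pf_from({"A": pa, "B": pb, "C": pc})
        r = f4_ratio(pf, "A", "B", "C")
        assert r.ratio == pytest.approx(1.0)

    def test_hand_computed_six_site_table(self):
        pf = pf_from({"A": [0.0, 0.5, 1.0, 0.0, 0.2, 0.0],
                      "B": [1.0, 0.5, 0.0, 0.5, 0.8, 0.0],
                      "C": [1.0, 1.0, 0.5, 0.5, 0.6, 0.0]})
        pa, pb, pc = (np.asarray(pf.pop(x)) for x in "ABC")
        num = ((1 - pa) * pb * pc - pa * (1 - pb) * pc).sum()
        pd = np.maximum(pb, pc)
        den = ((1 - pa) * pd * pc - pa * (1 - pd) * pc).sum()
        r = f4_ratio(pf, "A", "B", "C")
        assert r.raw == pytest.approx(num / den)


class TestFBranch:
    def test_toy_min_of_medians(self):
        # branch with descendants {B1,B2}, sister {A1,A2}, donor C
        sp = tree_from_newick("(((A1:1,A2:1):1,(B1:2,B2:2):1):1,"
                              "(C:3,O:3):1);")
        rng = np.random.default_rng(3)
        freqs = {p: rng.uniform(0, 1, 50)
                 for p in ("A1", "A2", "B1", "B2", "C")}
        pf = pf_from(freqs)
        cells = {(c.branch_id, c.donor): c
                 for c in f_branch(sp, pf, ["A1", "A2", "B1", "B2", "C"])}
        cell = cells[("B1,B2", "C")]
        med = []
        for b in ("B1", "B2"):
            ratios = [f4_ratio(pf, a, b, "C").ratio for a in ("A1", "A2")]
            med.append(np.median(ratios))
        assert cell.value == pytest.approx(min(med))

    def test_donor_inside_clade_gives_no_cell(self):
        sp = tree_from_newick("(((A:1,B:1):1,C:2):1,O:3);")
        rng = np.random.default_rng(4)
        pf = pf_from({p: rng.uniform(0, 1, 20) for p in "ABC"})
        cells = {(c.branch_id, c.donor) for c in f_branch(sp, pf, list("ABC"))}
        assert ("A,B", "A") not in cells
        assert ("A,B", "B") not in cells


class TestFdWindows:
    def test_equal_p1_p2_gives_zero(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(0.1, 0.9, 100)
        p3 = np.ones(100) * 0.8
        pf = pf_from({"P1": p, "P2": p.copy(), "P3": p3})
        wins = [WindowSpec("chr1", 0, 100)]
        [w] = fd_windows(pf, "P1", "P2", "P3", wins)
        assert w.value == pytest.approx(0.0)

    def test_full_donor_haplotype_gives_one(self):
        rng = np.random.default_rng(7)
        p3 = rng.uniform(0.5, 1.0, 100)
        pf = pf_from({"P1": np.zeros(100), "P2": p3.copy(), "P3": p3})
        [w] = fd_windows(pf, "P1", "P2", "P3",
                         [WindowSpec("chr1", 0, 100)])
        assert w.value == pytest.approx(1.0)

    def test_negative_numerator_undefined(self):
        pf = pf_from({"P1": [1.0] * 10, "P2": [0.0] * 10,
                      "P3": [1.0] * 10})
        [w] = fd_windows(pf, "P1", "P2", "P3",
                         [WindowSpec("chr1", 0, 10)])
        assert not w.defined


class TestTopFraction:
    def _stats(self, values):
        return [WindowStat(WindowSpec("chr1", i * 10, i * 10 + 10), "fd", v)
                for i, v in enumerate(values)]

    def test_five_percent_of_thousand_is_fifty(self):
        rng = np.random.default_rng(8)
        sel = top_fraction(self._stats(rng.random(1000)), 0.05)
        assert len(sel) == 50

    def test_one_percent_is_ten(self):
        rng = np.random.default_rng(9)
        sel = top_fraction(self._stats(rng.random(1000)), 0.01)
        assert len(sel) == 10

    def test_ties_resolved_by_genomic_order(self):
        sel = top_fraction(self._stats([1.0] * 100), 0.05)
        assert [s.window.start for s in sel] == [0, 10, 20, 30, 40]

    def test_undefined_windows_not_counted(self):
        vals = [math.nan] * 50 + list(np.linspace(0, 1, 50))
        sel = top_fraction(self._stats(vals), 0.1)
        assert len(sel) == 5  # ceil(0.1 * 50 defined)


class TestHudsonFst:
    def test_identical_frequencies_give_zero_expectation(self):
        rng = np.random.default_rng(10)
        # two large samples from the same population
        p = rng.uniform(0.2, 0.8, 500)
        ga = rng.binomial(2, p[:, None], (500, 30)).astype(np.int8)
        gb = rng.binomial(2, p[:, None], (500, 30)).astype(np.int8)
        pops = {f"a{i}": "A" for i in range(30)}
        pops.update({f"b{i}": "B" for i in range(30)})
        gm = toy_matrix(np.hstack([ga, gb]), pops)
        assert hudson_fst(gm, "A", "B") == pytest.approx(0.0, abs=0.02)

    def test_fixed_difference_approaches_one(self):
        ga = np.full((100, 20), 0, dtype=np.int8)
        gb = np.full((100, 20), 2, dtype=np.int8)
        pops = {f"a{i}": "A" for i in range(20)}
        pops.update({f"b{i}": "B" for i in range(20)})
        gm = toy_matrix(np.hstack([ga, gb]), pops)
        assert hudson_fst(gm, "A", "B") == pytest.approx(1.0)

    def test_matches_independent_site_by_site_oracle(self):
        rng = np.random.default_rng(11)
        p1 = rng.uniform(0.05, 0.95, 300)
        p2 = np.clip(p1 + rng.normal(0, 0.2, 300), 0, 1)
        n1, n2 = 12, 8
        ga = rng.binomial(2, p1[:, None], (300, n1)).astype(np.int8)
        gb = rng.binomial(2, p2[:, None], (300, n2)).astype(np.int8)
        pops = {f"a{i}": "A" for i in range(n1)}
        pops.update({f"b{i}": "B" for i in range(n2)})
        gm = toy_matrix(np.hstack([ga, gb]), pops)
        # oracle: independent re-implementation, python loop per site
        N_sum = D_sum = 0.0
        for i in range(300):
            x1 = ga[i].sum() / (2 * n1)
            x2 = gb[i].sum() / (2 * n2)
            N = (x1 - x2) ** 2 - x1 * (1 - x1) / (2 * n1 - 1) - \
                x2 * (1 - x2) / (2 * n2 - 1)
            D = x1 * (1 - x2) + x2 * (1 - x1)
            if D > 0:
                N_sum += N
                D_sum += D
        assert hudson_fst(gm, "A", "B") == pytest.approx(N_sum / D_sum)

    def test_no_polymorphic_site_undefined(self):
        gm = toy_matrix([[0, 0], [0, 0]], {"a": "A", "b": "B"})
        assert math.isnan(hudson_fst(gm, "A", "B"))


class TestHeterozygosity:
    def test_all_homozygous_is_zero(self):
        gm = toy_matrix([[0, 2]] * 10, {"x": "X", "y": "Y"},
                        pos=np.arange(10) * 1000)
        wins = make_windows({"chr1": 100_000}, 100_000)
        out = heterozygosity_windows(gm, wins)
        assert out["x"][0].value == 0.0

    def test_panmictic_rate_matches_coalescent_expectation(self):
        """Two haplotypes from one panmictic species: expected pairwise
        branch length is 2*E[T2] = 2 coalescent units, so the het rate
        per bp is 2 * mut_rate."""
        from phylodisc.simnet import (SpeciesNetwork, simulate_gene_trees,
                                      simulate_genotypes)
        net = SpeciesNetwork(newick="(A:1.0,B:1.0);")
        trees = simulate_gene_trees(net, 300, seed=91,
                                    samples={"A": 2, "B": 0})
        gm = simulate_genotypes(trees, 1000, mut_rate=0.01, seed=92,
                                diploid_pairing=True)
        wins = make_windows({"chr1": 300_000}, 300_000)
        out = heterozygosity_windows(gm, wins)
        rate = out["A-0"][0].value
        assert rate == pytest.approx(0.02, rel=0.25)

    def test_fifty_hets_in_100kb_is_5e4(self):
        genos = np.array([[1, 0]] * 50 + [[0, 0]] * 10, dtype=np.int8)
        gm = toy_matrix(genos, {"x": "X", "y": "Y"},
                        pos=np.arange(60) * 100)
        wins = make_windows({"chr1": 100_000}, 100_000)
        out = heterozygosity_windows(gm, wins)
        assert out["x"][0].value == pytest.approx(5e-4)
        assert out["y"][0].value == 0.0
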