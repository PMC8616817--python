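import itertools

import numpy as np
import pytest

from rpfdp.errors import EmptyPeakListError, EmptyShiftTableError
from rpfdp.proton_model import (
    ModelDistanceGraph,
    ProtonSite,
    build_distance_graph,
    build_proton_sites,
    r6_matrix,
)
from rpfdp.rpf_core import (
    AmbiguousNoeGraph,
    Classification,
    MatchTolerance,
    classify,
    contact_records,
    f_free,
    f_ideal,
    match_peaks,
    precision_weighted,
    score_rpf,
)
from rpfdp.synth_bench import make_noesy, make_world, SynthConfig
from rpfdp.types import AssignedShift, AtomRef, Conformer, NoesyPeak, PeakList


def _site(gid, ref, shift):
    return ProtonSite(gid, (ref,), ref.atom_name, (shift,))


class TestMatchPeaks:
    def _spec_example(self):
        """Three shifts, one N-edited peak; oracle = brute force over pairs."""
        refs = {
            "R15H": AtomRef("A", 15, "ARG", "H"),
            "R15N": AtomRef("A", 15, "ARG", "N"),
            "K3HA": AtomRef("A", 3, "LYS", "HA"),
            "E7HA": AtomRef("A", 7, "GLU", "HA"),
        }
        shifts = [
            AssignedShift(refs["R15H"], 8.21),
            AssignedShift(refs["R15N"], 120.5),
            AssignedShift(refs["K3HA"], 3.40),
            AssignedShift(refs["E7HA"], 3.43),
        ]
        sites = [
            _site("A.3.HA", refs["K3HA"], 3.40),
            _site("A.7.HA", refs["E7HA"], 3.43),
            _site("A.15.H", refs["R15H"], 8.21),
        ]
        peak = NoesyPeak(1, (3.41, 120.4, 8.20), ("H_indirect", "N_edit", "H_acq"))
        return shifts, sites, PeakList([peak], spectrum_label="t")

    def test_edited_match_brute_force_oracle(self):
        shifts, sites, plist = self._spec_example()
        tol = MatchTolerance(0.03, 0.4, 0.4)
        graph = match_peaks(plist, shifts, sites, tol)
        got = {
            tuple(sorted((sites[i].group_id, sites[j].group_id)))
            for i, j in graph.candidates[("t", 1)]
        }
        # brute-force oracle over all ordered site pairs
        expected = set()
        shift_of = {s.group_id: s.shifts[0] for s in sites}
        n_of = {"A.15.H": 120.5}  # attached 15N shift (only the amide has one)
        for a, b in itertools.permutations(sites, 2):
            if abs(shift_of[a.group_id] - 3.41) > 0.03:
                continue
            if abs(shift_of[b.group_id] - 8.20) > 0.03:
                continue
            if b.group_id not in n_of or abs(n_of[b.group_id] - 120.4) > 0.4:
                continue
            expected.add(tuple(sorted((a.group_id, b.group_id))))
        assert got == expected
        assert got == {("A.15.H", "A.3.HA"), ("A.15.H", "A.7.HA")}

    def test_zero_tolerance_exact_pair(self, small_world):
        sites = build_proton_sites(small_world.structure, small_world.shifts)
        tol = MatchTolerance(1e-9, 1e-6, 1e-6)
        graph = match_peaks(small_world.peaks_2d, small_world.shifts, sites, tol)
        # with exact synthetic shifts, at least the generating pair matches,
        # and every usable peak has at least one candidate
        assert graph.n_usable + len(graph.diagonal_peaks) + len(
            graph.unmatched_peaks
        ) == len(small_world.peaks_2d)
        assert graph.n_usable > 0

    def test_far_peak_unmatched(self):
        shifts, sites, _ = self._spec_example()
        peak = NoesyPeak(9, (99.0, 98.0), ("H_indirect", "H_acq"))
        graph = match_peaks(
            PeakList([peak], spectrum_label="u"), shifts, sites, MatchTolerance()
        )
        assert graph.unmatched_peaks == [("u", 9)]
        assert graph.candidates == {}

    def test_diagonal_peak_set_aside(self):
        shifts, sites, _ = self._spec_example()
        peak = NoesyPeak(2, (8.20, 8.21), ("H_indirect", "H_acq"))
        graph = match_peaks(
            PeakList([peak], spectrum_label="d"), shifts, sites, MatchTolerance()
        )
        assert graph.diagonal_peaks == [("d", 2)]

    def test_empty_shift_table_rejected(self):
        _, sites, plist = self._spec_example()
        with pytest.raises(EmptyShiftTableError):
            match_peaks(plist, [], sites, MatchTolerance())


def _toy_universe():
    """Four singleton sites with well-separated shifts; r6 built by hand."""
    sites = []
    for k, (num, shift) in enumerate([(1, 1.0), (2, 2.0), (3, 3.0), (4, 4.0)]):
        ref = AtomRef("A", num, "GLY", "HA2")
        sites.append(ProtonSite(f"s{k}", (ref,), "HA2", (shift,)))
    return sites


def _graph_from_distances(sites, dists, d_max=5.0):
    n = len(sites)
    r6 = np.zeros((n, n))
    for (i, j), d in dists.items():
        r6[i, j] = r6[j, i] = d**-6.0
    return ModelDistanceGraph(sites=list(sites), r6_sum=r6, d_max=d_max)


class TestClassify:
    def test_sole_candidate_tp(self):
        sites = _toy_universe()
        g = _graph_from_distances(sites, {(0, 1): 4.0})
        anoe = AmbiguousNoeGraph(sites, {("x", 1): ((0, 1),)}, [], [])
        cls = classify(g, anoe)
        assert (cls.tp, cls.fn, cls.fp) == (1, 0, 0)

    def test_any_candidate_rule(self):
        sites = _toy_universe()
        g = _graph_from_distances(sites, {(2, 3): 4.0})  # only (c,d) short
        anoe = AmbiguousNoeGraph(sites, {("x", 1): ((0, 1), (2, 3))}, [], [])
        cls = classify(g, anoe)
        assert cls.tp == 1 and cls.fn == 0

    def test_unsupported_edge_is_fp(self):
        sites = _toy_universe()
        g = _graph_from_distances(sites, {(0, 1): 4.0, (2, 3): 3.0})
        anoe = AmbiguousNoeGraph(sites, {("x", 1): ((0, 1),)}, [], [])
        cls = classify(g, anoe)
        assert cls.fp == 1
        assert cls.unsupported_edges == [(2, 3)]

    def test_brute_force_equivalence_random_instances(self):
        rng = np.random.default_rng(123)
        for trial in range(20):
            n = int(rng.integers(5, 40))
            refs = [AtomRef("A", i + 1, "GLY", "HA2") for i in range(n)]
            shifts_vals = rng.uniform(0, 10, size=n)
            sites = [
                ProtonSite(f"s{i}", (refs[i],), "HA2", (float(shifts_vals[i]),))
                for i in range(n)
            ]
            conf = Conformer([(r, rng.uniform(0, 15, size=3)) for r in refs])
            g = build_distance_graph(sites, conf, d_max=5.0)
            # random peaks with random candidate sets
            candidates = {}
            for p in range(int(rng.integers(1, 15))):
                k = int(rng.integers(1, 4))
                pairs = set()
                while len(pairs) < k:
                    i, j = rng.integers(0, n, size=2)
                    if i != j:
                        pairs.add((min(i, j), max(i, j)))
                candidates[("x", p)] = tuple(sorted((int(a), int(b)) for a, b in pairs))
            tol = MatchTolerance(tol_h=0.0)  # no diagonal exclusion
            anoe = AmbiguousNoeGraph(sites, candidates, [], [])
            cls = classify(g, anoe, tol)

            # oracle: exhaustive O(n^2) reference (0.5 A clash floor applies)
            dist = np.full((n, n), np.inf)
            for i in range(n):
                for j in range(n):
                    if i != j:
                        dist[i, j] = max(
                            0.5, float(np.linalg.norm(conf[refs[i]] - conf[refs[j]]))
                        )
            edge = dist <= 5.0
            tp = fn = 0
            for pairs in candidates.values():
                if any(edge[i, j] for i, j in pairs):
                    tp += 1
                else:
                    fn += 1
            cand_union = {p for pairs in candidates.values() for p in pairs}
            fp_edges = {
                (i, j)
                for i in range(n)
                for j in range(i + 1, n)
                if edge[i, j] and (i, j) not in cand_union
            }
            assert (cls.tp, cls.fn, cls.fp) == (tp, fn, len(fp_edges))
            assert set(cls.unsupported_edges) == fp_edges
            # weighted precision against the same oracle
            w_tp = sum(
                dist[i, j] ** -6.0
                for (i, j) in cand_union
                if edge[i, j]
            )
            w_fp = sum(dist[i, j] ** -6.0 for i, j in fp_edges)
            if w_tp + w_fp > 0:
                assert precision_weighted(cls, g) == pytest.approx(
                    w_tp / (w_tp + w_fp), rel=1e-9
                )


class TestPrecisionWeighted:
    def test_no_fp_is_one(self):
        sites = _toy_universe()
        g = _graph_from_distances(sites, {(0, 1): 2.5})
        cls = Classification([("x", 1)], [], [(0, 1)], [], [], 0)
        assert precision_weighted(cls, g) == 1.0

    def test_equal_distance_symmetry(self):
        sites = _toy_universe()
        g = _graph_from_distances(sites, {(0, 1): 2.5, (2, 3): 2.5})
        cls = Classification([("x", 1)], [], [(0, 1)], [(2, 3)], [], 0)
        assert precision_weighted(cls, g) == pytest.approx(0.5)

    def test_distance_weighting_oracle(self):
        # TP at 2 A, FP at 4 A: (2^-6)/(2^-6 + 4^-6) = 64/65
        sites = _toy_universe()
        g = _graph_from_distances(sites, {(0, 1): 2.0, (2, 3): 4.0})
        cls = Classification([("x", 1)], [], [(0, 1)], [(2, 3)], [], 0)
        assert precision_weighted(cls, g) == pytest.approx(64.0 / 65.0, rel=1e-12)


class TestFIdeal:
    def test_all_local_pairs_peaked(self, small_world):
        sites = build_proton_sites(small_world.structure, small_world.shifts)
        anoe = match_peaks(
            small_world.peaks_2d, small_world.shifts, sites, MatchTolerance()
        )
        ref_r6 = r6_matrix(sites, small_world.structure)
        assert f_ideal(anoe, ref_r6, MatchTolerance()) == pytest.approx(1.0)

    def test_half_local_pairs_arithmetic_oracle(self):
        # two geminal GLY pairs with equal weights; exactly one has a
        # supporting peak: precision = 0.5, F = 2 * 1 * 0.5 / 1.5 = 2/3
        refs = [
            AtomRef("A", 1, "GLY", "HA2"), AtomRef("A", 1, "GLY", "HA3"),
            AtomRef("A", 2, "GLY", "HA2"), AtomRef("A", 2, "GLY", "HA3"),
        ]
        sites = [
            ProtonSite("g1", (refs[0],), "HA2", (3.9,)),
            ProtonSite("g2", (refs[1],), "HA3", (3.5,)),
            ProtonSite("g3", (refs[2],), "HA2", (4.1,)),
            ProtonSite("g4", (refs[3],), "HA3", (4.4,)),
        ]
        n = 4
        r6 = np.full((n, n), 1.75**-6.0)
        np.fill_diagonal(r6, 0.0)
        anoe = AmbiguousNoeGraph(sites, {("x", 1): ((0, 1),)}, [], [])
        f = f_ideal(anoe, r6, MatchTolerance(tol_h=0.0))
        assert f == pytest.approx(2.0 / 3.0, rel=1e-9)

    def test_upper_bound_on_noise_free_data(self, small_world):
        sites = build_proton_sites(small_world.structure, small_world.shifts)
        anoe = match_peaks(
            small_world.peaks_2d, small_world.shifts, sites, MatchTolerance()
        )
        rep = score_rpf(
            small_world.structure, small_world.shifts, small_world.peaks_2d,
            mode="single", free_chain_size=20, protonate=False,
        )
        assert rep.f_ideal >= rep.per_conformer[0].f_measure - 1e-9


class TestFFree:
    def test_seeded_determinism(self, small_world):
        sites = build_proton_sites(small_world.structure, small_world.shifts)
        anoe = match_peaks(
            small_world.peaks_2d, small_world.shifts, sites, MatchTolerance()
        )
        v1 = f_free(anoe, seed=4, n_conformers=30)
        v2 = f_free(anoe, seed=4, n_conformers=30)
        assert v1 == v2

    def test_convergence_in_m(self, bench_world):
        sites = build_proton_sites(bench_world.structure, bench_world.shifts)
        anoe = match_peaks(
            bench_world.peaks_2d, bench_world.shifts, sites, MatchTolerance()
        )
        v100 = f_free(anoe, seed=4, n_conformers=100)
        v200 = f_free(anoe, seed=9, n_conformers=200)
        assert abs(v100 - v200) < 0.02

    def test_below_true_model_f(self, small_world):
        rep = score_rpf(
            small_world.structure, small_world.shifts, small_world.peaks_2d,
            mode="single", free_chain_size=50, protonate=False,
        )
        assert rep.f_free <= rep.per_conformer[0].f_measure


class TestScoreRpf:
    def test_true_model_high_dp(self, small_world):
        rep = score_rpf(
            small_world.structure, small_world.shifts, small_world.peaks_2d,
            mode="single", free_chain_size=50, protonate=False,
        )
        r = rep.per_conformer[0]
        assert r.recall == pytest.approx(1.0)
        assert r.precision_w == pytest.approx(1.0)
        assert r.dp >= 0.9

    def test_dp_one_when_f_equals_f_ideal(self, small_world):
        rep = score_rpf(
            small_world.structure, small_world.shifts, small_world.peaks_2d,
            mode="single", free_chain_size=50, protonate=False,
        )
        r = rep.per_conformer[0]
        # noise-free closed loop: F == F_ideal, so DP is exactly 1
        assert r.f_measure == pytest.approx(rep.f_ideal)
        assert r.dp == pytest.approx(1.0, abs=1e-9)

    def test_empty_usable_peaks_rejected(self, small_world):
        far = PeakList(
            [NoesyPeak(1, (90.0, 95.0), ("H_indirect", "H_acq"))],
            spectrum_label="far",
        )
        with pytest.raises(EmptyPeakListError):
            score_rpf(
                small_world.structure, small_world.shifts, far,
                mode="single", free_chain_size=5, protonate=False,
            )

    def test_per_residue_maps_populated_for_fn(self, small_world):
        # drop half the model's edges by perturbing coordinates: FNs appear
        rng = np.random.default_rng(0)
        noisy = small_world.structure.with_coords(
            small_world.structure.coords + rng.normal(0, 2.0, small_world.structure.coords.shape)
        )
        rep = score_rpf(
            noisy, small_world.shifts, small_world.peaks_2d,
            mode="single", free_chain_size=20, protonate=False,
        )
        r = rep.per_conformer[0]
        assert r.fn > 0
        assert sum(r.per_residue_recall_viol.values()) > 0
        # each FN peak contributes 2 * (1/ncand) * ncand = 2 total
        assert sum(r.per_residue_recall_viol.values()) == pytest.approx(2.0 * r.fn)

    def test_mode_validation(self, small_world):
        with pytest.raises(ValueError):
            score_rpf(
                small_world.structure, small_world.shifts, small_world.peaks_2d,
                mode="bogus",
            )


class TestContactRecords:
    def test_records_cover_all_candidates(self, small_world):
        sites = build_proton_sites(small_world.structure, small_world.shifts)
        anoe = match_peaks(
            small_world.peaks_2d, small_world.shifts, sites, MatchTolerance()
        )
        records = contact_records(anoe)
        assert len(records) == sum(len(p) for p in anoe.candidates.values())
        assert {r.peak_id for r in records} == {
            pid for _, pid in anoe.candidates
        }
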