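import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rpfdp.chain import build_conformer
from rpfdp.errors import OverlappingSitesError, ProtonPlacementWarning
from rpfdp.proton_model import (
    ProtonSite,
    add_hydrogens,
    build_distance_graph,
    build_proton_sites,
    summation_distance,
)
from rpfdp.types import AssignedShift, AtomRef, Conformer


def _site(gid, members, shifts=()):
    return ProtonSite(gid, tuple(members), gid.split(".")[-1], tuple(shifts))


def _singleton(name, resnum, xyz):
    ref = AtomRef("A", resnum, "GLY", name)
    return ref, xyz


class TestAddHydrogens:
    def test_ha_bond_length(self):
        conf = build_conformer(["ALA", "ALA"], [-57, -57], [-47, -47],
                               add_protons=False)
        protonated = add_hydrogens(conf)
        ha = protonated[AtomRef("A", 1, "ALA", "HA")]
        ca = protonated[AtomRef("A", 1, "ALA", "CA")]
        assert np.linalg.norm(ha - ca) == pytest.approx(1.09, abs=1e-6)

    def test_already_protonated_unchanged(self):
        conf = build_conformer(["ALA", "VAL"], [-57, -57], [-47, -47])
        again = add_hydrogens(conf)
        assert len(again) == len(conf)
        assert set(again.atoms) == set(conf.atoms)

    def test_collinear_frame_warns_and_skips(self):
        # degenerate geometry: N, CA, CB on a line leaves the HB methyl
        # rotor frame undefined
        conf = Conformer(
            [
                (AtomRef("A", 1, "ALA", "N"), (0.0, 0.0, 0.0)),
                (AtomRef("A", 1, "ALA", "CA"), (1.5, 0.0, 0.0)),
                (AtomRef("A", 1, "ALA", "C"), (3.0, 0.0, 0.0)),
                (AtomRef("A", 1, "ALA", "CB"), (4.5, 0.0, 0.0)),
                (AtomRef("A", 1, "ALA", "O"), (6.0, 0.0, 0.0)),
            ]
        )
        with pytest.warns(ProtonPlacementWarning):
            out = add_hydrogens(conf)
        assert AtomRef("A", 1, "ALA", "HB1") not in out

    def test_missing_heavy_atom_skips_dependents(self):
        conf = Conformer(
            [
                (AtomRef("A", 1, "ALA", "N"), (0.0, 0.0, 0.0)),
                (AtomRef("A", 1, "ALA", "CA"), (1.5, 0.0, 0.2)),
                (AtomRef("A", 1, "ALA", "C"), (2.1, 1.3, 0.4)),
                (AtomRef("A", 1, "ALA", "O"), (1.6, 2.4, 0.4)),
                # CB missing: HA and the HB methyl cannot be placed
            ]
        )
        with pytest.warns(ProtonPlacementWarning):
            out = add_hydrogens(conf)
        assert AtomRef("A", 1, "ALA", "HB1") not in out

    def test_all_residue_types_protonate(self, small_world):
        # every placeable proton of every residue type gets coordinates
        conf = small_world.structure
        names = {a.atom_name for a in conf if a.atom_name.startswith("H")}
        assert names  # fixture is protonated by construction


class TestBuildProtonSites:
    def _shifts(self, conf, values):
        return [
            AssignedShift(ref, val, amb)
            for ref, val, amb in values
            if ref in conf
        ]

    def test_methyl_grouped(self):
        conf = build_conformer(["ALA", "ALA"], [-57, -57], [-47, -47])
        refs = [AtomRef("A", 1, "ALA", f"HB{i}") for i in (1, 2, 3)]
        shifts = [AssignedShift(r, 1.39) for r in refs]
        sites = build_proton_sites(conf, shifts)
        methyl = [s for s in sites if s.representative_name == "QB"]
        assert len(methyl) == 1
        assert set(methyl[0].members) == set(refs)

    def test_gly_distinct_shifts_stay_singletons(self):
        conf = build_conformer(["GLY", "GLY"], [-57, -57], [-47, -47])
        shifts = [
            AssignedShift(AtomRef("A", 1, "GLY", "HA2"), 3.96, 1),
            AssignedShift(AtomRef("A", 1, "GLY", "HA3"), 3.90, 1),
        ]
        sites = build_proton_sites(conf, shifts)
        assert sorted(len(s.members) for s in sites) == [1, 1]

    def test_gly_identical_shifts_merge(self):
        conf = build_conformer(["GLY", "GLY"], [-57, -57], [-47, -47])
        shifts = [
            AssignedShift(AtomRef("A", 1, "GLY", "HA2"), 3.93, 1),
            AssignedShift(AtomRef("A", 1, "GLY", "HA3"), 3.93, 1),
        ]
        sites = build_proton_sites(conf, shifts)
        assert len(sites) == 1 and len(sites[0].members) == 2

    def test_val_isopropyl_six_member_site(self):
        conf = build_conformer(["VAL", "ALA"], [-57, -57], [-47, -47])
        shifts = [
            AssignedShift(AtomRef("A", 1, "VAL", f"HG{g}{i}"), 0.91, 2)
            for g in (1, 2)
            for i in (1, 2, 3)
        ]
        sites = build_proton_sites(conf, shifts)
        assert len(sites) == 1
        assert len(sites[0].members) == 6
        assert sites[0].representative_name == "QQG"

    def test_ambiguity_2_merges_despite_distinct_shifts(self):
        conf = build_conformer(["ASP", "ALA"], [-57, -57], [-47, -47])
        shifts = [
            AssignedShift(AtomRef("A", 1, "ASP", "HB2"), 2.72, 2),
            AssignedShift(AtomRef("A", 1, "ASP", "HB3"), 2.65, 2),
        ]
        sites = build_proton_sites(conf, shifts)
        merged = [s for s in sites if len(s.members) == 2]
        assert len(merged) == 1
        assert merged[0].shifts == (2.65, 2.72)

    def test_unmapped_assignment_warns_not_fatal(self):
        conf = build_conformer(["ALA", "ALA"], [-57, -57], [-47, -47])
        shifts = [
            AssignedShift(AtomRef("A", 1, "ALA", "HA"), 4.32),
            AssignedShift(AtomRef("A", 9, "ALA", "HA"), 4.40),  # absent residue
        ]
        with pytest.warns(UserWarning, match="no matching proton"):
            sites = build_proton_sites(conf, shifts)
        assert len(sites) == 1


class TestSummationDistance:
    def test_two_singletons(self):
        a = _site("A.1.H1", [AtomRef("A", 1, "GLY", "HA2")])
        b = _site("A.2.H2", [AtomRef("A", 2, "GLY", "HA2")])
        conf = Conformer(
            [
                (AtomRef("A", 1, "GLY", "HA2"), (0.0, 0.0, 0.0)),
                (AtomRef("A", 2, "GLY", "HA2"), (3.0, 0.0, 0.0)),
            ]
        )
        assert summation_distance(a, b, conf) == pytest.approx(3.0, abs=1e-9)

    def test_singleton_vs_pair_oracle(self):
        # both members exactly 3.0 A away: (2 * 3^-6)^(-1/6) by arithmetic
        a = _site("A.1.H", [AtomRef("A", 1, "GLY", "HA2")])
        b = ProtonSite(
            "A.2.Q",
            (AtomRef("A", 2, "GLY", "HA2"), AtomRef("A", 2, "GLY", "HA3")),
            "QA",
        )
        conf = Conformer(
            [
                (AtomRef("A", 1, "GLY", "HA2"), (0.0, 0.0, 0.0)),
                (AtomRef("A", 2, "GLY", "HA2"), (3.0, 0.0, 0.0)),
                (AtomRef("A", 2, "GLY", "HA3"), (0.0, 3.0, 0.0)),
            ]
        )
        expected = (2.0 * 3.0**-6) ** (-1 / 6)
        assert summation_distance(a, b, conf) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(3.0 * 2 ** (-1 / 6), abs=1e-12)

    def test_ensemble_average_oracle(self):
        # pair at 3.0 and 5.0 A in two conformers
        r1, r2 = AtomRef("A", 1, "GLY", "HA2"), AtomRef("A", 2, "GLY", "HA2")
        a, b = _site("A.1.H", [r1]), _site("A.2.H", [r2])
        c1 = Conformer([(r1, (0, 0, 0)), (r2, (3.0, 0, 0))])
        c2 = Conformer([(r1, (0, 0, 0)), (r2, (5.0, 0, 0))])
        expected = ((3.0**-6 + 5.0**-6) / 2.0) ** (-1 / 6)
        assert summation_distance(a, b, [c1, c2]) == pytest.approx(expected, abs=1e-9)

    def test_overlapping_sites_rejected(self):
        r1 = AtomRef("A", 1, "GLY", "HA2")
        a = _site("A.1.X", [r1])
        b = _site("A.1.Y", [r1])
        conf = Conformer([(r1, (0, 0, 0))])
        with pytest.raises(OverlappingSitesError):
            summation_distance(a, b, conf)

    @given(
        st.lists(
            st.tuples(
                st.floats(1.0, 20.0), st.floats(1.0, 20.0), st.floats(1.0, 20.0)
            ),
            min_size=1,
            max_size=3,
        ),
        st.floats(2.0, 15.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_never_exceeds_min_pair_distance(self, offsets, base):
        r_a = AtomRef("A", 1, "GLY", "HA2")
        members_b = []
        entries = [(r_a, (0.0, 0.0, 0.0))]
        names = ["HA2", "HA3", "HB2"]  # arbitrary distinct names, one residue
        for k, off in enumerate(offsets):
            ref = AtomRef("A", 2, "SER", names[k])
            members_b.append(ref)
            entries.append((ref, (base + off[0], off[1], off[2])))
        conf = Conformer(entries)
        site_a = _site("A.1.H", [r_a])
        site_b = ProtonSite("A.2.Q", tuple(members_b), "Q")
        d = summation_distance(site_a, site_b, conf)
        min_pair = min(
            np.linalg.norm(conf[m] - conf[r_a]) for m in members_b
        )
        assert d <= min_pair + 1e-9
        # symmetry
        assert summation_distance(site_b, site_a, conf) == pytest.approx(d, abs=1e-12)


class TestDistanceGraph:
    def _line_sites(self):
        refs = [
            AtomRef("A", 1, "GLY", "HA2"),
            AtomRef("A", 2, "GLY", "HA2"),
            AtomRef("A", 3, "GLY", "HA2"),
        ]
        conf = Conformer(
            [(refs[0], (0, 0, 0)), (refs[1], (4.0, 0, 0)), (refs[2], (8.0, 0, 0))]
        )
        sites = [_site(f"A.{i+1}.H", [r]) for i, r in enumerate(refs)]
        return sites, conf

    def test_line_graph_edges(self):
        sites, conf = self._line_sites()
        graph = build_distance_graph(sites, conf, d_max=5.0)
        edges = {(a, b) for a, b, _ in graph.edges()}
        assert edges == {("A.1.H", "A.2.H"), ("A.2.H", "A.3.H")}

    def test_tiny_cutoff_no_edges(self):
        sites, conf = self._line_sites()
        graph = build_distance_graph(sites, conf, d_max=0.1)
        assert graph.edges() == []

    def test_brute_force_equivalence_random_fixture(self):
        rng = np.random.default_rng(7)
        refs, entries = [], []
        for i in range(30):
            ref = AtomRef("A", i + 1, "GLY", "HA2")
            refs.append(ref)
            entries.append((ref, rng.uniform(0, 12, size=3)))
        conf = Conformer(entries)
        sites = [_site(f"A.{i+1}.H", [r]) for i, r in enumerate(refs)]
        graph = build_distance_graph(sites, conf, d_max=5.0)
        got = {(a, b) for a, b, _ in graph.edges()}
        expected = set()
        for i in range(30):
            for j in range(i + 1, 30):
                if np.linalg.norm(conf[refs[i]] - conf[refs[j]]) <= 5.0:
                    expected.add((sites[i].group_id, sites[j].group_id))
        assert got == expected

    def test_cutoff_monotonicity(self, small_world):
        sites = build_proton_sites(small_world.structure, small_world.shifts)
        g5 = build_distance_graph(sites, small_world.structure, 5.0)
        g7 = build_distance_graph(sites, small_world.structure, 7.0)
        e5 = {(a, b) for a, b, _ in g5.edges()}
        e7 = {(a, b) for a, b, _ in g7.edges()}
        assert e5 <= e7

    def test_singleton_matches_euclidean(self, small_world):
        conf = small_world.structure
        sites = build_proton_sites(conf, small_world.shifts)
        graph = build_distance_graph(sites, conf, 5.0)
        singles = [
            (i, s) for i, s in enumerate(graph.sites) if len(s.members) == 1
        ]
        i, si = singles[0]
        j, sj = singles[1]
        d_euclid = float(np.linalg.norm(conf[si.members[0]] - conf[sj.members[0]]))
        if d_euclid >= 0.5:  # below the clash floor the graph flattens
            assert graph.distances[i, j] == pytest.approx(d_euclid, abs=1e-9)
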