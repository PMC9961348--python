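import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carrierdyn.interactions import (
    CationPiDetector,
    HBondDetector,
    HydrophobicDetector,
    InteractionSeries,
    SaltBridgeDetector,
    build_series,
    cation_pi_series,
    detect_hydrophobic,
    detect_salt_bridges,
    filter_by_persistence,
    interhelix_contact_map,
)
from carrierdyn.structio import HelixDefinition, Structure, Trajectory
from carrierdyn.synthgen import (
    BundleSpec,
    PlantedInteraction,
    build_bundle,
    generate_trajectory,
    helix_definitions,
)
from oracles import brute_contact_count, brute_salt_bridges


def _structure(rows):
    """rows: (name, element, resname, resnum, xyz)"""
    return Structure(
        serials=range(1, len(rows) + 1),
        names=[r[0] for r in rows],
        elements=[r[1] for r in rows],
        residue_names=[r[2] for r in rows],
        residue_numbers=[r[3] for r in rows],
        chains=["A"] * len(rows),
        coords=np.array([r[4] for r in rows], float),
    )


class TestSaltBridge:
    def test_beyond_cutoff_is_absent(self):
        s = _structure([
            ("CA", "C", "ASP", 1, (0, 0, 0)),
            ("OD1", "O", "ASP", 1, (1, 0, 0)),
            ("CA", "C", "LYS", 2, (7, 0, 0)),
            ("NZ", "N", "LYS", 2, (6, 0, 0)),
        ])
        assert detect_salt_bridges(s, s.coords, cutoff=4.0) == []

    def test_minimum_over_oxygen_pair(self):
        s = _structure([
            ("CA", "C", "ASP", 1, (0, 0, 0)),
            ("OD1", "O", "ASP", 1, (0, 0, 0)),
            ("OD2", "O", "ASP", 1, (0, 0.7, 0)),
            ("CA", "C", "LYS", 2, (5, 0, 0)),
            ("NZ", "N", "LYS", 2, (3.5, 0, 0)),
        ])
        hits = detect_salt_bridges(s, s.coords, cutoff=4.0)
        assert len(hits) == 1
        (pair, dist) = hits[0]
        assert dist == pytest.approx(3.5)

    def test_scan_equals_brute_force(self, bundle_spec):
        plants = [
            PlantedInteraction("salt_bridge", 8, 52, 1.0, 2.9),
            PlantedInteraction("salt_bridge", 20, 40, 1.0, 3.8),
        ]
        traj, _ = generate_trajectory(bundle_spec, plants, 1, seed=9,
                                      jitter_sigma=0.05)
        top = traj.topology
        mine = sorted(detect_salt_bridges(top, traj.frames[0], 4.0))
        brute = sorted(brute_salt_bridges(top, traj.frames[0], 4.0))
        assert [p for p, _ in mine] == [p for p, _ in brute]
        np.testing.assert_allclose(
            [d for _, d in mine], [d for _, d in brute], atol=1e-12
        )

    def test_hydrogens_do_not_change_detection(self):
        rows = [
            ("CA", "C", "ASP", 1, (0, 0, 0)),
            ("OD1", "O", "ASP", 1, (1, 0, 0)),
            ("CA", "C", "LYS", 2, (6, 0, 0)),
            ("NZ", "N", "LYS", 2, (4.2, 0, 0)),
        ]
        with_h = rows + [("HZ1", "H", "LYS", 2, (4.5, 0.5, 0))]
        bare = _structure(rows)
        full = _structure(with_h)
        h1 = detect_salt_bridges(bare, bare.coords, 4.0)
        h2 = detect_salt_bridges(full, full.coords, 4.0)
        assert [(p, round(d, 9)) for p, d in h1] == [(p, round(d, 9)) for p, d in h2]

    def test_missing_sidechain_warns_and_skips(self):
        s = _structure([
            ("CA", "C", "ASP", 1, (0, 0, 0)),
            ("CA", "C", "LYS", 2, (3, 0, 0)),
            ("NZ", "N", "LYS", 2, (2, 0, 0)),
        ])
        with pytest.warns(UserWarning, match="skipped"):
            assert detect_salt_bridges(s, s.coords, 4.0) == []


class TestHBond:
    @staticmethod
    def _dha(d_a=2.8, angle=180.0):
        """Donor at origin, H on x, acceptor placed at the given D-H-A angle."""
        h = np.array([1.0, 0.0, 0.0])
        back = np.deg2rad(180.0 - angle)
        a_dir = np.array([np.cos(back), np.sin(back), 0.0])
        # place A so that |D-A| = d_a: A = H + t * a_dir with |H + t*a_dir| = d_a
        t = np.roots([1.0, 2 * h @ a_dir, 1 - d_a**2]).max()
        acceptor = h + t * a_dir
        return _structure([
            ("OG", "O", "SER", 1, (0, 0, 0)),
            ("HG", "H", "SER", 1, tuple(h)),
            ("OE1", "O", "GLU", 2, tuple(acceptor)),
        ])

    def test_linear_geometry_present(self):
        s = self._dha(2.8, 180.0)
        det = HBondDetector([("A", 1, "OG")], [("A", 2, "OE1")])
        hits = det.scan(s, s.coords)
        assert len(hits) == 1
        _, dist, angle = hits[0]
        assert dist == pytest.approx(2.8)
        assert angle == pytest.approx(180.0)

    def test_right_angle_gated_out(self):
        s = self._dha(2.8, 90.0)
        det = HBondDetector([("A", 1, "OG")], [("A", 2, "OE1")])
        assert det.scan(s, s.coords) == []

    def test_no_hydrogens_waives_angle(self):
        s = _structure([
            ("OG", "O", "SER", 1, (0, 0, 0)),
            ("OE1", "O", "GLU", 2, (2.8, 0, 0)),
        ])
        det = HBondDetector([("A", 1, "OG")], [("A", 2, "OE1")])
        hits = det.scan(s, s.coords)
        assert len(hits) == 1
        assert np.isnan(hits[0][2])

    def test_planted_tyrosine_carboxylate_geometry(self, bundle_spec):
        plant = PlantedInteraction("hbond", 8, 52, 1.0, bound_distance=2.7,
                                   bound_angle=164.0)
        traj, _ = generate_trajectory(bundle_spec, [plant], 5, seed=4,
                                      jitter_sigma=0.0)
        det = HBondDetector([("A", 8, "OH")], [("A", 52, "OE1")])
        series = build_series(traj, det, (("A", 8, "OH"), ("A", 52, "OE1")))
        assert series.fraction == 1.0
        assert series.avg_distance == pytest.approx(2.7, abs=1e-9)
        assert series.avg_angle == pytest.approx(164.0, abs=1e-6)


class TestHydrophobic:
    def test_stacked_apolar_atoms_present(self):
        s = _structure([
            ("CA", "C", "PHE", 1, (0, 0, 0)),
            ("CZ", "C", "PHE", 1, (0, 0, 1)),
            ("CA", "C", "PHE", 3, (0, 0, 6)),
            ("CZ", "C", "PHE", 3, (0, 0, 4.8)),
        ])
        hits = detect_hydrophobic(s, s.coords, cutoff=4.5)
        assert len(hits) == 1
        assert hits[0][1] == pytest.approx(3.8)

    def test_boundary_just_beyond_cutoff(self):
        s = _structure([
            ("CA", "C", "LEU", 1, (0, 0, 0)),
            ("CD1", "C", "LEU", 1, (0, 0, 0)),
            ("CA", "C", "LEU", 3, (4.6, 0, 0)),
            ("CD1", "C", "LEU", 3, (4.6, 0, 0)),
        ])
        assert detect_hydrophobic(s, s.coords, cutoff=4.5) == []

    def test_scan_matches_brute_force_min_distances(self, bundle):
        # every ALA in the bundle carries an apolar CB
        det = HydrophobicDetector(4.5)
        hits = det.scan(bundle, bundle.coords)
        assert hits, "bundle should have interhelix apolar contacts"
        for (ra, rb), dist in hits[:25]:
            ia = [i for i in bundle.residue_atoms(*ra) if bundle.names[i] == "CB"]
            ib = [i for i in bundle.residue_atoms(*rb) if bundle.names[i] == "CB"]
            brute = min(
                np.linalg.norm(bundle.coords[i] - bundle.coords[j])
                for i in ia for j in ib
            )
            assert dist == pytest.approx(brute)


class TestCationPi:
    def test_cation_on_ring_normal(self, bundle_spec):
        plant = PlantedInteraction("cation_pi", 8, 52, 1.0, bound_distance=4.0,
                                   bound_angle=90.0)
        traj, _ = generate_trajectory(bundle_spec, [plant], 2, seed=0,
                                      jitter_sigma=0.0)
        s = cation_pi_series(traj, ("A", 8), ("A", 52, "NZ"))
        assert s.distance[0] == pytest.approx(4.0, abs=1e-9)
        assert s.angle[0] == pytest.approx(90.0, abs=1e-6)
        assert s.fraction == 1.0

    def test_cation_in_ring_plane(self, bundle_spec):
        plant = PlantedInteraction("cation_pi", 8, 52, 1.0, bound_distance=5.0,
                                   bound_angle=0.0)
        traj, _ = generate_trajectory(bundle_spec, [plant], 2, seed=0,
                                      jitter_sigma=0.0)
        s = cation_pi_series(traj, ("A", 8), ("A", 52, "NZ"))
        assert s.distance[0] == pytest.approx(5.0, abs=1e-9)
        assert s.angle[0] == pytest.approx(0.0, abs=1e-6)

    def test_elevation_45_degrees(self, bundle_spec):
        plant = PlantedInteraction("cation_pi", 8, 52, 1.0, bound_distance=5.0,
                                   bound_angle=45.0)
        traj, _ = generate_trajectory(bundle_spec, [plant], 2, seed=0,
                                      jitter_sigma=0.0)
        s = cation_pi_series(traj, ("A", 8), ("A", 52, "NZ"))
        assert s.distance[0] == pytest.approx(5.0, abs=1e-6)
        assert s.angle[0] == pytest.approx(45.0, abs=1e-6)

    def test_missing_ring_atoms_named(self):
        s = _structure([
            ("CA", "C", "PHE", 1, (0, 0, 0)),
            ("CG", "C", "PHE", 1, (1, 0, 0)),
            ("NZ", "N", "LYS", 2, (5, 0, 0)),
        ])
        det = CationPiDetector()
        with pytest.raises(ValueError, match="missing ring atoms"):
            det.measure(s, s.coords, (("A", 1), ("A", 2, "NZ")))


class TestSeries:
    def test_always_present_fraction_one(self, bundle_spec):
        plant = PlantedInteraction("salt_bridge", 8, 52, 1.0, 2.9)
        traj, _ = generate_trajectory(bundle_spec, [plant], 20, seed=1,
                                      jitter_sigma=0.0)
        s = build_series(traj, SaltBridgeDetector(4.0), (("A", 8), ("A", 52)))
        assert s.fraction == 1.0
        assert s.avg_distance == pytest.approx(2.9, abs=1e-9)

    def test_planted_occupancy_recovered_frame_exactly(self, salt_bridge_fixture):
        traj, truth, plant = salt_bridge_fixture
        s = build_series(traj, SaltBridgeDetector(4.0), (("A", 8), ("A", 52)))
        gt = truth.bound[plant.label]
        assert np.array_equal(s.present, gt)
        assert abs(s.fraction - 0.60) <= 0.056  # binomial 99% CI at n=500
        assert s.avg_distance == pytest.approx(2.9, abs=0.02)

    def test_fraction_invariant_under_frame_reordering(self, salt_bridge_fixture):
        traj, _, _ = salt_bridge_fixture
        sub = Trajectory(traj.topology, traj.frames[:50])
        rng = np.random.default_rng(0)
        perm = rng.permutation(50)
        shuffled = Trajectory(traj.topology, [sub.frames[i] for i in perm])
        det = SaltBridgeDetector(4.0)
        a = build_series(sub, det, (("A", 8), ("A", 52)))
        b = build_series(shuffled, det, (("A", 8), ("A", 52)))
        assert a.fraction == b.fraction
        assert a.avg_distance == pytest.approx(b.avg_distance)

    def test_fraction_monotone_in_cutoff(self, salt_bridge_fixture):
        traj, _, _ = salt_bridge_fixture
        sub = Trajectory(traj.topology, traj.frames[:100])
        pair = (("A", 8), ("A", 52))
        fractions = [
            build_series(sub, SaltBridgeDetector(c), pair).fraction
            for c in (2.0, 3.0, 4.0, 6.0, 14.0)
        ]
        assert fractions == sorted(fractions)


class TestPersistenceFilter:
    @staticmethod
    def _series(fraction, n=100):
        present = np.zeros(n, bool)
        present[: int(round(fraction * n))] = True
        return InteractionSeries("salt_bridge", "a", "b", present,
                                 np.full(n, 3.0))

    @given(
        fractions=st.lists(st.integers(min_value=0, max_value=100), max_size=20),
        threshold_pct=st.integers(min_value=1, max_value=99),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_filter_properties_hold_for_any_input(self, fractions, threshold_pct):
        series = [self._series(f / 100) for f in fractions]
        threshold = threshold_pct / 100
        kept = filter_by_persistence(series, threshold)
        assert all(s.fraction > threshold for s in kept)
        assert len(kept) == sum(1 for f in fractions if f / 100 > threshold)
        out = [s.fraction for s in kept]
        assert out == sorted(out, reverse=True)

    def test_strict_threshold_boundary(self):
        series = [self._series(f) for f in (0.94, 0.50, 0.10, 0.05)]
        kept = filter_by_persistence(series, 0.10)
        assert [s.fraction for s in kept] == [0.94, 0.50]

    def test_empty_input(self):
        assert filter_by_persistence([], 0.10) == []

    def test_sorted_descending(self):
        kept = filter_by_persistence([self._series(0.12), self._series(0.84)], 0.10)
        assert [s.fraction for s in kept] == [0.84, 0.12]


class TestContactMap:
    def test_far_helices_have_no_contacts(self):
        spec = BundleSpec(n_helices=2, bundle_radius=30.0, seed=0)
        s = build_bundle(spec)
        cmap = interhelix_contact_map(s, helix_definitions(spec), cutoff=4.5)
        assert cmap.interfaces[0].count == 0
        assert cmap.interfaces[0].range_a is None

    def test_counts_match_brute_force(self, bundle, bundle_helices):
        cmap = interhelix_contact_map(bundle, bundle_helices, cutoff=4.5)
        by_pair = {(e.helix_a, e.helix_b): e.count for e in cmap.interfaces}
        for ha in bundle_helices[:3]:
            for hb in bundle_helices:
                if hb.label <= ha.label:
                    continue
                ia = [
                    i for i in range(bundle.n_atoms)
                    if ha.start <= bundle.residue_numbers[i] <= ha.end
                ]
                ib = [
                    i for i in range(bundle.n_atoms)
                    if hb.start <= bundle.residue_numbers[i] <= hb.end
                ]
                brute = brute_contact_count(
                    bundle.coords[ia], bundle.coords[ib], 4.5
                )
                assert by_pair[(ha.label, hb.label)] == brute

    def test_each_unordered_pair_once(self, bundle, bundle_helices):
        cmap = interhelix_contact_map(bundle, bundle_helices, cutoff=4.5)
        pairs = [frozenset((e.helix_a, e.helix_b)) for e in cmap.interfaces]
        assert len(pairs) == len(set(pairs)) == 15
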