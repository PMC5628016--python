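"""Aqueduct cylinder, hydration, phosphate series, traces, flip events,
and lipid orientation angles."""

from collections import Counter

import numpy as np
import pytest

import scrambletrack as st
from scrambletrack.aqueduct import ZTrace
from scrambletrack.core import FrameSet
from scrambletrack.synth import LINING_RANGES


def _trace(z, inside=None, times=None, species="POPC", lipid_id=1):
    z = np.asarray(z, dtype=float)
    inside = np.ones(len(z), bool) if inside is None else np.asarray(inside, bool)
    times = np.arange(len(z), dtype=float) if times is None else times
    return ZTrace(lipid_id, species, times, z, inside, "I")


class TestDefineCylinder:
    def test_axis_is_mean_of_lining_atoms(self):
        atoms = st.make_atom_table(
            ["CA", "CA"], ["ALA", "ALA"], [501, 502], ["I", "I"],
            ["protein", "protein"],
        )
        coords = np.array([[[0.0, 0, 0], [2.0, 0, 0]]])
        frames = FrameSet([0.0], [[50, 50, 50]], coords)
        cyl = st.define_cylinder(atoms, frames, [(501, 502)])["I"]
        np.testing.assert_allclose(cyl.axis_at(0), [1.0, 0.0])
        assert cyl.radius == 13.0  # default aqueduct radius

    def test_dimer_axes_related_by_c2(self, small_centered):
        """The two subunit axes of the symmetric dimer map onto each other
        under the 180-degree rotation about z."""
        _, _, _, cylinders = small_centered
        a1 = cylinders["I"].axis_at(0)
        a2 = cylinders["II"].axis_at(0)
        np.testing.assert_allclose(a1, -a2, atol=1e-5)

    def test_empty_selection_errors(self, small_centered):
        atoms, frames, _, _ = small_centered
        with pytest.raises(ValueError, match="9000"):
            st.define_cylinder(atoms, frames, [(9000, 9100)])


class TestHydrationProfile:
    def test_no_water_all_zero(self, small_centered):
        atoms, frames, _, cylinders = small_centered
        edges, prof = st.hydration_profile(
            frames, cylinders["I"], np.array([], dtype=int)
        )
        assert prof.sum() == 0.0

    def test_matches_brute_force_recount(self, small_centered):
        atoms, frames, _, cylinders = small_centered
        w_idx = atoms[(atoms["role"] == "water")]["atom_id"].to_numpy()
        cyl = cylinders["I"]
        edges, prof = st.hydration_profile(frames, cyl, w_idx, window=(0, 5))
        brute = np.zeros(len(edges) - 1)
        for f in range(5):
            ax = cyl.axis_at(f)
            for w in w_idx:
                x, y, z = frames.coords[f, w].astype(float)
                if np.hypot(x - ax[0], y - ax[1]) <= cyl.radius:
                    for s in range(len(brute)):
                        if edges[s] <= z < edges[s + 1]:
                            brute[s] += 1
        np.testing.assert_allclose(prof, brute / 5)

    def test_uniform_density_analytic(self, rng):
        """Uniform water density rho in the cylinder gives per-slab means
        within 3 SE of rho*pi*13^2*2."""
        sc = st.SyntheticScenario(
            n_lipids_per_leaflet=8, n_frames=40, water_per_slab=12,
            water_placement="uniform", event_schedule=[], noise_sigma=0.0,
            n_background_ions=0, seed=5,
        )
        atoms, frames, _ = st.generate(sc)
        pmap = st.lipid_phosphorus_map(atoms)
        frames = st.center_membrane(frames, np.fromiter(pmap.values(), dtype=int))
        cyl = st.define_cylinder(atoms, frames, LINING_RANGES)["I"]
        w_idx = atoms[atoms["role"] == "water"]["atom_id"].to_numpy()
        edges, prof = st.hydration_profile(frames, cyl, w_idx)
        n_slabs = len(prof)
        n_total = 12 * n_slabs  # per cylinder
        expected = n_total / n_slabs  # = rho * pi * R^2 * slab for uniform fill
        se = np.sqrt(n_total * (1 / n_slabs) * (1 - 1 / n_slabs))
        inner = prof[1:-1]  # edge slabs clip the uniform fill at the caps
        assert np.all(np.abs(inner - expected) < 3 * se)

    def test_boundary_water_goes_to_upper_slab(self):
        atoms = st.make_atom_table(
            ["CA", "OH2"], ["ALA", "TIP3"], [501, 1000], ["I", "-"],
            ["protein", "water"],
        )
        coords = np.zeros((1, 2, 3))
        coords[0, 1] = [0.0, 0.0, 0.0]  # exactly on the z=0 slab boundary
        frames = FrameSet([0.0], [[60, 60, 60]], coords)
        cyl = st.AqueductCylinder("I", [[0.0, 0.0]])
        edges, prof = st.hydration_profile(frames, cyl, np.array([1]))
        k = int(np.nonzero(prof)[0][0])
        assert edges[k] == 0.0  # upper slab [0, 2)

    def test_bad_window_errors(self, small_centered):
        atoms, frames, _, cylinders = small_centered
        with pytest.raises(ValueError, match="window"):
            st.hydration_profile(
                frames, cylinders["I"], np.array([0]),
                window=(0, frames.n_frames + 5),
            )


class TestPhosphateSeries:
    def test_empty_aqueduct(self):
        atoms = st.make_atom_table(["CA"], ["ALA"], [501], ["I"], ["protein"])
        frames = FrameSet(
            np.arange(4.0), np.tile([60.0] * 3, (4, 1)), np.zeros((4, 1, 3))
        )
        cyl = st.AqueductCylinder("I", [[30.0, 30.0]])
        counts, moving, hist = st.aqueduct_phosphate_series(
            frames, cyl, np.array([], dtype=int)
        )
        assert counts.sum() == 0
        assert hist == {0: 1.0}

    def test_alternating_occupancy_oracle(self):
        """Occupancy alternating 2 and 4 per frame: mean 3.0, histogram
        0.5/0.5 at {2, 4}; moving average of a constant series is that
        constant."""
        nf = 40
        coords = np.zeros((nf, 4, 3))
        coords[:, :, 0] = 100.0  # all out by default
        for f in range(nf):
            k = 2 if f % 2 == 0 else 4
            coords[f, :k, 0] = 0.0  # k atoms at the axis
        frames = FrameSet(
            np.arange(float(nf)), np.tile([300.0] * 3, (nf, 1)), coords
        )
        cyl = st.AqueductCylinder("I", [[0.0, 0.0]])
        counts, moving, hist = st.aqueduct_phosphate_series(
            frames, cyl, np.arange(4)
        )
        assert counts.mean() == 3.0
        assert hist == {2: 0.5, 4: 0.5}
        c, m, _ = st.aqueduct_phosphate_series(
            frames, cyl, np.array([0])  # atom 0 always inside -> constant 1
        )
        np.testing.assert_allclose(m, 1.0)

    def test_joint_radius_and_core_restriction(self):
        """Counting applies the 13 Å radius and |z| <= 10 Å jointly."""
        coords = np.zeros((1, 3, 3))
        coords[0, 0] = [0, 0, 5]     # in
        coords[0, 1] = [0, 0, 12]    # out of core
        coords[0, 2] = [14, 0, 5]    # out of radius
        frames = FrameSet([0.0], [[60.0] * 3], coords)
        cyl = st.AqueductCylinder("I", [[0.0, 0.0]])
        counts, _, _ = st.aqueduct_phosphate_series(frames, cyl, np.arange(3))
        assert counts[0] == 1


class TestTraceLipids:
    def test_outside_lipid_emits_no_trace(self, small_centered):
        """Background lipids placed away from both cylinders yield no
        traces; scripted lipids do."""
        atoms, frames, pmap, cylinders = small_centered
        traces_all = []
        for cyl in cylinders.values():
            traces, _ = st.trace_lipids(frames, cyl, atoms, pmap)
            traces_all += traces
        assert 0 < len(traces_all) < len(pmap)

    def test_histogram_mode_at_dwell_site(self):
        """A lipid scripted to dwell at the central site (z ~ -3) for most
        of the trajectory puts the z-histogram mode in the [-3, -2) bin."""
        from scrambletrack.synth import FlipScript

        sc = st.SyntheticScenario(
            n_lipids_per_leaflet=8, n_frames=200, water_per_slab=1,
            n_background_ions=0, noise_sigma=0.0, seed=9,
            event_schedule=[FlipScript("half_flop", "POPS", "I", 10, 199)],
        )
        atoms, frames, _ = st.generate(sc)  # generator output is centered
        pmap = st.lipid_phosphorus_map(atoms)
        cyl = st.define_cylinder(atoms, frames, LINING_RANGES)["I"]
        _, (edges, hist) = st.trace_lipids(frames, cyl, atoms, pmap)
        centers = 0.5 * (edges[:-1] + edges[1:])
        assert centers[np.argmax(hist)] == -2.5  # the [-3, -2) bin

    def test_histogram_conserves_samples(self, small_centered):
        atoms, frames, pmap, cylinders = small_centered
        cyl = cylinders["I"]
        traces, (edges, hist) = st.trace_lipids(frames, cyl, atoms, pmap)
        brute = sum(
            int(np.sum(tr.inside & (tr.z >= edges[0]) & (tr.z < edges[-1])))
            for tr in traces
        )
        assert hist.sum() == brute


class TestDetectFlipEvents:
    def test_monotone_full_flop(self):
        z = np.linspace(-18, 18, 50)
        events = st.detect_flip_events([_trace(z)])
        assert [e.event_class for e in events] == ["full_flop"]
        # completion = first frame beyond the far leaflet zone
        assert events[0].t_exit == float(np.argmax(z >= 15.0))

    def test_half_flop_at_trajectory_end(self):
        z = np.concatenate([np.linspace(-18, -1, 30), np.full(10, -1.0)])
        events = st.detect_flip_events([_trace(z)])
        assert [e.event_class for e in events] == ["half_flop"]

    def test_reversal_cancels(self):
        """A lipid that dips to the midplane band but returns to its entry
        leaflet produces no event."""
        z = np.concatenate(
            [np.linspace(-18, -2, 20), np.linspace(-2, -18, 20), [-18.0] * 5]
        )
        assert st.detect_flip_events([_trace(z)]) == []

    def test_radial_exit_suspends_not_cancels(self):
        """Radially leaving the cylinder mid-transit does not cancel a
        crossing that later completes."""
        z = np.linspace(-18, 18, 60)
        inside = np.ones(60, bool)
        inside[25:35] = False  # radial excursion near the midplane
        inside_mid = (np.abs(z) <= 5) & inside
        assert inside_mid.any()  # still touches the band while inside
        events = st.detect_flip_events([_trace(z, inside)])
        assert [e.event_class for e in events] == ["full_flop"]

    def test_outer_to_inner_is_flip(self):
        z = np.linspace(18, -18, 50)
        events = st.detect_flip_events([_trace(z)])
        assert [e.event_class for e in events] == ["full_flip"]

    def test_sequential_events_same_lipid(self):
        z = np.concatenate([np.linspace(-18, 18, 40), np.linspace(18, -18, 40)])
        classes = [e.event_class for e in st.detect_flip_events([_trace(z)])]
        assert classes == ["full_flop", "full_flip"]

    @pytest.mark.parametrize("sigma", [0.0, 1.0])
    def test_scripted_recovery(self, sigma):
        """Scripted event recovery is exact at zero noise and at the 1 Å
        hysteresis margin."""
        sc = st.SyntheticScenario(
            n_lipids_per_leaflet=32, n_frames=300, water_per_slab=1,
            n_background_ions=4, noise_sigma=sigma, seed=42,
        )
        atoms, frames, truth = st.generate(sc)
        pmap = st.lipid_phosphorus_map(atoms)
        frames = st.center_membrane(frames, np.fromiter(pmap.values(), dtype=int))
        cylinders = st.define_cylinder(atoms, frames, LINING_RANGES)
        detected = []
        for cyl in cylinders.values():
            traces, _ = st.trace_lipids(frames, cyl, atoms, pmap)
            detected += st.detect_flip_events(traces)
        got = Counter((e.event_class, e.species) for e in detected)
        want = Counter(
            (e.type, e.species)
            for e in truth.events
            if e.type.endswith(("flop", "flip"))
        )
        assert got == want

    def test_full_event_implies_leaflet_change(self, small_centered):
        """After a full flop the lipid's leaflet label flips inner->outer."""
        atoms, frames, pmap, cylinders = small_centered
        before = st.assign_leaflets(frames, pmap, frame=0)
        after = st.assign_leaflets(frames, pmap, frame=frames.n_frames - 1)
        for cyl in cylinders.values():
            traces, _ = st.trace_lipids(frames, cyl, atoms, pmap)
            for ev in st.detect_flip_events(traces):
                if ev.event_class == "full_flop":
                    assert before[ev.lipid_id] == "inner"
                    assert after[ev.lipid_id] == "outer"


class TestOrientationAngles:
    def _lipid_system(self, tail1_vec, tail2_vec, n_offset=(0, 0, 1.0)):
        """One lipid: P at origin, N at n_offset, two 2-carbon tails."""
        names = ["P", "N", "C1T1", "C2T1", "C1T2", "C2T2"]
        atoms = st.make_atom_table(
            names, ["POPC"] * 6, [1] * 6, ["-"] * 6,
            ["lipid_head", "lipid_head"] + ["lipid_tail"] * 4,
        )
        coords = np.zeros((1, 6, 3))
        coords[0, 1] = n_offset
        coords[0, 3] = tail1_vec  # C2T1 = C1T1 + vec (C1 at origin)
        coords[0, 5] = tail2_vec
        frames = FrameSet([0.0], [[60.0] * 3], coords)
        return atoms, frames

    @pytest.mark.parametrize(
        "t1,t2,expected",
        [
            ((0, 0, -1), (0, 0, -1), 180.0),          # both tails along -z
            ((1, 0, 1), (-1, 0, 1), 0.0),             # symmetric about +z
            ((0, 0, 1), (1, 0, 0), 45.0),             # one +z, one +x
        ],
    )
    def test_tilt_geometry(self, t1, t2, expected):
        atoms, frames = self._lipid_system(t1, t2)
        ang = st.tail_tilt_angles(frames, atoms, 1)
        np.testing.assert_allclose(ang, [expected], atol=1e-9)

    def test_antiparallel_tails_flagged(self):
        atoms, frames = self._lipid_system((0, 0, 1), (0, 0, -1))
        assert np.isnan(st.tail_tilt_angles(frames, atoms, 1)[0])

    @pytest.mark.parametrize(
        "n_offset,expected",
        [((0, 0, 2.0), 0.0), ((0, 0, -2.0), 180.0), ((1, 0, 1.0), 45.0)],
    )
    def test_pn_dipole_geometry(self, n_offset, expected):
        atoms, frames = self._lipid_system((0, 0, -1), (0, 0, -1), n_offset)
        z, ang = st.pn_dipole_angles(frames, atoms, 1)
        np.testing.assert_allclose(ang, [expected], atol=1e-9)
        assert z[0] == 0.0

    def test_rotation_about_z_invariance(self, rng):
        """Tilt and dipole angles are invariant under rigid rotation about
        z and xy-translation."""
        atoms, frames = self._lipid_system((0.3, 0.4, -1), (-0.2, 0.1, -1),
                                           (0.5, -0.2, 1.4))
        theta = 1.234
        R = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        rotated = frames.copy()
        rotated.coords = frames.coords @ R.T + np.array([5.0, -3.0, 0.0])
        for fn in (st.tail_tilt_angles,):
            np.testing.assert_allclose(
                fn(rotated, atoms, 1), fn(frames, atoms, 1), atol=1e-9
            )
        _, a1 = st.pn_dipole_angles(frames, atoms, 1)
        _, a2 = st.pn_dipole_angles(rotated, atoms, 1)
        np.testing.assert_allclose(a1, a2, atol=1e-9)
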