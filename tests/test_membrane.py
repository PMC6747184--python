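import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from boostmd.conformation import compute_dihedrals
from boostmd.membrane import (
    FieldSpec,
    bend_angle,
    electron_density_profile,
    field_convert,
    msd_diffusion,
    percent_helicity,
    pore_radius_profile,
    pore_water_count,
    scd_profile,
    water_grid_density,
)
from boostmd.synthetic import SyntheticMembraneSpec, hinged_helix, ideal_helix, make_membrane_system
from boostmd.synthetic.peptide import _backbone_topology, build_backbone
from boostmd.system import Topology, Trajectory


def _simple_topology(n, role="water", element="O", chains=None, vdw=None):
    top = Topology(
        names=np.array([f"{element}{i}" for i in range(n)], dtype=object),
        elements=np.array([element] * n, dtype=object),
        resids=np.arange(1, n + 1),
        resnames=np.array(["RES"] * n, dtype=object),
        chains=np.array(chains if chains is not None else ["A"] * n, dtype=object),
        roles=np.array([role] * n, dtype=object),
    )
    if vdw is not None:
        top.vdw_radii = np.full(n, float(vdw))
    return top


class TestElectronDensity:
    def test_uniform_gas_flat_profile(self, rng):
        n = 400
        top = _simple_topology(n)
        coords = rng.uniform(-25.0, 25.0, size=(200, n, 3))
        traj = Trajectory(coords, box=np.full(3, 50.0))
        prof = electron_density_profile(traj, top, bins=10)
        dens = prof.densities["water"]
        assert dens.std() / dens.mean() < 0.05

    def test_group_additivity_and_electron_conservation(self, membrane_system):
        traj, top, _ = membrane_system
        prof = electron_density_profile(traj, top, bins=30)
        total = prof.densities["total"]
        summed = sum(v for k, v in prof.densities.items() if k != "total")
        assert np.allclose(total, summed, rtol=1e-12)
        dz = prof.z_centers[1] - prof.z_centers[0]
        area = traj.box[0, 0] * traj.box[0, 1]
        assert total.sum() * dz * area == pytest.approx(top.electrons.sum(), rel=1e-6)

    def test_two_slab_step_profile(self):
        n = 200
        top = _simple_topology(n, element="C", role="lipid")
        z = np.concatenate([np.full(n // 2, -10.0), np.full(n // 2, 10.0)])
        coords = np.zeros((1, n, 3))
        coords[0, :, 2] = z
        traj = Trajectory(coords, box=np.full(3, 50.0))
        prof = electron_density_profile(traj, top, bins=10)
        d = prof.densities["total"]
        occupied = d > 0
        assert occupied.sum() == 2
        assert np.allclose(prof.z_centers[occupied], [-10.0, 10.0], atol=2.6)


class TestOrderParameters:
    def test_chain_along_normal_maximal_order(self):
        # straight chain along z: C–H vectors ⟂ normal → |S_CD| = 0.5
        n = 8
        coords = np.zeros((1, n, 3))
        coords[0, :, 2] = np.arange(n) * 1.25
        top = _simple_topology(n, role="lipid", element="C")
        prof = scd_profile(Trajectory(coords, box=np.full(3, 50.0)), top)
        assert np.allclose(prof.scd, 0.5, atol=1e-12)

    def test_magic_angle_vanishing_order(self):
        n = 8
        theta = np.radians(54.7356103)
        direction = np.array([np.sin(theta), 0.0, np.cos(theta)])
        coords = (np.arange(n)[:, None] * 1.25 * direction)[None]
        top = _simple_topology(n, role="lipid", element="C")
        prof = scd_profile(Trajectory(coords, box=np.full(3, 50.0)), top)
        assert np.all(np.abs(prof.scd) < 1e-3)

    def test_generator_target_recovered(self, membrane_system):
        traj, top, spec = membrane_system
        prof = scd_profile(traj, top)
        assert np.allclose(prof.scd, spec.target_scd, atol=0.01)
        assert set(prof.by_chain_type) == {"SN1", "SN2"}
        for per_chain in prof.by_chain_type.values():
            assert np.allclose(per_chain, spec.target_scd, atol=0.015)


class TestMSD:
    def test_ballistic_motion_flagged_nondiffusive(self):
        n_frames = 200
        coords = np.zeros((n_frames, 3, 3))
        coords[:, :, 0] = (0.05 * np.arange(n_frames))[:, None]
        traj = Trajectory(coords, box=np.full(3, 1e6), time=np.arange(n_frames) * 1.0)
        res = msd_diffusion(traj, np.arange(3), n_dim=3)
        assert res.exponent == pytest.approx(2.0, abs=0.05)
        assert not res.diffusive

    def test_brownian_diffusion_recovered(self):
        spec = SyntheticMembraneSpec(
            lipids_per_leaflet=0, include_pore=False, n_waters=40,
            d_water=0.03, n_frames=5000, seed=15,
        )
        traj, top, _ = make_membrane_system(spec)
        res = msd_diffusion(traj, top.select(role="water"), n_dim=3)
        assert res.diffusive
        assert res.diffusion == pytest.approx(0.03, rel=0.10)
        assert res.diffusion_scaled == pytest.approx(10.0 * res.diffusion)

    def test_axis_subsets_consistent(self):
        spec = SyntheticMembraneSpec(
            lipids_per_leaflet=0, include_pore=False, n_waters=60,
            d_water=0.03, n_frames=4000, seed=16,
        )
        traj, top, _ = make_membrane_system(spec)
        sel = top.select(role="water")
        d3 = msd_diffusion(traj, sel, n_dim=3).diffusion
        d1 = msd_diffusion(traj, sel, n_dim=1).diffusion
        assert d1 == pytest.approx(d3, rel=0.15)  # isotropy

    def test_diffusion_unbiased_across_seeds(self):
        """Mean recovered D over 20 independent walks within 3% of truth."""
        ds = []
        for seed in range(20):
            spec = SyntheticMembraneSpec(
                lipids_per_leaflet=0, include_pore=False, n_waters=50,
                d_water=0.03, n_frames=500, seed=seed,
            )
            traj, top, _ = make_membrane_system(spec)
            ds.append(msd_diffusion(traj, top.select(role="water"), n_dim=3).diffusion)
        assert np.mean(ds) == pytest.approx(0.03, rel=0.03)

    def test_wrapped_coordinates_rejected(self):
        coords = np.zeros((3, 1, 3))
        coords[1, 0, 0] = 30.0  # jump larger than box/2
        traj = Trajectory(coords, box=np.full(3, 40.0))
        with pytest.raises(ValueError, match="unwrap"):
            msd_diffusion(traj, np.array([0]), n_dim=3)

    def test_msd_starts_at_zero(self, membrane_system):
        traj, top, _ = membrane_system
        res = msd_diffusion(traj, top.select(role="water"))
        assert res.msd[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(res.msd >= -1e-9)


class TestWaterGrid:
    def test_single_static_water_single_voxel(self):
        top = _simple_topology(1)
        coords = np.full((5, 1, 3), 0.2)
        traj = Trajectory(coords, box=np.full(3, 20.0))
        vol = water_grid_density(traj, top, spacing=1.0)
        assert vol.grid.sum() == pytest.approx(1.0)
        assert (vol.grid > 0).sum() == 1

    def test_grid_sum_equals_mean_water_count(self, membrane_system):
        traj, top, _ = membrane_system
        vol = water_grid_density(traj, top, spacing=1.0)
        in_box = vol.grid.sum()
        assert in_box <= top.select(role="water").sum() + 1e-9
        assert in_box == pytest.approx(top.select(role="water").sum(), rel=1e-6)

    def test_pore_waters_concentrate_on_axis(self):
        # waters pinned inside the pore: occupancy stays within the radius
        spec = SyntheticMembraneSpec(n_waters=30, d_water=0.001, n_frames=20, seed=2)
        traj, top, _ = make_membrane_system(spec)
        wat = top.select(role="water")
        coords = traj.coords.copy()
        coords[:, wat, 0] *= 0.05
        coords[:, wat, 1] *= 0.05
        traj2 = Trajectory(coords, box=traj.box, time=traj.time)
        vol = water_grid_density(traj2, top, spacing=1.0)
        nx, ny, _ = vol.grid.shape
        x = vol.origin[0] + (np.arange(nx) + 0.5) * vol.spacing
        y = vol.origin[1] + (np.arange(ny) + 0.5) * vol.spacing
        r = np.hypot(x[:, None], y[None, :])
        frac_inside = vol.grid[r < spec.pore_radius].sum() / vol.grid.sum()
        assert frac_inside > 0.99

    def test_invalid_spacing_rejected(self, membrane_system):
        traj, top, _ = membrane_system
        with pytest.raises(ValueError):
            water_grid_density(traj, top, spacing=0.0)


class TestPoreWaterCount:
    def test_matches_brute_force_every_frame(self, membrane_system):
        traj, top, _ = membrane_system
        counts = pore_water_count(traj, top, cutoff=3.4)
        pore = np.flatnonzero(top.roles == "pore")
        wat = np.flatnonzero(top.roles == "water")
        for f in range(traj.n_frames):
            d = np.linalg.norm(
                traj.coords[f, wat][:, None, :] - traj.coords[f, pore][None, :, :],
                axis=2,
            )
            assert counts[f] == (d.min(axis=1) <= 3.4).sum()

    def test_constructed_frame_counts_inside_shell(self):
        pore_top = _simple_topology(1, role="pore", element="C")
        coords = np.zeros((1, 21, 3))
        # 7 of 20 waters within 3.4 Å of the single pore atom at the origin
        coords[0, 1:8, 0] = np.linspace(0.5, 3.3, 7)
        coords[0, 8:21, 0] = np.linspace(4.0, 15.0, 13)
        top = Topology(
            names=np.array(["P"] + [f"O{i}" for i in range(20)], dtype=object),
            elements=np.array(["C"] + ["O"] * 20, dtype=object),
            resids=np.arange(1, 22),
            resnames=np.array(["POR"] + ["WAT"] * 20, dtype=object),
            chains=np.array(["P"] + ["W"] * 20, dtype=object),
            roles=np.array(["pore"] + ["water"] * 20, dtype=object),
        )
        traj = Trajectory(coords, box=np.full(3, 50.0))
        assert pore_water_count(traj, top)[0] == 7

    def test_rigid_rotation_invariance(self, membrane_system):
        traj, top, _ = membrane_system
        sub = Trajectory(traj.coords[:5], box=traj.box[:5], time=traj.time[:5])
        base = pore_water_count(sub, top)
        rot = Rotation.from_rotvec([0.4, 0.2, -1.0])
        rotated = Trajectory(
            np.einsum("ij,fnj->fni", rot.as_matrix(), sub.coords),
            box=sub.box, time=sub.time,
        )
        assert np.array_equal(base, pore_water_count(rotated, top))

    def test_empty_pore_selection_rejected(self, membrane_system):
        traj, top, _ = membrane_system
        with pytest.raises(ValueError, match="empty pore"):
            pore_water_count(traj, top, pore_selection=np.zeros(top.n_atoms, bool))


class TestPoreRadius:
    def test_cylinder_free_radius(self, membrane_system):
        traj, top, spec = membrane_system
        sub = Trajectory(traj.coords[:10], box=traj.box[:10], time=traj.time[:10])
        prof = pore_radius_profile(sub, top, grid_spacing=0.25)
        expected = spec.pore_radius - spec.wall_vdw  # 9.5 Å
        mid = np.abs(prof.z_centers) < 5.0
        assert np.allclose(prof.mean_radius[mid], expected, atol=0.25)

    def test_wall_vdw_shift_is_linear(self, membrane_system):
        traj, top, spec = membrane_system
        sub = Trajectory(traj.coords[:3], box=traj.box[:3], time=traj.time[:3])
        prof1 = pore_radius_profile(sub, top, grid_spacing=0.25)
        top2 = Topology(
            top.names, top.elements, top.resids, top.resnames, top.chains, top.roles,
        )
        vdw = top.vdw_radii.copy()
        vdw[top.roles == "pore"] *= 2.0
        top2.vdw_radii = vdw
        prof2 = pore_radius_profile(sub, top2, grid_spacing=0.25)
        mid = np.abs(prof1.z_centers) < 5.0
        shift = prof1.mean_radius[mid] - prof2.mean_radius[mid]
        assert np.allclose(shift, spec.wall_vdw, atol=1e-9)

    def test_funnel_profile_monotone(self):
        # cone of rings widening with z
        zs = np.arange(-10.0, 11.0, 2.0)
        radii = 6.0 + 0.3 * (zs + 10.0)
        ang = 2 * np.pi * np.arange(16) / 16
        pts = []
        for z, r in zip(zs, radii):
            pts.append(np.column_stack([r * np.cos(ang), r * np.sin(ang), np.full(16, z)]))
        coords = np.concatenate(pts)[None]
        top = _simple_topology(coords.shape[1], role="pore", element="C", vdw=1.5)
        traj = Trajectory(coords, box=np.full(3, 60.0))
        prof = pore_radius_profile(traj, top, z_edges=np.arange(-11.0, 12.0, 2.0))
        good = ~prof.capped
        assert np.all(np.diff(prof.mean_radius[good]) > 0)

    def test_empty_slice_capped_and_flagged(self, membrane_system):
        traj, top, _ = membrane_system
        sub = Trajectory(traj.coords[:2], box=traj.box[:2], time=traj.time[:2])
        prof = pore_radius_profile(
            sub, top, z_edges=np.array([40.0, 45.0]), max_radius=12.0
        )
        assert prof.capped[0]
        assert prof.mean_radius[0] == 12.0


class TestHelicityAndBend:
    def _traj_from_coords(self, coords_list, n_res):
        coords = np.stack(coords_list)
        return Trajectory(coords, box=np.full(3, 200.0)), _backbone_topology(n_res)

    def test_ideal_helix_fully_helical(self):
        traj, top = self._traj_from_coords([ideal_helix(20)], 20)
        series, ids = percent_helicity(compute_dihedrals(traj, top))
        assert series[0, 0] == pytest.approx(100.0)

    def test_extended_chain_zero_helicity(self):
        traj, top = self._traj_from_coords([build_backbone(20, 180.0, 180.0)], 20)
        series, _ = percent_helicity(compute_dihedrals(traj, top))
        assert series[0, 0] == pytest.approx(0.0)

    def test_mixture_averages_fifty_percent(self):
        frames = [ideal_helix(20)] * 25 + [build_backbone(20, 180.0, 180.0)] * 25
        traj, top = self._traj_from_coords(frames, 20)
        series, _ = percent_helicity(compute_dihedrals(traj, top))
        assert series.mean() == pytest.approx(50.0, abs=1e-9)

    def test_straight_helix_bend_angle_180(self):
        traj, top = self._traj_from_coords([ideal_helix(20)], 20)
        angles, _ = bend_angle(traj, top, 6, 6)
        assert angles[0, 0] == pytest.approx(180.0, abs=8.0)

    def test_constructed_inter_arm_angle_recovered(self):
        traj, top = self._traj_from_coords([hinged_helix(20, 11, 90.0)], 20)
        angles, _ = bend_angle(traj, top, 6, 6)
        assert angles[0, 0] == pytest.approx(90.0, abs=10.0)

    def test_bend_angle_rotation_invariant(self):
        coords = hinged_helix(20, 11, 60.0)
        rot = Rotation.from_rotvec([1.0, -0.3, 0.2])
        traj1, top = self._traj_from_coords([coords], 20)
        traj2, _ = self._traj_from_coords([rot.apply(coords) + 7.0], 20)
        a1, _ = bend_angle(traj1, top)
        a2, _ = bend_angle(traj2, top)
        assert a1[0, 0] == pytest.approx(a2[0, 0], abs=1e-9)

    def test_short_window_rejected(self, membrane_system):
        traj, top, _ = membrane_system
        with pytest.raises(ValueError):
            bend_angle(traj, top, 1, 5)


class TestFieldConversion:
    def test_membrane_potential_to_field(self):
        out = field_convert(FieldSpec(potential=0.07, thickness=35.0))
        assert out.field_v_per_nm == pytest.approx(0.02)

    def test_efz_to_field_two_decimals(self):
        out = field_convert(FieldSpec(efz=0.080))
        assert out.field_v_per_nm == pytest.approx(0.0347, abs=5e-4)
        assert round(out.field_v_per_nm, 2) == 0.03

    def test_zero_field(self):
        assert field_convert(FieldSpec(efz=0.0)).field_v_per_nm == 0.0

    def test_round_trip_consistency(self):
        out = field_convert(FieldSpec(efz=0.18, thickness=35.0))
        back = field_convert(FieldSpec(potential=out.potential, thickness=35.0))
        assert back.efz == pytest.approx(0.18)

    def test_zero_thickness_rejected(self):
        with pytest.raises(ValueError):
            field_convert(FieldSpec(potential=0.07, thickness=0.0))
        with pytest.raises(ValueError):
            field_convert(FieldSpec())
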