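"""Bilayer-like slab with pseudo-lipid chains, Brownian waters and a pore.

The generator emulates the *statistics* of a membrane simulation, not
its chemistry:

* lipid chains are straight runs of carbons whose per-frame tilt from
  the bilayer normal is drawn from a Watson-type axial distribution
  p(u) ∝ exp(κu²) on u = cos θ.  With C–H vectors reconstructed
  perpendicular to the chain axis, the acyl order parameter
  |S_CD| = ⟨P₂(cos θ)⟩ / 2, so κ is solved numerically for any feasible
  target in [0, 0.5);
* waters perform an exact Brownian walk with per-step Gaussian
  displacements of variance 2DΔt per axis — the diffusion coefficient
  ground truth is exact by construction;
* the pore is a rigid cylinder of wall atoms with a prescribed
  van-der-Waals radius, so the free (probe) radius at the mid-plane is
  known analytically as R_cylinder − r_vdW.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from ..system import Topology, Trajectory

_U_GRID = np.linspace(-1.0, 1.0, 4097)


def _watson_mean_p2(kappa: float) -> float:
    w = np.exp(kappa * (_U_GRID**2 - 1.0))  # shifted for overflow safety
    p2 = 0.5 * (3.0 * _U_GRID**2 - 1.0)
    return float(np.trapezoid(p2 * w, _U_GRID) / np.trapezoid(w, _U_GRID))


def solve_watson_concentration(chain_order: float) -> float:
    """Concentration κ with ⟨P₂(cos θ)⟩ = chain_order under p(u) ∝ exp(κu²)."""
    if not -0.5 < chain_order < 1.0:
        raise ValueError("chain order parameter must lie in (-0.5, 1)")
    if abs(chain_order) < 1e-12:
        return 0.0
    lo, hi = -200.0, 200.0
    return float(brentq(lambda k: _watson_mean_p2(k) - chain_order, lo, hi, xtol=1e-10))


def _sample_watson(kappa: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw u = cos θ from p(u) ∝ exp(κu²) by inverse-CDF on a fine grid."""
    w = np.exp(kappa * (_U_GRID**2 - 1.0))
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (w[1:] + w[:-1]) * np.diff(_U_GRID))])
    cdf /= cdf[-1]
    return np.interp(rng.random(n), cdf, _U_GRID)


@dataclass(frozen=True)
class SyntheticMembraneSpec:
    """Parameters of the pseudo-membrane/pore/water system."""

    lipids_per_leaflet: int = 32
    chain_length: int = 10  # carbons per chain
    target_scd: float = 0.16  # |S_CD| magnitude (physical sign negative)
    n_waters: int = 60
    d_water: float = 0.03  # Å² ps⁻¹, true water diffusion coefficient
    pore_radius: float = 11.0  # Å, cylinder radius (wall-atom centers)
    pore_length: float = 30.0  # Å
    wall_vdw: float = 1.5  # Å
    box: tuple[float, float, float] = (46.0, 46.0, 60.0)
    include_pore: bool = True
    n_frames: int = 200
    frame_dt: float = 1.0  # ps
    carbon_spacing: float = 1.25  # Å along the chain axis
    wall_ring_atoms: int = 24
    wall_ring_spacing: float = 1.5  # Å along z
    seed: int = 0

    def __post_init__(self) -> None:
        if not -0.25 < self.target_scd < 0.5:
            raise ValueError(
                "target |S_CD| infeasible for perpendicular C–H reconstruction; "
                "reachable range is (-0.25, 0.5)"
            )
        if self.include_pore and self.pore_radius >= min(self.box[0], self.box[1]) / 2:
            raise ValueError("pore radius must fit inside the box cross-section")
        if self.d_water < 0 or self.n_waters < 0:
            raise ValueError("waters: counts and D must be non-negative")
        if self.lipids_per_leaflet > 0 and self.chain_length < 3:
            raise ValueError("chains need at least 3 carbons for order parameters")
        if self.n_frames < 1 or self.frame_dt <= 0:
            raise ValueError("n_frames and frame_dt must be positive")


class MembraneSystem(NamedTuple):
    trajectory: Trajectory
    topology: Topology
    spec: SyntheticMembraneSpec  # carries the ground-truth parameters


def _head_positions(spec: SyntheticMembraneSpec, rng: np.random.Generator) -> np.ndarray:
    """xy grid positions for one leaflet, excluding the pore footprint."""
    lx, ly = spec.box[0], spec.box[1]
    n_side = int(np.ceil(np.sqrt(spec.lipids_per_leaflet * 2)))
    xs = (np.arange(n_side) + 0.5) * lx / n_side - lx / 2
    ys = (np.arange(n_side) + 0.5) * ly / n_side - ly / 2
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if spec.include_pore:
        r = np.hypot(pts[:, 0], pts[:, 1])
        pts = pts[r > spec.pore_radius + 2.0]
    if len(pts) < spec.lipids_per_leaflet:
        raise ValueError("box too small to place the requested lipid count")
    sel = rng.permutation(len(pts))[: spec.lipids_per_leaflet]
    return pts[sel]


def make_membrane_system(spec: SyntheticMembraneSpec) -> MembraneSystem:
    """Generate the slab system; all randomness from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    nlip = 2 * spec.lipids_per_leaflet
    nc = spec.chain_length
    half_thick = nc * spec.carbon_spacing

    names, elements, resids, resnames, chains, roles = [], [], [], [], [], []
    vdw_override: list[float | None] = []

    # lipid chains: heads at ±half_thick, carbons pointing to z = 0
    heads = []
    if nlip > 0:
        top = _head_positions(spec, rng)
        bot = _head_positions(spec, rng)
        for leaflet, xy in ((1, top), (-1, bot)):
            for j, (x, y) in enumerate(xy):
                heads.append((x, y, leaflet))
        for li in range(nlip):
            cid = f"L{li:03d}"
            rn = "SN1" if li % 2 == 0 else "SN2"
            for k in range(nc):
                names.append(f"C{k + 1}")
                elements.append("C")
                resids.append(li + 1)
                resnames.append(rn)
                chains.append(cid)
                roles.append("head" if k == 0 else "lipid")
                vdw_override.append(None)

    # pore wall: rigid cylinder of rings
    wall_xyz = np.zeros((0, 3))
    if spec.include_pore:
        n_rings = int(np.floor(spec.pore_length / spec.wall_ring_spacing)) + 1
        zs = -spec.pore_length / 2 + np.arange(n_rings) * spec.wall_ring_spacing
        ang = 2 * np.pi * np.arange(spec.wall_ring_atoms) / spec.wall_ring_atoms
        ring = np.column_stack(
            [spec.pore_radius * np.cos(ang), spec.pore_radius * np.sin(ang)]
        )
        wall_xyz = np.concatenate(
            [np.column_stack([ring, np.full(len(ring), z)]) for z in zs]
        )
        for w in range(len(wall_xyz)):
            names.append("CW")
            elements.append("C")
            resids.append(w // spec.wall_ring_atoms + 1)
            resnames.append("POR")
            chains.append("P00")
            roles.append("pore")
            vdw_override.append(spec.wall_vdw)

    # waters: one oxygen each
    for wi in range(spec.n_waters):
        names.append("OW")
        elements.append("O")
        resids.append(wi + 1)
        resnames.append("WAT")
        chains.append("W00")
        roles.append("water")
        vdw_override.append(None)

    n_atoms = len(names)
    top_arr = Topology(
        np.array(names, dtype=object),
        np.array(elements, dtype=object),
        np.array(resids, dtype=int),
        np.array(resnames, dtype=object),
        np.array(chains, dtype=object),
        np.array(roles, dtype=object),
    )
    vdw = top_arr.vdw_radii.copy()
    for i, v in enumerate(vdw_override):
        if v is not None:
            vdw[i] = v
    top_arr.vdw_radii = vdw

    F = spec.n_frames
    coords = np.zeros((F, n_atoms, 3))
    kappa = solve_watson_concentration(2.0 * spec.target_scd)

    # lipids: directors redrawn independently every frame
    if nlip > 0:
        u = _sample_watson(kappa, F * nlip, rng).reshape(F, nlip)
        phi = rng.uniform(0.0, 2 * np.pi, size=(F, nlip))
        sin_t = np.sqrt(np.clip(1.0 - u**2, 0.0, 1.0))
        head_xy = np.array([(h[0], h[1]) for h in heads])
        leaflet = np.array([h[2] for h in heads])  # +1 top, -1 bottom
        # director z-sign points toward the bilayer center
        dirs = np.stack(
            [
                sin_t * np.cos(phi),
                sin_t * np.sin(phi),
                -leaflet[None, :] * np.abs(u),
            ],
            axis=-1,
        )  # (F, nlip, 3)
        ks = np.arange(nc) * spec.carbon_spacing
        start = np.column_stack(
            [head_xy[:, 0], head_xy[:, 1], leaflet * half_thick]
        )  # (nlip, 3)
        chain_coords = (
            start[None, :, None, :] + dirs[:, :, None, :] * ks[None, None, :, None]
        )  # (F, nlip, nc, 3)
        coords[:, : nlip * nc] = chain_coords.reshape(F, nlip * nc, 3)

    off = nlip * nc
    if spec.include_pore:
        coords[:, off : off + len(wall_xyz)] = wall_xyz[None]
        off += len(wall_xyz)

    if spec.n_waters > 0:
        w0 = rng.uniform(-0.5, 0.5, size=(spec.n_waters, 3)) * np.array(spec.box)
        sigma = np.sqrt(2.0 * spec.d_water * spec.frame_dt)
        steps = rng.normal(0.0, sigma, size=(F - 1, spec.n_waters, 3))
        walk = np.concatenate([w0[None], w0[None] + np.cumsum(steps, axis=0)])
        coords[:, off : off + spec.n_waters] = walk

    traj = Trajectory(
        coords=coords,
        box=np.array(spec.box),
        time=np.arange(F) * spec.frame_dt,
    )
    return MembraneSystem(traj, top_arr, spec)
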