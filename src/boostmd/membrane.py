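"""Bilayer, pore and peptide-in-membrane statistics.

Implements the standard channel/membrane observables: electron density
profiles along the bilayer normal, acyl-chain deuterium order parameters
|S_CD| = |0.5⟨3cos²θ − 1⟩|, mean-square displacement with diffusion
coefficients, volumetric water density on a 1 Å grid, pore water
occupancy within a shell of the pore atoms, a pore-radius profile along
z, per-monomer percent α-helicity, the N/C-terminal bend angle, and the
conversion between an external field in kcal (mol·Å·e)⁻¹ and V nm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .conformation import DihedralSeries
from .constants import KCAL_MOL_ANG_E_TO_V_PER_NM
from .system import Topology, Trajectory

# ---------------------------------------------------------------------------
# electron density


@dataclass
class DensityProfile:
    z_centers: np.ndarray  # Å
    densities: dict[str, np.ndarray]  # e⁻ Å⁻³ per group


def _wrap_centered(x: np.ndarray, length) -> np.ndarray:
    """Wrap coordinates into [-L/2, L/2) per frame."""
    return (x + length / 2.0) % length - length / 2.0


def electron_density_profile(
    traj: Trajectory,
    topology: Topology,
    bins: int = 50,
    groups: dict[str, np.ndarray] | None = None,
) -> DensityProfile:
    """Frame-averaged electron density along z for each atom group.

    Groups default to one per distinct topology role plus ``total``;
    densities are electrons per Å³ of slab volume, so the profile
    integrated over z times the box cross-section recovers the group's
    electron count.
    """
    if topology.electrons is None or np.any(~np.isfinite(topology.electrons)):
        raise ValueError("electron counts missing from topology")
    if groups is None:
        groups = {str(r): topology.roles == r for r in np.unique(topology.roles)}
    groups = dict(groups)
    groups["total"] = np.ones(topology.n_atoms, dtype=bool)
    lz = float(np.mean(traj.box[:, 2]))
    area = float(np.mean(traj.box[:, 0] * traj.box[:, 1]))
    edges = np.linspace(-lz / 2, lz / 2, bins + 1)
    dz = edges[1] - edges[0]
    z = _wrap_centered(traj.coords[:, :, 2], traj.box[:, 2:3])
    out = {}
    for label, mask in groups.items():
        hist, _ = np.histogram(
            z[:, mask].ravel(),
            bins=edges,
            weights=np.tile(topology.electrons[mask], traj.n_frames),
        )
        out[label] = hist / (traj.n_frames * area * dz)
    return DensityProfile(z_centers=0.5 * (edges[1:] + edges[:-1]), densities=out)


# ---------------------------------------------------------------------------
# acyl order parameters


@dataclass
class SCDProfile:
    carbon_index: np.ndarray  # 2..n-1 (carbons with both neighbours)
    scd: np.ndarray  # mean |S_CD| per carbon
    by_chain_type: dict[str, np.ndarray]  # resname -> per-carbon |S_CD|


def _chain_scd_samples(chain_coords: np.ndarray) -> np.ndarray:
    """Per-carbon S_CD samples for one chain, one or more frames.

    ``chain_coords``: (..., n_carbons, 3).  The two C–H vectors of carbon
    i are reconstructed perpendicular to the C(i−1)–C(i+1) axis; averaged
    over both hydrogens the order parameter reduces to (1 − 3cos²θ_axis)/4
    with θ_axis the axis tilt from the z normal.
    """
    axis = chain_coords[..., 2:, :] - chain_coords[..., :-2, :]
    norm = np.linalg.norm(axis, axis=-1)
    if np.any(norm < 1e-12):
        raise ValueError("degenerate chain geometry (coincident carbons)")
    cos2 = (axis[..., 2] / norm) ** 2
    return (1.0 - 3.0 * cos2) / 4.0


def scd_profile(traj: Trajectory, topology: Topology) -> SCDProfile:
    """Per-carbon acyl order parameter, averaged over lipids and frames."""
    lipid_mask = (topology.roles == "lipid") | (topology.roles == "head")
    chain_ids = [c for c in topology.chain_ids() if lipid_mask[topology.chains == c].any()]
    if not chain_ids:
        raise ValueError("no lipid chains in topology")
    per_type: dict[str, list[np.ndarray]] = {}
    all_samples: list[np.ndarray] = []
    n_carbons = None
    for cid in chain_ids:
        idx = np.flatnonzero((topology.chains == cid) & lipid_mask)
        if len(idx) < 3:
            raise ValueError(f"chain {cid} has fewer than 3 carbons")
        if n_carbons is None:
            n_carbons = len(idx)
        elif len(idx) != n_carbons:
            raise ValueError("lipid chains must share a common carbon count")
        s = _chain_scd_samples(traj.coords[:, idx, :])  # (F, n_carbons-2)
        all_samples.append(s)
        rn = str(topology.resnames[idx[0]])
        per_type.setdefault(rn, []).append(s)
    stacked = np.concatenate(all_samples, axis=0)
    scd = np.abs(stacked.mean(axis=0))
    by_type = {
        rn: np.abs(np.concatenate(chunks, axis=0).mean(axis=0))
        for rn, chunks in per_type.items()
    }
    assert n_carbons is not None
    return SCDProfile(
        carbon_index=np.arange(2, n_carbons), scd=scd, by_chain_type=by_type
    )


# ---------------------------------------------------------------------------
# MSD / diffusion


@dataclass
class MSDSeries:
    lag_times: np.ndarray  # ps
    msd: np.ndarray  # Å²
    n_dim: int
    slope: float  # Å² ps⁻¹
    diffusion: float  # Å² ps⁻¹  (= slope / 2N)
    diffusion_scaled: float  # slope × 10 / (2N), the conventional scaled report
    exponent: float  # log-log slope over the fit window
    diffusive: bool


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    n = len(x)
    f = np.fft.rfft(x, n=2 * n)
    acf = np.fft.irfft(f * np.conj(f))[:n]
    return acf / (n - np.arange(n))


def _msd_single(r: np.ndarray) -> np.ndarray:
    """Origin-averaged MSD for one particle, r of shape (F, d) — FFT method."""
    n = r.shape[0]
    d_sq = np.square(r).sum(axis=1)
    s2 = sum(_autocorr_fft(r[:, i]) for i in range(r.shape[1]))
    d_pad = np.append(d_sq, 0.0)
    q = 2.0 * d_sq.sum()
    s1 = np.empty(n)
    for m in range(n):
        q -= d_pad[m - 1] + d_pad[n - m]
        s1[m] = q / (n - m)
    return s1 - 2.0 * s2


def msd_diffusion(
    traj: Trajectory,
    selection: np.ndarray,
    n_dim: int = 3,
    fit_window: tuple[float, float] = (0.01, 0.1),
) -> MSDSeries:
    """Origin-averaged MSD and diffusion coefficient for selected atoms.

    ``n_dim`` chooses the dimensions analysed: 3 = xyz, 2 = xy, 1 = z.
    Requires unwrapped coordinates: inter-frame jumps larger than half a
    box edge are rejected with an unwrap hint.  The diffusion
    coefficient is the fitted slope over ``fit_window`` (fractions of
    the maximum lag) divided by 2N; ``diffusion_scaled`` additionally
    multiplies the slope by 10.0 as conventionally reported.  The
    default window keeps to short lags, where MSD estimates are both
    least noisy and least correlated between lag points.
    """
    if n_dim not in (1, 2, 3):
        raise ValueError("n_dim must be 1, 2 or 3")
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if sel.size == 0:
        raise ValueError("empty selection")
    r = traj.coords[:, sel, :]
    jumps = np.abs(np.diff(r, axis=0))
    if np.any(jumps > traj.box[:-1, None, :] / 2.0):
        raise ValueError(
            "wrapped coordinates detected (inter-frame jump > box/2); "
            "unwrap the trajectory before MSD analysis"
        )
    axes = {3: [0, 1, 2], 2: [0, 1], 1: [2]}[n_dim]
    r = r[:, :, axes]
    msd = np.mean([_msd_single(r[:, i, :]) for i in range(r.shape[1])], axis=0)
    dt = float(np.mean(np.diff(traj.time))) if traj.n_frames > 1 else 1.0
    lags = np.arange(len(msd)) * dt

    i0 = max(1, int(fit_window[0] * (len(msd) - 1)))
    i1 = max(i0 + 2, int(fit_window[1] * (len(msd) - 1)))
    fit = linregress(lags[i0:i1], msd[i0:i1])
    slope = float(fit.slope)
    with np.errstate(divide="ignore", invalid="ignore"):
        pos = msd[i0:i1] > 0
        exponent = (
            float(np.polyfit(np.log(lags[i0:i1][pos]), np.log(msd[i0:i1][pos]), 1)[0])
            if pos.sum() > 2
            else np.nan
        )
    diffusive = bool(np.isfinite(exponent) and exponent < 1.5)
    return MSDSeries(
        lag_times=lags,
        msd=msd,
        n_dim=n_dim,
        slope=slope,
        diffusion=slope / (2.0 * n_dim),
        diffusion_scaled=slope * 10.0 / (2.0 * n_dim),
        exponent=exponent,
        diffusive=diffusive,
    )


# ---------------------------------------------------------------------------
# volumetric water density


@dataclass
class VolumetricGrid:
    grid: np.ndarray  # mean occupancy per voxel per frame
    origin: np.ndarray  # Å, corner of voxel (0,0,0)
    spacing: float  # Å


def water_grid_density(
    traj: Trajectory, topology: Topology, spacing: float = 1.0
) -> VolumetricGrid:
    """3-D occupancy histogram of water oxygens, normalized per frame."""
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    mask = (topology.roles == "water") & (topology.elements == "O")
    if not mask.any():
        raise ValueError("no water oxygens identifiable in topology")
    box = traj.box.mean(axis=0)
    edges = [
        np.arange(-box[d] / 2.0, box[d] / 2.0 + spacing * 0.5, spacing) for d in range(3)
    ]
    pts = _wrap_centered(traj.coords[:, mask, :], traj.box[:, None, :]).reshape(-1, 3)
    grid, _ = np.histogramdd(pts, bins=edges)
    return VolumetricGrid(
        grid=grid / traj.n_frames,
        origin=np.array([e[0] for e in edges]),
        spacing=spacing,
    )


# ---------------------------------------------------------------------------
# pore water occupancy


def pore_water_count(
    traj: Trajectory,
    topology: Topology,
    pore_selection: np.ndarray | None = None,
    cutoff: float = 3.4,
) -> np.ndarray:
    """Waters within ``cutoff`` Å of any pore atom, per frame."""
    if pore_selection is None:
        pore_selection = topology.roles == "pore"
    pore_idx = np.flatnonzero(np.asarray(pore_selection))
    if pore_idx.size == 0:
        raise ValueError("empty pore selection")
    wat_idx = np.flatnonzero((topology.roles == "water") & (topology.elements == "O"))
    counts = np.empty(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        if wat_idx.size == 0:
            counts[f] = 0
            continue
        tree = cKDTree(traj.coords[f, pore_idx])
        d, _ = tree.query(traj.coords[f, wat_idx], k=1)
        counts[f] = int(np.count_nonzero(d <= cutoff))
    return counts


# ---------------------------------------------------------------------------
# pore radius profile


@dataclass
class PoreProfile:
    z_centers: np.ndarray
    mean_radius: np.ndarray
    per_frame: np.ndarray  # (n_slices, n_frames)
    capped: np.ndarray  # bool per slice: no wall atoms found, radius = cap


def pore_radius_profile(
    traj: Trajectory,
    topology: Topology,
    z_edges: np.ndarray | None = None,
    max_radius: float = 15.0,
    grid_spacing: float = 0.25,
    wall_selection: np.ndarray | None = None,
) -> PoreProfile:
    """Largest free-sphere radius per z-slice, deterministic grid search.

    Within each slice the radius at a candidate centre is the minimum
    over nearby wall atoms of (in-plane distance − atom vdW radius); the
    slice radius is the maximum over a 2-D grid of candidate centres
    (spacing ``grid_spacing``) around the slice centroid, capped at
    ``max_radius``.  Slices without wall atoms report the cap and are
    flagged.
    """
    if wall_selection is None:
        wall_selection = topology.roles == "pore"
    wall_idx = np.flatnonzero(np.asarray(wall_selection))
    if wall_idx.size == 0:
        raise ValueError("empty wall selection")
    vdw = topology.vdw_radii[wall_idx]
    zw = traj.coords[:, wall_idx, 2]
    if z_edges is None:
        z_edges = np.linspace(zw.min(), zw.max() + 1e-9, 21)
    z_edges = np.asarray(z_edges, dtype=float)
    ns = len(z_edges) - 1
    per_frame = np.full((ns, traj.n_frames), float(max_radius))
    capped = np.zeros(ns, dtype=bool)
    half = grid_spacing / 2.0
    g = np.arange(-max_radius, max_radius + half, grid_spacing)
    gx, gy = np.meshgrid(g, g, indexing="ij")
    grid_pts = np.column_stack([gx.ravel(), gy.ravel()])
    for f in range(traj.n_frames):
        xy = traj.coords[f, wall_idx, :2]
        for s in range(ns):
            in_slice = (zw[f] >= z_edges[s]) & (zw[f] < z_edges[s + 1])
            if not in_slice.any():
                capped[s] = True
                continue
            atoms = xy[in_slice]
            center = atoms.mean(axis=0)
            # candidate centres stay inside the wall ring: allowing them
            # beyond the nearest wall atom would let the search escape the
            # pore and report the open volume outside instead
            r_wall = float(np.linalg.norm(atoms - center, axis=1).min())
            inside = np.linalg.norm(grid_pts, axis=1) <= r_wall
            d = np.linalg.norm(
                grid_pts[inside, None, :] + center[None, None, :] - atoms[None, :, :],
                axis=2,
            )
            free = (d - vdw[in_slice][None, :]).min(axis=1)
            per_frame[s, f] = min(max(float(free.max()), 0.0), max_radius)
    return PoreProfile(
        z_centers=0.5 * (z_edges[1:] + z_edges[:-1]),
        mean_radius=per_frame.mean(axis=1),
        per_frame=per_frame,
        capped=capped,
    )


# ---------------------------------------------------------------------------
# helicity and bend angle

HELIX_PHI_RANGE = (-100.0, -30.0)
HELIX_PSI_RANGE = (-67.0, -7.0)


def percent_helicity(
    dihedrals: DihedralSeries,
    phi_range: tuple[float, float] = HELIX_PHI_RANGE,
    psi_range: tuple[float, float] = HELIX_PSI_RANGE,
) -> tuple[np.ndarray, list]:
    """Percent α-helical residues per frame per monomer.

    A residue counts as helical when (φ, ψ) falls inside the α-helical
    window; residues with an undefined angle are excluded from the
    assignable count.  Returns (array of shape (n_frames, n_monomers),
    monomer ids).
    """
    monomers = []
    seen: dict = {}
    for c in dihedrals.chains:
        seen.setdefault(c, None)
    monomers = list(seen)
    out = np.full((dihedrals.n_frames, len(monomers)), np.nan)
    for m, cid in enumerate(monomers):
        cols = np.flatnonzero(dihedrals.chains == cid)
        phi = dihedrals.phi[:, cols]
        psi = dihedrals.psi[:, cols]
        assignable = ~(np.isnan(phi) | np.isnan(psi))
        helical = (
            assignable
            & (phi >= phi_range[0])
            & (phi <= phi_range[1])
            & (psi >= psi_range[0])
            & (psi <= psi_range[1])
        )
        n_assign = assignable.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out[:, m] = np.where(
                n_assign > 0, 100.0 * helical.sum(axis=1) / n_assign, np.nan
            )
    return out, monomers


def _residue_centers(traj: Trajectory, topology: Topology, chain) -> np.ndarray:
    """Per-frame residue centers for one chain: CA position if present,
    otherwise the mean of the residue's atoms.  Shape (F, n_res, 3)."""
    res_map = topology.residue_atom_index(chain)
    centers = []
    for r in sorted(res_map):
        atoms = res_map[r]
        if "CA" in atoms:
            centers.append(traj.coords[:, atoms["CA"], :])
        else:
            idx = list(atoms.values())
            centers.append(traj.coords[:, idx, :].mean(axis=1))
    return np.stack(centers, axis=1)


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Line directions for (F, k, 3) windows -> (F, 3) unit vectors.

    The direction is the difference of the two half-window centroids:
    for helical backbones each half averages out the radial winding, so
    the estimate tracks the local helix axis far better than a plain
    least-squares line through the raw points.
    """
    h = points.shape[1] // 2
    v = points[:, h:, :].mean(axis=1) - points[:, :h, :].mean(axis=1)
    n = np.linalg.norm(v, axis=1, keepdims=True)
    if np.any(n < 1e-10):
        raise ValueError("degenerate (coincident-centroid) terminal window")
    return v / n


def bend_angle(
    traj: Trajectory,
    topology: Topology,
    n_term_residues: int = 6,
    c_term_residues: int = 6,
) -> tuple[np.ndarray, list]:
    """Angle between outward N- and C-terminal direction vectors.

    Each terminal vector is the axis direction fitted through that
    window's residue centers, oriented away from the chain midpoint, so
    a straight helix reads ≈ 180° and bending decreases the angle.
    Windows spanning at least 1.5 helical turns (6 residues) keep the
    axis estimate stable against the helical winding.
    Returns (angles (n_frames, n_monomers) in degrees, monomer ids).
    Monomers with fewer than n+c residues are skipped.
    """
    if n_term_residues < 2 or c_term_residues < 2:
        raise ValueError("each terminal window needs at least 2 residues")
    angles = []
    ids = []
    for cid in topology.chain_ids():
        centers = _residue_centers(traj, topology, cid)
        nres = centers.shape[1]
        if nres < n_term_residues + c_term_residues:
            continue
        wn = centers[:, :n_term_residues, :]
        wc = centers[:, -c_term_residues:, :]
        vn = _fit_direction(wn)
        vc = _fit_direction(wc)
        # orient outward: N vector toward residue 1, C vector toward residue n
        sn = np.sign(np.sum(vn * (wn[:, 0] - wn[:, -1]), axis=1))
        sc = np.sign(np.sum(vc * (wc[:, -1] - wc[:, 0]), axis=1))
        if np.any(sn == 0) or np.any(sc == 0):
            raise ValueError(f"degenerate (collinear-window) geometry in chain {cid}")
        vn = vn * sn[:, None]
        vc = vc * sc[:, None]
        cosang = np.clip(np.sum(vn * vc, axis=1), -1.0, 1.0)
        angles.append(np.degrees(np.arccos(cosang)))
        ids.append(cid)
    if not ids:
        raise ValueError("no chain has enough residues for both windows")
    return np.column_stack(angles), ids


# ---------------------------------------------------------------------------
# field conversion


@dataclass
class FieldSpec:
    """External-field bookkeeping along the membrane normal.

    ``efz`` in kcal (mol·Å·e)⁻¹, ``field_v_per_nm`` in V nm⁻¹,
    ``thickness`` in Å, ``potential`` in V.
    """

    efz: float | None = None
    field_v_per_nm: float | None = None
    thickness: float | None = None
    potential: float | None = None


def field_convert(spec: FieldSpec) -> FieldSpec:
    """Complete a partial field specification.

    Either ``efz`` or (``potential``, ``thickness``) must be given;
    1 kcal (mol·Å·e)⁻¹ ≈ 0.4336 V nm⁻¹.
    """
    efz, thickness, potential = spec.efz, spec.thickness, spec.potential
    if thickness is not None and thickness <= 0:
        raise ValueError("membrane thickness must be positive")
    if efz is not None:
        field = efz * KCAL_MOL_ANG_E_TO_V_PER_NM
        if thickness is not None and potential is None:
            potential = field * thickness / 10.0  # Å → nm
    elif potential is not None and thickness is not None:
        field = potential / (thickness / 10.0)
        efz = field / KCAL_MOL_ANG_E_TO_V_PER_NM
    else:
        raise ValueError("give efz, or potential together with thickness")
    return FieldSpec(
        efz=efz, field_v_per_nm=field, thickness=thickness, potential=potential
    )
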