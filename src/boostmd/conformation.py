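"""Backbone conformational analysis.

Dihedral extraction (φ/ψ via the standard four-atom IUPAC definitions),
dihedral PCA on the sin/cos-embedded angles, k-means clustering with
nearest-to-centroid representatives, Kabsch superposition RMSD, and a
Kullback-Leibler divergence diagnostic that measures whether two
independent runs have sampled the same distribution along a shared
principal-component mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import gaussian_kde
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .reweighting import FESurface, ReweightScheme, reweighted_pmf
from .system import Topology, Trajectory


# ---------------------------------------------------------------------------
# dihedrals


@dataclass
class DihedralSeries:
    """φ/ψ per frame per residue, degrees in (−180, 180]; NaN = undefined."""

    phi: np.ndarray  # (n_frames, n_residues)
    psi: np.ndarray
    resids: np.ndarray  # (n_residues,)
    chains: np.ndarray  # (n_residues,) chain/monomer id per residue column

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    @property
    def n_residues(self) -> int:
        return self.phi.shape[1]


def dihedral_angle(p1, p2, p3, p4) -> np.ndarray:
    """Signed torsion (degrees) about p2–p3; inputs (..., 3)."""
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b3 = np.asarray(p4) - np.asarray(p3)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m1 * n2, axis=-1)
    # IUPAC sign: clockwise rotation of the far bond viewed along b2 is positive
    return np.degrees(np.arctan2(-y, x))


def compute_dihedrals(traj: Trajectory, topology: Topology) -> DihedralSeries:
    """Backbone φ/ψ for every residue of every chain.

    Terminal residues lacking a neighbour get NaN for the undefined
    angle; a residue with a broken backbone (missing N/CA/C) is flagged
    by NaN in both columns rather than failing.
    """
    cols_phi, cols_psi, col_resid, col_chain = [], [], [], []
    X = traj.coords
    for chain in topology.chain_ids():
        res_map = topology.residue_atom_index(chain)
        resids = sorted(res_map)
        for r in resids:
            atoms = res_map[r]
            ok = all(k in atoms for k in ("N", "CA", "C"))
            phi = np.full(traj.n_frames, np.nan)
            psi = np.full(traj.n_frames, np.nan)
            if ok:
                prev_atoms = res_map.get(r - 1)
                next_atoms = res_map.get(r + 1)
                if prev_atoms is not None and "C" in prev_atoms:
                    phi = dihedral_angle(
                        X[:, prev_atoms["C"]],
                        X[:, atoms["N"]],
                        X[:, atoms["CA"]],
                        X[:, atoms["C"]],
                    )
                if next_atoms is not None and "N" in next_atoms:
                    psi = dihedral_angle(
                        X[:, atoms["N"]],
                        X[:, atoms["CA"]],
                        X[:, atoms["C"]],
                        X[:, next_atoms["N"]],
                    )
            cols_phi.append(phi)
            cols_psi.append(psi)
            col_resid.append(r)
            col_chain.append(chain)
    return DihedralSeries(
        phi=np.column_stack(cols_phi),
        psi=np.column_stack(cols_psi),
        resids=np.array(col_resid),
        chains=np.array(col_chain, dtype=object),
    )


# ---------------------------------------------------------------------------
# dihedral PCA


@dataclass
class PCModel:
    """Principal components of the sin/cos-embedded dihedral space."""

    mean: np.ndarray
    components: np.ndarray  # (n_modes, n_features)
    eigenvalues: np.ndarray  # non-increasing variances
    explained_variance_ratio: np.ndarray
    projections: np.ndarray  # (n_frames, n_modes)
    feature_mask: np.ndarray = field(default=None)  # type: ignore[assignment]


def _sincos_features(dihedrals: DihedralSeries) -> tuple[np.ndarray, np.ndarray]:
    ang = np.concatenate([dihedrals.phi, dihedrals.psi], axis=1)
    rad = np.radians(ang)
    feats = np.concatenate([np.cos(rad), np.sin(rad)], axis=1)
    mask = ~np.isnan(feats).any(axis=0)
    return feats[:, mask], mask


def dihedral_pca(dihedrals: DihedralSeries, n_components: int | None = None) -> PCModel:
    """PCA on (cos, sin) of each defined φ/ψ angle.

    Columns containing NaN (terminal or broken residues) are excluded.
    Zero-variance input yields all-zero eigenvalues and projections.
    """
    X, mask = _sincos_features(dihedrals)
    if X.shape[0] < 2:
        raise ValueError("dihedral PCA needs at least two frames")
    if np.allclose(X, X[0], atol=1e-12):
        k = X.shape[1] if n_components is None else n_components
        return PCModel(
            mean=X.mean(axis=0),
            components=np.zeros((k, X.shape[1])),
            eigenvalues=np.zeros(k),
            explained_variance_ratio=np.zeros(k),
            projections=np.zeros((X.shape[0], k)),
            feature_mask=mask,
        )
    k = min(X.shape) if n_components is None else n_components
    pca = PCA(n_components=k, svd_solver="full")
    proj = pca.fit_transform(X)
    return PCModel(
        mean=pca.mean_,
        components=pca.components_,
        eigenvalues=pca.explained_variance_,
        explained_variance_ratio=pca.explained_variance_ratio_,
        projections=proj,
        feature_mask=mask,
    )


def project_dihedrals(model: PCModel, dihedrals: DihedralSeries) -> np.ndarray:
    """Project another trajectory's dihedrals onto an existing PC basis."""
    X, mask = _sincos_features(dihedrals)
    if mask.sum() != model.components.shape[1]:
        raise ValueError("feature layout does not match the PC basis")
    return (X - model.mean) @ model.components.T


def fel_2d(
    pc_model: PCModel,
    delta_V: np.ndarray | None = None,
    scheme: ReweightScheme | None = None,
    bins: int = 60,
) -> FESurface:
    """Reweighted free-energy landscape over (PC1, PC2)."""
    if pc_model.projections.shape[1] < 2:
        raise ValueError("need at least two principal components for a 2-D FEL")
    return reweighted_pmf(pc_model.projections[:, :2], delta_V, bins=bins, scheme=scheme)


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    labels: np.ndarray  # per-frame cluster label
    n_clusters: int
    representative_frames: np.ndarray  # frame index per cluster
    populations: np.ndarray  # fraction per cluster

    def __post_init__(self) -> None:
        for c in range(self.n_clusters):
            rep = self.representative_frames[c]
            if self.labels[rep] != c:
                raise ValueError("representative frame outside its cluster")


def cluster_conformations(
    pc_model: PCModel, k: int, n_pcs: int = 2, seed: int = 0
) -> ClusterResult:
    """k-means on the leading PCs; representative = frame nearest its centroid."""
    if k < 1:
        raise ValueError("k must be >= 1")
    X = pc_model.projections[:, :n_pcs]
    if k > X.shape[0]:
        raise ValueError("k exceeds the number of frames")
    n_distinct = np.unique(np.round(X, 12), axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds the number of distinct points ({n_distinct})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(X)
    reps = np.empty(k, dtype=int)
    pops = np.empty(k)
    for c in range(k):
        members = np.flatnonzero(labels == c)
        d = np.linalg.norm(X[members] - km.cluster_centers_[c], axis=1)
        reps[c] = members[np.argmin(d)]
        pops[c] = len(members) / X.shape[0]
    return ClusterResult(labels=labels, n_clusters=k, representative_frames=reps, populations=pops)


# ---------------------------------------------------------------------------
# superposition RMSD


def superpose_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD (Å) after optimal rigid (proper-rotation) superposition.

    Atom correspondence is positional; both inputs are (n, 3) with n ≥ 3.
    """
    a = np.asarray(mobile, dtype=float)
    b = np.asarray(reference, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate sets must share shape (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 atoms")
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(b, a)
    return float(rssd / np.sqrt(n))


# ---------------------------------------------------------------------------
# KLD convergence


@dataclass
class KLDSeries:
    mode: int
    times: np.ndarray
    values: np.ndarray
    threshold: float = 0.025

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("window times must be strictly increasing")
        if self.values.min(initial=0.0) < -1e-12:
            raise ValueError("KLD values must be non-negative")

    @property
    def convergence_time(self) -> float | None:
        """First window time from which KLD stays below threshold."""
        below = self.values < self.threshold
        for i in range(len(below)):
            if below[i:].all():
                return float(self.times[i])
        return None


def histogram_kld(
    p_samples: np.ndarray,
    q_samples: np.ndarray,
    bins: int = 100,
    pseudocount: float = 1e-6,
    edges: np.ndarray | None = None,
    backend: str = "hist",
) -> float:
    """KLD(P‖Q) = Σ p ln(p/q) between two sample sets on shared bins.

    A pseudo-count keeps the divergence finite on disjoint supports.
    ``backend='kde'`` evaluates Gaussian kernel density estimates on the
    same bin centers instead of raw counts.
    """
    p_samples = np.asarray(p_samples, dtype=float).ravel()
    q_samples = np.asarray(q_samples, dtype=float).ravel()
    if pseudocount <= 0:
        raise ValueError("a positive pseudo-count is mandatory (finite KLD)")
    if edges is None:
        pooled = np.concatenate([p_samples, q_samples])
        lo, hi = pooled.min(), pooled.max()
        if hi <= lo:
            hi = lo + 1e-9
        pad = 1e-9 * max(1.0, abs(hi - lo))
        edges = np.linspace(lo - pad, hi + pad, bins + 1)
    if backend == "hist":
        p, _ = np.histogram(p_samples, bins=edges)
        q, _ = np.histogram(q_samples, bins=edges)
        p = p.astype(float)
        q = q.astype(float)
        p /= max(p.sum(), 1.0)
        q /= max(q.sum(), 1.0)
    elif backend == "kde":
        centers = 0.5 * (edges[1:] + edges[:-1])
        p = _kde_eval(p_samples, centers)
        q = _kde_eval(q_samples, centers)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    p = p + pseudocount
    q = q + pseudocount
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def _kde_eval(samples: np.ndarray, centers: np.ndarray) -> np.ndarray:
    if np.std(samples) < 1e-12:  # degenerate: delta at the sample value
        dens = np.zeros_like(centers)
        dens[np.argmin(np.abs(centers - samples[0]))] = 1.0
        return dens
    dens = gaussian_kde(samples)(centers)
    s = dens.sum()
    return dens / s if s > 0 else dens


def kld_convergence(
    projections_run_a: np.ndarray,
    projections_run_b: np.ndarray,
    mode: int = 0,
    window_times: np.ndarray | None = None,
    times: np.ndarray | None = None,
    threshold: float = 0.025,
    bins: int = 100,
    pseudocount: float = 1e-6,
    backend: str = "hist",
) -> KLDSeries:
    """KLD between two runs' PC projections over growing time windows.

    Both runs must be projected on a common basis (use the PCA of the
    concatenated runs).  For each window time t, the histograms of all
    frames with time ≤ t are compared; convergence is declared at the
    first t from which KLD stays below ``threshold``.
    """
    a = np.atleast_2d(np.asarray(projections_run_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(projections_run_b, dtype=float).T).T
    xa = a[:, mode]
    xb = b[:, mode]
    n = min(len(xa), len(xb))
    if times is None:
        times = np.arange(1, n + 1, dtype=float)
    times = np.asarray(times, dtype=float)
    if window_times is None:
        window_times = np.linspace(times[0], times[n - 1], min(10, n))
    pooled = np.concatenate([xa, xb])
    lo, hi = pooled.min(), pooled.max()
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    values = []
    kept_times = []
    for t in window_times:
        k = int(np.searchsorted(times[:n], t, side="right"))
        if k < 2:
            continue
        values.append(
            histogram_kld(
                xa[:k], xb[:k], pseudocount=pseudocount, edges=edges, backend=backend
            )
        )
        kept_times.append(t)
    return KLDSeries(
        mode=mode,
        times=np.array(kept_times),
        values=np.array(values),
        threshold=threshold,
    )
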