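"""Recovering unbiased distributions and PMFs from boosted sampling.

A frame sampled on the boosted surface carries weight exp(βΔV) in the
canonical ensemble of the bare potential.  Three estimators are
provided:

``maclaurin``
    truncated series Σ_{k=0..K} (βΔV)^k / k!, the first-order-cumulant
    family; suppresses noise from large boosts at the cost of a small
    systematic underweighting of the most-boosted frames.
``exponential``
    the exact weight exp(βΔV); unbiased but noisy when βΔV is large.
``cumulant2``
    a bin-level second-order cumulant correction
    exp(β⟨ΔV⟩_bin + β²σ²_bin/2), exact when ΔV is Gaussian within a bin.

The PMF along a coordinate is −kT ln p, minimum-shifted to zero;
unvisited bins are reported as missing (NaN), not as zero energy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, KB_KCAL_MOL_K
from .system import Topology, Trajectory

METHODS = ("maclaurin", "exponential", "cumulant2")


@dataclass(frozen=True)
class ReweightScheme:
    method: str = "maclaurin"
    maclaurin_order: int = 10
    temperature: float = DEFAULT_TEMPERATURE_K

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown reweighting method {self.method!r}")
        if self.maclaurin_order < 1:
            raise ValueError("maclaurin_order must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def beta(self) -> float:
        return 1.0 / (KB_KCAL_MOL_K * self.temperature)


@dataclass
class FESurface:
    """Binned reweighted probability and PMF grid (1-D or 2-D).

    ``prob`` sums to 1 over occupied bins; ``pmf`` is −kT ln p shifted so
    its minimum is exactly 0, NaN on empty bins; ``counts`` is the raw
    (unweighted) occupancy.
    """

    edges: tuple[np.ndarray, ...]
    prob: np.ndarray
    pmf: np.ndarray
    counts: np.ndarray
    kT: float
    flat: bool = False

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def centers(self) -> tuple[np.ndarray, ...]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)

    def to_dataframe(self) -> pd.DataFrame:
        if self.ndim == 1:
            return pd.DataFrame(
                {
                    "center": self.centers[0],
                    "prob": self.prob,
                    "pmf": self.pmf,
                    "count": self.counts,
                }
            )
        cx, cy = np.meshgrid(*self.centers, indexing="ij")
        return pd.DataFrame(
            {
                "center_x": cx.ravel(),
                "center_y": cy.ravel(),
                "prob": self.prob.ravel(),
                "pmf": self.pmf.ravel(),
                "count": self.counts.ravel(),
            }
        )


def frame_weights(delta_V: np.ndarray, scheme: ReweightScheme) -> np.ndarray:
    """Per-frame reweighting factors for frame-level estimators.

    The second-order cumulant correction is defined per bin, not per
    frame, and is rejected here (use :func:`reweighted_pmf`).
    """
    if scheme.method == "cumulant2":
        raise ValueError("cumulant2 is a bin-level method; use reweighted_pmf")
    dv = np.asarray(delta_V, dtype=float)
    if dv.min(initial=0.0) < 0:
        raise ValueError("boost energies must be non-negative")
    x = scheme.beta * dv
    if scheme.method == "exponential":
        return np.exp(np.minimum(x, 700.0))
    # Maclaurin: accumulate terms to avoid factorial overflow
    w = np.ones_like(x)
    term = np.ones_like(x)
    for k in range(1, scheme.maclaurin_order + 1):
        term = term * x / k
        w = w + term
    return w


def reweighted_pmf(
    coordinate: np.ndarray,
    delta_V: np.ndarray | None,
    bins: int | tuple = 50,
    scheme: ReweightScheme | None = None,
    hist_range=None,
) -> FESurface:
    """Weighted histogram of a 1-D or 2-D coordinate series → PMF.

    ``coordinate`` has shape (n,) or (n, 2) and must align frame-by-frame
    with ``delta_V`` (None means unboosted, all weights equal).
    """
    scheme = scheme or ReweightScheme()
    coord = np.asarray(coordinate, dtype=float)
    one_d = coord.ndim == 1
    n = coord.shape[0]
    if delta_V is None:
        dv = np.zeros(n)
    else:
        dv = np.asarray(delta_V, dtype=float)
        if dv.shape != (n,):
            raise ValueError("coordinate and delta_V must align frame-by-frame")
        if dv.min(initial=0.0) < 0:
            raise ValueError("boost energies must be non-negative")
    kT = 1.0 / scheme.beta

    if one_d:
        counts, edges = np.histogram(coord, bins=bins, range=hist_range)
        edges_t: tuple = (edges,)
    else:
        counts, ex, ey = np.histogram2d(coord[:, 0], coord[:, 1], bins=bins, range=hist_range)
        edges_t = (ex, ey)

    if scheme.method in ("maclaurin", "exponential"):
        w = frame_weights(dv, scheme)
        if one_d:
            hist, _ = np.histogram(coord, bins=edges_t[0], weights=w)
        else:
            hist, _, _ = np.histogram2d(
                coord[:, 0], coord[:, 1], bins=edges_t, weights=w
            )
    else:  # cumulant2: per-bin exp(β<ΔV> + β²σ²/2) anharmonic correction
        if one_d:
            idx = (np.digitize(coord, edges_t[0][1:-1]),)
            shape = (len(edges_t[0]) - 1,)
        else:
            idx = (
                np.digitize(coord[:, 0], edges_t[0][1:-1]),
                np.digitize(coord[:, 1], edges_t[1][1:-1]),
            )
            shape = (len(edges_t[0]) - 1, len(edges_t[1]) - 1)
        s1 = np.zeros(shape)
        s2 = np.zeros(shape)
        np.add.at(s1, idx, dv)
        np.add.at(s2, idx, dv * dv)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(counts > 0, s1 / np.maximum(counts, 1), 0.0)
            var = np.where(counts > 0, s2 / np.maximum(counts, 1) - mean**2, 0.0)
        var = np.maximum(var, 0.0)
        b = scheme.beta
        log_corr = b * mean + 0.5 * b * b * var
        log_corr -= log_corr.max(initial=0.0)  # overflow guard; constant cancels
        hist = counts * np.exp(log_corr)

    total = hist.sum()
    if total <= 0:
        raise ValueError("no samples fell inside the histogram range")
    prob = hist / total
    with np.errstate(divide="ignore"):
        pmf = np.where(prob > 0, -kT * np.log(np.where(prob > 0, prob, 1.0)), np.nan)
    pmf = pmf - np.nanmin(pmf)
    flat = int((counts > 0).sum()) <= 1
    return FESurface(edges=edges_t, prob=prob, pmf=pmf, counts=counts, kT=kT, flat=flat)


def end_to_end_distance(traj: Trajectory, topology: Topology) -> np.ndarray:
    """Per-frame distance between the terminal residues' CA atoms.

    Falls back to the first/last atom of the terminal residues when no
    CA is present.  Raises if the topology has fewer than two residues.
    """
    resids = topology.resids
    if len(np.unique(resids)) < 2:
        raise ValueError("end-to-end distance needs at least two residues")
    first, last = resids.min(), resids.max()

    def _pick(resid) -> int:
        sel = np.flatnonzero((resids == resid) & (topology.names == "CA"))
        if sel.size == 0:
            sel = np.flatnonzero(resids == resid)
        return int(sel[0])

    i, j = _pick(first), _pick(last)
    d = traj.coords[:, i, :] - traj.coords[:, j, :]
    return np.linalg.norm(d, axis=1)


def pmf_1d_end_to_end(
    traj: Trajectory,
    topology: Topology,
    scheme: ReweightScheme | None = None,
    delta_V: np.ndarray | None = None,
    bins: int = 50,
    hist_range=None,
):
    """End-to-end-distance PMF plus a basin summary.

    Returns ``(FESurface, summary)`` where ``summary`` lists local PMF
    minima as (distance, pmf) sorted by depth and the barrier (max PMF)
    between the two deepest minima when there are at least two.
    """
    dist = end_to_end_distance(traj, topology)
    surf = reweighted_pmf(dist, delta_V, bins=bins, scheme=scheme, hist_range=hist_range)
    centers = surf.centers[0]
    pmf = surf.pmf
    minima = []
    finite = np.isfinite(pmf)
    for i in np.flatnonzero(finite):
        left = pmf[i - 1] if i > 0 and finite[i - 1] else np.inf
        right = pmf[i + 1] if i < len(pmf) - 1 and finite[i + 1] else np.inf
        if pmf[i] <= left and pmf[i] <= right and not (left == np.inf and right == np.inf):
            minima.append((float(centers[i]), float(pmf[i])))
    if not minima and finite.any():
        i = int(np.nanargmin(pmf))
        minima = [(float(centers[i]), float(pmf[i]))]
    minima.sort(key=lambda t: t[1])
    summary = {"minima": minima, "barrier": None}
    if len(minima) >= 2:
        x1, x2 = minima[0][0], minima[1][0]
        lo, hi = sorted((x1, x2))
        sel = (centers >= lo) & (centers <= hi) & finite
        if sel.any():
            summary["barrier"] = float(np.nanmax(pmf[sel]))
    return surf, summary
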