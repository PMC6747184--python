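"""Analytic toy potentials with closed-form reference distributions.

These stand in for the peptide potential that the accelerated-MD boost
acts on: their Boltzmann density — hence the exact potential of mean
force — is available by quadrature, which makes the whole
boost → sampling → reweighting chain verifiable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid


class ToyPotential:
    """Base class: an analytic potential on 1 or 2 dimensions.

    Subclasses implement scalar-friendly ``energy`` and ``gradient``.
    ``dihedral`` optionally names a sub-potential treated as the
    "dihedral" energy component for dual-boost runs; when it is None a
    dual boost degenerates to a total-only boost.
    """

    dim: int = 1
    dihedral: "ToyPotential | None" = None

    def energy(self, x):
        raise NotImplementedError

    def gradient(self, x):
        raise NotImplementedError

    # -- reference quantities ------------------------------------------------

    def domain(self) -> tuple[float, float]:
        """Interval on which the Boltzmann density is effectively supported."""
        raise NotImplementedError

    def boltzmann_pdf(self, grid: np.ndarray, kT: float) -> np.ndarray:
        """Normalized Boltzmann density exp(-V/kT) on a 1-D grid."""
        if self.dim != 1:
            raise NotImplementedError("closed-form density only for 1-D potentials")
        w = np.exp(-np.asarray(self.energy(grid)) / kT)
        z = np.trapezoid(w, grid)
        return w / z

    def boltzmann_cdf(self, grid: np.ndarray, kT: float) -> np.ndarray:
        p = self.boltzmann_pdf(grid, kT)
        c = cumulative_trapezoid(p, grid, initial=0.0)
        return c / c[-1]

    def analytic_pmf(self, x) -> np.ndarray:
        """PMF = V shifted so its minimum is 0 (valid for any kT)."""
        v = np.asarray(self.energy(x), dtype=float)
        return v - v.min()


@dataclass(frozen=True)
class DoubleWell(ToyPotential):
    """Symmetric quartic double well V(x) = h[(x/a)² − 1]².

    ``barrier_height`` h is the barrier between the wells at x = ±a
    (kcal mol⁻¹); ``well_separation`` a is the half-distance between
    minima (Å).
    """

    barrier_height: float = 5.0
    well_separation: float = 1.0
    dim: int = 1
    dihedral = None

    def __post_init__(self) -> None:
        if self.barrier_height <= 0:
            raise ValueError("barrier_height must be positive")
        if self.well_separation <= 0:
            raise ValueError("well_separation must be positive")

    def energy(self, x):
        u = (x / self.well_separation) ** 2 - 1.0
        return self.barrier_height * u * u

    def gradient(self, x):
        a2 = self.well_separation**2
        return 4.0 * self.barrier_height * x * ((x * x) / a2 - 1.0) / a2

    def domain(self) -> tuple[float, float]:
        # wells ±a plus room for thermal excursions at any reasonable kT
        a = self.well_separation
        return (-2.2 * a, 2.2 * a)


@dataclass(frozen=True)
class DoubleWellTransverse(ToyPotential):
    """2-D potential: double well along x plus a harmonic transverse mode.

    V(x, y) = h[(x/a)² − 1]² + ½ k y².  The double-well term is
    designated the "dihedral" component, so dual-boost runs boost it
    separately from the total — the same code path an atomistic dual
    boost exercises.
    """

    barrier_height: float = 5.0
    well_separation: float = 1.0
    k_transverse: float = 10.0
    dim: int = 2

    def __post_init__(self) -> None:
        if self.barrier_height <= 0 or self.k_transverse <= 0:
            raise ValueError("barrier_height and k_transverse must be positive")
        object.__setattr__(
            self, "dihedral", _DoubleWellComponent(self.barrier_height, self.well_separation)
        )

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        u = (x[..., 0] / self.well_separation) ** 2 - 1.0
        return self.barrier_height * u * u + 0.5 * self.k_transverse * x[..., 1] ** 2

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        a2 = self.well_separation**2
        g = np.empty_like(x)
        g[..., 0] = 4.0 * self.barrier_height * x[..., 0] * (x[..., 0] ** 2 / a2 - 1.0) / a2
        g[..., 1] = self.k_transverse * x[..., 1]
        return g

    def domain(self) -> tuple[float, float]:
        a = self.well_separation
        return (-2.2 * a, 2.2 * a)


@dataclass(frozen=True)
class _DoubleWellComponent(ToyPotential):
    """x-component of :class:`DoubleWellTransverse`, evaluated on 2-D points."""

    barrier_height: float
    well_separation: float
    dim: int = 2

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        u = (x[..., 0] / self.well_separation) ** 2 - 1.0
        return self.barrier_height * u * u

    def gradient(self, x):
        x = np.asarray(x, dtype=float)
        a2 = self.well_separation**2
        g = np.zeros_like(x)
        g[..., 0] = 4.0 * self.barrier_height * x[..., 0] * (x[..., 0] ** 2 / a2 - 1.0) / a2
        return g


def make_double_well(
    barrier_height: float = 5.0, well_separation: float = 1.0, kT: float | None = None
) -> DoubleWell:
    """Quartic double well with barrier ``barrier_height`` (kcal mol⁻¹).

    ``kT`` is accepted for interface symmetry with the reference-density
    helpers but does not change the potential itself.
    """
    return DoubleWell(barrier_height=barrier_height, well_separation=well_separation)


def make_double_well_2d(
    barrier_height: float = 5.0,
    well_separation: float = 1.0,
    k_transverse: float = 10.0,
) -> DoubleWellTransverse:
    return DoubleWellTransverse(barrier_height, well_separation, k_transverse)
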