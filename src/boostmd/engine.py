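"""Langevin dynamics on toy potentials with the dual-boost aMD modification.

The accelerated-MD scheme raises the potential below a threshold E by

    ΔV(V) = (E − V)² / (α + E − V)   for V < E,   else 0,

which is non-negative, continuous, and flattens barriers while leaving
the landscape above E untouched.  A dual boost applies this once to the
designated dihedral component (threshold E_dihed, α_dihed) and once to
the resulting total energy (E_total, α_total).  Forces on the modified
surface follow from the chain rule: d(V + ΔV)/dV = α²/(α + E − V)².

Threshold/acceleration parameters come from per-residue and per-atom
coefficient rules:

    E_dihed = V_avg_dihed + b₁·N_res,    α_dihed = b₂·N_res / 5
    E_total = V_avg_total + a₁·N_atoms,  α_total = a₂·N_atoms

with the per-residue coefficients b (typically 4–4.5 kcal mol⁻¹) feeding
the dihedral boost and the per-atom coefficients a (typically
0.16–0.20 kcal mol⁻¹) the total boost; V_avg are averages from an
unboosted calibration run.

Integration uses BAOAB splitting with unit reduced mass
(m = 1 kcal mol⁻¹ ps² Å⁻²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import DEFAULT_TEMPERATURE_K, KB_KCAL_MOL_K
from .potentials import ToyPotential

BOOST_MODES = ("none", "total", "dihedral", "dual")


@dataclass(frozen=True)
class AMDParameters:
    """Thresholds and acceleration factors for the boost potential.

    ``mode`` selects which boosts are active.  Inactive components may
    be left as None.
    """

    mode: str = "dual"
    E_total: float | None = None
    alpha_total: float | None = None
    E_dihed: float | None = None
    alpha_dihed: float | None = None
    # bookkeeping from the parameter rule, optional
    V_avg_total: float | None = None
    V_avg_dihed: float | None = None
    n_res: int | None = None
    n_atoms: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in BOOST_MODES:
            raise ValueError(f"unknown boost mode {self.mode!r}")
        if self.mode in ("total", "dual"):
            if self.E_total is None or self.alpha_total is None:
                raise ValueError("total boost requires E_total and alpha_total")
            if self.alpha_total <= 0:
                raise ValueError("alpha_total must be positive for an active boost")
        if self.mode in ("dihedral", "dual"):
            if self.E_dihed is None or self.alpha_dihed is None:
                raise ValueError("dihedral boost requires E_dihed and alpha_dihed")
            if self.alpha_dihed <= 0:
                raise ValueError("alpha_dihed must be positive for an active boost")


def compute_boost_parameters(
    V_avg_dihed: float,
    V_avg_total: float,
    a1: float,
    a2: float,
    b1: float,
    b2: float,
    n_res: int,
    n_atoms: int,
    mode: str = "dual",
) -> AMDParameters:
    """Boost parameters from the per-residue/per-atom coefficient rules.

    ``a1, a2`` are the per-atom (total-boost) coefficients and
    ``b1, b2`` the per-residue (dihedral-boost) coefficients, all in
    kcal mol⁻¹.  The thresholds sit above the calibration averages by
    b₁·N_res (dihedral) and a₁·N_atoms (total); the acceleration factors
    are α_dihed = b₂·N_res/5 and α_total = a₂·N_atoms.
    """
    if n_res <= 0 or n_atoms <= 0:
        raise ValueError("n_res and n_atoms must be positive")
    if min(a1, a2, b1, b2) < 0:
        raise ValueError("coefficients must be non-negative")
    E_dihed = V_avg_dihed + b1 * n_res
    alpha_dihed = b2 * n_res / 5.0
    E_total = V_avg_total + a1 * n_atoms
    alpha_total = a2 * n_atoms
    if mode in ("total", "dual") and alpha_total == 0:
        raise ValueError("active total boost with zero alpha_total")
    if mode in ("dihedral", "dual") and alpha_dihed == 0:
        raise ValueError("active dihedral boost with zero alpha_dihed")
    return AMDParameters(
        mode=mode,
        E_total=E_total,
        alpha_total=alpha_total,
        E_dihed=E_dihed,
        alpha_dihed=alpha_dihed,
        V_avg_total=V_avg_total,
        V_avg_dihed=V_avg_dihed,
        n_res=n_res,
        n_atoms=n_atoms,
    )


def boost_energy(V, E, alpha):
    """Non-negative boost ΔV = (E−V)²/(α+E−V) below threshold, 0 above."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    V = np.asarray(V, dtype=float)
    u = E - V
    denom = np.where(u > 0, alpha + u, 1.0)
    out = np.where(u > 0, u * u / denom, 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def boost_scale(V, E, alpha):
    """d(V+ΔV)/dV = α²/(α+E−V)² below threshold, 1 above."""
    V = np.asarray(V, dtype=float)
    u = E - V
    out = np.where(u > 0, (alpha / np.where(u > 0, alpha + u, 1.0)) ** 2, 1.0)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class LangevinConfig:
    temperature: float = DEFAULT_TEMPERATURE_K  # K
    friction: float = 1.0  # ps⁻¹
    timestep: float = 0.002  # ps
    n_steps: int = 100_000
    save_stride: int = 100
    seed: int = 0
    x0: float | tuple | None = None

    def __post_init__(self) -> None:
        if min(self.temperature, self.friction, self.timestep) <= 0:
            raise ValueError("temperature, friction and timestep must be positive")
        if self.n_steps <= 0 or self.save_stride <= 0:
            raise ValueError("n_steps and save_stride must be positive")

    @property
    def kT(self) -> float:
        return KB_KCAL_MOL_K * self.temperature


@dataclass
class BoostedEnergySeries:
    """Per-frame energies and applied boosts (kcal mol⁻¹), time in ps."""

    time: np.ndarray
    V_total: np.ndarray
    V_dihed: np.ndarray
    dV_total: np.ndarray
    dV_dihed: np.ndarray

    def __post_init__(self) -> None:
        for name in ("time", "V_total", "V_dihed", "dV_total", "dV_dihed"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.dV_total.min(initial=0.0) < -1e-9 or self.dV_dihed.min(initial=0.0) < -1e-9:
            raise ValueError("boost energies must be non-negative")

    @property
    def total_boost(self) -> np.ndarray:
        """ΔV applied to each frame (dihedral + total contributions)."""
        return self.dV_total + self.dV_dihed

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.time,
                "V_total": self.V_total,
                "V_dihed": self.V_dihed,
                "dV_total": self.dV_total,
                "dV_dihed": self.dV_dihed,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "BoostedEnergySeries":
        return cls(
            time=df["time"].to_numpy(),
            V_total=df["V_total"].to_numpy(),
            V_dihed=df["V_dihed"].to_numpy(),
            dV_total=df["dV_total"].to_numpy(),
            dV_dihed=df["dV_dihed"].to_numpy(),
        )


@dataclass
class LangevinResult:
    positions: np.ndarray  # (n_saved, dim)
    energies: BoostedEnergySeries
    config: LangevinConfig = field(repr=False, default=None)  # type: ignore[assignment]

    def __iter__(self):
        yield self.positions
        yield self.energies


def _effective_mode(potential: ToyPotential, params: AMDParameters | None) -> str:
    if params is None or params.mode == "none":
        return "none"
    if params.mode == "dual" and potential.dihedral is None:
        # no designated dihedral component: dual degenerates to total-only
        return "total"
    return params.mode


def run_langevin(
    potential: ToyPotential,
    config: LangevinConfig,
    params: AMDParameters | None = None,
) -> LangevinResult:
    """BAOAB Langevin integration on the (optionally boosted) potential.

    Returns saved positions every ``save_stride`` steps together with the
    per-frame energies and applied boosts.  With ``params=None`` the
    boost is identically zero and sampling converges to the Boltzmann
    distribution of the bare potential.
    """
    mode = _effective_mode(potential, params)
    dim = potential.dim
    dt = config.timestep
    half = 0.5 * dt
    c1 = math.exp(-config.friction * dt)
    c2 = math.sqrt(config.kT * (1.0 - c1 * c1))
    rng = np.random.default_rng(config.seed)
    n = config.n_steps
    stride = config.save_stride
    n_saved = n // stride

    if params is not None:
        Et, at = params.E_total, params.alpha_total
        Ed, ad = params.E_dihed, params.alpha_dihed
    else:
        Et = at = Ed = ad = None

    dih = potential.dihedral
    energy = potential.energy
    gradient = potential.gradient

    def force_full(x):
        """Return (force, V, V_d, dV_d, dV_t) at x on the modified surface."""
        V = energy(x)
        g = gradient(x)
        if mode == "none":
            Vd = dih.energy(x) if dih is not None else V
            return -g, V, Vd, 0.0, 0.0
        if mode == "total":
            Vd = dih.energy(x) if dih is not None else V
            u = Et - V
            if u > 0:
                s = (at / (at + u)) ** 2
                return -g * s, V, Vd, 0.0, u * u / (at + u)
            return -g, V, Vd, 0.0, 0.0
        if mode == "dihedral":
            # with no designated component the whole potential is boosted
            # through the dihedral parameters
            if dih is None:
                u = Ed - V
                if u > 0:
                    s = (ad / (ad + u)) ** 2
                    return -g * s, V, V, u * u / (ad + u), 0.0
                return -g, V, V, 0.0, 0.0
            Vd = dih.energy(x)
            u = Ed - Vd
            if u > 0:
                sd = (ad / (ad + u)) ** 2
                gd = dih.gradient(x)
                return -(g + (sd - 1.0) * gd), V, Vd, u * u / (ad + u), 0.0
            return -g, V, Vd, 0.0, 0.0
        # dual with a designated component
        Vd = dih.energy(x)
        ud = Ed - Vd
        if ud > 0:
            dVd = ud * ud / (ad + ud)
            sd = (ad / (ad + ud)) ** 2
            gU = g + (sd - 1.0) * dih.gradient(x)
        else:
            dVd = 0.0
            gU = g
        U = V + dVd
        ut = Et - U
        if ut > 0:
            st = (at / (at + ut)) ** 2
            return -gU * st, V, Vd, dVd, ut * ut / (at + ut)
        return -gU, V, Vd, dVd, 0.0

    if dim == 1:
        x = 0.0 if config.x0 is None else float(config.x0)
        v = 0.0
        noise = rng.standard_normal(n)
        positions = np.empty(n_saved)
    else:
        x = np.zeros(dim) if config.x0 is None else np.asarray(config.x0, dtype=float)
        v = np.zeros(dim)
        noise = rng.standard_normal((n, dim))
        positions = np.empty((n_saved, dim))

    t_arr = np.empty(n_saved)
    V_arr = np.empty(n_saved)
    Vd_arr = np.empty(n_saved)
    dVt_arr = np.empty(n_saved)
    dVd_arr = np.empty(n_saved)

    def _diverged(step, exc=None):
        return FloatingPointError(
            f"integration diverged at step {step}; "
            "reduce the time step for this potential's stiffness"
            + (f" ({exc})" if exc else "")
        )

    F, V, Vd, dVd, dVt = force_full(x)
    k = 0
    for i in range(n):
        v = v + half * F
        x = x + half * v
        v = c1 * v + c2 * noise[i]
        x = x + half * v
        try:
            F, V, Vd, dVd, dVt = force_full(x)
        except OverflowError as exc:
            raise _diverged(i + 1, exc) from exc
        v = v + half * F
        if (i + 1) % stride == 0:
            if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e8:
                raise _diverged(i + 1)
            positions[k] = x
            t_arr[k] = (i + 1) * dt
            V_arr[k] = V
            Vd_arr[k] = Vd
            dVt_arr[k] = dVt
            dVd_arr[k] = dVd
            k += 1

    series = BoostedEnergySeries(
        time=t_arr, V_total=V_arr, V_dihed=Vd_arr, dV_total=dVt_arr, dV_dihed=dVd_arr
    )
    if dim == 1:
        positions = positions.reshape(-1, 1)
    return LangevinResult(positions=positions, energies=series, config=config)
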