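"""In-memory containers for molecular systems.

A :class:`Topology` holds per-atom metadata (name, element, residue,
monomer/chain id, analysis role) plus derived physical properties
(electron count, van-der-Waals radius, mass).  A :class:`Trajectory`
holds ordered frames of Cartesian coordinates with an orthorhombic
periodic box and a time stamp per frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ELEMENT_TABLE


def _as_object_array(values, n: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=object)
    if arr.shape != (n,):
        raise ValueError(f"{name} must have shape ({n},), got {arr.shape}")
    return arr


@dataclass
class Topology:
    """Per-atom metadata for a system of ``n_atoms`` atoms.

    Parameters
    ----------
    names, elements, resnames, chains, roles
        Length-``n`` string arrays.  ``chains`` doubles as the monomer id
        for multi-copy systems; ``roles`` tags atoms for analysis
        selections (e.g. ``water``, ``lipid``, ``head``, ``pore``,
        ``peptide``).
    resids
        1-based residue numbers, length ``n``.
    electrons, vdw_radii, masses
        Optional per-atom overrides; derived from ``elements`` via the
        element table when omitted.
    """

    names: np.ndarray
    elements: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chains: np.ndarray
    roles: np.ndarray
    electrons: np.ndarray | None = None
    vdw_radii: np.ndarray | None = None
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.names)
        self.names = _as_object_array(self.names, n, "names")
        self.elements = _as_object_array(self.elements, n, "elements")
        self.resnames = _as_object_array(self.resnames, n, "resnames")
        self.chains = _as_object_array(self.chains, n, "chains")
        self.roles = _as_object_array(self.roles, n, "roles")
        self.resids = np.asarray(self.resids, dtype=int)
        if self.resids.shape != (n,):
            raise ValueError("resids length mismatch")
        unknown = [e for e in np.unique(self.elements) if e not in ELEMENT_TABLE]
        if unknown:
            raise ValueError(f"elements not in table: {unknown}")
        if self.electrons is None:
            self.electrons = np.array(
                [ELEMENT_TABLE[e][0] for e in self.elements], dtype=float
            )
        else:
            self.electrons = np.asarray(self.electrons, dtype=float)
        if self.vdw_radii is None:
            self.vdw_radii = np.array(
                [ELEMENT_TABLE[e][1] for e in self.elements], dtype=float
            )
        else:
            self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        if self.masses is None:
            self.masses = np.array(
                [ELEMENT_TABLE[e][2] for e in self.elements], dtype=float
            )
        else:
            self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def select(
        self,
        role: str | None = None,
        element: str | None = None,
        name: str | None = None,
        chain: str | None = None,
    ) -> np.ndarray:
        """Boolean mask of atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if role is not None:
            mask &= self.roles == role
        if element is not None:
            mask &= self.elements == element
        if name is not None:
            mask &= self.names == name
        if chain is not None:
            mask &= self.chains == chain
        return mask

    def chain_ids(self) -> list:
        """Unique chain/monomer ids in first-appearance order."""
        seen: dict = {}
        for c in self.chains:
            seen.setdefault(c, None)
        return list(seen)

    def residue_atom_index(self, chain: str) -> dict[int, dict[str, int]]:
        """Map resid -> {atom name -> atom index} within one chain."""
        out: dict[int, dict[str, int]] = {}
        idx = np.flatnonzero(self.chains == chain)
        for i in idx:
            out.setdefault(int(self.resids[i]), {})[str(self.names[i])] = int(i)
        return out


@dataclass
class Trajectory:
    """Frames of coordinates with periodic box lengths and time stamps.

    coords : (n_frames, n_atoms, 3) Å
    box    : (n_frames, 3) orthorhombic box lengths, Å
    time   : (n_frames,) ps
    """

    coords: np.ndarray
    box: np.ndarray
    time: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        f = self.coords.shape[0]
        self.box = np.asarray(self.box, dtype=float)
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (f, 1))
        if self.box.shape != (f, 3):
            raise ValueError("box must have shape (n_frames, 3)")
        if self.time is None:
            self.time = np.arange(f, dtype=float)
        self.time = np.asarray(self.time, dtype=float)
        if self.time.shape != (f,):
            raise ValueError("time must have shape (n_frames,)")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]
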