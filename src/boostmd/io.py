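"""Readers and writers for the on-disk formats.

* PDB for topologies/structures (roles carried in the segment-id
  columns, elements inferred from atom names when columns 77–78 are
  blank);
* a self-describing multi-frame text trajectory (frame header with time
  and box, one coordinate line per atom) chosen so fixtures stay
  diff-able;
* CSV for all series and profiles (pandas);
* OpenDX text grids for volumetric water density (VMD-readable);
* YAML configs and JSON run manifests carrying seed and config hash.

All parsers reject malformed records with a line-numbered error rather
than silently coercing them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import ELEMENT_TABLE
from .engine import BoostedEnergySeries
from .membrane import VolumetricGrid
from .reweighting import FESurface
from .system import Topology, Trajectory

logger = logging.getLogger("boostmd")


class ParseError(ValueError):
    """Malformed record in an input file; message carries the line number."""


# ---------------------------------------------------------------------------
# PDB


def _infer_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    for cand in (stripped[:2].capitalize(), stripped[:1].upper()):
        if cand in ELEMENT_TABLE:
            return cand
    raise ParseError(f"cannot infer element from atom name {name!r}")


def write_pdb(topology: Topology, coords: np.ndarray, path) -> None:
    """Write one frame as ATOM records (3-decimal coordinate precision).

    The segment-id columns (73–76) carry the chain/monomer id; the
    analysis role is appended as a trailing token beyond column 78 —
    standard PDB software ignores it, :func:`read_pdb` recovers it.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coords shape must be (n_atoms, 3)")
    lines = []
    for i in range(topology.n_atoms):
        name = str(topology.names[i])
        pdb_name = f" {name:<3s}" if len(name) < 4 else name[:4]
        chain = str(topology.chains[i])
        lines.append(
            f"ATOM  {(i + 1) % 100000:5d} {pdb_name}"
            f" {str(topology.resnames[i])[:3]:>3s} {chain[0]:1s}"
            f"{int(topology.resids[i]) % 10000:4d}    "
            f"{coords[i, 0]:8.3f}{coords[i, 1]:8.3f}{coords[i, 2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}      "
            f"{chain[:4]:<4s}{str(topology.elements[i]):>2s}"
            f" {str(topology.roles[i])}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path) -> tuple[Topology, np.ndarray]:
    """Parse ATOM/HETATM records into a Topology and one coordinate frame."""
    names, elements, resids, resnames, chains, roles = [], [], [], [], [], []
    xyz = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        rec = line[:6]
        if rec not in ("ATOM  ", "HETATM"):
            continue
        if len(line) < 54:
            raise ParseError(f"line {ln}: truncated ATOM record")
        try:
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21].strip() or "A"
            resid = int(line[22:26])
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except ValueError as exc:
            raise ParseError(f"line {ln}: malformed ATOM record ({exc})") from exc
        seg = line[72:76].strip() if len(line) >= 76 else ""
        elem = line[76:78].strip() if len(line) >= 78 else ""
        trailing = line[78:].split() if len(line) > 78 else []
        if not elem:
            elem = _infer_element(name)
            logger.info("line %d: element inferred from atom name %r -> %s", ln, name, elem)
        elif elem.capitalize() not in ELEMENT_TABLE:
            raise ParseError(f"line {ln}: unknown element {elem!r}")
        else:
            elem = elem.capitalize()
        names.append(name)
        elements.append(elem)
        resids.append(resid)
        resnames.append(resname)
        chains.append(seg or chain)
        roles.append(trailing[0] if trailing else "none")
        xyz.append((x, y, z))
    if not names:
        raise ParseError("no ATOM records found")
    top = Topology(
        np.array(names, dtype=object),
        np.array(elements, dtype=object),
        np.array(resids, dtype=int),
        np.array(resnames, dtype=object),
        np.array(chains, dtype=object),
        np.array(roles, dtype=object),
    )
    return top, np.array(xyz, dtype=float)


# ---------------------------------------------------------------------------
# text trajectory

_TRJ_MAGIC = "# boostmd trajectory v1"


def write_trajectory(traj: Trajectory, path, precision: int = 6) -> None:
    fmt = f"%.{precision}f"
    with open(path, "w") as fh:
        fh.write(_TRJ_MAGIC + "\n")
        for f in range(traj.n_frames):
            bx = traj.box[f]
            fh.write(
                f"FRAME time={traj.time[f]:.6f} "
                f"box={bx[0]:.6f},{bx[1]:.6f},{bx[2]:.6f} "
                f"natoms={traj.n_atoms}\n"
            )
            np.savetxt(fh, traj.coords[f], fmt=fmt, delimiter=" ")


def read_trajectory(path, topology: Topology | None = None) -> Trajectory:
    """Read a text trajectory; a truncated final frame is dropped with a warning."""
    frames, boxes, times = [], [], []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# boostmd trajectory"):
            raise ParseError("line 1: not a boostmd trajectory file")
        ln = 1
        line = fh.readline()
        ln += 1
        frame_index = 0
        while line:
            if not line.startswith("FRAME "):
                raise ParseError(f"line {ln}: expected FRAME header, got {line!r}")
            try:
                fields = dict(tok.split("=", 1) for tok in line.split()[1:])
                t = float(fields["time"])
                box = np.array([float(v) for v in fields["box"].split(",")])
                natoms = int(fields["natoms"])
            except (KeyError, ValueError) as exc:
                raise ParseError(f"line {ln}: malformed FRAME header ({exc})") from exc
            if topology is not None and natoms != topology.n_atoms:
                raise ParseError(
                    f"frame {frame_index}: atom count {natoms} does not match "
                    f"topology ({topology.n_atoms})"
                )
            rows = []
            truncated = False
            for _ in range(natoms):
                aline = fh.readline()
                ln += 1
                if not aline:
                    truncated = True
                    break
                try:
                    rows.append([float(v) for v in aline.split()])
                except ValueError as exc:
                    raise ParseError(f"line {ln}: malformed coordinate line") from exc
                if len(rows[-1]) != 3:
                    raise ParseError(f"line {ln}: expected 3 coordinates")
            if truncated or len(rows) < natoms:
                warnings.warn(
                    f"dropping truncated final frame {frame_index}", stacklevel=2
                )
                break
            frames.append(np.array(rows))
            boxes.append(box)
            times.append(t)
            frame_index += 1
            line = fh.readline()
            ln += 1
    if not frames:
        raise ParseError("trajectory contains no complete frames")
    return Trajectory(
        coords=np.stack(frames), box=np.stack(boxes), time=np.array(times)
    )


# ---------------------------------------------------------------------------
# CSV series / surfaces


def write_energy_series(series: BoostedEnergySeries, path) -> None:
    series.to_dataframe().to_csv(path, index=False)


def read_energy_series(path) -> BoostedEnergySeries:
    return BoostedEnergySeries.from_dataframe(pd.read_csv(path))


def write_fes(surface: FESurface, path) -> None:
    surface.to_dataframe().to_csv(path, index=False)


def write_series_csv(data: dict, path) -> None:
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# OpenDX volumetric grid (VMD-readable)


def write_dx(vol: VolumetricGrid, path) -> None:
    nx, ny, nz = vol.grid.shape
    o = vol.origin
    d = vol.spacing
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write(f"origin {o[0]:.4f} {o[1]:.4f} {o[2]:.4f}\n")
        fh.write(f"delta {d:.4f} 0 0\ndelta 0 {d:.4f} 0\ndelta 0 0 {d:.4f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = vol.grid.ravel(order="C")
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "density" class field\n')


# ---------------------------------------------------------------------------
# config and manifest


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ParseError("config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir, command: str, params: dict, seed: int, outputs: list) -> Path:
    from . import __version__

    manifest = {
        "command": command,
        "parameters": params,
        "seed": seed,
        "config_hash": config_hash({"command": command, "seed": seed, **params}),
        "version": __version__,
        "outputs": sorted(str(o) for o in outputs),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return path
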