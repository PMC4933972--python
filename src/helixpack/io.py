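"""Readers and writers for the formats the pipeline consumes and emits.

PDB parsing/writing is delegated to biotite; DCD/XTC trajectories to
MDAnalysis (which natively uses Å and ps, matching package units).  The
free-energy grid dialect is plain text: whitespace-delimited
``alpha beta energy`` rows covering a full rectangular grid.
"""
from __future__ import annotations

import json
import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ContractError, FESGrid, Structure, Trajectory

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "FormatError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_fes_grid",
    "write_fes_grid",
    "write_table",
    "read_table",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class FormatError(ValueError):
    """Unsupported or inconsistent file format."""


# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------

def _atom_array_to_structure(arr, title: str = "") -> Structure:
    return Structure(
        atom_name=arr.atom_name.astype(object),
        element=arr.element.astype(object),
        res_name=arr.res_name.astype(object),
        res_id=arr.res_id.astype(int),
        chain_id=arr.chain_id.astype(object),
        coords=np.asarray(arr.coord, dtype=float),
        title=title,
    )


def _structure_to_atom_array(structure: Structure):
    import biotite.structure as struc

    arr = struc.AtomArray(structure.n_atoms)
    arr.coord = np.asarray(structure.coords, dtype=np.float32)
    arr.atom_name = structure.atom_name.astype("U6")
    arr.element = structure.element.astype("U2")
    arr.res_name = structure.res_name.astype("U5")
    arr.res_id = structure.res_id
    arr.chain_id = structure.chain_id.astype("U4")
    arr.hetero = np.array(
        [rn not in _STANDARD_RESIDUES for rn in structure.res_name], dtype=bool
    )
    return arr


_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def _locate_bad_pdb_line(path) -> int | None:
    """Best-effort scan for the first malformed ATOM/HETATM record."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38])
                    float(line[38:46])
                    float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return lineno
    return None


def _load_pdb_models(path):
    import biotite.structure.io.pdb as pdb

    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure()  # AtomArrayStack over all models
    except Exception as exc:
        lineno = _locate_bad_pdb_line(path)
        where = f"line {lineno}" if lineno is not None else "unknown line"
        raise ParseError(f"malformed PDB record in {path} at {where}: {exc}") from exc
    return stack


def read_structure(path) -> Structure:
    """Read a PDB file into a :class:`Structure` (first model).

    Chain identity and residue numbering are preserved exactly as read.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    stack = _load_pdb_models(path)
    arr = stack[0] if stack.stack_depth() > 0 else None
    if arr is None or arr.array_length() == 0:
        raise ParseError(f"no ATOM/HETATM records found in {path}")
    st = _atom_array_to_structure(arr, title=path.stem)
    log.info("read_structure: %s -> %d atoms", path, st.n_atoms)
    return st


def write_structure(structure: Structure, path) -> None:
    import biotite.structure.io.pdb as pdb

    arr = _structure_to_atom_array(structure)
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def read_trajectory(topology_path, traj_path=None, frame_interval_ps: float = 1.0,
                    time_origin_ps: float = 0.0) -> Trajectory:
    """Read a trajectory into package containers.

    Supported dialects: multi-model PDB (``traj_path`` omitted or equal to
    the topology path) and DCD/XTC next to a PDB topology.  Times come from
    the file header when present, otherwise from ``frame_interval_ps``.
    """
    topology_path = Path(topology_path)
    if traj_path is None or Path(traj_path) == topology_path:
        return _read_multimodel_pdb(topology_path, frame_interval_ps, time_origin_ps)
    traj_path = Path(traj_path)
    ext = traj_path.suffix.lower()
    if ext == ".pdb":
        topo = read_structure(topology_path)
        traj = _read_multimodel_pdb(traj_path, frame_interval_ps, time_origin_ps)
        if traj.n_atoms != topo.n_atoms:
            raise ContractError(
                f"topology has {topo.n_atoms} atoms but trajectory frames "
                f"have {traj.n_atoms}"
            )
        return Trajectory(topology=topo, coords=traj.coords, times=traj.times,
                          box=traj.box)
    if ext in (".dcd", ".xtc"):
        return _read_mda_trajectory(topology_path, traj_path, frame_interval_ps,
                                    time_origin_ps)
    raise FormatError(f"unsupported trajectory extension: {ext!r}")


def _read_multimodel_pdb(path, frame_interval_ps, time_origin_ps) -> Trajectory:
    stack = _load_pdb_models(path)
    n_models = stack.stack_depth()
    if n_models == 0:
        raise ParseError(f"no models found in {path}")
    topo = _atom_array_to_structure(stack[0], title=Path(path).stem)
    coords = np.asarray(stack.coord, dtype=float)
    times = time_origin_ps + frame_interval_ps * np.arange(n_models)
    if getattr(stack, "box", None) is not None:
        box = np.array([np.diag(b) for b in np.asarray(stack.box, dtype=float)])
    else:
        span = coords.max(axis=(0, 1)) - coords.min(axis=(0, 1))
        box = np.tile(np.maximum(span, 1.0), (n_models, 1))
    log.info("read_trajectory: %s -> %d frames, %d atoms", path, n_models,
             topo.n_atoms)
    return Trajectory(topology=topo, coords=coords, times=times, box=box)


def _read_mda_trajectory(topology_path, traj_path, frame_interval_ps,
                         time_origin_ps) -> Trajectory:
    import warnings

    import MDAnalysis as mda

    topo = read_structure(topology_path)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology_path), str(traj_path))
            if u.atoms.n_atoms != topo.n_atoms:
                raise ContractError(
                    f"topology has {topo.n_atoms} atoms but trajectory has "
                    f"{u.atoms.n_atoms}"
                )
            coords, times, box = [], [], []
            for ts in u.trajectory:
                coords.append(ts.positions.astype(float).copy())
                times.append(float(ts.time))
                dims = ts.dimensions
                box.append(np.asarray(dims[:3], dtype=float) if dims is not None
                           else np.zeros(3))
    except (ContractError, FileNotFoundError):
        raise
    except Exception as exc:
        if "number of atoms" in str(exc).lower():
            raise ContractError(
                f"topology/trajectory atom count mismatch: {exc}") from exc
        raise ParseError(f"failed to read trajectory {traj_path}: {exc}") from exc
    coords = np.asarray(coords)
    times = np.asarray(times)
    if traj_path.suffix.lower() == ".dcd":
        declared = _dcd_declared_frames(traj_path)
        if declared is not None and declared != coords.shape[0]:
            raise ParseError(
                f"{traj_path}: header declares {declared} frames but "
                f"{coords.shape[0]} were read (truncated file?)"
            )
    if times.size > 1 and not np.all(np.diff(times) > 0):
        # header without time information: synthesize from the frame interval
        times = time_origin_ps + frame_interval_ps * np.arange(len(times))
    log.info("read_trajectory: %s -> %d frames, %d atoms", traj_path,
             coords.shape[0], topo.n_atoms)
    return Trajectory(topology=topo, coords=coords, times=times,
                      box=np.asarray(box))


def _dcd_declared_frames(path) -> int | None:
    """NSET from the raw DCD header (frames the writer declared)."""
    import struct

    with open(path, "rb") as fh:
        head = fh.read(12)
    if len(head) < 12 or head[4:8] != b"CORD":
        return None
    return struct.unpack("<i", head[8:12])[0]


def write_trajectory(traj: Trajectory, path, dialect: str | None = None) -> None:
    """Write a trajectory as multi-model PDB or DCD (chosen by extension)."""
    path = Path(path)
    dialect = dialect or path.suffix.lower().lstrip(".")
    if dialect == "pdb":
        _write_multimodel_pdb(traj, path)
    elif dialect == "dcd":
        _write_dcd(traj, path)
    else:
        raise FormatError(f"unsupported trajectory dialect: {dialect!r}")


def _write_multimodel_pdb(traj: Trajectory, path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    arr = _structure_to_atom_array(traj.topology)
    stack = struc.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    boxes = np.array([np.diag(b) for b in traj.box], dtype=np.float32)
    stack.box = boxes
    f = pdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def _write_dcd(traj: Trajectory, path) -> None:
    import MDAnalysis as mda

    n = traj.n_atoms
    dt = float(np.mean(np.diff(traj.times))) if traj.n_frames > 1 else 1.0
    u = mda.Universe.empty(n, trajectory=True)
    with mda.Writer(str(path), n_atoms=n, dt=dt) as w:
        for i in range(traj.n_frames):
            u.atoms.positions = traj.coords[i]
            u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
            w.write(u.atoms)


# ---------------------------------------------------------------------------
# Free-energy grids
# ---------------------------------------------------------------------------

def read_fes_grid(path, shift_minimum: bool = True) -> FESGrid:
    """Read an ``alpha beta energy`` grid file.

    The file must cover a full rectangular grid; by default the energy is
    shifted so the global minimum is zero (the removed offset is kept in
    ``grid.offset``).
    """
    data = np.loadtxt(path, comments="#")
    if data.ndim == 1:
        data = data.reshape(1, -1)
    if data.shape[1] != 3:
        raise ParseError(f"{path}: expected 3 columns (alpha beta energy)")
    if not np.all(np.isfinite(data)):
        bad = int(np.argwhere(~np.isfinite(data).all(axis=1))[0][0]) + 1
        raise ParseError(f"{path}: non-finite value at data row {bad}")
    alphas = np.unique(data[:, 0])
    betas = np.unique(data[:, 1])
    if alphas.size * betas.size != data.shape[0]:
        raise ParseError(
            f"{path}: grid not rectangular ({alphas.size} x {betas.size} cells "
            f"expected, {data.shape[0]} rows found)"
        )
    energy = np.full((alphas.size, betas.size), np.nan)
    ia = np.searchsorted(alphas, data[:, 0])
    ib = np.searchsorted(betas, data[:, 1])
    energy[ia, ib] = data[:, 2]
    if np.any(np.isnan(energy)):
        raise ParseError(f"{path}: grid not rectangular (missing cells)")
    grid = FESGrid(alpha_axis=alphas, beta_axis=betas, energy=energy)
    return grid.shift_minimum_to_zero() if shift_minimum else grid


def write_fes_grid(grid: FESGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write("# alpha_deg beta_deg energy_kcal_mol\n")
        for i, a in enumerate(grid.alpha_axis):
            for j, b in enumerate(grid.beta_axis):
                fh.write(f"{a:.6f} {b:.6f} {grid.energy[i, j]:.6f}\n")


# ---------------------------------------------------------------------------
# Tabular reports
# ---------------------------------------------------------------------------

def write_table(records, path, fmt: str | None = None, header_comment: str | None = None) -> None:
    """Write homogeneous records (list of dicts) as CSV or JSON.

    Numeric values keep full double precision (well above 6 significant
    digits).  An optional comment line is prepended to CSV output.
    """
    records = list(records)
    if records:
        keys = set(records[0].keys())
        for i, r in enumerate(records):
            if set(r.keys()) != keys:
                raise ContractError(
                    f"heterogeneous records: row {i} keys differ from row 0"
                )
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower() or "csv"
    if fmt == "csv":
        df = pd.DataFrame.from_records(records)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            df.to_csv(fh, index=False)
    elif fmt == "json":
        with open(path, "w") as fh:
            json.dump(records, fh, indent=2, default=_json_default)
            fh.write("\n")
    else:
        raise FormatError(f"unsupported table format: {fmt!r}")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_table(path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            return pd.DataFrame.from_records(json.load(fh))
    try:
        return pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame()
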