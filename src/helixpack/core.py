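"""Core in-memory containers shared by every analysis module.

Units are fixed package-wide: coordinates in angstrom (Å), times in
picoseconds (ps), energies in kcal/mol, angles in degrees.  Converters to
other unit systems live only at I/O boundaries.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Structure",
    "Trajectory",
    "FESGrid",
    "ContractError",
    "BACKBONE_ATOMS",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


class ContractError(ValueError):
    """An operation was called with inputs violating its contract."""


@dataclass
class Structure:
    """A molecular structure as parallel per-atom arrays.

    Residue numbering is authoritative as read from file; nothing in the
    package renumbers residues (the helix of interest is addressed by its
    native numbering, 169-189).
    """

    atom_name: np.ndarray   # (n,) str
    element: np.ndarray     # (n,) str
    res_name: np.ndarray    # (n,) str
    res_id: np.ndarray      # (n,) int
    chain_id: np.ndarray    # (n,) str
    coords: np.ndarray      # (n, 3) float, Å
    title: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ContractError("coords must be an (n, 3) array")
        n = self.coords.shape[0]
        for name in ("atom_name", "element", "res_name", "chain_id"):
            arr = np.asarray(getattr(self, name), dtype=object)
            if arr.shape != (n,):
                raise ContractError(f"{name} must have length {n}")
            setattr(self, name, arr)
        self.res_id = np.asarray(self.res_id, dtype=int)
        if self.res_id.shape != (n,):
            raise ContractError(f"res_id must have length {n}")
        if not np.all(np.isfinite(self.coords)):
            raise ContractError("coordinates must be finite")

    # -- selection ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    def mask(self, chain=None, res_id=None, atom_name=None, element=None) -> np.ndarray:
        """Boolean mask over atoms; every keyword accepts a scalar or a sequence."""
        m = np.ones(self.n_atoms, dtype=bool)

        def _match(values, sel):
            if np.isscalar(sel) or isinstance(sel, str):
                sel = [sel]
            return np.isin(values, np.asarray(list(sel)))

        if chain is not None:
            m &= _match(self.chain_id, chain)
        if res_id is not None:
            m &= _match(self.res_id, res_id)
        if atom_name is not None:
            m &= _match(self.atom_name, atom_name)
        if element is not None:
            m &= _match(self.element, element)
        return m

    def select(self, **kw) -> "Structure":
        m = self.mask(**kw)
        return self.subset(m)

    def subset(self, mask_or_index) -> "Structure":
        idx = np.asarray(mask_or_index)
        return Structure(
            atom_name=self.atom_name[idx],
            element=self.element[idx],
            res_name=self.res_name[idx],
            res_id=self.res_id[idx],
            chain_id=self.chain_id[idx],
            coords=self.coords[idx],
            title=self.title,
        )

    def atom_coord(self, chain, res_id, atom_name) -> np.ndarray:
        """Coordinates of a single named atom; raises if absent or ambiguous."""
        m = self.mask(chain=chain, res_id=res_id, atom_name=atom_name)
        n = int(m.sum())
        if n != 1:
            raise ContractError(
                f"expected exactly one atom {chain}/{res_id}/{atom_name}, found {n}"
            )
        return self.coords[m][0]

    def chains(self) -> list:
        seen: dict = {}
        for c in self.chain_id:
            seen.setdefault(c, None)
        return list(seen)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float).reshape(self.n_atoms, 3)
        return out

    def copy(self) -> "Structure":
        return Structure(
            atom_name=self.atom_name.copy(),
            element=self.element.copy(),
            res_name=self.res_name.copy(),
            res_id=self.res_id.copy(),
            chain_id=self.chain_id.copy(),
            coords=self.coords.copy(),
            title=self.title,
        )

    @staticmethod
    def concat(parts: list) -> "Structure":
        return Structure(
            atom_name=np.concatenate([p.atom_name for p in parts]),
            element=np.concatenate([p.element for p in parts]),
            res_name=np.concatenate([p.res_name for p in parts]),
            res_id=np.concatenate([p.res_id for p in parts]),
            chain_id=np.concatenate([p.chain_id for p in parts]),
            coords=np.vstack([p.coords for p in parts]),
            title=parts[0].title if parts else "",
        )


@dataclass
class Trajectory:
    """Timed frames over a fixed topology.

    ``coords`` has shape (n_frames, n_atoms, 3) in Å, ``times`` in ps and
    strictly increasing, ``box`` holds orthorhombic box edge lengths per
    frame (n_frames, 3) in Å.  ``unwrapped`` optionally carries coordinates
    whose periodic jumps have been removed (filled by centering/dewrapping;
    required by mean-square-displacement analysis).
    """

    topology: Structure
    coords: np.ndarray
    times: np.ndarray
    box: np.ndarray
    unwrapped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ContractError("coords must be (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ContractError(
                f"frame atom count {self.coords.shape[1]} != topology "
                f"atom count {self.topology.n_atoms}"
            )
        if self.times.shape != (self.n_frames,):
            raise ContractError("times must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise ContractError("frame times must be strictly increasing")
        if self.box.shape != (self.n_frames, 3):
            raise ContractError("box must be (n_frames, 3) edge lengths")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def time_mask(self, t_start_ps: float, t_end_ps: float) -> np.ndarray:
        return (self.times >= t_start_ps) & (self.times <= t_end_ps)


@dataclass
class FESGrid:
    """Free-energy surface F(alpha, beta) on a rectangular grid.

    Axes are rotation angles in degrees, uniform and ascending; energies in
    kcal/mol with shape (len(alpha_axis), len(beta_axis)).  When
    ``minimum_shifted`` is true the global minimum is exactly zero.
    """

    alpha_axis: np.ndarray
    beta_axis: np.ndarray
    energy: np.ndarray
    minimum_shifted: bool = False
    offset: float = 0.0     # energy removed by min-shifting, kept for the record
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alpha_axis = np.asarray(self.alpha_axis, dtype=float)
        self.beta_axis = np.asarray(self.beta_axis, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.energy.shape != (self.alpha_axis.size, self.beta_axis.size):
            raise ContractError("energy shape must match axis lengths")
        for ax in (self.alpha_axis, self.beta_axis):
            if ax.size > 1:
                d = np.diff(ax)
                if not (np.all(d > 0) and np.allclose(d, d[0], rtol=1e-6, atol=1e-9)):
                    raise ContractError("axes must be uniform and ascending")
        if not np.all(np.isfinite(self.energy)):
            raise ContractError("energy must be finite on every cell")
        if self.minimum_shifted and abs(float(self.energy.min())) > 1e-9:
            raise ContractError("minimum_shifted grid must have min(energy) == 0")

    def shift_minimum_to_zero(self) -> "FESGrid":
        off = float(self.energy.min())
        return FESGrid(
            alpha_axis=self.alpha_axis.copy(),
            beta_axis=self.beta_axis.copy(),
            energy=self.energy - off,
            minimum_shifted=True,
            offset=self.offset + off,
            metadata=dict(self.metadata),
        )

    @property
    def shape(self) -> tuple:
        return self.energy.shape

    def cell_center(self, ij) -> tuple:
        i, j = ij
        return float(self.alpha_axis[i]), float(self.beta_axis[j])

    def nearest_cell(self, alpha: float, beta: float) -> tuple:
        i = int(np.argmin(np.abs(self.alpha_axis - alpha)))
        j = int(np.argmin(np.abs(self.beta_axis - beta)))
        return i, j
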