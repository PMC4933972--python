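"""Polar-contact detection and occupancy/duration statistics.

A polar contact exists when two polar atoms (N, O, or a lipid headgroup
bead / headgroup O, N, P atom) are within the cutoff, 3.6 Å by default.
Per-frame booleans are merged into maximal events; a pair whose longest
continuous event is shorter than 1 ns is classified ``transient``, the
complement ``frequent``.  Each frame represents the interval
[t, t + Δt), so summed event durations divided by the trajectory length
equal the occupancy exactly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .core import ContractError, Structure, Trajectory

__all__ = [
    "ContactEvent",
    "ContactSummary",
    "POLAR_CONTACT_CUTOFF",
    "TRANSIENT_MAX_NS",
    "polar_atom_mask",
    "detect_polar_contacts",
    "events_from_series",
    "contact_timeseries",
    "interface_contact_map",
]

POLAR_CONTACT_CUTOFF = 3.6   # Å
TRANSIENT_MAX_NS = 1.0       # contacts with max event below this are transient
POLAR_ELEMENTS = ("N", "O", "P")


@dataclass
class ContactEvent:
    pair: str
    start_ns: float
    end_ns: float
    duration_ns: float = field(init=False)

    def __post_init__(self):
        if self.end_ns < self.start_ns:
            raise ContractError("event end must be >= start")
        self.duration_ns = self.end_ns - self.start_ns


@dataclass
class ContactSummary:
    pair: str
    occupancy: float
    n_events: int
    max_duration_ns: float
    contact_class: str = field(init=False)

    def __post_init__(self):
        if not 0.0 <= self.occupancy <= 1.0:
            raise ContractError("occupancy must lie in [0, 1]")
        self.contact_class = ("transient" if self.max_duration_ns < TRANSIENT_MAX_NS
                              else "frequent")


def polar_atom_mask(structure: Structure) -> np.ndarray:
    """Polar atoms: N/O/P by element (protein backbone and side-chain N, O;
    lipid headgroup beads and headgroup O/N/P).  Carbons never participate."""
    return np.isin(structure.element.astype(str), POLAR_ELEMENTS)


def detect_polar_contacts(frame: Structure, mask_a, mask_b,
                          threshold: float = POLAR_CONTACT_CUTOFF) -> list:
    """Polar-atom pairs of two selections within the cutoff in one frame.

    Selections are boolean masks (or mask-keyword dicts); nonpolar atoms
    are filtered out before the distance test.  Returns a list of
    ``(index_a, index_b, distance)`` tuples in global atom indices.
    """
    polar = polar_atom_mask(frame)

    def _resolve(m):
        if isinstance(m, dict):
            m = frame.mask(**m)
        return np.asarray(m, bool) & polar

    a = np.flatnonzero(_resolve(mask_a))
    b = np.flatnonzero(_resolve(mask_b))
    if a.size == 0 or b.size == 0:
        raise ContractError("a polar-atom selection is empty")
    d = cdist(frame.coords[a], frame.coords[b])
    ii, jj = np.where(d <= threshold)
    return [(int(a[i]), int(b[j]), float(d[i, j])) for i, j in zip(ii, jj)]


def events_from_series(in_contact: np.ndarray, times_ps: np.ndarray,
                       pair: str = "", gap_tolerance: int = 0) -> list:
    """Merge a per-frame contact boolean series into maximal events.

    Frame k covers [t_k, t_k + Δt); an event's end is the last frame's
    start plus Δt, so a single-frame contact has duration Δt.  Zero gap
    tolerance by default (a 1-frame gap option absorbs flicker if asked).
    """
    in_contact = np.asarray(in_contact, bool)
    times_ps = np.asarray(times_ps, float)
    if in_contact.shape != times_ps.shape:
        raise ContractError("series and times must have equal length")
    if in_contact.size == 0:
        return []
    dt = float(np.mean(np.diff(times_ps))) if times_ps.size > 1 else 1.0
    series = in_contact.copy()
    if gap_tolerance > 0:
        for k in range(1, series.size - 1):
            if not series[k] and series[k - 1]:
                nxt = series[k + 1: k + 1 + gap_tolerance]
                if nxt.any():
                    series[k] = True
    events = []
    start = None
    for k, flag in enumerate(series):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            events.append((start, k - 1))
            start = None
    if start is not None:
        events.append((start, series.size - 1))
    return [
        ContactEvent(pair=pair,
                     start_ns=times_ps[i] / 1000.0,
                     end_ns=(times_ps[j] + dt) / 1000.0)
        for i, j in events
    ]


def contact_timeseries(traj: Trajectory, mask_a, mask_b,
                       threshold: float = POLAR_CONTACT_CUTOFF,
                       pair: str = "", gap_tolerance: int = 0):
    """Per-frame polar contact of a selection pair → events + summary.

    The pair is "in contact" in a frame when any polar-atom pair of the two
    selections is within the cutoff.
    """
    topo = traj.topology
    polar = polar_atom_mask(topo)

    def _resolve(m):
        if isinstance(m, dict):
            m = topo.mask(**m)
        return np.asarray(m, bool) & polar

    a = np.flatnonzero(_resolve(mask_a))
    b = np.flatnonzero(_resolve(mask_b))
    if a.size == 0 or b.size == 0:
        raise ContractError("a polar-atom selection is empty")
    series = np.empty(traj.n_frames, dtype=bool)
    for k in range(traj.n_frames):
        d = cdist(traj.coords[k][a], traj.coords[k][b])
        series[k] = bool((d <= threshold).any())
    events = events_from_series(series, traj.times, pair=pair,
                                gap_tolerance=gap_tolerance)
    summary = ContactSummary(
        pair=pair,
        occupancy=float(series.mean()),
        n_events=len(events),
        max_duration_ns=max((e.duration_ns for e in events), default=0.0),
    )
    return events, summary


def interface_contact_map(traj: Trajectory, chain_a, chain_b,
                          threshold: float = POLAR_CONTACT_CUTOFF) -> pd.DataFrame:
    """Occupancy of inter-monomer polar contacts per residue pair (i, j′).

    Rows are chain-A residues, columns chain-B residues; each entry is the
    fraction of frames in which any polar-atom pair of the two residues is
    within the cutoff.
    """
    topo = traj.topology
    for c in (chain_a, chain_b):
        if not topo.mask(chain=c).any():
            raise ContractError(f"chain {c} absent")
    polar = polar_atom_mask(topo)
    res_a = sorted(set(topo.res_id[topo.mask(chain=chain_a)]))
    res_b = sorted(set(topo.res_id[topo.mask(chain=chain_b)]))
    idx_a = [np.flatnonzero(topo.mask(chain=chain_a, res_id=r) & polar)
             for r in res_a]
    idx_b = [np.flatnonzero(topo.mask(chain=chain_b, res_id=r) & polar)
             for r in res_b]
    occ = np.zeros((len(res_a), len(res_b)))
    all_a = np.concatenate(idx_a)
    all_b = np.concatenate(idx_b)
    slices_a = np.cumsum([0] + [len(i) for i in idx_a])
    slices_b = np.cumsum([0] + [len(i) for i in idx_b])
    for k in range(traj.n_frames):
        d = cdist(traj.coords[k][all_a], traj.coords[k][all_b]) <= threshold
        for i in range(len(res_a)):
            da = d[slices_a[i]:slices_a[i + 1]]
            for j in range(len(res_b)):
                if da[:, slices_b[j]:slices_b[j + 1]].any():
                    occ[i, j] += 1
    occ /= traj.n_frames
    return pd.DataFrame(occ, index=res_a, columns=res_b)
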