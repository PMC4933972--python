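"""Per-frame geometric observables for transmembrane helix dimers.

Covers helix-axis fitting, the per-monomer rotation-angle collective
variables (α, β) used as free-energy-landscape coordinates, the signed
helix crossing angle, backbone RMSD after optimal superposition, helicity
by backbone-dihedral windows, and Cβ–Cβ distance series used as a
disulfide-crosslinkability surrogate.

Conventions (also echoed in report metadata):

* Rotation CVs are measured right-handed about each monomer's N→C axis,
  zeroed at a fixed reference structure, with Cβ of residue 175 as the
  azimuthal marker (mid-helix and present in both monomers).
* The crossing angle is reported positive for right-handed packing
  (the far helix appears rotated clockwise when viewed along the
  inter-axis normal), so GxxxA-type packing reads ≈ +40°.
* Glycine has no Cβ; position 179 (and any other glycine) uses Cα in all
  "Cβ" distance computations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import BACKBONE_ATOMS, ContractError, Structure, Trajectory

__all__ = [
    "HelixAxisFrame",
    "RotationCV",
    "CrosslinkReport",
    "fit_helix_axis",
    "rotation_cv",
    "crossing_angle",
    "backbone_rmsd",
    "helicity",
    "cb_distance_series",
    "cb_position",
    "DEFAULT_CV_REFERENCE_RESIDUE",
    "CROSSLINK_CB_THRESHOLD",
]

DEFAULT_CV_REFERENCE_RESIDUE = 175
CROSSLINK_CB_THRESHOLD = 7.0  # Å, Cβ–Cβ disulfide-linkable surrogate

# dihedral windows classifying a residue as α-helical
PHI_WINDOW = (-100.0, -30.0)
PSI_WINDOW = (-67.0, -7.0)


@dataclass
class HelixAxisFrame:
    """Fitted helix axis: origin (Cα centroid), unit direction (N→C sense),
    and an optional in-plane reference vector anchoring azimuth zero."""

    origin: np.ndarray
    direction: np.ndarray
    reference_vector: np.ndarray | None = None

    def __post_init__(self):
        self.direction = np.asarray(self.direction, float)
        n = np.linalg.norm(self.direction)
        if n == 0:
            raise ContractError("axis direction must be nonzero")
        self.direction = self.direction / n
        if self.reference_vector is not None:
            v = np.asarray(self.reference_vector, float)
            v = v - self.direction * (v @ self.direction)
            nv = np.linalg.norm(v)
            if nv < 1e-12:
                raise ContractError("reference vector parallel to axis")
            self.reference_vector = v / nv


@dataclass
class RotationCV:
    alpha: float  # degrees in (-180, 180]
    beta: float


@dataclass
class CrosslinkReport:
    pair: tuple
    distance_series: np.ndarray
    threshold: float = CROSSLINK_CB_THRESHOLD
    linkable_fraction: float = field(init=False)

    def __post_init__(self):
        self.distance_series = np.asarray(self.distance_series, float)
        if np.any(self.distance_series < 0):
            raise ContractError("distances must be non-negative")
        self.linkable_fraction = float(
            np.mean(self.distance_series <= self.threshold)
        )


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _wrap_angle(deg: float) -> float:
    """Map to (-180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else float(a)


def _ca_coords(structure: Structure, chain, residue_range=None) -> np.ndarray:
    m = structure.mask(chain=chain, atom_name="CA")
    if residue_range is not None:
        lo, hi = residue_range
        m &= (structure.res_id >= lo) & (structure.res_id <= hi)
    sub = structure.subset(m)
    order = np.argsort(sub.res_id, kind="stable")
    return sub.coords[order]


def cb_position(structure: Structure, chain, res_id) -> np.ndarray:
    """Cβ coordinates of a residue, substituting Cα for glycine."""
    m = structure.mask(chain=chain, res_id=res_id, atom_name="CB")
    if m.any():
        return structure.coords[m][0]
    mg = structure.mask(chain=chain, res_id=res_id)
    if not mg.any():
        raise ContractError(f"residue {res_id} absent from chain {chain}")
    res_name = structure.res_name[mg][0]
    if res_name != "GLY":
        raise ContractError(
            f"residue {chain}/{res_id} ({res_name}) lacks a CB atom"
        )
    return structure.atom_coord(chain, res_id, "CA")


# ---------------------------------------------------------------------------
# axis fitting
# ---------------------------------------------------------------------------

def _cylinder_refine(ca: np.ndarray, d0: np.ndarray) -> np.ndarray:
    """Refine an axis direction so Cα radial distances about it are uniform.

    The principal eigenvector of the Cα covariance is biased by up to ~1-2°
    when the helix spans a fractional number of turns; minimizing the
    variance of the radial distances (after an algebraic circle fit in the
    transverse plane) removes that bias — on an ideal helix the result is
    the exact screw axis.
    """
    from scipy.optimize import least_squares

    base = _minimal_rotation(np.array([0.0, 0.0, 1.0]), d0)

    def residuals(t):
        d = base.apply(Rotation.from_euler("xy", t).apply([0.0, 0.0, 1.0]))
        u = ca - ca.mean(axis=0)
        proj = u - np.outer(u @ d, d)
        e1 = proj[0] - (proj[0] @ d) * d
        n1 = np.linalg.norm(e1)
        if n1 < 1e-9:
            e1 = np.array([1.0, 0.0, 0.0]) - d[0] * d
            n1 = np.linalg.norm(e1)
        e1 /= n1
        e2 = np.cross(d, e1)
        x, y = proj @ e1, proj @ e2
        # Kasa circle fit: linear least squares for center and radius
        a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
        sol, *_ = np.linalg.lstsq(a_mat, x ** 2 + y ** 2, rcond=None)
        r = np.sqrt((x - sol[0]) ** 2 + (y - sol[1]) ** 2)
        return r - r.mean()

    fit = least_squares(residuals, [0.0, 0.0], xtol=1e-14, ftol=1e-14,
                        gtol=1e-14, method="lm")
    return base.apply(Rotation.from_euler("xy", fit.x).apply([0.0, 0.0, 1.0]))


def fit_helix_axis(structure: Structure, chain, residue_range=None) -> HelixAxisFrame:
    """Fit the helix principal axis from Cα coordinates.

    The principal eigenvector of the Cα coordinate covariance initializes
    the direction, which is then refined so the Cα radial spread about the
    axis is minimal (cylinder fit); the sign points N→C and the origin is
    the Cα centroid.
    """
    ca = _ca_coords(structure, chain, residue_range)
    if ca.shape[0] < 4:
        raise ContractError(
            f"need at least 4 Cα atoms to fit an axis, got {ca.shape[0]}"
        )
    centroid = ca.mean(axis=0)
    x = ca - centroid
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    direction = _cylinder_refine(ca, vt[0])
    if direction @ (ca[-1] - ca[0]) < 0:
        direction = -direction
    return HelixAxisFrame(origin=centroid, direction=direction)


def _azimuth_vector(structure: Structure, chain, ref_residue, axis: HelixAxisFrame):
    """Unit projection of axis→Cβ(ref) onto the plane ⟂ axis."""
    cb = cb_position(structure, chain, ref_residue)
    v = cb - axis.origin
    v = v - axis.direction * (v @ axis.direction)
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ContractError(
            f"Cβ of residue {ref_residue} lies on the helix axis; azimuth undefined"
        )
    return v / n


def _minimal_rotation(a: np.ndarray, b: np.ndarray) -> Rotation:
    """Smallest rotation taking unit vector a onto unit vector b."""
    cross = np.cross(a, b)
    s = np.linalg.norm(cross)
    c = float(a @ b)
    if s < 1e-12:
        return Rotation.identity()
    axis = cross / s
    return Rotation.from_rotvec(axis * np.arctan2(s, c))


# ---------------------------------------------------------------------------
# rotation-angle collective variables
# ---------------------------------------------------------------------------

def rotation_cv(dimer_frame: Structure, reference_dimer: Structure,
                ref_residue: int = DEFAULT_CV_REFERENCE_RESIDUE,
                chains=None) -> RotationCV:
    """Per-monomer rotation angles (α, β) about the helix principal axes.

    For each monomer the angle is measured from the reference structure's
    azimuth marker (projection of axis→Cβ(ref_residue)) to the current one,
    right-handed about the N→C axis direction.  The reference azimuth is
    transported onto the current axis by the smallest rotation aligning the
    two axis directions, so a pure rotation of a monomer about its own axis
    is recovered exactly and the CV is zero when frame equals reference.
    """
    if chains is None:
        chains = reference_dimer.chains()
    if len(chains) != 2:
        raise ContractError(f"expected 2 chains, got {chains}")
    angles = []
    for chain in chains:
        ax_ref = fit_helix_axis(reference_dimer, chain)
        ax_cur = fit_helix_axis(dimer_frame, chain)
        v_ref = _azimuth_vector(reference_dimer, chain, ref_residue, ax_ref)
        v_cur = _azimuth_vector(dimer_frame, chain, ref_residue, ax_cur)
        transport = _minimal_rotation(ax_ref.direction, ax_cur.direction)
        v0 = transport.apply(v_ref)
        v0 = v0 - ax_cur.direction * (v0 @ ax_cur.direction)
        v0 /= np.linalg.norm(v0)
        ang = np.degrees(np.arctan2(
            float(np.cross(v0, v_cur) @ ax_cur.direction), float(v0 @ v_cur)
        ))
        angles.append(_wrap_angle(ang))
    return RotationCV(alpha=angles[0], beta=angles[1])


# ---------------------------------------------------------------------------
# crossing angle
# ---------------------------------------------------------------------------

def _closest_points(o1, d1, o2, d2):
    """Closest points between two lines (o, d)."""
    w0 = o1 - o2
    a, b, c = d1 @ d1, d1 @ d2, d2 @ d2
    d, e = d1 @ w0, d2 @ w0
    denom = a * c - b * b
    if abs(denom) < 1e-12:
        return o1, o2 - d2 * e / c, True
    s = (b * e - c * d) / denom
    t = (a * e - b * d) / denom
    return o1 + s * d1, o2 + t * d2, False


def crossing_angle(dimer_frame: Structure = None, chains=None,
                   axes: tuple | None = None) -> float:
    """Signed helix crossing angle in degrees, |value| ≤ 90.

    Positive = right-handed crossing: looking along the inter-axis normal
    (from the near helix toward the far one), the far helix appears rotated
    clockwise relative to the near one.  Parallel coincident axes return 0
    with a degenerate-geometry warning.
    """
    if axes is None:
        if chains is None:
            chains = dimer_frame.chains()
        if len(chains) != 2:
            raise ContractError(f"expected 2 chains, got {chains}")
        axes = (fit_helix_axis(dimer_frame, chains[0]),
                fit_helix_axis(dimer_frame, chains[1]))
    ax1, ax2 = axes
    d1, d2 = ax1.direction.copy(), ax2.direction.copy()
    if d1 @ d2 < 0:       # report against co-aligned axes so |angle| <= 90
        d2 = -d2
    p1, p2, parallel = _closest_points(ax1.origin, d1, ax2.origin, d2)
    n = p2 - p1
    dist = np.linalg.norm(n)
    if parallel and dist < 1e-9:
        warnings.warn("degenerate geometry: parallel coincident axes; "
                      "crossing angle undefined, returning 0")
        return 0.0
    if dist < 1e-9:
        # intersecting axes: use the common normal instead
        n = np.cross(d1, d2)
        dist = np.linalg.norm(n)
        if dist < 1e-12:
            return 0.0
    nhat = n / dist
    # torsion-style angle about the inter-axis normal; right-handed packing
    # (GxxxA-type, i/i+4 interface stripes) gives a negative torsion in the
    # crystallographic convention, so the sign is flipped to report
    # right-handed crossings as positive
    ang = np.degrees(np.arctan2(float(np.cross(d1, d2) @ nhat), float(d1 @ d2)))
    return float(-ang)


# ---------------------------------------------------------------------------
# RMSD
# ---------------------------------------------------------------------------

def backbone_rmsd(frame: Structure, reference: Structure,
                  chain=None, atom_names=BACKBONE_ATOMS) -> float:
    """Backbone RMSD (Å) after optimal least-squares superposition (Kabsch)."""
    def _bb(st):
        m = st.mask(atom_name=list(atom_names))
        if chain is not None:
            m &= st.mask(chain=chain)
        sub = st.subset(m)
        order = np.lexsort((sub.atom_name.astype(str), sub.res_id,
                            sub.chain_id.astype(str)))
        return sub.coords[order], list(zip(sub.chain_id[order], sub.res_id[order],
                                           sub.atom_name[order]))

    x, ids_x = _bb(frame)
    y, ids_y = _bb(reference)
    if ids_x != ids_y:
        raise ContractError("backbone atom sets do not match between structures")
    if x.shape[0] < 3:
        raise ContractError("need at least 3 atoms for superposition")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    rot, rssd = Rotation.align_vectors(yc, xc)
    return float(rssd / np.sqrt(x.shape[0]))


# ---------------------------------------------------------------------------
# helicity
# ---------------------------------------------------------------------------

def _dihedral(p0, p1, p2, p3) -> float:
    """IUPAC torsion angle in degrees (praxeolitic formulation)."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - (b0 @ b1n) * b1n
    w = b2 - (b2 @ b1n) * b1n
    return float(np.degrees(np.arctan2(float(np.cross(b1n, v) @ w), float(v @ w))))


def phi_psi(structure: Structure, chain) -> list:
    """(res_id, phi, psi) for residues where both dihedrals are defined."""
    m = structure.mask(chain=chain)
    if not m.any():
        raise ContractError(f"chain {chain} absent")
    res_ids = sorted(set(structure.res_id[m]))
    get = {}
    for r in res_ids:
        for a in ("N", "CA", "C"):
            mm = structure.mask(chain=chain, res_id=r, atom_name=a)
            if mm.any():
                get[(r, a)] = structure.coords[mm][0]
    out = []
    for r in res_ids:
        prev_c = get.get((r - 1, "C"))
        n, ca, c = get.get((r, "N")), get.get((r, "CA")), get.get((r, "C"))
        next_n = get.get((r + 1, "N"))
        if any(v is None for v in (prev_c, n, ca, c, next_n)):
            continue
        phi = _dihedral(prev_c, n, ca, c)
        psi = _dihedral(n, ca, c, next_n)
        out.append((r, phi, psi))
    return out


def helicity(structure: Structure, chain) -> float:
    """Percent of assignable residues in the α-helical dihedral window.

    A residue is helical when φ ∈ [-100°, -30°] and ψ ∈ [-67°, -7°];
    terminal residues lacking a dihedral are excluded from the denominator.
    """
    assigned = phi_psi(structure, chain)
    if not assigned:
        raise ContractError(
            f"chain {chain} has no residues with computable dihedrals"
        )
    n_helical = sum(
        1 for (_, phi, psi) in assigned
        if PHI_WINDOW[0] <= phi <= PHI_WINDOW[1]
        and PSI_WINDOW[0] <= psi <= PSI_WINDOW[1]
    )
    return 100.0 * n_helical / len(assigned)


# ---------------------------------------------------------------------------
# crosslink distance series
# ---------------------------------------------------------------------------

def cb_distance_series(traj: Trajectory | Structure, pairs, chains=None,
                       threshold: float = CROSSLINK_CB_THRESHOLD) -> list:
    """Cβ–Cβ′ distances over time for inter-monomer residue pairs.

    ``pairs`` is a list of residue numbers (i paired with i′ in the partner
    chain) or of (i, j) tuples.  Glycine positions use Cα.
    """
    if isinstance(traj, Structure):
        frames = [traj]
        topo = traj
    else:
        frames = [traj.frame(i) for i in range(traj.n_frames)]
        topo = traj.topology
    if chains is None:
        chains = topo.chains()
    if len(chains) != 2:
        raise ContractError(f"expected 2 chains, got {chains}")
    reports = []
    for pair in pairs:
        i, j = (pair, pair) if np.isscalar(pair) else pair
        series = np.array([
            np.linalg.norm(cb_position(f, chains[0], i) -
                           cb_position(f, chains[1], j))
            for f in frames
        ])
        reports.append(CrosslinkReport(pair=(i, j), distance_series=series,
                                       threshold=threshold))
    return reports
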