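"""Synthetic-data generators with known ground truth.

Everything the analysis pipeline consumes can be generated here at desk
scale: ideal α-helices, crosslink-constrained helix-dimer fixtures for the
intersected / parallel / iso-parallel interface states (plus the A183I
steric perturbation), mitochondrial-outer-membrane-like bilayers of
headgroup beads, 2D Brownian lipid trajectories with optional
protein-proximity enrichment, rotation-scheduled dimer trajectories for
the (α, β) collective variables, and analytic multi-basin free-energy
surfaces.

Lipids are single headgroup beads: every analysis in scope (density maps,
radial stoichiometry, MSD diffusion, polar-contact surrogate sites) works
on headgroup positions, so acyl tails are not modelled; cardiolipin's
larger footprint enters through its double area weight in stoichiometry
percentages, not through geometry.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .core import ContractError, FESGrid, Structure, Trajectory
from . import geometry

__all__ = [
    "HelixSpec",
    "DimerState",
    "MembraneComposition",
    "BrownianParams",
    "FixtureError",
    "PackingError",
    "DIMER_STATES",
    "ALPHA9_SEQUENCE",
    "build_ideal_helix",
    "build_dimer_fixture",
    "apply_mutation_A183I",
    "build_membrane",
    "simulate_lipid_trajectory",
    "simulate_cv_rotation",
    "make_analytic_fes",
    "two_basin_fes",
    "six_state_fes",
]

# Bax helix α9 (residues 169-189)
ALPHA9_SEQUENCE = "TWQTVTIFVAGVLTASLTIWK"
ALPHA9_FIRST_RESIDUE = 169

AA_3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

CLASH_CUTOFF = 2.5        # Å, minimum allowed inter-monomer heavy-atom distance
ATOM_CLASH_RADIUS = CLASH_CUTOFF / 2.0  # per-atom share of the pair cutoff
PSEUDO_VDW_RADIUS = 1.7   # Å, carbon vdW radius for the bulky mutant pseudo-atom
CROSSLINK_MAX = 7.0       # Å, Cβ-Cβ distance a disulfide can bridge
DISULFIDE_CB_CB = 3.8     # Å, canonical Cβ-Cβ separation of a formed disulfide
MUTANT_EXTENSION = 1.5    # Å, pseudo side-chain extension for A183I
BURIED_CONTACT_DIST = 2 * PSEUDO_VDW_RADIUS  # Å, carbon-carbon vdW contact for buried residues

LIPID_TYPES = ("PC", "PE", "PI", "PS", "CL")
ANIONIC_TYPES = frozenset({"PI", "PS", "CL"})
BILAYER_HALF_THICKNESS = 19.0  # Å, headgroup plane offset from midplane


class FixtureError(RuntimeError):
    """The docking optimizer could not satisfy the fixture constraints."""


class PackingError(RuntimeError):
    """Lipids could not be placed in the requested box."""


# ---------------------------------------------------------------------------
# specs
# ---------------------------------------------------------------------------

@dataclass
class HelixSpec:
    sequence: str = ALPHA9_SEQUENCE
    first_residue_number: int = ALPHA9_FIRST_RESIDUE
    rise_per_residue: float = 1.5    # Å
    twist_per_residue: float = 100.0  # degrees
    radius: float = 2.3              # Å, Cα helix radius

    def __post_init__(self):
        if not self.sequence:
            raise ContractError("sequence must be non-empty")
        bad = [c for c in self.sequence if c not in AA_3]
        if bad:
            raise ContractError(f"unknown amino-acid letters: {bad}")


@dataclass
class DimerState:
    """An interface state defined by its disulfide-crosslinkable pairs.

    ``buried_contact_residues`` lists residues the state packs against the
    partner monomer *without* being crosslinkable; the iso-parallel state
    buries Ala183 at the interface, which is why its A183I mutant disrupts
    that dimer.
    """

    label: str
    crosslink_pairs: tuple
    target_crossing_angle_hint: float | None = None
    buried_contact_residues: tuple = ()


DIMER_STATES = {
    "intersected": DimerState("intersected", (175, 179, 183, 187), 40.0),
    "parallel": DimerState("parallel", (171, 178, 182, 185), 0.0),
    "iso_parallel": DimerState("iso_parallel", (172, 186), 10.0, (183,)),
}


@dataclass
class MembraneComposition:
    """Mole fractions of a 5-lipid mitochondrial-outer-membrane model."""

    fractions: dict = field(default_factory=lambda: {
        "PC": 0.465, "PE": 0.284, "PI": 0.089, "PS": 0.089, "CL": 0.073,
    })

    def __post_init__(self):
        unknown = set(self.fractions) - set(LIPID_TYPES)
        if unknown:
            raise ContractError(f"unknown lipid types: {unknown}")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ContractError(f"mole fractions must sum to 1, got {total}")

    def is_anionic(self, lipid_type: str) -> bool:
        return lipid_type in ANIONIC_TYPES


@dataclass
class BrownianParams:
    """Per-type 2D Brownian-walk parameters for lipid beads."""

    diffusion: dict = field(default_factory=lambda: {
        # Å²/ps; order of magnitude of lipid lateral diffusion (~1e-7 cm²/s)
        "PC": 0.05, "PE": 0.05, "PI": 0.04, "PS": 0.04, "CL": 0.03,
    })
    timestep: float = 10.0   # ps between stored frames
    n_steps: int = 1000
    enrichment_bias: dict = field(default_factory=dict)  # Å/ps inward drift
    enrichment_core: float = 10.0  # Å, no drift inside this radius
    seed: int = 0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ContractError("timestep must be positive")
        if any(d < 0 for d in self.diffusion.values()):
            raise ContractError("diffusion coefficients must be >= 0")


# ---------------------------------------------------------------------------
# ideal helix
# ---------------------------------------------------------------------------

# backbone internal coordinates (CHARMM-like ideal values)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.8
OMEGA = 180.0


def _place_atom(a, b, c, bond, angle_deg, torsion_deg):
    """NeRF: place atom d given positions a-b-c, bond |cd|, angle b-c-d, torsion a-b-c-d."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_backbone(n_res: int, phi: float, psi: float,
                    tau: float = A_N_CA_C) -> np.ndarray:
    """(n_res, 3, 3) array of N, CA, C positions for uniform (phi, psi).

    ``tau`` is the N-Cα-C bond angle, the one flexible backbone angle.
    """
    coords = np.zeros((n_res, 3, 3))
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (B_N_CA, 0.0, 0.0)
    ang = np.radians(tau)
    coords[0, 2] = coords[0, 1] + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res):
        n_i, ca_i, c_i = coords[i]
        if i + 1 < n_res:
            n_next = _place_atom(n_i, ca_i, c_i, B_C_N, A_CA_C_N, psi)
            ca_next = _place_atom(ca_i, c_i, n_next, B_N_CA, A_C_N_CA, OMEGA)
            c_next = _place_atom(c_i, n_next, ca_next, B_CA_C, tau, phi)
            coords[i + 1] = (n_next, ca_next, c_next)
    return coords


def _screw_axis(ca: np.ndarray):
    """(unit direction N→C, point on axis) of the exact screw through Cαs."""
    v1, v2, v3 = ca[1] - ca[0], ca[2] - ca[1], ca[3] - ca[2]

    def frame(a, b):
        e1 = a / np.linalg.norm(a)
        e2 = b - (b @ e1) * e1
        e2 /= np.linalg.norm(e2)
        return np.column_stack([e1, e2, np.cross(e1, e2)])

    rot = Rotation.from_matrix(frame(v2, v3) @ frame(v1, v2).T)
    rotvec = rot.as_rotvec()
    axis = rotvec / np.linalg.norm(rotvec)
    if axis @ (ca[-1] - ca[0]) < 0:
        axis = -axis
    r_mat = rot.as_matrix()
    t = ca[1] - r_mat @ ca[0]
    t_par = (t @ axis) * axis
    p0, *_ = np.linalg.lstsq(np.eye(3) - r_mat, t - t_par, rcond=None)
    return axis, p0


def _screw_parameters(ca: np.ndarray):
    """(rise, twist_deg, radius) of the exact screw relating consecutive residues."""
    # rotation mapping residue-i Cα triplet onto residue-(i+1) triplet
    p = ca[:-1]
    q = ca[1:]
    # direction via displacement sum is biased; use the rotation of the local frame
    v1 = ca[1] - ca[0]
    v2 = ca[2] - ca[1]
    v3 = ca[3] - ca[2]
    # frame at residue 0 and residue 1
    def frame(a, b):
        e1 = a / np.linalg.norm(a)
        e2 = b - (b @ e1) * e1
        e2 /= np.linalg.norm(e2)
        return np.column_stack([e1, e2, np.cross(e1, e2)])
    f0 = frame(v1, v2)
    f1 = frame(v2, v3)
    rot = Rotation.from_matrix(f1 @ f0.T)
    rotvec = rot.as_rotvec()
    twist = np.degrees(np.linalg.norm(rotvec))
    axis = rotvec / np.linalg.norm(rotvec)
    rise = abs((ca[1] - ca[0]) @ axis)
    # axis point: solve (I - R) p = t_perp for the screw axis
    r_mat = rot.as_matrix()
    t = ca[1] - r_mat @ ca[0]
    t_par = (t @ axis) * axis
    a_mat = np.eye(3) - r_mat
    p0, *_ = np.linalg.lstsq(a_mat, t - t_par, rcond=None)
    radial = ca[0] - p0
    radial -= (radial @ axis) * axis
    return rise, twist, float(np.linalg.norm(radial))


@lru_cache(maxsize=8)
def _solve_phi_psi(rise: float, twist: float):
    """Backbone (phi, psi, tau) whose helix has exactly the given screw.

    With all bond angles fixed at ideal values the reachable (rise, twist)
    set is a narrow band that misses (1.5 Å, 100°) slightly, so the
    flexible N-Cα-C angle tau is freed as a third unknown, softly anchored
    at its ideal value.
    """
    from scipy.optimize import least_squares

    def residual(x):
        ca = _build_backbone(6, x[0], x[1], x[2])[:, 1, :]
        r, t, _ = _screw_parameters(ca)
        return [1e4 * (r - rise), 1e3 * (t - twist), 0.02 * (x[2] - A_N_CA_C)]

    sol = least_squares(residual, x0=[-57.0, -47.0, A_N_CA_C],
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    res = residual(sol.x)
    if abs(res[0]) > 1e4 * 1e-6 or abs(res[1]) > 1e3 * 1e-5:
        raise ContractError(
            f"no ideal-geometry helix with rise {rise} Å / twist {twist}°"
        )
    return float(sol.x[0]), float(sol.x[1]), float(sol.x[2])


def build_ideal_helix(spec: HelixSpec | None = None, chain_id: str = "A") -> Structure:
    """Build a canonical α-helix (backbone + Cβ) with its principal axis on +z.

    Backbone dihedrals are solved so the Cα screw matches the requested
    rise and twist exactly; Cα radial distance is scaled to ``spec.radius``.
    The fitted principal axis (as :func:`geometry.fit_helix_axis` computes
    it) is aligned with +z in the N→C sense and the Cα centroid sits at the
    origin.
    """
    spec = spec or HelixSpec()
    n = len(spec.sequence)
    phi, psi, tau = _solve_phi_psi(spec.rise_per_residue, spec.twist_per_residue)
    bb = _build_backbone(n, phi, psi, tau)

    names, elements, res_names, res_ids, coords = [], [], [], [], []
    for i, letter in enumerate(spec.sequence):
        res3 = AA_3[letter]
        rid = spec.first_residue_number + i
        n_i, ca_i, c_i = bb[i]
        psi_i = psi  # uniform helix; last residue keeps the canonical value
        o_i = _place_atom(n_i, ca_i, c_i, B_C_O, A_CA_C_O, psi_i + 180.0)
        atoms = [("N", "N", n_i), ("CA", "C", ca_i), ("C", "C", c_i), ("O", "O", o_i)]
        if res3 != "GLY":
            # standard Cβ construction giving L-chirality
            b = ca_i - n_i
            c = c_i - ca_i
            a = np.cross(b, c)
            cb = -0.58273431 * a + 0.56802827 * b - 0.54067466 * c + ca_i
            atoms.append(("CB", "C", cb))
        for aname, elem, xyz in atoms:
            names.append(aname)
            elements.append(elem)
            res_names.append(res3)
            res_ids.append(rid)
            coords.append(xyz)

    st = Structure(
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(res_names, dtype=object),
        res_id=np.array(res_ids, dtype=int),
        chain_id=np.array([chain_id] * len(names), dtype=object),
        coords=np.array(coords, dtype=float),
        title="ideal helix",
    )

    # align the exact screw axis with +z, Cα centroid at z-origin
    ca_pre = st.coords[st.mask(atom_name="CA")]
    axis, point = _screw_axis(ca_pre)
    rot = geometry._minimal_rotation(axis, np.array([0.0, 0.0, 1.0]))
    st.coords = rot.apply(st.coords - point)
    st.coords[:, 2] -= st.coords[st.mask(atom_name="CA")][:, 2].mean()
    # scale Cα radial distance to the requested helix radius
    ca_mask = st.mask(atom_name="CA")
    mean_r = np.mean(np.linalg.norm(st.coords[ca_mask][:, :2], axis=1))
    st.coords[:, :2] *= spec.radius / mean_r
    # deterministic azimuth: Cβ of the first residue points along +x
    first = st.res_id.min()
    ref = st.coords[st.mask(res_id=first, atom_name="CB")]
    if ref.size == 0:
        ref = st.coords[st.mask(res_id=first, atom_name="CA")]
    az = np.arctan2(ref[0][1], ref[0][0])
    st.coords = Rotation.from_euler("z", -az).apply(st.coords)
    return st


# ---------------------------------------------------------------------------
# dimer docking
# ---------------------------------------------------------------------------

def _pair_atoms(st: Structure, chain, residues):
    """Cβ coordinates index (Cα for Gly) for the crosslink residues."""
    idx = []
    for r in residues:
        m = st.mask(chain=chain, res_id=r, atom_name="CB")
        if not m.any():
            m = st.mask(chain=chain, res_id=r, atom_name="CA")
        idx.append(int(np.flatnonzero(m)[0]))
    return np.array(idx, dtype=int)


def _circular_mean_deg(angles_deg):
    a = np.radians(np.asarray(angles_deg, float))
    return float(np.degrees(np.arctan2(np.sin(a).mean(), np.cos(a).mean())))


def _pose_transform(params, centroid):
    rot = Rotation.from_rotvec(params[:3])
    return lambda xyz: rot.apply(xyz - centroid) + centroid + params[3:6]


class _DockingProblem:
    """Rigid-body docking of monomer B against fixed monomer A.

    Minimizes the summed squared deviations of the crosslink Cβ-Cβ'
    distances from the canonical separation of a formed disulfide (4.0 Å)
    subject to a hard no-clash constraint (no inter-monomer heavy-atom pair
    below 2.5 Å), imposed as a quadratic penalty during optimization and
    verified exactly on the result.  Driving the pair distances to the
    disulfide geometry rather than to zero keeps the packing realistic for
    a Cβ-truncated model: collapsing the pairs onto the clash boundary
    would drag the flanking, non-interface residue pairs inside the
    crosslinkable range as well.
    """

    def __init__(self, coords_a, coords_b0, pairs_a, pairs_b,
                 clash_weight=400.0, cushion=0.2,
                 pair_target=DISULFIDE_CB_CB,
                 excl_a=None, excl_b=None, excl_margin=CROSSLINK_MAX + 0.5,
                 excl_weight=10.0, pack_weight=0.05, pack_dist=4.0,
                 pack_sigma=1.5, radii_a=None, radii_b=None,
                 bury_a=None, bury_b=None, bury_weight=5.0,
                 bury_target=BURIED_CONTACT_DIST):
        self.coords_a = coords_a
        self.coords_b0 = coords_b0
        self.centroid_b = coords_b0.mean(axis=0)
        self.pairs_a = pairs_a
        self.pairs_b = pairs_b
        # per-atom clash radii; the default reproduces the scalar 2.5 Å
        # heavy-atom pair cutoff, while bulky pseudo-atoms carry a larger,
        # vdW-sized radius
        ra = (np.full(len(coords_a), ATOM_CLASH_RADIUS) if radii_a is None
              else np.asarray(radii_a, float))
        rb = (np.full(len(coords_b0), ATOM_CLASH_RADIUS) if radii_b is None
              else np.asarray(radii_b, float))
        self.clash_dist = ra[:, None] + rb[None, :]
        # penalty switches on slightly above the hard cutoff so the
        # optimum does not sit marginally inside the forbidden zone
        self.soft = self.clash_dist + cushion
        self.w = clash_weight
        self.pair_target = pair_target
        # residue pairs of the *other* interface states, pushed beyond the
        # crosslinkable range so each fixture is identifiable by its
        # crosslink pattern
        self.excl_a = excl_a if excl_a is not None else np.array([], int)
        self.excl_b = excl_b if excl_b is not None else np.array([], int)
        self.excl_margin = excl_margin
        self.w_excl = excl_weight
        # weak shape-complementarity reward: helix dimers pack snugly, so
        # inter-monomer atom pairs near van der Waals contact are favoured
        self.w_pack = pack_weight
        self.pack_dist = pack_dist
        self.pack_sigma = pack_sigma
        # residues held in (non-crosslinkable) vdW contact with the partner
        self.bury_a = bury_a if bury_a is not None else np.array([], int)
        self.bury_b = bury_b if bury_b is not None else np.array([], int)
        self.w_bury = bury_weight
        self.bury_target = bury_target

    def transform(self, params):
        return _pose_transform(params, self.centroid_b)(self.coords_b0)

    def objective(self, params):
        b = self.transform(params)
        pd = np.linalg.norm(self.coords_a[self.pairs_a] - b[self.pairs_b],
                            axis=1)
        pair_d2 = np.sum((pd - self.pair_target) ** 2)
        d = cdist(self.coords_a, b)
        over = self.soft - d
        clash = np.sum(np.square(over, where=over > 0, out=np.zeros_like(over)))
        excl = 0.0
        if self.excl_a.size:
            ed = np.linalg.norm(self.coords_a[self.excl_a] - b[self.excl_b],
                                axis=1)
            short = ed < self.excl_margin
            excl = np.sum((self.excl_margin - ed[short]) ** 2)
        pack = np.sum(np.exp(-(d - self.pack_dist) ** 2
                             / (2.0 * self.pack_sigma ** 2)))
        bury = 0.0
        if self.bury_a.size:
            bury += np.sum((d[self.bury_a, :].min(axis=1)
                            - self.bury_target) ** 2)
        if self.bury_b.size:
            bury += np.sum((d[:, self.bury_b].min(axis=0)
                            - self.bury_target) ** 2)
        return (pair_d2 + self.w * clash + self.w_excl * excl
                - self.w_pack * pack + self.w_bury * bury)

    def evaluate(self, params):
        b = self.transform(params)
        pair_d = np.linalg.norm(
            self.coords_a[self.pairs_a] - b[self.pairs_b], axis=1
        )
        d = cdist(self.coords_a, b)
        clash_margin = float((d - self.clash_dist).min())
        n_leaky = 0
        if self.excl_a.size:
            ed = np.linalg.norm(self.coords_a[self.excl_a] - b[self.excl_b],
                                axis=1)
            n_leaky = int(np.sum(ed <= CROSSLINK_MAX))
        bury_err = 0.0
        if self.bury_a.size:
            bury_err += float(np.sum((d[self.bury_a, :].min(axis=1)
                                      - self.bury_target) ** 2))
        if self.bury_b.size:
            bury_err += float(np.sum((d[:, self.bury_b].min(axis=0)
                                      - self.bury_target) ** 2))
        return b, pair_d, clash_margin, n_leaky, bury_err


def build_dimer_fixture(state: DimerState | str, seed: int = 0,
                        spec: HelixSpec | None = None,
                        n_restarts: int = 32,
                        pair_max: float = CROSSLINK_MAX) -> Structure:
    """Dock two ideal helices into a crosslink-compatible dimer.

    Monomer A is the ideal helix pre-rotated so the circular-mean azimuth
    of its crosslink-pair Cβ atoms faces +x; monomer B starts as A's
    two-fold image across the inter-helix axis and is refined over 6
    rigid-body degrees of freedom by random-restart local minimization of
    the squared deviations of the pair distances from the canonical
    disulfide Cβ-Cβ separation, under the no-clash penalty.  The best
    feasible solution (all declared pairs ≤ 7 Å, no heavy-atom pair
    < 2.5 Å) is kept, then the dimer is re-oriented so the mean helix axis
    is +z (membrane normal) and the dimer centroid is at the origin.
    """
    if isinstance(state, str):
        state = DIMER_STATES[state]
    rng = np.random.default_rng(seed)
    helix = build_ideal_helix(spec, chain_id="A")
    pairs = list(state.crosslink_pairs)

    # face the interface stripe of monomer A toward +x
    pa = _pair_atoms(helix, "A", pairs)
    az = np.degrees(np.arctan2(helix.coords[pa, 1], helix.coords[pa, 0]))
    helix.coords = Rotation.from_euler(
        "z", -_circular_mean_deg(az), degrees=True
    ).apply(helix.coords)

    mono_b = helix.copy()
    mono_b.chain_id = np.array(["B"] * mono_b.n_atoms, dtype=object)

    # residue pairs declared by the *other* states must stay beyond the
    # crosslinkable range so the fixture is identifiable by its pattern
    all_pairs = sorted({r for st in DIMER_STATES.values()
                        for r in st.crosslink_pairs})
    excl = [r for r in all_pairs if r not in pairs]

    hint = state.target_crossing_angle_hint or 0.0
    problem = None
    best = None
    for trial in range(n_restarts):
        sep = rng.uniform(8.0, 12.0)
        # C2 image of A across the vertical axis at x = sep/2: (x,y,z) -> (sep-x, -y, z)
        b0 = mono_b.coords * np.array([-1.0, -1.0, 1.0]) + np.array([sep, 0.0, 0.0])
        problem = _DockingProblem(
            helix.coords, b0,
            _pair_atoms(helix, "A", pairs), _pair_atoms(mono_b, "B", pairs),
            excl_a=_pair_atoms(helix, "A", excl),
            excl_b=_pair_atoms(mono_b, "B", excl),
        )
        x0 = np.zeros(6)
        # tilt about the inter-axis normal (x) seeds the hinted crossing angle
        x0[0] = np.radians(-hint) * (0.5 + 0.5 * rng.random())
        x0[:3] += rng.normal(0.0, 0.25, 3)
        x0[3:] += rng.normal(0.0, 1.5, 3)
        res = minimize(problem.objective, x0, method="L-BFGS-B",
                       options={"maxiter": 400})
        if state.buried_contact_residues:
            # continuation stage: pull the buried residues into vdW contact
            # with the partner while a stiffened exclusion penalty keeps the
            # non-declared pairs outside the crosslinkable range
            problem = _DockingProblem(
                helix.coords, b0,
                _pair_atoms(helix, "A", pairs), _pair_atoms(mono_b, "B", pairs),
                excl_a=_pair_atoms(helix, "A", excl),
                excl_b=_pair_atoms(mono_b, "B", excl),
                excl_weight=50.0,
                bury_a=_pair_atoms(helix, "A", state.buried_contact_residues),
                bury_b=_pair_atoms(mono_b, "B", state.buried_contact_residues),
            )
            res = minimize(problem.objective, res.x, method="L-BFGS-B",
                           options={"maxiter": 400})
        b_coords, pair_d, margin, n_leaky, bury_err = problem.evaluate(res.x)
        feasible = bool(np.all(pair_d <= pair_max) and margin >= -1e-9)
        score = (n_leaky, float(np.sum((pair_d - DISULFIDE_CB_CB) ** 2)
                                + problem.w_bury * bury_err))
        if feasible and (best is None or score < best[0]):
            best = (score, b_coords, pair_d, margin)

    if best is None:
        _, pair_d, margin, _ = problem.evaluate(res.x)
        raise FixtureError(
            f"docking failed for state {state.label!r}: achieved pair "
            f"distances {np.round(pair_d, 2).tolist()} Å "
            f"(limit {pair_max} Å), clash margin {margin:.2f} Å"
        )

    mono_b.coords = best[1]
    dimer = Structure.concat([helix, mono_b])
    dimer.title = f"{state.label} dimer fixture"

    # membrane normal along z: mean axis -> +z, centroid -> origin
    ax_a = geometry.fit_helix_axis(dimer, "A")
    ax_b = geometry.fit_helix_axis(dimer, "B")
    mean_dir = ax_a.direction + ax_b.direction
    mean_dir /= np.linalg.norm(mean_dir)
    rot = geometry._minimal_rotation(mean_dir, np.array([0.0, 0.0, 1.0]))
    centroid = dimer.coords[dimer.mask(atom_name="CA")].mean(axis=0)
    dimer.coords = rot.apply(dimer.coords - centroid)
    return dimer


def apply_mutation_A183I(dimer: Structure) -> Structure:
    """Apply the A183I steric perturbation to both chains of a dimer fixture.

    Residue 183 is renamed ILE and given a pseudo side-chain atom 1.5 Å
    beyond Cβ along the Cα→Cβ direction, standing in for the branched
    isoleucine side chain; it therefore carries a full carbon vdW radius
    (1.7 Å) in the clash model rather than the bare-point 1.25 Å share.
    If a pseudo-atom overlaps the partner monomer under those radii, the
    monomers are separated along the inter-helix direction by the smallest
    translation that restores the clash margin, so the interface can only
    open — in an iso-parallel fixture (which buries Ala183 at the
    interface) this strictly increases the T186-T186' separation.
    """
    out = dimer.copy()
    chains = out.chains()
    if len(chains) != 2:
        raise ContractError(f"expected a 2-chain dimer, got chains {chains}")
    new_atoms = []
    for ch in chains:
        m183 = out.mask(chain=ch, res_id=183)
        if not m183.any() or out.res_name[m183][0] != "ALA":
            found = out.res_name[m183][0] if m183.any() else "absent"
            raise ContractError(f"residue 183 in chain {ch} is {found}, not ALA")
        ca = out.atom_coord(ch, 183, "CA")
        cb = out.atom_coord(ch, 183, "CB")
        direction = (cb - ca) / np.linalg.norm(cb - ca)
        pseudo = cb + MUTANT_EXTENSION * direction
        out.res_name[m183] = "ILE"
        new_atoms.append((ch, pseudo))

    add = Structure(
        atom_name=np.array(["CG1"] * 2, dtype=object),
        element=np.array(["C"] * 2, dtype=object),
        res_name=np.array(["ILE"] * 2, dtype=object),
        res_id=np.array([183, 183]),
        chain_id=np.array([c for c, _ in new_atoms], dtype=object),
        coords=np.array([p for _, p in new_atoms]),
    )
    out = Structure.concat([out, add])
    # keep residue/atom grouping tidy: sort by chain, residue
    order = np.lexsort((np.arange(out.n_atoms), out.res_id,
                        out.chain_id.astype(str)))
    out = out.subset(order)
    out.title = dimer.title + " A183I"

    a_mask = out.mask(chain=chains[0])
    coords_a = out.coords[a_mask]
    coords_b = out.coords[~a_mask]
    radii_a = np.where(out.atom_name[a_mask] == "CG1",
                       PSEUDO_VDW_RADIUS, ATOM_CLASH_RADIUS)
    radii_b = np.where(out.atom_name[~a_mask] == "CG1",
                       PSEUDO_VDW_RADIUS, ATOM_CLASH_RADIUS)
    overlap = cdist(coords_a, coords_b) - (radii_a[:, None] + radii_b[None, :])
    if overlap.min() >= 0:
        return out

    # relieve the overlap by separating the monomers along the inter-helix
    # direction, by the smallest translation restoring the clash margin;
    # a rigid opening translation strictly increases every interface pair
    # distance, so the mutation can only loosen the dimer
    u = coords_b.mean(axis=0) - coords_a.mean(axis=0)
    u[2] = 0.0  # open laterally; the membrane normal stays z
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        raise FixtureError("monomer centroids coincide; cannot open interface")
    u /= norm
    thresholds = radii_a[:, None] + radii_b[None, :]

    def margin_at(t: float) -> float:
        return float((cdist(coords_a, coords_b + t * u) - thresholds).min())

    t_hi = 5.0
    while margin_at(t_hi) < 0 and t_hi < 50.0:
        t_hi *= 2.0
    if margin_at(t_hi) < 0:
        raise FixtureError("A183I opening translation could not relieve the clash")
    t_lo = 0.0
    for _ in range(60):  # bisection to ~1e-16 Å resolution
        mid = 0.5 * (t_lo + t_hi)
        if margin_at(mid) < 0:
            t_lo = mid
        else:
            t_hi = mid
    out.coords[~a_mask] = coords_b + t_hi * u
    return out



# ---------------------------------------------------------------------------
# membrane
# ---------------------------------------------------------------------------

def _largest_remainder_counts(fractions: dict, n: int) -> dict:
    items = sorted(fractions.items())  # deterministic order
    raw = {k: v * n for k, v in items}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = n - sum(counts.values())
    remainders = sorted(items, key=lambda kv: raw[kv[0]] - counts[kv[0]],
                        reverse=True)
    for k, _ in remainders[:short]:
        counts[k] += 1
    return counts


def build_membrane(composition: MembraneComposition | None = None,
                   n_lipids: int = 200, box_xy: float = 120.0,
                   seed: int = 0, min_separation: float = 6.0):
    """Place lipid headgroup beads on two leaflets.

    Type counts follow round(fraction × n) with largest-remainder
    correction; lateral positions are uniform without overlap (< 6 Å)
    within each leaflet; leaflet planes sit at z = ±19 Å.

    Returns ``(Structure, LipidTable)`` where the table is a DataFrame with
    columns lipid_id, type, leaflet, anionic, area_weight, atom_index.
    """
    composition = composition or MembraneComposition()
    if n_lipids % 2:
        raise PackingError(f"n_lipids must be even to split across leaflets, "
                           f"got {n_lipids}")
    counts = _largest_remainder_counts(composition.fractions, n_lipids)
    rng = np.random.default_rng(seed)

    # split each type across leaflets as evenly as possible
    leaflet_types: dict = {"upper": [], "lower": []}
    flip = 0
    for t in LIPID_TYPES:
        c = counts.get(t, 0)
        hi = c // 2 + (c % 2) * (flip % 2 == 0)
        leaflet_types["upper"] += [t] * hi
        leaflet_types["lower"] += [t] * (c - hi)
        if c % 2:
            flip += 1
    n_up = len(leaflet_types["upper"])
    n_lo = len(leaflet_types["lower"])
    if abs(n_up - n_lo) > 1:  # rebalance if odd counts piled up
        donor, recv = ("upper", "lower") if n_up > n_lo else ("lower", "upper")
        while abs(len(leaflet_types[donor]) - len(leaflet_types[recv])) > 1:
            leaflet_types[recv].append(leaflet_types[donor].pop())

    def _place(n_beads):
        pts = np.empty((0, 2))
        tries = 0
        while pts.shape[0] < n_beads:
            cand = rng.uniform(0.0, box_xy, size=2)
            if pts.size == 0 or np.min(
                np.linalg.norm(_min_image(pts - cand, box_xy), axis=1)
            ) >= min_separation:
                pts = np.vstack([pts, cand])
            tries += 1
            if tries > 200 * n_beads + 1000:
                raise PackingError(
                    f"could not place {n_beads} lipids with {min_separation} Å "
                    f"separation in a {box_xy} Å box"
                )
        return pts

    rows = []
    names, elements, res_names, res_ids, chain_ids, coords = [], [], [], [], [], []
    lipid_id = 0
    for leaflet, zsign, chain in (("upper", 1.0, "U"), ("lower", -1.0, "L")):
        types = leaflet_types[leaflet]
        rng.shuffle(types)
        xy = _place(len(types))
        for t, pos in zip(types, xy):
            lipid_id += 1
            rows.append({
                "lipid_id": lipid_id,
                "type": t,
                "leaflet": leaflet,
                "anionic": composition.is_anionic(t),
                "area_weight": 2 if t == "CL" else 1,
                "atom_index": len(names),
            })
            names.append("P")
            elements.append("P")
            res_names.append(t)
            res_ids.append(lipid_id)
            chain_ids.append(chain)
            coords.append([pos[0], pos[1], zsign * BILAYER_HALF_THICKNESS])

    membrane = Structure(
        atom_name=np.array(names, dtype=object),
        element=np.array(elements, dtype=object),
        res_name=np.array(res_names, dtype=object),
        res_id=np.array(res_ids, dtype=int),
        chain_id=np.array(chain_ids, dtype=object),
        coords=np.array(coords, dtype=float),
        title="synthetic bilayer (headgroup beads)",
    )
    table = pd.DataFrame(rows)
    return membrane, table


def _min_image(delta, box):
    return delta - box * np.round(delta / box)


# ---------------------------------------------------------------------------
# Brownian lipid dynamics
# ---------------------------------------------------------------------------

def simulate_lipid_trajectory(membrane: Structure, lipid_table: pd.DataFrame,
                              params: BrownianParams,
                              protein: Structure | None = None,
                              box_xy: float | None = None) -> Trajectory:
    """2D Brownian walk of lipid beads, optionally with protein enrichment.

    Each bead takes Gaussian lateral steps of per-dimension variance
    2·D·Δt, wrapped by the periodic box.  When ``enrichment_bias[type]`` is
    positive and a protein is supplied, a deterministic inward radial drift
    of that speed (Å/ps) is added outside a 10 Å core, so that type
    accumulates near the protein.  Identical seeds give identical output.

    Frame k is at time k·Δt; frame 0 is the starting configuration, so
    ``n_steps`` frames cover ``(n_steps - 1)`` random increments.
    """
    rng = np.random.default_rng(params.seed)
    if box_xy is None:
        box_xy = float(np.ceil(membrane.coords[:, :2].max()))
    topo_parts = [membrane]
    if protein is not None:
        topo_parts.append(protein)
    topo = Structure.concat(topo_parts)
    n_lip = membrane.n_atoms
    n_frames = int(params.n_steps)
    if n_frames < 1:
        raise ContractError("n_steps must be >= 1")

    types = lipid_table.sort_values("atom_index")["type"].to_numpy()
    sigma = np.array([
        np.sqrt(2.0 * params.diffusion.get(t, 0.0) * params.timestep)
        for t in types
    ])
    bias = np.array([params.enrichment_bias.get(t, 0.0) for t in types])
    center = (protein.coords[:, :2].mean(axis=0) if protein is not None
              else None)

    coords = np.empty((n_frames, topo.n_atoms, 3))
    frame = topo.coords.copy()
    coords[0] = frame
    xy = frame[:n_lip, :2].copy()
    for k in range(1, n_frames):
        steps = rng.normal(0.0, 1.0, size=(n_lip, 2)) * sigma[:, None]
        if center is not None and np.any(bias > 0):
            delta = _min_image(xy - center, box_xy)
            r = np.linalg.norm(delta, axis=1)
            outside = r > params.enrichment_core
            drift = np.zeros_like(delta)
            drift[outside] = (-delta[outside] / r[outside, None]
                              * (bias[outside, None] * params.timestep))
            steps += drift
        xy = (xy + steps) % box_xy
        frame[:n_lip, :2] = xy
        coords[k] = frame

    times = params.timestep * np.arange(n_frames)
    box = np.tile([box_xy, box_xy, 4.0 * BILAYER_HALF_THICKNESS],
                  (n_frames, 1))
    return Trajectory(topology=topo, coords=coords, times=times, box=box)


# ---------------------------------------------------------------------------
# CV-scheduled rotations
# ---------------------------------------------------------------------------

def simulate_cv_rotation(dimer: Structure, alpha_schedule, beta_schedule,
                         frame_interval_ps: float = 1.0) -> Trajectory:
    """Rotate each monomer about its own fitted principal axis.

    Frame k applies ``alpha_schedule[k]`` degrees to monomer 1 and
    ``beta_schedule[k]`` to monomer 2, right-handed about each axis's N→C
    direction through the monomer's Cα centroid — the ground-truth motion
    for the rotation-angle collective variables.
    """
    alpha_schedule = np.asarray(alpha_schedule, float)
    beta_schedule = np.asarray(beta_schedule, float)
    if alpha_schedule.shape != beta_schedule.shape:
        raise ContractError("schedules must have equal length")
    chains = dimer.chains()
    if len(chains) != 2:
        raise ContractError(f"expected a 2-chain dimer, got chains {chains}")
    axes = {c: geometry.fit_helix_axis(dimer, c) for c in chains}
    masks = {c: dimer.mask(chain=c) for c in chains}

    n = alpha_schedule.size
    coords = np.empty((n, dimer.n_atoms, 3))
    for k in range(n):
        frame = dimer.coords.copy()
        for c, ang in zip(chains, (alpha_schedule[k], beta_schedule[k])):
            ax = axes[c]
            rot = Rotation.from_rotvec(np.radians(ang) * ax.direction)
            frame[masks[c]] = rot.apply(frame[masks[c]] - ax.origin) + ax.origin
        coords[k] = frame
    span = coords.max(axis=(0, 1)) - coords.min(axis=(0, 1))
    box = np.tile(np.maximum(span + 10.0, 1.0), (n, 1))
    return Trajectory(topology=dimer, coords=coords,
                      times=frame_interval_ps * np.arange(n), box=box)


# ---------------------------------------------------------------------------
# analytic free-energy surfaces
# ---------------------------------------------------------------------------

def make_analytic_fes(basins, alpha_range=(-30.0, 120.0),
                      beta_range=(-30.0, 120.0), spacing: float = 2.0) -> FESGrid:
    """Sum-of-Gaussian-wells surface with ground truth in ``metadata``.

    ``basins`` is a list of dicts with keys ``center`` (α°, β°), ``depth``
    (kcal/mol, > 0) and ``width`` (degrees).  The energy is
    −Σ depth·exp(−|x − center|²/2·width²), shifted so the minimum is zero.
    Metadata records the basin parameters, the located true minima, and
    closed-form inter-basin saddle information for adjacent basin pairs.
    """
    basins = list(basins)
    if not basins:
        raise ContractError("basin list must be non-empty")
    alpha = np.arange(alpha_range[0], alpha_range[1] + spacing / 2, spacing)
    beta = np.arange(beta_range[0], beta_range[1] + spacing / 2, spacing)

    def energy_fn(a, b):
        e = np.zeros(np.broadcast(a, b).shape)
        for bs in basins:
            ca, cb = bs["center"]
            e -= bs["depth"] * np.exp(
                -((a - ca) ** 2 + (b - cb) ** 2) / (2.0 * bs["width"] ** 2)
            )
        return e

    aa, bb = np.meshgrid(alpha, beta, indexing="ij")
    energy = energy_fn(aa, bb)

    minima = [_refine_minimum(energy_fn, bs["center"]) for bs in basins]
    saddles = []
    for i in range(len(basins)):
        for j in range(i + 1, len(basins)):
            saddles.append(_line_saddle(energy_fn, minima[i], minima[j], (i, j)))

    grid = FESGrid(alpha_axis=alpha, beta_axis=beta, energy=energy)
    grid = grid.shift_minimum_to_zero()
    grid.metadata = {
        "basins": [dict(b) for b in basins],
        "true_minima": [list(m) + [float(energy_fn(*m) - grid.offset)]
                        for m in minima],
        "line_saddles": saddles,
        "offset": grid.offset,
    }
    return grid


def _refine_minimum(energy_fn, center):
    res = minimize(lambda x: float(energy_fn(x[0], x[1])), np.asarray(center, float),
                   method="Nelder-Mead", options={"xatol": 1e-6, "fatol": 1e-12})
    return float(res.x[0]), float(res.x[1])


def _line_saddle(energy_fn, m1, m2, pair):
    """Highest point of the straight line between two minima (the exact
    saddle when the basins share a width and the path is the symmetry axis)."""
    t = np.linspace(0.0, 1.0, 4001)
    a = m1[0] + t * (m2[0] - m1[0])
    b = m1[1] + t * (m2[1] - m1[1])
    e = energy_fn(a, b)
    k = int(np.argmax(e))
    return {"pair": list(pair), "alpha": float(a[k]), "beta": float(b[k]),
            "energy_unshifted": float(e[k])}


def two_basin_fes(separation: float = 60.0, depths=(8.0, 4.5),
                  width: float = 12.0, spacing: float = 2.0) -> FESGrid:
    """Two Gaussian wells along α, mirroring an intersected-vs-parallel
    free-energy gap (default depths differ by 3.5 kcal/mol)."""
    basins = [
        {"center": (0.0, 0.0), "depth": depths[0], "width": width},
        {"center": (separation, 0.0), "depth": depths[1], "width": width},
    ]
    pad = 3.0 * width
    return make_analytic_fes(
        basins, alpha_range=(-pad, separation + pad),
        beta_range=(-pad, pad), spacing=spacing,
    )


# canned six-state layout echoing the I-VI labelling of the dimer landscape:
# four low-energy states (I, II, IV, VI) and two shallow high-energy
# transition basins (III, V) between them
SIX_STATE_BASINS = (
    {"center": (0.0, 0.0), "depth": 12.0, "width": 12.0, "label": "I"},
    {"center": (30.0, 20.0), "depth": 9.5, "width": 10.0, "label": "II"},
    {"center": (45.0, 30.0), "depth": 6.0, "width": 5.0, "label": "III"},
    {"center": (60.0, 40.0), "depth": 9.0, "width": 9.0, "label": "IV"},
    {"center": (65.0, 65.0), "depth": 4.5, "width": 5.0, "label": "V"},
    {"center": (70.0, 90.0), "depth": 8.5, "width": 9.0, "label": "VI"},
)


def six_state_fes(spacing: float = 2.0) -> FESGrid:
    """Six-basin surface over (α, β) mimicking the I→VI dimer transition."""
    grid = make_analytic_fes(SIX_STATE_BASINS, alpha_range=(-30.0, 110.0),
                             beta_range=(-30.0, 130.0), spacing=spacing)
    grid.metadata["labels"] = [b["label"] for b in SIX_STATE_BASINS]
    return grid
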