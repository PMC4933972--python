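# Methods

This note documents the models, estimators and numerical choices behind
helixpack, in the order data flows through the pipeline.  Units are Å,
ps, kcal/mol and degrees unless stated otherwise.

## Ideal helix construction

Helices are built from backbone internal coordinates (bond lengths
N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231 Å; angles Cα–C–N 116.2°,
C–N–Cα 121.7°; ω = 180°) by natural extension of reference frames.  With
every bond angle fixed at its ideal value the reachable (rise, twist)
pairs form a narrow band that misses the textbook α-helix values
(1.5 Å, 100°) slightly, so the flexible N–Cα–C angle τ is freed as a
third unknown and (φ, ψ, τ) are solved by least squares; the default
helix uses φ = −63.6°, ψ = −41.4°, τ = 109.7°, comfortably inside the
helicity windows below.  Cβ atoms are placed with the standard
three-vector construction (L-chirality); glycine gets none.  The exact
screw axis of the finished helix (computed from the frame-to-frame
rotation of consecutive Cα triplets) is aligned with +z, so Cα z-spacing
equals the requested rise to machine precision, and the Cα radial
distance is scaled to the requested helix radius (default 2.3 Å).

The default sequence is Bax helix α9, TWQTVTIFVAGVLTASLTIWK, numbered
169–189.

## Helix-axis fitting

The axis direction is initialized as the principal eigenvector of the Cα
covariance and then refined by a cylinder fit: the direction is adjusted
so the variance of the Cα radial distances (after an algebraic circle fit
in the transverse plane) is minimal.  Raw PCA is biased by 1–2° on a
21-residue helix spanning a fractional number of turns (5.83 turns); the
refinement removes the bias exactly on ideal helices and materially
sharpens crossing-angle and rotation-CV readouts.  The sign is N→C and
the origin is the Cα centroid.

## Crossing angle

The crossing angle is the torsion-style angle between the two axis
directions about the inter-axis normal at closest approach, with axes
co-aligned first so |Ω| ≤ 90°.  The *reported* sign is flipped relative
to the crystallographic torsion convention: right-handed packing (the
i/i+4 interface stripes of GxxxA-type dimers; Ω_cryst < 0) is reported
positive, matching the common prose description of such dimers as
"right-handed ~40°".  Coincident parallel axes return 0 with a
degenerate-geometry warning.

## Rotation-angle collective variables (α, β)

For each monomer, the azimuth marker is the projection of axis→Cβ(175)
onto the plane perpendicular to the axis (I175 is mid-helix and present
in both monomers).  The CV is the right-handed angle (about the N→C
direction) from the *reference structure's* marker — transported onto the
current axis by the smallest rotation aligning the two axis directions —
to the current marker.  This makes the CV exactly zero at the reference,
exactly recover any rotation applied about the monomer's own axis, and
well-defined frame by frame.  The reference is the intersected fixture by
convention.  Because a global rotation of the whole dimer about z shifts
α and β equally, the absolute values depend on a gauge; the package pins
it by building every fixture with the interface stripe of monomer A
facing +x.

## Dimer fixtures by crosslink-constrained docking

Each interface state is declared by its disulfide-crosslinkable residue
pairs (intersected 175/179/183/187, parallel 171/178/182/185,
iso-parallel 172/186).  Monomer A is fixed; monomer B starts as A's
two-fold image across the inter-helix axis and is refined over 6
rigid-body degrees of freedom by L-BFGS from 32 random restarts.  The
objective per restart:

* squared deviations of the declared Cβ–Cβ′ distances from the canonical
  disulfide separation (3.8 Å) — *not* from zero: collapsing the pairs
  onto the steric boundary is unphysical and drags flanking pairs into
  the crosslinkable range;
* a quadratic steric penalty below per-atom clash radii (1.25 Å per
  ordinary heavy atom, reproducing a 2.5 Å pair cutoff, with a 0.2 Å
  cushion so optima do not sit on the boundary);
* an exclusion penalty keeping the *other* states' declared pairs beyond
  7.5 Å, so each fixture is identifiable by its crosslink pattern — the
  property the crosslinking experiments rest on;
* a weak Gaussian shape-complementarity reward around 4 Å contacts
  (helix dimers pack snugly);
* for states that bury a residue at the interface without crosslinking
  it — the iso-parallel state buries Ala183, which is why A183I disrupts
  it — a two-stage continuation adds a restraint holding that residue's
  Cβ at carbon–carbon vdW contact (3.4 Å) with the partner while a
  stiffened exclusion penalty holds the pattern.

Feasibility is checked exactly (declared pairs ≤ 7 Å, no steric
overlap); among feasible restarts the fewest pattern leaks win, then the
best objective.  The finished dimer is oriented with the mean helix axis
along +z (membrane normal) and centroid at the origin.  The crossing
angles are emergent: the intersected state comes out right-handed near
+43°, the parallel state near +3°, the iso-parallel near −12°.

**A183I.**  Residue 183 is renamed ILE and given a pseudo side-chain
atom 1.5 Å beyond Cβ along Cα→Cβ, standing in for the branched Ile
methyls; it carries a full carbon vdW radius (1.7 Å) in the clash model.
If the pseudo-atom overlaps the partner under those radii, the monomers
are separated along the inter-helix direction by the smallest translation
(bisection) restoring the margin.  A rigid opening translation strictly
increases every interface pair distance, so the mutation can only loosen
the dimer; in the iso-parallel fixture it pushes T186–T186′ from ~6.8 Å
to just past the 7 Å crosslinkable limit, mirroring the loss of T186C
crosslinking observed experimentally.

## Helicity

A residue is α-helical when φ ∈ [−100°, −30°] and ψ ∈ [−67°, −7°];
the percentage is over residues with both dihedrals defined (terminal
residues excluded).  Dihedral windows rather than hydrogen-bond DSSP:
the structures here may lack amide hydrogens, and the windows classify
canonical helices with margin.

## Synthetic membrane and lipid dynamics

Lipids are single headgroup beads at z = ±19 Å: every in-scope analysis
(density, stoichiometry, MSD, polar-contact surrogate) uses headgroup
positions, so acyl tails are not modelled; cardiolipin's larger footprint
enters as its double area weight, not as geometry.  Type counts follow
round(fraction × n) with largest-remainder correction (the default MOM
composition gives exactly 465/284/89/89/73 at n = 1000); lateral
placement is uniform with a 6 Å minimum periodic separation, split evenly
across leaflets.

Dynamics are 2D Brownian: per stored frame (default Δt = 10 ps) each bead
takes Gaussian steps of per-dimension variance 2DΔt, wrapped by the
periodic box.  Default D values are 0.03–0.05 Å²/ps (3–5 × 10⁻⁶ cm²/s),
the order of magnitude of lipid lateral diffusion in fluid bilayers.
Protein-proximity enrichment adds a deterministic inward drift (default
0.02 Å/ps for CL only) outside a 10 Å core; the drift–diffusion balance
concentrates the biased type within a few tens of Å of the protein.  All
randomness flows through one explicit seed; identical seeds give
bit-identical trajectories.

## Centering, density, stoichiometry, diffusion

Frames are shifted so the protein centroid sits at the box centre
(removing overall drift), then rewrapped by minimal image; unwrapped
coordinates accumulate minimal-image inter-frame displacements so no
box-length jumps remain.  Density maps are time-averaged lateral
histograms per lipid type (both leaflets projected); total map mass
equals the mean in-box count.

Stoichiometry counts a lipid inside when its headgroup's lateral distance
to the dimer centroid is ≤ 20 Å (2D disc, following the "area with a
radial cutoff" reading).  Counts are time-averaged per window, reported
mean ± SD across windows (default: three 10-ns windows covering the last
30 ns).  Anionic/neutral percentages are area-weighted (CL × 2), computed
per leaflet and averaged over leaflets populated in the disc; per-leaflet
tables are also emitted since the single-leaflet-vs-both question is
underdetermined.

Lateral diffusion uses the 2D Einstein relation.  Per molecule, the
time-origin-averaged MSD over lag τ is fitted by through-origin least
squares on lags in 10–50% of the window (short lags are noise-dominated,
long lags statistics-poor), and D = slope/4.  The through-origin form is
the Einstein prediction and doubles as the linearity diagnostic: its R²
flags ballistic (MSD ∝ τ²) contamination below 0.9, which a fit with a
free intercept cannot (τ² correlates > 0.99 with τ on a narrow band).
Per-type means and SDs are over molecules, reported separately per window
for convergence checks; 1 Å²/ps = 10⁻⁴ cm²/s.

## Polar contacts

Polar atoms are N, O and P by element (protein backbone and side-chain
N/O; lipid beads are P).  A contact exists below 3.6 Å.  Per-frame
booleans merge into maximal events with zero gap tolerance (a 1-frame
tolerance is available but off — reproducibility over smoothing); frame k
represents [t, t+Δt), so summed event durations over the trajectory
length equal occupancy exactly.  A pair is *transient* when its longest
event is < 1 ns, otherwise *frequent* (the complement of the stated
transient rule).  With bead lipids the bead is the sole lipid polar site.
The inter-monomer residue contact map of the reduced fixtures uses a
relaxed cutoff in the examples, since backbone N/O across a Cβ-packed
interface cannot approach 3.6 Å without side chains.

## Free-energy landscapes

Grids F(α, β) are plain-text `alpha beta energy` rows; on load the global
minimum is shifted to zero (offset retained).  States are local minima on
the 8-connected grid with steepest-descent basin assignment; basins whose
escape depth is below `min_depth` (default 0.5 kcal/mol) merge into the
neighbor across their lowest boundary.  Labels I, II, … follow ascending
α+β of the centers (the transition-coordinate ordering).  Angle axes are
treated as non-periodic by default (the maps of interest span a bounded
range); a periodic flag enables wrap-around adjacency.

The block-minimum path tiles the grid into 20° × 20° blocks (configurable;
the last block absorbs the remainder), takes each block's lowest cell as
its candidate point, and finds the chain of candidates between the start
and end blocks (8-connected block moves) minimizing the *maximum* energy
en route — ties broken by total energy, then block index, making the
result deterministic.  A move's cost includes the grid cells on the
straight segment between the two candidate cells; without that, a coarse
path could tunnel under ridges and beat the cell-level optimum, breaking
refinement dominance.  The independent oracle is a cell-resolution
minimax (shortest-bottleneck) Dijkstra search.  All reported path
energies are grid values at cells; nothing is interpolated.

Barriers between consecutive visited states are the maximum path energy
between the basin anchors minus the origin center energy; the endpoint ΔG
is the difference of the two center energies.

Analytic test surfaces are sums of Gaussian wells with recorded ground
truth (refined minima, straight-line saddles between centers — exact for
equal-width pairs by symmetry).  The canned six-basin layout places four
major states at the nominal transition coordinates I (0,0), II (30,20),
IV (60,40), VI (70,90) with two shallow transition basins III and V
between them; widths and depths are chosen so all six are detectable and
the minimax corridor runs I→II→IV→VI.

## What the generator does and does not emulate

The synthetic data reproduces the *structure* of the analyses — crosslink
patterns, packing handedness, Brownian statistics, landscape topology —
with known ground truth, at desk scale (hundreds of lipids, thousands of
frames, tens of nanoseconds).  It does not emulate: side chains beyond
Cβ, helix bending or fraying (fixtures are rigid ideal helices, so
helicity is always 100% and backbone RMSD between time points is 0),
solvent, membrane deformation, or force-field energetics.  Two
consequences matter for interpretation.  First, trajectory-derived
observables of the real system (absolute stoichiometries, helicity decay,
landscape barrier heights) are not reproduced — only the estimators are
verified, against constructions with known answers.  Second, the
rotation-CV separation between the intersected and parallel fixtures
measures ≈ (105°, 94°), not the ≈ (70°, 90°) of the published full
side-chain models: with ideal helices and Cβ-level interfaces, the
azimuthal separation of the two crosslink stripes is ~110°, and the
Cβ-distance objective has no information to land closer to the full-atom
value.  The fixtures are constraint-compatible approximations of the
interface states, not replicas of undeposited coordinates.

## Numerical defaults

| parameter | default | note |
|---|---|---|
| crosslink Cβ–Cβ′ threshold | 7.0 Å | disulfide surrogate; Gly → Cα |
| disulfide Cβ–Cβ′ target | 3.8 Å | docking objective |
| heavy-atom clash cutoff | 2.5 Å | 1.25 Å per-atom radii |
| mutant pseudo-atom radius | 1.7 Å | carbon vdW |
| polar-contact cutoff | 3.6 Å | N/O/P atoms only |
| transient boundary | 1 ns | on the longest event |
| radial cutoff | 20 Å | lateral (2D) disc |
| analysis windows | three 10-ns, last 30 ns | mean ± SD across windows |
| MSD fit range | 10–50% of window | through-origin fit |
| path blocks | 20° × 20° | minimax, total-energy tie-break |
| basin merge depth | 0.5 kcal/mol | escape-depth criterion |
| docking restarts | 32 | seeded, best feasible kept |
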