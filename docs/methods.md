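# Methods

## The model

A gapped DNA duplex — two stiff double-stranded arms of 48 bp joined by a
flexible 20-base single-stranded spacer — is coarse-grained as a
*chain-stick*: two rigid hard cylinders of length `L = 16 nm` (0.33 nm per
base pair) and effective diameter `D = 3 nm` (the steric 2 nm plus
electrostatic repulsion at high salt), connected by a tether.  Each
cylinder carries two sites on its symmetry axis:

* **site A** (blunt end) at `L/2 + 0.15 D/2 = 8.225 nm` from the centre of
  mass.  A sites of *distinct* cylinders interact through an attractive
  square well of range `delta = 0.25 D = 0.75 nm` and depth
  `beta u0 = 8.06` kT, representing hydrophobic blunt-end stacking.
* **site B** (tethered end) at `-(L/2 + sigma/2) = -11.15 nm`.  The two B
  sites of one molecule are joined by a pure distance constraint: zero
  energy when closer than `sigma`, infinite otherwise.  `sigma = 6.3 nm`
  is half the 12.6 nm contour length of the 20-base spacer (0.63 nm per
  base); the molecule bends freely at no energetic cost.

The cylinder axis points from the tethered (B) end to the blunt (A) end.
The *folding angle* `theta_f` is the angle between the two axes of one
molecule: 0° is the folded hairpin (both blunt ends on one side, which
self-protects the sticky A sites), 180° the collinear unfolded rod, whose
end-to-end span `2L + sigma = 38.3 nm` equals the contour length of the
fully paired reference duplex.  The folding fraction `eta_f` is the
fraction of molecules with `theta_f < 45°`; for orientationally uniform
arms it equals `(1 - cos 45°)/2 = 0.146`.

Design choices worth stating explicitly:

* The well is implemented with *negative* energy `-u0` inside the range
  (the printed coupling is an attraction strength); bonded pairs lower the
  energy.
* A–A interactions between the two arms of the *same* molecule are
  included ("distinct cylinders" read literally); a flag disables them.
* The `sigma` sentence admits two parsings (6.3 or 12.6 nm).  We use
  6.3 nm — with it, `2L + sigma` reproduces the 38.3 nm reference-duplex
  contour length — and expose `sigma` in the configuration.

## Hard-core overlap test

Cylinders are convex, so the exact boolean intersection is computed by a
staged test: (1) bounding-sphere rejection at centre distance
`sqrt(L² + D²)`; (2) if the axis segments are at least `D` apart there is
no overlap (a cylinder is contained in its spherocylinder); (3) if the
segment closest points are interior to both segments by at least `D/2`
and closer than `D`, their midpoint lies inside both bodies — overlap;
(4) remaining end-dominated contacts (rim–rim, rim–face, face–face) are
decided by a GJK query on the two convex bodies.  Grazing contacts within
`1e-9 nm` count as non-overlapping (measure-zero events are irrelevant to
the sampling).  The kernel is refereed by an independent point-sampling
oracle: uniform points in one cylinder tested for containment in the
other; on 10⁴ random oblique pairs every overlap with volume above
`1e-3 v0` is flagged.  A `spherocylinder` overlap model is available as a
configuration switch for sensitivity studies.

## Constant-pressure Monte Carlo

States hold `N` molecules (2N cylinders) in an orthorhombic periodic box
whose three edges fluctuate independently.  One sweep is `N`
single-cylinder attempts (random displacement, or rotation about the
cylinder's own B site, which leaves the tether untouched), `max(1, N/4)`
rigid-molecule attempts, and three volume attempts (one per axis).
Volume moves propose `ln L_axis` uniformly and rescale the centroids of
*scaling units* affinely, keeping internal coordinates rigid; acceptance
is `min(1, exp(-dU - beta P dV + (N_units + 1) ln(V'/V)))`.

In cluster mode (default) the scaling units are the connected components
of the A–A bond graph, so compression cannot tear bonded stacks apart.
Any proposal that changes the bond graph is rejected outright — creation
*and* breaking; rejecting only creations would violate detailed balance,
since the reverse of an accepted bond-breaking expansion would be a
rejected bond-creating compression.  Because every existing bond joins
molecules of one rigidly co-moving cluster, bonds cannot break under the
scaling, and a changed total bond count detects any graph change; for
graph-preserving proposals `dU = 0` exactly.  With cluster moves off the
units are whole molecules and `dU` enters the Metropolis rule as usual.
The sampler is validated against the interaction-free closed forms
`<V> = (N+1)/(beta P)` and `Var V = (N+1)/(beta P)²`, and against the
`sin(theta)` folding-angle density on a fixed box.

Box edges are never allowed below `2 sqrt(L² + D²) ≈ 32.6 nm` while hard
cores are on: below that, a pair can interact with two periodic images of
the same particle and nearest-image-only scans become unsound.  Volume
proposals crossing the floor are rejected and initial states below it are
refused.  Without hard cores the remaining interactions (well range
0.75 nm, tether 6.3 nm) cannot double-count images in any sensible box
and no floor is applied — a floor would bias the shape ensemble of the
ideal gas, whose box shape performs a free logarithmic walk.

Bookkeeping details: the total bond count is tracked incrementally and a
full recomputation (energy, overlaps, tethers) runs every
`recheck_every = 10⁴` sweeps, aborting on any drift; duplexes are
re-imaged at those checkpoints so each molecule's unwrapped internal
geometry equals its minimum-image geometry (an affine rescaling would
otherwise tear a molecule whose stored coordinates straddle the
boundary).  Move sizes are autotuned toward ~35% acceptance during
equilibration only.  All randomness flows from one integer seed; a run is
bit-reproducible.

Initial configurations: a *crystal* builder (fully folded molecules, arms
side by side at lateral contact, all axes +z, on an nx × ny × nz grid
whose spacings are inflated above hard contact to reach a target packing
fraction with the most cubic box the lattice allows) and an *isotropic*
builder (random sequential insertion at a target mass concentration with
uniform axes and tether-uniform conformations).  Concentrations use a
molar mass of 65.7 kg/mol (212 nucleotides at 310 g/mol).

### Scaled problem sizes

The reference study conditions (840 molecules, several million sweeps)
are kept as a documented configuration but are not what the test-suite
runs.  The packaged runs use `N = 128` molecules with 10⁵ equilibration
plus 10⁵ production sweeps for the layered state point
(`beta P v0 = 4.1`, folded-crystal start) in the acceptance script, and
shorter 1–2 × 10⁴-sweep versions of the same state points in the test
suite; the isotropic point (`beta P v0 = 0.5`) starts from a dilute
random configuration.  At these sizes the layered phase shows the same
signatures as at full scale — high folding fraction, nematic order
S ≈ 0.95, ~18 nm monolayer period in `g(0, y, z)` — but box-shape
fluctuations are larger, only two to four layers fit in the box, and
melting from the folded crystal is incomplete on this schedule, so the
production-average folding fraction stays near 1 rather than relaxing to
the large-system smectic value of 0.4–0.5.  Passing tests demonstrate
the sampler and observables are correct at these sizes, not that the
full-scale phase diagram is quantitatively converged.

## Observables

* **Nematic order**: largest eigenvalue / eigenvector of
  `Q = (3 <u u> - I)/2` over all 2N cylinder axes (sign-free); a
  per-molecule bisector variant exists for comparison.
* **Pair correlations**: `g(0, y, z)` and `g(x, y, 0)` on molecule
  centroids in the director frame, normalized by the ideal-gas
  expectation per bin (slab half-thickness = bin width).
* **Layer spacing**: `d = 2 pi / q*` with `q*` maximizing the 1D
  structure factor over box-commensurate wavevectors along the box axis
  nearest the director.  The background is the *median* of the remaining
  spectrum (a sharp layer lattice feeds several harmonics, contaminating
  a mean) plus a small extreme-value floor so an ideal gas does not
  trigger false detections; among near-equal harmonics the fundamental is
  preferred.  Returns "absent" for featureless states.
* **Equation of state**: per-pressure block averages with block-bootstrap
  standard errors; heuristic phase labels (I for S < 0.3; Sm-fA for
  ordered layered states; K when the in-plane structure factor shows at
  least three sharp harmonics).  The labels are conveniences with
  documented thresholds, not claims.

## Excluded volumes

Pair excluded volumes of rigid two-cylinder conformers are estimated by
hit-or-miss integration: uniform displacements in a bounding box sized
from the conformer extents (containment is asserted by requiring zero
hits in the outer 5% shell), a hit being any hard overlap.  Alignment
modes: `fully_fixed`, `parallel_azimuth` (axes along a common director,
independent uniform azimuths — the strongly aligned smectic limit) and
`isotropic`.  The folded reference places the arms side by side at
lateral contact with tethered ends aligned; the unfolded reference is
collinear with coincident B sites (span 38.3 nm).  The integrator
reproduces the parallel-cylinder closed form `2 pi D² L = 904.8 nm³`
within one standard error at 10⁶ samples.

A caution on the unfolded/folded ratio: under perfect axis alignment the
two effects nearly cancel — the folded dimer excludes more area laterally,
the unfolded rod excludes more range axially — and the azimuth-averaged
ratio computes to ≈ 0.99 (a closed-form 2D estimate, excluded area times
axial overlap range, gives the same number).  Full isotropic averaging
gives ≈ 2.0.  Intermediate orientational ensembles interpolate between
these; the packaged default remains the declared `parallel_azimuth`
convention and both numbers are reported by the tests rather than tuned.

## SAXS analysis

Peak finding uses rolling-median background subtraction, prominence
filtering (default 12 × the median absolute deviation — roughly an 8-sigma
floor against pure noise) and parabolic sub-bin refinement; intensities
are background-subtracted trapezoidal integrals over ±3 widths.  Lamellar
indexing fits the least-squares ladder `q_h = h q*` (the first peak tried
as order 1–3, orders capped at 8 — uncapped, any positions fit some tall
ladder), giving `d = 2 pi / q*` identically.  The hexagonal interaxial
relation is `d = 4 pi / (sqrt(3) q)`.

Electron-density reconstruction:
`rho(z) = sum_h phi_h sqrt(h^e I_h) cos(2 pi h z / d)` with powder
Lorentz exponent `e = 2` (unoriented capillaries; configurable 0/1/2) and
centrosymmetric phases `phi_h = ±1`.  `auto` mode enumerates all `2^H`
sign vectors and ranks them by minimal total variation; note a
centrosymmetric profile is only defined up to global sign and a
half-period origin shift (factor `(-1)^h`), so the top-ranked vector may
be the shifted twin of the generator's.  Slab widths are measured by
least-squares fitting a two-slab density truncated to the *same* Fourier
orders as the reconstruction — a level-crossing estimate on a 4-order
series is biased by several nm by Gibbs ringing, while the equally
truncated fit is exact in the noise-free round trip; the crossing
estimator is retained as `method="crossings"`.

The synthetic generator produces the analytic two-slab profile (Fourier
coefficients `F_h = drho · d sin(pi h w/d) / (pi h)`, Lorentz-weighted,
Gaussian-broadened, smooth background, optional noise) with ground truth
attached; defaults match the experimental layered phase (period 34 nm,
31 nm duplex slab, 3 nm spacer gap, four orders).  It emulates peak
positions, relative intensities and noise, but not instrumental
resolution smearing, absolute scale, or the broad in-plane liquid peak —
round-trip tests therefore validate the indexing/reconstruction
machinery, not detector-specific corrections.  Measured lamellar
intensities for the real system are not published, so the synthetic
round trip stands in for them.

## Known limitations

* Nearest-image scans bound the box from below (32.6 nm with hard
  cores); very small systems at high packing are refused rather than
  silently mis-sampled.
* Cluster volume moves reject bond-graph changes, so volume relaxation
  slows in heavily bonded states; single-particle moves keep the chain
  ergodic.
* Scaled-down runs from the folded crystal do not fully melt; folding
  fractions at the layered state point are upper ends of the
  large-system range.
* Phase labels and the layering detector are heuristics with documented
  thresholds.
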