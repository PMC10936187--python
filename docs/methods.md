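# Methods

## Model and assumptions

`n2oflux` models steady-state diffusion of N₂O between two spherical cells
in water. The producer's surface is held at relative concentration 1, the
consumer's at 0 (a perfect sink), and the concentration field `C` obeys
Laplace's equation in the fluid. All concentrations are *relative*: the
absolute surface concentration of a single producing cell is unknown, so
only ratios of uptake rates are meaningful, and the diffusion coefficient
`D` defaults to 1 (dimensionless-relative). Lengths are micrometres
throughout. The consumer's uptake is the surface-integrated diffusive flux
`U = ∮ D ∇C · dA`; the volume-normalized uptake divides by the consumer
volume `(4/3)πr³`, reflecting that a cell's resource requirement scales
with its size.

Assumptions worth keeping in mind:

* spheres, rigid, non-motile; no advection, no reaction in the fluid;
* the consumer is a perfect absorber (Dirichlet 0), not a Michaelis–Menten
  surface — uptake values are upper bounds on transport limitation;
* steady state: boundary layers around µm-sized cells equilibrate in
  milliseconds, far faster than cell growth or movement.

## Analytic engine: iterated image charges

By the electrostatic analogy (concentration ↔ potential, flux ↔ 4πD ×
charge), the two-sphere Dirichlet problem in an unbounded medium is solved
with Kelvin images. A seed charge `q₀ = R` at the producer center puts its
isolated surface at exactly 1; a charge `q` at distance `s` from the center
of a grounded sphere of radius `a` is cancelled on that sphere by an image
`−aq/s` at `a²/s` from its center; alternating images between the spheres
converge geometrically for any positive gap. The consumer's total induced
charge `Q_c < 0` gives `U = 4πD|Q_c|`. Iteration stops when the latest
image is below `tolerance` (default 10⁻¹⁰ relative) of its sphere's running
total; hitting `max_iterations` (default 10⁵) returns a result flagged
non-converged, which downstream refuses to aggregate.

The engine is cross-checked in the test suite against Maxwell's closed-form
sinh series for the mutual capacitance of two spheres (an independent
derivation of the same quantity), against the far-field limit
`U → 4πD·rR/L`, and against the exact properties of the problem:
reciprocity under radius exchange, linearity in `D`, exact scale invariance
(lengths ×k ⇒ uptake ×k, volume-normalized ×k⁻²), and monotone decay with
separation.

### The attached (d = 0) convention

The mutual flux between touching spheres held at different concentrations
diverges logarithmically in the gap (the integrand `~1/ρ²` over the
near-contact annulus), so "attached uptake" is finite only under a
regularization. The package defines it by solving at gaps
`ε ∈ {10⁻³, 5·10⁻⁴, 2.5·10⁻⁴} × min(R, r)` and applying two levels of
fixed-order Richardson extrapolation (assumed order 1 across the halving
sequence). Order-*estimating* extrapolation is degenerate here — successive
increments of a logarithmic sequence are nearly equal, so the estimated
order is ~0 and the extrapolation blows up — whereas the fixed-order form
is stable and amounts to evaluating the series at an effective gap roughly
ten times smaller than the finest regularized one. Any simulation of the
contact geometry (including finite-element meshes) embeds an analogous
finite cutoff; ours is explicit, deterministic and documented. Attached
values are therefore convention-dependent in absolute terms, while ratios
between attached scenarios, and trends across the sweep, are robust.

## Finite-difference engine

The FD engine re-creates the boxed formulation directly: a uniform grid
over the 20 µm cube, nodes classified by a center-in-sphere test (ties at
tangency go to the producer), Dirichlet values on sphere nodes and on the
grounded walls (`wall_mode="no_flux"` swaps the walls for mirror-symmetry
Neumann conditions to expose the sensitivity). A sphere must span at least
1.5 grid cells and contain a node, else the grid is rejected. The 7-point
linear system is symmetric positive definite and is solved with conjugate
gradients to relative residual 10⁻⁸, preconditioned (grounded walls) by an
exact DST-I fast-Poisson inverse of the unobstructed box Laplacian —
iteration counts stay near 10 even on 200³ grids. The discrete maximum
principle is asserted on every solution.

Consumer uptake is the net flux through a closed axis-aligned box of grid
faces around the consumer; by the discrete divergence theorem this equals
the flux summed over the consumer's own voxel faces (both are reported, and
their agreement is tested). For near-contact geometries no axis-aligned box
separates the spheres, so the default mode falls back to the surface sum.

Voxelization incurs a first-order stair-casing error that biases uptake
low (the voxel ball's effective capacitance radius is below the true
radius). `refine_and_extrapolate` removes most of it by Richardson
extrapolation over grid spacings, assuming first order and reporting the
observed order and any non-monotonicity.

### Box effect and the validation subset

The analytic engine assumes an unbounded medium; the FD engine grounds the
cube. Measured with the FD engine itself, grounded walls *reduce* the
consumer's uptake by roughly `(r + d) / W`, with `W ≈ 10 µm` the distance
to the wall — the walls truncate the producer's boundary layer, lowering
the concentration the consumer sees. At a 2 µm gap this is a ~30% model
difference; it is physics, not solver error, and it is why ratio-type
statistics are always computed within one engine, never mixed.

Cross-engine validation therefore runs on scale replicas chosen where the
combined wall screening (< ~10%, i.e. `r + d ≤ 1 µm`) and residual
stair-casing stay within 15%: nine replicas in the 20 µm box with consumer
radii ≥ 4 cells on the finest grid, gaps ≥ 2 cells, radius ratios spanning
0.125–1 and relative gaps `d/(R+r)` spanning 0.056–0.5. By exact scale
invariance each replica certifies every geometrically similar scenario, so
this covers the sweep's size-ratio range without resolving a 0.05 µm
consumer in a 20 µm box (which would need ~10⁹ nodes). Two spacings
(0.25, 0.125 µm) suffice for most replicas; the two largest relative gaps
use a third (0.0625 µm). Measured relative differences after extrapolation
are 7–12%, and the per-spacing discrepancy shrinks monotonically under
refinement. Widely separated pairs are deliberately outside this subset:
there the comparison would measure the wall convention, which is instead
quantified directly (grounded vs no-flux, box-size sensitivity).

## The sweep as synthetic study conditions

The default grid — consumer radii {0.05, 0.1, 0.2, 0.35, 0.5} µm, producer
radii {0.5, 0.75, 1.0, 1.5} µm, gaps {0, 0.1, 0.5, 1, 2} µm, 20 µm domain —
is a reconstruction: it is constrained to 100 scenarios, 20 size
combinations per gap, gaps including 0, 0.1 and 2 µm, producer radii
spanning a threefold range, and consumer-to-producer radius ratios spanning
roughly 0.1–1, which are the published structural facts about the original
parameter table. It is tagged `default-reconstruction` and every axis is
overridable (`build_custom_sweep`, YAML config). The summary statistics are
deterministic simulation summaries over this fixed grid — the spread per
gap is the spread across size combinations (reported as mean ± 1 and 2
s.d., matching a box-and-whisker presentation), not sampling error — so the
package reports no inferential statistics. What passing tests show is that
the *model* reproduces the published effect sizes on a faithful
reconstruction of the conditions; they cannot certify the original grid's
exact values.

Headline definitions (`summarize`):

* reductions are `1 − U(gap)/U(0)` per size combination, averaged across
  the 20 combinations (max also reported for the 2 µm comparison, since the
  published phrasing does not pin the aggregation);
* the fold change maps the ratio endpoints ~0.1 and ~1 to the nearest grid
  ratios within 30% relative tolerance and averages over producers
  admitting both — on the default grid that is the 0.5 µm producer with
  consumers 0.05 and 0.5 µm, and the pairs used are recorded in the report.

## Protein screening rules

* Length filter: keep the closed interval [200, 800] aa ("under 200 and
  over 800 removed" read strictly); bounds configurable, because reported
  nosZ-like proteins themselves span 56–617 aa.
* Cu_A motif: every window with C at position 1, C at 5 and H at 9
  (`C-X₃-C-X₃-H`, X = any residue including X); overlapping hits all
  reported, 1-based inclusive coordinates. The scanner is property-tested
  against a brute-force window oracle.
* Cu_Z signature: a plain histidine count with threshold (default 5 per the
  cupredoxin-like upstream protein; 7 selects the canonical NosZ
  criterion). No positional pattern is invented — none is published.
* FASTA input is read by a small line-oriented reader so that malformed
  headers and illegal residues fail with line numbers; it is cross-checked
  against Bio.SeqIO on valid input.

## Numerical choices and degenerate inputs

* Image series: tolerance 10⁻¹⁰, max 10⁵ iterations; near-contact worst
  case in the sweep converges in ~2,000 iterations.
* FD: residual 10⁻⁸, x-fastest deterministic ordering, maximum-principle
  slack 10⁻⁸; duplicate extrapolation spacings and unresolved spheres are
  errors; non-monotone refinement sets a warning flag rather than failing.
* Sweeps reject empty axes, geometry that violates the clearance rule
  `R + r + d + max(R, r) < side/2` (named offending triple), and duplicate
  scenario ids; non-converged rows are flagged and aggregation refuses to
  proceed over them.
* Everything is deterministic; reruns produce byte-identical CSV/JSON.

## Problem sizes

The default sweep (100 scenarios, analytic) runs in under a second. The FD
validation subset solves nineteen grids up to 321³ nodes and takes about
four minutes on one CPU; unit tests use 10 µm boxes at 41³–81³ nodes.

## Known limitations

* Attached absolute uptake is regularization-defined (see above).
* The analytic engine ignores the domain walls; FD quantifies the
  difference but the production sweep statistics are infinite-medium.
* Perfect-sink consumer surfaces overstate uptake for low-affinity
  enzymes; no reactive boundary conditions are implemented.
* The default grid is a reconstruction, not the original parameter table;
  statistics carry that caveat explicitly via the provenance tag.
* Fold-change endpoints depend on the grid's available ratios; the report
  declares which pairs were used.
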