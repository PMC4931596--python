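# Methods

`rodconfine` simulates hard spherocylindrical rods confined between two
parallel plates inside disk- or annulus-shaped side walls, and analyses
the orientational patterns that strong confinement produces. This note
records the model, the algorithms, the numerical choices, and what the
synthetic-data path does and does not demonstrate.

## Model and units

Particles are hard, rigid spherocylinders: a cylinder of axis length
`L` capped by hemispheres of diameter `D`. `D = 1` is the internal unit
of length. Two rods interact only through excluded volume: they overlap
iff the minimum distance between their axis segments is strictly below
`D` (tangency at exactly `D` is allowed — the convention is measure-zero
and strictness is cheapest). The chamber is a disk (`R_inner = 0`) or an
annulus, closed above and below by plates a distance `H` apart, with
`D <= H < L` so rods cannot stand upright. Wall feasibility is exact:
both axis endpoints clear the plates and the outer wall by `D/2`
(sufficient by convexity for the outer wall), and the axis segment keeps
in-plane distance `>= R_inner + D/2` from the chamber axis. A
consequence of hard-core exclusion at a curved wall is that a rod's
centre stays more than `D/2` (and for non-tangential poses up to
several `D`) from the side walls; no additional centre-of-mass
constraint is imposed beyond the hard-core geometry.

The lateral confinement strength is `kappa = L / (2 R_outer)`; the
reference chamber `R_outer = 40 D` with `L/D = 15–25` gives
`kappa = 0.19–0.31`. Packing fractions are volume fractions:
`N = round(eta * V_chamber / v_rod)` with
`v_rod = pi D^2 L / 4 + pi D^3 / 6`; the realized `eta` after rounding
is recomputed and logged.

## Monte Carlo

Sampling is plain Metropolis for hard particles. One move picks a rod
uniformly at random, displaces its centre uniformly in a cube of side
`2 delta_t`, and rotates its axis by a uniform angle up to `delta_r`
about a random axis (in the strictly-2D mode, `H = D`, the centre stays
on the mid-plane and rotations are in-plane). The move is accepted iff
the displaced rod overlaps nothing. One sweep is `N` attempted moves.
Overlap candidates come from an in-plane cell list with cell edge
`>= L + D`, which makes the 3x3 neighbourhood provably sufficient; a
centre-distance prefilter (`|r_ij| < L + D`) rejects most candidates
before the exact segment-distance test. Step sizes default to values
tuned toward a 30–40% acceptance rate during initialization and are
frozen for production (tuning during production would break detailed
balance). All randomness in a run derives from a single seed via
`numpy.random.SeedSequence`; runs are bit-reproducible.

### Initialization

The part of the pipeline that took real design: a valid configuration
at `eta = 0.2` cannot be rejection-sampled directly at full diameter.
The protocol is shrink–insert–inflate:

1. Insert `N` rods at diameter `0.3 D` by rejection sampling (random
   positions and orientations). Wall clearances are enforced at the
   *full* diameter from the start, so they never tighten later.
2. Grow the diameter in stages (2% multiplicative, capped at `+0.01 D`,
   and `+0.005 D` above `0.95 D`). After each growth step, overlap
   depths are relaxed by sweeps that accept any move not increasing the
   rod's total violation depth measured at the target diameter; for
   rods that remain wedged, rescue rounds combine (a) re-insertion of
   violators elsewhere with orientations copied from their nearest
   neighbour (a random orientation has essentially zero insertion
   probability inside an ordered nematic), (b) a violator-only thermal
   kick (Metropolis on the violation depth, escalating temperature),
   and (c) greedy re-descent. Relaxation proposals span two decades of
   amplitude so tightly caged rods still receive acceptable fine moves.
3. Between stages, run ordinary hard-core MC at the current (valid)
   diameter — 150 sweeps per stage in the diameter window `>= 0.5 D`.
   This step is essential for long rods: packing at full diameter
   requires local nematic order, and order only develops under real
   sampling, not under violation-driven descent.

Initialization fails (with the achieved packing fraction reported) when
the rescue rounds stop making headway — the jamming signature, reached
quickly for targets such as `eta = 0.55` at `L/D = 8`. All study
conditions used here (`L/D = 15–25`, `eta = 0.2`, disk and annulus,
`H = 6 D`) initialize in ~10–30 s.

The inflation and rescue machinery is init-only and makes no claim of
detailed balance; production statistics come exclusively from the plain
Metropolis kernel acting on the initialized state.

### Equilibration monitoring

The largest positive eigenvalue `lambda_max` of the global tensor
`Q = <(3 u u^T - I)/2>` is recorded every sweep. `equilibrated(series,
window, tol)` declares a plateau when the means of the last two
non-overlapping windows agree to `tol` (default 2%).

## Field analysis

Fields are accumulated at sub-particle resolution: each rod axis is cut
into segments of length `seg_len = D/2`, and each segment deposits the
in-plane 2D nematic tensor `2 u u^T - I` (and its share `v_rod/n_seg`
of the rod volume, for the packing field) into the grid cell (default
`cell_size = D`) containing its midpoint. In quasi-2D data the 3D
orientations are projected in-plane first; the mean out-of-plane
amplitude is a logged diagnostic. Averaging over segments and
snapshots gives a per-cell symmetric traceless 2x2 tensor whose largest
eigenvalue is `S in [0, 1]` and whose principal axis is the director
`theta` (mod pi). Cells never visited are undefined; cells with
`S <= s_floor = 0.05` have no meaningful axis and their director is
undefined too. All angle arithmetic uses the doubled angle `2 theta`,
the faithful encoding of head–tail symmetry.

Singularities: the angular deficit at a grid vertex is the absolute
nematic winding of the director around the surrounding 2x2 plaquette
(successive differences wrapped to `(-pi/2, pi/2]`, summed, divided by
`pi`), which is 1 on the plaquette containing an ideal half-integer
defect and 0 on smooth plaquettes. Vertices above `threshold = 0.5`
are clustered (8-connectivity, clusters within `merge_radius = 2`
cells merged); each cluster becomes one defect at its deficit-weighted
centroid, charged by the director winding along a circle of
`charge_radius = 3` cells (rounded to the nearest half-integer, with
the rounding residual kept as a quality flag; loops that leave the
defined region are evaluated on the largest contained arc if it spans
at least 3/4 of a turn, else the defect is flagged uncharged). The
boundary winding along a ring at `0.95 R_outer` measures the total
enclosed charge; it equals the sum of detected charges only when no
virtual defects live outside the domain, so a mismatch is logged, not
enforced.

Statistical errors use contiguous-block subsampling: the snapshot
sequence is split into `k` blocks, the statistic is evaluated per
block, and the standard error is the between-block standard deviation
divided by `sqrt(k)`.

## Pattern classification

Disk taxonomy. The bipolar ansatz
`theta(r) = (phi_+ + phi_-)/2` (polar angles about defect points
`(+-a, 0)`, plus a global axis angle) is least-squares fitted to the
measured director with the angle-doubled residual
`(1 - cos 2 Dtheta)/2`, seeded by a coarse grid in `(log a, psi)` and
polished by Nelder–Mead. Two detected interior `+1/2` defects deeper
than the boundary band `w_b` (default `L/2`: the anchoring layer is of
order the rod length) give `B_i`; within the band, `B_b`; with no
detected defects, the fitted virtual-defect distance decides `B_o`
(`a_hat <= 5 R_outer`) versus `B_inf`. Parameter recovery is accurate
to well under 5% of `R_outer` for `a <= 1.5 R_outer`; beyond that the
field depends on `a` only through `O(R/a)` corrections and recovery
degrades gracefully to order-of-magnitude — still ample for the
`B_o`/`B_inf` split at `5 R_outer`.

Annulus taxonomy. `S` and the director's tangential misalignment
`sin^2(theta - (phi + pi/2))` are sampled along the mid-annulus circle;
their variance-normalized angular Fourier spectra are summed and the
dominant harmonic `n >= 2` is accepted if its power exceeds `rho = 2`
times the strongest non-multiple rival (harmonics of `n` support `n`
rather than competing — domain-wall dips are not sinusoidal). A
profile with modulation below a small floor, or no dominant harmonic,
reports the axisymmetric/defect-free sentinel (`D_inf`). Reading the
symmetry from the `S` modulation rather than defect counting alone is
deliberate: for `n >= 4` the domain boundaries are extended
disclination walls without pointlike outer defects.

The inscribed-n-gon rule: `n` rods of length `L` forming a regular
n-gon around the hole have apothem `(L/2) / tan(pi/n)`; the predicted
symmetry for hole radius `R_inner` is the largest `n >= 3` with
`(L/2)/tan(pi/n) + offset <= R_inner`, else 2. The offset convention
defaults to `-D/2` (the rod surface, not its axis, touches the hole)
and is a config option; the apothem construction is this package's
own reconstruction and the offset should be validated against
simulated regime boundaries before being leaned on.  The rule
describes the strictly-2D (`H = D`) regime boundaries; in shallow 3D
chambers the threefold state is stable beyond its nominal upper
boundary — our `H = 6 D` runs at `R_inner = 7.5 D` (which the rule
with the default offset places just on the fourfold side) settle into
the threefold state.

## Continuum baseline

The contrast model is a minimal single-elastic-constant 2D Q-tensor
theory. With `Q = [[q1, q2], [q2, -q1]]` and `S = sqrt(q1^2 + q2^2)`
(so `S` is the largest eigenvalue, matching the particle analysis), the
free-energy density is `a2 S^2 + a4 S^4 + (K/2)(|grad q1|^2 +
|grad q2|^2)` with `a2 = -1 < 0 < a4 = 1` (bulk minimum
`S_eq = sqrt(-a2/(2 a4)) = 1/sqrt(2)`) and `K = 2` in units of `D`,
making the defect core size `sqrt(K/|a2|) ~ 1.4 D` — well below the
chamber scale and resolved by the default grid spacing `0.41–0.5 D`.
Anchoring is strong: a band of cells outside the domain is pinned to
the tangential director at `S_eq`. Relaxation is explicit gradient
descent from a small seeded noise state (`0.01 S_eq` per component);
the step is backtracked (halved, state rewound) whenever an energy
check every 50 iterations detects an increase, so the recorded energy
trace is non-increasing by construction; convergence is declared when
the decrease per iteration falls below `tol * |F|` (`tol = 1e-9`).
Defect analysis of the converged field reuses the particle-side
detector (with `s_floor = 0`, since the continuum director is defined
down to the core) — one code path for both worlds.

Converged results: on the disk, two `+1/2` defects, antipodal, at
radius `~ R/5^{1/4} ~ 0.67 R` (the classic equilibrium of a bipolar
pair under strong tangential anchoring), boundary winding `+1`; on the
annulus, a defect-free tangential texture with zero net interior
charge. Only these topological outcomes are treated as quantitative;
the Landau coefficients are conventions, not fits.

## Synthetic fixtures

`make_defect_field` evaluates the standard multi-defect nematic ansatz
`theta = background + sum_i q_i phi_i` on a grid — winding around each
planted defect is exactly `q_i` by construction, which is what makes
the detector testable without any simulation. `make_dn_field` builds an
n-fold annulus texture from a `+1` virtual defect at the axis, `n`
`+1/2` defects just inside the outer rim and `n` virtual `-1/2`
defects inside the hole. `rods_from_field` draws rod positions
uniformly over the footprint and orientations from the field plus
wrapped-normal noise; the rods may overlap (`physical=False`) since the
analysis consumes orientations only. What passing these fixtures shows:
the analysis stack is exact on ideal singular textures. What it does
not show: behaviour under the density correlations, boundary layering
and sampling noise of real rod configurations — that is exercised by
the Monte Carlo acceptance runs.

## Problem sizes used in the test suite

Unit tests use a small chamber (`R_outer = 12 D`, `H = 3 D`,
`L/D = 8`). The end-to-end pattern checks run the published annulus
conditions — `(L/D = 15, R_inner = 7.5 D)` and `(L/D = 25,
R_inner = 15 D)` at `eta = 0.2`, `H = 6 D`, `R_outer = 40 D` — for
10^5 sweeps per seed with fields averaged over the final 1.5 x 10^3
stored snapshots, three seeds per condition with majority
classification. These run lengths are the package's choice of the
shortest runs that reach a stable domain pattern (the global
`lambda_max` plateaus within ~2 x 10^4 sweeps; the domain symmetry
stabilizes within ~10^5); longer runs sharpen the averaged fields but
do not change the classification. The continuum checks run the full
`R_outer = 40 D` geometry at a ~200^2 grid.

## Known limitations

- The initialization rescue machinery (aligned re-insertion, thermal
  kicks) is heuristic; it is validated only by the exhaustive validity
  audit of its output, never used during production sampling.
- Defect charges near `s_floor`-undefined cores rely on the charge
  circle clearing the undefined patch; for pathological fields with
  wide isotropic regions defects can be flagged uncharged.
- `symmetry_number` assumes domain modulation is visible on the
  mid-annulus circle; patterns confined entirely to one rim would need
  a different probe radius (exposed as a parameter).
- The continuum model is deliberately minimal: one elastic constant,
  strong anchoring, no hydrodynamics, no 3D effects.
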