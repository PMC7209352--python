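# Methods

## Model

A grid module's state is a phase φ ∈ **R**²/Λ, with Λ the hexagonal lattice
generated by b₁ = λ(1, 0)ᵀ and b₂ = λ(cos 60°, sin 60°)ᵀ.  The package fixes
λ = 1: the lattice period never enters independently of the projection
matrices, so module-scale differences are carried entirely by the A_α and the
units of Δ and of the torus metric are lattice periods.  Phases are stored in
lattice coordinates (k₁, k₂) ∈ [0, 1)², so wrapping is a pure fractional-part
operation; conversion to Cartesian coordinates happens only inside distance
computations.  The torus metric reduces the difference to the fundamental
domain and minimises over the 3×3 block of lattice translates, which covers
the Voronoi cell of a hexagonal lattice exactly (verified against a 9×9
enumeration in the tests).

A code for x ∈ **R**^N is the ordered set of M wrapped phases
φ_α = wrap(φ0_α + A_α(x − x0)).  Velocity-path integration is explicit Euler
with a wrap per step; because the phase update is exactly linear and wrapping
commutes with addition modulo Λ, the integrated code equals the direct
encoding of the endpoint to floating-point accuracy — there is nothing a
higher-order integrator would add.

Encoder variants:

* **mixed** (`sample_projections`): A_α i.i.d. standard normal, shape
  2 × N_max; restriction to N < N_max uses the left 2 × N blocks, so one draw
  serves all dimensions (this is what makes the flexibility claim testable).
* **disjoint** (`disjoint_projections`): modules split into N groups as
  equally as possible (remainder to low-index groups); a group-i module reads
  coordinate i through a random Gaussian 2-vector (a random 1D slice of the
  2D module).  The slice-direction distribution is a package choice; nothing
  in the source material pins it down.
* **classic 2D** (`classic_2d_projections`): a common 2×2 operator scaled by
  per-module gains, the conventional planar grid code.

## Coding range

Two codes collide when max_α d(φ_α, ψ_α) ≤ Δ/2 (boundary equality counts as
a collision).  The search requires Δ below the torus circumradius λ/√3.

**Ambiguity box.**  The set K = {x : ‖A_α x‖₂ ≤ Δ/2 ∀α} is the connected
component at the origin of the near-set, a convex intersection of M
elliptical cylinders; it is bounded iff the stacked 2M × N matrix has full
column rank (otherwise `UnboundedAmbiguityError`).  Its per-axis support
w_i = max{x_i : x ∈ K} is computed by SLSQP with analytic Jacobians from a
feasible boundary start, then rescaled back onto K so w is never an
overestimate; N = 1 uses the closed form Δ/(2 max_α‖a_α‖).  Relative accuracy
is ~1e−6 (checked against a closed form at M = 1 and a deterministic
interval-scan oracle at N = 2).

**Units.**  Coordinates are rescaled per axis by the minimal-box side 2w_i,
making the ambiguity box the unit cube; L is the side length of the largest
collision-free cube in these units (the dynamic range), so L ≥ 1 by
construction.  Collision candidates must lie outside the closed unit box.

**Search.**  The cube grows shell by shell; a shell [−s−t, s+t]^N \ [−s, s]^N
is decomposed into 2N overlapping slabs and each slab is refined by a
vectorised branch-and-bound:

* a box with centre c and half-widths h is **certified collision-free** if
  for some module d(wrap(C_α c), 0) − R_α > Δ/2, where
  R_α = ‖|C_α| h‖₂ bounds the phase displacement across the box (C_α is the
  rescaled projection);
* it is **certified colliding** if for every module
  d(wrap(C_α c), 0) + R_α ≤ Δ/2, in which case its nearest point to the
  origin (exactly computable) updates the best collision radius;
* otherwise it is split along its longest axis, or — below the ε half-width
  floor — resolved by evaluating its centre.

Boxes whose minimal ∞-norm cannot beat the best collision found are pruned.
The two certificates and the pruning keep the ε-floor work confined to the
oblique boundary of collision patches; without the collision certificate the
refinement near a patch would need ~(1/ε)^N boxes.  The search is exhaustive:
every point of every shell is covered by a certificate, a pruned region
(which provably cannot contain a closer collision), or an ε-resolved box.  L
is twice the smallest collision ∞-radius, resolved to ~ε; the first confirmed
collision point is reported in input units.

The frontier increment starts at `shell_step` and grows geometrically
(factor `shell_growth`, default 2).  1D ranges at Δ = 0.2 and M = 4 reach
~10⁵ units, so a fixed increment would mean ~10⁵ Python-level shell
iterations; geometric growth keeps the shell count logarithmic while the
union of shells still tiles the region exactly.  If no collision is found up
to `l_cap`, the result carries `certified=False` and L = l_cap for the caller
to judge.

A dense-scan oracle (`coding_range_bruteforce`, N ≤ 3) applies the same
collision rule on a regular grid.  Note its bias: a grid can only
*overestimate* the minimal collision radius, by up to about two diagonal grid
steps when a collision patch's near boundary is oblique, which is why the
oracle-equivalence tests use an asymmetric tolerance.

### Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| Δ (`delta`) | phase resolution, lattice periods | 0.2–0.4 by study | 0.2 for benchmark-scale runs; 0.3 for desk-scale tests (larger Δ → smaller L → cheaper exhaustive search) |
| `eps` | min box half-width, rescaled units | 1e−3 | termination floor; a collision thinner than ε·(box unit) can in principle be missed, and L is resolved to ~ε |
| `shell_step` | first shell increment, rescaled units | 1 | of the order of the ambiguity box itself |
| `shell_growth` | shell increment growth | 2 | logarithmic shell count up to L ~ 10⁵⁺ |
| `l_cap` | search extent bound | 1e7 | above the largest certified range reached in the test suite (~7·10⁵) |
| σ (decoding) | posterior likelihood width | Δ/2 | ties the read-out to the collision criterion |
| posterior threshold | suprathreshold mask | 50% of max | the display threshold is not otherwise determined |

## Experiments

Monte-Carlo sweeps draw one projection set per (M-block, trial) with seed
`base_seed + block·trials + trial` and reuse the draw across N (capacity
scaling, flexibility) or across Δ (resolution sweep), enabling per-seed
monotonicity checks.  Statistics are geometric mean and geometric SD
(population SD of logs, reported as a multiplicative factor), because the
per-draw ranges are heavy-tailed and roughly log-normal; at n = 200 a
high-power normality test does reject the log-normal approximation (skewness
down to −1.5), so "roughly" is quantified by effect size in the tests (KS
distance of standardized logs < 0.2).  Scaling fits are ordinary least
squares on log geometric means; OLS on three or more aggregated points is
the simplest defensible way to estimate the exponential growth rate, and
fits refuse fewer than 3 points.  Non-integer modules-per-dimension ratios are handled by
log-domain quantile interpolation between the bracketing integer-ratio
distributions.

**Excess dimension.**  A counting argument predicts the expected number of
collisions in a cube of side L to scale as L^N Δ^{2M−N}, hence
L ~ Δ^{−(2M−N)/N} per dimension and total coding volume L^N ~ Δ^{−(2M−N)}.
The package's own measurements (Δ = 0.3, M ≤ 4, N ≤ 3, 30 draws) agree: the
coding *volume* overlays at matched excess dimension 2M − N within a factor
1.6, while the side length L itself spreads by factors 6–63 across N at
matched excess.  The acceptance-criterion test asserting a factor-2 overlay
of L is therefore expected to fail and is kept failing deliberately; the
companion test asserts the volume form that the geometry actually supports.

## Tuning curves

Idealized rates are g(x) = exp(−d(wrap(Ax), φ0)²) with φ0 = 0 by default;
conjunctive cells sum m such responses (bounded by (0, m]).  Firing fields
threshold at min + 0.8·(max − min) over a cube of side 2 and are labelled
with *face* adjacency (conservative field separation; corner adjacency would
merge diagonal neighbours).  Default sampling: 64³ over the cube, 128² for
plane slices — the sampled domain is fixed by the analysis, the resolution is
a package choice.  Autocorrelograms are Pearson correlations over the overlap
region at every integer shift (FFT-accelerated; overlaps below 16 samples are
masked NaN); whether raw or Pearson correlation is the "right" definition is
unsettled, Pearson is the common choice in the gridness literature.  The
decoding map multiplies per-module Gaussian likelihoods of the phase
mismatch and normalises over the candidate grid; its σ and threshold
defaults are stated above, and with the relative-to-max threshold the
suprathreshold sets are exactly nested as modules are added, which is what
makes the blob-count monotonicity test sharp.

## What the generators emulate — and what a green test does not establish

The synthetic world is exactly the stated one: Gaussian-entry projections,
noise-free phases, a hard resolution Δ, idealized exponential tuning.  It
does not emulate spiking noise, heterogeneous per-module lattice periods or
orientations, boundary effects of finite environments, learning of the
projections, or the continuous-attractor dynamics that would realise the
phase updates in a real circuit.  Green tests therefore establish properties
of the coding scheme (geometry, capacity scaling, flexibility, tuning-curve
signatures), not claims about biological recordings.

## Known limitations

* The ε floor means a collision region thinner than ε in every axis can be
  missed in principle; ε is logged with every run and L is only resolved to
  ~2ε.
* `ambiguity_box` relies on SLSQP; for nearly rank-deficient stacked
  matrices the cylinders are extremely elongated and both the box and the
  search degrade (the rank guard catches the exactly deficient case only).
* The brute-force oracle is limited to N ≤ 3 and small extents by memory and
  time; above that the divide-and-conquer search is cross-checked only by
  its internal certificates and structural properties (monotonicity,
  disjoint decomposition, symmetry).
* Capacity at the literature scale (Δ = 0.025, 1000 trials, M = 9) is out of
  desk reach; the package exposes the configuration but the test suite runs
  scaled-down versions (Δ ≥ 0.15, ≤ 200 trials, M ≤ 4).
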