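# gridmix

Mixed modular grid-cell codes for N-dimensional variables: hexagonal-torus
phase arithmetic, a deterministic coding-range (capacity) search, scaling
experiments, and predicted tuning curves.

## The problem

Entorhinal grid cells are organised in modules; each module's joint activity
is confined to a 2D state, a phase φ on the twisted torus **R**²/Λ, where Λ is
a hexagonal lattice.  Velocity inputs update that phase linearly,
dφ/dt = A·dx/dt, and the phase wraps modulo the lattice.  With M modules the
population state lives on a 2M-dimensional torus even though each module is
only 2D — and that state space can encode much more than planar position.

The *mixed modular* scheme studied here gives every module its own random
2 × N projection A_α (i.i.d. standard-normal entries) of an N-dimensional
input velocity.  The stacked 2M × N matrix is full column rank almost surely
whenever N ≤ 2M, so M = 4…8 modules can encode variables of dimension up to
8…16 without any rewiring; the same fixed projections automatically trade
range per dimension against dimensionality when N changes.

## The statistic at its core

The quality of such a code is its **coding range** L(M, N, Δ): two codes
*collide* when the maximum over modules of the torus distances between their
phases is ≤ Δ/2, where Δ is the phase resolution of a module's population.
Near the origin the encoder is locally one-to-one; the minimal axis-aligned
box enclosing the trivially-similar inputs (the *ambiguity box*,
w_i = max{x_i : ‖A_α x‖₂ ≤ Δ/2 ∀α}) is excluded from the search and its side
lengths are the units of measurement.  L is then the side length of the
largest collision-free cube centred on the origin, in these dynamic-range
units, found by an exhaustive divide-and-conquer collision search (never by
sampling).  For a 1D input, the expected range follows the benchmark
E(L) ∝ Δ·(1/Δ²)^M — exponential in the number of modules.

## Worked example

```python
import numpy as np
import gridmix as gm

P = gm.sample_projections(M=3, N_max=6, seed=7)
print("stacked rank at N=6:", gm.stacked_rank(P, 6))

cfg = gm.SearchConfig(delta=0.3)
for N in (1, 2, 3):
    res = gm.coding_range(P, N, cfg)
    print(f"N={N}: L = {res.L:.2f} dynamic-range units "
          f"(ambiguity half-widths {np.round(res.box.half_widths, 4)})")

bench = gm.benchmark_1d([1, 2, 3], delta=0.3, trials=20, base_seed=0)
print(bench["summary"][["M", "geo_mean", "geo_sd"]].to_string(index=False))
print(f"slope of log L vs M: {bench['fit'].slope:.2f} "
      f"(benchmark log(1/delta^2) = {np.log(1/0.3**2):.2f})")
```

prints

```
stacked rank at N=6: 6
N=1: L = 717.93 dynamic-range units (ambiguity half-widths [0.0788])
N=2: L = 16.51 dynamic-range units (ambiguity half-widths [0.1252 0.1146])
N=3: L = 5.03 dynamic-range units (ambiguity half-widths [0.131  0.1298 0.0651])
 M   geo_mean   geo_sd
 1  12.861644 1.864498
 2  68.770642 2.898258
 3 377.821719 3.053242
slope of log L vs M: 1.69 (benchmark log(1/delta^2) = 2.41)
```

Reading the output: with 6 Gaussian modules stacked, all 6 input dimensions
are resolvable (full rank).  The same three 2×6 projections give a
collision-free range of ~718 ambiguity boxes when only their first column is
used (N = 1), shrinking to ~5 boxes when all three dimensions are in play —
the flexibility trade-off with nothing re-learned.  The 1D geometric means
grow by roughly 1/Δ² per added module; at this small desk scale (20 draws,
Δ = 0.3) the fitted slope underestimates the benchmark, and approaches it at
the scales used in the test suite (200 draws, Δ = 0.2).

A CLI mirrors the main workflows, e.g.

```sh
gridmix capacity --modules 3 --dim 2 --delta 0.3 --seed 7 --out out/
gridmix sweep --modules 2,3 --dims 1,2 --delta 0.3 --trials 5 --seed 1 --out out/
gridmix benchmark1d --modules 1,2,3 --trials 50 --delta 0.3 --out out/
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the maximum encodable dimension of the scheme: it
draws 100 seeded sets of Gaussian projection matrices for M = 8 and M = 4
modules, computes the numerical rank of every stacked 2M × N sub-matrix for
N = 1…16, and reports the largest N that is full column rank in all draws for
each case, written as JSON.

See `docs/methods.md` for the model details, algorithmic choices, and known
limitations.
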