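"""Coding range (capacity) of a multi-module grid code.

The coding range L(M, N, Δ) is the side length of the largest cube centred at
the origin of the encoded variable over which no two points receive grid codes
closer than Δ/2 (a "collision").  Near the origin the encoding map is locally
one-to-one, so every code has a small neighbourhood of trivially similar
codes; the minimal axis-aligned box enclosing that neighbourhood (the
*ambiguity box*) is excluded from the collision search and its side lengths
define the units in which L is reported (the dynamic range).  In these units
both the ambiguity box and the maximal collision-free region are cubes, and
L >= 1 by construction.

The search itself is deterministic and exhaustive (never sampled): the cube is
grown shell by shell; each frontier shell is decomposed into boxes which are
either certified collision-free, certified entirely colliding, or split along
their longest axis, using a per-module Lipschitz bound on the phase
displacement across a box.  Boxes below the ``eps`` half-width floor are
resolved by evaluating their centre.

A dense-scan brute-force oracle (:func:`coding_range_bruteforce`) is provided
for cross-checking at small N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .encoding import ProjectionSet, Anchor
from .lattice import HexLattice

__all__ = [
    "SearchConfig",
    "AmbiguityBox",
    "CapacityResult",
    "UnboundedAmbiguityError",
    "ambiguity_box",
    "coding_range",
    "coding_range_bruteforce",
    "disjoint_coding_range",
]

logger = logging.getLogger(__name__)

_TRANSLATES = np.array([[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float)
_CHUNK = 1 << 17  # boxes/points per vectorised evaluation block


class UnboundedAmbiguityError(ValueError):
    """The stacked projection matrix is rank deficient: the set of inputs with
    near-zero code is unbounded and no finite ambiguity box exists."""


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the collision search.

    Attributes
    ----------
    delta : float
        Phase resolution Δ, in the units of the torus metric.  Two codes
        collide when their code distance is <= Δ/2.  Must lie below the torus
        circumradius λ/√3, otherwise every pair of codes is "similar".
    eps : float
        Minimum box half-width, in rescaled (dynamic-range) units.  Boxes
        smaller than this are resolved by centre evaluation.
    shell_step : float
        Initial frontier expansion increment in rescaled units.
    shell_growth : float
        Multiplicative growth of the expansion increment per shell (>= 1).
        Keeps the shell count logarithmic in L while the union of shells still
        covers the search region exhaustively.
    l_cap : float
        Safety bound on the search extent (rescaled units).  If no collision
        is found up to ``l_cap`` the result is returned uncertified.
    """

    delta: float
    eps: float = 1e-3
    shell_step: float = 1.0
    shell_growth: float = 2.0
    l_cap: float = 1e7

    def validate(self, lattice: HexLattice) -> None:
        if not (0.0 < self.delta < lattice.circumradius):
            raise ValueError(
                f"delta must be in (0, {lattice.circumradius:.6f}), got {self.delta}"
            )
        if not (0.0 < self.eps < self.shell_step):
            raise ValueError("require 0 < eps < shell_step")
        if self.shell_growth < 1.0:
            raise ValueError("shell_growth must be >= 1")
        if self.l_cap <= 1.0:
            raise ValueError("l_cap must exceed 1")


@dataclass(frozen=True)
class AmbiguityBox:
    """Per-axis half-widths (input-space units) of the minimal box enclosing
    the inputs whose unwrapped phase displacements all stay within Δ/2."""

    half_widths: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "half_widths", np.asarray(self.half_widths, float))


@dataclass(frozen=True)
class CapacityResult:
    """Outcome of a coding-range search.

    ``L`` is the cube side length in dynamic-range units (multiples of the
    ambiguity-box side).  ``collision_point`` is in input-space units.
    ``certified`` is False when the search hit ``l_cap`` without a collision.
    """

    L: float
    box: AmbiguityBox
    collision_point: np.ndarray | None
    boxes_examined: int
    certified: bool
    M: int
    N: int
    delta: float
    seed: int | None = None


def ambiguity_box(
    P: ProjectionSet,
    N: int | None = None,
    delta: float = 0.2,
    lattice: HexLattice | None = None,
) -> AmbiguityBox:
    """Minimal axis-aligned box enclosing {x : ||A_α x||_2 <= Δ/2 for all α}.

    The half-width along axis i is the support ``max x_i`` over the convex
    intersection of the M elliptical cylinders, found by SLSQP (and polished
    back onto the feasible set).  Requires the stacked matrix to have full
    column rank, otherwise the set is unbounded.
    """
    lattice = lattice or HexLattice()
    N = P.N_max if N is None else N
    A = P.restrict(N).matrices  # (M, 2, N)
    stacked = A.reshape(-1, N)
    if np.linalg.matrix_rank(stacked) < N:
        raise UnboundedAmbiguityError(
            f"stacked {2 * P.M}x{N} matrix is rank deficient; ambiguity region unbounded"
        )
    r = delta / 2.0
    col_norms = np.linalg.norm(A, axis=1)  # (M, N): ||A_α e_i||
    if N == 1:
        return AmbiguityBox(np.array([r / col_norms[:, 0].max()]))

    Qs = [a.T @ a for a in A]
    w = np.empty(N)
    for i in range(N):
        e_i = np.zeros(N)
        e_i[i] = 1.0
        t0 = r / col_norms[:, i].max()  # the pure-axis point t0*e_i is feasible
        cons = [
            {
                "type": "ineq",
                "fun": (lambda x, Q=Q: r * r - x @ Q @ x),
                "jac": (lambda x, Q=Q: -2.0 * (Q @ x)),
            }
            for Q in Qs
        ]
        res = minimize(
            lambda x: -x[i],
            0.9 * t0 * e_i,
            jac=lambda x: -e_i,
            method="SLSQP",
            constraints=cons,
            options={"maxiter": 500, "ftol": 1e-14},
        )
        x = res.x
        # polish: rescale onto the feasible set so w is never an overestimate
        norms = np.linalg.norm(np.einsum("mij,j->mi", A, x), axis=1)
        scale = r / norms.max()
        if scale < 1.0:
            x = x * scale
        w[i] = max(x[i], t0)
    return AmbiguityBox(w)


# ---------------------------------------------------------------------------
# divide-and-conquer collision search
# ---------------------------------------------------------------------------


def _phase_dist_origin(C: np.ndarray, centers: np.ndarray, lattice: HexLattice) -> np.ndarray:
    """Torus distance to the zero phase of wrap(C_α z) for each box centre z.

    C: (M, 2, N) rescaled projections; centers: (K, N).  Returns (K, M).
    """
    B = lattice.basis
    Binv = lattice.inv_basis
    out = np.empty((centers.shape[0], C.shape[0]))
    for lo in range(0, centers.shape[0], _CHUNK):
        c = centers[lo : lo + _CHUNK]
        v = np.einsum("mij,kj->kmi", C, c)  # (k, M, 2)
        k = v @ Binv.T
        k -= np.floor(k)
        cand = k[..., None, :] - _TRANSLATES  # (k, M, 9, 2)
        cart = cand @ B.T
        out[lo : lo + _CHUNK] = np.sqrt(np.min(np.sum(cart * cart, axis=-1), axis=-1))
    return out


def _lipschitz_radius(absC: np.ndarray, halves: np.ndarray) -> np.ndarray:
    """Bound on the phase displacement ||C_α (x - c)||_2 over a box of
    half-widths h: R_α = || |C_α| h ||_2.  Returns (K, M)."""
    disp = np.einsum("mij,kj->kmi", absC, halves)
    return np.sqrt(np.sum(disp * disp, axis=-1))


def _box_min_radius(centers: np.ndarray, halves: np.ndarray) -> np.ndarray:
    """Minimal infinity-norm attained inside each box."""
    lo = centers - halves
    hi = centers + halves
    per_axis = np.where((lo <= 0) & (hi >= 0), 0.0, np.minimum(np.abs(lo), np.abs(hi)))
    return per_axis.max(axis=1)


def _closest_point(center: np.ndarray, half: np.ndarray) -> np.ndarray:
    """Point of the box closest to the origin in infinity norm (clip 0 into the box)."""
    return np.clip(np.zeros_like(center), center - half, center + half)


def _search_shell(
    C: np.ndarray,
    absC: np.ndarray,
    delta: float,
    lattice: HexLattice,
    s_lo: float,
    s_hi: float,
    eps: float,
) -> tuple[float, np.ndarray | None, int]:
    """Exhaustively resolve the shell [-s_hi, s_hi]^N \\ [-s_lo, s_lo]^N.

    Returns (best collision infinity-radius, collision point in rescaled
    units, number of boxes examined); radius is inf when the shell is
    collision-free.
    """
    N = C.shape[2]
    half_delta = delta / 2.0

    cen_list, half_list = [], []
    for axis in range(N):
        for sign in (1.0, -1.0):
            lo = np.full(N, -s_hi)
            hi = np.full(N, s_hi)
            if sign > 0:
                lo[axis], hi[axis] = s_lo, s_hi
            else:
                lo[axis], hi[axis] = -s_hi, -s_lo
            cen_list.append((lo + hi) / 2.0)
            half_list.append((hi - lo) / 2.0)
    centers = np.array(cen_list)
    halves = np.array(half_list)

    best_r = np.inf
    best_pt: np.ndarray | None = None
    examined = 0

    while centers.shape[0]:
        K = centers.shape[0]
        examined += K
        d = _phase_dist_origin(C, centers, lattice)  # (K, M)
        R = _lipschitz_radius(absC, halves)  # (K, M)
        free = np.any(d - R > half_delta, axis=1)
        colliding = np.all(d + R <= half_delta, axis=1)
        minrad = _box_min_radius(centers, halves)

        if colliding.any():
            idx = np.flatnonzero(colliding)
            j = idx[np.argmin(minrad[idx])]
            if minrad[j] < best_r:
                best_r = minrad[j]
                best_pt = _closest_point(centers[j], halves[j])

        undecided = ~(free | colliding) & (minrad < best_r)
        small = halves.max(axis=1) < eps
        leaf = undecided & small
        if leaf.any():
            hit = leaf & np.all(d <= half_delta, axis=1)
            hit &= np.max(np.abs(centers), axis=1) > 0.5  # outside ambiguity box
            if hit.any():
                idx = np.flatnonzero(hit)
                rads = np.max(np.abs(centers[idx]), axis=1)
                j = idx[np.argmin(rads)]
                if rads.min() < best_r:
                    best_r = rads.min()
                    best_pt = centers[j].copy()

        split = undecided & ~small
        if not split.any():
            break
        c = centers[split]
        h = halves[split].copy()
        axis = np.argmax(h, axis=1)
        rows = np.arange(h.shape[0])
        h[rows, axis] /= 2.0
        offs = np.zeros_like(h)
        offs[rows, axis] = h[rows, axis]
        centers = np.concatenate([c - offs, c + offs])
        halves = np.concatenate([h, h])

    return float(best_r), best_pt, examined


def coding_range(
    P: ProjectionSet,
    N: int | None = None,
    cfg: SearchConfig | None = None,
    lattice: HexLattice | None = None,
    anchor: Anchor | None = None,
) -> CapacityResult:
    """Coding range of a projection set: deterministic divide-and-conquer search.

    The input space is rescaled so that the ambiguity box becomes the unit
    cube; the search then expands a cube shell by shell, resolving each shell
    exhaustively, and stops at the first shell containing a collision.  L is
    twice the smallest collision infinity-radius (at ``eps`` resolution).

    ``anchor`` is accepted for interface symmetry but has no effect: the code
    is translation covariant, so the range is anchor independent.
    """
    lattice = lattice or HexLattice()
    cfg = cfg or SearchConfig(delta=0.2)
    cfg.validate(lattice)
    N = P.N_max if N is None else N
    box = ambiguity_box(P, N, cfg.delta, lattice)
    units = 2.0 * box.half_widths  # minimal-box side lengths
    A = P.restrict(N).matrices
    C = A * units[None, None, :]
    absC = np.abs(C)

    s = 0.5
    step = cfg.shell_step
    shell = 0
    boxes_examined = 0
    while True:
        s_hi = min(s + step, cfg.l_cap / 2.0)
        best_r, best_pt, n = _search_shell(
            C, absC, cfg.delta, lattice, s, s_hi, cfg.eps
        )
        boxes_examined += n
        logger.debug(
            "shell %d: [%g, %g], boxes=%d, collision=%s",
            shell, s, s_hi, n, best_r if np.isfinite(best_r) else None,
        )
        if np.isfinite(best_r):
            return CapacityResult(
                L=2.0 * best_r,
                box=box,
                collision_point=best_pt * units,
                boxes_examined=boxes_examined,
                certified=True,
                M=P.M,
                N=N,
                delta=cfg.delta,
                seed=P.seed,
            )
        s = s_hi
        if s >= cfg.l_cap / 2.0:
            return CapacityResult(
                L=cfg.l_cap,
                box=box,
                collision_point=None,
                boxes_examined=boxes_examined,
                certified=False,
                M=P.M,
                N=N,
                delta=cfg.delta,
                seed=P.seed,
            )
        step *= cfg.shell_growth
        shell += 1


def coding_range_bruteforce(
    P: ProjectionSet,
    N: int | None = None,
    cfg: SearchConfig | None = None,
    grid_step: float = 1e-3,
    lattice: HexLattice | None = None,
    max_points: float = 1e8,
) -> CapacityResult:
    """Dense-scan oracle: same collision rule on a regular grid (N <= 3).

    Scans an expanding cube at ``grid_step`` spacing (rescaled units) and
    returns twice the smallest infinity-radius of a colliding grid point.
    Cost grows with the volume of the range; refuses scans above
    ``max_points`` grid points.
    """
    lattice = lattice or HexLattice()
    cfg = cfg or SearchConfig(delta=0.2)
    cfg.validate(lattice)
    N = P.N_max if N is None else N
    if N > 3:
        raise ValueError("brute-force oracle supports N <= 3 only")
    box = ambiguity_box(P, N, cfg.delta, lattice)
    units = 2.0 * box.half_widths
    C = P.restrict(N).matrices * units[None, None, :]
    half_delta = cfg.delta / 2.0

    extent = max(1.0, 2.0 * grid_step)
    boxes_examined = 0
    while True:
        n = int(np.ceil(extent / grid_step))
        if (2 * n + 1) ** N > max_points:
            raise ValueError(
                f"dense scan would need {(2 * n + 1) ** N:.3g} points (> {max_points:.3g})"
            )
        axes = [np.arange(-n, n + 1) * grid_step] * N
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, N)
        radius = np.max(np.abs(pts), axis=1)
        keep = radius > 0.5  # outside the closed ambiguity box
        pts, radius = pts[keep], radius[keep]
        boxes_examined += pts.shape[0]
        d = _phase_dist_origin(C, pts, lattice)
        hit = np.all(d <= half_delta, axis=1)
        if hit.any():
            idx = np.flatnonzero(hit)
            j = idx[np.argmin(radius[idx])]
            return CapacityResult(
                L=2.0 * float(radius[j]),
                box=box,
                collision_point=pts[j] * units,
                boxes_examined=boxes_examined,
                certified=True,
                M=P.M,
                N=N,
                delta=cfg.delta,
                seed=P.seed,
            )
        if extent >= cfg.l_cap / 2.0:
            return CapacityResult(
                L=cfg.l_cap,
                box=box,
                collision_point=None,
                boxes_examined=boxes_examined,
                certified=False,
                M=P.M,
                N=N,
                delta=cfg.delta,
                seed=P.seed,
            )
        extent = min(extent * 2.0, cfg.l_cap / 2.0)


def disjoint_coding_range(L_components) -> float:
    """Range of a disjoint modular code: the minimum over its per-coordinate
    1D ranges."""
    L = np.asarray(L_components, dtype=float)
    if L.size == 0:
        raise ValueError("empty component list")
    if np.any(L <= 0) or not np.all(np.isfinite(L)):
        raise ValueError("component ranges must be positive and finite")
    return float(L.min())
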