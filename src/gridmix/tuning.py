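"""Predicted tuning curves of mixed modular grid codes.

An idealized grid cell anchored at phase φ0 in a module with projection A
fires at rate ``g(x; A) = exp(-d(wrap(A x), φ0)^2)``, where d is the torus
metric; a conjunctive cell sums such responses over several modules.  In 3D a
single module's field is a lift of a 2D hexagonal pattern — constant along the
kernel direction of A — while conjunctive cells with full stacked rank produce
localized fields without full grid periodicity.  This module also provides 2D
plane slices of those fields, firing-field extraction by thresholding, spatial
autocorrelograms, and the multi-module posterior used to visualise how
ambiguity shrinks as modules are added.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .encoding import ProjectionSet
from .lattice import GridCode, HexLattice, torus_distance, wrap_phase

__all__ = [
    "RateMap",
    "Plane",
    "grid_points",
    "ideal_rate",
    "ideal_rate_map",
    "conjunctive_rate",
    "conjunctive_rate_map",
    "threshold_fields",
    "plane_slice",
    "autocorrelation_2d",
    "decode_posterior",
]


@dataclass(frozen=True)
class RateMap:
    """A scalar field sampled on a regular axis-aligned grid (D = 2 or 3)."""

    values: np.ndarray
    origin: np.ndarray
    spacing: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        origin = np.broadcast_to(np.asarray(self.origin, float), (v.ndim,)).copy()
        spacing = np.broadcast_to(np.asarray(self.spacing, float), (v.ndim,)).copy()
        if v.ndim not in (1, 2, 3):
            raise ValueError(f"rate maps must be 1D-3D, got {v.ndim}D")
        if not np.all(np.isfinite(spacing)) or np.any(spacing <= 0):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "spacing", spacing)

    @property
    def D(self) -> int:
        return self.values.ndim

    def points(self) -> np.ndarray:
        """Sample coordinates, shape ``values.shape + (D,)``."""
        return grid_points(self.origin, self.spacing, self.values.shape)


@dataclass(frozen=True)
class Plane:
    """A plane in 3D given by a point and an orthonormal in-plane frame (u, v)."""

    point: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        point = np.asarray(self.point, float)
        u = np.asarray(self.u, float)
        v = np.asarray(self.v, float)
        for name, vec in (("point", point), ("u", u), ("v", v)):
            if vec.shape != (3,):
                raise ValueError(f"{name} must be a 3-vector")
        if abs(np.linalg.norm(u) - 1) > 1e-9 or abs(np.linalg.norm(v) - 1) > 1e-9:
            raise ValueError("u and v must be unit vectors")
        if abs(u @ v) > 1e-9:
            raise ValueError("u and v must be orthogonal")
        object.__setattr__(self, "point", point)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @classmethod
    def random_tilted(cls, seed: int, point=(0.0, 0.0, 0.0)) -> "Plane":
        """A uniformly random plane frame through ``point``."""
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
        return cls(np.asarray(point, float), q[:, 0], q[:, 1])


def grid_points(origin, spacing, shape) -> np.ndarray:
    shape = tuple(shape)
    origin = np.broadcast_to(np.asarray(origin, float), (len(shape),))
    spacing = np.broadcast_to(np.asarray(spacing, float), (len(shape),))
    axes = [o + s * np.arange(n) for o, s, n in zip(origin, spacing, shape)]
    return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def _phi0(phi0, lattice) -> np.ndarray:
    if phi0 is None:
        return np.zeros(2)
    p = np.asarray(phi0, float)
    return p - np.floor(p)


def ideal_rate(
    x: np.ndarray,
    A: np.ndarray,
    phi0=None,
    lattice: HexLattice | None = None,
) -> np.ndarray:
    """Idealized grid-cell rate ``exp(-d(wrap(A x), φ0)^2)`` at points x (..., N)."""
    lattice = lattice or HexLattice()
    A = np.asarray(A, float)
    x = np.asarray(x, float)
    if A.ndim != 2 or A.shape[0] != 2:
        raise ValueError(f"A must be 2 x N, got {A.shape}")
    if x.shape[-1] != A.shape[1]:
        raise ValueError(f"points have dimension {x.shape[-1]}, A expects {A.shape[1]}")
    phases = wrap_phase(x @ A.T, lattice)
    d = torus_distance(phases, _phi0(phi0, lattice), lattice)
    return np.exp(-(d**2))


def ideal_rate_map(
    A: np.ndarray,
    origin,
    spacing,
    shape,
    phi0=None,
    lattice: HexLattice | None = None,
) -> RateMap:
    pts = grid_points(origin, spacing, shape)
    return RateMap(ideal_rate(pts, A, phi0, lattice), origin, spacing)


def conjunctive_rate(
    x: np.ndarray,
    A_list,
    phi0_list=None,
    lattice: HexLattice | None = None,
) -> np.ndarray:
    """Conjunctive-cell rate: sum of idealized responses over m modules."""
    A_list = list(A_list)
    if not A_list:
        raise ValueError("need at least one module")
    if phi0_list is None:
        phi0_list = [None] * len(A_list)
    if len(phi0_list) != len(A_list):
        raise ValueError("phi0_list length must match A_list")
    total = np.zeros(np.asarray(x, float).shape[:-1])
    for A, phi0 in zip(A_list, phi0_list):
        total = total + ideal_rate(x, A, phi0, lattice)
    return total


def conjunctive_rate_map(
    A_list,
    origin,
    spacing,
    shape,
    phi0_list=None,
    lattice: HexLattice | None = None,
) -> RateMap:
    pts = grid_points(origin, spacing, shape)
    return RateMap(conjunctive_rate(pts, A_list, phi0_list, lattice), origin, spacing)


def threshold_fields(rmap: RateMap, rel: float = 0.8):
    """Firing fields by relative thresholding at ``min + rel*(max - min)``.

    Returns ``(mask, labels, n_fields)``; connected components use face
    adjacency.  A constant map yields a single all-true component.
    """
    if not 0.0 <= rel <= 1.0:
        raise ValueError("rel must be in [0, 1]")
    v = rmap.values
    theta = v.min() + rel * (v.max() - v.min())
    mask = v >= theta
    structure = ndimage.generate_binary_structure(v.ndim, 1)
    labels, n = ndimage.label(mask, structure=structure)
    return mask, labels, int(n)


def plane_slice(
    plane: Plane,
    extent: float,
    spacing: float,
    A: np.ndarray,
    phi0=None,
    lattice: HexLattice | None = None,
) -> RateMap:
    """Idealized 3D response sampled over a 2D plane patch.

    The patch is the square of side ``extent`` centred at ``plane.point``,
    spanned by the orthonormal frame (u, v).  A plane aligned with a module's
    response plane shows a perfect hexagonal pattern; a plane containing the
    kernel direction of A shows stripes.
    """
    n = int(np.floor(extent / spacing)) + 1
    coords = (np.arange(n) - (n - 1) / 2.0) * spacing
    S, T = np.meshgrid(coords, coords, indexing="ij")
    pts = (
        plane.point[None, None, :]
        + S[..., None] * plane.u[None, None, :]
        + T[..., None] * plane.v[None, None, :]
    )
    vals = ideal_rate(pts, A, phi0, lattice)
    return RateMap(vals, origin=[coords[0], coords[0]], spacing=[spacing, spacing])


def autocorrelation_2d(rmap: RateMap, min_overlap: int = 16) -> RateMap:
    """Spatial autocorrelogram: Pearson correlation at every integer shift.

    Computed over the overlap region of the map with its shifted copy (FFT
    accelerated); shifts whose overlap is below ``min_overlap`` samples or
    whose variance vanishes are NaN.  Value at zero shift is 1.
    """
    if rmap.D != 2:
        raise ValueError("autocorrelogram requires a 2D rate map")
    a = rmap.values
    ones = np.ones_like(a)

    def corr(x, y):
        return fftconvolve(x, y[::-1, ::-1], mode="full")

    n = corr(ones, ones)
    sx = corr(a, ones)  # sum of x over overlap for each shift
    sy = corr(ones, a)
    sxy = corr(a, a)
    sxx = corr(a * a, ones)
    syy = corr(ones, a * a)
    n = np.round(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = n * sxy - sx * sy
        den = np.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))
        out = num / den
    out[(n < min_overlap) | ~np.isfinite(out)] = np.nan
    # the zero-shift (full overlap) Pearson correlation is exactly 1
    center = tuple(s - 1 for s in a.shape)
    if np.std(a) > 0:
        out[center] = 1.0
    origin = [-(s - 1) * sp for s, sp in zip(a.shape, rmap.spacing)]
    return RateMap(out, origin=origin, spacing=rmap.spacing)


def decode_posterior(
    code: GridCode,
    P: ProjectionSet,
    origin,
    spacing,
    shape,
    sigma: float,
    rel_threshold: float = 0.5,
    lattice: HexLattice | None = None,
):
    """Posterior over candidate positions given a grid code.

    The unnormalized likelihood of candidate x is
    ``prod_α exp(-d(wrap(A_α x), φ_α)^2 / (2σ^2))``; it is normalized to sum
    to one over the candidate grid.  The suprathreshold mask keeps candidates
    whose posterior is at least ``rel_threshold`` times the maximum.

    Returns ``(posterior RateMap, mask, n_blobs)``; blobs are face-adjacent
    connected components of the mask.
    """
    lattice = lattice or HexLattice()
    if not (np.isfinite(sigma) and sigma > 0):
        raise ValueError(f"sigma must be positive, got {sigma}")
    if code.M != P.M:
        raise ValueError("code and projection set disagree on module count")
    pts = grid_points(origin, spacing, shape)
    N = pts.shape[-1]
    A = P.restrict(N).matrices
    loglik = np.zeros(pts.shape[:-1])
    for alpha in range(P.M):
        phases = wrap_phase(pts @ A[alpha].T, lattice)
        d = torus_distance(phases, code.phases[alpha], lattice)
        loglik -= d**2 / (2.0 * sigma**2)
    loglik -= loglik.max()
    post = np.exp(loglik)
    post /= post.sum()
    mask = post >= rel_threshold * post.max()
    structure = ndimage.generate_binary_structure(post.ndim, 1)
    _, n = ndimage.label(mask, structure=structure)
    return RateMap(post, origin, spacing), mask, int(n)
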