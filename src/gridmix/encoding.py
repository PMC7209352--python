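"""Projection sets and the encoding map from N-dimensional inputs to grid codes.

Each grid module α carries a 2 x N velocity projection matrix A_α.  The code
of a point x (relative to an anchor (x0, φ0)) is the ordered set of wrapped
phases ``φ_α = wrap(φ0_α + A_α (x - x0))``.  Three constructions are provided:

* :func:`sample_projections` — the mixed modular code: independent standard
  normal entries per module, so the stacked 2M x N matrix is full rank almost
  surely whenever N <= 2M.
* :func:`disjoint_projections` — the disjoint baseline: modules are split into
  N groups, group i reads only input coordinate i through a random Gaussian
  2-vector (a random 1D slice of the 2D module).
* :func:`classic_2d_projections` — the classical 2D grid code: a common 2 x 2
  operator premultiplied by per-module scalar gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import GridCode, HexLattice, wrap_phase

__all__ = [
    "ProjectionSet",
    "Anchor",
    "sample_projections",
    "classic_2d_projections",
    "disjoint_projections",
    "encode",
    "integrate_path",
    "stacked_rank",
]


@dataclass(frozen=True)
class ProjectionSet:
    """M per-module projection matrices, stored as an array of shape (M, 2, N_max)."""

    matrices: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrices, dtype=float)
        if m.ndim != 3 or m.shape[1] != 2:
            raise ValueError(f"matrices must have shape (M, 2, N_max), got {m.shape}")
        if m.shape[0] < 1 or m.shape[2] < 1:
            raise ValueError("need at least one module and one input dimension")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite projection entries")
        object.__setattr__(self, "matrices", m)

    @property
    def M(self) -> int:
        return self.matrices.shape[0]

    @property
    def N_max(self) -> int:
        return self.matrices.shape[2]

    def restrict(self, N: int) -> "ProjectionSet":
        """Left 2 x N blocks: the sub-matrices used when encoding an
        N-dimensional variable with N <= N_max."""
        if not 1 <= N <= self.N_max:
            raise ValueError(f"N must be in [1, {self.N_max}], got {N}")
        if N == self.N_max:
            return self
        return ProjectionSet(self.matrices[:, :, :N], seed=self.seed)

    def stacked(self, N: int | None = None) -> np.ndarray:
        """The 2M x N matrix obtained by stacking the module projections."""
        N = self.N_max if N is None else N
        return self.restrict(N).matrices.reshape(2 * self.M, N)


def sample_projections(M: int, N_max: int, seed: int) -> ProjectionSet:
    """Sample M independent 2 x N_max matrices with i.i.d. standard-normal entries."""
    if M < 1 or N_max < 1:
        raise ValueError(f"M and N_max must be >= 1, got M={M}, N_max={N_max}")
    rng = np.random.default_rng(seed)
    return ProjectionSet(rng.standard_normal((M, 2, N_max)), seed=seed)


def classic_2d_projections(
    M: int, base: np.ndarray, gains, N_max: int | None = None
) -> ProjectionSet:
    """The classical 2D grid code: A_α = gain_α * base, zero-padded to N_max columns."""
    base = np.asarray(base, dtype=float)
    if base.shape != (2, 2):
        raise ValueError(f"base must be 2x2, got {base.shape}")
    gains = np.asarray(gains, dtype=float)
    if gains.shape != (M,):
        raise ValueError(f"need exactly M={M} gains, got shape {gains.shape}")
    if np.any(gains <= 0):
        raise ValueError("gains must be positive")
    N_max = 2 if N_max is None else N_max
    if N_max < 2:
        raise ValueError("N_max must be >= 2 for a 2x2 base")
    mats = np.zeros((M, 2, N_max))
    mats[:, :, :2] = gains[:, None, None] * base[None]
    return ProjectionSet(mats)


def disjoint_projections(M: int, N: int, seed: int) -> ProjectionSet:
    """Disjoint baseline: N groups of modules, group i reads only coordinate i.

    Modules are split into N groups as equally as possible (remainders go to
    the lowest-index groups).  A module in group i has a single nonzero column
    i, drawn as a standard-normal 2-vector — a random 1D slice of that module.
    """
    if M < 1 or N < 1:
        raise ValueError("M and N must be >= 1")
    if M < N:
        raise ValueError(f"need at least one module per dimension: M={M} < N={N}")
    rng = np.random.default_rng(seed)
    sizes = np.full(N, M // N)
    sizes[: M % N] += 1
    mats = np.zeros((M, 2, N))
    alpha = 0
    for i, size in enumerate(sizes):
        for _ in range(size):
            mats[alpha, :, i] = rng.standard_normal(2)
            alpha += 1
    return ProjectionSet(mats, seed=seed)


def group_assignment(M: int, N: int) -> np.ndarray:
    """Group index of each module under the disjoint split (same rule as
    :func:`disjoint_projections`)."""
    sizes = np.full(N, M // N)
    sizes[: M % N] += 1
    return np.repeat(np.arange(N), sizes)


@dataclass(frozen=True)
class Anchor:
    """Assignment of a reference phase vector φ0 to a reference point x0."""

    x0: np.ndarray
    phases: np.ndarray  # (M, 2) lattice coordinates

    def __post_init__(self) -> None:
        object.__setattr__(self, "x0", np.asarray(self.x0, dtype=float))
        phases = np.asarray(self.phases, dtype=float)
        if phases.ndim != 2 or phases.shape[1] != 2:
            raise ValueError(f"anchor phases must have shape (M, 2), got {phases.shape}")
        object.__setattr__(self, "phases", phases - np.floor(phases))

    @classmethod
    def zero(cls, M: int, N: int) -> "Anchor":
        return cls(np.zeros(N), np.zeros((M, 2)))


def _check_dims(P: ProjectionSet, x: np.ndarray) -> int:
    N = x.shape[-1] if x.ndim else 0
    if x.ndim < 1 or N < 1 or N > P.N_max:
        raise ValueError(
            f"input dimension {N} incompatible with projection set (N_max={P.N_max})"
        )
    return N


def encode(
    x: np.ndarray,
    P: ProjectionSet,
    anchor: Anchor | None = None,
    lattice: HexLattice | None = None,
) -> GridCode:
    """Map an N-vector to its grid code: ``φ_α = wrap(φ0_α + A_α (x - x0))``.

    The input dimension is inferred from ``x``; the left 2 x N blocks of the
    projection matrices are used (flexible restriction).
    """
    lattice = lattice or HexLattice()
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("encode expects a single N-vector")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input")
    N = _check_dims(P, x)
    anchor = anchor or Anchor.zero(P.M, N)
    if anchor.phases.shape[0] != P.M:
        raise ValueError("anchor has wrong number of module phases")
    if anchor.x0.shape != (N,):
        raise ValueError(f"anchor x0 has dimension {anchor.x0.shape}, expected ({N},)")
    A = P.restrict(N).matrices  # (M, 2, N)
    raw = np.einsum("mij,j->mi", A, x - anchor.x0)
    raw = raw @ lattice.inv_basis.T + anchor.phases  # to lattice coords, add φ0
    return GridCode(raw, lattice)


def integrate_path(
    velocities: np.ndarray,
    dt: float,
    P: ProjectionSet,
    initial: GridCode,
    lattice: HexLattice | None = None,
) -> GridCode:
    """Euler integration of the phase dynamics ``dφ_α/dt = A_α v(t)``.

    Phases are wrapped at every step; because wrapping commutes with addition
    modulo the lattice, the result depends only on the path's endpoint, which
    makes the code well defined regardless of trajectory.
    """
    lattice = lattice or HexLattice()
    v = np.asarray(velocities, dtype=float)
    if v.size == 0:
        return initial
    if v.ndim != 2:
        raise ValueError("velocities must have shape (T, N)")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite velocities")
    if not (np.isfinite(dt) and dt > 0):
        raise ValueError(f"dt must be positive, got {dt}")
    N = _check_dims(P, v[0])
    A = P.restrict(N).matrices
    phases = initial.phases.copy()
    Binv = lattice.inv_basis
    for vt in v:
        step = np.einsum("mij,j->mi", A, vt) * dt @ Binv.T
        phases = phases + step
        phases -= np.floor(phases)
    return GridCode(phases, lattice)


def stacked_rank(P: ProjectionSet, N: int, tol: float | None = None) -> int:
    """Numerical rank of the stacked 2M x N matrix.

    For Gaussian draws this equals min(2M, N) almost surely: the largest input
    dimension with a locally injective (full-column-rank) code is N = 2M.
    """
    return int(np.linalg.matrix_rank(P.stacked(N), tol=tol))
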