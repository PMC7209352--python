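"""Phase arithmetic on the hexagonal twisted torus.

A grid module's internal state lives on the quotient of the plane by a
hexagonal lattice Λ — the "twisted torus".  Everything downstream (encoding,
capacity search, tuning curves) reduces to three primitives implemented here:

* :func:`wrap_phase` — reduce a 2-vector to its representative in the
  fundamental domain of Λ (lattice coordinates in ``[0, 1)^2``),
* :func:`torus_distance` — the quotient metric
  ``d(p, q) = min_{λ∈Λ} ||p - q - λ||_2``,
* :func:`code_distance` — the distance between two multi-module grid codes,
  the maximum of the component-wise torus distances.

Phases are represented throughout in *lattice coordinates*: the pair
``(k1, k2)`` such that the Cartesian phase is ``k1*b1 + k2*b2`` with
``b1 = λ(1, 0)`` and ``b2 = λ(cos 60°, sin 60°)``.  Wrapping is then a pure
fractional-part operation; conversion to Cartesian coordinates happens only
inside distance computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "HexLattice",
    "GridCode",
    "wrap_phase",
    "phase_to_cartesian",
    "torus_distance",
    "code_distance",
]

# 3x3 block of integer lattice translates; covers the Voronoi cell of a
# hexagonal lattice around any point of the fundamental domain.
_TRANSLATES_3x3 = np.array(
    [[i, j] for i in (-1, 0, 1) for j in (-1, 0, 1)], dtype=float
)


def _frac(k: np.ndarray) -> np.ndarray:
    """Fractional part guaranteed to lie in [0, 1): ``frac(-tiny)`` rounds to
    1.0 in floating point and is mapped back to 0."""
    out = k - np.floor(k)
    out[out >= 1.0] = 0.0
    return out


@dataclass(frozen=True)
class HexLattice:
    """Hexagonal lattice Λ with basis ``b1 = λ(1,0)``, ``b2 = λ(1/2, √3/2)``.

    Parameters
    ----------
    period : float
        Lattice constant λ (length of both basis vectors).  The package
        convention is λ = 1; module-scale differences are carried by the
        projection matrices, not by per-module lattices.
    """

    period: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.period) and self.period > 0):
            raise ValueError(f"lattice period must be positive, got {self.period}")

    @cached_property
    def basis(self) -> np.ndarray:
        """Basis matrix with b1, b2 as columns."""
        lam = self.period
        return np.array([[lam, lam / 2.0], [0.0, lam * np.sqrt(3.0) / 2.0]])

    @cached_property
    def inv_basis(self) -> np.ndarray:
        return np.linalg.inv(self.basis)

    @property
    def circumradius(self) -> float:
        """Circumradius of the Voronoi cell, λ/√3 — the largest possible
        torus distance between two phases."""
        return self.period / np.sqrt(3.0)


def wrap_phase(v: np.ndarray, lattice: HexLattice | None = None) -> np.ndarray:
    """Reduce Cartesian 2-vectors to the fundamental domain of the lattice.

    Parameters
    ----------
    v : array_like, shape (..., 2)
        Cartesian phase-plane vectors.
    lattice : HexLattice, optional

    Returns
    -------
    ndarray, shape (..., 2)
        Lattice coordinates in ``[0, 1)^2``; ``v - basis @ result`` is a
        lattice vector.
    """
    lattice = lattice or HexLattice()
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 2:
        raise ValueError(f"phase vectors must have last axis 2, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite phase vector")
    return _frac(v @ lattice.inv_basis.T)


def phase_to_cartesian(p: np.ndarray, lattice: HexLattice | None = None) -> np.ndarray:
    """Convert lattice coordinates to Cartesian phase-plane vectors."""
    lattice = lattice or HexLattice()
    return np.asarray(p, dtype=float) @ lattice.basis.T


def torus_distance(
    p: np.ndarray, q: np.ndarray, lattice: HexLattice | None = None
) -> np.ndarray:
    """Quotient metric on the twisted torus.

    ``d(p, q) = min_{λ∈Λ} ||cart(p) - cart(q) - λ||_2``, computed by reducing
    ``p - q`` to the fundamental domain and minimising over the 3x3 block of
    lattice translates (sufficient for a hexagonal lattice).

    Parameters are phases in lattice coordinates, broadcastable to a common
    shape ``(..., 2)``; the result has shape ``(...)``.
    """
    lattice = lattice or HexLattice()
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape[-1] != 2 or q.shape[-1] != 2:
        raise ValueError("phases must have last axis 2")
    diff = p - q
    diff = diff - np.floor(diff)
    cand = diff[..., None, :] - _TRANSLATES_3x3  # (..., 9, 2)
    cart = cand @ lattice.basis.T
    return np.sqrt(np.min(np.sum(cart * cart, axis=-1), axis=-1))


@dataclass(frozen=True)
class GridCode:
    """An ordered set of M module phases representing one encoded point.

    ``phases`` holds lattice coordinates, shape ``(M, 2)``; they are wrapped
    into ``[0, 1)^2`` on construction so re-wrapping is the identity.
    """

    phases: np.ndarray
    lattice: HexLattice = field(default_factory=HexLattice)

    def __post_init__(self) -> None:
        phases = np.asarray(self.phases, dtype=float)
        if phases.ndim != 2 or phases.shape[1] != 2:
            raise ValueError(f"phases must have shape (M, 2), got {phases.shape}")
        if not np.all(np.isfinite(phases)):
            raise ValueError("non-finite phases")
        object.__setattr__(self, "phases", _frac(phases))

    @property
    def M(self) -> int:
        return self.phases.shape[0]

    @classmethod
    def from_cartesian(
        cls, vectors: np.ndarray, lattice: HexLattice | None = None
    ) -> "GridCode":
        lattice = lattice or HexLattice()
        return cls(wrap_phase(np.asarray(vectors, float), lattice), lattice)

    @classmethod
    def zero(cls, M: int, lattice: HexLattice | None = None) -> "GridCode":
        return cls(np.zeros((M, 2)), lattice or HexLattice())


def code_distance(c1: GridCode, c2: GridCode) -> float:
    """Distance between two grid codes: max over modules of torus distance."""
    if not isinstance(c1, GridCode) or not isinstance(c2, GridCode):
        raise TypeError("code_distance expects GridCode arguments")
    if c1.M != c2.M:
        raise ValueError(f"module counts differ: {c1.M} != {c2.M}")
    if c1.lattice != c2.lattice:
        raise ValueError("grid codes refer to different lattices")
    return float(np.max(torus_distance(c1.phases, c2.phases, c1.lattice)))
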