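"""Polarization algebra for periodic systems.

In the modern theory of polarization the bulk polarization ``P`` of a
periodic cell is only defined modulo a *quantum of polarization*: adding an
integer combination of lattice vectors (times the elementary charge) to
``P`` leaves the physics unchanged.  This module provides the small algebra
needed to work with that multivalued quantity:

* the quantum matrix ``Q`` whose columns are ``e * a_k`` for lattice
  vectors ``a_k``,
* reduction of ``P`` to the dimensionless reduced polarization
  ``p = Q^-1 P`` wrapped into ``[-1/2, 1/2)`` together with the integer
  branch offsets ``n`` such that ``P = Q (p + n)``,
* the von Mises error, the circular metric appropriate for period-1 data,
* unit conversions between e*Angstrom and Debye.

Internally the elementary charge is 1 (polarizations in e*Angstrom);
conversions are applied only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateCellError, ValidationError

__all__ = [
    "EA_TO_DEBYE",
    "Cell",
    "Frame",
    "PolarizationRecord",
    "quantum_matrix",
    "reduce_polarization",
    "wrap_half_open",
    "von_mises_error",
    "ea_to_debye",
    "debye_to_ea",
]

#: 1 e*Angstrom in Debye (CODATA).
EA_TO_DEBYE = 4.803205


@dataclass(frozen=True)
class Cell:
    """Periodic simulation cell.

    Parameters
    ----------
    vectors : (3, 3) array
        Lattice vectors as rows ``a_1, a_2, a_3`` in Angstrom.
    """

    vectors: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vectors, dtype=float)
        if v.shape != (3, 3) or not np.all(np.isfinite(v)):
            raise ValidationError("cell must be a finite 3x3 matrix")
        object.__setattr__(self, "vectors", v)
        if abs(np.linalg.det(v)) < 1e-12:
            raise DegenerateCellError(
                "lattice vectors are linearly dependent (volume ~ 0)"
            )

    @property
    def volume(self) -> float:
        return float(abs(np.linalg.det(self.vectors)))

    @classmethod
    def cubic(cls, a: float) -> "Cell":
        return cls(np.eye(3) * float(a))


@dataclass
class Frame:
    """One atomic configuration with a periodic cell.

    ``species`` are element symbols, ``positions`` Cartesian Angstrom,
    ``bonds`` an optional list of 0-based index pairs.
    """

    species: list[str]
    positions: np.ndarray
    cell: Cell
    bonds: list[tuple[int, int]] | None = None
    frame_id: int | str | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = list(self.species)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must be (N, 3)")
        if len(self.species) != self.positions.shape[0]:
            raise ValidationError("species and positions lengths differ")
        if not np.all(np.isfinite(self.positions)):
            raise ValidationError("non-finite atomic positions")

    def __len__(self) -> int:
        return len(self.species)


def quantum_matrix(cell: Cell) -> np.ndarray:
    """Quantum of polarization ``Q`` for a cell.

    Columns are ``e * a_k`` (e = 1 internally), units e*Angstrom.  Shifting
    ``P -> P + Q n`` for any integer vector ``n`` is a gauge transformation.
    """
    if not isinstance(cell, Cell):
        cell = Cell(np.asarray(cell, dtype=float))
    return cell.vectors.T.copy()


def wrap_half_open(x: np.ndarray) -> np.ndarray:
    """Wrap values into ``[-1/2, 1/2)`` (ties at +1/2 map to -1/2)."""
    x = np.asarray(x, dtype=float)
    w = x - np.floor(x + 0.5)
    # floor(x + 0.5) sends exactly +0.5 to the next branch, giving -0.5.
    return w


@dataclass
class PolarizationRecord:
    """A polarization split into branch data: ``P = Q (p + n)``."""

    P: np.ndarray
    p: np.ndarray
    n: np.ndarray
    frame_id: int | str | None = None

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.n = np.asarray(self.n)


def reduce_polarization(
    P: np.ndarray, Q: np.ndarray, frame_id=None
) -> PolarizationRecord:
    """Reduce a polarization vector modulo the quantum.

    Returns the record with ``p = wrap(Q^-1 P)`` componentwise in
    ``[-1/2, 1/2)`` and integer offsets ``n = Q^-1 P - p``.
    """
    P = np.asarray(P, dtype=float)
    if P.shape != (3,) or not np.all(np.isfinite(P)):
        raise ValidationError("P must be a finite 3-vector")
    Q = np.asarray(Q, dtype=float)
    if abs(np.linalg.det(Q)) < 1e-12:
        raise DegenerateCellError("quantum matrix is singular")
    x = np.linalg.solve(Q, P)
    p = wrap_half_open(x)
    n = np.rint(x - p).astype(int)
    return PolarizationRecord(P=P, p=p, n=n, frame_id=frame_id)


def von_mises_error(p_pred, p_calc) -> float:
    """Circular (von Mises) error between reduced polarizations.

    ``vME = 1 - (1/3N) sum_i sum_a cos[2 pi (p_pred_ia - p_calc_ia)]``,
    which lies in ``[0, 2]`` and is invariant under shifting any component
    of either argument by an integer (a change of branch).
    """
    a = np.atleast_2d(np.asarray(p_pred, dtype=float))
    b = np.atleast_2d(np.asarray(p_calc, dtype=float))
    if a.shape != b.shape:
        raise ValidationError(
            f"length mismatch: {a.shape} vs {b.shape}"
        )
    if a.size == 0:
        raise ValidationError("need at least one data point")
    return float(1.0 - np.mean(np.cos(2.0 * np.pi * (a - b))))


def ea_to_debye(x):
    """Convert e*Angstrom to Debye."""
    return np.asarray(x, dtype=float) * EA_TO_DEBYE


def debye_to_ea(x):
    """Convert Debye to e*Angstrom."""
    return np.asarray(x, dtype=float) / EA_TO_DEBYE
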