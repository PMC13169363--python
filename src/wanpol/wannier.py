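"""Wannier-center assignment, repair, and polarization reconstruction.

Maximally localized Wannier centers are doubly occupied orbitals; with
valence nuclear charges ``Z_i`` the cell dipole is

    P = e sum_i Z_i R_i - 2 e sum_j r_j^W.

To learn center positions with atom-centered models, each center is
assigned to an atom.  Writing ``N_i^W`` for the number of centers owned by
atom ``i`` and ``delta_ij = r_j^W - R_i`` their displacements, the
charge-consistent regrouping is

    P = e sum_i [ (Z_i - 2 N_i^W) R_i - Delta_i ],   Delta_i = sum_j 2 delta_ij,

an identity for *any* ownership — assignment is bookkeeping.  (When
displacements are taken minimum-image across a periodic boundary the two
forms differ by an integer number of polarization quanta, i.e. they agree
after reduction.)

Assignment is nearest-atom; because a few centers land nearer the wrong
atom (e.g. a C-C bond center drifting toward the central carbon of
ethanol), atoms are labeled by their bonded surroundings, the most
probable center count per label is tabulated, and miscounts are repaired
by transferring a center between bonded surplus/deficit atoms.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .core import Frame
from .exceptions import (
    NeutralityError,
    RepairFailureError,
    TieError,
    ValidationError,
)
from .geometry import mic_distance_matrix, perceive_bonds

__all__ = [
    "DEFAULT_VALENCE",
    "WannierSet",
    "AtomLabel",
    "WannierAssignment",
    "ExpectedCounts",
    "assign_nearest",
    "atom_labels",
    "most_probable_counts",
    "repair_assignment",
    "polarization_from_wannier",
    "cell_dipole_direct",
    "displacement_targets",
]

logger = logging.getLogger(__name__)

#: Valence (pseudopotential) charges, as in plane-wave DFT setups.
DEFAULT_VALENCE = {"O": 6, "C": 4, "H": 1}


@dataclass
class WannierSet:
    """Positions of doubly occupied Wannier centers (Cartesian Angstrom)."""

    positions: np.ndarray
    occupancy: int = 2

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 3 or not np.all(np.isfinite(self.positions)):
            raise ValidationError("center positions must be finite (N, 3)")

    def __len__(self):
        return self.positions.shape[0]


@dataclass(frozen=True)
class AtomLabel:
    """Species plus the sorted multiset of neighbor species within a cutoff."""

    species: str
    neighbor_signature: tuple[str, ...]

    def __str__(self):
        return f"{self.species}({','.join(self.neighbor_signature) or '-'})"


@dataclass
class WannierAssignment:
    """Ownership of centers by atoms, with displacement bookkeeping.

    ``displacements[i]`` are the minimum-image vectors of atom ``i``'s
    centers; ``delta_sums[i] = sum_j 2 delta_ij`` (e*Angstrom with e = 1).
    """

    owner: np.ndarray
    counts: np.ndarray
    displacements: list[np.ndarray]
    delta_sums: np.ndarray


def _recompute(frame: Frame, centers: WannierSet, owner: np.ndarray) -> WannierAssignment:
    n_atoms = len(frame)
    counts = np.bincount(owner, minlength=n_atoms)
    _, vecs = mic_distance_matrix(
        frame.positions, centers.positions, frame.cell, return_vectors=True
    )
    displacements = [vecs[i, owner == i] for i in range(n_atoms)]
    delta_sums = np.array([2.0 * d.sum(axis=0) if len(d) else np.zeros(3)
                           for d in displacements])
    return WannierAssignment(owner, counts, displacements, delta_sums)


def assign_nearest(
    frame: Frame, centers: WannierSet, tie_tolerance: float = 1e-9
) -> WannierAssignment:
    """Assign every center to its nearest atom (minimum image)."""
    if len(centers) == 0:
        raise ValidationError("empty Wannier center set")
    dist = mic_distance_matrix(centers.positions, frame.positions, frame.cell)
    order = np.argsort(dist, axis=1)
    nearest = order[:, 0]
    if dist.shape[1] > 1:
        gap = dist[np.arange(len(centers)), order[:, 1]] - dist[
            np.arange(len(centers)), nearest
        ]
        ties = np.nonzero(gap < tie_tolerance)[0]
        if len(ties):
            raise TieError(
                f"center(s) {ties.tolist()} equidistant from two atoms "
                f"(within {tie_tolerance} A)"
            )
    return _recompute(frame, centers, nearest)


def atom_labels(frame: Frame, label_cutoff: float = 1.8) -> list[AtomLabel]:
    """Label atoms by the species found within ``label_cutoff``.

    The default 1.8 A covers covalent bonds while excluding hydrogen-bond
    partners, so chemically equivalent atoms share a label.
    """
    if label_cutoff <= 0:
        raise ValidationError("label_cutoff must be positive")
    dist = mic_distance_matrix(frame.positions, frame.positions, frame.cell)
    labels = []
    for i in range(len(frame)):
        near = np.nonzero((dist[i] <= label_cutoff) & (np.arange(len(frame)) != i))[0]
        sig = tuple(sorted(frame.species[j] for j in near))
        labels.append(AtomLabel(species=frame.species[i], neighbor_signature=sig))
    return labels


@dataclass
class ExpectedCounts:
    """Most probable number of Wannier centers per atom label."""

    table: dict[AtomLabel, int] = field(default_factory=dict)


def most_probable_counts(
    assignments: list[WannierAssignment], labels: list[list[AtomLabel]]
) -> ExpectedCounts:
    """Tabulate the modal center count for each atom label.

    Ties are broken toward the larger count (with a logged warning).
    """
    if not assignments:
        raise ValidationError("need at least one assignment")
    tally: dict[AtomLabel, Counter] = {}
    for asg, labs in zip(assignments, labels):
        for lab, c in zip(labs, asg.counts):
            tally.setdefault(lab, Counter())[int(c)] += 1
    table = {}
    for lab, counter in tally.items():
        best = max(counter.items(), key=lambda kv: (kv[1], kv[0]))
        if sum(1 for v in counter.values() if v == best[1]) > 1:
            logger.warning(
                "tie in modal center count for label %s; choosing %d", lab, best[0]
            )
        table[lab] = best[0]
    return ExpectedCounts(table=table)


def repair_assignment(
    frame: Frame,
    raw: WannierAssignment,
    expected: ExpectedCounts,
    centers: WannierSet,
    labels: list[AtomLabel] | None = None,
    bonds: list[tuple[int, int]] | None = None,
) -> WannierAssignment:
    """Move miscounted centers between bonded atoms until counts match.

    The transferred center is the surplus atom's center closest to the
    deficit atom.  Conserves the total center count exactly; idempotent on
    already-correct assignments.  Raises when no bonded surplus/deficit
    pair remains but counts still differ.
    """
    if labels is None:
        labels = atom_labels(frame)
    if bonds is None:
        bonds = frame.bonds if frame.bonds is not None else perceive_bonds(frame)
    try:
        target = np.array([expected.table[lab] for lab in labels])
    except KeyError as exc:
        raise RepairFailureError(f"no expected count for label {exc.args[0]}") from None

    adj: dict[int, set[int]] = {i: set() for i in range(len(frame))}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)

    owner = raw.owner.copy()
    counts = np.bincount(owner, minlength=len(frame))
    dist_ca = mic_distance_matrix(centers.positions, frame.positions, frame.cell)
    for _ in range(len(centers) + 1):
        deficit = np.nonzero(counts < target)[0]
        if len(deficit) == 0:
            break
        moved = False
        for d in deficit:
            donors = [s for s in adj[d] if counts[s] > target[s]]
            if not donors:
                continue
            owned = [
                (dist_ca[c, d], c, s)
                for s in donors
                for c in np.nonzero(owner == s)[0]
            ]
            _, c_best, s_best = min(owned)
            owner[c_best] = d
            counts[d] += 1
            counts[s_best] -= 1
            moved = True
        if not moved:
            break
    if not np.array_equal(counts, target):
        bad = np.nonzero(counts != target)[0]
        raise RepairFailureError(
            f"center counts unresolvable by bonded transfer at atoms {bad.tolist()}",
            atoms=bad.tolist(),
        )
    return _recompute(frame, centers, owner)


def _valence_vector(frame: Frame, valence: dict[str, int] | None) -> np.ndarray:
    val = DEFAULT_VALENCE if valence is None else valence
    try:
        return np.array([val[s] for s in frame.species], dtype=float)
    except KeyError as exc:
        raise ValidationError(f"no valence charge for species {exc.args[0]!r}") from None


def _check_neutral(Z: np.ndarray, n_centers: int):
    if int(round(Z.sum())) != 2 * n_centers:
        raise NeutralityError(
            f"sum of valences {Z.sum():g} != 2 x {n_centers} center electrons"
        )


def cell_dipole_direct(
    frame: Frame, centers: WannierSet, valence: dict[str, int] | None = None
) -> np.ndarray:
    """Total cell dipole from nuclei and raw center positions (e*Angstrom)."""
    Z = _valence_vector(frame, valence)
    _check_neutral(Z, len(centers))
    return Z @ frame.positions - 2.0 * centers.positions.sum(axis=0)


def polarization_from_wannier(
    frame: Frame,
    assignment: WannierAssignment,
    valence: dict[str, int] | None = None,
) -> np.ndarray:
    """Cell dipole from an assignment: ``sum_i (Z_i - 2 N_i^W) R_i - Delta_i``."""
    Z = _valence_vector(frame, valence)
    _check_neutral(Z, int(assignment.counts.sum()))
    charges = Z - 2.0 * assignment.counts
    return charges @ frame.positions - assignment.delta_sums.sum(axis=0)


def displacement_targets(
    frame: Frame, centers: WannierSet, expected: ExpectedCounts | None = None
) -> tuple[WannierAssignment, np.ndarray]:
    """Assign (and repair, when a count table is given) then return ``Delta_i``."""
    asg = assign_nearest(frame, centers)
    if expected is not None:
        asg = repair_assignment(frame, asg, expected, centers)
    return asg, asg.delta_sums
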