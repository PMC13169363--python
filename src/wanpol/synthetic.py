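"""Synthetic fixtures with known ground truth.

Generates every input the rest of the package consumes, so tests and the
acceptance checks run without any external data:

* dilute mixtures of rigid idealized water and ethanol molecules in a
  periodic box (random rigid rotations, rejection-sampled placement),
* Wannier centers placed at bond and lone-pair construction sites with
  optional Gaussian jitter,
* a smooth point-charge + bond-dipole polarization oracle (infinitely
  differentiable in the positions; the charge values are fixed but
  arbitrary — only smoothness and determinism matter),
* branch-scattered reduced polarizations with known integer offsets,
* harmonic dipole trajectories with known spectral lines.

Every generator is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Cell, Frame, quantum_matrix, reduce_polarization
from .exceptions import PackingError, ValidationError
from .geometry import identify_molecules, mic_distance_matrix
from .spectra import SPEED_OF_LIGHT_CM_FS, DipoleTrajectory
from .wannier import WannierSet

__all__ = [
    "FixtureSpec",
    "water_template",
    "ethanol_template",
    "make_mixture_frame",
    "make_dataset",
    "make_wannier_centers",
    "smooth_polarization_oracle",
    "wrap_with_random_branches",
    "score_offset_recovery",
    "harmonic_dipole_trajectory",
]

#: Oracle point charges (e); each molecule is neutral.
ORACLE_CHARGES = {
    "water": {"O": -0.8, "H": 0.4},
}
# ethanol charges are per-site (atom order of ethanol_template)
_ETHANOL_CHARGES = np.array(
    [-0.27, 0.15, -0.70, 0.06, 0.06, 0.06, 0.11, 0.11, 0.42]
)
#: Bond-dipole coefficients per unordered species pair (e).
ORACLE_BOND_DIPOLES = {
    frozenset(("O", "H")): 0.15,
    frozenset(("C", "H")): 0.05,
    frozenset(("C", "O")): 0.10,
    frozenset(("C", "C")): 0.0,
}
_BOND_DIPOLE_RANGE = 4.0  # Angstrom, smooth damping length


@dataclass(frozen=True)
class FixtureSpec:
    """Composition and randomness of a synthetic mixture fixture."""

    n_water: int = 4
    n_ethanol: int = 0
    box: float = 9.0
    seed: int = 0
    noise_scale: float = 0.0
    branch_offset_range: int = 2

    def __post_init__(self):
        if self.n_water < 0 or self.n_ethanol < 0:
            raise ValidationError("molecule counts must be >= 0")
        if self.box <= 0:
            raise ValidationError("box must be positive")


def _tetrahedral_completion(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two unit vectors completing a tetrahedron around given bonds a, b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    bisector = -(a + b)
    bisector /= np.linalg.norm(bisector)
    perp = np.cross(a, b)
    perp /= np.linalg.norm(perp)
    half = np.deg2rad(109.471 / 2.0)
    return np.stack(
        [
            np.cos(half) * bisector + np.sin(half) * perp,
            np.cos(half) * bisector - np.sin(half) * perp,
        ]
    )


def water_template() -> tuple[list[str], np.ndarray, list[tuple[int, int]]]:
    """Rigid bent water: r(OH) = 0.96 A, angle 104.5 deg."""
    half = np.deg2rad(104.5 / 2.0)
    pos = np.array(
        [
            [0.0, 0.0, 0.0],
            [0.96 * np.sin(half), 0.0, 0.96 * np.cos(half)],
            [-0.96 * np.sin(half), 0.0, 0.96 * np.cos(half)],
        ]
    )
    return ["O", "H", "H"], pos, [(0, 1), (0, 2)]


def ethanol_template() -> tuple[list[str], np.ndarray, list[tuple[int, int]]]:
    """Rigid idealized ethanol, atom order Cb, Ca, O, 3xHb, 2xHa, Ho."""
    tet = np.deg2rad(109.471)
    cb = np.zeros(3)
    ca = np.array([1.54, 0.0, 0.0])
    u_o = np.array([np.cos(np.pi - tet), np.sin(np.pi - tet), 0.0])
    o = ca + 1.43 * u_o
    # methyl hydrogens: tetrahedral about the C-C axis (+x), staggered
    ux, s = np.cos(tet), np.sin(tet)
    hb = [
        cb + 1.09 * np.array([ux, s * np.cos(phi), s * np.sin(phi)])
        for phi in (np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3)
    ]
    ha_dirs = _tetrahedral_completion(-ca / np.linalg.norm(ca), u_o)
    ha = [ca + 1.09 * d for d in ha_dirs]
    # hydroxyl H: 108.5 deg from the O->Ca bond, in the heavy-atom plane
    u_oc = (ca - o) / np.linalg.norm(ca - o)
    ang = np.deg2rad(108.5)
    perp = np.array([-u_oc[1], u_oc[0], 0.0])
    perp /= np.linalg.norm(perp)
    ho = o + 0.96 * (np.cos(ang) * u_oc + np.sin(ang) * perp)
    species = ["C", "C", "O", "H", "H", "H", "H", "H", "H"]
    pos = np.array([cb, ca, o, *hb, *ha, ho])
    bonds = [(0, 1), (1, 2), (0, 3), (0, 4), (0, 5), (1, 6), (1, 7), (2, 8)]
    return species, pos, bonds


def make_mixture_frame(spec: FixtureSpec, seed: int | None = None) -> Frame:
    """Place rigid molecules with random rotations, without overlap.

    Placement is rejection sampling with a heavy-atom minimum distance of
    2.2 A and a bounded attempt count.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    cell = Cell.cubic(spec.box)
    templates = [water_template()] * spec.n_water + [
        ethanol_template()
    ] * spec.n_ethanol
    species: list[str] = []
    positions: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    heavy: list[np.ndarray] = []
    for symbols, tpl_pos, tpl_bonds in templates:
        placed = False
        for _ in range(10_000):
            quat = rng.normal(size=4)
            R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
            center = rng.uniform(0.0, spec.box, size=3)
            pos = tpl_pos @ R.T + center
            new_heavy = pos[[i for i, s in enumerate(symbols) if s != "H"]]
            if heavy:
                d = mic_distance_matrix(new_heavy, np.concatenate(heavy), cell)
                if d.min() < 2.2:
                    continue
            offset = len(species)
            species.extend(symbols)
            positions.append(pos)
            bonds.extend((i + offset, j + offset) for i, j in tpl_bonds)
            heavy.append(new_heavy)
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place molecule in a {spec.box} A box; enlarge it"
            )
    if not positions:
        raise ValidationError("empty fixture (no molecules requested)")
    return Frame(
        species=species,
        positions=np.concatenate(positions),
        cell=cell,
        bonds=bonds,
    )


def make_dataset(spec: FixtureSpec, n_frames: int) -> list[Frame]:
    """Independent frames, deterministically seeded from ``spec.seed``."""
    frames = []
    for i in range(n_frames):
        f = make_mixture_frame(spec, seed=np.random.SeedSequence([spec.seed, i]))
        f.frame_id = i
        frames.append(f)
    return frames


def make_wannier_centers(
    frame: Frame, noise_scale: float = 0.0, seed: int = 0
) -> WannierSet:
    """Centers at bond/lone-pair construction sites, plus Gaussian jitter.

    Water O: 2 bond + 2 lone-pair sites (4 total).  Ethanol: 4 on the
    terminal (beta) carbon (3 C-H + the C-C bond center, placed nearer the
    beta carbon), 2 on the central carbon, 4 on oxygen.  Total centers are
    half the summed valence charges.  Bond and lone-pair radii differ
    (0.45 vs 0.25 A on oxygen) so the displacement sums carry a strong
    orientation-dependent signal rather than cancelling by symmetry.
    """
    rng = np.random.default_rng(seed)
    pos = frame.positions
    sites: list[np.ndarray] = []
    for mol in identify_molecules(frame):
        atoms = mol["atoms"]
        if mol["kind"] == "water":
            o = pos[mol["oxygen"]]
            u = [pos[h] - o for h in mol["hydrogens"]]
            u = [v / np.linalg.norm(v) for v in u]
            sites += [o + 0.45 * u[0], o + 0.45 * u[1]]
            sites += [o + 0.25 * d for d in _tetrahedral_completion(u[0], u[1])]
        elif mol["kind"] == "ethanol":
            o_i = mol["oxygen"]
            carbons = [i for i in atoms if frame.species[i] == "C"]
            beta = mol["beta_carbon"]
            alpha = next(c for c in carbons if c != beta)
            o = pos[o_i]
            u_oc = pos[alpha] - o
            u_oh = pos[mol["hydrogens"][0]] - o
            u_oc /= np.linalg.norm(u_oc)
            u_oh /= np.linalg.norm(u_oh)
            sites += [o + 0.5 * u_oc, o + 0.45 * u_oh]
            sites += [o + 0.25 * d for d in _tetrahedral_completion(u_oc, u_oh)]
            for c_i in (beta, alpha):
                hs = [
                    j
                    for j in atoms
                    if frame.species[j] == "H"
                    and np.linalg.norm(pos[j] - pos[c_i]) < 1.2
                ]
                for h in hs:
                    u = pos[h] - pos[c_i]
                    sites.append(pos[c_i] + 0.4 * u / np.linalg.norm(u))
            u_cc = pos[alpha] - pos[beta]
            sites.append(pos[beta] + 0.6 * u_cc / np.linalg.norm(u_cc))
        else:
            raise ValidationError("fixture frames must contain water/ethanol only")
    out = np.array(sites)
    if noise_scale > 0:
        out = out + rng.normal(scale=noise_scale, size=out.shape)
    return WannierSet(positions=out)


def _oracle_charges(frame: Frame) -> np.ndarray:
    q = np.zeros(len(frame))
    for mol in identify_molecules(frame):
        if mol["kind"] == "water":
            for i in mol["atoms"]:
                q[i] = ORACLE_CHARGES["water"][frame.species[i]]
        elif mol["kind"] == "ethanol":
            # template order is preserved inside each molecule
            q[mol["atoms"]] = _ETHANOL_CHARGES
        else:
            raise ValidationError("oracle defined for water/ethanol only")
    return q


def smooth_polarization_oracle(frame: Frame) -> np.ndarray:
    """Smooth ground-truth polarization (e*Angstrom).

    A fixed point-charge sum plus a smoothly damped bond-dipole term; the
    charge model is arbitrary but deterministic, and the result is an
    infinitely differentiable function of the positions.
    """
    q = _oracle_charges(frame)
    P = q @ frame.positions
    bonds = frame.bonds if frame.bonds is not None else []
    for i, j in bonds:
        kappa = ORACLE_BOND_DIPOLES[
            frozenset((frame.species[i], frame.species[j]))
        ]
        d = frame.positions[j] - frame.positions[i]
        r2 = float(d @ d)
        P = P + kappa * d * np.exp(-r2 / _BOND_DIPOLE_RANGE**2)
    return P


def wrap_with_random_branches(
    P_list: np.ndarray,
    Q: np.ndarray,
    seed: int = 0,
    offset_range: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter smooth polarizations across branches with known offsets.

    Each smooth polarization is reduced to ``[-1/2, 1/2)`` and then shifted
    by a uniform random integer 3-vector in ``[-offset_range, offset_range]``
    — the multivalued cloud an unconverged branch choice produces.  Returns
    the scattered reduced polarizations and the true offsets; unwrapping
    should undo the offsets up to a single global integer per component.
    """
    if offset_range < 1:
        raise ValidationError("offset_range must be >= 1")
    rng = np.random.default_rng(seed)
    P_list = np.atleast_2d(np.asarray(P_list, dtype=float))
    reduced = np.stack([reduce_polarization(P, Q).p for P in P_list])
    offsets = rng.integers(-offset_range, offset_range + 1, size=reduced.shape)
    return reduced + offsets, offsets


def score_offset_recovery(recovered: np.ndarray, true_offsets: np.ndarray) -> float:
    """Fraction of points whose branch offset is recovered exactly.

    Recovery is judged up to the global integer gauge: a point counts as
    recovered when ``recovered + true`` equals the componentwise mode of
    that sum over the dataset.
    """
    recovered = np.asarray(recovered, dtype=int)
    true_offsets = np.asarray(true_offsets, dtype=int)
    total = recovered + true_offsets
    gauge = np.array(
        [np.bincount(col - col.min()).argmax() + col.min() for col in total.T]
    )
    return float(np.mean(np.all(total == gauge, axis=1)))


def harmonic_dipole_trajectory(
    lines: list[tuple[float, float]],
    dt: float = 0.5,
    n_steps: int = 2**14,
    noise: float = 0.0,
    seed: int = 0,
) -> DipoleTrajectory:
    """Sum of cosines with known wavenumbers plus white noise.

    ``lines`` are (wavenumber cm^-1, amplitude) pairs; each line gets a
    random direction and phase drawn from the seed.
    """
    rng = np.random.default_rng(seed)
    nyquist = 1.0 / (2.0 * dt) / SPEED_OF_LIGHT_CM_FS
    t = np.arange(n_steps) * dt
    P = np.zeros((n_steps, 3))
    for wn, amp in lines:
        if wn >= nyquist:
            raise ValidationError(
                f"line at {wn} cm^-1 is above the Nyquist wavenumber {nyquist:.0f}"
            )
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        phase = rng.uniform(0, 2 * np.pi)
        f = wn * SPEED_OF_LIGHT_CM_FS
        P += amp * np.outer(np.cos(2 * np.pi * f * t + phase), direction)
    if noise > 0:
        P += rng.normal(scale=noise, size=P.shape)
    return DipoleTrajectory(times=t, P=P)
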