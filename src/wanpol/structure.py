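"""Hydrogen-bond statistics and hydration-shell structure.

Counts hydrogen bonds with a geometric criterion (O...O distance and
H-donor-O...acceptor-O angle; the Luzar-Chandler 3.5 A / 30 degree
convention by default), compares the per-water participation count
against an ideal-mixing baseline linear in the ethanol mole fraction, and
resolves the excess spatially as a function of the distance from each
water oxygen to the nearest ethanol beta-carbon (the methyl carbon, not
bonded to oxygen).  The first-shell cutoff is taken from the first
minimum of the beta-C--O(water) radial distribution function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Frame
from .exceptions import ValidationError
from .geometry import identify_molecules, mic_distance_matrix

__all__ = [
    "HBondCriterion",
    "HBondSummary",
    "RadialDistribution",
    "ExcessDensityProfile",
    "find_hydrogen_bonds",
    "water_participation_counts",
    "mean_hbonds_per_water",
    "ideal_hbond_baseline",
    "radial_distribution",
    "first_shell_membership",
    "excess_hbond_density",
    "water_beta_carbon_distances",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric hydrogen-bond definition."""

    max_OO_distance: float = 3.5
    max_angle: float = 30.0

    def __post_init__(self):
        if self.max_OO_distance <= 0 or self.max_angle <= 0:
            raise ValidationError("criterion parameters must be positive")


def find_hydrogen_bonds(
    frame: Frame,
    criterion: HBondCriterion = HBondCriterion(),
    molecules: list[dict] | None = None,
) -> list[tuple[int, int, int]]:
    """All (donor_O, H, acceptor_O) triplets satisfying the criterion.

    Donors are hydroxyl/water oxygens with their covalently bonded
    hydrogens; acceptors are all oxygens.  Each bond is counted once.
    """
    if molecules is None:
        molecules = identify_molecules(frame)
    oxygens = [m["oxygen"] for m in molecules if m["oxygen"] is not None]
    if not oxygens:
        return []
    pos = frame.positions
    o_pos = pos[oxygens]
    oo = mic_distance_matrix(o_pos, o_pos, frame.cell)
    cos_max = np.cos(np.deg2rad(criterion.max_angle))
    bonds = []
    for di, mol in enumerate(m for m in molecules if m["oxygen"] is not None):
        d_o = mol["oxygen"]
        for ai, a_o in enumerate(oxygens):
            if a_o == d_o or oo[di, ai] > criterion.max_OO_distance:
                continue
            v_oa = _mic_vec(pos[a_o] - pos[d_o], frame)
            for h in mol.get("hydrogens", []):
                v_oh = _mic_vec(pos[h] - pos[d_o], frame)
                cosang = float(
                    v_oh @ v_oa / (np.linalg.norm(v_oh) * np.linalg.norm(v_oa))
                )
                if cosang >= cos_max:
                    bonds.append((d_o, h, a_o))
    return bonds


def _mic_vec(d, frame):
    from .geometry import minimum_image

    return minimum_image(d, frame.cell)


def water_participation_counts(
    frame: Frame,
    criterion: HBondCriterion = HBondCriterion(),
    molecules: list[dict] | None = None,
) -> np.ndarray:
    """Hydrogen bonds each water takes part in (as donor or acceptor)."""
    if molecules is None:
        molecules = identify_molecules(frame)
    bonds = find_hydrogen_bonds(frame, criterion, molecules)
    waters = [m for m in molecules if m["kind"] == "water"]
    counts = np.zeros(len(waters))
    o_to_w = {m["oxygen"]: k for k, m in enumerate(waters)}
    for d_o, _h, a_o in bonds:
        if d_o in o_to_w:
            counts[o_to_w[d_o]] += 1
        if a_o in o_to_w:
            counts[o_to_w[a_o]] += 1
    return counts


def mean_hbonds_per_water(
    frames: list[Frame], criterion: HBondCriterion = HBondCriterion()
) -> float:
    """Average hydrogen-bond participation per water over frames."""
    vals = [water_participation_counts(f, criterion) for f in frames]
    all_counts = np.concatenate([v for v in vals if len(v)])
    if all_counts.size == 0:
        raise ValidationError("no water molecules found")
    return float(all_counts.mean())


@dataclass
class HBondSummary:
    """Mean H-bond count, the ideal-mixing baseline, and their difference."""

    x_e: float
    n_HB: float
    n_HB_ideal: float
    delta: float


def ideal_hbond_baseline(
    n_HB_at_x0: float,
    n_HB_at_x1: float,
    x0: float,
    x1: float,
    x_e: float,
    n_HB: float | None = None,
) -> HBondSummary:
    """Excess H-bond count relative to a linear-in-mole-fraction baseline.

    The ideal value interpolates linearly between two endpoint means; the
    excess is ``n_HB - n_HB_ideal`` and vanishes exactly at the endpoints.
    """
    if x0 == x1:
        raise ValidationError("baseline endpoints must differ")
    lo, hi = min(x0, x1), max(x0, x1)
    if not lo <= x_e <= hi:
        warnings.warn(
            f"x_e = {x_e} outside the baseline range [{lo}, {hi}]; extrapolating",
            stacklevel=2,
        )
    ideal = n_HB_at_x0 + (n_HB_at_x1 - n_HB_at_x0) * (x_e - x0) / (x1 - x0)
    value = ideal if n_HB is None else n_HB
    return HBondSummary(x_e=x_e, n_HB=value, n_HB_ideal=ideal, delta=value - ideal)


@dataclass
class RadialDistribution:
    """g(r) on a uniform grid with located first maximum and minimum."""

    r: np.ndarray
    g: np.ndarray
    first_max: float | None
    first_min: float | None


def _select_positions(frame: Frame, selector: str, molecules: list[dict]):
    if selector == "Cbeta":
        return np.array(
            [m["beta_carbon"] for m in molecules if m["kind"] == "ethanol"],
            dtype=int,
        )
    if selector == "Owater":
        return np.array(
            [m["oxygen"] for m in molecules if m["kind"] == "water"], dtype=int
        )
    return np.array(
        [i for i, s in enumerate(frame.species) if s == selector], dtype=int
    )


def radial_distribution(
    frames: list[Frame],
    species_pair: tuple[str, str],
    r_max: float,
    n_bins: int = 100,
    smooth_width: int = 3,
) -> RadialDistribution:
    """Normalized pair distribution g(r) between two selections.

    Selectors are element symbols or the special names ``"Cbeta"`` (the
    ethanol methyl carbon) and ``"Owater"``.  Extrema are located on a
    moving-average smoothed curve; ``first_min`` is the first local
    minimum after the first maximum.
    """
    if not frames:
        raise ValidationError("need at least one frame")
    half = 0.5 * min(np.linalg.norm(v) for v in frames[0].cell.vectors)
    if r_max > half + 1e-9:
        raise ValidationError(
            f"r_max {r_max} exceeds half the smallest cell width {half:.3f}"
        )
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    norm = 0.0
    for frame in frames:
        molecules = identify_molecules(frame)
        ia = _select_positions(frame, species_pair[0], molecules)
        ib = _select_positions(frame, species_pair[1], molecules)
        if len(ia) == 0 or len(ib) == 0:
            continue
        d = mic_distance_matrix(
            frame.positions[ia], frame.positions[ib], frame.cell
        )
        if species_pair[0] == species_pair[1]:
            iu = np.triu_indices(len(ia), k=1)
            dvals = d[iu]
            n_pairs = len(ia) * (len(ib) - 1) / 2
        else:
            shared = np.intersect1d(ia, ib)
            dvals = d[d > 1e-9] if len(shared) else d.ravel()
            n_pairs = len(ia) * len(ib) - len(shared)
        hist += np.histogram(dvals, bins=edges)[0]
        norm += n_pairs / frame.cell.volume
    if norm == 0:
        raise ValidationError("selections are empty in every frame")
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = hist / (shell * norm)
    r = 0.5 * (edges[1:] + edges[:-1])
    first_max, first_min = _first_extrema(r, g, smooth_width)
    return RadialDistribution(r=r, g=g, first_max=first_max, first_min=first_min)


def _first_extrema(r, g, smooth_width):
    if smooth_width > 1:
        kernel = np.ones(smooth_width) / smooth_width
        gs = np.convolve(g, kernel, mode="same")
    else:
        gs = g
    imax = None
    for i in range(1, len(gs) - 1):
        if gs[i] > 0 and gs[i] >= gs[i - 1] and gs[i] > gs[i + 1]:
            imax = i
            break
    if imax is None:
        return None, None
    for i in range(imax + 1, len(gs) - 1):
        if gs[i] <= gs[i - 1] and gs[i] < gs[i + 1]:
            return float(r[imax]), float(r[i])
    return float(r[imax]), None


def water_beta_carbon_distances(
    frame: Frame, molecules: list[dict] | None = None
) -> np.ndarray:
    """Distance from each water oxygen to the nearest ethanol beta-carbon."""
    if molecules is None:
        molecules = identify_molecules(frame)
    waters = [m["oxygen"] for m in molecules if m["kind"] == "water"]
    betas = [m["beta_carbon"] for m in molecules if m["kind"] == "ethanol"]
    if not betas:
        return np.full(len(waters), np.inf)
    d = mic_distance_matrix(
        frame.positions[waters], frame.positions[betas], frame.cell
    )
    return d.min(axis=1)


def first_shell_membership(
    frame: Frame, shell_cutoff: float, molecules: list[dict] | None = None
) -> np.ndarray:
    """One boolean per molecule: water in the first shell of any ethanol.

    Membership means the water oxygen lies within ``shell_cutoff`` of the
    nearest ethanol beta-carbon (minimum image).  Non-water molecules are
    always False; with no ethanol present all entries are False (with a
    warning).
    """
    if molecules is None:
        molecules = identify_molecules(frame)
    flags = np.zeros(len(molecules), dtype=bool)
    betas = [m["beta_carbon"] for m in molecules if m["kind"] == "ethanol"]
    if not betas:
        warnings.warn("no ethanol in frame; no water is first-shell", stacklevel=2)
        return flags
    dists = water_beta_carbon_distances(frame, molecules)
    wi = 0
    for k, m in enumerate(molecules):
        if m["kind"] == "water":
            flags[k] = dists[wi] <= shell_cutoff
            wi += 1
    return flags


@dataclass
class ExcessDensityProfile:
    """Excess H-bond density versus distance to the nearest beta-carbon."""

    bin_edges: np.ndarray
    delta_rho: np.ndarray
    first_max: float | None = None
    first_min: float | None = None

    def __post_init__(self):
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValidationError("bin edges must be ascending")


def excess_hbond_density(
    frames: list[Frame],
    bins: np.ndarray,
    baseline_n_HB: float,
    criterion: HBondCriterion = HBondCriterion(),
    first_max: float | None = None,
    first_min: float | None = None,
) -> ExcessDensityProfile:
    """Spatially resolved excess of H-bonds around ethanol.

    For each distance bin (water oxygen to nearest beta-carbon) the excess
    participation relative to the ideal-mixing baseline is accumulated and
    divided by the shell volume, then averaged over frames.  Bins never
    populated are reported as NaN, not zero.
    """
    bins = np.asarray(bins, dtype=float)
    if np.any(np.diff(bins) <= 0):
        raise ValidationError("bins must be strictly ascending")
    half = 0.5 * min(np.linalg.norm(v) for v in frames[0].cell.vectors)
    if bins[-1] > half + 1e-9:
        raise ValidationError("bins extend beyond half the cell width")
    nb = len(bins) - 1
    excess = np.zeros(nb)
    populated = np.zeros(nb, dtype=bool)
    for frame in frames:
        molecules = identify_molecules(frame)
        counts = water_participation_counts(frame, criterion, molecules)
        dists = water_beta_carbon_distances(frame, molecules)
        which = np.digitize(dists, bins) - 1
        for w, b in enumerate(which):
            if 0 <= b < nb:
                excess[b] += counts[w] - baseline_n_HB
                populated[b] = True
    shell = 4.0 / 3.0 * np.pi * (bins[1:] ** 3 - bins[:-1] ** 3)
    delta_rho = excess / (shell * len(frames))
    delta_rho[~populated] = np.nan
    return ExcessDensityProfile(
        bin_edges=bins, delta_rho=delta_rho, first_max=first_max, first_min=first_min
    )
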