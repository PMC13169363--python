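"""Atom-centered descriptors and rotationally covariant kernels.

The regression models in this package learn 3-vectors (polarizations,
Wannier displacement sums), so their kernels must transform covariantly
under rotation: ``K(R a, b) = R K(a, b)``.  We use the standard
symmetry-adapted construction: a neighbor-density expansion in products of
Gaussian radial functions and spherical harmonics yields

* rotationally *invariant* scalar features (the power spectrum of the
  density coefficients, per species pair), and
* λ=1 *covariant* vector features ``V[s, n] = sum_j g_n(r_ij) fc(r_ij)
  r_ij / |r_ij|`` (the l=1 channel written in Cartesian form).

The covariant kernel between environments ``a`` and ``b`` is

    K(a, b) = k0(a, b)^(zeta-1) * V_a^T V_b          (3x3 matrix)

with ``k0`` the normalized dot product of the scalar features.  Covariance
is exact by construction; the scalar prefactor injects the many-body
(power-spectrum order) sensitivity controlled by ``l_max`` and ``zeta``.
Environments with different central species have zero kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from .core import Frame
from .exceptions import ValidationError

__all__ = ["DescriptorConfig", "FrameFeatures", "compute_features", "covariant_kernel"]


@dataclass(frozen=True)
class DescriptorConfig:
    """Hyperparameters of the atomic-environment descriptor.

    Defaults (cutoff 4.0 A, 6 radial functions, l_max 4, width 0.3 A) are
    sensible for hydrogen-bonded molecular liquids; all are exposed.
    """

    radial_cutoff: float = 4.0
    n_radial: int = 6
    l_max: int = 4
    gaussian_width: float = 0.3
    species_list: tuple[str, ...] = ("H", "C", "O")

    def __post_init__(self):
        if self.radial_cutoff <= 0:
            raise ValidationError("radial_cutoff must be positive")
        if self.n_radial < 1 or self.l_max < 1:
            raise ValidationError("n_radial and l_max must be >= 1")
        object.__setattr__(self, "species_list", tuple(self.species_list))


@dataclass
class FrameFeatures:
    """Per-atom features of one frame.

    ``scalars``: (N, d_s) rotation-invariant, already L2-normalized.
    ``vectors``: (N, d_v, 3) covariant vector features.
    ``species_idx``: (N,) index into ``config.species_list``.
    """

    scalars: np.ndarray
    vectors: np.ndarray
    species_idx: np.ndarray
    config: DescriptorConfig


def _neighbors_within(frame: Frame, cutoff: float):
    """All periodic neighbors within ``cutoff`` of each atom.

    Returns per-atom arrays of displacement vectors and neighbor species
    indices; self-images at nonzero lattice shifts are included, the atom
    itself is not.
    """
    import itertools

    pos = frame.positions
    n = len(frame)
    shifts = np.array(
        list(itertools.product((-1, 0, 1), repeat=3)), dtype=float
    ) @ frame.cell.vectors
    disp = pos[None, :, None, :] + shifts[None, None, :, :] - pos[:, None, None, :]
    r2 = np.einsum("ijks,ijks->ijk", disp, disp)
    mask = (r2 <= cutoff * cutoff) & (r2 > 1e-14)
    out = []
    for i in range(n):
        jj, kk = np.nonzero(mask[i])
        out.append((disp[i, jj, kk], jj))
    return out


def compute_features(frame: Frame, config: DescriptorConfig) -> FrameFeatures:
    """Expand every atomic environment of a frame in the descriptor basis."""
    sp_map = {s: k for k, s in enumerate(config.species_list)}
    try:
        species_idx = np.array([sp_map[s] for s in frame.species])
    except KeyError as exc:
        raise ValidationError(
            f"species {exc.args[0]!r} not in species_list {config.species_list}"
        ) from None

    ns = len(config.species_list)
    nr = config.n_radial
    lmax = config.l_max
    rc = config.radial_cutoff
    centers = np.linspace(0.0, rc, nr)
    sig2 = 2.0 * config.gaussian_width**2

    neighbors = _neighbors_within(frame, rc)
    n_atoms = len(frame)
    d_v = ns * nr
    vectors = np.zeros((n_atoms, d_v, 3))
    # scalar block: central-species one-hot + power spectrum over the
    # combined (species, radial) channel, upper triangle, l = 0..l_max
    nch = ns * nr
    tri_i, tri_j = np.triu_indices(nch)
    d_ps = (lmax + 1) * len(tri_i)
    scalars = np.zeros((n_atoms, ns + d_ps))
    scalars[np.arange(n_atoms), species_idx] = 1.0

    for i, (disp, jsp) in enumerate(neighbors):
        if len(jsp) == 0:
            continue
        r = np.linalg.norm(disp, axis=1)
        fc = 0.5 * (1.0 + np.cos(np.pi * r / rc))
        g = np.exp(-((r[:, None] - centers[None, :]) ** 2) / sig2) * fc[:, None]
        sidx = species_idx[jsp]
        # covariant l=1 channel in Cartesian form
        unit = disp / r[:, None]
        gv = np.einsum("jn,jx->jnx", g, unit)
        np.add.at(vectors[i].reshape(ns, nr, 3), sidx, gv)

        theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))
        phi = np.arctan2(unit[:, 1], unit[:, 0])
        ps_parts = []
        for l in range(lmax + 1):
            # density coefficients c[(s,n), m] for m = 0..l; m<0 follows
            # from the density being real
            c = np.zeros((nch, l + 1), dtype=complex)
            for m in range(l + 1):
                ylm = sph_harm_y(l, m, theta, phi)
                cm = np.zeros((ns, nr), dtype=complex)
                np.add.at(cm, sidx, g * ylm[:, None].conj())
                c[:, m] = cm.reshape(nch)
            # m=0 counted once, |m|>0 twice (negative m by conjugation)
            p = (c @ c.conj().T).real
            if l > 0:
                p += (c[:, 1:] @ c[:, 1:].conj().T).real
            ps_parts.append(p[tri_i, tri_j])
        scalars[i, ns:] = np.concatenate(ps_parts)

    norms = np.linalg.norm(scalars, axis=1)
    scalars /= norms[:, None]
    return FrameFeatures(
        scalars=scalars, vectors=vectors, species_idx=species_idx, config=config
    )


def covariant_kernel(env_a, env_b, zeta: int = 2) -> np.ndarray:
    """Covariant kernel matrix between two atomic environments.

    ``env_a`` and ``env_b`` are ``(FrameFeatures, atom_index)`` pairs.
    Returns a 3x3 matrix satisfying ``K(R a, b) = R K(a, b)`` and zero when
    the central species differ.
    """
    fa, ia = env_a
    fb, ib = env_b
    if fa.species_idx[ia] != fb.species_idx[ib]:
        return np.zeros((3, 3))
    k0 = float(fa.scalars[ia] @ fb.scalars[ib])
    return k0 ** (zeta - 1) * (fa.vectors[ia].T @ fb.vectors[ib])
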