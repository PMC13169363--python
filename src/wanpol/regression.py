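"""Symmetry-adapted Gaussian process regression for 3-vector targets.

Two estimators, both scikit-learn compatible:

``PolarizationGPR``
    Learns the total cell polarization ``P`` of a frame as a sum of
    atom-centered 3-vectors.  The kernel between two frames is the sum of
    the covariant environment kernels over all atom pairs (same central
    species only), so every prediction decomposes exactly into per-atom
    dipole contributions — the decomposition used by the shell-resolved
    spectra.

``WannierGPR``
    Learns a per-atom 3-vector target (the Wannier displacement sum
    ``Delta_i``) with one sub-model per chemical species.

Training solves the regularized kernel system ``(K + sigma I) w = y`` with
``sigma`` scaled by the mean kernel diagonal; predictions are kernel
contractions against the stored training environments.  Rotational
equivariance and translation invariance are exact by construction of the
covariant kernel (see :mod:`wanpol.descriptors`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .core import Frame
from .descriptors import DescriptorConfig, FrameFeatures, compute_features
from .exceptions import IllConditionedError, InsufficientDataError, ValidationError

__all__ = [
    "AtomicDipoleDecomposition",
    "PolarizationGPR",
    "WannierGPR",
    "train_polarization_model",
    "predict_polarization",
    "train_wannier_model",
]

_FORMAT_VERSION = 1


@dataclass
class AtomicDipoleDecomposition:
    """Per-atom dipole contributions (e*Angstrom) and their total."""

    per_atom: np.ndarray
    total: np.ndarray

    def __post_init__(self):
        self.per_atom = np.asarray(self.per_atom, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        s = self.per_atom.sum(axis=0)
        scale = max(1.0, float(np.linalg.norm(s)))
        if np.linalg.norm(s - self.total) > 1e-10 * scale:
            raise ValidationError("total does not equal the per-atom sum")


def _stack_species(features: list[FrameFeatures], species: int):
    """Concatenate the environments of one central species across frames."""
    S, V, fidx, aidx = [], [], [], []
    for fi, ff in enumerate(features):
        sel = np.nonzero(ff.species_idx == species)[0]
        if len(sel):
            S.append(ff.scalars[sel])
            V.append(ff.vectors[sel])
            fidx.append(np.full(len(sel), fi))
            aidx.append(sel)
    if not S:
        return None
    return (
        np.concatenate(S),
        np.concatenate(V),
        np.concatenate(fidx),
        np.concatenate(aidx),
    )


def _pair_kernel(Sa, Va, Sb, Vb, zeta: int) -> np.ndarray:
    """Dense covariant kernel (na, nb, 3, 3) between two environment sets."""
    k0 = (Sa @ Sb.T) ** (zeta - 1)
    return np.einsum("ab,afx,bfy->abxy", k0, Va, Vb, optimize=True)


def _summed_kernel(
    feats_a: list[FrameFeatures],
    feats_b: list[FrameFeatures],
    zeta: int,
    n_species: int,
    per_env_rows: bool = False,
    chunk: int = 512,
):
    """Kernel between frames of A and frames of B, summed over atoms.

    Returns ``(MA, MB, 3, 3)``; with ``per_env_rows`` the A-atoms are kept
    unsummed and the result is a list (one entry per A frame) of
    ``(N_atoms, MB, 3, 3)`` arrays so per-atom contributions are available.
    """
    MA, MB = len(feats_a), len(feats_b)
    if per_env_rows:
        out = [np.zeros((len(ff.species_idx), MB, 3, 3)) for ff in feats_a]
    else:
        out = np.zeros((MA, MB, 3, 3))
    for sp in range(n_species):
        sa = _stack_species(feats_a, sp)
        sb = _stack_species(feats_b, sp)
        if sa is None or sb is None:
            continue
        Sa, Va, fa, aa = sa
        Sb, Vb, fb, _ = sb
        nb = Sb.shape[0]
        # group the B environments by frame once
        frame_sel = [np.nonzero(fb == F)[0] for F in range(MB)]
        for lo in range(0, Sa.shape[0], chunk):
            hi = min(lo + chunk, Sa.shape[0])
            k0 = (Sa[lo:hi] @ Sb.T) ** (zeta - 1)  # (c, nb)
            c = hi - lo
            U = np.zeros((c, MB, Vb.shape[1], 3))
            for F, sel in enumerate(frame_sel):
                if len(sel):
                    U[:, F] = (k0[:, sel] @ Vb[sel].reshape(len(sel), -1)).reshape(
                        c, Vb.shape[1], 3
                    )
            blk = np.einsum("afx,aFfy->aFxy", Va[lo:hi], U, optimize=True)
            if per_env_rows:
                for k in range(c):
                    out[fa[lo + k]][aa[lo + k]] += blk[k]
            else:
                np.add.at(out, fa[lo:hi], blk)
    return out


def _solve_blocks(K: np.ndarray, Y: np.ndarray, regularization: float) -> np.ndarray:
    """Solve the 3-vector kernel system; K is (M, M, 3, 3), Y is (M, 3)."""
    M = K.shape[0]
    big = K.transpose(0, 2, 1, 3).reshape(3 * M, 3 * M)
    big = 0.5 * (big + big.T)
    diag_mean = max(np.trace(big) / (3 * M), 1e-300)
    big = big + regularization * diag_mean * np.eye(3 * M)
    try:
        cho = scipy.linalg.cho_factor(big)
        w = scipy.linalg.cho_solve(cho, Y.reshape(3 * M))
    except scipy.linalg.LinAlgError as exc:
        raise IllConditionedError(
            "kernel system is singular; increase regularization (> 0)"
        ) from exc
    return w.reshape(M, 3)


class _VectorGPRBase(RegressorMixin, BaseEstimator):
    def __init__(
        self,
        radial_cutoff=4.0,
        n_radial=6,
        l_max=4,
        gaussian_width=0.3,
        zeta=2,
        regularization=1e-8,
        species_list=None,
    ):
        self.radial_cutoff = radial_cutoff
        self.n_radial = n_radial
        self.l_max = l_max
        self.gaussian_width = gaussian_width
        self.zeta = zeta
        self.regularization = regularization
        self.species_list = species_list

    def _make_config(self, frames: list[Frame]) -> DescriptorConfig:
        if self.species_list is not None:
            species = tuple(self.species_list)
        else:
            species = tuple(
                sorted({s for f in frames for s in f.species})
            )
        if int(self.zeta) != self.zeta or self.zeta < 1:
            raise ValidationError("zeta must be an integer >= 1")
        if self.regularization < 0:
            raise ValidationError("regularization must be >= 0")
        return DescriptorConfig(
            radial_cutoff=self.radial_cutoff,
            n_radial=self.n_radial,
            l_max=self.l_max,
            gaussian_width=self.gaussian_width,
            species_list=species,
        )

    def _featurize(self, frames: list[Frame]) -> list[FrameFeatures]:
        return [compute_features(f, self.config_) for f in frames]


class PolarizationGPR(_VectorGPRBase):
    """Covariant kernel model for the total cell polarization.

    Targets must lie on a single smooth branch (run the unwrapping
    preprocessor first if they do not); units e*Angstrom.
    """

    target_kind = "global_polarization"

    def fit(self, X, y):
        frames = list(X)
        y = np.asarray(y, dtype=float)
        if y.shape != (len(frames), 3):
            raise ValidationError("y must be (n_frames, 3)")
        if len(frames) < 2:
            raise InsufficientDataError("need at least 2 training frames")
        self.config_ = self._make_config(frames)
        self.train_features_ = self._featurize(frames)
        K = _summed_kernel(
            self.train_features_,
            self.train_features_,
            int(self.zeta),
            len(self.config_.species_list),
        )
        self.weights_ = _solve_blocks(K, y, self.regularization)
        return self

    def predict(self, X):
        frames = list(X)
        feats = self._featurize(frames)
        K = _summed_kernel(
            feats,
            self.train_features_,
            int(self.zeta),
            len(self.config_.species_list),
        )
        return np.einsum("aFxy,Fy->ax", K, self.weights_)

    def predict_decomposed(self, frame: Frame) -> AtomicDipoleDecomposition:
        """Predict one frame as explicit atom-centered dipole contributions."""
        feats = self._featurize([frame])
        rows = _summed_kernel(
            feats,
            self.train_features_,
            int(self.zeta),
            len(self.config_.species_list),
            per_env_rows=True,
        )[0]
        per_atom = np.einsum("iFxy,Fy->ix", rows, self.weights_)
        return AtomicDipoleDecomposition(per_atom=per_atom, total=per_atom.sum(axis=0))

    def save(self, path):
        _save_model(self, path)

    @classmethod
    def load(cls, path):
        return _load_model(cls, path)


class WannierGPR(_VectorGPRBase):
    """Per-species covariant kernel models for Wannier displacement sums.

    ``fit`` takes one ``(N_atoms, 3)`` target array per frame (zero vectors
    for atoms that own no centers); ``predict`` returns the same layout.
    """

    target_kind = "wannier_displacement"

    def fit(self, X, y):
        frames = list(X)
        targets = [np.asarray(t, dtype=float) for t in y]
        if len(targets) != len(frames) or any(
            t.shape != (len(f), 3) for t, f in zip(targets, frames)
        ):
            raise ValidationError("y must give an (N_atoms, 3) array per frame")
        self.config_ = self._make_config(frames)
        feats = self._featurize(frames)
        self.train_features_ = feats
        self.species_weights_ = {}
        self.species_refs_ = {}
        for sp, symbol in enumerate(self.config_.species_list):
            stacked = _stack_species(feats, sp)
            if stacked is None:
                continue
            S, V, fidx, aidx = stacked
            if S.shape[0] < 2:
                raise InsufficientDataError(
                    f"species {symbol!r} has fewer than 2 training environments"
                )
            Y = np.stack(
                [targets[f][a] for f, a in zip(fidx, aidx)]
            )
            K = _pair_kernel(S, V, S, V, int(self.zeta))
            self.species_weights_[symbol] = _solve_blocks(
                K, Y, self.regularization
            )
            self.species_refs_[symbol] = (S, V)
        return self

    def predict(self, X):
        single = isinstance(X, Frame)
        frames = [X] if single else list(X)
        out = []
        for frame in frames:
            ff = compute_features(frame, self.config_)
            pred = np.zeros((len(frame), 3))
            for sp, symbol in enumerate(self.config_.species_list):
                sel = np.nonzero(ff.species_idx == sp)[0]
                if len(sel) == 0 or symbol not in self.species_refs_:
                    continue
                S, V = self.species_refs_[symbol]
                K = _pair_kernel(ff.scalars[sel], ff.vectors[sel], S, V, int(self.zeta))
                pred[sel] = np.einsum(
                    "amxy,my->ax", K, self.species_weights_[symbol]
                )
            out.append(pred)
        return out[0] if single else out

    def save(self, path):
        _save_model(self, path)

    @classmethod
    def load(cls, path):
        return _load_model(cls, path)


def _save_model(model, path):
    """Serialize a fitted model to one self-describing .npz archive."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "kind": model.target_kind,
        "params": model.get_params(),
        "species_list": list(model.config_.species_list),
    }
    arrays = {"_meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
    for i, ff in enumerate(model.train_features_):
        arrays[f"scalars_{i}"] = ff.scalars
        arrays[f"vectors_{i}"] = ff.vectors
        arrays[f"species_{i}"] = ff.species_idx
    if model.target_kind == "global_polarization":
        arrays["weights"] = model.weights_
    else:
        for symbol, w in model.species_weights_.items():
            arrays[f"w_{symbol}"] = w
    np.savez(path, **arrays)


def _load_model(cls, path):
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(bytes(data["_meta"]).decode())
        if meta.get("format_version") != _FORMAT_VERSION:
            raise ValidationError("unsupported model archive version")
        if meta["kind"] != cls.target_kind:
            raise ValidationError(
                f"archive holds a {meta['kind']} model, not {cls.target_kind}"
            )
        params = meta["params"]
        params["species_list"] = tuple(meta["species_list"])
        model = cls(**params)
        model.config_ = DescriptorConfig(
            radial_cutoff=params["radial_cutoff"],
            n_radial=params["n_radial"],
            l_max=params["l_max"],
            gaussian_width=params["gaussian_width"],
            species_list=tuple(meta["species_list"]),
        )
        feats = []
        i = 0
        while f"scalars_{i}" in data:
            feats.append(
                FrameFeatures(
                    scalars=data[f"scalars_{i}"],
                    vectors=data[f"vectors_{i}"],
                    species_idx=data[f"species_{i}"],
                    config=model.config_,
                )
            )
            i += 1
        model.train_features_ = feats
        if cls.target_kind == "global_polarization":
            model.weights_ = data["weights"]
        else:
            model.species_weights_ = {}
            model.species_refs_ = {}
            for sp, symbol in enumerate(model.config_.species_list):
                key = f"w_{symbol}"
                if key in data:
                    model.species_weights_[symbol] = data[key]
                    stacked = _stack_species(feats, sp)
                    model.species_refs_[symbol] = (stacked[0], stacked[1])
    return model


def train_polarization_model(
    frames, targets, config: DescriptorConfig | None = None,
    regularization: float = 1e-8, seed: int | None = None, zeta: int = 2,
) -> PolarizationGPR:
    """Fit a :class:`PolarizationGPR` (thin functional wrapper).

    ``seed`` is accepted for interface symmetry; the fit is deterministic.
    """
    kw = {} if config is None else {
        "radial_cutoff": config.radial_cutoff,
        "n_radial": config.n_radial,
        "l_max": config.l_max,
        "gaussian_width": config.gaussian_width,
        "species_list": config.species_list,
    }
    return PolarizationGPR(regularization=regularization, zeta=zeta, **kw).fit(
        frames, targets
    )


def predict_polarization(model: PolarizationGPR, frame: Frame) -> AtomicDipoleDecomposition:
    """Per-atom dipole decomposition of one frame's predicted polarization."""
    return model.predict_decomposed(frame)


def train_wannier_model(
    frames, displacement_targets, config: DescriptorConfig | None = None,
    regularization: float = 1e-8, zeta: int = 2,
) -> WannierGPR:
    """Fit a :class:`WannierGPR` on per-atom displacement sums."""
    kw = {} if config is None else {
        "radial_cutoff": config.radial_cutoff,
        "n_radial": config.n_radial,
        "l_max": config.l_max,
        "gaussian_width": config.gaussian_width,
        "species_list": config.species_list,
    }
    return WannierGPR(regularization=regularization, zeta=zeta, **kw).fit(
        frames, displacement_targets
    )
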