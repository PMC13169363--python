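"""Data-driven unwrapping of multivalued polarization data.

Reduced polarizations ``p`` live on branches separated by integers: a
dataset assembled from raw periodic calculations mixes branches, and a
model trained on it sees discontinuous targets.  The preprocessing
implemented here restores a single smooth branch without any auxiliary
charge model:

1. train a *probe* model on a small random fraction (~5%) of the data;
2. predict the remainder and inspect the residual histogram with the
   Hartigan dip test.  A probe trained within one branch yields residuals
   clustered at integer separations (multimodal); a probe trained across
   branches predicts no better than chance (broad, unimodal residuals) and
   the probe subset is redrawn;
3. residual components below 0.5 in magnitude mark points already on the
   main branch;
4. the remaining points are shifted by the nearest-integer residual,
   bringing every point onto the main branch.

The dip statistic is computed exactly from its definition (the smallest
uniform-norm distance from the empirical CDF to a unimodal CDF, found by
scanning candidate modes with convex-minorant / concave-majorant fits);
its p-value comes from a seeded bootstrap against the uniform null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Frame, wrap_half_open
from .exceptions import (
    AmbiguousBranchError,
    InsufficientDataError,
    UnwrapFailureError,
    ValidationError,
)
from .regression import PolarizationGPR

__all__ = [
    "dip_statistic",
    "hartigan_dip",
    "ResidualDiagnostics",
    "UnwrapResult",
    "probe_and_diagnose",
    "assign_branches",
    "unwrap_dataset",
]


def _half_dips(z: np.ndarray, L: np.ndarray, U: np.ndarray) -> np.ndarray:
    """Convex-side dip contributions for every candidate mode position.

    ``z`` are distinct sorted values; at ``z_t`` the empirical CDF jumps
    from ``U[t]`` to ``L[t]``.  ``out[t]`` is the smallest ``d`` admitting
    a convex nondecreasing function through the bands of points left of a
    mode at ``z_t``: half the largest amount by which a lower jump value
    exceeds the lower convex hull of the upper jump values.
    """
    m = len(z)
    out = np.zeros(m)
    hull = [0]
    best = 0.0
    for t in range(1, m):
        # own-jump deviation of the newest real point (band nonemptiness)
        best = max(best, L[t - 1] - U[t - 1])
        while len(hull) >= 2:
            i, h = hull[-2], hull[-1]
            if (U[h] - U[i]) * (z[t] - z[i]) >= (U[t] - U[i]) * (z[h] - z[i]):
                hull.pop()
            else:
                break
        h = hull[-1]
        if t - h > 1:
            js = np.arange(h + 1, t)
            edge = U[h] + (U[t] - U[h]) * (z[js] - z[h]) / (z[t] - z[h])
            dev = float(np.max(L[js] - edge))
            if dev > best:
                best = dev
        hull.append(t)
        out[t] = 0.5 * best
    return out


def dip_statistic(sample) -> float:
    """Hartigan's dip: distance from the empirical CDF to unimodality."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 4:
        raise InsufficientDataError("dip test needs at least 4 observations")
    z, cnt = np.unique(x, return_counts=True)
    if len(z) == 1:
        return 0.0
    cum = np.cumsum(cnt) / n
    U = np.concatenate([[0.0], cum[:-1]])
    L = cum
    dl = _half_dips(z, L, U)
    dr = _half_dips(-z[::-1], 1.0 - U[::-1], 1.0 - L[::-1])[::-1]
    return float(np.min(np.maximum(dl, dr)))


_NULL_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _null_dips(n: int, n_boot: int, seed: int) -> np.ndarray:
    key = (n, n_boot, seed)
    if key not in _NULL_CACHE:
        rng = np.random.default_rng(seed)
        _NULL_CACHE[key] = np.array(
            [dip_statistic(rng.uniform(size=n)) for _ in range(n_boot)]
        )
    return _NULL_CACHE[key]


def hartigan_dip(
    sample, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Dip statistic and bootstrap p-value against the uniform null.

    Small p-values reject unimodality.  The bootstrap is seeded and its
    null distribution cached per sample size.
    """
    d = dip_statistic(sample)
    null = _null_dips(len(np.asarray(sample)), n_boot, seed)
    p = (1.0 + np.count_nonzero(null >= d)) / (n_boot + 1.0)
    return d, float(p)


@dataclass
class ResidualDiagnostics:
    """Probe-model residuals and their per-component dip verdict."""

    residuals: np.ndarray
    eval_indices: np.ndarray
    probe_indices: np.ndarray
    dip_statistics: np.ndarray
    p_values: np.ndarray
    verdict: str
    threshold: float
    model: PolarizationGPR | None = None


_PROBE_DEFAULTS = dict(regularization=1e-3)


def probe_and_diagnose(
    frames: list[Frame],
    p_calc: np.ndarray,
    probe_fraction: float = 0.05,
    seed: int = 0,
    probe_indices=None,
    dip_threshold: float = 0.05,
    n_boot: int = 1000,
    model_params: dict | None = None,
) -> ResidualDiagnostics:
    """Train a probe model on a random subset and diagnose the residuals.

    A multimodal residual distribution (any component with dip p-value
    below the threshold) indicates the probe subset sat on a single branch
    and the branch structure of the remaining points is resolvable.
    """
    p_calc = np.asarray(p_calc, dtype=float)
    N = len(frames)
    if p_calc.shape != (N, 3):
        raise ValidationError("p_calc must be (n_frames, 3)")
    if probe_indices is None:
        if not 0.0 < probe_fraction < 1.0:
            raise ValidationError("probe_fraction must be in (0, 1)")
        n_probe = max(2, int(round(probe_fraction * N)))
        if n_probe >= N:
            raise InsufficientDataError("probe subset would exhaust the dataset")
        rng = np.random.default_rng(seed)
        probe_indices = np.sort(rng.choice(N, size=n_probe, replace=False))
    else:
        probe_indices = np.sort(np.asarray(probe_indices, dtype=int))
        if len(probe_indices) < 2:
            raise InsufficientDataError("probe subset needs at least 2 members")

    sub = [frames[i] for i in probe_indices]
    spread = max(
        float(np.abs(f.positions - sub[0].positions).max())
        for f in sub
        if f.positions.shape == sub[0].positions.shape
    ) if all(f.positions.shape == sub[0].positions.shape for f in sub) else 1.0
    if spread < 1e-12:
        raise InsufficientDataError(
            "degenerate probe subset (identical frames); resample"
        )

    params = dict(_PROBE_DEFAULTS)
    if model_params:
        params.update(model_params)
    model = PolarizationGPR(**params).fit(sub, p_calc[probe_indices])
    pred = model.predict(frames)
    residuals = pred - p_calc
    eval_indices = np.setdiff1d(np.arange(N), probe_indices)
    dips, pvals = [], []
    for a in range(3):
        d, p = hartigan_dip(residuals[eval_indices, a], n_boot=n_boot, seed=seed)
        dips.append(d)
        pvals.append(p)
    verdict = "multimodal" if min(pvals) < dip_threshold else "unimodal"
    return ResidualDiagnostics(
        residuals=residuals,
        eval_indices=eval_indices,
        probe_indices=probe_indices,
        dip_statistics=np.array(dips),
        p_values=np.array(pvals),
        verdict=verdict,
        threshold=dip_threshold,
        model=model,
    )


def assign_branches(p_pred, p_calc, tolerance: float = 1e-6) -> np.ndarray:
    """Integer branch offsets from signed residuals.

    Componentwise: residuals below 0.5 in magnitude are on the main branch
    (offset 0); others get the nearest integer of the signed residual, so
    that ``|p_pred - (p_calc + offset)| < 0.5`` afterwards.  Residuals
    within ``tolerance`` of a half-integer are ambiguous and raise.
    """
    p_pred = np.atleast_2d(np.asarray(p_pred, dtype=float))
    p_calc = np.atleast_2d(np.asarray(p_calc, dtype=float))
    if p_pred.shape != p_calc.shape:
        raise ValidationError("p_pred and p_calc must have equal shapes")
    r = p_pred - p_calc
    near_half = np.abs(np.abs(r - np.rint(r)) - 0.5) < tolerance
    if np.any(near_half):
        bad = np.unique(np.nonzero(near_half)[0])
        raise AmbiguousBranchError(
            f"residual within {tolerance} of a half-integer at points "
            f"{bad.tolist()}",
            indices=bad,
        )
    return np.rint(r).astype(int)


@dataclass
class UnwrapResult:
    """Outcome of the unwrapping loop."""

    branch_offsets: np.ndarray
    unwrapped_p: np.ndarray
    n_restarts: int
    probe_indices: np.ndarray
    seed: int
    diagnostics: ResidualDiagnostics | None = None


def _circular_center(residuals: np.ndarray) -> np.ndarray:
    """Per-component circular mean of residuals modulo 1, in [-1/2, 1/2)."""
    ang = np.angle(np.mean(np.exp(2j * np.pi * residuals), axis=0)) / (2 * np.pi)
    return wrap_half_open(ang)


def unwrap_dataset(
    frames: list[Frame],
    p_calc: np.ndarray,
    probe_fraction: float = 0.05,
    seed: int = 0,
    max_restarts: int = 20,
    dip_threshold: float = 0.05,
    n_boot: int = 1000,
    model_params: dict | None = None,
    probe_regularizations: tuple[float, ...] = (1e-3, 1.0, 100.0),
) -> UnwrapResult:
    """Bring every reduced polarization onto one smooth branch.

    Repeats the probe/diagnose step with fresh random subsets until the
    residuals are multimodal (or the data is verified single-branch), then
    assigns nearest-integer branch offsets.

    Numerical safeguards beyond the basic loop:

    * Each probe subset is diagnosed at a ladder of regularization
      strengths.  A lightly regularized probe resolves branches when its
      subset happens to sit on one branch; a heavily shrunk probe (the
      probe need not be accurate) resolves them when the branch scatter is
      independent of the configuration, where a flexible fit would leak
      the scatter into its predictions and wash out the residual modes.
    * Residuals are re-centered by their circular mean before rounding so
      a fit level near a half-integer cannot split one residual mode
      across a rounding boundary.
    * The probe points themselves are assigned with a second model trained
      on the unwrapped remainder: a near-interpolating probe has ~zero
      in-sample residuals, which would silently leave its own points on
      their original branches.

    Deterministic given the seed.
    """
    p_calc = np.asarray(p_calc, dtype=float)
    N = len(frames)
    diag = None
    for restart in range(max_restarts):
        sub_seed = int(
            np.random.SeedSequence([seed, restart]).generate_state(1)[0] % (2**31)
        )
        rng = np.random.default_rng(sub_seed)
        if not 0.0 < probe_fraction < 1.0:
            raise ValidationError("probe_fraction must be in (0, 1)")
        n_probe = max(2, int(round(probe_fraction * N)))
        if n_probe >= N:
            raise InsufficientDataError("probe subset would exhaust the dataset")
        probe_idx = np.sort(rng.choice(N, size=n_probe, replace=False))
        best = None
        best_conc = -np.inf
        for reg in probe_regularizations:
            params = dict(model_params or {})
            params["regularization"] = reg
            diag = probe_and_diagnose(
                frames,
                p_calc,
                seed=sub_seed,
                probe_indices=probe_idx,
                dip_threshold=dip_threshold,
                n_boot=n_boot,
                model_params=params,
            )
            if np.all(np.abs(diag.residuals) < 0.5 - 1e-6):
                # verified single-branch: every point within half a quantum
                return UnwrapResult(
                    branch_offsets=np.zeros((N, 3), dtype=int),
                    unwrapped_p=p_calc.copy(),
                    n_restarts=restart,
                    probe_indices=diag.probe_indices,
                    seed=seed,
                    diagnostics=diag,
                )
            if diag.verdict == "multimodal":
                # concentration of the residual modes around integers
                r = diag.residuals[diag.eval_indices]
                conc = float(np.abs(np.mean(np.exp(2j * np.pi * r))))
                if conc > best_conc:
                    best, best_conc = diag, conc
        if best is None:
            continue
        diag = best
        rest = diag.eval_indices
        probe = diag.probe_indices
        shift = _circular_center(diag.residuals[rest])
        pred_rest = diag.residuals[rest] + p_calc[rest]  # probe predictions
        offsets = np.zeros((N, 3), dtype=int)
        offsets[rest] = assign_branches(pred_rest - shift, p_calc[rest])
        # Refinement: train on the provisionally unwrapped points, re-wrap
        # everything (including the probe subset) with that model, iterate
        # to a fixed point.
        second_params = dict(model_params or {})
        second_params.setdefault("regularization", 1e-3)
        train_idx = rest
        for _ in range(4):
            model = PolarizationGPR(**second_params).fit(
                [frames[i] for i in train_idx], (p_calc + offsets)[train_idx]
            )
            pred = model.predict(frames)
            shift2 = _circular_center(
                pred[train_idx] - (p_calc + offsets)[train_idx]
            )
            new_offsets = assign_branches(pred - shift2, p_calc)
            full = len(train_idx) == N
            if full and np.array_equal(new_offsets, offsets):
                break
            offsets = new_offsets
            train_idx = np.arange(N)
        return UnwrapResult(
            branch_offsets=offsets,
            unwrapped_p=p_calc + offsets,
            n_restarts=restart,
            probe_indices=probe,
            seed=seed,
            diagnostics=diag,
        )
    raise UnwrapFailureError(
        f"no single-branch probe subset found in {max_restarts} restarts",
        diagnostics=diag,
    )
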