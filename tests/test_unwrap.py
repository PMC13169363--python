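"""Branch unwrapping: dip test, probe diagnostics, offset assignment."""

import numpy as np
import pytest
from scipy.optimize import linprog

from wanpol.core import quantum_matrix
from wanpol.exceptions import (
    AmbiguousBranchError,
    InsufficientDataError,
    UnwrapFailureError,
)
from wanpol.synthetic import (
    FixtureSpec,
    make_dataset,
    score_offset_recovery,
    smooth_polarization_oracle,
    wrap_with_random_branches,
)
from wanpol.unwrap import (
    assign_branches,
    dip_statistic,
    hartigan_dip,
    probe_and_diagnose,
    unwrap_dataset,
)

# ---------------------------------------------------------------------------
# brute-force dip oracle: bisection on d, LP feasibility of a unimodal CDF
# within a uniform band of the empirical CDF (mode scanned over data points
# with the jump absorbed at the mode)
# ---------------------------------------------------------------------------


def _unimodal_band_feasible(z, L, U, t, d):
    m = len(z)
    lx = [z[i] for i in range(t)] + [z[t]]
    llo = [L[i] - d for i in range(t)] + [U[t] - d]
    lhi = [U[i] + d for i in range(t)] + [U[t] + d]
    rx = [z[t]] + [z[i] for i in range(t + 1, m)]
    rlo = [L[t] - d] + [L[i] - d for i in range(t + 1, m)]
    rhi = [L[t] + d] + [U[i] + d for i in range(t + 1, m)]
    nl, nr = len(lx), len(rx)
    n = nl + nr
    bounds = [
        (max(lo, 0.0), min(hi, 1.0)) for lo, hi in zip(llo + rlo, lhi + rhi)
    ]
    if any(lo > hi + 1e-12 for lo, hi in bounds):
        return False
    A, b = [], []
    for k in range(n - 1):  # monotone, including across the mode junction
        row = [0.0] * n
        row[k], row[k + 1] = 1.0, -1.0
        A.append(row)
        b.append(0.0)
    for k in range(nl - 2):  # convex left of the mode
        x0, x1, x2 = lx[k], lx[k + 1], lx[k + 2]
        row = [0.0] * n
        row[k] = -1.0 / (x1 - x0)
        row[k + 1] = 1.0 / (x1 - x0) + 1.0 / (x2 - x1)
        row[k + 2] = -1.0 / (x2 - x1)
        A.append(row)
        b.append(0.0)
    for k in range(nr - 2):  # concave right of the mode
        x0, x1, x2 = rx[k], rx[k + 1], rx[k + 2]
        row = [0.0] * n
        row[nl + k] = 1.0 / (x1 - x0)
        row[nl + k + 1] = -1.0 / (x1 - x0) - 1.0 / (x2 - x1)
        row[nl + k + 2] = 1.0 / (x2 - x1)
        A.append(row)
        b.append(0.0)
    res = linprog(
        np.zeros(n), A_ub=np.array(A), b_ub=np.array(b), bounds=bounds,
        method="highs",
    )
    return res.status == 0


def dip_oracle(x):
    x = np.sort(np.asarray(x, dtype=float))
    z, cnt = np.unique(x, return_counts=True)
    if len(z) == 1:
        return 0.0
    cum = np.cumsum(cnt) / len(x)
    U = np.concatenate([[0.0], cum[:-1]])
    L = cum
    best = np.inf
    for t in range(len(z)):
        lo, hi = 0.0, 0.5
        for _ in range(28):
            mid = 0.5 * (lo + hi)
            if _unimodal_band_feasible(z, L, U, t, mid):
                hi = mid
            else:
                lo = mid
        best = min(best, hi)
    return best


class TestDipStatistic:
    def test_two_point_masses(self):
        assert dip_statistic([0, 0, 0, 0, 1, 1, 1, 1]) == pytest.approx(0.25)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            d = dip_statistic(rng.normal(size=rng.integers(4, 60)))
            assert 0.0 <= d <= 0.25 + 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        assert dip_statistic(3.0 * x - 7.0) == pytest.approx(dip_statistic(x))

    def test_against_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        diffs = []
        for trial in range(24):
            k = int(rng.integers(4, 10))
            kind = trial % 4
            if kind == 0:
                x = rng.normal(size=k)
            elif kind == 1:
                x = rng.uniform(size=k)
            elif kind == 2:
                x = np.concatenate(
                    [rng.normal(-3, 0.5, size=k // 2),
                     rng.normal(3, 0.5, size=k - k // 2)]
                )
            else:
                x = rng.integers(0, 3, size=k).astype(float)
            fast = dip_statistic(x)
            exact = dip_oracle(x)
            # the implementation is a lower bound that is exact except for
            # the rare coupling between the two one-sided fits at the mode
            assert fast <= exact + 1e-6
            diffs.append(exact - fast)
        assert np.median(diffs) < 1e-6
        assert max(diffs) < 0.02

    def test_minimum_sample_size(self):
        with pytest.raises(InsufficientDataError):
            dip_statistic([0.0, 1.0, 2.0])


class TestHartiganDip:
    def test_unimodal_accepts(self):
        rng = np.random.default_rng(3)
        _, p = hartigan_dip(rng.normal(size=500), seed=0)
        assert p > 0.05

    def test_bimodal_rejects(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-5, 1, 250), rng.normal(5, 1, 250)])
        _, p = hartigan_dip(x, seed=0)
        assert p < 0.01

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=100)
        assert hartigan_dip(x, seed=9) == hartigan_dip(x, seed=9)


class TestAssignBranches:
    @pytest.mark.parametrize(
        "pred, calc, offset",
        [
            (0.2, 0.1, 0),
            (0.7, -0.3, 1),
            (-0.93, 0.02, -1),
            (2.4, 0.3, 2),
        ],
    )
    def test_examples(self, pred, calc, offset):
        out = assign_branches([[pred, 0, 0]], [[calc, 0, 0]])
        assert out[0, 0] == offset

    def test_post_condition(self):
        rng = np.random.default_rng(6)
        pred = rng.uniform(-0.4, 0.4, size=(50, 3))
        calc = pred + rng.integers(-3, 4, size=(50, 3)) + rng.uniform(
            -0.3, 0.3, size=(50, 3)
        )
        off = assign_branches(pred, calc)
        assert np.all(np.abs(pred - (calc + off)) < 0.5)

    def test_half_integer_ambiguity(self):
        with pytest.raises(AmbiguousBranchError) as exc:
            assign_branches([[0.5 + 1e-9, 0, 0]], [[0.0, 0, 0]])
        assert 0 in exc.value.indices

    def test_common_integer_shift_invariance(self):
        pred = np.array([[0.2, -0.1, 0.3], [0.8, 0.1, -0.2]])
        calc = np.array([[0.1, -0.2, 0.25], [-0.25, 0.0, -0.1]])
        off = assign_branches(pred, calc)
        off_shifted = assign_branches(pred, calc + 3)
        np.testing.assert_array_equal(off_shifted, off - 3)


@pytest.fixture(scope="module")
def folded_wide_dataset():
    """Data whose branch structure follows the configuration (folded)."""
    spec = FixtureSpec(n_water=4, n_ethanol=0, box=9.0, seed=31)
    frames = make_dataset(spec, 120)
    P = np.array([smooth_polarization_oracle(f) for f in frames])
    Q = quantum_matrix(frames[0].cell)
    p_wide = 5.0 * np.linalg.solve(Q, P.T).T  # spans a few branches
    n_true = np.rint(p_wide).astype(int)
    p_folded = p_wide - n_true
    return frames, p_folded, n_true, p_wide


class TestProbeAndDiagnose:
    def test_single_branch_subset_multimodal(self, folded_wide_dataset):
        frames, p_folded, n_true, _ = folded_wide_dataset
        same = np.nonzero(np.all(n_true == n_true[0], axis=1))[0][:10]
        diag = probe_and_diagnose(frames, p_folded, probe_indices=same, seed=0)
        assert diag.verdict == "multimodal"

    def test_mixed_branch_subset_unimodal(self, folded_wide_dataset):
        frames, p_folded, n_true, _ = folded_wide_dataset
        order = np.argsort(n_true[:, 0])
        mixed = np.concatenate([order[:5], order[-5:]])
        diag = probe_and_diagnose(frames, p_folded, probe_indices=mixed, seed=0)
        assert diag.verdict == "unimodal"

    def test_degenerate_subset_rejected(self, water_dataset):
        frames, P = water_dataset
        Q = quantum_matrix(frames[0].cell)
        p = np.linalg.solve(Q, P.T).T
        dup = [frames[0]] * len(frames)
        with pytest.raises(InsufficientDataError, match="resample"):
            probe_and_diagnose(dup, p, probe_indices=[0, 1, 2], seed=0)


class TestUnwrapDataset:
    def test_recovers_scattered_offsets(self, branch_scattered_dataset):
        frames, P, Q, wrapped, true_offsets, _ = branch_scattered_dataset
        result = unwrap_dataset(frames, wrapped, probe_fraction=0.05, seed=7)
        assert score_offset_recovery(result.branch_offsets, true_offsets) >= 0.99
        np.testing.assert_array_equal(
            result.unwrapped_p - wrapped, result.branch_offsets
        )

    def test_idempotent_on_smooth_data(self, branch_scattered_dataset):
        frames, P, Q, _, _, p_smooth = branch_scattered_dataset
        sub = frames[:60]
        result = unwrap_dataset(sub, p_smooth[:60], seed=3)
        assert np.all(result.branch_offsets == 0)

    def test_structureless_data_fails(self, water_dataset):
        frames, _ = water_dataset
        rng = np.random.default_rng(8)
        noise = rng.uniform(-0.5, 0.5, size=(len(frames), 3)) + rng.integers(
            -2, 3, size=(len(frames), 3)
        )
        with pytest.raises(UnwrapFailureError):
            unwrap_dataset(frames, noise, seed=0, max_restarts=3, n_boot=200)

    def test_offsets_invariant_under_global_shift(self, branch_scattered_dataset):
        frames, P, Q, wrapped, _, _ = branch_scattered_dataset
        sub = slice(0, 80)
        r1 = unwrap_dataset(frames[sub], wrapped[sub], seed=5)
        r2 = unwrap_dataset(frames[sub], wrapped[sub] + 2, seed=5)
        np.testing.assert_array_equal(
            r2.branch_offsets, r1.branch_offsets - 2
        )

    def test_deterministic(self, branch_scattered_dataset):
        frames, P, Q, wrapped, _, _ = branch_scattered_dataset
        sub = slice(0, 60)
        r1 = unwrap_dataset(frames[sub], wrapped[sub], seed=11)
        r2 = unwrap_dataset(frames[sub], wrapped[sub], seed=11)
        np.testing.assert_array_equal(r1.branch_offsets, r2.branch_offsets)
        assert r1.n_restarts == r2.n_restarts
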