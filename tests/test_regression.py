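"""Covariant kernels and the polarization / Wannier-displacement models."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from wanpol.core import Cell, Frame, quantum_matrix, von_mises_error
from wanpol.descriptors import DescriptorConfig, compute_features, covariant_kernel
from wanpol.exceptions import (
    IllConditionedError,
    InsufficientDataError,
    ValidationError,
)
from wanpol.regression import PolarizationGPR, WannierGPR
from wanpol.synthetic import (
    FixtureSpec,
    make_dataset,
    make_wannier_centers,
    smooth_polarization_oracle,
)
from wanpol.wannier import assign_nearest


def _rotated(frame, R):
    return Frame(
        frame.species,
        frame.positions @ R.T,
        Cell(frame.cell.vectors @ R.T),
        bonds=frame.bonds,
    )


class TestCovariantKernel:
    def test_gram_block_symmetric_psd(self, water_dataset):
        frames, _ = water_dataset
        ff = compute_features(frames[0], DescriptorConfig())
        oxygens = [i for i, s in enumerate(frames[0].species) if s == "O"]
        n = len(oxygens)
        big = np.zeros((3 * n, 3 * n))
        for a, i in enumerate(oxygens):
            for b, j in enumerate(oxygens):
                big[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] = covariant_kernel(
                    (ff, i), (ff, j)
                )
        np.testing.assert_allclose(big, big.T, atol=1e-12)
        assert np.linalg.eigvalsh(big).min() > -1e-10

    def test_rotation_covariance(self, water_dataset):
        frames, _ = water_dataset
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        cfg = DescriptorConfig()
        f0, f1 = frames[0], _rotated(frames[0], R)
        ff0 = compute_features(f0, cfg)
        ff1 = compute_features(f1, cfg)
        K = covariant_kernel((ff0, 0), (ff0, 3))
        K_rot = covariant_kernel((ff1, 0), (ff0, 3))
        np.testing.assert_allclose(K_rot, R @ K, rtol=1e-8, atol=1e-10)

    def test_locality_beyond_cutoff(self):
        """Environments without shared neighbors reduce to isolated ones."""
        cfg = DescriptorConfig(radial_cutoff=3.0)
        sp, pos, bonds = (
            ["O", "H", "H"],
            np.array([[0.0, 0, 0], [0.96, 0, 0], [-0.3, 0.9, 0]]),
            [(0, 1), (0, 2)],
        )
        big = Cell.cubic(40.0)
        # two copies far beyond 2 x cutoff
        both = Frame(sp + sp, np.vstack([pos + 5.0, pos + 25.0]), big)
        alone = Frame(sp, pos + 5.0, big)
        ff_both = compute_features(both, cfg)
        ff_alone = compute_features(alone, cfg)
        K_cross = covariant_kernel((ff_both, 0), (ff_both, 3))
        K_direct = covariant_kernel((ff_alone, 0), (ff_alone, 0))
        # the distant pair interacts only through self-environment overlap
        np.testing.assert_allclose(K_cross, K_direct, rtol=1e-8)

    def test_unknown_species_rejected(self, water_dataset):
        frames, _ = water_dataset
        cfg = DescriptorConfig(species_list=("C",))
        with pytest.raises(ValidationError):
            compute_features(frames[0], cfg)


class TestPolarizationGPR:
    def test_interpolates_duplicate_frames(self, water_dataset):
        frames, P = water_dataset
        model = PolarizationGPR().fit([frames[0], frames[0]], [P[0], P[0]])
        np.testing.assert_allclose(model.predict([frames[0]])[0], P[0], rtol=1e-4)

    def test_heldout_accuracy(self, water_dataset):
        frames, P = water_dataset
        model = PolarizationGPR().fit(frames[:50], P[:50])
        pred = model.predict(frames[50:])
        Qinv = np.linalg.inv(quantum_matrix(frames[0].cell))
        vme = von_mises_error(pred @ Qinv.T, P[50:] @ Qinv.T)
        assert vme < 0.01

    def test_zero_targets_give_zero_predictions(self, water_dataset):
        frames, P = water_dataset
        model = PolarizationGPR().fit(frames[:10], np.zeros((10, 3)))
        pred = model.predict(frames[10:15])
        assert np.abs(pred).max() < 1e-8 * max(1.0, np.abs(P).max())

    def test_prediction_equivariance(self, water_dataset):
        frames, P = water_dataset
        model = PolarizationGPR().fit(frames[:20], P[:20])
        rng = np.random.default_rng(5)
        frame = frames[30]
        d0 = model.predict_decomposed(frame)
        for _ in range(3):
            R = Rotation.random(random_state=rng).as_matrix()
            d1 = model.predict_decomposed(_rotated(frame, R))
            err = np.abs(d1.per_atom - d0.per_atom @ R.T).max()
            assert err <= 1e-6 * max(np.abs(d0.per_atom).max(), 1e-12)

    def test_translation_invariance(self, water_dataset):
        frames, P = water_dataset
        model = PolarizationGPR().fit(frames[:20], P[:20])
        frame = frames[25]
        shifted = Frame(
            frame.species, frame.positions + np.array([1.3, -0.7, 2.1]), frame.cell
        )
        p0 = model.predict([frame])[0]
        p1 = model.predict([shifted])[0]
        np.testing.assert_allclose(p1, p0, atol=1e-8 * max(1.0, np.abs(p0).max()))

    def test_permutation_invariance_of_total(self, water_dataset):
        frames, P = water_dataset
        model = PolarizationGPR().fit(frames[:20], P[:20])
        frame = frames[40]
        # swap two whole water molecules (same species pattern)
        order = np.arange(len(frame))
        order[[0, 1, 2, 3, 4, 5]] = [3, 4, 5, 0, 1, 2]
        permuted = Frame(
            [frame.species[i] for i in order], frame.positions[order], frame.cell
        )
        np.testing.assert_allclose(
            model.predict([permuted])[0], model.predict([frame])[0], atol=1e-9
        )

    def test_training_error_monotone_in_regularization(self, water_dataset):
        frames, P = water_dataset
        Qinv = np.linalg.inv(quantum_matrix(frames[0].cell))
        errs = []
        for reg in (1e-1, 1e-3, 1e-6):
            model = PolarizationGPR(regularization=reg).fit(frames[:20], P[:20])
            pred = model.predict(frames[:20])
            errs.append(von_mises_error(pred @ Qinv.T, P[:20] @ Qinv.T))
        assert errs[0] >= errs[1] >= errs[2] - 1e-12

    def test_singular_system_raises(self, water_dataset):
        frames, P = water_dataset
        with pytest.raises(IllConditionedError, match="regulari"):
            PolarizationGPR(regularization=0.0).fit(
                [frames[0]] * 4, np.tile(P[0], (4, 1))
            )

    def test_learning_curve_monotone(self):
        """Median held-out error is non-increasing as n_train doubles."""
        spec = FixtureSpec(n_water=4, n_ethanol=0, box=9.0, seed=11)
        frames = make_dataset(spec, 55)
        P = np.array([smooth_polarization_oracle(f) for f in frames])
        Qinv = np.linalg.inv(quantum_matrix(frames[0].cell))
        test_idx = np.arange(40, 55)
        medians = []
        for n_train in (10, 20, 40):
            errs = []
            for s in range(5):
                rng = np.random.default_rng([13, s])
                idx = rng.choice(40, size=n_train, replace=False)
                m = PolarizationGPR().fit([frames[i] for i in idx], P[idx])
                pred = m.predict([frames[i] for i in test_idx])
                errs.append(von_mises_error(pred @ Qinv.T, P[test_idx] @ Qinv.T))
            medians.append(np.median(errs))
        assert medians[0] >= medians[1] >= medians[2]

    def test_save_load_round_trip(self, tmp_path, water_dataset):
        frames, P = water_dataset
        model = PolarizationGPR().fit(frames[:10], P[:10])
        path = tmp_path / "pol.npz"
        model.save(path)
        loaded = PolarizationGPR.load(path)
        np.testing.assert_allclose(
            loaded.predict(frames[10:13]), model.predict(frames[10:13]), rtol=1e-12
        )


@pytest.fixture(scope="module")
def wannier_data():
    spec = FixtureSpec(n_water=3, n_ethanol=0, box=9.0, seed=21)
    frames = make_dataset(spec, 65)
    targets = []
    for i, f in enumerate(frames):
        centers = make_wannier_centers(f, noise_scale=0.001, seed=i)
        targets.append(assign_nearest(f, centers).delta_sums)
    return frames, targets


class TestWannierGPR:
    def test_training_atom_recovery(self, wannier_data):
        frames, targets = wannier_data
        model = WannierGPR().fit(frames[:20], targets[:20])
        pred = model.predict(frames[0])
        scale = np.abs(targets[0]).max()
        # bounded by regularization bias plus the small target jitter
        assert np.abs(pred - targets[0]).max() < 1e-2 * scale

    def test_heldout_relative_error(self, wannier_data):
        frames, targets = wannier_data
        model = WannierGPR().fit(frames[:50], targets[:50])
        errs, mags = [], []
        for f, t in zip(frames[50:], targets[50:]):
            pred = model.predict(f)
            errs.append(np.linalg.norm(pred - t, axis=1))
            mags.append(np.linalg.norm(t, axis=1))
        mean_err = np.concatenate(errs).mean()
        mean_mag = np.concatenate([m[m > 0] for m in mags]).mean()
        assert mean_err <= 0.05 * mean_mag

    def test_hydrogens_predict_near_zero(self, wannier_data):
        frames, targets = wannier_data
        model = WannierGPR().fit(frames[:20], targets[:20])
        pred = model.predict(frames[30])
        h_idx = [i for i, s in enumerate(frames[30].species) if s == "H"]
        o_idx = [i for i, s in enumerate(frames[30].species) if s == "O"]
        assert np.abs(pred[h_idx]).max() < 1e-6 * np.abs(pred[o_idx]).max()

    def test_insufficient_species_data(self, wannier_data):
        frames, targets = wannier_data
        single_o = Frame(
            ["O", "H", "H"],
            frames[0].positions[:3],
            frames[0].cell,
        )
        with pytest.raises(InsufficientDataError):
            WannierGPR().fit([single_o], [np.zeros((3, 3))])

    def test_save_load_round_trip(self, tmp_path, wannier_data):
        frames, targets = wannier_data
        model = WannierGPR().fit(frames[:15], targets[:15])
        path = tmp_path / "wan.npz"
        model.save(path)
        loaded = WannierGPR.load(path)
        np.testing.assert_allclose(
            loaded.predict(frames[20]), model.predict(frames[20]), rtol=1e-12
        )

    def test_sklearn_params_round_trip(self):
        model = WannierGPR(regularization=1e-4, zeta=2)
        params = model.get_params()
        clone = WannierGPR(**params)
        assert clone.get_params() == params
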