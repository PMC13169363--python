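import numpy as np
import pytest

from wanpol.core import quantum_matrix
from wanpol.synthetic import (
    FixtureSpec,
    make_dataset,
    make_mixture_frame,
    make_wannier_centers,
    smooth_polarization_oracle,
    wrap_with_random_branches,
)


@pytest.fixture(scope="session")
def water_dataset():
    """70 independent 4-water frames with smooth oracle polarizations."""
    spec = FixtureSpec(n_water=4, n_ethanol=0, box=9.0, seed=1)
    frames = make_dataset(spec, 70)
    P = np.array([smooth_polarization_oracle(f) for f in frames])
    return frames, P


@pytest.fixture(scope="session")
def branch_scattered_dataset():
    """The standard unwrapping fixture: 200 points, offsets in [-2, 2]^3."""
    spec = FixtureSpec(n_water=4, n_ethanol=0, box=9.0, seed=7)
    frames = make_dataset(spec, 200)
    P = np.array([smooth_polarization_oracle(f) for f in frames])
    Q = quantum_matrix(frames[0].cell)
    wrapped, true_offsets = wrap_with_random_branches(P, Q, seed=7, offset_range=2)
    p_smooth = np.linalg.solve(Q, P.T).T
    return frames, P, Q, wrapped, true_offsets, p_smooth


@pytest.fixture(scope="session")
def mixture_frame():
    """One frame with 4 waters and 1 ethanol, with ideal Wannier centers."""
    spec = FixtureSpec(n_water=4, n_ethanol=1, box=11.0, seed=3)
    frame = make_mixture_frame(spec)
    centers = make_wannier_centers(frame, noise_scale=0.0, seed=0)
    return frame, centers


@pytest.fixture(scope="session")
def ethanol_frame():
    spec = FixtureSpec(n_water=0, n_ethanol=1, box=10.0, seed=2)
    frame = make_mixture_frame(spec)
    centers = make_wannier_centers(frame, noise_scale=0.0, seed=0)
    return frame, centers
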