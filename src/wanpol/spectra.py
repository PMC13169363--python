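"""Infrared spectra from polarization time series.

The IR absorption of a classical trajectory is obtained from the dipole
autocorrelation function,

    I_IR(w) ~ w^2 Int <P(t).P(0)> e^{iwt} dt,

implemented as: remove the mean of ``P``, estimate the autocorrelation
summed over the three Cartesian components, truncate at half the
trajectory length, apodize (Hann by default), discrete cosine transform
with 2x zero-padding, multiply by the squared wavenumber.  The overall
proportionality constant is 1: intensities are in arbitrary units, peak
positions and shapes are the contract.  No quantum correction factor is
applied (classical trajectories in, classical spectra out).

When the polarization is split into first-hydration-shell and bulk water
contributions ``P = P1 + P2`` the spectrum splits as

    I(w) = I1(w) + I2(w) + Ic(w)

with ``I1``/``I2`` the auto-term spectra and ``Ic`` the cross-correlation
term, computed here as ``I - I1 - I2`` so the closure is exact (the
symmetrized cross-correlation route is algebraically identical and is
available as :func:`cross_spectrum`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import NoPeakError, ValidationError

__all__ = [
    "SPEED_OF_LIGHT_CM_FS",
    "DipoleTrajectory",
    "Spectrum",
    "PeakSeries",
    "ir_spectrum",
    "decompose_polarization",
    "decomposed_spectra",
    "cross_spectrum",
    "peak_position",
    "peak_shift_series",
]

#: Speed of light in cm/fs; wavenumber (cm^-1) = frequency (1/fs) / c.
SPEED_OF_LIGHT_CM_FS = 2.99792458e-5


@dataclass
class DipoleTrajectory:
    """Uniformly sampled dipole time series (times fs, P e*Angstrom)."""

    times: np.ndarray
    P: np.ndarray
    P1: np.ndarray | None = None
    P2: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        T = len(self.times)
        if T < 8:
            raise ValidationError("need at least 8 time steps")
        if self.P.shape != (T, 3):
            raise ValidationError("P must be (T, 3)")
        steps = np.diff(self.times)
        if steps.min() <= 0 or np.ptp(steps) > 1e-9 * steps[0]:
            raise ValidationError("time grid must be uniform and increasing")
        for name in ("P1", "P2"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != (T, 3):
                    raise ValidationError(f"{name} must be (T, 3)")
                setattr(self, name, v)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class Spectrum:
    """Wavenumber grid (cm^-1, ascending) and intensity (arbitrary units)."""

    wavenumbers: np.ndarray
    intensity: np.ndarray
    I1: np.ndarray | None = None
    I2: np.ndarray | None = None
    Ic: np.ndarray | None = None

    def __post_init__(self):
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValidationError("wavenumber grid must be ascending")
        if self.I1 is not None and self.I2 is not None and self.Ic is not None:
            closure = self.I1 + self.I2 + self.Ic
            scale = max(float(np.abs(self.intensity).max()), 1e-300)
            if np.abs(closure - self.intensity).max() > 1e-8 * scale:
                raise ValidationError("I1 + I2 + Ic does not close to the total")


@dataclass
class PeakSeries:
    """Peak positions and shifts relative to a reference concentration."""

    concentrations: np.ndarray
    peak_positions: np.ndarray
    shifts: np.ndarray
    reference: float


def _window(name: str, L: int) -> np.ndarray:
    name = name.lower()
    tau = np.arange(L)
    if name == "hann":
        return 0.5 * (1.0 + np.cos(np.pi * tau / L))
    if name in ("rect", "none", "boxcar"):
        return np.ones(L)
    if name == "blackman":
        w = np.blackman(2 * L)
        return w[L:]
    raise ValidationError(f"unknown window {name!r}")


def _autocorrelation(x: np.ndarray, L: int) -> np.ndarray:
    """Biased autocorrelation of the 3 components summed, lags 0..L-1."""
    T = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * T)))
    acf = np.zeros(L)
    for a in range(3):
        f = np.fft.rfft(x[:, a], nfft)
        c = np.fft.irfft(f * f.conj(), nfft)[:L]
        acf += c / T
    return acf


def _spectrum_from_acf(acf, dt, window, max_wavenumber):
    L = len(acf)
    w = _window(window, L)
    cw = acf * w
    nfft = 4 * L  # 2x zero-padding of the L-point correlation
    # one-sided cosine transform: C(-t) = C(t)
    ft = np.fft.rfft(cw, nfft).real * 2.0 - cw[0]
    freqs = np.fft.rfftfreq(nfft, d=dt)
    wn = freqs / SPEED_OF_LIGHT_CM_FS
    keep = wn <= max_wavenumber
    return wn[keep], (wn[keep] ** 2) * ft[keep] * dt


def ir_spectrum(
    traj: DipoleTrajectory,
    window: str = "hann",
    max_wavenumber: float = 4000.0,
) -> Spectrum:
    """IR spectrum of the total polarization of a trajectory."""
    x = traj.P - traj.P.mean(axis=0)
    L = len(traj.times) // 2
    acf = _autocorrelation(x, L)
    wn, inten = _spectrum_from_acf(acf, traj.dt, window, max_wavenumber)
    return Spectrum(wavenumbers=wn, intensity=inten)


def decompose_polarization(frame, per_atom: np.ndarray, molecules: list[dict],
                           shell_flags) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Partial sums of per-atom dipole contributions by hydration shell.

    ``molecules`` is the output of :func:`wanpol.geometry.identify_molecules`
    and ``shell_flags`` one boolean per molecule (first hydration shell of
    ethanol or not).  Returns ``(P1, P2, P_other)``: first-shell water,
    remaining water, and non-water contributions.
    """
    per_atom = np.asarray(per_atom, dtype=float)
    if per_atom.shape != (len(frame), 3):
        raise ValidationError("per_atom must be (N_atoms, 3)")
    flags = np.asarray(shell_flags, dtype=bool)
    if flags.shape != (len(molecules),):
        raise ValidationError(
            "shell_flags must hold one boolean per molecule "
            f"({len(molecules)} molecules, got {flags.shape})"
        )
    P1 = np.zeros(3)
    P2 = np.zeros(3)
    other = np.zeros(3)
    for mol, flag in zip(molecules, flags):
        contrib = per_atom[mol["atoms"]].sum(axis=0)
        if mol["kind"] == "water":
            if flag:
                P1 += contrib
            else:
                P2 += contrib
        else:
            other += contrib
    return P1, P2, other


def decomposed_spectra(
    traj: DipoleTrajectory,
    window: str = "hann",
    max_wavenumber: float = 4000.0,
) -> Spectrum:
    """Shell-resolved spectrum ``I = I1 + I2 + Ic`` from a split trajectory."""
    if traj.P1 is None or traj.P2 is None:
        raise ValidationError("trajectory has no P1/P2 components")
    scale = max(float(np.abs(traj.P).max()), 1e-300)
    if np.abs(traj.P1 + traj.P2 - traj.P).max() > 1e-8 * scale:
        raise ValidationError("P1 + P2 is inconsistent with the stored total")
    total = ir_spectrum(traj, window, max_wavenumber)
    I1 = ir_spectrum(
        DipoleTrajectory(traj.times, traj.P1), window, max_wavenumber
    ).intensity
    I2 = ir_spectrum(
        DipoleTrajectory(traj.times, traj.P2), window, max_wavenumber
    ).intensity
    Ic = total.intensity - I1 - I2
    return Spectrum(
        wavenumbers=total.wavenumbers,
        intensity=total.intensity,
        I1=I1,
        I2=I2,
        Ic=Ic,
    )


def cross_spectrum(
    traj: DipoleTrajectory,
    window: str = "hann",
    max_wavenumber: float = 4000.0,
) -> Spectrum:
    """Cross term from the symmetrized P1/P2 cross-correlation directly.

    Used as an independent check of the ``I - I1 - I2`` route; the two are
    algebraically identical.
    """
    if traj.P1 is None or traj.P2 is None:
        raise ValidationError("trajectory has no P1/P2 components")
    x1 = traj.P1 - traj.P1.mean(axis=0)
    x2 = traj.P2 - traj.P2.mean(axis=0)
    T = x1.shape[0]
    L = T // 2
    nfft = 1 << int(np.ceil(np.log2(2 * T)))
    acf = np.zeros(L)
    for a in range(3):
        f1 = np.fft.rfft(x1[:, a], nfft)
        f2 = np.fft.rfft(x2[:, a], nfft)
        c = np.fft.irfft(f1 * f2.conj() + f2 * f1.conj(), nfft)[:L]
        acf += c / T
    wn, inten = _spectrum_from_acf(acf, traj.dt, window, max_wavenumber)
    return Spectrum(wavenumbers=wn, intensity=inten)


def peak_position(spectrum: Spectrum, search_window: tuple[float, float]) -> float:
    """Peak wavenumber in a window, refined by 3-point quadratic fit."""
    lo, hi = search_window
    wn = spectrum.wavenumbers
    if lo < wn[0] or hi > wn[-1] or lo >= hi:
        raise ValidationError("search window must lie inside the grid")
    sel = np.nonzero((wn >= lo) & (wn <= hi))[0]
    if len(sel) < 3:
        raise ValidationError("window contains fewer than 3 grid points")
    y = spectrum.intensity[sel]
    k = int(np.argmax(y))
    if np.ptp(y) == 0:
        raise NoPeakError("spectrum is flat in the search window")
    if k == 0 or k == len(y) - 1:
        return float(wn[sel[k]])
    curv = y[k - 1] - 2 * y[k] + y[k + 1]
    if curv >= 0:
        raise NoPeakError("no local maximum (curvature >= 0) in the window")
    delta = 0.5 * (y[k - 1] - y[k + 1]) / curv
    spacing = wn[sel[k] + 1] - wn[sel[k]]
    return float(wn[sel[k]] + delta * spacing)


def peak_shift_series(
    spectra: dict[float, Spectrum],
    search_window: tuple[float, float],
    reference_concentration: float,
) -> PeakSeries:
    """Peak positions versus concentration, shifted to a reference."""
    if reference_concentration not in spectra:
        raise ValidationError(
            f"reference concentration {reference_concentration} not in the map"
        )
    concs = np.array(sorted(spectra))
    pos = np.array([peak_position(spectra[c], search_window) for c in concs])
    ref_pos = pos[np.nonzero(concs == reference_concentration)[0][0]]
    shifts = pos - ref_pos
    shifts[concs == reference_concentration] = 0.0
    return PeakSeries(
        concentrations=concs,
        peak_positions=pos,
        shifts=shifts,
        reference=reference_concentration,
    )
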