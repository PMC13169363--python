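"""Readers and writers for the package's on-disk formats.

* multi-frame extended XYZ with a ``Lattice="..."`` comment line (frames),
* plain xyz with a dummy element symbol for Wannier centers,
* CSV tables for polarizations, dipole trajectories, and spectra
  (via pandas),
* a JSON run configuration that round-trips losslessly and rejects
  unknown keys.

Coordinates are Cartesian Angstrom, atoms 0-indexed; cells are stored
row-major (lattice vectors as rows) in files.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core import EA_TO_DEBYE, Cell, Frame
from .exceptions import ParseError, ValidationError
from .spectra import DipoleTrajectory, Spectrum
from .wannier import WannierSet

__all__ = [
    "read_extxyz",
    "write_extxyz",
    "read_wannier_xyz",
    "write_wannier_xyz",
    "read_polarization_csv",
    "write_polarization_csv",
    "read_dipole_csv",
    "write_dipole_csv",
    "write_spectrum_csv",
    "RunConfig",
]

logger = logging.getLogger(__name__)

_LATTICE_RE = re.compile(r'Lattice\s*=\s*"([^"]+)"', re.IGNORECASE)


def read_extxyz(path) -> list[Frame]:
    """Parse a (multi-frame) extended-XYZ file with a lattice header."""
    frames = []
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    fid = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise ParseError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i].strip()!r}"
            ) from None
        if i + 1 >= len(lines):
            raise ParseError(f"{path}:{i + 1}: truncated file (missing comment line)")
        comment = lines[i + 1]
        m = _LATTICE_RE.search(comment)
        if not m:
            raise ParseError(
                f"{path}:{i + 2}: no Lattice=\"...\" entry in the comment line"
            )
        vals = [float(v) for v in m.group(1).split()]
        if len(vals) != 9:
            raise ParseError(f"{path}:{i + 2}: lattice needs 9 numbers")
        cell = Cell(np.array(vals).reshape(3, 3))
        body = lines[i + 2 : i + 2 + natoms]
        if len(body) < natoms:
            raise ParseError(
                f"{path}:{i + 1}: frame declares {natoms} atoms but the file ends"
            )
        species, pos = [], []
        for k, ln in enumerate(body):
            parts = ln.split()
            if len(parts) < 4:
                raise ParseError(f"{path}:{i + 3 + k}: malformed atom line")
            species.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
        frames.append(
            Frame(species=species, positions=np.array(pos), cell=cell, frame_id=fid)
        )
        fid += 1
        i += 2 + natoms
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames


def write_extxyz(path, frames: list[Frame]):
    with open(path, "w") as fh:
        for frame in frames:
            lat = " ".join(f"{v:.10f}" for v in frame.cell.vectors.ravel())
            fh.write(f"{len(frame)}\n")
            fh.write(f'Lattice="{lat}" Properties=species:S:1:pos:R:3\n')
            for s, p in zip(frame.species, frame.positions):
                fh.write(f"{s} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")


def read_wannier_xyz(path, dummy_symbol: str = "X") -> WannierSet:
    """Wannier centers from an xyz-dialect file (dummy symbol rows)."""
    centers = []
    skipped = 0
    with open(path) as fh:
        for ln in fh:
            parts = ln.split()
            if len(parts) < 4:
                continue
            try:
                xyz = [float(v) for v in parts[1:4]]
            except ValueError:
                continue
            if parts[0] == dummy_symbol:
                centers.append(xyz)
            else:
                skipped += 1
    if skipped:
        logger.info("ignored %d non-center rows in %s", skipped, path)
    if not centers:
        raise ParseError(
            f"{path}: no rows with dummy symbol {dummy_symbol!r} found"
        )
    return WannierSet(positions=np.array(centers))


def write_wannier_xyz(path, centers: WannierSet, dummy_symbol: str = "X"):
    with open(path, "w") as fh:
        fh.write(f"{len(centers)}\n")
        fh.write("Wannier centers\n")
        for p in centers.positions:
            fh.write(f"{dummy_symbol} {p[0]:.10f} {p[1]:.10f} {p[2]:.10f}\n")


def write_polarization_csv(path, P: np.ndarray, frame_ids=None, units: str = "eA",
                           extra: dict[str, np.ndarray] | None = None):
    """Polarization table with the unit convention recorded in the header."""
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if frame_ids is None:
        frame_ids = np.arange(len(P))
    df = pd.DataFrame(
        {"frame_id": frame_ids, "Px": P[:, 0], "Py": P[:, 1], "Pz": P[:, 2]}
    )
    for k, v in (extra or {}).items():
        df[k] = v
    with open(path, "w") as fh:
        fh.write(f"# units: {units}\n")
        df.to_csv(fh, index=False)


def read_polarization_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a polarization table; Debye values are converted to e*Angstrom."""
    units = "eA"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            m = re.search(r"units:\s*(\S+)", first)
            if m:
                units = m.group(1)
            df = pd.read_csv(fh)
        else:
            df = pd.read_csv(path)
    for col in ("frame_id", "Px", "Py", "Pz"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    P = df[["Px", "Py", "Pz"]].to_numpy(dtype=float)
    if units.lower() in ("d", "debye"):
        P = P / EA_TO_DEBYE
    elif units not in ("eA", "e*A", "e*Angstrom", "eAngstrom"):
        raise ParseError(f"{path}: unknown polarization units {units!r}")
    return df["frame_id"].to_numpy(), P


def write_dipole_csv(path, traj: DipoleTrajectory):
    data = {"time_fs": traj.times}
    for name, arr in (("P", traj.P), ("P1", traj.P1), ("P2", traj.P2)):
        if arr is not None:
            for a, ax in enumerate("xyz"):
                data[f"{name}{ax}"] = arr[:, a]
    pd.DataFrame(data).to_csv(path, index=False)


def read_dipole_csv(path) -> DipoleTrajectory:
    df = pd.read_csv(path)
    if "time_fs" not in df.columns:
        raise ParseError(f"{path}: missing column 'time_fs'")
    def block(name):
        cols = [f"{name}{ax}" for ax in "xyz"]
        if all(c in df.columns for c in cols):
            return df[cols].to_numpy(dtype=float)
        return None
    P = block("P")
    if P is None:
        raise ParseError(f"{path}: missing Px/Py/Pz columns")
    return DipoleTrajectory(
        times=df["time_fs"].to_numpy(dtype=float),
        P=P,
        P1=block("P1"),
        P2=block("P2"),
    )


def write_spectrum_csv(path, spectrum: Spectrum):
    data = {
        "wavenumber_cm-1": spectrum.wavenumbers,
        "intensity": spectrum.intensity,
    }
    for name in ("I1", "I2", "Ic"):
        v = getattr(spectrum, name)
        if v is not None:
            data[name] = v
    pd.DataFrame(data).to_csv(path, index=False)


@dataclass
class RunConfig:
    """Complete run configuration; JSON round-trip is lossless.

    Unknown keys in a configuration file are rejected rather than ignored,
    so typos cannot silently fall back to defaults.
    """

    radial_cutoff: float = 4.0
    n_radial: int = 6
    l_max: int = 4
    gaussian_width: float = 0.3
    zeta: int = 2
    regularization: float = 1e-8
    probe_fraction: float = 0.05
    max_restarts: int = 20
    dip_threshold: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    hbond_max_OO: float = 3.5
    hbond_max_angle: float = 30.0
    shell_cutoff: float | None = None
    dummy_symbol: str = "X"
    units: str = "eA"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        data = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)
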