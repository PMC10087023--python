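"""Trajectory frames: coordinates, forces, box and per-atom energies.

All quantities are converted on load to the package's internal units
(Å, kJ mol⁻¹, kJ mol⁻¹ Å⁻¹).  Coordinate/force streams are read through
MDAnalysis (DCD with a PSF/PDB topology, or a LAMMPS text dump with custom
columns ``id x y z fx fy fz``).  Per-atom potential and kinetic energies are
read from a columnar TSV dialect with header ``frame  atom  pe  ke``
(0-based ids, energies in the declared unit system), so fixtures need no MD
engine.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import KCAL_TO_KJ

logger = logging.getLogger(__name__)

_FORCE_FACTORS = {"real": KCAL_TO_KJ, "kcal": KCAL_TO_KJ, "kj": 1.0, "metal": None}


@dataclass
class FrameBatch:
    """Congruent per-frame arrays for one analysis window.

    coordinates : (n_frames, n_atoms, 3) Å
    forces      : (n_frames, n_atoms, 3) kJ mol⁻¹ Å⁻¹, or None
    box         : (n_frames, 3) orthorhombic box lengths, Å
    pe_per_atom, ke_per_atom : (n_frames, n_atoms) kJ mol⁻¹, or None
    temperature : K
    """

    coordinates: np.ndarray
    box: np.ndarray
    temperature: float = 298.0
    forces: np.ndarray | None = None
    pe_per_atom: np.ndarray | None = None
    ke_per_atom: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        self.box = np.asarray(self.box, dtype=float).reshape(-1, 3)
        if self.box.shape[0] == 1 and self.n_frames > 1:
            self.box = np.repeat(self.box, self.n_frames, axis=0)
        if self.box.shape[0] != self.n_frames:
            raise ValueError("box frame count does not match coordinates")
        if np.any(self.box <= 0):
            raise ValueError("box lengths must be positive")
        for name in ("forces",):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.coordinates.shape:
                    raise ValueError(f"{name} shape mismatch with coordinates")
                setattr(self, name, arr)
        for name in ("pe_per_atom", "ke_per_atom"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.coordinates.shape[:2]:
                    raise ValueError(f"{name} shape mismatch with coordinates")
                setattr(self, name, arr)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]


def _force_factor(units: str) -> float:
    f = _FORCE_FACTORS.get(units.lower())
    if f is None:
        raise ValueError(f"unknown unit system {units!r}; use 'real' or 'kj'")
    return f


def _read_mda(path: str, topology: str | None, stride: int):
    import MDAnalysis as mda

    path = str(path)
    kwargs = {}
    if path.endswith((".dump", ".lammpstrj", ".lammpsdump")):
        kwargs = {"format": "LAMMPSDUMP",
                  "additional_columns": ["fx", "fy", "fz"]}
        u = mda.Universe(path, **kwargs)
    elif topology is not None:
        u = mda.Universe(str(topology), path)
    else:
        u = mda.Universe(path)
    coords, forces, boxes = [], [], []
    for ts in u.trajectory[::stride]:
        coords.append(ts.positions.astype(float).copy())
        boxes.append(np.asarray(ts.dimensions[:3], dtype=float))
        if ts.has_forces:
            forces.append(ts.forces.astype(float).copy())
        elif "fx" in ts.data:
            forces.append(np.column_stack(
                [ts.data["fx"], ts.data["fy"], ts.data["fz"]]).astype(float))
    c = np.asarray(coords)
    f = np.asarray(forces) if len(forces) == len(coords) and coords else None
    return c, f, np.asarray(boxes)


def read_energy_tsv(path: str, n_frames: int, n_atoms: int,
                    units: str = "kj") -> tuple[np.ndarray, np.ndarray]:
    """Read the per-atom energy TSV dialect (frame, atom, pe, ke)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    cols = {c.lower(): c for c in df.columns}
    missing = [k for k in ("frame", "atom", "pe", "ke") if k not in cols]
    if missing:
        raise ValueError(
            f"energy file {path} lacks columns {missing}; expected the "
            "TSV dialect with header 'frame atom pe ke'"
        )
    fac = _force_factor(units)
    pe = np.full((n_frames, n_atoms), np.nan)
    ke = np.full((n_frames, n_atoms), np.nan)
    fr = df[cols["frame"]].to_numpy(dtype=int)
    at = df[cols["atom"]].to_numpy(dtype=int)
    if fr.max(initial=-1) >= n_frames or at.max(initial=-1) >= n_atoms:
        raise ValueError(f"energy file {path} indexes beyond the trajectory")
    pe[fr, at] = df[cols["pe"]].to_numpy(dtype=float) * fac
    ke[fr, at] = df[cols["ke"]].to_numpy(dtype=float) * fac
    if np.isnan(pe).any() or np.isnan(ke).any():
        raise ValueError(f"energy file {path} does not cover every atom/frame")
    return pe, ke


def write_energy_tsv(path: str, pe: np.ndarray, ke: np.ndarray) -> None:
    n_frames, n_atoms = pe.shape
    fr, at = np.divmod(np.arange(n_frames * n_atoms), n_atoms)
    pd.DataFrame({"frame": fr, "atom": at,
                  "pe": pe.ravel(), "ke": ke.ravel()}).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def write_lammps_dump(path: str, coords: np.ndarray, box: np.ndarray,
                      forces: np.ndarray | None = None) -> None:
    """Write a LAMMPS-style text dump with ``id x y z [fx fy fz]`` columns."""
    coords = np.asarray(coords, dtype=float)
    box = np.asarray(box, dtype=float).reshape(-1, 3)
    n_frames, n_atoms = coords.shape[:2]
    cols = "id x y z" + (" fx fy fz" if forces is not None else "")
    with open(path, "w") as fh:
        for t in range(n_frames):
            fh.write(f"ITEM: TIMESTEP\n{t}\n")
            fh.write(f"ITEM: NUMBER OF ATOMS\n{n_atoms}\n")
            fh.write("ITEM: BOX BOUNDS pp pp pp\n")
            for d in range(3):
                fh.write(f"0.0 {box[t, d]:.10g}\n")
            fh.write(f"ITEM: ATOMS {cols}\n")
            for i in range(n_atoms):
                row = f"{i + 1} " + " ".join(f"{v:.10g}" for v in coords[t, i])
                if forces is not None:
                    row += " " + " ".join(f"{v:.10g}" for v in forces[t, i])
                fh.write(row + "\n")


def load_frames(coords: str, forces: str | None = None,
                energies: str | None = None, topology: str | None = None,
                stride: int = 1, units: str = "kj",
                temperature: float = 298.0) -> FrameBatch:
    """Load coordinate/force/energy streams into a :class:`FrameBatch`.

    ``coords`` may be a DCD (with ``topology``) or a LAMMPS text dump; if the
    dump carries ``fx fy fz`` columns a separate force file is unnecessary.
    ``units`` declares the source unit system for forces/energies
    (``'real'`` = kcal-based LAMMPS real units, ``'kj'`` = already kJ).
    """
    fac = _force_factor(units)
    c, f, box = _read_mda(coords, topology, stride)
    if forces is not None:
        cf, ff, _ = _read_mda(forces, topology, stride)
        f = ff if ff is not None else cf  # force-only DCD stores them as coords
        if f.shape[0] != c.shape[0]:
            raise ValueError(
                f"frame-count mismatch: {c.shape[0]} coordinate frames vs "
                f"{f.shape[0]} force frames"
            )
    if f is not None:
        f = f * fac
    pe = ke = None
    if energies is not None:
        suffix = Path(str(energies)).suffix
        if suffix in (".tsv", ".txt", ".dat", ".csv"):
            pe, ke = read_energy_tsv(energies, c.shape[0], c.shape[1], units)
        else:
            raise ValueError(
                f"unsupported energy format {suffix!r}; provide the TSV "
                "dialect (columns: frame atom pe ke)"
            )
    logger.info("loaded %d frames, %d atoms (stride=%d)",
                c.shape[0], c.shape[1], stride)
    return FrameBatch(coordinates=c, box=box, temperature=temperature,
                      forces=f, pe_per_atom=pe, ke_per_atom=ke)
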