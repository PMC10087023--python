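"""Lightweight molecular topology container.

The analysis only needs atom identities, masses, partial charges, the
residue/segment layout and the covalent bond list, so the container is a
plain set of NumPy arrays.  Real systems are ingested through MDAnalysis
(PSF, PDB, LAMMPS data); synthetic fixtures construct a :class:`Topology`
directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_MASS_TO_ELEMENT = [
    (1.5, "H"), (5.0, "He"), (11.5, "B"), (13.5, "C"), (14.5, "N"),
    (17.5, "O"), (20.0, "F"), (23.5, "Na"), (25.0, "Mg"), (29.0, "Si"),
    (31.5, "P"), (33.5, "S"), (36.5, "Cl"), (39.5, "K"), (41.0, "Ca"),
    (66.0, "Zn"), (81.0, "Br"), (128.0, "I"),
]


def element_from_mass(mass: float) -> str:
    for upper, sym in _MASS_TO_ELEMENT:
        if mass < upper:
            return sym
    return "X"


@dataclass
class Topology:
    """Atom-level description of the system.

    Parameters
    ----------
    names, elements : object arrays of per-atom labels
    masses : amu
    charges : elementary charge
    resids : integer residue ids (need not be contiguous)
    resnames : residue names (used for water/ion/protein classification)
    segids : chain/segment labels
    bonds : (n_bonds, 2) int array of 0-based atom indices
    """

    names: np.ndarray
    elements: np.ndarray
    masses: np.ndarray
    charges: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    segids: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))

    def __post_init__(self) -> None:
        n = len(self.names)
        for attr in ("elements", "masses", "charges", "resids", "resnames", "segids"):
            if len(getattr(self, attr)) != n:
                raise ValueError(f"topology field {attr!r} has wrong length")
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.bonds = np.asarray(self.bonds, dtype=int).reshape(-1, 2)
        if np.any(self.masses <= 0):
            bad = int(np.argmax(self.masses <= 0))
            raise ValueError(f"atom {bad} has non-positive mass")

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def is_hydrogen(self) -> np.ndarray:
        return np.asarray([e == "H" for e in self.elements], dtype=bool)

    def bonded_neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for a, b in self.bonds:
            adj[a].append(int(b))
            adj[b].append(int(a))
        return [sorted(x) for x in adj]

    @classmethod
    def from_mdanalysis(cls, universe) -> "Topology":
        """Build from an ``MDAnalysis.Universe`` (PSF/PDB/...)."""
        ag = universe.atoms
        n = len(ag)
        masses = np.asarray(ag.masses, dtype=float)
        try:
            elements = np.asarray([str(e).capitalize() for e in ag.elements],
                                  dtype=object)
        except Exception:
            elements = np.asarray([element_from_mass(m) for m in masses],
                                  dtype=object)
        try:
            charges = np.asarray(ag.charges, dtype=float)
        except Exception:
            charges = np.zeros(n)
        try:
            bonds = np.asarray([(b[0].index, b[1].index) for b in ag.bonds],
                               dtype=int).reshape(-1, 2)
        except Exception:
            bonds = np.empty((0, 2), dtype=int)
        try:
            segids = np.asarray([str(s) for s in ag.segids], dtype=object)
        except Exception:
            segids = np.asarray(["A"] * n, dtype=object)
        return cls(
            names=np.asarray([str(x) for x in ag.names], dtype=object),
            elements=elements,
            masses=masses,
            charges=charges,
            resids=np.asarray(ag.resids, dtype=int),
            resnames=np.asarray([str(x) for x in ag.resnames], dtype=object),
            segids=segids,
            bonds=bonds,
        )


def save_topology_json(top: Topology, path: str) -> None:
    """Write the package's JSON topology dialect (atoms + bonds).

    PDB cannot carry partial charges and PSF writing is engine territory,
    so synthetic fixtures round-trip through this plain-text dialect.
    """
    import json

    data = {
        "atoms": [
            {"name": str(top.names[i]), "element": str(top.elements[i]),
             "mass": float(top.masses[i]), "charge": float(top.charges[i]),
             "resid": int(top.resids[i]), "resname": str(top.resnames[i]),
             "segid": str(top.segids[i])}
            for i in range(top.n_atoms)
        ],
        "bonds": [[int(a), int(b)] for a, b in top.bonds],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


def _load_topology_json(path: str) -> Topology:
    import json

    with open(path) as fh:
        data = json.load(fh)
    atoms = data["atoms"]
    return Topology(
        names=np.asarray([a["name"] for a in atoms], dtype=object),
        elements=np.asarray([a["element"] for a in atoms], dtype=object),
        masses=np.asarray([a["mass"] for a in atoms], dtype=float),
        charges=np.asarray([a["charge"] for a in atoms], dtype=float),
        resids=np.asarray([a["resid"] for a in atoms], dtype=int),
        resnames=np.asarray([a["resname"] for a in atoms], dtype=object),
        segids=np.asarray([a["segid"] for a in atoms], dtype=object),
        bonds=np.asarray(data.get("bonds", []), dtype=int).reshape(-1, 2),
    )


def load_topology(path: str, **kwargs) -> Topology:
    """Read a topology file (PSF, PDB via MDAnalysis; .json dialect)."""
    if str(path).endswith(".json"):
        return _load_topology_json(str(path))
    import MDAnalysis as mda

    return Topology.from_mdanalysis(mda.Universe(str(path), **kwargs))
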