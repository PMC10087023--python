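"""Three-level unit hierarchy: united atoms, monomers, polymers.

The multiscale cell correlation decomposition discretises the system into
units at three length scales: a united atom (UA) is a heavy atom plus all
hydrogens covalently bonded to it, a monomer is a residue (or a whole small
molecule such as water or an ion), and a polymer is a whole molecule.  Each
UA carries a geometry class that fixes how many rotational (torque) modes it
contributes: 3 for a nonlinear constituent, 2 for a linear one (heavy atom
plus a single hydrogen), 0 for a bare heavy atom.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import ION_RESNAMES, PROTEIN_RESNAMES, WATER_RESNAMES
from .topology import Topology

GEOMETRY_POINT = "point"
GEOMETRY_LINEAR = "linear"
GEOMETRY_NONLINEAR = "nonlinear"

ROTATIONAL_MODES = {GEOMETRY_NONLINEAR: 3, GEOMETRY_LINEAR: 2, GEOMETRY_POINT: 0}


@dataclass
class UnitedAtom:
    id: int
    heavy_atom: int
    hydrogens: list[int]
    geometry_class: str
    monomer: int = -1

    @property
    def atoms(self) -> list[int]:
        return [self.heavy_atom, *self.hydrogens]

    @property
    def rotational_modes(self) -> int:
        return ROTATIONAL_MODES[self.geometry_class]


@dataclass
class Monomer:
    id: int
    kind: str                      # protein_residue | water | ion | other
    residue_name: str
    resid: int
    segid: str
    uas: list[int]
    backbone_atoms: dict[str, int] = field(default_factory=dict)
    polymer: int = -1

    @property
    def is_terminal_capable(self) -> bool:
        return self.kind == "protein_residue"


@dataclass
class Polymer:
    id: int
    monomers: list[int]
    net_charge: float = 0.0


@dataclass
class UnitHierarchy:
    """Atoms partitioned into UAs, monomers and polymers."""

    topology: Topology
    uas: list[UnitedAtom]
    monomers: list[Monomer]
    polymers: list[Polymer]
    atom_to_ua: np.ndarray
    atom_to_monomer: np.ndarray
    atom_to_polymer: np.ndarray

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def ua_atoms(self, ua_id: int) -> list[int]:
        return self.uas[ua_id].atoms

    def monomer_atoms(self, mon_id: int) -> list[int]:
        return [a for ua in self.monomers[mon_id].uas
                for a in self.uas[ua].atoms]

    def polymer_atoms(self, pol_id: int) -> list[int]:
        return [a for m in self.polymers[pol_id].monomers
                for a in self.monomer_atoms(m)]

    def ua_mass(self, ua_id: int) -> float:
        return float(self.topology.masses[self.uas[ua_id].atoms].sum())

    def monomer_mass(self, mon_id: int) -> float:
        return float(self.topology.masses[self.monomer_atoms(mon_id)].sum())

    @property
    def water_monomers(self) -> list[int]:
        return [m.id for m in self.monomers if m.kind == "water"]

    @property
    def protein_polymers(self) -> list[int]:
        out = []
        for p in self.polymers:
            if any(self.monomers[m].kind == "protein_residue" for m in p.monomers):
                out.append(p.id)
        return out

    def ua_positions(self, coords: np.ndarray) -> np.ndarray:
        """Heavy-atom position of every UA (the UA centre point)."""
        heavy = np.asarray([ua.heavy_atom for ua in self.uas])
        return coords[heavy]

    def is_water_ua(self) -> np.ndarray:
        return np.asarray([self.monomers[ua.monomer].kind == "water"
                           for ua in self.uas], dtype=bool)


def make_whole(hier: UnitHierarchy, coordinates: np.ndarray,
               box: np.ndarray) -> np.ndarray:
    """Undo periodic wrapping within each molecule.

    Walks the bond graph of every polymer and shifts each atom to the
    minimum-image position relative to an already-visited bonded partner,
    so local frames and inertia tensors see contiguous molecules.  Accepts
    a single frame (n_atoms, 3) or a batch (n_frames, n_atoms, 3).
    """
    coords = np.array(coordinates, dtype=float)
    single = coords.ndim == 2
    if single:
        coords = coords[None]
    box = np.asarray(box, dtype=float).reshape(-1, 3)
    adj = hier.topology.bonded_neighbors()
    orders: list[list[tuple[int, int]]] = []
    for pol in hier.polymers:
        atoms = hier.polymer_atoms(pol.id)
        if len(atoms) < 2:
            continue
        seen = {atoms[0]}
        stack = [atoms[0]]
        order = []
        while stack:
            a = stack.pop()
            for b in adj[a]:
                if b not in seen:
                    seen.add(b)
                    order.append((a, b))
                    stack.append(b)
        orders.append(order)
    for t in range(coords.shape[0]):
        b = box[t if box.shape[0] > 1 else 0]
        frame = coords[t]
        for order in orders:
            for parent, child in order:
                d = frame[child] - frame[parent]
                frame[child] = frame[parent] + d - b * np.round(d / b)
    return coords[0] if single else coords


def _monomer_kind(resname: str, n_atoms: int) -> str:
    rn = resname.upper()
    if rn in WATER_RESNAMES:
        return "water"
    if rn in ION_RESNAMES and n_atoms == 1:
        return "ion"
    if rn in PROTEIN_RESNAMES:
        return "protein_residue"
    return "other"


def build_hierarchy(top: Topology) -> UnitHierarchy:
    """Group atoms into united atoms, monomers and polymers.

    Raises
    ------
    ValueError
        If a hydrogen is not bonded to exactly one heavy atom, or masses
        are missing/non-positive (checked by :class:`Topology`).
    """
    n = top.n_atoms
    is_h = top.is_hydrogen()
    adj = top.bonded_neighbors()

    atom_to_ua = np.full(n, -1, dtype=int)
    uas: list[UnitedAtom] = []
    for i in range(n):
        if is_h[i]:
            continue
        ua_id = len(uas)
        hydrogens = [j for j in adj[i] if is_h[j]]
        nh = len(hydrogens)
        geom = (GEOMETRY_POINT if nh == 0
                else GEOMETRY_LINEAR if nh == 1
                else GEOMETRY_NONLINEAR)
        uas.append(UnitedAtom(ua_id, i, hydrogens, geom))
        atom_to_ua[i] = ua_id
        for j in hydrogens:
            atom_to_ua[j] = ua_id

    for i in np.nonzero(is_h)[0]:
        heavies = [j for j in adj[i] if not is_h[j]]
        if len(heavies) != 1:
            raise ValueError(
                f"hydrogen atom {i} ({top.names[i]}) is bonded to "
                f"{len(heavies)} heavy atoms; expected exactly 1"
            )
        if atom_to_ua[i] != atom_to_ua[heavies[0]]:  # pragma: no cover
            raise ValueError(f"inconsistent UA assignment for hydrogen {i}")

    # monomers: contiguous (segid, resid) runs
    monomers: list[Monomer] = []
    atom_to_monomer = np.full(n, -1, dtype=int)
    key = None
    atoms_in_res: list[int] = []

    def _close_residue() -> None:
        if not atoms_in_res:
            return
        mid = len(monomers)
        resname = str(top.resnames[atoms_in_res[0]])
        kind = _monomer_kind(resname, len(atoms_in_res))
        ua_ids = sorted({int(atom_to_ua[a]) for a in atoms_in_res})
        backbone = {}
        if kind == "protein_residue":
            for a in atoms_in_res:
                nm = str(top.names[a]).upper()
                if nm in ("N", "CA", "C") and nm not in backbone:
                    backbone[nm] = a
        mon = Monomer(mid, kind, resname, int(top.resids[atoms_in_res[0]]),
                      str(top.segids[atoms_in_res[0]]), ua_ids, backbone)
        monomers.append(mon)
        for a in atoms_in_res:
            atom_to_monomer[a] = mid
        for u in ua_ids:
            uas[u].monomer = mid

    for a in range(n):
        k = (str(top.segids[a]), int(top.resids[a]))
        if k != key:
            _close_residue()
            atoms_in_res = []
            key = k
        atoms_in_res.append(a)
    _close_residue()

    for mon in monomers:
        if mon.kind == "water" and len(mon.uas) != 1:
            raise ValueError(
                f"water residue {mon.residue_name}{mon.resid} has "
                f"{len(mon.uas)} united atoms; expected exactly 1"
            )

    # polymers: connected components of the bond graph, promoted to monomers
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in top.bonds:
        ra, rb = find(int(a)), find(int(b))
        if ra != rb:
            parent[rb] = ra
    # atoms of one monomer always share a polymer even if bonds are missing
    for mon in monomers:
        atoms = [a for u in mon.uas for a in uas[u].atoms]
        r0 = find(atoms[0])
        for a in atoms[1:]:
            ra = find(a)
            if ra != r0:
                parent[ra] = r0

    comp_of_monomer = [find(uas[m.uas[0]].heavy_atom) for m in monomers]
    polymers: list[Polymer] = []
    comp_to_pol: dict[int, int] = {}
    for mid, comp in enumerate(comp_of_monomer):
        if comp not in comp_to_pol:
            comp_to_pol[comp] = len(polymers)
            polymers.append(Polymer(len(polymers), []))
        pid = comp_to_pol[comp]
        polymers[pid].monomers.append(mid)
        monomers[mid].polymer = pid

    atom_to_polymer = np.full(n, -1, dtype=int)
    for pol in polymers:
        q = 0.0
        for mid in pol.monomers:
            for u in monomers[mid].uas:
                for a in uas[u].atoms:
                    atom_to_polymer[a] = pol.id
                    q += top.charges[a]
        pol.net_charge = float(q)

    hier = UnitHierarchy(top, uas, monomers, polymers,
                         atom_to_ua, atom_to_monomer, atom_to_polymer)
    assert np.all(atom_to_ua >= 0) and np.all(atom_to_monomer >= 0)
    assert np.all(atom_to_polymer >= 0)
    return hier
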