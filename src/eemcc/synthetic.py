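"""Synthetic systems with known ground truth.

Every generator is seeded and bit-reproducible, and attaches the analytic
or planted quantity the downstream analysis should recover:

* Boltzmann-sampled harmonic oscillators (positions Gaussian with variance
  kB T / k, forces -k x) with the exact quantum-harmonic-oscillator
  entropy of each mode;
* a lattice-perturbed box of rigid waters with TIP3P masses/charges for
  coordination-shell and hydrogen-bond exercises;
* an alanine dipeptide built from an internal-coordinate (Z-matrix)
  template whose backbone dihedrals are drawn from planted conformer
  states, with the generating labels and the exact -kB sum p ln p.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KJ, OMEGA_SQ_TO_SI, R_J
from .frames import FrameBatch
from .topology import Topology
from .vibrational import qho_entropy


# ---------------------------------------------------------------------------
# harmonic oscillators

@dataclass
class HarmonicSpec:
    """Isotropic-per-dof harmonic system: one atom per 3 dofs."""
    spring_constants: np.ndarray        # kJ mol^-1 Å^-2, one per dof
    masses: np.ndarray                  # amu, one per atom
    temperature: float = 298.0
    n_samples: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.spring_constants = np.atleast_1d(
            np.asarray(self.spring_constants, dtype=float))
        self.masses = np.atleast_1d(np.asarray(self.masses, dtype=float))
        if self.spring_constants.size != 3 * self.masses.size:
            raise ValueError("need one spring constant per dof (3 per atom)")
        if np.any(self.spring_constants <= 0) or np.any(self.masses <= 0):
            raise ValueError("spring constants and masses must be positive")

    @property
    def analytic_frequencies(self) -> np.ndarray:
        """Exact mode frequencies (s^-1): nu = sqrt(k/m)/2pi per dof."""
        m = np.repeat(self.masses, 3)
        return np.sqrt(self.spring_constants / m * OMEGA_SQ_TO_SI) / (2 * np.pi)

    @property
    def analytic_entropy(self) -> float:
        """Exact QHO vibrational entropy, J K^-1 mol^-1."""
        return qho_entropy(self.analytic_frequencies, self.temperature)


def sample_harmonic(spec: HarmonicSpec) -> FrameBatch:
    """Draw Boltzmann samples: x ~ N(0, kBT/k), F = -k x.

    Per-atom potential energies are the exact 0.5 k x^2 sums; kinetic
    energies come from Maxwell-Boltzmann velocities.
    """
    rng = np.random.default_rng(spec.seed)
    kbt = KB_KJ * spec.temperature
    n_atoms = spec.masses.size
    k = spec.spring_constants.reshape(n_atoms, 3)
    x = rng.normal(0.0, np.sqrt(kbt / k), size=(spec.n_samples, n_atoms, 3))
    forces = -k * x
    pe = 0.5 * (k * x ** 2).sum(axis=2)
    m = spec.masses[None, :, None]
    v = rng.normal(0.0, np.sqrt(kbt / m),
                   size=(spec.n_samples, n_atoms, 3))
    ke = 0.5 * (m * v ** 2).sum(axis=2)
    span = 4.0 * float(np.sqrt(kbt / k.min())) + 10.0
    return FrameBatch(coordinates=x, box=np.full((1, 3), span),
                      temperature=spec.temperature, forces=forces,
                      pe_per_atom=pe, ke_per_atom=ke)


# ---------------------------------------------------------------------------
# topology builders

def water_topology(n_waters: int, resid_start: int = 1) -> Topology:
    names, elements, masses, charges, resids, resnames = [], [], [], [], [], []
    bonds = []
    for w in range(n_waters):
        base = 3 * w
        names += ["O", "H1", "H2"]
        elements += ["O", "H", "H"]
        masses += [15.9994, 1.008, 1.008]
        charges += [-0.834, 0.417, 0.417]
        resids += [resid_start + w] * 3
        resnames += ["WAT"] * 3
        bonds += [(base, base + 1), (base, base + 2)]
    n = 3 * n_waters
    return Topology(
        names=np.asarray(names, dtype=object),
        elements=np.asarray(elements, dtype=object),
        masses=np.asarray(masses), charges=np.asarray(charges),
        resids=np.asarray(resids),
        resnames=np.asarray(resnames, dtype=object),
        segids=np.asarray(["W"] * n, dtype=object),
        bonds=np.asarray(bonds),
    )


def ion_topology(symbol: str = "Na", charge: float = 1.0,
                 mass: float = 22.9898, resid: int = 1) -> Topology:
    return Topology(
        names=np.asarray([symbol.upper()], dtype=object),
        elements=np.asarray([symbol.capitalize()], dtype=object),
        masses=np.asarray([mass]), charges=np.asarray([charge]),
        resids=np.asarray([resid]),
        resnames=np.asarray([symbol.upper()], dtype=object),
        segids=np.asarray(["I"], dtype=object),
    )


def concat_topologies(tops: list[Topology]) -> Topology:
    offset = 0
    fields: dict[str, list] = {k: [] for k in
                               ("names", "elements", "masses", "charges",
                                "resids", "resnames", "segids")}
    bonds = []
    for t in tops:
        for k in fields:
            fields[k].append(getattr(t, k))
        bonds.append(t.bonds + offset)
        offset += t.n_atoms
    return Topology(
        **{k: np.concatenate(v) for k, v in fields.items()},
        bonds=np.concatenate(bonds) if bonds else np.empty((0, 2), int),
    )


# alanine dipeptide (ACE-ALA-NME, 22 atoms) internal-coordinate template:
# (name, resname, resid, element, mass, charge, refs (A,B,C), r, theta, phi)
# phi entries 'PHI'/'PSI' are filled per frame; offsets keep H/CB attached.
_DIPEPTIDE_ZMAT = [
    ("CH3", "ACE", 1, "C", 12.011, -0.3662, None, None, None, None),
    ("C", "ACE", 1, "C", 12.011, 0.5972, (0, None, None), 1.522, None, None),
    ("O", "ACE", 1, "O", 15.9994, -0.5679, (1, 0, None), 1.229, 121.0, None),
    ("N", "ALA", 2, "N", 14.007, -0.4157, (1, 0, 2), 1.335, 115.0, 180.0),
    ("CA", "ALA", 2, "C", 12.011, 0.0337, (3, 1, 0), 1.449, 121.9, 180.0),
    ("C", "ALA", 2, "C", 12.011, 0.5973, (4, 3, 1), 1.522, 110.1, "PHI"),
    ("CB", "ALA", 2, "C", 12.011, -0.1825, (4, 3, 1), 1.526, 110.5, "PHI+120"),
    ("O", "ALA", 2, "O", 15.9994, -0.5679, (5, 4, 3), 1.229, 121.0, "PSI+180"),
    ("N", "NME", 3, "N", 14.007, -0.4157, (5, 4, 3), 1.335, 115.0, "PSI"),
    ("CH3", "NME", 3, "C", 12.011, -0.1490, (8, 5, 4), 1.449, 121.9, 180.0),
    ("HH31", "ACE", 1, "H", 1.008, 0.1123, (0, 1, 2), 1.090, 109.5, 60.0),
    ("HH32", "ACE", 1, "H", 1.008, 0.1123, (0, 1, 2), 1.090, 109.5, 180.0),
    ("HH33", "ACE", 1, "H", 1.008, 0.1123, (0, 1, 2), 1.090, 109.5, 300.0),
    ("H", "ALA", 2, "H", 1.008, 0.2719, (3, 1, 0), 1.010, 119.0, 0.0),
    ("HA", "ALA", 2, "H", 1.008, 0.0823, (4, 3, 1), 1.090, 109.5, "PHI-120"),
    ("HB1", "ALA", 2, "H", 1.008, 0.0603, (6, 4, 3), 1.090, 109.5, 60.0),
    ("HB2", "ALA", 2, "H", 1.008, 0.0603, (6, 4, 3), 1.090, 109.5, 180.0),
    ("HB3", "ALA", 2, "H", 1.008, 0.0603, (6, 4, 3), 1.090, 109.5, 300.0),
    ("H", "NME", 3, "H", 1.008, 0.2719, (8, 5, 4), 1.010, 119.0, 0.0),
    ("HH31", "NME", 3, "H", 1.008, 0.0976, (9, 8, 5), 1.090, 109.5, 60.0),
    ("HH32", "NME", 3, "H", 1.008, 0.0976, (9, 8, 5), 1.090, 109.5, 180.0),
    ("HH33", "NME", 3, "H", 1.008, 0.0976, (9, 8, 5), 1.090, 109.5, 300.0),
]

_DIPEPTIDE_BONDS = [(0, 1), (1, 2), (1, 3), (3, 4), (4, 5), (4, 6), (5, 7),
                    (5, 8), (8, 9), (0, 10), (0, 11), (0, 12), (3, 13),
                    (4, 14), (6, 15), (6, 16), (6, 17), (8, 18), (9, 19),
                    (9, 20), (9, 21)]


def _nerf_place(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
                r: float, theta_deg: float, phi_deg: float) -> np.ndarray:
    """Place an atom bonded to p3 with angle new-p3-p2 and torsion
    new-p3-p2-p1 (natural extension reference frame)."""
    theta = np.radians(theta_deg)
    phi = np.radians(phi_deg)
    b2 = p3 - p2
    b2n = b2 / np.linalg.norm(b2)
    n = np.cross(p2 - p1, b2n)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2n)
    d = np.array([-r * np.cos(theta),
                  r * np.sin(theta) * np.cos(phi),
                  -r * np.sin(theta) * np.sin(phi)])
    return p3 + d[0] * b2n + d[1] * m + d[2] * n


def _eval_phi(spec, phi: float, psi: float) -> float:
    if isinstance(spec, str):
        base = phi if spec.startswith("PHI") else psi
        off = float(spec[3:]) if len(spec) > 3 else 0.0
        return base + off
    return float(spec)


def dipeptide_topology() -> Topology:
    """Alanine dipeptide (ACE-ALA-NME, 22 atoms) with amber-style charges."""
    order = sorted(range(len(_DIPEPTIDE_ZMAT)),
                   key=lambda i: (_DIPEPTIDE_ZMAT[i][2], i))
    rows = [_DIPEPTIDE_ZMAT[i] for i in order]
    remap = {old: new for new, old in enumerate(order)}
    return Topology(
        names=np.asarray([r[0] for r in rows], dtype=object),
        elements=np.asarray([r[3] for r in rows], dtype=object),
        masses=np.asarray([r[4] for r in rows]),
        charges=np.asarray([r[5] for r in rows]),
        resids=np.asarray([r[2] for r in rows]),
        resnames=np.asarray([r[1] for r in rows], dtype=object),
        segids=np.asarray(["P"] * len(rows), dtype=object),
        bonds=np.asarray([(remap[a], remap[b]) for a, b in _DIPEPTIDE_BONDS]),
    )


def dipeptide_coordinates(phi: float, psi: float) -> np.ndarray:
    """Cartesian coordinates (Å, Z-matrix order remapped to topology order)
    of the dipeptide at given backbone dihedrals (degrees)."""
    coords = np.zeros((len(_DIPEPTIDE_ZMAT), 3))
    coords[0] = (0.0, 0.0, 0.0)
    coords[1] = (1.522, 0.0, 0.0)
    th = np.radians(121.0)
    coords[2] = coords[1] + 1.229 * np.array([-np.cos(th), np.sin(th), 0.0])
    for i, row in enumerate(_DIPEPTIDE_ZMAT[3:], start=3):
        a, b, c = row[6]
        coords[i] = _nerf_place(coords[c], coords[b], coords[a],
                                row[7], row[8], _eval_phi(row[9], phi, psi))
    order = sorted(range(len(_DIPEPTIDE_ZMAT)),
                   key=lambda i: (_DIPEPTIDE_ZMAT[i][2], i))
    return coords[order]


@dataclass
class ConformerPlan:
    """Planted backbone conformer states for the toy dipeptide."""
    probabilities: np.ndarray = field(
        default_factory=lambda: np.array([1.0]))
    phi_means: np.ndarray = field(default_factory=lambda: np.array([-80.0]))
    psi_means: np.ndarray = field(default_factory=lambda: np.array([150.0]))
    sigma: float = 10.0

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        self.phi_means = np.asarray(self.phi_means, dtype=float)
        self.psi_means = np.asarray(self.psi_means, dtype=float)
        if not np.isclose(self.probabilities.sum(), 1.0):
            raise ValueError("state probabilities must sum to 1")

    @property
    def analytic_entropy(self) -> float:
        """Exact -kB sum p ln p of the planted states, J K^-1 mol^-1."""
        p = self.probabilities[self.probabilities > 0]
        return float(-R_J * np.sum(p * np.log(p)))


def make_toy_dipeptide(n_frames: int, plan: ConformerPlan | None = None,
                       seed: int = 0, box_length: float = 40.0,
                       ) -> tuple[Topology, FrameBatch, np.ndarray]:
    """Dipeptide trajectory with planted backbone conformer states.

    Returns (topology, batch, state_labels).  Forces are white-noise
    placeholders (the fixture targets the conformational analysis);
    per-atom energies follow equipartition-scale noise.
    """
    plan = plan or ConformerPlan()
    rng = np.random.default_rng(seed)
    top = dipeptide_topology()
    states = rng.choice(plan.probabilities.size, size=n_frames,
                        p=plan.probabilities)
    phis = plan.phi_means[states] + rng.normal(0, plan.sigma, n_frames)
    psis = plan.psi_means[states] + rng.normal(0, plan.sigma, n_frames)
    coords = np.stack([dipeptide_coordinates(phi, psi)
                       for phi, psi in zip(phis, psis)])
    coords += box_length / 2.0
    forces = rng.normal(0.0, 30.0, size=coords.shape)
    kbt = KB_KJ * 298.0
    pe = rng.normal(-50.0, 1.0, size=coords.shape[:2])
    ke = rng.gamma(1.5, kbt, size=coords.shape[:2])
    batch = FrameBatch(coordinates=coords,
                       box=np.full((n_frames, 3), box_length),
                       temperature=298.0, forces=forces,
                       pe_per_atom=pe, ke_per_atom=ke)
    return top, batch, states


# ---------------------------------------------------------------------------
# water boxes

def _water_geometry(o_pos: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rigid TIP3P-geometry water (O, H1, H2) at a random orientation."""
    r_oh, half = 0.9572, np.radians(104.52 / 2.0)
    h1 = np.array([r_oh * np.cos(half), r_oh * np.sin(half), 0.0])
    h2 = np.array([r_oh * np.cos(half), -r_oh * np.sin(half), 0.0])
    # uniform random rotation via QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return np.stack([o_pos, o_pos + q @ h1, o_pos + q @ h2])


def make_water_box_frames(n_waters: int, density: float = 0.0334,
                          n_frames: int = 1, jitter: float = 0.25,
                          seed: int = 0) -> tuple[Topology, FrameBatch]:
    """Lattice-perturbed liquid-like water box.

    Oxygens sit on a cubic lattice at the requested number density
    (default 0.0334 Å⁻³, liquid water at ambient conditions), jittered by
    a Gaussian of width ``jitter``; orientations are uniform.  Forces are
    zero (the box targets shell/H-bond analyses).
    """
    if n_waters < 2:
        raise ValueError("need at least two waters")
    rng = np.random.default_rng(seed)
    per_side = int(np.ceil(n_waters ** (1.0 / 3.0)))
    spacing = (1.0 / density) ** (1.0 / 3.0)
    box_len = per_side * spacing
    sites = np.array([(i, j, k) for i in range(per_side)
                      for j in range(per_side) for k in range(per_side)],
                     dtype=float)[:n_waters] * spacing + spacing / 2.0
    top = water_topology(n_waters)
    frames = []
    for _ in range(n_frames):
        o = sites + rng.normal(0.0, jitter, size=sites.shape)
        o %= box_len          # wrap whole molecules, never individual atoms
        coords = np.concatenate([_water_geometry(p, rng) for p in o])
        frames.append(coords)
    coords = np.stack(frames)
    return top, FrameBatch(coordinates=coords,
                           box=np.full((n_frames, 3), box_len),
                           temperature=298.0,
                           forces=np.zeros_like(coords))


def make_solvated_dipeptide(n_frames: int = 3, n_waters: int = 40,
                            plan: ConformerPlan | None = None,
                            seed: int = 0, with_ion: bool = True,
                            ) -> tuple[Topology, FrameBatch]:
    """Toy solvated system: dipeptide + water shell (+ one Na⁺).

    Exercises the whole pipeline (shells, H-bonds, proximity grouping,
    all entropy terms, enthalpy).  Waters overlapping the solute are
    culled, so the realised water count can be below ``n_waters``.
    """
    rng = np.random.default_rng(seed)
    ptop, pbatch, _ = make_toy_dipeptide(n_frames, plan, seed=seed + 1,
                                         box_length=1.0)
    solute = pbatch.coordinates - 0.5
    wtop0, wbatch = make_water_box_frames(n_waters, n_frames=1,
                                          seed=seed + 2)
    box_len = float(wbatch.box[0, 0])
    center = box_len / 2.0
    solute = solute + center
    keep = []
    w0 = wbatch.coordinates[0]
    for w in range(wtop0.n_atoms // 3):
        d = np.linalg.norm(w0[3 * w][None, :] - solute[0], axis=1)
        if d.min() > 3.0:
            keep.append(w)
    wtop = water_topology(len(keep), resid_start=10)
    tops = [ptop, wtop]
    if with_ion:
        tops.append(ion_topology(resid=1000))
    top = concat_topologies(tops)
    frames = []
    for t in range(n_frames):
        parts = [solute[t]]
        wc = np.concatenate([w0[3 * w:3 * w + 3] for w in keep])
        parts.append(wc + rng.normal(0, 0.15, size=wc.shape))
        if with_ion:
            corner = np.full(3, box_len - 2.0)
            parts.append(corner[None, :] + rng.normal(0, 0.05, size=(1, 3)))
        frames.append(np.concatenate(parts))
    coords = np.stack(frames)
    forces = rng.normal(0.0, 30.0, size=coords.shape)
    kbt = KB_KJ * 298.0
    pe = rng.normal(-40.0, 1.0, size=coords.shape[:2])
    ke = rng.gamma(1.5, kbt, size=coords.shape[:2])
    batch = FrameBatch(coordinates=coords,
                       box=np.full((n_frames, 3), box_len),
                       temperature=298.0, forces=forces,
                       pe_per_atom=pe, ke_per_atom=ke)
    return top, batch
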