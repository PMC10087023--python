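"""Vibrational entropy from force/torque covariance matrices.

Within the multiscale cell correlation framework the entropy of motion
inside an energy well is evaluated per structural level from the covariance
of mass-weighted net forces (translations) and inertia-weighted torques
(rotations) on the units of that level, expressed in level-appropriate
local frames:

* whole molecule (polymer, and each water molecule): principal axes of
  inertia with the origin at the centre of mass;
* residue: origin at the mean of the N, CA, C backbone atoms, x along
  N->C, y normal to the N-CA-C plane, z completing the right-handed set
  (residue *translations* use the polymer principal axes);
* united atom: origin at the heavy atom, z along the mean covalent-bond
  vector to the hydrogens, x anchored to the heavy-atom bond graph.

Each covariance eigenvalue lambda gives a quasi-harmonic frequency
``nu = sqrt(lambda / (kB T)) / (2 pi)`` and the per-mode entropy is that of
a quantum harmonic oscillator.  At every level below the whole molecule the
six smallest force-covariance eigenvalues are removed (they duplicate the
rigid-body translation/rotation carried by the level above); torque
matrices are assembled only over constituents with rotational modes, which
number 3, 2 and 0 for nonlinear, linear and point units.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import KB_KJ, KB_SI, OMEGA_SQ_TO_SI, PLANCK_SI, R_J
from .frames import FrameBatch
from .hierarchy import UnitHierarchy

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# local frames

@dataclass
class LocalFrame:
    """Origin (Å) and right-handed orthonormal axes (rows) of a unit frame."""
    origin: np.ndarray
    axes: np.ndarray

    def to_local(self, vectors: np.ndarray) -> np.ndarray:
        return vectors @ self.axes.T


def _sign_fix(axes: np.ndarray, refs: list[np.ndarray]) -> np.ndarray:
    """Deterministic, rotation-covariant sign convention for frame axes.

    Each of the first two axes is flipped so its projection on the first
    reference vector with non-negligible overlap is positive; the third is
    rebuilt as the cross product, enforcing right-handedness.
    """
    axes = axes.copy()
    for i in range(2):
        for ref in refs:
            d = float(axes[i] @ ref)
            if abs(d) > 1e-8:
                if d < 0:
                    axes[i] = -axes[i]
                break
    axes[2] = np.cross(axes[0], axes[1])
    return axes


def principal_frame(coords: np.ndarray, masses: np.ndarray) -> LocalFrame:
    """Principal axes of inertia about the centre of mass."""
    m = np.asarray(masses, dtype=float)
    com = m @ coords / m.sum()
    r = coords - com
    r2 = np.einsum("ij,ij->i", r, r)
    inertia = np.einsum("i,ij,ik->jk", m, r, r)
    inertia = np.diag([float(m @ r2)] * 3) - inertia
    _, vecs = np.linalg.eigh(inertia)
    axes = vecs.T  # rows, ascending moments
    refs = [r[0], r[-1], np.cross(r[0], r[-1])]
    return LocalFrame(com, _sign_fix(axes, refs))


def residue_frame(coords: np.ndarray, n_idx: int, ca_idx: int,
                  c_idx: int) -> LocalFrame:
    """Backbone-anchored residue frame (x: N->C, y: normal of N-CA-C)."""
    pn, pca, pc = coords[n_idx], coords[ca_idx], coords[c_idx]
    origin = (pn + pca + pc) / 3.0
    x = pc - pn
    nx = np.linalg.norm(x)
    normal = np.cross(pca - pn, pc - pn)
    nn = np.linalg.norm(normal)
    if nx < 1e-8 or nn < 1e-8:
        raise ValueError("degenerate backbone geometry")
    x = x / nx
    y = normal / nn
    y = y - (y @ x) * x
    y /= np.linalg.norm(y)
    return LocalFrame(origin, np.array([x, y, np.cross(x, y)]))


def ua_frame(coords: np.ndarray, heavy: int, hydrogens: list[int],
             heavy_neighbors: list[int]) -> LocalFrame:
    """United-atom rotational frame.

    z is the mean covalent-bond vector to the hydrogens; x is anchored to
    the first heavy-atom bond (orthogonalised against z) so the frame
    co-rotates with the molecule, falling back to an H-bond vector and then
    to a global-axis projection for isolated units.
    """
    origin = coords[heavy]
    if not hydrogens:
        return LocalFrame(origin, np.eye(3))
    z = np.mean([coords[h] - origin for h in hydrogens], axis=0)
    z = z / np.linalg.norm(z)
    refs = [coords[j] - origin for j in heavy_neighbors]
    refs += [coords[h] - origin for h in hydrogens]
    refs += [np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])]
    for ref in refs:
        x = ref - (ref @ z) * z
        nx = np.linalg.norm(x)
        if nx > 1e-8:
            x = x / nx
            break
    return LocalFrame(origin, np.array([x, np.cross(z, x), z]))


def build_frames(hier: UnitHierarchy, coords: np.ndarray,
                 levels: tuple[str, ...] = ("polymer", "monomer", "ua"),
                 ) -> dict[str, dict[int, LocalFrame]]:
    """Local frames for every unit of the requested levels in one frame."""
    top = hier.topology
    out: dict[str, dict[int, LocalFrame]] = {}
    if "polymer" in levels:
        out["polymer"] = {}
        for pol in hier.polymers:
            atoms = hier.polymer_atoms(pol.id)
            if len(atoms) == 1:
                out["polymer"][pol.id] = LocalFrame(coords[atoms[0]], np.eye(3))
            else:
                out["polymer"][pol.id] = principal_frame(
                    coords[atoms], top.masses[atoms])
    if "monomer" in levels:
        out["monomer"] = {}
        for mon in hier.monomers:
            atoms = hier.monomer_atoms(mon.id)
            bb = mon.backbone_atoms
            if len(bb) == 3:
                try:
                    out["monomer"][mon.id] = residue_frame(
                        coords, bb["N"], bb["CA"], bb["C"])
                    continue
                except ValueError:
                    logger.warning("collinear backbone in monomer %d; "
                                   "falling back to principal axes", mon.id)
            if len(atoms) == 1:
                out["monomer"][mon.id] = LocalFrame(coords[atoms[0]], np.eye(3))
            else:
                out["monomer"][mon.id] = principal_frame(
                    coords[atoms], top.masses[atoms])
    if "ua" in levels:
        adj = top.bonded_neighbors()
        is_h = top.is_hydrogen()
        out["ua"] = {}
        for ua in hier.uas:
            heavy_nb = [j for j in adj[ua.heavy_atom] if not is_h[j]]
            out["ua"][ua.id] = ua_frame(coords, ua.heavy_atom,
                                        ua.hydrogens, heavy_nb)
    return out


# ---------------------------------------------------------------------------
# covariance accumulation

class CovarianceAccumulator:
    """Running mean of outer products of stacked per-unit vectors."""

    def __init__(self, dim: int, level: str = "", label: str = ""):
        self.dim = dim
        self.level = level
        self.label = label
        self._sum = np.zeros((dim, dim))
        self.n_samples = 0

    def add(self, vector: np.ndarray) -> None:
        v = np.asarray(vector, dtype=float).ravel()
        if v.size != self.dim:
            raise ValueError("sample dimension mismatch")
        self._sum += np.outer(v, v)
        self.n_samples += 1

    @property
    def matrix(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.zeros((self.dim, self.dim))
        if self.n_samples < self.dim:
            logger.warning("covariance %s/%s: %d samples for dimension %d "
                           "(rank deficient)", self.level, self.label,
                           self.n_samples, self.dim)
        m = self._sum / self.n_samples
        return 0.5 * (m + m.T)


def _net_force(forces: np.ndarray, atoms: list[int]) -> np.ndarray:
    return forces[atoms].sum(axis=0)


def _torque(coords: np.ndarray, forces: np.ndarray, atoms: list[int],
            origin: np.ndarray) -> np.ndarray:
    r = coords[atoms] - origin
    return np.cross(r, forces[atoms]).sum(axis=0)


def _axis_inertia(coords: np.ndarray, masses: np.ndarray, atoms: list[int],
                  frame: LocalFrame, axis_rows: np.ndarray) -> np.ndarray:
    """Per-frame moment of inertia about each local axis through the origin."""
    r = coords[atoms] - frame.origin
    m = masses[atoms]
    r2 = np.einsum("ij,ij->i", r, r)
    proj = r @ axis_rows.T                      # (n_atoms, n_axes)
    return m @ (r2[:, None] - proj ** 2)


def _rot_axes(frame: LocalFrame, geometry_class: str) -> np.ndarray | None:
    """Rows of the local axes that carry rotational modes for a unit."""
    if geometry_class == "point":
        return None
    if geometry_class == "linear":
        return frame.axes[:2]                   # modes normal to the H axis
    return frame.axes


def accumulate_covariance(batch: FrameBatch, hier: UnitHierarchy, level: str,
                          polymer: int | None = None,
                          monomer: int | None = None,
                          ) -> tuple[CovarianceAccumulator, CovarianceAccumulator]:
    """Force and torque covariance accumulators for one level.

    ``level='polymer'`` treats the whole molecule ``polymer`` as a single
    unit; ``level='monomer'`` stacks the residues of ``polymer``;
    ``level='ua'`` stacks the united atoms of residue ``monomer``.
    """
    if batch.forces is None:
        raise ValueError("FrameBatch carries no forces")
    top = hier.topology
    if level == "polymer":
        units = [("polymer", polymer)]
    elif level == "monomer":
        units = [("monomer", m) for m in hier.polymers[polymer].monomers]
    elif level == "ua":
        units = [("ua", u) for u in hier.monomers[monomer].uas]
    else:
        raise ValueError(f"unknown level {level!r}")

    unit_atoms = []
    unit_masses = []
    for kind, uid in units:
        atoms = (hier.polymer_atoms(uid) if kind == "polymer"
                 else hier.monomer_atoms(uid) if kind == "monomer"
                 else hier.ua_atoms(uid))
        unit_atoms.append(atoms)
        unit_masses.append(float(top.masses[atoms].sum()))

    geom = [("nonlinear" if kind != "ua" else hier.uas[uid].geometry_class)
            for kind, uid in units]
    rot_dims = [{"nonlinear": 3, "linear": 2, "point": 0}[g] for g in geom]

    label = f"pol{polymer}" if level != "ua" else f"mon{monomer}"
    f_acc = CovarianceAccumulator(3 * len(units), level, label)
    t_acc = CovarianceAccumulator(sum(rot_dims), level, label)

    for t in range(batch.n_frames):
        coords = batch.coordinates[t]
        forces = batch.forces[t]
        frames = build_frames(hier, coords,
                              levels=("polymer",) if level == "polymer"
                              else ("polymer", "monomer") if level == "monomer"
                              else ("monomer", "ua"))
        fvec = np.empty(3 * len(units))
        tvec = np.empty(t_acc.dim)
        tpos = 0
        for k, (kind, uid) in enumerate(units):
            atoms = unit_atoms[k]
            if kind == "polymer":
                trans_frame = rot_frame = frames["polymer"][uid]
            elif kind == "monomer":
                trans_frame = frames["polymer"][hier.monomers[uid].polymer]
                rot_frame = frames["monomer"][uid]
            else:
                trans_frame = frames["monomer"][monomer]
                rot_frame = frames["ua"][uid]
            fnet = trans_frame.axes @ _net_force(forces, atoms)
            fvec[3 * k:3 * k + 3] = fnet / np.sqrt(unit_masses[k])
            axes = _rot_axes(rot_frame, geom[k])
            if axes is not None:
                tau = axes @ _torque(coords, forces, atoms, rot_frame.origin)
                inertia = _axis_inertia(coords, top.masses, atoms,
                                        rot_frame, axes)
                good = inertia > 1e-12
                w = np.zeros_like(tau)
                w[good] = tau[good] / np.sqrt(inertia[good])
                tvec[tpos:tpos + len(w)] = w
                tpos += len(w)
        f_acc.add(fvec)
        if t_acc.dim:
            t_acc.add(tvec)
    return f_acc, t_acc


def accumulate_water_covariance(batch: FrameBatch, hier: UnitHierarchy,
                                water_monomers: list[int],
                                ) -> tuple[CovarianceAccumulator, CovarianceAccumulator]:
    """Pooled single-molecule covariances over a class of water molecules.

    Each water is its own top-level unit (3 translational + 3 rotational
    modes in its principal frame); statistics are pooled over molecules and
    frames before diagonalisation so that small groups converge.
    """
    if batch.forces is None:
        raise ValueError("FrameBatch carries no forces")
    top = hier.topology
    f_acc = CovarianceAccumulator(3, "water", "class")
    t_acc = CovarianceAccumulator(3, "water", "class")
    atom_lists = [hier.monomer_atoms(m) for m in water_monomers]
    masses = [float(top.masses[a].sum()) for a in atom_lists]
    for t in range(batch.n_frames):
        coords = batch.coordinates[t]
        forces = batch.forces[t]
        for atoms, mass in zip(atom_lists, masses):
            frame = principal_frame(coords[atoms], top.masses[atoms])
            fnet = frame.axes @ _net_force(forces, atoms)
            f_acc.add(fnet / np.sqrt(mass))
            tau = frame.axes @ _torque(coords, forces, atoms, frame.origin)
            inertia = _axis_inertia(coords, top.masses, atoms, frame,
                                    frame.axes)
            good = inertia > 1e-12
            w = np.zeros_like(tau)
            w[good] = tau[good] / np.sqrt(inertia[good])
            t_acc.add(w)
    return f_acc, t_acc


# ---------------------------------------------------------------------------
# spectra and entropy

@dataclass
class ModeSpectrum:
    """Quasi-harmonic frequencies (s⁻¹) with mode bookkeeping."""
    frequencies: np.ndarray
    n_removed: int = 0
    n_clamped: int = 0

    @property
    def n_kept(self) -> int:
        return int(np.count_nonzero(self.frequencies > 0))


def spectrum_from_covariance(cov, temperature: float,
                             n_remove: int = 0) -> ModeSpectrum:
    """Eigenvalues -> frequencies, dropping the ``n_remove`` smallest.

    Sub-molecule levels pass ``n_remove=6`` so the rigid-body motion of the
    unit collection (counted once at the level above) is not double counted.
    Negative eigenvalues (statistical noise) are clamped to zero and
    excluded from the kept-mode count.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    matrix = cov.matrix if isinstance(cov, CovarianceAccumulator) else cov
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        return ModeSpectrum(np.empty(0))
    lam = np.linalg.eigvalsh(matrix)            # ascending
    n_remove = min(n_remove, lam.size)
    lam = lam[n_remove:]
    n_clamped = int(np.count_nonzero(lam < 0))
    if n_clamped:
        logger.info("clamped %d negative eigenvalues", n_clamped)
    lam = np.clip(lam, 0.0, None)
    omega_sq = lam / (KB_KJ * temperature) * OMEGA_SQ_TO_SI
    nu = np.sqrt(omega_sq) / (2.0 * np.pi)
    return ModeSpectrum(np.sort(nu)[::-1], n_removed=n_remove,
                        n_clamped=n_clamped)


def qho_entropy(frequencies, temperature: float) -> float:
    """Quantum-harmonic-oscillator entropy of a set of modes, J K⁻¹ mol⁻¹.

    S = kB * sum_i [ x_i/(exp(x_i)-1) - ln(1-exp(-x_i)) ],  x = h nu / kB T.
    Zero-frequency (removed/clamped) modes contribute nothing by convention.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if isinstance(frequencies, ModeSpectrum):
        frequencies = frequencies.frequencies
    nu = np.atleast_1d(np.asarray(frequencies, dtype=float))
    if np.any(~np.isfinite(nu)) or np.any(nu < 0):
        raise ValueError("frequencies must be finite and non-negative")
    x = PLANCK_SI * nu / (KB_SI * temperature)
    s = np.zeros_like(x)
    small = (x > 0) & (x < 700.0)
    xs = x[small]
    s[small] = xs / np.expm1(xs) - np.log(-np.expm1(-xs))
    return float(R_J * s.sum())


# ---------------------------------------------------------------------------
# assembled per-molecule entropies

@dataclass
class EntropyLedger:
    """Vibrational entropy terms (J K⁻¹ mol⁻¹) with mode bookkeeping."""
    terms: dict[str, float] = field(default_factory=dict)
    mode_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.terms.values()))


def vibrational_entropy_molecule(batch: FrameBatch, hier: UnitHierarchy,
                                 polymer: int) -> EntropyLedger:
    """Polymer + monomer + united-atom vibrational entropy of one molecule."""
    T = batch.temperature
    ledger = EntropyLedger()
    f_acc, t_acc = accumulate_covariance(batch, hier, "polymer",
                                         polymer=polymer)
    sp_f = spectrum_from_covariance(f_acc, T, n_remove=0)
    sp_t = spectrum_from_covariance(t_acc, T, n_remove=0)
    ledger.terms["S_P_transvib"] = qho_entropy(sp_f, T)
    ledger.terms["S_P_rovib"] = qho_entropy(sp_t, T)
    ledger.mode_counts["polymer"] = (sp_f.n_kept, sp_t.n_kept)

    monomers = hier.polymers[polymer].monomers
    if len(monomers) > 1:
        f_acc, t_acc = accumulate_covariance(batch, hier, "monomer",
                                             polymer=polymer)
        sp_f = spectrum_from_covariance(f_acc, T, n_remove=6)
        sp_t = spectrum_from_covariance(t_acc, T, n_remove=0)
        ledger.terms["S_M_transvib"] = qho_entropy(sp_f, T)
        ledger.terms["S_M_rovib"] = qho_entropy(sp_t, T)
        ledger.mode_counts["monomer"] = (sp_f.n_kept, sp_t.n_kept)

    s_ua_t = s_ua_r = 0.0
    for mon in monomers:
        if len(hier.monomers[mon].uas) < 2 and len(monomers) == 1:
            continue  # single-UA molecule: fully described at the top level
        f_acc, t_acc = accumulate_covariance(batch, hier, "ua", monomer=mon)
        sp_f = spectrum_from_covariance(f_acc, T, n_remove=6)
        sp_t = spectrum_from_covariance(t_acc, T, n_remove=0)
        s_ua_t += qho_entropy(sp_f, T)
        s_ua_r += qho_entropy(sp_t, T)
    ledger.terms["S_UA_transvib"] = s_ua_t
    ledger.terms["S_UA_rovib"] = s_ua_r
    return ledger


def water_class_vibrational_entropy(batch: FrameBatch, hier: UnitHierarchy,
                                    water_monomers: list[int]) -> EntropyLedger:
    """Per-molecule vibrational entropy of a pooled class of waters."""
    T = batch.temperature
    f_acc, t_acc = accumulate_water_covariance(batch, hier, water_monomers)
    ledger = EntropyLedger()
    sp_f = spectrum_from_covariance(f_acc, T)
    sp_t = spectrum_from_covariance(t_acc, T)
    ledger.terms["S_W_transvib"] = qho_entropy(sp_f, T)
    ledger.terms["S_W_rovib"] = qho_entropy(sp_t, T)
    ledger.mode_counts["water"] = (sp_f.n_kept, sp_t.n_kept)
    return ledger
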