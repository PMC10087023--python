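"""Parameter-free coordination shells and topological hydrogen bonds.

Coordination shells are computed at the united-atom level with the relative
angular distance (RAD) construction: neighbour ``j`` belongs to the shell of
``i`` unless some closer particle ``k`` blocks it, i.e. unless

    1/r_ij**2  <=  (1/r_ik**2) * cos(theta_jik)

for any ``k`` with r_ik < r_ij, where theta_jik is the angle at ``i``
between ``j`` and ``k``.  The construction has no distance parameter; a
generous pre-filter cutoff is used only to bound the candidate list.

Hydrogen bonds are assigned topologically: each donor hydrogen bonds to the
acceptor atom (negative partial charge, inside the donor UA's shell) for
which q_D * q_A / r**2 is most negative.

First-shell waters are grouped by their nearest non-water UA and the residue
containing it (the proximity criterion); waters whose shell holds UAs from
two or more residues additionally emit residue-pair labels.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hierarchy import UnitHierarchy

BULK_LABEL = "bulk"


def minimum_image(disp: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box is None:
        return disp
    return disp - box * np.round(disp / box)


def rad_shell(positions: np.ndarray, center: int,
              box: np.ndarray | None = None, cutoff: float = 8.0,
              blockers: str = "all-closer") -> list[int]:
    """Ordered (closest-first) RAD coordination shell of one particle.

    ``blockers`` selects whether a candidate may be blocked by every closer
    particle (``'all-closer'``, the default) or only by closer particles
    already accepted into the shell (``'accepted'``).
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    if n < 2:
        return []
    disp = minimum_image(positions - positions[center], box)
    r2 = np.einsum("ij,ij->i", disp, disp)
    r2[center] = np.inf
    if np.any(r2 == 0.0):
        j = int(np.argmin(r2))
        raise ValueError(f"coincident UA positions: {center} and {j}")
    cand = np.nonzero(r2 <= cutoff * cutoff)[0]
    if cand.size == 0:  # isolated particle: fall back to the full list
        cand = np.nonzero(np.isfinite(r2))[0]
    order = cand[np.argsort(r2[cand], kind="stable")]
    r = np.sqrt(r2)
    shell: list[int] = []
    for idx, j in enumerate(order):
        closer = shell if blockers == "accepted" else order[:idx]
        blocked = False
        for k in closer:
            cos_t = float(np.dot(disp[j], disp[k]) / (r[j] * r[k]))
            if 1.0 / r2[j] <= cos_t / r2[k]:
                blocked = True
                break
        if not blocked:
            shell.append(int(j))
    return shell


def rad_shell_bruteforce(positions: np.ndarray, center: int,
                         box: np.ndarray | None = None) -> list[int]:
    """Direct enumeration of the RAD condition over all particle pairs.

    Independent oracle used in tests: no cutoff, no sorting shortcuts.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    disp = minimum_image(positions - positions[center], box)
    r = np.linalg.norm(disp, axis=1)
    shell = []
    for j in range(n):
        if j == center:
            continue
        ok = True
        for k in range(n):
            if k in (center, j) or r[k] >= r[j]:
                continue
            cos_t = float(np.dot(disp[j], disp[k]) / (r[j] * r[k]))
            if 1.0 / r[j] ** 2 <= cos_t / r[k] ** 2:
                ok = False
                break
        if ok:
            shell.append(j)
    return sorted(shell, key=lambda j: r[j])


@dataclass
class HBondRecord:
    frame: int
    donor_hydrogen: int
    donor_ua: int
    acceptor_ua: int
    acceptor_atom: int
    r: float


@dataclass
class WaterLabel:
    """Nearest-solute assignment of one first-shell (or bulk) water."""
    water_monomer: int
    nearest_ua: int = -1            # -1 for bulk
    nearest_monomer: int = -1
    nearest_distance: float = np.inf
    second_monomer: int = -1
    contacted_monomers: list[int] = field(default_factory=list)

    @property
    def is_bulk(self) -> bool:
        return self.nearest_ua < 0

    @property
    def label(self) -> str:
        return BULK_LABEL if self.is_bulk else f"mon{self.nearest_monomer}"

    def residue_pairs(self) -> list[tuple[int, int]]:
        ms = self.contacted_monomers
        return [(a, b) for ai, a in enumerate(ms) for b in ms[ai + 1:]]


@dataclass
class ShellMap:
    """Per-frame RAD shells and water labels for a trajectory window."""

    shells: list[list[list[int]]]          # [frame][ua] -> neighbour UA ids
    water_labels: list[dict[int, WaterLabel]]
    hbonds: list[list[HBondRecord]]

    @property
    def n_frames(self) -> int:
        return len(self.shells)


def compute_frame_shells(hier: UnitHierarchy, coords: np.ndarray,
                         box: np.ndarray | None, cutoff: float = 8.0,
                         blockers: str = "all-closer") -> list[list[int]]:
    pos = hier.ua_positions(coords)
    return [rad_shell(pos, i, box, cutoff, blockers)
            for i in range(pos.shape[0])]


def assign_hbonds(hier: UnitHierarchy, coords: np.ndarray,
                  box: np.ndarray | None, shells: list[list[int]],
                  frame: int = 0) -> list[HBondRecord]:
    """Topological H-bond assignment: argmin of q_D*q_A/r^2 per hydrogen.

    Ties are broken toward the lowest acceptor atom index.
    """
    top = hier.topology
    records: list[HBondRecord] = []
    for ua in hier.uas:
        for h in ua.hydrogens:
            q_d = top.charges[h]
            if q_d <= 0:
                continue
            best = None
            for acc_ua in shells[ua.id]:
                for a in hier.uas[acc_ua].atoms:
                    q_a = top.charges[a]
                    if q_a >= 0:
                        continue
                    d = minimum_image(coords[a] - coords[h], box)
                    r2 = float(d @ d)
                    val = q_d * q_a / r2
                    key = (val, a)
                    if best is None or key < best[0]:
                        best = (key, acc_ua, a, np.sqrt(r2))
            if best is not None:
                records.append(HBondRecord(frame, int(h), ua.id,
                                           int(best[1]), int(best[2]),
                                           float(best[3])))
    return records


def label_waters(hier: UnitHierarchy, coords: np.ndarray,
                 box: np.ndarray | None,
                 shells: list[list[int]]) -> dict[int, WaterLabel]:
    """Nearest-solute grouping of every water from its RAD shell.

    Ties in distance are broken toward the lowest monomer id.
    """
    is_water_ua = hier.is_water_ua()
    pos = hier.ua_positions(coords)
    out: dict[int, WaterLabel] = {}
    for wm in hier.water_monomers:
        wua = hier.monomers[wm].uas[0]
        best: dict[int, float] = {}        # non-water monomer -> min distance
        best_ua: dict[int, int] = {}
        for nb in shells[wua]:
            if is_water_ua[nb]:
                continue
            mon = hier.uas[nb].monomer
            d = float(np.linalg.norm(minimum_image(pos[nb] - pos[wua], box)))
            if d < best.get(mon, np.inf):
                best[mon] = d
                best_ua[mon] = nb
        lab = WaterLabel(wm)
        if best:
            ranked = sorted(best, key=lambda m: (best[m], m))
            lab.nearest_monomer = ranked[0]
            lab.nearest_ua = best_ua[ranked[0]]
            lab.nearest_distance = best[ranked[0]]
            if len(ranked) > 1:
                lab.second_monomer = ranked[1]
            lab.contacted_monomers = sorted(ranked)
        out[wm] = lab
    return out


def compute_shell_map(hier: UnitHierarchy, coordinates: np.ndarray,
                      box: np.ndarray, cutoff: float = 8.0,
                      blockers: str = "all-closer",
                      with_hbonds: bool = True) -> ShellMap:
    """RAD shells, water labels and H-bonds for every frame of a batch."""
    coordinates = np.atleast_3d(coordinates)
    if coordinates.ndim == 3 and coordinates.shape[-1] != 3:
        raise ValueError("coordinates must end in xyz")
    box = np.asarray(box, dtype=float).reshape(-1, 3)
    shells_all, labels_all, hb_all = [], [], []
    for t in range(coordinates.shape[0]):
        b = box[t if box.shape[0] > 1 else 0]
        sh = compute_frame_shells(hier, coordinates[t], b, cutoff, blockers)
        shells_all.append(sh)
        labels_all.append(label_waters(hier, coordinates[t], b, sh))
        hb_all.append(assign_hbonds(hier, coordinates[t], b, sh, frame=t)
                      if with_hbonds else [])
    return ShellMap(shells_all, labels_all, hb_all)


def shell_statistics(hier: UnitHierarchy, smap: ShellMap):
    """Aggregate counts: mean Nc per UA, and per-residue NWc / NRc.

    NWc(r): mean number of waters whose shell contains a UA of residue r.
    NRc(r): mean number of distinct UAs from other residues inside the
    shells of residue r's UAs.
    """
    import pandas as pd

    n_ua = len(hier.uas)
    is_water_ua = hier.is_water_ua()
    nc = np.zeros(n_ua)
    prot_mons = [m.id for m in hier.monomers if m.kind != "water"]
    nwc = {m: 0.0 for m in prot_mons}
    nrc = {m: 0.0 for m in prot_mons}
    for t in range(smap.n_frames):
        sh = smap.shells[t]
        for i in range(n_ua):
            nc[i] += len(sh[i])
        water_contacts = {m: set() for m in prot_mons}
        for wm, lab in smap.water_labels[t].items():
            wua = hier.monomers[wm].uas[0]
            for nb in sh[wua]:
                if not is_water_ua[nb]:
                    water_contacts[hier.uas[nb].monomer].add(wm)
        for m in prot_mons:
            nwc[m] += len(water_contacts[m])
            others = set()
            for u in hier.monomers[m].uas:
                for nb in sh[u]:
                    if not is_water_ua[nb] and hier.uas[nb].monomer != m:
                        others.add(nb)
            nrc[m] += len(others)
    nf = max(smap.n_frames, 1)
    nc /= nf
    per_res = pd.DataFrame({
        "monomer": prot_mons,
        "NWc": [nwc[m] / nf for m in prot_mons],
        "NRc": [nrc[m] / nf for m in prot_mons],
    })
    return nc, per_res
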