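"""Topographical (conformational) entropy from dihedral conformer states.

Every dihedral built from four heavy atoms of a residue is histogrammed on
a 30°-bin circular grid; the local maxima of the histogram define the
conformer peaks and each frame is labelled by the nearest peak in circular
distance.  The residue's topographical entropy is the Shannon entropy of
the joint distribution of conformer labels over all its dihedrals,

    S_topo = -kB * sum_i p_i ln p_i,

where i runs over the observed unique label tuples.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .constants import R_J
from .hierarchy import UnitHierarchy

BIN_WIDTH = 30.0
N_BINS = 12


@dataclass
class DihedralSeries:
    """Per-frame dihedral angle (degrees, wrapped to [-180, 180))."""
    residue: int
    atoms: tuple[int, int, int, int]
    angles: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        self.angles = (a + 180.0) % 360.0 - 180.0


def wrap_angle(a: np.ndarray) -> np.ndarray:
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


def dihedral_angles(coords: np.ndarray, quad: tuple[int, int, int, int]
                    ) -> np.ndarray:
    """Dihedral angle(s) in degrees for coordinates (..., n_atoms, 3)."""
    a, b, c, d = quad
    b1 = coords[..., b, :] - coords[..., a, :]
    b2 = coords[..., c, :] - coords[..., b, :]
    b3 = coords[..., d, :] - coords[..., c, :]
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m1, n2)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def enumerate_dihedrals(hier: UnitHierarchy) -> dict[int, list[tuple[int, int, int, int]]]:
    """Heavy-atom dihedral inventory per residue from the bond graph.

    One dihedral per heavy-heavy central bond: the terminal atoms are the
    lowest-index heavy neighbours of each central atom.  Backbone dihedrals
    whose central bond spans two residues (the omega-type quadruples) are
    attached to the later residue; impropers are not generated.
    """
    top = hier.topology
    is_h = top.is_hydrogen()
    adj = top.bonded_neighbors()
    heavy_adj = [[j for j in nbrs if not is_h[j]] for nbrs in adj]
    out: dict[int, list[tuple[int, int, int, int]]] = {
        m.id: [] for m in hier.monomers}
    seen = set()
    for b in range(top.n_atoms):
        if is_h[b]:
            continue
        for c in heavy_adj[b]:
            if c <= b:
                continue
            a_cands = [x for x in heavy_adj[b] if x != c]
            d_cands = [x for x in heavy_adj[c] if x != b]
            if not a_cands or not d_cands:
                continue
            quad = (min(a_cands), b, c, min(d_cands))
            if quad in seen:
                continue
            seen.add(quad)
            res = max(int(hier.atom_to_monomer[b]), int(hier.atom_to_monomer[c]))
            out[res].append(quad)
    return out


def find_conformers(angles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Histogram peaks and per-frame conformer labels for one dihedral.

    A bin is a peak when its count strictly exceeds both circular
    neighbours; plateau runs are merged to their lowest bin index.  Frames
    are labelled by the nearest peak centre in circular distance, ties
    resolved toward the lower peak angle.

    Returns (peak_centers_deg, labels).
    """
    a = wrap_angle(angles)
    if a.size == 0:
        raise ValueError("empty dihedral series")
    bins = ((a + 180.0) // BIN_WIDTH).astype(int) % N_BINS
    counts = np.bincount(bins, minlength=N_BINS)
    peaks = []
    for i in range(N_BINS):
        c = counts[i]
        if c == 0:
            continue
        left, right = counts[(i - 1) % N_BINS], counts[(i + 1) % N_BINS]
        if c > left and c > right:
            peaks.append(i)
        elif c == right and c > left:
            # plateau: only its lowest-index bin may represent the peak
            j = i
            while counts[(j + 1) % N_BINS] == c:
                j = (j + 1) % N_BINS
                if j == i:
                    break
            if counts[(j + 1) % N_BINS] < c:
                peaks.append(i)
    if not peaks:
        peaks = [int(np.argmax(counts))]
    centers = wrap_angle(np.asarray(peaks) * BIN_WIDTH - 180.0 + BIN_WIDTH / 2)
    order = np.argsort(centers, kind="stable")
    centers = centers[order]
    dist = np.abs(wrap_angle(a[:, None] - centers[None, :]))
    labels = np.argmin(dist, axis=1)  # argmin takes the first (lower angle) tie
    return centers, labels


@dataclass
class ConformerStateTrace:
    """Joint conformer labels per frame for one residue."""
    residue: int
    dihedrals: list[tuple[int, int, int, int]]
    labels: np.ndarray              # (n_frames, n_dihedrals)
    peak_centers: list[np.ndarray]

    def state_probabilities(self) -> np.ndarray:
        counts = Counter(map(tuple, self.labels))
        p = np.asarray(list(counts.values()), dtype=float)
        return p / p.sum()


def topographical_entropy(trace_or_labels) -> float:
    """Shannon entropy (J K⁻¹ mol⁻¹) of the joint conformer distribution."""
    if isinstance(trace_or_labels, ConformerStateTrace):
        p = trace_or_labels.state_probabilities()
    else:
        labels = np.atleast_2d(np.asarray(trace_or_labels))
        counts = Counter(map(tuple, labels))
        p = np.asarray(list(counts.values()), dtype=float)
        p = p / p.sum()
    p = p[p > 0]
    return float(-R_J * np.sum(p * np.log(p))) + 0.0


def entropy_from_probabilities(p) -> float:
    """-kB sum p ln p for explicit state probabilities (J K⁻¹ mol⁻¹)."""
    p = np.asarray(p, dtype=float)
    p = p[p > 0]
    return float(-R_J * np.sum(p * np.log(p))) + 0.0


def residue_conformer_traces(hier: UnitHierarchy, coordinates: np.ndarray
                             ) -> dict[int, ConformerStateTrace]:
    """Conformer label traces for every residue with >= 1 heavy dihedral."""
    coordinates = np.asarray(coordinates, dtype=float)
    inventory = enumerate_dihedrals(hier)
    out: dict[int, ConformerStateTrace] = {}
    for res, quads in inventory.items():
        if not quads:
            continue
        labels = np.empty((coordinates.shape[0], len(quads)), dtype=int)
        centers = []
        for k, quad in enumerate(quads):
            angles = dihedral_angles(coordinates, quad)
            pc, lab = find_conformers(angles)
            centers.append(pc)
            labels[:, k] = lab
        out[res] = ConformerStateTrace(res, quads, labels, centers)
    return out
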