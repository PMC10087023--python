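"""Orientational (topographical) entropy of water.

A water molecule's orientational entropy counts the effective number of
distinct hydrogen-bonding arrangements available in its coordination
shell.  Per coordination-shell class c (bulk, or the nearest-residue label
from the proximity grouping):

    S_or = kB * sum_c p_c ln( N_eff * pi^(3/2) * p_HB_av / sigma )

with sigma = 2 the symmetry number of water.  p_HB_n combines the
probabilities of donating to and accepting from neighbours of type n,

    p_HB_n = [p_D_n/(p_D_n+p_A_n)] * [p_A_n/(p_D_n+p_A_n)],

p_HB_av is its shell-composition-weighted average, and
N_eff = sum_n p_HB_n N_n / 0.25, where 0.25 is the ideal value for two
hydrogen bonds each with probability 0.5 to donate and to accept.
Classes whose logarithm argument falls to or below 1 contribute zero
(a single available orientation carries no entropy).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import P_HB_IDEAL, R_J, WATER_SYMMETRY_NUMBER
from .hierarchy import UnitHierarchy
from .shells import BULK_LABEL, ShellMap

logger = logging.getLogger(__name__)

# neighbour-type taxonomy around the protein surface
TYPE_WATER_FIRST_SHELL = "water_first_shell"
TYPE_WATER_OUTSIDE = "water_outside"
TYPE_PROTEIN_UA = "protein_ua"
TYPE_ION = "ion"


@dataclass
class ClassStats:
    """Accumulated donate/accept statistics for one water class."""
    n_waterframes: int = 0
    neighbor_counts: dict[str, float] = field(default_factory=dict)   # sum N_n
    donations: dict[str, float] = field(default_factory=dict)         # N_D_n
    acceptances: dict[str, float] = field(default_factory=dict)       # N_A_n

    def mean_neighbors(self) -> dict[str, float]:
        if self.n_waterframes == 0:
            return {}
        return {n: c / self.n_waterframes
                for n, c in self.neighbor_counts.items()}

    @property
    def shell_size(self) -> float:
        return float(sum(self.mean_neighbors().values()))

    def p_donate(self) -> dict[str, float]:
        tot = sum(self.donations.values())
        return {n: v / tot for n, v in self.donations.items()} if tot else {}

    def p_accept(self) -> dict[str, float]:
        tot = sum(self.acceptances.values())
        return {n: v / tot for n, v in self.acceptances.items()} if tot else {}


@dataclass
class DonorAcceptorStats:
    """Per-class statistics plus class weights p_c."""
    classes: dict[str, ClassStats] = field(default_factory=dict)

    def class_weights(self) -> dict[str, float]:
        tot = sum(c.n_waterframes for c in self.classes.values())
        if tot == 0:
            return {}
        return {k: c.n_waterframes / tot for k, c in self.classes.items()}


def phb(p_d: float, p_a: float) -> float:
    """Hydrogen-bond probability for one neighbour type.

    Equal donate/accept propensities give the ideal value 0.25; one-sided
    propensities give 0, as does an inert neighbour (both zero).
    """
    s = p_d + p_a
    if s <= 0:
        return 0.0
    return (p_d / s) * (p_a / s)


def phb_avg(stats: ClassStats) -> float:
    """Shell-weighted average hydrogen-bond probability for a class."""
    nn = stats.mean_neighbors()
    nc = sum(nn.values())
    if nc <= 0:
        raise ValueError("empty coordination shell: p_HB_av undefined")
    pd, pa = stats.p_donate(), stats.p_accept()
    return sum(phb(pd.get(n, 0.0), pa.get(n, 0.0)) * nn[n] for n in nn) / nc


def neff(stats: ClassStats) -> float:
    """Effective number of hydrogen-bond-available neighbours."""
    nn = stats.mean_neighbors()
    pd, pa = stats.p_donate(), stats.p_accept()
    return sum(phb(pd.get(n, 0.0), pa.get(n, 0.0)) * nn[n]
               for n in nn) / P_HB_IDEAL


def class_orientational_entropy(n_eff: float, p_hb_av: float,
                                sigma: float = WATER_SYMMETRY_NUMBER) -> float:
    """kB ln(N_eff pi^1.5 p_HB_av / sigma) for one class, clamped at 0."""
    arg = n_eff * np.pi ** 1.5 * p_hb_av / sigma
    if arg <= 1.0:
        return 0.0
    return float(R_J * np.log(arg))


@dataclass
class OrientationalResult:
    per_class: dict[str, dict[str, float]]
    entropy: float                  # J K^-1 mol^-1, class-weighted


def orientational_entropy(stats: DonorAcceptorStats) -> OrientationalResult:
    """Class-weighted orientational entropy over all observed shells."""
    weights = stats.class_weights()
    per_class: dict[str, dict[str, float]] = {}
    total = 0.0
    for cls, w in weights.items():
        cs = stats.classes[cls]
        if cs.shell_size <= 0:
            logger.info("class %s has an empty shell; skipped", cls)
            continue
        ne = neff(cs)
        pav = phb_avg(cs)
        s = class_orientational_entropy(ne, pav)
        per_class[cls] = {"p_c": w, "N_c": cs.shell_size, "N_eff": ne,
                          "p_HB_av": pav, "S_or": s}
        total += w * s
    return OrientationalResult(per_class, float(total))


def accumulate_donor_acceptor_stats(hier: UnitHierarchy, smap: ShellMap
                                    ) -> DonorAcceptorStats:
    """Build per-class donate/accept statistics from shells and H-bonds.

    The class of a water is its nearest-solute label (bulk or nearest
    residue); neighbour types distinguish first-shell water, outer water,
    protein UAs and ions.
    """
    stats = DonorAcceptorStats()
    is_water_ua = hier.is_water_ua()
    water_of_ua = {hier.monomers[m].uas[0]: m for m in hier.water_monomers}

    def neighbor_type(ua_id: int, labels) -> str:
        if is_water_ua[ua_id]:
            wl = labels.get(water_of_ua[ua_id])
            first = wl is not None and not wl.is_bulk
            return TYPE_WATER_FIRST_SHELL if first else TYPE_WATER_OUTSIDE
        mon = hier.monomers[hier.uas[ua_id].monomer]
        return TYPE_ION if mon.kind == "ion" else TYPE_PROTEIN_UA

    for t in range(smap.n_frames):
        labels = smap.water_labels[t]
        shells = smap.shells[t]
        donations_by_h = {}
        acceptances = {}
        for rec in smap.hbonds[t]:
            donations_by_h[rec.donor_hydrogen] = rec
            acceptances.setdefault(rec.acceptor_ua, []).append(rec)
        for wm, lab in labels.items():
            cls = lab.label
            cs = stats.classes.setdefault(cls, ClassStats())
            cs.n_waterframes += 1
            wua = hier.monomers[wm].uas[0]
            for nb in shells[wua]:
                n = neighbor_type(nb, labels)
                cs.neighbor_counts[n] = cs.neighbor_counts.get(n, 0.0) + 1
            for h in hier.uas[wua].hydrogens:
                rec = donations_by_h.get(h)
                if rec is not None:
                    n = neighbor_type(rec.acceptor_ua, labels)
                    cs.donations[n] = cs.donations.get(n, 0.0) + 1
            for rec in acceptances.get(wua, []):
                if hier.uas[rec.donor_ua].monomer == wm:
                    continue
                n = neighbor_type(rec.donor_ua, labels)
                cs.acceptances[n] = cs.acceptances.get(n, 0.0) + 1
    return stats


def bulk_reference_entropy(n_c: float = 5.2) -> float:
    """Closed form for a homogeneous shell with equal donate/accept odds.

    With a single neighbour type and p_D = p_A, N_eff reduces to N_c and
    p_HB_av to 0.25, so S_or = kB ln(N_c pi^1.5 / 8).
    """
    return float(R_J * np.log(n_c * np.pi ** 1.5 / 8.0))
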