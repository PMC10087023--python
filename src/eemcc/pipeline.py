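"""End-to-end orchestration: shells -> entropies -> enthalpy -> reports.

A single validated :class:`RunConfig` drives the whole analysis and every
output is a TSV (plus a provenance JSON echoing the configuration, frame
counts and bookkeeping), so reruns on identical inputs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enthalpy import atomic_energies, free_energy, unit_enthalpy
from .conformational import residue_conformer_traces, topographical_entropy
from .frames import FrameBatch, load_frames
from .hierarchy import UnitHierarchy, build_hierarchy, make_whole
from .orientational import (accumulate_donor_acceptor_stats,
                            orientational_entropy)
from .shells import compute_shell_map, shell_statistics
from .topology import load_topology
from .vibrational import (vibrational_entropy_molecule,
                          water_class_vibrational_entropy)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated inputs and toggles for one analysis run."""
    topology: str
    coords: str
    outdir: str
    forces: str | None = None
    energies: str | None = None
    stride: int = 1
    temperature: float = 298.0
    units: str = "kj"
    cutoff: float = 8.0
    blockers: str = "all-closer"
    include_pv: bool = False
    pool_water_classes: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        for key in ("topology", "coords"):
            p = getattr(self, key)
            if not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")
        for key in ("forces", "energies"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key} file not found: {p}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def analyse_waters(hier: UnitHierarchy, batch: FrameBatch, smap,
                   temperature: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class water thermodynamics and residue-pair water table."""
    stats = accumulate_donor_acceptor_stats(hier, smap)
    orient = orientational_entropy(stats)

    # waters per class (by nearest residue label), pooled across frames
    class_members: dict[str, set[int]] = {}
    pair_members: dict[tuple[int, int], list[tuple[int, int]]] = {}
    for t in range(smap.n_frames):
        for wm, lab in smap.water_labels[t].items():
            class_members.setdefault(lab.label, set()).add(wm)
            for pair in lab.residue_pairs():
                pair_members.setdefault(pair, []).append((t, wm))

    have_energy = batch.pe_per_atom is not None and batch.ke_per_atom is not None
    e_atom = atomic_energies(batch) if have_energy else None

    rows = []
    class_entropy: dict[str, float] = {}
    for cls, members in sorted(class_members.items()):
        members = sorted(members)
        ledger = water_class_vibrational_entropy(batch, hier, members) \
            if batch.forces is not None else None
        s_vib = ledger.total if ledger else np.nan
        oc = orient.per_class.get(cls, {})
        s_or = oc.get("S_or", 0.0)
        s_tot = (s_vib if np.isfinite(s_vib) else 0.0) + s_or
        class_entropy[cls] = s_tot
        h = np.nan
        if have_energy:
            atoms = [a for m in members for a in hier.monomer_atoms(m)]
            h = float(e_atom[atoms].sum()) / len(members)
        rows.append({
            "class": cls, "n_waters": len(members),
            "p_c": oc.get("p_c", np.nan), "N_c": oc.get("N_c", np.nan),
            "N_eff": oc.get("N_eff", np.nan),
            "p_HB_av": oc.get("p_HB_av", np.nan),
            "S_vib": s_vib, "S_or": s_or, "S_total": s_tot, "H": h,
        })
    classes = pd.DataFrame(rows)
    if not classes.empty:
        classes["S"] = classes["S_total"]
        classes = free_energy(classes, temperature).drop(columns=["S"])

    prows = []
    for (a, b), hits in sorted(pair_members.items()):
        h = np.nan
        if have_energy:
            per = [float(e_atom[hier.monomer_atoms(wm)].sum())
                   for _, wm in hits]
            h = float(np.mean(per))
        labels = [smap.water_labels[t][wm].label for t, wm in hits]
        s = float(np.mean([class_entropy.get(l, 0.0) for l in labels]))
        prows.append({"monomer_a": a, "monomer_b": b,
                      "n_waterframes": len(hits), "H": h, "S": s,
                      "G": h - temperature * s * 1e-3 if np.isfinite(h)
                      else np.nan})
    return classes, pd.DataFrame(prows)


def analyse_protein(hier: UnitHierarchy, batch: FrameBatch,
                    temperature: float
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Whole-molecule entropy ledgers and per-residue table."""
    have_energy = batch.pe_per_atom is not None and batch.ke_per_atom is not None
    traces = residue_conformer_traces(hier, batch.coordinates)
    topo = {res: topographical_entropy(tr) for res, tr in traces.items()}

    mol_rows, res_rows = [], []
    for pid in hier.protein_polymers:
        ledger = vibrational_entropy_molecule(batch, hier, pid) \
            if batch.forces is not None else None
        monomers = hier.polymers[pid].monomers
        n_res = len(monomers)
        s_topo = float(sum(topo.get(m, 0.0) for m in monomers))
        row = {"polymer": pid, "n_residues": n_res,
               "S_UA_topo": s_topo}
        if ledger:
            row.update(ledger.terms)
            row["S_total"] = ledger.total + s_topo
        if have_energy:
            atoms = hier.polymer_atoms(pid)
            e_atom = atomic_energies(batch)
            row["H"] = float(e_atom[atoms].sum())
            if "S_total" in row:
                row["G"] = row["H"] - temperature * row["S_total"] * 1e-3
        mol_rows.append(row)
        for k, m in enumerate(monomers):
            mon = hier.monomers[m]
            rrow = {"monomer": m, "restype": mon.residue_name,
                    "resid": mon.resid, "chain": mon.segid, "position": k,
                    "is_terminal": k in (0, n_res - 1),
                    "S_topo": topo.get(m, 0.0)}
            if have_energy:
                e_atom = atomic_energies(batch)
                rrow["H"] = float(e_atom[hier.monomer_atoms(m)].sum())
            res_rows.append(rrow)
    return pd.DataFrame(mol_rows), pd.DataFrame(res_rows)


def run_all(config: RunConfig) -> Path:
    """Execute the full analysis; returns the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    top = load_topology(config.topology)
    hier = build_hierarchy(top)
    batch = load_frames(config.coords, forces=config.forces,
                        energies=config.energies, topology=config.topology,
                        stride=config.stride, units=config.units,
                        temperature=config.temperature)
    logger.info("system: %d atoms, %d UAs, %d monomers, %d polymers, "
                "%d frames", hier.n_atoms, len(hier.uas),
                len(hier.monomers), len(hier.polymers), batch.n_frames)
    batch.coordinates = make_whole(hier, batch.coordinates, batch.box)

    smap = compute_shell_map(hier, batch.coordinates, batch.box,
                             cutoff=config.cutoff, blockers=config.blockers)
    nc, per_res_counts = shell_statistics(hier, smap)

    classes, pairs = analyse_waters(hier, batch, smap, config.temperature)
    _write(classes, outdir / "water_classes.tsv")
    _write(pairs, outdir / "water_pairs.tsv")

    molecules, residues = analyse_protein(hier, batch, config.temperature)
    if not residues.empty:
        residues = residues.merge(per_res_counts, on="monomer", how="left")
    _write(molecules, outdir / "molecules.tsv")
    _write(residues, outdir / "residues.tsv")

    grouping = {f"ua{u.id}": u.atoms for u in hier.uas}
    if batch.pe_per_atom is not None and batch.ke_per_atom is not None:
        _write(unit_enthalpy(batch, grouping,
                             include_pv=config.include_pv),
               outdir / "ua_enthalpy.tsv")

    cfg = dataclasses.asdict(config)
    provenance = {
        "package": "eemcc", "version": __version__,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "n_frames": batch.n_frames, "n_atoms": batch.n_atoms,
        "n_united_atoms": len(hier.uas),
        "n_waters": len(hier.water_monomers),
        "mean_shell_size": float(nc.mean()) if nc.size else None,
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return outdir
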