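"""Enthalpy partition and free-energy assembly.

The ensemble-average system Hamiltonian is partitioned over atoms: each
atom carries its kinetic energy plus its equal share of every potential
term it participates in (as dumped per atom by the MD engine).  The
enthalpy of any atom group is then the sum of its atoms' mean energies,

    H_j = sum_{i in j} ( <K_i> + <U_i> ),

which makes the partition exactly additive under any regrouping.  The
pressure-volume term is a fraction of a J/mol per water or residue at
ambient pressure and is ignored by default (a toggle adds it back for
sensitivity checks).  Free energies combine the partitioned enthalpy with
the entropy ledger as G = H - T S.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import AVOGADRO
from .frames import FrameBatch


def atomic_energies(batch: FrameBatch) -> np.ndarray:
    """Mean per-atom enthalpy <K_i> + <U_i> over frames, kJ mol⁻¹."""
    if batch.pe_per_atom is None or batch.ke_per_atom is None:
        raise ValueError(
            "FrameBatch carries no per-atom energies; supply an energy "
            "stream in the TSV dialect (columns: frame atom pe ke)"
        )
    return (batch.pe_per_atom + batch.ke_per_atom).mean(axis=0)


def unit_enthalpy(batch: FrameBatch, grouping: dict[str, list[int]],
                  include_pv: bool = False,
                  pressure_atm: float = 1.0) -> pd.DataFrame:
    """Partition the system enthalpy over an atom grouping.

    ``grouping`` maps group labels to atom-index lists forming a partition
    (groups may also cover a subset; additivity holds over whatever is
    covered).  Returns a DataFrame with columns ``group, H, n_atoms``.
    """
    e = atomic_energies(batch)
    rows = []
    pv_per_atom = 0.0
    if include_pv:
        volume = float(np.prod(batch.box.mean(axis=0))) * 1e-30  # m^3
        pv = pressure_atm * 101325.0 * volume * AVOGADRO * 1e-3  # kJ/mol
        pv_per_atom = pv / batch.n_atoms
    for label, atoms in grouping.items():
        atoms = np.asarray(atoms, dtype=int)
        rows.append({"group": label,
                     "H": float(e[atoms].sum()) + pv_per_atom * atoms.size,
                     "n_atoms": int(atoms.size)})
    return pd.DataFrame(rows)


def free_energy(table: pd.DataFrame, temperature: float,
                h_col: str = "H", s_col: str = "S") -> pd.DataFrame:
    """G = H - T S with H in kJ mol⁻¹ and S in J K⁻¹ mol⁻¹.

    Adds ``TS`` (kJ mol⁻¹) and ``G`` columns; raises if the entropy column
    is missing so unit mismatches surface early.
    """
    if h_col not in table or s_col not in table:
        raise ValueError(f"table must carry {h_col!r} and {s_col!r} columns")
    out = table.copy()
    ts = temperature * out[s_col].astype(float) * 1e-3
    out["TS"] = ts
    out["G"] = out[h_col].astype(float) - ts
    return out
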