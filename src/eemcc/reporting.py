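"""Analysis surfaces over per-group thermodynamic tables.

All functions operate on plain DataFrames so they compose with both the
pipeline outputs and hand-built tables: feature covariance on standardised
columns, referencing of per-residue values against capped-amino-acid
baselines, N-/C-side bonded-neighbour effect matrices, a hydrophobicity
ranking from water free energies, and secondary-structure grouping of
water thermodynamics.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SS_CLASSES = ["bridge", "coil", "extended", "turn", "310_helix", "alpha_helix"]

AMINO_ACIDS = ["ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS",
               "ILE", "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP",
               "TYR", "VAL"]


def feature_covariance(features: pd.DataFrame) -> pd.DataFrame:
    """Covariance matrix of standardised feature columns.

    Each column is normalised to zero mean and unit population standard
    deviation, after which cov(X, Y) = (1/N) sum (X_i - X̄)(Y_i - Ȳ) lies in
    [-1, 1] with an exactly unit diagonal.  Constant columns are dropped
    with a warning.
    """
    num = features.select_dtypes(include=[np.number])
    if len(num) < 2:
        raise ValueError("need at least two rows to compute covariance")
    sd = num.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        logger.warning("dropping constant feature columns: %s", constant)
        num = num.drop(columns=constant)
        sd = sd.drop(constant)
    z = (num - num.mean()) / sd
    cov = z.T @ z / len(z)
    np.fill_diagonal(cov.values, 1.0)
    return cov


def referenced_deltas(residues: pd.DataFrame, baselines: pd.DataFrame,
                      value_cols: tuple[str, ...] = ("TS", "H", "G"),
                      ) -> pd.DataFrame:
    """Per-residue Δ values against capped-amino-acid baselines.

    ``residues`` needs ``restype`` plus the value columns and an
    ``is_terminal`` flag; ``baselines`` maps ``restype`` to reference
    values.  Terminal residues are excluded (their atom counts and charges
    differ from the capped references); residues with no baseline are
    skipped with a log entry.
    """
    base = baselines.set_index("restype")
    rows = []
    for _, r in residues.iterrows():
        if bool(r.get("is_terminal", False)):
            continue
        rt = r["restype"]
        if rt not in base.index:
            logger.warning("no baseline for residue type %s; skipped", rt)
            continue
        row = {k: r[k] for k in residues.columns
               if k not in value_cols and not k.startswith("d")}
        for c in value_cols:
            row[f"d{c}"] = float(r[c]) - float(base.loc[rt, c])
        rows.append(row)
    return pd.DataFrame(rows)


def neighbor_effect_matrix(deltas: pd.DataFrame,
                           value_col: str = "dG"
                           ) -> dict[str, pd.DataFrame]:
    """Mean Δ value of residue type a by bonded-neighbour type b.

    ``deltas`` needs ``chain``, ``position`` (sequence index within the
    chain), ``restype`` and the value column.  Returns ``{'N': means,
    'C': means, 'N_counts': ..., 'C_counts': ...}`` where entry (a, b) of
    the N-side matrix is the mean value of residues of type a whose
    sequence predecessor (n-1) is of type b; the C-side matrix uses the
    successor (n+1).  Unobserved pairs are NaN with zero count.
    """
    types = AMINO_ACIDS
    acc = {side: {} for side in ("N", "C")}
    for chain, grp in deltas.groupby("chain"):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        rt = grp["restype"].to_numpy()
        val = grp[value_col].to_numpy(dtype=float)
        index_of = {p: i for i, p in enumerate(pos)}
        for i, p in enumerate(pos):
            for side, q in (("N", p - 1), ("C", p + 1)):
                j = index_of.get(q)
                if j is None:
                    continue
                acc[side].setdefault((rt[i], rt[j]), []).append(val[i])
    out = {}
    for side in ("N", "C"):
        mean = pd.DataFrame(np.nan, index=types, columns=types)
        count = pd.DataFrame(0, index=types, columns=types, dtype=int)
        for (a, b), vals in acc[side].items():
            if a in types and b in types:
                mean.loc[a, b] = float(np.mean(vals))
                count.loc[a, b] = len(vals)
        out[side] = mean
        out[f"{side}_counts"] = count
    return out


def hydrophobicity_rank(water_by_type: pd.DataFrame,
                        g_col: str = "G") -> pd.DataFrame:
    """Rank amino-acid types by the free energy of their shell water.

    Most stable (lowest G) water gets rank 1; ties are ordered
    alphabetically.  Rows flagged ``exclude`` (capping groups, ions) are
    removed first.
    """
    df = water_by_type.copy()
    if "exclude" in df:
        df = df[~df["exclude"].astype(bool)]
    df = df.sort_values([g_col, "restype"], kind="stable").reset_index(drop=True)
    df["HR"] = np.arange(1, len(df) + 1)
    return df[["restype", g_col, "HR"]]


def secondary_structure_grouping(water_table: pd.DataFrame,
                                 ss_labels: pd.DataFrame) -> pd.DataFrame:
    """Water thermodynamics grouped by nearest secondary-structure class.

    ``water_table`` needs ``monomer`` (nearest residue id), ``n_waters``
    and TS/H/G columns on a per-water basis; ``ss_labels`` maps ``monomer``
    to ``ss`` class strings.  Unlabelled residues fall into class
    ``other``.  Percent columns each sum to 100 over the emitted rows.
    """
    lab = ss_labels.set_index("monomer")["ss"]
    df = water_table.copy()
    df["ss"] = [lab.get(m, "other") for m in df["monomer"]]
    unlabeled = int((df["ss"] == "other").sum())
    if unlabeled:
        logger.info("%d water groups near residues without a secondary-"
                    "structure label", unlabeled)
    total_res = ss_labels["monomer"].nunique()
    total_wat = df["n_waters"].sum()
    rows = []
    for ss, grp in df.groupby("ss"):
        w = grp["n_waters"].to_numpy(dtype=float)
        if w.sum() == 0:
            continue
        row = {"ss": ss,
               "pct_residues": 100.0 * (ss_labels["ss"] == ss).sum() / total_res
               if total_res else 0.0,
               "pct_waters": 100.0 * w.sum() / total_wat}
        for c in ("TS", "H", "G"):
            if c in grp:
                row[c] = float(np.average(grp[c], weights=w))
        rows.append(row)
    order = {s: i for i, s in enumerate(SS_CLASSES)}
    rows.sort(key=lambda r: order.get(r["ss"], len(order)))
    return pd.DataFrame(rows)
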