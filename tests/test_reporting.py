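import numpy as np
import pandas as pd
import pytest

from eemcc.reporting import (feature_covariance, hydrophobicity_rank,
                             neighbor_effect_matrix, referenced_deltas,
                             secondary_structure_grouping)


class TestFeatureCovariance:
    def test_identical_and_negated_columns(self):
        x = np.array([0.3, 1.7, -2.0, 0.5])
        df = pd.DataFrame({"x": x, "same": x, "neg": -x})
        cov = feature_covariance(df)
        assert cov.loc["x", "same"] == pytest.approx(1.0)
        assert cov.loc["x", "neg"] == pytest.approx(-1.0)

    def test_three_point_example(self):
        df = pd.DataFrame({"X": [1.0, 2.0, 3.0], "Y": [1.0, 3.0, 2.0]})
        cov = feature_covariance(df)
        assert cov.loc["X", "Y"] == pytest.approx(0.5, abs=1e-12)

    def test_matrix_properties(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 5)),
                          columns=list("abcde"))
        cov = feature_covariance(df)
        np.testing.assert_allclose(cov.values, cov.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(cov.values), 1.0)
        assert np.all(np.abs(cov.values) <= 1.0 + 1e-12)

    def test_constant_column_dropped(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]})
        cov = feature_covariance(df)
        assert "const" not in cov.columns


class TestReferencedDeltas:
    def _tables(self):
        residues = pd.DataFrame({
            "restype": ["ALA", "GLY", "ALA", "LYS"],
            "chain": ["A"] * 4, "position": [0, 1, 2, 3],
            "is_terminal": [True, False, False, True],
            "TS": [10.0, 12.0, 11.0, 14.0],
            "H": [-100.0, -108.0, -100.0, -90.0],
            "G": [-110.0, -120.0, -111.0, -104.0],
        })
        baselines = pd.DataFrame({
            "restype": ["ALA", "GLY"],
            "TS": [11.0, 12.0], "H": [-100.0, -100.0], "G": [-111.0, -112.0],
        })
        return residues, baselines

    def test_deltas_and_terminal_exclusion(self):
        residues, baselines = self._tables()
        out = referenced_deltas(residues, baselines)
        # terminals dropped; LYS (no baseline) dropped
        assert list(out["restype"]) == ["GLY", "ALA"]
        assert out.loc[0, "dH"] == pytest.approx(-8.0)
        assert out.loc[1, "dH"] == pytest.approx(0.0)
        assert out.loc[1, "dG"] == pytest.approx(0.0)

    def test_referencing_is_affine(self):
        residues, baselines = self._tables()
        out1 = referenced_deltas(residues, baselines)
        residues2 = residues.copy()
        residues2["H"] += 42.0
        baselines2 = baselines.copy()
        baselines2["H"] += 42.0
        out2 = referenced_deltas(residues2, baselines2)
        np.testing.assert_allclose(out1["dH"], out2["dH"])


class TestNeighborEffects:
    def test_two_residue_chain_indexing(self):
        deltas = pd.DataFrame({
            "chain": ["A", "A"], "position": [0, 1],
            "restype": ["ALA", "GLY"], "dG": [-1.0, 2.0],
        })
        mats = neighbor_effect_matrix(deltas)
        assert mats["C"].loc["ALA", "GLY"] == pytest.approx(-1.0)
        assert mats["N"].loc["GLY", "ALA"] == pytest.approx(2.0)
        assert mats["N_counts"].loc["GLY", "ALA"] == 1
        assert mats["C_counts"].loc["GLY", "ALA"] == 0
        assert np.isnan(mats["N"].loc["ALA", "GLY"])

    def test_constructed_signal_recovery(self, rng):
        # every residue following LYS is stabilised by exactly -2
        types = ["ALA", "LYS", "GLY", "LYS", "SER", "VAL"]
        dg = [0.0, 0.5, -2.0, 0.3, -2.0, 0.1]
        deltas = pd.DataFrame({"chain": ["A"] * 6,
                               "position": range(6),
                               "restype": types, "dG": dg})
        mats = neighbor_effect_matrix(deltas)
        col = mats["N"].loc[:, "LYS"].dropna()
        assert np.allclose(col.values, -2.0)


class TestHydrophobicityRank:
    def test_orders_by_water_free_energy(self):
        table = pd.DataFrame({"restype": ["ALA", "ASP"],
                              "G": [-54.0, -56.0]})
        ranked = hydrophobicity_rank(table)
        assert list(ranked["restype"]) == ["ASP", "ALA"]
        assert list(ranked["HR"]) == [1, 2]

    def test_tie_breaks_alphabetically_and_matches_argsort(self, rng):
        types = ["TRP", "ALA", "GLY", "SER"]
        g = [-55.0, -55.0, -57.0, -56.0]
        ranked = hydrophobicity_rank(pd.DataFrame({"restype": types,
                                                   "G": g}))
        assert list(ranked["restype"]) == ["GLY", "SER", "ALA", "TRP"]
        order = np.argsort(np.asarray(g), kind="stable")
        assert list(ranked["G"]) == sorted(g)
        assert order[0] == 2

    def test_excluded_rows_removed(self):
        table = pd.DataFrame({"restype": ["ALA", "CAP"],
                              "G": [-54.0, -99.0],
                              "exclude": [False, True]})
        ranked = hydrophobicity_rank(table)
        assert list(ranked["restype"]) == ["ALA"]


class TestSecondaryStructure:
    def _tables(self):
        water = pd.DataFrame({
            "monomer": [0, 1, 2, 3],
            "n_waters": [4, 6, 2, 8],
            "TS": [20.0, 21.0, 19.0, 20.5],
            "H": [-33.0, -34.0, -32.0, -33.5],
            "G": [-53.0, -55.0, -51.0, -54.0],
        })
        ss = pd.DataFrame({"monomer": [0, 1, 2, 3],
                           "ss": ["coil", "coil", "alpha_helix",
                                  "alpha_helix"]})
        return water, ss

    def test_percentages_sum_to_hundred(self):
        water, ss = self._tables()
        out = secondary_structure_grouping(water, ss)
        assert out["pct_residues"].sum() == pytest.approx(100.0, abs=0.1)
        assert out["pct_waters"].sum() == pytest.approx(100.0, abs=0.1)

    def test_class_means_are_water_weighted(self):
        water, ss = self._tables()
        out = secondary_structure_grouping(water, ss).set_index("ss")
        expected = np.average([-53.0, -55.0], weights=[4, 6])
        assert out.loc["coil", "G"] == pytest.approx(expected)

    def test_all_coil_and_empty_class_omitted(self):
        water, ss = self._tables()
        ss["ss"] = "coil"
        out = secondary_structure_grouping(water, ss)
        assert list(out["ss"]) == ["coil"]
        assert out.loc[0, "pct_waters"] == pytest.approx(100.0)

    def test_unlabeled_residues_fall_into_other(self):
        water, ss = self._tables()
        out = secondary_structure_grouping(water, ss.iloc[:2])
        assert "other" in set(out["ss"])
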