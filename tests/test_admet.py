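"""Unit tests for the QED desirability functions and the EAC screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from netpharm.admet import (
    ADS_PARAMS,
    QED_PROPERTIES,
    ads_desirability,
    qed_score,
    screen_compounds,
    veber_pass,
)

# descriptor ranges that bracket drug-like space, used for random sampling
_RANGES = {
    "MW": (50.0, 1500.0),
    "ALOGP": (-5.0, 10.0),
    "HBA": (0, 15),
    "HBD": (0, 10),
    "PSA": (0.0, 300.0),
    "ROTB": (0, 20),
    "AROM": (0, 8),
    "ALERT": (0, 12),
}


def _grid(prop, num=400):
    lo, hi = _RANGES[prop]
    return np.linspace(lo, hi, num)


class TestDesirability:
    @pytest.mark.parametrize("prop", QED_PROPERTIES)
    def test_matches_published_double_sigmoid(self, prop):
        """Each desirability equals an independent evaluation of the published
        asymmetric double-sigmoid (RDKit's QED implementation)."""
        QED = pytest.importorskip("rdkit.Chem.QED")
        rd_key = "ALERTS" if prop == "ALERT" else prop
        rd_param = QED.adsParameters[rd_key]
        for x in _grid(prop, 60):
            assert ads_desirability(prop, float(x)) == pytest.approx(
                QED.ads(float(x), rd_param), rel=1e-9
            )

    @pytest.mark.parametrize("prop", QED_PROPERTIES)
    def test_mode_scores_one_and_bounded(self, prop):
        vals = [ads_desirability(prop, float(x)) for x in _grid(prop)]
        assert all(0 < v <= 1.0 + 1e-12 for v in vals)
        # max-normalisation puts the best attainable value at ~1
        assert max(vals) > 0.95

    def test_extreme_mw_less_drug_like(self):
        assert ads_desirability("MW", 10000.0) < ads_desirability("MW", 300.0)

    @pytest.mark.parametrize("prop", QED_PROPERTIES)
    def test_monotone_away_from_mode(self, prop):
        xs = _grid(prop, 801)
        vals = np.array([ads_desirability(prop, float(x)) for x in xs])
        mode = int(np.argmax(vals))
        right = vals[mode:]
        left = vals[: mode + 1]
        assert np.all(np.diff(right) <= 1e-9)
        assert np.all(np.diff(left) >= -1e-9)

    def test_unknown_property_rejected(self):
        with pytest.raises(ValueError, match="unknown descriptor"):
            ads_desirability("LOGS", 1.0)
        with pytest.raises(ValueError, match="finite"):
            ads_desirability("MW", float("nan"))


class TestQEDScore:
    def test_geometric_mean_of_desirabilities(self):
        """Unweighted QED equals exp(mean ln d_i) recomputed by hand."""
        desc = {"MW": 300.0, "ALOGP": 2.5, "HBA": 4, "HBD": 1, "PSA": 70.0, "ROTB": 4, "AROM": 2, "ALERT": 0}
        d = [ads_desirability(p, desc[p]) for p in QED_PROPERTIES]
        expect = math.exp(sum(map(math.log, d)) / 8)
        assert qed_score(desc) == pytest.approx(expect, rel=1e-12)

    def test_frozen_geometric_mean_arithmetic(self):
        """The geometric mean of (0.9, 0.8, 1, 1, 0.7, 1, 0.6, 1) is 0.861138."""
        d = [0.9, 0.8, 1, 1, 0.7, 1, 0.6, 1]
        assert math.exp(sum(map(math.log, d)) / 8) == pytest.approx(0.861138, abs=1e-6)

    def test_weighted_matches_rdkit_on_real_molecules(self):
        """Mean-weighted QED from RDKit-computed descriptors reproduces RDKit's
        own QED score (dual-route check on real structures)."""
        pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem import QED

        smiles = {
            "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
            "apigenin": "c1cc(ccc1-c1cc(=O)c2c(O)cc(O)cc2o1)O",
            "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
        }
        for name, smi in smiles.items():
            mol = Chem.MolFromSmiles(smi)
            props = QED.properties(mol)
            desc = {p: getattr(props, "ALERTS" if p == "ALERT" else p) for p in QED_PROPERTIES}
            assert qed_score(desc, weights="mean") == pytest.approx(QED.qed(mol), rel=1e-9), name

    @settings(derandomize=True, max_examples=60)
    @given(
        mw=st.floats(50, 1500), alogp=st.floats(-5, 10), hba=st.integers(0, 15),
        hbd=st.integers(0, 10), psa=st.floats(0, 300), rotb=st.integers(0, 20),
        arom=st.integers(0, 8), alert=st.integers(0, 12),
    )
    def test_qed_in_unit_interval(self, mw, alogp, hba, hbd, psa, rotb, arom, alert):
        q = qed_score(
            {"MW": mw, "ALOGP": alogp, "HBA": hba, "HBD": hbd,
             "PSA": psa, "ROTB": rotb, "AROM": arom, "ALERT": alert}
        )
        assert 0 < q <= 1

    def test_bad_weights_rejected(self):
        desc = {p: 1 for p in QED_PROPERTIES}
        with pytest.raises(ValueError):
            qed_score(desc, weights={p: 0.0 for p in QED_PROPERTIES})


class TestVeber:
    def test_boundary_values_pass(self):
        assert veber_pass({"ROTB": 10, "HBA": 6, "HBD": 6, "PSA": 140.0})

    def test_single_violation_fails(self):
        assert not veber_pass({"ROTB": 11, "HBA": 2, "HBD": 1, "PSA": 60.0})

    def test_all_eight_pass_fail_combinations(self):
        """Brute force over the three criteria: TRUE only in the all-pass cell."""
        vals = {
            "rotb": {True: 5, False: 12},
            "sum": {True: (4, 2), False: (9, 5)},
            "psa": {True: 100.0, False: 160.0},
        }
        for r_ok, s_ok, p_ok in itertools.product([True, False], repeat=3):
            hba, hbd = vals["sum"][s_ok]
            desc = {"ROTB": vals["rotb"][r_ok], "HBA": hba, "HBD": hbd, "PSA": vals["psa"][p_ok]}
            assert veber_pass(desc) == (r_ok and s_ok and p_ok)


class TestScreen:
    def _frame(self, rows):
        return pd.DataFrame(rows)

    def test_empty_input(self):
        df = pd.DataFrame(columns=["compound_id", *QED_PROPERTIES])
        assert len(screen_compounds(df)) == 0

    def test_duplicate_ids_rejected(self):
        row = {"compound_id": "C1", "MW": 300.0, "ALOGP": 2.0, "HBA": 3, "HBD": 1,
               "PSA": 60.0, "ROTB": 3, "AROM": 2, "ALERT": 0}
        df = pd.DataFrame([row, row])
        with pytest.raises(ValueError, match="duplicate"):
            screen_compounds(df)

    def test_verdict_is_pure_and_order_preserving(self):
        good = {"MW": 300.0, "ALOGP": 2.0, "HBA": 3, "HBD": 1, "PSA": 60.0, "ROTB": 3, "AROM": 2, "ALERT": 0}
        bad_veber = dict(good, ROTB=14)
        rows = [dict(good, compound_id="A"), dict(bad_veber, compound_id="B"), dict(good, compound_id="C")]
        out = screen_compounds(pd.DataFrame(rows))
        assert out["compound_id"].tolist() == ["A", "B", "C"]
        assert out["is_eac"].tolist() == [True, False, True]
        # verdict equality for identical descriptor vectors regardless of position
        assert out.loc[0, "qed"] == out.loc[2, "qed"]
        # is_eac <=> qed >= 0.3 and veber_ok
        assert (out["is_eac"] == ((out["qed"] >= 0.3) & out["veber_ok"])).all()
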