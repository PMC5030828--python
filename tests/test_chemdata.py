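import numpy as np
import pandas as pd
import pytest

from toxclust.chemdata import (
    EndpointGlossary,
    EndpointLoelMatrix,
    FilterCriteria,
    aggregate_endpoints,
    filter_studies,
    read_compounds,
)


def _study(cid="X", species="rat", route="oral", duration=30, reliability="A",
           purity=95.0, organ="liver", effect="degeneration", loel=50.0):
    return {"compound_id": cid, "species": species, "route": route,
            "duration_days": duration, "reliability": reliability,
            "purity_pct": purity, "organ": organ, "effect": effect,
            "loel_mg_per_kg": loel}


GLOSSARY = EndpointGlossary(
    mapping={("liver", "degeneration"): "liver",
             ("liver", "hypertrophy"): "liver",
             ("kidney", "weight_change"): "kidney"},
    prevalence_cutoff=0.05)


class TestReadCompounds:
    def test_smiles_table(self, tmp_path):
        p = tmp_path / "c.smi"
        p.write_text("CCO etoh\nc1ccccc1 benzene\n")
        df = read_compounds(p)
        assert list(df["compound_id"]) == ["etoh", "benzene"]
        assert df.set_index("compound_id").loc["etoh", "mw"] == pytest.approx(46.07, abs=0.01)
        assert df.attrs["rejected"] == []

    def test_invalid_smiles_reported_not_dropped_silently(self, tmp_path):
        p = tmp_path / "c.smi"
        p.write_text("CCO a\nnot_a_smiles b\nCC c\n")
        df = read_compounds(p)
        assert len(df) == 2
        assert len(df.attrs["rejected"]) == 1
        assert "not_a_smiles" in df.attrs["rejected"][0]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.smi"
        p.write_text("")
        df = read_compounds(p)
        assert len(df) == 0

    def test_duplicate_id_fatal(self, tmp_path):
        p = tmp_path / "c.smi"
        p.write_text("CCO x\nCC x\n")
        with pytest.raises(ValueError, match="x"):
            read_compounds(p)

    def test_missing_file_fatal(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_compounds(tmp_path / "absent.smi")

    def test_sdf_roundtrip(self, tmp_path):
        from rdkit import Chem
        p = tmp_path / "c.sdf"
        w = Chem.SDWriter(str(p))
        for smi, name in [("CCO", "etoh"), ("c1ccccc1", "benzene")]:
            mol = Chem.MolFromSmiles(smi)
            mol.SetProp("compound_id", name)
            w.write(mol)
        w.close()
        df = read_compounds(p, format="sdf")
        assert sorted(df["compound_id"]) == ["benzene", "etoh"]


class TestFilterStudies:
    def test_kept_and_labeled_subacute(self):
        kept, report = filter_studies(pd.DataFrame([_study(duration=30)]))
        assert len(kept) == 1
        assert kept["duration_class"].iloc[0] == "subacute"
        assert sum(report.values()) == 0

    def test_subchronic_window(self):
        kept, _ = filter_studies(pd.DataFrame([_study(duration=90)]))
        assert kept["duration_class"].iloc[0] == "subchronic"

    @pytest.mark.parametrize("kwargs,reason", [
        ({"purity": 85.0, "duration": 90}, "purity"),
        ({"duration": 50}, "duration"),
        ({"species": "mouse"}, "species"),
        ({"reliability": "C"}, "reliability"),
        ({"route": "dermal"}, "route"),
    ])
    def test_rejection_reasons(self, kwargs, reason):
        kept, report = filter_studies(pd.DataFrame([_study(**kwargs)]))
        assert len(kept) == 0
        assert report[reason] == 1

    def test_overlapping_windows_invalid(self):
        with pytest.raises(ValueError):
            FilterCriteria(subacute_window=(28, 90), subchronic_window=(84, 99))


class TestAggregateEndpoints:
    @pytest.fixture
    def compounds(self):
        return pd.DataFrame([
            {"compound_id": "X", "smiles": "CCO", "mw": 100.0, "logp": 0.0},
            {"compound_id": "Y", "smiles": "CC", "mw": 50.0, "logp": 0.0},
        ])

    def test_lowest_loel_and_mmol_conversion(self, compounds):
        studies = pd.DataFrame([
            _study("X", organ="liver", effect="degeneration", loel=50.0),
            _study("X", organ="liver", effect="hypertrophy", loel=30.0),
        ])
        kept, _ = filter_studies(studies)
        mat = aggregate_endpoints(kept, GLOSSARY, compounds)
        # min(50, 30) mg / MW 100 = 0.30 mmol/kg
        assert mat.loel.at["X", ("liver", "subacute")] == pytest.approx(0.30)

    def test_min_rule_matches_brute_force(self, compounds):
        rng = np.random.default_rng(5)
        loels = rng.uniform(1, 400, size=12)
        studies = pd.DataFrame([
            _study("X", organ="liver",
                   effect=("degeneration", "hypertrophy")[i % 2], loel=v)
            for i, v in enumerate(loels)])
        kept, _ = filter_studies(studies)
        mat = aggregate_endpoints(kept, GLOSSARY, compounds)
        assert mat.loel.at["X", ("liver", "subacute")] == pytest.approx(
            loels.min() / 100.0)
        # unit roundtrip: stored mmol * MW recovers the raw mg minimum
        assert mat.loel.at["X", ("liver", "subacute")] * 100.0 == pytest.approx(
            loels.min())

    def test_permutation_invariance(self, compounds):
        studies = pd.DataFrame([
            _study("X", organ="liver", loel=50.0),
            _study("Y", organ="kidney", effect="weight_change", loel=10.0),
            _study("X", organ="liver", effect="hypertrophy", loel=30.0),
        ])
        kept, _ = filter_studies(studies)
        m1 = aggregate_endpoints(kept, GLOSSARY, compounds)
        m2 = aggregate_endpoints(kept.iloc[::-1].reset_index(drop=True),
                                 GLOSSARY, compounds)
        pd.testing.assert_frame_equal(m1.loel, m2.loel)

    def test_prevalence_cutoff_drops_rare_endpoint(self):
        compounds = pd.DataFrame([
            {"compound_id": f"C{i}", "smiles": "CC", "mw": 100.0, "logp": 0.0}
            for i in range(100)])
        studies = pd.DataFrame(
            [_study(f"C{i}", organ="liver", loel=10.0) for i in range(100)]
            + [_study(f"C{i}", organ="kidney", effect="weight_change", loel=5.0)
               for i in range(4)])
        kept, _ = filter_studies(studies)
        mat = aggregate_endpoints(kept, GLOSSARY, compounds)
        assert mat.endpoints == ["liver"]
        assert mat.dropped_endpoints == ["kidney"]
        # every surviving endpoint observed for >= cutoff fraction
        assert mat.loel["liver"].notna().any(axis=1).mean() >= 0.05

    def test_unknown_pair_dropped_or_fatal(self, compounds):
        studies = pd.DataFrame([_study("X", organ="brain", effect="odd", loel=5.0)])
        kept, _ = filter_studies(studies)
        mat = aggregate_endpoints(kept, GLOSSARY, compounds)
        assert mat.loel.isna().all().all()
        with pytest.raises(KeyError):
            aggregate_endpoints(kept, GLOSSARY, compounds, on_unknown_pair="error")

    def test_missingness_reasons(self, compounds):
        studies = pd.DataFrame([_study("X", organ="liver", loel=50.0)])
        kept, _ = filter_studies(studies)
        glossary = EndpointGlossary(mapping=GLOSSARY.mapping,
                                    prevalence_cutoff=0.0)
        mat = aggregate_endpoints(kept, glossary, compounds)
        # X has subacute studies but no kidney finding -> no_finding
        assert mat.reasons.at["X", ("kidney", "subacute")] == "no_finding"
        # X has no subchronic study at all -> not_investigated
        assert mat.reasons.at["X", ("liver", "subchronic")] == "not_investigated"
        # Y has no studies whatsoever -> no_information
        assert mat.reasons.at["Y", ("liver", "subacute")] == "no_information"

    def test_csv_roundtrip_with_reason_sentinels(self, tmp_path, compounds):
        studies = pd.DataFrame([_study("X", organ="liver", loel=50.0)])
        kept, _ = filter_studies(studies)
        glossary = EndpointGlossary(mapping=GLOSSARY.mapping,
                                    prevalence_cutoff=0.0)
        mat = aggregate_endpoints(kept, glossary, compounds)
        p = tmp_path / "matrix.csv"
        mat.to_csv(p)
        text = p.read_text()
        assert "NA:no_finding" in text and "NA:not_investigated" in text
        back = EndpointLoelMatrix.from_csv(p)
        pd.testing.assert_frame_equal(back.loel, mat.loel, check_names=False)


def test_glossary_yaml_roundtrip(tmp_path):
    p = tmp_path / "glossary.yaml"
    GLOSSARY.to_yaml(p)
    back = EndpointGlossary.from_yaml(p)
    assert back.mapping == dict(GLOSSARY.mapping)
    assert back.prevalence_cutoff == GLOSSARY.prevalence_cutoff
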