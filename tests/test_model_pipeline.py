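import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from symtraj import io as sio
from symtraj.cli import main as cli_main
from symtraj.model import SymptomTrajectoryModel
from symtraj.pipeline import RunConfig
from symtraj.synthetic import SimConfig


@pytest.fixture(scope="module")
def fitted_registry(planted_sim):
    cfg, registry, truth = planted_sim
    model = SymptomTrajectoryModel(registry, source="registry", min_support=5)
    return model.fit(seed=1)


class TestRegistryModel:
    def test_planted_pair_is_top_edge(self, fitted_registry):
        assert ("R10", "R17") in fitted_registry.edges

    def test_refit_is_deterministic(self, planted_sim):
        cfg, registry, _ = planted_sim
        res1 = SymptomTrajectoryModel(registry, min_support=5).fit(seed=3)
        res2 = SymptomTrajectoryModel(registry, min_support=5).fit(seed=3)
        pd.testing.assert_frame_equal(res1.pair_table, res2.pair_table)
        assert res1.manifest == res2.manifest

    def test_manifest_counts_non_increasing_along_preprocessing(self, fitted_registry):
        m = fitted_registry.manifest
        assert m["n_patients_active"] <= m["n_patients_raw"]
        assert m["n_events_typed"] <= m["n_events_raw"]
        assert m["n_cases"] <= m["n_patients_active"]
        assert m["m_direction"] <= m["m_effect"]

    def test_summary_mentions_key_quantities(self, fitted_registry):
        text = fitted_registry.summary()
        assert "cases: 120" in text
        assert "R10→R17" in text

    def test_enrichment_table_covers_codes(self, fitted_registry):
        enr = fitted_registry.enrichment
        assert set(enr.code) == set(fitted_registry.manifest["codes"])
        planted = enr.set_index("code").loc["R17"]
        assert planted["odds_ratio"] > 1

    def test_temporal_distribution_accessor(self, fitted_registry):
        out = fitted_registry.temporal_distribution("R10")
        assert out["summary"].shape[0] == 2

    def test_alpha_validation(self, planted_sim):
        _, registry, _ = planted_sim
        with pytest.raises(ValueError):
            SymptomTrajectoryModel(registry, alpha=0.0)


class TestNotesModel:
    def test_planted_pair_detected_from_text(self):
        prev = {"R52": 0.30, "R17": 0.04, "R50": 0.02, "R10": 0.02}
        cfg = SimConfig(
            n_cases=250, seed=17, planted_pairs=[("R52", "R17", 5.0, 0.9)],
            baseline_code_prevalences=prev, note_rate=0.2,
        )
        model = SymptomTrajectoryModel.from_synthetic(cfg, source="notes", min_support=5)
        res = model.fit(seed=18)
        table = res.pair_table.set_index(["d1", "d2"])
        planted = table.loc[("R52", "R17")]
        assert planted["effect"] > 1.5
        assert planted["effect_p_corrected"] < 0.05
        assert planted["n_forward"] > planted["n_backward"]
        assert res.manifest["n_mentions_active"] < res.manifest["n_mentions"]


class TestRoundTripsAndValidation:
    def test_registry_tsv_round_trip(self, planted_sim, tmp_path):
        _, registry, _ = planted_sim
        path = tmp_path / "registry.tsv"
        sio.write_registry_tsv(registry, path)
        back = sio.read_registry_tsv(path, registry.confirmed_case_ids)
        assert len(back.events) == len(registry.events)
        assert set(back.patients.patient_id) == set(registry.patients.patient_id)
        merged = back.events.merge(
            registry.events, on=["patient_id", "encounter_id", "event_code"],
            suffixes=("_a", "_b"),
        )
        assert (merged.admission_date_a == merged.admission_date_b).all()

    def test_validate_clean_files(self, planted_sim, tmp_path, dictionary):
        _, registry, _ = planted_sim
        reg = tmp_path / "registry.tsv"
        sio.write_registry_tsv(registry, reg)
        dic = tmp_path / "dictionary.tsv"
        dictionary.to_tsv(dic)
        issues = sio.validate_inputs(registry_path=reg, dictionary_path=dic)
        assert [i for i in issues if i["level"] == "error"] == []

    def test_validate_flags_bad_rows(self, tmp_path):
        reg = tmp_path / "bad.tsv"
        header = "\t".join(
            ["patient_id", "sex", "birth_date", "status_code", "death_date",
             "event_code", "admission_date", "discharge_date", "diagnosis_type",
             "encounter_id"]
        )
        rows = [
            "p1\tF\t1950-01-01\t01\t\tR17\t2020-13-01\t2020-01-02\tA\te1",
            "p2\tM\t1950-01-01\t01\t\tC255\t2020-01-01\t2020-01-02\tA\te2",
        ]
        reg.write_text(header + "\n" + "\n".join(rows) + "\n")
        issues = sio.validate_inputs(registry_path=reg)
        assert any(
            i["level"] == "error" and "2020-13-01" in i["message"] and i["line"] == 2
            for i in issues
        )
        assert any(
            i["level"] == "warning" and "C25" in i["message"] for i in issues
        )

    def test_run_config_yaml_round_trip(self, tmp_path):
        cfg = RunConfig(seed=5, out_dir=str(tmp_path / "out"))
        path = tmp_path / "run.yaml"
        cfg.to_yaml(path)
        assert RunConfig.from_yaml(path) == cfg

    def test_run_config_rejects_bad_alpha_and_unknown_keys(self, tmp_path):
        with pytest.raises(ValueError):
            RunConfig(alpha=0.0).validate()
        path = tmp_path / "run.yaml"
        path.write_text("alpha: 0.05\nbogus_key: 1\n")
        with pytest.raises(ValueError):
            RunConfig.from_yaml(path)


class TestCli:
    def test_simulate_validate_report_cycle(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "syn"
        res = runner.invoke(
            cli_main,
            ["simulate", "--n-cases", "60", "--seed", "2",
             "--plant", "R10,R17,4.0,0.9", "--out-dir", str(out)],
        )
        assert res.exit_code == 0, res.output
        for name in ("registry.tsv", "notes.jsonl", "gold.tsv", "dictionary.tsv"):
            assert (out / name).exists()

        res = runner.invoke(
            cli_main,
            ["validate", "--registry", str(out / "registry.tsv"),
             "--notes", str(out / "notes.jsonl"),
             "--dictionary", str(out / "dictionary.tsv")],
        )
        assert res.exit_code == 0, res.output

        cfg = RunConfig(
            source="registry",
            registry_path=str(out / "registry.tsv"),
            confirmed_path=str(out / "cancer_registry_ids.txt"),
            min_support=5,
            out_dir=str(tmp_path / "run"),
            seed=4,
        )
        cfg_path = tmp_path / "run.yaml"
        cfg.to_yaml(cfg_path)
        res = runner.invoke(cli_main, ["report", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        manifest = json.loads((tmp_path / "run" / "run_manifest.json").read_text())
        assert manifest["sources"]["registry"]["n_cases"] == 60
        assert (tmp_path / "run" / "registry" / "pair_stats.tsv").exists()

    def test_evaluate_command_scores_gold(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "syn"
        res = runner.invoke(
            cli_main,
            ["simulate", "--n-cases", "40", "--seed", "3", "--out-dir", str(out)],
        )
        assert res.exit_code == 0, res.output
        res = runner.invoke(
            cli_main,
            ["evaluate", "--notes", str(out / "notes.jsonl"),
             "--dictionary", str(out / "dictionary.tsv"),
             "--gold", str(out / "gold.tsv"),
             "--out", str(tmp_path / "eval.json")],
        )
        assert res.exit_code == 0, res.output
        report = json.loads((tmp_path / "eval.json").read_text())
        assert report["sensitivity"] > 0.9
        assert report["specificity"] > 0.99

    def test_harvest_variants_command(self, tmp_path, dictionary):
        runner = CliRunner()
        notes = tmp_path / "notes.jsonl"
        notes.write_text(
            json.dumps({"note_id": "n1", "patient_id": "p1", "date": "2010-01-01",
                        "text": "patient has jaundyce today"}) + "\n"
        )
        dic = tmp_path / "dictionary.tsv"
        dictionary.to_tsv(dic)
        res = runner.invoke(
            cli_main,
            ["harvest-variants", "--notes", str(notes), "--dictionary", str(dic),
             "--out", str(tmp_path / "variants.tsv")],
        )
        assert res.exit_code == 0, res.output
        variants = pd.read_csv(tmp_path / "variants.tsv", sep="\t")
        assert ("jaundyce", "jaundice") in set(
            variants.itertuples(index=False, name=None)
        )

    def test_results_export(self, fitted_registry, tmp_path):
        fitted_registry.to_tsv(tmp_path / "out")
        for name in ("pair_stats.tsv", "trajectories.tsv", "enrichment.tsv",
                     "trajectory_graph.json", "manifest.json"):
            assert (tmp_path / "out" / name).exists()
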