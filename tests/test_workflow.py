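import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner
from pydantic import ValidationError

from tearmrm.cli import main as cli_main
from tearmrm.synthetic import generate_study
from tearmrm.workflow import (
    StudyConfig,
    fit_curves,
    quantify_qc,
    quantify_tears,
    read_curves,
    run_study,
    study_statistics,
    validate_study,
)


@pytest.fixture
def config(tmp_path):
    return StudyConfig(seed=5, out_dir=str(tmp_path / "run"))


class TestPipelineIdentities:
    def test_noiseless_end_to_end_identity(self, noiseless_design):
        bundle = generate_study(noiseless_design, seed=0)
        curves = fit_curves(bundle)
        qc = quantify_qc(bundle, curves)
        assert np.allclose(qc["measured_ug"], qc["deposited_ug"], rtol=1e-9)
        direct, strip = quantify_tears(bundle, curves)
        assert np.allclose(
            direct["measured_conc_ug_per_ml"], direct["true_conc_ug_per_ml"], rtol=1e-9
        )
        assert np.allclose(
            strip["measured_conc_ug_per_ml"], strip["true_conc_ug_per_ml"], rtol=1e-9
        )

    def test_is_correction_cancels_shared_loss(self, noiseless_design):
        # Imperfect recovery with perfect IS tracking must not bias results.
        lossy = dataclasses.replace(
            noiseless_design,
            extraction=dataclasses.replace(
                noiseless_design.extraction,
                recovery={"Albumin": 0.5, "Lactoferrin": 0.7, "Lysozyme": 0.9},
            ),
        )
        bundle = generate_study(lossy, seed=0)
        curves = fit_curves(bundle)
        qc = quantify_qc(bundle, curves)
        assert np.allclose(qc["measured_ug"], qc["deposited_ug"], rtol=1e-9)

    def test_digestion_loss_cancels_in_ratio(self, noiseless_design):
        with_digestion_noise = dataclasses.replace(
            noiseless_design,
            instrument=dataclasses.replace(
                noiseless_design.instrument, digestion_cv=0.3
            ),
        )
        bundle = generate_study(with_digestion_noise, seed=1)
        curves = fit_curves(bundle)
        qc = quantify_qc(bundle, curves)
        assert np.allclose(qc["measured_ug"], qc["deposited_ug"], rtol=1e-9)

    def test_default_study_statistics_within_thresholds(self, default_design):
        stats = study_statistics(default_design, seed=0)
        assert stats["max_qc_bias_percent"] < 5.0
        assert stats["max_qc_cv_percent"] < 5.0
        assert stats["max_comparison_bias_percent"] < 8.0
        assert stats["min_comparison_p"] > 0.05


class TestValidationStage:
    def test_report_blocks_present(self, default_design):
        bundle = generate_study(default_design, seed=2)
        curves = fit_curves(bundle)
        report = validate_study(bundle, curves, np.random.default_rng(0))
        assert set(report.qc["level"]) == {"low", "medium", "high"}
        assert len(report.qc) == 9
        assert len(report.comparison) == 3
        assert all(r.loq is None or r.lod <= r.loq for r in report.lod_loq.values())
        text = report.to_text()
        assert "LOD" in text and "ANOVA" in text

    def test_matrix_effect_in_configured_band(self, default_design):
        bundle = generate_study(default_design, seed=2)
        curves = fit_curves(bundle)
        report = validate_study(bundle, curves, np.random.default_rng(0))
        me = report.matrix_effect["me_percent"]
        assert ((me > 0.5) & (me < 3.5)).all()  # factors 1.013-1.025 ± noise

    def test_recovery_summary_tracks_buffer_means(self, default_design):
        bundle = generate_study(default_design, seed=3)
        curves = fit_curves(bundle)
        report = validate_study(bundle, curves, np.random.default_rng(1))
        expected = {"Albumin": 95.0, "Lactoferrin": 92.0, "Lysozyme": 84.0}
        for protein, target in expected.items():
            rows = report.qc[report.qc["protein"] == protein]
            assert rows["rec_mean_percent"].mean() == pytest.approx(target, abs=6.0)


class TestRunStudy:
    def test_outputs_and_manifest(self, config):
        manifest = run_study(config)
        out = Path(config.out_dir)
        assert (out / "run_manifest.json").exists()
        stage_names = [s["name"] for s in manifest.stages]
        assert stage_names == ["transitions", "generate", "calibrate", "quantify",
                              "validate"]
        listed = {name for s in manifest.stages for name in s["outputs"]}
        on_disk = {p.name for p in out.rglob("*") if p.is_file()}
        assert listed <= on_disk
        # no orphan outputs beside the manifest itself
        assert on_disk - listed == {"run_manifest.json"}

    def test_run_twice_identical(self, config):
        run_study(config)
        out = Path(config.out_dir)
        snapshot = {p: p.read_bytes() for p in out.rglob("*") if p.is_file()}
        run_study(config)
        for p, content in snapshot.items():
            assert p.read_bytes() == content, p

    def test_noiseless_config_zero_bias_zero_cv(self, tmp_path):
        config = StudyConfig(
            seed=1,
            out_dir=str(tmp_path / "clean"),
            design={
                "extraction": {"recovery": {"Albumin": 1.0, "Lactoferrin": 1.0,
                                            "Lysozyme": 1.0},
                               "replicate_cv": 0.0},
                "instrument": {"area_cv": 0.0, "baseline_sd": 0.0,
                               "digestion_cv": 0.0},
                "strip": {"length_noise_sd_mm": 0.0},
            },
        )
        run_study(config)
        summary = pd.read_csv(Path(config.out_dir) / "validation_summary.csv")
        assert np.allclose(summary["bias_percent"], 0.0, atol=1e-9)
        assert np.allclose(summary["cv_percent"], 0.0, atol=1e-9)

    def test_curve_files_round_trip(self, config):
        run_study(config)
        curves = read_curves(Path(config.out_dir) / "calibration_curves.csv")
        assert set(curves) == {"Albumin", "Lactoferrin", "Lysozyme"}
        for curve in curves.values():
            assert curve.slope > 0
            assert len(curve.levels) == 7

    def test_bad_transition_table_fails_with_stage_name(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text(
            "protein,peptide,precursor_mz,precursor_charge,product_mz,"
            "fragment_annotation,collision_energy,retention_time_min,quantifier\n"
            "Albumin,LVNEVTEFAK,580.0,2,595.3,y5,25,9.85,true\n"
        )
        config = StudyConfig(
            seed=1, out_dir=str(tmp_path / "run"), transition_table=str(bad)
        )
        with pytest.raises(RuntimeError, match="transitions"):
            run_study(config)

    def test_config_schema_violations_listed(self):
        with pytest.raises(ValidationError) as exc:
            StudyConfig(
                seed="not-an-int",
                design={"n_tear_samples": 0, "extraction": {"buffer": "Buffer Z"}},
            )
        message = str(exc.value)
        assert "seed" in message
        assert "n_tear_samples" in message
        assert "Buffer Z" in message

    def test_seed_fanout_documented_rule(self, config):
        manifest = run_study(config)
        state = np.random.SeedSequence(config.seed).generate_state(2)
        assert manifest.child_seeds == (int(state[0]), int(state[1]))


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text(
            "seed: 9\n"
            "weighting: '1/x'\n"
            "design:\n"
            "  n_tear_samples: 5\n"
            "  extraction:\n"
            "    buffer: Buffer A\n"
        )
        config = StudyConfig.from_yaml(path)
        assert config.seed == 9
        assert config.weighting == "1/x"
        design = config.to_design()
        assert design.n_tear_samples == 5
        assert design.extraction.recovery["Lysozyme"] == pytest.approx(0.76)


class TestCli:
    def run_cli(self, *args):
        return CliRunner().invoke(cli_main, args, catch_exceptions=False)

    def test_transitions_verify_bundled(self):
        result = self.run_cli("transitions", "verify")
        assert result.exit_code == 0
        assert "within 0.1 m/z" in result.output

    def test_transitions_verify_failure_exit_code(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text(
            "protein,peptide,precursor_mz,precursor_charge,product_mz,"
            "fragment_annotation,collision_energy,retention_time_min,quantifier\n"
            "Albumin,LVNEVTEFAK,580.0,2,595.3,y5,25,9.85,true\n"
        )
        result = CliRunner().invoke(cli_main, ["transitions", "verify", "--table", str(bad)])
        assert result.exit_code == 1

    def test_transitions_design_from_bundled_panel(self, tmp_path):
        import importlib.resources as resources

        data = resources.files("tearmrm.data")
        out = tmp_path / "designed.csv"
        with resources.as_file(data / "panel.fasta") as fasta, resources.as_file(
            data / "panel.csv"
        ) as manifest:
            result = self.run_cli(
                "transitions", "design", "--panel", str(fasta),
                "--manifest", str(manifest), "--out", str(out),
            )
        assert result.exit_code == 0
        designed = pd.read_csv(out)
        assert len(designed) == 12  # 6 proteins x 2 transitions

    def test_generate_writes_bundle(self, tmp_path):
        out = tmp_path / "bundle"
        result = self.run_cli("generate", "--seed", "3", "--out", str(out))
        assert result.exit_code == 0
        assert (out / "calibration.csv").exists()
        assert (out / "bundle_manifest.json").exists()

    def test_calibrate_then_quantify(self, tmp_path):
        bundle_dir = tmp_path / "bundle"
        self.run_cli("generate", "--seed", "3", "--out", str(bundle_dir))
        curves_path = tmp_path / "curves.csv"
        result = self.run_cli(
            "quantify", "calibrate", "--areas", str(bundle_dir / "calibration.csv"),
            "--out", str(curves_path),
        )
        assert result.exit_code == 0
        areas_path = tmp_path / "areas.csv"
        pd.read_csv(bundle_dir / "tears_direct.csv").to_csv(areas_path, index=False)
        quant_path = tmp_path / "quant.csv"
        result = self.run_cli(
            "quantify", "run", "--areas", str(areas_path),
            "--curve", str(curves_path), "--out", str(quant_path),
        )
        assert result.exit_code == 0
        quant = pd.read_csv(quant_path)
        truth = pd.read_csv(bundle_dir / "tears_direct.csv")
        merged = quant.merge(truth, on=["sample", "protein"])
        rel = (
            merged["measured_conc_ug_per_ml"] - merged["true_conc_ug_per_ml"]
        ).abs() / merged["true_conc_ug_per_ml"]
        assert rel.max() < 0.15

    def test_study_run_and_validate_run(self, tmp_path):
        out = tmp_path / "study"
        result = self.run_cli("study", "run", "--seed", "4", "--out", str(out))
        assert result.exit_code == 0
        assert (out / "run_manifest.json").exists()
        report_dir = tmp_path / "report"
        result = self.run_cli("validate", "run", "--seed", "4", "--report-dir",
                              str(report_dir))
        assert result.exit_code == 0
        assert (report_dir / "validation_report.txt").exists()
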