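"""End-to-end study orchestration.

``run_study`` chains the stages — transition verification, synthetic
bundle generation, calibration, quantification, validation — writes
every artifact under one output directory and records a manifest
sufficient to reproduce the run.

Seeding rule: the master seed is expanded with
``numpy.random.SeedSequence(seed).generate_state(2)`` into a bundle seed
and a validation seed, so the generator and the validation-stage
simulations (matrix-effect references, dilution series) are individually
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .quantify import (
    CalibrationCurve,
    amount_from_extract,
    estimate_conversion_factor,
    fit_calibration,
    quantify,
    response_ratio,
)
from .synthetic import (
    ANALYTES,
    BUFFER_PRESETS,
    ExtractionModel,
    InstrumentModel,
    IS_LABEL,
    StripModel,
    StudyBundle,
    StudyDesign,
    generate_study,
    simulate_measurement,
)
from .transitions import (
    TransitionTable,
    bundled_reference_table,
    read_transition_table,
    verify_transition_table,
)
from .validation import (
    DilutionSeries,
    LodLoqResult,
    ValidationReport,
    bias_percent,
    compare_methods,
    cv_percent,
    estimate_lod_loq,
    matrix_effect_percent,
    recovery_percent,
)

__all__ = [
    "StudyConfig",
    "RunManifest",
    "run_study",
    "fit_curves",
    "quantify_qc",
    "quantify_tears",
    "validate_study",
    "study_statistics",
]


class StripConfig(BaseModel):
    conversion_factor_mm_per_ul: float = 1.15
    length_noise_sd_mm: float = 0.2
    section_length_mm: float = 5.0


class ExtractionConfig(BaseModel):
    buffer: str = "Buffer B"
    recovery: dict[str, float] | None = None  # None -> buffer preset
    replicate_cv: float = 0.03

    @field_validator("buffer")
    @classmethod
    def _known_buffer(cls, v: str) -> str:
        if v not in BUFFER_PRESETS:
            raise ValueError(f"unknown buffer {v!r}; choose from {sorted(BUFFER_PRESETS)}")
        return v


class InstrumentConfig(BaseModel):
    area_cv: float = 0.01
    baseline_sd: float = 0.5
    digestion_cv: float = 0.05
    response_factors: dict[str, float] | None = None
    matrix_factors: dict[str, float] | None = None


class DesignConfig(BaseModel):
    n_tear_samples: int = Field(default=20, ge=1)
    tear_volume_ul: float = Field(default=20.0, gt=0)
    tear_range_ug_per_ml: tuple[float, float] = (10.0, 50.0)
    calibration_levels: list[float] = [0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0]
    calibration_is_ug_per_ml: float = Field(default=2.0, gt=0)
    qc_replicates: int = Field(default=3, ge=1)
    calibration_replicates: int = Field(default=3, ge=1)
    is_amount_ug: float = Field(default=2.0, gt=0)
    extraction_volume_ml: float = Field(default=1.0, gt=0)
    is_tracking: float = Field(default=1.0, ge=-1.0, le=1.0)
    strip: StripConfig = StripConfig()
    extraction: ExtractionConfig = ExtractionConfig()
    instrument: InstrumentConfig = InstrumentConfig()


class ThresholdConfig(BaseModel):
    bias_limit_percent: float = 5.0
    cv_limit_percent: float = 5.0
    comparison_bias_limit_percent: float = 8.0
    alpha: float = 0.05


class StudyConfig(BaseModel):
    """Schema-validated configuration for a full study run."""

    seed: int = 0
    out_dir: str = "study_out"
    transition_table: str | None = None  # path; None -> bundled reference table
    verify_tolerance_mz: float = 0.1
    weighting: Literal["none", "1/x", "1/x2"] = "1/x2"
    design: DesignConfig = DesignConfig()
    thresholds: ThresholdConfig = ThresholdConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(raw)

    def to_design(self) -> StudyDesign:
        d = self.design
        preset = BUFFER_PRESETS[d.extraction.buffer]
        extraction = ExtractionModel(
            buffer=d.extraction.buffer,
            recovery=d.extraction.recovery or dict(preset.recovery),
            replicate_cv=d.extraction.replicate_cv,
        )
        instrument_kwargs = dict(
            area_cv=d.instrument.area_cv,
            baseline_sd=d.instrument.baseline_sd,
            digestion_cv=d.instrument.digestion_cv,
        )
        if d.instrument.response_factors:
            instrument_kwargs["response_factors"] = d.instrument.response_factors
        if d.instrument.matrix_factors is not None:
            instrument_kwargs["matrix_factors"] = d.instrument.matrix_factors
        return StudyDesign(
            n_tear_samples=d.n_tear_samples,
            tear_profile={a: tuple(d.tear_range_ug_per_ml) for a in ANALYTES},
            tear_volume_ul=d.tear_volume_ul,
            calibration_levels=tuple(d.calibration_levels),
            calibration_is_ug_per_ml=d.calibration_is_ug_per_ml,
            calibration_replicates=d.calibration_replicates,
            qc_replicates=d.qc_replicates,
            is_amount_ug=d.is_amount_ug,
            extraction_volume_ml=d.extraction_volume_ml,
            strip=StripModel(
                conversion_factor_mm_per_ul=d.strip.conversion_factor_mm_per_ul,
                length_noise_sd_mm=d.strip.length_noise_sd_mm,
                section_length_mm=d.strip.section_length_mm,
            ),
            extraction=extraction,
            instrument=InstrumentModel(**instrument_kwargs),
            is_tracking=d.is_tracking,
        )


# ---------------------------------------------------------------------------
# Stage logic (pure functions over bundles)


def fit_curves(
    bundle: StudyBundle, weighting: Literal["none", "1/x", "1/x2"] = "1/x2"
) -> dict[str, CalibrationCurve]:
    """Per-protein calibration from the bundle's calibration table.

    Replicate ratios at the same level are averaged before fitting.
    """
    curves = {}
    for protein, group in bundle.calibration.groupby("protein"):
        ratios = group.assign(
            ratio=[
                response_ratio(a, i)
                for a, i in zip(group["analyte_area"], group["is_area"])
            ]
        )
        levels = (
            ratios.groupby("level_ug_per_ml")["ratio"].mean().sort_index().reset_index()
        )
        curves[protein] = fit_calibration(
            list(zip(levels["level_ug_per_ml"], levels["ratio"])),
            weighting=weighting,
            protein=protein,
        )
    return curves


def quantify_qc(
    bundle: StudyBundle, curves: Mapping[str, CalibrationCurve]
) -> pd.DataFrame:
    """Back-calculate QC amounts (µg per strip) from measured areas."""
    design = bundle.design
    rows = []
    for row in bundle.qc.itertuples(index=False):
        ratio = response_ratio(row.analyte_area, row.is_area)
        result = quantify(ratio, curves[row.protein])
        amount = amount_from_extract(
            result.concentration_ug_per_ml,
            design.is_amount_ug,
            design.calibration_is_ug_per_ml,
        )
        rows.append(
            (row.level, row.replicate, row.protein, row.deposited_ug, amount,
             result.clamped, result.extrapolated)
        )
    return pd.DataFrame(
        rows,
        columns=["level", "replicate", "protein", "deposited_ug", "measured_ug",
                 "clamped", "extrapolated"],
    )


def quantify_tears(
    bundle: StudyBundle, curves: Mapping[str, CalibrationCurve]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify the paired tear splits.

    Direct splits read straight off the curve.  Strip splits are
    back-calculated to an absolute amount via the IS anchor and divided
    by the deposited volume (known by design here, as in a spiked study;
    in field use it would come from ``strip_volume``).
    """
    design = bundle.design
    direct_rows = []
    for row in bundle.tears_direct.itertuples(index=False):
        ratio = response_ratio(row.analyte_area, row.is_area)
        result = quantify(ratio, curves[row.protein])
        direct_rows.append(
            (row.sample, row.protein, row.true_conc_ug_per_ml,
             result.concentration_ug_per_ml, result.extrapolated)
        )
    direct = pd.DataFrame(
        direct_rows,
        columns=["sample", "protein", "true_conc_ug_per_ml", "measured_conc_ug_per_ml",
                 "extrapolated"],
    )
    strip_rows = []
    for row in bundle.tears_strip.itertuples(index=False):
        ratio = response_ratio(row.analyte_area, row.is_area)
        result = quantify(ratio, curves[row.protein])
        amount = amount_from_extract(
            result.concentration_ug_per_ml,
            design.is_amount_ug,
            design.calibration_is_ug_per_ml,
        )
        conc = amount * 1000.0 / row.deposit_volume_ul
        strip_rows.append(
            (row.sample, row.protein, row.true_conc_ug_per_ml, conc,
             result.extrapolated)
        )
    strip = pd.DataFrame(
        strip_rows,
        columns=["sample", "protein", "true_conc_ug_per_ml", "measured_conc_ug_per_ml",
                 "extrapolated"],
    )
    return direct, strip


def _matrix_effect_table(
    design: StudyDesign, rng: np.random.Generator, replicates: int = 12
) -> pd.DataFrame:
    """ME% per protein and level: spiked-buffer vs neat mean responses.

    Each replicate pair is a post-digestion split of the same standard
    digest — one aliquot in extraction-buffer matrix, one neat — so the
    shared digestion factor cancels and only the matrix shift remains.
    """
    from .synthetic import _lognormal_factor

    levels = sorted(design.qc_levels.values())
    rows = []
    for level in levels:
        conc = {a: level / design.extraction_volume_ml for a in ANALYTES}
        conc.update({IS_LABEL[a]: design.calibration_is_ug_per_ml for a in ANALYTES})
        spiked, neat = [], []
        for _ in range(replicates):
            shared = _lognormal_factor(rng, design.instrument.digestion_cv)
            spiked.append(
                simulate_measurement(conc, design.instrument, "strip", rng,
                                     digestion_factor=shared)
            )
            neat.append(
                simulate_measurement(conc, design.instrument, "direct", rng,
                                     digestion_factor=shared)
            )
        for a in ANALYTES:
            me = matrix_effect_percent(
                float(np.mean([m.areas[a] for m in spiked])),
                float(np.mean([m.areas[a] for m in neat])),
            )
            rows.append((a, level, me))
    return pd.DataFrame(rows, columns=["protein", "level_ug", "me_percent"])


def _lod_loq_per_protein(
    design: StudyDesign,
    rng: np.random.Generator,
    grid_ug_per_ml: tuple[float, ...] = (0.1, 0.03, 0.01, 0.003, 0.001),
    replicates: int = 3,
) -> dict[str, LodLoqResult]:
    """Dilution-series LOD/LOQ using the instrument's baseline SD as noise."""
    responses: dict[str, list[tuple[float, ...]]] = {a: [] for a in ANALYTES}
    for conc_level in grid_ug_per_ml:
        conc = {a: conc_level for a in ANALYTES}
        conc.update({IS_LABEL[a]: design.calibration_is_ug_per_ml for a in ANALYTES})
        reps = [
            simulate_measurement(conc, design.instrument, "direct", rng)
            for _ in range(replicates)
        ]
        for a in ANALYTES:
            responses[a].append(tuple(m.areas[a] for m in reps))
    noise = design.instrument.baseline_sd or 1e-9
    return {
        a: estimate_lod_loq(
            DilutionSeries(tuple(grid_ug_per_ml), tuple(responses[a]), noise)
        )
        for a in ANALYTES
    }


def _recovery_reference_areas(
    design: StudyDesign, rng: np.random.Generator, replicates: int = 6
) -> dict[tuple[str, str], float]:
    """Mean spiked-buffer areas matching each QC level's nominal content.

    The reference buffer is spiked at the concentration a loss-free
    extraction would give, and measured under the strip matrix (a clean
    strip is soaked in the reference to match matrix effects), so the
    area ratio isolates extraction recovery.
    """
    refs = {}
    for level, amount in design.qc_levels.items():
        conc = {a: amount / design.extraction_volume_ml for a in ANALYTES}
        conc.update({IS_LABEL[a]: design.calibration_is_ug_per_ml for a in ANALYTES})
        reps = [
            simulate_measurement(conc, design.instrument, "strip", rng)
            for _ in range(replicates)
        ]
        for a in ANALYTES:
            refs[(level, a)] = float(np.mean([m.areas[a] for m in reps]))
    return refs


def validate_study(
    bundle: StudyBundle,
    curves: Mapping[str, CalibrationCurve],
    rng: np.random.Generator | int | None = None,
) -> ValidationReport:
    """Compute the full validation report for one simulated study."""
    rng = np.random.default_rng(rng)
    design = bundle.design
    qc_quant = quantify_qc(bundle, curves)

    refs = _recovery_reference_areas(design, rng)
    qc_rows = []
    for (protein, level), group in qc_quant.groupby(["protein", "level"]):
        measured = group["measured_ug"].to_numpy()
        deposited = group["deposited_ug"].iloc[0]
        bias = bias_percent(float(measured.mean()), float(deposited))
        cv = cv_percent(measured) if measured.size >= 2 else float("nan")
        raw = bundle.qc[(bundle.qc["protein"] == protein) & (bundle.qc["level"] == level)]
        recs = [
            recovery_percent(area, refs[(level, protein)])
            for area in raw["analyte_area"]
        ]
        qc_rows.append(
            (protein, level, len(group), bias, cv, float(np.mean(recs)),
             float(np.std(recs, ddof=1)) if len(recs) > 1 else 0.0)
        )
    qc_summary = pd.DataFrame(
        qc_rows,
        columns=["protein", "level", "n", "bias_percent", "cv_percent",
                 "rec_mean_percent", "rec_sd_percent"],
    )

    me = _matrix_effect_table(design, rng)
    lod_loq = _lod_loq_per_protein(design, rng)

    direct, strip = quantify_tears(bundle, curves)
    direct_by = {
        p: g.sort_values("sample")["measured_conc_ug_per_ml"].to_numpy()
        for p, g in direct.groupby("protein")
    }
    strip_by = {
        p: g.sort_values("sample")["measured_conc_ug_per_ml"].to_numpy()
        for p, g in strip.groupby("protein")
    }
    comparison = compare_methods(direct_by, strip_by)
    return ValidationReport(
        qc=qc_summary, matrix_effect=me, lod_loq=lod_loq, comparison=comparison
    )


def study_statistics(
    design: StudyDesign,
    seed: int,
    weighting: Literal["none", "1/x", "1/x2"] = "1/x2",
) -> dict:
    """Fast path: key validation statistics of one simulated study.

    Returns max |QC Bias%|, max QC CV%, the worst direct-vs-strip
    |Bias%| and the smallest ANOVA p-value, without touching disk.
    """
    bundle = generate_study(design, seed)
    curves = fit_curves(bundle, weighting)
    qc_quant = quantify_qc(bundle, curves)
    biases, cvs = [], []
    for _, group in qc_quant.groupby(["protein", "level"]):
        measured = group["measured_ug"].to_numpy()
        biases.append(abs(bias_percent(float(measured.mean()),
                                       float(group["deposited_ug"].iloc[0]))))
        if measured.size >= 2:
            cvs.append(cv_percent(measured))
    direct, strip = quantify_tears(bundle, curves)
    direct_by = {
        p: g.sort_values("sample")["measured_conc_ug_per_ml"].to_numpy()
        for p, g in direct.groupby("protein")
    }
    strip_by = {
        p: g.sort_values("sample")["measured_conc_ug_per_ml"].to_numpy()
        for p, g in strip.groupby("protein")
    }
    comparison = compare_methods(direct_by, strip_by)
    return {
        "max_qc_bias_percent": max(biases),
        "max_qc_cv_percent": max(cvs) if cvs else 0.0,
        "max_comparison_bias_percent": max(
            c.max_abs_bias_percent for c in comparison.values()
        ),
        "min_comparison_p": min(c.p_value for c in comparison.values()),
    }


# ---------------------------------------------------------------------------
# Full run


@dataclass(frozen=True)
class RunManifest:
    seed: int
    child_seeds: tuple[int, int]
    version: str
    config: dict
    stages: tuple[dict, ...]  # name, status, outputs

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "child_seeds": list(self.child_seeds),
                "version": self.version,
                "config": self.config,
                "stages": list(self.stages),
            },
            indent=2,
            sort_keys=True,
        ) + "\n"


def _curves_frame(curves: Mapping[str, CalibrationCurve]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": list(curves),
            "weighting": [c.weighting for c in curves.values()],
            "slope": [c.slope for c in curves.values()],
            "intercept": [c.intercept for c in curves.values()],
            "levels": [
                ";".join(f"{conc:.12g}:{ratio:.12g}" for conc, ratio in c.levels)
                for c in curves.values()
            ],
            "accuracy_percent": [
                ";".join(f"{a:.6g}" for a in c.accuracy_percent)
                for c in curves.values()
            ],
        }
    )


def read_curves(path: str | Path) -> dict[str, CalibrationCurve]:
    """Read back a curves table written by ``run_study``/CLI calibrate."""
    df = pd.read_csv(path)
    curves = {}
    for row in df.itertuples(index=False):
        levels = tuple(
            (float(p.split(":")[0]), float(p.split(":")[1]))
            for p in str(row.levels).split(";")
        )
        curves[row.protein] = CalibrationCurve(
            protein=row.protein,
            levels=levels,
            weighting=row.weighting,
            slope=float(row.slope),
            intercept=float(row.intercept),
            accuracy_percent=tuple(
                float(a) for a in str(row.accuracy_percent).split(";")
            ),
        )
    return curves


def run_study(config: StudyConfig) -> RunManifest:
    """Execute every stage, writing artifacts under ``config.out_dir``.

    Any stage failure raises with the stage name; outputs and the run
    manifest are deterministic given the config and seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = np.random.SeedSequence(config.seed).generate_state(2)
    bundle_seed, validation_seed = int(state[0]), int(state[1])
    design = config.to_design()
    design.validate()
    stages: list[dict] = []

    def stage(name):
        def done(outputs, **extra):
            stages.append(
                {
                    "name": name,
                    "status": "ok",
                    "outputs": [str(Path(p).name) for p in outputs],
                    **extra,
                }
            )

        return done

    # 1. Transition verification.
    done = stage("transitions")
    if config.transition_table:
        table = read_transition_table(config.transition_table)
    else:
        table = bundled_reference_table()
    report = verify_transition_table(table, tolerance=config.verify_tolerance_mz)
    verification_path = out / "transition_verification.csv"
    report.to_frame().to_csv(verification_path, index=False, float_format="%.6f")
    if not report.passed:
        raise RuntimeError(
            f"stage 'transitions': declared m/z verification failed at tolerance "
            f"{config.verify_tolerance_mz}; see {verification_path}"
        )
    done([verification_path], n_rows=len(report.rows))

    # 2. Synthetic bundle.
    done = stage("generate")
    bundle = generate_study(design, bundle_seed)
    bundle_dir = out / "bundle"
    bundle_files = bundle.write(bundle_dir)
    done(bundle_files)

    # 3. Calibration.
    done = stage("calibrate")
    curves = fit_curves(bundle, config.weighting)
    curves_path = out / "calibration_curves.csv"
    _curves_frame(curves).to_csv(curves_path, index=False)
    done([curves_path])

    # 4. Quantification (QCs, tears, conversion factor).
    done = stage("quantify")
    qc_quant = quantify_qc(bundle, curves)
    direct, strip = quantify_tears(bundle, curves)
    factor = estimate_conversion_factor(
        bundle.wetting["volume_ul"], bundle.wetting["length_mm"]
    )
    qc_path = out / "qc_quantified.csv"
    tears_path = out / "tears_quantified.csv"
    factor_path = out / "conversion_factor.json"
    qc_quant.to_csv(qc_path, index=False, float_format="%.12g")
    tears = pd.concat(
        [direct.assign(workflow="direct"), strip.assign(workflow="strip")],
        ignore_index=True,
    )
    tears.to_csv(tears_path, index=False, float_format="%.12g")
    factor_path.write_text(
        json.dumps(
            {
                "estimate_mm_per_ul": factor.estimate_mm_per_ul,
                "sd_mm_per_ul": factor.sd_mm_per_ul,
                "volumes_ul": list(factor.volumes_ul),
                "n_observations": factor.n_observations,
            },
            indent=2,
        )
        + "\n"
    )
    done([qc_path, tears_path, factor_path])

    # 5. Validation.
    done = stage("validate")
    report = validate_study(bundle, curves, np.random.default_rng(validation_seed))
    summary_path = out / "validation_summary.csv"
    text_path = out / "validation_report.txt"
    report.qc.to_csv(summary_path, index=False, float_format="%.6g")
    text_path.write_text(report.to_text())
    th = config.thresholds
    checks = {
        "qc_bias_ok": bool((report.qc["bias_percent"].abs() < th.bias_limit_percent).all()),
        "qc_cv_ok": bool((report.qc["cv_percent"] < th.cv_limit_percent).all()),
        "comparison_bias_ok": bool(
            max(c.max_abs_bias_percent for c in report.comparison.values())
            < th.comparison_bias_limit_percent
        ),
        "comparison_p_ok": bool(
            min(c.p_value for c in report.comparison.values()) > th.alpha
        ),
    }
    done([summary_path, text_path], checks=checks)

    manifest = RunManifest(
        seed=config.seed,
        child_seeds=(bundle_seed, validation_seed),
        version=__version__,
        config=config.model_dump(mode="json"),
        stages=tuple(stages),
    )
    (out / "run_manifest.json").write_text(manifest.to_json())
    return manifest
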