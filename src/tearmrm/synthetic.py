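"""Seeded simulation of the full wet-lab workflow.

Everything the bench produced is emulated here with known ground truth:
tear samples, Schirmer-strip wetting, buffer-dependent extraction with
analyte/IS co-processing, and a linear MRM instrument response with
multiplicative noise.  Downstream calibration, quantification and
validation are therefore testable without any real data.

Noise conventions: peak areas and recoveries get mean-1 multiplicative
lognormal noise (positive quantities whose error is naturally a CV);
wetted lengths get additive Gaussian noise truncated at zero.

Units: protein amounts in µg, concentrations in µg/mL, volumes in µL for
deposits and mL for extraction buffer, lengths in mm.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "IS_LABEL",
    "TearSample",
    "StripModel",
    "ExtractionModel",
    "InstrumentModel",
    "QCSpec",
    "MeasuredSample",
    "StudyDesign",
    "StudyBundle",
    "BUFFER_PRESETS",
    "simulate_tear_samples",
    "simulate_strip_wetting",
    "simulate_extraction",
    "simulate_measurement",
    "simulate_chromatogram",
    "generate_study",
]

#: Analyte labels, matching the bundled transition table's protein column.
ANALYTES: tuple[str, ...] = ("Albumin", "Lactoferrin", "Lysozyme")

#: Analyte label -> its internal-standard label.
IS_LABEL: Mapping[str, str] = {a: f"IS {a}" for a in ANALYTES}


def _lognormal_factor(rng_or_z, cv: float, rng: np.random.Generator | None = None):
    """Mean-1 lognormal multiplier with coefficient of variation ``cv``.

    Accepts either a Generator (draws z internally) or a pre-drawn
    standard-normal z (for correlated draws).
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    if isinstance(rng_or_z, np.random.Generator):
        z = rng_or_z.standard_normal()
    else:
        z = rng_or_z
    return float(np.exp(sigma * z - 0.5 * sigma * sigma))


@dataclass(frozen=True)
class TearSample:
    """One simulated tear specimen with known per-protein truth."""

    label: str
    concentrations: Mapping[str, float]  # µg/mL per analyte
    volume_ul: float

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise ValueError("tear volume must be positive")
        if any(c < 0 for c in self.concentrations.values()):
            raise ValueError("concentrations must be >= 0")


@dataclass(frozen=True)
class StripModel:
    """Schirmer-strip wetting behaviour."""

    conversion_factor_mm_per_ul: float = 1.15
    length_noise_sd_mm: float = 0.2
    section_length_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.conversion_factor_mm_per_ul <= 0:
            raise ValueError("conversion factor must be positive")
        if self.length_noise_sd_mm < 0:
            raise ValueError("length noise SD must be >= 0")


@dataclass(frozen=True)
class ExtractionModel:
    """Buffer-dependent extraction recovery with between-replicate scatter."""

    buffer: str
    recovery: Mapping[str, float]  # analyte -> mean recovered fraction
    replicate_cv: float = 0.04

    def __post_init__(self) -> None:
        if not all(0.0 <= r <= 1.0 for r in self.recovery.values()):
            raise ValueError("mean recovery fractions must lie in [0, 1]")
        if self.replicate_cv < 0:
            raise ValueError("replicate CV must be >= 0")


#: Extraction-buffer presets.  "Buffer A" (CHAPS only) and "Buffer B"
#: (Triton + CHAPS) carry measured mean recoveries; plain ammonium
#: bicarbonate ("ABC") has no published figure and its 0.60 default is an
#: arbitrary placeholder for a clearly inferior buffer.
BUFFER_PRESETS: Mapping[str, ExtractionModel] = {
    "ABC": ExtractionModel(
        "ABC", {"Albumin": 0.60, "Lactoferrin": 0.60, "Lysozyme": 0.60}
    ),
    "Buffer A": ExtractionModel(
        "Buffer A", {"Albumin": 0.92, "Lactoferrin": 0.85, "Lysozyme": 0.76}
    ),
    "Buffer B": ExtractionModel(
        "Buffer B", {"Albumin": 0.95, "Lactoferrin": 0.92, "Lysozyme": 0.84}
    ),
}


def _default_response_factors() -> dict[str, float]:
    # Arbitrary but deterministic instrument sensitivities (area per µg/mL).
    return {
        "Albumin": 1000.0,
        "IS Albumin": 900.0,
        "Lactoferrin": 1100.0,
        "IS Lactoferrin": 950.0,
        "Lysozyme": 1050.0,
        "IS Lysozyme": 1000.0,
    }


def _default_matrix_factors() -> dict[str, float]:
    # Small response shifts in strip extracts vs neat solution, spanning
    # a ~1.3-2.5% deviation from unity; shared by an analyte and its IS.
    return {"Albumin": 1.020, "Lactoferrin": 1.013, "Lysozyme": 1.025}


@dataclass(frozen=True)
class InstrumentModel:
    """Linear MRM response with multiplicative noise and additive baseline.

    ``digestion_cv`` scales one shared per-sample efficiency factor
    applied to every channel — it models digestion/injection losses that
    an internal standard is meant to cancel.
    """

    response_factors: Mapping[str, float] = field(default_factory=_default_response_factors)
    area_cv: float = 0.01
    baseline_sd: float = 0.5
    matrix_factors: Mapping[str, float] = field(default_factory=_default_matrix_factors)
    digestion_cv: float = 0.05
    peak_sigma_min: float = 0.1
    runtime_min: float = 17.0
    trace_points: int = 600

    def __post_init__(self) -> None:
        if any(rf <= 0 for rf in self.response_factors.values()):
            raise ValueError("response factors must be positive")
        if any(mf <= 0 for mf in self.matrix_factors.values()):
            raise ValueError("matrix-effect factors must be positive")
        if self.area_cv < 0 or self.baseline_sd < 0 or self.digestion_cv < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass(frozen=True)
class QCSpec:
    """A quality-control strip: known deposit plus the IS mix."""

    level: Literal["low", "medium", "high"]
    amount_ug: float
    volume_ul: float = 20.0
    is_amount_ug: float = 2.0
    is_volume_ul: float = 10.0
    replicates: int = 3

    def __post_init__(self) -> None:
        if self.amount_ug <= 0 or self.volume_ul <= 0:
            raise ValueError("QC amount and volume must be positive")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")


#: The three standard QC levels (µg of each protein per strip).
QC_LEVELS: Mapping[str, float] = {"low": 0.2, "medium": 2.0, "high": 20.0}


@dataclass(frozen=True)
class MeasuredSample:
    """Quantifier peak areas for one injected sample.

    ``truth`` carries the underlying concentrations (µg/mL in the
    injected solution) for oracle checks; estimators must only read
    ``areas``.
    """

    label: str
    workflow: Literal["direct", "strip"]
    areas: Mapping[str, float]
    truth: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.areas.values()):
            raise ValueError("areas must be >= 0")


def simulate_tear_samples(
    n: int,
    profile: Mapping[str, tuple[float, float]] | None = None,
    volume_ul: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> list[TearSample]:
    """Draw ``n`` tear samples with uniform per-protein concentrations.

    The default 10-50 µg/mL per-protein range is an arbitrary choice, not
    a physiological claim: it keeps direct splits inside the validated
    calibration range and keeps strip extracts (diluted ~100x by the
    extraction volume) clear of the baseline-noise floor.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    profile = dict(profile) if profile else {a: (10.0, 50.0) for a in ANALYTES}
    for protein, (lo, hi) in profile.items():
        if not 0 <= lo < hi:
            raise ValueError(f"invalid concentration range {lo, hi} for {protein}")
    rng = np.random.default_rng(rng)
    samples = []
    for i in range(n):
        conc = {p: float(rng.uniform(lo, hi)) for p, (lo, hi) in profile.items()}
        samples.append(TearSample(label=f"tear_{i + 1:02d}", concentrations=conc,
                                  volume_ul=volume_ul))
    return samples


def simulate_strip_wetting(
    volume_ul: float,
    model: StripModel = StripModel(),
    rng: np.random.Generator | int | None = None,
) -> float:
    """Wetted length (mm) for a deposited volume; Gaussian noise, floored at 0."""
    if volume_ul <= 0:
        raise ValueError("volume must be positive")
    rng = np.random.default_rng(rng)
    length = model.conversion_factor_mm_per_ul * volume_ul
    if model.length_noise_sd_mm > 0:
        length += rng.normal(0.0, model.length_noise_sd_mm)
    return max(length, 0.0)


def simulate_extraction(
    deposited_ug: Mapping[str, float],
    model: ExtractionModel,
    rng: np.random.Generator | int | None = None,
    is_deposited_ug: Mapping[str, float] | None = None,
    is_tracking: float = 1.0,
) -> tuple[dict[str, float], dict[str, float]]:
    """Extract deposited protein from a strip section.

    Each analyte's recovered amount is ``deposited × mean recovery ×
    lognormal(1, cv)``.  The internal standard deposited alongside an
    analyte experiences the *same* recovery draw when ``is_tracking`` is
    1 (the homolog-IS premise); lower values decorrelate the log-noise.

    Returns ``(extracted, is_extracted)`` in µg.
    """
    if not -1.0 <= is_tracking <= 1.0:
        raise ValueError("is_tracking must be a correlation in [-1, 1]")
    for protein, amount in deposited_ug.items():
        if amount < 0:
            raise ValueError(f"negative deposit for {protein}")
        if protein not in model.recovery:
            raise ValueError(
                f"no recovery defined for {protein!r} in buffer {model.buffer!r}"
            )
    rng = np.random.default_rng(rng)
    extracted: dict[str, float] = {}
    is_extracted: dict[str, float] = {}
    for protein, amount in deposited_ug.items():
        z = rng.standard_normal()
        noise = _lognormal_factor(z, model.replicate_cv)
        recovery = model.recovery[protein] * noise
        extracted[protein] = amount * recovery
        if is_deposited_ug is not None and protein in is_deposited_ug:
            z_is = is_tracking * z + np.sqrt(1 - is_tracking**2) * rng.standard_normal()
            is_noise = _lognormal_factor(z_is, model.replicate_cv)
            is_extracted[protein] = (
                is_deposited_ug[protein] * model.recovery[protein] * is_noise
            )
    return extracted, is_extracted


def simulate_measurement(
    concentrations_ug_per_ml: Mapping[str, float],
    instrument: InstrumentModel = InstrumentModel(),
    workflow: Literal["direct", "strip"] = "direct",
    rng: np.random.Generator | int | None = None,
    label: str = "sample",
    digestion_factor: float | None = None,
) -> MeasuredSample:
    """Quantifier peak areas for one injection.

    ``concentrations_ug_per_ml`` must contain, for every analyte present,
    its internal standard's channel as well (key ``"IS <analyte>"``).
    Area model: response factor × concentration × matrix factor (strip
    workflow only, shared within an analyte/IS pair) × shared digestion
    factor × lognormal(1, area_cv), plus Gaussian baseline noise floored
    at zero.  ``digestion_factor`` fixes the shared efficiency factor
    instead of drawing it — used when two injections come from splits of
    the same digest (e.g. post-digestion matrix-effect references).
    """
    if workflow not in ("direct", "strip"):
        raise ValueError(f"unknown workflow {workflow!r}")
    for protein, conc in concentrations_ug_per_ml.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {protein}")
    for protein in concentrations_ug_per_ml:
        partner = IS_LABEL.get(protein)
        if partner is not None and partner not in concentrations_ug_per_ml:
            raise ValueError(f"missing internal standard channel for {protein!r}")
    rng = np.random.default_rng(rng)
    if digestion_factor is None:
        digestion = _lognormal_factor(rng, instrument.digestion_cv)
    else:
        if digestion_factor <= 0:
            raise ValueError("digestion_factor must be positive")
        digestion = digestion_factor
    areas: dict[str, float] = {}
    for channel, conc in concentrations_ug_per_ml.items():
        rf = instrument.response_factors.get(channel)
        if rf is None:
            raise ValueError(f"no response factor for channel {channel!r}")
        analyte = channel.removeprefix("IS ").strip()
        matrix = instrument.matrix_factors.get(analyte, 1.0) if workflow == "strip" else 1.0
        area = rf * conc * matrix * digestion * _lognormal_factor(rng, instrument.area_cv)
        if instrument.baseline_sd > 0:
            area += rng.normal(0.0, instrument.baseline_sd)
        areas[channel] = max(area, 0.0)
    return MeasuredSample(
        label=label,
        workflow=workflow,
        areas=areas,
        truth=dict(concentrations_ug_per_ml),
    )


def simulate_chromatogram(
    area: float,
    retention_time_min: float,
    instrument: InstrumentModel = InstrumentModel(),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """A Gaussian elution peak of the given area on a noisy baseline.

    Returns (times in min, intensities); ``trace_points`` samples over
    the instrument runtime.
    """
    if area < 0:
        raise ValueError("area must be >= 0")
    if not 0 < retention_time_min < instrument.runtime_min:
        raise ValueError("retention time outside the runtime")
    rng = np.random.default_rng(rng)
    t = np.linspace(0.0, instrument.runtime_min, instrument.trace_points)
    sigma = instrument.peak_sigma_min
    trace = area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -0.5 * ((t - retention_time_min) / sigma) ** 2
    )
    if instrument.baseline_sd > 0:
        trace = trace + rng.normal(0.0, instrument.baseline_sd, size=t.shape)
    return t, np.maximum(trace, 0.0)


# ---------------------------------------------------------------------------
# Whole-study generation


@dataclass(frozen=True)
class StudyDesign:
    """Everything needed to simulate one complete bench study."""

    n_tear_samples: int = 20
    tear_profile: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {a: (10.0, 50.0) for a in ANALYTES}
    )
    tear_volume_ul: float = 20.0
    calibration_levels: tuple[float, ...] = (0.1, 0.5, 1.0, 5.0, 10.0, 50.0, 100.0)
    calibration_is_ug_per_ml: float = 2.0
    calibration_replicates: int = 3
    qc_levels: Mapping[str, float] = field(default_factory=lambda: dict(QC_LEVELS))
    qc_replicates: int = 3
    qc_volume_ul: float = 20.0
    is_amount_ug: float = 2.0
    extraction_volume_ml: float = 1.0  # 2 x 0.5 mL pooled
    wetting_volumes_ul: tuple[float, ...] = (5, 10, 15, 20, 25, 30, 35, 40)
    wetting_replicates: int = 3
    strip: StripModel = StripModel()
    extraction: ExtractionModel = BUFFER_PRESETS["Buffer B"]
    instrument: InstrumentModel = InstrumentModel()
    is_tracking: float = 1.0

    def validate(self) -> None:
        errors = []
        if self.n_tear_samples < 1:
            errors.append("n_tear_samples: must be >= 1")
        if len(self.calibration_levels) < 5:
            errors.append("calibration_levels: need at least 5 levels")
        if list(self.calibration_levels) != sorted(set(self.calibration_levels)):
            errors.append("calibration_levels: must be strictly increasing")
        if self.qc_replicates < 1:
            errors.append("qc_replicates: must be >= 1")
        if self.extraction_volume_ml <= 0:
            errors.append("extraction_volume_ml: must be positive")
        if len(set(self.wetting_volumes_ul)) < 3:
            errors.append("wetting_volumes_ul: need >= 3 distinct volumes")
        if not -1.0 <= self.is_tracking <= 1.0:
            errors.append("is_tracking: must be in [-1, 1]")
        for protein in ANALYTES:
            if protein not in self.extraction.recovery:
                errors.append(f"extraction.recovery.{protein}: missing")
        if errors:
            raise ValueError("invalid study design:\n  " + "\n  ".join(errors))

    def noiseless(self) -> "StudyDesign":
        """A copy with every noise source at zero and recovery at 1."""
        return dataclasses.replace(
            self,
            strip=dataclasses.replace(self.strip, length_noise_sd_mm=0.0),
            extraction=ExtractionModel(
                self.extraction.buffer,
                {p: 1.0 for p in self.extraction.recovery},
                0.0,
            ),
            instrument=dataclasses.replace(
                self.instrument, area_cv=0.0, baseline_sd=0.0, digestion_cv=0.0
            ),
        )


@dataclass(frozen=True)
class StudyBundle:
    """The simulated study as flat tables (ground truth included)."""

    design: StudyDesign
    seed: int
    calibration: pd.DataFrame   # protein, level_ug_per_ml, replicate, analyte_area, is_area
    qc: pd.DataFrame            # level, replicate, protein, deposited_ug, extracted_ug, analyte_area, is_area
    tears_direct: pd.DataFrame  # sample, protein, true_conc_ug_per_ml, analyte_area, is_area
    tears_strip: pd.DataFrame   # + deposit_volume_ul, wetted_length_mm
    wetting: pd.DataFrame       # volume_ul, replicate, length_mm

    TABLES = ("calibration", "qc", "tears_direct", "tears_strip", "wetting")

    def write(self, out_dir: str | Path) -> list[Path]:
        """Write the bundle as delimited tables plus a JSON manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name in self.TABLES:
            path = out / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False, float_format="%.12g")
            written.append(path)
        manifest = {
            "seed": self.seed,
            "design": _design_to_dict(self.design),
            "tables": [p.name for p in written],
        }
        path = out / "bundle_manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(path)
        return written


def _design_to_dict(design: StudyDesign) -> dict:
    def convert(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, Mapping):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    return convert(design)


def _measure_pair_rows(sample: MeasuredSample) -> dict[str, tuple[float, float]]:
    return {
        a: (sample.areas[a], sample.areas[IS_LABEL[a]])
        for a in ANALYTES
        if a in sample.areas
    }


def generate_study(
    design: StudyDesign = StudyDesign(), seed: int = 0
) -> StudyBundle:
    """Simulate a complete study: calibration standards, QC strips,
    paired direct/strip tear samples, and the wetting series.

    A single master seed fans out to one child stream per stage via
    ``numpy.random.SeedSequence.spawn``, so each stage is individually
    reproducible.
    """
    design.validate()
    streams = np.random.SeedSequence(seed).spawn(4)
    rng_cal, rng_qc, rng_tears, rng_wet = (np.random.default_rng(s) for s in streams)
    instrument = design.instrument
    vol = design.extraction_volume_ml

    # Calibration standards: neat solutions measured directly.
    cal_rows = []
    for level in design.calibration_levels:
        for rep in range(1, design.calibration_replicates + 1):
            conc = {a: level for a in ANALYTES}
            conc.update({IS_LABEL[a]: design.calibration_is_ug_per_ml for a in ANALYTES})
            m = simulate_measurement(conc, instrument, "direct", rng_cal,
                                     label=f"cal_{level}_{rep}")
            for a, (area, is_area) in _measure_pair_rows(m).items():
                cal_rows.append((a, level, rep, area, is_area))
    calibration = pd.DataFrame(
        cal_rows,
        columns=["protein", "level_ug_per_ml", "replicate", "analyte_area", "is_area"],
    )

    # QC strips: deposit -> extraction -> measurement of the extract.
    qc_rows = []
    for level, amount in design.qc_levels.items():
        for rep in range(1, design.qc_replicates + 1):
            deposited = {a: amount for a in ANALYTES}
            is_deposited = {a: design.is_amount_ug for a in ANALYTES}
            extracted, is_extracted = simulate_extraction(
                deposited, design.extraction, rng_qc, is_deposited, design.is_tracking
            )
            conc = {a: extracted[a] / vol for a in ANALYTES}
            conc.update({IS_LABEL[a]: is_extracted[a] / vol for a in ANALYTES})
            m = simulate_measurement(conc, instrument, "strip", rng_qc,
                                     label=f"qc_{level}_{rep}")
            for a, (area, is_area) in _measure_pair_rows(m).items():
                qc_rows.append((level, rep, a, amount, extracted[a], area, is_area))
    qc = pd.DataFrame(
        qc_rows,
        columns=["level", "replicate", "protein", "deposited_ug", "extracted_ug",
                 "analyte_area", "is_area"],
    )

    # Paired tear samples: a direct split and a strip split of each.
    tears = simulate_tear_samples(
        design.n_tear_samples, design.tear_profile, design.tear_volume_ul, rng_tears
    )
    direct_rows, strip_rows = [], []
    for t in tears:
        conc = dict(t.concentrations)
        conc.update({IS_LABEL[a]: design.calibration_is_ug_per_ml for a in ANALYTES})
        m = simulate_measurement(conc, instrument, "direct", rng_tears, label=t.label)
        for a, (area, is_area) in _measure_pair_rows(m).items():
            direct_rows.append((t.label, a, t.concentrations[a], area, is_area))

        deposited = {a: t.concentrations[a] * t.volume_ul / 1000.0 for a in ANALYTES}
        is_deposited = {a: design.is_amount_ug for a in ANALYTES}
        extracted, is_extracted = simulate_extraction(
            deposited, design.extraction, rng_tears, is_deposited, design.is_tracking
        )
        length = simulate_strip_wetting(t.volume_ul, design.strip, rng_tears)
        conc = {a: extracted[a] / vol for a in ANALYTES}
        conc.update({IS_LABEL[a]: is_extracted[a] / vol for a in ANALYTES})
        m = simulate_measurement(conc, instrument, "strip", rng_tears, label=t.label)
        for a, (area, is_area) in _measure_pair_rows(m).items():
            strip_rows.append(
                (t.label, a, t.concentrations[a], t.volume_ul, length, area, is_area)
            )
    tears_direct = pd.DataFrame(
        direct_rows,
        columns=["sample", "protein", "true_conc_ug_per_ml", "analyte_area", "is_area"],
    )
    tears_strip = pd.DataFrame(
        strip_rows,
        columns=["sample", "protein", "true_conc_ug_per_ml", "deposit_volume_ul",
                 "wetted_length_mm", "analyte_area", "is_area"],
    )

    # Conversion-factor wetting series.
    wet_rows = []
    for v in design.wetting_volumes_ul:
        for rep in range(1, design.wetting_replicates + 1):
            wet_rows.append((v, rep, simulate_strip_wetting(v, design.strip, rng_wet)))
    wetting = pd.DataFrame(wet_rows, columns=["volume_ul", "replicate", "length_mm"])

    return StudyBundle(
        design=design,
        seed=seed,
        calibration=calibration,
        qc=qc,
        tears_direct=tears_direct,
        tears_strip=tears_strip,
        wetting=wetting,
    )


def read_bundle(bundle_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read a written bundle's tables back as data frames."""
    out = {}
    for name in StudyBundle.TABLES:
        path = Path(bundle_dir) / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"bundle table missing: {path}")
        out[name] = pd.read_csv(path)
    return out
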