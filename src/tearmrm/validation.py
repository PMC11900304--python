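"""Bioanalytical method-validation statistics.

Covers recovery, matrix effect, accuracy (Bias%), precision (CV%),
signal-to-noise LOD/LOQ estimation and the direct-vs-strip method
comparison.  Conventions that the underlying protocol leaves implicit:

* ME% is the absolute deviation of the spiked/neat response ratio from
  unity, × 100 (a raw ratio × 100 would sit near 100%, not the low
  single digits reported for negligible matrix effects);
* LOD and LOQ use the 3σ and 10σ signal-to-noise rules, with a 20% CV
  gate at the LOQ;
* the method comparison is an unpaired one-way ANOVA between the two
  method groups (for two groups, F = t²).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DilutionSeries",
    "LodLoqResult",
    "MethodComparison",
    "ValidationReport",
    "recovery_percent",
    "matrix_effect_percent",
    "bias_percent",
    "cv_percent",
    "estimate_lod_loq",
    "compare_methods",
]


def recovery_percent(extracted: float, reference: float) -> float:
    """Extraction recovery: 100 × extracted / reference amount."""
    if reference <= 0:
        raise ValueError("reference amount must be positive")
    if extracted < 0:
        raise ValueError("extracted amount must be >= 0")
    return 100.0 * extracted / reference


def matrix_effect_percent(spiked_response: float, neat_response: float) -> float:
    """Matrix effect as |spiked/neat − 1| × 100 (deviation from unity)."""
    if neat_response <= 0:
        raise ValueError("neat response must be positive")
    if spiked_response < 0:
        raise ValueError("spiked response must be >= 0")
    return 100.0 * abs(spiked_response / neat_response - 1.0)


def bias_percent(measured: float, expected: float) -> float:
    """Signed accuracy error: 100 × (measured − expected) / expected."""
    if expected <= 0:
        raise ValueError("expected value must be positive")
    return 100.0 * (measured - expected) / expected


def cv_percent(values: Sequence[float]) -> float:
    """Percent coefficient of variation, sample SD (n−1) over the mean."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicates for a CV")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * arr.std(ddof=1) / abs(mean))


@dataclass(frozen=True)
class DilutionSeries:
    """Step-wise dilution responses plus an instrument noise estimate.

    ``concentrations`` are strictly decreasing; ``responses[i]`` holds
    the replicate responses at ``concentrations[i]``.
    """

    concentrations: tuple[float, ...]
    responses: tuple[tuple[float, ...], ...]
    noise_sd: float

    def __post_init__(self) -> None:
        if len(self.concentrations) != len(self.responses):
            raise ValueError("one replicate set per concentration required")
        if any(len(r) < 1 for r in self.responses):
            raise ValueError("every level needs at least one replicate")
        diffs = np.diff(self.concentrations)
        if len(self.concentrations) > 1 and not np.all(diffs < 0):
            raise ValueError("concentrations must be strictly decreasing")
        if self.noise_sd <= 0:
            raise ValueError("noise SD estimate must be positive")


@dataclass(frozen=True)
class LodLoqResult:
    """Detection and quantification limits on the tested grid.

    ``lod``/``loq`` are None when no tested level met the criterion; the
    flags and ``lowest_tested`` make the open-ended outcome explicit.
    """

    lod: float | None
    loq: float | None
    lod_reached: bool
    loq_reached: bool
    lowest_tested: float


def estimate_lod_loq(series: DilutionSeries, loq_cv_limit: float = 20.0) -> LodLoqResult:
    """3σ/10σ signal-to-noise limits from a dilution series.

    LOD is the lowest tested concentration whose mean response is at
    least 3 × noise SD; LOQ additionally requires 10 × noise SD and a
    replicate CV of at most ``loq_cv_limit`` (the CV gate is waived for
    single-replicate levels).  LOQ ≥ LOD holds by construction.
    """
    lod = loq = None
    # Walk from the most dilute level upward.
    for conc, reps in sorted(zip(series.concentrations, series.responses)):
        mean = float(np.mean(reps))
        if lod is None and mean >= 3.0 * series.noise_sd:
            lod = conc
        if loq is None and mean >= 10.0 * series.noise_sd:
            if len(reps) < 2 or cv_percent(reps) <= loq_cv_limit:
                loq = conc
        if lod is not None and loq is not None:
            break
    if lod is not None and loq is not None and loq < lod:
        loq = lod  # cannot quantify below the detection limit
    return LodLoqResult(
        lod=lod,
        loq=loq,
        lod_reached=lod is not None,
        loq_reached=loq is not None,
        lowest_tested=min(series.concentrations),
    )


@dataclass(frozen=True)
class MethodComparison:
    """Direct-vs-strip agreement for one protein."""

    protein: str
    bias_percent: tuple[float, ...]  # per sample, strip vs direct reference
    max_abs_bias_percent: float
    f_statistic: float
    p_value: float
    n_pairs: int


def compare_methods(
    direct: Mapping[str, Sequence[float]],
    strip: Mapping[str, Sequence[float]],
) -> dict[str, MethodComparison]:
    """Compare paired direct and strip quantifications per protein.

    The direct measurement is the reference for each per-sample Bias%.
    A one-way ANOVA between the two method groups tests for a systematic
    difference (for two groups this equals a two-sample t-test, F = t²).
    """
    if set(direct) != set(strip):
        raise ValueError(
            f"protein labels differ between methods: {sorted(direct)} vs {sorted(strip)}"
        )
    out = {}
    for protein in direct:
        d = np.asarray(direct[protein], dtype=float)
        s = np.asarray(strip[protein], dtype=float)
        if d.shape != s.shape:
            raise ValueError(f"unpaired measurements for {protein}")
        if d.size < 3:
            raise ValueError(f"need >= 3 pairs for {protein}, got {d.size}")
        biases = tuple(bias_percent(si, di) for si, di in zip(s, d))
        f_stat, p = stats.f_oneway(d, s)
        out[protein] = MethodComparison(
            protein=protein,
            bias_percent=biases,
            max_abs_bias_percent=float(max(abs(b) for b in biases)),
            f_statistic=float(f_stat),
            p_value=float(p),
            n_pairs=int(d.size),
        )
    return out


@dataclass(frozen=True)
class ValidationReport:
    """All validation statistics for one study run."""

    qc: pd.DataFrame  # protein, level, n, bias_percent, cv_percent, rec_mean, rec_sd
    matrix_effect: pd.DataFrame  # protein, level_ug_per_ml, me_percent
    lod_loq: Mapping[str, LodLoqResult]
    comparison: Mapping[str, MethodComparison]

    def to_text(self) -> str:
        lines = ["Method validation report", "=" * 24, "", "QC accuracy / precision / recovery:"]
        lines.append(self.qc.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        lines += ["", "Matrix effect:"]
        lines.append(
            self.matrix_effect.to_string(index=False, float_format=lambda v: f"{v:.2f}")
        )
        lines += ["", "LOD / LOQ (ng/mL):"]
        for protein, r in self.lod_loq.items():
            lod = f"{r.lod * 1000:.3g}" if r.lod_reached else f"not reached (> {r.lowest_tested * 1000:.3g} tested)"
            loq = f"{r.loq * 1000:.3g}" if r.loq_reached else f"not reached (> {r.lowest_tested * 1000:.3g} tested)"
            lines.append(f"  {protein}: LOD {lod}, LOQ {loq}")
        lines += ["", "Direct vs strip method comparison:"]
        for protein, c in self.comparison.items():
            lines.append(
                f"  {protein}: max |Bias%| {c.max_abs_bias_percent:.2f} over "
                f"{c.n_pairs} pairs, ANOVA F = {c.f_statistic:.3g}, p = {c.p_value:.3g}"
            )
        return "\n".join(lines) + "\n"
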