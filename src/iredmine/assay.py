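"""Photometric assay arithmetic for IRED characterisation.

Specific activity is computed from the NADPH absorbance decay at 370 nm:

    A = dOD / (epsilon * l * c_P)

with A in U/mg (umol NADPH consumed per minute per mg protein), dOD the
blank-corrected slope of absorbance decrease in 1/min, epsilon the NADPH
extinction coefficient (2.216 L mmol^-1 cm^-1 at 370 nm), l the optical
path length in cm, and c_P the protein concentration in mg/mL. The blank
slope (negative control without enzyme) accounts for spontaneous NADPH
oxidation; a corrected slope <= 0 is reported as zero activity with a
flag, since the assay cannot produce negative consumption.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: NADPH extinction coefficient at 370 nm [L mmol^-1 cm^-1].
NADPH_EPSILON_370NM = 2.216


@dataclass(frozen=True)
class SlopeMeasurement:
    """One photometric rate measurement."""

    delta_od: float  # absorbance decrease per minute [1/min]
    protein_conc: float  # [mg/mL]
    blank_delta_od: float = 0.0
    epsilon: float = NADPH_EPSILON_370NM  # [L mmol^-1 cm^-1]
    path_length: float = 1.0  # [cm]
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("extinction coefficient must be positive")
        if self.path_length <= 0:
            raise ValueError("path length must be positive")
        if self.protein_conc <= 0:
            raise ValueError("protein concentration must be positive")


@dataclass
class ActivityResult:
    """Specific activity in U/mg, optionally with replicate spread."""

    activity: float  # [U/mg]
    corrected_slope: float  # [1/min]
    zero_flagged: bool = False
    sd: float | None = None
    n_replicates: int = 1

    @property
    def activity_mU(self) -> float:
        return self.activity * 1000.0


@dataclass(frozen=True)
class ProfilePoint:
    """An activity measured at one condition (pH value or temperature)."""

    condition: float
    result: ActivityResult = field(compare=False)


def specific_activity(m: SlopeMeasurement) -> ActivityResult:
    """Blank-corrected specific activity A = dOD / (epsilon * l * c_P)."""
    corrected = m.delta_od - m.blank_delta_od
    if corrected <= 0:
        return ActivityResult(activity=0.0, corrected_slope=corrected, zero_flagged=True)
    activity = corrected / (m.epsilon * m.path_length * m.protein_conc)
    return ActivityResult(activity=activity, corrected_slope=corrected)


def aggregate_replicates(measurements: list[SlopeMeasurement]) -> ActivityResult:
    """Mean +/- sample standard deviation over replicate measurements."""
    if not measurements:
        raise ValueError("no measurements to aggregate")
    results = [specific_activity(m) for m in measurements]
    acts = np.array([r.activity for r in results])
    sd = float(np.std(acts, ddof=1)) if len(acts) > 1 else None
    return ActivityResult(
        activity=float(np.mean(acts)),
        corrected_slope=float(np.mean([r.corrected_slope for r in results])),
        zero_flagged=any(r.zero_flagged for r in results),
        sd=sd,
        n_replicates=len(acts),
    )


def ph_optimum(points: list[ProfilePoint]) -> tuple[set[float], dict[float, float]]:
    """Condition(s) of maximal activity and the profile normalised to 100 %.

    Ties at the maximum are reported as a set.
    """
    if len(points) < 2:
        raise ValueError("need at least 2 profile points")
    acts = {p.condition: p.result.activity for p in points}
    peak = max(acts.values())
    if peak <= 0:
        raise ValueError("all activities are zero; no optimum")
    optima = {c for c, a in acts.items() if math.isclose(a, peak, rel_tol=1e-12)}
    profile = {c: 100.0 * a / peak for c, a in acts.items()}
    return optima, profile


def thermal_retention(
    points: list[ProfilePoint], reference_temp: float
) -> dict[float, float]:
    """Fraction of activity retained after pre-incubation at each temperature,
    relative to the reference temperature."""
    acts = {p.condition: p.result.activity for p in points}
    if reference_temp not in acts:
        raise ValueError(f"reference temperature {reference_temp} not measured")
    ref = acts[reference_temp]
    if ref <= 0:
        raise ValueError("zero activity at the reference temperature")
    return {t: a / ref for t, a in acts.items()}


def conversion_and_ee(
    product_major: float,
    product_minor: float,
    substrate: float,
    internal_standard_factor: float = 1.0,
) -> tuple[float, float | None]:
    """Conversion [%] and enantiomeric excess [%] from peak areas.

    ee = (major - minor) / (major + minor) * 100; conversion uses a
    response-factor-scaled product/(product + substrate) ratio. ee is
    ``None`` (flagged undefined) when both enantiomer areas are zero.
    """
    for name, area in (
        ("product_major", product_major),
        ("product_minor", product_minor),
        ("substrate", substrate),
    ):
        if area < 0:
            raise ValueError(f"negative peak area for {name}")
    product = (product_major + product_minor) * internal_standard_factor
    total = product + substrate
    if total <= 0:
        raise ValueError("no signal: all peak areas are zero")
    conversion = 100.0 * product / total
    enantiomer_sum = product_major + product_minor
    ee = (
        100.0 * (product_major - product_minor) / enantiomer_sum
        if enantiomer_sum > 0
        else None
    )
    return conversion, ee


def fit_slope(
    times_min: np.ndarray, absorbances: np.ndarray, window: tuple[float, float] | None = None
) -> float:
    """Ordinary least-squares slope of absorbance decrease [1/min].

    Returns the magnitude of the (negative) OLS slope over the optional
    time window. This is a convenience for raw time series; the assay
    functions themselves consume already-fitted slopes.
    """
    t = np.asarray(times_min, dtype=float)
    y = np.asarray(absorbances, dtype=float)
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        t, y = t[mask], y[mask]
    if t.size < 2:
        raise ValueError("need at least two points to fit a slope")
    slope = np.polyfit(t, y, 1)[0]
    return float(-slope)
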