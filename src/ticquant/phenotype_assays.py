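"""Closed-form quantitation for the membrane and stress phenotype assays.

Laurdan fluidity ratios (F440/F490), GC acyl-chain percentages against a
C17:1 internal standard, ergosterol content normalised to 5a-cholestanol,
catalase specific activity, and DCF-fluorescence ROS levels normalised to
protein mass.  All operations are exact arithmetic on instrument exports;
replicate aggregation and two-sample comparison live in
:func:`compare_groups`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegeneratePopulationError, ParameterError

__all__ = [
    "LaurdanSeries",
    "FattyAcidProfile",
    "SterolMeasurement",
    "laurdan_ratio",
    "acyl_percentages",
    "ergosterol_relative",
    "catalase_units",
    "ros_relative",
    "compare_groups",
]

#: GC internal standard for fatty-acid quantitation.
FA_INTERNAL_STANDARD = "C17:1"


@dataclass
class LaurdanSeries:
    """Laurdan emission ratios across a temperature ramp.

    A higher F440/F490 ratio indicates *lower* membrane fluidity (the probe
    emission red-shifts toward 490 nm in the fluid phase).
    """

    temperature: np.ndarray
    f440: np.ndarray
    f490: np.ndarray
    ratio: np.ndarray


@dataclass
class FattyAcidProfile:
    """Acyl-chain composition as percentages of total GC peak area."""

    chain_areas: dict[str, float]
    internal_standard_area: float | None
    percentages: dict[str, float]
    absolute: dict[str, float] | None = None

    def chain_ratio(self, a: str, b: str) -> float:
        """Ratio of two chains (identical from percentages or raw areas)."""
        if self.percentages[b] == 0:
            raise ParameterError(f"chain {b} has zero abundance")
        return self.percentages[a] / self.percentages[b]


@dataclass
class SterolMeasurement:
    """Ergosterol GC peak area normalised to the 5a-cholestanol standard."""

    ergosterol_area: float
    internal_standard_area: float

    @property
    def normalized(self) -> float:
        if self.internal_standard_area <= 0:
            raise ParameterError("internal standard area must be positive")
        return self.ergosterol_area / self.internal_standard_area


def laurdan_ratio(
    temperature: Sequence[float], f440: Sequence[float], f490: Sequence[float]
) -> LaurdanSeries:
    """Pointwise F440/F490 fluidity ratio over a temperature series."""
    t = np.asarray(temperature, dtype=float)
    a = np.asarray(f440, dtype=float)
    b = np.asarray(f490, dtype=float)
    if not (t.shape == a.shape == b.shape):
        raise ParameterError("temperature, f440 and f490 must have equal length")
    if (b <= 0).any():
        bad = t[b <= 0][0]
        raise ParameterError(f"F490 must be positive; ratio undefined at T={bad} degC")
    return LaurdanSeries(temperature=t, f440=a, f490=b, ratio=a / b)


def acyl_percentages(
    areas: Mapping[str, float],
    internal_standard_area: float | None = None,
    internal_standard: str = FA_INTERNAL_STANDARD,
) -> FattyAcidProfile:
    """Percent composition of each acyl chain relative to the total peak area.

    The internal standard is excluded from the total; if its area is given,
    absolute quantities (area / standard area) are computed as well.
    """
    chains = {k: float(v) for k, v in areas.items() if k != internal_standard}
    if not chains:
        raise ParameterError("need at least one acyl chain")
    if any(v < 0 for v in chains.values()):
        raise ParameterError("peak areas must be non-negative")
    total = sum(chains.values())
    if total == 0:
        raise DegeneratePopulationError("total peak area is zero")
    percentages = {k: 100.0 * v / total for k, v in chains.items()}
    absolute = None
    if internal_standard_area is not None:
        if internal_standard_area <= 0:
            raise ParameterError("internal standard area must be positive")
        absolute = {k: v / internal_standard_area for k, v in chains.items()}
    return FattyAcidProfile(
        chain_areas=chains,
        internal_standard_area=internal_standard_area,
        percentages=percentages,
        absolute=absolute,
    )


def ergosterol_relative(sample: SterolMeasurement, reference: SterolMeasurement) -> float:
    """Sample ergosterol as a percentage of the reference (reference = 100%)."""
    ref = reference.normalized
    if ref == 0:
        raise ParameterError("reference normalized sterol is zero")
    return 100.0 * sample.normalized / ref


def catalase_units(umol_h2o2_decomposed: float, minutes: float, protein_mg: float) -> float:
    """Catalase specific activity in U/mg.

    One unit decomposes 1 umol of H2O2 per minute; activity is normalised to
    the protein mass in the assay.
    """
    if minutes <= 0 or protein_mg <= 0 or umol_h2o2_decomposed < 0:
        raise ParameterError("minutes and protein mass must be positive, substrate non-negative")
    return (umol_h2o2_decomposed / minutes) / protein_mg


def ros_relative(
    fluor_sample: float, protein_sample: float, fluor_ref: float, protein_ref: float
) -> float:
    """DCF fluorescence per mg protein, as a percent of the reference strain."""
    if min(fluor_sample, protein_sample, fluor_ref, protein_ref) <= 0:
        raise ParameterError("all fluorescence and protein values must be positive")
    return 100.0 * (fluor_sample / protein_sample) / (fluor_ref / protein_ref)


def compare_groups(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> dict[str, float]:
    """Replicate summary (mean, SD) and a two-sample t-test for two groups.

    The pooled-variance Student form is the default; set ``welch=True`` for
    the unequal-variance variant.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("need at least two replicates per group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return {
        "mean_a": float(a.mean()),
        "sd_a": float(a.std(ddof=1)),
        "mean_b": float(b.mean()),
        "sd_b": float(b.std(ddof=1)),
        "t": float(t),
        "p_value": float(p),
    }
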