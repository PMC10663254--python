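"""Scalar quantification formulas and the Benjamini–Hochberg procedure.

Small, exactly specified computations used around the electrophysiology
pipeline: monosynaptic-tracing input counts normalized per starter
neuron, dendritic spine density with its segment-length inclusion rule,
Cavalieri volume estimation from serial section areas, microdialysis
percent-of-baseline normalization, and the BH step-up false-discovery-
rate procedure. Ordinary group-comparison tests are not reimplemented
here — call scipy/statsmodels directly.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import ValidationError

__all__ = [
    "TracedInputCounts",
    "DendriteMeasure",
    "SectionAreas",
    "DialysateSeries",
    "PvalueSet",
    "normalize_traced_inputs",
    "spine_density",
    "cavalieri_volume",
    "percent_of_baseline",
    "benjamini_hochberg",
]


@dataclass
class TracedInputCounts:
    """Retrograde-tracing counts: traced cells per region and starters."""

    traced: dict[str, int]  # region -> cells expressing the tracer only
    starter_count: int  # double-labelled striatal starter neurons

    def validate(self) -> None:
        for region, n in self.traced.items():
            if n < 0 or int(n) != n:
                raise ValidationError(f"traced count for {region} must be a "
                                      "non-negative integer")
        if self.starter_count <= 0:
            raise ValidationError("starter_count must be positive for "
                                  "normalization")


def normalize_traced_inputs(counts: TracedInputCounts) -> dict[str, float]:
    """Traced neurons per starter neuron, per region."""
    counts.validate()
    return {r: n / counts.starter_count for r, n in counts.traced.items()}


@dataclass
class DendriteMeasure:
    """One dendritic segment: spine count and segment length (µm)."""

    n_spines: int
    segment_length_um: float
    included: bool = True
    density: float | None = None  # spines/µm, filled by spine_density


def spine_density(
    measure: DendriteMeasure, min_length_um: float = 20.0
) -> DendriteMeasure:
    """Spines per µm, applying the >20 µm segment inclusion rule.

    Segments at or below the minimum length are flagged excluded
    (``included=False``, density left None) rather than raising — short
    segments are real data, just outside the inclusion criterion.
    """
    if measure.segment_length_um <= 0:
        raise ValidationError("segment_length_um must be positive")
    if measure.n_spines < 0:
        raise ValidationError("n_spines must be non-negative")
    if measure.segment_length_um <= min_length_um:
        measure.included = False
        measure.density = None
        return measure
    measure.included = True
    measure.density = measure.n_spines / measure.segment_length_um
    return measure


@dataclass
class SectionAreas:
    """Serial section areas (µm²) at uniform spacing (µm)."""

    areas_um2: list[float]
    section_spacing_um: float

    def validate(self) -> None:
        if len(self.areas_um2) < 1:
            raise ValidationError("need at least one section")
        if any(a < 0 for a in self.areas_um2):
            raise ValidationError("section areas must be non-negative")
        if self.section_spacing_um <= 0:
            raise ValidationError("section spacing must be positive")


def cavalieri_volume(sections: SectionAreas) -> float:
    """Cavalieri volume estimate: spacing × sum of section areas (µm³)."""
    sections.validate()
    return sections.section_spacing_um * float(np.sum(sections.areas_um2))


@dataclass
class DialysateSeries:
    """Microdialysis fractions (fmol per 20-min fraction)."""

    fractions_fmol: list[float]
    n_baseline: int = 5  # pre-drug fractions defining 100%

    def validate(self) -> None:
        if len(self.fractions_fmol) < self.n_baseline:
            raise ValidationError(
                f"need at least {self.n_baseline} fractions for the baseline"
            )


def percent_of_baseline(series: DialysateSeries) -> np.ndarray:
    """Each fraction as a percentage of the mean of the baseline fractions.

    The baseline is the mean of the first ``n_baseline`` (pre-drug)
    fractions; by construction the baseline fractions themselves average
    exactly 100%.
    """
    series.validate()
    x = np.asarray(series.fractions_fmol, dtype=float)
    base = float(np.mean(x[: series.n_baseline]))
    if base <= 0:
        raise ValidationError("baseline mean must be positive")
    return 100.0 * x / base


# ---------------------------------------------------------------------------
# Benjamini–Hochberg FDR


@dataclass
class PvalueSet:
    """Result of the BH step-up procedure at level q."""

    pvalues: np.ndarray
    q: float
    rejections: np.ndarray  # boolean, original order
    adjusted: np.ndarray  # BH-adjusted p-values, original order
    n_rejected: int = field(init=False)

    def __post_init__(self) -> None:
        self.n_rejected = int(np.sum(self.rejections))


def benjamini_hochberg(pvalues, q: float = 0.05) -> PvalueSet:
    """Benjamini–Hochberg step-up control of the false discovery rate.

    Sort the m p-values ascending, find the largest rank i with
    ``p_(i) <= i*q/m`` and reject every test of rank <= i. Adjusted
    values are ``min_{j >= i} m*p_(j)/j`` capped at 1, so that rejecting
    at level q is equivalent to ``adjusted <= q``. Ties are handled by a
    stable sort on the original index. p-values of exactly 0 are rejected
    as invalid input — they are almost always an upstream bug.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValidationError("pvalues must be a non-empty 1-D sequence")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("all p-values must lie in (0, 1]")
    if not (0 < q < 1):
        raise ValidationError("q must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresholds = (np.arange(1, m + 1) * q) / m
    passing = np.flatnonzero(ranked <= thresholds)
    k = passing[-1] + 1 if passing.size else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k] = True
    adj_sorted = np.minimum.accumulate(
        (m * ranked / np.arange(1, m + 1))[::-1]
    )[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    rejections = np.empty(m, dtype=bool)
    adjusted = np.empty(m, dtype=float)
    rejections[order] = reject_sorted
    adjusted[order] = adj_sorted
    return PvalueSet(pvalues=p, q=q, rejections=rejections, adjusted=adjusted)
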