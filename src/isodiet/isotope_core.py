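"""Deterministic stable-isotope arithmetic.

Delta (δ) notation, lipid normalization of δ13C, trophic-position
estimation from δ15N, and consumer–source enrichment.  All δ values are
carried as plain per-mil (‰) floats; isotope ratios appear only at
ingestion, through :func:`delta_value`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

__all__ = [
    "IsotopeMeasurement",
    "IsotopeRatioPair",
    "LipidNormParams",
    "TrophicPositionParams",
    "delta_value",
    "lipid_normalize",
    "needs_lipid_normalization",
    "trophic_position",
    "enrichment",
]


@dataclass(frozen=True)
class IsotopeMeasurement:
    """One sample's bulk isotope record: the pipeline's atomic unit.

    Parameters
    ----------
    sample_id
        Unique identifier of the biopsy / net haul.
    species
        Group label (e.g. ``"Manta birostris"`` or ``"zooplankton"``).
    d13C, d15N
        Bulk δ13C and δ15N in ‰ relative to VPDB / atmospheric N2.
    c_to_n
        Carbon-to-nitrogen mass ratio, a lipid-content proxy; optional.
    sex, year
        Optional stratification labels.
    """

    sample_id: str
    species: str
    d13C: float
    d15N: float
    c_to_n: Optional[float] = None
    sex: Optional[str] = None
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.d13C) and math.isfinite(self.d15N)):
            raise ValueError(
                f"sample {self.sample_id!r}: d13C and d15N must be finite"
            )
        if self.c_to_n is not None and not (self.c_to_n > 0):
            raise ValueError(
                f"sample {self.sample_id!r}: C:N must be strictly positive"
            )


@dataclass(frozen=True)
class IsotopeRatioPair:
    """Heavy-to-light isotope ratios of a sample and its reference standard."""

    r_sample: float
    r_standard: float

    def __post_init__(self) -> None:
        if not (self.r_sample > 0 and self.r_standard > 0):
            raise ValueError("isotope ratios must be strictly positive")


@dataclass(frozen=True)
class LipidNormParams:
    """Constants of the arithmetic lipid correction for δ13C.

    ``slope`` (‰) and ``cn_ref`` define the correction
    ``slope * (C:N - cn_ref) / C:N``; ``trigger_threshold`` is the mean
    C:N above which a group is considered lipid-rich enough to normalize.
    """

    slope: float = 7.95
    cn_ref: float = 3.8
    trigger_threshold: float = 3.5

    def __post_init__(self) -> None:
        if not (self.cn_ref > 0 and self.trigger_threshold > 0):
            raise ValueError("cn_ref and trigger_threshold must be positive")


@dataclass(frozen=True)
class TrophicPositionParams:
    """Baseline and discrimination constants for trophic-position estimates.

    ``d15N_primary`` is the δ15N of the baseline (a mix of primary and
    secondary consumers, hence the half-integer ``base_level`` 2.5);
    ``dtdf_n`` is the per-trophic-step δ15N discrimination in ‰.
    """

    d15N_primary: float = 7.0
    dtdf_n: float = 3.7
    base_level: float = 2.5

    def __post_init__(self) -> None:
        if not (self.dtdf_n > 0):
            raise ValueError("dtdf_n must be strictly positive")


def delta_value(pair: IsotopeRatioPair) -> float:
    """δ notation in ‰: ``(R_sample / R_standard - 1) * 1000``."""
    return (pair.r_sample / pair.r_standard - 1.0) * 1000.0


def lipid_normalize(
    d13C_bulk: float,
    c_to_n: float,
    params: LipidNormParams = LipidNormParams(),
) -> float:
    """Arithmetic lipid correction of a single bulk δ13C value.

    Returns ``d13C_bulk + slope * (c_to_n - cn_ref) / c_to_n``.  The
    correction vanishes exactly at ``c_to_n == cn_ref`` and is bounded in
    magnitude by ``slope`` for any positive C:N.  Apply per sample and
    average afterwards; applying the formula once to a group-mean C:N
    gives a different (biased) answer because the correction is nonlinear
    in C:N.
    """
    if not (c_to_n > 0):
        raise ValueError("c_to_n must be strictly positive")
    return d13C_bulk + params.slope * (c_to_n - params.cn_ref) / c_to_n


def needs_lipid_normalization(
    c_to_n_values: Sequence[float],
    params: LipidNormParams = LipidNormParams(),
) -> bool:
    """Whether a group's mean C:N warrants lipid normalization.

    True iff the mean C:N strictly exceeds ``params.trigger_threshold``
    (default 3.5).  A mean of exactly 3.5 does not trigger: the rule is
    that ratios *below* 3.5 indicate lipid-poor tissue.
    """
    values = list(c_to_n_values)
    if not values:
        raise ValueError("c_to_n_values must be non-empty")
    return (sum(values) / len(values)) > params.trigger_threshold


def trophic_position(
    d15N_consumer: float,
    params: TrophicPositionParams = TrophicPositionParams(),
) -> float:
    """Relative trophic level from δ15N above a baseline.

    ``(d15N_consumer - d15N_primary) / dtdf_n + base_level``; linear in
    the consumer value with slope ``1 / dtdf_n``.
    """
    return (d15N_consumer - params.d15N_primary) / params.dtdf_n + params.base_level


def enrichment(consumer_mean: float, source_mean: float) -> float:
    """Consumer-minus-source isotopic difference in ‰."""
    if not (math.isfinite(consumer_mean) and math.isfinite(source_mean)):
        raise ValueError("means must be finite")
    return consumer_mean - source_mean
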