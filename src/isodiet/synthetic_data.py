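"""Seeded synthetic-data generators.

Forward simulators for every input the pipeline consumes: consumers
drawn from the mixing model's own likelihood at known diet proportions
(for parameter-recovery tests), zooplankton tows at specified bulk
moments, and multi-group bivariate clouds for niche-ellipse analysis.
All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np

from .isotope_core import IsotopeMeasurement
from .mixing_model import DiscriminationFactor, SourceSpec, corrected_source
from .niche_ellipse import GroupObservations

__all__ = [
    "DEFAULT_SEED",
    "ConsumerSimSpec",
    "TowSimSpec",
    "simulate_consumers",
    "simulate_tows",
    "simulate_community",
    "consumers_from_moments",
]

DEFAULT_SEED = 20161130


@dataclass(frozen=True)
class ConsumerSimSpec:
    """Forward-model specification for consumer isotope values.

    Consumers are drawn per isotope j from
    ``Normal(sum_k p_k (mu_kj + c_kj), sum_k p_k^2 (omega_kj^2 + tau_kj^2) + eps_j^2)``
    — exactly the mixing model's likelihood, so posterior recovery of
    ``proportions`` is well-posed.
    """

    proportions: Tuple[float, ...]
    sources: Tuple[SourceSpec, ...]
    dtdf: DiscriminationFactor
    residual_sds: Tuple[float, float]
    n: int
    seed: int = DEFAULT_SEED
    correlation: float = 0.0  # δ13C–δ15N within-consumer correlation

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("proportions must lie on the simplex")
        if len(self.sources) != len(p):
            raise ValueError("one proportion per source required")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not -1.0 < self.correlation < 1.0:
            raise ValueError("correlation must be in (-1, 1)")


@dataclass(frozen=True)
class TowSimSpec:
    """Moments of a zooplankton tow population (bulk values)."""

    mean_d13C: float = -20.5
    sd_d13C: float = 0.6
    mean_d15N: float = 7.8
    sd_d15N: float = 1.0
    mean_cn: float = 4.3
    sd_cn: float = 0.5
    n: int = 35
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if min(self.sd_d13C, self.sd_d15N, self.sd_cn) < 0 or self.n < 1:
            raise ValueError("SDs must be >= 0 and n >= 1")


def simulate_consumers(
    spec: ConsumerSimSpec, species: str = "consumer"
) -> List[IsotopeMeasurement]:
    """Draw consumers from the mass-balance likelihood at known p*."""
    p = np.asarray(spec.proportions, dtype=float)
    corr = [corrected_source(s, spec.dtdf) for s in spec.sources]
    mu = np.array([m for m, _ in corr])  # (K, 2)
    var = np.array([v for _, v in corr])
    mean = p @ mu
    total_var = (p**2) @ var + np.asarray(spec.residual_sds) ** 2
    sd = np.sqrt(total_var)
    cov = np.array(
        [
            [total_var[0], spec.correlation * sd[0] * sd[1]],
            [spec.correlation * sd[0] * sd[1], total_var[1]],
        ]
    )
    rng = np.random.default_rng(spec.seed)
    draws = rng.multivariate_normal(mean, cov, size=spec.n)
    return [
        IsotopeMeasurement(
            sample_id=f"sim-{i:04d}", species=species,
            d13C=float(d13c), d15N=float(d15n),
        )
        for i, (d13c, d15n) in enumerate(draws)
    ]


def simulate_tows(
    spec: TowSimSpec, species: str = "zooplankton"
) -> List[IsotopeMeasurement]:
    """Draw zooplankton tows with independent normal fields.

    C:N is truncated below at 1 to exclude nonphysical ratios (at the
    default moments the truncation is never reached in practice).
    """
    rng = np.random.default_rng(spec.seed)
    d13c = rng.normal(spec.mean_d13C, spec.sd_d13C, spec.n)
    d15n = rng.normal(spec.mean_d15N, spec.sd_d15N, spec.n)
    cn = np.maximum(rng.normal(spec.mean_cn, spec.sd_cn, spec.n), 1.0)
    return [
        IsotopeMeasurement(
            sample_id=f"tow-{i:04d}", species=species,
            d13C=float(c), d15N=float(n), c_to_n=float(r),
        )
        for i, (c, n, r) in enumerate(zip(d13c, d15n, cn))
    ]


def simulate_community(
    groups: Sequence[Tuple[str, Sequence[float], np.ndarray, int]],
    seed: int = DEFAULT_SEED,
) -> List[GroupObservations]:
    """Bivariate-normal isotope clouds for several co-occurring groups.

    ``groups`` is a sequence of ``(label, centroid, covariance, n)``.
    Covariances must be symmetric positive definite.
    """
    rng = np.random.default_rng(seed)
    out: List[GroupObservations] = []
    for label, centroid, cov, n in groups:
        cov = np.asarray(cov, dtype=float)
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            raise ValueError(f"group {label!r}: covariance not positive definite")
        pts = rng.multivariate_normal(np.asarray(centroid, float), cov, size=n)
        out.append(GroupObservations(label=label, points=pts))
    return out


def consumers_from_moments(
    mean_d13C: float,
    sd_d13C: float,
    mean_d15N: float,
    sd_d15N: float,
    n: int,
    seed: int = DEFAULT_SEED,
    species: str = "consumer",
    match_moments: bool = False,
) -> List[IsotopeMeasurement]:
    """Independent-normal consumers at given per-isotope moments.

    Used when only group means and SDs are available: the mixing model
    takes consumers individually, so individuals are reconstituted from
    the printed moments under independence.  With ``match_moments`` the
    draw is standardized so its sample mean and SD (ddof=1) equal the
    given values exactly — appropriate when the moments are known
    summary statistics of a real sample rather than population
    parameters, since simulating them would add spurious error to the
    very quantities the downstream model fits.
    """
    rng = np.random.default_rng(seed)
    d13c = rng.normal(mean_d13C, sd_d13C, n)
    d15n = rng.normal(mean_d15N, sd_d15N, n)
    if match_moments:
        if n < 2:
            raise ValueError("match_moments requires n >= 2")
        d13c = (d13c - d13c.mean()) / d13c.std(ddof=1) * sd_d13C + mean_d13C
        d15n = (d15n - d15n.mean()) / d15n.std(ddof=1) * sd_d15N + mean_d15N
    return [
        IsotopeMeasurement(
            sample_id=f"cons-{i:04d}", species=species,
            d13C=float(c), d15N=float(x),
        )
        for i, (c, x) in enumerate(zip(d13c, d15n))
    ]
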