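"""Trophic-level estimation and Layman community trophic-structure metrics.

A consumer's trophic level is estimated from its δ¹⁵N signature relative to
a site baseline (here bulk surface-sediment δ¹⁵N, which integrates the
deposited algal food pool):

    TL = (δ¹⁵N_consumer − δ¹⁵N_sediment) / Δ + 1,

with Δ the per-trophic-level δ¹⁵N enrichment (3.8‰ for this Arctic food
web).  TL 1 is the baseline resource pool, TL 2 a primary consumer of it.

The community-wide metrics follow Layman: the mean Euclidean distance of
taxa to the δ¹³C–δ¹⁵N centroid (CD, trophic diversity/separation) and the
mean nearest-neighbour distance in the same biplot space (NND, inverse
trophic redundancy).  Both operate on unscaled per-mil coordinates.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "BaselineSignature",
    "TrophicParams",
    "BiplotPoint",
    "round_half_up",
    "trophic_level",
    "reported_trophic_level",
    "food_web_length",
    "tl_class_counts",
    "layman_cd",
    "layman_nnd",
    "baseline_for_site",
]


@dataclass(frozen=True)
class BaselineSignature:
    """Per-site sediment baseline (δ¹⁵N used as the TL reference)."""

    site: str
    d15n_sediment: float
    d13c_sediment: float = float("nan")
    sd: float = 0.0
    n: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"baseline replicate count must be >= 1, got {self.n}")


@dataclass(frozen=True)
class TrophicParams:
    """Trophic-level parameters: per-level δ¹⁵N enrichment (‰) and the
    number of decimals used for reported (rounded) values."""

    enrichment_per_level: float = 3.8
    reporting_precision: int = 1

    def __post_init__(self) -> None:
        if self.enrichment_per_level <= 0:
            raise ValueError("enrichment_per_level must be positive")


@dataclass(frozen=True)
class BiplotPoint:
    """A taxon's coordinates in δ¹³C (x) – δ¹⁵N (y) space."""

    taxon: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite biplot coordinates for {self.taxon!r}")


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (1.45 → 1.5 at one decimal).

    Python's built-in ``round`` is banker's rounding; reported values here
    follow the half-up convention of the printed tables instead.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def trophic_level(
    d15n_consumer: float,
    baseline: BaselineSignature,
    params: TrophicParams = TrophicParams(),
) -> float:
    """Full-precision trophic level of a consumer relative to a baseline.

    The baseline is treated as a point value; its SD is carried on the
    :class:`BaselineSignature` but not propagated.
    """
    return (d15n_consumer - baseline.d15n_sediment) / params.enrichment_per_level + 1.0


def reported_trophic_level(
    d15n_consumer: float,
    baseline: BaselineSignature,
    params: TrophicParams = TrophicParams(),
) -> float:
    """Trophic level rounded half-up at the reporting precision."""
    return round_half_up(
        trophic_level(d15n_consumer, baseline, params), params.reporting_precision
    )


def food_web_length(
    levels: Iterable[float],
    params: TrophicParams = TrophicParams(),
) -> float:
    """Food-web length: the maximum trophic level, at reporting precision."""
    levels = list(levels)
    if not levels:
        raise ValueError("food_web_length requires a non-empty collection")
    return round_half_up(max(levels), params.reporting_precision)


def tl_class_counts(levels: Mapping[str, float] | Iterable[float]) -> dict[int, int]:
    """Count taxa per integer trophic class.

    Each taxon is assigned to the nearest integer class with half-up ties
    (TL 1.5 → class 2).  The banding rule behind published tallies is often
    unstated, so treat cross-study comparisons of these counts with care.
    """
    values = list(levels.values()) if isinstance(levels, Mapping) else list(levels)
    if not values:
        raise ValueError("tl_class_counts requires a non-empty collection")
    counts = Counter(int(round_half_up(v, 0)) for v in values)
    return dict(sorted(counts.items()))


def _coords(points: Sequence) -> np.ndarray:
    if len(points) == 0:
        raise ValueError("at least one biplot point is required")
    if isinstance(points[0], BiplotPoint):
        return np.array([[p.x, p.y] for p in points], dtype=float)
    return np.atleast_2d(np.asarray(points, dtype=float))


def layman_cd(points: Sequence) -> float:
    """Mean Euclidean distance of points to their δ¹³C–δ¹⁵N centroid (‰)."""
    xy = _coords(points)
    centroid = xy.mean(axis=0)
    return float(np.linalg.norm(xy - centroid, axis=1).mean())


def layman_nnd(points: Sequence) -> float:
    """Mean nearest-neighbour Euclidean distance between points (‰).

    Duplicated points yield zero nearest-neighbour distances; that is a
    meaningful statement of complete trophic redundancy, not an error.
    """
    xy = _coords(points)
    if xy.shape[0] < 2:
        raise ValueError("layman_nnd requires at least two points")
    d = squareform(pdist(xy))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).mean())


def baseline_for_site(
    baselines: Iterable[BaselineSignature], site: str
) -> BaselineSignature:
    """Find the baseline for a site, raising a clear error if absent."""
    for b in baselines:
        if b.site == site:
            return b
    raise KeyError(f"no sediment baseline available for site {site!r}")
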