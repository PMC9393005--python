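"""Incidence-based species richness estimation per latitudinal band.

Each latitudinal band is treated as an independent assemblage whose
sampling units are the retained (ocean) 5-degree longitudinal cells.
Incidence is boolean presence of a species in a unit, so duplicate
records never inflate richness.  Two nonparametric estimators are
provided:

    Chao2       S_obs + Q1^2 (N-1) / (2 N Q2)
    Jackknife1  S_obs + Q1 (N-1) / N

where S_obs is observed richness, N the number of sampling units, and
Q1 / Q2 the numbers of species found in exactly one / exactly two units
("uniques" and "duplicates").  When Q2 = 0 the Chao2 estimate uses the
bias-corrected limit S_obs + Q1 (Q1-1) (N-1) / (2N), the same fallback
the vegan specpool implementation applies.  Standard errors follow the
classical Chao variance and the first-order jackknife variance; 95%
confidence intervals are normal approximations.

Range-through richness counts a species in every band between its
southernmost and northernmost occupied bands, without splitting at the
equator: a species seen in both hemispheres is credited to every band
in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geo import BandGrid, assign_units

__all__ = [
    "IncidenceSummary",
    "RichnessEstimate",
    "BandIncidence",
    "build_incidence",
    "summarize_band",
    "chao2",
    "jackknife1",
    "richness_profile",
    "range_through",
    "NOT_DEFINED",
]

#: Sentinel for quantities whose defining ratio has a zero denominator.
NOT_DEFINED = float("nan")


def _defined(x: float) -> bool:
    return not math.isnan(x)


@dataclass(frozen=True)
class IncidenceSummary:
    """Sufficient statistics of one band's incidence matrix.

    ``uniques_per_unit`` (optional) gives, for each retained unit, the
    number of unique species (Q1 species) whose single occupied unit is
    that unit; it is required for the jackknife variance and is filled in
    automatically by :func:`summarize_band`.
    """

    band_index: int
    s_obs: int
    n_units: int
    q1: int
    q2: int
    uniques_per_unit: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if min(self.s_obs, self.n_units, self.q1, self.q2) < 0:
            raise ValueError("incidence summary fields must be non-negative")
        if self.q1 + self.q2 > self.s_obs:
            raise ValueError("Q1 + Q2 cannot exceed S_obs")
        if self.uniques_per_unit is not None and sum(self.uniques_per_unit) != self.q1:
            raise ValueError("uniques_per_unit must sum to Q1")


@dataclass(frozen=True)
class RichnessEstimate:
    band_index: int
    estimator: str
    estimate: float
    se: float = NOT_DEFINED
    ci95: tuple[float, float] = (NOT_DEFINED, NOT_DEFINED)


@dataclass
class BandIncidence:
    """Per-band species-by-unit incidence, stored sparsely.

    ``occupancy[band][species]`` is the set of retained lon-unit indices
    where the species is present.  ``grid`` supplies N per band.
    """

    grid: BandGrid
    occupancy: dict[int, dict[str, set[int]]] = field(default_factory=dict)

    def add(self, band: int, species: str, unit: int) -> None:
        self.occupancy.setdefault(band, {}).setdefault(species, set()).add(unit)

    def band_matrix(self, band: int) -> pd.DataFrame:
        """Dense boolean species x retained-unit matrix for audit/export."""
        units = sorted(np.flatnonzero(self.grid.retained[band]))
        occ = self.occupancy.get(band, {})
        data = {
            sp: [u in occ[sp] for u in units] for sp in sorted(occ)
        }
        return pd.DataFrame.from_dict(data, orient="index", columns=units, dtype=bool)


def build_incidence(records: Sequence, grid: BandGrid) -> BandIncidence:
    """Assign records to sampling units and collapse to boolean incidence.

    Point records occupy one cell; bounding-box records occupy every
    retained cell they intersect.  Records must expose ``.name`` (the
    accepted species binomial) and ``.geometry``.
    """
    inc = BandIncidence(grid=grid)
    for rec in records:
        for band, unit in assign_units(rec.geometry, grid, retained_only=True):
            inc.add(band, rec.name, unit)
    return inc


def summarize_band(inc: BandIncidence, band: int) -> IncidenceSummary:
    occ = inc.occupancy.get(band, {})
    n = int(inc.grid.retained[band].sum())
    counts = {sp: len(units) for sp, units in occ.items()}
    q1 = sum(1 for c in counts.values() if c == 1)
    q2 = sum(1 for c in counts.values() if c == 2)
    per_unit: dict[int, int] = {}
    for sp, units in occ.items():
        if len(units) == 1:
            (u,) = units
            per_unit[u] = per_unit.get(u, 0) + 1
    unit_ids = sorted(np.flatnonzero(inc.grid.retained[band]))
    return IncidenceSummary(
        band_index=band,
        s_obs=len(counts),
        n_units=n,
        q1=q1,
        q2=q2,
        uniques_per_unit=tuple(per_unit.get(u, 0) for u in unit_ids),
    )


_Z95 = 1.959963984540054


def _normal_ci(est: float, se: float) -> tuple[float, float]:
    if not _defined(se):
        return (NOT_DEFINED, NOT_DEFINED)
    return (est - _Z95 * se, est + _Z95 * se)


def chao2(s: IncidenceSummary) -> RichnessEstimate:
    """Chao2 estimate with the classical variance (vegan conventions)."""
    if s.n_units == 0:
        return RichnessEstimate(s.band_index, "chao2", NOT_DEFINED)
    a = (s.n_units - 1) / s.n_units  # small-sample correction factor
    if s.q2 > 0:
        est = s.s_obs + s.q1 ** 2 * (s.n_units - 1) / (2.0 * s.n_units * s.q2)
        r = s.q1 / s.q2
        var = s.q1 * a * (0.5 + a * (1.0 + r / 4.0) * r) * r
    else:
        est = s.s_obs + s.q1 * (s.q1 - 1) * (s.n_units - 1) / (2.0 * s.n_units)
        if est > 0:
            var = a * (
                a * (s.q1 * (2.0 * s.q1 - 1.0) ** 2 / 4.0 - s.q1 ** 4 / est / 4.0)
                + s.q1 * (s.q1 - 1.0) / 2.0
            )
        else:
            var = 0.0
    se = math.sqrt(max(var, 0.0))
    return RichnessEstimate(s.band_index, "chao2", est, se, _normal_ci(est, se))


def jackknife1(s: IncidenceSummary) -> RichnessEstimate:
    """First-order incidence-based jackknife estimate.

    The variance needs the distribution of unique species over units
    (vegan's convention); without ``uniques_per_unit`` the SE is
    NOT-DEFINED rather than silently zero.
    """
    if s.n_units == 0:
        return RichnessEstimate(s.band_index, "jackknife1", NOT_DEFINED)
    n = s.n_units
    est = s.s_obs + s.q1 * (n - 1) / n
    if s.q1 == 0:
        se = 0.0
    elif s.uniques_per_unit is None:
        se = NOT_DEFINED
    else:
        var = (sum(k * k for k in s.uniques_per_unit) - s.q1 / n) * (n - 1) / n
        se = math.sqrt(max(var, 0.0))
    return RichnessEstimate(s.band_index, "jackknife1", est, se, _normal_ci(est, se))


_ESTIMATORS = {"chao2": chao2, "jackknife1": jackknife1}


def richness_profile(
    records: Sequence, grid: BandGrid, estimator: str = "chao2"
) -> pd.DataFrame:
    """Per-band richness table: observed plus the requested estimator.

    Bands are estimated independently.  Bands with no retained sampling
    units get NOT-DEFINED estimates, never zero.  ``estimator`` may be
    "observed", "chao2", "jackknife1" or "range_through".
    """
    inc = build_incidence(records, grid)
    rt = range_through(records, grid) if estimator == "range_through" else None
    rows = []
    for b in range(grid.n_bands):
        s = summarize_band(inc, b)
        if estimator == "observed":
            est = RichnessEstimate(b, "observed", float(s.s_obs), 0.0, (s.s_obs, s.s_obs))
        elif estimator == "range_through":
            est = RichnessEstimate(b, "range_through", float(rt[b]))
        else:
            est = _ESTIMATORS[estimator](s)
        rows.append(
            {
                "band_lo": grid.band_edges[b],
                "band_hi": grid.band_edges[b + 1],
                "band_mid": grid.band_mids[b],
                "S_obs": s.s_obs,
                "N": s.n_units,
                "Q1": s.q1,
                "Q2": s.q2,
                "estimator": est.estimator,
                "estimate": est.estimate,
                "se": est.se,
                "ci_lo": est.ci95[0],
                "ci_hi": est.ci95[1],
            }
        )
    return pd.DataFrame(rows)


def range_through(records: Sequence, grid: BandGrid) -> np.ndarray:
    """Species count per band under the range-through assumption.

    Every species is credited to all bands between (inclusive) its
    southernmost and northernmost occupied bands; hemispheres are not
    split.  Box records contribute their full intersected band span.
    """
    extremes: dict[str, tuple[int, int]] = {}
    for rec in records:
        bands = {b for b, _ in assign_units(rec.geometry, grid, retained_only=True)}
        if not bands:
            continue
        lo, hi = min(bands), max(bands)
        if rec.name in extremes:
            plo, phi = extremes[rec.name]
            extremes[rec.name] = (min(lo, plo), max(hi, phi))
        else:
            extremes[rec.name] = (lo, hi)
    counts = np.zeros(grid.n_bands, dtype=int)
    for lo, hi in extremes.values():
        counts[lo : hi + 1] += 1
    return counts
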