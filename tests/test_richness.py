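"""Richness estimators against hand arithmetic, a brute-force oracle, and
the reference R implementation's frozen values."""

import math

import numpy as np
import pytest

from bryolat.geo import GeoBox, make_band_grid
from bryolat.harmonize import CleanRecord
from bryolat.richness import (
    IncidenceSummary,
    build_incidence,
    chao2,
    jackknife1,
    range_through,
    richness_profile,
    summarize_band,
)


def brute_force_estimates(matrix: np.ndarray):
    """Independent implementation of both estimators from a 0/1 matrix.

    ``matrix``: species x units booleans.  Recomputes S_obs, N, Q1, Q2 by
    direct counting and applies the published formulas verbatim.
    """
    m = np.asarray(matrix, dtype=bool)
    present = m.any(axis=1)
    s_obs = int(present.sum())
    n = m.shape[1]
    occ = m.sum(axis=1)
    q1 = int((occ == 1).sum())
    q2 = int((occ == 2).sum())
    if q2 > 0:
        chao = s_obs + q1 * q1 * (n - 1) / (2 * n * q2)
    else:
        chao = s_obs + q1 * (q1 - 1) * (n - 1) / (2 * n)
    jack = s_obs + q1 * (n - 1) / n
    return chao, jack


def summary_from_matrix(matrix: np.ndarray) -> IncidenceSummary:
    m = np.asarray(matrix, dtype=bool)
    occ = m.sum(axis=1)
    uniques = np.zeros(m.shape[1], dtype=int)
    for row in m[occ == 1]:
        uniques[np.argmax(row)] += 1
    return IncidenceSummary(
        band_index=0,
        s_obs=int((occ > 0).sum()),
        n_units=m.shape[1],
        q1=int((occ == 1).sum()),
        q2=int((occ == 2).sum()),
        uniques_per_unit=tuple(uniques),
    )


class TestEstimatorFormulas:
    def test_chao2_hand_example(self):
        est = chao2(IncidenceSummary(0, 6, 4, 3, 1))
        assert est.estimate == pytest.approx(9.375)  # 6 + 9*3/(2*4*1)

    def test_jackknife_hand_example(self):
        est = jackknife1(IncidenceSummary(0, 6, 4, 3, 1))
        assert est.estimate == pytest.approx(8.25)  # 6 + 3*0.75

    def test_chao2_q2_zero_fallback(self):
        est = chao2(IncidenceSummary(0, 5, 4, 2, 0))
        assert est.estimate == pytest.approx(5.75)  # 5 + 2*1*3/8

    def test_no_uniques_collapse_to_observed(self):
        s = IncidenceSummary(0, 7, 5, 0, 2)
        assert chao2(s).estimate == 7
        assert jackknife1(s).estimate == 7

    def test_single_unit_jackknife(self):
        assert jackknife1(IncidenceSummary(0, 4, 1, 4, 0)).estimate == 4

    def test_empty_band_not_defined(self):
        assert math.isnan(chao2(IncidenceSummary(0, 0, 0, 0, 0)).estimate)
        assert math.isnan(jackknife1(IncidenceSummary(0, 0, 0, 0, 0)).estimate)

    def test_oracle_equivalence_random_matrices(self):
        """Both estimators match the brute-force coding on random matrices."""
        rng = np.random.default_rng(12)
        for _ in range(100):
            m = rng.random((rng.integers(1, 11), rng.integers(1, 7))) < 0.4
            s = summary_from_matrix(m)
            chao_b, jack_b = brute_force_estimates(m)
            assert chao2(s).estimate == pytest.approx(chao_b, abs=1e-12)
            assert jackknife1(s).estimate == pytest.approx(jack_b, abs=1e-12)

    def test_estimators_dominate_observed(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            m = rng.random((rng.integers(1, 11), rng.integers(2, 7))) < 0.35
            s = summary_from_matrix(m)
            assert chao2(s).estimate >= s.s_obs
            assert jackknife1(s).estimate >= s.s_obs
            if s.q1 == 0:
                assert chao2(s).estimate == s.s_obs == jackknife1(s).estimate


class TestReferenceImplementationValues:
    """Estimates and SEs frozen from vegan::specpool on two fixed matrices."""

    M1 = np.array(  # 8 species x 6 units, Q1=3, Q2=2
        [
            [1, 0, 0, 0, 0, 0],
            [1, 1, 0, 0, 0, 0],
            [1, 1, 1, 0, 0, 0],
            [0, 0, 0, 1, 0, 0],
            [0, 1, 0, 1, 1, 0],
            [1, 1, 1, 1, 1, 1],
            [0, 0, 0, 0, 1, 0],
            [0, 0, 1, 1, 0, 0],
        ]
    )
    M2 = np.array(  # 5 species x 4 units, Q2=0 branch
        [
            [1, 0, 0, 0],
            [0, 1, 0, 0],
            [1, 1, 1, 0],
            [1, 1, 1, 1],
            [1, 0, 1, 1],
        ]
    )

    @pytest.mark.parametrize(
        "matrix,chao_est,chao_se,jack_est,jack_se",
        [
            (M1, 9.875, 2.8844951898, 10.5, 1.44337567297),
            (M2, 5.75, 1.69998401527, 6.5, 1.06066017178),
        ],
    )
    def test_matches_specpool(self, matrix, chao_est, chao_se, jack_est, jack_se):
        s = summary_from_matrix(matrix)
        c, j = chao2(s), jackknife1(s)
        assert c.estimate == pytest.approx(chao_est, abs=1e-9)
        assert c.se == pytest.approx(chao_se, abs=1e-9)
        assert j.estimate == pytest.approx(jack_est, abs=1e-9)
        assert j.se == pytest.approx(jack_se, abs=1e-9)
        assert c.ci95[0] <= c.estimate <= c.ci95[1]


class TestIncidence:
    def test_duplicates_collapse(self, equal_angle_grid):
        recs = [
            CleanRecord("Aa bb", (12.5, 2.0), "DB"),
            CleanRecord("Aa bb", (12.6, 2.1), "DB"),
        ]
        inc = build_incidence(recs, equal_angle_grid)
        s = summarize_band(inc, 20)
        assert s.s_obs == 1 and s.q1 == 1

    def test_box_spans_bands(self, equal_angle_grid):
        recs = [CleanRecord("Aa bb", GeoBox(12.5, 21, 0, 4), "TMO")]
        inc = build_incidence(recs, equal_angle_grid)
        for band in (20, 21, 22):
            assert summarize_band(inc, band).s_obs == 1
        assert summarize_band(inc, 0).s_obs == 0

    def test_band_independence_under_permutation(self, equal_angle_grid):
        rng = np.random.default_rng(3)
        recs = [
            CleanRecord(f"Sp {chr(97 + i)}a", (float(rng.uniform(-89, 89)), float(rng.uniform(-179, 179))), "DB")
            for i in range(20)
        ]
        df = richness_profile(recs, equal_angle_grid, "chao2")
        # estimates depend only on each band's own records
        for b in range(36):
            sub = [r for r in recs if equal_angle_grid.band_index(r.geometry[0]) == b]
            df_b = richness_profile(sub, equal_angle_grid, "chao2")
            assert df_b.loc[b, "estimate"] == pytest.approx(df.loc[b, "estimate"], nan_ok=True)


class TestRangeThrough:
    def _rec(self, name, lat):
        return CleanRecord(name, (lat, 0.0), "DB")

    def test_interval_fill(self, equal_angle_grid):
        recs = [self._rec("Aa bb", -72.0), self._rec("Aa bb", -52.0)]  # bands 3, 7
        counts = range_through(recs, equal_angle_grid)
        assert list(np.flatnonzero(counts)) == [3, 4, 5, 6, 7]

    def test_single_band(self, equal_angle_grid):
        counts = range_through([self._rec("Aa bb", 0.5)], equal_angle_grid)
        assert counts.sum() == 1 and counts[18] == 1

    def test_cross_hemisphere_no_split(self, equal_angle_grid):
        recs = [self._rec("Aa bb", -37.5), self._rec("Aa bb", 12.5)]
        counts = range_through(recs, equal_angle_grid)
        lo = equal_angle_grid.band_index(-37.5)
        hi = equal_angle_grid.band_index(12.5)
        assert (counts[lo : hi + 1] == 1).all()
        assert counts[equal_angle_grid.band_index(0.0)] == 1  # tropics included

    def test_dominates_observed(self, equal_angle_grid):
        rng = np.random.default_rng(9)
        recs = [
            self._rec(f"Sp {chr(97 + i % 24)}x", float(rng.uniform(-85, 85)))
            for i in range(60)
        ]
        rt = range_through(recs, equal_angle_grid)
        df = richness_profile(recs, equal_angle_grid, "observed")
        assert (rt >= df["estimate"].to_numpy()).all()
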