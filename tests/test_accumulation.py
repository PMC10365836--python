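"""Chemotaxis metrics: kymograph, accumulation index, response summary and
Sørensen similarity."""

import numpy as np
import pandas as pd
import pytest

from mcdkit.accumulation import (
    AccumulationSeries,
    accumulation_index,
    kymograph,
    response_summary,
    sorensen_similarity,
)
from mcdkit.errors import UndefinedIndexError

W = 1000.0


def table_from(frames):
    """Build a PositionTable from {frame: [y positions]} (8-s cadence)."""
    rows = []
    for f, ys in sorted(frames.items()):
        for i, y in enumerate(ys):
            rows.append({"channel": 0, "frame": f, "time_s": 8.0 * f,
                         "x_um": 0.0, "y_um": float(y), "cell_id": i})
    return pd.DataFrame(rows)


class TestKymograph:
    def test_point_mass_occupies_single_bin(self):
        t = table_from({0: [512.0] * 20, 1: [512.0] * 20})
        km = kymograph(t, bin_width_um=25.0, W_um=W)
        row = km.density[0]
        assert row[row > 0].size == 1
        assert row.max() == pytest.approx(1.0 / 25.0)

    def test_density_integrates_to_one_each_frame(self):
        rng = np.random.default_rng(5)
        t = table_from({f: rng.uniform(0, W, 200) for f in range(5)})
        km = kymograph(t)
        widths = np.diff(km.y_edges)
        for row in km.density:
            assert (row * widths).sum() == pytest.approx(1.0)

    def test_uniform_positions_within_multinomial_band(self):
        rng = np.random.default_rng(12)
        t = table_from({0: rng.uniform(0, W, 10000)})
        km = kymograph(t, bin_width_um=25.0)
        p = 25.0 / W
        # 99 % band of Binomial(10000, 1/40), Bonferroni across 40 bins
        sd = np.sqrt(10000 * p * (1 - p))
        band = 3.2 * sd
        counts = km.density[0] * 25.0 * 10000
        assert np.all(np.abs(counts - 10000 * p) < band)

    def test_display_mask_hides_central_band_only(self):
        rng = np.random.default_rng(3)
        t = table_from({0: rng.uniform(0, W, 500)})
        km = kymograph(t, central_exclusion_um=250.0)
        disp = km.display_density()
        centers = km.y_centers
        central = (centers > 375.0) & (centers < 625.0)
        assert np.all(np.isnan(disp[0, central]))
        assert np.array_equal(disp[0, ~central], km.density[0, ~central])


class TestAccumulationIndex:
    def test_mirror_symmetric_positions_give_zero(self):
        frames = {f: [100.0, 900.0, 150.0, 850.0, 500.0] for f in range(4)}
        acc = accumulation_index(table_from(frames))
        assert np.all(acc.beta == 0.0)

    def test_hand_computed_value(self):
        # frame 0: Np=30, Nn=10; final frame: Np=20, Nn=20 → β(0) = 0.5
        frames = {0: [950.0] * 30 + [50.0] * 10,
                  1: [950.0] * 20 + [50.0] * 20}
        acc = accumulation_index(table_from(frames))
        assert acc.beta[0] == pytest.approx(0.5)
        assert acc.beta[1] == pytest.approx(0.0)

    def test_all_cells_positive_at_final_frame(self):
        frames = {0: [500.0] * 10, 1: [900.0] * 10}
        acc = accumulation_index(table_from(frames))
        assert acc.beta[-1] == 1.0

    def test_reflection_negates_beta(self):
        rng = np.random.default_rng(8)
        frames = {f: rng.uniform(0, W, 100) for f in range(5)}
        t = table_from(frames)
        mirrored = t.copy()
        mirrored["y_um"] = W - mirrored["y_um"]
        a = accumulation_index(t)
        b = accumulation_index(mirrored)
        assert np.array_equal(a.beta, -b.beta)

    def test_mid_channel_cells_do_not_affect_beta(self):
        frames = {0: [950.0] * 5 + [50.0] * 2, 1: [950.0] * 3 + [50.0] * 3}
        base = accumulation_index(table_from(frames))
        # extra mid-channel cells at a non-final frame: no change at all
        frames2 = dict(frames)
        frames2[0] = frames[0] + [500.0] * 50
        with_mid = accumulation_index(table_from(frames2))
        assert np.array_equal(base.beta, with_mid.beta)
        # at the final frame they are outside both regions: denominator
        # unchanged as well
        frames3 = dict(frames)
        frames3[1] = frames[1] + [500.0] * 50
        with_mid_final = accumulation_index(table_from(frames3))
        assert np.array_equal(base.beta, with_mid_final.beta)

    def test_empty_final_regions_rejected(self):
        frames = {0: [950.0] * 5, 1: [500.0] * 5}
        with pytest.raises(UndefinedIndexError):
            accumulation_index(table_from(frames))

    def test_central_display_exclusion_has_no_impact_on_beta(self):
        rng = np.random.default_rng(21)
        frames = {f: rng.uniform(0, W, 300) for f in range(6)}
        t = table_from(frames)
        a = accumulation_index(t)
        km_masked = kymograph(t, central_exclusion_um=250.0)
        km_unmasked = kymograph(t, central_exclusion_um=0.0)
        # the mask only affects the display densities, never β or P(y|t)
        assert np.array_equal(km_masked.density, km_unmasked.density)
        b = accumulation_index(t)
        assert np.array_equal(a.beta, b.beta)


class TestResponseSummary:
    def _series(self, times, beta):
        n = np.ones_like(beta)
        return AccumulationSeries(np.asarray(times, float),
                                  np.asarray(beta, float), n, n)

    def test_constant_beta(self):
        s = self._series(np.arange(10) * 8.0, np.full(10, -0.3))
        rs = response_summary(s)
        assert rs.beta_max == pytest.approx(-0.3)
        assert rs.max_rate_per_s == pytest.approx(0.0, abs=1e-15)

    def test_linear_ramp_rate(self):
        t = np.arange(20) * 8.0
        k = 0.004
        rs = response_summary(self._series(t, k * t))
        assert rs.max_rate_per_s == pytest.approx(k, abs=1e-12)

    def test_negative_sine_response(self):
        n = 75
        total = 600.0
        t = np.linspace(0.0, total, n)
        beta = -0.4 * np.sin(np.pi * t / total)
        rs = response_summary(self._series(t, beta))
        assert rs.beta_max == pytest.approx(-0.4, rel=0.01)
        assert rs.t_max_s == pytest.approx(total / 2.0, abs=total / n)
        analytic_extreme = -0.4 * np.pi / total  # steepest pre-peak slope
        assert rs.max_rate_per_s == pytest.approx(analytic_extreme, rel=0.01)

    def test_peak_on_first_frame_has_no_rate(self):
        s = self._series(np.arange(5) * 8.0, [0.9, 0.1, 0.05, 0.0, 0.0])
        rs = response_summary(s, window=1)
        assert rs.max_rate_per_s is None


class TestSorensen:
    def _km(self, masses_by_frame, edges=(0.0, 500.0, 1000.0)):
        edges = np.asarray(edges)
        widths = np.diff(edges)
        times = np.array(sorted(masses_by_frame))
        dens = np.array([np.asarray(masses_by_frame[t]) / widths
                         for t in times])
        counts = np.full(times.size, 100)
        from mcdkit.accumulation import Kymograph
        return Kymograph(edges, times, dens, counts)

    def test_identical_kymographs_score_one(self):
        a = self._km({0.0: [0.3, 0.7], 8.0: [0.6, 0.4]})
        b = self._km({0.0: [0.3, 0.7], 8.0: [0.6, 0.4]})
        assert sorensen_similarity(a, b) == 1.0

    def test_disjoint_supports_score_zero(self):
        a = self._km({0.0: [1.0, 0.0]})
        b = self._km({0.0: [0.0, 1.0]})
        assert sorensen_similarity(a, b) == 0.0

    def test_hand_computed_overlap(self):
        a = self._km({0.0: [1.0, 0.0]})
        b = self._km({0.0: [0.5, 0.5]})
        assert sorensen_similarity(a, b) == pytest.approx(0.5)

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(9)
        fa = {t: rng.dirichlet(np.ones(2)) for t in (0.0, 8.0, 16.0)}
        fb = {t: rng.dirichlet(np.ones(2)) for t in (0.0, 8.0, 16.0)}
        a, b = self._km(fa), self._km(fb)
        s1, s2 = sorensen_similarity(a, b), sorensen_similarity(b, a)
        assert s1 == pytest.approx(s2, rel=1e-12)
        assert 0.0 <= s1 <= 1.0
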