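"""Simulator contracts: determinism, geometry, counts, rendering physics."""

import numpy as np
import pytest
from dataclasses import replace
from shapely.geometry import LineString, Point

from dsbquant import (
    SimConfig,
    generate_axes,
    generate_cell,
    generate_cohort,
    plant_foci,
    polyline_length,
    render,
)


def synapsed_length_fraction(traces, pixel_size=0.1):
    lens = [polyline_length(t, pixel_size) for t in traces]
    syn = sum(l for t, l in zip(traces, lens) if t.synapsed)
    return syn / sum(lens)


class TestGenerateAxes:
    def test_seeded_determinism(self, small_config):
        t1, m1 = generate_axes(small_config)
        t2, m2 = generate_axes(small_config)
        assert np.array_equal(m1, m2)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.vertices, b.vertices)
            assert a.synapsed == b.synapsed

    def test_all_vertices_inside_mask(self, small_config):
        traces, mask = generate_axes(small_config)
        for t in traces:
            for r, c in t.vertices:
                assert mask[int(r), int(c)]

    def test_synapsed_fraction_zero(self, small_config):
        traces, _ = generate_axes(replace(small_config, synapsed_fraction=0.0))
        assert not any(t.synapsed for t in traces)

    def test_synapsed_fraction_hit(self):
        cfg = SimConfig(n_axes=20, synapsed_fraction=0.75, seed=5)
        traces, _ = generate_axes(cfg)
        assert 0.70 <= synapsed_length_fraction(traces) <= 0.80

    def test_lengths_within_range(self, small_config):
        traces, _ = generate_axes(small_config)
        # split axes may be shorter; group by original length via totals
        total = sum(polyline_length(t, small_config.pixel_size) for t in traces)
        lo, hi = small_config.axis_length_range
        assert small_config.n_axes * lo * 0.99 <= total <= small_config.n_axes * hi * 1.01

    def test_impossible_geometry_raises(self):
        cfg = SimConfig(image_shape=(64, 64), axis_length_range=(500.0, 600.0))
        with pytest.raises(ValueError):
            generate_axes(cfg)


class TestPlantFoci:
    def test_zero_counts_empty(self, small_config):
        cfg = replace(small_config, n_cofoci=0, n_single_ch1=0,
                      n_single_ch2=0, n_large_foci=0)
        traces, mask = generate_axes(cfg)
        truth = plant_foci(traces, cfg, mask=mask)
        assert len(truth) == 0

    def test_exact_counts(self, small_config):
        traces, mask = generate_axes(small_config)
        truth = plant_foci(traces, small_config, mask=mask)
        cfg = small_config
        assert (truth.is_cofocus & (truth.channel == "MEI4")).sum() == cfg.n_cofoci
        assert int(truth.is_large.sum()) == cfg.n_large_foci
        singles1 = ((~truth.is_cofocus) & (~truth.is_large)
                    & (truth.channel == "MEI4")).sum()
        assert singles1 == cfg.n_single_ch1
        # conservation: rows = 2 per co-focus + singles + large
        assert len(truth) == 2 * cfg.n_cofoci + cfg.n_single_ch1 \
            + cfg.n_single_ch2 + cfg.n_large_foci

    def test_cofoci_share_center(self, small_config):
        traces, mask = generate_axes(small_config)
        truth = plant_foci(traces, small_config, mask=mask)
        co = truth[truth.is_cofocus]
        for _, grp in co.groupby("object_id"):
            assert len(grp) == 2
            assert grp.row.nunique() == 1 and grp.col.nunique() == 1

    def test_on_axis_objects_near_polyline(self, small_config):
        traces, mask = generate_axes(small_config)
        truth = plant_foci(traces, small_config, mask=mask)
        geoms = {t.segment_id: LineString(t.vertices) for t in traces}
        on = truth[truth.on_axis]
        for row in on.itertuples():
            d = geoms[int(row.host_segment_id)].distance(Point(row.row, row.col))
            assert d <= 1.0

    def test_poisson_density_mode_ratio(self):
        """Planted density ratio consistent with the Poisson law at rate 2:1."""
        cfg = SimConfig(density_unsyn_per_um=0.4, density_syn_per_um=0.2,
                        channels=("DMC1", "RPA2"), synapsed_fraction=0.5)
        n_u = n_s = 0
        L_u = L_s = 0.0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            traces, mask = generate_axes(replace(cfg, seed=seed), rng)
            truth = plant_foci(traces, cfg, rng, mask)
            by_seg = {t.segment_id: t for t in traces}
            for t in traces:
                L = polyline_length(t, cfg.pixel_size)
                n = (truth.host_segment_id == t.segment_id).sum()
                if t.synapsed:
                    n_s += n
                    L_s += L
                else:
                    n_u += n
                    L_u += L
        ratio = (n_u / L_u) / (n_s / L_s)
        # ~500 µm per class: 95% interval of the rate ratio around 2.0
        se_log = np.sqrt(1 / n_u + 1 / n_s)
        assert 2.0 * np.exp(-1.96 * se_log) <= ratio <= 2.0 * np.exp(1.96 * se_log)


class TestRender:
    def test_flat_background(self):
        cfg = SimConfig(n_cofoci=0, n_single_ch1=0, n_single_ch2=0, n_large_foci=0,
                        noise_sd=0.0, background_gradient_amplitude=0.0)
        traces, mask = generate_axes(cfg)
        truth = plant_foci(traces, cfg, mask=mask)
        stack = render(truth, cfg)
        for arr in stack.channels.values():
            assert np.allclose(arr, cfg.background_level)

    def test_single_gaussian_mass_and_peak(self):
        import pandas as pd
        from dsbquant.simulate import TRUTH_COLUMNS

        cfg = SimConfig(noise_sd=0.0, background_level=0.0,
                        background_gradient_amplitude=0.0)
        truth = pd.DataFrame([dict(object_id=0, channel="MEI4", row=100.0, col=120.0,
                                   amplitude=50.0, sigma_px=2.0, on_axis=False,
                                   host_segment_id=None, is_cofocus=False,
                                   is_large=False)], columns=TRUTH_COLUMNS)
        img = render(truth, cfg).channels["MEI4"]
        assert img[100, 120] == pytest.approx(50.0, rel=0.01)
        assert img.sum() == pytest.approx(50.0 * 2 * np.pi * 4, rel=0.02)

    def test_seeded_determinism_bitwise(self, small_config):
        c1 = generate_cell(small_config)
        c2 = generate_cell(small_config)
        for ch in c1.stack.channels:
            assert np.array_equal(c1.stack.channels[ch], c2.stack.channels[ch])
        assert c1.truth.equals(c2.truth)

    def test_nonnegative_intensities(self, small_config):
        cell = generate_cell(replace(small_config, noise_sd=200.0))
        for arr in cell.stack.channels.values():
            assert arr.min() >= 0


class TestCohorts:
    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            generate_cohort("nonsense", 1)

    def test_empty_cohort(self):
        assert generate_cohort("wildtype_like", 0) == []

    def test_same_seed_identical_truth(self):
        a = generate_cohort("wildtype_like", 2, seed=3, render_images=False)
        b = generate_cohort("wildtype_like", 2, seed=3, render_images=False)
        for ca, cb in zip(a, b):
            assert ca.truth.equals(cb.truth)

    def test_seeding_deficient_fewer_brighter(self):
        wt = generate_cohort("wildtype_like", 3, seed=1, render_images=False)
        mut = generate_cohort("seeding_deficient_like", 3, seed=1,
                              render_images=False)
        for w, m in zip(wt, mut):
            w_co = w.truth[w.truth.is_cofocus]
            m_co = m.truth[m.truth.is_cofocus]
            assert m_co.object_id.nunique() < w_co.object_id.nunique()
            assert m_co.amplitude.mean() > w_co.amplitude.mean()

    def test_growth_deficient_same_count_dimmer(self):
        wt = generate_cohort("wildtype_like", 2, seed=1, render_images=False)
        mut = generate_cohort("growth_deficient_like", 2, seed=1,
                              render_images=False)
        for w, m in zip(wt, mut):
            assert m.truth[m.truth.is_cofocus].object_id.nunique() \
                == w.truth[w.truth.is_cofocus].object_id.nunique()
            assert m.truth[m.truth.is_cofocus].amplitude.mean() \
                < w.truth[w.truth.is_cofocus].amplitude.mean()

    def test_planted_count_ratio_wt_vs_seeding_deficient(self):
        """Planted co-focus reduction sits in the 1.8-3.9x band (2.5 by design)."""
        wt = generate_cohort("wildtype_like", 1, seed=0, render_images=False)[0]
        mut = generate_cohort("seeding_deficient_like", 1, seed=0,
                              render_images=False)[0]
        n_wt = wt.truth[wt.truth.is_cofocus].object_id.nunique()
        n_mut = mut.truth[mut.truth.is_cofocus].object_id.nunique()
        assert 1.8 <= n_wt / n_mut <= 3.9
        assert n_wt / n_mut == pytest.approx(2.5, abs=0.01)
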