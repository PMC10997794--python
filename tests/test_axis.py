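"""Axis traces, focus merging, assignment, and density computation."""

import math

import numpy as np
import pytest

from dsbquant import (
    AxisTrace,
    assign_to_axis,
    compute_density,
    merge_two_channel_foci,
    polyline_length,
)
from dsbquant.axis import RecombinationFocus
from conftest import make_focus


def trace(verts, seg_id=0, synapsed=False):
    return AxisTrace(seg_id, np.asarray(verts, float), synapsed)


class TestPolylineLength:
    def test_hypotenuse(self):
        assert polyline_length(trace([(0, 0), (3, 4)]), 0.1) == pytest.approx(0.5)

    def test_single_vertex(self):
        assert polyline_length(trace([(5, 5)]), 0.1) == 0.0

    def test_square_path(self):
        sq = trace([(0, 0), (0, 10), (10, 10), (10, 0), (0, 0)])
        assert polyline_length(sq, 1.0) == pytest.approx(40.0)

    def test_scales_with_pixel_size(self):
        t = trace([(0, 0), (0, 7), (5, 7)])
        assert polyline_length(t, 0.2) == pytest.approx(2 * polyline_length(t, 0.1))


class TestMergeTwoChannelFoci:
    def disc(self, center, radius, fid=0, channel="DMC1"):
        rr, cc = np.mgrid[center[0] - radius:center[0] + radius + 1,
                          center[1] - radius:center[1] + radius + 1]
        keep = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2
        return make_focus(np.column_stack([rr[keep], cc[keep]]),
                          focus_id=fid, channel=channel)

    def test_centroid_inside_other_merges(self):
        d = self.disc((10, 10), 3, fid=0)
        r = self.disc((11, 10), 3, fid=0, channel="RPA2")
        merged = merge_two_channel_foci([d], [r])
        assert len(merged) == 1
        assert merged[0].dmc1_id == 0 and merged[0].rpa2_id == 0

    def test_touching_without_center_overlap_stays_separate(self):
        d = self.disc((10, 10), 3, fid=0)
        r = self.disc((10, 17), 3, fid=0, channel="RPA2")  # adjacent, no center overlap
        merged = merge_two_channel_foci([d], [r])
        assert len(merged) == 2

    def test_disjoint(self):
        d = self.disc((5, 5), 2)
        r = self.disc((30, 30), 2, channel="RPA2")
        assert len(merge_two_channel_foci([d], [r])) == 2

    def test_each_focus_merges_at_most_once(self):
        # one DMC1 focus coincident with two RPA2 foci: one pair + one singleton
        d = self.disc((10, 10), 4, fid=0)
        r1 = self.disc((10, 10), 3, fid=0, channel="RPA2")
        r2 = self.disc((10, 12), 2, fid=1, channel="RPA2")
        merged = merge_two_channel_foci([d], [r1, r2])
        assert len(merged) == 2
        pairs = [m for m in merged if m.dmc1_id is not None and m.rpa2_id is not None]
        assert len(pairs) == 1
        assert pairs[0].rpa2_id == 0  # larger overlap wins

    def test_count_conservation(self, rng):
        dmc1 = [self.disc(tuple(c), 2, fid=i)
                for i, c in enumerate(rng.integers(5, 60, (8, 2)))]
        rpa2 = [self.disc(tuple(c), 2, fid=i, channel="RPA2")
                for i, c in enumerate(rng.integers(5, 60, (8, 2)))]
        merged = merge_two_channel_foci(dmc1, rpa2)
        n_pairs = sum(1 for m in merged
                      if m.dmc1_id is not None and m.rpa2_id is not None)
        assert len(merged) == len(dmc1) + len(rpa2) - n_pairs


class TestAssignToAxis:
    def test_on_vertex_distance_zero(self):
        t = trace([(0, 0), (0, 10)], seg_id=0)
        f = RecombinationFocus(0, None, (0.0, 5.0))
        assert assign_to_axis([f], [t], 0.3, 0.1) == [0]

    def test_beyond_max_distance_unassigned(self):
        t = trace([(0, 0), (0, 10)], seg_id=0)
        f = RecombinationFocus(0, None, (30.0, 5.0))  # 3 µm away at 0.1 µm/px
        assert assign_to_axis([f], [t], 1.0, 0.1) == [None]

    def test_tie_goes_to_lower_segment_id(self):
        t2 = trace([(0, 0), (0, 10)], seg_id=2)
        t5 = trace([(4, 0), (4, 10)], seg_id=5)
        f = RecombinationFocus(0, None, (2.0, 5.0))  # equidistant
        assert assign_to_axis([f], [t5, t2], 1.0, 0.1) == [2]


class TestComputeDensity:
    def two_region_cell(self):
        syn = trace([(0, 0), (0, 500)], seg_id=0, synapsed=True)      # 50 µm
        unsyn = trace([(50, 0), (50, 500)], seg_id=1, synapsed=False)  # 50 µm
        return syn, unsyn

    def foci_on(self, t, n, ch="d"):
        out = []
        for i in range(n):
            frac = (i + 0.5) / n
            p = t.vertices[0] + frac * (t.vertices[-1] - t.vertices[0])
            out.append(RecombinationFocus(i, None, (float(p[0]), float(p[1]))))
        return out

    def test_density_and_ratio(self):
        syn, unsyn = self.two_region_cell()
        foci = self.foci_on(unsyn, 10) + self.foci_on(syn, 5)
        res = compute_density(foci, [syn, unsyn], 0.1, 0.3, "c")
        assert res.density_unsyn == pytest.approx(0.20)
        assert res.density_syn == pytest.approx(0.10)
        assert res.ratio_unsyn_to_syn == pytest.approx(2.0)
        assert res.percent_synapsed == pytest.approx(50.0)

    def test_equal_densities_ratio_one(self):
        syn, unsyn = self.two_region_cell()
        foci = self.foci_on(unsyn, 6) + self.foci_on(syn, 6)
        res = compute_density(foci, [syn, unsyn], 0.1, 0.3, "c")
        assert res.ratio_unsyn_to_syn == pytest.approx(1.0)

    def test_synapsis_classification_strict_70(self):
        syn = trace([(0, 0), (0, 600)], seg_id=0, synapsed=True)   # 60 µm
        unsyn = trace([(50, 0), (50, 200)], seg_id=1, synapsed=False)  # 20 µm
        res = compute_density([], [syn, unsyn], 0.1, 0.3, "c")
        assert res.percent_synapsed == pytest.approx(75.0)
        assert res.synapsis_class == ">70%"
        # exactly 70% falls in the lower class (strict >)
        syn2 = trace([(0, 0), (0, 700)], seg_id=0, synapsed=True)
        unsyn2 = trace([(50, 0), (50, 300)], seg_id=1, synapsed=False)
        res2 = compute_density([], [syn2, unsyn2], 0.1, 0.3, "c")
        assert res2.percent_synapsed == pytest.approx(70.0)
        assert res2.synapsis_class == "<=70%"

    def test_zero_synapsed_count_ratio_undefined(self):
        syn, unsyn = self.two_region_cell()
        res = compute_density(self.foci_on(unsyn, 4), [syn, unsyn], 0.1, 0.3, "c")
        assert math.isnan(res.ratio_unsyn_to_syn)

    def test_conservation_of_focus_counts(self):
        syn, unsyn = self.two_region_cell()
        near = self.foci_on(unsyn, 5)
        far = [RecombinationFocus(99, None, (500.0, 500.0))]
        res = compute_density(near + far, [syn, unsyn], 0.1, 0.3, "c")
        assert res.n_syn + res.n_unsyn + res.n_unassigned == 6
        assert res.n_unassigned == 1

    def test_pixel_size_rescaling_invariance(self):
        syn, unsyn = self.two_region_cell()
        foci = self.foci_on(unsyn, 9) + self.foci_on(syn, 4)
        r1 = compute_density(foci, [syn, unsyn], 0.1, 0.3, "c")
        r2 = compute_density(foci, [syn, unsyn], 0.2, 0.6, "c")
        assert r2.length_syn == pytest.approx(2 * r1.length_syn)
        assert r2.density_unsyn == pytest.approx(r1.density_unsyn / 2)
        assert r2.ratio_unsyn_to_syn == pytest.approx(r1.ratio_unsyn_to_syn)

    def test_no_traces_raises(self):
        with pytest.raises(ValueError):
            compute_density([], [], 0.1, 0.3, "c")
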