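import numpy as np
import pytest
from shapely import affinity
from shapely.geometry import Polygon

from ca1quant import puncta as pun
from ca1quant.puncta import Punctum, SomaContour
from ca1quant.synth import gen_scene, rasterize_scene


def square_soma(soma_id, cx, cy, half=5.0, positive=True):
    poly = Polygon(
        [(cx - half, cy - half), (cx + half, cy - half),
         (cx + half, cy + half), (cx - half, cy + half)]
    )
    return SomaContour(soma_id=soma_id, polygon=poly, marker_positive=positive)


def point_segment_distance(p, a, b):
    """Brute-force point-to-segment distance (independent geometry oracle)."""
    p, a, b = map(np.asarray, (p, a, b))
    ab = b - a
    t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0.0, 1.0)
    return float(np.linalg.norm(p - (a + t * ab)))


def brute_polygon_distance(p, polygon):
    """Distance to polygon boundary via every edge; 0 inside."""
    from matplotlib.path import Path

    verts = np.asarray(polygon.exterior.coords)
    if Path(verts).contains_point((p.x_um, p.y_um)):
        return 0.0
    return min(
        point_segment_distance((p.x_um, p.y_um), verts[i], verts[i + 1])
        for i in range(len(verts) - 1)
    )


class TestMaxIntensityProjection:
    def test_constant_stack(self):
        stack = np.full((7, 5, 5), 3.0)
        np.testing.assert_array_equal(
            pun.max_intensity_projection(stack, 7), np.full((5, 5), 3.0)
        )

    def test_single_bright_voxel_survives(self):
        stack = np.zeros((10, 8, 8))
        stack[3, 4, 5] = 9.0
        assert pun.max_intensity_projection(stack, 7)[4, 5] == 9.0

    def test_matches_elementwise_oracle(self, rng):
        stack = rng.normal(size=(9, 16, 16))
        got = pun.max_intensity_projection(stack, 6)
        brute = np.array(
            [[max(stack[k, i, j] for k in range(6)) for j in range(16)] for i in range(16)]
        )
        np.testing.assert_allclose(got, brute)

    def test_too_many_slices(self):
        with pytest.raises(ValueError, match="depth"):
            pun.max_intensity_projection(np.zeros((3, 4, 4)), 5)


class TestDetectPuncta:
    def test_known_spots_recovered_within_one_pixel(self, rng):
        px = 0.04
        truth = [
            Punctum(x, y)
            for x, y in zip(rng.uniform(2, 18, 25), rng.uniform(2, 18, 25))
        ]
        img = rasterize_scene(truth, extent_um=20.0, pixel_size_um=px,
                              amplitude=100.0, noise_sd=10.0, seed=0)
        found = pun.detect_puncta(img, px, expected_diameter_um=0.25)
        assert len(found) == 25
        fx = np.array([(f.x_um, f.y_um) for f in found])
        for t in truth:
            d = np.min(np.hypot(fx[:, 0] - t.x_um, fx[:, 1] - t.y_um))
            assert d <= px

    def test_blank_image_no_detections(self):
        assert pun.detect_puncta(np.zeros((100, 100)), 0.04) == []

    def test_nearby_spots_not_merged(self):
        px = 0.04
        spots = [Punctum(5.0, 5.0), Punctum(5.0 + 0.75, 5.0)]  # 3x diameter apart
        img = rasterize_scene(spots, extent_um=10.0, pixel_size_um=px, noise_sd=1.0)
        assert len(pun.detect_puncta(img, px)) == 2

    def test_subresolution_diameter_rejected(self):
        with pytest.raises(ValueError, match="2 pixels"):
            pun.detect_puncta(np.zeros((10, 10)), pixel_size_um=1.0,
                              expected_diameter_um=0.25)


class TestProximityFilters:
    def test_punctum_on_vertex_kept(self):
        soma = square_soma(0, 10, 10)
        kept = pun.filter_gephyrin_by_soma([Punctum(5.0, 5.0)], [soma])
        assert len(kept) == 1

    def test_far_punctum_dropped(self):
        soma = square_soma(0, 10, 10)
        assert pun.filter_gephyrin_by_soma([Punctum(16.5, 10.0)], [soma]) == []

    def test_presyn_distance_boundary(self):
        geph = [Punctum(0.0, 0.0)]
        kept = pun.filter_presyn_by_gephyrin(
            [Punctum(0.9, 0.0), Punctum(1.01, 0.0)], geph
        )
        assert [round(p.x_um, 2) for p in kept] == [0.9]

    @pytest.mark.parametrize("seed", range(5))
    def test_soma_filter_matches_geometry_oracle(self, seed):
        scene = gen_scene(bias=1.0, seed=seed)
        geph = scene.puncta["gephyrin"]
        kept = {
            (p.x_um, p.y_um)
            for p in pun.filter_gephyrin_by_soma(geph, scene.somas)
        }
        for p in geph:
            d = min(brute_polygon_distance(p, s.polygon) for s in scene.somas)
            assert ((p.x_um, p.y_um) in kept) == (d <= 1.0 + 1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_presyn_filter_matches_all_pairs_bruteforce(self, seed):
        scene = gen_scene(bias=1.0, seed=100 + seed)
        geph = pun.filter_gephyrin_by_soma(scene.puncta["gephyrin"], scene.somas)
        kept = pun.filter_presyn_by_gephyrin(scene.puncta["presyn"], geph)
        kept_set = {(p.x_um, p.y_um) for p in kept}
        for p in scene.puncta["presyn"]:
            d = min(np.hypot(p.x_um - g.x_um, p.y_um - g.y_um) for g in geph)
            assert ((p.x_um, p.y_um) in kept_set) == (d <= 1.0)


class TestCountOnSomas:
    def test_equidistant_tie_lower_id(self):
        somas = [square_soma(0, 0, 0), square_soma(1, 20, 0)]
        counts = pun.count_on_somas([Punctum(10.0, 0.0)], somas, radius_um=6.0)
        assert counts == {0: 1, 1: 0}

    def test_beyond_radius_uncounted(self):
        somas = [square_soma(0, 0, 0)]
        counts = pun.count_on_somas([Punctum(5.3, 0.0)], somas)
        assert counts == {0: 0}

    def test_only_in_analysis_somas_count(self):
        near = square_soma(0, 0, 0)
        near.in_analysis = False
        counts = pun.count_on_somas([Punctum(5.1, 0.0)], [near, square_soma(1, 20, 0)])
        assert counts == {1: 0}


class TestInnervationBias:
    def make_counts(self, pos, neg):
        somas = [square_soma(i, 20 * i, 0, positive=(i < 6)) for i in range(12)]
        counts = {i: (pos if i < 6 else neg) for i in range(12)}
        return counts, somas

    def test_equal_totals_ratio_one(self):
        counts, somas = self.make_counts(10, 10)
        assert pun.innervation_bias(counts, somas).bias_ratio == pytest.approx(1.0)

    def test_printed_scale_example(self):
        counts, somas = self.make_counts(11, 0)
        counts.update({i: 50 // 6 + (1 if i < 6 + 50 % 6 else 0) for i in range(6, 12)})
        res = pun.innervation_bias(counts, somas)
        assert res.total_pos == 66 and res.total_neg == 50
        assert res.bias_ratio == pytest.approx(1.32)

    def test_zero_negative_total_undefined(self):
        counts, somas = self.make_counts(5, 0)
        with pytest.raises(ZeroDivisionError):
            pun.innervation_bias(counts, somas)


class TestSceneProperties:
    @pytest.mark.parametrize("seed", range(100))
    def test_filter_order_independence(self, seed):
        """Filtering presyn against all gephyrin first, then against the
        soma-filtered set, yields the same final counts (disjoint channels)."""
        scene = gen_scene(bias=1.0, puncta_rate_per_soma=4.0,
                          n_distractor_presyn=10, n_distractor_gephyrin=15,
                          seed=seed)
        geph_kept = pun.filter_gephyrin_by_soma(scene.puncta["gephyrin"], scene.somas)
        a = pun.count_on_somas(
            pun.filter_presyn_by_gephyrin(scene.puncta["presyn"], geph_kept),
            scene.somas,
        )
        pre_first = pun.filter_presyn_by_gephyrin(
            scene.puncta["presyn"], scene.puncta["gephyrin"]
        )
        b = pun.count_on_somas(
            pun.filter_presyn_by_gephyrin(pre_first, geph_kept), scene.somas
        )
        assert a == b

    @pytest.mark.parametrize("seed", range(3))
    def test_counted_puncta_satisfy_all_rules_bruteforce(self, seed):
        scene = gen_scene(bias=1.32, seed=seed)
        geph_kept = pun.filter_gephyrin_by_soma(scene.puncta["gephyrin"], scene.somas)
        pre_kept = pun.filter_presyn_by_gephyrin(scene.puncta["presyn"], geph_kept)
        counts = pun.count_on_somas(pre_kept, scene.somas)
        counted = [p for p in pre_kept
                   if min(s.distance_um(p) for s in scene.somas) <= 0.2]
        assert sum(counts.values()) == len(counted)
        for p in counted:
            d_geph = min(np.hypot(p.x_um - g.x_um, p.y_um - g.y_um) for g in geph_kept)
            assert d_geph <= 1.0
            d_soma = min(brute_polygon_distance(p, s.polygon) for s in scene.somas)
            assert d_soma <= 0.2 + 1e-9

    def test_counts_invariant_under_rigid_motion(self):
        scene = gen_scene(bias=1.0, seed=4)
        base = pun.quantify_scene(scene)

        def move(p):
            x, y = p.x_um + 7.0, p.y_um - 3.0
            ang = np.deg2rad(30.0)
            return Punctum(
                x * np.cos(ang) - y * np.sin(ang),
                x * np.sin(ang) + y * np.cos(ang),
                p.diameter_um, p.channel, p.provenance,
            )

        moved = pun.PunctaScene(
            pixel_size_um=scene.pixel_size_um,
            somas=[
                SomaContour(
                    s.soma_id,
                    affinity.rotate(
                        affinity.translate(s.polygon, 7.0, -3.0), 30.0, origin=(0, 0)
                    ),
                    s.marker_positive,
                )
                for s in scene.somas
            ],
            puncta={ch: [move(p) for p in ps] for ch, ps in scene.puncta.items()},
        )
        res = pun.quantify_scene(moved)
        assert res.bias_ratio == pytest.approx(base.bias_ratio, rel=1e-9)
        assert res.total_pos == base.total_pos and res.total_neg == base.total_neg

    def test_distractor_only_scene_counts_nothing(self):
        scene = gen_scene(bias=1.0, puncta_rate_per_soma=0.0, seed=9)
        geph = pun.filter_gephyrin_by_soma(scene.puncta["gephyrin"], scene.somas)
        pre = pun.filter_presyn_by_gephyrin(scene.puncta["presyn"], geph)
        counts = pun.count_on_somas(pre, scene.somas)
        assert sum(counts.values()) == 0
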