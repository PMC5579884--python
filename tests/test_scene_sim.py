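"""Transect simulator: geometry, mixing, ground truth, scoring."""

import math

import numpy as np
import pytest

import labweed as lw
from labweed.color_core import LabColor
from labweed.decision import Thresholds
from labweed.scene_sim import transect_from_csv, transect_to_csv, scene_from_json


def mc_overlap(c1, r1, c2, r2, n=400_000, seed=0):
    """Monte-Carlo oracle: sample the smaller disc uniformly, count the
    fraction falling inside the other disc."""
    if r2 < r1:
        c1, r1, c2, r2 = c2, r2, c1, r1
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi, n)
    rad = r1 * np.sqrt(rng.uniform(0, 1, n))
    x = c1[0] + rad * np.cos(theta)
    y = c1[1] + rad * np.sin(theta)
    inside = (x - c2[0]) ** 2 + (y - c2[1]) ** 2 <= r2 ** 2
    return inside.mean() * math.pi * r1 ** 2


class TestSpotOverlap:
    def test_containment(self):
        assert lw.spot_overlap_area((0, 0), 2.5, (0.5, 0), 1.0) == pytest.approx(
            math.pi
        )

    def test_disjoint(self):
        assert lw.spot_overlap_area((0, 0), 2.5, (3.5, 0), 1.0) == 0.0

    def test_symmetric(self):
        a = lw.spot_overlap_area((0, 0), 2.5, (2.0, 1.0), 1.5)
        b = lw.spot_overlap_area((2.0, 1.0), 1.5, (0, 0), 2.5)
        assert a == pytest.approx(b, rel=1e-12)

    def test_partial_overlap_against_monte_carlo(self):
        exact = lw.spot_overlap_area((0, 0), 2.5, (2.5, 0), 1.0)
        assert exact == pytest.approx(mc_overlap((0, 0), 2.5, (2.5, 0), 1.0), rel=5e-3)

    def test_hundred_random_configs_against_monte_carlo(self):
        # overlaps below 15% of the smaller disc are skipped so that the
        # Monte-Carlo standard error stays well inside the 1% tolerance
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 100:
            r1 = rng.uniform(1.0, 3.0)
            r2 = rng.uniform(0.5, 2.0)
            d = rng.uniform(0.0, r1 + r2)
            exact = lw.spot_overlap_area((0, 0), r1, (d, 0), r2)
            if exact < 0.15 * math.pi * min(r1, r2) ** 2:
                continue
            approx = mc_overlap((0, 0), r1, (d, 0), r2, n=1_000_000, seed=checked)
            assert exact == pytest.approx(approx, rel=0.01), (r1, r2, d)
            checked += 1

    def test_continuous_in_distance(self):
        ds = np.linspace(0, 4.0, 200)
        areas = [lw.spot_overlap_area((0, 0), 2.5, (d, 0), 1.0) for d in ds]
        jumps = np.abs(np.diff(areas))
        assert jumps.max() < 0.2  # no discontinuities at regime boundaries
        assert all(x >= y - 1e-12 for x, y in zip(areas, areas[1:]))  # monotone

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError):
            lw.spot_overlap_area((0, 0), 0.0, (1, 0), 1.0)


class TestMixedColor:
    def test_endpoints(self, field, green1):
        assert lw.mixed_color(field.stats, green1.stats, 0.0, None) == field.stats.mean
        assert lw.mixed_color(field.stats, green1.stats, 1.0, None) == green1.stats.mean

    def test_midpoint(self, field, green1):
        mid = lw.mixed_color(field.stats, green1.stats, 0.5, None)
        assert mid.as_tuple() == pytest.approx((28.06, -5.215, 32.245))

    @pytest.mark.parametrize("f", [-0.1, 1.1])
    def test_fraction_out_of_range(self, field, green1, f):
        with pytest.raises(ValueError):
            lw.mixed_color(field.stats, green1.stats, f, None)

    def test_noise_is_deterministic_given_rng_state(self, field, green1):
        a = lw.mixed_color(field.stats, green1.stats, 0.3, np.random.default_rng(5))
        b = lw.mixed_color(field.stats, green1.stats, 0.3, np.random.default_rng(5))
        assert a == b


@pytest.fixture()
def paved_scene(db, grey_pavings):
    objects = tuple(
        lw.SceneObject(center_x=30.0 * (i + 1), center_y=0.0, radius=1.0,
                       green=db.green(f"Green {i + 1}"))
        for i in range(4)
    )
    return lw.SceneSpec(background=grey_pavings, objects=objects, seed=11)


class TestMakeTransect:
    def test_reference_sampling_grid(self, paved_scene):
        tr = lw.make_transect(paved_scene)
        assert len(tr) == 150
        assert np.allclose(np.diff(tr.x_cm), 1.0)
        assert np.allclose(np.diff(tr.t_s), 0.1)

    def test_empty_scene_noise_free_is_flat_background(self, field):
        spec = lw.SceneSpec(background=field, objects=(), noise=False)
        tr = lw.make_transect(spec)
        assert np.all(tr.truth_coverage == 0)
        assert np.allclose(tr.lab, field.stats.mean.as_tuple())
        assert all(g is None for g in tr.truth_green)

    def test_max_coverage_of_small_disc(self, field, green1):
        spec = lw.SceneSpec(
            background=field,
            objects=(lw.SceneObject(75.0, 0.0, 1.0, green1),),
            noise=False,
        )
        tr = lw.make_transect(spec)
        assert tr.truth_coverage.max() == pytest.approx(1.0 / 6.25)  # r^2 ratio

    def test_bit_identical_reproducibility(self, paved_scene):
        a = lw.make_transect(paved_scene)
        b = lw.make_transect(paved_scene)
        assert np.array_equal(a.lab, b.lab)
        assert np.array_equal(a.truth_coverage, b.truth_coverage)

    def test_noise_free_readings_colinear_with_mixing_segment(self, field, green1):
        spec = lw.SceneSpec(
            background=field,
            objects=(lw.SceneObject(75.0, 0.0, 2.0, green1),),
            noise=False,
        )
        tr = lw.make_transect(spec)
        bg = np.array(field.stats.mean.as_tuple())
        direction = np.array(green1.stats.mean.as_tuple()) - bg
        for row, f in zip(tr.lab, tr.truth_coverage):
            assert np.allclose(row, bg + f * direction, atol=1e-9)

    def test_bad_object_rejected(self, field, green1):
        with pytest.raises(ValueError):
            lw.SceneObject(10.0, 0.0, -1.0, green1)


class TestEvaluateDetection:
    @pytest.fixture()
    def transect_and_decisions(self, paved_scene, grey_pavings):
        tr = lw.make_transect(paved_scene)
        decs = [
            lw.detect_delta_e(c, grey_pavings.stats, Thresholds(t_dE=5.0))
            for c in tr.colors()
        ]
        return tr, decs

    def test_paved_scene_all_objects_found_no_false_alarms(
        self, transect_and_decisions
    ):
        tr, decs = transect_and_decisions
        m = lw.evaluate_detection(decs, tr, coverage_cutoff=0.0)
        assert m.objects_total == 4
        assert m.objects_detected == 4
        assert m.fp == 0
        assert m.precision == 1.0

    def test_all_negative_decisions_give_zero_recall(self, paved_scene, grey_pavings):
        tr = lw.make_transect(paved_scene)
        decs = [
            lw.detect_delta_e(c, grey_pavings.stats, Thresholds(t_dE=1e6))
            for c in tr.colors()
        ]
        m = lw.evaluate_detection(decs, tr)
        assert m.recall == 0.0
        assert m.objects_detected == 0

    def test_length_mismatch_rejected(self, transect_and_decisions):
        tr, decs = transect_and_decisions
        with pytest.raises(ValueError):
            lw.evaluate_detection(decs[:-1], tr)

    def test_recall_non_increasing_in_threshold(self, paved_scene, grey_pavings):
        tr = lw.make_transect(paved_scene)
        recalls = []
        for t in (1.0, 3.0, 5.0, 10.0, 30.0):
            decs = [
                lw.detect_delta_e(c, grey_pavings.stats, Thresholds(t_dE=t))
                for c in tr.colors()
            ]
            recalls.append(lw.evaluate_detection(decs, tr).recall)
        assert all(x >= y for x, y in zip(recalls, recalls[1:]))


class TestSerialization:
    def test_transect_csv_round_trip(self, paved_scene, tmp_path):
        tr = lw.make_transect(paved_scene)
        path = tmp_path / "tr.csv"
        transect_to_csv(tr, path)
        again = transect_from_csv(path)
        assert np.allclose(again.lab, tr.lab, atol=1e-6)
        assert np.allclose(again.truth_coverage, tr.truth_coverage, atol=1e-6)
        assert again.truth_green == tr.truth_green

    def test_scene_json(self, db, tmp_path):
        path = tmp_path / "scene.json"
        path.write_text(
            '{"background": "Grey paving stones", "seed": 3,'
            ' "objects": [{"center_x": 40, "radius": 1, "green": "Green 2"}]}'
        )
        spec = scene_from_json(path, db)
        assert spec.background.name == "Grey paving stones"
        assert spec.objects[0].green.name == "Green 2"
        assert spec.step_cm == pytest.approx(1.0)

    def test_scene_json_missing_field(self, db, tmp_path):
        path = tmp_path / "scene.json"
        path.write_text('{"objects": []}')
        with pytest.raises(ValueError, match="background"):
            scene_from_json(path, db)
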