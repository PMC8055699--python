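import numpy as np
import pytest

from irismooth.errors import (
    ConnectivityError,
    DegenerateMeasurementError,
    LandmarkError,
    StageError,
)
from irismooth.preprocess import GrayImage, PreprocessConfig
from irismooth.segment import BorderMask
from irismooth.smoothness import (
    LandmarkSet,
    SideMeasurement,
    compute_overall_si,
    euclidean_length,
    geodesic_length,
    measure_si,
    resample_path,
    side_measurement,
    snap_landmark,
    trace_geodesic,
)
from irismooth.synthetic import SyntheticIrisSpec, render_iris
from oracles import dijkstra_length, random_connected_curve


def line_border(n=30, row=5, width=40):
    px = np.zeros((row * 2 + 2, width), bool)
    px[row, 2 : 2 + n] = True
    return BorderMask(px)


class TestSnapLandmark:
    def test_point_on_border_unchanged(self):
        b = line_border()
        assert snap_landmark((5, 10), b) == (5, 10)

    def test_snaps_horizontally_to_vertical_line(self):
        px = np.zeros((30, 30), bool)
        px[5:25, 20] = True
        assert snap_landmark((12, 17), BorderMask(px), radius=10) == (12, 20)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(50):
            px = rng.random((40, 40)) > 0.95
            if not px.any():
                continue
            b = BorderMask(px)
            pt = (int(rng.integers(40)), int(rng.integers(40)))
            got = snap_landmark(pt, b, radius=100.0)
            coords = np.argwhere(px)
            d = np.hypot(coords[:, 0] - pt[0], coords[:, 1] - pt[1])
            assert np.isclose(
                np.hypot(got[0] - pt[0], got[1] - pt[1]), d.min()
            )

    def test_out_of_radius_reports_distance(self):
        b = line_border()
        with pytest.raises(LandmarkError, match="nearest"):
            snap_landmark((20, 10), b, radius=3)

    def test_tie_break_smaller_row_then_col(self):
        px = np.zeros((10, 10), bool)
        px[2, 5] = px[8, 5] = True  # equidistant from (5, 5)
        assert snap_landmark((5, 5), BorderMask(px), radius=10) == (2, 5)


class TestEuclideanLength:
    def test_three_four_five(self):
        assert euclidean_length((0, 0), (3, 4)) == pytest.approx(5.0)

    def test_anisotropic_spacing(self):
        assert euclidean_length((0, 0), (0, 10), spacing=(1.0, 0.5)) == pytest.approx(5.0)

    def test_symmetric(self, rng):
        for _ in range(20):
            p = tuple(rng.integers(0, 100, 2))
            q = tuple(rng.integers(0, 100, 2))
            if p == q:
                continue
            assert euclidean_length(p, q) == euclidean_length(q, p)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateMeasurementError):
            euclidean_length((3, 3), (3, 3))


class TestGeodesicLength:
    def test_straight_line(self):
        b = line_border(n=11)
        assert geodesic_length(b, (5, 2), (5, 12)) == pytest.approx(10.0)

    def test_diagonal_weights(self):
        px = np.zeros((10, 10), bool)
        for i in range(5):
            px[i, i] = True
        assert geodesic_length(BorderMask(px), (0, 0), (4, 4)) == pytest.approx(
            4 * np.sqrt(2)
        )

    def test_disconnected_names_endpoint(self):
        px = np.zeros((5, 12), bool)
        px[2, 0:3] = True
        px[2, 8:11] = True
        with pytest.raises(ConnectivityError, match=r"\(2, 10\)"):
            geodesic_length(BorderMask(px), (2, 0), (2, 10))

    def test_symmetric_and_matches_dijkstra(self, rng):
        for _ in range(25):
            mask, p, q = random_connected_curve(rng, shape=(60, 60), n_steps=120)
            if p == q:
                continue
            b = BorderMask(mask)
            fwd = geodesic_length(b, p, q)
            assert fwd == pytest.approx(geodesic_length(b, q, p), abs=1e-9)
            assert fwd == pytest.approx(dijkstra_length(mask, p, q), abs=1e-9)

    def test_anisotropic_spacing_matches_dijkstra(self, rng):
        mask, p, q = random_connected_curve(rng, shape=(50, 50), n_steps=100)
        if p == q:
            p = (p[0], p[1] + 1) if mask[p[0], p[1] + 1] else p
        b = BorderMask(mask, 0.02, 0.013)
        assert geodesic_length(b, p, q) == pytest.approx(
            dijkstra_length(mask, p, q, (0.02, 0.013)), abs=1e-9
        )

    def test_at_least_chord(self, rng):
        for _ in range(20):
            mask, p, q = random_connected_curve(rng, shape=(60, 60))
            if p == q:
                continue
            assert geodesic_length(BorderMask(mask), p, q) >= euclidean_length(p, q) - 1e-9

    def test_off_border_endpoint_rejected(self):
        b = line_border()
        with pytest.raises(LandmarkError, match="not a border pixel"):
            geodesic_length(b, (0, 0), (5, 10))


class TestResampledPath:
    def test_resample_keeps_endpoints(self):
        path = np.array([[0, i] for i in range(23)])
        out = resample_path(path, 7)
        assert (out[0] == path[0]).all() and (out[-1] == path[-1]).all()

    def test_step_one_is_identity(self):
        path = np.array([[0, i] for i in range(10)])
        np.testing.assert_array_equal(resample_path(path, 1), path)


class TestSideMeasurement:
    def test_flat_border_si_exactly_one(self):
        b = line_border(n=26)
        sm = side_measurement(b, (5, 2), (5, 27))
        assert sm.si == 1.0
        assert sm.basal_length == sm.actual_length == 25.0

    def test_half_circle_arc_near_two_over_pi(self):
        radius = 60
        theta = np.linspace(0, np.pi, 2000)
        rows = np.round(80 - radius * np.sin(theta)).astype(int)
        cols = np.round(80 + radius * np.cos(theta)).astype(int)
        px = np.zeros((100, 160), bool)
        px[rows, cols] = True
        b = BorderMask(px)
        p, q = (80, 80 + radius), (80, 80 - radius)
        sm = side_measurement(b, p, q)
        # independent bound: the raw chain cost from the Dijkstra oracle
        oracle_cost = dijkstra_length(px, p, q)
        assert sm.basal_length / oracle_cost <= sm.si <= 1.0
        assert sm.si == pytest.approx(2 / np.pi, abs=0.02)

    def test_si_never_exceeds_one(self, rng):
        for _ in range(20):
            mask, p, q = random_connected_curve(rng, shape=(60, 60))
            if p == q:
                continue
            sm = side_measurement(BorderMask(mask), p, q)
            assert 0 < sm.si <= 1.0
            assert sm.actual_length >= sm.basal_length
            assert sm.actual_length <= sm.path_cost + 1e-9

    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            SideMeasurement("nasal", basal_length=10.0, actual_length=5.0)
        with pytest.raises(ValueError):
            SideMeasurement("nasal", basal_length=0.0, actual_length=5.0)


class TestOverallSI:
    def _sm(self, side, bl, al):
        return SideMeasurement(side, basal_length=bl, actual_length=al)

    def test_simple_arithmetic(self):
        res = compute_overall_si(self._sm("nasal", 100, 125), self._sm("temporal", 100, 125))
        assert res.overall_si == pytest.approx(0.800)

    def test_equal_sides_give_same_overall(self):
        res = compute_overall_si(self._sm("nasal", 90, 100), self._sm("temporal", 45, 50))
        assert res.overall_si == pytest.approx(0.9)

    def test_mediant_between_side_sis(self):
        nasal = self._sm("nasal", 90, 100)
        temporal = self._sm("temporal", 110, 130)
        res = compute_overall_si(nasal, temporal)
        assert res.overall_si == pytest.approx(200 / 230)
        assert min(nasal.si, temporal.si) < res.overall_si < max(nasal.si, temporal.si)


class TestMeasureSI:
    def test_flat_synthetic_scene(self):
        spec = SyntheticIrisSpec(crypt_amplitude=0.0, speckle_sigma=0.05, seed=1)
        image, _, landmarks = render_iris(spec)
        res = measure_si(image, landmarks)
        assert res.overall_si >= 0.99

    def test_recovers_deep_crypt_analytic_si(self):
        # frequency/amplitude chosen so the analytic overall SI is ~0.85
        spec = SyntheticIrisSpec(
            crypt_amplitude=14.0, crypt_frequency=4, speckle_sigma=0.08, seed=7
        )
        image, truth, landmarks = render_iris(spec)
        assert truth.true_si_overall == pytest.approx(0.85, abs=0.02)
        res = measure_si(image, landmarks)
        assert res.overall_si == pytest.approx(truth.true_si_overall, abs=0.02)

    def test_deterministic(self):
        spec = SyntheticIrisSpec(crypt_amplitude=8.0, seed=3)
        image, _, landmarks = render_iris(spec)
        r1 = measure_si(image, landmarks)
        r2 = measure_si(image, landmarks)
        assert r1.overall_si == r2.overall_si
        assert r1.to_dict() == r2.to_dict()

    @pytest.mark.filterwarnings("ignore:constant input image")
    def test_stage_error_names_stage(self):
        img = GrayImage(np.full((50, 80), 100.0))
        lms = LandmarkSet((1, 1), (1, 10), (2, 1), (2, 10))
        with pytest.raises(StageError, match="binarize"):
            measure_si(img, lms)

    def test_crop_window_shifts_landmarks(self):
        spec = SyntheticIrisSpec(crypt_amplitude=6.0, seed=5)
        image, _, landmarks = render_iris(spec)
        res_full = measure_si(image, landmarks)
        # pad the image and shift the landmarks; crop back to the scene
        pad = 15
        padded = np.full(
            (image.shape[0] + pad, image.shape[1] + pad),
            int(spec.background_level),
            dtype=np.uint8,
        )
        padded[pad:, pad:] = image.pixels
        cfg = PreprocessConfig(
            crop_window=(pad, pad + image.shape[0], pad, pad + image.shape[1])
        )
        res_crop = measure_si(
            GrayImage(padded), landmarks.shifted(pad, pad), preprocess_cfg=cfg
        )
        assert res_crop.overall_si == pytest.approx(res_full.overall_si, abs=2e-3)

    def test_scale_invariance(self):
        base = SyntheticIrisSpec(
            crypt_amplitude=8.0, crypt_frequency=2, speckle_sigma=0.0, blur_sigma=1.0, seed=9
        )
        scaled = SyntheticIrisSpec(
            width=1500,
            height=480,
            side_span=570,
            margin=45,
            baseline_row=210.0,
            crypt_amplitude=12.0,
            crypt_frequency=2,
            iris_thickness=90,
            speckle_sigma=0.0,
            blur_sigma=1.5,
            seed=9,
        )
        r_base = measure_si(*_image_and_lms(base))
        r_scaled = measure_si(*_image_and_lms(scaled))
        assert r_scaled.overall_si == pytest.approx(r_base.overall_si, abs=0.01)

    def test_provenance_carries_config_hash(self):
        spec = SyntheticIrisSpec(crypt_amplitude=4.0, seed=2)
        image, _, landmarks = render_iris(spec)
        res = measure_si(image, landmarks)
        assert "cfg:" in res.provenance and "synthetic" in res.provenance


def _image_and_lms(spec):
    image, _, landmarks = render_iris(spec)
    return image, landmarks


class TestLandmarkSet:
    def test_coincident_side_rejected(self):
        with pytest.raises(ValueError, match="nasal"):
            LandmarkSet((1, 1), (1, 1), (2, 1), (2, 10))

    def test_shift(self):
        lms = LandmarkSet((1, 1), (1, 10), (2, 1), (2, 10))
        assert lms.shifted(3, 4).nasal_peripheral == (4, 5)
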