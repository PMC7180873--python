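"""The scanpath -> PI/MI/LI view transformation, checked against brute force."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scanpix.encoding import (
    CHANNEL_LAYOUT,
    EncodingConfig,
    compute_angle,
    compute_lag_distance,
    compute_lead_time,
    encode_scanpath,
    map_to_grid,
    normalize_channel,
    read_image,
    write_image_set,
)
from scanpix.fixation_io import FixationRecord

from conftest import make_scanpath, random_scanpath


class TestAngle:
    @pytest.mark.parametrize(
        "prev,curr,expected",
        [
            ((0, 0), (1, 1), math.pi / 4),
            ((0, 0), (0, 5), math.pi / 2),   # vertical: slope form undefined
            ((0, 0), (-3, 0), math.pi),      # straight left
            ((5, 5), (5, 5), 0.0),           # coincident -> convention
        ],
    )
    def test_reference_directions(self, prev, curr, expected):
        assert compute_angle(prev, curr) == pytest.approx(expected)

    def test_matches_slope_arctan_in_right_half_plane(self, rng):
        """Whenever dx > 0, atan2(dy, dx) equals arctan of the slope dy/dx."""
        for _ in range(1000):
            p = rng.uniform(0, 1000, 2)
            q = p + [rng.uniform(1e-6, 500), rng.uniform(-500, 500)]
            slope_form = math.atan((q[1] - p[1]) / (q[0] - p[0]))
            assert compute_angle(tuple(p), tuple(q)) == pytest.approx(slope_form, abs=1e-12)

    def test_range(self, rng):
        for _ in range(200):
            a = compute_angle(tuple(rng.uniform(0, 100, 2)), tuple(rng.uniform(0, 100, 2)))
            assert -math.pi < a <= math.pi


class TestLagDistance:
    def test_three_four_five(self):
        sp = make_scanpath([(0, 0), (3, 4)])
        assert compute_lag_distance(sp, 1, 1) == 5.0

    def test_no_predecessor_is_zero(self):
        sp = make_scanpath([(10, 10), (20, 20)])
        assert compute_lag_distance(sp, 0, 1) == 0.0
        assert compute_lag_distance(sp, 1, 5) == 0.0

    def test_matches_pairwise_table(self, rng):
        sp = random_scanpath(rng, 50)
        pts = np.array(sp.xy())
        for i in range(50):
            for k in (1, 2, 3, 5, 10):
                expected = 0.0 if i < k else float(np.linalg.norm(pts[i] - pts[i - k]))
                assert compute_lag_distance(sp, i, k) == pytest.approx(expected, abs=1e-9)

    def test_index_out_of_range(self):
        sp = make_scanpath([(0, 0)])
        with pytest.raises(IndexError):
            compute_lag_distance(sp, 1, 1)


class TestLeadTime:
    def test_plain_window_sum(self):
        sp = make_scanpath([(0, 0)] * 4, [100, 200, 300, 50])
        assert compute_lead_time(sp, 3, 3) == 600

    def test_no_predecessors(self):
        sp = make_scanpath([(0, 0)], [100])
        assert compute_lead_time(sp, 0, 10) == 0

    def test_matches_explicit_loop(self, rng):
        sp = random_scanpath(rng, 30)
        durs = sp.durations()
        for i in range(30):
            for n in (1, 3, 10):
                expected = sum(durs[j] for j in range(len(durs)) if i - n <= j < i)
                assert compute_lead_time(sp, i, n) == pytest.approx(expected, abs=1e-9)


class TestNormalize:
    def test_peak_maps_to_255(self, rng):
        values = rng.uniform(0, 123.0, (10, 10))
        out = normalize_channel(values, EncodingConfig())
        assert out.max() == 255
        assert out.dtype == np.uint8

    def test_all_zero_stays_zero(self):
        out = normalize_channel(np.zeros((4, 4)), EncodingConfig())
        assert not out.any()

    def test_half_rounds_away_from_zero(self):
        out = normalize_channel(np.array([0.0, 5.0, 10.0]), EncodingConfig())
        assert out.tolist() == [0, 128, 255]

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            normalize_channel(np.array([-1.0, 2.0]), EncodingConfig())


class TestMapToGrid:
    @pytest.mark.parametrize(
        "xy,expected",
        [((0, 0), (0, 0)), ((1919, 1079), (223, 223)), ((960, 540), (112, 112))],
    )
    def test_reference_points(self, xy, expected):
        rec = FixationRecord(x=xy[0], y=xy[1], duration_ms=1, subject="s")
        assert map_to_grid(rec, (1920, 1080), (224, 224)) == expected

    def test_identity_when_grid_equals_screen(self, rng):
        for _ in range(100):
            x, y = int(rng.integers(0, 1920)), int(rng.integers(0, 1080))
            rec = FixationRecord(x=x, y=y, duration_ms=1, subject="s")
            assert map_to_grid(rec, (1920, 1080), (1920, 1080)) == (x, y)

    @given(x=st.floats(0, 1919.999), y=st.floats(0, 1079.999))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_always_in_bounds(self, x, y):
        rec = FixationRecord(x=x, y=y, duration_ms=1, subject="s")
        col, row = map_to_grid(rec, (1920, 1080), (224, 224))
        assert 0 <= col < 224 and 0 <= row < 224


def brute_force_raw(sp, config):
    """Independent recomputation of all nine per-fixation channel values."""
    pts = sp.xy()
    durs = sp.durations()
    rows = []
    for i in range(len(sp)):
        vals = {}
        if i == 0:
            vals["theta"] = 0.0
        else:
            dy = pts[i][1] - pts[i - 1][1]
            dx = pts[i][0] - pts[i - 1][0]
            vals["theta"] = (math.atan2(dy, dx) if (dx, dy) != (0, 0) else 0.0) + math.pi
        for k in (1, 2, 3, 5, 10):
            vals[f"r-{k}"] = (
                math.dist(pts[i], pts[i - k]) if i >= k else 0.0
            )
        vals["duration"] = durs[i]
        for n in (3, 10):
            vals[f"leadtime-{n}"] = sum(durs[max(0, i - n):i])
        rows.append(vals)
    return rows


class TestEncodeScanpath:
    def test_single_fixation_conventions(self):
        sp = make_scanpath([(960, 540)], [250])
        iset = encode_scanpath(sp)
        # history-dependent channels carry no information
        assert not iset.pi[..., 0].any()          # theta
        assert not iset.pi[..., 1].any()          # r-1
        assert not iset.mi.any() and not iset.li.any()
        dur = iset.pi[..., 2]
        assert dur.sum() == 255 and dur[112, 112] == 255

    def test_collision_keeps_max_duration(self):
        # both fixations land in grid cell (0, 0)
        sp = make_scanpath([(1, 1), (2, 2)], [100, 200])
        iset = encode_scanpath(sp)
        assert iset.pi[0, 0, 2] == 255  # normalization of max(100, 200)

    def test_last_policy_is_order_dependent(self):
        sp = make_scanpath([(1, 1), (2, 2)], [200, 100])
        iset = encode_scanpath(sp, EncodingConfig(collision_policy="last"))
        # last deposit (100) normalized by the channel max (100 at that cell)
        assert iset.pi[0, 0, 2] == 255

    def test_sparsity_bound(self, rng):
        sp = random_scanpath(rng, 40)
        iset = encode_scanpath(sp)
        for img in iset.images().values():
            for c in range(3):
                assert (img[..., c] > 0).sum() <= 40

    def test_determinism(self, rng):
        sp = random_scanpath(rng, 25)
        a, b = encode_scanpath(sp), encode_scanpath(sp)
        for k in ("pi", "mi", "li"):
            assert np.array_equal(getattr(a, k), getattr(b, k))

    def test_raw_values_match_brute_force(self, rng):
        """Deposited values equal the independent recomputation, pre-normalization."""
        config = EncodingConfig(grid_dims=(1920, 1080))  # identity mapping, no collisions
        for _ in range(20):
            n = int(rng.integers(2, 50))
            pts = set()
            while len(pts) < n:  # distinct cells so deposits don't merge
                pts.add((int(rng.integers(0, 1920)), int(rng.integers(0, 1080))))
            sp = make_scanpath(sorted(pts), rng.uniform(50, 600, n).tolist())
            raw = brute_force_raw(sp, config)
            iset = encode_scanpath(sp, config)
            for kind, channels in CHANNEL_LAYOUT.items():
                img = iset.images()[kind]
                for c, name in enumerate(channels):
                    expected_raw = np.array([row[name] for row in raw])
                    peak = expected_raw.max()
                    for (x, y), val in zip(sp.xy(), expected_raw):
                        got = img[int(y), int(x), c]
                        want = 0 if peak == 0 else np.floor(val * 255 / peak + 0.5)
                        assert got == want

    def test_empty_scanpath_rejected(self):
        from scanpix.fixation_io import Scanpath
        with pytest.raises(ValueError):
            encode_scanpath(Scanpath(records=[]))

    def test_grid_dims_honoured(self, rng):
        sp = random_scanpath(rng, 10)
        iset = encode_scanpath(sp, EncodingConfig(grid_dims=(64, 32)))
        assert iset.pi.shape == (32, 64, 3)


class TestWriteImageSet:
    def test_lossless_round_trip_and_file_count(self, tmp_path, rng):
        sp = random_scanpath(rng, 15)
        iset = encode_scanpath(sp)
        paths = write_image_set(iset, tmp_path)
        assert len(paths) == 3
        for p, (kind, arr) in zip(paths, iset.images().items()):
            assert kind in p.name
            assert np.array_equal(read_image(p), arr)
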