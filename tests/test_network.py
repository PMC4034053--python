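"""Drive equations, filter stage, and exact network symmetries."""

import dataclasses

import numpy as np
import pytest

from fgspike.network import (
    DEFAULT_FILTERS,
    NetworkConfig,
    area1_drive,
    area2_drive,
    area3_drive,
    area4_drive,
    area5_drive,
    binarize_map,
    default_w5,
    feature_map,
    make_channels,
    permutation_invariant_mean,
    run_network,
)
from fgspike.stimuli import BinaryImage, contrast_reverse, mirror_reverse, rotate90


def brute_force_feature_map(S, kernel):
    """Independent double-loop implementation of the thresholded correlation."""
    H, W = S.shape
    out = np.zeros_like(S)
    for r in range(H):
        for c in range(W):
            corr = 0
            for off, coef in ((kernel.plus, 1), (kernel.minus, -1)):
                rr, cc = r + off[0], c + off[1]
                if 0 <= rr < H and 0 <= cc < W:
                    corr += coef * int(S[rr, cc])
            out[r, c] = 1 if corr - 1 >= 0 else 0
    return out


class TestDriveEquations:
    def test_area1_drive_values(self):
        T = np.array([[0, 1], [1, 0]], dtype=np.uint8)
        I = area1_drive(T, 10.0)
        np.testing.assert_array_equal(I, [[0.0, 10.0], [10.0, 0.0]])
        assert I.mean() == 10.0 * T.mean()

    def test_area2_uniform_input_gives_net_inhibition(self):
        x1 = np.ones((10, 10))
        I = area2_drive(x1, 400.0, -750.0)
        np.testing.assert_allclose(I, 400.0 - 750.0)

    def test_area2_zero_input_gives_zero(self):
        np.testing.assert_array_equal(area2_drive(np.zeros((5, 5)), 400.0, -750.0), 0.0)

    def test_area2_partial_coverage_splits_on_off_sites(self):
        # activity on 29.78% of sites: off-sites -223.4, on-sites +176.6
        x1 = np.zeros(10000)
        x1[:2978] = 1.0
        I = area2_drive(x1, 400.0, -750.0)
        assert I[0] == pytest.approx(400.0 - 750.0 * 0.2978, abs=1e-9)
        assert I[-1] == pytest.approx(-750.0 * 0.2978, abs=1e-9)

    def test_binarize_thresholds(self):
        x = np.array([0.0, 0.39, 0.4, 2.0])
        np.testing.assert_array_equal(binarize_map(x, 0.4, 1.0), [0, 0, 1, 1])
        assert binarize_map(np.zeros(4), 0.5).sum() == 0
        assert binarize_map(np.full(4, 9.9), 0.5).sum() == 4

    def test_area3_drive_scales_detections(self):
        det = np.zeros((6, 6), dtype=np.uint8)
        det[2, 3] = 1
        I = area3_drive(det, 500.0)
        assert I[2, 3] == 500.0
        assert I.sum() == 500.0 * det.sum()

    def test_area4_drive_substitution(self):
        x3 = np.zeros(5776)
        x3[:250] = 0.5
        assert area4_drive(x3, 5.0, 1.0) == pytest.approx(5.0 * 125 / 5776, abs=1e-9)
        assert area4_drive(x3, 5.0, 250.0) == pytest.approx(250 * 5.0 * 125 / 5776, abs=1e-6)
        assert area4_drive(np.zeros(100), 5.0, 250.0) == 0.0

    def test_area5_drive_substitution(self):
        w5 = default_w5(100.0, 5.0)
        x4 = np.zeros((2, 4))
        x4[0, 1] = x4[0, 3] = 0.5  # F=1, even j
        assert area5_drive(x4, w5[0]) == pytest.approx(100.0)
        x4b = np.zeros((2, 4))
        x4b[1, 1] = x4b[1, 3] = 0.5  # same activity moved to F=2
        assert area5_drive(x4b, w5[0]) == pytest.approx(5.0)
        assert area5_drive(np.zeros((2, 4)), w5[0]) == 0.0

    def test_default_w5_structure(self):
        w5 = default_w5(100.0, 5.0)
        assert w5.shape == (2, 2, 4)
        assert (np.count_nonzero(w5[0]), np.count_nonzero(w5[1])) == (4, 4)
        even_support = np.nonzero(w5[0].sum(axis=0))[0]
        odd_support = np.nonzero(w5[1].sum(axis=0))[0]
        assert set(even_support) | set(odd_support) == {0, 1, 2, 3}
        assert set(even_support) & set(odd_support) == set()
        with pytest.raises(ValueError):
            default_w5(100.0, 100.0)


class TestFeatureMap:
    def test_uniform_maps_give_no_interior_detections(self):
        # All-zero: no detections anywhere.  All-one: the interior has no
        # transitions; only the zero-padded array boundary can detect (framed
        # stimuli keep the boundary black, so this never matters in runs).
        for k in DEFAULT_FILTERS:
            assert feature_map(np.zeros((6, 6), dtype=np.uint8), k).sum() == 0
            ones = feature_map(np.ones((6, 6), dtype=np.uint8), k)
            assert ones[1:-1, 1:-1].sum() == 0

    def test_row_fragment_detects_single_transition(self):
        S = np.array([[0, 0, 1, 1, 0]], dtype=np.uint8)
        k2 = DEFAULT_FILTERS[1]  # along-row, -1 then +1
        det = feature_map(S, k2)
        np.testing.assert_array_equal(det, [[0, 1, 0, 0, 0]])

    @pytest.mark.parametrize("k", [3, 5])
    def test_filled_square_left_edge_count(self, k):
        S = np.zeros((12, 12), dtype=np.uint8)
        S[3 : 3 + k, 3 : 3 + k] = 1
        det = feature_map(S, DEFAULT_FILTERS[1])
        assert det.sum() == k
        assert brute_force_feature_map(S, DEFAULT_FILTERS[1]).sum() == k

    def test_matches_brute_force_on_random_maps(self, rng):
        for _ in range(50):
            S = rng.integers(0, 2, size=(10, 10), dtype=np.uint8)
            for kern in DEFAULT_FILTERS:
                np.testing.assert_array_equal(
                    feature_map(S, kern), brute_force_feature_map(S, kern)
                )


class TestConfig:
    def test_defaults_reproduce_published_values(self):
        cfg = NetworkConfig()
        assert (cfg.w1, cfg.w2e, cfg.w2i, cfg.w3, cfg.w4) == (10.0, 400.0, -750.0, 500.0, 5.0)
        assert (cfg.A, cfg.B, cfg.duration) == (100.0, 5.0, 100.0)

    def test_b_not_smaller_than_a_rejected(self):
        with pytest.raises(ValueError, match="B"):
            NetworkConfig(A=100.0, B=200.0)

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            NetworkConfig.from_dict({"w1": 10.0, "bogus": 1})

    def test_roundtrip_and_hash_stability(self):
        cfg = NetworkConfig(duration=50.0)
        again = NetworkConfig.from_dict(cfg.to_dict())
        assert again == cfg
        assert again.config_hash() == cfg.config_hash()

    def test_permutation_invariant_mean_is_permutation_invariant(self, rng):
        x = rng.random(1000)
        y = rng.permutation(x)
        assert permutation_invariant_mean(x) == permutation_invariant_mean(y)


class TestChannels:
    def test_channel_construction(self, small_set):
        img = small_set.original
        T1, T2 = make_channels(img)
        assert T1 == img
        assert T2 == contrast_reverse(img)
        assert T2.white_count == img.N**2 - img.white_count
        sw1, sw2 = make_channels(contrast_reverse(img))
        assert (sw1, sw2) == (T2, T1)


@pytest.fixture(scope="module")
def small_runs(small_set, config):
    """Runs of the half-scale stimulus and its transforms (shared, ~2 s)."""
    img = small_set.original
    return {
        "original": run_network(img, config),
        "mirror": run_network(mirror_reverse(img), config),
        "contrast": run_network(contrast_reverse(img), config),
        "rotated": run_network(rotate90(img), config),
    }


class TestNetworkSymmetries:
    def test_mirror_invariance_is_exact(self, small_runs):
        o, m = small_runs["original"], small_runs["mirror"]
        np.testing.assert_array_equal(o.drive_log["I5"], m.drive_log["I5"])
        np.testing.assert_array_equal(
            np.sort(o.drive_log["I4"], axis=-1), np.sort(m.drive_log["I4"], axis=-1)
        )
        np.testing.assert_array_equal(
            o.rasters["area5"].spikes, m.rasters["area5"].spikes
        )
        np.testing.assert_array_equal(
            o.rasters["area2", 1].spikes, m.rasters["area2", 1].spikes[:, :, ::-1]
        )

    def test_contrast_reversal_swaps_channels_exactly(self, small_runs):
        o, c = small_runs["original"], small_runs["contrast"]
        for area in ("area1", "area2"):
            np.testing.assert_array_equal(
                o.rasters[area, 1].spikes, c.rasters[area, 2].spikes
            )
            np.testing.assert_array_equal(
                o.rasters[area, 2].spikes, c.rasters[area, 1].spikes
            )
        for j in range(1, 5):
            np.testing.assert_array_equal(
                o.rasters["area3", 1, j].spikes, c.rasters["area3", 2, j].spikes
            )

    def test_rotation_swaps_output_cells_exactly(self, small_runs):
        o, r = small_runs["original"], small_runs["rotated"]
        np.testing.assert_array_equal(
            o.rasters["area5"].spikes[:, 0], r.rasters["area5"].spikes[:, 1]
        )
        np.testing.assert_array_equal(
            o.rasters["area5"].spikes[:, 1], r.rasters["area5"].spikes[:, 0]
        )
        # area-4: even-j and odd-j subchannel activity exchanges
        oc = o.rasters["area4"].counts()
        rc = r.rasters["area4"].counts()
        assert sorted(oc[:, [1, 3]].ravel()) == sorted(rc[:, [0, 2]].ravel())

    def test_feedforward_causality_area5_after_area4(self, small_runs):
        run = small_runs["original"]
        i5 = run.drive_log["I5"]
        first4 = np.argwhere(run.rasters["area4"].spikes.any(axis=(1, 2)))
        first_nonzero_i5 = np.argwhere((i5 != 0).any(axis=1))
        assert first_nonzero_i5.min() > first4.min()

    def test_determinism_bit_identical_reruns(self, small_set, config):
        a = run_network(small_set.original, config)
        b = run_network(small_set.original, config)
        np.testing.assert_array_equal(a.rasters["area5"].spikes, b.rasters["area5"].spikes)
        np.testing.assert_array_equal(a.drive_log["I5"], b.drive_log["I5"])

    def test_all_black_image_drives_only_second_channel(self, config):
        img = BinaryImage(np.zeros((38, 38), dtype=np.uint8), n=32, m=3)
        cfg = dataclasses.replace(config, duration=30.0)
        run = run_network(img, cfg)
        assert run.rasters["area1", 1].total_count() == 0
        assert run.rasters["area1", 2].total_count() > 0
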