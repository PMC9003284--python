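import math

import numpy as np
import pytest

from focusfield import pcnn
from focusfield.errors import ConvergenceError, DegenerateStatsError, InvalidParameterError
from focusfield.pcnn import BandStats, PcnnParams


def flood_fill_labels(mask):
    """Independent BFS component-labeling oracle (8-connectivity)."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        current += 1
        stack = [start]
        labels[start] = current
        while stack:
            i, j = stack.pop()
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ni, nj = i + di, j + dj
                    if (
                        0 <= ni < mask.shape[0]
                        and 0 <= nj < mask.shape[1]
                        and mask[ni, nj]
                        and not labels[ni, nj]
                    ):
                        labels[ni, nj] = current
                        stack.append((ni, nj))
    return labels


def same_partition(a, b):
    """Two labelings induce the same partition of their support."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a > 0, b > 0):
        return False
    pairs = set(zip(a[a > 0].ravel(), b[b > 0].ravel()))
    return len(pairs) == len({p for p, _ in pairs}) == len({q for _, q in pairs})


def default_params(**kw):
    kw.setdefault("delta", 0.5)
    kw.setdefault("f_e", 0.4)
    kw.setdefault("td_min", 0.05)
    kw.setdefault("theta_e", 1.0)
    return PcnnParams(**kw)


class TestBandStats:
    def test_three_band_fixture(self):
        h = 30
        flat = np.full((h, h), 0.5)
        medium = np.full((h, h), 0.5)
        medium[(np.indices((h, h)).sum(axis=0) // 3) % 2 == 0] += 0.1
        medium[(np.indices((h, h)).sum(axis=0) // 3) % 2 == 1] -= 0.1
        fine = np.where(np.indices((h, h)).sum(axis=0) % 2 == 0, 0.8, 0.2)
        img = np.hstack([flat, medium, fine])
        stats = pcnn.band_stats(img)
        for m in (stats.m_lf, stats.m_mf, stats.m_hf):
            assert abs(m - 0.5) < 0.05
        assert stats.sigma_lf < stats.sigma_mf < stats.sigma_hf

    def test_population_statistics_match_tercile_oracle(self, rng):
        img = rng.uniform(0, 1, (20, 20))
        stats = pcnn.band_stats(img)
        # oracle: recompute from scratch with the same tercile rule
        from scipy import ndimage

        grad = (
            ndimage.maximum_filter(img, size=3, mode="nearest")
            - ndimage.minimum_filter(img, size=3, mode="nearest")
        ).ravel()
        vals = img.ravel()[np.argsort(grad, kind="stable")]
        thirds = np.array_split(vals, 3)
        assert stats.m_lf == pytest.approx(thirds[0].mean(), abs=1e-12)
        assert stats.sigma_hf == pytest.approx(thirds[2].std(), abs=1e-12)

    def test_constant_image_degenerates_downstream(self):
        img = np.full((16, 16), 0.5)
        stats = pcnn.band_stats(img)
        assert stats.sigma_lf == stats.sigma_hf == 0.0
        with pytest.raises(DegenerateStatsError):
            pcnn.estimate_params(img, stats)


class TestEstimateParams:
    # frozen oracle values: direct evaluation of the closed forms
    F_E = math.log(0.6 / 0.4)  # = 0.405465...
    C = math.log(0.9 / 0.7) / F_E
    DELTA = 3 * 0.1 / (C * (0.5 - 0.1))

    def stats(self):
        return BandStats(0.5, 0.55, 0.8, 0.1, 0.1, 0.1)

    def test_decay_factor(self, rng):
        p = pcnn.estimate_params(rng.uniform(0.1, 1, (16, 16)), self.stats())
        assert p.f_e == pytest.approx(self.F_E, abs=1e-12)
        assert round(p.f_e, 6) == 0.405465

    def test_judgment_criterion(self, rng):
        p = pcnn.estimate_params(rng.uniform(0.1, 1, (16, 16)), self.stats())
        assert p.c == pytest.approx(self.C, abs=1e-12)

    def test_linking_strength(self, rng):
        p = pcnn.estimate_params(rng.uniform(0.1, 1, (16, 16)), self.stats())
        assert p.delta == pytest.approx(self.DELTA, abs=1e-12)

    def test_td_min_is_sixth_percentile(self, rng):
        img = rng.uniform(0.2, 1.0, (32, 32))
        p = pcnn.estimate_params(img, self.stats())
        assert p.td_min == pytest.approx(np.quantile(img, 0.06, method="lower"))
        assert np.mean(img >= p.td_min) >= 0.94

    def test_kernel_default(self, rng):
        p = pcnn.estimate_params(rng.uniform(0.1, 1, (16, 16)), self.stats())
        np.testing.assert_array_equal(
            p.w_con, [[0.5, 1, 0.5], [1, 0, 1], [0.5, 1, 0.5]]
        )

    def test_theta_e_is_the_image(self, rng):
        img = rng.uniform(0.1, 1, (16, 16))
        p = pcnn.estimate_params(img, self.stats())
        np.testing.assert_array_equal(p.theta_e, img)

    @pytest.mark.parametrize(
        "stats",
        [
            BandStats(0.1, 0.5, 0.8, 0.2, 0.1, 0.1),  # M_LF <= sigma_LF
            BandStats(0.5, 0.5, 0.1, 0.1, 0.1, 0.2),  # M_HF <= sigma_HF
            BandStats(0.5, 0.5, 0.8, 0.0, 0.1, 0.1),  # zero LF variance
            BandStats(0.5, 0.5, 0.8, 0.1, 0.1, 0.0),  # C == 0
        ],
    )
    def test_degenerate_stats_rejected(self, rng, stats):
        with pytest.raises(DegenerateStatsError):
            pcnn.estimate_params(rng.uniform(0.1, 1, (16, 16)), stats)


class TestStep:
    def test_uniform_input_fires_synchronously(self):
        img = np.full((6, 6), 0.8)
        params = default_params(theta_e=img.copy())
        state = pcnn.init_state(img, params)
        pcnn.pcnn_step(state, params, img)
        assert state.y.all()
        assert np.all(state.fired == 1)

    def test_per_pixel_init_fires_both_blocks_at_once(self):
        img = np.full((4, 4), 0.2)
        img[:, :2] = 0.9
        params = default_params(theta_e=img.copy())
        state = pcnn.init_state(img, params)
        pcnn.pcnn_step(state, params, img)
        assert state.y.all()

    def test_max_init_fires_bright_before_dark(self):
        img = np.full((4, 4), 0.2)
        img[:, :2] = 0.9
        params = default_params(theta_e=0.9, delta=1e-9)
        edge, state = pcnn.pcnn_run(img, params)
        bright_iter = np.unique(state.fired[:, :2])
        dark_iter = np.unique(state.fired[:, 2:])
        assert bright_iter.size == 1 and dark_iter.size == 1
        assert bright_iter[0] < dark_iter[0]

    def test_refractory_after_firing(self):
        img = np.full((4, 4), 0.8)
        params = default_params(theta_e=img.copy())
        state = pcnn.init_state(img, params)
        for _ in range(5):
            pcnn.pcnn_step(state, params, img)
        assert np.all(state.fired == 1)
        assert not state.y.any()  # Y stays 0 after the refractory jump

    def test_threshold_decay_closed_form(self):
        img = np.zeros((3, 3))
        params = default_params(theta_e=1.0, f_e=0.3, td_min=0.001)
        state = pcnn.init_state(img, params)
        for n in range(1, 15):
            pcnn.pcnn_step(state, params, img)
            expected = math.exp(-0.3 * (n - 1)) * 1.0
            assert state.e.flat[0] == pytest.approx(expected, abs=1e-12)


class TestRun:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_every_neuron_fires_exactly_once(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, (12, 12))
        params = pcnn.estimate_params(img)
        state = pcnn.init_state(img, params)
        fire_counts = np.zeros(img.shape, dtype=int)
        while (state.fired == 0).any() and state.n < params.max_iters:
            pcnn.pcnn_step(state, params, img)
            fire_counts += state.y
        np.testing.assert_array_equal(fire_counts, 1)
        assert np.all(state.fired > 0)

    def test_two_squares_same_wave_distinct_labels(self):
        img = np.full((12, 12), 0.1)
        img[2:5, 2:5] = 0.9
        img[7:10, 7:10] = 0.9
        params = default_params(theta_e=0.9, delta=1e-9)
        edge, state = pcnn.pcnn_run(img, params)
        sq1, sq2 = state.fired[3, 3], state.fired[8, 8]
        assert sq1 == sq2 == 1
        assert edge.labels[3, 3] != edge.labels[8, 8]
        assert state.fired[0, 0] > sq1
        wave1 = state.fired == 1
        assert same_partition(edge.labels * wave1, flood_fill_labels(wave1))

    def test_single_square_first_wave_exact(self):
        img = np.full((8, 8), 0.2)
        img[2:6, 2:6] = 0.9
        params = default_params(theta_e=0.9, delta=1e-9)
        edge, state = pcnn.pcnn_run(img, params)
        expected = np.zeros((8, 8), dtype=bool)
        expected[2:6, 2:6] = True
        np.testing.assert_array_equal(state.fired == 1, expected)
        np.testing.assert_array_equal(edge.first_wave, expected)

    @pytest.mark.parametrize("seed", range(8))
    def test_wave_labels_agree_with_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0.05, 1.0, (8, 8))
        params = pcnn.estimate_params(img)
        edge, state = pcnn.pcnn_run(img, params)
        for n in range(1, state.n + 1):
            wave = state.fired == n
            if wave.any():
                assert same_partition(edge.labels * wave, flood_fill_labels(wave))

    def test_max_iters_exhaustion_carries_state(self):
        img = np.full((4, 4), 0.2)
        img[0, 0] = 0.9
        params = default_params(theta_e=0.9, delta=1e-9, max_iters=1, td_min=0.01)
        with pytest.raises(ConvergenceError) as exc:
            pcnn.pcnn_run(img, params)
        assert exc.value.state is not None
        assert exc.value.state.fired[0, 0] == 1

    def test_uninitialized_state_rejected(self):
        state = pcnn.PcnnState(None, None, None, None, None, None)
        with pytest.raises(InvalidParameterError):
            pcnn.pcnn_step(state, default_params(), np.zeros((3, 3)))


class TestParamValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(f_e=0.0),
            dict(f_e=-1.0),
            dict(c=9.0),
            dict(delta=0.0),
            dict(td_min=0.0),
            dict(td_min=1.0),
        ],
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(InvalidParameterError):
            default_params(**kw)


class TestBinarizeAndClean:
    def make_edge(self, m_edge, first_wave=None):
        m_edge = np.asarray(m_edge, dtype=bool)
        if first_wave is None:
            first_wave = m_edge
        return pcnn.EdgeMap(
            m_edge,
            np.zeros(m_edge.shape, dtype=np.int32),
            np.zeros(m_edge.shape, dtype=np.int32),
            np.asarray(first_wave, dtype=bool),
        )

    def test_empty_edge_map(self):
        out = pcnn.binarize_and_clean(self.make_edge(np.zeros((8, 8))))
        np.testing.assert_array_equal(out, False)

    def test_ring_fills_to_disk(self):
        yy, xx = np.mgrid[0:32, 0:32]
        r2 = (yy - 15.5) ** 2 + (xx - 15.5) ** 2
        ring = (r2 <= 100) & (r2 >= 64)
        disk = r2 <= 100
        out = pcnn.binarize_and_clean(self.make_edge(ring), min_size=1, closing_iters=1)
        # hole-filled ring covers the disk and stays within one dilation step
        assert np.all(out[disk])
        assert not out[r2 > 12.0**2].any()

    def test_zero_threshold_keeps_positive_evidence(self):
        evidence = np.ones((8, 8), dtype=bool)
        out = pcnn.binarize_and_clean(self.make_edge(evidence), td=0.0, min_size=1)
        assert out.all()
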