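"""Representation transforms against brute-force oracles and algebra checks."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import roarid as R
from roarid.representations import (RepresentationConfig, StubEmbedder,
                                    _bilinear_resize, band_center_hz,
                                    mel_filterbank)

SMALL = RepresentationConfig(window_length=64, hop_length=32, fft_length=64,
                             n_mel_bands=16, n_mfcc=8)


def dft_matrix(n):
    k = np.arange(n)
    return np.exp(-2j * np.pi * np.outer(k, k) / n)


def tone_clip(freq_hz, sr=16000, dur=0.25, amp=0.8):
    t = np.arange(int(sr * dur)) / sr
    return R.AudioClip(amp * np.sin(2 * np.pi * freq_hz * t), sr)


# ---------------------------------------------------------------------------
# spectrogram
# ---------------------------------------------------------------------------

class TestSpectrogram:
    def test_tone_bin_and_shape(self):
        cfg = RepresentationConfig()
        clip = tone_clip(1000.0)
        img = R.compute_spectrogram(clip, cfg)
        n = len(clip)
        assert img.values.shape == (cfg.fft_length // 2 + 1,
                                    1 + (n - cfg.window_length) // cfg.hop_length)
        assert np.all(np.argmax(img.values, axis=0) == 32)  # 1000/(16000/512)

    def test_zero_clip_all_zero(self):
        img = R.compute_spectrogram(R.AudioClip(np.zeros(256), 8000), SMALL)
        assert np.all(img.values == 0)

    def test_single_frame_matches_direct_dft(self):
        """One column equals |DFT(window * frame)|^2 by an O(N^2) sum."""
        rng = np.random.default_rng(1)
        x = rng.uniform(-1, 1, 64)
        img = R.compute_spectrogram(R.AudioClip(x, 8000), SMALL)
        direct = np.abs(dft_matrix(64) @ (x * SMALL.window()))[:33] ** 2
        assert np.max(np.abs(img.values[:, 0] - direct)) <= 1e-8 * direct.max()

    def test_short_clip_rejected(self):
        with pytest.raises(R.ShortSignalError):
            R.compute_spectrogram(R.AudioClip(np.zeros(10), 8000), SMALL)


# ---------------------------------------------------------------------------
# Mel scale and Mel spectrogram
# ---------------------------------------------------------------------------

class TestMel:
    def test_closed_forms(self):
        assert R.hz_to_mel(0.0) == 0.0
        assert np.isclose(R.hz_to_mel(700.0), 2595 * np.log10(2))

    @given(st.floats(0, 7999), st.floats(1e-3, 8000))
    def test_strictly_increasing(self, f, delta):
        assert R.hz_to_mel(f + delta) > R.hz_to_mel(f)

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError):
            R.hz_to_mel(-1.0)

    def test_white_noise_all_bands_positive(self):
        rng = np.random.default_rng(2)
        clip = R.AudioClip(rng.uniform(-0.9, 0.9, 2048), 8000)
        img = R.compute_mel_spectrogram(clip, SMALL)
        assert np.all(img.values > 0)

    @pytest.mark.parametrize("band", [4, 8, 12])
    def test_tone_at_band_center_maximises_that_band(self, band):
        cfg = RepresentationConfig(n_mel_bands=32)
        sr = 16000
        center = band_center_hz(band, cfg, sr)
        img = R.compute_mel_spectrogram(tone_clip(center, sr, 0.5), cfg)
        assert np.argmax(img.values.sum(axis=1)) == band

    def test_zero_clip_all_zero(self):
        img = R.compute_mel_spectrogram(R.AudioClip(np.zeros(256), 8000), SMALL)
        assert np.all(img.values == 0)

    def test_too_many_bands_rejected(self):
        with pytest.raises(ValueError):
            mel_filterbank(64, 64, 8000)


# ---------------------------------------------------------------------------
# LM / L2M / L3M chain
# ---------------------------------------------------------------------------

def _img(values, representation="mel"):
    return R.TimeFrequencyImage(np.asarray(values, float), representation, "mel")


class TestLMChain:
    CFG = RepresentationConfig()

    def test_lm_fixed_points(self):
        out = R.compute_lm(_img([[1.0, 100.0, 10.0]]), self.CFG).values
        assert np.allclose(out, [[0.0, 200.0, 100.0]])

    def test_l2m_hand_evaluation(self):
        lm = _img([[0.0, 100.0]], "lm")
        out = R.compute_l2m(lm, self.CFG).values
        assert np.allclose(out, [[100 * np.log10(self.CFG.log_floor), 200.0]])

    def test_constant_input_hits_log_floor_everywhere(self):
        lm = _img(np.full((3, 4), 7.5), "lm")
        out = R.compute_l2m(lm, self.CFG).values
        assert np.allclose(out, 100 * np.log10(self.CFG.log_floor))

    @pytest.mark.parametrize("offset", [-42.0, 0.0, 13.7])
    def test_global_offset_invariance(self, offset):
        rng = np.random.default_rng(3)
        base = rng.uniform(-50, 150, (6, 9))
        for fn, tag in [(R.compute_l2m, "lm"), (R.compute_l3m, "l2m")]:
            a = fn(_img(base, tag), self.CFG).values
            b = fn(_img(base + offset, tag), self.CFG).values
            assert np.allclose(a, b)

    def test_chain_order_enforced(self):
        with pytest.raises(ValueError):
            R.compute_lm(_img([[1.0]], "spectrogram"), self.CFG)
        with pytest.raises(ValueError):
            R.compute_l2m(_img([[1.0]], "mel"), self.CFG)
        with pytest.raises(ValueError):
            R.compute_l3m(_img([[1.0]], "lm"), self.CFG)

    def test_full_chain_finite_on_real_audio(self):
        clip = tone_clip(500, 8000, 0.25)
        lm = R.compute_lm(R.compute_mel_spectrogram(clip, SMALL), SMALL)
        l3m = R.compute_l3m(R.compute_l2m(lm, SMALL), SMALL)
        assert np.all(np.isfinite(l3m.values))


# ---------------------------------------------------------------------------
# MFCC
# ---------------------------------------------------------------------------

class TestMFCC:
    def test_matches_direct_evaluation(self):
        """|IDFT(log(mel(|DFT(frame)|^2) + floor))|^2 by O(N^2) transforms."""
        rng = np.random.default_rng(4)
        x = rng.uniform(-1, 1, 64)
        img = R.compute_mfcc(R.AudioClip(x, 8000), SMALL)

        F = dft_matrix(64)
        power = np.abs(F @ (x * SMALL.window()))[:33] ** 2
        fb = mel_filterbank(SMALL.n_mel_bands, 64, 8000)
        log_mel = np.log(fb @ power + SMALL.log_floor)
        m = SMALL.n_mel_bands
        inv = np.conj(dft_matrix(m)) / m
        ceps = np.abs(inv @ log_mel) ** 2
        direct = ceps[: SMALL.n_mfcc]
        assert np.max(np.abs(img.values[:, 0] - direct)) <= 1e-8 * direct.max()

    def test_zero_clip_columns_identical(self):
        img = R.compute_mfcc(R.AudioClip(np.zeros(256), 8000), SMALL)
        assert np.allclose(img.values, img.values[:, :1])

    def test_gain_change_preserves_frame_ranking(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-0.5, 0.5, 512)
        a = R.compute_mfcc(R.AudioClip(x, 8000), SMALL).values
        b = R.compute_mfcc(R.AudioClip(0.5 * x, 8000), SMALL).values
        assert np.array_equal(np.argsort(a[2]), np.argsort(b[2]))

    def test_too_many_coefficients_rejected(self):
        cfg = RepresentationConfig(n_mel_bands=8, n_mfcc=13)
        with pytest.raises(ValueError):
            R.compute_mfcc(tone_clip(500), cfg)


# ---------------------------------------------------------------------------
# Stockwell
# ---------------------------------------------------------------------------

def stockwell_brute_force(x):
    """O(N^3) time-domain S-transform with periodized Gaussian windows of
    width N/n for voice n."""
    n_samp = len(x)
    d = np.arange(n_samp)
    out = np.zeros((n_samp // 2, n_samp))
    for v in range(1, n_samp // 2 + 1):
        wrap = np.zeros(n_samp)
        for k in range(-8, 9):
            wrap += v / (n_samp * np.sqrt(2 * np.pi)) * np.exp(
                -v**2 * (d + k * n_samp) ** 2 / (2 * n_samp**2))
        phase = np.exp(-2j * np.pi * v * d / n_samp)
        for tau in range(n_samp):
            out[v - 1, tau] = np.abs(np.sum(x * phase * wrap[(tau - d) % n_samp]))
    return out


class TestStockwell:
    NODEC = RepresentationConfig(window_length=8, hop_length=8, fft_length=8,
                                 stockwell_decimation=1)

    def test_matches_time_domain_definition(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(-1, 1, 64)
        img = R.compute_stockwell(R.AudioClip(x, 64), self.NODEC)
        direct = stockwell_brute_force(x)
        assert np.max(np.abs(img.values - direct)) <= 1e-6 * direct.max()

    def test_tone_localised_at_its_voice(self):
        n0, n_samp = 9, 256
        t = np.arange(n_samp)
        img = R.compute_stockwell(
            R.AudioClip(np.sin(2 * np.pi * n0 * t / n_samp), n_samp), self.NODEC)
        interior = img.values[:, n_samp // 4 : 3 * n_samp // 4]
        assert np.all(np.argmax(interior, axis=0) + 1 == n0)

    def test_decimation_applied(self):
        cfg = RepresentationConfig(window_length=8, hop_length=8, fft_length=8,
                                   stockwell_decimation=10)
        clip = tone_clip(100, 16000, 0.1)  # 1600 samples -> 160 decimated
        img = R.compute_stockwell(clip, cfg)
        assert img.values.shape == (80, 160)

    def test_zero_signal_zero_matrix(self):
        img = R.compute_stockwell(R.AudioClip(np.zeros(64), 64), self.NODEC)
        assert np.all(img.values == 0)

    def test_too_short_after_decimation(self):
        cfg = RepresentationConfig(window_length=8, hop_length=8, fft_length=8,
                                   stockwell_decimation=1)
        with pytest.raises(R.ShortSignalError):
            R.compute_stockwell(R.AudioClip(np.zeros(4), 64), cfg)


# ---------------------------------------------------------------------------
# embedding image
# ---------------------------------------------------------------------------

class TestEmbedding:
    def test_deterministic_and_column_count(self):
        emb = StubEmbedder(8000, window_s=0.25)
        clip = tone_clip(300, 8000, 1.0)
        a = R.compute_embedding_image(clip, emb)
        b = R.compute_embedding_image(clip, emb)
        assert a.values.shape == (128, 4)
        assert np.array_equal(a.values, b.values)

    def test_distinct_individuals_distinct_embeddings(self):
        emb = StubEmbedder(8000)
        profiles = [R.make_individual_profile(s, f"i{s}", (150 + 40 * s, 170 + 40 * s))
                    for s in range(2)]
        means = []
        for i, p in enumerate(profiles):
            clip = R.synthesize_roar(p, 0.5, 8000, 25.0, seed=i)
            means.append(R.compute_embedding_image(clip, emb).values.mean(axis=1))
        assert np.linalg.norm(means[0] - means[1]) > 0

    def test_clip_shorter_than_window_rejected(self):
        emb = StubEmbedder(8000, window_s=0.5)
        with pytest.raises(R.ShortSignalError):
            R.compute_embedding_image(R.AudioClip(np.zeros(1000), 8000), emb)


# ---------------------------------------------------------------------------
# scaling and network images
# ---------------------------------------------------------------------------

class TestScaling:
    def test_min_max_extremes(self):
        img = _img(np.arange(11, dtype=float).reshape(1, 11))
        out = R.apply_scaling(img, "min_max").values
        assert out.min() == 0.0 and out.max() == 255.0

    def test_min_max_idempotent(self):
        rng = np.random.default_rng(7)
        img = _img(rng.uniform(-5, 40, (6, 8)))
        once = R.apply_scaling(img, "min_max")
        twice = R.apply_scaling(once, "min_max")
        assert np.allclose(once.values, twice.values)

    def test_db_of_zero_is_minus_160(self):
        out = R.apply_scaling(_img(np.zeros((2, 2))), "db").values
        assert np.allclose(out, -160.0)

    def test_db_rejects_negatives(self):
        with pytest.raises(ValueError):
            R.apply_scaling(_img([[-1.0, 1.0]]), "db")

    def test_box_n_1000_reproduces_mel_normalisation(self):
        img = _img(np.linspace(0.0, 0.025, 12).reshape(3, 4))
        out = R.apply_scaling(img, "box_n", 1000.0).values
        assert out.min() == 0.0 and np.isclose(out.max(), 1000.0)

    def test_constant_matrix_maps_to_zeros(self, caplog):
        with caplog.at_level("WARNING"):
            out = R.apply_scaling(_img(np.full((2, 3), 4.0)), "min_max").values
        assert np.all(out == 0)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            R.apply_scaling(_img([[1.0, 2.0]]), "zscore")

    def test_all_representations_finite_under_all_scalings(self, paper_ds, rep_cfg):
        clip = paper_ds.samples[0].clip
        for name in R.REPRESENTATIONS:
            img = R.extract_representation(clip, name, rep_cfg)
            assert np.all(np.isfinite(img.values)), name
            for mode in ("min_max", "box_n"):
                assert np.all(np.isfinite(R.apply_scaling(img, mode).values))
            if np.all(img.values >= 0):
                assert np.all(np.isfinite(R.apply_scaling(img, "db").values))


class TestNetworkImage:
    def test_identity_path(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 255, (16, 16))
        x[0, 0], x[-1, -1] = 0.0, 255.0
        out = R.to_network_image(_img(x), 16, 16)
        for c in range(3):
            assert np.allclose(out[:, :, c], x)

    def test_constant_maps_to_mid_gray(self, caplog):
        with caplog.at_level("WARNING"):
            out = R.to_network_image(_img(np.full((4, 4), 9.0)), 8, 8)
        assert np.all(out == 127.5)

    def test_checkerboard_downsize_is_block_mean(self):
        x = np.indices((8, 8)).sum(axis=0) % 2 * 255.0
        out = _bilinear_resize(x, 4, 4)
        assert np.allclose(out, 127.5)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            R.to_network_image(_img(np.zeros((1, 5))), 8, 8)


def test_unknown_representation_name():
    with pytest.raises(ValueError, match="spectrogram"):
        R.extract_representation(tone_clip(200), "cqt")
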