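"""Morse filter bank, CWT scalograms and image conversion."""

import numpy as np
import pytest
from PIL import Image

from cspcwt.csp import csp_fit
from cspcwt.io_gal import EVENT_NAMES, EpochSet
from cspcwt.scalogram import (
    MorseBankSpec,
    Scalogram,
    build_morse_bank,
    cwt_scalogram,
    make_dataset,
    morse_freq_domain,
    resize_bicubic,
    stack_rgb,
    to_grayscale,
)


class TestMorseBank:
    def test_mother_peak_frequency(self):
        spec = MorseBankSpec()
        expected = (20.0 / 3.0) ** (1.0 / 3.0)
        assert abs(spec.peak_omega - expected) < 1e-12
        # the frequency response indeed peaks there
        omega = np.linspace(0.01, np.pi, 20_000)
        resp = morse_freq_domain(omega, spec.gamma, spec.beta)
        assert abs(omega[np.argmax(resp)] - expected) < 1e-3

    def test_standard_window_gives_69_scales(self, default_bank):
        assert default_bank.n_scales == 69
        assert len(default_bank.frequencies) == 69
        assert np.all(np.diff(default_bank.frequencies) < 0)

    def test_longer_window_extends_long_scale_end_only(self, default_bank):
        double = build_morse_bank(MorseBankSpec(n_samples=800))
        assert double.n_scales > default_bank.n_scales
        assert np.allclose(double.scales[: default_bank.n_scales],
                           default_bank.scales)

    def test_analyticity(self, default_bank):
        filters = default_bank.filters(512)
        omega = 2 * np.pi * np.fft.fftfreq(512)
        assert not filters[:, omega <= 0].any()

    def test_too_short_signal_rejected(self):
        with pytest.raises(ValueError):
            build_morse_bank(MorseBankSpec(n_samples=16))


class TestCWT:
    def test_zero_in_zero_out(self, default_bank):
        sg = cwt_scalogram(np.zeros(400), default_bank)
        assert sg.magnitudes.shape == (69, 400)
        assert not sg.magnitudes.any()

    def test_tone_peaks_at_nearest_center_frequency(self, default_bank):
        t = np.arange(400) / 500.0
        sg = cwt_scalogram(np.sin(2 * np.pi * 15.0 * t), default_bank)
        row = sg.magnitudes[:, 100:300].sum(axis=1).argmax()
        nearest = np.abs(default_bank.frequencies - 15.0).argmin()
        assert row == nearest

    def test_homogeneity(self, default_bank, rng):
        x = rng.normal(size=400)
        a = cwt_scalogram(x, default_bank).magnitudes
        b = cwt_scalogram(-2.5 * x, default_bank).magnitudes
        assert np.allclose(b, 2.5 * a, rtol=1e-9, atol=1e-12)

    def test_matches_naive_circular_convolution(self, rng):
        """FFT-based CWT equals an explicit O(N^2) DFT evaluation."""
        bank = build_morse_bank(MorseBankSpec(n_samples=64))
        x = rng.normal(size=64)
        sg = cwt_scalogram(x, bank)
        pad = 32
        xp = np.concatenate([x[pad:0:-1], x, x[-2 : -pad - 2 : -1]])
        n_fft = 128
        k = np.arange(n_fft)
        dft = np.exp(-2j * np.pi * np.outer(k, k) / n_fft)
        X = dft @ xp
        omega = 2 * np.pi * np.fft.fftfreq(n_fft)
        for si in np.linspace(5, bank.n_scales - 5, 5, dtype=int):
            resp = morse_freq_domain(bank.scales[si] * omega, 3.0, 20.0)
            coeff = dft.conj().T @ (X * resp) / n_fft
            ref = np.abs(coeff[pad : pad + 64])
            err = np.linalg.norm(ref - sg.magnitudes[si])
            assert err / np.linalg.norm(ref) < 1e-6

    def test_band_limited_energy_stays_in_band(self, default_bank, rng):
        from scipy import signal as sps

        sos = sps.butter(4, [7, 30], btype="bandpass", fs=500, output="sos")
        x = sps.sosfilt(sos, rng.standard_normal(2000))[-400:]
        sg = cwt_scalogram(x, default_bank)
        energy = (sg.magnitudes**2).sum(axis=1)
        inband = (default_bank.frequencies >= 5) & (default_bank.frequencies <= 35)
        assert energy[inband].sum() / energy.sum() >= 0.90

    def test_length_mismatch_rejected(self, default_bank):
        with pytest.raises(ValueError):
            cwt_scalogram(np.zeros(399), default_bank)


class TestImages:
    def test_grayscale_mapping(self):
        sg = Scalogram(
            magnitudes=np.array([[0.0, 1.0], [0.5, 0.25]]),
            scales=np.ones(2), frequencies=np.ones(2),
        )
        assert to_grayscale(sg).tolist() == [[0, 255], [128, 64]]

    def test_constant_scalogram_maps_to_zero(self):
        sg = Scalogram(magnitudes=np.full((3, 4), 7.0),
                       scales=np.ones(3), frequencies=np.ones(3))
        assert not to_grayscale(sg).any()

    def test_grayscale_monotone_and_bounded(self, rng):
        m = rng.uniform(size=(20, 30))
        g = to_grayscale(Scalogram(m, np.ones(20), np.ones(20)))
        order = np.argsort(m.ravel())
        assert np.all(np.diff(g.ravel()[order].astype(int)) >= 0)
        assert g.min() >= 0 and g.max() <= 255

    def test_resize_shapes(self, rng):
        img = rng.integers(0, 256, size=(69, 400)).astype(np.uint8)
        out = resize_bicubic(img)
        assert out.shape == (224, 224)
        assert out.dtype == np.uint8

    def test_resize_preserves_constants_and_identity(self, rng):
        const = np.full((69, 400), 77, dtype=np.uint8)
        assert np.all(resize_bicubic(const) == 77)
        same = rng.integers(0, 256, size=(224, 224)).astype(np.uint8)
        assert np.abs(resize_bicubic(same).astype(int) - same.astype(int)).max() <= 1

    def test_resize_rejects_tiny_source(self):
        with pytest.raises(ValueError):
            resize_bicubic(np.zeros((3, 3), dtype=np.uint8))

    def test_rgb_stack_round_trip(self, rng):
        planes = [rng.integers(0, 256, size=(224, 224)).astype(np.uint8)
                  for _ in range(3)]
        rgb = stack_rgb(*planes)
        assert rgb.shape == (224, 224, 3)
        for i, p in enumerate(planes):
            assert np.array_equal(rgb[..., i], p)
        gray = stack_rgb(planes[0], planes[0], planes[0])
        assert np.array_equal(gray[..., 0], gray[..., 1])


class TestMakeDataset:
    def _models_and_epochs(self, rng, n_windows=3):
        epochs, labels = [], []
        for i in range(n_windows):
            epochs.append(rng.normal(size=(6, 400)))
            labels.append(i % 6)
        ep = EpochSet(
            epochs=np.stack(epochs), labels=np.array(labels),
            window_length=400, step=400,
            channel_names=["C3", "Cz", "C4", "P3", "Pz", "P4"],
            starts=np.arange(n_windows) * 400,
        )
        e1 = [rng.normal(size=(6, 50)) for _ in range(3)]
        e2 = [rng.normal(size=(6, 50)) for _ in range(3)]
        models = {name: csp_fit(e1, e2, contrast=(name, "rest"))
                  for name in EVENT_NAMES}
        return models, ep

    def test_counting_contract(self, rng, default_bank, tmp_path):
        models, ep = self._models_and_epochs(rng)
        ds = make_dataset(models, ep, default_bank, out_dir=tmp_path)
        assert len(ds) == 3 * 6 * 2
        assert ds.images.shape == (36, 224, 224, 3)
        for _, row in ds.manifest.iterrows():
            img = np.asarray(Image.open(row["path"]))
            assert img.shape == (224, 224, 3)
        assert (tmp_path / "manifest.csv").exists()

    def test_binary_labels_follow_contrast(self, rng, default_bank):
        models, ep = self._models_and_epochs(rng)
        ds = make_dataset({"GS": models["GS"]}, ep, default_bank)
        by_window = ds.manifest.groupby("window_start")["label"].first()
        assert by_window.tolist() == [0, 1, 0]  # labels are 0,1,2 -> GS is idx 1

    def test_empty_epoch_set_gives_empty_manifest(self, rng, default_bank):
        models, ep = self._models_and_epochs(rng)
        empty = EpochSet(
            epochs=np.empty((0, 6, 400)), labels=np.empty(0, dtype=int),
            window_length=400, step=400, channel_names=ep.channel_names,
        )
        ds = make_dataset(models, empty, default_bank)
        assert len(ds) == 0
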