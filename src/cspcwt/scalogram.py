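"""Morse-wavelet scalograms and their conversion to CNN-ready RGB images.

A generalized Morse wavelet with symmetry γ = 3 and time-bandwidth product
P² = 60 (so β = P²/γ = 20) is used as an analytic filter bank over a
geometric scale grid with 10 voices per octave.  The scale bounds follow an
energy-spread rule: the smallest scale places the wavelet's peak frequency at
Nyquist, and the largest scale is limited so that a fixed number of wavelet
time standard deviations fits in the analysis window.  The cutoff constant of
that rule is calibrated so a 400-sample window at 500 Hz yields a 69 x 400
scalogram, and then frozen.

Scalogram magnitudes are min-max quantized to 8-bit grayscale, resized to
224 x 224 with bicubic interpolation (no antialias filter), and stacked in
electrode triads — (C3, Cz, C4) and (P3, Pz, P4) — into RGB composites.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from .csp import CSPModel, csp_project
from .io_gal import EpochSet

#: Frozen cutoff constant of the max-scale rule: s_max = n_samples / (K · σ_t).
#: Calibrated once so that (n=400, fs=500, γ=3, P²=60, 10 voices) gives 69 scales.
SCALE_CUTOFF_K = 1.98

#: Target side length of classifier input images.
IMAGE_SIZE = 224

#: Electrode triads mapped to RGB planes (R, G, B order within each triad).
TRIADS: dict[str, tuple[str, str, str]] = {
    "motor": ("C3", "Cz", "C4"),
    "parietal": ("P3", "Pz", "P4"),
}


class BankError(ValueError):
    """The signal is too short to support even one octave of scales."""


@dataclass(frozen=True)
class MorseBankSpec:
    """Morse filter bank parameters; ``beta = P2 / gamma``."""

    gamma: float = 3.0
    P2: float = 60.0
    voices_per_octave: int = 10
    fs: float = 500.0
    n_samples: int = 400

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.P2 <= self.gamma:
            raise ValueError("need gamma > 0 and P2 > gamma (beta > 1)")
        if self.n_samples < 32:
            raise BankError("need at least 32 samples for a filter bank")

    @property
    def beta(self) -> float:
        return self.P2 / self.gamma

    @property
    def peak_omega(self) -> float:
        """Peak angular frequency of the mother wavelet, (β/γ)^(1/γ) rad/sample."""
        return (self.beta / self.gamma) ** (1.0 / self.gamma)


def morse_freq_domain(omega: np.ndarray, gamma: float, beta: float) -> np.ndarray:
    """Frequency response a·ω^β·e^{-ω^γ} of the analytic Morse wavelet (ω ≥ 0).

    Normalized to peak value 2 (the usual analytic-wavelet convention); the
    response is identically zero for ω ≤ 0.
    """
    omega = np.asarray(omega, dtype=float)
    out = np.zeros_like(omega)
    pos = omega > 0
    amp = 2.0 * (np.e * gamma / beta) ** (beta / gamma)
    with np.errstate(over="ignore"):
        out[pos] = amp * omega[pos] ** beta * np.exp(-(omega[pos] ** gamma))
    return out


def morse_time_std(gamma: float, beta: float, n_grid: int = 2**16, dw: float = 0.002) -> float:
    """Time-domain standard deviation (in samples at unit scale) of the wavelet.

    Computed numerically as the energy spread of |ψ(t)|² obtained by inverse
    Fourier transform of the frequency response on a dense grid.
    """
    w = np.arange(n_grid) * dw
    psi_hat = morse_freq_domain(w, gamma, beta)
    psi_t = np.fft.ifft(psi_hat) * (n_grid * dw / (2 * np.pi))
    dt = 2 * np.pi / (n_grid * dw)
    t = np.arange(n_grid) * dt
    t[t > t[-1] / 2] -= n_grid * dt
    energy = np.abs(psi_t) ** 2
    tbar = (t * energy).sum() / energy.sum()
    return float(np.sqrt((((t - tbar) ** 2) * energy).sum() / energy.sum()))


@dataclass
class WaveletFilterBank:
    """Analytic Morse filters on a geometric scale grid."""

    spec: MorseBankSpec
    scales: np.ndarray
    frequencies: np.ndarray  # center frequencies in Hz, descending with row
    _sigma_t: float = field(repr=False, default=0.0)

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def filters(self, n_fft: int) -> np.ndarray:
        """(n_scales, n_fft) frequency responses on the DFT grid; zero at ω ≤ 0."""
        omega = 2 * np.pi * np.fft.fftfreq(n_fft)
        return np.stack(
            [morse_freq_domain(s * omega, self.spec.gamma, self.spec.beta)
             for s in self.scales]
        )


def build_morse_bank(spec: MorseBankSpec = MorseBankSpec()) -> WaveletFilterBank:
    """Build the scale grid from the energy-spread rule and return the bank.

    ``s_min = ω_peak / π`` (peak response at Nyquist); ``s_max = n / (K·σ_t)``
    with the frozen calibration constant :data:`SCALE_CUTOFF_K`; scale count is
    ``floor(voices · log2(s_max/s_min)) + 1``.  Row 0 is the smallest scale
    (highest frequency).
    """
    sigma_t = morse_time_std(spec.gamma, spec.beta)
    s_min = spec.peak_omega / np.pi
    s_max = spec.n_samples / (SCALE_CUTOFF_K * sigma_t)
    if s_max < 2 * s_min:
        raise BankError(
            f"window of {spec.n_samples} samples supports no full octave of scales"
        )
    n_scales = int(np.floor(spec.voices_per_octave * np.log2(s_max / s_min))) + 1
    scales = s_min * 2.0 ** (np.arange(n_scales) / spec.voices_per_octave)
    freqs = spec.peak_omega / scales * spec.fs / (2 * np.pi)
    return WaveletFilterBank(spec=spec, scales=scales, frequencies=freqs, _sigma_t=sigma_t)


@dataclass
class Scalogram:
    """Nonnegative |CWT| magnitudes over (scale, time)."""

    magnitudes: np.ndarray
    scales: np.ndarray
    frequencies: np.ndarray


def cwt_scalogram(segment: np.ndarray, bank: WaveletFilterBank) -> Scalogram:
    """Continuous wavelet transform magnitudes of one real segment.

    Computed by frequency-domain multiplication with each bank filter after
    reflection padding (to soften circular wrap-around at the window edges).
    """
    segment = np.asarray(segment, dtype=float).ravel()
    n = bank.spec.n_samples
    if len(segment) != n:
        raise ValueError(f"segment length {len(segment)} does not match bank ({n})")
    pad = n // 2
    padded = np.concatenate([segment[pad:0:-1], segment, segment[-2 : -pad - 2 : -1]])
    n_fft = int(2 ** np.ceil(np.log2(len(padded))))
    X = np.fft.fft(padded, n_fft)
    coeff = np.fft.ifft(X[None, :] * bank.filters(n_fft), axis=1)
    mags = np.abs(coeff[:, pad : pad + n])
    return Scalogram(magnitudes=mags, scales=bank.scales, frequencies=bank.frequencies)


def to_grayscale(sg: Scalogram, lo: float | None = None,
                 hi: float | None = None) -> np.ndarray:
    """Min-max quantize magnitudes to uint8; a constant range maps to 0.

    By default the range is the image's own min/max; pass ``lo``/``hi`` to
    share one range across several scalograms (e.g. the six CSP components of
    one window) so that their relative amplitudes survive quantization.
    Round-half-up is used so the mapping is deterministic across platforms.
    """
    m = sg.magnitudes if isinstance(sg, Scalogram) else np.asarray(sg, dtype=float)
    lo = m.min() if lo is None else lo
    hi = m.max() if hi is None else hi
    if hi == lo:
        return np.zeros(m.shape, dtype=np.uint8)
    scaled = np.clip((m - lo) / (hi - lo), 0.0, 1.0) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)


def resize_bicubic(img: np.ndarray, size: int = IMAGE_SIZE) -> np.ndarray:
    """Bicubic resize of a grayscale image to ``size`` x ``size`` (uint8).

    Pure spline interpolation (no antialias prefilter), values clipped to
    [0, 255].
    """
    img = np.asarray(img)
    if img.shape[0] < 4 or img.shape[1] < 4:
        raise ValueError(f"source image {img.shape} too small for bicubic resize")
    out = _sk_resize(
        img.astype(float), (size, size), order=3, anti_aliasing=False,
        preserve_range=True, mode="edge",
    )
    return np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)


def stack_rgb(img_r: np.ndarray, img_g: np.ndarray, img_b: np.ndarray) -> np.ndarray:
    """Stack three grayscale planes into an RGB image (losslessly separable)."""
    if not (img_r.shape == img_g.shape == img_b.shape):
        raise ValueError("RGB planes must share one shape")
    return np.stack([img_r, img_g, img_b], axis=-1)


@dataclass
class ImageDataset:
    """RGB scalogram images plus their provenance manifest.

    ``images`` is (n, 224, 224, 3) uint8; ``manifest`` has one row per image
    with columns path, contrast, label, subject, series, window_start, triad.
    ``path`` is empty when images were kept in memory only.
    """

    images: np.ndarray
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.manifest)


def _window_images(model: CSPModel, window: np.ndarray, bank: WaveletFilterBank,
                   channel_names: list[str],
                   normalization: str = "per-window") -> dict[str, np.ndarray]:
    """Two triad RGB images for one window under one CSP contrast.

    Row i of the projected components Z is identified with electrode i of the
    input ordering, so triads address Z rows through the channel-name list.
    With ``normalization="per-window"`` all component scalograms of the window
    share one grayscale range, preserving the between-component variance
    contrast that CSP produces; ``"per-image"`` scales each independently.
    """
    Z = csp_project(model, window)
    sgs = [cwt_scalogram(Z[i], bank) for i in range(len(channel_names))]
    if normalization == "per-window":
        lo = min(s.magnitudes.min() for s in sgs)
        hi = max(s.magnitudes.max() for s in sgs)
    elif normalization == "per-image":
        lo = hi = None
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    grays = {
        name: resize_bicubic(to_grayscale(sg, lo, hi))
        for name, sg in zip(channel_names, sgs)
    }
    return {
        triad: stack_rgb(*(grays[ch] for ch in chans))
        for triad, chans in TRIADS.items()
        if all(ch in grays for ch in chans)
    }


def make_dataset(
    models: dict[str, CSPModel],
    epochs: EpochSet,
    bank: WaveletFilterBank,
    out_dir: str | os.PathLike | None = None,
    subject: str = "",
    series: str = "",
    normalization: str = "per-window",
) -> ImageDataset:
    """Render the full image set: every window under every one-vs-rest contrast.

    For each contrast and window, the window is CSP-projected, each component
    row is transformed to a 69 x 400 scalogram, quantized, resized to 224 x 224,
    and the motor and parietal triads stacked into two RGB images.  The binary
    label is 1 when the window's event equals the contrast event.  With
    ``out_dir`` set, images are written as PNG and the manifest carries their
    paths; otherwise images stay in memory.
    """
    from .io_gal import EVENT_NAMES

    rows, imgs = [], []
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    for contrast, model in models.items():
        event_idx = EVENT_NAMES.index(contrast)
        for w, start in enumerate(
            epochs.starts if len(epochs.starts) else range(epochs.n_epochs)
        ):
            window = epochs.epochs[w]
            label = int(epochs.labels[w] == event_idx)
            for triad, rgb in _window_images(
                model, window, bank, epochs.channel_names, normalization
            ).items():
                path = ""
                if out_dir is not None:
                    path = os.path.join(
                        out_dir, f"{contrast}_{triad}_w{int(start):07d}.png"
                    )
                    Image.fromarray(rgb, mode="RGB").save(path)
                rows.append(
                    dict(path=path, contrast=contrast, label=label, subject=subject,
                         series=series, window_start=int(start), triad=triad,
                         norm=normalization)
                )
                imgs.append(rgb)
    images = (np.stack(imgs) if imgs
              else np.empty((0, IMAGE_SIZE, IMAGE_SIZE, 3), dtype=np.uint8))
    manifest = pd.DataFrame(
        rows, columns=["path", "contrast", "label", "subject", "series",
                       "window_start", "triad", "norm"],
    )
    if out_dir is not None:
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return ImageDataset(images=images, manifest=manifest)
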