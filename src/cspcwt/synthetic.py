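"""Synthetic multichannel EEG with class-specific spatial structure.

Each grasp-and-lift event is emulated as a block of band-limited Gaussian
sources (center frequencies inside the 7-30 Hz µ/β band) mixed into six
channels by a fixed full-rank spatial mixing matrix; events differ by which
source carries high variance, which is exactly the structure CSP is designed
to recover.  Typical EEG artifacts are added on top: eye-blink bursts
(< 4 Hz), a periodic ~1.2 Hz heartbeat waveform, a 60 Hz mains sinusoid and
band-limited muscle noise (> 30 Hz).  Sources are shaped by generator-internal
4th-order Butterworth filters so that tests of the analysis band-pass filter
are not circular.

Within every trial the six events occur in their natural sequential order
HS → GS → LT → HD → RP → RL, with block durations drawn uniformly from
0.8-2.0 s and short event-free gaps between trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .io_gal import EEGRecording, EventAnnotations, EVENT_NAMES


class ScenarioError(ValueError):
    """The scenario is inconsistent (e.g. singular mixing matrix)."""


@dataclass(frozen=True)
class ArtifactToggles:
    """Artifact amplitudes (same units as the mixed sources); 0 disables."""

    blink: float = 0.0
    heartbeat: float = 0.0
    line: float = 0.0
    muscle: float = 0.0

    def any_on(self) -> bool:
        return any((self.blink, self.heartbeat, self.line, self.muscle))


@dataclass
class SimScenario:
    """Full description of one synthetic recording session."""

    mixing: np.ndarray  # (6, 6) spatial mixing, sources -> channels
    source_freqs: np.ndarray  # center frequency (Hz) per source
    source_bandwidths: np.ndarray  # bandwidth (Hz) per source
    class_variances: np.ndarray  # (6 events, 6 sources) source variances
    artifacts: ArtifactToggles = field(default_factory=ArtifactToggles)
    noise_sd: float = 0.1
    fs: float = 500.0
    n_trials: int = 20
    block_duration_s: tuple[float, float] = (0.8, 2.0)
    gap_duration_s: tuple[float, float] = (0.4, 0.8)
    amplitude_uv: float = 10.0  # overall output scale, µV per unit source SD
    seed: int = 0

    def __post_init__(self) -> None:
        self.mixing = np.asarray(self.mixing, dtype=float)
        n = self.mixing.shape[0]
        if self.mixing.shape != (n, n) or np.linalg.matrix_rank(self.mixing) < n:
            raise ScenarioError("mixing matrix must be square and full rank")
        nyq = self.fs / 2
        if not np.all((0 < np.asarray(self.source_freqs))
                      & (np.asarray(self.source_freqs) < nyq)):
            raise ScenarioError("source center frequencies must lie in (0, fs/2)")

    @property
    def n_channels(self) -> int:
        return self.mixing.shape[0]

    def planted_direction(self, event: str | int) -> np.ndarray:
        """Unit spatial filter that isolates the event-discriminative source.

        For X = A·S the filter extracting source k is row k of A⁻¹; the
        standard scenarios put the variance contrast on source k for event k,
        so this is the direction a perfect CSP fit should recover.
        """
        k = EVENT_NAMES.index(event) if isinstance(event, str) else int(event)
        w = np.linalg.inv(self.mixing)[k]
        return w / np.linalg.norm(w)


def standard_scenario(separation: str = "strong", seed: int = 0, **overrides) -> SimScenario:
    """Canonical six-event scenario for pipeline tests.

    Event k boosts the variance of source k (ratio 10:1 for ``strong``,
    1.5:1 for ``weak``) against a flat background; source center frequencies
    span the µ/β band.  Artifacts default to on at moderate amplitudes.
    """
    ratios = {"strong": 10.0, "weak": 1.5}
    if separation not in ratios:
        raise ScenarioError(f"separation must be one of {sorted(ratios)}")
    rng = np.random.default_rng(seed)
    # well-conditioned random mixing: orthogonal basis plus mild anisotropy
    q, _ = np.linalg.qr(rng.normal(size=(6, 6)))
    mixing = q * rng.uniform(0.8, 1.25, size=6)
    variances = np.ones((6, 6))
    np.fill_diagonal(variances, ratios[separation])
    params = dict(
        mixing=mixing,
        source_freqs=np.array([9.0, 12.0, 15.0, 18.0, 21.0, 25.0]),
        source_bandwidths=np.full(6, 3.0),
        class_variances=variances,
        artifacts=ArtifactToggles(blink=3.0, heartbeat=1.0, line=1.5, muscle=0.5),
        noise_sd=0.1,
        seed=seed,
    )
    params.update(overrides)
    return SimScenario(**params)


def _band_source(n: int, f0: float, bw: float, fs: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-passed around f0 (4th-order Butterworth)."""
    lo = max(0.5, f0 - bw / 2)
    hi = min(fs / 2 - 1, f0 + bw / 2)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    # pad to let the filter settle, then trim
    pad = int(fs)
    x = signal.sosfilt(sos, rng.standard_normal(n + pad))[pad:]
    sd = x.std()
    return x / sd if sd > 0 else x


def _blink_waveform(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Sparse smoothed pulses ~0.4 s wide (spectral content below ~4 Hz)."""
    out = np.zeros(n)
    width = int(0.4 * fs)
    rate_hz = 0.25  # about one blink every four seconds
    n_blinks = rng.poisson(rate_hz * n / fs)
    bump = np.hanning(width)
    for _ in range(n_blinks):
        start = rng.integers(0, max(1, n - width))
        out[start : start + width] += bump[: n - start] * rng.uniform(0.7, 1.3)
    return out


def _heartbeat_waveform(n: int, fs: float, rng: np.random.Generator,
                        rate_hz: float = 1.2) -> np.ndarray:
    """Periodic train of narrow Gaussian pulses at the heartbeat rate."""
    t = np.arange(n) / fs
    period = 1.0 / rate_hz
    phase = rng.uniform(0, period)
    out = np.zeros(n)
    beat = phase
    while beat < t[-1] + period:
        out += np.exp(-0.5 * ((t - beat) / 0.04) ** 2)
        beat += period
    return out


def _muscle_waveform(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited (>30 Hz) noise emulating EMG contamination."""
    sos = signal.butter(4, [35.0, min(120.0, fs / 2 - 1)], btype="bandpass",
                        fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def inject_artifacts(rec: EEGRecording, toggles: ArtifactToggles,
                     rng: np.random.Generator | None = None) -> EEGRecording:
    """Add the enabled artifact components to every channel (additive only).

    Each artifact has a fixed per-channel topography drawn from ``rng`` so
    the contamination is spatially coherent, as real artifacts are.
    """
    if not toggles.any_on():
        return rec
    rng = np.random.default_rng(0) if rng is None else rng
    n = rec.n_samples
    data = rec.data.copy()

    def spread() -> np.ndarray:
        return rng.uniform(0.5, 1.0, size=rec.n_channels)

    if toggles.blink:
        data += toggles.blink * np.outer(spread(), _blink_waveform(n, rec.fs, rng))
    if toggles.heartbeat:
        data += toggles.heartbeat * np.outer(spread(), _heartbeat_waveform(n, rec.fs, rng))
    if toggles.line:
        t = np.arange(n) / rec.fs
        wave = np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
        data += toggles.line * np.outer(spread(), wave)
    if toggles.muscle:
        data += toggles.muscle * np.outer(spread(), _muscle_waveform(n, rec.fs, rng))
    return replace(rec, data=data)


def generate(scenario: SimScenario) -> tuple[EEGRecording, EventAnnotations]:
    """Synthesize a full recording with per-sample event annotations.

    Trials are laid out sequentially; within each trial the six events occupy
    contiguous blocks in the order HS, GS, LT, HD, RP, RL, separated from the
    next trial by an event-free gap during which every source has baseline
    unit variance.  Fully deterministic for a fixed scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    fs = scenario.fs
    n_events = len(EVENT_NAMES)

    # lay out the block schedule first: (event index or -1 for gap, length)
    schedule: list[tuple[int, int]] = []
    for _ in range(scenario.n_trials):
        for k in range(n_events):
            schedule.append(
                (k, int(round(rng.uniform(*scenario.block_duration_s) * fs)))
            )
        schedule.append(
            (-1, int(round(rng.uniform(*scenario.gap_duration_s) * fs)))
        )
    total = sum(n for _, n in schedule)

    # sources run continuously over the whole recording; the class-specific
    # variance enters as a smoothed per-block gain, so block transitions do not
    # inject the broadband power that hard splices would
    S = np.stack(
        [
            _band_source(total, f, bw, fs, rng)
            for f, bw in zip(scenario.source_freqs, scenario.source_bandwidths)
        ]
    )
    gains = np.ones((len(scenario.source_freqs), total))
    labels = np.zeros((n_events, total), dtype=np.int8)
    pos = 0
    for event, n in schedule:
        if event >= 0:
            gains[:, pos : pos + n] = np.sqrt(
                scenario.class_variances[event]
            )[:, None]
            labels[event, pos : pos + n] = 1
        pos += n
    ramp = int(round(0.04 * fs))  # ~40 ms raised-cosine power transitions
    if ramp > 1:
        kernel = np.hanning(ramp)
        kernel /= kernel.sum()
        gains = np.apply_along_axis(
            lambda g: np.convolve(g, kernel, mode="same"), 1, gains
        )
    data = scenario.mixing @ (S * gains)
    if scenario.noise_sd > 0:
        data = data + scenario.noise_sd * rng.standard_normal(data.shape)
    rec = EEGRecording(
        data=scenario.amplitude_uv * data,
        fs=fs,
        channel_names=["C3", "Cz", "C4", "P3", "Pz", "P4"][: scenario.n_channels],
        subject_id="sim",
        series_id=f"seed{scenario.seed}",
    )
    rec = inject_artifacts(
        rec,
        replace(
            scenario.artifacts,
            **{
                k: getattr(scenario.artifacts, k) * scenario.amplitude_uv
                for k in ("blink", "heartbeat", "line", "muscle")
            },
        ),
        rng,
    )
    return rec, EventAnnotations(labels=labels)
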