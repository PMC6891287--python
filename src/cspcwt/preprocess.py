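"""Equiripple FIR band-pass filtering to the 7-30 Hz µ/β band and z-scoring.

The band-pass keeps the sensorimotor µ (8-13 Hz) and β (13-30 Hz) rhythms
while rejecting the main EEG artifact bands: eye blinks (<4 Hz), heartbeat
(~1.2 Hz), 60 Hz mains and muscle activity (>30 Hz).  Stopbands are at 5 and
33 Hz with 65 dB attenuation; the passband ripple defaults to 0.5 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal


class DesignError(ValueError):
    """The filter specification is infeasible or the design did not converge."""


class DegenerateChannelError(ValueError):
    """A channel has zero variance and cannot be z-scored."""


@dataclass(frozen=True)
class BandpassSpec:
    """Band edges (Hz), stopband attenuation and passband ripple (dB)."""

    f_pass_lo: float = 7.0
    f_pass_hi: float = 30.0
    f_stop_lo: float = 5.0
    f_stop_hi: float = 33.0
    stop_atten_db: float = 65.0
    pass_ripple_db: float = 0.5
    fs: float = 500.0

    def __post_init__(self) -> None:
        if not (0 < self.f_stop_lo < self.f_pass_lo < self.f_pass_hi
                < self.f_stop_hi < self.fs / 2):
            raise DesignError(
                "band edges must satisfy 0 < f_stop_lo < f_pass_lo < f_pass_hi "
                "< f_stop_hi < fs/2"
            )
        if self.stop_atten_db <= 0 or self.pass_ripple_db <= 0:
            raise DesignError("attenuation and ripple must be positive")


def _estimate_order(spec: BandpassSpec) -> int:
    # Bellanger's estimate from the narrower transition band, rounded up to even
    # (type-I linear phase).
    delta_p = (10 ** (spec.pass_ripple_db / 20) - 1) / (10 ** (spec.pass_ripple_db / 20) + 1)
    delta_s = 10 ** (-spec.stop_atten_db / 20)
    df = min(spec.f_pass_lo - spec.f_stop_lo, spec.f_stop_hi - spec.f_pass_hi)
    n = 2.0 / 3.0 * np.log10(1.0 / (10.0 * delta_p * delta_s)) * spec.fs / df
    order = int(np.ceil(n))
    return order + order % 2


def measure_response(h: np.ndarray, freqs_hz: np.ndarray, fs: float) -> np.ndarray:
    """Magnitude response in dB of FIR taps ``h`` at the given frequencies."""
    _, resp = signal.freqz(h, worN=2 * np.pi * np.asarray(freqs_hz) / fs)
    return 20 * np.log10(np.maximum(np.abs(resp), 1e-300))


def _meets_spec(h: np.ndarray, spec: BandpassSpec, n_probes: int = 64) -> bool:
    stop = np.concatenate(
        [
            np.linspace(0.05, spec.f_stop_lo, n_probes),
            np.linspace(spec.f_stop_hi, spec.fs / 2 * 0.999, n_probes),
        ]
    )
    band = np.linspace(spec.f_pass_lo, spec.f_pass_hi, n_probes)
    if measure_response(h, stop, spec.fs).max() > -spec.stop_atten_db:
        return False
    pass_db = measure_response(h, band, spec.fs)
    return bool(np.all(np.abs(pass_db) <= spec.pass_ripple_db))


def design_bandpass(spec: BandpassSpec = BandpassSpec()) -> np.ndarray:
    """Design the linear-phase equiripple band-pass FIR for ``spec``.

    The order is estimated from the spec, the filter designed by the
    Parks-McClellan exchange, and the measured response verified against the
    stopband/passband constraints; the order is grown until the measured
    response meets them.  Returns the (odd-length, symmetric) tap vector.
    """
    delta_p = (10 ** (spec.pass_ripple_db / 20) - 1) / (10 ** (spec.pass_ripple_db / 20) + 1)
    delta_s = 10 ** (-spec.stop_atten_db / 20)
    bands = [0, spec.f_stop_lo, spec.f_pass_lo, spec.f_pass_hi, spec.f_stop_hi, spec.fs / 2]
    order = _estimate_order(spec)
    for _ in range(12):
        h = signal.remez(
            order + 1,
            bands,
            [0, 1, 0],
            weight=[1 / delta_s, 1 / delta_p, 1 / delta_s],
            fs=spec.fs,
        )
        if _meets_spec(h, spec):
            return h
        order += max(2, int(0.08 * order) * 2 // 2 * 2)
    raise DesignError("equiripple design failed to meet the specification")


def apply_bandpass(rec, h: np.ndarray):
    """Filter every channel, compensating the (L-1)/2-sample group delay.

    The output is time-aligned with the input and of equal length; the final
    (L-1)/2 samples are zero-padded.  Causal FIR filtering is used (not
    forward-backward), so the realized response equals the designed one.
    """
    L = len(h)
    if rec.n_samples <= 3 * L:
        raise ValueError(
            f"signal of {rec.n_samples} samples too short for filter of length {L}"
        )
    delay = (L - 1) // 2
    padded = np.concatenate([rec.data, np.zeros((rec.n_channels, delay))], axis=1)
    out = signal.lfilter(h, 1.0, padded, axis=1)[:, delay:]
    return replace(rec, data=out)


def zscore_normalize(rec):
    """Z-score each channel over the whole recording (mean 0, SD 1)."""
    mean = rec.data.mean(axis=1, keepdims=True)
    sd = rec.data.std(axis=1, keepdims=True)
    dead = np.flatnonzero(sd[:, 0] == 0)
    if dead.size:
        names = [rec.channel_names[i] for i in dead]
        raise DegenerateChannelError(f"constant channel(s) cannot be normalized: {names}")
    return replace(rec, data=(rec.data - mean) / sd)
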