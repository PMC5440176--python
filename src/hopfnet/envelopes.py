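"""Carrier-band amplitude envelopes of regions x time signals.

The analysis chain mirrors standard resting-state MEG envelope processing:

1. zero-phase band-pass into a narrow carrier band [f-2, f+2] Hz;
2. Hilbert transform -> instantaneous amplitude A(t) and carrier phase;
3. zero-phase low-pass of A(t) at 0.2 Hz -> the ultra-slow envelope
   component that carries meaningful long-range correlations;
4. decimation of the slow arrays to a low analysis rate (default 5 Hz);
5. per-region demeaning + a second Hilbert transform -> envelope phases.

The same code path serves empirical source-space matrices and simulated
signals.  Filters are 4th-order Butterworth applied forward-backward
(sosfiltfilt); one second of data is discarded at each edge after every
filter/Hilbert stage to keep transform edge artifacts out of the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ValidationError

LOWPASS_CUTOFF = 0.2  # Hz; ultra-slow envelope component


@dataclass(frozen=True)
class CarrierBand:
    """Narrow carrier band [f_carrier - half_width, f_carrier + half_width] Hz."""

    f_carrier: float
    half_width: float = 2.0

    @property
    def low(self) -> float:
        return self.f_carrier - self.half_width

    @property
    def high(self) -> float:
        return self.f_carrier + self.half_width

    def validate(self, rate: float) -> None:
        if self.low <= 0:
            raise ValidationError(
                f"band [{self.low}, {self.high}] Hz: lower edge must be positive"
            )
        if self.high >= rate / 2:
            raise ValidationError(
                f"band [{self.low}, {self.high}] Hz exceeds Nyquist of {rate} Hz input"
            )


def default_carrier_bands(half_width: float = 2.0) -> list[CarrierBand]:
    """The standard analysis grid: centers 4:2:28 Hz, half-width 2 Hz."""
    return [CarrierBand(float(f), half_width) for f in range(4, 29, 2)]


@dataclass(frozen=True)
class EnvelopeConfig:
    """Tunables of the envelope chain (defaults match the standard analysis)."""

    filter_order: int = 4
    lowpass_cutoff: float = LOWPASS_CUTOFF
    env_rate: float = 5.0  # Hz; analysis rate for envelope phases / CCD
    edge_trim: float = 1.0  # s removed per side after each stage
    #: keep at least this multiple of the band's upper edge when decimating
    #: the narrowband signal after the band-pass (Nyquist safety margin)
    carrier_rate_margin: float = 2.5
    #: long records are split into sessions of at most this length for the
    #: CCD (time-pair similarity) computation; upper-triangle values are
    #: pooled across sessions, mirroring the handling of multi-session
    #: empirical recordings and bounding the T x T matrix size
    ccd_segment_seconds: float = 300.0


@dataclass
class BandEnvelope:
    """Envelope, slow envelope, and envelope phase on a shared time base.

    All arrays are ``(n, T)`` at ``sampling_rate`` (the decimated analysis
    rate).  ``trim`` records the equivalent per-side samples (at
    ``sampling_rate``) removed across all stages.
    """

    envelope: np.ndarray
    slow_envelope: np.ndarray
    envelope_phase: np.ndarray
    band: CarrierBand
    sampling_rate: float
    trim: int = 0

    def __post_init__(self) -> None:
        if not (
            self.envelope.shape == self.slow_envelope.shape == self.envelope_phase.shape
        ):
            raise ValidationError("BandEnvelope arrays must share one shape")


def bandpass(signal: np.ndarray, rate: float, band: CarrierBand,
             order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward) into ``band``."""
    band.validate(rate)
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    sos = sps.butter(order, [band.low, band.high], btype="bandpass", fs=rate,
                     output="sos")
    return sps.sosfiltfilt(sos, signal, axis=-1)


def hilbert_envelope(
    narrowband: np.ndarray, rate: float | None = None, trim_seconds: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic-signal magnitude and phase of a band-limited signal.

    Returns full-length ``(envelope, carrier_phase)``; callers discard
    ``trim_seconds`` per side (edge samples are distorted by the transform's
    implicit periodicity).  When ``rate`` is given, records shorter than two
    trim windows are rejected.
    """
    narrowband = np.atleast_2d(np.asarray(narrowband, dtype=float))
    if rate is not None:
        min_len = int(np.ceil(2 * trim_seconds * rate))
        if narrowband.shape[-1] <= min_len:
            raise ValidationError(
                f"record of {narrowband.shape[-1]} samples is shorter than "
                f"2 x {trim_seconds} s trim window at {rate} Hz"
            )
    from scipy.fft import next_fast_len

    T = narrowband.shape[-1]
    analytic = sps.hilbert(narrowband, N=next_fast_len(T), axis=-1)[..., :T]
    return np.abs(analytic), np.angle(analytic)


def lowpass_envelope(
    envelope: np.ndarray, rate: float, cutoff: float = LOWPASS_CUTOFF,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass; isolates the ultra-slow component.

    DC gain is 1 (a constant envelope passes unchanged).  The record must
    cover at least 3 cutoff periods for the filter to settle.
    """
    envelope = np.atleast_2d(np.asarray(envelope, dtype=float))
    if cutoff >= rate / 2:
        raise ValidationError(f"cutoff {cutoff} Hz at or above Nyquist of {rate} Hz")
    if envelope.shape[-1] < 3 * rate / cutoff:
        raise ValidationError(
            f"record too short to low-pass at {cutoff} Hz: need >= 3 cutoff periods"
        )
    sos = sps.butter(order, cutoff, btype="lowpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, envelope, axis=-1)


def envelope_phase(slow_envelope: np.ndarray) -> np.ndarray:
    """Instantaneous phase of the slow envelope fluctuations.

    The per-region mean is removed first: the raw envelope is one-sided
    (nonnegative), and the analytic phase of a signal with a large DC offset
    is degenerate.  Returns angles in (-pi, pi].
    """
    slow = np.atleast_2d(np.asarray(slow_envelope, dtype=float))
    if np.any(slow.std(axis=-1) == 0):
        raise ValidationError("constant envelope: phase undefined")
    from scipy.fft import next_fast_len

    demeaned = slow - slow.mean(axis=-1, keepdims=True)
    T = slow.shape[-1]
    analytic = sps.hilbert(demeaned, N=next_fast_len(T), axis=-1)[..., :T]
    return np.angle(analytic)


def analyze_band(
    signal: np.ndarray,
    rate: float,
    band: CarrierBand,
    config: EnvelopeConfig = EnvelopeConfig(),
) -> BandEnvelope:
    """Full envelope chain for one carrier band.

    After the band-pass the narrowband signal is decimated by plain striding
    to an intermediate carrier rate of at least ``carrier_rate_margin`` times
    the band's upper edge (the band-pass stopband is the anti-alias filter);
    the Hilbert envelope and the 0.2 Hz low-pass then run at that rate.  The
    final decimation to ``config.env_rate`` is again plain striding: the
    slow arrays are band-limited below the low-pass cutoff, and the raw
    envelope channel is strided with the same offsets so all outputs share
    one time base.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=float))
    total_stride = rate / config.env_rate
    if abs(total_stride - round(total_stride)) > 1e-9:
        raise ValidationError(
            f"input rate {rate} Hz must be an integer multiple of env_rate "
            f"{config.env_rate} Hz"
        )
    total_stride = int(round(total_stride))
    # largest divisor of the total stride that keeps the carrier rate safe
    stride1 = 1
    for d in range(total_stride, 0, -1):
        if total_stride % d == 0 and rate / d >= config.carrier_rate_margin * band.high:
            stride1 = d
            break
    mid_rate = rate / stride1
    stride2 = total_stride // stride1
    k0 = int(round(config.edge_trim * rate))

    nb = bandpass(signal, rate, band, order=config.filter_order)[:, ::stride1]
    env, _ = hilbert_envelope(nb, mid_rate, trim_seconds=config.edge_trim)
    k = int(round(config.edge_trim * mid_rate))
    env = env[:, k:-k] if k else env

    slow = lowpass_envelope(
        env, mid_rate, config.lowpass_cutoff, order=config.filter_order
    )
    env = env[:, k:-k] if k else env
    slow = slow[:, k:-k] if k else slow

    env_d = env[:, ::stride2]
    slow_d = slow[:, ::stride2]

    phase = envelope_phase(slow_d)
    k2 = int(round(config.edge_trim * config.env_rate))
    sl = np.s_[:, k2:-k2] if k2 else np.s_[:, :]
    total_trim = k2 + int(round(2 * k0 / total_stride))
    return BandEnvelope(
        envelope=np.ascontiguousarray(env_d[sl]),
        slow_envelope=np.ascontiguousarray(slow_d[sl]),
        envelope_phase=np.ascontiguousarray(phase[sl]),
        band=band,
        sampling_rate=config.env_rate,
        trim=total_trim,
    )
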