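"""Time-segment extraction and band-pass filtering of epoched trials.

Motor-imagery pipelines work on a fixed window of each trial (the part of
the recording where the imagery happens) restricted to the 8-30 Hz band
that covers the mu and beta sensorimotor rhythms.  Both operations preserve
trial count, labels and channel order; the pipeline order is fixed as
segment first, then filter.

Filtering is a Butterworth band-pass of the given design order applied
forward-backward (zero phase).  A band-pass design of order ``k`` has an
effective transfer-function order of ``2k``, and the forward-backward pass
squares the magnitude response; both facts are echoed in run configs rather
than hidden.  Zero-phase application is chosen because the filter's job
here is to produce zero-mean band-limited signals for covariance
estimation, and offline epoched analysis permits acausal filtering.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sps

from .epochs import EpochedSignal

__all__ = ["extract_time_segment", "bandpass_filter", "design_bandpass"]


def extract_time_segment(
    signal: EpochedSignal, t_start: float, t_end: float
) -> EpochedSignal:
    """Keep the sample block ``[floor(t_start*fs), floor(t_end*fs))`` of each trial.

    Windows are given in seconds and converted to 0-based half-open sample
    indices by flooring.  Labels, sampling rate and channel order are
    unchanged.
    """
    if not (0 <= t_start < t_end):
        raise ValueError(f"need 0 <= t_start < t_end; got [{t_start}, {t_end})")
    i0 = math.floor(t_start * signal.fs)
    i1 = math.floor(t_end * signal.fs)
    n = signal.n_samples
    if round(t_end * signal.fs) > n:
        raise ValueError(
            f"window [{t_start}, {t_end}) s needs samples up to {i1} but every "
            f"trial (first offender: trial 0) has only {n} samples at "
            f"{signal.fs} Hz"
        )
    if i1 - i0 < 2:
        raise ValueError(f"window [{t_start}, {t_end}) s keeps fewer than 2 samples")
    return EpochedSignal(
        data=signal.data[:, i0:i1, :],
        labels=signal.labels.copy(),
        fs=signal.fs,
        channel_names=signal.channel_names,
    )


def design_bandpass(low_hz: float, high_hz: float, order: int, fs: float) -> np.ndarray:
    """Second-order-section Butterworth band-pass design (order per band edge)."""
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz):
        raise ValueError(f"need 0 < low < high; got ({low_hz}, {high_hz}) Hz")
    if high_hz >= nyq:
        raise ValueError(
            f"high edge {high_hz} Hz must be below the Nyquist rate {nyq} Hz"
        )
    if order < 1:
        raise ValueError(f"filter order must be >= 1; got {order}")
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass_filter(
    signal: EpochedSignal, low_hz: float = 8.0, high_hz: float = 30.0, order: int = 5
) -> EpochedSignal:
    """Zero-phase Butterworth band-pass of every channel of every trial.

    The default 8-30 Hz band isolates the sensorimotor rhythms and removes
    the DC offset, so filtered channels are (numerically) zero-mean.
    """
    sos = design_bandpass(low_hz, high_hz, order, signal.fs)
    # sosfiltfilt needs padlen < n; also guard against meaningless warm-up.
    padlen = 3 * (2 * sos.shape[0])
    if signal.n_samples <= max(padlen, 3 * order):
        raise ValueError(
            f"trials of {signal.n_samples} samples are too short for a "
            f"zero-phase order-{order} band-pass (needs > {padlen} samples)"
        )
    filtered = sps.sosfiltfilt(sos, signal.data, axis=1)
    return EpochedSignal(
        data=np.ascontiguousarray(filtered),
        labels=signal.labels.copy(),
        fs=signal.fs,
        channel_names=signal.channel_names,
    )
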