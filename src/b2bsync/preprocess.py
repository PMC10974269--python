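"""Per-window signal conditioning.

Each 4-s window is conditioned independently (zero initial filter state) so
the pipeline can restart at any window boundary, matching a real-time
acquisition loop: linear detrend, then a causal 4th-order Butterworth
0.1-100 Hz bandpass, then a 4th-order Butterworth 58-62 Hz band-stop against
mains interference. Filtering is single-pass (causal) because zero-phase
forward-backward filtering is impossible online; edge transients are
accepted. Linked-ears re-referencing (C3' = C3 - (A1+A2)/2, likewise C4')
runs after filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import scipy.signal

from .core import FrequencyAxis
from .errors import FilterSpecError, MissingChannelError, TooShortError


@dataclass
class SampleWindow:
    """One window of per-channel voltage samples for one subject.

    ``channel_samples`` maps channel label -> 1-D float array (microvolts);
    all channels share one length. ``start_time`` is seconds on the shared
    session clock; ``window_index`` is the 0-based window ordinal.
    """

    subject_id: str
    window_index: int
    channel_samples: dict[str, np.ndarray]
    start_time: float

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channel_samples.values()}
        if len(lengths) > 1:
            raise TooShortError(
                f"channels of window {self.window_index} differ in length: {lengths}"
            )

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channel_samples.values())))

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.channel_samples)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass + notch parameters.

    Defaults: 4th-order 0.1-100 Hz bandpass and 4th-order 58-62 Hz band-stop
    (the notch realisation; centre 60 Hz). Orders are the design order of the
    lowpass prototype; positive even integers.
    """

    bandpass_low: float = 0.1
    bandpass_high: float = 100.0
    bandpass_order: int = 4
    notch_center: float = 60.0
    notch_low: float = 58.0
    notch_high: float = 62.0
    notch_order: int = 4

    def validate(self, fs: float) -> None:
        nyq = fs / 2.0
        for lo, hi, what in (
            (self.bandpass_low, self.bandpass_high, "bandpass"),
            (self.notch_low, self.notch_high, "notch"),
        ):
            if not (0 < lo < hi):
                raise FilterSpecError(f"{what} band [{lo}, {hi}] Hz is not ordered")
            if hi >= nyq:
                raise FilterSpecError(
                    f"{what} upper edge {hi} Hz >= Nyquist {nyq} Hz"
                )
        for order, what in (
            (self.bandpass_order, "bandpass"),
            (self.notch_order, "notch"),
        ):
            if order <= 0 or order % 2 != 0:
                raise FilterSpecError(
                    f"{what} order {order} must be a positive even integer"
                )


def detrend_linear(samples: np.ndarray) -> np.ndarray:
    """Subtract the least-squares straight line from a sample sequence.

    Removes slow electrode drift and DC offset; the residual has zero mean
    and zero linear trend.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise TooShortError(f"detrend needs >= 2 samples, got {x.size}")
    return scipy.signal.detrend(x, type="linear")


@lru_cache(maxsize=32)
def _sos_bandpass(spec: FilterSpec, fs: float) -> np.ndarray:
    return scipy.signal.butter(
        spec.bandpass_order,
        [spec.bandpass_low, spec.bandpass_high],
        btype="bandpass",
        fs=fs,
        output="sos",
    )


@lru_cache(maxsize=32)
def _sos_notch(spec: FilterSpec, fs: float) -> np.ndarray:
    return scipy.signal.butter(
        spec.notch_order,
        [spec.notch_low, spec.notch_high],
        btype="bandstop",
        fs=fs,
        output="sos",
    )


def bandpass(samples: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Causal 4th-order Butterworth bandpass, zero initial state, one pass."""
    spec.validate(fs)
    return scipy.signal.sosfilt(_sos_bandpass(spec, fs), np.asarray(samples, float))


def notch(samples: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Causal Butterworth band-stop around the mains frequency."""
    spec.validate(fs)
    return scipy.signal.sosfilt(_sos_notch(spec, fs), np.asarray(samples, float))


def preprocess_window(window: SampleWindow, spec: FilterSpec, fs: float) -> SampleWindow:
    """Detrend -> bandpass -> notch each channel; metadata unchanged."""
    processed = {
        ch: notch(bandpass(detrend_linear(x), spec, fs), spec, fs)
        for ch, x in window.channel_samples.items()
    }
    return replace(window, channel_samples=processed)


def rereference(window: SampleWindow) -> SampleWindow:
    """Linked-ears re-reference: subtract the ear average from C3 and C4.

    C3' = C3 - (A1+A2)/2 and C4' = C4 - (A1+A2)/2, sample-wise; the ear
    channels are dropped from the output.
    """
    for ch in ("A1", "A2", "C3", "C4"):
        if ch not in window.channel_samples:
            raise MissingChannelError(
                f"re-referencing needs channel {ch}; have {window.channels}"
            )
    ears = (window.channel_samples["A1"] + window.channel_samples["A2"]) / 2.0
    referenced = {
        "C3'": window.channel_samples["C3"] - ears,
        "C4'": window.channel_samples["C4"] - ears,
    }
    return replace(window, channel_samples=referenced)


def butterworth_bandpass_gain(f: float, spec: FilterSpec) -> float:
    """Analytic analog-prototype magnitude response of the bandpass filter.

    Used as an independent oracle for post-transient sine amplitudes: for a
    Butterworth bandpass of design order N with edges f1 < f2,
    ``|H(f)| = 1 / sqrt(1 + W^(2N))`` with ``W = (f^2 - f1 f2) / (f (f2-f1))``.
    """
    f1, f2 = spec.bandpass_low, spec.bandpass_high
    if f == 0:
        return 0.0
    w = (f * f - f1 * f2) / (f * (f2 - f1))
    return 1.0 / np.sqrt(1.0 + w ** (2 * spec.bandpass_order))


def butterworth_bandstop_gain(f: float, spec: FilterSpec) -> float:
    """Analytic analog-prototype magnitude response of the notch filter."""
    f1, f2 = spec.notch_low, spec.notch_high
    if f * f == f1 * f2:
        return 0.0
    w = (f * (f2 - f1)) / (f * f - f1 * f2)
    return 1.0 / np.sqrt(1.0 + w ** (2 * spec.notch_order))
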