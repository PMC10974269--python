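"""Diagonal cross-bispectrum estimation, calibration and band aggregation.

For one 4-s window the full-length DFT of each channel is taken per subject.
On the bifrequency diagonal (f_i = f_j) the cross-bispectrum of a subject-a
channel against a subject-b channel is

    B[i] = log | X_a(f_i) * X_b(f_i) * X_b*(2 f_i) |

evaluated at every one-sided bin i (the sum-frequency factor indexes the
full-length DFT at bin 2i, which always exists since 2i < n_samples). The
third, conjugated factor is a higher-order-statistics convention choice; it
is taken from subject b by default and is switchable to subject a. The
magnitude is clamped at eps = 1e-12 before the natural log.

Per-window matrices (combinations x bins) from a no-interaction calibration
period are averaged element-wise into a baseline; task windows are then
normalized per bin with the bounded relative difference

    n = (B - Bcal) / (|B| + |Bcal| + eps)

which is 0 at calibration level, has the sign of B - Bcal, and always lies
strictly inside [-1, 1]. Normalized matrices are finally averaged over each
EEG band's bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BandTable, Combination, FrequencyAxis, band_bin_map
from .errors import (
    AlignmentError,
    MissingChannelError,
    NoCalibrationError,
    ShapeError,
    TooShortError,
)
from .preprocess import SampleWindow

#: Magnitude clamp applied before the log, and the normalization guard.
EPS = 1e-12


@dataclass
class SpectralFrame:
    """Full-length complex DFT per channel for one subject's window."""

    subject_id: str
    window_index: int
    spectra: dict[str, np.ndarray]  # channel -> length-n_samples complex DFT
    axis: FrequencyAxis

    def one_sided(self, channel: str) -> np.ndarray:
        """First n_bins entries of the channel's DFT."""
        return self.full(channel)[: self.axis.n_bins]

    def full(self, channel: str) -> np.ndarray:
        if channel not in self.spectra:
            raise MissingChannelError(
                f"frame for {self.subject_id} has no channel {channel}"
            )
        return self.spectra[channel]


@dataclass
class BispectrumMatrix:
    """combinations x n_bins log-magnitude bispectrum values for one window."""

    window_index: int
    values: np.ndarray
    combinations: list[Combination]
    kind: str  # "raw" | "normalized"

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.combinations):
            raise ShapeError(
                f"{self.values.shape[0]} rows != {len(self.combinations)} combinations"
            )


@dataclass
class CalibrationBaseline:
    """Element-wise mean raw matrix over the calibration windows."""

    values: np.ndarray
    combinations: list[Combination]
    n_windows: int


@dataclass
class BandSummary:
    """bands x combinations mean normalized bispectrum for one window."""

    window_index: int
    values: np.ndarray
    band_names: tuple[str, ...]
    combinations: list[Combination]
    start_time: float = float("nan")


def spectral_frame(window: SampleWindow, axis: FrequencyAxis) -> SpectralFrame:
    """Unnormalized forward DFT of every channel of a (preprocessed) window."""
    if window.n_samples != axis.n_samples:
        raise TooShortError(
            f"window has {window.n_samples} samples, axis expects {axis.n_samples}"
        )
    spectra = {ch: np.fft.fft(x) for ch, x in window.channel_samples.items()}
    return SpectralFrame(window.subject_id, window.window_index, spectra, axis)


def bispectrum_pair(
    frame_a: SpectralFrame,
    channel_a: str,
    frame_b: SpectralFrame,
    channel_b: str,
    axis: FrequencyAxis,
    sum_factor: str = "b",
) -> np.ndarray:
    """Diagonal log-magnitude cross-bispectrum of one channel pair.

    ``sum_factor`` selects which subject supplies the conjugated
    sum-frequency factor X*(2f): ``"b"`` (default) or ``"a"``.
    """
    if frame_a.window_index != frame_b.window_index:
        raise AlignmentError(
            f"window index mismatch: {frame_a.window_index} != {frame_b.window_index}"
        )
    if sum_factor not in ("a", "b"):
        raise ValueError(f"sum_factor must be 'a' or 'b', got {sum_factor!r}")
    xa = frame_a.full(channel_a)
    xb = frame_b.full(channel_b)
    xs = xb if sum_factor == "b" else xa
    i = np.arange(axis.n_bins)
    triple = xa[i] * xb[i] * np.conj(xs[2 * i])
    return np.log(np.maximum(np.abs(triple), EPS))


def window_matrix(
    frame_a: SpectralFrame,
    frame_b: SpectralFrame,
    combos: list[Combination],
    axis: FrequencyAxis,
    sum_factor: str = "b",
) -> BispectrumMatrix:
    """Raw bispectrum matrix: one row per combination, in combination order."""
    rows = [
        bispectrum_pair(
            frame_a, c.subject_a_channel, frame_b, c.subject_b_channel, axis, sum_factor
        )
        for c in combos
    ]
    return BispectrumMatrix(frame_a.window_index, np.vstack(rows), list(combos), "raw")


def calibration_baseline(matrices: list[BispectrumMatrix]) -> CalibrationBaseline:
    """Element-wise arithmetic mean of raw matrices from calibration windows."""
    if not matrices:
        raise NoCalibrationError("calibration requires at least one window")
    shapes = {m.values.shape for m in matrices}
    if len(shapes) > 1:
        raise ShapeError(f"calibration matrices differ in shape: {shapes}")
    mean = np.mean([m.values for m in matrices], axis=0)
    return CalibrationBaseline(mean, matrices[0].combinations, len(matrices))


def normalize(
    matrix: BispectrumMatrix, baseline: CalibrationBaseline
) -> BispectrumMatrix:
    """Per-bin bounded relative difference against the calibration baseline.

    n = (B - Bcal) / (|B| + |Bcal| + eps): zero at calibration level, the
    sign of B - Bcal, strictly inside [-1, 1] for any finite inputs (large
    magnitudes can round onto the endpoints at float precision).
    """
    if matrix.values.shape != baseline.values.shape:
        raise ShapeError(
            f"matrix {matrix.values.shape} vs baseline {baseline.values.shape}"
        )
    b, c = matrix.values, baseline.values
    norm = (b - c) / (np.abs(b) + np.abs(c) + EPS)
    return BispectrumMatrix(matrix.window_index, norm, matrix.combinations, "normalized")


def band_average(
    matrix: BispectrumMatrix, bands: BandTable, axis: FrequencyAxis
) -> BandSummary:
    """Mean normalized bispectrum over each band's bins, per combination."""
    if matrix.values.shape[1] != axis.n_bins:
        raise ShapeError(
            f"matrix has {matrix.values.shape[1]} bins, axis {axis.n_bins}"
        )
    bin_map = band_bin_map(bands, axis)  # raises BandRangeError on empty bands
    values = np.vstack(
        [matrix.values[:, bin_map[b.name]].mean(axis=1) for b in bands]
    )
    return BandSummary(matrix.window_index, values, bands.names, matrix.combinations)
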