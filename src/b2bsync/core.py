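"""Channel, frequency-axis, band and combination model shared by all stages.

The estimator works on two synchronized 4-channel EEG streams. Channels carry
the ear-cup / top-band labels of the acquisition device (A1, A2, C3, C4);
after linked-ears re-referencing only the derived scalp channels (C3', C4')
remain. Cross-subject channel pairs ("combinations") are enumerated row-major
over subject-1 channels then subject-2 channels, which fixes the column order
of every downstream matrix and CSV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import BandRangeError, InvalidChannelSetError, InvalidWindowError

DEFAULT_CHANNELS = ("A1", "A2", "C3", "C4")
REFERENCED_CHANNELS = ("C3'", "C4'")


@dataclass(frozen=True)
class ChannelSet:
    """Ordered channel labels before and after re-referencing."""

    labels: tuple[str, ...] = DEFAULT_CHANNELS
    referenced_labels: tuple[str, ...] = REFERENCED_CHANNELS

    def __post_init__(self) -> None:
        if not self.labels:
            raise InvalidChannelSetError("channel set must be non-empty")
        if len(set(self.labels)) != len(self.labels):
            raise InvalidChannelSetError(f"duplicate channel labels: {self.labels}")
        if len(set(self.referenced_labels)) != len(self.referenced_labels):
            raise InvalidChannelSetError(
                f"duplicate referenced labels: {self.referenced_labels}"
            )


@dataclass(frozen=True)
class FrequencyAxis:
    """Geometry of the one-sided DFT of one analysis window.

    A window of ``window_seconds`` at ``sampling_rate`` holds
    ``n_samples = sampling_rate * window_seconds`` samples, yielding
    ``n_bins = n_samples / 2`` one-sided bins of width ``1/window_seconds`` Hz
    up to (but excluding) the Nyquist frequency. Bin ``k`` sits at
    ``k * resolution`` Hz.
    """

    sampling_rate: float
    window_seconds: float
    n_samples: int
    n_bins: int
    resolution: float
    nyquist: float

    def bin_frequency(self, k: int | np.ndarray) -> float | np.ndarray:
        return k * self.resolution

    @property
    def frequencies(self) -> np.ndarray:
        """One-sided bin centre frequencies in Hz."""
        return np.arange(self.n_bins) * self.resolution


def make_axis(sampling_rate: float, window_seconds: float) -> FrequencyAxis:
    """Build the frequency axis for a given sampling rate and window length.

    Raises
    ------
    InvalidWindowError
        If ``sampling_rate * window_seconds`` is not a positive even integer.
    """
    n_float = sampling_rate * window_seconds
    n_samples = int(round(n_float))
    if not math.isclose(n_float, n_samples, rel_tol=0, abs_tol=1e-9) or n_samples <= 0:
        raise InvalidWindowError(
            f"window of {window_seconds}s at {sampling_rate}Hz gives a "
            f"non-integer sample count ({n_float})"
        )
    if n_samples % 2 != 0:
        raise InvalidWindowError(f"sample count {n_samples} must be even")
    return FrequencyAxis(
        sampling_rate=float(sampling_rate),
        window_seconds=float(window_seconds),
        n_samples=n_samples,
        n_bins=n_samples // 2,
        resolution=1.0 / window_seconds,
        nyquist=sampling_rate / 2.0,
    )


@dataclass(frozen=True)
class Band:
    """One named EEG frequency band, inclusive printed edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise BandRangeError(f"band {self.name}: low {self.low} >= high {self.high}")


#: Canonical EEG band table. The printed table leaves gaps at 7-8 Hz and
#: 12-13 Hz; bins falling in a gap belong to no band.
DEFAULT_BANDS = (
    Band("Delta", 0.1, 4.0),
    Band("Theta", 4.0, 7.0),
    Band("Alpha", 8.0, 12.0),
    Band("Beta", 13.0, 30.0),
    Band("Gamma", 30.0, 50.0),
)


@dataclass(frozen=True)
class BandTable:
    """Ordered list of non-overlapping bands with strictly increasing lows."""

    entries: tuple[Band, ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        lows = [b.low for b in self.entries]
        if any(a >= b for a, b in zip(lows, lows[1:])):
            raise BandRangeError("band lows must be strictly increasing")
        for prev, nxt in zip(self.entries, self.entries[1:]):
            if prev.high > nxt.low:
                raise BandRangeError(
                    f"bands {prev.name} and {nxt.name} overlap ({prev.high} > {nxt.low})"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class Combination:
    """One cross-subject channel pair with its 1-based ordinal index."""

    subject_a_channel: str
    subject_b_channel: str
    index: int

    @property
    def label(self) -> str:
        return f"{self.subject_a_channel}-{self.subject_b_channel}"


def enumerate_combinations(
    channels_a: tuple[str, ...] | list[str],
    channels_b: tuple[str, ...] | list[str],
) -> list[Combination]:
    """All subject-1 x subject-2 channel pairs in row-major order.

    Row-major over subject-1 channels then subject-2 channels, giving
    ``|channels_a| * |channels_b|`` combinations: 16 for two full 4-channel
    sets, 4 for the referenced 2-channel sets. Index is 1-based.
    """
    for name, chans in (("subject a", channels_a), ("subject b", channels_b)):
        if not chans:
            raise InvalidChannelSetError(f"{name} channel list is empty")
        if len(set(chans)) != len(chans):
            raise InvalidChannelSetError(f"{name} has duplicate labels: {chans}")
    combos = []
    idx = 1
    for ca in channels_a:
        for cb in channels_b:
            combos.append(Combination(ca, cb, idx))
            idx += 1
    return combos


def band_bins(
    band: Band, axis: FrequencyAxis, table: BandTable | None = None
) -> np.ndarray:
    """Contiguous one-sided bin indices whose frequency lies in [low, high].

    Both printed edges are inclusive. When ``table`` is given and the band
    touches a neighbour exactly on a bin frequency, the shared bin is assigned
    to the higher band: the band keeps a bin at its own low edge but cedes a
    bin at its high edge to the band above (4 Hz -> Theta, 30 Hz -> Gamma).

    Raises
    ------
    BandRangeError
        If the band lies outside [0, nyquist] or contains no bins at this
        resolution.
    """
    if band.low < 0 or band.high > axis.nyquist:
        raise BandRangeError(
            f"band {band.name} ({band.low}-{band.high} Hz) outside "
            f"[0, {axis.nyquist}] Hz axis"
        )
    res = axis.resolution
    k_lo = int(math.ceil(band.low / res - 1e-9))
    k_hi = int(math.floor(band.high / res + 1e-9))
    k_hi = min(k_hi, axis.n_bins - 1)
    if table is not None:
        pos = [i for i, b in enumerate(table.entries) if b == band]
        if pos:
            i = pos[0]
            nxt = table.entries[i + 1] if i + 1 < len(table.entries) else None
            # cede a shared top-edge bin to the band above
            if nxt is not None and math.isclose(nxt.low, band.high):
                shared = band.high / res
                if math.isclose(shared, round(shared), abs_tol=1e-9):
                    k_hi = int(round(shared)) - 1
    if k_lo > k_hi:
        raise BandRangeError(
            f"band {band.name} contains no bins at {res} Hz resolution"
        )
    return np.arange(k_lo, k_hi + 1)


def band_bin_map(table: BandTable, axis: FrequencyAxis) -> dict[str, np.ndarray]:
    """Band name -> bin indices for a whole table, tie-breaks applied."""
    return {b.name: band_bins(b, axis, table) for b in table}
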