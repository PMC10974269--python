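"""Session orchestration: two aligned window streams, one consumer, all file I/O.

The real-time system runs one producer per EEG headset plus one consumer, all
synchronized on a shared clock; the consumer only processes a window once
both subjects' samples for that index are complete. Here that contract is
satisfied by a deterministic single-threaded scheduler that pulls window l
from both sources before computing anything for l — a live concurrent
adapter can be plugged in through the same ``StreamSource`` seam.

Window schedule: window 0 is discarded (process start-up overhead); the next
``calibration_seconds / window_seconds`` windows form the calibration
baseline; every later window is a task window, normalized against the
baseline and band-averaged. All stage outputs are persisted as CSV.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import yaml

from .bispectrum import (
    BandSummary,
    BispectrumMatrix,
    CalibrationBaseline,
    band_average,
    calibration_baseline,
    normalize,
    spectral_frame,
    window_matrix,
)
from .core import (
    BandTable,
    Band,
    ChannelSet,
    Combination,
    FrequencyAxis,
    enumerate_combinations,
    make_axis,
)
from .errors import (
    B2BError,
    DesyncError,
    InsufficientCalibrationError,
    ParseError,
)
from .preprocess import FilterSpec, SampleWindow, preprocess_window, rereference

logger = logging.getLogger("b2bsync.session")

RAW_COLUMNS = ["time_s", "A1", "A2", "C3", "C4"]


@dataclass
class SessionConfig:
    """Everything a session run needs, mirroring the YAML config file."""

    sampling_rate: float = 250.0
    window_seconds: float = 4.0
    calibration_seconds: float = 60.0
    reference_mode: str = "raw-4ch"  # or "referenced-2ch"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    band_table: BandTable = field(default_factory=BandTable)
    channel_set: ChannelSet = field(default_factory=ChannelSet)
    sum_factor: str = "b"  # subject supplying the conjugated sum-frequency factor
    output_dir: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.reference_mode not in ("raw-4ch", "referenced-2ch"):
            raise B2BError(f"unknown reference_mode {self.reference_mode!r}")
        n_cal = self.calibration_seconds / self.window_seconds
        if abs(n_cal - round(n_cal)) > 1e-9 or n_cal < 1:
            raise B2BError(
                f"calibration_seconds {self.calibration_seconds} must be a "
                f"positive multiple of window_seconds {self.window_seconds}"
            )
        self.filter_spec.validate(self.sampling_rate)
        _ = self.axis  # validates window geometry

    @property
    def axis(self) -> FrequencyAxis:
        return make_axis(self.sampling_rate, self.window_seconds)

    @property
    def n_calibration_windows(self) -> int:
        return int(round(self.calibration_seconds / self.window_seconds))

    def combinations(self) -> list[Combination]:
        if self.reference_mode == "referenced-2ch":
            labels = self.channel_set.referenced_labels
        else:
            labels = self.channel_set.labels
        return enumerate_combinations(labels, labels)

    # -- YAML round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "sampling_rate": self.sampling_rate,
            "window_seconds": self.window_seconds,
            "calibration_seconds": self.calibration_seconds,
            "reference_mode": self.reference_mode,
            "sum_factor": self.sum_factor,
            "seed": self.seed,
            "bandpass_low": self.filter_spec.bandpass_low,
            "bandpass_high": self.filter_spec.bandpass_high,
            "bandpass_order": self.filter_spec.bandpass_order,
            "notch_low": self.filter_spec.notch_low,
            "notch_high": self.filter_spec.notch_high,
            "notch_order": self.filter_spec.notch_order,
            "channels": list(self.channel_set.labels),
            "bands": [[b.name, b.low, b.high] for b in self.band_table],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        kwargs = {}
        for key in (
            "sampling_rate",
            "window_seconds",
            "calibration_seconds",
            "reference_mode",
            "sum_factor",
            "seed",
        ):
            if key in d:
                kwargs[key] = d[key]
        fkeys = {
            k: d[k]
            for k in (
                "bandpass_low",
                "bandpass_high",
                "bandpass_order",
                "notch_low",
                "notch_high",
                "notch_order",
            )
            if k in d
        }
        if fkeys:
            kwargs["filter_spec"] = FilterSpec(**fkeys)
        if "channels" in d:
            kwargs["channel_set"] = ChannelSet(labels=tuple(d["channels"]))
        if "bands" in d:
            kwargs["band_table"] = BandTable(
                tuple(Band(str(n), float(lo), float(hi)) for n, lo, hi in d["bands"])
            )
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


class StreamSource:
    """Provider of consecutive SampleWindows for one subject.

    Wraps any iterable of windows; windows must arrive in index order and
    both subjects' sources must produce the same index sequence.
    """

    def __init__(self, subject_id: str, windows: Iterable[SampleWindow]):
        self.subject_id = subject_id
        self._iter: Iterator[SampleWindow] = iter(windows)

    def __iter__(self) -> Iterator[SampleWindow]:
        return self._iter


def windows_from_frame(
    df: pd.DataFrame, subject_id: str, axis: FrequencyAxis
) -> list[SampleWindow]:
    """Chunk a raw recording table into consecutive windows.

    The table follows the raw recording schema (time_s plus one column per
    channel). A trailing partial window is dropped.
    """
    channels = [c for c in df.columns if c != "time_s"]
    n = axis.n_samples
    n_windows = len(df) // n
    out = []
    for l in range(n_windows):
        chunk = df.iloc[l * n : (l + 1) * n]
        samples = {ch: chunk[ch].to_numpy(dtype=float) for ch in channels}
        out.append(
            SampleWindow(
                subject_id=subject_id,
                window_index=l,
                channel_samples=samples,
                start_time=l * axis.window_seconds,
            )
        )
    return out


def replay_source(
    path: str | Path, subject_id: str, axis: FrequencyAxis
) -> StreamSource:
    """Stream a previously written raw recording CSV as a live source would.

    Raises ParseError on schema violations; a trailing partial window is
    dropped (its sample count is logged).
    """
    path = Path(path)
    try:
        # round_trip parsing: the written repr of a sample re-parses to the
        # exact same float, so write -> replay is lossless
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, OSError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "time_s" not in df.columns or len(df.columns) < 2:
        raise ParseError(
            f"{path}: expected columns time_s plus channels, got {list(df.columns)}"
        )
    bad = df.drop(columns="time_s").apply(
        lambda col: pd.to_numeric(col, errors="coerce")
    )
    if bad.isna().any().any():
        line = int(bad.isna().any(axis=1).idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path}: non-numeric sample near line {line}")
    windows = windows_from_frame(df, subject_id, axis)
    dropped = len(df) - len(windows) * axis.n_samples
    if dropped:
        logger.info("%s: dropped trailing partial window (%d samples)", path, dropped)
    return StreamSource(subject_id, windows)


@dataclass
class SessionRecord:
    """Everything one session run produced, ready to persist."""

    config: SessionConfig
    raw_windows: dict[str, list[SampleWindow]]  # subject -> windows (undiscarded)
    pre_windows: dict[str, list[SampleWindow]]
    matrices_raw: list[BispectrumMatrix]  # calibration + task windows
    matrices_norm: list[BispectrumMatrix]  # task windows only
    band_summaries: list[BandSummary]  # task windows only
    baseline: CalibrationBaseline
    n_produced: int
    n_discarded: int = 1

    @property
    def n_task_windows(self) -> int:
        return len(self.band_summaries)


def run_session(
    source_a: StreamSource, source_b: StreamSource, config: SessionConfig
) -> SessionRecord:
    """Run the full pipeline over two aligned window streams.

    Discards window 0, averages the calibration windows into the baseline,
    then normalizes and band-averages every later window. A window is only
    consumed once both subjects' copies for that index exist; a mismatch in
    the index sequences aborts with DesyncError.
    """
    axis = config.axis
    combos = config.combinations()
    n_cal = config.n_calibration_windows
    referenced = config.reference_mode == "referenced-2ch"
    if source_a.subject_id == source_b.subject_id:
        raise B2BError(f"both sources claim subject id {source_a.subject_id!r}")

    raw_windows: dict[str, list[SampleWindow]] = {
        source_a.subject_id: [],
        source_b.subject_id: [],
    }
    pre_windows: dict[str, list[SampleWindow]] = {
        source_a.subject_id: [],
        source_b.subject_id: [],
    }
    cal_matrices: list[BispectrumMatrix] = []
    task_raw: list[BispectrumMatrix] = []
    task_pending: list[tuple[BispectrumMatrix, float]] = []

    n_produced = 0
    it_a, it_b = iter(source_a), iter(source_b)
    expected_index = 0
    while True:
        wa = next(it_a, None)
        wb = next(it_b, None)
        if wa is None and wb is None:
            break
        if (wa is None) != (wb is None):
            short = source_a.subject_id if wa is None else source_b.subject_id
            raise DesyncError(
                f"stream for {short} ended early at window {expected_index}"
            )
        # both copies of window l exist: the consumer may now read it
        if wa.window_index != wb.window_index:
            raise DesyncError(
                f"window index mismatch: {source_a.subject_id}={wa.window_index} "
                f"{source_b.subject_id}={wb.window_index}"
            )
        if wa.window_index != expected_index:
            raise DesyncError(
                f"expected window {expected_index}, sources produced {wa.window_index}"
            )
        expected_index += 1
        n_produced += 1
        l = wa.window_index
        t0 = time.perf_counter()
        # the raw record keeps everything received, including window 0, so a
        # replay of raw_s*.csv reproduces this session exactly
        raw_windows[wa.subject_id].append(wa)
        raw_windows[wb.subject_id].append(wb)
        if l == 0:  # start-up overhead window, not considered for calculations
            logger.info("window %d: discarded (start-up)", l)
            continue
        pa = preprocess_window(wa, config.filter_spec, config.sampling_rate)
        pb = preprocess_window(wb, config.filter_spec, config.sampling_rate)
        if referenced:
            pa, pb = rereference(pa), rereference(pb)
        pre_windows[pa.subject_id].append(pa)
        pre_windows[pb.subject_id].append(pb)
        fa = spectral_frame(pa, axis)
        fb = spectral_frame(pb, axis)
        matrix = window_matrix(fa, fb, combos, axis, config.sum_factor)
        if len(cal_matrices) < n_cal:
            cal_matrices.append(matrix)
            stage = "calibration"
        else:
            task_raw.append(matrix)
            task_pending.append((matrix, wa.start_time))
            stage = "task"
        logger.info(
            "window %d: %s (%.1f ms)", l, stage, 1e3 * (time.perf_counter() - t0)
        )

    if len(cal_matrices) < n_cal:
        raise InsufficientCalibrationError(
            f"calibration needs {n_cal} windows, session produced "
            f"{len(cal_matrices)} (plus 1 discarded)"
        )
    baseline = calibration_baseline(cal_matrices)
    matrices_norm = []
    band_summaries = []
    for matrix, start_time in task_pending:
        nm = normalize(matrix, baseline)
        matrices_norm.append(nm)
        summary = band_average(nm, config.band_table, axis)
        summary.start_time = start_time
        band_summaries.append(summary)
    return SessionRecord(
        config=config,
        raw_windows=raw_windows,
        pre_windows=pre_windows,
        matrices_raw=cal_matrices + task_raw,
        matrices_norm=matrices_norm,
        band_summaries=band_summaries,
        baseline=baseline,
        n_produced=n_produced,
    )


# -- persistence ------------------------------------------------------------


def _signal_frame(windows: list[SampleWindow], axis: FrequencyAxis) -> pd.DataFrame:
    channels = windows[0].channels if windows else ()
    rows = {ch: [] for ch in channels}
    times = []
    for w in windows:
        times.append(w.start_time + np.arange(axis.n_samples) / axis.sampling_rate)
        for ch in channels:
            rows[ch].append(w.channel_samples[ch])
    data = {"time_s": np.concatenate(times) if times else np.array([])}
    for ch in channels:
        data[ch] = np.concatenate(rows[ch]) if rows[ch] else np.array([])
    return pd.DataFrame(data)


def _matrix_frame(
    matrices: list[BispectrumMatrix], axis: FrequencyAxis
) -> pd.DataFrame:
    frames = []
    freqs = axis.frequencies
    for m in matrices:
        n_c, n_b = m.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "window_index": np.repeat(m.window_index, n_c * n_b),
                    "combination": np.repeat([c.label for c in m.combinations], n_b),
                    "bin_hz": np.tile(freqs, n_c),
                    "value": m.values.ravel(),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["window_index", "combination", "bin_hz", "value"])
    return pd.concat(frames, ignore_index=True)


def band_summary_frame(summaries: list[BandSummary]) -> pd.DataFrame:
    """Long-format table: window_index, start_time_s, band, combination, value."""
    rows = []
    for s in summaries:
        for bi, band in enumerate(s.band_names):
            for ci, combo in enumerate(s.combinations):
                rows.append(
                    (s.window_index, s.start_time, band, combo.label, s.values[bi, ci])
                )
    return pd.DataFrame(
        rows, columns=["window_index", "start_time_s", "band", "combination", "value"]
    )


def write_session_outputs(record: SessionRecord, out_dir: str | Path) -> dict[str, Path]:
    """Persist every stage of a session run to CSV in the session root.

    File set: raw_s1.csv, raw_s2.csv, pre_s1.csv, pre_s2.csv, bispec_raw.csv,
    bispec_norm.csv, bands.csv, session.json. Returns name -> path.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise B2BError(f"cannot create output directory {out}: {exc}") from exc
    axis = record.config.axis
    subjects = list(record.raw_windows)
    paths = {}
    for i, subj in enumerate(subjects, start=1):
        p = out / f"raw_s{i}.csv"
        _signal_frame(record.raw_windows[subj], axis).to_csv(p, index=False)
        paths[f"raw_s{i}.csv"] = p
        p = out / f"pre_s{i}.csv"
        _signal_frame(record.pre_windows[subj], axis).to_csv(p, index=False)
        paths[f"pre_s{i}.csv"] = p
    p = out / "bispec_raw.csv"
    _matrix_frame(record.matrices_raw, axis).to_csv(p, index=False)
    paths["bispec_raw.csv"] = p
    p = out / "bispec_norm.csv"
    _matrix_frame(record.matrices_norm, axis).to_csv(p, index=False)
    paths["bispec_norm.csv"] = p
    p = out / "bands.csv"
    band_summary_frame(record.band_summaries).to_csv(p, index=False)
    paths["bands.csv"] = p
    meta = {
        "config": record.config.to_dict(),
        "subjects": subjects,
        "n_produced": record.n_produced,
        "n_discarded": record.n_discarded,
        "n_calibration_windows": record.baseline.n_windows,
        "n_task_windows": record.n_task_windows,
        "combinations": [c.label for c in record.baseline.combinations],
    }
    p = out / "session.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    paths["session.json"] = p
    return paths
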