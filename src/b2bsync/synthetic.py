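"""Seeded two-subject pseudo-EEG generator with controllable coupling.

Each channel is a sum of one band-limited oscillator per EEG band (random
phase per subject/channel), 1/f ("pink") background noise, 60 Hz mains
contamination and a slow linear drift — the signal structure the
preprocessing and bispectrum stages are built to handle. Cross-subject
coupling is injected as a shared oscillator at f0 plus a half-amplitude
harmonic at 2f0, phase-locked (the harmonic carries twice the fundamental's
phase), added to both subjects' scalp channels C3/C4 with one shared random
phase per segment. The diagonal bispectrum's sum-frequency factor X*(2f)
rewards exactly this f0/2f0 phase lock, so detection power is a monotone
function of the coupling amplitude kappa.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DEFAULT_CHANNELS
from .errors import ValidationError
from .session import SessionConfig

#: Per-band oscillator (frequency Hz, amplitude uV): mid-band tones with
#: amplitudes falling off with frequency, as in resting scalp EEG.
DEFAULT_OSCILLATORS = (
    ("Delta", 2.0, 20.0),
    ("Theta", 5.5, 10.0),
    ("Alpha", 10.0, 15.0),
    ("Beta", 21.5, 5.0),
    ("Gamma", 40.0, 3.0),
)

#: Gamma oscillator amplitude (uV); the reference coupled presets inject a
#: shared Gamma-range oscillator at 5x this amplitude.
GAMMA_AMPLITUDE = 3.0
DEFAULT_COUPLING = 5.0 * GAMMA_AMPLITUDE


@dataclass(frozen=True)
class Segment:
    """One labelled stretch of the session with a fixed coupling amplitude."""

    label: str
    start: float
    end: float
    kappa: float


@dataclass
class SyntheticSpec:
    """Generator parameters for one two-subject session.

    Amplitudes are in microvolts; ``drift_slope`` in uV/s. ``segments`` must
    tile [0, duration] without gaps or overlap; windows falling in a segment
    with kappa > 0 carry the shared f0 / 2*f0 oscillator on C3 and C4 of
    both subjects.
    """

    duration: float
    sampling_rate: float = 250.0
    oscillators: tuple[tuple[str, float, float], ...] = DEFAULT_OSCILLATORS
    pink_amplitude: float = 10.0
    line_amplitude: float = 5.0
    line_frequency: float = 60.0
    drift_slope: float = 1.0
    f0: float = 40.0
    segments: tuple[Segment, ...] = ()
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError(f"duration {self.duration} must be positive")
        nyq = self.sampling_rate / 2.0
        if not (0 < self.f0 and 2 * self.f0 < nyq):
            raise ValidationError(f"f0={self.f0}: need 0 < 2*f0 < Nyquist {nyq}")
        amps = [a for _, _, a in self.oscillators] + [
            self.pink_amplitude,
            self.line_amplitude,
        ]
        if any(a < 0 for a in amps):
            raise ValidationError("amplitudes must be non-negative")
        if not self.segments:
            self.segments = (Segment("task", 0.0, self.duration, 0.0),)
        segs = sorted(self.segments, key=lambda s: s.start)
        if abs(segs[0].start) > 1e-9 or abs(segs[-1].end - self.duration) > 1e-9:
            raise ValidationError(
                f"segments must tile [0, {self.duration}] s, got "
                f"[{segs[0].start}, {segs[-1].end}]"
            )
        for a, b in zip(segs, segs[1:]):
            if abs(a.end - b.start) > 1e-9:
                raise ValidationError(
                    f"segment gap/overlap between {a.label} and {b.label}"
                )
        if any(s.kappa < 0 for s in segs):
            raise ValidationError("coupling kappa must be >= 0")
        self.segments = tuple(segs)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))


def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping of seeded white noise.

    The rFFT of white noise is scaled by a 1/sqrt(f) amplitude profile
    (DC zeroed), inverted, and re-standardised.
    """
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale, n=n)
    sd = shaped.std()
    return shaped / sd if sd > 0 else shaped


def _coupling_signal(spec: SyntheticSpec, t: np.ndarray, rng: np.random.Generator
                     ) -> np.ndarray:
    """Shared f0 + phase-locked 2*f0 component, segment-gated by kappa."""
    out = np.zeros_like(t)
    for seg in spec.segments:
        phi = rng.uniform(0, 2 * np.pi)  # drawn per segment even when unused
        if seg.kappa <= 0:
            continue
        mask = (t >= seg.start - 1e-12) & (t < seg.end - 1e-12)
        ts = t[mask]
        out[mask] = seg.kappa * (
            np.cos(2 * np.pi * spec.f0 * ts + phi)
            + 0.5 * np.cos(2 * np.pi * 2 * spec.f0 * ts + 2 * phi)
        )
    return out


def generate_dyad(
    spec: SyntheticSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate both subjects' raw recording tables (time_s + channels).

    Per channel: band oscillators with independent random phases, pink
    noise, mains tone (random phase) and linear drift. During kappa > 0
    segments both subjects share the coupling oscillator on C3 and C4.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    t = np.arange(n) / spec.sampling_rate
    coupling = _coupling_signal(spec, t, rng)
    frames = []
    for _subject in ("a", "b"):
        data = {"time_s": t}
        for ch in spec.channels:
            sig = np.zeros(n)
            for _name, f, amp in spec.oscillators:
                sig += amp * np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            sig += spec.pink_amplitude * pink_noise(n, rng)
            sig += spec.line_amplitude * np.cos(
                2 * np.pi * spec.line_frequency * t + rng.uniform(0, 2 * np.pi)
            )
            sig += spec.drift_slope * t
            if ch in ("C3", "C4"):
                sig = sig + coupling
            data[ch] = sig
        frames.append(pd.DataFrame(data))
    return frames[0], frames[1]


def write_dyad(
    spec: SyntheticSpec, seed: int, out_dir: str | Path
) -> tuple[Path, Path]:
    """Generate and persist a dyad as subject_a.csv / subject_b.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df_a, df_b = generate_dyad(spec, seed)
    pa, pb = out / "subject_a.csv", out / "subject_b.csv"
    df_a.to_csv(pa, index=False)
    df_b.to_csv(pb, index=False)
    return pa, pb


# -- presets ----------------------------------------------------------------

#: Discard window + 60 s calibration at 4-s windows.
_LEAD_IN = 64.0

PRESETS = ("tiny", "tiny-null", "standard")


def preset_spec(preset: str, kappa: float = DEFAULT_COUPLING) -> SyntheticSpec:
    """Synthetic session layouts.

    tiny      — 90 s: discard + 60 s calibration + 26 s coupled task
                (22 windows end-to-end: 1 + 15 + 6).
    tiny-null — same layout, kappa = 0 throughout (no coupling anywhere).
    standard  — 1264 s: discard + calibration + two 10-min tasks, coupling
                only in the first ("collab") task (150 windows per task).
    """
    if preset == "tiny":
        return SyntheticSpec(
            duration=90.0,
            segments=(
                Segment("baseline", 0.0, _LEAD_IN, 0.0),
                Segment("collab", _LEAD_IN, 90.0, kappa),
            ),
        )
    if preset == "tiny-null":
        return SyntheticSpec(
            duration=90.0,
            segments=(
                Segment("baseline", 0.0, _LEAD_IN, 0.0),
                Segment("collab", _LEAD_IN, 90.0, 0.0),
            ),
        )
    if preset == "standard":
        return SyntheticSpec(
            duration=_LEAD_IN + 1200.0,
            segments=(
                Segment("baseline", 0.0, _LEAD_IN, 0.0),
                Segment("collab", _LEAD_IN, _LEAD_IN + 600.0, kappa),
                Segment("compete", _LEAD_IN + 600.0, _LEAD_IN + 1200.0, 0.0),
            ),
        )
    raise ValidationError(f"unknown preset {preset!r}; choose from {PRESETS}")


def make_fixture_session(
    preset: str, seed: int, out_dir: str | Path
) -> tuple[SessionConfig, Path, Path]:
    """Write a preset dyad plus a matching session config.

    Returns (config, subject_a_path, subject_b_path); the config uses the
    referenced 2-channel mode so the comparison grid has 4 combinations.
    """
    spec = preset_spec(preset)
    pa, pb = write_dyad(spec, seed, out_dir)
    config = SessionConfig(
        sampling_rate=spec.sampling_rate,
        reference_mode="referenced-2ch",
        seed=seed,
    )
    config.to_yaml(Path(out_dir) / "config.yaml")
    return config, pa, pb


def task_segments(preset: str) -> list[tuple[str, float, float]]:
    """(label, start, end) for the task segments of a preset (lead-in excluded)."""
    spec = preset_spec(preset)
    return [(s.label, s.start, s.end) for s in spec.segments if s.start >= _LEAD_IN]
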