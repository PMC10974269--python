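"""Shared fixtures: the standard axis/bands and small synthetic sessions."""

import numpy as np
import pytest

from b2bsync.core import BandTable, make_axis
from b2bsync.session import SessionConfig, StreamSource, run_session, windows_from_frame
from b2bsync.synthetic import generate_dyad, preset_spec


@pytest.fixture(scope="session")
def axis():
    """250 Hz / 4 s axis: 1000 samples, 500 one-sided bins."""
    return make_axis(250, 4)


@pytest.fixture(scope="session")
def bands():
    return BandTable()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20261001)


def run_preset_session(preset: str, seed: int, **config_kwargs):
    """Generate a preset dyad and run the full pipeline in memory."""
    spec = preset_spec(preset)
    axis = make_axis(spec.sampling_rate, config_kwargs.get("window_seconds", 4.0))
    da, db = generate_dyad(spec, seed)
    config = SessionConfig(
        sampling_rate=spec.sampling_rate,
        reference_mode=config_kwargs.pop("reference_mode", "referenced-2ch"),
        seed=seed,
        **config_kwargs,
    )
    src_a = StreamSource("s1", windows_from_frame(da, "s1", axis))
    src_b = StreamSource("s2", windows_from_frame(db, "s2", axis))
    return run_session(src_a, src_b, config)


@pytest.fixture(scope="session")
def tiny_record():
    """One fully-run tiny session (22 windows, referenced 2-channel mode)."""
    return run_preset_session("tiny", seed=7)


def brute_force_bispectrum(xa, xb, sum_factor="b"):
    """Independent oracle: direct O(N^2) DFT summation + the literal formula.

    No FFT — each DFT coefficient is a literal sum; one log-magnitude value
    per one-sided bin i using the sum-frequency coefficient at bin 2i.
    """
    from b2bsync.bispectrum import EPS

    n = len(xa)

    def dft(x, k):
        ns = np.arange(n)
        return np.sum(x * np.exp(-2j * np.pi * k * ns / n))

    out = []
    for i in range(n // 2):
        fa = dft(xa, i)
        fb = dft(xb, i)
        fs = dft(xb if sum_factor == "b" else xa, 2 * i)
        out.append(np.log(max(abs(fa * fb * np.conj(fs)), EPS)))
    return np.array(out)
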