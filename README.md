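# b2bsync

Real-time brain-to-brain (B2B) EEG synchrony estimation for hyperscanning
experiments. Two people wear 4-channel EEG headsets (ear-cup electrodes A1,
A2 and scalp electrodes C3, C4) while interacting; `b2bsync` estimates, every
4 seconds, how coupled their brain signals are, relative to a no-interaction
calibration baseline, and tests whether that coupling differs between task
conditions (e.g. collaboration vs competition).

It is written for researchers who want a device-agnostic, fully testable
version of this pipeline: live hardware is replaced by CSV replay sources and
a seeded synthetic dyad generator, so every stage can run and be verified
without headsets.

## Method

For each 4-s window *l* (1000 samples at 250 Hz) and each cross-subject
channel pair *(a, b)*, the per-channel signal is linearly detrended,
band-passed (4th-order Butterworth, 0.1–100 Hz), notch-filtered (58–62 Hz
band-stop) and optionally re-referenced to linked ears
(C3′ = C3 − (A1+A2)/2, C4′ = C4 − (A1+A2)/2). The diagonal cross-bispectrum
is then evaluated at every one-sided DFT bin *f*:

    B_l(f) = log | X_a,l(f) · X_b,l(f) · X*_b,l(2f) |

where X_l is the window's DFT. This third-order statistic is sensitive to
quadratic phase coupling: energy at *f* phase-locked to energy at *2f*. With
all pairs of two 4-channel montages it yields a 16 × 500 matrix per window
(4 × 500 after re-referencing).

Windows from a calibration period (default: the first minute, subjects at
rest) are averaged element-wise into a baseline B̄. Task windows are
normalized per bin with the bounded relative difference

    n = (B − B̄) / (|B| + |B̄| + ε),   n ∈ (−1, 1),

so 0 means "at calibration level", positive means more synchrony than rest.
Normalized values are averaged over the canonical EEG bands — Delta
(0.1–4 Hz), Theta (4–7), Alpha (8–12), Beta (13–30), Gamma (30–50) — giving
a bands × combinations summary per window.

Dyad-level inference compares the per-window band means between two task
conditions with one-sided Wilcoxon rank sum (Mann–Whitney) tests, both
tails, over the dyad × band × combination grid, Bonferroni-corrected
(8 dyads × 5 bands × 4 combinations = 160 cells → per-test level
0.05/160 = 0.0003125).

## Worked example

```bash
b2b simulate --preset tiny --seed 7 --out sim_collab     # coupled dyad
b2b simulate --preset tiny-null --seed 8 --out sim_compete   # independent dyad
b2b run --config sim_collab/config.yaml \
        --subject-a sim_collab/subject_a.csv \
        --subject-b sim_collab/subject_b.csv --out out_collab
b2b run --config sim_compete/config.yaml \
        --subject-a sim_compete/subject_a.csv \
        --subject-b sim_compete/subject_b.csv --out out_compete
b2b compare --collab out_collab --compete out_compete --out grid.csv
```

The runs print

```
session complete: 6 task windows, 8 files in out_collab
session complete: 6 task windows, 8 files in out_compete
grid: m=20 threshold=0.0025 sig_right=0 sig_left=0 -> grid.csv
```

Each 90-s `tiny` session yields 22 windows: 1 discarded (start-up), 15
calibration, 6 task windows; `m=20` is the grid size for one dyad (5 bands ×
4 referenced combinations) and `threshold` the Bonferroni level 0.05/20.
With only 6 windows per condition nothing reaches that corrected threshold —
detecting the injected coupling reliably takes the 10-minute tasks of the
`standard` preset (see `b2bsync.study.coupling_power_study`). Each session
directory holds the raw and pre-processed signals (`raw_s*.csv`,
`pre_s*.csv`), the raw and normalized bispectrum matrices
(`bispec_raw.csv`, `bispec_norm.csv`), the per-window band summary
(`bands.csv`) and `session.json`; `grid.csv` lists `p_right`/`p_left` with
significance flags per dyad, band and combination.

A session config is a flat YAML file; the fields and their defaults are
exactly `SessionConfig.to_dict()`:

```yaml
sampling_rate: 250.0      # Hz
window_seconds: 4.0
calibration_seconds: 60.0 # must be a multiple of window_seconds
reference_mode: referenced-2ch   # or raw-4ch
sum_factor: b             # subject supplying the conjugated X*(2f) factor
bandpass_low: 0.1         # Hz, 4th-order Butterworth bandpass
bandpass_high: 100.0
bandpass_order: 4
notch_low: 58.0           # Hz, band-stop realisation of the 60 Hz notch
notch_high: 62.0
notch_order: 4
channels: [A1, A2, C3, C4]
bands: [[Delta, 0.1, 4.0], [Theta, 4.0, 7.0], [Alpha, 8.0, 12.0],
        [Beta, 13.0, 30.0], [Gamma, 30.0, 50.0]]
seed: 7
```

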