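# Methods

## Pipeline

One session processes two synchronized 4-channel EEG streams (250 Hz;
channels A1, A2, C3, C4 per subject) in non-overlapping 4-s windows on a
shared clock. Per window and channel: linear detrend → causal 4th-order
Butterworth 0.1–100 Hz bandpass → causal 4th-order Butterworth 58–62 Hz
band-stop → (optionally) linked-ears re-referencing
C3′ = C3 − (A1+A2)/2, C4′ = C4 − (A1+A2)/2. For every cross-subject channel
pair the diagonal cross-bispectrum is evaluated at each one-sided DFT bin:

    B(f) = ln max( |X_a(f) X_b(f) X*_b(2f)|, ε ),  ε = 1e−12.

Window 0 is discarded as process start-up overhead. The following
`calibration_seconds / window_seconds` windows (default 15) are averaged
element-wise into the calibration baseline B̄; every later ("task") window
is normalized per bin as n = (B − B̄)/(|B| + |B̄| + ε) and averaged over the
bins of each EEG band. Task conditions are compared per dyad, band and
combination with one-sided Mann–Whitney tests, both tails, under Bonferroni
control.

## Assumptions and conventions

- **Diagonal slice.** The bispectrum is evaluated only at f₁ = f₂, one value
  per bin; the full bifrequency plane is out of scope. This makes the
  per-window product a 16 × 500 (or 4 × 500) matrix at the default geometry.
- **Conjugate-factor assignment.** The cross-bispectrum convention leaves
  open which subject supplies the sum-frequency factor X*(2f). The default
  takes it from subject b, so the statistic couples subject a's oscillation
  at f to subject b's phase-locked pair (f, 2f). `sum_factor: a` switches
  it; the choice is recorded in the session config and output metadata.
- **Natural log, clamped.** The log base only shifts values by a constant
  factor and the normalization is scale-tolerant, so the natural log is
  used. Clamping |·| at ε = 1e−12 keeps all-zero windows finite
  (ln ε ≈ −27.63).
- **Sum-frequency indexing.** X(2f) is read from the full-length DFT at
  index 2i. Since i < N/2, 2i < N always; no aliasing rule is needed. For
  i ≥ N/4 the index lands above Nyquist, where the full DFT holds the
  conjugate-symmetric image — this is the literal value of the transform at
  that index, used as-is.
- **Normalization form.** The published contract for normalized values is
  behavioural — zero at calibration, bounded by ±1, sign giving the
  direction of change — without a formula. The bounded relative difference
  (B − B̄)/(|B| + |B̄| + ε) is the simplest form satisfying all three; it is
  strictly inside (−1, 1) for finite inputs, though magnitudes ≳ 10¹⁶ round
  onto the endpoints in double precision.
- **Band edges.** The band table is implemented with inclusive printed
  edges. A bin shared by two touching bands (4 Hz, 30 Hz at 0.25 Hz
  resolution) is assigned to the higher band, keeping band means
  deterministic. The printed gaps 7–8 Hz and 12–13 Hz are honoured
  literally: their bins belong to no band and enter no mean. DC (bin 0)
  likewise falls below Delta's 0.1 Hz edge and is excluded.
- **Per-window causal filtering.** Each window is filtered independently
  with zero initial state, matching a restartable real-time loop; edge
  transients are accepted. Zero-phase forward–backward filtering is
  deliberately not used because it is impossible online. The notch is
  realised as a Butterworth band-stop (58–62 Hz, order 4); bandpass runs
  before notch, a fixed order chosen for determinism.
- **Re-referencing after filtering**, producing C3′/C4′ and dropping the ear
  channels; downstream combinations then span the 2 × 2 referenced set.
- **Scheduling contract.** The live system's process/lock machinery is
  modelled as a contract: both sources emit the same window-index sequence,
  and the consumer touches a window only when both subjects' copies exist.
  A deterministic single-threaded scheduler satisfies the contract and is
  the reference implementation; `StreamSource` is the seam for a concurrent
  live adapter. Index mismatches or one stream ending early abort with a
  desync error; sub-window device skew is out of scope for replay.

## Statistical choices

- "Wilcoxon rank sum" is the unpaired two-sample Mann–Whitney test: the
  compared samples are per-window values from two different task periods,
  not paired differences. p-values are exact (full enumeration) when the
  combined sample is ≤ 12 and tie-free, otherwise normal approximation with
  mid-rank tie correction and continuity correction (the two agree within
  0.02 at the switchover, which the suite checks).
- Both tails are reported for every cell; the Bonferroni threshold is
  α/m with m = dyads × bands × combinations (0.05/160 = 0.0003125 for the
  reference 8-dyad design). Per-window values from repeated runs of the
  same task are pooled by default; callers can pass per-repetition series
  as separate dyad entries if they prefer.

## Synthetic dyads

The generator emulates the signal structure the estimator is designed for,
per channel: one oscillator per band at mid-band frequency (Delta 2 Hz
20 µV, Theta 5.5 Hz 10 µV, Alpha 10 Hz 15 µV, Beta 21.5 Hz 5 µV, Gamma
40 Hz 3 µV — amplitudes falling with frequency as in resting scalp EEG),
unit-variance 1/f pink noise scaled to 10 µV (spectral shaping of seeded
white noise), a 5 µV 60 Hz mains tone, and a 1 µV/s linear drift. All phases
are drawn from a single seeded generator.

Coupling is injected as a shared oscillator at f₀ = 40 Hz plus a
half-amplitude harmonic at 2f₀ carrying twice the fundamental's phase,
added identically to both subjects' C3 and C4 during segments with coupling
amplitude κ > 0 (one shared random phase per segment). The estimator's
X*(2f) factor rewards exactly this f₀/2f₀ phase lock, so detection power is
a controllable, monotone function of κ. The reference coupled condition
uses κ = 15 µV (5 × the Gamma oscillator amplitude).

What the generator does **not** emulate: eye-blink/EMG artifacts,
non-stationary band power, volume conduction, inter-channel correlation
beyond the injected coupling, or device skew. Passing tests therefore show
that the pipeline recovers quadratic phase coupling of known strength from
realistic background spectra — not that it detects social synchrony in real
recordings.

Presets: `tiny` (90 s = 1 discarded + 15 calibration + 6 coupled task
windows; fast fixtures), `tiny-null` (same, κ = 0), `standard` (64 s lead-in
plus two 10-minute tasks, coupling only in the first, 150 windows per task —
the reference protocol timing).

## Validation studies and problem sizes

- *Power study*: 20 seeded `standard`-scale sessions; right-tailed rank sum
  on the coupled cell (Gamma, C3′–C3′), 150 vs 150 windows. At κ = 15 µV
  detection at α = 0.05 occurs in 100% of runs; at the `tiny` scale
  (6 windows per condition) the same effect is not reliably significant,
  which is why inference defaults to the 10-minute task length.
- *Null study*: 20 seeded uncoupled sessions (26 s tasks); fraction of
  (run × band × combination) cells whose task-window mean lies within ±0.1
  of the calibration zero line.
- *Direction study*: 50 seeded sessions with 152 s tasks; fraction of runs
  where the coupled cell's mean is strictly higher in the coupled segment.
  The shorter task length keeps the 50-run study inexpensive while the
  direction statistic remains stable.
- *Oracle agreement*: the FFT-based estimator is checked against a direct
  O(N²) DFT-summation implementation of the defining formula on 64-sample
  windows (relative agreement ~1e−12, asserted at 1e−6).

## Numerical and I/O notes

- CSV floats are written with pandas' shortest round-trip repr and replayed
  with `float_precision="round_trip"`, so write → replay → rerun reproduces
  downstream CSVs byte-for-byte; the raw per-subject CSVs include the
  discarded window 0 for the same reason.
- Sessions are deterministic given (input samples, config); the only
  randomness anywhere is the synthetic generator's single seed.
- Degenerate inputs are rejected loudly (empty channel sets, odd window
  lengths, bands with no bins at the current resolution, empty calibration,
  mismatched window indices) rather than patched over.

## Known limitations

- Single-pass causal filters leave edge transients inside each 4-s window;
  the 0.1 Hz corner in particular settles over many seconds, so very-low
  Delta content is attenuated unevenly within a window.
- Per-bin normalization against a log-scale baseline compresses large
  effects: even strong injected coupling moves one bin by ~0.15, and band
  means by ~3 × 10⁻³, which is why window counts dominate detection power.
- The comparison grid treats windows as exchangeable samples; serial
  correlation between consecutive windows is ignored, as in the original
  per-window design.
- Two-subject dyads only; no multi-dyad sessions, no FDR alternatives to
  Bonferroni, no bicoherence or full bifrequency analysis.
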