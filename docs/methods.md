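# Methods

## Model and assumptions

Surface EMG during walking is modeled as a small number of synergies:
`EMG ≈ W · H`, with `W` (Nm × Nsyn) nonnegative muscle weights and `H`
(Nsyn × Nc·Nt) nonnegative activation time courses over Nc
time-normalized strides of Nt samples. The analysis assumes (i) the
linear envelope is the physiologically meaningful signal, (ii) amplitude
differences between channels and sessions are nuisance (electrode
placement), removed by dividing each channel by its own SD, and (iii)
goodness of fit is well summarized by the VAF statistic — the squared
uncentered correlation of the vectorized experimental and reconstructed
matrices, times 100. VAF is scale-invariant and lies in [0, 100] by
Cauchy–Schwarz; it is deliberately uncentered (the all-positive envelope
baseline counts as signal, not offset).

Two adaptation hypotheses are operationalized as constrained
reconstructions of a target EMG from a reference synergy set: AOA fixes
the weights and refits nonnegative activations (one NNLS per time
column); WOA fixes the stride-averaged activation profiles, tiled across
the target's strides, and refits nonnegative weights (one NNLS per
muscle row). Both subproblems are convex and solved to global optimality
with an active-set NNLS, so differences in VAF reflect the constraint,
never solver failure. WOA is intrinsically the stricter test: a
phase-shifted burst cannot be absorbed by re-weighting muscles, whereas
AOA can re-time activations freely. On strongly burst-like data WOA
VAF_POST therefore drops much faster with profile perturbations than AOA
VAF_POST does with weight perturbations — visible in the synthetic
summaries, where AOA GOOD stays near zero while WOA GOOD grows steeply.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| high-pass cutoff | 40 | Hz | removes motion artifact below the EMG band |
| low-pass cutoff | 6 | Hz | linear-envelope bandwidth for gait |
| filter order | 6 | — | Butterworth order per pass |
| zero-phase | true | — | forward–backward filtering, no envelope lag |
| Nt | 101 | samples/stride | 0–100% gait cycle, 1% resolution |
| required strides | 5 | — | eligibility rule for a leg |
| NNMF restarts | 10 | — | escape local minima of multiplicative updates |
| NNMF tol | 1e-6 | relative | per-iteration objective decrease threshold |
| NNMF max_iter | 2000 | — | cap per restart |
| bootstrap resamples | 500 | — | VAF distribution per candidate rank |
| percentile / threshold | 95 / 90 | % | rank accepted when P95(VAF) > 90% |

The filtering chain is zero-phase by default (switchable); the "order"
is the designed order per pass. Stride resampling is linear
interpolation on a uniform phase grid including both endpoints —
monotone, so nonnegativity survives. Demeaning is per channel over the
whole recording; low-pass undershoot is clipped at zero because NNMF
requires nonnegative input.

## Bootstrap rank selection

For each candidate rank (scanned upward from 1) the NNMF is fit once on
the full matrix; each replicate draws time-column indices with
replacement and applies the same indices to the data and to `H`,
recomputing VAF with `W` fixed. The alternative — refitting NNMF inside
every replicate — is deliberately not implemented: the fixed-`W` reading
matches resampling the signal and its activations "consistently", and a
per-replicate refit would confound sampling variability with NNMF local
minima. If no rank up to Nm qualifies, Nm is returned with an explicit
warning flag. Degenerate resamples (all-zero draw) are redrawn; they are
astronomically unlikely but the contract is total.

## Synthetic data: what it emulates, what it does not

The generator produces ground-truth synergies and plays them through the
same observation model the pipeline assumes:

* **Weights**: the muscles are partitioned among the synergies; each
  synergy strongly activates its own group (uniform 0.8–1.5), adds one
  modest cross weight (0.1–0.25) and a small common baseline (≤ 0.06).
  This mirrors the anatomical grouping of locomotor synergies and makes
  the factorization identifiable — every synergy owns enough unique
  variance that the bootstrap criterion distinguishes rank k from k−1.
* **Profiles**: one (75%) or two (25%) narrow Gaussian bursts in
  gait-cycle phase (width 0.035–0.06 cycle), peak phases spread over the
  cycle, peak-normalized to 1.
* **Envelope**: `W·H` over Nc strides with optional per-stride
  amplitude/phase jitter, plus additive Gaussian noise (SD a fraction of
  the envelope SD) truncated at zero; multiplicative noise is an option.
* **Raw EMG**: band-limited Gaussian noise (20–450 Hz), a standard
  surrogate for the surface-EMG interference pattern, amplitude-modulated
  by the envelope at 2000 Hz; stride durations 1.1 s ± 5% CV; half a
  second of held-envelope padding keeps filter transients out of the
  strides. Amplitudes are arbitrary since the pipeline scales by SD.
* **Treatment effects**: weights are mixed toward a random nonnegative
  equal-norm direction by fraction `dW_mag`; profiles are circularly
  phase-shifted by `dH_mag` times a per-synergy random fraction
  (0.15–0.4) of the cycle. Both are monotone effect-size dials with an
  exact identity at zero.
* **TD surrogates**: an independent 5-synergy ground truth, richer than
  the 2–4-synergy patient sets, so specificity (SPEC) has a true
  positive signal.
* **Cohorts**: each Nsyn group shares a group-level ground truth from
  which members deviate slightly (weight 0.15 / profile 0.10), giving
  generic synergies something real to capture; default effect sizes
  dW_mag = dH_mag = 0.2. These effect sizes are free parameters of the
  simulation, not calibrated to any clinical population.

What the generator does **not** emulate: motor-unit physiology,
crosstalk between electrodes, within-stride duration asymmetries,
non-stationary noise, movement artifact, or the broad, overlapping
activation profiles of severely impaired gait. Passing tests therefore
demonstrate correctness of the algorithms under the stated generative
assumptions — not clinical performance. In particular, synthetic VAFs
run close to 100% because the data are nearly exactly low-rank; real
envelopes are not.

## Comparing recovered and generative weights

Extraction operates on unit-SD channels, so a recovered `W` lives in the
scaled space `D⁻¹·W_true` (D the per-channel SDs). Pearson correlation
of weight columns is invariant to the NNMF column-scale ambiguity but
not to this row rescaling; recovery checks therefore map the ground
truth through the same divisors (`synkit.synthetic.scaled_weights`)
before matching.

## Numerical choices

* NNMF: Lee–Seung multiplicative updates with a 1e-12 additive guard in
  the denominators; initialization uniform in (0.1, 1.1) scaled to the
  data magnitude; best of the seeded restarts by final Frobenius error.
  The objective trace is retained per run and is non-increasing.
* NNLS: `scipy.optimize.nnls` per column/row — exact active-set, no
  tolerance tuning. Rank-deficient fixed factors are still solved (the
  objective is convex) but flagged `non_unique`.
* Synergy matching: Hungarian assignment maximizing summed Pearson
  correlation (exact for all K; exhaustive enumeration is the test
  oracle for K ≤ 4); a greedy alternative is available. Zero-variance
  columns yield undefined (NaN) correlations, matched last and excluded
  from dW rather than counted as zero.
* dH normalization: profiles are peak-normalized (max = 1) before RMSE;
  "normalized to one" is ambiguous between peak and unit-norm
  conventions, so peak normalization is the recorded choice here (it
  keeps both profiles in [0, 1], making RMSE readable as a fraction of
  peak activation).
* Undefined per-muscle VAFs (all-zero experimental row) propagate as
  NaN, never as 0.
* All randomness flows from `numpy.random.SeedSequence` spawning, so
  every stage is a pure function of the master seed.

## Problem sizes

Validation suites run the study-shaped geometry (8 muscles, 5 strides,
101 samples) with 20 seeds per property, 100 bootstrap resamples and
3–10 NNMF restarts; the acceptance script uses a ten-leg cohort
(3/4/3 legs in Nsyn groups 2/3/4) with seven TD surrogates. The library
defaults remain 500 resamples and 10 restarts. These sizes are the
package's own validation choices; the algorithms scale linearly in
resamples and restarts.

## Known limitations

* The bootstrap criterion inherits VAF's leniency: on data where one
  synergy carries little unique variance, the criterion can accept a
  lower rank. This is a property of the published criterion, not of the
  implementation.
* Generic synergies are extracted from members' already unit-SD-scaled
  matrices (per-subject scaling, not pooled); members are not excluded
  from the generic set when reconstructing their own data.
* WOA tiles the averaged profile across target strides; it cannot model
  stride-to-stride timing variability in the target. A config switch
  (`woa_average_target`) fits the stride-averaged target instead.
* `fit_vaf` of the subject-specific NNMF is used as VAF_PRE for both
  approaches, so WOA's GOOD conflates profile averaging with treatment
  change when stride-to-stride variability is high.
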