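# synkit — muscle-synergy analysis of gait EMG

`synkit` quantifies how well a set of muscle synergies extracted from one
walking session explains the EMG of another: the question clinicians and
modelers face when deciding whether pre-treatment motor control carries
over after an intervention (e.g. botulinum toxin injections or multilevel
surgery in children with cerebral palsy), and whether it differs from
typically-developing (TD) control.

It is aimed at motor-control researchers and gait-lab engineers working
with multi-channel surface EMG (8 muscles per leg is the canonical
montage) plus heel-strike annotations.

## The method

1. **Envelope preprocessing.** Per channel: 40 Hz high-pass Butterworth,
   demean, full-wave rectification, 6 Hz low-pass Butterworth (6th order,
   zero-phase). Each stride (heel strike to heel strike) is resampled to
   Nt = 101 points; Nc = 5 strides are concatenated into a matrix *EMG*
   (Nm × Nc·Nt) and every channel is divided by its own SD.
2. **Synergy extraction.** Non-negative matrix factorization
   *EMG* ≈ *W·H* (multiplicative updates, Frobenius loss, best of several
   random restarts). Goodness of fit is the variance accounted for

   VAF = (Σₘₜ EMGₘₜ·recEMGₘₜ)² / (Σₘₜ EMGₘₜ² · Σₘₜ recEMGₘₜ²) × 100,

   the squared uncentered correlation of the vectorized matrices.
3. **Model order.** The number of synergies Nsyn is the smallest rank
   whose bootstrap VAF distribution (500 column resamples applied
   consistently to *EMG* and *H*) has its 95th percentile above 90%.
4. **Reconstruction of other data.** A target EMG (post-treatment or TD)
   is fitted with one factor fixed: AOA keeps *W* fixed and optimizes
   nonnegative activations; WOA keeps the stride-averaged activation
   profiles fixed and optimizes nonnegative weights. Both are separable
   convex problems solved exactly by per-column / per-row NNLS.
5. **Metrics.** GOOD = VAF_PRE − VAF_POST, SPEC = VAF_POST − VAF_TD,
   IMP = VAF_PRE − VAF_TD (so SPEC = IMP − GOOD); generic synergies are
   extracted per Nsyn group from concatenated multi-subject data and used
   the same way; dW (mean matched-weight correlation) and dH (mean RMSE
   of matched peak-normalized profiles) quantify pre-to-post synergy
   change after Hungarian matching on the weight columns.

Because clinical recordings are rarely shareable, `synkit` ships a seeded
synthetic-EMG generator with known ground-truth synergies (burst-like
activation profiles, muscle-group-partitioned weights, band-limited
amplitude-modulated carrier) that every stage is validated against.

## Worked example

```python
import synkit as sk
from synkit.preprocessing import ensure_scaled

gt_pre = sk.make_ground_truth(n_muscles=8, n_syn=3, seed=42)
gt_post = sk.perturb_ground_truth(gt_pre, dW_mag=0.2, dH_mag=0.2, seed=43)
cfg = sk.SimulationConfig(envelope_noise_sd=0.05)
pre = ensure_scaled(sk.simulate_envelope(gt_pre, cfg.replace(seed=1)))
post = ensure_scaled(sk.simulate_envelope(gt_post, cfg.replace(seed=2)))
td = ensure_scaled(sk.simulate_td_like(cfg, n_syn_td=5, seed=3))

sel = sk.bootstrap_select_nsyn(pre, n_boot=100, seed=4, n_restarts=5)
syn = sel.selected_fit
print(f"selected Nsyn = {sel.n_syn}, fit VAF = {syn.fit_vaf:.1f}%")

aoa_post = sk.reconstruct_aoa(syn.W, post)
aoa_td = sk.reconstruct_aoa(syn.W, td)
m = sk.compute_leg_metrics(syn.fit_vaf, aoa_post.vaf_global, aoa_td.vaf_global)
print(f"VAF_POST = {m['vaf_post']:.1f}%, VAF_TD = {m['vaf_td']:.1f}%")
print(f"GOOD = {m['good']:.1f}, SPEC = {m['spec']:.1f}, IMP = {m['imp']:.1f}")

post_fit = sk.nnmf(post, sel.n_syn, seed=5)
match = sk.match_synergies(syn.W, post_fit.W)
print(f"dW = {sk.delta_w(match.correlations):.3f}, "
      f"dH = {sk.delta_h(syn.H_avg, post_fit.H_avg, match.permutation):.3f}")
```

Output:

```
selected Nsyn = 3, fit VAF = 99.9%
VAF_POST = 99.4%, VAF_TD = 65.8%
GOOD = 0.4, SPEC = 33.7, IMP = 34.1
dW = 0.992, dH = 0.186
```

The bootstrap recovers the generative rank; the pre-treatment weights
still explain the perturbed post-treatment data almost perfectly under
AOA (GOOD ≈ 0) but explain the richer TD surrogate far worse
(SPEC ≈ 34), and the injected weight/profile perturbations register in
dW < 1 and dH > 0.

## Command line

```bash
synkit simulate --seed 1 --out cohort/           # synthetic cohort + manifest
synkit extract --emg leg_pre.csv --select-nsyn --seed 1 --out syn/
synkit reconstruct --synergies syn/synergies.json --target leg_post.csv \
    --approach aoa --out rec/
synkit run-all --manifest cohort/manifest.yaml --seed 1 --out report/
```

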