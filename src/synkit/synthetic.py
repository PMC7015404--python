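"""Synthetic gait-EMG generator with known synergy ground truth.

Real pre/post-treatment recordings from clinical motion labs are rarely
shareable, so the pipeline is exercised on surrogate data built from the
same generative assumptions the analysis makes: a small set of nonnegative
muscle-weight vectors ``W`` activated by smooth, burst-like, periodic
profiles ``H`` over the gait cycle. The envelope is ``W @ H`` plus noise;
the raw signal is a band-limited stochastic carrier amplitude-modulated by
that envelope, so the standard rectify-and-filter chain recovers it.

Treatment effects are emulated by perturbing either the weights (mixing
each column toward a random nonnegative direction) or the activation
profiles (phase-shifting the bursts), mirroring the two adaptation
mechanisms the reconstruction approaches probe. Typically-developing (TD)
surrogates come from an independent, richer synergy set so that low-rank
patient synergies genuinely fail to explain them.

All generators are pure functions of their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng
from scipy import signal as sps

from .datatypes import (
    ConfigurationError,
    GaitCycleMatrix,
    RawEMGRecording,
    default_channel_names,
)

__all__ = [
    "GroundTruthSynergies",
    "SimulationConfig",
    "make_ground_truth",
    "simulate_envelope",
    "simulate_raw",
    "perturb_ground_truth",
    "simulate_td_like",
    "scaled_weights",
]

_MAX_WEIGHT_CORR = 0.9  # distinctness bound for generated weight columns


def _as_seedseq(seed) -> SeedSequence:
    return seed if isinstance(seed, SeedSequence) else SeedSequence(seed)


@dataclass
class GroundTruthSynergies:
    """A known generative synergy set: weights and one-cycle profiles.

    ``W_true`` is ``Nm x Nsyn`` (dimensionless, nonnegative);
    ``H_true_profile`` is ``Nsyn x Nt`` over a single gait cycle, each row
    peak-normalized to maximum 1.
    """

    W_true: np.ndarray
    H_true_profile: np.ndarray
    n_syn: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        self.H_true_profile = np.asarray(self.H_true_profile, dtype=float)
        if np.any(self.W_true < 0) or np.any(self.H_true_profile < 0):
            raise ConfigurationError("ground-truth factors must be nonnegative")
        if self.W_true.shape[1] != self.n_syn or self.H_true_profile.shape[0] != self.n_syn:
            raise ConfigurationError("factor shapes inconsistent with n_syn")
        if np.any(self.W_true.max(axis=0) <= 0):
            raise ConfigurationError("W_true has an all-zero column")
        peaks = self.H_true_profile.max(axis=1)
        if np.any(peaks <= 0):
            raise ConfigurationError("H_true_profile has an all-zero row")
        if not np.allclose(peaks, 1.0, atol=1e-9):
            raise ConfigurationError("activation profiles must be peak-normalized to 1")

    @property
    def n_muscles(self) -> int:
        return self.W_true.shape[0]

    @property
    def n_samples(self) -> int:
        return self.H_true_profile.shape[1]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults mirror the clinical recording protocol the pipeline expects:
    8 muscles, 5 strides normalized to 101 samples, 2000 Hz raw EMG with a
    20-450 Hz interference-pattern carrier. ``envelope_noise_sd`` is the
    additive noise SD as a fraction of the envelope's own SD;
    ``dW_mag`` / ``dH_mag`` set the post-treatment perturbation strength;
    ``amplitude_jitter`` / ``phase_jitter`` add small stride-to-stride
    variability to the activation bursts.
    """

    n_muscles: int = 8
    n_cycles: int = 5
    n_samples: int = 101
    sampling_rate: float = 2000.0
    cycle_duration_mean: float = 1.1
    cycle_duration_cv: float = 0.05
    envelope_noise_sd: float = 0.05
    multiplicative_noise: bool = False
    carrier_band: tuple[float, float] = (20.0, 450.0)
    dW_mag: float = 0.0
    dH_mag: float = 0.0
    amplitude_jitter: float = 0.0
    phase_jitter: float = 0.0
    edge_pad_s: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_muscles < 1 or self.n_cycles < 1 or self.n_samples < 2:
            raise ConfigurationError("n_muscles, n_cycles, n_samples out of range")
        lo, hi = self.carrier_band
        if not 0 < lo < hi:
            raise ConfigurationError("carrier_band must satisfy 0 < low < high")
        if self.sampling_rate <= 2 * hi:
            raise ConfigurationError(
                "sampling_rate must exceed twice the upper carrier band edge"
            )
        for name in ("envelope_noise_sd", "dW_mag", "dH_mag", "amplitude_jitter", "phase_jitter"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.cycle_duration_mean <= 0 or self.cycle_duration_cv < 0:
            raise ConfigurationError("invalid cycle duration parameters")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


def _periodic_bump(phase: np.ndarray, center: float, width: float) -> np.ndarray:
    """Gaussian burst in gait-cycle phase, wrapped on the unit circle."""
    d = phase - center
    d = d - np.round(d)  # wrap to [-0.5, 0.5)
    return np.exp(-0.5 * (d / width) ** 2)


def _circular_shift(profile: np.ndarray, shift: float) -> np.ndarray:
    """Shift a one-cycle profile by ``shift`` (fraction of cycle), periodic."""
    nt = profile.size
    phase = np.linspace(0.0, 1.0, nt)
    src = (phase - shift) % 1.0
    # periodic linear interpolation on the closed [0, 1] grid
    return np.interp(src, phase, profile, period=1.0)


def make_ground_truth(
    n_muscles: int, n_syn: int, seed, n_samples: int = 101
) -> GroundTruthSynergies:
    """Draw a random synergy ground truth with distinct weights and bursts.

    The structure mimics locomotor synergies: the muscles are partitioned
    among the synergies so each synergy strongly activates its own group
    (plus one modest cross weight and a small common baseline), and each
    activation profile is one or, occasionally, two narrow Gaussian bursts
    whose peak phases are spread over the gait cycle, peak-normalized to
    1. This makes the factorization essentially unique and gives every
    synergy a substantial share of the signal variance, as burst-like
    gait EMG does. Pairwise weight-column correlations are verified to be
    below 0.9.
    """
    if not 1 <= n_syn <= n_muscles:
        raise ConfigurationError(f"need 1 <= n_syn <= n_muscles, got {n_syn} > {n_muscles}")
    ss = _as_seedseq(seed)
    rng = default_rng(ss)

    phase = np.linspace(0.0, 1.0, n_samples)
    profiles = np.empty((n_syn, n_samples))
    centers = (np.arange(n_syn) + rng.uniform(0.1, 0.9)) / n_syn
    for i in range(n_syn):
        c = centers[i] + rng.uniform(-0.12, 0.12) / n_syn
        prof = _periodic_bump(phase, c, rng.uniform(0.035, 0.06))
        if rng.random() < 0.25:  # bimodal burst
            c2 = (c + 0.45 / n_syn + rng.uniform(0.0, 0.1)) % 1.0
            prof = prof + rng.uniform(0.25, 0.5) * _periodic_bump(
                phase, c2, rng.uniform(0.035, 0.06)
            )
        profiles[i] = prof / prof.max()

    chunks = np.array_split(rng.permutation(n_muscles), n_syn)
    W = rng.uniform(0.0, 0.06, (n_muscles, n_syn))
    for i, chunk in enumerate(chunks):
        W[chunk, i] += rng.uniform(0.8, 1.5, chunk.size)
        others = np.setdiff1d(np.arange(n_muscles), chunk)
        if others.size:
            W[rng.choice(others), i] += rng.uniform(0.1, 0.25)
    for i in range(n_syn):
        for j in range(i):
            if np.corrcoef(W[:, i], W[:, j])[0, 1] >= _MAX_WEIGHT_CORR:
                raise ConfigurationError("generated weight columns are not distinct")

    seed_int = int(ss.entropy) if isinstance(ss.entropy, int) and ss.entropy < 2**63 else 0
    return GroundTruthSynergies(
        W_true=W,
        H_true_profile=profiles,
        n_syn=n_syn,
        seed=seed_int,
    )


def _tiled_profiles(gt: GroundTruthSynergies, cfg: SimulationConfig, rng) -> np.ndarray:
    """Nc copies of the one-cycle profiles with optional per-stride jitter."""
    blocks = []
    for _ in range(cfg.n_cycles):
        block = gt.H_true_profile
        if cfg.phase_jitter > 0 or cfg.amplitude_jitter > 0:
            block = block.copy()
            for i in range(gt.n_syn):
                if cfg.phase_jitter > 0:
                    block[i] = _circular_shift(
                        block[i], cfg.phase_jitter * 0.05 * rng.uniform(-1.0, 1.0)
                    )
                if cfg.amplitude_jitter > 0:
                    block[i] = block[i] * max(
                        0.0, 1.0 + cfg.amplitude_jitter * 0.5 * rng.uniform(-1.0, 1.0)
                    )
        blocks.append(block)
    return np.hstack(blocks)


def simulate_envelope(gt: GroundTruthSynergies, cfg: SimulationConfig) -> GaitCycleMatrix:
    """Build the noisy envelope matrix ``W_true @ H`` over Nc strides.

    With ``envelope_noise_sd = 0`` and zero jitter the output equals the
    exact product. Additive Gaussian noise (SD expressed as a fraction of
    the clean envelope's SD) is clipped at zero to preserve nonnegativity;
    multiplicative noise is available via ``cfg.multiplicative_noise``.
    """
    if gt.n_muscles != cfg.n_muscles or gt.n_samples != cfg.n_samples:
        raise ConfigurationError("ground truth and config dimensions disagree")
    rng = default_rng(_as_seedseq(cfg.seed).spawn(3)[0])
    h_tiled = _tiled_profiles(gt, cfg, rng)
    env = gt.W_true @ h_tiled
    if cfg.envelope_noise_sd > 0:
        sd = cfg.envelope_noise_sd * env.std()
        if cfg.multiplicative_noise:
            env = env * (1.0 + cfg.envelope_noise_sd * rng.standard_normal(env.shape))
        else:
            env = env + sd * rng.standard_normal(env.shape)
        env = np.clip(env, 0.0, None)
    return GaitCycleMatrix(
        data=env,
        n_cycles=cfg.n_cycles,
        n_samples_per_cycle=cfg.n_samples,
        channel_names=default_channel_names(cfg.n_muscles),
    )


def simulate_raw(envelope: GaitCycleMatrix, cfg: SimulationConfig) -> RawEMGRecording:
    """Amplitude-modulate a band-limited noise carrier by the envelope.

    Each channel is zero-mean Gaussian noise band-passed to
    ``cfg.carrier_band`` (a standard surrogate for the surface-EMG
    interference pattern), multiplied by the envelope upsampled to the raw
    sampling rate. Stride durations are drawn around
    ``cycle_duration_mean`` with CV ``cycle_duration_cv``; heel-strike
    times (``n_cycles + 1`` of them) are emitted accordingly, and
    ``edge_pad_s`` of held-envelope signal is prepended/appended so the
    filtering chain's transients fall outside the strides.
    """
    lo, hi = cfg.carrier_band
    if hi >= cfg.sampling_rate / 2:
        raise ConfigurationError("carrier band must lie below the Nyquist frequency")
    rng = default_rng(_as_seedseq(cfg.seed).spawn(4)[1])
    fs = cfg.sampling_rate
    nc, nt = envelope.n_cycles, envelope.n_samples_per_cycle

    durations = cfg.cycle_duration_mean * (
        1.0 + cfg.cycle_duration_cv * rng.standard_normal(nc)
    )
    durations = np.clip(durations, 0.4 * cfg.cycle_duration_mean, None)
    heel_strikes = cfg.edge_pad_s + np.concatenate(([0.0], np.cumsum(durations)))
    total = heel_strikes[-1] + cfg.edge_pad_s
    n = int(round(total * fs))
    t = np.arange(n) / fs

    # envelope sample times: stride c occupies [hs_c, hs_{c+1}], its Nt
    # columns sit on a uniform phase grid including both endpoints; shared
    # boundaries are deduplicated by dropping the repeated phase-0 sample
    knot_t: list[np.ndarray] = []
    knot_idx: list[np.ndarray] = []
    phase = np.linspace(0.0, 1.0, nt)
    for c in range(nc):
        tt = heel_strikes[c] + phase * durations[c]
        cols = np.arange(c * nt, (c + 1) * nt)
        if c > 0:
            tt, cols = tt[1:], cols[1:]
        knot_t.append(tt)
        knot_idx.append(cols)
    tt = np.concatenate(knot_t)
    cols = np.concatenate(knot_idx)

    nm = envelope.n_muscles
    env_t = np.empty((nm, n))
    for m in range(nm):
        env_t[m] = np.interp(t, tt, envelope.data[m, cols])

    sos = sps.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
    carrier = sps.sosfiltfilt(sos, rng.standard_normal((nm, n)), axis=1)
    csd = carrier.std(axis=1, keepdims=True)
    carrier = carrier / np.where(csd > 0, csd, 1.0)

    return RawEMGRecording(
        signals=env_t * carrier,
        sampling_rate=fs,
        channel_names=list(envelope.channel_names),
        heel_strikes=heel_strikes,
    )


def perturb_ground_truth(
    gt: GroundTruthSynergies, dW_mag: float, dH_mag: float, seed
) -> GroundTruthSynergies:
    """Emulate a post-treatment synergy change of controllable size.

    Weights: each column of ``W_true`` is mixed toward a random nonnegative
    direction of equal norm, ``(1 - dW_mag) * w + dW_mag * d`` — the column
    correlation with the original decays monotonically with ``dW_mag``.
    Profiles: each activation burst is phase-shifted by ``dH_mag`` times a
    per-synergy random fraction of the cycle (up to ~0.4), then
    re-peak-normalized. ``(0, 0)`` returns the ground truth unchanged.
    """
    if not (0.0 <= dW_mag <= 1.0 and 0.0 <= dH_mag <= 1.0):
        raise ConfigurationError("perturbation magnitudes must lie in [0, 1]")
    if dW_mag == 0.0 and dH_mag == 0.0:
        return dataclasses.replace(gt)
    rng = default_rng(_as_seedseq(seed).spawn(5)[2])

    W = gt.W_true.copy()
    if dW_mag > 0:
        direction = rng.uniform(0.05, 1.0, W.shape)
        direction *= np.linalg.norm(W, axis=0) / np.linalg.norm(direction, axis=0)
        W = (1.0 - dW_mag) * W + dW_mag * direction

    H = gt.H_true_profile.copy()
    if dH_mag > 0:
        for i in range(gt.n_syn):
            shift = dH_mag * rng.choice([-1.0, 1.0]) * rng.uniform(0.15, 0.4)
            H[i] = _circular_shift(H[i], shift)
        H = H / H.max(axis=1, keepdims=True)

    return GroundTruthSynergies(W_true=W, H_true_profile=H, n_syn=gt.n_syn, seed=gt.seed)


def scaled_weights(gt: GroundTruthSynergies, channel_scale: np.ndarray) -> np.ndarray:
    """Map ground-truth weights into the unit-SD channel space.

    The pipeline divides every EMG channel by its own SD before
    extraction, so a recovered ``W`` lives in that scaled space; to
    compare it against the generative weights, the same per-channel
    divisors must be applied to ``W_true``. Column correlations are
    unaffected by the subsequent (column-wise) scale ambiguity of NNMF,
    not by this row scaling — hence the explicit mapping.
    """
    return gt.W_true / np.asarray(channel_scale, dtype=float)[:, None]


def simulate_td_like(
    cfg: SimulationConfig, n_syn_td: int = 5, seed=0
) -> GaitCycleMatrix:
    """Typically-developing surrogate from an independent, richer synergy set.

    Generated from its own ``n_syn_td``-synergy ground truth (default 5,
    richer than typical patient ranks of 2-4), so patient-derived low-rank
    synergies explain it poorly and the specificity statistic has a true
    positive signal.
    """
    if n_syn_td < 1:
        raise ConfigurationError("n_syn_td must be >= 1")
    ss = _as_seedseq(seed)
    gt_td = make_ground_truth(cfg.n_muscles, n_syn_td, ss.spawn(2)[1], cfg.n_samples)
    return simulate_envelope(gt_td, cfg.replace(seed=ss.spawn(2)[0]))
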