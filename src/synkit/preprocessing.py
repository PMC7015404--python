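"""Raw EMG to the unit-variance, time-normalized envelope matrix.

The chain is the standard gait-EMG recipe: per channel, high-pass
Butterworth at 40 Hz, demean, full-wave rectify, low-pass Butterworth at
6 Hz (6th order); each stride (heel strike to next heel strike) is then
resampled to 101 points on a uniform phase grid, strides are concatenated,
and every channel is divided by its own standard deviation. Unit-SD
scaling removes amplitude differences caused by electrode placement across
sessions and subjects; the divisors are kept so the scaling is invertible.

Filters are applied forward-backward (zero phase) by default so the
envelope is not delayed relative to the gait events; rectification must
precede the low-pass stage — the order is what turns the interference
pattern into an amplitude envelope.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .datatypes import (
    ConfigurationError,
    DegenerateChannelError,
    EligibilityError,
    GaitCycleMatrix,
    RawEMGRecording,
    SignalLengthError,
)

__all__ = ["envelope", "segment_normalize", "concatenate_scale", "preprocess", "ensure_scaled"]

_MIN_CHANNEL_SD = 1e-12


def envelope(
    raw: RawEMGRecording,
    hp_cutoff: float = 40.0,
    lp_cutoff: float = 6.0,
    order: int = 6,
    zero_phase: bool = True,
) -> RawEMGRecording:
    """High-pass, demean, rectify and low-pass each channel.

    Returns a recording of the same shape holding the nonnegative linear
    envelope. ``order`` is the designed Butterworth order per pass; with
    ``zero_phase`` the filter runs forward and backward (no group delay).
    """
    nyquist = raw.sampling_rate / 2.0
    for name, cutoff in (("hp_cutoff", hp_cutoff), ("lp_cutoff", lp_cutoff)):
        if not 0 < cutoff < nyquist:
            raise ConfigurationError(
                f"{name}={cutoff} Hz outside (0, Nyquist={nyquist} Hz)"
            )
    if raw.n_samples <= 3 * (2 * order + 1):
        raise SignalLengthError(
            f"{raw.n_samples} samples is too short for an order-{order} filter"
        )
    sos_hp = sps.butter(order, hp_cutoff, btype="highpass", fs=raw.sampling_rate, output="sos")
    sos_lp = sps.butter(order, lp_cutoff, btype="lowpass", fs=raw.sampling_rate, output="sos")
    apply = sps.sosfiltfilt if zero_phase else sps.sosfilt

    x = apply(sos_hp, raw.signals, axis=1)
    x = x - x.mean(axis=1, keepdims=True)
    x = np.abs(x)
    x = apply(sos_lp, x, axis=1)
    x = np.clip(x, 0.0, None)  # low-pass ringing may undershoot zero
    return dataclasses.replace(raw, signals=x)


def segment_normalize(
    rec: RawEMGRecording,
    heel_strikes: np.ndarray | None = None,
    n_samples: int = 101,
    require_cycles: int | None = None,
) -> list[np.ndarray]:
    """Cut the envelope into strides and resample each to ``n_samples``.

    Each stride runs from one heel strike (phase 0) to the next (phase 1,
    inclusive) and is linearly interpolated onto a uniform phase grid of
    ``n_samples`` points — monotone and nonnegativity-preserving. Only
    strides fully contained in the recording are used. If
    ``require_cycles`` is given, at least that many complete strides must
    be present (the study's eligibility rule uses 5) and exactly that many
    (the first ones) are returned.
    """
    if n_samples < 2:
        raise ConfigurationError("n_samples must be >= 2")
    hs = np.asarray(rec.heel_strikes if heel_strikes is None else heel_strikes, dtype=float)
    if hs.ndim != 1 or hs.size < 2 or not np.all(np.diff(hs) > 0):
        raise EligibilityError("need >= 2 strictly increasing heel-strike times")

    t_end = (rec.n_samples - 1) / rec.sampling_rate
    tol = 0.5 / rec.sampling_rate
    pairs = [
        (hs[i], hs[i + 1])
        for i in range(hs.size - 1)
        if hs[i] >= -tol and hs[i + 1] <= t_end + tol
    ]
    if not pairs:
        raise EligibilityError("no complete gait cycle inside the recording")
    if require_cycles is not None:
        if len(pairs) < require_cycles:
            raise EligibilityError(
                f"leg has {len(pairs)} complete gait cycles, {require_cycles} required"
            )
        pairs = pairs[:require_cycles]

    t = np.arange(rec.n_samples) / rec.sampling_rate
    phase = np.linspace(0.0, 1.0, n_samples)
    cycles = []
    for a, b in pairs:
        tt = a + phase * (b - a)
        cyc = np.empty((rec.n_channels, n_samples))
        for m in range(rec.n_channels):
            cyc[m] = np.interp(tt, t, rec.signals[m])
        cycles.append(np.clip(cyc, 0.0, None))
    return cycles


def concatenate_scale(
    cycles: list[np.ndarray], channel_names: list[str] | None = None
) -> GaitCycleMatrix:
    """Concatenate strides along time and scale each channel to unit SD.

    The per-channel divisors (the original SDs over the concatenated
    signal) are stored in ``channel_scale`` so the scaling round-trips. A
    flat channel cannot be scaled and raises, naming the muscle.
    """
    if not cycles:
        raise EligibilityError("no cycles to concatenate")
    nm = cycles[0].shape[0]
    nt = cycles[0].shape[1]
    if any(c.shape != (nm, nt) for c in cycles):
        raise ConfigurationError("all cycles must share the same shape")
    if channel_names is None:
        from .datatypes import default_channel_names

        channel_names = default_channel_names(nm)

    data = np.hstack(cycles)
    sd = data.std(axis=1, ddof=0)
    flat = np.flatnonzero(sd < _MIN_CHANNEL_SD)
    if flat.size:
        names = ", ".join(channel_names[i] for i in flat)
        raise DegenerateChannelError(f"zero-variance channel(s): {names}")
    return GaitCycleMatrix(
        data=data / sd[:, None],
        n_cycles=len(cycles),
        n_samples_per_cycle=nt,
        channel_names=list(channel_names),
        channel_scale=sd,
    )


def preprocess(
    raw: RawEMGRecording,
    hp_cutoff: float = 40.0,
    lp_cutoff: float = 6.0,
    order: int = 6,
    zero_phase: bool = True,
    n_samples: int = 101,
    require_cycles: int | None = None,
) -> GaitCycleMatrix:
    """Full chain: envelope -> stride segmentation -> unit-SD matrix."""
    env = envelope(raw, hp_cutoff=hp_cutoff, lp_cutoff=lp_cutoff, order=order, zero_phase=zero_phase)
    cycles = segment_normalize(env, n_samples=n_samples, require_cycles=require_cycles)
    return concatenate_scale(cycles, channel_names=list(raw.channel_names))


def ensure_scaled(emg: GaitCycleMatrix) -> GaitCycleMatrix:
    """Return ``emg`` with unit-SD channels, scaling it if not yet scaled."""
    if emg.is_scaled:
        return emg
    sd = emg.data.std(axis=1, ddof=0)
    flat = np.flatnonzero(sd < _MIN_CHANNEL_SD)
    if flat.size:
        names = ", ".join(emg.channel_names[i] for i in flat)
        raise DegenerateChannelError(f"zero-variance channel(s): {names}")
    return GaitCycleMatrix(
        data=emg.data / sd[:, None],
        n_cycles=emg.n_cycles,
        n_samples_per_cycle=emg.n_samples_per_cycle,
        channel_names=list(emg.channel_names),
        channel_scale=sd,
    )
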