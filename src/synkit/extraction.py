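"""Synergy extraction: NNMF, the VAF statistic, and bootstrap rank selection.

The factorization ``EMG ~ W @ H`` (both factors nonnegative) is fit with
multiplicative updates under the Frobenius loss, restarted from several
seeded random initializations and keeping the best fit. Goodness of fit is
the variance accounted for,

    VAF = (sum_mt EMG_mt * recEMG_mt)^2
          / (sum_mt EMG_mt^2 * sum_mt recEMG_mt^2) * 100,

the squared uncentered correlation of the vectorized matrices — scale
invariant and bounded in [0, 100] by Cauchy-Schwarz.

The number of synergies is chosen by a bootstrap: with the full-data fit
held fixed, time columns are resampled with replacement (the same column
indices applied to the data and to ``H``) and VAF recomputed per
replicate; the smallest rank whose 95th-percentile VAF exceeds 90% is
selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.random import SeedSequence, default_rng

from .datatypes import (
    ConfigurationError,
    DataError,
    GaitCycleMatrix,
    SynergySet,
    UndefinedVAFError,
)

__all__ = [
    "vaf",
    "vaf_per_muscle",
    "nnmf",
    "bootstrap_select_nsyn",
    "average_activation_profile",
    "NsynSelection",
]

_EPS = 1e-12


def vaf(emg_xp: np.ndarray, rec_emg: np.ndarray) -> float:
    """Variance accounted for, in percent.

    Squared uncentered correlation between the vectorized experimental and
    reconstructed matrices, times 100. Undefined (raises) when either
    signal is identically zero.
    """
    x = np.asarray(emg_xp, dtype=float)
    r = np.asarray(rec_emg, dtype=float)
    if x.shape != r.shape:
        raise DataError(f"shape mismatch: {x.shape} vs {r.shape}")
    sx = float(np.sum(x * x))
    sr = float(np.sum(r * r))
    if sx <= 0.0 or sr <= 0.0:
        raise UndefinedVAFError("VAF undefined for an identically zero signal")
    cross = float(np.sum(x * r))
    return min(cross * cross / (sx * sr) * 100.0, 100.0)


def vaf_per_muscle(emg_xp: np.ndarray, rec_emg: np.ndarray) -> np.ndarray:
    """The VAF formula applied to each muscle row independently.

    Rows where either signal is identically zero are undefined and
    returned as NaN rather than zero.
    """
    x = np.asarray(emg_xp, dtype=float)
    r = np.asarray(rec_emg, dtype=float)
    if x.shape != r.shape:
        raise DataError(f"shape mismatch: {x.shape} vs {r.shape}")
    out = np.full(x.shape[0], np.nan)
    for m in range(x.shape[0]):
        try:
            out[m] = vaf(x[m], r[m])
        except UndefinedVAFError:
            pass
    return out


def _multiplicative_update(V, n_syn, rng, tol, max_iter):
    """One Lee-Seung Frobenius NNMF run; returns (W, H, error trace)."""
    nm, nc = V.shape
    scale = np.sqrt(V.mean() / max(n_syn, 1)) + _EPS
    W = scale * (0.1 + rng.random((nm, n_syn)))
    H = scale * (0.1 + rng.random((n_syn, nc)))
    norm_v = np.linalg.norm(V)
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        err = np.linalg.norm(V - W @ H)
        trace.append(err)
        if prev - err < tol * max(norm_v, _EPS):
            break
        prev = err
    return W, H, np.asarray(trace)


def nnmf(
    emg: GaitCycleMatrix | np.ndarray,
    n_syn: int,
    n_restarts: int = 10,
    seed=0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_samples: int | None = None,
    source: str = "subject-specific",
) -> SynergySet:
    """Best-of-restarts NNMF of the envelope matrix.

    Runs ``n_restarts`` seeded multiplicative-update fits and keeps the one
    with the smallest Frobenius reconstruction error. ``tol`` is the
    per-iteration objective decrease (relative to ``||EMG||_F``) below
    which a run stops. ``fit_vaf`` is the VAF of ``W @ H`` against the
    input; ``H_avg`` averages the per-stride windows of ``H``.
    """
    if isinstance(emg, GaitCycleMatrix):
        V = emg.data
        n_samples = emg.n_samples_per_cycle
    else:
        V = np.asarray(emg, dtype=float)
        if n_samples is None:
            n_samples = V.shape[1]
    if not np.all(np.isfinite(V)):
        raise DataError("envelope matrix contains non-finite values")
    if np.any(V < 0):
        raise DataError("envelope matrix must be nonnegative")
    if not 1 <= n_syn <= V.shape[0]:
        raise ConfigurationError(
            f"need 1 <= n_syn <= n_muscles, got n_syn={n_syn}, n_muscles={V.shape[0]}"
        )
    if n_restarts < 1:
        raise ConfigurationError("n_restarts must be >= 1")

    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        W, H, trace = _multiplicative_update(V, n_syn, default_rng(child), tol, max_iter)
        if best is None or trace[-1] < best[2][-1]:
            best = (W, H, trace)
    W, H, _ = best

    h_avg = average_activation_profile(H, n_samples)
    return SynergySet(
        W=W,
        H=H,
        H_avg=h_avg,
        n_syn=n_syn,
        source=source,
        fit_vaf=vaf(V, W @ H),
    )


def average_activation_profile(H: np.ndarray, n_samples: int) -> np.ndarray:
    """Average the per-stride windows of ``H`` into an ``Nsyn x Nt`` profile.

    ``H`` may span several strides of one subject or of a whole cohort
    group; its column count must be a multiple of ``n_samples``.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[1] % n_samples != 0:
        raise DataError(
            f"H column count {H.shape[1]} is not a multiple of n_samples={n_samples}"
        )
    n_windows = H.shape[1] // n_samples
    return H.reshape(H.shape[0], n_windows, n_samples).mean(axis=1)


@dataclass
class NsynSelection:
    """Outcome of the bootstrap model-order selection.

    ``vaf_distributions`` maps each candidate rank to its ``n_boot``
    bootstrap VAF values; ``fits`` keeps the full-data NNMF per candidate
    so the selected factorization can be reused without refitting.
    """

    n_syn: int
    criterion_met: bool
    percentiles: dict[int, float]
    vaf_distributions: dict[int, np.ndarray]
    fits: dict[int, SynergySet]

    @property
    def selected_fit(self) -> SynergySet:
        return self.fits[self.n_syn]


def bootstrap_select_nsyn(
    emg: GaitCycleMatrix,
    n_boot: int = 500,
    percentile: float = 95.0,
    vaf_threshold: float = 90.0,
    seed=0,
    n_restarts: int = 10,
    tol: float = 1e-6,
    max_iter: int = 2000,
    max_n_syn: int | None = None,
) -> NsynSelection:
    """Smallest rank whose bootstrap VAF percentile clears the threshold.

    For each candidate rank (scanned upward from 1) the NNMF is fit once
    on the full data; each bootstrap replicate draws time-column indices
    with replacement and applies the same indices to the data and to
    ``H``, so VAF is recomputed on resampled columns with ``W`` fixed.
    The first rank whose ``percentile``-th VAF percentile exceeds
    ``vaf_threshold`` is returned. If no rank qualifies, the largest
    candidate is returned with ``criterion_met=False`` and a warning.
    Replicates whose resampled data are identically zero are redrawn.
    """
    if n_boot < 1:
        raise ConfigurationError("n_boot must be >= 1")
    nm = emg.n_muscles
    max_n_syn = nm if max_n_syn is None else min(max_n_syn, nm)
    ss = seed if isinstance(seed, SeedSequence) else SeedSequence(seed)
    fit_seeds = ss.spawn(max_n_syn + 1)

    distributions: dict[int, np.ndarray] = {}
    percentiles: dict[int, float] = {}
    fits: dict[int, SynergySet] = {}
    rng = default_rng(fit_seeds[-1])
    n_cols = emg.data.shape[1]

    for n_syn in range(1, max_n_syn + 1):
        syn = nnmf(
            emg, n_syn, n_restarts=n_restarts, seed=fit_seeds[n_syn - 1],
            tol=tol, max_iter=max_iter,
        )
        fits[n_syn] = syn
        rec = syn.reconstruction()
        vals = np.empty(n_boot)
        for b in range(n_boot):
            for _ in range(100):
                idx = rng.integers(0, n_cols, n_cols)
                if emg.data[:, idx].any():
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise DataError("could not draw a nonzero bootstrap resample")
            vals[b] = vaf(emg.data[:, idx], rec[:, idx])
        distributions[n_syn] = vals
        percentiles[n_syn] = float(np.percentile(vals, percentile))
        if percentiles[n_syn] > vaf_threshold:
            return NsynSelection(n_syn, True, percentiles, distributions, fits)

    warnings.warn(
        f"bootstrap criterion not met up to n_syn={max_n_syn}; returning {max_n_syn}",
        stacklevel=2,
    )
    return NsynSelection(max_n_syn, False, percentiles, distributions, fits)
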