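"""Reconstruct target EMG with one pre-treatment factor held fixed.

Two hypotheses about how motor control adapts after treatment are probed
by reconstructing the post-treatment (or typically-developing) envelope
from the pre-treatment synergies:

* AOA (activation optimization approach): the weight vectors ``W_pre``
  stay fixed, the activations ``H_opt >= 0`` are optimized.
* WOA (weight optimization approach): the stride-averaged activation
  profiles ``H_pre`` stay fixed (tiled over the target's strides), the
  weights ``W_opt >= 0`` are optimized.

Both minimize ``sum_mt (EMG_xp - fixed @ free)^2`` under nonnegativity.
The problem is separable — per time column for AOA, per muscle row for
WOA — and each subproblem is a convex nonnegative least-squares solved
exactly (active-set NNLS), so the global optimum is attained.

Targets are unit-SD scaled by their own channel SDs before fitting, the
same rule applied before extraction, so session-to-session amplitude
differences (electrode placement) do not enter the comparison.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import nnls

from .datatypes import (
    ConfigurationError,
    DataError,
    GaitCycleMatrix,
    ReconstructionResult,
)
from .extraction import vaf, vaf_per_muscle
from .preprocessing import ensure_scaled

__all__ = ["reconstruct_aoa", "reconstruct_woa", "nnls_columns", "tile_profile"]


def nnls_columns(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve ``min ||A X - B||_F`` s.t. ``X >= 0`` column by column."""
    A = np.ascontiguousarray(A, dtype=float)
    X = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        X[:, j], _ = nnls(A, B[:, j])
    return X


def tile_profile(h_avg: np.ndarray, n_cycles: int) -> np.ndarray:
    """Repeat a one-stride profile over ``n_cycles`` strides."""
    return np.tile(np.asarray(h_avg, dtype=float), (1, n_cycles))


def _target_matrix(target: GaitCycleMatrix | np.ndarray, scale_target: bool) -> np.ndarray:
    if isinstance(target, GaitCycleMatrix):
        return (ensure_scaled(target) if scale_target else target).data
    return np.asarray(target, dtype=float)


def reconstruct_aoa(
    w_pre: np.ndarray,
    target: GaitCycleMatrix | np.ndarray,
    target_label: str = "",
    source: str = "subject-specific",
    scale_target: bool = True,
) -> ReconstructionResult:
    """Fit the target with fixed weights and free nonnegative activations.

    ``H_opt`` solves an exact NNLS per time column; rank-deficient
    ``w_pre`` still yields an optimal objective but the solution is
    flagged ``non_unique``.
    """
    w_pre = np.asarray(w_pre, dtype=float)
    T = _target_matrix(target, scale_target)
    if T.shape[0] != w_pre.shape[0]:
        raise DataError(
            f"target has {T.shape[0]} muscles but weights have {w_pre.shape[0]} rows"
        )
    if np.any(w_pre.max(axis=0) <= 0):
        raise ConfigurationError("w_pre has an all-zero column")

    h_opt = nnls_columns(w_pre, T)
    rec = w_pre @ h_opt
    return ReconstructionResult(
        approach="AOA",
        target_label=target_label,
        optimized_factor=h_opt,
        rec_emg=rec,
        vaf_global=vaf(T, rec),
        vaf_per_muscle=vaf_per_muscle(T, rec),
        source=source,
        non_unique=np.linalg.matrix_rank(w_pre) < w_pre.shape[1],
    )


def reconstruct_woa(
    h_pre_avg: np.ndarray,
    target: GaitCycleMatrix | np.ndarray,
    n_cycles: int | None = None,
    target_label: str = "",
    source: str = "subject-specific",
    scale_target: bool = True,
    average_target: bool = False,
) -> ReconstructionResult:
    """Fit the target with fixed activation profiles and free weights.

    The one-stride profile ``h_pre_avg`` (``Nsyn x Nt``) is tiled across
    the target's strides so every target stride enters the fit; ``W_opt``
    solves an exact NNLS per muscle row. With ``average_target`` the
    target strides are averaged to a single ``Nm x Nt`` matrix instead of
    tiling the profile.
    """
    h_pre_avg = np.asarray(h_pre_avg, dtype=float)
    if np.any(h_pre_avg.max(axis=1) <= 0):
        raise ConfigurationError("h_pre_avg has an all-zero row")
    T = _target_matrix(target, scale_target)
    if isinstance(target, GaitCycleMatrix):
        n_cycles = target.n_cycles
        nt = target.n_samples_per_cycle
    else:
        nt = h_pre_avg.shape[1]
        if n_cycles is None:
            if T.shape[1] % nt != 0:
                raise DataError("target columns not a multiple of the profile length")
            n_cycles = T.shape[1] // nt
        elif T.shape[1] != n_cycles * nt:
            raise DataError(
                f"target has {T.shape[1]} columns, expected {n_cycles} x {nt}"
            )
    if nt != h_pre_avg.shape[1]:
        raise DataError(
            f"profile has {h_pre_avg.shape[1]} samples but target strides have {nt}"
        )

    if average_target:
        T_fit = T.reshape(T.shape[0], n_cycles, nt).mean(axis=1)
        H = h_pre_avg
    else:
        T_fit = T
        H = tile_profile(h_pre_avg, n_cycles)

    # per-row NNLS: min ||H^T w_m - t_m||
    w_opt = nnls_columns(H.T, T_fit.T).T
    rec = w_opt @ tile_profile(h_pre_avg, n_cycles)
    return ReconstructionResult(
        approach="WOA",
        target_label=target_label,
        optimized_factor=w_opt,
        rec_emg=rec,
        vaf_global=vaf(T, rec),
        vaf_per_muscle=vaf_per_muscle(T, rec),
        source=source,
        non_unique=np.linalg.matrix_rank(h_pre_avg) < h_pre_avg.shape[0],
    )
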