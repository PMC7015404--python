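"""Core containers and exceptions shared across the synergy pipeline.

All matrices follow the muscles-by-time convention: rows are EMG channels
(muscles), columns are time samples. A gait-cycle matrix holds ``Nc``
time-normalized strides of ``Nt`` samples each, concatenated along time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: The eight lower-limb muscles recorded per leg in clinical gait analysis.
DEFAULT_MUSCLES = (
    "rectus_femoris",
    "vastus_lateralis",
    "biceps_femoris_long",
    "medial_hamstrings",
    "tibialis_anterior",
    "gastrocnemius",
    "soleus",
    "gluteus_medius",
)


class SynkitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SynkitError, ValueError):
    """A parameter is outside its valid range."""


class DataError(SynkitError, ValueError):
    """Input data violates a structural requirement (shape, finiteness)."""


class SignalLengthError(DataError):
    """The recording is too short for the requested filter."""


class EligibilityError(DataError):
    """A leg does not meet the inclusion rule (complete gait cycles)."""


class DegenerateChannelError(DataError):
    """A channel has (near-)zero variance and cannot be unit-SD scaled."""


class UndefinedVAFError(DataError):
    """VAF is undefined because one of the signals is identically zero."""


class UndefinedMetricError(DataError):
    """A summary metric has no valid constituent values."""


def default_channel_names(n: int) -> list[str]:
    """Muscle names for ``n`` channels (standard set for n=8, generic otherwise)."""
    if n == len(DEFAULT_MUSCLES):
        return list(DEFAULT_MUSCLES)
    return [f"muscle_{i + 1}" for i in range(n)]


@dataclass
class RawEMGRecording:
    """Multi-channel raw EMG plus gait events.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)``, arbitrary units.
    sampling_rate
        Sampling frequency in Hz.
    channel_names
        One label per channel, in row order.
    heel_strikes
        Strictly increasing event times in seconds; ``k + 1`` heel strikes
        delimit ``k`` complete gait cycles.
    """

    signals: np.ndarray
    sampling_rate: float
    channel_names: list[str]
    heel_strikes: np.ndarray

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.heel_strikes = np.asarray(self.heel_strikes, dtype=float)
        if self.signals.ndim != 2:
            raise DataError("signals must be a 2-D channels x samples array")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if len(self.channel_names) != self.signals.shape[0]:
            raise DataError("channel_names length must match number of signal rows")
        if self.heel_strikes.size >= 2 and not np.all(np.diff(self.heel_strikes) > 0):
            raise DataError("heel_strikes must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def n_cycles(self) -> int:
        """Number of complete gait cycles delimited by the heel strikes."""
        return max(0, self.heel_strikes.size - 1)


@dataclass
class GaitCycleMatrix:
    """Envelope EMG segmented into strides and time-normalized.

    ``data`` has ``Nm`` rows and ``Nc * Nt`` columns: ``Nc`` strides of
    ``Nt`` samples each, concatenated along time. When ``channel_scale`` is
    set, each row has been divided by that per-channel standard deviation and
    therefore has unit SD.
    """

    data: np.ndarray
    n_cycles: int
    n_samples_per_cycle: int
    channel_names: list[str]
    channel_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError("data must be 2-D")
        if self.data.shape[1] != self.n_cycles * self.n_samples_per_cycle:
            raise DataError(
                f"column count {self.data.shape[1]} != n_cycles * n_samples_per_cycle "
                f"({self.n_cycles} * {self.n_samples_per_cycle})"
            )
        if np.any(self.data < 0):
            raise DataError("gait-cycle matrix must be nonnegative")
        if len(self.channel_names) != self.data.shape[0]:
            raise DataError("channel_names length must match number of rows")
        if self.channel_scale is not None:
            self.channel_scale = np.asarray(self.channel_scale, dtype=float)
            if self.channel_scale.shape != (self.data.shape[0],):
                raise DataError("channel_scale must have one entry per channel")

    @property
    def n_muscles(self) -> int:
        return self.data.shape[0]

    @property
    def is_scaled(self) -> bool:
        return self.channel_scale is not None

    def cycle(self, index: int) -> np.ndarray:
        """Return stride ``index`` as an ``Nm x Nt`` view."""
        nt = self.n_samples_per_cycle
        return self.data[:, index * nt : (index + 1) * nt]

    def unscaled(self) -> np.ndarray:
        """Undo the unit-SD scaling, recovering the pre-scaling envelope."""
        if self.channel_scale is None:
            return self.data.copy()
        return self.data * self.channel_scale[:, None]


@dataclass
class SynergySet:
    """An NNMF factorization ``EMG ~ W @ H`` plus the stride-averaged profiles.

    ``W`` (``Nm x Nsyn``) holds the synergy weight vectors, ``H``
    (``Nsyn x columns``) the activation time courses over all concatenated
    strides, and ``H_avg`` (``Nsyn x Nt``) the element-wise average of the
    per-stride windows of ``H``.
    """

    W: np.ndarray
    H: np.ndarray
    H_avg: np.ndarray
    n_syn: int
    source: str = "subject-specific"
    fit_vaf: float = float("nan")

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.H = np.asarray(self.H, dtype=float)
        self.H_avg = np.asarray(self.H_avg, dtype=float)
        if self.W.shape[1] != self.n_syn or self.H.shape[0] != self.n_syn:
            raise DataError("W / H dimensions inconsistent with n_syn")
        if self.H_avg.shape[0] != self.n_syn:
            raise DataError("H_avg must have n_syn rows")
        if np.any(self.W < 0) or np.any(self.H < 0) or np.any(self.H_avg < 0):
            raise DataError("synergy factors must be nonnegative")
        if self.source not in ("subject-specific", "generic", "ground-truth"):
            raise ConfigurationError(f"unknown synergy source {self.source!r}")

    @property
    def n_muscles(self) -> int:
        return self.W.shape[0]

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class ReconstructionResult:
    """Outcome of fitting a target EMG with one factor fixed.

    ``approach`` is ``"AOA"`` (weights fixed, activations optimized) or
    ``"WOA"`` (activation profiles fixed, weights optimized).
    ``optimized_factor`` is ``H_opt`` for AOA and ``W_opt`` for WOA;
    ``rec_emg`` is the product of the fixed and the optimized factor.
    """

    approach: str
    target_label: str
    optimized_factor: np.ndarray
    rec_emg: np.ndarray
    vaf_global: float
    vaf_per_muscle: np.ndarray
    source: str = "subject-specific"
    non_unique: bool = False

    def __post_init__(self) -> None:
        if self.approach not in ("AOA", "WOA"):
            raise ConfigurationError("approach must be 'AOA' or 'WOA'")
        self.optimized_factor = np.asarray(self.optimized_factor, dtype=float)
        self.rec_emg = np.asarray(self.rec_emg, dtype=float)
        self.vaf_per_muscle = np.asarray(self.vaf_per_muscle, dtype=float)
        if np.any(self.optimized_factor < 0):
            raise DataError("optimized factor must be nonnegative")
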