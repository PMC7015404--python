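"""Derived statistics: GOOD, SPEC, IMP, synergy matching, dW and dH.

All VAF-difference statistics are in percentage points:

* ``GOOD = VAF_PRE - VAF_POST`` — how much worse pre-treatment synergies
  explain post-treatment data than the data they were fit on (0 means the
  post-treatment EMG is explained just as well).
* ``SPEC = VAF_POST - VAF_TD`` — specificity: how much better the
  patient's own post-treatment data is explained than typically-developing
  data (0 means the synergies fail to distinguish impaired from healthy).
* ``IMP = VAF_PRE - VAF_TD`` — a proxy for pre-treatment motor-control
  impairment. Algebraically ``SPEC = IMP - GOOD``.

Generic-synergy variants compare against the subject-specific ``VAF_PRE``
reference: ``GOOD_PRE_gen = VAF_PRE - VAF_PRE_gen``, ``GOOD_POST_gen =
VAF_PRE - VAF_POST_gen``, ``SPEC_PRE_gen = VAF_PRE_gen - VAF_TD_gen``,
``SPEC_POST_gen = VAF_POST_gen - VAF_TD_gen``.

Pre/post synergy change is measured after matching synergies one-to-one
on their weight vectors (optimal assignment maximizing summed Pearson
correlation): ``dW`` is the mean correlation of the matched weight
columns, ``dH`` the mean RMSE of the matched peak-normalized activation
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .datatypes import DataError, UndefinedMetricError

__all__ = [
    "SynergyMatching",
    "match_synergies",
    "delta_w",
    "delta_h",
    "compute_leg_metrics",
]


@dataclass
class SynergyMatching:
    """A one-to-one pairing of synergies between two sets.

    ``permutation[i] = j`` pairs column ``i`` of the first set with column
    ``j`` of the second; ``correlations[i]`` is the Pearson correlation of
    that pair (NaN where a zero-variance column makes it undefined).
    """

    permutation: np.ndarray
    correlations: np.ndarray

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.correlations).sum())


def _weight_correlations(w_a: np.ndarray, w_b: np.ndarray) -> np.ndarray:
    k = w_a.shape[1]
    corr = np.full((k, k), np.nan)
    sa = w_a.std(axis=0)
    sb = w_b.std(axis=0)
    for i in range(k):
        if sa[i] == 0:
            continue
        for j in range(k):
            if sb[j] == 0:
                continue
            corr[i, j] = np.corrcoef(w_a[:, i], w_b[:, j])[0, 1]
    return corr


def match_synergies(
    w_a: np.ndarray, w_b: np.ndarray, method: str = "optimal"
) -> SynergyMatching:
    """Pair each synergy of ``w_a`` with its most similar one in ``w_b``.

    ``method="optimal"`` solves the assignment maximizing total Pearson
    correlation between paired weight columns (Hungarian algorithm, exact
    for any K); ``method="greedy"`` repeatedly takes the best remaining
    pair. Zero-variance columns get NaN correlations and are matched last.
    """
    w_a = np.asarray(w_a, dtype=float)
    w_b = np.asarray(w_b, dtype=float)
    if w_a.ndim != 2 or w_a.shape != w_b.shape:
        raise DataError(f"weight matrices must share a shape, got {w_a.shape} vs {w_b.shape}")
    k = w_a.shape[1]
    corr = _weight_correlations(w_a, w_b)
    cost = np.where(np.isnan(corr), -2.0, corr)  # below any real correlation

    if method == "optimal":
        rows, cols = linear_sum_assignment(-cost)
        perm = np.empty(k, dtype=int)
        perm[rows] = cols
    elif method == "greedy":
        perm = np.full(k, -1, dtype=int)
        masked = cost.copy()
        for _ in range(k):
            i, j = np.unravel_index(np.argmax(masked), masked.shape)
            perm[i] = j
            masked[i, :] = -np.inf
            masked[:, j] = -np.inf
    else:
        raise DataError(f"unknown matching method {method!r}")

    return SynergyMatching(permutation=perm, correlations=corr[np.arange(k), perm])


def delta_w(correlations: np.ndarray) -> float:
    """Mean matched-pair weight correlation (one value per leg)."""
    correlations = np.asarray(correlations, dtype=float)
    valid = correlations[~np.isnan(correlations)]
    if valid.size == 0:
        raise UndefinedMetricError("no valid synergy pair for dW")
    return float(valid.mean())


def delta_h(
    h_a_avg: np.ndarray, h_b_avg: np.ndarray, permutation: np.ndarray
) -> float:
    """Mean RMSE between matched peak-normalized activation profiles.

    Each profile is divided by its maximum (so both lie in [0, 1]) before
    the per-pair RMSE over the stride samples; pairs with an all-zero
    profile are undefined and skipped.
    """
    h_a_avg = np.asarray(h_a_avg, dtype=float)
    h_b_avg = np.asarray(h_b_avg, dtype=float)
    if h_a_avg.shape[1] != h_b_avg.shape[1]:
        raise DataError("activation profiles must share the number of samples")
    rmses = []
    for i, j in enumerate(permutation):
        pa, pb = h_a_avg[i], h_b_avg[j]
        if pa.max() <= 0 or pb.max() <= 0:
            continue
        diff = pa / pa.max() - pb / pb.max()
        rmses.append(np.sqrt(np.mean(diff**2)))
    if not rmses:
        raise UndefinedMetricError("no valid synergy pair for dH")
    return float(np.mean(rmses))


def compute_leg_metrics(
    vaf_pre: float,
    vaf_post: float,
    vaf_td_mean: float,
    generic_vafs: dict[str, float] | None = None,
) -> dict[str, float]:
    """Exact arithmetic differences GOOD / SPEC / IMP for one leg.

    ``generic_vafs`` may provide ``vaf_pre_gen``, ``vaf_post_gen``,
    ``vaf_td_gen`` to populate the generic variants; absent values yield
    NaN entries rather than omissions so reports stay rectangular.
    """
    rec = {
        "vaf_pre": vaf_pre,
        "vaf_post": vaf_post,
        "vaf_td": vaf_td_mean,
        "good": vaf_pre - vaf_post,
        "spec": vaf_post - vaf_td_mean,
        "imp": vaf_pre - vaf_td_mean,
        "vaf_pre_gen": np.nan,
        "vaf_post_gen": np.nan,
        "vaf_td_gen": np.nan,
        "good_pre_gen": np.nan,
        "good_post_gen": np.nan,
        "spec_pre_gen": np.nan,
        "spec_post_gen": np.nan,
    }
    if generic_vafs:
        g_pre = generic_vafs.get("vaf_pre_gen", np.nan)
        g_post = generic_vafs.get("vaf_post_gen", np.nan)
        g_td = generic_vafs.get("vaf_td_gen", np.nan)
        rec.update(
            vaf_pre_gen=g_pre,
            vaf_post_gen=g_post,
            vaf_td_gen=g_td,
            good_pre_gen=vaf_pre - g_pre,
            good_post_gen=vaf_pre - g_post,
            spec_pre_gen=g_pre - g_td,
            spec_post_gen=g_post - g_td,
        )
    return rec
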