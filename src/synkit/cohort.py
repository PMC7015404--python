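"""Generic (group-level) synergies from concatenated multi-subject data.

Legs are grouped by their individually selected number of synergies; the
pre-treatment envelope matrices of all members of a group — each already
unit-SD scaled per channel within its own session — are concatenated
along time into an ``Nm x (Nc * Nt * Np)`` matrix, and one NNMF with the
group's rank yields the generic synergy set. Generic synergies are then
used exactly like subject-specific ones to reconstruct each member's pre-
and post-treatment data and the typically-developing recordings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import DataError, GaitCycleMatrix, SynergySet
from .extraction import nnmf
from .reconstruction import reconstruct_aoa, reconstruct_woa, ReconstructionResult

__all__ = ["CohortGroup", "group_by_nsyn", "extract_generic", "reconstruct_with_generic"]


@dataclass
class CohortGroup:
    """Legs sharing the same selected synergy count, concatenated."""

    n_syn: int
    member_ids: list[str]
    concatenated_emg: GaitCycleMatrix
    generic_synergies: SynergySet | None = None

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def group_by_nsyn(
    legs: list[tuple[str, GaitCycleMatrix, int]],
) -> list[CohortGroup]:
    """Partition legs into groups by selected Nsyn (ascending group label).

    Members are concatenated in input order. Every leg appears in exactly
    one group; empty groups do not exist by construction.
    """
    if not legs:
        return []
    nm = legs[0][1].n_muscles
    nt = legs[0][1].n_samples_per_cycle
    buckets: dict[int, list[tuple[str, GaitCycleMatrix]]] = {}
    for leg_id, emg, n_syn in legs:
        if emg.n_muscles != nm or emg.n_samples_per_cycle != nt:
            raise DataError(f"leg {leg_id!r} has inconsistent dimensions")
        buckets.setdefault(int(n_syn), []).append((leg_id, emg))

    groups = []
    for n_syn in sorted(buckets):
        members = buckets[n_syn]
        data = np.hstack([emg.data for _, emg in members])
        total_cycles = sum(emg.n_cycles for _, emg in members)
        concatenated = GaitCycleMatrix(
            data=data,
            n_cycles=total_cycles,
            n_samples_per_cycle=nt,
            channel_names=list(members[0][1].channel_names),
        )
        groups.append(
            CohortGroup(
                n_syn=n_syn,
                member_ids=[leg_id for leg_id, _ in members],
                concatenated_emg=concatenated,
            )
        )
    return groups


def extract_generic(group: CohortGroup, seed=0, **nnmf_kwargs) -> SynergySet:
    """NNMF with the group's rank on the concatenated member data.

    ``H_avg`` averages all ``Nc * Np`` stride windows, across cycles and
    members alike. The result is stored on the group and returned.
    """
    if not group.member_ids:
        raise DataError("cannot extract generic synergies from an empty group")
    syn = nnmf(group.concatenated_emg, group.n_syn, seed=seed, source="generic", **nnmf_kwargs)
    group.generic_synergies = syn
    return syn


def reconstruct_with_generic(
    group: CohortGroup,
    pre: dict[str, GaitCycleMatrix],
    post: dict[str, GaitCycleMatrix] | None = None,
    td: list[GaitCycleMatrix] | None = None,
) -> dict[str, dict[str, dict[str, ReconstructionResult | list[ReconstructionResult]]]]:
    """Reconstruct member and TD data with the group's generic synergies.

    Returns ``{member_id: {approach: {target: result}}}`` where approach is
    ``"AOA"`` / ``"WOA"`` and target is ``"pre"``, ``"post"`` or ``"td"``
    (the latter a list, one result per TD recording; members share them
    since generic synergies do not depend on the member).
    """
    if group.generic_synergies is None:
        raise DataError("generic synergies not extracted yet; call extract_generic")
    syn = group.generic_synergies

    td_aoa = [
        reconstruct_aoa(syn.W, t, target_label=f"td_{i}", source="generic")
        for i, t in enumerate(td or [])
    ]
    td_woa = [
        reconstruct_woa(syn.H_avg, t, target_label=f"td_{i}", source="generic")
        for i, t in enumerate(td or [])
    ]

    out: dict[str, dict[str, dict[str, object]]] = {}
    for member_id in group.member_ids:
        rec: dict[str, dict[str, object]] = {"AOA": {}, "WOA": {}}
        rec["AOA"]["pre"] = reconstruct_aoa(
            syn.W, pre[member_id], target_label=f"{member_id}:pre", source="generic"
        )
        rec["WOA"]["pre"] = reconstruct_woa(
            syn.H_avg, pre[member_id], target_label=f"{member_id}:pre", source="generic"
        )
        if post is not None and member_id in post:
            rec["AOA"]["post"] = reconstruct_aoa(
                syn.W, post[member_id], target_label=f"{member_id}:post", source="generic"
            )
            rec["WOA"]["post"] = reconstruct_woa(
                syn.H_avg, post[member_id], target_label=f"{member_id}:post", source="generic"
            )
        if td:
            rec["AOA"]["td"] = td_aoa
            rec["WOA"]["td"] = td_woa
        out[member_id] = rec
    return out
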