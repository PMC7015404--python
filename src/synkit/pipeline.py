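"""End-to-end study workflow: simulate or load a cohort, run every stage.

``run_all`` composes the full analysis per leg: preprocessing (or unit-SD
scaling of an already-enveloped matrix) -> eligibility check -> bootstrap
selection of the number of synergies -> subject-specific NNMF -> AOA/WOA
reconstructions of pre-, post-treatment and typically-developing data ->
grouping by Nsyn -> generic synergies -> generic reconstructions ->
GOOD/SPEC/IMP/dW/dH metrics, collected into a tidy per-leg x approach
table. Every stage is seeded from one master seed, so a run is
reproducible bit-for-bit; ineligible or failing legs are skipped with a
logged reason and never silently imputed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.random import SeedSequence

from . import io as sio
from .cohort import extract_generic, group_by_nsyn, reconstruct_with_generic
from .datatypes import (
    ConfigurationError,
    GaitCycleMatrix,
    RawEMGRecording,
    SynkitError,
)
from .extraction import bootstrap_select_nsyn, nnmf
from .metrics import compute_leg_metrics, delta_h, delta_w, match_synergies
from .preprocessing import ensure_scaled, preprocess
from .reconstruction import reconstruct_aoa, reconstruct_woa
from .synthetic import (
    GroundTruthSynergies,
    SimulationConfig,
    make_ground_truth,
    perturb_ground_truth,
    simulate_envelope,
    simulate_raw,
)

__all__ = [
    "PipelineConfig",
    "CohortSpec",
    "SyntheticLeg",
    "SyntheticCohort",
    "simulate_cohort",
    "run_all",
]

logger = logging.getLogger("synkit")


@dataclass
class PipelineConfig:
    """All tunables of the workflow, serializable to/from YAML."""

    # preprocessing
    hp_cutoff: float = 40.0
    lp_cutoff: float = 6.0
    filter_order: int = 6
    zero_phase: bool = True
    n_samples: int = 101
    require_cycles: int = 5
    # extraction
    n_restarts: int = 10
    tol: float = 1e-6
    max_iter: int = 2000
    n_boot: int = 500
    percentile: float = 95.0
    vaf_threshold: float = 90.0
    # reconstruction
    woa_average_target: bool = False
    scale_targets: bool = True
    # metrics
    matching_method: str = "optimal"
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.percentile <= 100:
            raise ConfigurationError("percentile must lie in (0, 100]")
        if not 0 <= self.vaf_threshold <= 100:
            raise ConfigurationError("vaf_threshold must lie in [0, 100]")
        if self.require_cycles < 1 or self.n_samples < 2:
            raise ConfigurationError("require_cycles / n_samples out of range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def save(self, path) -> None:
        sio.write_yaml(self.to_dict(), path)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(sio.read_yaml(path))


@dataclass
class CohortSpec:
    """Shape and effect sizes of a synthetic study cohort.

    ``group_sizes`` maps a generative synergy count to the number of legs
    built from it; each group shares a group-level ground truth from which
    members deviate by small weight/profile perturbations
    (``subject_dev_w`` / ``subject_dev_h``), so generic synergies have
    something real to capture. ``dW_mag`` / ``dH_mag`` set the
    pre-to-post treatment perturbation; ``n_td`` typically-developing
    surrogates are generated from an independent ``n_syn_td``-synergy
    ground truth. ``raw_signals`` additionally synthesizes 2000-Hz raw
    EMG so the run exercises the filtering chain.
    """

    group_sizes: dict[int, int] = field(default_factory=lambda: {2: 3, 3: 5, 4: 3})
    n_td: int = 7
    n_syn_td: int = 5
    dW_mag: float = 0.2
    dH_mag: float = 0.2
    subject_dev_w: float = 0.15
    subject_dev_h: float = 0.10
    raw_signals: bool = False
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.group_sizes.values()):
            raise ConfigurationError("group sizes must be >= 1")
        if any(not 1 <= k <= self.sim.n_muscles for k in self.group_sizes):
            raise ConfigurationError("group synergy counts must lie in [1, n_muscles]")
        if self.n_td < 0:
            raise ConfigurationError("n_td must be >= 0")


@dataclass
class SyntheticLeg:
    leg_id: str
    true_n_syn: int
    gt_pre: GroundTruthSynergies
    gt_post: GroundTruthSynergies
    pre: GaitCycleMatrix | RawEMGRecording
    post: GaitCycleMatrix | RawEMGRecording
    treatment: str = "BOTOX"  # metadata only; no computational branch


@dataclass
class SyntheticCohort:
    legs: list[SyntheticLeg]
    td: list[GaitCycleMatrix | RawEMGRecording]
    td_n_syn: int
    seed: int


def simulate_cohort(spec: CohortSpec, seed: int = 0, out_dir=None) -> SyntheticCohort:
    """Generate a full synthetic cohort (pre, post, TD) with ground truth.

    Deterministic given ``seed``. With ``out_dir`` all recordings, ground
    truths and a YAML manifest are written there (CSV/JSON), enabling the
    file-based entry point of :func:`run_all`.
    """
    ss = SeedSequence(seed)
    legs: list[SyntheticLeg] = []
    n_groups = len(spec.group_sizes)
    group_seeds = ss.spawn(n_groups + 2)

    for g, (n_syn, size) in enumerate(sorted(spec.group_sizes.items())):
        g_ss = group_seeds[g]
        member_seeds = g_ss.spawn(size + 1)
        group_gt = make_ground_truth(
            spec.sim.n_muscles, n_syn, member_seeds[-1], spec.sim.n_samples
        )
        for i in range(size):
            m_ss = member_seeds[i]
            sub_seeds = m_ss.spawn(4)
            gt_pre = perturb_ground_truth(
                group_gt, spec.subject_dev_w, spec.subject_dev_h, sub_seeds[0]
            )
            gt_post = perturb_ground_truth(gt_pre, spec.dW_mag, spec.dH_mag, sub_seeds[1])
            leg = SyntheticLeg(
                leg_id=f"leg_{n_syn}s_{i:02d}",
                true_n_syn=n_syn,
                gt_pre=gt_pre,
                gt_post=gt_post,
                pre=_materialize(gt_pre, spec, sub_seeds[2]),
                post=_materialize(gt_post, spec, sub_seeds[3]),
                treatment="BOTOX" if i % 2 == 0 else "SEMLS",
            )
            legs.append(leg)

    td_list = []
    td_seeds = group_seeds[n_groups].spawn(max(spec.n_td, 1))
    for j in range(spec.n_td):
        gt_td = make_ground_truth(
            spec.sim.n_muscles, spec.n_syn_td, td_seeds[j].spawn(2)[0], spec.sim.n_samples
        )
        td_list.append(_materialize(gt_td, spec, td_seeds[j].spawn(2)[1]))

    cohort = SyntheticCohort(legs=legs, td=td_list, td_n_syn=spec.n_syn_td, seed=seed)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _materialize(gt, spec: CohortSpec, child_seed) -> GaitCycleMatrix | RawEMGRecording:
    cfg = spec.sim.replace(seed=child_seed)
    env = simulate_envelope(gt, cfg)
    if spec.raw_signals:
        return simulate_raw(env, cfg)
    return env


def _write_cohort(cohort: SyntheticCohort, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cohort.seed, "legs": [], "td": []}
    for leg in cohort.legs:
        entry = {"id": leg.leg_id, "true_n_syn": leg.true_n_syn, "treatment": leg.treatment}
        for cond in ("pre", "post"):
            rec = getattr(leg, cond)
            stem = out_dir / f"{leg.leg_id}_{cond}"
            if isinstance(rec, RawEMGRecording):
                sio.write_raw_csv(rec, stem)
                entry[cond] = {"kind": "raw", "path": f"{leg.leg_id}_{cond}"}
            else:
                sio.write_envelope_csv(rec, stem.with_suffix(".csv"))
                entry[cond] = {"kind": "envelope", "path": f"{leg.leg_id}_{cond}.csv"}
            sio.write_ground_truth_json(
                getattr(leg, f"gt_{cond}"), out_dir / f"{leg.leg_id}_{cond}_truth.json"
            )
        manifest["legs"].append(entry)
    for j, rec in enumerate(cohort.td):
        stem = out_dir / f"td_{j:02d}"
        if isinstance(rec, RawEMGRecording):
            sio.write_raw_csv(rec, stem)
            manifest["td"].append({"kind": "raw", "path": f"td_{j:02d}"})
        else:
            sio.write_envelope_csv(rec, stem.with_suffix(".csv"))
            manifest["td"].append({"kind": "envelope", "path": f"td_{j:02d}.csv"})
    sio.write_yaml(manifest, out_dir / "manifest.yaml")
    return out_dir / "manifest.yaml"


def load_cohort(manifest_path) -> SyntheticCohort:
    """Load a cohort written by :func:`simulate_cohort` (ground truth optional)."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = sio.read_yaml(manifest_path)

    def _load(entry):
        if entry["kind"] == "raw":
            return sio.read_raw_csv(base / entry["path"])
        return sio.read_envelope_csv(base / entry["path"])

    legs = []
    for e in manifest["legs"]:
        gt = {}
        for cond in ("pre", "post"):
            truth = base / f"{e['id']}_{cond}_truth.json"
            gt[cond] = sio.read_ground_truth_json(truth) if truth.exists() else None
        legs.append(
            SyntheticLeg(
                leg_id=e["id"],
                true_n_syn=e.get("true_n_syn", -1),
                gt_pre=gt["pre"],
                gt_post=gt["post"],
                pre=_load(e["pre"]),
                post=_load(e["post"]),
                treatment=e.get("treatment", ""),
            )
        )
    td = [_load(e) for e in manifest["td"]]
    return SyntheticCohort(legs=legs, td=td, td_n_syn=-1, seed=manifest.get("seed", 0))


def _to_matrix(rec, config: PipelineConfig) -> GaitCycleMatrix:
    if isinstance(rec, RawEMGRecording):
        return preprocess(
            rec,
            hp_cutoff=config.hp_cutoff,
            lp_cutoff=config.lp_cutoff,
            order=config.filter_order,
            zero_phase=config.zero_phase,
            n_samples=config.n_samples,
            require_cycles=config.require_cycles,
        )
    from .datatypes import EligibilityError

    if rec.n_cycles < config.require_cycles:
        raise EligibilityError(
            f"matrix has {rec.n_cycles} cycles, {config.require_cycles} required"
        )
    return ensure_scaled(rec)


def run_all(
    cohort: SyntheticCohort | str | Path,
    config: PipelineConfig | None = None,
    out_dir=None,
) -> pd.DataFrame:
    """Run the complete analysis on a cohort; return the tidy metrics table.

    One row per eligible leg and approach (AOA / WOA) with the VAF values,
    the GOOD/SPEC/IMP differences, their generic-synergy variants, the
    selected number of synergies and the pre-to-post dW / dH. ``VAF_PRE``
    is the NNMF fit VAF (identical across approaches); ``VAF_TD`` averages
    the reconstructions of all TD recordings.
    """
    if not isinstance(cohort, SyntheticCohort):
        cohort = load_cohort(cohort)
    config = config or PipelineConfig()
    ss = SeedSequence(config.seed)
    leg_seeds = ss.spawn(len(cohort.legs) + 1)

    td_matrices = [_to_matrix(t, config) for t in cohort.td]
    per_leg: list[dict] = []
    legs_ok: list[tuple] = []  # (leg, pre matrix, post matrix, selection, post fit, seeds)

    for leg, leg_ss in zip(cohort.legs, leg_seeds):
        try:
            pre_m = _to_matrix(leg.pre, config)
            post_m = _to_matrix(leg.post, config)
        except SynkitError as exc:
            logger.warning("leg %s excluded: %s", leg.leg_id, exc)
            continue
        sub = leg_ss.spawn(3)
        try:
            selection = bootstrap_select_nsyn(
                pre_m,
                n_boot=config.n_boot,
                percentile=config.percentile,
                vaf_threshold=config.vaf_threshold,
                seed=sub[0],
                n_restarts=config.n_restarts,
                tol=config.tol,
                max_iter=config.max_iter,
            )
            post_fit = nnmf(
                post_m,
                selection.n_syn,
                n_restarts=config.n_restarts,
                seed=sub[1],
                tol=config.tol,
                max_iter=config.max_iter,
            )
        except SynkitError as exc:
            logger.warning("leg %s failed during extraction: %s", leg.leg_id, exc)
            continue
        legs_ok.append((leg, pre_m, post_m, selection, post_fit))

    # subject-specific reconstructions + dW/dH
    records: list[dict] = []
    grouped_inputs = []
    for leg, pre_m, post_m, selection, post_fit in legs_ok:
        syn = selection.selected_fit
        grouped_inputs.append((leg.leg_id, pre_m, selection.n_syn))

        matching = match_synergies(syn.W, post_fit.W, method=config.matching_method)
        d_w = delta_w(matching.correlations)
        d_h = delta_h(syn.H_avg, post_fit.H_avg, matching.permutation)

        for approach, rec_fn, fixed in (
            ("AOA", reconstruct_aoa, syn.W),
            ("WOA", reconstruct_woa, syn.H_avg),
        ):
            kwargs = {"scale_target": config.scale_targets}
            if approach == "WOA":
                kwargs["average_target"] = config.woa_average_target
            r_post = rec_fn(fixed, post_m, target_label=f"{leg.leg_id}:post", **kwargs)
            r_td = [
                rec_fn(fixed, t, target_label=f"{leg.leg_id}:td_{i}", **kwargs)
                for i, t in enumerate(td_matrices)
            ]
            vaf_td = float(np.mean([r.vaf_global for r in r_td])) if r_td else np.nan
            row = {
                "id": leg.leg_id,
                "treatment": leg.treatment,
                "n_syn": selection.n_syn,
                "true_n_syn": leg.true_n_syn,
                "nsyn_criterion_met": selection.criterion_met,
                "approach": approach,
                "d_w": d_w,
                "d_h": d_h,
            }
            row.update(
                compute_leg_metrics(
                    vaf_pre=syn.fit_vaf, vaf_post=r_post.vaf_global, vaf_td_mean=vaf_td
                )
            )
            for name, v in zip(pre_m.channel_names, r_post.vaf_per_muscle):
                row[f"vaf_post_m_{name}"] = v
            if r_td:
                td_mu = np.nanmean([r.vaf_per_muscle for r in r_td], axis=0)
                for name, v in zip(pre_m.channel_names, td_mu):
                    row[f"vaf_td_m_{name}"] = v
            records.append(row)

    # generic synergies per Nsyn group
    groups = group_by_nsyn(grouped_inputs)
    pre_by_id = {leg.leg_id: pre_m for leg, pre_m, *_ in legs_ok}
    post_by_id = {leg.leg_id: post_m for leg, _, post_m, *_ in legs_ok}
    gen_seed_parent = leg_seeds[-1].spawn(max(len(groups), 1))
    for group, g_seed in zip(groups, gen_seed_parent):
        extract_generic(
            group,
            seed=g_seed,
            n_restarts=config.n_restarts,
            tol=config.tol,
            max_iter=config.max_iter,
        )
        gen = reconstruct_with_generic(group, pre_by_id, post_by_id, td_matrices)
        for member_id, by_approach in gen.items():
            for approach, by_target in by_approach.items():
                td_res = by_target.get("td", [])
                gvafs = {
                    "vaf_pre_gen": by_target["pre"].vaf_global,
                    "vaf_post_gen": by_target["post"].vaf_global
                    if "post" in by_target
                    else np.nan,
                    "vaf_td_gen": float(np.mean([r.vaf_global for r in td_res]))
                    if td_res
                    else np.nan,
                }
                for row in records:
                    if row["id"] == member_id and row["approach"] == approach:
                        row.update(
                            compute_leg_metrics(
                                row["vaf_pre"], row["vaf_post"], row["vaf_td"], gvafs
                            )
                        )

    report = pd.DataFrame.from_records(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        report.to_csv(out_dir / "report.csv", index=False)
        config.save(out_dir / "config.yaml")
        summary = {}
        if len(report):
            for approach, sub_df in report.groupby("approach"):
                summary[approach] = {
                    k: {"mean": float(sub_df[k].mean()), "sd": float(sub_df[k].std())}
                    for k in ("vaf_pre", "vaf_post", "vaf_td", "good", "spec", "imp", "d_w", "d_h")
                }
        sio.write_yaml(summary, out_dir / "summary.yaml")
    return report
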