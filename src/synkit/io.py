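"""Plain-text serialization: CSV for signals, JSON for synergies, YAML for config.

File dialects
-------------
* Raw recording: ``<stem>.csv`` with a ``time_s`` column plus one column
  per muscle, and ``<stem>_events.csv`` with ``cycle_index,heel_strike_s``.
  The sampling rate rides in a ``# sampling_rate_hz:`` comment line.
* Envelope matrix: CSV with a 3-line metadata header
  (``# n_cycles``, ``# n_samples``, ``# scaling``) followed by one row per
  muscle.
* Ground truth and synergy sets: JSON with nested lists.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import DataError, GaitCycleMatrix, RawEMGRecording, SynergySet
from .synthetic import GroundTruthSynergies

__all__ = [
    "write_raw_csv",
    "read_raw_csv",
    "write_envelope_csv",
    "read_envelope_csv",
    "write_ground_truth_json",
    "read_ground_truth_json",
    "write_synergies_json",
    "read_synergies_json",
]


def write_raw_csv(raw: RawEMGRecording, stem: Path | str) -> tuple[Path, Path]:
    """Write ``<stem>.csv`` (signals) and ``<stem>_events.csv`` (heel strikes)."""
    stem = Path(stem)
    sig_path = stem.with_suffix(".csv")
    ev_path = stem.parent / f"{stem.stem}_events.csv"

    t = np.arange(raw.n_samples) / raw.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for i, name in enumerate(raw.channel_names):
        df[name] = raw.signals[i]
    with open(sig_path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {raw.sampling_rate}\n")
        df.to_csv(fh, index=False)

    pd.DataFrame(
        {"cycle_index": np.arange(raw.heel_strikes.size), "heel_strike_s": raw.heel_strikes}
    ).to_csv(ev_path, index=False)
    return sig_path, ev_path


def read_raw_csv(stem: Path | str) -> RawEMGRecording:
    stem = Path(stem)
    sig_path = stem.with_suffix(".csv")
    ev_path = stem.parent / f"{stem.stem}_events.csv"
    with open(sig_path) as fh:
        first = fh.readline()
        if not first.startswith("# sampling_rate_hz:"):
            raise DataError(f"{sig_path} lacks the '# sampling_rate_hz:' header line")
        fs = float(first.split(":", 1)[1])
        df = pd.read_csv(fh)
    events = pd.read_csv(ev_path)
    channels = [c for c in df.columns if c != "time_s"]
    return RawEMGRecording(
        signals=df[channels].to_numpy().T,
        sampling_rate=fs,
        channel_names=channels,
        heel_strikes=events["heel_strike_s"].to_numpy(),
    )


def write_envelope_csv(emg: GaitCycleMatrix, path: Path | str) -> Path:
    path = Path(path)
    scaling = (
        "none"
        if emg.channel_scale is None
        else ",".join(repr(float(s)) for s in emg.channel_scale)
    )
    with open(path, "w") as fh:
        fh.write(f"# n_cycles: {emg.n_cycles}\n")
        fh.write(f"# n_samples: {emg.n_samples_per_cycle}\n")
        fh.write(f"# scaling: {scaling}\n")
        pd.DataFrame(emg.data, index=emg.channel_names).to_csv(fh, header=False)
    return path


def read_envelope_csv(path: Path | str) -> GaitCycleMatrix:
    path = Path(path)
    with open(path) as fh:
        meta = {}
        for _ in range(3):
            key, value = fh.readline().lstrip("# ").split(":", 1)
            meta[key.strip()] = value.strip()
        df = pd.read_csv(fh, header=None, index_col=0)
    scale = (
        None
        if meta["scaling"] == "none"
        else np.array([float(s) for s in meta["scaling"].split(",")])
    )
    return GaitCycleMatrix(
        data=df.to_numpy(),
        n_cycles=int(meta["n_cycles"]),
        n_samples_per_cycle=int(meta["n_samples"]),
        channel_names=[str(c) for c in df.index],
        channel_scale=scale,
    )


def write_ground_truth_json(gt: GroundTruthSynergies, path: Path | str) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "W_true": gt.W_true.tolist(),
                "H_true_profile": gt.H_true_profile.tolist(),
                "n_syn": gt.n_syn,
                "seed": gt.seed,
            },
            indent=1,
        )
    )
    return path


def read_ground_truth_json(path: Path | str) -> GroundTruthSynergies:
    d = json.loads(Path(path).read_text())
    return GroundTruthSynergies(
        W_true=np.array(d["W_true"]),
        H_true_profile=np.array(d["H_true_profile"]),
        n_syn=d["n_syn"],
        seed=d.get("seed", 0),
    )


def write_synergies_json(syn: SynergySet, path: Path | str) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps(
            {
                "W": syn.W.tolist(),
                "H": syn.H.tolist(),
                "H_avg": syn.H_avg.tolist(),
                "n_syn": syn.n_syn,
                "source": syn.source,
                "fit_vaf": syn.fit_vaf,
            },
            indent=1,
        )
    )
    return path


def read_synergies_json(path: Path | str) -> SynergySet:
    d = json.loads(Path(path).read_text())
    return SynergySet(
        W=np.array(d["W"]),
        H=np.array(d["H"]),
        H_avg=np.array(d["H_avg"]),
        n_syn=d["n_syn"],
        source=d.get("source", "subject-specific"),
        fit_vaf=d.get("fit_vaf", float("nan")),
    )


def write_yaml(obj: dict, path: Path | str) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def read_yaml(path: Path | str) -> dict:
    return yaml.safe_load(Path(path).read_text())
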