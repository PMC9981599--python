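"""On-disk formats for synthetic cohorts.

EEG goes through MNE's raw container (one FIF file per partner, µV data
stored in volts per MNE convention); gaze events and frame timelines are
tab-separated text; simulation configs are YAML.  A dyad directory holds::

    dyad_000/
        infant_raw.fif
        adult_raw.fif
        events.tsv          # onset_s  sender  gaze_type  receiver_state
        timelines.tsv       # frame  time_s  infant_state  adult_state
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import (
    CouplingSpec,
    DyadRecording,
    ERPComponentSpec,
    GazeEvent,
    GazeTimeline,
    OscillatorSpec,
    SimulationConfig,
)

__all__ = [
    "save_dyad",
    "load_dyad",
    "save_config",
    "load_config",
    "save_cohort",
    "load_cohort",
]


def _raw_from_array(data, labels, fs):
    import mne

    info = mne.create_info(list(labels), sfreq=fs, ch_types="eeg", verbose="error")
    return mne.io.RawArray(data * 1e-6, info, verbose="error")  # µV -> V


def save_dyad(dyad: DyadRecording, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for role in ("infant", "adult"):
        raw = _raw_from_array(dyad.data(role), dyad.channel_labels, dyad.fs)
        raw.save(out / f"{role}_raw.fif", overwrite=True, verbose="error")
    pd.DataFrame(
        [
            {
                "onset_s": e.onset_time,
                "sender": e.sender,
                "gaze_type": e.gaze_type,
                "receiver_state": e.receiver_state_at_onset,
            }
            for e in dyad.events
        ]
    ).to_csv(out / "events.tsv", sep="\t", index=False)
    tl_i, tl_a = dyad.timelines["infant"], dyad.timelines["adult"]
    n = tl_i.n_frames
    pd.DataFrame(
        {
            "frame": np.arange(n),
            "time_s": np.arange(n) / tl_i.frame_rate,
            "infant_state": tl_i.states,
            "adult_state": tl_a.states,
        }
    ).to_csv(out / "timelines.tsv", sep="\t", index=False)
    return out


def load_dyad(dyad_dir) -> DyadRecording:
    import mne

    d = Path(dyad_dir)
    data, labels, fs = {}, None, None
    for role in ("infant", "adult"):
        raw = mne.io.read_raw_fif(d / f"{role}_raw.fif", preload=True, verbose="error")
        data[role] = raw.get_data() * 1e6  # V -> µV
        labels, fs = raw.ch_names, raw.info["sfreq"]
    ev = pd.read_csv(d / "events.tsv", sep="\t")
    events = [
        GazeEvent(row.onset_s, row.sender, row.gaze_type, row.receiver_state)
        for row in ev.itertuples()
    ]
    tl = pd.read_csv(d / "timelines.tsv", sep="\t")
    frame_rate = 1.0 / (tl.time_s.iloc[1] - tl.time_s.iloc[0]) if len(tl) > 1 else 50.0
    timelines = {
        "infant": GazeTimeline("infant", tl.infant_state.to_numpy(), round(frame_rate, 6)),
        "adult": GazeTimeline("adult", tl.adult_state.to_numpy(), round(frame_rate, 6)),
    }
    return DyadRecording(data["infant"], data["adult"], labels, fs, events, timelines)


def _config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["channel_labels"] = list(cfg.channel_labels)
    d["erp_components"] = {
        role: [dataclasses.asdict(c) for c in comps]
        for role, comps in cfg.erp_components.items()
    }
    d["oscillators"] = [dataclasses.asdict(o) for o in cfg.oscillators]
    d["erp_channels"] = list(cfg.erp_channels)
    d["erp_roles"] = list(cfg.erp_roles)
    d["reset_roles"] = list(cfg.reset_roles)
    return d


def save_config(cfg: SimulationConfig, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(_config_to_dict(cfg), fh, sort_keys=False)
    return path


def load_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["erp_components"] = {
        role: tuple(ERPComponentSpec(**c) for c in comps)
        for role, comps in d.get("erp_components", {}).items()
    } or None
    if d["erp_components"] is None:
        d.pop("erp_components")
    if "oscillators" in d:
        d["oscillators"] = tuple(OscillatorSpec(**o) for o in d["oscillators"])
    if "coupling" in d:
        d["coupling"] = CouplingSpec(**d["coupling"])
    for key in ("erp_roles", "reset_roles", "channel_labels", "erp_channels"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def save_cohort(dyads, out_dir) -> Path:
    out = Path(out_dir)
    for i, dyad in enumerate(dyads):
        save_dyad(dyad, out / f"dyad_{i:03d}")
    return out


def load_cohort(cohort_dir):
    root = Path(cohort_dir)
    dirs = sorted(p for p in root.iterdir() if p.is_dir() and p.name.startswith("dyad_"))
    if not dirs:
        raise FileNotFoundError(f"no dyad_* directories under {root}")
    return [load_dyad(p) for p in dirs]
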