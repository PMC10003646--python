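"""File formats: WAV stimuli, CSV events/contours/kernels, HDF5 epochs,
JSON reports, YAML configs, and run manifests.

All internal formats round-trip losslessly and keep their units (ms, Hz,
microvolts).
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .deconv import Kernel
from .events import PulseTrain
from .preprocess import EpochSet
from .stimuli import AudioStimulus, F0Contour


def write_wav(path, stimulus: AudioStimulus) -> None:
    from scipy.io import wavfile
    wavfile.write(path, int(stimulus.rate),
                  stimulus.samples.astype(np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    from scipy.io import wavfile
    rate, samples = wavfile.read(path)
    return np.asarray(samples, dtype=float), float(rate)


def write_contour_csv(path, contour: F0Contour) -> None:
    pd.DataFrame({"time_ms": contour.t_ms,
                  "f0_hz": contour.f0_hz}).to_csv(path, index=False)


def read_contour_csv(path, tone_id: str = "custom") -> F0Contour:
    df = pd.read_csv(path)
    for col in ("time_ms", "f0_hz"):
        if col not in df:
            raise ValueError(f"contour CSV {path} is missing column {col!r}")
    return F0Contour(tone_id=tone_id, t_ms=df["time_ms"].to_numpy(),
                     f0_hz=df["f0_hz"].to_numpy())


def write_events_csv(path, trains: list[PulseTrain]) -> None:
    rows = [{"stimulus_id": t.stimulus_id, "onset_ms": o, "amplitude": a}
            for t in trains for o, a in zip(t.onsets_ms, t.amplitudes)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events_csv(path) -> list[PulseTrain]:
    df = pd.read_csv(path)
    for col in ("stimulus_id", "onset_ms", "amplitude"):
        if col not in df:
            raise ValueError(f"events CSV {path} is missing column {col!r}")
    trains = []
    for sid, grp in df.groupby("stimulus_id", sort=True):
        onsets = grp["onset_ms"].to_numpy(dtype=float)
        amps = grp["amplitude"].to_numpy(dtype=float)
        if np.any(np.diff(onsets) <= 0):
            warnings.warn(f"events for {sid} were not sorted; sorting on load")
            order = np.argsort(onsets)
            onsets, amps = onsets[order], amps[order]
        trains.append(PulseTrain(stimulus_id=str(sid), onsets_ms=onsets,
                                 amplitudes=amps))
    return trains


def write_kernel_csv(path, kernel: Kernel) -> None:
    w = np.atleast_2d(kernel.weights)
    cols = {"lag_ms": kernel.lags_ms}
    if w.shape[0] == 1:
        cols["weight"] = w[0]
    else:
        for c in range(w.shape[0]):
            cols[f"weight_ch{c}"] = w[c]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    sidecar = {"response_type": kernel.response_type, "meta": kernel.meta,
               "n_channels": int(w.shape[0]), "version": __version__}
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_kernel_csv(path) -> Kernel:
    df = pd.read_csv(path, float_precision="round_trip")
    if "lag_ms" not in df:
        raise ValueError(f"kernel CSV {path} is missing column 'lag_ms'")
    wcols = [c for c in df.columns if c.startswith("weight")]
    if not wcols:
        raise ValueError(f"kernel CSV {path} has no weight columns")
    w = df[wcols].to_numpy(dtype=float).T
    if w.shape[0] == 1:
        w = w[0]
    meta, rtype = {}, "ENV"
    try:
        with open(str(path) + ".json") as fh:
            side = json.load(fh)
        meta, rtype = side.get("meta", {}), side.get("response_type", "ENV")
    except FileNotFoundError:
        pass
    return Kernel(lags_ms=df["lag_ms"].to_numpy(dtype=float), weights=w,
                  response_type=rtype, meta=meta)


def write_epochs_h5(path, epochs: EpochSet) -> None:
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip",
                         compression_opts=1)
        f.create_dataset("stimulus_ids",
                         data=np.asarray(epochs.stimulus_ids, dtype="S"))
        f.create_dataset("polarities",
                         data=np.asarray(epochs.polarities, dtype="S"))
        f.create_dataset("rejected", data=epochs.rejected)
        f.attrs["rate"] = epochs.rate
        f.attrs["t_start_ms"] = epochs.t_start_ms


def read_epochs_h5(path) -> EpochSet:
    import h5py
    with h5py.File(path, "r") as f:
        return EpochSet(
            data=f["data"][()], rate=float(f.attrs["rate"]),
            t_start_ms=float(f.attrs["t_start_ms"]),
            stimulus_ids=f["stimulus_ids"][()].astype(str),
            polarities=f["polarities"][()].astype(str),
            rejected=f["rejected"][()])


def read_edf(path, channels: list[str] | None = None):
    """Continuous EEG from an EDF file via MNE: (data_uV, rate, names)."""
    import mne
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    if channels:
        missing = [c for c in channels if c not in raw.ch_names]
        if missing:
            raise ValueError(f"EDF {path} is missing channel(s): "
                             f"{', '.join(missing)}")
        raw.pick(channels)
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def report_to_dict(reports: dict) -> dict:
    """Convert nested VarianceReport structures to plain JSON-able dicts."""
    from .metrics import VarianceReport

    def conv(x):
        if isinstance(x, VarianceReport):
            return {"tms_uv2": x.tms, "rms_uv2": x.rms, "bms_uv2": x.bms,
                    "window_ms": list(x.window_ms),
                    "pve_percent": None if not x.valid else x.pve,
                    "valid": bool(x.valid)}
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        if isinstance(x, (np.floating, np.integer)):
            return x.item()
        return x

    return conv(reports)


def write_report_json(path, reports: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(reports), fh, indent=2)


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is not None and not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg or {}


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    args: dict
    inputs: list
    outputs: list
    seed: int | None
    version: str = __version__
    timestamp: str = ""
    config_hash: str = ""

    def finalize(self) -> "RunManifest":
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        blob = json.dumps({"command": self.command, "args": self.args,
                           "seed": self.seed}, sort_keys=True)
        self.config_hash = hashlib.sha256(blob.encode()).hexdigest()[:16]
        return self

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self.finalize()), fh, indent=2)
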