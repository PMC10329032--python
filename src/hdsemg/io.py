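"""HDF5 / JSON persistence for sessions, windowed datasets and ground truth.

Session layout: datasets ``/emg`` (T x rows x cols, float), ``/label`` (T),
``/repetition`` (T); attributes ``fs``, ``grid``, ``subject_id``.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .session import RecordingSession, WindowSpec, WindowedDataset
from .synth import GroundTruth


def save_session(session: RecordingSession, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("emg", data=session.emg)
        f.create_dataset("label", data=session.label)
        f.create_dataset("repetition", data=session.repetition)
        f.attrs["fs"] = float(session.fs)
        f.attrs["grid"] = np.asarray(session.grid, dtype=np.int64)
        f.attrs["subject_id"] = session.subject_id


def load_session(path) -> RecordingSession:
    """Load and validate a session file, with a distinct diagnostic per defect."""
    with h5py.File(path, "r") as f:
        for name in ("emg", "label", "repetition"):
            if name not in f:
                raise KeyError(f"session file is missing dataset '/{name}'")
        if "fs" not in f.attrs:
            raise KeyError("session file is missing required attribute 'fs'")
        fs = float(f.attrs["fs"])
        if fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {fs}")
        grid = tuple(int(g) for g in f.attrs.get("grid", f["emg"].shape[1:]))
        subject = str(f.attrs.get("subject_id", "unknown"))
        if f["emg"].shape[0] == 0:
            raise ValueError("session file holds no samples")
        emg = f["emg"][...]
        label = f["label"][...]
        repetition = f["repetition"][...]
    return RecordingSession(emg=emg, fs=fs, label=label, repetition=repetition,
                            subject_id=subject, grid=grid)


def save_windowed(dataset: WindowedDataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("windows", data=dataset.windows)
        f.create_dataset("labels", data=dataset.labels)
        f.create_dataset("repetitions", data=dataset.repetitions)
        f.attrs["window"] = dataset.spec.window
        f.attrs["skip"] = dataset.spec.skip
        f.attrs["n_ch"] = dataset.spec.n_ch
        f.attrs["n_cv"] = dataset.spec.n_cv


def load_windowed(path) -> WindowedDataset:
    with h5py.File(path, "r") as f:
        spec = WindowSpec(window=int(f.attrs["window"]), skip=int(f.attrs["skip"]),
                          n_ch=int(f.attrs["n_ch"]), n_cv=int(f.attrs["n_cv"]))
        return WindowedDataset(f["windows"][...], f["labels"][...],
                               f["repetitions"][...], spec)


def save_ground_truth(truth: GroundTruth, path) -> None:
    """Ground truth as a JSON sidecar (spike indices, templates as lists)."""
    payload = {
        "spike_trains": {f"{g},{r},{m}": v.tolist()
                         for (g, r, m), v in truth.spike_trains.items()},
        "templates": truth.templates.tolist(),
        "temporal_templates": truth.temporal_templates.tolist(),
        "weights": {f"{g},{r},{m}": w.tolist()
                    for (g, r, m), w in truth.weights.items()},
        "template_offsets": truth.template_offsets.tolist(),
        "template_lengths": truth.template_lengths.tolist(),
        "labels": truth.labels.tolist(),
        "repetitions": truth.repetitions.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    trains = {}
    for key, v in payload["spike_trains"].items():
        g, r, m = (int(x) for x in key.split(","))
        trains[(g, r, m)] = np.asarray(v, dtype=int)
    weights = {}
    for key, w in payload["weights"].items():
        g, r, m = (int(x) for x in key.split(","))
        weights[(g, r, m)] = np.asarray(w)
    return GroundTruth(
        spike_trains=trains,
        templates=np.asarray(payload["templates"]),
        temporal_templates=np.asarray(payload["temporal_templates"]),
        weights=weights,
        template_offsets=np.asarray(payload["template_offsets"], dtype=int),
        template_lengths=np.asarray(payload["template_lengths"], dtype=int),
        labels=np.asarray(payload["labels"], dtype=np.int64),
        repetitions=np.asarray(payload["repetitions"], dtype=np.int64))
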