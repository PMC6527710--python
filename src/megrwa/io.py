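"""Array-container I/O (HDF5 layout), RDM CSV export and a FIF adapter.

Canonical interchange for epoched sensor data is a flat HDF5 layout::

    data               float  (trials, sensors, times)
    trial_stimulus_id  int/str (trials,)
    sensor_ids         str    (sensors,)
    sensor_pos         float  (sensors, 2)
    attrs: sfreq, t0

Pseudo-trials, neural RDM series and epsilon maps use analogous layouts.
Reading real MEG recordings from the standard FIF interchange format is
supported through an optional adapter that combines planar-gradiometer
pairs into one sensor per site (root-mean-square combination).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import (
    EpochedData,
    EpsilonMap,
    ModelRDM,
    NeuralRDMSeries,
    PseudoTrials,
    StimulusSet,
)

__all__ = [
    "write_epochs",
    "read_epochs",
    "write_pseudo_trials",
    "read_pseudo_trials",
    "write_neural_rdms",
    "read_neural_rdms",
    "write_epsilon_map",
    "read_epsilon_map",
    "write_model_rdm",
    "read_model_rdm",
    "write_stimulus_set",
    "read_stimulus_set",
    "read_fif_epochs",
]


def _encode_ids(ids: np.ndarray) -> np.ndarray:
    if ids.dtype.kind in "US":
        return np.asarray([str(x) for x in ids], dtype=h5py.string_dtype())
    return np.asarray(ids)


def _decode_ids(ds) -> np.ndarray:
    arr = ds[()]
    if arr.dtype.kind in ("O", "S"):
        return np.asarray([x.decode() if isinstance(x, bytes) else str(x) for x in arr])
    return arr


def write_epochs(path: str | Path, epochs: EpochedData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, track_times=False)
        f.create_dataset("trial_stimulus_id", data=_encode_ids(epochs.trial_stimulus_id), track_times=False)
        f.create_dataset("sensor_ids", data=_encode_ids(epochs.sensor_ids), track_times=False)
        f.create_dataset("sensor_pos", data=epochs.sensor_pos, track_times=False)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["t0"] = epochs.t0


def read_epochs(path: str | Path) -> EpochedData:
    with h5py.File(path, "r") as f:
        return EpochedData(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            t0=float(f.attrs["t0"]),
            trial_stimulus_id=_decode_ids(f["trial_stimulus_id"]),
            sensor_ids=_decode_ids(f["sensor_ids"]),
            sensor_pos=f["sensor_pos"][()],
        )


def write_pseudo_trials(path: str | Path, pseudo: PseudoTrials) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=pseudo.data, track_times=False)
        f.create_dataset("stimulus_ids", data=_encode_ids(pseudo.stimulus_ids), track_times=False)
        f.create_dataset("sensor_ids", data=_encode_ids(pseudo.sensor_ids), track_times=False)
        f.create_dataset("sensor_pos", data=pseudo.sensor_pos, track_times=False)
        f.attrs["sfreq"] = pseudo.sfreq
        f.attrs["t0"] = pseudo.t0


def read_pseudo_trials(path: str | Path) -> PseudoTrials:
    with h5py.File(path, "r") as f:
        return PseudoTrials(
            data=f["data"][()],
            stimulus_ids=_decode_ids(f["stimulus_ids"]),
            sfreq=float(f.attrs["sfreq"]),
            t0=float(f.attrs["t0"]),
            sensor_ids=_decode_ids(f["sensor_ids"]),
            sensor_pos=f["sensor_pos"][()],
        )


def write_neural_rdms(path: str | Path, series: NeuralRDMSeries) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("rdms", data=series.rdms, track_times=False)
        f.create_dataset("sensor_ids", data=_encode_ids(series.sensor_ids), track_times=False)
        f.create_dataset("times", data=np.asarray(series.times, dtype=float), track_times=False)
        f.create_dataset("stimulus_ids", data=_encode_ids(np.asarray(series.stimulus_ids)), track_times=False)


def read_neural_rdms(path: str | Path) -> NeuralRDMSeries:
    with h5py.File(path, "r") as f:
        return NeuralRDMSeries(
            rdms=f["rdms"][()],
            sensor_ids=_decode_ids(f["sensor_ids"]),
            times=f["times"][()],
            stimulus_ids=_decode_ids(f["stimulus_ids"]),
        )


def write_epsilon_map(path: str | Path, emap: EpsilonMap) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epsilon", data=emap.epsilon, track_times=False)
        f.create_dataset("sensor_ids", data=_encode_ids(emap.sensor_ids), track_times=False)
        f.create_dataset("times", data=np.asarray(emap.times, dtype=float), track_times=False)
        f.attrs["model_names"] = json.dumps(list(emap.model_names))


def read_epsilon_map(path: str | Path) -> EpsilonMap:
    with h5py.File(path, "r") as f:
        return EpsilonMap(
            epsilon=f["epsilon"][()],
            model_names=json.loads(f.attrs["model_names"]),
            sensor_ids=_decode_ids(f["sensor_ids"]),
            times=f["times"][()],
        )


def epsilon_map_to_frame(emap: EpsilonMap, subject: str | int = 0) -> pd.DataFrame:
    """Long-format table: subject, sensor, time_ms, model, epsilon."""
    s, t, p = emap.epsilon.shape
    sensor = np.repeat(np.asarray(emap.sensor_ids), t * p)
    time_ms = np.tile(np.repeat(np.asarray(emap.times) * 1000.0, p), s)
    model = np.tile(np.asarray(emap.model_names, dtype=object), s * t)
    return pd.DataFrame(
        {
            "subject": subject,
            "sensor": sensor,
            "time_ms": time_ms,
            "model": model,
            "epsilon": emap.epsilon.reshape(-1),
        }
    )


def write_model_rdm(path: str | Path, rdm: ModelRDM, parameters: dict | None = None) -> None:
    """Write an RDM as an n x n CSV plus a JSON sidecar with metadata."""
    path = Path(path)
    ids = (
        [str(x) for x in rdm.stimulus_ids]
        if rdm.stimulus_ids is not None
        else [f"s{i:03d}" for i in range(rdm.n)]
    )
    pd.DataFrame(rdm.matrix, index=ids, columns=ids).to_csv(path)
    sidecar = {
        "name": rdm.name,
        "parameters": parameters or {},
        "stimulus_order": ids,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def read_model_rdm(path: str | Path) -> ModelRDM:
    path = Path(path)
    frame = pd.read_csv(path, index_col=0)
    name = "rdm"
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        name = json.loads(sidecar.read_text()).get("name", name)
    return ModelRDM(name=name, matrix=frame.to_numpy(), stimulus_ids=np.asarray(frame.index))


def write_stimulus_set(out_dir: str | Path, stimuli: StimulusSet) -> None:
    """Write stimuli as PNG + mask PNG plus a labels CSV (stimulus_id, category)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for i, sid in enumerate(stimuli.stimulus_ids):
        img = np.clip(stimuli.images[i] * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(out_dir / f"{sid}.png", img)
        iio.imwrite(out_dir / f"{sid}_mask.png", (stimuli.masks[i] * 255).astype(np.uint8))
    pd.DataFrame(
        {"stimulus_id": [str(s) for s in stimuli.stimulus_ids], "category": stimuli.labels}
    ).to_csv(out_dir / "labels.csv", index=False)


def read_stimulus_set(in_dir: str | Path) -> StimulusSet:
    """Read a stimulus directory written by :func:`write_stimulus_set`.

    Expects ``<id>.png`` / ``<id>_mask.png`` pairs and a ``labels.csv``
    with columns (stimulus_id, category); images are rescaled to [0, 1].
    """
    import imageio.v3 as iio

    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "labels.csv")
    images, masks = [], []
    for sid in table["stimulus_id"]:
        images.append(np.asarray(iio.imread(in_dir / f"{sid}.png"), dtype=float) / 255.0)
        masks.append(np.asarray(iio.imread(in_dir / f"{sid}_mask.png")) > 127)
    return StimulusSet(
        images=np.stack(images),
        masks=np.stack(masks),
        labels=table["category"].to_numpy(),
        stimulus_ids=table["stimulus_id"].to_numpy(),
    )


def read_fif_epochs(path: str | Path) -> EpochedData:
    """Read epochs from a FIF file, combining planar-gradiometer pairs.

    Planar gradiometers are retained (magnetometers dropped) and the two
    orthogonal gradiometers of each site are combined into one sensor by
    root-mean-square, the standard planar combination.  Sensor layout
    positions are the 2-D projection of the site locations.
    """
    import mne

    epochs = mne.read_epochs(str(path), preload=True, verbose="error")
    epochs.pick("grad", verbose="error")
    data = epochs.get_data(copy=True)  # trials x channels x time
    names = epochs.ch_names
    locs = np.array([epochs.info["chs"][i]["loc"][:3] for i in range(len(names))])
    # Neuromag planar pairs share the first 6 name characters (e.g. MEG2442/MEG2443).
    sites: dict[str, list[int]] = {}
    for i, name in enumerate(names):
        sites.setdefault(name[:-1], []).append(i)
    site_names = sorted(sites)
    combined = np.stack(
        [np.sqrt(np.mean(data[:, sites[s], :] ** 2, axis=1)) for s in site_names], axis=1
    )
    pos = np.stack([locs[sites[s]].mean(axis=0)[:2] for s in site_names])
    stim_id = np.asarray(epochs.events[:, 2])
    return EpochedData(
        data=combined,
        sfreq=float(epochs.info["sfreq"]),
        t0=float(epochs.times[0]),
        trial_stimulus_id=stim_id,
        sensor_ids=np.asarray(site_names),
        sensor_pos=pos,
    )
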