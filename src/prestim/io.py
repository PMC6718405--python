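"""Session persistence.

A session directory contains ``trials.tsv`` (the trial table),
``epochs.h5`` (trial x sensor x time array with sampling-rate/window
metadata and the planted sensor patterns when known), ``pupil.tsv``
(time, diameter) and ``manifest.json`` (design, generator parameters and
seed).  An optional adapter imports real epochs from FIF recordings
through MNE when that package is available; the core pipeline only ever
consumes the array container and the TSV tables.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet, PupilTrace
from .design import DesignSpec, Session

__all__ = ["write_session", "read_session", "epochs_from_fif"]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_session(session: Session, directory) -> Path:
    """Write one session to ``directory`` (created if needed)."""
    path = Path(directory)
    path.mkdir(parents=True, exist_ok=True)
    session.trials.to_csv(path / "trials.tsv", sep="\t", index=False)

    with h5py.File(path / "epochs.h5", "w") as f:
        d = f.create_dataset("epochs", data=session.epochs.values)
        d.attrs["sampling_rate"] = session.epochs.sampling_rate
        d.attrs["window"] = session.epochs.window
        f.create_dataset("block", data=session.epochs.block)
        f.create_dataset("onsets", data=session.epochs.onsets)
        f.create_dataset("pattern_general", data=session.w_g)
        f.create_dataset("pattern_categories", data=session.W_c)
        f.create_dataset("latent_g", data=session.latents.g)
        f.create_dataset(
            "latent_preferred",
            data=np.asarray(session.latents.preferred_category, dtype="S"),
        )

    pupil = session.pupil
    pd.DataFrame({"time": pupil.time, "diameter": pupil.diameter}).to_csv(
        path / "pupil.tsv", sep="\t", index=False, float_format="%.6f"
    )
    manifest = {
        "seed": session.seed,
        "design": _jsonable(session.spec),
        "generator": _jsonable(session.params),
        "pupil_sampling_rate": pupil.sampling_rate,
        "stimulus_duration": pupil.stimulus_duration,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def read_session(directory) -> tuple[pd.DataFrame, EpochSet, PupilTrace, dict]:
    """Read back a session directory written by :func:`write_session`."""
    path = Path(directory)
    trials = pd.read_csv(path / "trials.tsv", sep="\t")
    manifest = json.loads((path / "manifest.json").read_text())
    cats = DesignSpec(**{k: tuple(v) if isinstance(v, list) else v
                         for k, v in manifest["design"].items()}).categories
    trials["objective_category"] = pd.Categorical(
        trials["objective_category"], categories=list(cats)
    )
    with h5py.File(path / "epochs.h5", "r") as f:
        epochs = EpochSet(
            values=f["epochs"][()],
            sampling_rate=float(f["epochs"].attrs["sampling_rate"]),
            window=float(f["epochs"].attrs["window"]),
            block=f["block"][()],
            onsets=f["onsets"][()],
        )
    pupil_tab = pd.read_csv(path / "pupil.tsv", sep="\t")
    pupil = PupilTrace(
        diameter=pupil_tab["diameter"].to_numpy(),
        sampling_rate=float(manifest["pupil_sampling_rate"]),
        onsets=trials["prestim_onset"].to_numpy(),
        stimulus_duration=float(manifest["stimulus_duration"]),
        t0=float(pupil_tab["time"].iloc[0]),
    )
    return trials, epochs, pupil, manifest


def epochs_from_fif(path, tmin: float = -2.0, tmax: float = 0.0,
                    block_labels=None) -> EpochSet:
    """Optional adapter: load pre-stimulus epochs from an MNE FIF file.

    Requires the ``mne`` package (not a core dependency).  The epochs are
    cropped to ``[tmin, tmax)`` relative to stimulus onset.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("reading FIF files requires the optional 'mne' package") from exc
    epochs = mne.read_epochs(str(path), preload=True, verbose="error")
    epochs = epochs.crop(tmin=tmin, tmax=tmax, include_tmax=False)
    data = epochs.get_data()
    n = data.shape[0]
    block = np.zeros(n, dtype=int) if block_labels is None else np.asarray(block_labels)
    return EpochSet(
        values=data,
        sampling_rate=float(epochs.info["sfreq"]),
        window=float(tmax - tmin),
        block=block,
    )
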