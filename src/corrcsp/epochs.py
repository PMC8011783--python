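"""Epoched multi-channel signal container and on-disk formats.

The whole pipeline operates on :class:`EpochedSignal`: a stack of trials,
each an ``n x c`` matrix (rows = time samples, columns = channels) recorded
at a fixed sampling rate, with one integer class label per trial.  Class
ids are contiguous integers starting at 1, matching the convention of
motor-imagery benchmark datasets.

The native on-disk format is a directory holding ``epochs.npy`` (a
``trials x samples x channels`` float array) next to a ``meta.json``
sidecar with the sampling rate, labels and optional channel names.  GDF/EDF
recordings can be ingested through MNE when it is installed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("corrcsp")

__all__ = ["EpochedSignal", "read_epochs", "write_epochs"]


@dataclass
class EpochedSignal:
    """Labeled collection of equally shaped EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_samples, n_channels)
        The trials.  Rows of each trial are time samples, columns are
        channels.
    labels : ndarray of int, shape (n_trials,)
        Class id per trial; ids are contiguous integers starting at 1.
    fs : float
        Sampling rate in Hz.
    channel_names : list of str, optional
        One name per channel.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.data.ndim != 3:
            raise ValueError(
                f"data must be 3-D (trials, samples, channels); got shape {self.data.shape}"
            )
        n_trials, n, c = self.data.shape
        if n < 2 or c < 2:
            raise ValueError(
                f"need at least 2 samples and 2 channels per trial; got n={n}, c={c}"
            )
        if self.labels.shape != (n_trials,):
            raise ValueError(
                f"labels has {self.labels.size} entries for {n_trials} trials"
            )
        if n_trials:
            ids = np.unique(self.labels)
            if ids[0] != 1 or not np.array_equal(ids, np.arange(1, ids.size + 1)):
                raise ValueError(
                    f"class ids must be contiguous integers starting at 1; got {ids.tolist()}"
                )
        if self.channel_names is not None and len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if not float(self.fs) > 0:
            raise ValueError(f"sampling rate must be positive; got {self.fs}")
        self.fs = float(self.fs)

    # -- basic introspection -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique class ids."""
        return np.unique(self.labels)

    def class_trials(self, class_id: int) -> np.ndarray:
        """All trials of one class, shape (t, n, c)."""
        mask = self.labels == class_id
        if not mask.any():
            raise ValueError(f"no trials with class id {class_id}")
        return self.data[mask]

    def subset(self, index: np.ndarray) -> "EpochedSignal":
        """New signal holding ``data[index]`` / ``labels[index]``.

        The label-contiguity invariant is not re-checked: folds of a valid
        signal may lack some class entirely, which downstream fitting code
        rejects with a clearer message.
        """
        out = object.__new__(EpochedSignal)
        out.data = self.data[index]
        out.labels = self.labels[index]
        out.fs = self.fs
        out.channel_names = self.channel_names
        return out


# -- native format -----------------------------------------------------------

_ARRAY_NAME = "epochs.npy"
_META_NAME = "meta.json"


def write_epochs(signal: EpochedSignal, path: str | Path) -> Path:
    """Write a signal to the native directory format; returns the directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.save(path / _ARRAY_NAME, signal.data)
    meta = {
        "fs": signal.fs,
        "labels": signal.labels.tolist(),
        "channel_names": signal.channel_names,
    }
    (path / _META_NAME).write_text(json.dumps(meta, indent=1))
    return path


def _read_native(path: Path) -> EpochedSignal:
    array_file = path / _ARRAY_NAME
    meta_file = path / _META_NAME
    if not array_file.exists():
        raise FileNotFoundError(f"missing {array_file}")
    if not meta_file.exists():
        raise FileNotFoundError(f"missing sidecar {meta_file}")
    data = np.load(array_file)
    try:
        meta = json.loads(meta_file.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed sidecar {meta_file}: {exc}") from exc
    for key in ("fs", "labels"):
        if key not in meta:
            raise ValueError(f"sidecar {meta_file} lacks required key {key!r}")
    labels = np.asarray(meta["labels"], dtype=int)
    if data.ndim != 3:
        raise ValueError(f"{array_file} must be trials x samples x channels")
    if labels.size != data.shape[0]:
        raise ValueError(
            f"sidecar lists {labels.size} labels but {array_file} holds "
            f"{data.shape[0]} trials"
        )
    return EpochedSignal(
        data=data, labels=labels, fs=meta["fs"], channel_names=meta.get("channel_names")
    )


def _read_biosig(
    path: Path,
    fmt: str,
    event_map: dict[str, int],
    tmin: float,
    tmax: float,
    channels: list[str] | None,
) -> EpochedSignal:
    # GDF/EDF ingestion goes through MNE; optional dependency.
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading GDF/EDF files requires the 'mne' package "
            "(install corrcsp[io])"
        ) from exc
    if not event_map:
        raise ValueError("GDF/EDF epoching needs an event-name -> class-id map")
    reader = mne.io.read_raw_gdf if fmt == "gdf" else mne.io.read_raw_edf
    raw = reader(str(path), preload=True, verbose="error")
    if channels:
        raw.pick(channels)
    events, event_ids = mne.events_from_annotations(raw, verbose="error")
    selected = {name: code for name, code in event_ids.items() if name in event_map}
    unknown = set(event_map) - set(event_ids)
    if unknown:
        raise ValueError(
            f"events {sorted(unknown)} not present in {path.name}; "
            f"available: {sorted(event_ids)}"
        )
    ep = mne.Epochs(
        raw, events, event_id=selected, tmin=tmin, tmax=tmax,
        baseline=None, preload=True, verbose="error",
    )
    data = ep.get_data().transpose(0, 2, 1)  # -> trials x samples x channels
    codes = ep.events[:, 2]
    code_to_class = {selected[name]: event_map[name] for name in selected}
    labels = np.array([code_to_class[c] for c in codes], dtype=int)
    return EpochedSignal(
        data=data, labels=labels, fs=float(ep.info["sfreq"]),
        channel_names=list(ep.ch_names),
    )


def read_epochs(
    path: str | Path,
    format: str = "native",
    *,
    event_map: dict[str, int] | None = None,
    tmin: float = 0.0,
    tmax: float = 4.0,
    channels: list[str] | None = None,
) -> EpochedSignal:
    """Read epoched data.

    ``format='native'`` expects the directory layout written by
    :func:`write_epochs`.  ``'gdf'``/``'edf'`` read a raw biosignal file and
    epoch it around the annotated events named in ``event_map`` (event name
    to class id), taking ``[tmin, tmax]`` seconds around each event.
    """
    path = Path(path)
    if format == "native":
        return _read_native(path)
    if format in ("gdf", "edf"):
        return _read_biosig(path, format, event_map or {}, tmin, tmax, channels)
    raise ValueError(f"unknown format {format!r}; expected native, gdf or edf")
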