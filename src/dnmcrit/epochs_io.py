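"""Data model and on-disk study archive.

A study directory holds ``manifest.json`` plus one container per subject.
The default container is HDF5 (datasets ``standard`` / ``deviant``, attrs
``sampling_rate``, ``group``, ``time_axis``); a plain-text CSV fallback
(long format: epoch, kind, channel, sample, value) is available for
archives that must stay text-only.  Continuous recordings (signal + event
stream) use the same manifest with per-subject ``signal`` / ``events``
datasets.

Channel identifiers are 1-based, matching the 64-channel montage numbering
used in scalp-EEG work (e.g. FCz = channel 4); in-memory arrays are indexed
0-based as usual.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from dnmcrit.synthetic import OddballRecording

__all__ = [
    "EpochSet",
    "CorrectedEpochs",
    "write_study",
    "read_study",
    "read_edf_recording",
]

_MANIFEST = "manifest.json"


@dataclass(frozen=True)
class EpochSet:
    """Per-subject stacks of standard and deviant epochs.

    Arrays are epoch x channel x time (µV); ``time_axis`` is in ms relative
    to stimulus onset on a uniform grid of step ``1000 / sampling_rate``.
    """

    subject_id: str
    group: str
    sampling_rate: float
    time_axis: np.ndarray
    standard_epochs: np.ndarray
    deviant_epochs: np.ndarray
    channel_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        t = np.asarray(self.time_axis, dtype=float)
        std = np.asarray(self.standard_epochs, dtype=float)
        dev = np.asarray(self.deviant_epochs, dtype=float)
        if std.ndim != 3 or dev.ndim != 3:
            raise ValueError("epoch arrays must be epoch x channel x time")
        if std.shape[1:] != dev.shape[1:]:
            raise ValueError("standard and deviant epochs must share channel/time dims")
        if t.shape != (std.shape[2],):
            raise ValueError("time_axis length must match the time dimension")
        step = 1000.0 / self.sampling_rate
        if t.size > 1 and not np.allclose(np.diff(t), step, atol=1e-6):
            raise ValueError("time_axis must increase uniformly at the sample interval")
        ids = tuple(int(c) for c in self.channel_ids) or tuple(
            range(1, std.shape[1] + 1)
        )
        if len(set(ids)) != len(ids) or len(ids) != std.shape[1]:
            raise ValueError("channel_ids must be unique, one per channel")
        object.__setattr__(self, "time_axis", t)
        object.__setattr__(self, "standard_epochs", std)
        object.__setattr__(self, "deviant_epochs", dev)
        object.__setattr__(self, "channel_ids", ids)

    @property
    def n_channels(self) -> int:
        return self.standard_epochs.shape[1]


@dataclass(frozen=True)
class CorrectedEpochs:
    """Deviant epochs with the subject's mean standard response subtracted
    (the empirical difference process z(t), one realization per epoch)."""

    subject_id: str
    group: str
    sampling_rate: float
    time_axis: np.ndarray
    data: np.ndarray  # epoch x channel x time, µV
    channel_ids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        t = np.asarray(self.time_axis, dtype=float)
        if d.ndim != 3:
            raise ValueError("data must be epoch x channel x time")
        if t.shape != (d.shape[2],):
            raise ValueError("time_axis length must match the time dimension")
        ids = tuple(int(c) for c in self.channel_ids) or tuple(range(1, d.shape[1] + 1))
        object.__setattr__(self, "data", d)
        object.__setattr__(self, "time_axis", t)
        object.__setattr__(self, "channel_ids", ids)

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]


# ---------------------------------------------------------------------------
# writing


def _write_epochs_h5(path: Path, es: EpochSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("standard", data=es.standard_epochs)
        f.create_dataset("deviant", data=es.deviant_epochs)
        f.create_dataset("time_axis", data=es.time_axis)
        f.attrs["sampling_rate"] = es.sampling_rate
        f.attrs["group"] = es.group
        f.attrs["channel_ids"] = np.asarray(es.channel_ids, dtype=int)


def _write_epochs_csv(path: Path, es: EpochSet) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["epoch", "kind", "channel", "sample", "value"])
        for kind, arr in (("standard", es.standard_epochs), ("deviant", es.deviant_epochs)):
            for e in range(arr.shape[0]):
                for c in range(arr.shape[1]):
                    for s in range(arr.shape[2]):
                        w.writerow([e, kind, c, s, repr(float(arr[e, c, s]))])


def _write_corrected_h5(path: Path, ce: CorrectedEpochs) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ce.data)
        f.create_dataset("time_axis", data=ce.time_axis)
        f.attrs["sampling_rate"] = ce.sampling_rate
        f.attrs["group"] = ce.group
        f.attrs["channel_ids"] = np.asarray(ce.channel_ids, dtype=int)


def _write_recording_h5(path: Path, rec: OddballRecording) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("event_onsets", data=np.array([o for o, _ in rec.events]))
        f.create_dataset(
            "event_kinds",
            data=np.array([k for _, k in rec.events], dtype="S8"),
        )
        f.attrs["sampling_rate"] = rec.sampling_rate
        f.attrs["group"] = rec.group


def write_study(path, items, fmt: str = "h5") -> dict:
    """Write a study directory and return its manifest.

    ``items`` is a collection of :class:`EpochSet` or
    :class:`OddballRecording` (not mixed).  ``fmt`` is ``"h5"`` or ``"csv"``
    (CSV only for epoch sets).  Duplicate subject ids are rejected.
    """
    items = list(items)
    if not items:
        raise ValueError("write_study: empty collection")
    kinds = {type(it).__name__ for it in items}
    if len(kinds) > 1:
        raise ValueError(f"write_study: mixed item types {kinds}")
    is_epochs = isinstance(items[0], EpochSet)
    is_corrected = isinstance(items[0], CorrectedEpochs)
    if not (is_epochs or is_corrected or isinstance(items[0], OddballRecording)):
        raise TypeError(
            "write_study accepts EpochSet, CorrectedEpochs or OddballRecording items"
        )
    if fmt not in ("h5", "csv"):
        raise ValueError(f"unknown format {fmt!r}")
    if fmt == "csv" and not is_epochs:
        raise ValueError("CSV fallback is only defined for epoch archives")

    ids = [it.subject_id for it in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject_id in study")

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    ext = "h5" if fmt == "h5" else "csv"
    if is_epochs:
        kind = "epochs"
    elif is_corrected:
        kind = "corrected"
    else:
        kind = "recordings"
    manifest = {
        "kind": kind,
        "format": fmt,
        "sampling_rate": float(items[0].sampling_rate),
        "subjects": [
            {"subject_id": it.subject_id, "group": it.group, "file": f"{it.subject_id}.{ext}"}
            for it in items
        ],
    }
    if is_epochs or is_corrected:
        manifest["n_channels"] = int(items[0].n_channels)
        manifest["channel_ids"] = list(items[0].channel_ids)
        manifest["time_axis"] = [float(t) for t in items[0].time_axis]
    else:
        manifest["n_channels"] = int(items[0].signal.shape[0])

    for it in items:
        target = path / f"{it.subject_id}.{ext}"
        if is_epochs:
            if fmt == "h5":
                _write_epochs_h5(target, it)
            else:
                _write_epochs_csv(target, it)
        elif is_corrected:
            _write_corrected_h5(target, it)
        else:
            _write_recording_h5(target, it)

    with open(path / _MANIFEST, "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# reading


def _read_epochs_h5(path: Path, sid: str, group: str) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        return EpochSet(
            subject_id=sid,
            group=group,
            sampling_rate=float(f.attrs["sampling_rate"]),
            time_axis=f["time_axis"][()],
            standard_epochs=f["standard"][()],
            deviant_epochs=f["deviant"][()],
            channel_ids=tuple(int(c) for c in f.attrs["channel_ids"]),
        )


def _read_epochs_csv(
    path: Path, sid: str, group: str, sampling_rate: float,
    time_axis: np.ndarray, channel_ids: tuple[int, ...],
) -> EpochSet:
    rows = {"standard": {}, "deviant": {}}
    with open(path, newline="") as f:
        r = csv.reader(f)
        next(r)
        for epoch, kind, channel, sample, value in r:
            rows[kind][(int(epoch), int(channel), int(sample))] = float(value)
    arrays = {}
    for kind, d in rows.items():
        if not d:
            arrays[kind] = np.zeros((0, len(channel_ids), len(time_axis)))
            continue
        ne = max(k[0] for k in d) + 1
        nc = max(k[1] for k in d) + 1
        ns = max(k[2] for k in d) + 1
        a = np.empty((ne, nc, ns))
        for (e, c, s), v in d.items():
            a[e, c, s] = v
        arrays[kind] = a
    return EpochSet(
        subject_id=sid, group=group, sampling_rate=sampling_rate,
        time_axis=time_axis, standard_epochs=arrays["standard"],
        deviant_epochs=arrays["deviant"], channel_ids=channel_ids,
    )


def _read_recording_h5(path: Path, sid: str, group: str) -> OddballRecording:
    import h5py

    with h5py.File(path, "r") as f:
        onsets = f["event_onsets"][()]
        kinds = [k.decode() for k in f["event_kinds"][()]]
        return OddballRecording(
            subject_id=sid,
            group=group,
            signal=f["signal"][()],
            sampling_rate=float(f.attrs["sampling_rate"]),
            events=list(zip((int(o) for o in onsets), kinds)),
        )


def read_study(path) -> list:
    """Read a study directory back into :class:`EpochSet` (or
    :class:`OddballRecording`) objects, validating against the manifest."""
    path = Path(path)
    mf = path / _MANIFEST
    if not mf.exists():
        raise FileNotFoundError(f"no {_MANIFEST} under {path}")
    with open(mf) as f:
        manifest = json.load(f)

    out = []
    for entry in manifest["subjects"]:
        target = path / entry["file"]
        if not target.exists():
            raise FileNotFoundError(f"missing subject file {entry['file']}")
        if manifest["kind"] == "recordings":
            out.append(_read_recording_h5(target, entry["subject_id"], entry["group"]))
            continue
        if manifest["kind"] == "corrected":
            import h5py

            with h5py.File(target, "r") as f:
                ce = CorrectedEpochs(
                    subject_id=entry["subject_id"],
                    group=entry["group"],
                    sampling_rate=float(f.attrs["sampling_rate"]),
                    time_axis=f["time_axis"][()],
                    data=f["data"][()],
                    channel_ids=tuple(int(c) for c in f.attrs["channel_ids"]),
                )
            if ce.n_channels != manifest["n_channels"]:
                raise ValueError(
                    f"{entry['subject_id']}: channel count mismatch vs manifest"
                )
            out.append(ce)
            continue
        if manifest["format"] == "h5":
            es = _read_epochs_h5(target, entry["subject_id"], entry["group"])
        else:
            es = _read_epochs_csv(
                target, entry["subject_id"], entry["group"],
                float(manifest["sampling_rate"]),
                np.asarray(manifest["time_axis"], dtype=float),
                tuple(manifest["channel_ids"]),
            )
        if es.n_channels != manifest["n_channels"]:
            raise ValueError(
                f"{entry['subject_id']}: {es.n_channels} channels on disk, "
                f"manifest says {manifest['n_channels']}"
            )
        out.append(es)
    return out


def read_edf_recording(edf_path, events_path, subject_id: str, group: str) -> OddballRecording:
    """Optional EDF import of a continuous recording.

    ``events_path`` is a two-column delimited text file (onset_sample, kind).
    Requires :mod:`mne`.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF import requires the optional dependency 'mne'") from exc

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    events = []
    with open(events_path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            onset, kind = line.replace(",", " ").split()
            events.append((int(onset), kind))
    return OddballRecording(
        subject_id=subject_id,
        group=group,
        signal=raw.get_data() * 1e6,  # volts -> µV
        sampling_rate=float(raw.info["sfreq"]),
        events=events,
    )
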