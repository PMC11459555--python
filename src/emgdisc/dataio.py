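"""Cohort manifest I/O and gesture segmentation.

A cohort on disk is a JSON manifest plus one CSV per recording (header
``ch1..ch8``, one integer row per sample at 200 Hz).  Segmentation turns a
rest-padded recording into a :class:`GestureTemplate` — the variable-length
multi-channel sequence spanning one discrete gesture — either from the true
start/end indices carried as metadata or by active thresholding against a
rest baseline.  All indices are 0-based, half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Protocol

import numpy as np

__all__ = [
    "EMGRecording",
    "GestureTemplate",
    "ManifestEntry",
    "DatasetManifest",
    "write_cohort",
    "read_manifest",
    "load_recording",
    "segment_by_indices",
    "segment_by_threshold",
    "crop_rest",
    "rest_baseline",
    "DatasetAdapter",
]

N_CHANNELS = 8


@dataclass
class EMGRecording:
    """Raw multi-channel integer EMG with identity and segment metadata."""

    samples: np.ndarray  # (8, T) integer
    fs: int = 200
    user_id: str = ""
    gesture: str = "unknown"
    rep: int = 0
    condition: str = "base"
    start_index: int | None = None
    end_index: int | None = None
    demographics: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[0] != N_CHANNELS:
            raise ValueError(
                f"expected an 8 x T sample matrix, got {self.samples.shape}"
            )
        T = self.samples.shape[1]
        if self.start_index is not None or self.end_index is not None:
            if self.start_index is None or self.end_index is None:
                raise ValueError("start_index and end_index must come together")
            if not (0 <= self.start_index < self.end_index <= T):
                raise ValueError(
                    f"segment [{self.start_index}, {self.end_index}) out of "
                    f"bounds for T={T}"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class GestureTemplate:
    """One segmented discrete gesture event (channels x length)."""

    samples: np.ndarray
    label: str
    user_id: str = ""
    rep: int = 0
    condition: str = "base"
    source: object | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2 or self.samples.shape[1] < 1:
            raise ValueError("template must be channels x length with length >= 1")

    @property
    def length(self) -> int:
        return self.samples.shape[1]


@dataclass
class ManifestEntry:
    path: str
    user_id: str
    gesture: str
    rep: int
    condition: str
    demographics: dict[str, str]
    start_index: int | None
    end_index: int | None
    extra: dict = field(default_factory=dict)


@dataclass
class DatasetManifest:
    root: Path
    fs_hz: int
    entries: list[ManifestEntry]

    def __len__(self) -> int:
        return len(self.entries)


class DatasetAdapter(Protocol):
    """Interface real-dataset loaders implement: enumerate, then load."""

    def entries(self) -> list[ManifestEntry]: ...

    def load(self, entry: ManifestEntry) -> EMGRecording: ...


_CSV_HEADER = ",".join(f"ch{i + 1}" for i in range(N_CHANNELS))


def _write_recording_csv(path: Path, samples: np.ndarray) -> None:
    np.savetxt(
        path, np.asarray(samples).T, fmt="%d", delimiter=",",
        header=_CSV_HEADER, comments="",
    )


def write_cohort(
    recordings: Iterable[EMGRecording], out_dir: str | Path, fs_hz: int = 200
) -> DatasetManifest:
    """Write recordings as CSVs plus a JSON manifest; returns the manifest."""
    root = Path(out_dir)
    root.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in recordings:
        rel = Path(rec.user_id) / (
            f"{rec.gesture}_r{rec.rep:02d}_{rec.condition}.csv"
        )
        (root / rel).parent.mkdir(parents=True, exist_ok=True)
        _write_recording_csv(root / rel, rec.samples)
        entries.append(
            ManifestEntry(
                path=str(rel),
                user_id=rec.user_id,
                gesture=rec.gesture,
                rep=rec.rep,
                condition=rec.condition,
                demographics=dict(rec.demographics),
                start_index=rec.start_index,
                end_index=rec.end_index,
            )
        )
    manifest = DatasetManifest(root=root, fs_hz=fs_hz, entries=entries)
    doc = {
        "fs_hz": fs_hz,
        "entries": [asdict(e) for e in entries],
    }
    (root / "manifest.json").write_text(json.dumps(doc, indent=1, sort_keys=True))
    return manifest


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read a manifest written by :func:`write_cohort`.

    ``path`` may be the manifest file or the cohort directory.  Unknown
    per-entry keys are preserved under ``entry.extra``.
    """
    p = Path(path)
    if p.is_dir():
        p = p / "manifest.json"
    doc = json.loads(p.read_text())
    known = {
        "path", "user_id", "gesture", "rep", "condition", "demographics",
        "start_index", "end_index", "extra",
    }
    entries = []
    for e in doc["entries"]:
        extra = {k: v for k, v in e.items() if k not in known}
        extra.update(e.get("extra", {}))
        entries.append(
            ManifestEntry(
                path=e["path"],
                user_id=e["user_id"],
                gesture=e["gesture"],
                rep=e["rep"],
                condition=e["condition"],
                demographics=e.get("demographics", {}),
                start_index=e.get("start_index"),
                end_index=e.get("end_index"),
                extra=extra,
            )
        )
    return DatasetManifest(root=p.parent, fs_hz=doc["fs_hz"], entries=entries)


def load_recording(
    entry: ManifestEntry, root: str | Path, fs_hz: int = 200
) -> EMGRecording:
    """Load one recording CSV described by a manifest entry."""
    path = Path(root) / entry.path
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2, dtype=np.int64)
    if data.ndim != 2 or data.shape[1] != N_CHANNELS:
        raise ValueError(
            f"{path}: expected {N_CHANNELS} columns, got "
            f"{data.shape[1] if data.ndim == 2 else 1}"
        )
    return EMGRecording(
        samples=data.T,
        fs=fs_hz,
        user_id=entry.user_id,
        gesture=entry.gesture,
        rep=entry.rep,
        condition=entry.condition,
        start_index=entry.start_index,
        end_index=entry.end_index,
        demographics=dict(entry.demographics),
    )


def load_cohort(manifest: DatasetManifest) -> list[EMGRecording]:
    """Load every recording listed in a manifest."""
    return [load_recording(e, manifest.root, manifest.fs_hz)
            for e in manifest.entries]


def segment_by_indices(rec: EMGRecording) -> GestureTemplate:
    """Crop the true active segment using the recording's index metadata."""
    if rec.start_index is None or rec.end_index is None:
        raise ValueError("recording carries no start/end indices")
    return GestureTemplate(
        samples=rec.samples[:, rec.start_index : rec.end_index],
        label=rec.gesture,
        user_id=rec.user_id,
        rep=rec.rep,
        condition=rec.condition,
        source=rec,
    )


def rest_baseline(rest_recs: Iterable[EMGRecording]) -> np.ndarray:
    """Per-channel mean absolute amplitude over a user's rest recordings."""
    recs = list(rest_recs)
    if not recs:
        raise ValueError("need at least one rest recording")
    return np.mean(
        [np.mean(np.abs(r.samples.astype(float)), axis=1) for r in recs],
        axis=0,
    )


def segment_by_threshold(
    rec: EMGRecording,
    rest_baseline: np.ndarray | float,
    k: float = 3.0,
    min_duration: int = 40,
    smooth_win: int = 15,
) -> GestureTemplate:
    """Segment by active thresholding against a rest-class baseline.

    The channel-summed absolute amplitude is smoothed with a ``smooth_win``
    moving average; the active region is the longest run (ties: earliest)
    where the trace exceeds ``k`` times the summed baseline for at least
    ``min_duration`` samples.
    """
    base = np.asarray(rest_baseline, dtype=float)
    threshold = k * (base.sum() if base.ndim else float(base) * N_CHANNELS)
    trace = np.abs(rec.samples.astype(float)).sum(axis=0)
    if smooth_win > 1:
        kernel = np.ones(smooth_win) / smooth_win
        trace = np.convolve(trace, kernel, mode="same")
    above = trace > threshold
    # longest supra-threshold run of at least min_duration samples
    best = None  # (length, start)
    start = None
    padded = np.concatenate([above, [False]])
    for i, a in enumerate(padded):
        if a and start is None:
            start = i
        elif not a and start is not None:
            run = i - start
            if run >= min_duration and (best is None or run > best[0]):
                best = (run, start)
            start = None
    if best is None:
        raise ValueError("no activity detected above threshold")
    run, s = best
    return GestureTemplate(
        samples=rec.samples[:, s : s + run],
        label=rec.gesture,
        user_id=rec.user_id,
        rep=rec.rep,
        condition=rec.condition,
        source=rec,
    )


def crop_rest(rec: EMGRecording, target_length: int) -> GestureTemplate:
    """Center-crop a rest recording to ``target_length`` samples."""
    T = rec.n_samples
    if target_length > T:
        raise ValueError(f"target_length {target_length} exceeds T={T}")
    if target_length < 1:
        raise ValueError("target_length must be >= 1")
    start = (T - target_length) // 2
    return GestureTemplate(
        samples=rec.samples[:, start : start + target_length],
        label=rec.gesture,
        user_id=rec.user_id,
        rep=rec.rep,
        condition=rec.condition,
        source=rec,
    )
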