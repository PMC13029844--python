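"""Data model and I/O for six-channel ground-reaction-force gait cycles.

A *gait cycle* here is a fixed-length recording of the forces a walker exerts
on two force plates, one stance per limb, sampled at 960 Hz.  Each limb
contributes three orthogonal components — anterior–posterior (AP), vertical
(V) and medial–lateral (ML) — giving six ordered channels
``(L_AP, L_V, L_ML, R_AP, R_V, R_ML)``.  Outside a limb's stance interval its
channels are exactly zero; shorter cycles are zero-padded at the end so a
whole dataset shares one length.  Forces stay in raw newtons throughout:
signals are deliberately never rescaled by body weight, because a deployed
identification system cannot measure body mass separately from the plates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "CHANNEL_NAMES",
    "LEFT_CHANNELS",
    "RIGHT_CHANNELS",
    "VERTICAL_CHANNELS",
    "CONDITIONS",
    "DEFAULT_SAMPLE_RATE",
    "DEFAULT_STANCE_THRESHOLD_N",
    "SchemaError",
    "FormatError",
    "NoStanceError",
    "StanceInterval",
    "Subject",
    "GRFCycle",
    "GaitDataset",
    "detect_stance",
    "stance_intervals",
    "pad_to_uniform",
    "read_dataset",
    "write_dataset",
]

CHANNEL_NAMES = ("L_AP", "L_V", "L_ML", "R_AP", "R_V", "R_ML")
LEFT_CHANNELS = (0, 1, 2)
RIGHT_CHANNELS = (3, 4, 5)
#: indices of the two vertical-force channels (left, right)
VERTICAL_CHANNELS = (1, 4)
CONDITIONS = ("unloaded", "loaded_left", "loaded_right")

DEFAULT_SAMPLE_RATE = 960.0
#: stance-detection threshold: well above plate noise, far below body weight
DEFAULT_STANCE_THRESHOLD_N = 10.0
#: tolerance for "vertical force is non-negative" (sensor-noise allowance)
VERTICAL_EPS_N = 1e-6


class SchemaError(ValueError):
    """Manifest/file collection violates the dataset schema."""


class FormatError(ValueError):
    """A cycle file does not conform to the six-channel format."""


class NoStanceError(ValueError):
    """No sample of the vertical force exceeds the stance threshold."""


@dataclass(frozen=True)
class StanceInterval:
    """Half-open sample interval ``[start, end)`` of one limb's ground contact."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid stance interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def duration_s(self, sample_rate: float) -> float:
        return self.length / sample_rate


@dataclass
class Subject:
    """Roster entry: identity plus the anthropometrics recorded at enrolment."""

    subject_id: str
    body_mass_kg: float
    height_cm: float = float("nan")
    carrying_hand: str = "right"

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")
        if self.carrying_hand not in ("left", "right"):
            raise ValueError(f"unknown carrying hand {self.carrying_hand!r}")


@dataclass
class GRFCycle:
    """One gait cycle: a ``(6, N)`` force array in newtons plus metadata.

    ``body_mass_kg`` is carried as metadata only — no operation in this
    package divides the signal by body mass or body weight.
    """

    subject_id: str
    condition: str
    trial_id: int
    signal: np.ndarray
    body_mass_kg: float
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[0] != 6:
            raise FormatError(
                f"cycle signal must have 6 channels, got shape {self.signal.shape}"
            )
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")
        for ch in VERTICAL_CHANNELS:
            if np.any(self.signal[ch] < -VERTICAL_EPS_N):
                raise ValueError("vertical force component is negative")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel(self, name: str) -> np.ndarray:
        return self.signal[CHANNEL_NAMES.index(name)]

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.subject_id, self.condition, self.trial_id)

    def copy_with(self, signal: np.ndarray) -> "GRFCycle":
        """New cycle with the same metadata and a replaced signal array."""
        return GRFCycle(
            subject_id=self.subject_id,
            condition=self.condition,
            trial_id=self.trial_id,
            signal=signal,
            body_mass_kg=self.body_mass_kg,
            sample_rate=self.sample_rate,
        )


def detect_stance(
    fv: np.ndarray, threshold: float = DEFAULT_STANCE_THRESHOLD_N
) -> StanceInterval:
    """Locate ground contact from a vertical-force series.

    Returns the envelope of supra-threshold samples: ``start`` is the first
    index with ``fv > threshold`` and ``end`` one past the last.  Brief dips
    below the threshold inside the contact (e.g. sensor flutter) are
    tolerated because only the first and last exceedance matter.
    """
    fv = np.asarray(fv, dtype=np.float64)
    if fv.ndim != 1 or fv.size == 0:
        raise ValueError("vertical force series must be a nonempty 1-D array")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    above = np.flatnonzero(fv > threshold)
    if above.size == 0:
        raise NoStanceError(f"no sample exceeds {threshold} N")
    return StanceInterval(int(above[0]), int(above[-1]) + 1)


def stance_intervals(
    cycle: GRFCycle, threshold: float = DEFAULT_STANCE_THRESHOLD_N
) -> tuple[StanceInterval, StanceInterval]:
    """Per-limb stance intervals (left, right) from the vertical channels."""
    left = detect_stance(cycle.signal[VERTICAL_CHANNELS[0]], threshold)
    right = detect_stance(cycle.signal[VERTICAL_CHANNELS[1]], threshold)
    return left, right


@dataclass
class GaitDataset:
    """An ordered collection of cycles padded to one unified length."""

    cycles: list[GRFCycle]
    subjects: dict[str, Subject] = field(default_factory=dict)
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        if not self.subjects:
            # build a minimal roster from the cycles themselves
            self.subjects = {
                c.subject_id: Subject(c.subject_id, c.body_mass_kg)
                for c in self.cycles
            }
        self.validate()

    def validate(self) -> None:
        lengths = {c.n_samples for c in self.cycles}
        if len(lengths) > 1:
            raise ValueError(f"cycles have mixed lengths {sorted(lengths)}")
        for c in self.cycles:
            if abs(c.sample_rate - self.sample_rate) > 1e-9:
                raise ValueError("mixed sample rates in dataset")
            if c.subject_id not in self.subjects:
                raise SchemaError(f"cycle subject {c.subject_id!r} not in roster")
        keys = [c.key for c in self.cycles]
        if len(set(keys)) != len(keys):
            raise SchemaError("duplicate (subject, condition, trial) keys")

    @property
    def unified_length(self) -> int:
        return self.cycles[0].n_samples if self.cycles else 0

    def __len__(self) -> int:
        return len(self.cycles)

    def __iter__(self):
        return iter(self.cycles)

    def signals(self) -> np.ndarray:
        """Stacked ``(M, 6, N)`` array of all cycle signals."""
        if not self.cycles:
            return np.zeros((0, 6, 0))
        return np.stack([c.signal for c in self.cycles])

    def subject_ids(self) -> list[str]:
        return [c.subject_id for c in self.cycles]

    def class_ids(self) -> list[str]:
        """Sorted roster subject ids — the closed identification class set."""
        return sorted(self.subjects)

    def labels(self) -> np.ndarray:
        """Integer labels of each cycle, indices into :meth:`class_ids`."""
        index = {s: i for i, s in enumerate(self.class_ids())}
        return np.array([index[c.subject_id] for c in self.cycles], dtype=np.intp)

    def subset(self, indices) -> "GaitDataset":
        """New dataset with the selected cycles and the full roster."""
        return GaitDataset(
            cycles=[self.cycles[int(i)] for i in indices],
            subjects=dict(self.subjects),
            sample_rate=self.sample_rate,
        )


def pad_to_uniform(
    cycles,
    subjects: dict[str, Subject] | None = None,
    target_length: int | None = None,
) -> GaitDataset:
    """Zero-pad every cycle at the end to the longest cycle's length.

    Cycles are aligned at the first heel strike, so padding is appended;
    pre-existing samples are never altered.  ``target_length`` may force a
    longer common length (used when two datasets must share one length).
    """
    cycles = list(cycles)
    if not cycles:
        raise ValueError("cannot pad an empty cycle collection")
    rates = {c.sample_rate for c in cycles}
    if len(rates) > 1:
        raise ValueError(f"mixed sample rates {sorted(rates)}")
    n_max = max(c.n_samples for c in cycles)
    if target_length is not None:
        if target_length < n_max:
            raise ValueError("target_length shorter than the longest cycle")
        n_max = target_length
    padded = []
    for c in cycles:
        if c.n_samples == n_max:
            padded.append(c)
        else:
            sig = np.zeros((6, n_max))
            sig[:, : c.n_samples] = c.signal
            padded.append(c.copy_with(sig))
    return GaitDataset(cycles=padded, subjects=subjects or {}, sample_rate=cycles[0].sample_rate)


# ---------------------------------------------------------------------------
# File I/O
#
# Two on-disk layouts are supported:
#   * "csv":       one CSV per cycle (columns: sample_index + the six
#                  channels) plus a JSON manifest — human-readable, values
#                  round-trip to >= 9 significant digits;
#   * "container": a single HDF5 file (/cycles/<key>/signal with metadata
#                  attributes) — bit-exact round trips, suited to large
#                  synthetic datasets.
# ---------------------------------------------------------------------------

_MANIFEST_NAME = "manifest.json"


def _cycle_filename(cycle: GRFCycle) -> str:
    return f"{cycle.subject_id}__{cycle.condition}__{cycle.trial_id}.csv"


def write_dataset(ds: GaitDataset, path, format: str = "csv") -> None:
    """Write a dataset in the requested layout (see module notes)."""
    path = Path(path)
    if format == "csv":
        _write_csv(ds, path)
    elif format == "container":
        _write_container(ds, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_dataset(path, format: str = "csv") -> GaitDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format == "container":
        return _read_container(path)
    raise ValueError(f"unknown format {format!r}")


def _manifest_dict(ds: GaitDataset) -> dict:
    return {
        "channel_order": list(CHANNEL_NAMES),
        "sample_rate_hz": ds.sample_rate,
        "unified_length": ds.unified_length,
        "subjects": [
            {
                "id": s.subject_id,
                "body_mass_kg": s.body_mass_kg,
                "height_cm": s.height_cm,
                "carrying_hand": s.carrying_hand,
            }
            for s in ds.subjects.values()
        ],
        "cycles": [
            {
                "file": _cycle_filename(c),
                "subject": c.subject_id,
                "condition": c.condition,
                "trial": c.trial_id,
            }
            for c in ds.cycles
        ],
    }


def _roster_from_manifest(entries) -> dict[str, Subject]:
    roster = {}
    for e in entries:
        sid = e["id"]
        if sid in roster:
            raise SchemaError(f"duplicate subject {sid!r} in manifest")
        roster[sid] = Subject(
            subject_id=sid,
            body_mass_kg=float(e["body_mass_kg"]),
            height_cm=float(e.get("height_cm", float("nan"))),
            carrying_hand=e.get("carrying_hand", "right"),
        )
    return roster


def _write_csv(ds: GaitDataset, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    header = "sample_index," + ",".join(CHANNEL_NAMES)
    for c in ds.cycles:
        rows = np.column_stack([np.arange(c.n_samples), c.signal.T])
        np.savetxt(
            path / _cycle_filename(c),
            rows,
            delimiter=",",
            header=header,
            comments="",
            fmt=["%d"] + ["%.12g"] * 6,
        )
    (path / _MANIFEST_NAME).write_text(json.dumps(_manifest_dict(ds), indent=1))


def _read_csv(path: Path) -> GaitDataset:
    manifest_path = path / _MANIFEST_NAME
    if not manifest_path.exists():
        raise SchemaError(f"missing {_MANIFEST_NAME} in {path}")
    manifest = json.loads(manifest_path.read_text())
    sample_rate = float(manifest["sample_rate_hz"])
    if sample_rate <= 0:
        raise ValueError("sample_rate_hz must be positive")
    roster = _roster_from_manifest(manifest["subjects"])
    cycles = []
    seen = set()
    for entry in manifest["cycles"]:
        key = (entry["subject"], entry["condition"], int(entry["trial"]))
        if key in seen:
            raise SchemaError(f"duplicate cycle key {key}")
        seen.add(key)
        table = np.loadtxt(path / entry["file"], delimiter=",", skiprows=1, ndmin=2)
        if table.shape[1] != 7:
            raise FormatError(
                f"{entry['file']}: expected 7 columns (index + 6 channels), "
                f"got {table.shape[1]}"
            )
        if key[0] not in roster:
            raise SchemaError(f"cycle subject {key[0]!r} missing from manifest roster")
        cycles.append(
            GRFCycle(
                subject_id=key[0],
                condition=key[1],
                trial_id=key[2],
                signal=table[:, 1:].T,
                body_mass_kg=roster[key[0]].body_mass_kg,
                sample_rate=sample_rate,
            )
        )
    return GaitDataset(cycles=cycles, subjects=roster, sample_rate=sample_rate)


def _write_container(ds: GaitDataset, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["sample_rate_hz"] = ds.sample_rate
        f.attrs["unified_length"] = ds.unified_length
        f.attrs["channel_order"] = ",".join(CHANNEL_NAMES)
        f.attrs["roster"] = json.dumps(_manifest_dict(ds)["subjects"])
        grp = f.create_group("cycles")
        for i, c in enumerate(ds.cycles):
            g = grp.create_group(f"{i:06d}")
            g.create_dataset("signal", data=c.signal)
            g.attrs["subject"] = c.subject_id
            g.attrs["condition"] = c.condition
            g.attrs["trial"] = c.trial_id
            g.attrs["body_mass_kg"] = c.body_mass_kg


def _read_container(path: Path) -> GaitDataset:
    with h5py.File(path, "r") as f:
        sample_rate = float(f.attrs["sample_rate_hz"])
        roster = _roster_from_manifest(json.loads(f.attrs["roster"]))
        cycles = []
        for key in sorted(f["cycles"]):
            g = f["cycles"][key]
            signal = g["signal"][()]
            if signal.shape[0] != 6:
                raise FormatError(f"cycle {key}: expected 6 channels")
            cycles.append(
                GRFCycle(
                    subject_id=str(g.attrs["subject"]),
                    condition=str(g.attrs["condition"]),
                    trial_id=int(g.attrs["trial"]),
                    signal=signal,
                    body_mass_kg=float(g.attrs["body_mass_kg"]),
                    sample_rate=sample_rate,
                )
            )
    return GaitDataset(cycles=cycles, subjects=roster, sample_rate=sample_rate)
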