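"""Episodic sweep recordings: data model, validation, and fixture I/O.

A :class:`Recording` is an ordered set of uniformly sampled sweeps acquired in
either current clamp (signal in mV, commanded current steps in pA) or voltage
clamp (signal in pA, commanded voltage steps in mV).  Command-step metadata is
mandatory for every sweep: all downstream analyses assume the commanded step is
known, and inferring it from the recorded trace is refused by design.

Time is expressed in seconds from sweep start; sample ``i`` corresponds to time
``i / sampling_rate`` and command intervals are half-open
``[onset, onset + duration)``.

The portable fixture format is a JSON manifest (metadata and per-sweep step
commands) next to an array container holding the samples, either HDF5
(``.h5``) or CSV (``.csv``).  Round-tripping through
:func:`write_recording` / :func:`read_recording` is exact for metadata and
lossless for samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "ClampMode",
    "GroupLabel",
    "ProtocolTag",
    "StepCommand",
    "Sweep",
    "Recording",
    "read_recording",
    "write_recording",
    "validate_recording",
    "RecordingError",
]


class RecordingError(ValueError):
    """Raised for malformed recordings or unreadable fixture files."""


class ClampMode(str, Enum):
    CURRENT_CLAMP = "current_clamp"
    VOLTAGE_CLAMP = "voltage_clamp"


class GroupLabel(str, Enum):
    """The three experimental arms of the cohort design."""

    CONTROL = "control"
    PAE_SALINE = "PAE_saline"
    PAE_NBOH = "PAE_NBOH"


class ProtocolTag(str, Enum):
    FI_STEPS = "fi_steps"
    RHEOBASE_STEPS = "rheobase_steps"
    HYPERPOLARIZING_STEPS = "hyperpolarizing_steps"
    SEPSC = "sepsc"


@dataclass(frozen=True)
class StepCommand:
    """A rectangular command step within a sweep.

    ``amplitude`` and ``baseline_level`` are in pA for current clamp and mV
    for voltage clamp; ``onset`` and ``duration`` are seconds from sweep
    start.
    """

    amplitude: float
    onset: float
    duration: float
    baseline_level: float = 0.0

    def to_dict(self) -> dict:
        return {
            "amplitude": self.amplitude,
            "onset": self.onset,
            "duration": self.duration,
            "baseline_level": self.baseline_level,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StepCommand":
        return cls(
            amplitude=float(d["amplitude"]),
            onset=float(d["onset"]),
            duration=float(d["duration"]),
            baseline_level=float(d.get("baseline_level", 0.0)),
        )


@dataclass
class Sweep:
    """One uniformly sampled trace plus its command step."""

    samples: np.ndarray
    sampling_rate: float
    command: StepCommand
    sweep_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_rate

    def time(self) -> np.ndarray:
        """Sample times in seconds from sweep start."""
        return np.arange(self.n_samples) / self.sampling_rate

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sweep):
            return NotImplemented
        return (
            self.sweep_index == other.sweep_index
            and self.sampling_rate == other.sampling_rate
            and self.command == other.command
            and np.array_equal(self.samples, other.samples)
        )


@dataclass
class Recording:
    """Ordered sweeps from one cell under one protocol."""

    sweeps: list[Sweep]
    clamp_mode: ClampMode
    cell_id: str
    group_label: GroupLabel
    protocol_tag: ProtocolTag
    holding_level: float = 0.0

    def __post_init__(self) -> None:
        self.clamp_mode = ClampMode(self.clamp_mode)
        self.group_label = GroupLabel(self.group_label)
        self.protocol_tag = ProtocolTag(self.protocol_tag)

    @property
    def sampling_rate(self) -> float:
        if not self.sweeps:
            raise RecordingError("recording has no sweeps")
        return self.sweeps[0].sampling_rate

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Recording):
            return NotImplemented
        return (
            self.cell_id == other.cell_id
            and self.clamp_mode == other.clamp_mode
            and self.group_label == other.group_label
            and self.protocol_tag == other.protocol_tag
            and self.holding_level == other.holding_level
            and self.sweeps == other.sweeps
        )


def validate_recording(recording: Recording) -> list[str]:
    """Check all type invariants; return a list of human-readable violations.

    An empty list means the recording is well formed.  Violations name the
    offending sweep index and field; they are returned as data, never raised.
    """
    violations: list[str] = []
    if not recording.sweeps:
        violations.append("sweeps: recording contains no sweeps")
        return violations

    rates = {s.sampling_rate for s in recording.sweeps}
    if len(rates) > 1:
        violations.append(f"sampling_rate: non-uniform sampling across sweeps ({sorted(rates)})")

    for sweep in recording.sweeps:
        tag = f"sweep {sweep.sweep_index}"
        if sweep.sampling_rate <= 0:
            violations.append(f"{tag}: sampling_rate must be > 0, got {sweep.sampling_rate}")
        if sweep.n_samples == 0:
            violations.append(f"{tag}: samples empty")
            continue
        if not np.all(np.isfinite(sweep.samples)):
            bad = int(np.flatnonzero(~np.isfinite(sweep.samples))[0])
            violations.append(f"{tag}: samples contain non-finite value at index {bad}")
        cmd = sweep.command
        if cmd.onset < 0:
            violations.append(f"{tag}: command.onset must be >= 0, got {cmd.onset}")
        if cmd.duration < 0:
            violations.append(f"{tag}: command.duration must be >= 0, got {cmd.duration}")
        if sweep.sampling_rate > 0 and cmd.onset + cmd.duration > sweep.duration + 0.5 * sweep.dt:
            violations.append(
                f"{tag}: command extends past sweep end "
                f"(onset + duration = {cmd.onset + cmd.duration:g} s > {sweep.duration:g} s)"
            )
    return violations


# ---------------------------------------------------------------------------
# Fixture format

_MANIFEST_FIELDS = ("cell_id", "group_label", "clamp_mode", "sampling_rate", "protocol_tag")


def write_recording(recording: Recording, path: str | Path, container: str = "h5") -> Path:
    """Write a recording as a JSON manifest plus an array container.

    ``path`` is the manifest path (``.json`` appended if missing); the sample
    container is written next to it with the same stem and extension ``.h5``
    or ``.csv`` per ``container``.  Returns the manifest path.
    """
    violations = validate_recording(recording)
    if violations:
        raise RecordingError("cannot write invalid recording: " + "; ".join(violations))
    if container not in ("h5", "csv"):
        raise RecordingError(f"unknown container format {container!r}")

    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    path.parent.mkdir(parents=True, exist_ok=True)
    container_path = path.with_suffix("." + container)

    manifest = {
        "cell_id": recording.cell_id,
        "group_label": recording.group_label.value,
        "clamp_mode": recording.clamp_mode.value,
        "sampling_rate": recording.sampling_rate,
        "protocol_tag": recording.protocol_tag.value,
        "holding_level": recording.holding_level,
        "container": container_path.name,
        "sweeps": [
            {
                "sweep_index": s.sweep_index,
                "n_samples": s.n_samples,
                "command": s.command.to_dict(),
            }
            for s in recording.sweeps
        ],
    }
    path.write_text(json.dumps(manifest, indent=1))

    if container == "h5":
        import h5py

        with h5py.File(container_path, "w") as f:
            for s in recording.sweeps:
                f.create_dataset(f"sweep_{s.sweep_index:04d}", data=s.samples)
    else:
        # One column per sweep; ragged sweeps padded with empty cells.
        n_rows = max(s.n_samples for s in recording.sweeps)
        cols = []
        for s in recording.sweeps:
            col = np.full(n_rows, "", dtype=object)
            col[: s.n_samples] = [repr(float(v)) for v in s.samples]
            cols.append(col)
        header = ",".join(f"sweep_{s.sweep_index:04d}" for s in recording.sweeps)
        lines = [header] + [",".join(row) for row in zip(*cols)]
        container_path.write_text("\n".join(lines) + "\n")
    return path


def read_recording(path: str | Path, format: str = "fixture") -> Recording:
    """Read a recording from disk.

    ``format="fixture"`` reads the JSON-manifest format written by
    :func:`write_recording`.  ``format="abf"`` ingests an Axon Binary Format
    file via the optional ``pyabf`` dependency.
    """
    if format == "fixture":
        return _read_fixture(Path(path))
    if format == "abf":
        return _read_abf(Path(path))
    raise RecordingError(f"unknown format {format!r}; expected 'fixture' or 'abf'")


def _read_fixture(path: Path) -> Recording:
    if not path.exists():
        raise RecordingError(f"fixture manifest not found: {path}")
    try:
        manifest = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise RecordingError(f"fixture manifest is not valid JSON: {path}: {exc}") from exc
    for field_name in _MANIFEST_FIELDS:
        if field_name not in manifest:
            raise RecordingError(f"fixture manifest missing required field {field_name!r}")
    if "sweeps" not in manifest or not manifest["sweeps"]:
        raise RecordingError("fixture manifest missing per-sweep command metadata ('sweeps')")

    container_path = path.parent / manifest["container"]
    if not container_path.exists():
        raise RecordingError(f"sample container not found: {container_path}")

    if container_path.suffix == ".h5":
        import h5py

        with h5py.File(container_path, "r") as f:
            arrays = {name: np.asarray(f[name], dtype=np.float64) for name in f}
    elif container_path.suffix == ".csv":
        arrays = _read_csv_container(container_path)
    else:
        raise RecordingError(f"unknown container extension {container_path.suffix!r}")

    rate = float(manifest["sampling_rate"])
    sweeps = []
    for entry in manifest["sweeps"]:
        if "command" not in entry:
            raise RecordingError(
                f"sweep {entry.get('sweep_index')}: missing command metadata in manifest"
            )
        idx = int(entry["sweep_index"])
        key = f"sweep_{idx:04d}"
        if key not in arrays:
            raise RecordingError(f"container missing dataset {key!r}")
        samples = arrays[key]
        if "n_samples" in entry and int(entry["n_samples"]) != samples.size:
            raise RecordingError(
                f"sweep {idx}: manifest declares {entry['n_samples']} samples, "
                f"container holds {samples.size}"
            )
        sweeps.append(
            Sweep(
                samples=samples,
                sampling_rate=rate,
                command=StepCommand.from_dict(entry["command"]),
                sweep_index=idx,
            )
        )

    rec = Recording(
        sweeps=sweeps,
        clamp_mode=ClampMode(manifest["clamp_mode"]),
        cell_id=str(manifest["cell_id"]),
        group_label=GroupLabel(manifest["group_label"]),
        protocol_tag=ProtocolTag(manifest["protocol_tag"]),
        holding_level=float(manifest.get("holding_level", 0.0)),
    )
    violations = validate_recording(rec)
    # Non-uniform sampling cannot arise from a single-rate manifest, but keep
    # the explicit check so hand-edited fixtures fail loudly.
    if violations:
        raise RecordingError("invalid fixture: " + "; ".join(violations))
    return rec


def _read_csv_container(path: Path) -> dict[str, np.ndarray]:
    lines = path.read_text().splitlines()
    names = lines[0].split(",")
    cols: dict[str, list[float]] = {n: [] for n in names}
    for line in lines[1:]:
        for name, cell in zip(names, line.split(",")):
            if cell:
                cols[name].append(float(cell))
    return {n: np.asarray(v, dtype=np.float64) for n, v in cols.items()}


def _read_abf(path: Path) -> Recording:  # pragma: no cover - optional dependency
    try:
        import pyabf
    except ImportError as exc:
        raise RecordingError(
            "ABF ingestion requires the optional 'pyabf' package; "
            "install it or convert the file to the fixture format"
        ) from exc
    abf = pyabf.ABF(str(path))
    rates = {abf.dataRate}
    if len(rates) != 1:
        raise RecordingError("non-uniform sampling")
    mode = ClampMode.CURRENT_CLAMP if abf.adcUnits[0].lower().startswith("mv") else ClampMode.VOLTAGE_CLAMP
    sweeps = []
    for i in abf.sweepList:
        abf.sweepSetChannel = 0
        abf.setSweep(i)
        epochs = getattr(abf.sweepEpochs, "levels", None)
        if epochs is None:
            raise RecordingError("ABF file lacks epoch (command step) metadata")
        levels = np.asarray(abf.sweepEpochs.levels, dtype=float)
        p1s = np.asarray(abf.sweepEpochs.p1s, dtype=float)
        p2s = np.asarray(abf.sweepEpochs.p2s, dtype=float)
        base = levels[0]
        step = np.flatnonzero(levels != base)
        if step.size:
            j = int(step[0])
            cmd = StepCommand(
                amplitude=float(levels[j] - base),
                onset=float(p1s[j] / abf.dataRate),
                duration=float((p2s[j] - p1s[j]) / abf.dataRate),
                baseline_level=float(base),
            )
        else:
            cmd = StepCommand(amplitude=0.0, onset=0.0, duration=0.0, baseline_level=float(base))
        sweeps.append(Sweep(np.asarray(abf.sweepY, dtype=np.float64), float(abf.dataRate), cmd, i))
    return Recording(
        sweeps=sweeps,
        clamp_mode=mode,
        cell_id=str(abf.abfID),
        group_label=GroupLabel.CONTROL,
        protocol_tag=ProtocolTag.FI_STEPS,
    )
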