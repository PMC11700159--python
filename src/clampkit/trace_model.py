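"""Core data types for episodic whole-cell recordings.

Unit conventions, fixed project-wide:

* membrane potential in mV, membrane current in pA
* reported spike/step features in ms, internal time axes in seconds
* resistances in MOhm, capacitance in pF
* inward current negative, outward current positive

A :class:`Sweep` is the atomic unit of analysis: one uniformly sampled
response trace plus the command step applied while it was recorded.  A
:class:`CellRecording` bundles every sweep acquired from one neuron under
one recording condition together with the cell's metadata.

The on-disk container is one directory per cell holding a ``meta.json``
sidecar and one CSV table per protocol (columns ``sweep``, ``time_s``,
``command``, ``response``, ``repetition``).  Sample values are written with
17 significant digits so that float64 traces round-trip bit-exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CURRENT_CLAMP",
    "VOLTAGE_CLAMP",
    "GENOTYPES",
    "TREATMENTS",
    "CONDITIONS",
    "ClampKitError",
    "FormatError",
    "IntegrityError",
    "UnitError",
    "Sweep",
    "StepProtocol",
    "CellRecording",
    "PassiveProperties",
    "SpikeEvent",
    "FICurve",
    "RheobaseFeatures",
    "VClampFeatures",
    "read_recording",
    "write_recording",
]

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"
_MODES = (CURRENT_CLAMP, VOLTAGE_CLAMP)

GENOTYPES = ("WT", "Tau", "APP_PS1")
TREATMENTS = ("vehicle", "AR")
CONDITIONS = ("from_rest", "held_minus60")

#: response units implied by each clamp mode
_RESPONSE_UNITS = {CURRENT_CLAMP: "mV", VOLTAGE_CLAMP: "pA"}
_COMMAND_UNITS = {CURRENT_CLAMP: "pA", VOLTAGE_CLAMP: "mV"}

#: reserved protocol key for -5 mV membrane-test sweeps
MEMBRANE_TEST = "membrane_test"


class ClampKitError(Exception):
    """Base class for all package errors."""


class FormatError(ClampKitError):
    """Container layout or sidecar is malformed."""


class IntegrityError(ClampKitError):
    """Container contents contradict the declared protocol."""


class UnitError(ClampKitError):
    """Declared units are unknown or inconsistent with the clamp mode."""


def _as_float_array(x: Sequence[float]) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("samples must be one-dimensional")
    return arr


@dataclass(eq=False)
class Sweep:
    """One response trace plus the command step it answers.

    ``samples`` holds membrane potential (mV) in current clamp and membrane
    current (pA) in voltage clamp.  ``command_level`` is the step amplitude
    relative to ``holding_level``; the step occupies the half-open window
    ``[step_onset, step_offset)`` in seconds from the start of the sweep.
    """

    samples: np.ndarray
    sampling_rate: float
    command_level: float
    step_onset: float
    step_offset: float
    holding_level: float
    mode: str
    repetition_index: int = 0
    response_units: str = ""

    def __post_init__(self) -> None:
        self.samples = _as_float_array(self.samples)
        if self.samples.size == 0:
            raise ValueError("sweep has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("sweep contains non-finite samples")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")
        if self.mode not in _MODES:
            raise UnitError(f"unknown clamp mode {self.mode!r}")
        expected = _RESPONSE_UNITS[self.mode]
        if self.response_units == "":
            self.response_units = expected
        elif self.response_units != expected:
            raise UnitError(
                f"{self.mode} sweeps carry {expected}, not {self.response_units!r}"
            )
        if not (self.step_onset < self.step_offset <= self.duration + 1e-12):
            raise ValueError(
                "require step_onset < step_offset <= sweep duration "
                f"(got {self.step_onset}, {self.step_offset}, {self.duration})"
            )

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds; time zero is the start of the sweep."""
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def command_units(self) -> str:
        return _COMMAND_UNITS[self.mode]

    def command_trace(self) -> np.ndarray:
        """Command value at every sample (holding outside the step window)."""
        t = self.times
        cmd = np.full(self.samples.size, self.holding_level, dtype=np.float64)
        inside = (t >= self.step_onset) & (t < self.step_offset)
        cmd[inside] += self.command_level
        return cmd

    def step_slice(self) -> slice:
        """Sample indices of the half-open step window."""
        i0 = int(math.ceil(self.step_onset * self.sampling_rate - 1e-9))
        i1 = int(math.ceil(self.step_offset * self.sampling_rate - 1e-9))
        return slice(i0, i1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sweep):
            return NotImplemented
        return (
            np.array_equal(self.samples, other.samples)
            and self.sampling_rate == other.sampling_rate
            and self.command_level == other.command_level
            and self.step_onset == other.step_onset
            and self.step_offset == other.step_offset
            and self.holding_level == other.holding_level
            and self.mode == other.mode
            and self.repetition_index == other.repetition_index
        )


@dataclass(frozen=True)
class StepProtocol:
    """A grid of command steps: shared timing, ordered unique amplitudes."""

    mode: str
    holding_level: float
    pre_duration: float
    step_duration: float
    post_duration: float
    amplitudes: tuple
    repetitions: int = 1

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise UnitError(f"unknown clamp mode {self.mode!r}")
        amps = tuple(float(a) for a in self.amplitudes)
        object.__setattr__(self, "amplitudes", amps)
        if len(amps) == 0:
            raise ValueError("protocol needs at least one amplitude")
        if any(b <= a for a, b in zip(amps, amps[1:])):
            raise ValueError("amplitudes must be strictly increasing and unique")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        for name in ("pre_duration", "step_duration", "post_duration"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")

    @property
    def step_onset(self) -> float:
        return self.pre_duration

    @property
    def step_offset(self) -> float:
        return self.pre_duration + self.step_duration

    @property
    def total_duration(self) -> float:
        return self.pre_duration + self.step_duration + self.post_duration

    @property
    def n_sweeps(self) -> int:
        return len(self.amplitudes) * self.repetitions

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "holding_level": self.holding_level,
            "pre_duration": self.pre_duration,
            "step_duration": self.step_duration,
            "post_duration": self.post_duration,
            "amplitudes": list(self.amplitudes),
            "repetitions": self.repetitions,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StepProtocol":
        try:
            return cls(
                mode=d["mode"],
                holding_level=float(d["holding_level"]),
                pre_duration=float(d["pre_duration"]),
                step_duration=float(d["step_duration"]),
                post_duration=float(d["post_duration"]),
                amplitudes=tuple(d["amplitudes"]),
                repetitions=int(d["repetitions"]),
            )
        except KeyError as exc:
            raise FormatError(f"protocol description missing field {exc}") from exc


@dataclass(eq=False)
class CellRecording:
    """All sweeps and metadata for one neuron under one recording condition.

    ``sweeps`` maps a protocol name to the sweeps acquired under it;
    ``protocols`` maps the same names to their :class:`StepProtocol`.  The
    reserved name ``membrane_test`` holds the -5 mV test-pulse sweeps used
    for passive-property estimation.
    """

    cell_id: str
    genotype: str
    treatment: str
    condition: str
    resting_potential: float
    sweeps: dict = field(default_factory=dict)
    protocols: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.treatment not in TREATMENTS:
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        rates = {s.sampling_rate for group in self.sweeps.values() for s in group}
        if len(rates) > 1:
            raise IntegrityError(f"sweeps mix sampling rates: {sorted(rates)}")

    @property
    def sampling_rate(self) -> Optional[float]:
        for group in self.sweeps.values():
            for s in group:
                return s.sampling_rate
        return None

    @property
    def test_pulse_sweeps(self) -> list:
        return list(self.sweeps.get(MEMBRANE_TEST, []))

    @property
    def group(self) -> str:
        """Genotype x treatment label used in group statistics."""
        return self.genotype if self.treatment == "vehicle" else f"{self.genotype}+AR"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellRecording):
            return NotImplemented
        return (
            self.cell_id == other.cell_id
            and self.genotype == other.genotype
            and self.treatment == other.treatment
            and self.condition == other.condition
            and self.resting_potential == other.resting_potential
            and self.protocols == other.protocols
            and set(self.sweeps) == set(other.sweeps)
            and all(self.sweeps[k] == other.sweeps[k] for k in self.sweeps)
        )


@dataclass(frozen=True)
class PassiveProperties:
    """Passive membrane parameters from the -5 mV membrane test."""

    input_resistance: float  # MOhm
    series_resistance: float  # MOhm
    capacitance: float  # pF
    resting_potential: float  # mV
    fit_rss: float  # squared pA, residual sum of the transient fit
    capacitance_reliable: bool = True

    def __post_init__(self) -> None:
        if not (self.input_resistance > 0 and self.series_resistance > 0):
            raise ValueError("resistances must be positive")
        if not (self.capacitance > 0):
            raise ValueError("capacitance must be positive")


@dataclass(frozen=True)
class SpikeEvent:
    """One detected action potential.

    Detection fills the up-cross/peak fields; the rheobase feature pass
    fills threshold, latency, amplitude and width.  ``width`` and
    ``end_time`` are ``None`` when the spike never re-crosses below its
    threshold before the sweep ends.
    """

    upcross_time: float  # s, crossing of the up-slope criterion
    peak_time: float  # s
    peak_voltage: float  # mV
    threshold_time: Optional[float] = None  # s
    threshold_voltage: Optional[float] = None  # mV
    end_time: Optional[float] = None  # s
    latency: Optional[float] = None  # ms from step onset to threshold
    amplitude: Optional[float] = None  # mV, threshold to peak
    width: Optional[float] = None  # ms, full width at half amplitude
    classification: str = "unclassified"

    def __post_init__(self) -> None:
        if self.threshold_time is not None and self.threshold_time > self.peak_time:
            raise ValueError("threshold_time must not follow peak_time")
        if self.amplitude is not None and self.amplitude < 0:
            raise ValueError("amplitude is peak minus threshold, must be >= 0")
        if (self.width is None) != (self.end_time is None):
            raise ValueError("width and end_time are defined together")

    @property
    def width_defined(self) -> bool:
        return self.width is not None


@dataclass(eq=False)
class FICurve:
    """Spike counts and firing proportions per current-step amplitude.

    Counts are means of *evoked* spike counts across repetitions;
    ``p_one_or_more`` / ``p_exactly_one`` are per-repetition indicator
    proportions.
    """

    amplitudes: np.ndarray  # pA
    spike_count: np.ndarray  # mean evoked spikes per step
    p_one_or_more: np.ndarray
    p_exactly_one: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = _as_float_array(self.amplitudes)
        self.spike_count = _as_float_array(self.spike_count)
        self.p_one_or_more = _as_float_array(self.p_one_or_more)
        self.p_exactly_one = _as_float_array(self.p_exactly_one)
        n = self.amplitudes.size
        if not (self.spike_count.size == self.p_one_or_more.size == self.p_exactly_one.size == n):
            raise ValueError("FICurve arrays must share length")
        if np.any(self.spike_count < 0):
            raise ValueError("spike counts must be non-negative")
        for p in (self.p_one_or_more, self.p_exactly_one):
            if np.any((p < 0) | (p > 1)):
                raise ValueError("proportions must lie in [0, 1]")


@dataclass(frozen=True)
class RheobaseFeatures:
    """Rheobase current and the first spike fired at it."""

    rheobase_current: float  # pA, member of the protocol's depolarizing grid
    first_spike: SpikeEvent


@dataclass(eq=False)
class VClampFeatures:
    """Per-injection leak-subtracted voltage-clamp features for one cell."""

    injections: np.ndarray  # mV relative to holding, ascending
    early_max_inward: np.ndarray  # pA, <= 0 by convention
    early_max_outward: np.ndarray  # pA, >= 0
    late_mean: np.ndarray  # pA, signed (negative = net inward)
    leak_subtracted: bool = True
    zeroed: bool = True

    def __post_init__(self) -> None:
        self.injections = _as_float_array(self.injections)
        self.early_max_inward = _as_float_array(self.early_max_inward)
        self.early_max_outward = _as_float_array(self.early_max_outward)
        self.late_mean = _as_float_array(self.late_mean)
        n = self.injections.size
        if not (
            self.early_max_inward.size
            == self.early_max_outward.size
            == self.late_mean.size
            == n
        ):
            raise ValueError("VClampFeatures arrays must share length")
        if np.any(np.diff(self.injections) <= 0):
            raise ValueError("injections must be strictly increasing")
        if np.any(self.early_max_inward > 1e-9) or np.any(self.early_max_outward < -1e-9):
            raise ValueError("sign convention: inward <= 0 <= outward")


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

_META_FIELDS = (
    "cell_id",
    "genotype",
    "treatment",
    "condition",
    "resting_potential",
    "sampling_rate",
    "protocols",
)


def write_recording(recording: CellRecording, path, fmt: str = "csv") -> Path:
    """Write one cell to its own container directory under ``path``.

    Two sample layouts share the same ``meta.json`` sidecar:

    * ``fmt="csv"`` — one long table per protocol (columns ``sweep``,
      ``time_s``, ``command``, ``response``, ``repetition``), the
      interchange format; values written with 17 significant digits.
    * ``fmt="npy"`` — one explicit little-endian float64 array per protocol
      (sweeps x samples) plus a small CSV index of per-sweep command levels
      and repetitions; the bulk layout used for large cohorts.

    Returns the container directory (``path / cell_id``).
    """
    if fmt not in ("csv", "npy"):
        raise ValueError(f"unknown container format {fmt!r}")
    root = Path(path)
    container = root / recording.cell_id
    container.mkdir(parents=True, exist_ok=True)

    sr = recording.sampling_rate
    meta = {
        "cell_id": recording.cell_id,
        "genotype": recording.genotype,
        "treatment": recording.treatment,
        "condition": recording.condition,
        "resting_potential": recording.resting_potential,
        "sampling_rate": sr,
        "protocols": {name: p.to_dict() for name, p in recording.protocols.items()},
    }
    (container / "meta.json").write_text(json.dumps(meta, indent=1))

    for name, group in recording.sweeps.items():
        if fmt == "npy":
            stack = np.stack([sw.samples for sw in group]).astype("<f8")
            np.save(container / f"sweeps_{name}.npy", stack)
            index = pd.DataFrame(
                {
                    "sweep": range(len(group)),
                    "command": [sw.command_level for sw in group],
                    "repetition": [sw.repetition_index for sw in group],
                }
            )
            index.to_csv(
                container / f"index_{name}.csv", index=False, float_format="%.17g"
            )
            continue
        frames = []
        for i, sw in enumerate(group):
            frames.append(
                pd.DataFrame(
                    {
                        "sweep": i,
                        "time_s": sw.times,
                        "command": sw.command_trace(),
                        "response": sw.samples,
                        "repetition": sw.repetition_index,
                    }
                )
            )
        table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["sweep", "time_s", "command", "response", "repetition"]
        )
        table.to_csv(container / f"sweeps_{name}.csv", index=False, float_format="%.17g")
    return container


def read_recording(path) -> CellRecording:
    """Read one cell container written by :func:`write_recording`."""
    container = Path(path)
    meta_path = container / "meta.json"
    if not meta_path.exists():
        raise FormatError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    for fieldname in _META_FIELDS:
        if fieldname not in meta or meta[fieldname] is None:
            raise FormatError(f"metadata sidecar missing {fieldname!r}")
    sr = float(meta["sampling_rate"])

    protocols = {
        name: StepProtocol.from_dict(d) for name, d in meta["protocols"].items()
    }

    sweeps: dict = {}
    for name, proto in protocols.items():
        expected_len = int(round(proto.total_duration * sr))

        def _make_sweep(resp, level, rep, source):
            if resp.size != expected_len:
                raise IntegrityError(
                    f"sweep length {resp.size} does not match protocol "
                    f"({expected_len} samples) in {source}"
                )
            return Sweep(
                samples=resp,
                sampling_rate=sr,
                command_level=level,
                step_onset=proto.step_onset,
                step_offset=proto.step_offset,
                holding_level=proto.holding_level,
                mode=proto.mode,
                repetition_index=rep,
            )

        npy_path = container / f"sweeps_{name}.npy"
        csv_path = container / f"sweeps_{name}.csv"
        group = []
        if npy_path.exists():
            stack = np.load(npy_path).astype(np.float64)
            index = pd.read_csv(
                container / f"index_{name}.csv", float_precision="round_trip"
            )
            if stack.shape[0] != len(index):
                raise IntegrityError(
                    f"{npy_path.name} holds {stack.shape[0]} sweeps but the "
                    f"index lists {len(index)}"
                )
            for row, resp in zip(index.itertuples(), stack):
                group.append(
                    _make_sweep(resp, float(row.command), int(row.repetition), npy_path.name)
                )
        elif csv_path.exists():
            table = pd.read_csv(csv_path, float_precision="round_trip")
            onset_idx = int(round(proto.step_onset * sr))
            for _, block in table.groupby("sweep", sort=True):
                resp = block["response"].to_numpy(dtype=np.float64)
                cmd = block["command"].to_numpy(dtype=np.float64)
                level = cmd[onset_idx] - proto.holding_level if resp.size > onset_idx else 0.0
                group.append(
                    _make_sweep(resp, level, int(block["repetition"].iloc[0]), csv_path.name)
                )
        else:
            raise FormatError(f"missing sweep table for protocol {name!r} in {container}")
        sweeps[name] = group

    return CellRecording(
        cell_id=meta["cell_id"],
        genotype=meta["genotype"],
        treatment=meta["treatment"],
        condition=meta["condition"],
        resting_potential=float(meta["resting_potential"]),
        sweeps=sweeps,
        protocols=protocols,
    )
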