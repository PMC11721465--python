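"""Sensorgram data model and pre-processing.

A :class:`Sensorgram` is one sensor's time/response trace segmented into
ordered assay steps (``baseline``, ``assoc1``, ``dissoc``, ``assoc2``).  A
:class:`Plate` bundles the sensorgrams of one experiment together with the
reference channels needed for double-reference subtraction.

Units are seconds for time, nanometres for response and molar for analyte
concentration throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InterpolationRangeError,
    ReferenceMissingError,
    StepLookupError,
)

STEP_ORDER = {"baseline": 0, "assoc1": 1, "dissoc": 2, "assoc2": 3}

ROLE_SAMPLE = "sample"
ROLE_REFERENCE_BUFFER = "reference_buffer"
ROLE_REFERENCE_PIN = "reference_pin"
ROLES = (ROLE_SAMPLE, ROLE_REFERENCE_BUFFER, ROLE_REFERENCE_PIN)

PLATE_COLUMNS = [
    "sensor_id",
    "step",
    "time_s",
    "response_nm",
    "analyte",
    "concentration_M",
    "role",
]


@dataclass
class Step:
    """One assay step: a strictly increasing time grid and its responses."""

    label: str
    time: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape or self.time.ndim != 1:
            raise FormatError(f"step {self.label!r}: time/response shape mismatch")
        if self.time.size and not np.all(np.diff(self.time) > 0):
            raise FormatError(f"step {self.label!r}: time not strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise FormatError(f"step {self.label!r}: non-finite response")

    def copy(self) -> "Step":
        return Step(self.label, self.time.copy(), self.response.copy())


@dataclass
class Sensorgram:
    sensor_id: str
    steps: list[Step]
    analyte: str = ""
    concentration: float = 0.0  # molar
    role: str = ROLE_SAMPLE

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(f"sensor {self.sensor_id!r}: unknown role {self.role!r}")
        order = [STEP_ORDER.get(s.label, len(STEP_ORDER)) for s in self.steps]
        if order != sorted(order):
            raise FormatError(f"sensor {self.sensor_id!r}: steps out of order")
        if len({s.label for s in self.steps}) != len(self.steps):
            raise FormatError(f"sensor {self.sensor_id!r}: duplicate step label")

    def step(self, label: str) -> Step:
        for s in self.steps:
            if s.label == label:
                return s
        raise StepLookupError(f"sensor {self.sensor_id!r} has no step {label!r}")

    def has_step(self, label: str) -> bool:
        return any(s.label == label for s in self.steps)

    def copy(self) -> "Sensorgram":
        return replace(self, steps=[s.copy() for s in self.steps])


@dataclass
class Plate:
    sensorgrams: list[Sensorgram]
    metadata: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[Sensorgram]:
        return [s for s in self.sensorgrams if s.role == ROLE_SAMPLE]

    @property
    def references(self) -> list[Sensorgram]:
        return [s for s in self.sensorgrams if s.role != ROLE_SAMPLE]

    def sensor(self, sensor_id: str) -> Sensorgram:
        for s in self.sensorgrams:
            if s.sensor_id == sensor_id:
                return s
        raise StepLookupError(f"no sensor {sensor_id!r} on plate")


# ---------------------------------------------------------------------------
# Plate CSV I/O
# ---------------------------------------------------------------------------

def write_plate(plate: Plate, path) -> None:
    """Write a plate to CSV using the canonical long-format schema."""
    rows = []
    for sg in plate.sensorgrams:
        for st in sg.steps:
            rows.append(
                pd.DataFrame(
                    {
                        "sensor_id": sg.sensor_id,
                        "step": st.label,
                        "time_s": st.time,
                        "response_nm": st.response,
                        "analyte": sg.analyte,
                        "concentration_M": sg.concentration,
                        "role": sg.role,
                    }
                )
            )
    frame = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=PLATE_COLUMNS)
    frame.to_csv(path, index=False, float_format="%.17g")


def read_plate(path) -> Plate:
    """Read a plate CSV, canonically sorting rows by (sensor, step, time).

    Tolerates Windows line endings and a UTF-8 BOM.  Raises
    :class:`FormatError` naming the offending sensor/step on schema or
    monotonicity violations.
    """
    frame = pd.read_csv(path, encoding="utf-8-sig", float_precision="round_trip")
    missing = [c for c in PLATE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"plate file missing required column(s): {', '.join(missing)}")

    sensorgrams = []
    for sensor_id, group in frame.groupby("sensor_id", sort=True):
        steps = []
        labels = sorted(group["step"].unique(), key=lambda s: STEP_ORDER.get(s, len(STEP_ORDER)))
        for label in labels:
            sub = group[group["step"] == label].sort_values("time_s")
            t = sub["time_s"].to_numpy(dtype=float)
            if np.any(np.diff(t) <= 0):
                raise FormatError(
                    f"sensor {sensor_id!r}, step {label!r}: repeated or non-increasing time"
                )
            steps.append(Step(label, t, sub["response_nm"].to_numpy(dtype=float)))
        first = group.iloc[0]
        sensorgrams.append(
            Sensorgram(
                sensor_id=str(sensor_id),
                steps=steps,
                analyte=str(first["analyte"]),
                concentration=float(first["concentration_M"]),
                role=str(first["role"]),
            )
        )
    return Plate(sensorgrams)


# ---------------------------------------------------------------------------
# Pre-processing
# ---------------------------------------------------------------------------

def _interp_reference(ref: Sensorgram, label: str, t: np.ndarray) -> np.ndarray:
    st = ref.step(label)
    tol = 1e-9 * max(1.0, abs(st.time[-1]))
    if t[0] < st.time[0] - tol or t[-1] > st.time[-1] + tol:
        raise InterpolationRangeError(
            f"reference {ref.sensor_id!r}, step {label!r}: grid "
            f"[{st.time[0]}, {st.time[-1]}] does not cover sample grid [{t[0]}, {t[-1]}]"
        )
    return np.interp(t, st.time, st.response)


def _pick_pin_reference(pins: list[Sensorgram], sample: Sensorgram) -> Sensorgram:
    for ref in pins:
        if np.isclose(ref.concentration, sample.concentration, rtol=1e-9, atol=0.0):
            return ref
    if len(pins) == 1:
        return pins[0]
    raise ReferenceMissingError(
        f"no reference_pin trace matches concentration of sample {sample.sensor_id!r}"
    )


def double_reference(plate: Plate) -> Plate:
    """Double-reference subtraction: corrected = sample − buffer ref − pin ref.

    The buffer reference is the loaded-sensor-into-buffer trace; the pin
    reference is the unloaded-pin-into-analyte trace (matched on analyte
    concentration when several are present).  Both references are linearly
    interpolated onto the sample time grid, step by step.  Step boundaries
    and sample counts are preserved.
    """
    buffers = [s for s in plate.sensorgrams if s.role == ROLE_REFERENCE_BUFFER]
    pins = [s for s in plate.sensorgrams if s.role == ROLE_REFERENCE_PIN]
    if not buffers:
        raise ReferenceMissingError("plate has no reference_buffer trace")
    if not pins:
        raise ReferenceMissingError("plate has no reference_pin trace")
    buf = buffers[0]

    corrected = []
    for sg in plate.samples:
        pin = _pick_pin_reference(pins, sg)
        steps = []
        for st in sg.steps:
            if not buf.has_step(st.label):
                raise ReferenceMissingError(
                    f"reference_buffer lacks step {st.label!r} needed by {sg.sensor_id!r}"
                )
            if not pin.has_step(st.label):
                raise ReferenceMissingError(
                    f"reference_pin lacks step {st.label!r} needed by {sg.sensor_id!r}"
                )
            resp = (
                st.response
                - _interp_reference(buf, st.label, st.time)
                - _interp_reference(pin, st.label, st.time)
            )
            steps.append(Step(st.label, st.time.copy(), resp))
        corrected.append(replace(sg, steps=steps))

    meta = dict(plate.metadata)
    meta["double_referenced"] = True
    return Plate(corrected, meta)


def align_to_step_start(sensorgram: Sensorgram, step_label: str) -> Sensorgram:
    """Re-zero one step's time and response at its first sample.

    Idempotent; other steps are untouched.
    """
    target = sensorgram.step(step_label)  # raises StepLookupError if absent
    steps = []
    for st in sensorgram.steps:
        if st.label == step_label and st.time.size:
            steps.append(Step(st.label, st.time - st.time[0], st.response - st.response[0]))
        else:
            steps.append(st.copy())
    del target
    return replace(sensorgram, steps=steps)
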