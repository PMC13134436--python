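"""Plain-text study files and run configuration.

A study file is tab-delimited text, one row per frame, with a mandatory
header and optional ``#`` comment lines::

    frame_start_s  frame_duration_s  clv_kbq_ml  crv_kbq_ml  seg01 ... seg17

Frame contiguity and the 17-segment schema are enforced on load, so any
file accepted here is a valid fitting input.  Configuration is a flat
key–value YAML document whose keys mirror the model constants.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import N_SEGMENTS, PerfusionResult, StudyTacSet
from .geometry import SchemeKind, TerritoryScheme
from .kinetics import FrameSchedule, ModelKind, ModelSpec, TimeActivityCurve

__all__ = [
    "StudyParseError",
    "RunConfig",
    "SEGMENT_COLUMNS",
    "read_study",
    "write_study",
    "write_perfusion_result",
    "load_config",
]

SEGMENT_COLUMNS = tuple(f"seg{i:02d}" for i in range(1, N_SEGMENTS + 1))
REQUIRED_COLUMNS = (
    "frame_start_s",
    "frame_duration_s",
    "clv_kbq_ml",
    "crv_kbq_ml",
    *SEGMENT_COLUMNS,
)


class StudyParseError(ValueError):
    """A study file violated the format contract."""


def read_study(path, condition: str | None = None) -> StudyTacSet:
    """Load and validate a study file.

    The stress/rest condition is taken from a ``# condition: ...`` comment
    line if present; an explicit ``condition`` argument overrides it.
    """
    path = Path(path)
    file_condition = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "condition:" in line:
                file_condition = line.split("condition:")[1].strip()
                break
            if not line.startswith("#"):
                break
    condition = condition or file_condition or "stress"

    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise StudyParseError(f"{path.name}: missing columns {missing}")
    extra = [c for c in df.columns if c not in REQUIRED_COLUMNS]
    if extra:
        raise StudyParseError(f"{path.name}: unexpected columns {extra}")
    nan_rows = df.index[df.isna().any(axis=1)].tolist()
    if nan_rows:
        raise StudyParseError(f"{path.name}: NaN cells in data rows {nan_rows}")

    starts = df["frame_start_s"].to_numpy(float)
    durations = df["frame_duration_s"].to_numpy(float)
    expected = starts[:-1] + durations[:-1]
    gaps = np.nonzero(~np.isclose(starts[1:], expected, rtol=0, atol=1e-6))[0]
    if gaps.size:
        row = int(gaps[0]) + 1
        raise StudyParseError(
            f"{path.name}: frames not contiguous at data row {row} "
            f"(starts at {starts[row]} s, previous frame ends at {expected[row - 1]} s)"
        )
    try:
        schedule = FrameSchedule(starts=starts, durations=durations)
    except ValueError as err:
        raise StudyParseError(f"{path.name}: {err}") from err

    def tac(col: str) -> TimeActivityCurve:
        return TimeActivityCurve(
            schedule=schedule, values=df[col].to_numpy(float), region_label=col
        )

    return StudyTacSet(
        condition=condition,
        schedule=schedule,
        clv=tac("clv_kbq_ml"),
        crv=tac("crv_kbq_ml"),
        segments=tuple(tac(c) for c in SEGMENT_COLUMNS),
    )


def write_study(study: StudyTacSet, path) -> None:
    """Write a study file; round-trips value-identically through read_study."""
    path = Path(path)
    data = {
        "frame_start_s": study.schedule.starts,
        "frame_duration_s": study.schedule.durations,
        "clv_kbq_ml": study.clv.values,
        "crv_kbq_ml": study.crv.values,
    }
    for col, seg in zip(SEGMENT_COLUMNS, study.segments):
        data[col] = seg.values
    df = pd.DataFrame(data)
    with open(path, "w") as fh:
        fh.write(f"# condition: {study.condition}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def write_perfusion_result(result: PerfusionResult, path) -> None:
    """Write segmental + territorial + global MBF/MFR as delimited text."""
    path = Path(path)
    df = pd.DataFrame(result.to_rows())
    with open(path, "w") as fh:
        fh.write(f"# model: {result.model_kind.value}\n")
        fh.write(f"# territory_scheme: {result.scheme.kind.value}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration; every model constant is overridable."""

    model: str = "1tcm"
    window_start: float | None = None  # minutes; None -> model default
    window_end: float | None = None
    t0: float = 0.48          # delayed-exp correction onset, min
    half_life: float = 6.69   # delayed-exp effective half-life, min
    v_nd: float = 0.8         # UCLA distribution volume, mL/g
    m_corr: float = 0.0       # linear metabolite slope, 1/min (0 = disabled)
    carryover: bool = False
    territory: str = "aha"    # "aha" or "geometric"
    weights: str = "duration"
    seed: int = 0

    def model_spec(self) -> ModelSpec:
        window = None
        if self.window_start is not None and self.window_end is not None:
            window = (self.window_start, self.window_end)
        return ModelSpec.for_model(
            ModelKind(self.model),
            window=window,
            t0=self.t0,
            half_life=self.half_life,
            v_nd=self.v_nd,
            m_corr=self.m_corr,
        )

    def territory_scheme(self) -> TerritoryScheme:
        return TerritoryScheme(kind=SchemeKind(self.territory))

    def validate(self) -> None:
        self.model_spec()
        self.territory_scheme()
        if self.weights not in ("duration", "uniform"):
            raise ValueError("weights must be 'duration' or 'uniform'")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config must be a flat key-value document")
    unknown = set(raw) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**raw)
    cfg.validate()
    return cfg
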