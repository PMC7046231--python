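"""Performance metrics computed from a raw recording.

The validated neurosurgical model uses four metrics, two per category:

=====================  ========  =======  =============================================
Name                   Category  Units    Definition
=====================  ========  =======  =============================================
Max Force w/ Bipolar   safety    N        max of the bipolar force trace
Rate of Bleeding       safety    mL/s     net blood volume over net trial time
Instrument Tip Distance movement mm       mean Euclidean distance between the two tips
Acceleration w/ Bipolar movement mm/s^2   mean second-finite-difference acceleration
                                           magnitude of the bipolar tip
=====================  ========  =======  =============================================

The registry is extensible: a metric is any named, unit-bearing function of a
:class:`~voa.recording.RawRecording`, and the full candidate space explored in
practice (hundreds of kinematic summaries) is represented by registering more
definitions, not by a fixed enumeration here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from functools import partial
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    InputError,
    MetricComputationError,
    NonUniformSamplingWarning,
    SchemaError,
)
from .recording import RawRecording

__all__ = [
    "max_force",
    "bleeding_rate",
    "mean_tip_distance",
    "mean_acceleration",
    "MetricDefinition",
    "MetricValue",
    "MetricVector",
    "default_registry",
    "compute_metric_vector",
    "cohort_metric_table",
    "extract_from_manifest",
    "write_metric_table",
    "read_metric_table",
    "metric_columns",
    "SAFETY",
    "MOVEMENT",
]

SAFETY = "safety"
MOVEMENT = "movement"

_INSTRUMENTS = ("ua", "bp")

#: Non-metric columns of a cohort metric table.
ID_COLUMNS = ("trial_id", "group")


def _force_trace(rec: RawRecording, instrument: str) -> np.ndarray:
    if instrument not in _INSTRUMENTS:
        raise InputError(f"instrument must be one of {_INSTRUMENTS}, got {instrument!r}")
    return rec.ua_force if instrument == "ua" else rec.bp_force


def _positions(rec: RawRecording, instrument: str) -> np.ndarray:
    if instrument not in _INSTRUMENTS:
        raise InputError(f"instrument must be one of {_INSTRUMENTS}, got {instrument!r}")
    return rec.ua_pos if instrument == "ua" else rec.bp_pos


def max_force(rec: RawRecording, instrument: str = "bp") -> float:
    """Maximum instantaneous force (N) applied with the chosen instrument."""
    trace = _force_trace(rec, instrument)
    if trace.size == 0:
        raise InputError("empty force trace")
    return float(np.max(trace))


def bleeding_rate(rec: RawRecording) -> float:
    """Net bleeding rate (mL/s): blood volume gained over elapsed trial time."""
    elapsed = rec.t[-1] - rec.t[0]
    if elapsed <= 0:
        raise InputError("recording has zero duration")
    return float((rec.blood_ml[-1] - rec.blood_ml[0]) / elapsed)


def mean_tip_distance(rec: RawRecording) -> float:
    """Mean Euclidean distance (mm) between the two instrument tips."""
    if rec.ua_pos.shape != rec.bp_pos.shape:
        raise InputError("tip position channels have mismatched shapes")
    return float(np.mean(np.linalg.norm(rec.ua_pos - rec.bp_pos, axis=1)))


def mean_acceleration(rec: RawRecording, instrument: str = "bp") -> float:
    """Mean acceleration magnitude (mm/s^2) of the chosen instrument tip.

    Uses the second divided difference over each interior sample (endpoints
    dropped), which is exact on quadratic trajectories and handles mildly
    non-uniform sampling; warns if sampling intervals vary by more than 10%.
    """
    pos = _positions(rec, instrument)
    if rec.n_samples < 3:
        raise InputError("mean_acceleration needs at least 3 samples")
    dt = np.diff(rec.t)
    if dt.max() > 1.1 * dt.min():
        warnings.warn(
            "sampling intervals vary by more than 10%; finite-difference "
            "acceleration may be noisy",
            NonUniformSamplingWarning,
            stacklevel=2,
        )
    dt_prev = dt[:-1, None]  # t[i] - t[i-1]
    dt_next = dt[1:, None]   # t[i+1] - t[i]
    accel = 2.0 * (
        dt_prev * pos[2:] - (dt_prev + dt_next) * pos[1:-1] + dt_next * pos[:-2]
    ) / (dt_prev * dt_next * (dt_prev + dt_next))
    return float(np.mean(np.linalg.norm(accel, axis=1)))


# -- registry ----------------------------------------------------------------

@dataclass(frozen=True)
class MetricDefinition:
    """A named, unit-bearing metric function of a recording."""

    name: str
    units: str
    category: str
    fn: Callable[[RawRecording], float]


@dataclass(frozen=True)
class MetricValue:
    value: float
    units: str
    category: str


class MetricVector(Mapping[str, MetricValue]):
    """Ordered mapping metric name -> (value, units, category).

    Order is the registry order it was computed with; names are unique and
    values finite.
    """

    def __init__(self, items: Sequence[tuple[str, MetricValue]]):
        names = [name for name, _ in items]
        if len(set(names)) != len(names):
            raise InputError("metric names must be unique")
        for name, mv in items:
            if not np.isfinite(mv.value):
                raise InputError(f"metric {name!r} has a non-finite value")
        self._data: dict[str, MetricValue] = dict(items)

    def __getitem__(self, name: str) -> MetricValue:
        return self._data[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    def __repr__(self) -> str:
        inner = ", ".join(f"{n}={mv.value:.4g} {mv.units}" for n, mv in self._data.items())
        return f"MetricVector({inner})"

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._data)

    @property
    def values_array(self) -> np.ndarray:
        return np.array([mv.value for mv in self._data.values()], dtype=float)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(mv.category for mv in self._data.values())

    @property
    def units(self) -> tuple[str, ...]:
        return tuple(mv.units for mv in self._data.values())

    def subset(self, names: Sequence[str]) -> "MetricVector":
        missing = [n for n in names if n not in self._data]
        if missing:
            raise SchemaError(f"metric vector is missing metrics: {missing}")
        return MetricVector([(n, self._data[n]) for n in names])


def default_registry() -> tuple[MetricDefinition, ...]:
    """The four validated metrics, in their published order."""
    return (
        MetricDefinition(
            "Max Force w/ Bipolar", "N", SAFETY, partial(max_force, instrument="bp")
        ),
        MetricDefinition("Rate of Bleeding", "mL/s", SAFETY, bleeding_rate),
        MetricDefinition("Instrument Tip Distance", "mm", MOVEMENT, mean_tip_distance),
        MetricDefinition(
            "Acceleration w/ Bipolar", "mm/s^2", MOVEMENT,
            partial(mean_acceleration, instrument="bp"),
        ),
    )


def compute_metric_vector(
    rec: RawRecording, registry: Sequence[MetricDefinition] | None = None
) -> MetricVector:
    """Evaluate every registered metric on ``rec``, in registry order."""
    if registry is None:
        registry = default_registry()
    if len(registry) == 0:
        raise InputError("metric registry is empty")
    names = [d.name for d in registry]
    if len(set(names)) != len(names):
        raise InputError("metric registry contains duplicate names")
    items = []
    for d in registry:
        try:
            value = float(d.fn(rec))
        except Exception as exc:  # noqa: BLE001 - re-raised with the metric named
            raise MetricComputationError(f"metric {d.name!r} failed: {exc}") from exc
        items.append((d.name, MetricValue(value, d.units, d.category)))
    return MetricVector(items)


# -- cohort tables -----------------------------------------------------------

def cohort_metric_table(
    cohort: Sequence[tuple[RawRecording, str]],
    registry: Sequence[MetricDefinition] | None = None,
    trial_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Metric table for a labelled cohort: ``trial_id, group, <metrics...>``."""
    if registry is None:
        registry = default_registry()
    if trial_ids is None:
        trial_ids = [f"trial_{i:03d}" for i in range(len(cohort))]
    rows = []
    for trial_id, (rec, label) in zip(trial_ids, cohort):
        vec = compute_metric_vector(rec, registry)
        row: dict[str, object] = {"trial_id": trial_id, "group": label}
        row.update({n: mv.value for n, mv in vec.items()})
        rows.append(row)
    columns = list(ID_COLUMNS) + [d.name for d in registry]
    return pd.DataFrame(rows, columns=columns)


def extract_from_manifest(
    manifest_path: str | Path, registry: Sequence[MetricDefinition] | None = None
) -> pd.DataFrame:
    """Read every trial listed in a cohort manifest and tabulate its metrics."""
    from .simdata import read_manifest  # local import to avoid a cycle

    entries = read_manifest(manifest_path)
    cohort = [(RawRecording.from_csv(fp), group) for _, fp, group in entries]
    return cohort_metric_table(
        cohort, registry, trial_ids=[tid for tid, _, _ in entries]
    )


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def write_metric_table(
    table: pd.DataFrame,
    path: str | Path,
    registry: Sequence[MetricDefinition] | None = None,
) -> Path:
    """Write the metric CSV plus a sidecar JSON of units and categories."""
    if registry is None:
        registry = default_registry()
    path = Path(path)
    table.to_csv(path, index=False)
    meta = {
        "schema_version": "voa-metrics/1",
        "metrics": {
            d.name: {"units": d.units, "category": d.category} for d in registry
        },
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return sidecar


def read_metric_table(path: str | Path) -> tuple[pd.DataFrame, dict | None]:
    """Read a metric CSV and, if present, its sidecar metadata."""
    path = Path(path)
    table = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"metric table is missing columns: {missing}")
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    return table, meta


def metric_columns(table: pd.DataFrame) -> list[str]:
    """Metric column names of a cohort table (everything but the id columns)."""
    return [c for c in table.columns if c not in ID_COLUMNS]
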