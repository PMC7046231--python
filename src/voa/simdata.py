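"""Synthetic simulator recordings with controllable skill-group separation.

No public dataset of raw bimanual simulator trials exists for the subpial
tumour-resection task, so this module generates them.  It emulates the four
behaviours that separate skilled from novice operators — instrument force,
bleeding induced, inter-tip distance, and movement smoothness — with simple,
analytically tractable models:

* **Base path**: each trial drifts at constant velocity from a random start
  point, so the base trajectory contributes exactly zero acceleration and the
  tremor parameter alone controls the acceleration metric.
* **Tremor**: white Gaussian acceleration (per axis, per instrument) is
  integrated twice through leaky (exponentially damped) integrators, giving a
  stationary jitter around the base path whose finite-difference acceleration
  scales with the tremor parameter instead of wandering off like a random
  walk.
* **Tip separation**: the bipolar tip is offset from the aspirator tip along a
  fixed random direction by a distance that combines a per-trial level draw
  with a slow sinusoidal wander, both scaled by ``tip_separation_sd_mm``.
* **Forces**: a per-trial force level is drawn around the group mean, then
  per-sample Gaussian jitter is added; both use ``*_force_jitter_n``.
* **Bleeding**: a per-trial rate is drawn around the group mean, per-sample
  jitter added, clipped at zero, and integrated to a non-decreasing cumulative
  volume.

Every scale parameter at zero collapses the corresponding channel to its
analytic ideal (constant force, exact separation, zero acceleration, linear
blood accumulation), which is what the metric oracle tests rely on.

Group-level realism (how a human actually moves a bipolar forceps) is an
explicit non-goal; the generator exists to give the downstream pipeline two
classes whose metric distributions differ in a known, controllable way, with
skilled operators lower on all four behaviours.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import CohortError, ParameterError
from .recording import GROUP_LABELS, NOVICE, SKILLED, RawRecording

__all__ = [
    "SimulationProfile",
    "CohortSpec",
    "generate_recording",
    "generate_cohort",
    "write_cohort",
    "read_manifest",
    "default_skilled_profile",
    "default_novice_profile",
    "default_cohort_spec",
]


@dataclass(frozen=True)
class SimulationProfile:
    """Generative parameters for one skill group.

    All scale parameters are non-negative; ``*_jitter_*`` fields set both the
    between-trial spread of the corresponding level and (where meaningful) the
    per-sample noise.  Units: seconds, Hz, newtons, millimetres, mm/s^2, mL/s.
    """

    group_label: str
    duration_s: float = 120.0
    sample_rate_hz: float = 20.0
    ua_force_mean_n: float = 0.6
    ua_force_jitter_n: float = 0.1
    bp_force_mean_n: float = 0.5
    bp_force_jitter_n: float = 0.1
    tip_separation_mean_mm: float = 20.0
    tip_separation_sd_mm: float = 4.0
    tremor_accel_mm_s2: float = 50.0
    tremor_jitter_mm_s2: float = 8.0
    bleed_rate_ml_s: float = 0.02
    bleed_jitter_ml_s: float = 0.005
    drift_speed_mm_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_label not in GROUP_LABELS:
            raise ParameterError(
                f"group_label must be one of {GROUP_LABELS}, got {self.group_label!r}"
            )
        if self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ParameterError("duration_s and sample_rate_hz must be positive")
        if round(self.duration_s * self.sample_rate_hz) < 2:
            raise ParameterError("duration_s x sample_rate_hz must cover >= 2 samples")
        for name in (
            "ua_force_mean_n", "ua_force_jitter_n",
            "bp_force_mean_n", "bp_force_jitter_n",
            "tip_separation_mean_mm", "tip_separation_sd_mm",
            "tremor_accel_mm_s2", "tremor_jitter_mm_s2",
            "bleed_rate_ml_s", "bleed_jitter_ml_s",
            "drift_speed_mm_s",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")

    @classmethod
    def from_dict(cls, group_label: str, values: dict) -> "SimulationProfile":
        unknown = set(values) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ParameterError(f"unknown profile fields: {sorted(unknown)}")
        return cls(group_label=group_label, **values)


@dataclass(frozen=True)
class CohortSpec:
    """A labelled two-group cohort: member counts, group profiles, master seed."""

    n_skilled: int
    n_novice: int
    skilled_profile: SimulationProfile
    novice_profile: SimulationProfile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_skilled < 0 or self.n_novice < 0:
            raise ParameterError("member counts must be non-negative")
        if self.n_skilled + self.n_novice < 2:
            raise ParameterError("a cohort needs at least 2 members")
        if self.skilled_profile.group_label != SKILLED:
            raise ParameterError("skilled_profile must carry group_label 'skilled'")
        if self.novice_profile.group_label != NOVICE:
            raise ParameterError("novice_profile must carry group_label 'novice'")


# -- deterministic per-member seeding ---------------------------------------

_MIX_A = 1_000_003
_MIX_B = 7_919
_MIX_MOD = 2**31 - 1


def member_seed(cohort_seed: int, index: int) -> int:
    """Portable per-member seed: ``(seed*1000003 + 7919*index + 1) mod (2^31-1)``.

    A fixed affine mixing rule (rather than an opaque hash) so the same cohort
    can be regenerated from the spec alone in any language.
    """
    return (cohort_seed * _MIX_A + _MIX_B * index + 1) % _MIX_MOD


# -- recording generation ----------------------------------------------------

def _unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    norm = np.linalg.norm(v)
    if norm == 0.0:  # pragma: no cover - probability zero
        return np.array([1.0, 0.0, 0.0])
    return v / norm


#: Damping time constants of the tremor integrators (seconds).  Velocity
#: decorrelates over ~0.1 s and displacement relaxes back to the base path
#: over ~0.5 s, so tremor stays a bounded jitter rather than a random walk.
_TREMOR_TAU_V = 0.1
_TREMOR_TAU_D = 0.5


def _tremor_displacement(
    rng: np.random.Generator, n: int, dt: float, scale: float
) -> np.ndarray:
    """White Gaussian acceleration, integrated twice with damping, to a
    stationary displacement jitter of shape (n, 3)."""
    from scipy.signal import lfilter

    # scale 0 draws zeros, so the rng stream advances identically either way
    accel = rng.normal(0.0, scale, size=(n, 3))
    rho_v = np.exp(-dt / _TREMOR_TAU_V)
    rho_d = np.exp(-dt / _TREMOR_TAU_D)
    vel = lfilter([dt], [1.0, -rho_v], accel, axis=0)
    return lfilter([dt], [1.0, -rho_d], vel, axis=0)


def _force_trace(
    rng: np.random.Generator, n: int, mean: float, jitter: float
) -> np.ndarray:
    level = max(rng.normal(mean, jitter), 0.0) if jitter > 0 else mean
    trace = rng.normal(level, jitter, size=n) if jitter > 0 else np.full(n, level)
    return np.clip(trace, 0.0, None)


def generate_recording(
    profile: SimulationProfile, seed: int | None = None
) -> RawRecording:
    """Simulate one trial under ``profile``.

    Deterministic for a fixed ``(profile, seed)``; ``seed`` defaults to
    ``profile.seed``.  The recording has exactly
    ``round(duration_s * sample_rate_hz)`` samples.
    """
    rng = np.random.default_rng(profile.seed if seed is None else seed)
    n = int(round(profile.duration_s * profile.sample_rate_hz))
    dt = 1.0 / profile.sample_rate_hz
    t = np.arange(n) * dt

    # Base path: constant-velocity drift (zero intrinsic acceleration).
    start = rng.uniform(-40.0, 40.0, size=3)
    drift_dir = _unit_vector(rng)
    base = start[None, :] + profile.drift_speed_mm_s * t[:, None] * drift_dir[None, :]

    # Per-instrument tremor levels.
    tj = profile.tremor_jitter_mm_s2
    ua_tremor = max(rng.normal(profile.tremor_accel_mm_s2, tj), 0.0) if tj > 0 else profile.tremor_accel_mm_s2
    bp_tremor = max(rng.normal(profile.tremor_accel_mm_s2, tj), 0.0) if tj > 0 else profile.tremor_accel_mm_s2

    ua_pos = base + _tremor_displacement(rng, n, dt, ua_tremor)

    # Bipolar tip: offset from the base path along a fixed direction by a
    # slowly wandering distance, plus its own tremor.
    sep_dir = _unit_vector(rng)
    sd = profile.tip_separation_sd_mm
    level = max(rng.normal(profile.tip_separation_mean_mm, sd), 0.0) if sd > 0 else profile.tip_separation_mean_mm
    wander_freq = rng.uniform(0.02, 0.08)
    wander_phase = rng.uniform(0.0, 2.0 * np.pi)
    distance = np.clip(
        level + sd * np.sin(2.0 * np.pi * wander_freq * t + wander_phase), 0.0, None
    )
    bp_pos = base + distance[:, None] * sep_dir[None, :] + _tremor_displacement(
        rng, n, dt, bp_tremor
    )

    ua_force = _force_trace(rng, n, profile.ua_force_mean_n, profile.ua_force_jitter_n)
    bp_force = _force_trace(rng, n, profile.bp_force_mean_n, profile.bp_force_jitter_n)

    bj = profile.bleed_jitter_ml_s
    bleed_level = max(rng.normal(profile.bleed_rate_ml_s, bj), 0.0) if bj > 0 else profile.bleed_rate_ml_s
    inst_rate = np.clip(
        rng.normal(bleed_level, bj, size=n) if bj > 0 else np.full(n, bleed_level),
        0.0,
        None,
    )
    blood_ml = np.cumsum(inst_rate) * dt
    blood_ml -= blood_ml[0]  # volume is zero at trial start

    return RawRecording(
        t=t,
        ua_pos=ua_pos,
        bp_pos=bp_pos,
        ua_force=ua_force,
        bp_force=bp_force,
        blood_ml=blood_ml,
    )


# -- cohort generation -------------------------------------------------------

def generate_cohort(
    spec: CohortSpec, require_both_classes: bool = True
) -> list[tuple[RawRecording, str]]:
    """Generate the labelled cohort: skilled members first, then novices.

    Member ``i`` (0-based, across the whole cohort) is generated with
    ``member_seed(spec.seed, i)``, so the cohort is reproducible from the spec
    alone and insensitive to generation order.
    """
    if require_both_classes and (spec.n_skilled == 0 or spec.n_novice == 0):
        raise CohortError(
            "cohort has an empty class; both groups are required for training use"
        )
    members: list[tuple[RawRecording, str]] = []
    labels = [SKILLED] * spec.n_skilled + [NOVICE] * spec.n_novice
    for index, label in enumerate(labels):
        profile = spec.skilled_profile if label == SKILLED else spec.novice_profile
        rec = generate_recording(profile, seed=member_seed(spec.seed, index))
        members.append((rec, label))
    return members


def write_cohort(
    cohort: Sequence[tuple[RawRecording, str]], out_dir: str | Path
) -> Path:
    """Write one CSV per trial plus a ``manifest.csv`` (trial_id,file,group).

    Returns the manifest path.  File paths in the manifest are relative to its
    own directory.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (rec, label) in enumerate(cohort):
        trial_id = f"trial_{i:03d}"
        filename = f"{trial_id}.csv"
        rec.to_csv(out_dir / filename)
        rows.append({"trial_id": trial_id, "file": filename, "group": label})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["trial_id", "file", "group"]).to_csv(
        manifest, index=False
    )
    return manifest


def read_manifest(path: str | Path) -> list[tuple[str, Path, str]]:
    """Read a cohort manifest; returns (trial_id, absolute file path, group)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("trial_id", "file", "group") if c not in df.columns]
    if missing:
        raise CohortError(f"manifest is missing columns: {missing}")
    bad = set(df["group"]) - set(GROUP_LABELS)
    if bad:
        raise CohortError(f"manifest contains unknown group labels: {sorted(bad)}")
    return [
        (str(r.trial_id), path.parent / str(r.file), str(r.group))
        for r in df.itertuples()
    ]


# -- default study conditions ------------------------------------------------

def default_skilled_profile(**overrides) -> SimulationProfile:
    """Skilled group defaults: lower force, bleeding, tip separation, tremor.

    The group gaps are deliberately moderate (roughly 1.3-1.7 pooled standard
    deviations per metric), so the default cohorts overlap the way real skill
    cohorts do and classification stays hard but achievable.
    """
    params = dict(
        ua_force_mean_n=0.65, ua_force_jitter_n=0.12,
        bp_force_mean_n=0.55, bp_force_jitter_n=0.10,
        tip_separation_mean_mm=18.0, tip_separation_sd_mm=4.0,
        tremor_accel_mm_s2=45.0, tremor_jitter_mm_s2=12.0,
        bleed_rate_ml_s=0.015, bleed_jitter_ml_s=0.005,
    )
    params.update(overrides)
    return SimulationProfile(group_label=SKILLED, **params)


def default_novice_profile(**overrides) -> SimulationProfile:
    """Novice group defaults: higher on all four separating behaviours."""
    params = dict(
        ua_force_mean_n=0.80, ua_force_jitter_n=0.15,
        bp_force_mean_n=0.70, bp_force_jitter_n=0.12,
        tip_separation_mean_mm=24.0, tip_separation_sd_mm=5.0,
        tremor_accel_mm_s2=65.0, tremor_jitter_mm_s2=15.0,
        bleed_rate_ml_s=0.025, bleed_jitter_ml_s=0.007,
    )
    params.update(overrides)
    return SimulationProfile(group_label=NOVICE, **params)


def default_cohort_spec(
    n_skilled: int = 28, n_novice: int = 22, seed: int = 0
) -> CohortSpec:
    """The default study-shaped cohort: 28 skilled and 22 novice trials."""
    return CohortSpec(
        n_skilled=n_skilled,
        n_novice=n_novice,
        skilled_profile=default_skilled_profile(),
        novice_profile=default_novice_profile(),
        seed=seed,
    )
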