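"""Raw trial recording: time-aligned bimanual tool kinematics, forces, and blood loss.

A trial on the simulator produces, at a fixed sampling rate, the 3-D tip
position and applied force of the two instruments — the ultrasonic aspirator
(``ua``, dominant hand) and the bipolar forceps (``bp``, non-dominant hand) —
together with the cumulative volume of simulated bleeding.  Units are fixed
package-wide: seconds, millimetres, newtons, millilitres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError, SchemaError

#: Column order of the on-disk recording CSV (one file per trial).
CSV_COLUMNS = (
    "t",
    "ua_x", "ua_y", "ua_z", "ua_force",
    "bp_x", "bp_y", "bp_z", "bp_force",
    "blood_ml",
)

#: Group labels used throughout the package.
SKILLED = "skilled"
NOVICE = "novice"
GROUP_LABELS = (SKILLED, NOVICE)


@dataclass(eq=False)
class RawRecording:
    """One trial's raw channels.

    Parameters
    ----------
    t : array of float, seconds
        Sample times, strictly increasing, length >= 2.
    ua_pos, bp_pos : array of shape (n, 3), millimetres
        Instrument tip positions (ultrasonic aspirator / bipolar).
    ua_force, bp_force : array of float, newtons
        Applied force magnitudes, non-negative.
    blood_ml : array of float, millilitres
        Cumulative blood volume, non-decreasing.
    """

    t: np.ndarray
    ua_pos: np.ndarray
    bp_pos: np.ndarray
    ua_force: np.ndarray
    bp_force: np.ndarray
    blood_ml: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.ua_pos = np.asarray(self.ua_pos, dtype=float)
        self.bp_pos = np.asarray(self.bp_pos, dtype=float)
        self.ua_force = np.asarray(self.ua_force, dtype=float)
        self.bp_force = np.asarray(self.bp_force, dtype=float)
        self.blood_ml = np.asarray(self.blood_ml, dtype=float)
        self._validate()

    def _validate(self) -> None:
        n = self.t.shape[0]
        if self.t.ndim != 1 or n < 2:
            raise InputError("recording needs a 1-D time axis with at least 2 samples")
        for name in ("ua_pos", "bp_pos"):
            arr = getattr(self, name)
            if arr.shape != (n, 3):
                raise InputError(f"{name} must have shape ({n}, 3), got {arr.shape}")
        for name in ("ua_force", "bp_force", "blood_ml"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise InputError(f"{name} must have shape ({n},), got {arr.shape}")
        for name in ("t", "ua_pos", "bp_pos", "ua_force", "bp_force", "blood_ml"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise InputError(f"{name} contains non-finite values")
        if np.any(np.diff(self.t) <= 0.0):
            raise InputError("t must be strictly increasing")
        if np.any(self.ua_force < 0.0) or np.any(self.bp_force < 0.0):
            raise InputError("forces must be non-negative")
        if np.any(np.diff(self.blood_ml) < 0.0):
            raise InputError("blood_ml must be non-decreasing")

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return int(self.t.shape[0])

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])

    # -- equality (channel-wise, exact) -------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RawRecording):
            return NotImplemented
        return all(
            np.array_equal(getattr(self, name), getattr(other, name))
            for name in ("t", "ua_pos", "bp_pos", "ua_force", "bp_force", "blood_ml")
        )

    # -- serialization ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "ua_x": self.ua_pos[:, 0],
                "ua_y": self.ua_pos[:, 1],
                "ua_z": self.ua_pos[:, 2],
                "ua_force": self.ua_force,
                "bp_x": self.bp_pos[:, 0],
                "bp_y": self.bp_pos[:, 1],
                "bp_z": self.bp_pos[:, 2],
                "bp_force": self.bp_force,
                "blood_ml": self.blood_ml,
            },
            columns=list(CSV_COLUMNS),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RawRecording":
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"recording table is missing columns: {missing}")
        return cls(
            t=df["t"].to_numpy(),
            ua_pos=df[["ua_x", "ua_y", "ua_z"]].to_numpy(),
            bp_pos=df[["bp_x", "bp_y", "bp_z"]].to_numpy(),
            ua_force=df["ua_force"].to_numpy(),
            bp_force=df["bp_force"].to_numpy(),
            blood_ml=df["blood_ml"].to_numpy(),
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "RawRecording":
        return cls.from_frame(pd.read_csv(path))
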