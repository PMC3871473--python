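"""Waveform-record and beat-table I/O plus clinical-unit conversions.

Channels live on disk in clinical units (mmHg, L/min, mL) as delimited
text with a JSON metadata sidecar; all energy arithmetic elsewhere in the
package is done in coherent SI units (Pa, m^3/s, m^3 -> J, W).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, UnitError

#: Conversion factors from clinical to SI units.
MMHG_TO_PA = 133.322
LPM_TO_M3S = 1.0 / 60000.0
ML_TO_M3 = 1.0e-6

_TO_SI = {"mmHg": MMHG_TO_PA, "L/min": LPM_TO_M3S, "mL": ML_TO_M3}

#: Column order of a waveform CSV file.
WAVEFORM_COLUMNS = ["time_s", "ecg", "p_ao_mmHg", "q_ao_lpm", "p_lv_mmHg", "v_lv_ml"]

#: Column order of a beat-table CSV file.
BEAT_COLUMNS = [
    "animal_id",
    "condition",
    "measurement_index",
    "cycle_index",
    "sw_J",
    "pwr_integral_J",
    "sv_mL",
    "co_Lmin",
    "map_mmHg",
    "cpo_W",
]


def to_si(value, unit: str):
    """Convert ``value`` from a clinical unit to its SI counterpart.

    mmHg -> Pa, L/min -> m^3/s, mL -> m^3.  Works elementwise on arrays.
    """
    try:
        return value * _TO_SI[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}; expected one of {sorted(_TO_SI)}") from None


def from_si(value, unit: str):
    """Inverse of :func:`to_si` (SI value back to the named clinical unit)."""
    try:
        return value / _TO_SI[unit]
    except KeyError:
        raise UnitError(f"unknown unit {unit!r}; expected one of {sorted(_TO_SI)}") from None


@dataclasses.dataclass
class WaveformRecord:
    """One synchronized multichannel measurement.

    Channels are 1-D arrays of equal length: ``ecg`` (arbitrary units),
    ``p_ao`` (aortic pressure, mmHg), ``q_ao`` (aortic flow, L/min),
    ``p_lv`` (left-ventricular pressure, mmHg), ``v_lv`` (left-ventricular
    volume, mL).  ``meta`` carries at least animal_id / condition /
    measurement_index.
    """

    fs: float
    ecg: np.ndarray
    p_ao: np.ndarray
    q_ao: np.ndarray
    p_lv: np.ndarray
    v_lv: np.ndarray
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise FormatError(f"sampling rate must be positive, got fs={self.fs}")
        arrays = {}
        for name in ("ecg", "p_ao", "q_ao", "p_lv", "v_lv"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 1:
                raise FormatError(f"channel {name!r} must be 1-D")
            if not np.all(np.isfinite(arr)):
                raise FormatError(f"channel {name!r} contains non-finite samples")
            arrays[name] = arr
            object.__setattr__(self, name, arr)
        lengths = {name: len(a) for name, a in arrays.items()}
        if len(set(lengths.values())) != 1:
            raise FormatError(f"channel lengths differ: {lengths}")
        if self.n_samples < 2:
            raise FormatError("record must contain at least 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.p_ao)

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def replace(self, **kwargs: Any) -> "WaveformRecord":
        """Copy with some channels or metadata replaced."""
        return dataclasses.replace(self, **kwargs)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_record(record: WaveformRecord, path) -> Path:
    """Write a record as CSV plus a ``<path>.meta.json`` sidecar.

    Values are written with 12 significant digits so that a read/write
    round trip reproduces every channel to better than 1e-9 relative.
    """
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": record.t,
            "ecg": record.ecg,
            "p_ao_mmHg": record.p_ao,
            "q_ao_lpm": record.q_ao,
            "p_lv_mmHg": record.p_lv,
            "v_lv_ml": record.v_lv,
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")
    sidecar = {"fs": record.fs, "meta": record.meta}
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_record(path) -> WaveformRecord:
    """Read a record written by :func:`write_record`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"waveform file not found: {path}")
    df = pd.read_csv(path)
    for col in WAVEFORM_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"waveform file {path} is missing column {col!r}")
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FormatError(f"metadata sidecar not found: {sidecar_file}")
    sidecar = json.loads(sidecar_file.read_text())
    if "fs" not in sidecar:
        raise FormatError(f"sidecar {sidecar_file} is missing field 'fs'")
    return WaveformRecord(
        fs=float(sidecar["fs"]),
        ecg=df["ecg"].to_numpy(),
        p_ao=df["p_ao_mmHg"].to_numpy(),
        q_ao=df["q_ao_lpm"].to_numpy(),
        p_lv=df["p_lv_mmHg"].to_numpy(),
        v_lv=df["v_lv_ml"].to_numpy(),
        meta=dict(sidecar.get("meta", {})),
    )


def write_beat_table(table: pd.DataFrame, path) -> Path:
    """Write a beat table (one row per cardiac cycle) as CSV."""
    missing = [c for c in BEAT_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"beat table is missing columns {missing}")
    path = Path(path)
    table.to_csv(path, index=False, columns=BEAT_COLUMNS, float_format="%.12g")
    return path


def read_beat_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"beat table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in BEAT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"beat table {path} is missing columns {missing}")
    return df


def record_to_frame(record: WaveformRecord) -> pd.DataFrame:
    """Channels as a DataFrame (convenience for plotting / inspection)."""
    return pd.DataFrame(
        {
            "time_s": record.t,
            "ecg": record.ecg,
            "p_ao_mmHg": record.p_ao,
            "q_ao_lpm": record.q_ao,
            "p_lv_mmHg": record.p_lv,
            "v_lv_ml": record.v_lv,
        }
    )


def meta_lookup(meta: Mapping[str, Any], key: str, path: Path | None = None):
    if key not in meta:
        where = f" in {path}" if path else ""
        raise FormatError(f"metadata field {key!r} missing{where}")
    return meta[key]
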