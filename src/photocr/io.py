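"""Run-file formats and hashing.

A run is a single CSV with a ``# key: value`` comment header for metadata
(role, seed, volumes, program, calibration reference) followed by the fixed
column contract::

    time_s, dP_heat_uW, o2_liquid_pct, o2_gas_pct, led_current_mA

Times are seconds since run start; heat is the differential signal in µW;
the liquid optode reads % air saturation and the headspace optode % volume
fraction (dialect selectable downstream).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("time_s", "dP_heat_uW", "o2_liquid_pct", "o2_gas_pct", "led_current_mA")

#: sampling gaps larger than this are flagged on read
GAP_THRESHOLD_S = 5.0


@dataclass
class InstrumentTrace:
    """Synchronized raw channels of one run, plus free-form metadata."""

    time_s: np.ndarray
    dp_heat_uW: np.ndarray
    o2_liquid_pct: np.ndarray
    o2_gas_pct: np.ndarray
    led_current_mA: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        arrays = [self.time_s, self.dp_heat_uW, self.o2_liquid_pct,
                  self.o2_gas_pct, self.led_current_mA]
        arrays = [np.asarray(a, dtype=float) for a in arrays]
        n = arrays[0].size
        if any(a.size != n for a in arrays):
            raise ValueError("all channels must have the same length")
        (self.time_s, self.dp_heat_uW, self.o2_liquid_pct,
         self.o2_gas_pct, self.led_current_mA) = arrays

    @property
    def n(self) -> int:
        return int(self.time_s.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time_s,
            "dP_heat_uW": self.dp_heat_uW,
            "o2_liquid_pct": self.o2_liquid_pct,
            "o2_gas_pct": self.o2_gas_pct,
            "led_current_mA": self.led_current_mA,
        })


def write_run_csv(trace: InstrumentTrace, path) -> None:
    """Write a run CSV with its metadata comment header (lossless floats)."""
    with open(path, "w", newline="") as fh:
        for key, value in trace.meta.items():
            fh.write(f"# {key}: {value}\n")
        trace.to_frame().to_csv(fh, index=False, float_format="%.17g")


def read_run_csv(path) -> InstrumentTrace:
    """Read a run CSV, validating the column contract and the time axis.

    Raises with the offending column name or data line numbers; sampling
    gaps > 5 s are flagged in ``meta['gap_lines']`` with a warning.
    """
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {missing}; found {list(df.columns)}"
        )
    time = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(time) <= 0)[0]
    if bad.size:
        # +2: 1-based line numbering plus the column-header line
        lines = [int(i) + n_header + 2 + 1 for i in bad[:10]]
        raise ValueError(f"{path}: time_s not strictly increasing at line(s) {lines}")
    gaps = np.nonzero(np.diff(time) > GAP_THRESHOLD_S)[0]
    if gaps.size:
        lines = [int(i) + n_header + 2 + 1 for i in gaps]
        meta["gap_lines"] = ",".join(map(str, lines))
        warnings.warn(f"{path}: sampling gaps > {GAP_THRESHOLD_S:g} s before line(s) {lines[:10]}")
    return InstrumentTrace(
        time_s=time,
        dp_heat_uW=df["dP_heat_uW"].to_numpy(dtype=float),
        o2_liquid_pct=df["o2_liquid_pct"].to_numpy(dtype=float),
        o2_gas_pct=df["o2_gas_pct"].to_numpy(dtype=float),
        led_current_mA=df["led_current_mA"].to_numpy(dtype=float),
        meta=meta,
    )


def config_hash(obj) -> str:
    """Short stable hash of any JSON-serialisable configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
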