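"""CSV/JSON readers and writers for the measurement and config formats.

Interchange conventions: CSV with a header row, decimal point, UTF-8 and
``\\n`` newlines for measurements; JSON for fitted parameters and thermal
scenarios.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_observations_csv",
    "read_gas_csv",
    "read_spad_csv",
    "read_grain_csv",
    "read_scenario_json",
    "write_json",
    "read_json",
    "write_csv",
    "file_sha256",
]

_SCHEMAS = {
    "observations": ["temperature_C", "rate"],
    "gas": ["treatment", "t_day_C", "t_night_C", "photosynthesis_umol_m2_s",
            "respiration_umol_m2_s", "replicate"],
    "spad": ["treatment", "plant_id", "days_after_anthesis", "spad"],
    "grain": ["treatment", "spike_id", "days_after_anthesis",
              "grain_weight_mg", "seed_count", "is_maturity"],
}


def _read_checked(path, schema_name: str) -> pd.DataFrame:
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in _SCHEMAS[schema_name] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def read_observations_csv(path) -> pd.DataFrame:
    """Rate observations: ``temperature_C, rate[, replicate]``."""
    return _read_checked(path, "observations")


def read_gas_csv(path) -> pd.DataFrame:
    """Instantaneous gas-exchange measurements per treatment/replicate."""
    return _read_checked(path, "gas")


def read_spad_csv(path) -> pd.DataFrame:
    """SPAD time courses: ``treatment, plant_id, days_after_anthesis, spad``."""
    return _read_checked(path, "spad")


def read_grain_csv(path) -> pd.DataFrame:
    """Grain-weight time courses with seed counts and maturity flags."""
    return _read_checked(path, "grain")


def read_scenario_json(path) -> dict:
    """Thermal-scenario config: constants or per-day arrays (see
    :func:`thermodev.simulator.build_series`)."""
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def read_json(path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_csv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, encoding="utf-8", lineterminator="\n")


def file_sha256(path) -> str:
    """Hex digest of a file, for output provenance records."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
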