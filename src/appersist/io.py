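"""Delimited-text I/O and the flat key-value configuration format.

All tables are tab-separated with a header row; dates are ISO-8601 strings
and booleans are ``True``/``False``.  Config files are flat ``key = value``
lines with ``#`` comments.
"""

from __future__ import annotations

import hashlib
import json
from datetime import date
from pathlib import Path

import pandas as pd

from .errors import ConfigError

#: Date / boolean columns per table name (used when reading back).
DATE_COLS = {
    "residents": ["birth_date", "dementia_onset_date", "death_date"],
    "stays": ["entry_date", "exit_date"],
    "enrollment": ["start_date", "end_date"],
    "deaths": ["death_date"],
    "dispensings": ["dispense_date"],
    "episodes": ["index_date"],
    "analysis": ["index_date"],
    "facility_years": [],
}
BOOL_COLS = {
    "residents": ["dual_eligible", "exclusionary_dx", "medicare_advantage",
                  "anxiety", "depression", "bipolar", "physical_aggression",
                  "verbal_aggression"],
    "facility_years": ["urban"],
}


def _parse_date(v):
    if v is None or (isinstance(v, float) and pd.isna(v)) or v == "" or pd.isna(v):
        return None
    return date.fromisoformat(str(v))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, kind: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"person_id": str, "facility_id": str,
                                            "drug_code": str})
    if kind:
        for col in DATE_COLS.get(kind, []):
            if col in df.columns:
                df[col] = df[col].map(_parse_date)
        for col in BOOL_COLS.get(kind, []):
            if col in df.columns and df[col].dtype == object:
                df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


def parse_flat_config(path: str | Path) -> dict[str, str]:
    """Parse a flat ``key = value`` config file into a string mapping."""
    mapping: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        mapping[key.strip()] = value.strip()
    return mapping


def coerce(value: str, like):
    """Coerce a config string to the type of an existing default value."""
    if isinstance(like, bool):
        if value.lower() in ("true", "1", "yes"):
            return True
        if value.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"expected a boolean, got {value!r}")
    if isinstance(like, int):
        return int(value)
    if isinstance(like, float):
        return float(value)
    if isinstance(like, date):
        return date.fromisoformat(value)
    if isinstance(like, tuple):
        parts = [p for p in value.replace(",", " ").split() if p]
        elem = like[0] if like else 0.0
        return tuple(type(elem)(p) for p in parts)
    return value


def config_hash(obj) -> str:
    """Stable short hash of a configuration object for the run manifest."""
    def default(o):
        if isinstance(o, date):
            return o.isoformat()
        if isinstance(o, Path):
            return str(o)
        if hasattr(o, "__dict__"):
            return o.__dict__
        return repr(o)
    payload = json.dumps(obj, default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
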