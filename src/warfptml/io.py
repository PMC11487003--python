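"""Case-table and configuration I/O.

Case tables travel as CSV with a one-line manifest header (``# warfptml cases
v1 scheme=<name>``) so a file's scheme provenance survives the round trip.
Floats are written with shortest round-trip decimal representation, so
write -> read reproduces values bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .fusion import META_COLUMNS

__all__ = ["read_cases", "write_cases", "RunConfig", "config_hash"]

_MAGIC = "# warfptml cases v1"

MANDATORY = list(META_COLUMNS)


def write_cases(table: pd.DataFrame, path: str | Path, scheme_name: str = "default") -> None:
    missing = [c for c in MANDATORY if c not in table.columns]
    if missing:
        raise ValueError(f"case table lacks mandatory columns: {missing}")
    if table["case_id"].duplicated().any():
        raise ValueError("duplicate case_id values")
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_MAGIC} scheme={scheme_name}\n")
        table.to_csv(fh, index=False, float_format=lambda x: repr(float(x)))


def read_cases(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with path.open() as fh:
        first = fh.readline()
        if first.startswith(_MAGIC):
            scheme_name = first.strip().split("scheme=", 1)[-1]
            table = pd.read_csv(fh, float_precision="round_trip")
        else:
            scheme_name = "unknown"
            table = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in MANDATORY if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns: {missing}")
    if table["case_id"].duplicated().any():
        dup = table.loc[table["case_id"].duplicated(), "case_id"].iloc[0]
        raise ValueError(f"{path}: duplicate case_id {dup!r}")
    table.attrs["scheme"] = scheme_name
    return table


@dataclass
class RunConfig:
    """One self-describing pipeline run; a single seed drives every stage."""

    out_dir: str = "run"
    seed: int = 0
    level: str = "ma"  # {raw, ma, ed}
    task: str = "classification"  # {classification, regression}
    algorithm: str = "LDA"
    algorithm_settings: dict = field(default_factory=dict)
    split_fraction: float = 0.75
    split_mode: str = "case"  # {case, patient}
    stepwise: bool = True
    expert_set: list[str] = field(default_factory=list)
    p_enter: float = 0.05
    max_steps: int = 30
    n_patients: int | None = None  # None -> generator default
    cohort_dir: str | None = None  # reuse an existing cohort instead of simulating
    scheme_file: str | None = None
    f_ref_mode: str = "joint"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = (
            yaml.safe_load(path.read_text())
            if path.suffix in {".yml", ".yaml"}
            else json.loads(path.read_text())
        )
        return cls(**raw)


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the analysis configuration (output location excluded)."""
    payload = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    canon = json.dumps(payload, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
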