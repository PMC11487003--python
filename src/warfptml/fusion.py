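"""Information-fusion stage: longitudinal records -> flat case table.

A *case* is one patient at one INR measurement.  Horizontal fusion assembles,
per case, the observed INR (the output), the continuous inputs (the 63-day dose
and treatment-day windows, demographics, labs, co-medication daily doses) and
the categorical label vector (sex, surgery type, genotypes...).  Vertical
fusion stacks all patients into one table, one row per case.

The output is dichotomised against a clinical target interval: a case is
``Within`` when its INR lies inside the closed target range (default 1.8-2.5),
otherwise ``Out``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic_cohort import DOSE_WINDOW, PatientRecord

__all__ = [
    "PartitionScheme",
    "default_scheme",
    "label_output",
    "encode_dose_history",
    "build_case_table",
    "impute_missing",
    "META_COLUMNS",
]

log = logging.getLogger(__name__)

WITHIN = "Within"
OUT = "Out"

#: bookkeeping columns of a case table; everything else is a registered input
META_COLUMNS = ["case_id", "patient_id", "visit_day", "inr", "output_class"]


@dataclass
class PartitionScheme:
    """Registry of categorical partitions and continuous-variable groups.

    ``partitions`` maps a partition name (e.g. ``PKGeneCat``) to the label
    column that realizes it; ``variable_groups`` maps a group name (e.g.
    ``Doses``) to the continuous columns it contains.  The scheme is data, not
    code: study-specific rosters are registered through configuration, so extra
    columns in user-supplied tables can be added without touching the package.
    """

    name: str = "default"
    partitions: dict[str, str] = field(default_factory=dict)
    variable_groups: dict[str, list[str]] = field(default_factory=dict)
    continuous_vars: list[str] = field(default_factory=list)
    target_interval: tuple[float, float] = (1.8, 2.5)

    def validate(self) -> None:
        lo, hi = self.target_interval
        if not lo < hi:
            raise ValueError("target interval lower bound must be < upper bound")
        seen: set[str] = set()
        for gname, members in self.variable_groups.items():
            if not members:
                raise ValueError(f"variable group {gname!r} is empty")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"variable groups overlap on {sorted(overlap)}")
            seen |= set(members)
        unknown = seen - set(self.continuous_vars)
        if unknown:
            raise ValueError(f"grouped variables not registered: {sorted(unknown)}")

    @property
    def label_columns(self) -> list[str]:
        return list(dict.fromkeys(self.partitions.values()))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "partitions": self.partitions,
            "variable_groups": self.variable_groups,
            "continuous_vars": self.continuous_vars,
            "target_interval": list(self.target_interval),
        }

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            yaml.safe_dump(self.to_dict(), sort_keys=False)
            if path.suffix in {".yml", ".yaml"}
            else json.dumps(self.to_dict(), indent=1)
        )
        path.write_text(text)

    @classmethod
    def from_dict(cls, raw: dict) -> "PartitionScheme":
        scheme = cls(
            name=raw.get("name", "default"),
            partitions=dict(raw["partitions"]),
            variable_groups={k: list(v) for k, v in raw["variable_groups"].items()},
            continuous_vars=list(raw["continuous_vars"]),
            target_interval=tuple(raw.get("target_interval", (1.8, 2.5))),
        )
        scheme.validate()
        return scheme

    @classmethod
    def from_file(cls, path: str | Path) -> "PartitionScheme":
        path = Path(path)
        raw = (
            yaml.safe_load(path.read_text())
            if path.suffix in {".yml", ".yaml"}
            else json.loads(path.read_text())
        )
        return cls.from_dict(raw)


def default_scheme(
    labs: tuple[str, ...] = ("Neutrophil", "Plateletcrit", "PDW", "HDCL", "Hemoglobin"),
    comeds: tuple[str, ...] = (
        "Cefoperazone", "Ceftriaxone", "Spironolactone", "Aspirin", "Human_albumin",
    ),
    window: int = DOSE_WINDOW,
) -> PartitionScheme:
    """Scheme matching the synthetic generator's column roster."""
    dose_cols = [f"Dose{k:02d}" for k in range(1, window + 1)]
    day_cols = [f"TreatDay{k:02d}" for k in range(1, window + 1)]
    demo = ["age", "height", "weight", "POD"]
    scheme = PartitionScheme(
        name="synthetic-default",
        partitions={
            "DemoCat": "sex",
            "TypeCat": "surgery_type",
            "ValveCat": "valve_type",
            "PKGeneCat": "genotype_CYP2C9",
            "PDGeneCat": "genotype_VKORC1",
        },
        variable_groups={
            "Doses": dose_cols,
            "TreatDays": day_cols,
            "DEMO": demo,
            "Labs": list(labs),
            "Comeds": list(comeds),
        },
        continuous_vars=dose_cols + day_cols + demo + list(labs) + list(comeds),
        target_interval=(1.8, 2.5),
    )
    scheme.validate()
    return scheme


def label_output(inr: float, target: tuple[float, float] = (1.8, 2.5)) -> str:
    """Dichotomise an INR against the closed target interval."""
    if not inr > 0:
        raise ValueError(f"INR must be positive, got {inr}")
    lo, hi = target
    return WITHIN if lo <= inr <= hi else OUT


def encode_dose_history(
    record: PatientRecord, visit_day: int, window: int = DOSE_WINDOW
) -> tuple[np.ndarray, np.ndarray]:
    """Fixed-arity look-back encoding of the dose record at one visit.

    ``DoseK`` is the dose administered on day ``visit_day - K`` (0 before the
    first dosed day); ``TreatDayK`` is how many consecutive days that dose
    level had been held as of that day.  Returns two arrays of length
    ``window`` (so 2 x window features per case).
    """
    if visit_day not in record.inr_series:
        raise ValueError(f"day {visit_day} has no INR measurement")
    if not record.dose_series or visit_day <= min(record.dose_series):
        raise ValueError(f"visit day {visit_day} precedes any dosing")
    first = min(record.dose_series)
    last = max(record.dose_series)
    daily = np.zeros(last + 1)
    run = np.zeros(last + 1)
    for d in range(first, last + 1):
        daily[d] = record.dose_series.get(d, 0.0)
        run[d] = run[d - 1] + 1 if d > first and daily[d] == daily[d - 1] else 1
    doses = np.zeros(window)
    days = np.zeros(window)
    for k in range(1, window + 1):
        d = visit_day - k
        if first <= d <= last:
            doses[k - 1] = daily[d]
            days[k - 1] = run[d]
    return doses, days


def build_case_table(
    records: list[PatientRecord], scheme: PartitionScheme, window: int = DOSE_WINDOW
) -> pd.DataFrame:
    """One row per (patient, INR measurement), ordered by (patient_id, visit_day)."""
    if not records:
        raise ValueError("no patient records supplied")
    scheme.validate()
    labs = sorted({lab for r in records for lab in r.lab_series})
    drugs = sorted({d for r in records for d in r.comed_series})
    rows = []
    for rec in sorted(records, key=lambda r: r.patient_id):
        seen_days: set[int] = set()
        for day, inr in sorted(rec.inr_series.items()):
            if day in seen_days:
                raise ValueError(
                    f"duplicate INR entry for patient {rec.patient_id} on day {day}"
                )
            seen_days.add(day)
            doses, days = encode_dose_history(rec, day, window)
            row: dict[str, object] = {
                "case_id": f"{rec.patient_id}-d{day:04d}",
                "patient_id": rec.patient_id,
                "visit_day": day,
                "inr": inr,
                "output_class": label_output(inr, scheme.target_interval),
            }
            row.update({f"Dose{k:02d}": doses[k - 1] for k in range(1, window + 1)})
            row.update({f"TreatDay{k:02d}": days[k - 1] for k in range(1, window + 1)})
            row.update(
                {
                    "age": rec.age,
                    "height": rec.height,
                    "weight": rec.weight,
                    "POD": float(day),  # days since first dose ~ post-operative day
                    "sex": rec.sex,
                    "surgery_type": rec.surgery_type,
                    "valve_type": rec.valve_type,
                }
            )
            row.update({f"genotype_{s}": g for s, g in rec.genotypes.items()})
            for lab in labs:
                row[lab] = rec.lab_series.get(lab, {}).get(day, np.nan)
            for drug in drugs:
                row[drug] = rec.comed_series.get(drug, {}).get(day, 0.0)
            rows.append(row)
    table = pd.DataFrame(rows)
    table = table.sort_values(["patient_id", "visit_day"], kind="stable").reset_index(drop=True)
    if table["case_id"].duplicated().any():
        raise ValueError("duplicate case identifiers produced")
    return table


def impute_missing(
    table: pd.DataFrame,
    scheme: PartitionScheme,
    reference_means: pd.Series | None = None,
) -> pd.DataFrame:
    """LOCF within patient, then mean-fill; leakage-safe via ``reference_means``.

    Labs are sampled irregularly in clinic, so per patient each variable is
    carried forward from its last observation; any value still missing is
    replaced by the training-table mean of that variable (``reference_means``
    when given — use the means of the *training* table when imputing a
    validation table — else the mean of ``table`` itself).
    """
    out = table.copy()
    vars_present = [v for v in scheme.continuous_vars if v in out.columns]
    counts: dict[str, int] = {}
    for var in vars_present:
        n_missing = int(out[var].isna().sum())
        if n_missing == 0:
            continue
        out[var] = (
            out.sort_values("visit_day", kind="stable")
            .groupby("patient_id")[var]
            .ffill()
            .reindex(out.index)
        )
        still = int(out[var].isna().sum())
        if still:
            fill = (
                reference_means[var]
                if reference_means is not None and var in reference_means
                else out[var].mean()
            )
            if pd.isna(fill):
                raise ValueError(f"variable {var!r} is missing for all cases")
            out[var] = out[var].fillna(float(fill))
        counts[var] = n_missing
    for var, n in counts.items():
        log.info("imputed %d values for %s", n, var)
    return out
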