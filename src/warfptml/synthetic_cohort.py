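"""Synthetic longitudinal warfarin cohort generator.

Real anticoagulation follow-up data of the kind this pipeline analyses (one INR
measurement per clinic visit, a daily warfarin dose record in between, static
demographics and pharmacogene genotypes) are typically not publicly depositable.
This module generates cohorts with the same statistical shape so that every
downstream stage — information fusion, perturbation-theory operators, model
fitting, evaluation — is exercisable and testable end to end.

The response model is deliberately simple and fully parameterised: the INR at a
visit is a baseline plus a genotype-scaled, weight-normalised function of the
exponentially weighted recent dose history, plus Gaussian noise.  A bang-bang
titration rule feeds the measured INR back into the next dose.  Because the
clinician-feedback loop pushes sensitive genotypes onto lower doses, the
generated cohorts reproduce the negative genotype-to-dose correlation that real
warfarin cohorts exhibit, without any mechanistic PK/PD machinery.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SimulationParams",
    "PatientRecord",
    "default_params",
    "inr_response",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

def _REPR(x) -> str:  # shortest round-trip float text for lossless CSV
    return repr(float(x))


#: encoding window, in days, used to weight the recent dose history
DOSE_WINDOW = 63

# Surgery-type marginals of the emulated cohort (double/aortic/mitral/tricuspid
# valve replacement and a residual "other" class covering large-vessel surgery).
_SURGERY_PROBS = {"DVR": 0.102, "AVR": 0.146, "MVR": 0.394, "TVR": 0.012, "other": 0.346}
_VALVE_PROBS = {"mechanical": 0.35, "bioprosthetic": 0.50, "other": 0.15}


@dataclass
class SimulationParams:
    """Tunable knobs of the cohort generator.

    Marginal-distribution fields (sex, genotype frequencies, age/weight/height
    moments, dose summaries, visit gaps) default to the emulated cohort's
    published summary table.  Response-model constants (``sensitivity_beta``,
    ``genotype_multipliers``, ``exposure_halflife_days``, ``noise_sd``) are
    generator design choices, not estimates from any study.
    """

    n_patients: int = 246
    follow_up_days: tuple[int, int] = (12, 188)  # uniform integer range
    visit_gap_mean: float = 6.7
    visit_gap_sd: float = 7.8
    sex_male_frac: float = 0.638
    genotype_freqs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "CYP2C9": {"*1/*1": 0.923, "*1/*3": 0.077},
            # as printed these sum to 1.005; renormalized at sampling time
            "VKORC1": {"AA": 0.855, "AG": 0.138, "GG": 0.012},
        }
    )
    age_mean: float = 58.0
    age_sd: float = 13.0
    weight_mean: float = 63.9
    weight_sd: float = 11.8
    height_mean: float = 164.7
    height_sd: float = 8.8
    dose_init: float = 1.0  # mg/d, conservative post-operative starting dose
    dose_step: float = 0.25  # mg/d per titration move
    target_inr: tuple[float, float] = (1.8, 2.5)
    baseline_inr: float = 1.0
    #: INR gained per (mg/d of effective exposure per kg body weight)
    sensitivity_beta: float = 27.0
    genotype_multipliers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "CYP2C9": {"*1/*1": 1.0, "*1/*3": 1.4},
            "VKORC1": {"AA": 1.3, "AG": 1.0, "GG": 0.7},
        }
    )
    exposure_halflife_days: float = 4.0
    noise_sd: float = 0.15  # INR units
    #: drug -> (prevalence, (daily-dose low, high))
    comedication_spec: dict[str, tuple[float, tuple[float, float]]] = field(
        default_factory=lambda: {
            "Cefoperazone": (0.15, (2.0, 6.0)),  # g/d
            "Ceftriaxone": (0.10, (1.0, 2.0)),  # g/d
            "Spironolactone": (0.30, (20.0, 60.0)),  # mg/d
            "Aspirin": (0.12, (75.0, 100.0)),  # mg/d
            "Human_albumin": (0.20, (10.0, 20.0)),  # g/d
        }
    )
    #: analyte -> (between-patient mean, between-patient sd, within sd, measure prob)
    lab_spec: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "Neutrophil": (65.0, 8.0, 4.0, 0.6),  # %
            "Plateletcrit": (0.23, 0.05, 0.02, 0.6),  # %
            "PDW": (13.0, 2.0, 0.8, 0.6),  # fL
            "HDCL": (1.2, 0.3, 0.1, 0.5),  # mmol/L
            "Hemoglobin": (125.0, 15.0, 5.0, 0.6),  # g/L
        }
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dose_step <= 0:
            raise ValueError("dose_step must be > 0")
        lo, hi = self.target_inr
        if not lo < hi:
            raise ValueError("target_inr lower bound must be < upper bound")
        if not 0.0 <= self.sex_male_frac <= 1.0:
            raise ValueError("sex_male_frac must lie in [0, 1]")
        for snp, freqs in self.genotype_freqs.items():
            if any(p < 0 or p > 1 for p in freqs.values()):
                raise ValueError(f"genotype frequencies for {snp} must lie in [0, 1]")
            if not freqs:
                raise ValueError(f"empty genotype distribution for {snp}")

    def normalized_genotype_freqs(self) -> dict[str, dict[str, float]]:
        """Genotype distributions rescaled to sum exactly to one."""
        out: dict[str, dict[str, float]] = {}
        for snp, freqs in self.genotype_freqs.items():
            total = sum(freqs.values())
            out[snp] = {g: p / total for g, p in freqs.items()}
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationParams":
        raw = json.loads(Path(path).read_text())
        raw["follow_up_days"] = tuple(raw["follow_up_days"])
        raw["target_inr"] = tuple(raw["target_inr"])
        raw["comedication_spec"] = {
            k: (v[0], tuple(v[1])) for k, v in raw["comedication_spec"].items()
        }
        raw["lab_spec"] = {k: tuple(v) for k, v in raw["lab_spec"].items()}
        return cls(**raw)


@dataclass
class PatientRecord:
    """One simulated (or imported) patient: static covariates plus day-indexed series."""

    patient_id: str
    sex: str
    surgery_type: str
    valve_type: str
    genotypes: dict[str, str]
    age: float
    height: float
    weight: float
    dose_series: dict[int, float]  # day -> mg/d, day 1 = first dosed day
    inr_series: dict[int, float]  # day -> INR
    comed_series: dict[str, dict[int, float]] = field(default_factory=dict)
    lab_series: dict[str, dict[int, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, series in [("dose_series", self.dose_series), ("inr_series", self.inr_series)]:
            days = list(series)
            if any(d < 0 for d in days):
                raise ValueError(f"{name} contains a negative day index")
            if days != sorted(days):
                raise ValueError(f"{name} day indices must be strictly increasing")
        if any(v < 0 for v in self.dose_series.values()):
            raise ValueError("doses must be >= 0")
        if self.dose_series:
            first_dose_day = min(self.dose_series)
            for d in self.inr_series:
                if d <= first_dose_day:
                    raise ValueError("every INR day needs at least one preceding dosed day")


def default_params() -> SimulationParams:
    """Parameters whose implied marginals match the emulated cohort's summary table."""
    return SimulationParams()


def _exposure_weights(halflife: float, window: int = DOSE_WINDOW) -> np.ndarray:
    """Normalized exponential look-back weights w_d, d = 1..window (most recent first)."""
    w = 2.0 ** (-(np.arange(window, dtype=float)) / halflife)
    return w / w.sum()


def _genotype_factor(genotypes: dict[str, str], params: SimulationParams) -> float:
    g = 1.0
    for snp, cat in genotypes.items():
        g *= params.genotype_multipliers.get(snp, {}).get(cat, 1.0)
    return g


def inr_response(
    dose_history: dict[int, float],
    weight: float,
    genotypes: dict[str, str],
    params: SimulationParams,
    noise_draw: float = 0.0,
) -> float:
    """INR on the morning after the last day of ``dose_history``.

    The effective exposure E is the exponentially weighted mean of the doses on
    the ``DOSE_WINDOW`` days preceding the measurement (weight halving every
    ``exposure_halflife_days``; missing days count as dose 0, so a constant
    history of d mg/d gives E = d exactly).  The response is

        INR = baseline + sensitivity_beta * G * E / weight + noise,

    floored at 0.8, with G the product of the patient's genotype multipliers.
    """
    if not dose_history:
        raise ValueError("dose_history must cover at least one day")
    if any(v < 0 for v in dose_history.values()):
        raise ValueError("negative dose in history")
    if weight <= 0:
        raise ValueError("weight must be > 0")
    t = max(dose_history) + 1  # measurement day
    w = _exposure_weights(params.exposure_halflife_days)
    exposure = sum(w[k - 1] * dose_history.get(t - k, 0.0) for k in range(1, DOSE_WINDOW + 1))
    g = _genotype_factor(genotypes, params)
    inr = params.baseline_inr + params.sensitivity_beta * g * exposure / weight + noise_draw
    return max(inr, 0.8)


def _draw_categorical(rng: np.random.Generator, probs: dict[str, float]) -> str:
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    return cats[rng.choice(len(cats), p=p / p.sum())]


def _simulate_patient(pid: str, rng: np.random.Generator, params: SimulationParams) -> PatientRecord:
    freqs = params.normalized_genotype_freqs()
    sex = "male" if rng.random() < params.sex_male_frac else "female"
    genotypes = {snp: _draw_categorical(rng, f) for snp, f in freqs.items()}
    age = float(np.clip(rng.normal(params.age_mean, params.age_sd), 18, 95))
    height = float(np.clip(rng.normal(params.height_mean, params.height_sd), 130, 200))
    weight = float(np.clip(rng.normal(params.weight_mean, params.weight_sd), 35, 120))
    surgery = _draw_categorical(rng, _SURGERY_PROBS)
    valve = _draw_categorical(rng, _VALVE_PROBS)
    follow_up = int(rng.integers(params.follow_up_days[0], params.follow_up_days[1] + 1))

    comed_doses: dict[str, float] = {}
    for drug, (prev, (lo, hi)) in params.comedication_spec.items():
        if rng.random() < prev:
            comed_doses[drug] = float(rng.uniform(lo, hi))

    lab_baseline = {
        lab: float(rng.normal(mu, sd_b)) for lab, (mu, sd_b, _, _) in params.lab_spec.items()
    }

    dose = params.dose_init
    dose_series: dict[int, float] = {}
    inr_series: dict[int, float] = {}
    lab_series: dict[str, dict[int, float]] = {lab: {} for lab in params.lab_spec}
    lo, hi = params.target_inr
    t = 1  # day 1 = first dosed day
    prev_day = 0
    first_visit = True
    while True:
        gap = max(1, int(round(rng.normal(params.visit_gap_mean, params.visit_gap_sd))))
        visit_day = max(prev_day + gap, 2)
        if visit_day > follow_up:
            break
        for d in range(t, visit_day):
            dose_series[d] = dose
        t = visit_day
        noise = float(rng.normal(0.0, params.noise_sd)) if params.noise_sd > 0 else 0.0
        inr = inr_response(dose_series, weight, genotypes, params, noise)
        inr_series[visit_day] = inr
        for lab, (_, _, sd_w, p_meas) in params.lab_spec.items():
            if first_visit or rng.random() < p_meas:
                lab_series[lab][visit_day] = lab_baseline[lab] + float(rng.normal(0.0, sd_w))
        # bang-bang titration toward the target interval
        if inr < lo:
            dose = dose + params.dose_step
        elif inr > hi:
            dose = max(dose - params.dose_step, 0.0)
        dose_series[visit_day] = dose
        prev_day = visit_day
        first_visit = False

    if not inr_series:  # very short follow-up: force one measurable visit
        dose_series = {1: dose}
        visit_day = 2
        noise = float(rng.normal(0.0, params.noise_sd)) if params.noise_sd > 0 else 0.0
        inr_series[visit_day] = inr_response(dose_series, weight, genotypes, params, noise)
        dose_series[visit_day] = dose

    comed_series = {
        drug: {d: dval for d in sorted(dose_series)} for drug, dval in comed_doses.items()
    }
    return PatientRecord(
        patient_id=pid,
        sex=sex,
        surgery_type=surgery,
        valve_type=valve,
        genotypes=genotypes,
        age=age,
        height=height,
        weight=weight,
        dose_series=dict(sorted(dose_series.items())),
        inr_series=dict(sorted(inr_series.items())),
        comed_series=comed_series,
        lab_series={k: dict(sorted(v.items())) for k, v in lab_series.items() if v},
    )


def simulate_cohort(params: SimulationParams | None = None) -> list[PatientRecord]:
    """Simulate a full cohort; deterministic given ``params.rng_seed``."""
    params = params or default_params()
    params.validate()
    rng = np.random.default_rng(params.rng_seed)
    width = max(3, len(str(params.n_patients)))
    return [
        _simulate_patient(f"P{i:0{width}d}", rng, params) for i in range(1, params.n_patients + 1)
    ]


# ---------------------------------------------------------------------------
# cohort <-> CSV
# ---------------------------------------------------------------------------

def write_cohort(records: list[PatientRecord], out_dir: str | Path,
                 params: SimulationParams | None = None) -> None:
    """Write ``patients.csv`` / ``visits.csv`` (+ params sidecar) under ``out_dir``.

    ``visits.csv`` holds one row per dosing event or INR measurement; the daily
    dose series is piecewise-constant between rows, so the full series is
    reconstructible losslessly by :func:`read_cohort`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    snps = sorted({s for r in records for s in r.genotypes})
    pat_rows = []
    for r in records:
        row = {
            "patient_id": r.patient_id,
            "sex": r.sex,
            "surgery_type": r.surgery_type,
            "valve_type": r.valve_type,
            "age": r.age,
            "height": r.height,
            "weight": r.weight,
        }
        row.update({f"genotype_{s}": r.genotypes.get(s, "") for s in snps})
        pat_rows.append(row)
    pd.DataFrame(pat_rows).to_csv(out / "patients.csv", index=False, float_format=_REPR)

    labs = sorted({lab for r in records for lab in r.lab_series})
    drugs = sorted({d for r in records for d in r.comed_series})
    visit_rows = []
    for r in records:
        days = sorted(set(r.dose_series) | set(r.inr_series))
        event_days = []
        prev_dose = None
        for d in days:
            dose = r.dose_series.get(d)
            if d in r.inr_series or dose != prev_dose:
                event_days.append(d)
            prev_dose = dose if dose is not None else prev_dose
        for d in event_days:
            row: dict[str, object] = {
                "patient_id": r.patient_id,
                "day": d,
                "dose_mg": r.dose_series.get(d, np.nan),
                "inr": r.inr_series.get(d, np.nan),
            }
            for lab in labs:
                row[f"lab_{lab}"] = r.lab_series.get(lab, {}).get(d, np.nan)
            for drug in drugs:
                row[f"comed_{drug}"] = r.comed_series.get(drug, {}).get(d, np.nan)
            visit_rows.append(row)
    pd.DataFrame(visit_rows).to_csv(out / "visits.csv", index=False, float_format=_REPR)
    if params is not None:
        params.to_json(out / "params.json")


def read_cohort(in_dir: str | Path) -> list[PatientRecord]:
    """Rebuild :class:`PatientRecord` objects from ``patients.csv``/``visits.csv``."""
    src = Path(in_dir)
    patients = pd.read_csv(src / "patients.csv", float_precision="round_trip")
    visits = pd.read_csv(src / "visits.csv", float_precision="round_trip")
    if patients.empty:
        raise ValueError(f"no patients found in {src}")
    snp_cols = [c for c in patients.columns if c.startswith("genotype_")]
    lab_cols = [c for c in visits.columns if c.startswith("lab_")]
    drug_cols = [c for c in visits.columns if c.startswith("comed_")]
    records = []
    for _, p in patients.iterrows():
        pv = visits[visits["patient_id"] == p["patient_id"]].sort_values("day")
        dose_series: dict[int, float] = {}
        inr_series: dict[int, float] = {}
        lab_series: dict[str, dict[int, float]] = {}
        comed_series: dict[str, dict[int, float]] = {}
        last_day = int(pv["day"].max()) if len(pv) else 0
        dose = np.nan
        events = {int(r["day"]): r for _, r in pv.iterrows()}
        for d in range(1, last_day + 1):
            if d in events:
                row = events[d]
                if not math.isnan(row["dose_mg"]):
                    dose = float(row["dose_mg"])
                if not math.isnan(row["inr"]):
                    inr_series[d] = float(row["inr"])
                for c in lab_cols:
                    if not math.isnan(row[c]):
                        lab_series.setdefault(c[4:], {})[d] = float(row[c])
                for c in drug_cols:
                    if not math.isnan(row[c]):
                        comed_series.setdefault(c[6:], {})[d] = float(row[c])
            if not math.isnan(dose):
                dose_series[d] = dose
        # carry comedication doses across days (piecewise-constant like doses)
        for drug, series in comed_series.items():
            carried: dict[int, float] = {}
            cur = np.nan
            for d in range(1, last_day + 1):
                if d in series:
                    cur = series[d]
                if not math.isnan(cur):
                    carried[d] = cur
            comed_series[drug] = carried
        records.append(
            PatientRecord(
                patient_id=str(p["patient_id"]),
                sex=str(p["sex"]),
                surgery_type=str(p["surgery_type"]),
                valve_type=str(p["valve_type"]),
                genotypes={c[9:]: str(p[c]) for c in snp_cols},
                age=float(p["age"]),
                height=float(p["height"]),
                weight=float(p["weight"]),
                dose_series=dose_series,
                inr_series=inr_series,
                comed_series=comed_series,
                lab_series=lab_series,
            )
        )
    return records
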