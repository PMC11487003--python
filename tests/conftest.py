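import numpy as np
import pandas as pd
import pytest

import warfptml as w
from warfptml import evaluation as ev
from warfptml import fusion
from warfptml import pt_operators as pt


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort (one simulation shared across the session)."""
    params = w.default_params()
    return params, w.simulate_cohort(params)


@pytest.fixture(scope="session")
def scheme():
    return w.default_scheme()


@pytest.fixture(scope="session")
def case_table(default_cohort, scheme):
    _, records = default_cohort
    return w.build_case_table(records, scheme)


@pytest.fixture(scope="session")
def split_tables(case_table, scheme):
    train, val = ev.split_train_validation(case_table, 0.75, "case", seed=7)
    train = w.impute_missing(train, scheme)
    ref = train[scheme.continuous_vars].mean()
    val = w.impute_missing(val, scheme, reference_means=ref)
    return train, val


@pytest.fixture(scope="session")
def small_cohort():
    """30-patient cohort for oracle-equivalence and cheap end-to-end checks."""
    params = w.SimulationParams(n_patients=30, rng_seed=11)
    return params, w.simulate_cohort(params)


@pytest.fixture(scope="session")
def small_table(small_cohort, scheme):
    _, records = small_cohort
    table = w.build_case_table(records, scheme)
    return w.impute_missing(table, scheme)


def make_record(
    pid="P001",
    doses=None,
    inr_days=(10,),
    sex="male",
    genotypes=None,
    weight=64.0,
    **kwargs,
):
    """Hand-built patient: constant or explicit dose series, INRs at given days."""
    if doses is None:
        doses = {d: 2.5 for d in range(1, max(inr_days))}
    inr = {d: kwargs.pop("inr_value", 2.0) for d in inr_days}
    return w.PatientRecord(
        patient_id=pid,
        sex=sex,
        surgery_type=kwargs.pop("surgery_type", "MVR"),
        valve_type=kwargs.pop("valve_type", "mechanical"),
        genotypes=genotypes or {"CYP2C9": "*1/*1", "VKORC1": "AA"},
        age=kwargs.pop("age", 58.0),
        height=kwargs.pop("height", 165.0),
        weight=weight,
        dose_series=dict(sorted(doses.items())),
        inr_series=dict(sorted(inr.items())),
        comed_series=kwargs.pop("comed_series", {}),
        lab_series=kwargs.pop("lab_series", {}),
    )


@pytest.fixture()
def tiny_scheme():
    """Two partitions, two small variable groups over four variables."""
    return fusion.PartitionScheme(
        name="tiny",
        partitions={"TypeCat": "surgery_type", "PKGeneCat": "genotype_CYP2C9"},
        variable_groups={"g1": ["x1", "x2"], "g2": ["x3", "x4"]},
        continuous_vars=["x1", "x2", "x3", "x4"],
        target_interval=(1.8, 2.5),
    )


@pytest.fixture()
def tiny_table(tiny_scheme):
    """Deterministic 8-case table over the tiny scheme."""
    rng = np.random.default_rng(5)
    n = 8
    return pd.DataFrame(
        {
            "case_id": [f"c{i}" for i in range(n)],
            "patient_id": [f"p{i//2}" for i in range(n)],
            "visit_day": [3 + i for i in range(n)],
            "inr": rng.uniform(1.2, 3.2, n).round(2),
            "output_class": None,
            "surgery_type": ["MVR", "AVR"] * 4,
            "genotype_CYP2C9": ["*1/*1"] * 6 + ["*1/*3"] * 2,
            "x1": rng.normal(2, 1, n),
            "x2": rng.normal(0, 1, n),
            "x3": rng.normal(5, 2, n),
            "x4": rng.normal(-1, 1, n),
        }
    ).assign(
        output_class=lambda t: [fusion.label_output(v) for v in t["inr"]]
    )


@pytest.fixture(scope="session")
def ma_pipeline(split_tables, scheme):
    """Fitted ma-level transform shared by model/evaluation tests."""
    train, val = split_tables
    cfg = pt.PTConfig.preset("ma")
    means = pt.fit_group_means(train, scheme)
    f_train = pt.build_features(train, means, train, cfg, scheme)
    f_val = pt.build_features(val, means, train, cfg, scheme)
    return {"cfg": cfg, "means": means, "train": train, "val": val,
            "f_train": f_train, "f_val": f_val}
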