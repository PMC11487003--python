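"""Perturbation-theory operators over the fused case table.

The central idea: instead of feeding raw clinical variables to a model, each
continuous variable v_k is *centered against the expectation of its peer
group* — the mean of v_k over training cases sharing a categorical label
(a partition such as surgery type or a pharmacogene genotype).  The first-order
operator is the deviation

    Delta v_k(P) = v_k - alpha * <v_k | label of the case in partition P>,

and the second-order operator collapses a whole variable group g into one
non-negative magnitude

    || Delta g(P) || = ( sum_{k in g} Delta_k^q )^r,

the Euclidean norm of the group's deviation vector when q=2, r=1/2.  A scalar
reference function f_ref — the training prevalence of the desired outcome in
the case's label cell — completes the feature set.  Three preset data levels
are exposed: ``raw`` (alpha=0, q=1, r=1: identity), ``ma`` (alpha=1, q=1, r=1:
all per-partition deviations) and ``ed`` (alpha=1, q=2, r=1/2: per-group
distances).

Group means are always fitted on the training table only and frozen; applying
them to validation or prediction rows never re-estimates anything (leakage
contract).  Labels unseen in training back off to the global mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .fusion import WITHIN, PartitionScheme

__all__ = [
    "PTConfig",
    "GroupMeanTable",
    "fit_group_means",
    "first_order",
    "second_order",
    "reference_function",
    "build_features",
    "delta_name",
    "ed_name",
    "F_REF",
    "PRESETS",
]

F_REF = "f_ref"

#: the three published data levels: (alpha, q, r)
PRESETS: dict[str, tuple[float, float, float]] = {
    "raw": (0.0, 1.0, 1.0),
    "ma": (1.0, 1.0, 1.0),
    "ed": (1.0, 2.0, 0.5),
}


def delta_name(var: str, partition: str) -> str:
    return f"Δ{var}({partition})"


def ed_name(group: str, partition: str) -> str:
    return f"ǁΔ{group}({partition})ǁ"


@dataclass
class PTConfig:
    """Hyperparameters of the operator: alpha switches centering on/off, q is the
    moment power, r the distance power."""

    alpha: float = 1.0
    q: float = 1.0
    r: float = 1.0
    level: str | None = None
    min_group_size: int = 1  # back-off threshold for group means
    f_ref_mode: str = "joint"  # {global, joint, partition}
    f_ref_partition: str | None = None
    f_ref_min_group: int = 10

    def __post_init__(self) -> None:
        if self.level is not None:
            if self.level not in PRESETS:
                raise ValueError(f"unknown preset {self.level!r}")
            if (self.alpha, self.q, self.r) != PRESETS[self.level]:
                raise ValueError(
                    f"preset {self.level!r} implies (alpha,q,r)={PRESETS[self.level]}, "
                    f"got ({self.alpha}, {self.q}, {self.r})"
                )
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.q <= 0 or self.r <= 0:
            raise ValueError("q and r must be positive")
        if self.f_ref_mode not in {"global", "joint", "partition"}:
            raise ValueError(f"unknown f_ref_mode {self.f_ref_mode!r}")

    @classmethod
    def preset(cls, level: str, **kwargs) -> "PTConfig":
        alpha, q, r = PRESETS[level]
        return cls(alpha=alpha, q=q, r=r, level=level, **kwargs)


@dataclass
class GroupMeanTable:
    """Frozen training-set moving averages <v_k | partition label>.

    ``means[partition]`` is a label-indexed frame of per-variable means,
    ``sizes[partition]`` the member count behind each label, and
    ``global_means`` the unconditional training means used for back-off.
    """

    means: dict[str, pd.DataFrame]
    sizes: dict[str, pd.Series]
    global_means: pd.Series
    fitted_on: int
    scheme_name: str

    def group_mean(self, partition: str, label: str, var: str,
                   min_group_size: int = 1) -> float:
        """Mean of ``var`` in the (partition, label) cell, backing off globally."""
        frame = self.means.get(partition)
        if frame is None:
            raise KeyError(f"partition {partition!r} not fitted")
        if var not in self.global_means.index:
            raise KeyError(f"variable {var!r} not fitted")
        if label in frame.index and self.sizes[partition][label] >= min_group_size:
            return float(frame.loc[label, var])
        return float(self.global_means[var])

    def to_json(self, path: str | Path) -> None:
        payload = {
            "fitted_on": self.fitted_on,
            "scheme_name": self.scheme_name,
            "global_means": {k: repr(float(v)) for k, v in self.global_means.items()},
            "means": {
                p: {str(lab): {v: repr(float(frame.loc[lab, v])) for v in frame.columns}
                    for lab in frame.index}
                for p, frame in self.means.items()
            },
            "sizes": {p: {str(lab): int(n) for lab, n in s.items()}
                      for p, s in self.sizes.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroupMeanTable":
        raw = json.loads(Path(path).read_text())
        means = {
            p: pd.DataFrame(
                {lab: {v: float(x) for v, x in row.items()} for lab, row in frame.items()}
            ).T
            for p, frame in raw["means"].items()
        }
        sizes = {p: pd.Series({lab: int(n) for lab, n in s.items()}, dtype=int)
                 for p, s in raw["sizes"].items()}
        return cls(
            means=means,
            sizes=sizes,
            global_means=pd.Series({k: float(v) for k, v in raw["global_means"].items()}),
            fitted_on=int(raw["fitted_on"]),
            scheme_name=raw["scheme_name"],
        )


def fit_group_means(train: pd.DataFrame, scheme: PartitionScheme) -> GroupMeanTable:
    """Per-(partition, label) training means of every registered variable."""
    if train.empty:
        raise ValueError("training table is empty")
    variables = [v for v in scheme.continuous_vars if v in train.columns]
    missing = set(scheme.continuous_vars) - set(variables)
    if missing:
        raise KeyError(f"continuous variables absent from table: {sorted(missing)}")
    means: dict[str, pd.DataFrame] = {}
    sizes: dict[str, pd.Series] = {}
    for pname, col in scheme.partitions.items():
        if col not in train.columns:
            raise KeyError(f"label column {col!r} for partition {pname!r} absent")
        grouped = train.groupby(col, observed=True)
        means[pname] = grouped[variables].mean()
        sizes[pname] = grouped.size()
    return GroupMeanTable(
        means=means,
        sizes=sizes,
        global_means=train[variables].mean(),
        fitted_on=len(train),
        scheme_name=scheme.name,
    )


def first_order(
    case: pd.Series | dict,
    means: GroupMeanTable,
    cfg: PTConfig,
    scheme: PartitionScheme,
) -> dict[str, float]:
    """Per-partition deviations Delta var(P) for one case (alpha=0: raw values)."""
    case = pd.Series(case)
    out: dict[str, float] = {}
    for pname, col in scheme.partitions.items():
        label = case[col]
        for var in scheme.continuous_vars:
            if var not in case.index:
                raise KeyError(f"variable {var!r} missing from case")
            centre = means.group_mean(pname, label, var, cfg.min_group_size)
            out[delta_name(var, pname)] = float(case[var]) - cfg.alpha * centre
    return out


def second_order(
    deltas: dict[str, float] | pd.Series,
    group: list[str],
    cfg: PTConfig,
) -> float:
    """Collapse a group's deviations to (sum_k delta_k^q)^r."""
    if not group:
        raise ValueError("empty variable group")
    deltas = pd.Series(deltas)
    missing = [g for g in group if g not in deltas.index]
    if missing:
        raise KeyError(f"deltas missing for {missing}")
    vals = deltas[group].to_numpy(dtype=float)
    return float(np.sum(vals**cfg.q) ** cfg.r)


def _prevalence(labels: pd.Series) -> float:
    return float((labels == WITHIN).mean())


def _f_ref_table(
    train: pd.DataFrame, table: pd.DataFrame, cfg: PTConfig, scheme: PartitionScheme
) -> pd.Series:
    """Vectorized reference function for every row of ``table``."""
    if train.empty:
        raise ValueError("no training rows to estimate the reference function")
    global_prev = _prevalence(train["output_class"])
    if cfg.f_ref_mode == "global":
        return pd.Series(global_prev, index=table.index, name=F_REF)
    if cfg.f_ref_mode == "partition":
        pname = cfg.f_ref_partition or next(iter(scheme.partitions))
        cols = [scheme.partitions[pname]]
    else:  # joint over the full label vector
        cols = scheme.label_columns
    grouped = train.groupby(cols, observed=True)["output_class"]
    prev = grouped.apply(_prevalence)
    count = grouped.size()
    keep = count[count >= cfg.f_ref_min_group].index
    prev = prev[prev.index.isin(keep)]
    key = pd.MultiIndex.from_frame(table[cols]) if len(cols) > 1 else pd.Index(table[cols[0]])
    mapped = prev.reindex(key).to_numpy()
    out = pd.Series(mapped, index=table.index, name=F_REF)
    return out.fillna(global_prev)


def reference_function(
    train: pd.DataFrame,
    case: pd.Series | dict,
    cfg: PTConfig,
    scheme: PartitionScheme,
) -> float:
    """Prior probability of the desired outcome for one case's label cell."""
    row = pd.DataFrame([pd.Series(case)])
    return float(_f_ref_table(train, row, cfg, scheme).iloc[0])


def _delta_frames(
    table: pd.DataFrame,
    means: GroupMeanTable,
    cfg: PTConfig,
    scheme: PartitionScheme,
) -> dict[str, pd.DataFrame]:
    """Per-partition frames of deviations, back-off applied row-wise."""
    variables = [v for v in scheme.continuous_vars]
    values = table[variables].astype(float)
    frames: dict[str, pd.DataFrame] = {}
    for pname, col in scheme.partitions.items():
        mtab = means.means[pname]
        sizes = means.sizes[pname]
        ok_labels = sizes[sizes >= cfg.min_group_size].index
        centre = mtab.reindex(table[col]).reset_index(drop=True)
        centre.index = table.index
        small = ~table[col].isin(ok_labels)
        if small.any():
            centre.loc[small, :] = np.nan
        centre = centre.fillna(means.global_means)
        frames[pname] = values - cfg.alpha * centre[variables]
    return frames


def build_features(
    table: pd.DataFrame,
    means: GroupMeanTable,
    train: pd.DataFrame,
    cfg: PTConfig,
    scheme: PartitionScheme,
) -> pd.DataFrame:
    """Assemble the model-ready feature table for one data level.

    ``raw``: the registered continuous variables unchanged.  ``ma``: one
    deviation column per (partition x variable), partition-major.  ``ed``: one
    distance column per (partition x variable group).  All levels carry the
    ``f_ref`` column (raw-level models simply give it a zero weight).  The
    result is indexed like ``table`` and carries provenance in ``attrs``.
    """
    if cfg.level not in PRESETS:
        raise ValueError("build_features requires a preset PTConfig (raw/ma/ed)")
    if means.scheme_name != scheme.name:
        raise ValueError(
            f"group means fitted on scheme {means.scheme_name!r}, got {scheme.name!r}"
        )
    fref = _f_ref_table(train, table, cfg, scheme)
    if cfg.level == "raw":
        feats = table[list(scheme.continuous_vars)].astype(float).copy()
    elif cfg.level == "ma":
        frames = _delta_frames(table, means, cfg, scheme)
        cols = {
            delta_name(var, pname): frames[pname][var]
            for pname in scheme.partitions
            for var in scheme.continuous_vars
        }
        feats = pd.DataFrame(cols, index=table.index)
    else:  # ed
        frames = _delta_frames(table, means, cfg, scheme)
        cols = {}
        for pname in scheme.partitions:
            deltas = frames[pname]
            for gname, members in scheme.variable_groups.items():
                vals = deltas[members].to_numpy()
                cols[ed_name(gname, pname)] = np.sum(vals**cfg.q, axis=1) ** cfg.r
        feats = pd.DataFrame(cols, index=table.index)
    feats.insert(0, F_REF, fref)
    if feats.columns.duplicated().any():
        raise ValueError("feature column namespace collision")
    feats.attrs["level"] = cfg.level
    feats.attrs["scheme"] = scheme.name
    feats.attrs["fitted_on"] = means.fitted_on
    return feats


def write_features(feats: pd.DataFrame, path: str | Path) -> None:
    """CSV with a provenance comment header."""
    path = Path(path)
    header = (
        f"# warfptml features level={feats.attrs.get('level', '?')} "
        f"scheme={feats.attrs.get('scheme', '?')} fitted_on={feats.attrs.get('fitted_on', '?')}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        feats.to_csv(fh, index=False)
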