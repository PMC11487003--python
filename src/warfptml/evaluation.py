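"""Evaluation protocol: splits, univariate screening, regression/classification
metrics and predicted-bias bins.

Regression fits are summarised by the Pearson correlation between observed and
predicted INR, the mean absolute error, the root mean squared error, and the
two relative errors (RAE, RRSE, in %) that normalise against a mean-only
predictor on the same evaluation set.  Predicted bias PB = 100*(pred-obs)/obs
is binned into <-20%, [-20%, 20%] ("ideal") and >20%.  Classification is
summarised per class (TPR, FPR, precision, recall, F-measure, ROC area) plus
overall accuracy, sensitivity/specificity of the target-range class, and the
chi-squared of the 2x2 confusion table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fusion import OUT, WITHIN, PartitionScheme

__all__ = [
    "MetricsReport",
    "split_train_validation",
    "regression_metrics",
    "predicted_bias",
    "pb_bins",
    "classification_metrics",
    "univariate_screen",
]

PB_IDEAL = 20.0  # |PB| <= 20% counts as an ideal prediction


@dataclass
class MetricsReport:
    """Container mirroring the tabular evaluation layout (one set x level x algorithm)."""

    set_tag: str  # {training, validation}
    level: str = "raw"
    algorithm: str = ""
    regression: dict | None = None
    pb: dict | None = None
    classification: dict | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "set": self.set_tag,
            "level": self.level,
            "algorithm": self.algorithm,
            "regression": self.regression,
            "pb": self.pb,
            "classification": self.classification,
            **self.extras,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=float))

    def to_row(self) -> pd.Series:
        flat: dict[str, object] = {
            "set": self.set_tag, "level": self.level, "algorithm": self.algorithm,
        }
        for block in (self.regression, self.pb):
            if block:
                flat.update(block)
        if self.classification:
            for cls, vals in self.classification.get("per_class", {}).items():
                flat.update({f"{cls}_{k}": v for k, v in vals.items()})
            flat.update(self.classification.get("overall", {}))
        return pd.Series(flat)


def split_train_validation(
    table: pd.DataFrame,
    fraction: float = 0.75,
    mode: str = "case",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/validation split; deterministic per seed.

    ``case`` mode draws rows uniformly (train size = round(fraction * N));
    ``patient`` mode assigns whole patients to one side, which is the
    conservative choice for longitudinal data since case-level splitting lets
    a patient's other visits inform their validation rows.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    n = len(table)
    rng = np.random.default_rng(seed)
    if mode == "case":
        n_train = round(fraction * n)
        if n_train in (0, n):
            raise ValueError("split would leave one side empty")
        perm = rng.permutation(n)
        train_idx = np.sort(perm[:n_train])
        val_idx = np.sort(perm[n_train:])
        return table.iloc[train_idx].copy(), table.iloc[val_idx].copy()
    if mode == "patient":
        patients = table["patient_id"].drop_duplicates().to_numpy()
        order = rng.permutation(len(patients))
        counts = table["patient_id"].value_counts()
        target = fraction * n
        train_pat, total = [], 0
        for i in order:
            pid = patients[i]
            if total < target:
                train_pat.append(pid)
                total += int(counts[pid])
        train_mask = table["patient_id"].isin(train_pat)
        if train_mask.all() or not train_mask.any():
            raise ValueError("split would leave one side empty")
        return table[train_mask].copy(), table[~train_mask].copy()
    raise ValueError(f"unknown split mode {mode!r}")


def regression_metrics(obs, pred) -> dict[str, float]:
    """corr / MAE / RMSE / RAE(%) / RRSE(%) of predicted vs observed values."""
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if o.shape != p.shape:
        raise ValueError("obs and pred must have equal length")
    if o.size < 2:
        raise ValueError("need at least 2 observations")
    centred = o - o.mean()
    if np.allclose(centred, 0.0):
        raise ValueError("constant observations: correlation, RAE and RRSE undefined")
    e = p - o
    mae = float(np.mean(np.abs(e)))
    rmse = float(np.sqrt(np.mean(e**2)))
    if np.allclose(p - p.mean(), 0.0):
        corr = float("nan")  # constant predictions carry no linear association
    else:
        corr = float(stats.pearsonr(o, p)[0])
    rae = float(100.0 * np.sum(np.abs(e)) / np.sum(np.abs(centred)))
    rrse = float(100.0 * np.sqrt(np.sum(e**2) / np.sum(centred**2)))
    return {"corr": corr, "mae": mae, "rmse": rmse, "rae": rae, "rrse": rrse}


def predicted_bias(obs, pred):
    """PB(%) = 100 * (pred - obs) / obs, elementwise."""
    o = np.asarray(obs, dtype=float)
    p = np.asarray(pred, dtype=float)
    if np.any(o <= 0):
        raise ValueError("observed values must be positive for predicted bias")
    pb = 100.0 * (p - o) / o
    return float(pb) if pb.ndim == 0 else pb


def pb_bins(obs, pred) -> dict[str, float]:
    """Percent of cases with PB < -20, within [-20, 20] (ideal), and > 20."""
    pb = np.atleast_1d(predicted_bias(obs, pred))
    n = pb.size
    low = float(100.0 * np.sum(pb < -PB_IDEAL) / n)
    mid = float(100.0 * np.sum((pb >= -PB_IDEAL) & (pb <= PB_IDEAL)) / n)
    high = float(100.0 * np.sum(pb > PB_IDEAL) / n)
    return {"pb_low": low, "pb_ideal": mid, "pb_high": high}


def classification_metrics(obs_labels, pred_labels, scores=None) -> dict:
    """Per-class and overall Within/Out classification metrics.

    ``scores`` (higher = more Within-like), when given, adds the ROC area
    per class; Sn/Sp are the TPR/TNR of the Within class; the chi-squared is
    that of the 2x2 confusion table, 1 df, no continuity correction.
    """
    y = pd.Series(obs_labels).reset_index(drop=True)
    yhat = pd.Series(pred_labels).reset_index(drop=True)
    bad = set(y.unique()) | set(yhat.unique())
    if not bad <= {WITHIN, OUT}:
        raise ValueError(f"labels outside {{{WITHIN!r}, {OUT!r}}}: {sorted(bad - {WITHIN, OUT})}")
    if y.nunique() < 2:
        raise ValueError("need both classes among the observed labels")
    per_class: dict[str, dict[str, float]] = {}
    for cls in (OUT, WITHIN):
        tp = int(((y == cls) & (yhat == cls)).sum())
        fn = int(((y == cls) & (yhat != cls)).sum())
        fp = int(((y != cls) & (yhat == cls)).sum())
        tn = int(((y != cls) & (yhat != cls)).sum())
        tpr = tp / (tp + fn) if tp + fn else float("nan")
        fpr = fp / (fp + tn) if fp + tn else float("nan")
        prec = tp / (tp + fp) if tp + fp else 0.0
        f1 = 2 * prec * tpr / (prec + tpr) if prec + tpr else 0.0
        entry = {"tpr": tpr, "fpr": fpr, "precision": prec, "recall": tpr, "f_measure": f1}
        if scores is not None:
            from sklearn.metrics import roc_auc_score

            s = np.asarray(scores, dtype=float)
            entry["roc"] = float(
                roc_auc_score((y == cls).astype(int), s if cls == WITHIN else -s)
            )
        per_class[cls] = entry
    accuracy = float(100.0 * (y == yhat).mean())
    confusion = pd.crosstab(y, yhat).reindex(
        index=[OUT, WITHIN], columns=[OUT, WITHIN], fill_value=0
    )
    if (confusion.to_numpy().sum(axis=0) > 0).all():
        chi2, p_val = stats.chi2_contingency(confusion, correction=False)[:2]
    else:  # degenerate: everything predicted as one class
        chi2, p_val = float("nan"), float("nan")
    overall = {
        "accuracy": accuracy,
        "sn": 100.0 * per_class[WITHIN]["tpr"],
        "sp": 100.0 * (1.0 - per_class[WITHIN]["fpr"]),
        "chi2": float(chi2),
        "p_value": float(p_val),
    }
    return {"per_class": per_class, "overall": overall}


def univariate_screen(
    table: pd.DataFrame,
    scheme: PartitionScheme,
    alpha: float = 0.05,
    extra_continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Variable-by-variable association screen against both outputs.

    Continuous inputs: Pearson r against the observed INR and a Wilcoxon
    rank-sum test against the Within/Out class.  Categorical inputs:
    Mann-Whitney (2 levels) or Kruskal-Wallis (>2) against the INR and a
    chi-squared test against the class.  The report is advisory — nothing is
    dropped automatically, and degenerate (single-valued) variables are
    flagged untested.
    """
    rows = []
    inr = table["inr"].to_numpy(dtype=float)
    cls = table["output_class"]
    cont = [v for v in scheme.continuous_vars if v in table.columns]
    cont += [v for v in (extra_continuous or []) if v in table.columns]
    for var in cont:
        x = table[var].to_numpy(dtype=float)
        if len(np.unique(x[~np.isnan(x)])) < 2:
            rows.append({"variable": var, "kind": "continuous", "test": None,
                         "statistic": np.nan, "p": np.nan, "significant": False,
                         "degenerate": True})
            continue
        r, p_cont = stats.pearsonr(x, inr)
        stat_cat, p_cat = stats.ranksums(x[cls == WITHIN], x[cls == OUT])
        rows.append({"variable": var, "kind": "continuous", "test": "pearson",
                     "statistic": float(r), "p": float(p_cont),
                     "significant": bool(p_cont < alpha), "degenerate": False})
        rows.append({"variable": var, "kind": "continuous", "test": "ranksum_vs_class",
                     "statistic": float(stat_cat), "p": float(p_cat),
                     "significant": bool(p_cat < alpha), "degenerate": False})
    for pname, col in scheme.partitions.items():
        if col not in table.columns:
            continue
        levels = [g.to_numpy(dtype=float) for _, g in pd.Series(inr).groupby(table[col])]
        if len(levels) < 2:
            rows.append({"variable": col, "kind": "categorical", "test": None,
                         "statistic": np.nan, "p": np.nan, "significant": False,
                         "degenerate": True})
            continue
        if len(levels) == 2:
            stat, p_val = stats.mannwhitneyu(levels[0], levels[1], alternative="two-sided")
            test = "mannwhitney"
        else:
            stat, p_val = stats.kruskal(*levels)
            test = "kruskal"
        rows.append({"variable": col, "kind": "categorical", "test": test,
                     "statistic": float(stat), "p": float(p_val),
                     "significant": bool(p_val < alpha), "degenerate": False})
        contingency = pd.crosstab(table[col], cls)
        chi2, p_chi = stats.chi2_contingency(contingency)[:2]
        rows.append({"variable": col, "kind": "categorical", "test": "chi2_vs_class",
                     "statistic": float(chi2), "p": float(p_chi),
                     "significant": bool(p_chi < alpha), "degenerate": False})
    return pd.DataFrame(rows)
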