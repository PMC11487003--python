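"""Model layer: linear discriminant scoring, stepwise selection, ML battery.

The linear classification model is a discriminant score

    f_calc = a_0 + a_1 * f_ref + sum_k a_k * feature_k,

with ``score > 0`` read as the *Within* (target-range) class.  Three published
fitted instances of this score — one per data level (raw variables, first-order
deviations, second-order distances) — are shipped verbatim as builtin models so
their predictions are reproducible without any training data.

``fit_lda`` trains a fresh two-class linear discriminant (pooled within-class
covariance, closed form, light ridge against near-singularity).
``forward_stepwise`` adds features greedily by partial-F with an always-included
expert set.  ``fit_ml`` adapts the standard scikit-learn battery (logistic,
naive Bayes, MLP, SVM, KNN, bagging, random forest, linear regression) behind
one uniform predict surface for both the regression task (predict the INR) and
the classification task (predict Within/Out).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .fusion import OUT, WITHIN
from .pt_operators import F_REF, delta_name, ed_name

__all__ = [
    "LinearModel",
    "ModelSpec",
    "ScoreCalibration",
    "builtin_model",
    "score_linear",
    "posterior_probability",
    "fit_lda",
    "forward_stepwise",
    "fit_ml",
    "BUILTIN_MODELS",
]


@dataclass
class LinearModel:
    """Linear discriminant scorer: intercept + ref coefficient + named terms."""

    intercept: float
    ref_coef: float = 0.0
    terms: dict[str, float] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = [self.intercept, self.ref_coef, *self.terms.values()]
        if not np.all(np.isfinite(values)):
            raise ValueError("model coefficients must be finite")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "intercept": self.intercept,
            "ref_coef": self.ref_coef,
            "terms": self.terms,
            "metadata": self.metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearModel":
        raw = json.loads(Path(path).read_text())
        return cls(
            intercept=float(raw["intercept"]),
            ref_coef=float(raw["ref_coef"]),
            terms={k: float(v) for k, v in raw["terms"].items()},
            metadata=raw.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# builtin (published) fitted models, coefficients verbatim
# ---------------------------------------------------------------------------

_EQ2 = LinearModel(
    intercept=-1.6772,
    ref_coef=0.0,
    terms={
        "Dose03": 0.1204,  # warfarin dose 3 days before the INR
        "POD": 0.0112,  # post-operative days
        "Cefoperazone": 0.1188,
        "Ceftriaxone": 0.9305,
        "Ticarcillin": 0.1086,
        "Tigecycline": 12.84,
        "Spironolactone": 9.82,
        "Neutrophil": -0.0644,
        "Plateletcrit": 2.264,
        "Human_albumin": -0.019,
    },
    metadata={"level": "raw", "n_train": 2446, "chi2": 222.839, "source": "published fit"},
)

_EQ3 = LinearModel(
    intercept=17.04,
    ref_coef=-34.04,
    terms={
        delta_name("Dose01", "TypeCat"): 0.6244,
        delta_name("CEFUSROV", "TypeCat"): -1.137,  # cefuroxime sodium
        delta_name("Dose01", "PKGeneCat"): -0.5472,
        delta_name("Bifidobacterium", "PKGeneCat"): -6.191,
        delta_name("HALB", "VKPKGeneCat"): -0.162,  # human albumin
        delta_name("CEFUSROV", "NRGeneCat"): 0.8073,
        delta_name("HDCL", "NRGeneCat"): -1.585,  # high-density cholesterol
        delta_name("Dose03", "ClotGeneCat"): 0.3398,
        delta_name("PDW", "ClotGeneCat"): -0.2648,  # platelet distribution width
    },
    metadata={"level": "ma", "n_train": 2446, "chi2": 2919.95, "source": "published fit"},
)

_EQ4 = LinearModel(
    intercept=17.81,
    ref_coef=-34.83,
    terms={
        ed_name("Dose", "TypeCat"): 0.115,
        ed_name("MWDiuretic", "TypeCat"): -0.1031,
        ed_name("MWDiuretic", "PKGeneCat"): -0.1314,
        ed_name("LOGDAspirin", "PKGeneCat"): 10.93,
        ed_name("LOGDDiclofenac", "PKGeneCat"): 40.92,
        ed_name("Blood_cell_count", "PKGeneCat"): -0.0104,
        ed_name("DEMO", "PDGeneCat"): -0.069,
        ed_name("DEMO", "VKPKGeneCat"): 0.0302,
        ed_name("Probiotics", "VKPKGeneCat"): -0.6514,
    },
    metadata={"level": "ed", "n_train": 2446, "chi2": 2952.951, "source": "published fit"},
)

BUILTIN_MODELS: dict[str, LinearModel] = {"eq2_raw": _EQ2, "eq3_ma": _EQ3, "eq4_ed": _EQ4}


def builtin_model(name: str) -> LinearModel:
    """Return one of the published fitted discriminant models by name."""
    try:
        src = BUILTIN_MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin model {name!r}; choose from {sorted(BUILTIN_MODELS)}"
        ) from None
    return LinearModel(src.intercept, src.ref_coef, dict(src.terms), dict(src.metadata))


def score_linear(model: LinearModel, features: pd.DataFrame | pd.Series | dict):
    """Evaluate the discriminant score; missing terms are an error, never 0."""
    single = not isinstance(features, pd.DataFrame)
    frame = pd.DataFrame([pd.Series(features)]) if single else features
    missing = [t for t in model.terms if t not in frame.columns]
    if model.ref_coef != 0.0 and F_REF not in frame.columns:
        missing.append(F_REF)
    if missing:
        raise KeyError(f"features missing for model terms: {missing}")
    score = np.full(len(frame), model.intercept, dtype=float)
    if model.ref_coef != 0.0:
        score += model.ref_coef * frame[F_REF].to_numpy(dtype=float)
    for term, coef in model.terms.items():
        score += coef * frame[term].to_numpy(dtype=float)
    return float(score[0]) if single else pd.Series(score, index=frame.index, name="score")


def classify_score(score, threshold: float = 0.0):
    """Score above the threshold -> Within, else Out."""
    if np.isscalar(score):
        return WITHIN if score > threshold else OUT
    arr = np.asarray(score)
    out = np.where(arr > threshold, WITHIN, OUT)
    if isinstance(score, pd.Series):
        return pd.Series(out, index=score.index, name="predicted_class")
    return out


@dataclass
class ScoreCalibration:
    """Monotone logistic map from discriminant score to P(Within)."""

    slope: float | None = None
    midpoint: float | None = None

    def fit(self, scores, labels) -> "ScoreCalibration":
        from sklearn.linear_model import LogisticRegression

        y = (pd.Series(labels).to_numpy() == WITHIN).astype(int)
        if y.min() == y.max():
            raise ValueError("calibration needs both classes present")
        x = np.asarray(scores, dtype=float).reshape(-1, 1)
        lr = LogisticRegression(C=1e6).fit(x, y)
        self.slope = float(lr.coef_[0, 0])
        self.midpoint = float(-lr.intercept_[0] / lr.coef_[0, 0])
        return self

    def __call__(self, score):
        return posterior_probability(score, self)


def posterior_probability(score, calibration: ScoreCalibration):
    """P(Within | score) under a fitted logistic calibration."""
    if calibration.slope is None or calibration.midpoint is None:
        raise ValueError("calibration has not been fitted")
    arr = np.asarray(score, dtype=float)
    p = 1.0 / (1.0 + np.exp(-calibration.slope * (arr - calibration.midpoint)))
    return float(p) if np.isscalar(score) or arr.ndim == 0 else p


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def fit_lda(
    features: pd.DataFrame,
    labels,
    ridge_scale: float = 1e-6,
    positive: str = WITHIN,
) -> LinearModel:
    """Two-class linear discriminant with pooled within-class covariance.

    Constant features are dropped with a warning; of exactly duplicated columns
    one is retained.  A ridge of ``ridge_scale * mean(diag(S_w))`` guards the
    pooled covariance against near-singularity.  The fitted score's sign
    convention puts the ``positive`` class above zero.
    """
    y = pd.Series(labels).reset_index(drop=True)
    classes = sorted(y.unique())
    if len(classes) != 2:
        raise ValueError(f"fit_lda needs exactly 2 classes, got {classes}")
    X = features.reset_index(drop=True).astype(float)
    if len(X) <= X.shape[1] + 1:
        raise ValueError("need more cases than selected features")

    const = X.columns[X.nunique() <= 1]
    if len(const):
        warnings.warn(f"dropping constant features: {list(const)}", stacklevel=2)
        X = X.drop(columns=const)
    dup = X.T.duplicated()
    if dup.any():
        warnings.warn(f"dropping duplicated features: {list(X.columns[dup])}", stacklevel=2)
        X = X.loc[:, ~dup]
    if X.shape[1] == 0:
        raise ValueError("no usable features remain")

    neg = [c for c in classes if c != positive][0]
    Xp = X[y == positive].to_numpy()
    Xn = X[y == neg].to_numpy()
    mu_p, mu_n = Xp.mean(axis=0), Xn.mean(axis=0)
    n_p, n_n = len(Xp), len(Xn)
    sw = (np.cov(Xp, rowvar=False, ddof=1) * (n_p - 1)
          + np.cov(Xn, rowvar=False, ddof=1) * (n_n - 1)) / (n_p + n_n - 2)
    sw = np.atleast_2d(sw)
    lam = ridge_scale * float(np.mean(np.diag(sw)))
    sw = sw + lam * np.eye(sw.shape[0])
    w = np.linalg.solve(sw, mu_p - mu_n)
    a0 = float(-w @ (mu_p + mu_n) / 2.0 + np.log(n_p / n_n))

    terms = dict(zip(X.columns, map(float, w)))
    ref_coef = terms.pop(F_REF, 0.0)
    model = LinearModel(intercept=a0, ref_coef=ref_coef, terms=terms)
    score = score_linear(model, X)
    pred = classify_score(score)
    confusion = pd.crosstab(y, pd.Series(pred.to_numpy(), index=y.index))
    chi2 = float(stats.chi2_contingency(confusion, correction=False)[0]) \
        if confusion.shape == (2, 2) else float("nan")
    model.metadata.update(
        {
            "n_train": int(len(X)),
            "chi2": chi2,
            "training_accuracy": float((pred.to_numpy() == y.to_numpy()).mean()),
            "dropped_constant": list(const),
            "positive_class": positive,
        }
    )
    return model


# ---------------------------------------------------------------------------
# forward stepwise selection
# ---------------------------------------------------------------------------

def forward_stepwise(
    features: pd.DataFrame,
    labels,
    expert_set: tuple[str, ...] = (),
    p_enter: float = 0.05,
    max_steps: int | None = None,
) -> list[str]:
    """Greedy partial-F forward selection with a forced expert set.

    The target is the 0/1 class indicator for classification labels (the
    two-group partial F is then the classic F-to-enter of stepwise discriminant
    analysis) or the raw values for a continuous target.  Ties break by column
    order; the expert set is always included regardless of significance.
    """
    y = pd.Series(labels).reset_index(drop=True)
    if y.dtype == object:
        y = (y == WITHIN).astype(float)
    yv = y.to_numpy(dtype=float)
    X = features.reset_index(drop=True).astype(float)
    unknown = [f for f in expert_set if f not in X.columns]
    if unknown:
        raise KeyError(f"expert features not in table: {unknown}")
    n = len(X)
    selected = list(dict.fromkeys(expert_set))
    candidates = [c for c in X.columns if c not in selected]
    max_steps = max_steps if max_steps is not None else X.shape[1]

    def design(cols: list[str]) -> np.ndarray:
        return np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in cols])

    q_base, _ = np.linalg.qr(design(selected))
    resid = yv - q_base @ (q_base.T @ yv)
    steps = 0
    while candidates and steps < max_steps:
        cmat = np.column_stack([X[c].to_numpy() for c in candidates])
        c_perp = cmat - q_base @ (q_base.T @ cmat)
        denom = np.einsum("ij,ij->j", c_perp, c_perp)
        num = c_perp.T @ resid
        with np.errstate(divide="ignore", invalid="ignore"):
            ss_gain = np.where(denom > 1e-12, num**2 / denom, 0.0)
        sse = float(resid @ resid)
        df_resid = n - (len(selected) + 2)  # intercept + selected + candidate
        if df_resid <= 0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stat = ss_gain / ((sse - ss_gain) / df_resid)
        f_stat = np.nan_to_num(f_stat, nan=0.0, posinf=np.inf)
        best = int(np.argmax(f_stat))  # first max wins: column-order tie-break
        p_val = float(stats.f.sf(f_stat[best], 1, df_resid))
        if not p_val < p_enter:
            break
        chosen = candidates.pop(best)
        selected.append(chosen)
        q_base, _ = np.linalg.qr(design(selected))
        resid = yv - q_base @ (q_base.T @ yv)
        steps += 1
    return selected


# ---------------------------------------------------------------------------
# ML battery adapters
# ---------------------------------------------------------------------------

_REGRESSORS = {"LR", "MLP", "SVM", "KNN", "Bagging", "RF"}
_CLASSIFIERS = {"LDA", "Logistic", "BayesNet", "MLP", "SVM", "KNN", "Bagging", "RF"}


@dataclass
class ModelSpec:
    task: str  # {regression, classification}
    algorithm: str
    settings: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in {"regression", "classification"}:
            raise ValueError(f"unknown task {self.task!r}")
        allowed = _REGRESSORS if self.task == "regression" else _CLASSIFIERS
        if self.algorithm not in allowed:
            raise ValueError(
                f"algorithm {self.algorithm!r} not available for task {self.task!r}; "
                f"choose from {sorted(allowed)}"
            )


def _make_estimator(spec: ModelSpec):
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import (
        BaggingClassifier,
        BaggingRegressor,
        RandomForestClassifier,
        RandomForestRegressor,
    )
    from sklearn.linear_model import LinearRegression, LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
    from sklearn.neural_network import MLPClassifier, MLPRegressor
    from sklearn.svm import SVC, SVR

    s = dict(spec.settings)
    seeded = {"random_state": spec.seed}
    if spec.task == "regression":
        registry = {
            "LR": lambda: LinearRegression(**s),
            "MLP": lambda: MLPRegressor(max_iter=s.pop("max_iter", 500), **seeded, **s),
            "SVM": lambda: SVR(**s),
            "KNN": lambda: KNeighborsRegressor(n_neighbors=s.pop("n_neighbors", 5), **s),
            "Bagging": lambda: BaggingRegressor(**seeded, **s),
            "RF": lambda: RandomForestRegressor(**seeded, **s),
        }
    else:
        registry = {
            "LDA": lambda: LinearDiscriminantAnalysis(**s),
            "Logistic": lambda: LogisticRegression(max_iter=s.pop("max_iter", 1000), **s),
            "BayesNet": lambda: GaussianNB(**s),  # naive-Bayes baseline
            "MLP": lambda: MLPClassifier(max_iter=s.pop("max_iter", 500), **seeded, **s),
            "SVM": lambda: SVC(**seeded, **s),
            "KNN": lambda: KNeighborsClassifier(n_neighbors=s.pop("n_neighbors", 5), **s),
            "Bagging": lambda: BaggingClassifier(**seeded, **s),
            "RF": lambda: RandomForestClassifier(**seeded, **s),
        }
    return registry[spec.algorithm]()


@dataclass
class FittedPredictor:
    """Uniform predict surface over the sklearn battery."""

    spec: ModelSpec
    estimator: object
    feature_names: list[str]

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise KeyError(f"features missing at predict time: {missing}")
        return features[self.feature_names].to_numpy(dtype=float)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        pred = self.estimator.predict(self._matrix(features))
        return pd.Series(pred, index=features.index, name="prediction")

    def predict_score(self, features: pd.DataFrame) -> pd.Series:
        """Continuous score for ROC (classification: score for the Within class)."""
        X = self._matrix(features)
        est = self.estimator
        if self.spec.task == "regression":
            score = est.predict(X)
        elif hasattr(est, "predict_proba"):
            cls = list(est.classes_)
            score = est.predict_proba(X)[:, cls.index(WITHIN)]
        elif hasattr(est, "decision_function"):
            raw = est.decision_function(X)
            score = raw if list(est.classes_)[1] == WITHIN else -raw
        else:
            score = (est.predict(X) == WITHIN).astype(float)
        return pd.Series(score, index=features.index, name="score")


def fit_ml(spec: ModelSpec, features: pd.DataFrame, target) -> FittedPredictor:
    """Fit one battery member; the input table is never mutated."""
    est = _make_estimator(spec)
    X = features.to_numpy(dtype=float)
    y = pd.Series(target).to_numpy()
    if spec.task == "regression":
        y = y.astype(float)
    est.fit(X, y)
    return FittedPredictor(spec=spec, estimator=est, feature_names=list(features.columns))
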