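"""Logistic-regression phase-behaviour classification.

Each heteropolymer sequence contributes one row of features (B22, Rg,
contact-map mean and variance, split sums, divergence index, ...) and a
binary label: 1 for phase separating (macroscopic dense/dilute coexistence),
0 for aggregating (finite clusters at all concentrations).  The labels are
consumed as input; producing them (direct-coexistence simulation) is outside
this package.

The model is deliberately plain: features are standardised to z-scores with
the population standard deviation of the *training* rows, and a
maximum-likelihood logistic regression is fitted by damped Newton/IRLS with
a tiny ridge (1e-8, on the coefficients but not the intercept) purely as a
safeguard against perfectly separable folds.  Predictive performance is the
ROC-AUC (rank-based, ties credited 1/2), summarised as mean +/- standard
error over many randomised 80/20 train-test splits.

Usage follows the Model/Results convention::

    model = PhaseClassifier.from_dataframe(df, features=["contact_variance"])
    res = model.fit()
    print(res.summary())
    ev = model.evaluate_splits(n_splits=185, seed=7)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .errors import ClassImbalanceError, UndefinedAUCError

__all__ = [
    "FEATURE_COLUMNS",
    "validate_feature_table",
    "Standardization",
    "standardize",
    "FitResult",
    "fit_logistic",
    "roc_auc",
    "PhaseClassifier",
    "PhaseClassifierResults",
    "EvaluationResult",
    "evaluate_splits",
    "classification_accuracy",
    "subset_by_divergence_index",
]

#: canonical feature columns of a feature table (any subset may be present)
FEATURE_COLUMNS = (
    "B22",
    "Rg",
    "contact_mean",
    "contact_variance",
    "S_leq",
    "S_gt",
    "divergence_index",
)

RIDGE = 1e-8


def validate_feature_table(
    df: pd.DataFrame, features: list[str] | None = None, label_col: str = "label"
) -> None:
    """Check the feature-table contract: finite features, complete binary labels."""
    if label_col not in df.columns:
        raise ValueError(f"missing label column {label_col!r}")
    labels = df[label_col]
    if labels.isna().any():
        bad = df.index[labels.isna()].tolist()
        raise ValueError(f"missing labels for rows {bad}")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    cols = features if features is not None else [
        c for c in FEATURE_COLUMNS if c in df.columns
    ]
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"missing feature column {c!r}")
        vals = df[c].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            bad = df.index[~np.isfinite(vals)].tolist()
            raise ValueError(f"non-finite values in feature {c!r} at rows {bad}")


@dataclass(frozen=True)
class Standardization:
    """Per-feature training mean and population standard deviation."""

    mean: np.ndarray
    sd: np.ndarray
    degenerate: np.ndarray  # True where the training sd was zero

    def transform(self, X: np.ndarray) -> np.ndarray:
        sd = np.where(self.degenerate, 1.0, self.sd)
        Z = (X - self.mean) / sd
        Z[:, self.degenerate] = 0.0
        return Z


def standardize(
    X: np.ndarray, fit_rows: np.ndarray | None = None
) -> tuple[np.ndarray, Standardization]:
    """Z-scores from the statistics of ``fit_rows`` applied to all rows.

    Uses the population (1/n) standard deviation.  A zero-variance feature
    maps to all zeros and is flagged as degenerate rather than failing: the
    B22 column of a B22-matched dataset is constant by construction.
    """
    X = np.asarray(X, dtype=float)
    fit = X if fit_rows is None else X[fit_rows]
    if fit.shape[0] == 0:
        raise ValueError("fit_rows must be non-empty")
    mean = fit.mean(axis=0)
    sd = fit.std(axis=0)  # population sd (ddof=0)
    degenerate = sd == 0.0
    params = Standardization(mean=mean, sd=sd, degenerate=degenerate)
    return params.transform(X), params


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood logistic fit on standardised features."""

    coefficients: np.ndarray
    intercept: float
    converged: bool
    separation: bool
    n_iterations: int
    negative_log_likelihood: float

    def decision_function(self, Z: np.ndarray) -> np.ndarray:
        return Z @ self.coefficients + self.intercept

    def predict_proba(self, Z: np.ndarray) -> np.ndarray:
        return expit(self.decision_function(Z))


def _penalized_nll(beta: np.ndarray, Xb: np.ndarray, y: np.ndarray, ridge: float) -> float:
    eta = Xb @ beta
    # log(1 + e^eta) - y*eta, computed overflow-safe
    nll = float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    return nll + 0.5 * ridge * float(np.sum(beta[1:] ** 2))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    ridge: float = RIDGE,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> FitResult:
    """Damped Newton/IRLS maximum-likelihood logistic regression.

    The ridge penalty acts on the coefficients only (never the intercept)
    and exists solely so the optimum stays finite under perfect separation;
    separation is detected and flagged.  Deterministic for a fixed input
    order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present to fit")
    n, p = X.shape
    Xb = np.hstack([np.ones((n, 1)), X])
    R = np.full(p + 1, ridge)
    R[0] = 0.0
    beta = np.zeros(p + 1)
    nll = _penalized_nll(beta, Xb, y, ridge)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(Xb @ beta)
        w = np.maximum(mu * (1.0 - mu), 1e-12)
        grad = Xb.T @ (y - mu) - R * beta
        H = (Xb * w[:, None]).T @ Xb + np.diag(np.maximum(R, 1e-12))
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        # backtracking line search on the penalised NLL
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            cand_nll = _penalized_nll(cand, Xb, y, ridge)
            if cand_nll <= nll + 1e-14:
                break
            t *= 0.5
        else:
            converged = True
            break
        moved = t * np.max(np.abs(step))
        beta, nll = cand, cand_nll
        if moved < tol or np.max(np.abs(grad)) < tol:
            converged = True
            break
    scores = Xb @ beta
    s0 = scores[y == 0]
    s1 = scores[y == 1]
    separation = bool(len(s0) and len(s1) and s0.max() < s1.min() and np.ptp(scores) > 0)
    return FitResult(
        coefficients=beta[1:],
        intercept=float(beta[0]),
        converged=converged,
        separation=separation,
        n_iterations=it,
        negative_log_likelihood=float(nll - 0.5 * ridge * np.sum(beta[1:] ** 2)),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) ROC-AUC; tied scores credited 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class PhaseClassifier:
    """Logistic-regression phase-behaviour model over a feature table.

    Parameters
    ----------
    table
        DataFrame with one row per sequence, the requested feature columns,
        and a binary label column (1 = phase separating, 0 = aggregating).
    features
        Feature columns to use, in order.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        features: list[str],
        label_col: str = "label",
    ):
        validate_feature_table(table, features, label_col)
        self.table = table
        self.features = list(features)
        self.label_col = label_col
        self.X = table[self.features].to_numpy(dtype=float)
        self.y = table[label_col].to_numpy(dtype=int)
        if len(np.unique(self.y)) < 2:
            raise ValueError("feature table must contain both classes")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, features: list[str] | None = None, label_col: str = "label"
    ) -> "PhaseClassifier":
        if features is None:
            features = [c for c in FEATURE_COLUMNS if c in df.columns]
        return cls(df, features, label_col)

    def fit(self, ridge: float = RIDGE) -> "PhaseClassifierResults":
        """Standardise on all rows, fit, and wrap the estimates."""
        Z, std = standardize(self.X)
        fr = fit_logistic(Z, self.y, ridge=ridge)
        return PhaseClassifierResults(model=self, standardization=std, fit=fr)

    def evaluate_splits(
        self,
        n_splits: int = 185,
        test_fraction: float = 0.2,
        seed: int = 0,
        metric: str = "auc",
        threshold: float = 0.5,
        resample_cap: int = 1000,
    ) -> "EvaluationResult":
        return evaluate_splits(
            self.table,
            self.features,
            n_splits=n_splits,
            test_fraction=test_fraction,
            seed=seed,
            label_col=self.label_col,
            metric=metric,
            threshold=threshold,
            resample_cap=resample_cap,
        )


@dataclass
class PhaseClassifierResults:
    """Fitted coefficients (on z-scored features) plus diagnostics."""

    model: PhaseClassifier
    standardization: Standardization
    fit: FitResult

    @property
    def params(self) -> pd.Series:
        return pd.Series(
            np.concatenate([[self.fit.intercept], self.fit.coefficients]),
            index=["intercept"] + self.model.features,
        )

    def predict_proba(self, df: pd.DataFrame | None = None) -> np.ndarray:
        X = (
            self.model.X
            if df is None
            else df[self.model.features].to_numpy(dtype=float)
        )
        return self.fit.predict_proba(self.standardization.transform(X))

    def predict(self, df: pd.DataFrame | None = None, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(df) >= threshold).astype(int)

    def training_auc(self) -> float:
        return roc_auc(self.predict_proba(), self.model.y)

    def summary(self) -> str:
        lines = [
            "Phase-behaviour logistic regression",
            "===================================",
            f"observations: {len(self.model.y)}   "
            f"phase separating: {int(self.model.y.sum())}",
            f"converged: {self.fit.converged}   "
            f"separation: {self.fit.separation}   "
            f"iterations: {self.fit.n_iterations}",
            f"training NLL: {self.fit.negative_log_likelihood:.6g}",
            f"training AUC: {self.training_auc():.4f}",
            "",
            f"{'term':<20}{'coef (z-scored)':>18}",
        ]
        for name, val in self.params.items():
            flag = ""
            if name != "intercept":
                j = self.model.features.index(name)
                if self.standardization.degenerate[j]:
                    flag = "  (constant feature)"
            lines.append(f"{name:<20}{val:>18.6g}{flag}")
        return "\n".join(lines)


@dataclass(frozen=True)
class EvaluationResult:
    """Per-split metric values with their mean and standard error."""

    per_split: np.ndarray
    n_splits: int
    test_fraction: float
    seed: int
    metric: str = "auc"

    @property
    def mean(self) -> float:
        return float(np.mean(self.per_split))

    @property
    def standard_error(self) -> float:
        if len(self.per_split) < 2:
            return 0.0
        return float(np.std(self.per_split, ddof=1) / np.sqrt(len(self.per_split)))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EvaluationResult({self.metric} = {self.mean:.4f} "
            f"+/- {self.standard_error:.4f}, n_splits={self.n_splits})"
        )


def _one_split(rng: np.random.Generator, n: int, y: np.ndarray, n_test: int, cap: int):
    for _ in range(cap):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        if len(np.unique(y[train])) == 2 and len(np.unique(y[test])) == 2:
            return train, test
    raise ClassImbalanceError(
        f"could not draw a split with both classes in train and test "
        f"within {cap} attempts"
    )


def evaluate_splits(
    table: pd.DataFrame,
    features: list[str],
    *,
    n_splits: int = 185,
    test_fraction: float = 0.2,
    seed: int = 0,
    label_col: str = "label",
    metric: str = "auc",
    threshold: float = 0.5,
    resample_cap: int = 1000,
) -> EvaluationResult:
    """Mean +/- SE of a metric over randomised train-test splits.

    Per split: standardise on the training rows only, fit, score the test
    rows, and record the ROC-AUC (or the accuracy at the probability
    ``threshold`` for ``metric='accuracy'``).  Splits are randomised, not
    stratified; a split leaving a single class in either part is redrawn
    (up to ``resample_cap`` attempts).  Fully reproducible given the seed.
    """
    validate_feature_table(table, features, label_col)
    X = table[list(features)].to_numpy(dtype=float)
    y = table[label_col].to_numpy(dtype=int)
    n = len(y)
    n_test = max(1, int(round(test_fraction * n)))
    if n_test >= n:
        raise ValueError("test fraction leaves no training rows")
    rng = np.random.default_rng(int(seed))
    values = np.empty(n_splits)
    for s in range(n_splits):
        train, test = _one_split(rng, n, y, n_test, resample_cap)
        Z_all, _ = _standardize_on(X, train)
        fr = fit_logistic(Z_all[train], y[train])
        scores = fr.predict_proba(Z_all[test])
        if metric == "auc":
            values[s] = roc_auc(scores, y[test])
        elif metric == "accuracy":
            values[s] = float(np.mean((scores >= threshold).astype(int) == y[test]))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return EvaluationResult(
        per_split=values,
        n_splits=n_splits,
        test_fraction=test_fraction,
        seed=int(seed),
        metric=metric,
    )


def _standardize_on(X: np.ndarray, train: np.ndarray):
    mask = np.zeros(X.shape[0], dtype=bool)
    mask[train] = True
    return standardize(X, fit_rows=mask)


def classification_accuracy(
    table: pd.DataFrame,
    features: list[str],
    *,
    threshold: float = 0.5,
    n_splits: int = 185,
    test_fraction: float = 0.2,
    seed: int = 0,
    label_col: str = "label",
    resample_cap: int = 1000,
) -> EvaluationResult:
    """Fraction of correct test-set predictions at the probability threshold,
    under the same split protocol as :func:`evaluate_splits`."""
    return evaluate_splits(
        table,
        features,
        n_splits=n_splits,
        test_fraction=test_fraction,
        seed=seed,
        label_col=label_col,
        metric="accuracy",
        threshold=threshold,
        resample_cap=resample_cap,
    )


def subset_by_divergence_index(
    table: pd.DataFrame,
    fraction: float = 0.1,
    end: str = "top",
    column: str = "divergence_index",
    id_col: str = "sequence_id",
) -> pd.DataFrame:
    """Rows in the top (or bottom) decile of the variance divergence index.

    Ties at the decile boundary are broken deterministically by sequence id;
    a fully tied column triggers a warning.
    """
    if column not in table.columns:
        raise ValueError(f"missing column {column!r}")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if end not in ("top", "bottom"):
        raise ValueError("end must be 'top' or 'bottom'")
    m = int(np.ceil(fraction * len(table)))
    key = table[column].to_numpy(dtype=float)
    ids = (
        table[id_col].astype(str).to_numpy()
        if id_col in table.columns
        else table.index.astype(str).to_numpy()
    )
    sign = -1.0 if end == "top" else 1.0
    order = np.lexsort((ids, sign * key))
    chosen = order[:m]
    boundary_tied = len(table) > m and key[order[m - 1]] == key[order[m]]
    if boundary_tied:
        warnings.warn(
            f"divergence-index tie at the {end}-{fraction:.0%} boundary; "
            "broken by sequence id",
            RuntimeWarning,
            stacklevel=2,
        )
    return table.iloc[np.sort(chosen)]
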