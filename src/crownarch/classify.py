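"""Species classification and accuracy statistics.

The feature table is a plain :class:`pandas.DataFrame` whose first two
columns are ``tree_id`` and ``species``, followed by named feature columns.
Classification is a leave-one-out cross-validated support vector machine:
for each tree, the feature columns are z-score standardized on the other
n-1 trees only (no leakage), an RBF-kernel SVM (C = 1, gamma = 1/#features,
one-vs-one multi-class) is trained on them, and the held-out tree is
predicted.  The result is fully deterministic and independent of row order.

An exhaustive subset search evaluates every unordered feature subset of the
requested sizes; ties between equal-accuracy subsets are broken towards the
smaller subset, then lexicographic column order.  A Wilks'-lambda MANOVA
p-value serves as a purely-reported gate on class separability before
classification; it never blocks the pipeline.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

__all__ = [
    "SVMConfig",
    "ClassificationReport",
    "SubsetSearchResult",
    "validate_feature_table",
    "manova_gate",
    "loocv_svm",
    "subset_search",
    "cohens_kappa",
    "r2_rmse",
]


ID_COLUMNS = ("tree_id", "species")


@dataclass(frozen=True)
class SVMConfig:
    """SVM settings, fixed for reproducibility rather than tuned per subset.

    ``gamma='auto'`` is 1/#features, appropriate after standardization.
    Multi-class handling is LIBSVM's native one-vs-one scheme.
    """

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "auto"

    def make(self) -> SVC:
        return SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion matrix and accuracy metrics of one LOOCV run."""

    confusion: pd.DataFrame  # true (rows) x predicted (columns)
    recall: dict[str, float]  # per class: correct / class size
    precision: dict[str, float]  # per class: correct / classified-into-class
    overall_accuracy: float
    kappa: float
    columns: tuple[str, ...]
    svm: SVMConfig
    predictions: pd.Series  # tree_id -> predicted label

    @property
    def n(self) -> int:
        return int(self.confusion.to_numpy().sum())

    def to_dict(self) -> dict:
        return {
            "confusion": {
                "classes": list(self.confusion.index),
                "matrix": self.confusion.to_numpy().tolist(),
            },
            "recall": self.recall,
            "precision": self.precision,
            "overall_accuracy": self.overall_accuracy,
            "kappa": self.kappa,
            "columns": list(self.columns),
            "svm": asdict(self.svm),
            "predictions": self.predictions.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class SizeResult:
    n_cases: int
    best_accuracy: float | None
    best_subsets: list[tuple[str, ...]] = field(default_factory=list)


@dataclass
class SubsetSearchResult:
    per_size: dict[int, SizeResult]
    best_subset: tuple[str, ...] | None
    best_accuracy: float | None
    best_report: ClassificationReport | None


def validate_feature_table(
    table: pd.DataFrame, columns: Sequence[str] | None = None, for_loocv: bool = True
) -> None:
    """Check the feature-table contract; raise ValueError on violation."""
    for col in ID_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"feature table missing required column {col!r}")
    cols = list(columns) if columns is not None else [
        c for c in table.columns if c not in ID_COLUMNS
    ]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table missing feature columns {missing}")
    X = table[cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        bad = [c for c in cols if not np.all(np.isfinite(table[c].to_numpy(dtype=float)))]
        raise ValueError(f"non-finite feature values in columns {bad}")
    if table["species"].isna().any():
        raise ValueError("missing species labels in supervised table")
    if for_loocv:
        sizes = table["species"].value_counts()
        singletons = sizes[sizes < 2]
        if len(singletons):
            raise ValueError(
                f"classes with a single member cannot be cross-validated: "
                f"{sorted(singletons.index)}"
            )


# ---------------------------------------------------------------------------
# MANOVA gate


def _wilks_p(X: np.ndarray, groups: np.ndarray, ridge: float = 0.0) -> float:
    """Wilks'-lambda MANOVA p-value via Rao's F approximation."""
    labels = np.unique(groups)
    n, p = X.shape
    g = len(labels)
    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    for lab in labels:
        sub = X[groups == lab]
        d = sub - sub.mean(axis=0)
        W += d.T @ d
    if ridge:
        W = W + ridge * np.eye(p)
    d = X - grand
    T = d.T @ d + (ridge * np.eye(p) if ridge else 0.0)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_w <= 0 or sign_t <= 0:
        return float("nan")
    lam = math.exp(logdet_w - logdet_t)
    nu_h = g - 1
    nu_e = n - g
    denom = p**2 + nu_h**2 - 5
    t = math.sqrt((p**2 * nu_h**2 - 4) / denom) if denom > 0 else 1.0
    df1 = p * nu_h
    df2 = (nu_e + nu_h - (p + nu_h + 1) / 2.0) * t - (p * nu_h - 2) / 2.0
    if df2 <= 0 or lam <= 0:
        return float("nan")
    lam_t = lam ** (1.0 / t)
    F = (1.0 - lam_t) / lam_t * df2 / df1
    return float(stats.f.sf(F, df1, df2))


def manova_gate(table: pd.DataFrame, columns: Sequence[str]) -> float:
    """Wilks'-lambda MANOVA p-value for species differences on ``columns``.

    Purely a reported gate: a warning is issued when p >= 0.05, the
    pipeline is never blocked.  A singular within-class scatter triggers a
    ridge-regularized retry (1e-8 on the diagonal), logged as a warning.
    """
    validate_feature_table(table, columns, for_loocv=False)
    X = table[list(columns)].to_numpy(dtype=float)
    groups = table["species"].to_numpy()
    g = len(np.unique(groups))
    if g < 2:
        raise ValueError("MANOVA requires at least 2 classes")
    if len(table) <= len(columns) + g:
        raise ValueError(
            f"MANOVA requires n > #columns + #classes "
            f"({len(table)} <= {len(columns)} + {g})"
        )
    with np.errstate(all="ignore"):
        p = _wilks_p(X, groups)
    if not np.isfinite(p):
        warnings.warn("MANOVA: singular within-class scatter; ridge-regularized retry (1e-8)")
        with np.errstate(all="ignore"):
            p = _wilks_p(X, groups, ridge=1e-8)
    if not np.isfinite(p):
        raise ValueError("MANOVA p-value could not be computed even after regularization")
    if p >= 0.05:
        warnings.warn(f"MANOVA gate: species differences not significant (p={p:.3g})")
    return p


# ---------------------------------------------------------------------------
# LOOCV-SVM


def loocv_svm(
    table: pd.DataFrame,
    columns: Sequence[str],
    svm: SVMConfig | None = None,
) -> ClassificationReport:
    """Leave-one-out cross-validated SVM species classification.

    Standardization statistics come from the training fold only.  Rows are
    canonically sorted by ``tree_id`` internally, so the report is
    independent of table row order.
    """
    svm = svm or SVMConfig()
    validate_feature_table(table, columns)
    df = table.sort_values("tree_id", kind="mergesort").reset_index(drop=True)
    X = df[list(columns)].to_numpy(dtype=float)
    y = df["species"].to_numpy()
    classes = sorted(np.unique(y))
    n = len(df)
    preds = np.empty(n, dtype=object)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        mu = X[mask].mean(axis=0)
        sd = X[mask].std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        clf = svm.make()
        clf.fit((X[mask] - mu) / sd, y[mask])
        preds[i] = clf.predict(((X[i] - mu) / sd)[None, :])[0]

    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(y, preds):
        confusion.loc[t, p] += 1
    m = confusion.to_numpy()
    recall = {
        c: float(m[i, i] / m[i].sum()) if m[i].sum() else 0.0
        for i, c in enumerate(classes)
    }
    precision = {
        c: float(m[i, i] / m[:, i].sum()) if m[:, i].sum() else 0.0
        for i, c in enumerate(classes)
    }
    return ClassificationReport(
        confusion=confusion,
        recall=recall,
        precision=precision,
        overall_accuracy=float(np.trace(m) / n),
        kappa=cohens_kappa(m),
        columns=tuple(columns),
        svm=svm,
        predictions=pd.Series(preds, index=df["tree_id"], name="predicted"),
    )


def subset_search(
    table: pd.DataFrame,
    pool: Sequence[str],
    sizes: Iterable[int],
    svm: SVMConfig | None = None,
    evaluator: Callable[[pd.DataFrame, tuple[str, ...]], float] | None = None,
    count_only: bool = False,
) -> SubsetSearchResult:
    """Exhaustively evaluate every unordered feature subset of each size.

    ``evaluator(table, columns) -> accuracy`` defaults to the LOOCV-SVM
    overall accuracy; an injectable evaluator (or ``count_only=True``,
    which skips evaluation entirely) supports fast combinatorial checks.
    Ties between equal-accuracy subsets break towards the smaller size,
    then lexicographic column order.
    """
    pool = list(pool)
    missing = [c for c in pool if c not in table.columns]
    if missing:
        raise ValueError(f"pool columns not in table: {missing}")
    sizes = sorted(set(int(k) for k in sizes))
    for k in sizes:
        if k < 1 or k > len(pool):
            raise ValueError(f"subset size {k} outside 1..{len(pool)}")
    if evaluator is None and not count_only:
        svm_cfg = svm or SVMConfig()
        evaluator = lambda tbl, cols: loocv_svm(tbl, cols, svm_cfg).overall_accuracy

    per_size: dict[int, SizeResult] = {}
    best: tuple[float, int, tuple[str, ...]] | None = None  # (-acc, size, subset)
    for k in sizes:
        n_cases = 0
        best_acc: float | None = None
        best_subsets: list[tuple[str, ...]] = []
        for subset in combinations(sorted(pool), k):
            n_cases += 1
            if count_only:
                continue
            acc = float(evaluator(table, subset))
            if best_acc is None or acc > best_acc + 1e-12:
                best_acc, best_subsets = acc, [subset]
            elif abs(acc - best_acc) <= 1e-12:
                best_subsets.append(subset)
        assert n_cases == math.comb(len(pool), k)
        per_size[k] = SizeResult(n_cases=n_cases, best_accuracy=best_acc,
                                 best_subsets=best_subsets)
        if best_acc is not None:
            cand = (-best_acc, k, min(best_subsets))
            if best is None or cand < best:
                best = cand

    if best is None:
        return SubsetSearchResult(per_size=per_size, best_subset=None,
                                  best_accuracy=None, best_report=None)
    best_subset = best[2]
    report = loocv_svm(table, best_subset, svm or SVMConfig()) if evaluator else None
    return SubsetSearchResult(
        per_size=per_size,
        best_subset=best_subset,
        best_accuracy=-best[0],
        best_report=report,
    )


# ---------------------------------------------------------------------------
# agreement and regression statistics


def cohens_kappa(confusion: np.ndarray) -> float:
    """Cohen's kappa from a square confusion matrix.

    ``kappa = (p_o - p_e) / (1 - p_e)`` with observed agreement
    ``p_o = trace/n`` and chance agreement ``p_e = sum_k row_k*col_k / n^2``;
    returns 1 for the degenerate all-in-one-cell case (p_e = p_o = 1).
    """
    m = np.asarray(confusion, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"confusion matrix must be square, got {m.shape}")
    if (m < 0).any() or m.sum() <= 0:
        raise ValueError("confusion matrix must be nonnegative with positive total")
    n = m.sum()
    p_o = np.trace(m) / n
    p_e = float((m.sum(axis=1) * m.sum(axis=0)).sum()) / n**2
    if abs(1.0 - p_e) < 1e-12:
        return 1.0
    return float((p_o - p_e) / (1.0 - p_e))


def r2_rmse(estimates: np.ndarray, references: np.ndarray) -> tuple[float, float]:
    """Coefficient of determination and root mean squared error.

    ``RMSE = sqrt(sum((d_i - d_i^R)^2) / n)``.  R^2 is computed against the
    fitted values of the ordinary least-squares regression of the estimates
    on the references, with the total sum of squares about the mean of the
    estimates.  Zero variance in the estimates yields ``(nan, rmse)`` with
    a warning.
    """
    d = np.asarray(estimates, dtype=float)
    r = np.asarray(references, dtype=float)
    if d.shape != r.shape or d.ndim != 1 or len(d) < 2:
        raise ValueError("estimates and references must be equal-length 1-D, n >= 2")
    rmse = float(np.sqrt(np.mean((d - r) ** 2)))
    if np.std(d) < 1e-12 or np.std(r) < 1e-12:
        warnings.warn("r2_rmse: zero variance; R^2 undefined (returning nan)")
        return float("nan"), rmse
    slope, intercept = np.polyfit(r, d, 1)
    d_hat = intercept + slope * r
    ss_res = float(np.sum((d - d_hat) ** 2))
    ss_tot = float(np.sum((d - d.mean()) ** 2))
    return 1.0 - ss_res / ss_tot, rmse
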