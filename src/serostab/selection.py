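"""Stability selection, final sparse models, evaluation and transfer.

The candidate proteins for a trait are fed to an elastic net (mixing
parameter α = 0.95, so the penalty behaves nearly like a LASSO while
tolerating correlated predictors). Because the chosen support depends on
the random train/validation split, the cross-validation is repeated R = 100
times with fresh fold splits; proteins selected in at least T = 60 of the
repeats form the stable set, which is then confirmed by one final LASSO
model. Models are evaluated by the squared Pearson correlation between
predicted and observed outcomes (against the repeated-measure mean and
against each single visit), and transferred to related outcomes by ridge
regression over the same proteins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNetCV, LassoCV, Ridge
from sklearn.model_selection import KFold

__all__ = [
    "standardize",
    "lambda_grid",
    "enet_coefficients",
    "elastic_net_select",
    "stability_counts",
    "apply_threshold",
    "fit_final_lasso",
    "evaluate",
    "ridge_transfer",
    "sign_concordance",
    "StabilityProfile",
    "SparseLinearModel",
]


def standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Column-standardize ``X``; returns (Z, params) with per-column mean/sd."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant predictor columns: {bad}")
    z = (X - mean) / sd
    params = pd.DataFrame({"mean": mean, "sd": sd})
    return z, params


def lambda_grid(
    X: np.ndarray, y: np.ndarray, alpha: float, n_lambdas: int = 100, eps: float = 1e-4
) -> np.ndarray:
    """Descending log-spaced penalty grid from λ_max down to eps·λ_max.

    λ_max is the smallest penalty that zeroes every coefficient for the
    elastic net with mixing parameter ``alpha`` (for the ridge limit the
    l1 part of the formula is evaluated at a small floor).
    """
    n = X.shape[0]
    yc = y - y.mean()
    lam_max = np.max(np.abs(X.T @ yc)) / (n * max(alpha, 1e-3))
    return np.logspace(np.log10(lam_max), np.log10(lam_max * eps), n_lambdas)


def _kfold(folds: int, seed: int) -> KFold:
    return KFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))


def enet_coefficients(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = 1.0,
    tol: float = 1e-10,
) -> tuple[float, np.ndarray]:
    """Elastic-net fit at a fixed penalty; returns (intercept, coefficients).

    Minimizes (1/2n)‖y − β₀ − Xβ‖² + λ[(1−α)/2‖β‖² + α‖β‖₁]. Used by the
    selection machinery and directly testable against closed forms
    (soft-thresholded OLS on orthonormal designs; plain OLS as λ → 0).
    """
    from sklearn.linear_model import ElasticNet

    m = ElasticNet(
        alpha=float(lam), l1_ratio=alpha, fit_intercept=True,
        max_iter=1_000_000, tol=tol,
    )
    m.fit(np.asarray(X, float), np.asarray(y, float))
    return float(m.intercept_), m.coef_.copy()


def elastic_net_select(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    alpha: float = 0.95,
    folds: int = 10,
    seed: int = 0,
    tol: float = 1e-4,
) -> list[str]:
    """Support of the elastic net at the CV-minimizing penalty.

    The penalty is chosen as the value on the descending grid that
    minimizes mean cross-validated squared error over seeded shuffled
    k-fold splits; the model is then refit on the full data at that penalty
    and the nonzero-coefficient proteins are returned.
    """
    yv = np.asarray(y, dtype=float)
    if np.std(yv) == 0:
        raise ValueError("degenerate (constant) outcome")
    if X.shape[0] < folds:
        raise ValueError(f"need at least {folds} subjects for {folds}-fold CV")
    Xv = X.to_numpy(dtype=float)
    grid = lambda_grid(Xv, yv, alpha)
    model = ElasticNetCV(
        l1_ratio=alpha,
        alphas=grid,
        cv=_kfold(folds, seed),
        fit_intercept=True,
        max_iter=5000,
        tol=tol,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xv, yv)
    support = np.flatnonzero(model.coef_ != 0)
    return [X.columns[j] for j in support]


@dataclass
class StabilityProfile:
    """Per-protein selection counts over repeated-CV elastic-net runs."""

    counts: pd.Series
    repeats: int = 100
    folds: int = 10
    alpha: float = 0.95
    threshold: int = 60
    seed: int = 0

    def selected(self, threshold: int | None = None) -> list[str]:
        t = self.threshold if threshold is None else threshold
        return list(self.counts.index[self.counts >= t])


def stability_counts(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    repeats: int = 100,
    alpha: float = 0.95,
    folds: int = 10,
    threshold: int = 60,
    seed: int = 0,
    tol: float = 1e-4,
) -> StabilityProfile:
    """Count elastic-net selections over ``repeats`` fresh CV fold splits.

    The master seed spawns one independent fold-split seed per repeat, so
    the whole profile is deterministic given (data, parameters, seed).
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(repeats)]
    counts = pd.Series(0, index=X.columns, dtype=int)
    for rep_seed in child_seeds:
        support = elastic_net_select(
            X, y, alpha=alpha, folds=folds, seed=rep_seed, tol=tol
        )
        counts[support] += 1
    return StabilityProfile(
        counts=counts, repeats=repeats, folds=folds, alpha=alpha,
        threshold=threshold, seed=seed,
    )


def apply_threshold(profile: StabilityProfile, threshold: int = 60) -> list[str]:
    """Proteins selected in at least ``threshold`` of the repeated CVs."""
    return profile.selected(threshold)


@dataclass
class SparseLinearModel:
    """Regularized linear model of one outcome over a protein panel.

    Coefficients are stored on the standardized-predictor scale together
    with the standardization parameters, so predictions are reproducible
    from the stored state alone; ``coef_original`` gives the coefficients
    on the raw predictor scale.
    """

    outcome: str
    intercept: float
    coef: pd.Series
    mixing_alpha: float
    lam: float
    training_subjects: list[str] = field(default_factory=list)
    standardization: pd.DataFrame | None = None

    @property
    def support(self) -> list[str]:
        return list(self.coef.index[self.coef != 0])

    @property
    def coef_original(self) -> pd.Series:
        if self.standardization is None:
            return self.coef
        return self.coef / self.standardization["sd"]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xs = X[list(self.coef.index)].to_numpy(dtype=float)
        if self.standardization is not None:
            mean = self.standardization["mean"].to_numpy()
            sd = self.standardization["sd"].to_numpy()
            Xs = (Xs - mean) / sd
        return self.intercept + Xs @ self.coef.to_numpy()


def fit_final_lasso(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    outcome: str = "",
    folds: int = 10,
    seed: int = 0,
) -> SparseLinearModel:
    """Final LASSO (α = 1) over the stability-selected proteins.

    The penalty is chosen by 10-fold CV minimum mean squared error on the
    same descending grid construction as the selection step. Proteins the
    final LASSO zeroes out remain in the stored coefficient vector as exact
    zeros and are reported as not retained via :attr:`SparseLinearModel.support`.
    """
    if X.shape[1] == 0:
        raise ValueError("empty selection: no proteins to fit")
    yv = np.asarray(y, dtype=float)
    Z, params = standardize(X)
    Zv = Z.to_numpy(dtype=float)
    grid = lambda_grid(Zv, yv, alpha=1.0)
    model = LassoCV(
        alphas=grid, cv=_kfold(folds, seed), fit_intercept=True,
        max_iter=100000, tol=1e-6,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Zv, yv)
    return SparseLinearModel(
        outcome=outcome,
        intercept=float(model.intercept_),
        coef=pd.Series(model.coef_, index=X.columns),
        mixing_alpha=1.0,
        lam=float(model.alpha_),
        training_subjects=list(X.index),
        standardization=params,
    )


def _squared_pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def evaluate(
    model: SparseLinearModel,
    X: pd.DataFrame,
    y_mean: np.ndarray | pd.Series,
    y_per_visit: pd.DataFrame | None = None,
) -> dict:
    """Squared correlation of predictions with the mean outcome and per visit.

    ``y_per_visit`` (subjects × visits) supplies each single-visit raw
    outcome; its per-visit R² values are computed against the same
    predictions and are expected to sit below the mean-outcome R² when the
    visit noise is independent of the model.
    """
    pred = model.predict(X)
    out = {"r2_mean": _squared_pearson(pred, np.asarray(y_mean, float))}
    if y_per_visit is not None:
        out["r2_per_visit"] = {
            str(v): _squared_pearson(pred, y_per_visit[v].to_numpy(dtype=float))
            for v in y_per_visit.columns
        }
    return out


def ridge_transfer(
    proteins: list[str],
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    outcome: str = "",
    folds: int = 10,
    seed: int = 0,
    penalties: np.ndarray | None = None,
) -> tuple[SparseLinearModel, float]:
    """Refit a panel on another outcome with ridge regression (α = 0).

    All proteins from the source-outcome model are kept (no selection); the
    ridge penalty is chosen by seeded k-fold CV minimum mean squared error.
    Returns the model and the squared correlation between its in-sample
    predictions and the target outcome.
    """
    if not proteins:
        raise ValueError("empty protein panel for transfer")
    yv = np.asarray(y, dtype=float)
    Z, params = standardize(X[proteins])
    Zv = Z.to_numpy(dtype=float)
    if penalties is None:
        penalties = np.logspace(4, -6, 60)
    kf = _kfold(folds, seed)
    splits = list(kf.split(Zv))
    mse = np.zeros(len(penalties))
    for tr, te in splits:
        for i, lam in enumerate(penalties):
            r = Ridge(alpha=float(lam), fit_intercept=True)
            r.fit(Zv[tr], yv[tr])
            mse[i] += float(np.mean((yv[te] - r.predict(Zv[te])) ** 2))
    best = penalties[int(np.argmin(mse))]
    r = Ridge(alpha=float(best), fit_intercept=True)
    r.fit(Zv, yv)
    model = SparseLinearModel(
        outcome=outcome,
        intercept=float(r.intercept_),
        coef=pd.Series(r.coef_, index=proteins),
        mixing_alpha=0.0,
        lam=float(best),
        training_subjects=list(X.index),
        standardization=params,
    )
    return model, _squared_pearson(model.predict(X), yv)


def sign_concordance(models: list[SparseLinearModel]) -> tuple[pd.Series, int]:
    """Per-protein coefficient-direction agreement across models.

    A protein is concordant when all its nonzero coefficients across the
    models share one sign (zero coefficients are ignored; a protein nonzero
    in at most one model is trivially concordant). Returns the per-protein
    flags and the concordant count.
    """
    if len(models) < 2:
        raise ValueError("need at least 2 models for concordance")
    proteins = sorted(set().union(*(m.coef.index for m in models)))
    flags = {}
    for p in proteins:
        signs = {
            np.sign(m.coef[p]) for m in models if p in m.coef.index and m.coef[p] != 0
        }
        flags[p] = len(signs) <= 1
    series = pd.Series(flags)
    return series, int(series.sum())
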