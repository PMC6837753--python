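"""Ranking-SVM survival evaluation with concordance-index testing.

The prognostic value of a feature set is measured by fitting a linear
ranking SVM on right-censored survival data and scoring the concordance
index (CI) on held-out folds. The SVM minimizes

    w'w + alpha * sum_{(i,j) in P} max(0, 1 - (w'x_i - w'x_j))^2

over the comparable pairs P = {(i, j): y_i >= y_j and delta_j = 1}: pairs
where patient i is known to have lived at least as long as patient j. The
CI of a risk score s is the fraction of comparable pairs ranked
concordantly (higher risk for the shorter survivor), with ties counting
one half. Significance against CI = 0.5 uses the asymptotic Noether
(U-statistic) variance estimator with a one-sided upper-tail test;
per-fold p-values are aggregated with Fisher's method and corrected
across settings with Benjamini-Hochberg. Clinical covariates enter
through a screening rule combining level-size cuts and univariate Cox
significance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

GRADIENT_TOL = 1e-6


@dataclass
class SurvivalDataset:
    """Feature matrix with right-censored survival labels."""

    features: np.ndarray  # (n, p)
    time: np.ndarray  # (n,)
    event: np.ndarray  # (n,) in {0, 1}; 1 = death observed

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = self.features.shape[0]
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("features, time and event lengths disagree")
        if np.any(self.time < 0):
            raise ValueError("negative survival times")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicators must be 0 or 1")

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def p(self) -> int:
        return self.features.shape[1]

    def subset(self, idx: np.ndarray) -> "SurvivalDataset":
        return SurvivalDataset(self.features[idx], self.time[idx], self.event[idx])


def comparable_pairs(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Ordered index pairs (i, j) with y_i >= y_j, delta_j = 1, i != j.

    For such pairs patient i is known to have survived at least as long
    as patient j (whose death was observed). Returned as an (m, 2) array;
    empty when no pair is comparable.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    mask = (time[:, None] >= time[None, :]) & (event[None, :] == 1)
    np.fill_diagonal(mask, False)
    return np.argwhere(mask)


@dataclass
class RankSvmModel:
    """Fitted linear ranking SVM with its standardization parameters."""

    w: np.ndarray
    alpha: float
    mean_: np.ndarray
    scale_: np.ndarray

    def standardize(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.w.shape[0]:
            raise ValueError(
                f"expected {self.w.shape[0]} features, got {features.shape[1]}"
            )
        return (features - self.mean_) / self.scale_


def fit_rank_svm(
    data: SurvivalDataset, alpha: float = 1.0, tol: float = GRADIENT_TOL
) -> RankSvmModel:
    """Minimize the squared-hinge pairwise ranking objective.

    Features are z-scored internally (constant columns get unit scale).
    The objective is strictly convex, so the minimizer is unique; L-BFGS
    is run to projected-gradient tolerance ``tol``.
    """
    if not np.all(np.isfinite(data.features)):
        raise ValueError("non-finite feature values")
    pairs = comparable_pairs(data.time, data.event)
    if len(pairs) == 0:
        raise ValueError("no comparable pairs; cannot fit")

    mean = data.features.mean(axis=0)
    scale = data.features.std(axis=0)
    scale[scale == 0] = 1.0
    x = (data.features - mean) / scale
    # rows of D are x_i - x_j over comparable pairs (i outlives j)
    d = x[pairs[:, 0]] - x[pairs[:, 1]]

    def objective(w: np.ndarray) -> tuple[float, np.ndarray]:
        margin = 1.0 - d @ w
        active = np.maximum(margin, 0.0)
        value = w @ w + alpha * float(active @ active)
        grad = 2.0 * w - 2.0 * alpha * (d.T @ active)
        return value, grad

    result = optimize.minimize(
        objective,
        np.zeros(x.shape[1]),
        jac=True,
        method="L-BFGS-B",
        options={"gtol": tol, "ftol": 1e-14, "maxiter": 1000},
    )
    return RankSvmModel(w=result.x, alpha=alpha, mean_=mean, scale_=scale)


def predict_risk(model: RankSvmModel, features: np.ndarray) -> np.ndarray:
    """Risk scores ``-w'x`` on standardized features.

    The SVM pushes ``w'x`` higher for longer survivors; negating yields a
    risk score whose larger values predict shorter survival, matching the
    concordance index's direction.
    """
    return -(model.standardize(features) @ model.w)


@dataclass(frozen=True)
class ConcordanceResult:
    ci: float
    n_pairs: int
    se: float
    p_one_sided: float


def concordance_index(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray
) -> ConcordanceResult:
    """Concordance between risk scores and observed survival.

    Over comparable pairs (i, j) — i outlived j — a pair is concordant
    when the predicted risk of j exceeds that of i; score ties count one
    half. The standard error is the Noether U-statistic estimator built
    from per-patient concordant/discordant pair counts; the one-sided
    p-value tests CI > 0.5 against the random-predictor null.
    """
    scores = np.asarray(scores, dtype=float)
    pairs = comparable_pairs(time, event)
    if len(pairs) == 0:
        raise ValueError("no comparable pairs")
    i, j = pairs[:, 0], pairs[:, 1]
    diff = scores[j] - scores[i]
    contrib = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    ci = float(contrib.mean())

    n = len(scores)
    conc = np.zeros(n)
    disc = np.zeros(n)
    # each pair credits both its patients; ties split evenly
    np.add.at(conc, i, contrib)
    np.add.at(conc, j, contrib)
    np.add.at(disc, i, 1.0 - contrib)
    np.add.at(disc, j, 1.0 - contrib)
    c, d = conc.sum(), disc.sum()
    if c + d == 0:
        raise ValueError("no comparable pairs")
    var = (
        4.0
        * (
            d**2 * np.sum(conc**2)
            - 2.0 * c * d * np.sum(conc * disc)
            + c**2 * np.sum(disc**2)
        )
        / (c + d) ** 4
    )
    se = float(np.sqrt(max(var, 0.0)))
    p = noether_p(ci, se) if se > 0 else (0.5 if ci == 0.5 else np.nan)
    return ConcordanceResult(ci=ci, n_pairs=len(pairs), se=se, p_one_sided=p)


def noether_p(ci: float, se: float) -> float:
    """One-sided upper-tail p for CI > 0.5 with Noether standard error."""
    if se == 0:
        raise ValueError("zero standard error")
    z = (ci - 0.5) / se
    return float(stats.norm.sf(z))


def noether_ci_test(result: ConcordanceResult) -> float:
    """One-sided test of a concordance result against CI = 0.5."""
    return noether_p(result.ci, result.se)


def cross_validated_ci(
    data: SurvivalDataset,
    k: int = 5,
    seed: int = 0,
    alpha: float = 1.0,
) -> list[ConcordanceResult]:
    """k-fold cross-validated test concordance of the ranking SVM.

    Folds come from a seeded shuffle without stratification. A fold whose
    test split has no comparable pair is skipped with a warning.
    """
    from sklearn.model_selection import KFold

    if k < 2:
        raise ValueError("need k >= 2 folds")
    if k > data.n:
        raise ValueError(f"k={k} folds exceed n={data.n} samples")
    results = []
    kfold = KFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(kfold.split(data.features)):
        model = fit_rank_svm(data.subset(train_idx), alpha=alpha)
        test = data.subset(test_idx)
        scores = predict_risk(model, test.features)
        try:
            results.append(concordance_index(scores, test.time, test.event))
        except ValueError:
            warnings.warn(f"fold {fold}: no comparable pairs in test split; skipped")
    return results


def fisher_aggregate(pvals: Sequence[float]) -> float:
    """Fisher combination of independent p-values.

    ``chi2 = -2 sum(ln p)`` on 2k degrees of freedom; upper-tail p.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to aggregate")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(chi2, df=2 * p.size))


def bh_correct(
    pvals: Sequence[float], fdr: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection mask, adjusted p-values)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    reject, adjusted, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return reject, adjusted


def compare_ci_paired(
    ci_a: Sequence[float], ci_b: Sequence[float]
) -> float:
    """Two-sided paired t-test between per-fold concordance indexes.

    Identical fold values (zero-variance differences) return p = 1: the
    data carry no evidence of a difference.
    """
    a = np.asarray(ci_a, dtype=float)
    b = np.asarray(ci_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired fold values")
    if np.allclose(a, b):
        return 1.0
    res = stats.ttest_rel(a, b)
    return float(res.pvalue)


def select_clinical_variables(
    clinical: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    min_level_size: int = 50,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Screen clinical covariates for the survival model.

    Categorical columns are one-hot encoded; a level survives only when
    at least ``min_level_size`` patients carry it and at least
    ``min_level_size`` patients carry another level. Numeric columns
    survive only when observed for every patient. Surviving candidates
    are then screened by a univariate Cox proportional-hazards model
    (Breslow ties), keeping those whose Wald p-values pass
    Benjamini-Hochberg at ``fdr``. Returns the selected design matrix
    (possibly empty, with a warning).
    """
    from lifelines import CoxPHFitter

    n = len(clinical)
    candidates: dict[str, pd.Series] = {}
    for col in clinical.columns:
        series = clinical[col]
        if pd.api.types.is_numeric_dtype(series):
            if series.isna().any():
                continue
            candidates[col] = series.astype(float)
        else:
            counts = series.value_counts(dropna=True)
            for level, count in counts.items():
                others = int(counts.sum() - count) + int(series.isna().sum())
                if count >= min_level_size and others >= min_level_size:
                    candidates[f"{col}={level}"] = (
                        (series == level).astype(float)
                    )
    if not candidates:
        warnings.warn("no clinical variables survive the availability rules")
        return pd.DataFrame(index=clinical.index)

    design = pd.DataFrame(candidates, index=clinical.index)
    pvals = []
    names = []
    for name in design.columns:
        frame = pd.DataFrame(
            {"x": design[name].to_numpy(), "time": time, "event": event}
        )
        cph = CoxPHFitter()
        try:
            cph.fit(frame, duration_col="time", event_col="event")
            pvals.append(float(cph.summary.loc["x", "p"]))
            names.append(name)
        except Exception as exc:  # degenerate fits are screened out
            logger.warning("cox screening failed for %s: %s", name, exc)
    if not pvals:
        warnings.warn("no clinical variables could be screened by Cox model")
        return pd.DataFrame(index=clinical.index)
    reject, _ = bh_correct(pvals, fdr=fdr)
    selected = [name for name, rej in zip(names, reject) if rej]
    if not selected:
        warnings.warn("no clinical variables pass the Cox/BH screen")
    return design[selected]
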