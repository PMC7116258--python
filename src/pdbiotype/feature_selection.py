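"""Symptom-correlated voxel selection.

Voxel values are first residualized against nuisance covariates (age, sex,
years of education, race coded white/other, and acquisition site), then a
voxel enters the mask for a clinical score when its Spearman rank
correlation with that score is significant at an uncorrected two-sided
p < alpha (default 0.01).  The union over the six baseline scores is the
neuroanatomic feature set passed to clustering.

Residualization is fitted within the PD patients (selection happens within
patients); the fitted coefficients can be applied to controls when the two
groups are later compared on the same footing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import OUTCOMES

__all__ = [
    "CONFOUNDS",
    "ConfoundModel",
    "FeatureMask",
    "residualize",
    "spearman_rho",
    "spearman_select",
    "select_features",
]

CONFOUNDS = ("age", "education", "sex", "race", "site")

#: minimum complete cases required to run selection for one score
MIN_COMPLETE_CASES = 10


def confound_design(
    covariates: pd.DataFrame,
    categories: dict[str, list] | None = None,
    check_rank: bool = True,
) -> np.ndarray:
    """Intercept + age + education (continuous) + sex/race/site dummies.

    ``categories`` freezes the dummy-coded levels so a design built on a
    held-out subset (e.g. controls missing a site) stays column-compatible
    with the fitted one.
    """
    missing = [c for c in CONFOUNDS if c not in covariates.columns]
    if missing:
        raise ValueError(f"covariate table lacks columns {missing}")
    if covariates[list(CONFOUNDS)].isna().any().any():
        raise ValueError("missing covariate values among included subjects")
    cols = [np.ones(len(covariates)), covariates["age"].to_numpy(float), covariates["education"].to_numpy(float)]
    names = ["intercept", "age", "education"]
    for cat in ("sex", "race", "site"):
        levels = categories.get(cat) if categories else None
        series = pd.Categorical(covariates[cat], categories=levels)
        dummies = pd.get_dummies(series, prefix=cat, drop_first=True)
        for name in dummies.columns:
            cols.append(dummies[name].to_numpy(float))
            names.append(str(name))
    X = np.column_stack(cols)
    if check_rank:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(f"collinear confound design (rank {rank} < {X.shape[1]}): columns {names}")
    return X


@dataclass
class ConfoundModel:
    """OLS confound fit, reusable on held-out subjects (e.g. controls)."""

    coef: np.ndarray  # design-columns x features
    design_columns: tuple[str, ...]
    categories: dict[str, list]

    @classmethod
    def fit(cls, values: np.ndarray, covariates: pd.DataFrame) -> "ConfoundModel":
        categories = {
            cat: sorted(pd.unique(covariates[cat]).tolist()) for cat in ("sex", "race", "site")
        }
        X = confound_design(covariates, categories)
        coef, *_ = np.linalg.lstsq(X, np.asarray(values, dtype=float), rcond=None)
        return cls(coef=coef, design_columns=("intercept",) + CONFOUNDS, categories=categories)

    def residuals(self, values: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
        X = confound_design(covariates, self.categories, check_rank=False)
        return np.asarray(values, dtype=float) - X @ self.coef


def residualize(values: np.ndarray, covariates: pd.DataFrame) -> np.ndarray:
    """OLS residuals of every feature column on the confound design.

    ``values`` is subjects x features; the confound design is intercept,
    age, education, and dummy-coded sex, race and site.  Residuals are
    orthogonal to every design column by construction.
    """
    return ConfoundModel.fit(values, covariates).residuals(values, covariates)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with mid-ranks for ties.

    Returns (rho, two-sided p) where rho is the Pearson correlation of the
    mid-ranks and p comes from the t approximation
    ``t = rho sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need two equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def spearman_select(values: np.ndarray, score: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman test of every feature column against one score.

    Returns (rho, mask) over features.  Mid-ranks handle ties; p-values use
    the same t approximation as :func:`spearman_rho`.
    """
    n = score.size
    rx = stats.rankdata(values, axis=0)
    ry = stats.rankdata(score)
    rx = rx - rx.mean(axis=0)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=0) * (ry**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rx * ry[:, None]).sum(axis=0) / denom
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(rho), np.where(np.isfinite(t), p, 0.0), 1.0)
    return rho, p < alpha


@dataclass
class FeatureMask:
    """Per-score selection masks over features, and their union."""

    masks: dict[str, np.ndarray]
    union: np.ndarray
    counts: dict[str, int]
    alpha: float
    n_cases: dict[str, int]

    @property
    def union_count(self) -> int:
        return int(self.union.sum())


def select_features(
    residualized: np.ndarray,
    scores: pd.DataFrame,
    alpha: float = 0.01,
    score_names: tuple[str, ...] = OUTCOMES,
) -> FeatureMask:
    """Select features correlated with any baseline clinical score.

    Per score, subjects with a missing value are dropped (complete cases
    per variable); a score with fewer than 10 complete cases is refused.
    The union mask is the logical OR of the six per-score masks.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    residualized = np.asarray(residualized, dtype=float)
    masks: dict[str, np.ndarray] = {}
    n_cases: dict[str, int] = {}
    for k in score_names:
        score = scores[k].to_numpy(float)
        ok = np.isfinite(score)
        n_cases[k] = int(ok.sum())
        if n_cases[k] < MIN_COMPLETE_CASES:
            raise ValueError(
                f"score {k!r} has only {n_cases[k]} complete cases (< {MIN_COMPLETE_CASES})"
            )
        _, masks[k] = spearman_select(residualized[ok], score[ok], alpha)
    union = np.logical_or.reduce(list(masks.values()))
    counts = {k: int(m.sum()) for k, m in masks.items()}
    return FeatureMask(masks=masks, union=union, counts=counts, alpha=alpha, n_cases=n_cases)
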