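"""Biotype validation: contrast maps, baseline tables, biotype diagnosis.

Three complementary checks of a biotype solution:

* voxelwise two-sample t maps of each biotype against healthy controls,
  on confound-residualized DBM values, thresholded by Benjamini-Hochberg
  false-discovery-rate control;
* a baseline comparison table (t tests on residualized continuous
  variables, Pearson chi-square for categorical ones, BH-FDR across the
  variable family);
* a stratified 10-fold cross-validated RBF-kernel support vector machine
  that diagnoses the biotype of an individual patient from the selected
  neuroanatomic features alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .feature_selection import residualize

__all__ = [
    "ContrastMap",
    "ClassifierMetrics",
    "bh_fdr",
    "voxelwise_group_ttest",
    "baseline_comparison",
    "crossval_svm",
]


def bh_fdr(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask, in input order.

    Rejects every p <= p_(i*) where i* = max{i : p_(i) <= (i/m) q}.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError(f"q must lie in (0, 1), got {q}")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


@dataclass
class ContrastMap:
    """Voxelwise two-sample contrast with FDR thresholding."""

    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray  # significant after BH-FDR at level q
    q: float
    df: int
    n_a: int
    n_b: int


def _pooled_t(A: np.ndarray, B: np.ndarray, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sample pooled-variance t per feature column, with NaN for zero variance."""
    na, nb = A.shape[0], B.shape[0]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    ssa = ((A - ma) ** 2).sum(axis=0)
    ssb = ((B - mb) ** 2).sum(axis=0)
    sp2 = (ssa + ssb) / df
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    t = np.where(sp2 > 0, t, np.nan)
    p = 2.0 * stats.t.sf(np.abs(t), df=df)
    return t, p


def voxelwise_group_ttest(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    covariates: pd.DataFrame | None = None,
    q: float = 0.005,
) -> ContrastMap:
    """Two-sample t map of group A minus group B with BH-FDR control.

    ``maps_a`` / ``maps_b`` are subjects x voxels matrices.  When
    covariates are supplied (rows for group A first, then group B) the
    values are residualized against the confound design before testing,
    and the degrees of freedom are reduced by the number of non-intercept
    design columns.  Voxels with zero pooled variance are flagged NaN and
    excluded from the FDR family.
    """
    A = np.asarray(maps_a, dtype=float)
    B = np.asarray(maps_b, dtype=float)
    if A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the voxel grid")
    n_cov = 0
    if covariates is not None:
        if len(covariates) != A.shape[0] + B.shape[0]:
            raise ValueError("covariate rows must match the stacked groups")
        stacked = residualize(np.vstack([A, B]), covariates)
        from .feature_selection import confound_design

        n_cov = confound_design(covariates).shape[1] - 1
        A, B = stacked[: A.shape[0]], stacked[A.shape[0] :]
    df = A.shape[0] + B.shape[0] - 2 - n_cov
    t, p = _pooled_t(A, B, df)
    mask = np.zeros(t.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        mask[ok] = bh_fdr(p[ok], q)
    return ContrastMap(t=t, p=p, mask=mask, q=float(q), df=df, n_a=A.shape[0], n_b=B.shape[0])


def baseline_comparison(
    cohort: pd.DataFrame,
    labels: np.ndarray,
    continuous: tuple[str, ...],
    categorical: tuple[str, ...] = (),
    q: float = 0.05,
    confounds: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group comparison table for baseline demographic/clinical variables.

    Continuous variables: two-sample t on confound-residualized values
    (complete cases per variable).  Categorical variables: Pearson
    chi-square on the contingency table.  BH-FDR at ``q`` across the whole
    variable family.  Output has one row per variable with group
    mean (SD), the test statistic, raw and adjusted p.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size != 2:
        raise ValueError("baseline comparison expects exactly two groups")
    rows = []
    for var in continuous:
        x = cohort[var].to_numpy(float)
        ok = np.isfinite(x)
        vals = x[ok][:, None]
        if confounds is not None:
            vals = residualize(vals, confounds.iloc[np.flatnonzero(ok)])
        a = vals[labels[ok] == groups[0], 0]
        b = vals[labels[ok] == groups[1], 0]
        if np.ptp(np.concatenate([a, b])) == 0:
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_ind(a, b)
        rows.append(
            {
                "variable": var,
                "kind": "continuous",
                f"mean_sd_{groups[0]}": f"{x[ok][labels[ok] == groups[0]].mean():.2f} ({x[ok][labels[ok] == groups[0]].std(ddof=1):.2f})",
                f"mean_sd_{groups[1]}": f"{x[ok][labels[ok] == groups[1]].mean():.2f} ({x[ok][labels[ok] == groups[1]].std(ddof=1):.2f})",
                "statistic": float(stat),
                "p": float(p),
            }
        )
    for var in categorical:
        tab = pd.crosstab(cohort[var], labels, dropna=False)
        expected = stats.contingency.expected_freq(tab.to_numpy())
        if (expected == 0).any():
            raise ValueError(f"chi-square for {var!r} has a zero expected cell; merge sparse categories")
        chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        rows.append(
            {
                "variable": var,
                "kind": "categorical",
                f"mean_sd_{groups[0]}": "",
                f"mean_sd_{groups[1]}": "",
                "statistic": float(chi2),
                "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    out.loc[:, "p_fdr"] = multipletests(out["p"].to_numpy(), alpha=q, method="fdr_bh")[1]
    out["significant"] = bh_fdr(out["p"].to_numpy(), q)
    return out


@dataclass
class ClassifierMetrics:
    """Pooled out-of-fold performance of the biotype classifier."""

    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    confusion: np.ndarray  # pooled 2x2, rows = truth (pos, neg)
    fold_confusions: list[np.ndarray]
    positive_class: int
    folds: int
    seed: int
    predictions: np.ndarray | None = None  # pooled out-of-fold labels
    decision_values: np.ndarray | None = None


def crossval_svm(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    gamma: str | float = "scale",
    positive_class: int | None = None,
) -> ClassifierMetrics:
    """Stratified k-fold cross-validated Gaussian-kernel SVM.

    Feature standardization is fitted on each training split only and
    applied to the held-out fold, so no information leaks across the
    split.  Metrics are computed from the pooled out-of-fold predictions;
    the positive class defaults to the minority biotype (biotype 1) and
    the AUC comes from the pooled decision values.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("biotype diagnosis is a two-class problem")
    if counts.min() < folds:
        raise ValueError(f"each class needs >= {folds} members for {folds}-fold stratified CV")
    if positive_class is None:
        positive_class = classes[np.argmin(counts)]
    neg_class = classes[classes != positive_class][0]

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty(y.shape, dtype=y.dtype)
    decision = np.empty(y.shape, dtype=float)
    fold_confusions = []
    for train, test in skf.split(X, y):
        clf = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=C, gamma=gamma))
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
        d = clf.decision_function(X[test])
        # decision_function is signed toward the lexically larger class
        decision[test] = d if clf.classes_[1] == positive_class else -d
        tp = int(((pred[test] == positive_class) & (y[test] == positive_class)).sum())
        fn = int(((pred[test] != positive_class) & (y[test] == positive_class)).sum())
        fp = int(((pred[test] == positive_class) & (y[test] != positive_class)).sum())
        tn = int(((pred[test] != positive_class) & (y[test] != positive_class)).sum())
        fold_confusions.append(np.array([[tp, fn], [fp, tn]]))

    confusion = np.sum(fold_confusions, axis=0)
    tp, fn = confusion[0]
    fp, tn = confusion[1]
    n = tp + fn + fp + tn
    auc = float(roc_auc_score((y == positive_class).astype(int), decision))
    return ClassifierMetrics(
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        auc=auc,
        confusion=confusion,
        fold_confusions=fold_confusions,
        positive_class=int(positive_class),
        folds=folds,
        seed=seed,
        predictions=pred,
        decision_values=decision,
    )
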