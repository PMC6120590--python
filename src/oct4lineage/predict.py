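"""Predicting pro-fate from pre-stimulus single-cell features.

Cells that completed a full cell cycle before the stimulus contribute
three predictors — lifetime-mean OCT4 level (a.f.u.), pulse frequency
(per hour) and cell-cycle duration (hours) — and a binary pro-fate
label.  A binomial GLM with logit link supplies coefficients and Wald
p-values; predictive accuracy is estimated by seeded stratified
five-fold cross-validation, pooling held-out calls at a posterior
threshold of 0.5.  Pro-mixed cells are excluded from the binary
training set but kept in the per-group feature distributions that the
Kolmogorov-Smirnov comparisons use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import ks_2samp
from sklearn.model_selection import StratifiedKFold

from .fates import PRO_DIFF, PRO_MIXED, PRO_SELF
from .lineage import CellSummary, LineageForest, filter_complete_before

__all__ = [
    "FEATURES",
    "ClassifierFit",
    "extract_features",
    "compare_groups",
    "train_logistic",
    "decision_surface",
]

FEATURES = ("mean_oct4", "pulse_frequency", "cycle_duration")


def extract_features(
    forest: LineageForest,
    summaries: dict[str, CellSummary],
    profate_labels: dict[str, str],
    t0: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble feature rows for cells with a full pre-stimulus cycle.

    Returns ``(training, groups)``: ``training`` holds only pro-self /
    pro-diff cells (the binary classification set); ``groups`` also
    keeps pro-mixed cells for the three-way feature-distribution
    comparisons.  Cells with undetermined pro-fate, censored cycles or
    missing pulse frequency are dropped from both.
    """
    rows = []
    for cid in sorted(filter_complete_before(forest, t0)):
        s = summaries.get(cid)
        lab = profate_labels.get(cid)
        if s is None or lab not in (PRO_SELF, PRO_DIFF, PRO_MIXED):
            continue
        if s.cycle_duration is None or s.pulse_frequency is None:
            continue
        rows.append(
            {
                "cell_id": cid,
                "mean_oct4": s.mean_level,
                "pulse_frequency": s.pulse_frequency,
                "cycle_duration": s.cycle_duration,
                "label": lab,
            }
        )
    groups = pd.DataFrame(
        rows, columns=["cell_id", *FEATURES, "label"]
    )
    training = groups[groups["label"] != PRO_MIXED].reset_index(drop=True)
    return training, groups


def compare_groups(groups: pd.DataFrame) -> pd.DataFrame:
    """Pairwise two-sample KS tests per feature across pro-fate groups.

    Output columns: feature, group_a, group_b, n_a, n_b, ks_d, p_value,
    tier (*** for p < 0.0005, * for p < 0.05, ns otherwise).  Pairs with
    fewer than two observations on either side get null statistics.
    """
    labels = sorted(groups["label"].unique())
    out = []
    for feat in FEATURES:
        for i, ga in enumerate(labels):
            for gb in labels[i + 1 :]:
                a = groups.loc[groups["label"] == ga, feat].to_numpy()
                b = groups.loc[groups["label"] == gb, feat].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    d = p = np.nan
                else:
                    res = ks_2samp(a, b)
                    d, p = float(res.statistic), float(res.pvalue)
                tier = "ns"
                if np.isfinite(p):
                    if p < 0.0005:
                        tier = "***"
                    elif p < 0.05:
                        tier = "*"
                out.append(
                    {
                        "feature": feat,
                        "group_a": ga,
                        "group_b": gb,
                        "n_a": len(a),
                        "n_b": len(b),
                        "ks_d": d,
                        "p_value": p,
                        "tier": tier,
                    }
                )
    return pd.DataFrame(out)


@dataclass
class ClassifierFit:
    """Fitted logistic model on z-scored predictors plus CV accuracy.

    ``coefficients``/``p_values`` are keyed by predictor name (plus
    ``intercept``); ``feature_means``/``feature_sds`` record the
    standardization so raw-feature probabilities can be evaluated.
    Positive class is pro-diff (label 1).
    """

    coefficients: dict[str, float]
    p_values: dict[str, float]
    cv_accuracy: float
    fold_assignments: np.ndarray
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    seed: int
    separation_warning: bool = False
    n_obs: int = 0
    class_balance: dict[str, int] = field(default_factory=dict)

    def predict_proba(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """P(pro-diff) for raw (unstandardized) feature rows."""
        if isinstance(X, pd.DataFrame):
            X = X[list(FEATURES)].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        z = (X - np.array([self.feature_means[f] for f in FEATURES])) / np.array(
            [self.feature_sds[f] for f in FEATURES]
        )
        eta = self.coefficients["intercept"] + z @ np.array(
            [self.coefficients[f] for f in FEATURES]
        )
        return 1.0 / (1.0 + np.exp(-eta))

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients,
            "p_values": self.p_values,
            "cv_accuracy": self.cv_accuracy,
            "folds": self.fold_assignments.tolist(),
            "feature_means": self.feature_means,
            "feature_sds": self.feature_sds,
            "seed": self.seed,
            "separation_warning": self.separation_warning,
            "n_obs": self.n_obs,
            "class_balance": self.class_balance,
        }


def _fit_glm(z: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    """Binomial GLM fit; ridge-stabilized fallback on perfect separation."""
    X = sm.add_constant(z, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
            return np.asarray(res.params), np.asarray(res.pvalues), False
        except Exception:
            pass
    # perfect or quasi-separation: small L2 penalty keeps estimates finite;
    # Wald p-values are not meaningful under the penalty and are reported NaN
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
        alpha=1e-3, L1_wt=0.0
    )
    params = np.asarray(res.params)
    return params, np.full_like(params, np.nan), True


def train_logistic(
    features: pd.DataFrame, *, k: int = 5, seed: int = 0
) -> ClassifierFit:
    """Fit the pro-fate logistic model and estimate CV accuracy.

    Predictors are z-scored on the full data (fitted probabilities and
    p-values are invariant to this).  Accuracy is the pooled fraction
    of held-out cells called correctly at posterior 0.5 over ``k``
    seeded stratified folds.  Raises on single-class input.
    """
    labels = features["label"].to_numpy()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("logistic training needs both pro-fate classes")
    y = (labels == PRO_DIFF).astype(int)
    X = features[list(FEATURES)].to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (X - mu) / sd

    params, pvals, sep = _fit_glm(z, y)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    correct = 0
    for f, (tr, te) in enumerate(skf.split(z, y)):
        folds[te] = f
        p_tr, _, _ = _fit_glm(z[tr], y[tr])
        eta = p_tr[0] + z[te] @ p_tr[1:]
        correct += int(np.sum((eta > 0).astype(int) == y[te]))

    names = ["intercept", *FEATURES]
    return ClassifierFit(
        coefficients=dict(zip(names, map(float, params))),
        p_values=dict(zip(names, map(float, pvals))),
        cv_accuracy=correct / len(y),
        fold_assignments=folds,
        feature_means=dict(zip(FEATURES, map(float, mu))),
        feature_sds=dict(zip(FEATURES, map(float, sd))),
        seed=seed,
        separation_warning=sep,
        n_obs=len(y),
        class_balance={c: int(np.sum(labels == c)) for c in classes},
    )


def decision_surface(
    fit: ClassifierFit,
    fixed: dict[str, float],
    grid: dict[str, np.ndarray] | None = None,
    n_points: int = 50,
) -> pd.DataFrame:
    """Posterior P(pro-diff) on a 2-D slice of feature space.

    ``fixed`` pins exactly one of the three predictors (the published
    slices fix cycle_duration = 14 h or pulse_frequency = 0.25 / h);
    the other two span ``grid`` (or a default range of +/-2.5 SD around
    the training mean).  Long-format output: one row per grid node.
    """
    if len(fixed) != 1 or next(iter(fixed)) not in FEATURES:
        raise ValueError(f"fixed must name exactly one of {FEATURES}")
    fixed_name = next(iter(fixed))
    free = [f for f in FEATURES if f != fixed_name]
    grid = dict(grid or {})
    for f in free:
        if f not in grid:
            m, s = fit.feature_means[f], fit.feature_sds[f]
            grid[f] = np.linspace(m - 2.5 * s, m + 2.5 * s, n_points)
    g0, g1 = np.meshgrid(grid[free[0]], grid[free[1]], indexing="ij")
    rows = pd.DataFrame(
        {
            free[0]: g0.ravel(),
            free[1]: g1.ravel(),
            fixed_name: fixed[fixed_name],
        }
    )
    rows["p_diff"] = fit.predict_proba(rows)
    return rows
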