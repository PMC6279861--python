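"""Stratified train/test splitting and multivariable logistic models.

The three contrasts mirror the study design: Model 1 NWM vs dNAWM,
Model 2 non-dNAWM vs dNAWM, Model 3 NWM vs non-dNAWM.  Features selected
by the LASSO stage are refit with an *unpenalized* maximum-likelihood
logistic regression (selection/estimation split); standardization
statistics are estimated on the training rows only and reused verbatim at
prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InvalidArgumentError
from .selection import FeatureMatrix, SelectionResult

CONTRASTS = {
    "model1": ("NWM", "dNAWM"),
    "model2": ("non_dNAWM", "dNAWM"),
    "model3": ("NWM", "non_dNAWM"),
}


def split_train_test(
    labels: np.ndarray | pd.Series,
    train_fraction: float = 0.7,
    seed: int = 0,
    stratify: bool = True,
) -> np.ndarray:
    """Random train/test assignment, stratified by class by default.

    The per-class training count is ``round(train_fraction * n_class)``
    (half-up), so a balanced 51/51 cohort at fraction 0.7 yields the
    72-train / 30-test split of the study design.
    """
    labels = np.asarray(labels)
    if not 0.0 < train_fraction <= 1.0:
        raise InvalidArgumentError("train_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(labels), dtype=object)
    groups = [np.arange(len(labels))] if not stratify else [
        np.nonzero(labels == v)[0] for v in np.unique(labels)
    ]
    for idx in groups:
        if stratify and len(idx) < 2:
            raise InvalidArgumentError("every class needs at least 2 samples")
        n_train = int(np.floor(train_fraction * len(idx) + 0.5))
        perm = rng.permutation(idx)
        assignment[perm[:n_train]] = "train"
        assignment[perm[n_train:]] = "test"
    return assignment.astype(str)


@dataclass
class LogisticModel:
    """Unpenalized logistic fit on standardized selected features."""

    intercept: float
    weights: dict[str, float]
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    contrast: str = ""
    n_train: int = 0
    converged: bool = True
    separation_flag: bool = False
    fallback_stage2: bool = False

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "weights": self.weights,
            "feature_means": self.feature_means,
            "feature_sds": self.feature_sds,
            "contrast": self.contrast,
            "n_train": self.n_train,
            "converged": self.converged,
            "separation_flag": self.separation_flag,
            "fallback_stage2": self.fallback_stage2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(**d)


@dataclass
class ModelResult:
    model: LogisticModel
    prob_train: pd.Series
    prob_test: pd.Series
    y_train: pd.Series
    y_test: pd.Series
    selection: SelectionResult | None = None
    evaluation: dict = field(default_factory=dict)


def fit_logistic(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    contrast: str = "",
    tol: float = 1e-8,
) -> LogisticModel:
    """Maximum-likelihood logistic regression on standardized features.

    Complete separation is detected (via statsmodels' perfect-prediction
    check) and flagged rather than silently returning unstable
    coefficients; non-convergence raises.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[0] != len(y):
        raise InvalidArgumentError("X and y lengths differ")
    means = X.mean()
    sds = X.std(ddof=0)
    if (sds == 0).any():
        raise InvalidArgumentError(
            f"constant features cannot be standardized: "
            f"{list(sds.index[sds == 0])}"
        )
    Z = (X - means) / sds
    design = sm.add_constant(Z.to_numpy(), has_constant="add")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(disp=0, method="newton", tol=tol, maxiter=200)
        except Exception as exc:  # statsmodels PerfectSeparationError
            if "separation" in str(exc).lower() or "Singular" in str(exc):
                separation = True
                res = sm.Logit(y, design).fit_regularized(
                    disp=0, alpha=1e-6, maxiter=500
                )
            else:
                raise
        for w in caught:
            if "separat" in str(w.message).lower():
                separation = True
    converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
    if not converged and not separation:
        raise RuntimeError(f"logistic fit did not converge for {contrast or 'model'}")
    params = np.asarray(res.params, dtype=float)
    if separation:
        warnings.warn(
            f"complete separation detected in {contrast or 'model'}; "
            "coefficients are unstable",
            UserWarning,
            stacklevel=2,
        )
    return LogisticModel(
        intercept=float(params[0]),
        weights={n: float(w) for n, w in zip(X.columns, params[1:])},
        feature_means=means.to_dict(),
        feature_sds=sds.to_dict(),
        contrast=contrast,
        n_train=len(y),
        converged=converged or separation,
        separation_flag=separation,
    )


def predict_prob(model: LogisticModel, x) -> float | pd.Series:
    """Logistic probability 1/(1+exp(-eta)) using the training
    standardization statistics.

    Accepts a mapping/Series (returns a float) or a DataFrame (returns a
    Series).  A missing model feature raises, naming the feature.
    """
    if isinstance(x, pd.DataFrame):
        frame = x
        scalar = False
    else:
        frame = pd.DataFrame([dict(x)])
        scalar = True
    missing = [n for n in model.weights if n not in frame.columns]
    if missing:
        raise InvalidArgumentError(f"missing model feature(s): {missing}")
    eta = np.full(len(frame), model.intercept)
    for name, w in model.weights.items():
        z = (frame[name].to_numpy(dtype=float) - model.feature_means[name]) / (
            model.feature_sds[name]
        )
        eta = eta + w * z
    prob = 1.0 / (1.0 + np.exp(-eta))
    if scalar:
        return float(prob[0])
    return pd.Series(prob, index=frame.index)


def build_model(
    fm: FeatureMatrix, selection: SelectionResult, contrast: str = ""
) -> ModelResult:
    """Fit the contrast model on the training rows of ``fm`` using the
    stage-3 survivors (falling back to stage-2 survivors when the LASSO
    kept nothing) and predict both splits."""
    features = selection.stage3_survivors
    fallback = False
    if not features:
        features = selection.stage2_survivors
        fallback = True
        warnings.warn(
            f"empty LASSO selection for {contrast or 'model'}; "
            "falling back to stage-2 survivors",
            UserWarning,
            stacklevel=2,
        )
    if not features:
        raise InvalidArgumentError("no features available to fit")
    train_mask = fm.split == "train"
    model = fit_logistic(
        fm.features.loc[train_mask, features], fm.labels[train_mask], contrast=contrast
    )
    model.fallback_stage2 = fallback
    prob_train = predict_prob(model, fm.features.loc[train_mask, features])
    prob_test = predict_prob(model, fm.features.loc[~train_mask, features])
    return ModelResult(
        model=model,
        prob_train=prob_train,
        prob_test=prob_test,
        y_train=fm.labels[train_mask],
        y_test=fm.labels[~train_mask],
        selection=selection,
    )
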