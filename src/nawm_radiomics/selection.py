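"""Three-stage feature-selection cascade.

Stage 1: univariate filtering — a feature survives when it is significant
under *both* the two-group ANOVA (equivalent to the t-test) and the
Mann–Whitney U test (two-sided, normal approximation with tie correction).
Stage 2: Spearman redundancy pruning — among pairs with \\|rho\\| above the
threshold, the member with the larger mean absolute correlation against the
remaining features is dropped, deterministically.
Stage 3: L1-penalized (LASSO) logistic regression with the penalty chosen
by stratified cross-validated deviance; features with nonzero coefficients
survive.

All stages operate on training rows only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .errors import InvalidArgumentError

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Samples x features table with class labels and train/test split.

    ``labels`` is a binary {0, 1} vector for the active contrast; ``split``
    holds the strings "train"/"test".  Rows or columns with missing values
    must be excluded before the cascade (see :meth:`drop_missing`).
    """

    features: pd.DataFrame
    labels: pd.Series
    split: pd.Series

    def __post_init__(self) -> None:
        if not self.features.index.equals(self.labels.index) or not self.features.index.equals(
            self.split.index
        ):
            raise InvalidArgumentError("features/labels/split indexes must align")
        bad = set(np.unique(self.labels)) - {0, 1}
        if bad:
            raise InvalidArgumentError(f"labels must be binary 0/1, got extras {bad}")

    def drop_missing(self) -> "FeatureMatrix":
        """Exclude feature columns containing any non-finite value, with a
        logged report."""
        finite = np.isfinite(self.features.to_numpy()).all(axis=0)
        dropped = list(self.features.columns[~finite])
        if dropped:
            logger.info("excluding %d features with flagged missing values: %s",
                        len(dropped), dropped[:10])
        return FeatureMatrix(
            self.features.loc[:, finite], self.labels, self.split
        )

    @property
    def train(self) -> "FeatureMatrix":
        m = self.split == "train"
        return FeatureMatrix(self.features[m], self.labels[m], self.split[m])


@dataclass
class SelectionResult:
    stage1_survivors: list[str]
    stage2_survivors: list[str]
    stage3_survivors: list[str]
    lasso_lambda: float
    nonzero_weights: dict[str, float]
    univariate_p: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage1_survivors": self.stage1_survivors,
            "stage2_survivors": self.stage2_survivors,
            "stage3_survivors": self.stage3_survivors,
            "lasso_lambda": self.lasso_lambda,
            "nonzero_weights": self.nonzero_weights,
        }


@dataclass
class SelectionConfig:
    alpha: float = 0.05
    combine: str = "both"  # "both" (intersection) or "either"
    rho_max: float = 0.9
    n_folds: int = 10
    bh_correction: bool = False

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "combine": self.combine,
            "rho_max": self.rho_max,
            "n_folds": self.n_folds,
            "bh_correction": self.bh_correction,
        }


# ---------------------------------------------------------------------------
# stage 1


def univariate_filter(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    alpha: float = 0.05,
    combine: str = "both",
    bh_correction: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Keep features significant under the ANOVA and the Mann–Whitney test.

    Returns the surviving names (input column order) and a per-feature
    p-value table with columns ``p_anova``, ``p_mw`` and ``p_max``.
    Constant features are excluded with a warning (the tests are undefined
    on them).
    """
    y = np.asarray(y)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise InvalidArgumentError("need at least 2 samples per class")
    rows = {}
    for name in X.columns:
        v = X[name].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            warnings.warn(f"constant feature {name!r} excluded from stage 1",
                          UserWarning, stacklevel=2)
            continue
        a, b = v[y == 0], v[y == 1]
        p_anova = float(sps.f_oneway(a, b).pvalue)
        p_mw = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        rows[name] = (p_anova, p_mw)
    ptab = pd.DataFrame(rows, index=["p_anova", "p_mw"]).T
    if bh_correction and len(ptab):
        from statsmodels.stats.multitest import multipletests

        for col in ("p_anova", "p_mw"):
            ptab[col] = multipletests(ptab[col], method="fdr_bh")[1]
    if combine == "both":
        ptab["p_max"] = ptab.max(axis=1)
        keep = (ptab["p_anova"] <= alpha) & (ptab["p_mw"] <= alpha)
    elif combine == "either":
        ptab["p_max"] = ptab.min(axis=1)
        keep = (ptab["p_anova"] <= alpha) | (ptab["p_mw"] <= alpha)
    else:
        raise InvalidArgumentError("combine must be 'both' or 'either'")
    survivors = [n for n in X.columns if n in ptab.index and keep[n]]
    return survivors, ptab


# ---------------------------------------------------------------------------
# stage 2


def redundancy_filter(
    X: pd.DataFrame,
    rho_max: float = 0.9,
    univariate_p: pd.Series | dict | None = None,
) -> list[str]:
    """Greedy Spearman pruning.

    While some remaining pair has \\|rho\\| > ``rho_max``: take the pair with
    the largest \\|rho\\| (ties by name pair); drop its member with the larger
    mean \\|rho\\| against all other remaining features (ties by larger
    univariate p, then by lexicographically larger name).
    """
    names = list(X.columns)
    if len(names) < 2:
        return names
    pvals = pd.Series(univariate_p) if univariate_p is not None else None
    rho = X.corr(method="spearman").abs().to_numpy()
    np.fill_diagonal(rho, 0.0)
    alive = list(range(len(names)))
    while True:
        sub = rho[np.ix_(alive, alive)]
        if sub.size == 0 or np.nanmax(sub) <= rho_max:
            break
        ai, aj = np.unravel_index(np.nanargmax(sub), sub.shape)
        i, j = alive[ai], alive[aj]

        def _drop_key(k: int) -> tuple:
            others = [o for o in alive if o != i and o != j]
            mean_rho = float(np.mean(rho[k, others])) if others else 0.0
            p = float(pvals.get(names[k], 0.0)) if pvals is not None else 0.0
            return (mean_rho, p, names[k])

        loser = max((i, j), key=_drop_key)
        alive.remove(loser)
    return [names[k] for k in sorted(alive)]


# ---------------------------------------------------------------------------
# stage 3


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    n_folds: int = 10,
    seed: int = 0,
    n_lambdas: int = 50,
) -> tuple[dict[str, float], float]:
    """L1-penalized logistic path with lambda chosen by stratified
    cross-validated deviance (minimum mean deviance).

    Features are standardized internally (training mean/SD).  Returns the
    nonzero coefficients (on the standardized scale) and the chosen lambda
    (sum-log-loss convention, lambda = 1/C).
    """
    y = np.asarray(y)
    n_per_class = min((y == 0).sum(), (y == 1).sum())
    if n_per_class < n_folds:
        raise InvalidArgumentError(
            f"need >= {n_folds} samples per class for {n_folds}-fold CV"
        )
    Z = (X - X.mean()) / X.std(ddof=0)
    Z = Z.loc[:, X.std(ddof=0) > 0]
    if Z.shape[1] == 0:
        warnings.warn("no non-constant feature for the LASSO", UserWarning, stacklevel=2)
        return {}, float("inf")
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    model = LogisticRegressionCV(
        Cs=np.logspace(-3.5, 2.5, n_lambdas),
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=2000,
        refit=True,
        random_state=seed,
    )
    model.fit(Z.to_numpy(), y)
    lam = float(1.0 / model.C_[0])
    coefs = model.coef_.ravel()
    nonzero = {n: float(c) for n, c in zip(Z.columns, coefs) if c != 0.0}
    if not nonzero:
        warnings.warn(
            "LASSO selected no feature at lambda_min; downstream models fall "
            "back to the stage-2 survivor set",
            UserWarning,
            stacklevel=2,
        )
    return nonzero, lam


# ---------------------------------------------------------------------------
# the cascade


def run_cascade(
    fm: FeatureMatrix, config: SelectionConfig | None = None, seed: int = 0
) -> SelectionResult:
    """Apply the three stages in sequence on the training rows only."""
    config = config or SelectionConfig()
    fm = fm.drop_missing()
    train = fm.train
    s1, ptab = univariate_filter(
        train.features,
        train.labels,
        alpha=config.alpha,
        combine=config.combine,
        bh_correction=config.bh_correction,
    )
    logger.info("stage 1: %d/%d features survive", len(s1), fm.features.shape[1])
    if len(s1) >= 2:
        s2 = redundancy_filter(
            train.features[s1], rho_max=config.rho_max, univariate_p=ptab["p_max"]
        )
    else:
        s2 = list(s1)
    logger.info("stage 2: %d features survive", len(s2))
    if s2:
        weights, lam = lasso_select(
            train.features[s2], train.labels, n_folds=config.n_folds, seed=seed
        )
    else:
        weights, lam = {}, float("inf")
    s3 = [n for n in s2 if n in weights]
    logger.info("stage 3: %d features survive (lambda=%.4g)", len(s3), lam)
    assert set(s3) <= set(s2) <= set(s1), "stage nesting violated"
    return SelectionResult(
        stage1_survivors=s1,
        stage2_survivors=s2,
        stage3_survivors=s3,
        lasso_lambda=lam,
        nonzero_weights=weights,
        univariate_p=ptab["p_max"].to_dict(),
    )
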