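"""Model evaluation statistics: ROC/AUC with confidence intervals,
Hosmer–Lemeshow calibration, and intraclass correlation for reader
agreement.

The AUC is the trapezoidal area under the empirical ROC curve, computed
via the rank (Mann–Whitney) identity with half credit for ties; its
default confidence interval is DeLong's, with a bootstrap alternative.
The operating point maximizes the Youden index.  The ICC form is
two-way random effects, absolute agreement, single measures — ICC(2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import roc_curve

from .errors import InvalidArgumentError


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    ci_method: str
    threshold: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "ci_method": self.ci_method,
            "operating_point": {
                "threshold": self.threshold,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            },
            "thresholds": self.thresholds.tolist(),
            "sensitivities": self.sensitivities.tolist(),
            "specificities": self.specificities.tolist(),
        }


@dataclass
class CalibrationResult:
    statistic: float
    df: int
    p_value: float
    table: pd.DataFrame  # per-group n, observed, expected

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "table": self.table.to_dict(orient="list"),
        }


@dataclass
class IccResult:
    icc: float
    ci: tuple[float, float]
    form: str = "two-way random, absolute agreement, single measures (ICC(2,1))"
    degenerate: bool = False


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the rank identity: (R1 - n1(n1+1)/2) / (n0*n1), average
    ranks giving half credit to ties.  Numerically exact."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n0 == 0 or n1 == 0:
        raise InvalidArgumentError("both classes must be present")
    ranks = sps.rankdata(scores)
    r1 = ranks[labels == 1].sum()
    return float((r1 - n1 * (n1 + 1) / 2.0) / (n0 * n1))


def _delong_ci(scores, labels, alpha=0.95):
    """DeLong variance of the AUC via the structural-component (midrank)
    decomposition."""
    pos = np.asarray(scores)[np.asarray(labels) == 1]
    neg = np.asarray(scores)[np.asarray(labels) == 0]
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = sps.rankdata(all_scores)
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = (r_all[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (r_all[:m] - r_pos) / n  # per-positive placement values
    v10 = 1.0 - (r_all[m:] - r_neg) / m
    var = 0.0
    if m > 1:
        var += np.var(v01, ddof=1) / m
    if n > 1:
        var += np.var(v10, ddof=1) / n
    z = sps.norm.ppf(0.5 + alpha / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(auc), (max(0.0, auc - half), min(1.0, auc + half))


def _bootstrap_ci(scores, labels, alpha=0.95, n_boot=2000, seed=0):
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos_idx = np.nonzero(labels == 1)[0]
    neg_idx = np.nonzero(labels == 0)[0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        idx = np.concatenate(
            [rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        )
        aucs[b] = auc_mann_whitney(scores[idx], labels[idx])
    lo, hi = np.percentile(aucs, [(1 - alpha) / 2 * 100, (1 + alpha) / 2 * 100])
    return float(lo), float(hi)


def roc_auc(
    probs,
    labels,
    ci_method: str = "delong",
    alpha: float = 0.95,
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """Empirical ROC curve, AUC with CI, and the Youden operating point
    (ties broken toward the lower threshold)."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(set(labels)) < 2:
        raise InvalidArgumentError("labels contain a single class")
    fpr, tpr, thr = roc_curve(labels, probs)
    sens, spec = tpr, 1.0 - fpr
    auc = auc_mann_whitney(probs, labels)
    if ci_method == "delong":
        _, ci = _delong_ci(probs, labels, alpha)
    elif ci_method == "bootstrap":
        ci = _bootstrap_ci(probs, labels, alpha, n_boot=n_boot, seed=seed)
    else:
        raise InvalidArgumentError("ci_method must be 'delong' or 'bootstrap'")
    youden = sens + spec - 1.0
    # thresholds from roc_curve are decreasing; the last argmax tie is the
    # lowest threshold
    best = len(youden) - 1 - int(np.argmax(youden[::-1]))
    return RocResult(
        thresholds=thr,
        sensitivities=sens,
        specificities=spec,
        auc=auc,
        auc_ci=ci,
        ci_method=ci_method,
        threshold=float(thr[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
    )


def hosmer_lemeshow(probs, labels, groups: int = 10) -> CalibrationResult:
    """Deciles-of-risk Hosmer–Lemeshow goodness-of-fit test.

    Groups are quantile bins of the predicted probability with ties kept
    together; groups whose expected event or non-event count is ~0 are
    merged with their neighbor.  The statistic sums
    (O - E)^2 / (E (1 - E/n_g)) over groups; df = groups - 2.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels).astype(int)
    if len(probs) < groups:
        raise InvalidArgumentError("need at least as many samples as groups")
    try:
        bins = pd.qcut(probs, groups, labels=False, duplicates="drop")
    except (ValueError, IndexError):
        bins = np.zeros(len(probs), dtype=int)
    if np.all(pd.isna(bins)):
        bins = np.zeros(len(probs), dtype=int)
    df = pd.DataFrame({"p": probs, "y": labels, "g": bins})
    agg = (
        df.groupby("g")
        .agg(n=("y", "size"), observed=("y", "sum"), expected=("p", "sum"))
        .reset_index(drop=True)
    )
    # merge degenerate groups (expected events or non-events ~ 0) forward
    rows = agg.to_dict(orient="records")
    merged: list[dict] = []
    for row in rows:
        if merged and (
            merged[-1]["expected"] < 1e-9
            or merged[-1]["n"] - merged[-1]["expected"] < 1e-9
        ):
            merged[-1] = {
                "n": merged[-1]["n"] + row["n"],
                "observed": merged[-1]["observed"] + row["observed"],
                "expected": merged[-1]["expected"] + row["expected"],
            }
        else:
            merged.append(dict(row))
    if len(merged) > 1 and (
        merged[-1]["expected"] < 1e-9 or merged[-1]["n"] - merged[-1]["expected"] < 1e-9
    ):
        last = merged.pop()
        merged[-1] = {
            "n": merged[-1]["n"] + last["n"],
            "observed": merged[-1]["observed"] + last["observed"],
            "expected": merged[-1]["expected"] + last["expected"],
        }
    table = pd.DataFrame(merged)
    n_g = table["n"].to_numpy(dtype=float)
    o = table["observed"].to_numpy(dtype=float)
    e = table["expected"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (o - e) ** 2 / (e * (1.0 - e / n_g))
    stat = float(np.nansum(terms))
    dof = max(len(table) - 2, 0)
    # with < 3 risk groups the chi-square reference has no degrees of
    # freedom left; the statistic is still reported, the p-value is not
    p = float(sps.chi2.sf(stat, dof)) if dof >= 1 else float("nan")
    return CalibrationResult(statistic=stat, df=dof, p_value=p, table=table)


def icc(ratings, alpha: float = 0.95) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single
    measures, with an F-distribution confidence interval.

    ``ratings`` is a subjects x raters array.  Zero between-subject
    variance yields icc = 0 with the degenerate flag set.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 5:
        raise InvalidArgumentError("need >= 5 subjects and >= 2 raters")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if msr <= mse or denom <= 0:
        return IccResult(icc=0.0, ci=(0.0, 0.0), degenerate=True)
    value = (msr - mse) / denom
    # McGraw & Wong CI for ICC(A,1)
    fj = msc / mse if mse > 0 else np.inf
    a = (k * value) / (n * (1.0 - value))
    b = 1.0 + (k * value * (n - 1.0)) / (n * (1.0 - value))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        v = (a * fj + b) ** 2 / (
            (a * fj) ** 2 / (k - 1) + b**2 / ((n - 1) * (k - 1))
        )
    f1 = sps.f.ppf(0.5 + alpha / 2.0, n - 1, v)
    f2 = sps.f.ppf(0.5 + alpha / 2.0, v, n - 1)
    lower = n * (msr - f1 * mse) / (
        f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f2 * msr
    )
    return IccResult(icc=float(value), ci=(float(lower), float(upper)))


def icc_per_feature(ratings_a: pd.DataFrame, ratings_b: pd.DataFrame) -> pd.Series:
    """ICC(2,1) for every shared feature column of two reader tables
    (index = subjects); summarize reproducibility as a range."""
    common = [c for c in ratings_a.columns if c in ratings_b.columns]
    out = {}
    for c in common:
        pair = np.column_stack(
            [ratings_a[c].to_numpy(dtype=float), ratings_b[c].to_numpy(dtype=float)]
        )
        out[c] = icc(pair).icc
    return pd.Series(out)
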