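"""Baseline-characteristics statistics for the case/control table:
2x2 chi-square tests (no continuity correction by default), the
two-sample t-test (pooled or Welch, from raw samples or printed
summaries), and the Mann–Whitney U test for scan intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidArgumentError


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts: a = case positive, b = case negative, c = control positive,
    d = control negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise InvalidArgumentError("counts must be non-negative")


def chi_square_2x2(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    correction: bool = False,
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, df = 1.

    Yates continuity correction is off by default.  Zero marginals are
    rejected (the statistic is undefined).
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    counts = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise InvalidArgumentError("all marginals must be positive")
    res = sps.chi2_contingency(counts, correction=correction)
    return float(res.statistic), float(res.pvalue)


def t_test_two_sample(
    x,
    y,
    pooled: bool = True,
) -> tuple[float, float, float]:
    """Student's (pooled, default) or Welch t-test.

    ``x`` and ``y`` are either raw 1D samples or ``(n, mean, sd)``
    summary triples (sample SD); both modes share the same closed form.
    Returns (t, df, two-sided p).
    """

    def _summary(v):
        if isinstance(v, tuple) and len(v) == 3:
            n, m, s = v
            return int(n), float(m), float(s)
        arr = np.asarray(v, dtype=float)
        return len(arr), float(arr.mean()), float(arr.std(ddof=1))

    n1, m1, s1 = _summary(x)
    n2, m2, s2 = _summary(y)
    if n1 < 2 or n2 < 2:
        raise InvalidArgumentError("need n >= 2 per group")
    if s1 == 0 and s2 == 0:
        raise InvalidArgumentError("zero variance in both groups")
    if pooled:
        sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        df = n1 + n2 - 2
    else:
        se = np.sqrt(s1**2 / n1 + s2**2 / n2)
        df = se**4 / (
            (s1**2 / n1) ** 2 / (n1 - 1) + (s2**2 / n2) ** 2 / (n2 - 1)
        )
    t = (m1 - m2) / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with tie-corrected normal approximation.

    Reports the min(U_x, U_y) convention, so fully dominated samples give
    U = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise InvalidArgumentError("need n >= 1 per group")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    u = min(float(res.statistic), len(x) * len(y) - float(res.statistic))
    return u, float(res.pvalue)


_BINARY_CHARACTERISTICS = (
    ("female", "Female (%)"),
    ("hypertension", "Hypertension (%)"),
    ("diabetes", "Diabetic (%)"),
    ("hyperlipidemia", "Hyperlipidemia (%)"),
    ("smoking", "Smoking (%)"),
    ("drinking", "Drinking (%)"),
    ("atrial_fibrillation", "Atrial fibrillation (%)"),
)


def cohort_table(manifest: pd.DataFrame) -> pd.DataFrame:
    """Baseline-characteristics table from a cohort manifest (one row per
    subject is extracted from the per-ROI manifest).

    Binary risk factors get chi-square tests, age the pooled t-test, the
    scan interval the Mann–Whitney U test; Fazekas scores are summarized
    descriptively only.
    """
    subjects = manifest.drop_duplicates("subject_id")
    cases = subjects[subjects["group"] == "case"]
    controls = subjects[subjects["group"] == "control"]
    if len(cases) == 0 or len(controls) == 0:
        raise InvalidArgumentError("manifest must contain both groups")
    rows = []
    for key, pretty in _BINARY_CHARACTERISTICS:
        if key == "female":
            pos_case = int((cases["sex"] == "F").sum())
            pos_ctrl = int((controls["sex"] == "F").sum())
        else:
            if key not in subjects.columns:
                continue
            pos_case = int(cases[key].astype(bool).sum())
            pos_ctrl = int(controls[key].astype(bool).sum())
        tab = ContingencyTable2x2(
            pos_case, len(cases) - pos_case, pos_ctrl, len(controls) - pos_ctrl
        )
        stat, p = chi_square_2x2(tab)
        rows.append(
            {
                "characteristic": pretty,
                "case": f"{pos_case} ({100 * pos_case / len(cases):.2f}%)",
                "control": f"{pos_ctrl} ({100 * pos_ctrl / len(controls):.2f}%)",
                "test": "chi-square",
                "statistic": round(stat, 3),
                "p_value": round(p, 3),
            }
        )
    if "age" in subjects.columns:
        t, _, p = t_test_two_sample(
            cases["age"].to_numpy(), controls["age"].to_numpy()
        )
        rows.append(
            {
                "characteristic": "Age (mean ± SD)",
                "case": f"{cases['age'].mean():.2f} ± {cases['age'].std(ddof=1):.2f}",
                "control": f"{controls['age'].mean():.2f} ± {controls['age'].std(ddof=1):.2f}",
                "test": "t-test",
                "statistic": round(t, 3),
                "p_value": round(p, 3),
            }
        )
    if "interval_days" in subjects.columns:
        u, p = mann_whitney_u(
            cases["interval_days"].to_numpy(), controls["interval_days"].to_numpy()
        )

        def _iqr(v):
            q1, q2, q3 = np.percentile(v, [25, 50, 75])
            return f"{q2:.0f} ({q1:.0f}, {q3:.0f})"

        rows.append(
            {
                "characteristic": "Interval time (median, IQR)",
                "case": _iqr(cases["interval_days"]),
                "control": _iqr(controls["interval_days"]),
                "test": "mann-whitney",
                "statistic": round(u, 2),
                "p_value": round(p, 3),
            }
        )
    if "fazekas" in subjects.columns:
        rows.append(
            {
                "characteristic": "Fazekas (median)",
                "case": f"{cases['fazekas'].median():.0f}",
                "control": f"{controls['fazekas'].median():.0f}",
                "test": "descriptive",
                "statistic": float("nan"),
                "p_value": float("nan"),
            }
        )
    return pd.DataFrame(rows)
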