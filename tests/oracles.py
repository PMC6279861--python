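"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately written as naive loops, separate from the
package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np

_VECTORS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_brute(grid: np.ndarray, n_gray: int, angle: int, offset: int,
               symmetric: bool = True) -> np.ndarray | None:
    """O(N) per-pixel double loop co-occurrence count; None if no pair."""
    dr, dc = _VECTORS[angle]
    dr, dc = dr * offset, dc * offset
    n_rows, n_cols = grid.shape
    count = np.zeros((n_gray, n_gray))
    for r in range(n_rows):
        for c in range(n_cols):
            if grid[r, c] <= 0:
                continue
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < n_rows and 0 <= c2 < n_cols and grid[r2, c2] > 0:
                count[grid[r, c] - 1, grid[r2, c2] - 1] += 1
    if symmetric:
        count = count + count.T
    total = count.sum()
    if total == 0:
        return None
    return count / total


def glcm_features_brute(p: np.ndarray, log_base: float = 2.0) -> dict[str, float]:
    """Element-wise direct summation of every Haralick feature."""
    ng = p.shape[0]
    log = lambda v: np.log(v) / np.log(log_base)
    energy = entropy = idm = contrast = 0.0
    mu_x = mu_y = 0.0
    px = [p[i, :].sum() for i in range(ng)]
    py = [p[:, j].sum() for j in range(ng)]
    for i in range(ng):
        mu_x += (i + 1) * px[i]
        mu_y += (i + 1) * py[i]
    var_x = sum((i + 1 - mu_x) ** 2 * px[i] for i in range(ng))
    var_y = sum((j + 1 - mu_y) ** 2 * py[j] for j in range(ng))
    p_sum = {}
    p_diff = {}
    corr_num = shade = prom = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            energy += v**2
            if v > 0:
                entropy -= v * log(v)
            idm += v / (1 + (i - j) ** 2)
            contrast += (i - j) ** 2 * v
            corr_num += (i + 1 - mu_x) * (j + 1 - mu_y) * v
            shade += (i + j + 2 - mu_x - mu_y) ** 3 * v
            prom += (i + j + 2 - mu_x - mu_y) ** 4 * v
            p_sum[i + j + 2] = p_sum.get(i + j + 2, 0.0) + v
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + v
    sum_entropy = -sum(v * log(v) for v in p_sum.values() if v > 0)
    diff_entropy = -sum(v * log(v) for v in p_diff.values() if v > 0)
    sum_average = sum(k * v for k, v in p_sum.items())
    sd = (var_x * var_y) ** 0.5
    corr = corr_num / sd if sd > 0 else 0.0
    return {
        "Energy": energy,
        "Entropy": entropy,
        "InverseDifferenceMoment": idm,
        "Contrast": contrast,
        "Correlation": corr,
        "SumEntropy": sum_entropy,
        "DifferenceEntropy": diff_entropy,
        "SumAverage": sum_average,
        "ClusterShade": shade,
        "ClusterProminence": prom,
    }


def rlm_brute(grid: np.ndarray, n_gray: int, angle: int, offset: int):
    """Run-length counts by explicitly walking every stride line.

    Returns (dict {(gray, length): count}, n_runs, pixels_covered).
    """
    dr, dc = _VECTORS[angle]
    sr, sc = dr * offset, dc * offset
    n_rows, n_cols = grid.shape
    runs: dict[tuple[int, int], int] = {}
    n_runs = 0
    covered = 0
    for r0 in range(n_rows):
        for c0 in range(n_cols):
            # start of a stride line: predecessor falls off the grid
            rp, cp = r0 - sr, c0 - sc
            if 0 <= rp < n_rows and 0 <= cp < n_cols:
                continue
            seq = []
            r, c = r0, c0
            while 0 <= r < n_rows and 0 <= c < n_cols:
                seq.append(int(grid[r, c]))
                r, c = r + sr, c + sc
            k = 0
            while k < len(seq):
                if seq[k] <= 0:
                    k += 1
                    continue
                j = k
                while j < len(seq) and seq[j] == seq[k]:
                    j += 1
                runs[(seq[k], j - k)] = runs.get((seq[k], j - k), 0) + 1
                n_runs += 1
                covered += j - k
                k = j
    return runs, n_runs, covered


def rlm_features_brute(runs: dict, n_runs: int, n_pixels: int) -> dict[str, float]:
    feats = {
        "ShortRunEmphasis": 0.0,
        "LongRunEmphasis": 0.0,
        "LowGreyLevelRunEmphasis": 0.0,
        "HighGreyLevelRunEmphasis": 0.0,
        "ShortRunLowGreyLevelEmphasis": 0.0,
        "ShortRunHighGreyLevelEmphasis": 0.0,
        "LongRunLowGreyLevelEmphasis": 0.0,
        "LongRunHighGreyLevelEmphasis": 0.0,
    }
    by_gray: dict[int, int] = {}
    by_len: dict[int, int] = {}
    for (i, l), r in runs.items():
        feats["ShortRunEmphasis"] += r / l**2
        feats["LongRunEmphasis"] += r * l**2
        feats["LowGreyLevelRunEmphasis"] += r / i**2
        feats["HighGreyLevelRunEmphasis"] += r * i**2
        feats["ShortRunLowGreyLevelEmphasis"] += r / (i**2 * l**2)
        feats["ShortRunHighGreyLevelEmphasis"] += r * i**2 / l**2
        feats["LongRunLowGreyLevelEmphasis"] += r * l**2 / i**2
        feats["LongRunHighGreyLevelEmphasis"] += r * i**2 * l**2
        by_gray[i] = by_gray.get(i, 0) + r
        by_len[l] = by_len.get(l, 0) + r
    out = {k: v / n_runs for k, v in feats.items()}
    out["GreyLevelNonuniformity"] = sum(v**2 for v in by_gray.values()) / n_runs
    out["RunLengthNonuniformity"] = sum(v**2 for v in by_len.values()) / n_runs
    out["RunPercentage"] = n_runs / n_pixels
    return out


def auc_pair_count(scores, labels) -> float:
    """Exhaustive pair counting with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def logistic_newton(X: np.ndarray, y: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """Plain Newton–Raphson on the logistic log-likelihood; X includes the
    intercept column."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = X.T @ (X * w[:, None])
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    return beta


def greedy_spearman_prune(X, rho_max: float, pvals: dict) -> list[str]:
    """Reference greedy redundancy pruning following the documented rule,
    written with explicit pairwise loops."""
    from scipy.stats import spearmanr

    names = list(X.columns)
    rho = {}
    for a in names:
        for b in names:
            if a < b:
                rho[(a, b)] = abs(spearmanr(X[a], X[b]).statistic)
    alive = list(names)
    while True:
        worst, worst_pair = rho_max, None
        for a in alive:
            for b in alive:
                if a < b and rho[(a, b)] > worst:
                    worst, worst_pair = rho[(a, b)], (a, b)
        if worst_pair is None:
            return sorted(alive, key=names.index)
        a, b = worst_pair

        def key(k):
            others = [o for o in alive if o not in (a, b)]
            mean_rho = (
                sum(rho[tuple(sorted((k, o)))] for o in others) / len(others)
                if others
                else 0.0
            )
            return (mean_rho, pvals.get(k, 0.0), k)

        alive.remove(max((a, b), key=key))
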