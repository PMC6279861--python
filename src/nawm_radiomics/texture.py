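"""Texture feature battery: histogram, form factor, GLCM and RLM features.

Gray-level co-occurrence (Haralick) and run-length features are computed on
an ROI-local quantization of the masked intensities: equal-width bins over
the ROI min–max, so the battery is invariant to affine intensity rescaling.
GLCMs are mask-aware (both endpoints of a displaced pair must lie inside
the ROI) and symmetric by default.  Run-length matrices follow the classic
maximal-run construction; for an offset (stride) ``d`` the traversal lines
sample every ``d``-th pixel along the run direction, the ``d`` phase-shifted
sub-lattices together covering every mask pixel exactly once, so
``sum(length * count) = mask pixel count`` holds for every (angle, offset).

Directional features are computed at angles {0°, 45°, 90°, 135°} and
aggregated into an ``AllDirection`` arithmetic mean and an
``AllDirection..._SD`` population standard deviation, mirroring the naming
convention ``<Feature>_<angle|AllDirection>_offset<d>[_SD]``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from skimage import measure as skmeasure

from .core import ImageSlice, MaskedPatch, RoiMask
from .errors import (
    DegenerateFeatureWarning,
    DegenerateGlcmError,
    DegenerateRlmError,
    InvalidArgumentError,
)
from .roi import extract_patch, validate_roi

ANGLES = (0, 45, 90, 135)
#: displacement (d_row, d_col) per unit offset, array convention
ANGLE_VECTORS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

GLCM_FEATURES = (
    "Energy",
    "Entropy",
    "InverseDifferenceMoment",
    "Contrast",
    "Correlation",
    "SumEntropy",
    "DifferenceEntropy",
    "SumAverage",
    "ClusterShade",
    "ClusterProminence",
)

RLM_FEATURES = (
    "ShortRunEmphasis",
    "LongRunEmphasis",
    "GreyLevelNonuniformity",
    "RunLengthNonuniformity",
    "RunPercentage",
    "LowGreyLevelRunEmphasis",
    "HighGreyLevelRunEmphasis",
    "ShortRunLowGreyLevelEmphasis",
    "ShortRunHighGreyLevelEmphasis",
    "LongRunLowGreyLevelEmphasis",
    "LongRunHighGreyLevelEmphasis",
)

HISTOGRAM_FEATURES = (
    "mean",
    "stdDeviation",
    "Uniformity",
    "entropy",
    "skewness",
    "kurtosis",
    "Percentile5",
    "Percentile10",
    "Percentile25",
    "Percentile50",
    "Percentile75",
    "Percentile90",
    "Percentile95",
)

FORM_FACTOR_FEATURES = (
    "area",
    "perimeter",
    "compactness",
    "equivalentDiameter",
    "eccentricity",
)


@dataclass
class ExtractionConfig:
    """Knobs of the feature battery."""

    n_gray: int = 16
    angles: tuple[int, ...] = ANGLES
    offsets: tuple[int, ...] = (1, 4, 7)
    log_base: float = 2.0
    symmetric_glcm: bool = True
    population_sd: bool = True  # divisor 4 in AllDirection_SD
    min_pixels: int = 100

    def to_dict(self) -> dict:
        return {
            "n_gray": self.n_gray,
            "angles": list(self.angles),
            "offsets": list(self.offsets),
            "log_base": self.log_base,
            "symmetric_glcm": self.symmetric_glcm,
            "population_sd": self.population_sd,
            "min_pixels": self.min_pixels,
        }


@dataclass
class QuantizedPatch:
    """Gray bins 1..n_gray on the mask support, plus a dense grid over the
    mask bounding box with 0 marking out-of-ROI pixels."""

    bins: np.ndarray  # 1D, aligned with rows/cols
    rows: np.ndarray
    cols: np.ndarray
    n_gray: int
    grid: np.ndarray  # 2D int, bounding-box local, 0 = outside ROI

    def __len__(self) -> int:
        return len(self.bins)


@dataclass
class GLCMatrix:
    matrix: np.ndarray  # Ng x Ng, sums to 1
    angle: int
    offset: int
    symmetric: bool
    n_pairs: int


@dataclass
class RunLengthMatrix:
    counts: np.ndarray  # Ng x Rmax integer counts, counts[i-1, l-1] = r(i, l)
    angle: int
    offset: int
    n_runs: int
    n_pixels: int  # pixels covered by the traversal

    @property
    def run_lengths(self) -> np.ndarray:
        return np.arange(1, self.counts.shape[1] + 1)


# ---------------------------------------------------------------------------
# quantization


def quantize(patch: MaskedPatch, n_gray: int = 16, mode: str = "minmax") -> QuantizedPatch:
    """Equal-width binning of the ROI min–max range into ``n_gray`` bins.

    A constant patch maps every pixel to bin 1.
    """
    if len(patch) == 0:
        raise InvalidArgumentError("cannot quantize an empty patch")
    if n_gray < 2:
        raise InvalidArgumentError("n_gray must be >= 2")
    if mode != "minmax":
        raise InvalidArgumentError(f"unknown quantization mode {mode!r}")
    v = patch.values
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        bins = np.ones(len(v), dtype=int)
    else:
        bins = np.floor((v - lo) / (hi - lo) * n_gray).astype(int) + 1
        np.clip(bins, 1, n_gray, out=bins)
    r0, c0 = patch.rows.min(), patch.cols.min()
    grid = np.zeros(
        (patch.rows.max() - r0 + 1, patch.cols.max() - c0 + 1), dtype=int
    )
    grid[patch.rows - r0, patch.cols - c0] = bins
    return QuantizedPatch(
        bins=bins, rows=patch.rows, cols=patch.cols, n_gray=n_gray, grid=grid
    )


# ---------------------------------------------------------------------------
# histogram features


def _xlogx(p: np.ndarray, log_base: float) -> np.ndarray:
    """p * log(p) with the 0*log 0 = 0 convention."""
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz]) / math.log(log_base)
    return out


def histogram_features(
    patch: MaskedPatch, n_gray: int = 16, log_base: float = 2.0
) -> dict[str, float]:
    """First-order statistics of the masked intensities.

    ``Uniformity`` (histogram energy) and ``entropy`` are computed over the
    ``n_gray``-bin ROI-local histogram; moments and percentiles over the raw
    values.  Population (divisor N) SD, skewness and kurtosis (Fisher,
    excess); both are defined as 0 for a constant patch.
    """
    if len(patch) == 0:
        raise InvalidArgumentError("empty patch")
    v = patch.values
    qp = quantize(patch, n_gray=n_gray)
    counts = np.bincount(qp.bins, minlength=n_gray + 1)[1:]
    p = counts / counts.sum()
    sd = float(v.std())  # population SD
    if sd > 0:
        skew = float(sps.skew(v, bias=True))
        kurt = float(sps.kurtosis(v, bias=True))
    else:
        skew, kurt = 0.0, 0.0
    out = {
        "mean": float(v.mean()),
        "stdDeviation": sd,
        "Uniformity": float(np.sum(p**2)),
        "entropy": float(-np.sum(_xlogx(p, log_base))),
        "skewness": skew,
        "kurtosis": kurt,
    }
    for q in (5, 10, 25, 50, 75, 90, 95):
        out[f"Percentile{q}"] = float(np.percentile(v, q))
    return out


# ---------------------------------------------------------------------------
# form factor


def form_factor_features(mask: RoiMask, pixel_spacing: float = 1.0) -> dict[str, float]:
    """Shape descriptors of the binary ROI.

    ``perimeter`` counts exposed pixel edges (a 10x10 square has perimeter
    40, a single pixel 4), scaled by the spacing; ``compactness`` is the
    isoperimetric ratio 4*pi*area/perimeter^2.  Eccentricity comes from the
    moment-based best-fit ellipse.
    """
    if mask.n_pixels == 0:
        raise InvalidArgumentError("empty mask")
    m = mask.pixels
    area_px = mask.n_pixels
    edges = 0
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        shifted = np.zeros_like(m)
        rs = slice(max(dr, 0), m.shape[0] + min(dr, 0))
        rd = slice(max(-dr, 0), m.shape[0] + min(-dr, 0))
        cs = slice(max(dc, 0), m.shape[1] + min(dc, 0))
        cd = slice(max(-dc, 0), m.shape[1] + min(-dc, 0))
        shifted[rd, cd] = m[rs, cs]
        edges += int(np.sum(m & ~shifted))
    area = area_px * pixel_spacing**2
    perimeter = edges * pixel_spacing
    props = skmeasure.regionprops(m.astype(int))[0]
    return {
        "area": float(area),
        "perimeter": float(perimeter),
        "compactness": float(4.0 * math.pi * area / perimeter**2),
        "equivalentDiameter": float(math.sqrt(4.0 * area / math.pi)),
        "eccentricity": float(props.eccentricity),
    }


# ---------------------------------------------------------------------------
# GLCM


def compute_glcm(
    qpatch: QuantizedPatch, angle: int, offset: int, symmetric: bool = True
) -> GLCMatrix:
    """Mask-aware gray-level co-occurrence matrix for one (angle, offset).

    Counts ordered pairs (p, p + d*u) with both endpoints inside the ROI,
    optionally symmetrized by adding the transpose, then normalized to
    sum 1.
    """
    if angle not in ANGLE_VECTORS:
        raise InvalidArgumentError(f"angle must be one of {ANGLES}")
    if offset < 1:
        raise InvalidArgumentError("offset must be >= 1")
    dr, dc = ANGLE_VECTORS[angle]
    dr, dc = dr * offset, dc * offset
    g = qpatch.grid
    n_rows, n_cols = g.shape
    # source window such that (r+dr, c+dc) stays in the grid
    r_src = slice(max(-dr, 0), n_rows - max(dr, 0))
    c_src = slice(max(-dc, 0), n_cols - max(dc, 0))
    r_dst = slice(max(dr, 0), n_rows - max(-dr, 0))
    c_dst = slice(max(dc, 0), n_cols - max(-dc, 0))
    a = g[r_src, c_src]
    b = g[r_dst, c_dst]
    valid = (a > 0) & (b > 0)
    ng = qpatch.n_gray
    mat = np.zeros((ng, ng), dtype=float)
    if valid.any():
        np.add.at(mat, (a[valid] - 1, b[valid] - 1), 1.0)
    n_pairs = int(valid.sum())
    if symmetric:
        mat = mat + mat.T
        n_pairs *= 2
    if n_pairs == 0:
        raise DegenerateGlcmError(
            f"no valid pixel pair at angle {angle}, offset {offset}"
        )
    mat /= mat.sum()
    return GLCMatrix(
        matrix=mat, angle=angle, offset=offset, symmetric=symmetric, n_pairs=n_pairs
    )


def glcm_features(glcm: GLCMatrix, log_base: float = 2.0) -> dict[str, float]:
    """Haralick features of one co-occurrence matrix.

    Gray levels are 1-based in all index-weighted sums.  If either marginal
    SD vanishes, Correlation is reported as 0 and flagged with a
    :class:`DegenerateFeatureWarning`.
    """
    p = glcm.matrix
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sd_x = math.sqrt(max(float(np.sum((i - mu_x) ** 2 * px)), 0.0))
    sd_y = math.sqrt(max(float(np.sum((i - mu_y) ** 2 * py)), 0.0))
    # p_{x+y}(k), k = 2..2Ng ; p_{x-y}(k), k = 0..Ng-1
    sums = (ii + jj).ravel()
    diffs = np.abs(ii - jj).ravel()
    p_sum = np.bincount(sums, weights=p.ravel(), minlength=2 * ng + 1)[2:]
    p_diff = np.bincount(diffs, weights=p.ravel(), minlength=ng)
    k_sum = np.arange(2, 2 * ng + 1)
    if sd_x > 0 and sd_y > 0:
        corr = float(np.sum((ii - mu_x) * (jj - mu_y) * p) / (sd_x * sd_y))
    else:
        corr = 0.0
        warnings.warn(
            "degenerate GLCM marginal (zero variance); Correlation set to 0",
            DegenerateFeatureWarning,
            stacklevel=2,
        )
    return {
        "Energy": float(np.sum(p**2)),
        "Entropy": float(-np.sum(_xlogx(p, log_base))),
        "InverseDifferenceMoment": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": corr,
        "SumEntropy": float(-np.sum(_xlogx(p_sum, log_base))),
        "DifferenceEntropy": float(-np.sum(_xlogx(p_diff, log_base))),
        "SumAverage": float(np.sum(k_sum * p_sum)),
        "ClusterShade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "ClusterProminence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
    }


# ---------------------------------------------------------------------------
# RLM


def _line_runs(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Values and lengths of maximal constant nonzero runs in a 1D array.

    Zeros (out-of-ROI samples) break runs and are not counted.
    """
    if line.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    change = np.nonzero(np.diff(line) != 0)[0]
    starts = np.concatenate(([0], change + 1))
    ends = np.concatenate((change, [line.size - 1]))
    vals = line[starts]
    keep = vals > 0
    return vals[keep], (ends - starts + 1)[keep]


def _traversal_lines(grid: np.ndarray, angle: int, stride: int):
    """Yield the 1D sample sequences covering the grid along ``angle`` with
    the given stride; the stride phases partition every pixel."""
    if angle == 0:
        for r in range(grid.shape[0]):
            row = grid[r]
            for phase in range(min(stride, row.size)):
                yield row[phase::stride]
    elif angle == 90:
        for c in range(grid.shape[1]):
            col = grid[:, c]
            for phase in range(min(stride, col.size)):
                yield col[phase::stride]
    elif angle in (45, 135):
        # 135° runs lie along (1,1) diagonals; 45° along (1,-1)
        g = grid if angle == 135 else grid[:, ::-1]
        n_rows, n_cols = g.shape
        for off in range(-(n_rows - 1), n_cols):
            diag = np.diagonal(g, offset=off)
            for phase in range(min(stride, diag.size)):
                yield diag[phase::stride]
    else:
        raise InvalidArgumentError(f"angle must be one of {ANGLES}")


def compute_rlm(qpatch: QuantizedPatch, angle: int, offset: int) -> RunLengthMatrix:
    """Gray-level run-length matrix along ``angle`` with stride ``offset``.

    ``offset = 1`` is the classical Galloway construction; larger strides
    sample every ``offset``-th pixel along the direction, with all stride
    phases traversed so that each mask pixel belongs to exactly one run.
    Runs break at ROI boundaries.
    """
    if offset < 1:
        raise InvalidArgumentError("offset must be >= 1")
    all_vals: list[np.ndarray] = []
    all_lens: list[np.ndarray] = []
    for line in _traversal_lines(qpatch.grid, angle, offset):
        v, l = _line_runs(np.ascontiguousarray(line))
        if v.size:
            all_vals.append(v)
            all_lens.append(l)
    n_pixels = len(qpatch)
    if not all_vals:
        return RunLengthMatrix(
            counts=np.zeros((qpatch.n_gray, 1), dtype=int),
            angle=angle,
            offset=offset,
            n_runs=0,
            n_pixels=n_pixels,
        )
    vals = np.concatenate(all_vals)
    lens = np.concatenate(all_lens)
    rmax = int(lens.max())
    counts = np.zeros((qpatch.n_gray, rmax), dtype=int)
    np.add.at(counts, (vals - 1, lens - 1), 1)
    return RunLengthMatrix(
        counts=counts,
        angle=angle,
        offset=offset,
        n_runs=int(len(vals)),
        n_pixels=n_pixels,
    )


def rlm_features(rlm: RunLengthMatrix) -> dict[str, float]:
    """Run-length features (Galloway / Chu / Dasarathy-Holder set)."""
    if rlm.n_runs == 0:
        raise DegenerateRlmError("run-length matrix has no runs")
    r = rlm.counts.astype(float)
    nr = float(rlm.n_runs)
    ng, rmax = r.shape
    i = np.arange(1, ng + 1)[:, None].astype(float)
    l = np.arange(1, rmax + 1)[None, :].astype(float)
    return {
        "ShortRunEmphasis": float(np.sum(r / l**2) / nr),
        "LongRunEmphasis": float(np.sum(r * l**2) / nr),
        "GreyLevelNonuniformity": float(np.sum(r.sum(axis=1) ** 2) / nr),
        "RunLengthNonuniformity": float(np.sum(r.sum(axis=0) ** 2) / nr),
        "RunPercentage": float(nr / rlm.n_pixels),
        "LowGreyLevelRunEmphasis": float(np.sum(r / i**2) / nr),
        "HighGreyLevelRunEmphasis": float(np.sum(r * i**2) / nr),
        "ShortRunLowGreyLevelEmphasis": float(np.sum(r / (i**2 * l**2)) / nr),
        "ShortRunHighGreyLevelEmphasis": float(np.sum(r * i**2 / l**2) / nr),
        "LongRunLowGreyLevelEmphasis": float(np.sum(r * l**2 / i**2) / nr),
        "LongRunHighGreyLevelEmphasis": float(np.sum(r * i**2 * l**2) / nr),
    }


# ---------------------------------------------------------------------------
# direction aggregation and the full battery


def aggregate_directions(
    per_angle_values, population_sd: bool = True
) -> tuple[float, float]:
    """Mean and (population, by default) SD over the four angle values."""
    v = np.asarray(per_angle_values, dtype=float)
    if v.shape != (4,):
        raise InvalidArgumentError("expected exactly four per-angle values")
    if not np.all(np.isfinite(v)):
        warnings.warn(
            "non-finite per-angle feature value; AllDirection aggregate is missing",
            DegenerateFeatureWarning,
            stacklevel=2,
        )
        return float("nan"), float("nan")
    mean = float(v.mean())
    sd = float(v.std(ddof=0 if population_sd else 1))
    return mean, sd


def battery_feature_names(config: ExtractionConfig | None = None) -> list[str]:
    """Deterministic ordered name manifest of the full battery."""
    config = config or ExtractionConfig()
    names: list[str] = list(HISTOGRAM_FEATURES) + list(FORM_FACTOR_FEATURES)
    for group in (GLCM_FEATURES, RLM_FEATURES):
        for feat in group:
            for d in config.offsets:
                for a in config.angles:
                    names.append(f"{feat}_angle{a}_offset{d}")
                names.append(f"{feat}_AllDirection_offset{d}")
                names.append(f"{feat}_AllDirection_offset{d}_SD")
    return names


def key_homogeneity_features(
    image: ImageSlice, mask: RoiMask, offset: int = 7, n_gray: int = 16
) -> dict[str, float]:
    """Fast path for the two local-homogeneity features shared by all
    three contrast models: histogram Uniformity and the all-direction
    inverse difference moment at the given offset."""
    patch = extract_patch(image, mask)
    qp = quantize(patch, n_gray=n_gray)
    idm = [
        glcm_features(compute_glcm(qp, a, offset))["InverseDifferenceMoment"]
        for a in ANGLES
    ]
    mean_idm, _ = aggregate_directions(idm)
    return {
        "Uniformity": histogram_features(patch, n_gray=n_gray)["Uniformity"],
        f"InverseDifferenceMoment_AllDirection_offset{offset}": mean_idm,
    }


def extract_battery(
    image: ImageSlice, mask: RoiMask, config: ExtractionConfig | None = None
) -> dict[str, float]:
    """Compute the full named feature battery for one image/ROI pair.

    Degenerate sub-computations yield NaN entries (flagged by warnings
    during computation), never silent zeros.  The returned dict follows the
    order of :func:`battery_feature_names`.
    """
    config = config or ExtractionConfig()
    check = validate_roi(mask, min_pixels=config.min_pixels)
    if not check.passed:
        raise InvalidArgumentError(
            f"ROI has {check.n_pixels} px, below the {check.min_pixels} px minimum"
        )
    patch = extract_patch(image, mask)
    out: dict[str, float] = {}
    out.update(histogram_features(patch, n_gray=config.n_gray, log_base=config.log_base))
    out.update(form_factor_features(mask, pixel_spacing=image.spacing))
    qp = quantize(patch, n_gray=config.n_gray)

    def _directional(compute_one):
        per_feature: dict[str, dict[int, dict[int, float]]] = {}
        for d in config.offsets:
            for a in config.angles:
                try:
                    feats = compute_one(a, d)
                except (DegenerateGlcmError, DegenerateRlmError):
                    warnings.warn(
                        f"degenerate texture matrix at angle {a}, offset {d}",
                        DegenerateFeatureWarning,
                        stacklevel=3,
                    )
                    feats = None
                for name in feats or {}:
                    per_feature.setdefault(name, {}).setdefault(d, {})[a] = feats[name]
                if feats is None:
                    for name in per_feature:
                        per_feature[name].setdefault(d, {})[a] = float("nan")
        return per_feature

    def _emit(per_feature, feature_order):
        for feat in feature_order:
            by_offset = per_feature.get(feat, {})
            for d in config.offsets:
                by_angle = by_offset.get(d, {})
                vals = [by_angle.get(a, float("nan")) for a in config.angles]
                for a, v in zip(config.angles, vals):
                    out[f"{feat}_angle{a}_offset{d}"] = v
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", DegenerateFeatureWarning)
                    mean, sd = aggregate_directions(
                        vals, population_sd=config.population_sd
                    )
                out[f"{feat}_AllDirection_offset{d}"] = mean
                out[f"{feat}_AllDirection_offset{d}_SD"] = sd

    glcm_vals = _directional(
        lambda a, d: glcm_features(
            compute_glcm(qp, a, d, symmetric=config.symmetric_glcm),
            log_base=config.log_base,
        )
    )
    _emit(glcm_vals, GLCM_FEATURES)
    rlm_vals = _directional(lambda a, d: rlm_features(compute_rlm(qp, a, d)))
    _emit(rlm_vals, RLM_FEATURES)
    return out
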