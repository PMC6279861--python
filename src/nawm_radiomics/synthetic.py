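"""Seeded synthetic longitudinal cohorts of textured image pairs.

Each *case* subject carries a periventricular-like elliptical hyperintense
lesion that enlarges between baseline and follow-up; the annulus gained at
follow-up (follow-up WMH minus baseline WMH) is the developing
normal-appearing white matter (dNAWM) ROI on the baseline image, and its
mirror image about the vertical midline is the non-developing (non-dNAWM)
ROI.  Each *control* subject contributes one normal-white-matter (NWM) ROI
of matching annular geometry.  All generators are pure functions of
(spec, seed).

Texture model
-------------
A stationary random field built from spectrally filtered Gaussian white
noise (Gaussian smoothing with periodic boundary), standardized and scaled
to the requested marginal SD.  Because downstream texture features are
computed after ROI-local min–max quantization (and are therefore invariant
to affine intensity changes), class heterogeneity is encoded in two
*shape/structure* knobs in addition to ``noise_sd``:

* ``correlation_length`` — spatial smoothness; shorter correlation means
  rougher co-occurrence structure (lower inverse difference moment).
* ``marginal_flatness`` — a rank-preserving interpolation of the marginal
  between Gaussian (0) and uniform (1); flatter marginals spread the
  ROI-local histogram across its bins (lower histogram Uniformity).

The default class parameters grade heterogeneity NWM < non-dNAWM < dNAWM
(in ``noise_sd``, flatness and roughness simultaneously), with non-dNAWM
deliberately close to NWM, so the cohort reproduces the qualitative
orderings of the underlying study design: texture values lowest in dNAWM,
and the NWM-vs-dNAWM contrast far easier than NWM-vs-non-dNAWM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .core import ImageSlice, RoiMask, SubjectRecord
from .errors import GenerationError, InvalidArgumentError
from .roi import mirror_mask, subtract_masks


@dataclass(frozen=True)
class TextureParams:
    """Knobs of the stationary random-field texture model (arbitrary
    intensity units)."""

    mean_intensity: float = 500.0
    noise_sd: float = 40.0
    correlation_length: float = 2.0
    lesion_intensity_boost: float = 0.0
    marginal_flatness: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidArgumentError("noise_sd must be >= 0")
        if self.correlation_length <= 0:
            raise InvalidArgumentError("correlation_length must be > 0")
        if self.lesion_intensity_boost < 0:
            raise InvalidArgumentError("lesion_intensity_boost must be >= 0")
        if not 0.0 <= self.marginal_flatness <= 1.0:
            raise InvalidArgumentError("marginal_flatness must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "mean_intensity": self.mean_intensity,
            "noise_sd": self.noise_sd,
            "correlation_length": self.correlation_length,
            "lesion_intensity_boost": self.lesion_intensity_boost,
            "marginal_flatness": self.marginal_flatness,
        }


def default_class_params() -> dict[str, TextureParams]:
    """Graded heterogeneity: NWM most homogeneous, dNAWM least; non-dNAWM
    close to NWM."""
    return {
        "NWM": TextureParams(500.0, 36.0, 2.2, 0.0, 0.00),
        "non_dNAWM": TextureParams(500.0, 40.0, 2.05, 0.0, 0.15),
        "dNAWM": TextureParams(500.0, 52.0, 1.25, 0.0, 0.9),
        "WMH": TextureParams(500.0, 36.0, 2.0, 300.0, 0.0),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Design of one simulated cohort."""

    n_cases: int = 51
    n_controls: int = 51
    image_size: tuple[int, int] = (64, 64)
    roi_min_pixels: int = 100
    class_params: dict[str, TextureParams] = field(default_factory=default_class_params)
    pixel_spacing: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise InvalidArgumentError("n_cases and n_controls must be positive")
        if self.roi_min_pixels < 1:
            raise InvalidArgumentError("roi_min_pixels must be >= 1")
        for key in ("NWM", "non_dNAWM", "dNAWM"):
            if key not in self.class_params:
                raise InvalidArgumentError(f"class_params missing {key!r}")

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "image_size": list(self.image_size),
            "roi_min_pixels": self.roi_min_pixels,
            "pixel_spacing": self.pixel_spacing,
            "seed": self.seed,
            "class_params": {k: v.to_dict() for k, v in self.class_params.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "image_size" in d:
            d["image_size"] = tuple(d["image_size"])
        if "class_params" in d:
            d["class_params"] = {
                k: TextureParams(**v) for k, v in d["class_params"].items()
            }
        return cls(**d)


# ---------------------------------------------------------------------------
# random fields


def generate_texture_field(
    size: tuple[int, int], params: TextureParams, seed: int | np.random.Generator
) -> ImageSlice:
    """Stationary textured field with the requested mean, marginal SD,
    autocorrelation scale and marginal flatness; deterministic given seed."""
    n_rows, n_cols = size
    if n_rows < 16 or n_cols < 16:
        raise InvalidArgumentError("field size must be at least 16x16")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if params.noise_sd == 0:
        return ImageSlice(np.full(size, params.mean_intensity))
    g = rng.standard_normal(size)
    g = gaussian_filter(g, sigma=params.correlation_length, mode="wrap")
    g = (g - g.mean()) / g.std()
    w = params.marginal_flatness
    if w > 0:
        # monotone (rank-preserving) push toward a flat marginal
        flat = (norm.cdf(g) - 0.5) * np.sqrt(12.0)
        g = (1.0 - w) * g + w * flat
        g = (g - g.mean()) / g.std()
    return ImageSlice(params.mean_intensity + params.noise_sd * g)


# ---------------------------------------------------------------------------
# lesion geometry


def _ellipse(shape, center, radii) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return ((rr - center[0]) / radii[0]) ** 2 + ((cc - center[1]) / radii[1]) ** 2 <= 1.0


def _case_geometry(shape, roi_min_pixels, rng, max_tries: int = 25):
    """Baseline/follow-up WMH ellipses plus the mirrored non-dNAWM mask."""
    for _ in range(max_tries):
        r0 = shape[0] / 2.0 + rng.uniform(-2.0, 2.0)
        c0 = shape[1] * 0.28 + rng.uniform(-1.5, 1.5)
        base_radii = (rng.uniform(6.8, 7.8), rng.uniform(5.6, 6.4))
        grow = (rng.uniform(5.0, 6.0), rng.uniform(4.5, 5.5))
        fu_radii = (base_radii[0] + grow[0], base_radii[1] + grow[1])
        base = _ellipse(shape, (r0, c0), base_radii)
        fu = _ellipse(shape, (r0, c0), fu_radii)
        annulus = fu & ~base
        mirrored = np.zeros_like(annulus)
        rr, cc = np.nonzero(annulus)
        mc = shape[1] - 1 - cc
        if mc.min(initial=0) < 0 or mc.max(initial=0) >= shape[1]:
            continue
        mirrored[rr, mc] = True
        ok = (
            base.any()
            and (base <= fu).all()
            and base.sum() < fu.sum()
            and annulus.sum() >= roi_min_pixels
            and not (mirrored & fu).any()
            and fu[0, :].sum() == 0
            and fu[-1, :].sum() == 0
            and fu[:, 0].sum() == 0
            and fu[:, -1].sum() == 0
        )
        if ok:
            return base, fu, annulus, mirrored
    raise GenerationError(
        f"could not place a lesion with a >= {roi_min_pixels}-pixel annulus "
        f"inside a {shape[0]}x{shape[1]} image"
    )


# ---------------------------------------------------------------------------
# metadata

_RISK_FACTORS = {
    # probabilities for (case, control) groups
    "female": (23 / 51, 22 / 51),
    "hypertension": (41 / 51, 33 / 51),
    "diabetes": (25 / 51, 16 / 51),
    "hyperlipidemia": (18 / 51, 12 / 51),
    "smoking": (22 / 51, 17 / 51),
    "drinking": (14 / 51, 16 / 51),
    "atrial_fibrillation": (13 / 51, 10 / 51),
}

_FAZEKAS_P = np.array([4, 12, 13, 7, 10, 5]) / 51.0


def _metadata(group: str, rng: np.random.Generator) -> dict:
    idx = 0 if group == "case" else 1
    meta = {k: bool(rng.random() < p[idx]) for k, p in _RISK_FACTORS.items()}
    if group == "case":
        meta["age"] = float(rng.normal(76.61, 7.72))
        meta["interval_days"] = float(np.exp(rng.normal(np.log(615.0), 0.53)))
        meta["fazekas"] = int(rng.choice(np.arange(1, 7), p=_FAZEKAS_P))
    else:
        meta["age"] = float(rng.normal(74.82, 5.47))
        meta["interval_days"] = float(np.exp(rng.normal(np.log(581.0), 0.43)))
        meta["fazekas"] = 0
    meta["sex"] = "F" if meta.pop("female") else "M"
    return meta


# ---------------------------------------------------------------------------
# subjects and cohorts


def _paste(target: np.ndarray, mask: np.ndarray, source_field: ImageSlice) -> None:
    target[mask] = source_field.data[mask]


def generate_case_subject(
    spec: CohortSpec, seed: int, subject_id: str = "case"
) -> SubjectRecord:
    """One case subject: enlarging lesion, dNAWM annulus, mirrored
    non-dNAWM region."""
    rng = np.random.default_rng(seed)
    shape = spec.image_size
    base_wmh, fu_wmh, _, _ = _case_geometry(shape, spec.roi_min_pixels, rng)
    cp = spec.class_params
    wmh_params = cp.get("WMH", TextureParams(lesion_intensity_boost=300.0))

    background = generate_texture_field(shape, cp["NWM"], rng)
    dnawm_field = generate_texture_field(shape, cp["dNAWM"], rng)
    ndnawm_field = generate_texture_field(shape, cp["non_dNAWM"], rng)
    boosted = replace(
        wmh_params,
        mean_intensity=wmh_params.mean_intensity + wmh_params.lesion_intensity_boost,
    )
    wmh_field_base = generate_texture_field(shape, boosted, rng)
    fu_background = generate_texture_field(shape, cp["NWM"], rng)
    wmh_field_fu = generate_texture_field(shape, boosted, rng)

    baseline_mask = RoiMask(base_wmh, "WMH_baseline", subject_id)
    followup_mask = RoiMask(fu_wmh, "WMH_followup", subject_id)
    dnawm_mask = subtract_masks(followup_mask, baseline_mask)
    dnawm_mask.subject_id = subject_id
    ndnawm_mask = mirror_mask(dnawm_mask)

    baseline = background.data.copy()
    _paste(baseline, dnawm_mask.pixels, dnawm_field)
    _paste(baseline, ndnawm_mask.pixels, ndnawm_field)
    _paste(baseline, base_wmh, wmh_field_base)

    followup = fu_background.data.copy()
    _paste(followup, ndnawm_mask.pixels, ndnawm_field)
    _paste(followup, fu_wmh, wmh_field_fu)

    for m, name in ((dnawm_mask, "dNAWM"), (ndnawm_mask, "non-dNAWM")):
        if m.n_pixels < spec.roi_min_pixels:
            raise GenerationError(
                f"{name} ROI of subject {subject_id} has {m.n_pixels} px "
                f"(minimum {spec.roi_min_pixels})"
            )
    return SubjectRecord(
        subject_id=subject_id,
        group="case",
        baseline=ImageSlice(baseline, spec.pixel_spacing),
        followup=ImageSlice(followup, spec.pixel_spacing),
        masks=[baseline_mask, followup_mask, dnawm_mask, ndnawm_mask],
        metadata=_metadata("case", rng),
    )


def generate_control_subject(
    spec: CohortSpec, seed: int, subject_id: str = "control"
) -> SubjectRecord:
    """One control subject: no lesion; an NWM ROI of matching annular
    geometry at a matching location."""
    rng = np.random.default_rng(seed)
    shape = spec.image_size
    _, _, annulus, _ = _case_geometry(shape, spec.roi_min_pixels, rng)
    background = generate_texture_field(shape, spec.class_params["NWM"], rng)
    fu_background = generate_texture_field(shape, spec.class_params["NWM"], rng)
    nwm_mask = RoiMask(annulus, "NWM", subject_id)
    return SubjectRecord(
        subject_id=subject_id,
        group="control",
        baseline=ImageSlice(background.data.copy(), spec.pixel_spacing),
        followup=ImageSlice(fu_background.data.copy(), spec.pixel_spacing),
        masks=[nwm_mask],
        metadata=_metadata("control", rng),
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Full cohort: ``n_cases`` case subjects (dNAWM + non-dNAWM ROIs each)
    and ``n_controls`` controls (one NWM ROI each); reproducible from
    ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    records: list[SubjectRecord] = []
    for i in range(spec.n_cases):
        sub_seed = int(rng.integers(2**31))
        records.append(
            generate_case_subject(spec, sub_seed, subject_id=f"case_{i + 1:03d}")
        )
    for i in range(spec.n_controls):
        sub_seed = int(rng.integers(2**31))
        records.append(
            generate_control_subject(spec, sub_seed, subject_id=f"ctrl_{i + 1:03d}")
        )
    return records


def generate_null_cohort(
    spec: CohortSpec, shared_params: TextureParams | None = None
) -> list[SubjectRecord]:
    """Cohort with *no* class effect: all three analysis ROI classes share
    one TextureParams (default: the spec's NWM parameters)."""
    shared = shared_params or spec.class_params["NWM"]
    null_params = dict(spec.class_params)
    for key in ("NWM", "non_dNAWM", "dNAWM"):
        null_params[key] = shared
    null_spec = replace(spec, class_params=null_params)
    return generate_cohort(null_spec)
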