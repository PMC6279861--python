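import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nawm_radiomics import ImageSlice, RoiMask
from nawm_radiomics.core import MaskedPatch
from nawm_radiomics.errors import DegenerateGlcmError, InvalidArgumentError
from nawm_radiomics.texture import (
    ExtractionConfig,
    aggregate_directions,
    battery_feature_names,
    compute_glcm,
    compute_rlm,
    extract_battery,
    form_factor_features,
    glcm_features,
    histogram_features,
    quantize,
    rlm_features,
)

from .conftest import random_quantized_patch
from .oracles import glcm_brute, glcm_features_brute, rlm_brute, rlm_features_brute


def _patch_from_grid(values, mask=None):
    values = np.asarray(values, dtype=float)
    mask = np.ones(values.shape, bool) if mask is None else np.asarray(mask, bool)
    rr, cc = np.nonzero(mask)
    return MaskedPatch(values[rr, cc], rr, cc)


class TestQuantize:
    def test_constant_patch_maps_to_bin_one(self):
        qp = quantize(_patch_from_grid(np.full((4, 4), 7.0)), n_gray=16)
        assert np.all(qp.bins == 1)

    def test_equal_width_partition(self):
        qp = quantize(_patch_from_grid([[0.0, 10.0, 20.0, 30.0]]), n_gray=4)
        np.testing.assert_array_equal(qp.bins, [1, 2, 3, 4])

    def test_uniform_values_fill_bins_evenly(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, size=(40, 25))
        qp = quantize(_patch_from_grid(vals), n_gray=16)
        counts = np.bincount(qp.bins, minlength=17)[1:]
        from scipy.stats import chisquare

        assert chisquare(counts).pvalue > 0.01

    def test_n_gray_below_two_rejected(self):
        with pytest.raises(InvalidArgumentError):
            quantize(_patch_from_grid([[1.0, 2.0]]), n_gray=1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_bins_always_within_range(self, seed):
        rng = np.random.default_rng(seed)
        qp = random_quantized_patch(rng)
        assert qp.bins.min() >= 1 and qp.bins.max() <= qp.n_gray


class TestHistogramFeatures:
    def test_constant_patch_limits(self):
        f = histogram_features(_patch_from_grid(np.full((10, 10), 3.0)))
        assert f["Uniformity"] == 1.0
        assert f["entropy"] == 0.0
        assert f["stdDeviation"] == 0.0

    def test_two_equally_occupied_bins(self):
        f = histogram_features(_patch_from_grid([[0.0] * 8 + [1.0] * 8]), n_gray=2)
        assert f["Uniformity"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(1.0)

    def test_uniformity_matches_direct_counting(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(9, 9))
        f = histogram_features(_patch_from_grid(vals), n_gray=8)
        qp = quantize(_patch_from_grid(vals), n_gray=8)
        counts = {}
        for b in qp.bins:
            counts[b] = counts.get(b, 0) + 1
        expected = sum((c / len(qp.bins)) ** 2 for c in counts.values())
        assert f["Uniformity"] == pytest.approx(expected, rel=1e-12)


class TestFormFactor:
    def test_square_geometry(self):
        m = np.zeros((14, 14), bool)
        m[2:12, 2:12] = True
        f = form_factor_features(RoiMask(m, "NWM"))
        assert f["area"] == 100.0 and f["perimeter"] == 40.0

    def test_single_pixel(self):
        m = np.zeros((5, 5), bool)
        m[2, 2] = True
        f = form_factor_features(RoiMask(m, "NWM"))
        assert f["area"] == 1.0 and f["perimeter"] == 4.0

    def test_compactness_respects_isoperimetric_bound(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            m = np.zeros((24, 24), bool)
            rr, cc = np.mgrid[0:24, 0:24]
            r0, c0 = rng.uniform(8, 16, 2)
            m |= (rr - r0) ** 2 + (cc - c0) ** 2 <= rng.uniform(3, 7) ** 2
            f = form_factor_features(RoiMask(m, "NWM"))
            assert f["compactness"] <= 1.0 + 1e-9


class TestGlcm:
    def test_constant_full_patch(self):
        qp = quantize(_patch_from_grid(np.full((3, 3), 5.0)), n_gray=4)
        g = compute_glcm(qp, 0, 1)
        assert g.matrix[0, 0] == 1.0 and g.matrix.sum() == 1.0

    def test_two_by_two_alternating_columns(self):
        qp = quantize(_patch_from_grid([[0.0, 1.0], [0.0, 1.0]]), n_gray=2)
        g = compute_glcm(qp, 0, 1, symmetric=True)
        assert g.matrix[0, 1] == pytest.approx(0.5)
        assert g.matrix[1, 0] == pytest.approx(0.5)

    def test_no_valid_pair_raises(self):
        qp = quantize(_patch_from_grid([[1.0, 2.0]]), n_gray=2)
        with pytest.raises(DegenerateGlcmError):
            compute_glcm(qp, 90, 1)  # single row, vertical displacement

    def test_diagonal_glcm_feature_limits(self):
        p = np.diag([0.25, 0.25, 0.5])
        from nawm_radiomics.texture import GLCMatrix

        f = glcm_features(GLCMatrix(p, 0, 1, True, 10))
        assert f["InverseDifferenceMoment"] == pytest.approx(1.0)
        assert f["Contrast"] == 0.0

    def test_uniform_two_level_glcm_closed_forms(self):
        from nawm_radiomics.texture import GLCMatrix

        f = glcm_features(GLCMatrix(np.full((2, 2), 0.25), 0, 1, True, 8))
        assert f["Energy"] == pytest.approx(0.25)
        assert f["Entropy"] == pytest.approx(2.0)

    def test_matches_brute_force_on_random_patches(self):
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(30):
            qp = random_quantized_patch(rng)
            for angle in (0, 45, 90, 135):
                for offset in (1, 2):
                    expected = glcm_brute(qp.grid, qp.n_gray, angle, offset)
                    if expected is None:
                        continue
                    g = compute_glcm(qp, angle, offset)
                    np.testing.assert_allclose(g.matrix, expected, atol=1e-12)
                    checked += 1
        assert checked > 50


class TestRlm:
    def test_single_line_single_run(self):
        qp = quantize(_patch_from_grid([[3.0] * 5]), n_gray=4)
        r = compute_rlm(qp, 0, 1)
        assert r.n_runs == 1
        assert r.counts[0, 4] == 1  # constant patch -> bin 1, length 5

    def test_alternating_line_four_unit_runs(self):
        qp = quantize(_patch_from_grid([[0.0, 1.0, 0.0, 1.0]]), n_gray=2)
        r = compute_rlm(qp, 0, 1)
        assert r.n_runs == 4
        assert r.counts.shape[1] == 1

    def test_coverage_conservation_random_patches(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            qp = random_quantized_patch(rng)
            for angle in (0, 45, 90, 135):
                for offset in (1, 2, 3):
                    r = compute_rlm(qp, angle, offset)
                    covered = int(np.sum(r.counts * r.run_lengths[None, :]))
                    assert covered == len(qp)

    def test_all_unit_runs_feature_limits(self):
        qp = quantize(_patch_from_grid([[0.0, 1.0, 0.0], [1.0, 0.0, 1.0]]), n_gray=2)
        f = rlm_features(compute_rlm(qp, 0, 1))
        assert f["ShortRunEmphasis"] == 1.0
        assert f["RunPercentage"] == 1.0

    def test_single_run_closed_form(self):
        from nawm_radiomics.texture import RunLengthMatrix

        counts = np.zeros((4, 4), dtype=int)
        counts[1, 3] = 1  # gray level 2, length 4
        f = rlm_features(RunLengthMatrix(counts, 0, 1, n_runs=1, n_pixels=4))
        assert f["LongRunHighGreyLevelEmphasis"] == pytest.approx(64.0)

    def test_matches_brute_force_walker(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            qp = random_quantized_patch(rng)
            for angle in (0, 45, 90, 135):
                for offset in (1, 2, 3):
                    runs, n_runs, covered = rlm_brute(qp.grid, qp.n_gray, angle, offset)
                    r = compute_rlm(qp, angle, offset)
                    assert r.n_runs == n_runs
                    got = {
                        (i + 1, l + 1): int(r.counts[i, l])
                        for i, l in zip(*np.nonzero(r.counts))
                    }
                    assert got == runs


class TestAggregateDirections:
    def test_equal_values(self):
        mean, sd = aggregate_directions([3.0, 3.0, 3.0, 3.0])
        assert mean == 3.0 and sd == 0.0

    def test_closed_form(self):
        mean, sd = aggregate_directions([0.0, 0.0, 0.0, 4.0])
        assert mean == 1.0 and sd == pytest.approx(np.sqrt(3.0))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-100, 100), min_size=4, max_size=4))
    def test_matches_two_pass_oracle(self, vals):
        mean, sd = aggregate_directions(vals)
        m = sum(vals) / 4.0
        s = (sum((v - m) ** 2 for v in vals) / 4.0) ** 0.5
        assert mean == pytest.approx(m, abs=1e-9)
        assert sd == pytest.approx(s, abs=1e-9)


class TestBattery:
    def test_deterministic(self, case_subject):
        a = extract_battery(case_subject.baseline, case_subject.mask("dNAWM"))
        b = extract_battery(case_subject.baseline, case_subject.mask("dNAWM"))
        assert a == b

    def test_contains_all_study_feature_names(self, case_subject):
        feats = extract_battery(case_subject.baseline, case_subject.mask("dNAWM"))
        required = [
            "Uniformity",
            "stdDeviation",
            "InverseDifferenceMoment_AllDirection_offset7",
            "InverseDifferenceMoment_angle90_offset4",
            "InverseDifferenceMoment_angle135_offset7",
            "Correlation_AllDirection_offset4_SD",
            "SumEntropy_AllDirection_offset1",
            "DifferenceEntropy_AllDirection_offset1",
            "GreyLevelNonuniformity_angle90_offset1",
            "ShortRunLowGreyLevelEmphasis_AllDirection_offset1_SD",
            "ShortRunEmphasis_angle90_offset7",
            "ShortRunEmphasis_AllDirection_offset7",
            "ShortRunEmphasis_angle135_offset4",
            "ShortRunEmphasis_AllDirection_offset4_SD",
            "ShortRunHighGreyLevelEmphasis_AllDirection_offset4_SD",
            "LongRunHighGreyLevelEmphasis_AllDirection_offset7",
            "LongRunHighGreyLevelEmphasis_angle135_offset7",
            "LongRunHighGreyLevelEmphasis_angle0_offset7",
        ]
        for name in required:
            assert name in feats, name
        assert list(feats) == battery_feature_names()

    def test_constant_roi_homogeneity_limits(self):
        img = ImageSlice(np.full((32, 32), 42.0))
        m = np.zeros((32, 32), bool)
        m[4:28, 4:28] = True
        feats = extract_battery(img, RoiMask(m, "NWM"))
        assert feats["Uniformity"] == 1.0
        assert feats["InverseDifferenceMoment_AllDirection_offset7"] == 1.0

    def test_undersized_roi_rejected(self, case_subject):
        m = np.zeros(case_subject.baseline.shape, bool)
        m[:7, :7] = True
        with pytest.raises(InvalidArgumentError):
            extract_battery(case_subject.baseline, RoiMask(m, "NWM"))

    def test_heterogeneity_monotonicity_across_class_params(self):
        """Mean Uniformity and IDM decrease along the graded default
        heterogeneity axis NWM -> non-dNAWM -> dNAWM."""
        from nawm_radiomics import default_class_params, generate_texture_field
        from nawm_radiomics.roi import extract_patch
        from nawm_radiomics.texture import quantize

        params = default_class_params()
        m = np.zeros((48, 48), bool)
        m[8:40, 8:40] = True
        mask = RoiMask(m, "NWM")
        means = {}
        for label in ("NWM", "non_dNAWM", "dNAWM"):
            u, idm = [], []
            for seed in range(8):
                img = generate_texture_field((48, 48), params[label], seed)
                patch = extract_patch(img, mask)
                u.append(histogram_features(patch)["Uniformity"])
                qp = quantize(patch)
                vals = [
                    glcm_features(compute_glcm(qp, a, 7))["InverseDifferenceMoment"]
                    for a in (0, 45, 90, 135)
                ]
                idm.append(np.mean(vals))
            means[label] = (np.mean(u), np.mean(idm))
        assert means["NWM"][0] > means["non_dNAWM"][0] > means["dNAWM"][0]
        assert means["NWM"][1] > means["non_dNAWM"][1] > means["dNAWM"][1]

    def test_glcm_rlm_feature_values_match_brute_oracles(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            qp = random_quantized_patch(rng, max_side=10)
            for angle in (0, 90):
                expected_p = glcm_brute(qp.grid, qp.n_gray, angle, 1)
                if expected_p is not None:
                    got = glcm_features(compute_glcm(qp, angle, 1))
                    want = glcm_features_brute(expected_p)
                    for k, v in want.items():
                        assert got[k] == pytest.approx(v, rel=1e-10, abs=1e-12), k
                runs, n_runs, covered = rlm_brute(qp.grid, qp.n_gray, angle, 1)
                got_r = rlm_features(compute_rlm(qp, angle, 1))
                want_r = rlm_features_brute(runs, n_runs, covered)
                for k, v in want_r.items():
                    assert got_r[k] == pytest.approx(v, rel=1e-10), k

    def test_range_bounds_on_real_roi(self, case_subject):
        feats = extract_battery(case_subject.baseline, case_subject.mask("dNAWM"))
        for d in (1, 4, 7):
            assert 0 < feats["Uniformity"] <= 1
            assert 0 < feats[f"InverseDifferenceMoment_AllDirection_offset{d}"] <= 1
            assert 0 < feats[f"ShortRunEmphasis_AllDirection_offset{d}"] <= 1
            assert 0 < feats[f"RunPercentage_AllDirection_offset{d}"] <= 1


class TestAgainstSkimage:
    def test_glcm_matches_skimage_on_full_rectangle(self):
        """On an unmasked rectangle the mask-aware GLCM must agree with
        skimage's graycomatrix (independent implementation)."""
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(12)
        img = rng.integers(0, 6, size=(14, 11)).astype(float)
        patch = _patch_from_grid(img)
        qp = quantize(patch, n_gray=6)
        # bins reproduce the integers when they span 0..5
        assert qp.grid.max() == 6
        # skimage's angle theta displaces by (sin, cos)*d, so its pi/4 is
        # the (1,1) diagonal = our 135-degree direction (and vice versa);
        # symmetric matrices make direction reversal immaterial
        # skimage's angle theta displaces by round(sin(theta)*d),
        # round(cos(theta)*d): its pi/4 is the (1,1) diagonal = our
        # 135-degree direction (and vice versa), and its diagonal distance
        # collapses to the chessboard step only at d = 1
        for angle, sk_angle, dists in (
            (0, 0.0, (1, 2, 3)),
            (45, 3 * np.pi / 4, (1,)),
            (90, np.pi / 2, (1, 2, 3)),
            (135, np.pi / 4, (1,)),
        ):
            for d in dists:
                ours = compute_glcm(qp, angle, d, symmetric=True)
                sk = graycomatrix(
                    (qp.grid - 1).astype(np.uint8),
                    distances=[d],
                    angles=[sk_angle],
                    levels=6,
                    symmetric=True,
                    normed=True,
                )[:, :, 0, 0]
                np.testing.assert_allclose(ours.matrix, sk, atol=1e-12)
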