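import numpy as np
import pytest

from nawm_radiomics import CohortSpec, generate_case_subject, generate_cohort


def random_quantized_patch(rng, max_side=12, n_gray_max=8, density=0.75):
    """A random masked quantized patch for oracle comparisons: random bins
    on a random (connected-ish) mask."""
    from nawm_radiomics.core import MaskedPatch
    from nawm_radiomics.texture import quantize

    n_rows = rng.integers(4, max_side + 1)
    n_cols = rng.integers(4, max_side + 1)
    n_gray = int(rng.integers(2, n_gray_max + 1))
    mask = rng.random((n_rows, n_cols)) < density
    if not mask.any():
        mask[n_rows // 2, n_cols // 2] = True
    values = rng.integers(0, n_gray, size=(n_rows, n_cols)).astype(float)
    rr, cc = np.nonzero(mask)
    patch = MaskedPatch(values[rr, cc], rr, cc)
    # values already in 0..n_gray-1: equal-width bins reproduce them + 1
    return quantize(patch, n_gray=n_gray)


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_cases=4, n_controls=4, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def case_subject():
    return generate_case_subject(CohortSpec(), seed=123, subject_id="case_fixture")
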