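"""Tests of the SSM core: log transform, double centering (against a
centering-projector oracle), and the decomposition (against an independent
covariance eigendecomposition)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ssmpattern import (
    CohortParams,
    default_planted_weights,
    generate_cohort,
    double_center,
    log_volume_matrix,
    ssm_decompose,
)
from ssmpattern.cohort import REGIONS


def _centering_projector_oracle(m):
    """(I - J/n) M (I - J/p): dense double-centering by projection matrices."""
    n, p = m.shape
    Pn = np.eye(n) - np.ones((n, n)) / n
    Pp = np.eye(p) - np.ones((p, p)) / p
    return Pn @ m @ Pp


def test_log_volume_matrix_values_and_shape(default_cohort):
    m = log_volume_matrix(default_cohort)
    assert m.shape == (178, 14)
    df = default_cohort.copy()
    df.loc[df.index[0], "caudate_l"] = 1000.0
    m = log_volume_matrix(df)
    assert m[0, 0] == pytest.approx(6.907755278982137, abs=1e-12)


def test_log_volume_matrix_errors(default_cohort):
    df = default_cohort.copy()
    df.loc[df.index[3], "putamen_r"] = -5.0
    with pytest.raises(ValueError, match="putamen_r"):
        log_volume_matrix(df)
    df = default_cohort.copy()
    df.loc[df.index[2], "thalamus_l"] = 0.0
    with pytest.raises(ValueError, match="thalamus_l"):
        log_volume_matrix(df)
    with pytest.raises(KeyError, match="putamen_l"):
        log_volume_matrix(default_cohort.drop(columns=["putamen_l"]))


def test_double_center_identities(rng):
    m = rng.normal(8.0, 0.5, size=(25, 14))
    cm = double_center(m)
    assert np.abs(cm.values.mean(axis=0)).max() < 1e-10
    assert np.abs(cm.values.mean(axis=1)).max() < 1e-10
    recon = cm.values + cm.subject_means[:, None] + cm.region_means[None, :]
    assert np.abs(recon - m).max() < 1e-10


def test_double_center_annihilates_constants():
    cm = double_center(np.full((7, 5), 3.14), region_names=tuple("abcde"))
    assert np.abs(cm.values).max() < 1e-12


def test_double_center_fixes_centered_outer_product(rng):
    u = rng.normal(size=8)
    u -= u.mean()
    v = rng.normal(size=6)
    v -= v.mean()
    m = np.outer(u, v)
    cm = double_center(m, region_names=tuple("abcdef"))
    assert np.abs(cm.values - m).max() < 1e-12


def test_double_center_matches_projector_oracle(rng):
    m = rng.normal(size=(6, 4))
    cm = double_center(m, region_names=tuple("wxyz"))
    assert np.abs(cm.values - _centering_projector_oracle(m)).max() < 1e-12


def test_double_center_order_invariance(rng):
    # removing region means before subject means gives the same residuals
    m = rng.normal(size=(12, 9))
    colfirst = m - m.mean(axis=0)
    colfirst = colfirst - colfirst.mean(axis=1)[:, None]
    cm = double_center(m, region_names=tuple("abcdefghi"))
    assert np.abs(cm.values - colfirst).max() < 1e-10


def test_double_center_rejects_missing():
    m = np.ones((5, 4))
    m[2, 1] = np.nan
    with pytest.raises(ValueError, match="missing"):
        double_center(m, region_names=tuple("abcd"))


@settings(max_examples=25, deadline=None)
@given(
    arrays(
        np.float64,
        st.tuples(st.integers(3, 12), st.integers(2, 8)),
        elements=st.floats(-50, 50, allow_nan=False),
    )
)
def test_double_center_projector_property(m):
    cm = double_center(m, region_names=tuple(str(j) for j in range(m.shape[1])))
    scale = max(1.0, np.abs(m).max())
    assert np.abs(cm.values - _centering_projector_oracle(m)).max() < 1e-10 * scale
    assert np.abs(cm.values.mean(axis=0)).max() < 1e-10 * scale
    assert np.abs(cm.values.mean(axis=1)).max() < 1e-10 * scale


def test_decomposition_oracle(rng):
    """Loadings/eigenvalues agree with an independent eigendecomposition of
    the p x p covariance of the centered values, up to sign."""
    m = rng.normal(8.0, 0.3, size=(20, 14))
    cm = double_center(m)
    dec = ssm_decompose(cm)
    n = cm.values.shape[0]
    cov = cm.values.T @ cm.values / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][: dec.n_components]
    assert np.abs(dec.eigenvalues - evals[order]).max() < 1e-8
    for j, k in enumerate(order):
        v = evecs[:, k]
        dot = abs(float(v @ dec.loadings[:, j]))
        assert dot > 1 - 1e-8
    # completeness: all kept components reconstruct the matrix
    recon = dec.scores @ dec.loadings.T
    assert np.abs(recon - cm.values).max() < 1e-8


def test_decomposition_invariants(small_cohort):
    cm = double_center(log_volume_matrix(small_cohort))
    dec = ssm_decompose(cm)
    k = dec.n_components
    assert k == min(cm.values.shape[0] - 1, cm.values.shape[1] - 1)
    assert np.abs(dec.loadings.T @ dec.loadings - np.eye(k)).max() < 1e-8
    off = dec.scores.T @ dec.scores
    assert np.abs(off - np.diag(np.diag(off))).max() < 1e-8
    assert (np.diff(dec.eigenvalues) <= 1e-12).all()
    assert dec.variance_fraction.sum() <= 1 + 1e-12
    # sign convention: largest-magnitude loading element is positive
    anchors = np.argmax(np.abs(dec.loadings), axis=0)
    assert (dec.loadings[anchors, np.arange(k)] > 0).all()


def test_rank_one_cohort_concentrates_variance():
    p = CohortParams(seed=9, n_subjects=40, noise_sd_regions=1e-10, global_scale_sd=0.0)
    cm = double_center(log_volume_matrix(generate_cohort(p)))
    dec = ssm_decompose(cm)
    assert dec.variance_fraction[0] >= 0.999


def test_permutation_equivariance(small_cohort, rng):
    cm = double_center(log_volume_matrix(small_cohort))
    dec = ssm_decompose(cm)
    perm = rng.permutation(cm.values.shape[0])
    cm_p = double_center(log_volume_matrix(small_cohort.iloc[perm]))
    dec_p = ssm_decompose(cm_p)
    assert np.abs(dec_p.loadings - dec.loadings).max() < 1e-8
    assert np.abs(dec_p.scores - dec.scores[perm]).max() < 1e-8


def test_global_scale_equivariance(small_cohort):
    """Multiplying all volumes by k shifts subject means by ln k and leaves
    the residuals, loadings and scores unchanged."""
    scaled = small_cohort.copy()
    for r in REGIONS:
        scaled[r] = scaled[r] * 2.0
    cm = double_center(log_volume_matrix(small_cohort))
    cm_s = double_center(log_volume_matrix(scaled))
    assert np.abs(cm_s.values - cm.values).max() < 1e-10
    assert np.abs(cm_s.subject_means - cm.subject_means - np.log(2.0)).max() < 1e-10
    dec, dec_s = ssm_decompose(cm), ssm_decompose(cm_s)
    assert np.abs(dec_s.loadings - dec.loadings).max() < 1e-8
    assert np.abs(dec_s.scores - dec.scores).max() < 1e-8


def test_planted_component_recovered_at_low_noise():
    p = CohortParams(seed=13, n_subjects=400, noise_sd_regions=0.05)
    cm = double_center(log_volume_matrix(generate_cohort(p)))
    dec = ssm_decompose(cm)
    cos = float(dec.loadings[:, 0] @ default_planted_weights())
    assert abs(cos) >= 0.99


def test_decompose_size_errors():
    with pytest.raises(ValueError, match="subjects"):
        ssm_decompose(double_center(np.ones((2, 5)), region_names=tuple("abcde")))
    with pytest.raises(ValueError, match="regions"):
        ssm_decompose(double_center(np.ones((5, 1)), region_names=("a",)))
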