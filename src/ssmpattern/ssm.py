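"""Scaled Subprofile Model core: log transform, double centering, and
principal-component decomposition of the subject x region residual matrix.

The SSM residual matrix is obtained by natural-log transforming the region
volumes and removing both each subject's mean across regions (the global
scaling factor) and each region's group-mean profile.  Its singular value
decomposition yields regional loading vectors and per-subject component
scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import REGIONS


@dataclass
class CenteredMatrix:
    """Double-centered natural-log volume matrix with the removed means.

    ``values`` has zero row and column means; adding back the broadcast
    ``subject_means`` and ``region_means`` reconstructs the log-volume matrix.
    Both mean vectors are stored for out-of-sample pattern scoring.
    """

    values: np.ndarray  # (n_subjects, n_regions)
    subject_means: np.ndarray  # (n_subjects,)
    region_means: np.ndarray  # (n_regions,)
    region_names: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class SSMDecomposition:
    """SSM components: unit-norm regional loadings, participant scores, and
    eigenvalues (squared singular values / (n-1)), ordered by decreasing
    eigenvalue."""

    loadings: np.ndarray  # (n_regions, K), orthonormal columns
    scores: np.ndarray  # (n_subjects, K), mutually orthogonal columns
    eigenvalues: np.ndarray  # (K,), nonnegative, non-increasing
    variance_fraction: np.ndarray  # (K,), sums to <= 1
    region_names: tuple[str, ...]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def log_volume_matrix(
    cohort: pd.DataFrame, region_names: tuple[str, ...] = REGIONS
) -> np.ndarray:
    """Natural-log volume matrix, columns ordered by ``region_names``.

    Raises a schema error for absent region columns and a domain error naming
    subject and region for nonpositive volumes.
    """
    missing = [r for r in region_names if r not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table missing region columns: {missing}")
    vols = cohort.loc[:, list(region_names)].to_numpy(dtype=float)
    if np.isnan(vols).any():
        i, j = np.argwhere(np.isnan(vols))[0]
        raise ValueError(
            f"missing volume for subject index {i}, region {region_names[j]!r}; "
            "region volumes may not be imputed"
        )
    if (vols <= 0).any():
        i, j = np.argwhere(vols <= 0)[0]
        sid = cohort["subject_id"].iloc[i] if "subject_id" in cohort.columns else i
        raise ValueError(
            f"nonpositive volume for subject {sid!r}, region {region_names[j]!r}"
        )
    return np.log(vols)


def double_center(
    logmat: np.ndarray, region_names: tuple[str, ...] = REGIONS
) -> CenteredMatrix:
    """Remove per-subject means then per-region means from ``logmat``.

    Row (subject) centering removes each subject's global scaling factor;
    the subsequent column (region) centering removes the group mean regional
    profile.  The composition is order-invariant.
    """
    logmat = np.asarray(logmat, dtype=float)
    if np.isnan(logmat).any():
        raise ValueError("missing entries are not permitted in the log-volume matrix")
    subject_means = logmat.mean(axis=1)
    rowc = logmat - subject_means[:, None]
    region_means = rowc.mean(axis=0)
    values = rowc - region_means[None, :]
    return CenteredMatrix(
        values=values,
        subject_means=subject_means,
        region_means=region_means,
        region_names=tuple(region_names),
    )


def ssm_decompose(cm: CenteredMatrix) -> SSMDecomposition:
    """SVD of the double-centered matrix.

    Loadings are the right singular vectors; scores are left singular vectors
    scaled by the singular values, so ``scores @ loadings.T`` reconstructs the
    centered matrix.  Double centering removes one rank in each direction, so
    ``min(n-1, p-1)`` components are kept.  Sign convention: the element of
    largest magnitude in each loading column is positive.
    """
    n, p = cm.values.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if p < 2:
        raise ValueError(f"need at least 2 regions, got {p}")
    u, sv, vt = np.linalg.svd(cm.values, full_matrices=False)
    k = min(n - 1, p - 1)
    u, sv, vt = u[:, :k], sv[:k], vt[:k]
    loadings = vt.T
    # deterministic sign: largest-|.| element of each loading column positive
    anchor = np.argmax(np.abs(loadings), axis=0)
    signs = np.sign(loadings[anchor, np.arange(k)])
    signs[signs == 0] = 1.0
    loadings = loadings * signs[None, :]
    scores = u * (sv * signs)[None, :]
    eigenvalues = sv**2 / (n - 1)
    total_var = float((cm.values**2).sum())
    variance_fraction = (
        sv**2 / total_var if total_var > 0 else np.zeros_like(sv)
    )
    return SSMDecomposition(
        loadings=loadings,
        scores=scores,
        eigenvalues=eigenvalues,
        variance_fraction=variance_fraction,
        region_names=cm.region_names,
    )
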