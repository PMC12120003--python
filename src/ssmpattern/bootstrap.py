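"""Subject-resampling bootstrap confidence intervals for pattern weights.

Each replicate redraws subjects with replacement and reruns the whole
pattern derivation (log transform, double centering, decomposition, combined
regression) with the number of components fixed at the point-estimate
selection.  Replicate weight vectors are unit-normalized and sign-aligned to
the point estimate by dot product; per-region 95% CIs are empirical
percentiles, and a region is flagged significant when its CI excludes zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pattern import CombinedPattern, log_wmh, select_pattern
from .ssm import log_volume_matrix, ssm_decompose

#: replicates whose weights are orthogonal to the point estimate are degenerate
_ALIGN_TOL = 1e-12
_CHUNK = 256


@dataclass
class BootstrapWeights:
    """Per-region percentile CIs and significance flags for pattern weights."""

    region_names: tuple[str, ...]
    point_estimate: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    significant: np.ndarray  # bool, CI excludes zero
    n_boot: int
    n_failed: int
    seed: int | None
    alpha: float = 0.05
    alignment: str = "dot-sign-to-point-estimate"
    replicates: np.ndarray | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region_names,
                "weight": self.point_estimate,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "significant": self.significant,
            }
        )


def _replicate_weights_batch(
    logmat: np.ndarray, y: np.ndarray, idx: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Combined pattern weights for a batch of bootstrap replicates.

    Performs exactly the point-estimate computation — double centering,
    eigendecomposition of the region covariance (equivalent to the SVD route),
    OLS of log WMH on the top-k component scores, coefficient-combined
    loadings — batched across replicates.  Returns (weights, ok_mask);
    failed (rank-deficient/degenerate) replicates have ok=False.
    """
    B, n = idx.shape
    p = logmat.shape[1]
    X = logmat[idx]  # (B, n, p)
    X = X - X.mean(axis=2, keepdims=True)
    X = X - X.mean(axis=1, keepdims=True)
    yb = y[idx]
    yc = yb - yb.mean(axis=1, keepdims=True)

    G = np.einsum("bni,bnj->bij", X, X)  # (B, p, p)
    evals, evecs = np.linalg.eigh(G)  # ascending
    # top-k eigenvectors, descending eigenvalue order
    Vk = evecs[:, :, ::-1][:, :, :k]  # (B, p, k)
    S = np.einsum("bnp,bpk->bnk", X, Vk)  # component scores
    StS = np.einsum("bnk,bnl->bkl", S, S)
    Sty = np.einsum("bnk,bn->bk", S, yc)

    ok = np.ones(B, dtype=bool)
    # rank check: k-th largest eigenvalue must carry signal
    ok &= evals[:, ::-1][:, :k].min(axis=1) > 1e-10 * np.maximum(evals[:, -1], 1e-30)
    beta = np.zeros((B, k))
    try:
        beta[ok] = np.linalg.solve(StS[ok], Sty[ok][..., None])[..., 0]
    except np.linalg.LinAlgError:
        for b in np.flatnonzero(ok):
            try:
                beta[b] = np.linalg.solve(StS[b], Sty[b])
            except np.linalg.LinAlgError:
                ok[b] = False
    w = np.einsum("bpk,bk->bp", Vk, beta)
    norms = np.linalg.norm(w, axis=1)
    ok &= norms > _ALIGN_TOL
    w[ok] = w[ok] / norms[ok, None]
    return w, ok


def bootstrap_pattern(
    cohort: pd.DataFrame,
    pattern: CombinedPattern,
    n_boot: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    reselect: bool = False,
    k_max: int | None = None,
    keep_replicates: bool = True,
) -> BootstrapWeights:
    """Percentile bootstrap CIs for the combined pattern's regional weights.

    The number of components is fixed at ``pattern.k_selected`` in every
    replicate (no per-replicate BIC reselection) so the CIs reflect weight
    variability only; pass ``reselect=True`` to rerun BIC selection within
    each replicate instead.  Deterministic given ``seed``.
    """
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    region_names = pattern.region_names
    logmat = log_volume_matrix(cohort, region_names)
    y = log_wmh(cohort)
    n = logmat.shape[0]
    p = len(region_names)
    k = pattern.k_selected
    w0 = pattern.weights
    rng = np.random.default_rng(seed)

    reps = np.empty((n_boot, p))
    kept = 0
    n_failed = 0
    if reselect:
        # slow path: full reselection per replicate through the public API
        from .ssm import double_center

        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            try:
                cm = double_center(logmat[idx], region_names)
                dec = ssm_decompose(cm)
                pat = select_pattern(dec, y[idx], k_max=k_max)
                w = pat.weights
            except np.linalg.LinAlgError:
                n_failed += 1
                continue
            dot = float(w @ w0)
            if abs(dot) < _ALIGN_TOL:
                n_failed += 1
                continue
            reps[kept] = w if dot >= 0 else -w
            kept += 1
    else:
        done = 0
        while done < n_boot:
            b = min(_CHUNK, n_boot - done)
            idx = rng.integers(0, n, size=(b, n))
            w, ok = _replicate_weights_batch(logmat, y, idx, k)
            dots = w @ w0
            ok &= np.abs(dots) > _ALIGN_TOL
            w[dots < 0] *= -1.0
            m = int(ok.sum())
            reps[kept : kept + m] = w[ok]
            kept += m
            n_failed += b - m
            done += b
    reps = reps[:kept]
    if kept == 0:
        raise np.linalg.LinAlgError("all bootstrap replicates failed")
    if n_failed / n_boot > 0.01:
        warnings.warn(
            f"{n_failed}/{n_boot} bootstrap replicates were degenerate and "
            "discarded",
            RuntimeWarning,
            stacklevel=2,
        )
    ci_low, ci_high = np.quantile(reps, [alpha / 2, 1 - alpha / 2], axis=0)
    significant = (ci_low > 0) | (ci_high < 0)
    return BootstrapWeights(
        region_names=region_names,
        point_estimate=w0.copy(),
        ci_low=ci_low,
        ci_high=ci_high,
        significant=significant,
        n_boot=n_boot,
        n_failed=n_failed,
        seed=seed,
        alpha=alpha,
        replicates=reps if keep_replicates else None,
    )
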