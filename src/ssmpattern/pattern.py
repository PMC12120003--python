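"""BIC-driven selection of the WMH-related covariance pattern.

Log WMH volume is regressed on the participant scores of the leading SSM
components; the number of components is chosen by the Bayesian information
criterion over nested first-k models.  The selected component loadings are
combined with their regression coefficients into a single unit-norm regional
weight vector whose per-subject expression score is z-scored and sign-anchored
to correlate positively with log WMH.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ssm import SSMDecomposition, double_center, log_volume_matrix

#: BIC ties within this margin resolve to the more parsimonious model.
_BIC_TIE_TOL = 1e-9


def log_wmh(cohort: pd.DataFrame) -> np.ndarray:
    """Natural log of total WMH volume (mL)."""
    wmh = cohort["wmh_ml"].to_numpy(dtype=float)
    if np.isnan(wmh).any() or (wmh <= 0).any():
        bad = int(np.argmax(~(wmh > 0)))
        sid = cohort["subject_id"].iloc[bad] if "subject_id" in cohort.columns else bad
        raise ValueError(f"nonpositive or missing WMH volume for subject {sid!r}")
    return np.log(wmh)


def _gaussian_bic(rss: float, n: int, k: int) -> float:
    """BIC of an OLS fit with k slopes + intercept: n ln(RSS/n) + (k+1) ln n.

    Constant terms (the error-variance parameter, 2*pi factors) are omitted;
    they are identical across candidate models and cannot change the argmin.
    """
    return n * np.log(rss / n) + (k + 1) * np.log(n)


@dataclass
class CombinedPattern:
    """BIC-selected combined pattern: regional weights, expression scores and
    fit statistics, plus the centering conventions needed to score new
    subjects (:func:`express_pattern`)."""

    weights: np.ndarray  # (p,), unit norm, sign-anchored to log WMH
    expression: np.ndarray  # (n,), z-scored participant scores
    k_selected: int
    components: tuple[int, ...]  # 1-based indices of the selected components
    beta: np.ndarray  # slopes over the selected component scores
    intercept: float
    r2: float
    adj_r2: float
    f_stat: float
    f_pvalue: float
    df: tuple[int, int]
    bic_path: np.ndarray  # BIC per candidate k (nested search)
    aic_path: np.ndarray  # reported as a diagnostic only
    region_names: tuple[str, ...]
    region_means: np.ndarray  # training group-mean log-volume profile
    expr_loc: float  # training mean of the raw projection
    expr_scale: float  # training SD of the raw projection
    n: int
    bic_by_subset: dict = field(default_factory=dict, repr=False)

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-np.abs(self.weights))
        rank = np.empty_like(order)
        rank[order] = np.arange(1, len(order) + 1)
        return pd.DataFrame(
            {"region": self.region_names, "weight": self.weights, "rank": rank}
        )


def _ols_rss(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares fit with intercept; returns (coefs incl. intercept, RSS)."""
    design = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design in pattern regression")
    resid = y - design @ coef
    return coef, float(resid @ resid)


def select_pattern(
    decomp: SSMDecomposition,
    y: np.ndarray,
    k_max: int | None = None,
    search: str = "nested",
) -> CombinedPattern:
    """Select the combination of SSM components best predicting log WMH.

    For ``search="nested"`` (default), ordinary least squares models
    ``y ~ intercept + scores[:, :k]`` are fitted for k = 1..k_max and the k
    with minimal BIC is chosen, ties resolving to smaller k.
    ``search="exhaustive"`` scans all non-empty subsets of the first k_max
    components instead (sensitivity analysis).

    The combined regional weight vector is the coefficient-weighted sum of the
    selected loadings, unit-normalized; expression scores are the z-scored
    fitted combination, globally signed so that corr(expression, y) >= 0.
    """
    y = np.asarray(y, dtype=float)
    n, k_avail = decomp.scores.shape
    p = decomp.loadings.shape[0]
    if len(y) != n:
        raise ValueError("response length does not match number of subjects")
    if k_max is None:
        k_max = min(n - 2, p - 1, 10)
    if k_max < 1:
        raise ValueError(f"k_max must be >= 1, got {k_max}")
    if k_max > k_avail:
        raise ValueError(f"k_max={k_max} exceeds available components ({k_avail})")
    if n <= k_max + 2:
        raise ValueError(f"need n > k_max + 2 (n={n}, k_max={k_max})")

    # floor the RSS at numerical zero relative to the total sum of squares so
    # an exactly-fitting model does not keep "improving" through rounding noise
    tss = float(((y - y.mean()) ** 2).sum())
    rss_floor = max(tss, 1.0) * 1e-24

    bic_path = np.empty(k_max)
    aic_path = np.empty(k_max)
    for k in range(1, k_max + 1):
        _, rss = _ols_rss(decomp.scores[:, :k], y)
        rss = max(rss, rss_floor)
        bic_path[k - 1] = _gaussian_bic(rss, n, k)
        aic_path[k - 1] = n * np.log(rss / n) + 2 * (k + 1)

    bic_by_subset: dict = {}
    if search == "nested":
        best_k = 1
        for k in range(2, k_max + 1):
            if bic_path[k - 1] < bic_path[best_k - 1] - _BIC_TIE_TOL:
                best_k = k
        components = tuple(range(1, best_k + 1))
    elif search == "exhaustive":
        best_subset, best_bic = None, np.inf
        for r in range(1, k_max + 1):
            for subset in itertools.combinations(range(1, k_max + 1), r):
                cols = [c - 1 for c in subset]
                _, rss = _ols_rss(decomp.scores[:, cols], y)
                bic = _gaussian_bic(max(rss, rss_floor), n, len(subset))
                bic_by_subset[subset] = bic
                if bic < best_bic - _BIC_TIE_TOL:
                    best_subset, best_bic = subset, bic
        components = best_subset
    else:
        raise ValueError(f"unknown search mode {search!r}")

    cols = [c - 1 for c in components]
    model = sm.OLS(y, sm.add_constant(decomp.scores[:, cols])).fit()
    beta = np.asarray(model.params[1:], dtype=float)
    intercept = float(model.params[0])

    raw_weights = decomp.loadings[:, cols] @ beta
    norm = float(np.linalg.norm(raw_weights))
    if norm < 1e-12:
        raise np.linalg.LinAlgError("combined pattern weights are degenerate (norm 0)")
    weights = raw_weights / norm
    fitted_combo = decomp.scores[:, cols] @ beta
    # sign anchor: expression correlates nonnegatively with log WMH
    sign = 1.0
    if np.corrcoef(fitted_combo, y)[0, 1] < 0:
        sign = -1.0
    weights = sign * weights
    raw_proj = sign * fitted_combo / norm  # equals centered matrix @ weights
    expr_loc = float(raw_proj.mean())
    expr_scale = float(raw_proj.std())
    if expr_scale < 1e-15:
        raise np.linalg.LinAlgError("pattern expression is constant")
    expression = (raw_proj - expr_loc) / expr_scale

    k_sel = len(components)
    return CombinedPattern(
        weights=weights,
        expression=expression,
        k_selected=k_sel,
        components=components,
        beta=beta,
        intercept=intercept,
        r2=float(model.rsquared),
        adj_r2=float(model.rsquared_adj),
        f_stat=float(model.fvalue),
        f_pvalue=float(model.f_pvalue),
        df=(k_sel, n - k_sel - 1),
        bic_path=bic_path,
        aic_path=aic_path,
        region_names=decomp.region_names,
        region_means=None,  # filled by derive_pattern / caller
        expr_loc=expr_loc,
        expr_scale=expr_scale,
        n=n,
        bic_by_subset=bic_by_subset,
    )


def derive_pattern(
    cohort: pd.DataFrame,
    region_names=None,
    k_max: int | None = None,
    search: str = "nested",
) -> tuple[CombinedPattern, SSMDecomposition]:
    """End-to-end pattern derivation from a cohort table.

    Runs log transform, double centering, SSM decomposition and BIC selection
    against log WMH, and stores the training centering conventions on the
    returned pattern so it can score held-out subjects.
    """
    from .ssm import ssm_decompose

    if region_names is None:
        from .cohort import REGIONS

        region_names = REGIONS
    logmat = log_volume_matrix(cohort, region_names)
    cm = double_center(logmat, region_names)
    decomp = ssm_decompose(cm)
    pattern = select_pattern(decomp, log_wmh(cohort), k_max=k_max, search=search)
    pattern.region_means = cm.region_means
    return pattern, decomp


def express_pattern(pattern: CombinedPattern, cohort: pd.DataFrame) -> np.ndarray:
    """Forward-apply a trained pattern to (new) subjects.

    Each subject's log-volume profile is centered by its own row mean, the
    stored training region means are removed, the profile is projected onto
    the pattern weights, and the projection is standardized by the training
    expression mean/SD.  On the training cohort this reproduces
    ``pattern.expression``; subject-mean centering makes the score invariant
    to global volume scaling.
    """
    if pattern.region_means is None:
        raise ValueError("pattern carries no training region means")
    logmat = log_volume_matrix(cohort, pattern.region_names)
    centered = logmat - logmat.mean(axis=1)[:, None] - pattern.region_means[None, :]
    proj = centered @ pattern.weights
    return (proj - pattern.expr_loc) / pattern.expr_scale
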