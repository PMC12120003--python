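"""Simple and serial mediation models with percentile-bootstrap CIs.

Path models are fitted by ordinary least squares on listwise-complete rows.
Continuous variables (predictor, mediators, outcome, continuous covariates)
are z-scored so that reported paths are standardized coefficients; binary
covariates stay on their 0/1 scale, where they only absorb variance.
Completely standardized indirect effects are products of standardized paths;
their sampling distribution is obtained by resampling subjects with
replacement, re-standardizing and refitting within every replicate, and
reporting the empirical SD (bootstrap SE) and percentile CI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

#: Covariate sets used in the mediation models: the base set, the base set
#: plus vascular health risk factors, and that plus depression ratings.
COVARIATE_TIERS: dict[str, tuple[str, ...]] = {
    "base": ("tiv", "sex", "education", "apoe4", "hypertension", "interval_days"),
    "vascular": (
        "tiv",
        "sex",
        "education",
        "apoe4",
        "hypertension",
        "interval_days",
        "high_cholesterol",
        "smoking",
        "bmi",
        "vo2max",
    ),
    "depression": (
        "tiv",
        "sex",
        "education",
        "apoe4",
        "hypertension",
        "interval_days",
        "high_cholesterol",
        "smoking",
        "bmi",
        "vo2max",
        "gds",
    ),
}


def preprocess_cognition(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add derived cognition columns for the mediation models.

    ``log_tmt_a``, ``log_tmt_b`` and ``log_gpt`` are natural logs of the
    timed scores (log-transformed to normalize their right-skewed
    distributions).  ``tmt_b_resid`` is the z-scored residual of an OLS
    regression of raw TMT-B time on raw TMT-A time over complete pairs — the
    set-shifting score with processing speed statistically removed.  Note the
    residualization uses raw scores even though TMT-A enters the mediation
    models log-transformed.  Rows with missing inputs get missing outputs.
    """
    df = cohort.copy()
    for raw, logged in (
        ("tmt_a_sec", "log_tmt_a"),
        ("tmt_b_sec", "log_tmt_b"),
        ("gpt_sec", "log_gpt"),
    ):
        vals = df[raw].to_numpy(dtype=float)
        if (vals[~np.isnan(vals)] <= 0).any():
            raise ValueError(f"nonpositive timed score in {raw!r}")
        df[logged] = np.log(vals)
    a = df["tmt_a_sec"].to_numpy(dtype=float)
    b = df["tmt_b_sec"].to_numpy(dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 3:
        raise ValueError("too few complete TMT-A/TMT-B pairs to residualize")
    X = np.column_stack([np.ones(ok.sum()), a[ok]])
    coef, *_ = np.linalg.lstsq(X, b[ok], rcond=None)
    resid = np.full_like(a, np.nan)
    resid[ok] = b[ok] - X @ coef
    sd = np.nanstd(resid, ddof=1)
    if sd < 1e-10 * max(1.0, float(np.nanstd(b))):
        # degenerate: TMT-B is an exact affine function of TMT-A
        resid[ok] = 0.0
        df["tmt_b_resid"] = resid
    else:
        df["tmt_b_resid"] = (resid - np.nanmean(resid)) / sd
    return df


@dataclass
class MediationSpec:
    """Specification of a simple (one-mediator) or serial (two-mediator,
    order matters) mediation model."""

    x: str
    mediators: tuple[str, ...]
    y: str
    covariates: tuple[str, ...] = COVARIATE_TIERS["base"]
    n_boot: int = 10_000
    seed: int | None = None
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        self.mediators = tuple(self.mediators)
        self.covariates = tuple(self.covariates)
        if len(self.mediators) not in (1, 2):
            raise ValueError("mediators must list 1 or 2 columns")
        cols = [self.x, *self.mediators, self.y, *self.covariates]
        if len(set(cols)) != len(cols):
            raise ValueError(
                "x, mediators, y and covariates must be disjoint columns"
            )
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")


@dataclass
class PathEstimate:
    estimate: float
    se: float
    p_value: float


@dataclass
class IndirectEffect:
    estimate: float
    boot_se: float
    ci_low: float
    ci_high: float
    significant: bool


@dataclass
class MediationResult:
    """Standardized path coefficients and bootstrap inference for one model."""

    spec: MediationSpec
    paths: dict  # name -> PathEstimate (a1, [a2, d21], b1, [b2], c_prime, c_total)
    indirect: dict  # name -> IndirectEffect ("a1*b1", ["a2*b2", "a1*d21*b2"])
    n_used: int
    n_boot: int
    n_failed: int = 0
    serial: bool = False
    boot_replicates: dict = field(default_factory=dict, repr=False)

    @property
    def total_indirect(self) -> float:
        return sum(e.estimate for e in self.indirect.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, pe in self.paths.items():
            rows.append(
                {
                    "term": name,
                    "estimate": pe.estimate,
                    "se": pe.se,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p": pe.p_value,
                }
            )
        for name, ie in self.indirect.items():
            rows.append(
                {
                    "term": f"indirect[{name}]",
                    "estimate": ie.estimate,
                    "se": ie.boot_se,
                    "ci_low": ie.ci_low,
                    "ci_high": ie.ci_high,
                    "p": np.nan,
                }
            )
        out = pd.DataFrame(rows)
        out.insert(0, "outcome", self.spec.y)
        out.insert(1, "mediators", "->".join(self.spec.mediators))
        out["n_used"] = self.n_used
        return out


def _is_binary(col: np.ndarray) -> bool:
    vals = np.unique(col)
    return vals.size <= 2 and np.isin(vals, (0.0, 1.0)).all()


def _standardize(mat: np.ndarray, continuous: np.ndarray) -> np.ndarray:
    """Z-score the continuous columns of ``mat`` (ddof=1); binary stay 0/1."""
    out = mat.copy()
    sub = out[:, continuous]
    sd = sub.std(axis=0, ddof=1)
    if (sd < 1e-12).any():
        raise ValueError("constant continuous column cannot be standardized")
    out[:, continuous] = (sub - sub.mean(axis=0)) / sd
    return out


def _check_full_rank(design: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"collinear design; check columns {names}")


def _equations(n_med: int, n_cov: int) -> list[tuple[list[int], int]]:
    """Index plan for the path regressions on the standardized data matrix.

    Column layout: 0 = x, 1..n_med = mediators, n_med+1 = y, rest covariates.
    Returns (predictor columns, response column) per equation, ordered:
    mediator equations, outcome equation, total-effect equation.
    """
    x, y = 0, n_med + 1
    covs = list(range(n_med + 2, n_med + 2 + n_cov))
    eqs = []
    for m in range(1, n_med + 1):
        eqs.append(([x, *range(1, m), *covs], m))
    eqs.append(([x, *range(1, n_med + 1), *covs], y))
    eqs.append(([x, *covs], y))
    return eqs


def _path_names(n_med: int) -> list[list[str]]:
    if n_med == 1:
        return [["a1"], ["c_prime", "b1"], ["c_total"]]
    return [["a1"], ["a2", "d21"], ["c_prime", "b1", "b2"], ["c_total"]]


def _indirect_values(coefs: dict) -> dict:
    if "a2" in coefs:
        return {
            "a1*b1": coefs["a1"] * coefs["b1"],
            "a2*b2": coefs["a2"] * coefs["b2"],
            "a1*d21*b2": coefs["a1"] * coefs["d21"] * coefs["b2"],
        }
    return {"a1*b1": coefs["a1"] * coefs["b1"]}


def _fit_mediation(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    n_med = len(spec.mediators)
    cols = [spec.x, *spec.mediators, spec.y, *spec.covariates]
    for c in cols:
        if c not in data.columns:
            raise KeyError(f"column {c!r} not found in data")
    raw = data.loc[:, cols].to_numpy(dtype=float)
    raw = raw[~np.isnan(raw).any(axis=1)]
    n_used = raw.shape[0]
    if n_used < 10 + len(cols):
        raise ValueError(
            f"too few complete rows (n={n_used}) for {len(cols)} model columns"
        )
    continuous = np.array([not _is_binary(raw[:, j]) for j in range(raw.shape[1])])
    # x, mediators and y are standardized even if they happen to look binary
    continuous[: n_med + 2] = True
    std = _standardize(raw, continuous)

    eqs = _equations(n_med, len(spec.covariates))
    names = _path_names(n_med)
    paths: dict[str, PathEstimate] = {}
    for (pred_cols, resp), coef_names in zip(eqs, names):
        design = sm.add_constant(std[:, pred_cols])
        _check_full_rank(design, [cols[j] for j in pred_cols])
        fit = sm.OLS(std[:, resp], design).fit()
        for i, nm in enumerate(coef_names):
            # named coefficients come first in each equation's predictor list
            paths[nm] = PathEstimate(
                estimate=float(fit.params[1 + i]),
                se=float(fit.bse[1 + i]),
                p_value=float(fit.pvalues[1 + i]),
            )
    point_coefs = {nm: pe.estimate for nm, pe in paths.items()}
    point_indirect = _indirect_values(point_coefs)

    boot = _bootstrap_paths(raw, continuous, spec, n_med, eqs, names)
    alpha = 1.0 - spec.ci_level
    indirect: dict[str, IndirectEffect] = {}
    for nm, est in point_indirect.items():
        reps = boot[nm]
        lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
        indirect[nm] = IndirectEffect(
            estimate=est,
            boot_se=float(reps.std(ddof=1)),
            ci_low=float(lo),
            ci_high=float(hi),
            significant=bool(lo > 0 or hi < 0),
        )
    return MediationResult(
        spec=spec,
        paths=paths,
        indirect=indirect,
        n_used=n_used,
        n_boot=spec.n_boot,
        n_failed=int(boot["n_failed"]),
        serial=n_med == 2,
        boot_replicates=boot,
    )


def _bootstrap_paths(raw, continuous, spec, n_med, eqs, names) -> dict:
    """Vectorized subject-resampling bootstrap of all path coefficients.

    Each replicate re-standardizes its own resample (standardization is part
    of the estimator) and refits every equation by batched normal equations.
    Returns arrays of replicate indirect effects keyed by effect name.
    """
    rng = np.random.default_rng(spec.seed)
    n, q = raw.shape
    B = spec.n_boot
    cont = np.flatnonzero(continuous)
    flat_names = [nm for eq_names in names for nm in eq_names]
    out = {nm: np.empty(B) for nm in flat_names}
    n_failed = 0
    kept = 0
    chunk = max(1, min(512, int(2e7 // (n * q))))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        idx = rng.integers(0, n, size=(b, n))
        Z = raw[idx]  # (b, n, q)
        sub = Z[:, :, cont]
        sd = sub.std(axis=1, ddof=1)
        ok = (sd > 1e-12).all(axis=1)
        sd[sd < 1e-12] = 1.0
        Z[:, :, cont] = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None, :]
        coefs = {}
        for (pred_cols, resp), coef_names in zip(eqs, names):
            X = np.concatenate(
                [np.ones((b, n, 1)), Z[:, :, pred_cols]], axis=2
            )
            G = np.einsum("bni,bnj->bij", X, X)
            h = np.einsum("bni,bn->bi", X, Z[:, :, resp])
            beta = np.full((b, X.shape[2]), np.nan)
            try:
                beta[ok] = np.linalg.solve(G[ok], h[ok][..., None])[..., 0]
            except np.linalg.LinAlgError:
                for r in np.flatnonzero(ok):
                    try:
                        beta[r] = np.linalg.solve(G[r], h[r])
                    except np.linalg.LinAlgError:
                        ok[r] = False
            for i, nm in enumerate(coef_names):
                coefs[nm] = beta[:, 1 + i]
        m = int(ok.sum())
        for nm in flat_names:
            out[nm][kept : kept + m] = coefs[nm][ok]
        kept += m
        n_failed += b - m
        done += b
    result = {nm: arr[:kept] for nm, arr in out.items()}
    for nm, vals in _indirect_values(
        {nm: result[nm] for nm in flat_names}
    ).items():
        result[nm] = vals
    result["n_failed"] = n_failed
    return result


def fit_simple_mediation(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Fit a one-mediator model: x -> m1 -> y with covariates.

    Path equations (all OLS on the standardized, listwise-complete data):
    ``m1 ~ a1*x + covs``; ``y ~ c'*x + b1*m1 + covs``; ``y ~ c_total*x +
    covs``.  The completely standardized indirect effect is ``a1*b1`` with a
    percentile bootstrap CI.  In-sample, ``c_total = c' + a1*b1`` exactly.
    """
    if len(spec.mediators) != 1:
        raise ValueError("fit_simple_mediation requires exactly one mediator")
    return _fit_mediation(data, spec)


def fit_serial_mediation(data: pd.DataFrame, spec: MediationSpec) -> MediationResult:
    """Fit a two-mediator serial model: x -> m1 -> m2 -> y with covariates.

    Path equations: ``m1 ~ a1*x + covs``; ``m2 ~ a2*x + d21*m1 + covs``;
    ``y ~ c'*x + b1*m1 + b2*m2 + covs``.  The three completely standardized
    indirect effects are ``a1*b1``, ``a2*b2`` and the headline serial effect
    ``a1*d21*b2``; in-sample their sum plus ``c'`` equals ``c_total``.
    """
    if len(spec.mediators) != 2:
        raise ValueError("fit_serial_mediation requires exactly two mediators")
    return _fit_mediation(data, spec)
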