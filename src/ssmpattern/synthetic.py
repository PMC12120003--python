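"""Synthetic cohort generator with planted ground truth.

The generator emulates the study conditions of a healthy-aging volumetrics
cohort: marginal distributions of demographics, vascular risk factors and
cognition scores; a planted low-rank regional covariance pattern in the log
subcortical volumes coupled to log WMH burden; and the serial path structure
age -> pattern -> processing speed (log TMT-A) -> downstream cognition.
Because the latent pattern score is returned as a ground-truth column, every
downstream stage is testable by parameter recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import CohortParams, GROUND_TRUTH_COLUMNS  # noqa: F401


def _lognormal_mu_sigma(mean: float, sd: float) -> tuple[float, float]:
    """Natural-scale moments -> (mu, sigma) of the matching log-normal."""
    sigma2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - sigma2 / 2.0, np.sqrt(sigma2)


def _draw_gds(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Depression ratings: nonnegative ordinal, moment-matched.

    Negative binomial when overdispersed (variance > mean), Poisson otherwise.
    """
    var = sd**2
    if var > mean:
        r = mean**2 / (var - mean)
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=n).astype(float)
    return rng.poisson(mean, size=n).astype(float)


def _draw_interval(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Scan-test interval in days: nonnegative, right-skewed (gamma)."""
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return rng.gamma(shape, scale, size=n)


def generate_path_data(
    n: int,
    a1: float,
    b1: float,
    c_prime: float = 0.0,
    d21: float | None = None,
    b2: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate bare path-model data for mediation testing.

    All variables are constructed with unit population variance, so the
    planted coefficients are exactly the completely standardized paths: the
    simple indirect effect is ``a1*b1`` and the serial headline effect is
    ``a1*d21*b2``.  Simple model: ``m1 = a1*x + e``, ``y = c_prime*x + b1*m1
    + e``; with ``d21``/``b2`` given, the serial chain ``m2 = a2*x + d21*m1 +
    e`` (here a2 = 0) and ``y = c_prime*x + b1*m1 + b2*m2 + e`` is generated
    instead.  Raises ``ValueError`` when the couplings leave no residual
    variance.
    """

    def _noise_sd(explained: float, what: str) -> float:
        resid = 1.0 - explained
        if resid <= 0:
            raise ValueError(f"couplings leave nonpositive residual variance for {what}")
        return float(np.sqrt(resid))

    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m1 = a1 * x + _noise_sd(a1**2, "m1") * rng.standard_normal(n)
    cols = {"x": x, "m1": m1}
    if d21 is None:
        # var(y) = c'^2 + b1^2 + 2 c' b1 cov(x, m1) + noise
        expl = c_prime**2 + b1**2 + 2 * c_prime * b1 * a1
        y = c_prime * x + b1 * m1 + _noise_sd(expl, "y") * rng.standard_normal(n)
    else:
        if b2 is None:
            raise ValueError("b2 is required when d21 is given")
        m2 = d21 * m1 + _noise_sd(d21**2, "m2") * rng.standard_normal(n)
        cols["m2"] = m2
        cov_x_m2 = d21 * a1
        cov_m1_m2 = d21
        expl = (
            c_prime**2
            + b1**2
            + b2**2
            + 2 * c_prime * b1 * a1
            + 2 * c_prime * b2 * cov_x_m2
            + 2 * b1 * b2 * cov_m1_m2
        )
        y = (
            c_prime * x
            + b1 * m1
            + b2 * m2
            + _noise_sd(expl, "y") * rng.standard_normal(n)
        )
    cols["y"] = y
    return pd.DataFrame(cols)


def _generate(params: CohortParams, planted: bool) -> pd.DataFrame:
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_subjects
    p = len(params.region_names)

    z_age = rng.standard_normal(n)
    age = params.age_mean + params.age_sd * z_age

    # latent pattern expression score (unit variance by construction)
    a = params.coupling_age_pattern
    s = a * z_age + np.sqrt(1.0 - a**2) * rng.standard_normal(n)

    # log region volumes: baseline + per-subject global size factor +
    # planted pattern + residual noise
    global_scale = params.global_scale_sd * rng.standard_normal(n)
    noise = params.noise_sd_regions * rng.standard_normal((n, p))
    logvol = params.region_log_means[None, :] + global_scale[:, None] + noise
    if planted:
        logvol = logvol + np.outer(s, params.planted_weights)
    volumes = np.exp(logvol)

    # log WMH: coupled to the pattern score, affinely rescaled so the
    # untransformed marginal approximately matches (wmh_mean_ml, wmh_sd_ml)
    c = params.coupling_pattern_logwmh if planted else 0.0
    z_wmh = c * s + np.sqrt(1.0 - c**2) * rng.standard_normal(n)
    mu_w, sigma_w = _lognormal_mu_sigma(params.wmh_mean_ml, params.wmh_sd_ml)
    wmh_ml = np.exp(mu_w + sigma_w * z_wmh)

    # processing speed: z(log TMT-A) = b*s + c_a*z(age) + noise, unit variance
    b = params.pattern_to_speed if planted else 0.0
    c_a = params.age_to_speed_direct
    var_speed_noise = 1.0 - b**2 - c_a**2 - 2.0 * b * c_a * a
    if var_speed_noise <= 0:
        raise ValueError(
            "pattern_to_speed/age_to_speed_direct imply nonpositive residual "
            "variance for log TMT-A"
        )
    z_speed = b * s + c_a * z_age + np.sqrt(var_speed_noise) * rng.standard_normal(n)
    rho_speed_age = b * a + c_a  # corr(z_speed, z_age)
    mu_a, sig_a = _lognormal_mu_sigma(*params.cognition_moments["tmt_a"])
    tmt_a = np.exp(mu_a + sig_a * z_speed)

    # downstream outcomes: z(outcome) = d*z_speed + c*z(age) + noise
    z_out = {}
    for key in ("srt_cltr", "tmt_b", "wais_lns", "scwt", "gpt"):
        d = params.speed_couplings[key]
        cd = params.direct_age_effects[key]
        var_noise = 1.0 - d**2 - cd**2 - 2.0 * d * cd * rho_speed_age
        if var_noise <= 0:
            raise ValueError(
                f"speed_couplings/direct_age_effects for {key!r} imply "
                "nonpositive residual variance"
            )
        z_out[key] = (
            d * z_speed + cd * z_age + np.sqrt(var_noise) * rng.standard_normal(n)
        )

    def raw_scale(key: str, z: np.ndarray) -> np.ndarray:
        m, sd = params.cognition_moments[key]
        return m + sd * z

    def raw_timed(key: str, z: np.ndarray) -> np.ndarray:
        mu, sig = _lognormal_mu_sigma(*params.cognition_moments[key])
        return np.exp(mu + sig * z)

    srt = raw_scale("srt_cltr", z_out["srt_cltr"])
    lns = raw_scale("wais_lns", z_out["wais_lns"])
    scwt = raw_scale("scwt", z_out["scwt"])
    tmt_b = raw_timed("tmt_b", z_out["tmt_b"])
    gpt = raw_timed("gpt", z_out["gpt"])

    df = pd.DataFrame({"subject_id": [f"sub-{i + 1:04d}" for i in range(n)]})
    for j, r in enumerate(params.region_names):
        df[r] = volumes[:, j]
    df["wmh_ml"] = wmh_ml
    df["tiv"] = params.tiv_mean + params.tiv_sd * rng.standard_normal(n)
    df["age"] = age
    df["sex"] = rng.binomial(1, params.sex_p_female, size=n).astype(float)
    df["education"] = params.education_mean + params.education_sd * rng.standard_normal(
        n
    )
    df["apoe4"] = rng.binomial(1, params.apoe4_p, size=n).astype(float)
    df["hypertension"] = rng.binomial(1, params.hypertension_p, size=n).astype(float)
    df["high_cholesterol"] = rng.binomial(
        1, params.high_cholesterol_p, size=n
    ).astype(float)
    df["smoking"] = rng.binomial(1, params.smoking_p, size=n).astype(float)
    df["bmi"] = params.bmi_mean + params.bmi_sd * rng.standard_normal(n)
    df["vo2max"] = params.vo2max_mean + params.vo2max_sd * rng.standard_normal(n)
    df["gds"] = _draw_gds(rng, params.gds_mean, params.gds_sd, n)
    df["interval_days"] = _draw_interval(
        rng, params.interval_mean, params.interval_sd, n
    )
    df["srt_cltr"] = srt
    df["tmt_a_sec"] = tmt_a
    df["tmt_b_sec"] = tmt_b
    df["wais_lns"] = lns
    df["scwt"] = scwt
    df["gpt_sec"] = gpt

    # plant missingness in cognition only (distinct subjects when possible)
    n_miss = params.missing_tmt_b + params.missing_gpt
    if n_miss > 0:
        idx = rng.choice(n, size=min(n_miss, n), replace=False)
        df.loc[df.index[idx[: params.missing_tmt_b]], "tmt_b_sec"] = np.nan
        df.loc[df.index[idx[params.missing_tmt_b : n_miss]], "gpt_sec"] = np.nan

    df["true_pattern_score"] = s
    return df


def generate_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Generate a synthetic cohort table with planted ground truth.

    Deterministic given ``params.seed``.  The returned frame carries the
    latent pattern score in the non-analytic column ``true_pattern_score``.
    """
    return _generate(params or CohortParams(), planted=True)


def generate_null_cohort(params: CohortParams | None = None) -> pd.DataFrame:
    """Generate a null cohort: no pattern in the volumes, WMH independent of
    them, and no pattern-mediated cognition paths.  Used for type-I-error
    calibration of the bootstrap and mediation stages."""
    return _generate(params or CohortParams(), planted=False)
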