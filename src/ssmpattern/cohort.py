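"""Cohort table schema, simulation parameters, and CSV I/O.

The cohort table is the pipeline's sole input: one row per subject with the
14 bilateral subcortical gray-matter (SGM) volumes in mm^3, total white-matter
hyperintensity (WMH) volume in mL, demographic/vascular covariates, and the
neuropsychological scores.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

#: The seven bilateral subcortical structures, left then right, in the fixed
#: column order used throughout the pipeline.
REGIONS: tuple[str, ...] = (
    "caudate_l",
    "caudate_r",
    "putamen_l",
    "putamen_r",
    "pallidum_l",
    "pallidum_r",
    "hippocampus_l",
    "hippocampus_r",
    "accumbens_l",
    "accumbens_r",
    "amygdala_l",
    "amygdala_r",
    "thalamus_l",
    "thalamus_r",
)

#: Cognition columns; the only columns in which missing values are allowed.
COGNITION_COLUMNS: tuple[str, ...] = (
    "srt_cltr",
    "tmt_a_sec",
    "tmt_b_sec",
    "wais_lns",
    "scwt",
    "gpt_sec",
)

COVARIATE_COLUMNS: tuple[str, ...] = (
    "tiv",
    "age",
    "sex",
    "education",
    "apoe4",
    "hypertension",
    "high_cholesterol",
    "smoking",
    "bmi",
    "vo2max",
    "gds",
    "interval_days",
)

#: Fixed column order of a serialized cohort CSV.  ``true_pattern_score`` is a
#: ground-truth column emitted by the synthetic generator; it is flagged
#: non-analytic and never read by the analysis stages.
COHORT_COLUMNS: tuple[str, ...] = (
    ("subject_id",) + REGIONS + ("wmh_ml",) + COVARIATE_COLUMNS + COGNITION_COLUMNS
)

GROUND_TRUTH_COLUMNS: tuple[str, ...] = ("true_pattern_score",)

# Typical FreeSurfer per-structure volumes (mm^3) for older adults, used as
# natural-log baselines for the generator.
_TYPICAL_VOLUMES_MM3 = {
    "caudate": 3500.0,
    "putamen": 5000.0,
    "pallidum": 1800.0,
    "hippocampus": 4000.0,
    "accumbens": 600.0,
    "amygdala": 1600.0,
    "thalamus": 7000.0,
}


def _default_region_log_means() -> np.ndarray:
    return np.array(
        [np.log(_TYPICAL_VOLUMES_MM3[r.rsplit("_", 1)[0]]) for r in REGIONS]
    )


def default_planted_weights(region_names: tuple[str, ...] = REGIONS) -> np.ndarray:
    """Default planted pattern topography.

    Negative weights on bilateral putamen and left nucleus accumbens (regions
    whose volume decreases with WMH burden), positive weights on bilateral
    caudate (relative increases), zero elsewhere; the raw vector is
    mean-removed so it lives in the double-centered space, then unit-normalized.
    """
    raw = {
        "putamen_l": -1.0,
        "putamen_r": -1.0,
        "accumbens_l": -0.7,
        "caudate_l": 0.8,
        "caudate_r": 0.8,
    }
    w = np.array([raw.get(r, 0.0) for r in region_names])
    w = w - w.mean()
    return w / np.linalg.norm(w)


# Standardized path couplings of the cognition model.  Keys are outcome
# domains; the processing-speed coupling (d) is the standardized slope of the
# outcome on z(log TMT-A), and the direct coupling (c) the standardized slope
# on z(age).  Defaults reproduce the reported standardized direct effects and
# the serial indirect effects implied by the age->pattern (0.492) and
# pattern->speed (0.234) paths.
_DEFAULT_DIRECT_AGE = {
    "srt_cltr": -0.497,
    "tmt_b": 0.234,
    "wais_lns": -0.416,
    "scwt": -0.423,
    "gpt": 0.639,
}
_DEFAULT_SPEED_COUPLING = {
    "srt_cltr": -0.278,
    "tmt_b": 0.539,
    "wais_lns": -0.287,
    "scwt": -0.347,
    "gpt": 0.182,
}

# Marginal moments of the cognition scores: (mean, sd) on the raw scale.
_DEFAULT_COGNITION_MOMENTS = {
    "srt_cltr": (63.38, 37.16),
    "tmt_a": (32.62, 10.67),
    "tmt_b": (75.80, 30.27),
    "wais_lns": (18.77, 2.80),
    "scwt": (36.71, 9.33),
    "gpt": (92.10, 26.77),
}


@dataclass
class CohortParams:
    """Parameters of the synthetic cohort generator.

    Defaults emulate the study sample: n = 178 community-dwelling healthy
    older adults, age 69.77 (10.22) years, total WMH volume 6.68 (10.28) mL,
    a planted low-rank covariance pattern with negative putamen/left-accumbens
    and positive caudate weights coupled to log WMH, and the serial path
    structure age -> pattern -> log TMT-A -> downstream cognition.
    """

    n_subjects: int = 178
    age_mean: float = 69.77
    age_sd: float = 10.22
    region_names: tuple[str, ...] = REGIONS
    region_log_means: np.ndarray = field(default_factory=_default_region_log_means)
    global_scale_sd: float = 0.08
    planted_weights: np.ndarray = field(default_factory=default_planted_weights)
    noise_sd_regions: float = 0.4
    # standardized couplings of the latent pattern score
    coupling_age_pattern: float = 0.492
    coupling_pattern_logwmh: float = 0.62
    # cognition path coefficients (standardized)
    pattern_to_speed: float = 0.234
    age_to_speed_direct: float = 0.262
    direct_age_effects: dict = field(default_factory=lambda: dict(_DEFAULT_DIRECT_AGE))
    speed_couplings: dict = field(
        default_factory=lambda: dict(_DEFAULT_SPEED_COUPLING)
    )
    # marginal moments
    wmh_mean_ml: float = 6.68
    wmh_sd_ml: float = 10.28
    cognition_moments: dict = field(
        default_factory=lambda: dict(_DEFAULT_COGNITION_MOMENTS)
    )
    tiv_mean: float = 1.4e6
    tiv_sd: float = 1.4e5
    sex_p_female: float = 0.506
    education_mean: float = 16.72
    education_sd: float = 2.80
    apoe4_p: float = 0.315
    hypertension_p: float = 0.331
    high_cholesterol_p: float = 0.702
    smoking_p: float = 0.399
    bmi_mean: float = 25.21
    bmi_sd: float = 3.87
    vo2max_mean: float = 24.43
    vo2max_sd: float = 5.81
    gds_mean: float = 1.01
    gds_sd: float = 1.58
    interval_mean: float = 56.49
    interval_sd: float = 46.69
    # one missing TMT-B and one missing GPT by default (n = 177 complete)
    missing_tmt_b: int = 1
    missing_gpt: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.region_names = tuple(self.region_names)
        self.region_log_means = np.asarray(self.region_log_means, dtype=float)
        self.planted_weights = np.asarray(self.planted_weights, dtype=float)

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending field on invalid input."""
        if self.n_subjects < 30:
            raise ValueError(f"n_subjects must be >= 30, got {self.n_subjects}")
        p = len(self.region_names)
        if self.region_log_means.shape != (p,):
            raise ValueError("region_log_means length must match region_names")
        if self.planted_weights.shape != (p,):
            raise ValueError("planted_weights length must match region_names")
        norm = float(np.linalg.norm(self.planted_weights))
        if norm > 0 and (
            abs(norm - 1.0) > 1e-8 or abs(self.planted_weights.sum()) > 1e-8
        ):
            raise ValueError(
                "planted_weights must have unit norm and zero sum "
                "(or be all-zero for a null cohort)"
            )
        for name in (
            "age_sd",
            "noise_sd_regions",
            "wmh_sd_ml",
            "tiv_sd",
            "education_sd",
            "bmi_sd",
            "vo2max_sd",
            "gds_sd",
            "interval_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.global_scale_sd < 0:
            raise ValueError("global_scale_sd must be >= 0")
        for name in ("coupling_age_pattern", "coupling_pattern_logwmh"):
            if not -1.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1]")
        for name in (
            "sex_p_female",
            "apoe4_p",
            "hypertension_p",
            "high_cholesterol_p",
            "smoking_p",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        missing = set(self.direct_age_effects) ^ set(_DEFAULT_DIRECT_AGE)
        if missing:
            raise ValueError(f"direct_age_effects keys mismatch: {sorted(missing)}")
        missing = set(self.speed_couplings) ^ set(_DEFAULT_SPEED_COUPLING)
        if missing:
            raise ValueError(f"speed_couplings keys mismatch: {sorted(missing)}")

    def with_(self, **kwargs) -> "CohortParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        d = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in self.__dict__.items()
        }
        d["region_names"] = list(self.region_names)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


def validate_cohort(df: pd.DataFrame, region_names=REGIONS) -> None:
    """Check cohort-table invariants; raise ``ValueError`` on violation.

    Volumes, WMH and timed scores must be strictly positive (they are
    log-transformed downstream); subject ids must be unique; missing values
    are permitted only in cognition columns.
    """
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"cohort table missing columns: {missing_cols}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicated subject_id: {dup!r}")
    for col in (*region_names, "wmh_ml"):
        vals = df[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"missing values not permitted in {col!r}")
        if (vals <= 0).any():
            bad = df["subject_id"].iloc[int(np.argmax(vals <= 0))]
            raise ValueError(f"nonpositive value in {col!r} for subject {bad!r}")
    for col in ("tmt_a_sec", "tmt_b_sec", "gpt_sec"):
        vals = df[col].to_numpy(dtype=float)
        if (vals[~np.isnan(vals)] <= 0).any():
            raise ValueError(f"nonpositive timed score in {col!r}")
    non_cognition = [
        c for c in COHORT_COLUMNS if c not in COGNITION_COLUMNS and c != "subject_id"
    ]
    if df[non_cognition].isna().any().any():
        bad = df[non_cognition].isna().any()
        raise ValueError(
            f"missing values permitted only in cognition columns; found in "
            f"{list(bad.index[bad])}"
        )


def write_cohort(df: pd.DataFrame, path, seed: int | None = None) -> None:
    """Write a cohort table as CSV in the documented fixed column order.

    The generator seed, when known, is recorded in a leading ``#`` comment
    line so runs are auditable from the file alone.
    """
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in GROUND_TRUTH_COLUMNS if c in df.columns]
    buf = io.StringIO()
    if seed is not None:
        buf.write(f"# seed={seed}\n")
    df[cols].to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV written by :func:`write_cohort` and validate it."""
    df = pd.read_csv(path, comment="#")
    validate_cohort(df)
    return df
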