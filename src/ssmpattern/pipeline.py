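"""End-to-end orchestration: simulate/load -> SSM -> selection -> bootstrap ->
mediation suite, with serialized stage outputs and a reproducibility manifest.

Every stage writes plain CSV/JSON so any stage can be re-run from the
serialized output of the one before it; rerunning with the same config
reproduces all numeric outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import REGIONS, CohortParams, read_cohort, validate_cohort, write_cohort
from .bootstrap import bootstrap_pattern
from .mediation import (
    COVARIATE_TIERS,
    MediationSpec,
    fit_serial_mediation,
    fit_simple_mediation,
    preprocess_cognition,
)
from .pattern import derive_pattern, express_pattern, log_wmh
from .synthetic import generate_cohort

#: Outcome domains: simple-model outcome and serial-model outcome columns.
#: Processing speed (log TMT-A) is the second mediator of the serial models,
#: so it appears only as a simple-model outcome.  In the simple models the
#: set-shifting outcome is the TMT-B residual (speed removed); in the serial
#: models it is log TMT-B time, with speed handled by the mediator chain.
OUTCOME_DOMAINS: dict[str, dict] = {
    "memory": {"simple": "srt_cltr", "serial": "srt_cltr"},
    "shifting": {"simple": "tmt_b_resid", "serial": "log_tmt_b"},
    "working_memory": {"simple": "wais_lns", "serial": "wais_lns"},
    "inhibition": {"simple": "scwt", "serial": "scwt"},
    "speed": {"simple": "log_tmt_a", "serial": None},
    "fine_motor": {"simple": "log_gpt", "serial": "log_gpt"},
}

MEDIATOR_PATTERN = "pattern_expression"
MEDIATOR_SPEED = "log_tmt_a"


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str | Path
    cohort_csv: str | Path | None = None  # load this cohort ...
    params: CohortParams | None = None  # ... or simulate one
    region_names: tuple[str, ...] = REGIONS
    k_max: int | None = None
    n_boot_pattern: int = 10_000
    n_boot_mediation: int = 10_000
    seed: int = 0
    tiers: tuple[str, ...] = ("base", "vascular", "depression")
    outcomes: tuple[str, ...] = tuple(OUTCOME_DOMAINS)
    search: str = "nested"

    def validate(self) -> None:
        for t in self.tiers:
            if t not in COVARIATE_TIERS:
                raise ValueError(
                    f"unknown covariate tier {t!r}; expected one of "
                    f"{sorted(COVARIATE_TIERS)}"
                )
        for o in self.outcomes:
            if o not in OUTCOME_DOMAINS:
                raise ValueError(f"unknown outcome domain {o!r}")
        if self.cohort_csv is None and self.params is None:
            self.params = CohortParams(seed=self.seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _spawn_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent child seeds (< 2^31) from the run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every stage in order and return the machine-readable manifest.

    Outputs under ``config.out_dir``: cohort snapshot, SSM loadings/scores,
    pattern weights + fit report, bootstrap CIs, a Fig.-1A-style scatter
    export (expression vs log WMH), one tidy mediation CSV per covariate tier
    and outcome domain, the reversed-mediator comparison model per tier, and
    ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed_sim, seed_boot, seed_med = _spawn_seeds(config.seed, 3)
    stages: list[dict] = []
    files: dict[str, str] = {}

    def _stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        stages.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        return result

    # --- cohort ---------------------------------------------------------
    def _load_cohort():
        if config.cohort_csv is not None:
            df = read_cohort(config.cohort_csv)
        else:
            df = generate_cohort(config.params.with_(seed=seed_sim))
            config.params.with_(seed=seed_sim).to_yaml(out / "params.yaml")
        validate_cohort(df, config.region_names)
        write_cohort(df, out / "cohort.csv", seed=seed_sim)
        return df

    cohort = _stage("cohort", _load_cohort)

    # --- SSM + pattern selection ---------------------------------------
    def _pattern():
        pattern, decomp = derive_pattern(
            cohort, config.region_names, k_max=config.k_max, search=config.search
        )
        pd.DataFrame(
            decomp.loadings,
            index=pd.Index(decomp.region_names, name="region"),
            columns=[f"component_{i + 1}" for i in range(decomp.n_components)],
        ).to_csv(out / "ssm_loadings.csv")
        pd.DataFrame(
            decomp.scores,
            index=pd.Index(cohort["subject_id"], name="subject_id"),
            columns=[f"component_{i + 1}" for i in range(decomp.n_components)],
        ).to_csv(out / "ssm_scores.csv")
        (out / "ssm_eigenvalues.json").write_text(
            json.dumps(
                {
                    "eigenvalues": decomp.eigenvalues.tolist(),
                    "variance_fraction": decomp.variance_fraction.tolist(),
                    "sign_convention": "largest-|loading| element positive",
                },
                indent=2,
            )
        )
        pattern.to_frame().to_csv(out / "pattern_weights.csv", index=False)
        (out / "pattern_fit.json").write_text(
            json.dumps(
                {
                    "k_selected": pattern.k_selected,
                    "components": list(pattern.components),
                    "bic_path": pattern.bic_path.tolist(),
                    "aic_path": pattern.aic_path.tolist(),
                    "r2": pattern.r2,
                    "adj_r2": pattern.adj_r2,
                    "f_stat": pattern.f_stat,
                    "f_pvalue": pattern.f_pvalue,
                    "df": list(pattern.df),
                    "n": pattern.n,
                },
                indent=2,
            )
        )
        pd.DataFrame(
            {
                "subject_id": cohort["subject_id"],
                "pattern_expression": pattern.expression,
                "log_wmh": log_wmh(cohort),
            }
        ).to_csv(out / "scatter_expression_logwmh.csv", index=False)
        return pattern

    pattern = _stage("pattern", _pattern)

    # --- bootstrap CIs on weights --------------------------------------
    def _bootstrap():
        bw = bootstrap_pattern(
            cohort,
            pattern,
            n_boot=config.n_boot_pattern,
            seed=seed_boot,
            keep_replicates=False,
        )
        bw.to_frame().to_csv(out / "bootstrap_weights.csv", index=False)
        return bw

    _stage("bootstrap", _bootstrap)

    # --- mediation suite ------------------------------------------------
    def _mediation():
        data = preprocess_cognition(cohort)
        data[MEDIATOR_PATTERN] = express_pattern(pattern, cohort)
        med_seeds = iter(
            _spawn_seeds(seed_med, len(config.tiers) * (2 * len(config.outcomes) + 1))
        )
        n_files = 0
        for tier in config.tiers:
            covs = COVARIATE_TIERS[tier]
            tier_dir = out / "mediation" / tier
            tier_dir.mkdir(parents=True, exist_ok=True)
            for domain in config.outcomes:
                frames = []
                simple_y = OUTCOME_DOMAINS[domain]["simple"]
                res = fit_simple_mediation(
                    data,
                    MediationSpec(
                        x="age",
                        mediators=(MEDIATOR_PATTERN,),
                        y=simple_y,
                        covariates=covs,
                        n_boot=config.n_boot_mediation,
                        seed=next(med_seeds),
                    ),
                )
                frames.append(res.to_frame().assign(model="simple"))
                serial_y = OUTCOME_DOMAINS[domain]["serial"]
                serial_seed = next(med_seeds)
                if serial_y is not None:
                    res = fit_serial_mediation(
                        data,
                        MediationSpec(
                            x="age",
                            mediators=(MEDIATOR_PATTERN, MEDIATOR_SPEED),
                            y=serial_y,
                            covariates=covs,
                            n_boot=config.n_boot_mediation,
                            seed=serial_seed,
                        ),
                    )
                    frames.append(res.to_frame().assign(model="serial"))
                path = tier_dir / f"{domain}.csv"
                pd.concat(frames, ignore_index=True).to_csv(path, index=False)
                n_files += 1
            # reversed-mediator comparison: fine motor before speed
            res = fit_serial_mediation(
                data,
                MediationSpec(
                    x="age",
                    mediators=(MEDIATOR_PATTERN, "log_gpt"),
                    y=MEDIATOR_SPEED,
                    covariates=covs,
                    n_boot=config.n_boot_mediation,
                    seed=next(med_seeds),
                ),
            )
            res.to_frame().assign(model="serial_reversed").to_csv(
                tier_dir / "comparison_reversed.csv", index=False
            )
        return n_files

    n_mediation_files = _stage("mediation", _mediation)

    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            files[str(f.relative_to(out))] = _sha256(f)

    from . import __version__ as version

    manifest = {
        "package": "ssmpattern",
        "version": version,
        "seed": config.seed,
        "stage_seeds": {
            "simulate": seed_sim,
            "bootstrap": seed_boot,
            "mediation": seed_med,
        },
        "tiers": list(config.tiers),
        "outcomes": list(config.outcomes),
        "n_mediation_files": n_mediation_files,
        "stages": stages,
        "files": files,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
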