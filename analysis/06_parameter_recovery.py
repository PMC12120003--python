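#!/usr/bin/env python
"""Parameter-recovery and calibration experiments.

Because every cohort is synthetic with known ground truth, the pipeline can
be validated end to end: (1) cosine similarity between estimated and planted
pattern topography across repeated cohorts at n=1000; (2) bootstrap
significance rates for core-topography regions on strong-pattern cohorts and
for all regions on null cohorts; (3) recovery of a planted completely
standardized indirect effect and the empirical coverage of its percentile
bootstrap CI.
"""

import json
from pathlib import Path

import numpy as np

from ssmpattern import (
    CohortParams,
    MediationSpec,
    bootstrap_pattern,
    default_planted_weights,
    fit_simple_mediation,
    generate_cohort,
    generate_null_cohort,
    generate_path_data,
)
from ssmpattern.pattern import derive_pattern

SEED = 20_250_929
OUT = Path("results")
CORE = ("putamen_l", "putamen_r", "accumbens_l", "caudate_l", "caudate_r")


def main() -> None:
    report = {}
    truth = default_planted_weights()

    cosines = []
    for rep in range(25):
        pat, _ = derive_pattern(
            generate_cohort(
                CohortParams(seed=SEED + rep, n_subjects=1_000,
                             coupling_pattern_logwmh=0.6)
            )
        )
        cosines.append(abs(float(pat.weights @ truth)))
    report["recovery_cosine_median"] = float(np.median(cosines))
    report["recovery_cosine_min"] = float(np.min(cosines))
    print(f"topography recovery at n=1000 (25 cohorts): median |cos| = "
          f"{report['recovery_cosine_median']:.3f}, min = "
          f"{report['recovery_cosine_min']:.3f}")

    core_flags, null_flags = [], []
    for rep in range(25):
        df = generate_cohort(
            CohortParams(seed=SEED + 100 + rep, n_subjects=500,
                         coupling_pattern_logwmh=0.7)
        )
        pat, _ = derive_pattern(df)
        bw = bootstrap_pattern(df, pat, n_boot=1_000, seed=rep,
                               keep_replicates=False)
        flags = dict(zip(bw.region_names, bw.significant))
        core_flags.append(all(flags[r] for r in CORE))
        dfn = generate_null_cohort(
            CohortParams(seed=SEED + 200 + rep, n_subjects=500)
        )
        pat_n, _ = derive_pattern(dfn)
        bw_n = bootstrap_pattern(dfn, pat_n, n_boot=1_000, seed=rep,
                                 keep_replicates=False)
        null_flags.append(float(bw_n.significant.mean()))
    report["core_regions_all_flagged_rate"] = float(np.mean(core_flags))
    report["null_significance_rate"] = float(np.mean(null_flags))
    print(f"strong-pattern cohorts: all five core regions flagged in "
          f"{report['core_regions_all_flagged_rate']:.0%} of 25 cohorts")
    print(f"null cohorts: per-region significance rate "
          f"{report['null_significance_rate']:.4f} (the sign-aligned "
          "percentile CI is conservative under the null)")

    estimates, covered = [], 0
    n_sim = 100
    for i in range(n_sim):
        d = generate_path_data(500, a1=0.5, b1=0.4, c_prime=0.2,
                               seed=SEED + 300 + i)
        res = fit_simple_mediation(
            d,
            MediationSpec(x="x", mediators=("m1",), y="y", covariates=(),
                          n_boot=1_000, seed=i),
        )
        ie = res.indirect["a1*b1"]
        estimates.append(ie.estimate)
        covered += ie.ci_low <= 0.20 <= ie.ci_high
    report["indirect_mean_estimate"] = float(np.mean(estimates))
    report["indirect_ci_coverage"] = covered / n_sim
    print(f"planted indirect 0.20 at n=500: mean estimate "
          f"{report['indirect_mean_estimate']:.3f}, 95% CI coverage "
          f"{report['indirect_ci_coverage']:.2f} over {n_sim} simulations")

    (OUT / "parameter_recovery.json").write_text(json.dumps(report, indent=2))
    print(f"wrote {OUT/'parameter_recovery.json'}")


if __name__ == "__main__":
    main()
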