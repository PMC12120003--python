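"""Tests of the mediation models: OLS-oracle equality of every path, the
effect-decomposition identity, planted-effect recovery, scale invariance and
bootstrap behavior."""

import numpy as np
import pandas as pd
import pytest

from ssmpattern import (
    CohortParams,
    MediationSpec,
    fit_serial_mediation,
    fit_simple_mediation,
    generate_cohort,
    generate_path_data,
    preprocess_cognition,
)
from ssmpattern.mediation import COVARIATE_TIERS
from ssmpattern.pattern import derive_pattern, express_pattern


@pytest.fixture(scope="module")
def analysis_table():
    df = generate_cohort(CohortParams(seed=51))
    pat, _ = derive_pattern(df)
    data = preprocess_cognition(df)
    data["pattern_expression"] = express_pattern(pat, df)
    return data


def _ols_oracle(X, y):
    """Independent normal-equations solve with intercept."""
    D = np.column_stack([np.ones(len(y)), X])
    return np.linalg.solve(D.T @ D, D.T @ y)[1:]


# --- preprocessing ---------------------------------------------------------


def test_log_transforms(analysis_table):
    row = analysis_table.dropna(subset=["tmt_a_sec"]).iloc[0]
    assert row["log_tmt_a"] == pytest.approx(np.log(row["tmt_a_sec"]), abs=1e-12)
    df = analysis_table.copy()
    df.loc[df.index[0], "tmt_a_sec"] = 30.0
    assert preprocess_cognition(df)["log_tmt_a"].iloc[0] == pytest.approx(
        3.4012, abs=1e-4
    )


def test_tmt_b_residualization_against_two_pass_oracle(analysis_table):
    a = analysis_table["tmt_a_sec"].to_numpy()
    b = analysis_table["tmt_b_sec"].to_numpy()
    ok = ~np.isnan(a) & ~np.isnan(b)
    slope = _ols_oracle(a[ok][:, None], b[ok])[0]
    intercept = b[ok].mean() - slope * a[ok].mean()
    resid = b[ok] - intercept - slope * a[ok]
    resid = (resid - resid.mean()) / resid.std(ddof=1)
    got = analysis_table["tmt_b_resid"].to_numpy()[ok]
    assert np.abs(got - resid).max() < 1e-10
    # rows with a missing input have a missing residual
    assert np.isnan(analysis_table["tmt_b_resid"].to_numpy()[~ok]).all()


def test_proportional_tmt_b_residual_is_zero():
    df = generate_cohort(CohortParams(seed=52, missing_tmt_b=0, missing_gpt=0))
    df["tmt_b_sec"] = 2.5 * df["tmt_a_sec"]
    out = preprocess_cognition(df)
    assert np.nanmax(np.abs(out["tmt_b_resid"])) < 1e-6


def test_nonpositive_timed_score_rejected():
    df = generate_cohort(CohortParams(seed=53))
    df.loc[df.index[0], "gpt_sec"] = -1.0
    with pytest.raises(ValueError, match="gpt_sec"):
        preprocess_cognition(df)


# --- path estimation -------------------------------------------------------


def test_simple_paths_match_normal_equations_oracle(analysis_table):
    covs = COVARIATE_TIERS["base"]
    spec = MediationSpec(
        x="age",
        mediators=("pattern_expression",),
        y="log_tmt_a",
        covariates=covs,
        n_boot=200,
        seed=1,
    )
    res = fit_simple_mediation(analysis_table, spec)
    cols = ["age", "pattern_expression", "log_tmt_a", *covs]
    raw = analysis_table[cols].dropna().to_numpy()
    z = raw.copy()
    for j in range(raw.shape[1]):
        col = raw[:, j]
        binary = np.isin(np.unique(col), (0.0, 1.0)).all()
        if not binary or j < 3:
            z[:, j] = (col - col.mean()) / col.std(ddof=1)
    x, m, y = z[:, 0], z[:, 1], z[:, 2]
    C = z[:, 3:]
    assert res.paths["a1"].estimate == pytest.approx(
        _ols_oracle(np.column_stack([x, C]), m)[0], abs=1e-10
    )
    coef = _ols_oracle(np.column_stack([x, m, C]), y)
    assert res.paths["c_prime"].estimate == pytest.approx(coef[0], abs=1e-10)
    assert res.paths["b1"].estimate == pytest.approx(coef[1], abs=1e-10)
    assert res.paths["c_total"].estimate == pytest.approx(
        _ols_oracle(np.column_stack([x, C]), y)[0], abs=1e-10
    )
    assert res.n_used == len(raw)


def test_effect_decomposition_identity(analysis_table):
    for mediators, y, fit in (
        (("pattern_expression",), "log_tmt_a", fit_simple_mediation),
        (("pattern_expression", "log_tmt_a"), "srt_cltr", fit_serial_mediation),
    ):
        res = fit(
            analysis_table,
            MediationSpec(
                x="age", mediators=mediators, y=y, n_boot=200, seed=2
            ),
        )
        assert abs(
            res.paths["c_total"].estimate
            - res.paths["c_prime"].estimate
            - res.total_indirect
        ) < 1e-8


def test_scale_invariance(analysis_table):
    spec = MediationSpec(
        x="age",
        mediators=("pattern_expression", "log_tmt_a"),
        y="srt_cltr",
        n_boot=150,
        seed=3,
    )
    res = fit_serial_mediation(analysis_table, spec)
    scaled = analysis_table.copy()
    scaled["age"] = scaled["age"] * 12.0  # months
    scaled["srt_cltr"] = scaled["srt_cltr"] * 0.01
    scaled["tiv"] = scaled["tiv"] / 1000.0
    res_s = fit_serial_mediation(scaled, spec)
    for name in res.paths:
        assert res_s.paths[name].estimate == pytest.approx(
            res.paths[name].estimate, abs=1e-10
        )
    for name in res.indirect:
        assert res_s.indirect[name].estimate == pytest.approx(
            res.indirect[name].estimate, abs=1e-10
        )


def test_simple_indirect_recovery_large_n():
    d = generate_path_data(5_000, a1=0.5, b1=0.4, c_prime=0.2, seed=61)
    res = fit_simple_mediation(
        d,
        MediationSpec(
            x="x", mediators=("m1",), y="y", covariates=(), n_boot=1_000, seed=4
        ),
    )
    ie = res.indirect["a1*b1"]
    assert ie.estimate == pytest.approx(0.20, abs=0.03)
    assert ie.significant


def test_serial_indirect_recovery_large_n():
    d = generate_path_data(
        5_000, a1=0.5, b1=0.0, c_prime=0.0, d21=0.3, b2=-0.4, seed=62
    )
    res = fit_serial_mediation(
        d,
        MediationSpec(
            x="x", mediators=("m1", "m2"), y="y", covariates=(), n_boot=1_000, seed=5
        ),
    )
    ie = res.indirect["a1*d21*b2"]
    assert ie.estimate == pytest.approx(-0.06, abs=0.02)
    assert ie.significant


def test_null_indirect_ci_contains_zero_mostly():
    """With the x->m1 path absent the indirect-effect CI should contain 0 at
    close to the nominal rate (the percentile bootstrap is known to be
    slightly anticonservative under a single-path null)."""
    hits = 0
    n_sim = 120
    for i in range(n_sim):
        d = generate_path_data(400, a1=0.0, b1=0.4, c_prime=0.2, seed=7_000 + i)
        res = fit_simple_mediation(
            d,
            MediationSpec(
                x="x", mediators=("m1",), y="y", covariates=(), n_boot=500, seed=i
            ),
        )
        ie = res.indirect["a1*b1"]
        hits += ie.ci_low <= 0.0 <= ie.ci_high
    assert hits / n_sim >= 0.85


def test_bootstrap_determinism(analysis_table):
    spec = MediationSpec(
        x="age", mediators=("pattern_expression",), y="log_gpt", n_boot=300, seed=9
    )
    a = fit_simple_mediation(analysis_table, spec)
    b = fit_simple_mediation(analysis_table, spec)
    for name in a.indirect:
        assert a.indirect[name].ci_low == b.indirect[name].ci_low
        assert a.indirect[name].boot_se == b.indirect[name].boot_se


def test_listwise_deletion(analysis_table):
    res = fit_simple_mediation(
        analysis_table,
        MediationSpec(
            x="age", mediators=("pattern_expression",), y="log_gpt", n_boot=200,
            seed=10,
        ),
    )
    assert res.n_used == 177  # one planted missing GPT value


def test_identical_mediators_raise_collinearity_error(analysis_table):
    data = analysis_table.copy()
    data["speed_copy"] = data["log_tmt_a"]
    with pytest.raises(ValueError, match="collinear"):
        fit_serial_mediation(
            data,
            MediationSpec(
                x="age",
                mediators=("log_tmt_a", "speed_copy"),
                y="srt_cltr",
                n_boot=200,
                seed=11,
            ),
        )


@pytest.mark.parametrize(
    "kwargs",
    [
        {"mediators": ()},
        {"mediators": ("m1", "m2", "m3")},
        {"mediators": ("m1",), "y": "m1"},
        {"mediators": ("m1",), "ci_level": 1.5},
    ],
)
def test_spec_validation(kwargs):
    base = dict(x="x", mediators=("m1",), y="y", covariates=())
    base.update(kwargs)
    with pytest.raises(ValueError):
        MediationSpec(**base)
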