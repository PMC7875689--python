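"""TSLS estimation, compliance weights, and the weighted-average identity."""
import numpy as np
import pytest
from statsmodels.sandbox.regression.gmm import IV2SLS

from surveyiv.late import (tsls_arrays, estimate_tsls, estimate_compliance_weights,
                           compliance_weights_from_counts, verify_weighted_identity)
from surveyiv import reference as ref
from surveyiv.scm import scenario_presets
from conftest import make_table


def closed_form_iv(y, d, z, W=None):
    """Independent oracle: just-identified IV by direct moment algebra."""
    n = len(y)
    ones = np.ones((n, 1))
    W = np.empty((n, 0)) if W is None else W
    Zm = np.hstack([ones, z[:, None], W])
    Xm = np.hstack([ones, d[:, None], W])
    return np.linalg.solve(Zm.T @ Xm, Zm.T @ y)[1]


def test_no_covariate_tsls_equals_wald_ratio(rng):
    z = rng.integers(0, 2, 500).astype(float)
    d = np.clip(z * 2 + rng.integers(0, 3, 500), 0, 4).astype(float)
    y = 1 + np.clip(d + rng.integers(0, 2, 500), 0, 4)
    res = tsls_arrays(y, d, z)
    wald = (y[z == 1].mean() - y[z == 0].mean()) / (d[z == 1].mean() - d[z == 0].mean())
    assert res.estimate == pytest.approx(wald, abs=1e-10)


def test_eight_row_hand_fixture_gives_unit_effect():
    rows = [(1, 2, 5), (1, 2, 4), (1, 1, 4), (1, 0, 3),
            (0, 1, 4), (0, 0, 3), (0, 0, 3), (0, 0, 2)]
    z, d, y = (np.array(c, float) for c in zip(*rows))
    # Wald by hand: ((16/4)-(12/4)) / ((5/4)-(1/4)) = 1.0
    assert tsls_arrays(y, d, z).estimate == pytest.approx(1.0, abs=1e-12)


def test_tsls_matches_moment_oracle_on_random_datasets(rng):
    for _ in range(50):
        n = int(rng.integers(30, 80))
        z = rng.integers(0, 2, n).astype(float)
        if z.std() == 0:
            z[0] = 1 - z[0]
        d = np.clip(z + rng.integers(0, 3, n), 0, 4).astype(float)
        if np.ptp(d) == 0:
            d[0] += 1
        y = d * 0.5 + rng.normal(size=n)
        assert tsls_arrays(y, d, z).estimate == pytest.approx(
            closed_form_iv(y, d, z), abs=1e-10)


def test_tsls_matches_statsmodels_iv2sls_with_covariates(rng):
    n = 400
    z = rng.integers(0, 2, n).astype(float)
    w = rng.integers(0, 3, n)
    W = np.column_stack([(w == 1).astype(float), (w == 2).astype(float)])
    d = np.clip(z * 2 + w + rng.integers(0, 2, n) - 1, 0, 4).astype(float)
    y = 0.4 * d + 0.3 * w + rng.normal(size=n)
    res = tsls_arrays(y, d, z, W)
    ones = np.ones((n, 1))
    exog = np.hstack([ones, d[:, None], W])
    instr = np.hstack([ones, z[:, None], W])
    ref_fit = IV2SLS(y, exog, instr).fit()
    assert res.estimate == pytest.approx(ref_fit.params[1], abs=1e-8)


def test_covariate_level_relabeling_leaves_estimate_unchanged(forward_table):
    table, _ = forward_table
    res = estimate_tsls(table, "confidence", covariates="all")
    relabeled = table.copy()
    # reverse the income coding (permutes the one-hot columns)
    inc = relabeled.df["income"]
    relabeled.df["income"] = 3 - inc
    res2 = estimate_tsls(relabeled, "confidence", covariates="all")
    assert res2.estimate == pytest.approx(res.estimate, abs=1e-10)


def test_irrelevant_instrument_is_error(rng):
    n = 200
    z = rng.integers(0, 2, n).astype(float)
    d = rng.integers(0, 5, n).astype(float)  # unrelated to z
    d = d - d.mean() + 2  # keep variation
    # force exactly zero first-stage: make d identical across arms
    d = np.tile(d[:100], 2)
    z = np.repeat([0.0, 1.0], 100)
    y = rng.normal(size=n)
    with pytest.raises(ValueError, match="instrument"):
        tsls_arrays(y, d, z)


def test_binary_treatment_gives_single_unit_weight():
    t = make_table({"encouraged": [1, 1, 1, 0, 0, 0],
                    "portal_use": [1, 1, 0, 0, 0, 0],
                    "confidence": [4, 5, 3, 3, 2, 3]})
    w = estimate_compliance_weights(t)
    assert w.raw_diffs[0] == pytest.approx(2 / 3)
    assert w.omega[0] == pytest.approx(1.0)
    assert np.all(w.omega[1:] == 0)


def test_published_usage_counts_reproduce_weights():
    w = compliance_weights_from_counts(ref.ENCOURAGEMENT_BY_USAGE["encouraged"],
                                       ref.ENCOURAGEMENT_BY_USAGE["not encouraged"])
    # hand oracle: survivor-function differences from the printed counts
    c1 = np.array([549, 383, 267, 176], float)
    c0 = np.array([1646, 113, 46, 18], float)
    expect_raw = np.array([c1[j:].sum() / c1.sum() - c0[j:].sum() / c0.sum()
                           for j in (1, 2, 3)])
    assert np.allclose(w.raw_diffs, expect_raw, atol=1e-12)
    assert np.round(w.raw_diffs, 4).tolist() == [0.5036, 0.2871, 0.1181]
    assert np.round(w.omega, 3).tolist() == [0.554, 0.316, 0.130]
    assert w.omega.sum() == pytest.approx(1.0, abs=1e-12)


def test_perfect_compliance_weights():
    z = [0, 0, 0, 1, 1, 1]
    t = make_table({"encouraged": z, "portal_use": [2 * v for v in z],
                    "confidence": [3, 3, 3, 4, 4, 4]})
    w = estimate_compliance_weights(t)
    assert w.omega[:2].tolist() == [0.5, 0.5]


def test_no_net_compliance_is_error():
    t = make_table({"encouraged": [1, 1, 0, 0], "portal_use": [0, 0, 2, 2],
                    "confidence": [3, 3, 3, 3]})
    with pytest.raises(ValueError, match="no net compliance"):
        estimate_compliance_weights(t)


def test_weighted_identity_constant_effect():
    cfg = scenario_presets()["forward_weak"].with_updates(missing_rates={})
    rep = verify_weighted_identity(cfg, n=3200, reps=120, seed=4)
    assert rep.weighted_truth == pytest.approx(0.14, abs=0.01)
    assert abs(rep.difference) <= 3 * rep.tsls_mc_se


def test_weighted_identity_null_effect():
    cfg = scenario_presets()["forward_null"].with_updates(missing_rates={})
    rep = verify_weighted_identity(cfg, n=3200, reps=80, seed=4)
    assert rep.weighted_truth == pytest.approx(0.0, abs=1e-12)
    assert abs(rep.tsls_mean) <= 3 * rep.tsls_mc_se


def test_ci_bounds_bracket_estimate(forward_table):
    table, _ = forward_table
    res = estimate_tsls(table, "confidence")
    assert res.ci_low <= res.estimate <= res.ci_high
    assert res.ci_high - res.estimate == pytest.approx(1.96 * res.std_error, rel=1e-3)


def test_homoskedastic_se_option(forward_table):
    table, _ = forward_table
    robust = estimate_tsls(table, "confidence", se_method="robust")
    homo = estimate_tsls(table, "confidence", se_method="homoskedastic")
    assert robust.estimate == pytest.approx(homo.estimate, abs=1e-12)
    assert robust.std_error != homo.std_error
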