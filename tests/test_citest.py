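"""Conditional-independence tests: oracles, determinism, calibration, power."""
from itertools import combinations

import numpy as np
import pytest

from surveyiv.citest import CITestSpec, run_test_pair
from surveyiv.citest import test_ci_ordinal_lrt as ci_lrt
from surveyiv.citest import test_ci_permutation as ci_perm
from surveyiv.ordinal import fit_proportional_odds
from surveyiv.scm import scenario_presets, generate
from conftest import make_table


def _spec(conditioning, method="ordinal-lrt", **kw):
    return CITestSpec(instrument="encouraged", target="confidence",
                      conditioning=conditioning, method=method, **kw)


def test_constant_instrument_gives_p_one():
    t = make_table({"encouraged": [1] * 12, "portal_use": [0, 1] * 6,
                    "confidence": [1, 2, 3, 4, 5, 3] * 2})
    res = ci_lrt(t, _spec(("portal_use",)))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_lrt_detects_strong_marginal_dependence():
    rng = np.random.default_rng(0)
    z = rng.integers(0, 2, 600)
    y = 1 + np.clip(z * 2 + rng.integers(0, 3, 600), 0, 4)
    t = make_table({"encouraged": z.tolist(), "portal_use": [0] * 600,
                    "confidence": y.tolist()})
    res = ci_lrt(t, _spec(()))
    assert res.p_value < 1e-6


def test_permutation_matches_exhaustive_enumeration_on_12_row_fixture():
    """Exact within-stratum enumeration oracle on 2 strata of 6 rows."""
    z = [1, 1, 0, 0, 0, 0, 1, 1, 1, 0, 0, 0]
    g = [0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
    y = [5, 4, 3, 2, 3, 1, 4, 5, 4, 2, 3, 2]
    t = make_table({"encouraged": z, "portal_use": [0] * 12, "confidence": y,
                    "stratum": g}, confounders=[("stratum", 2)])
    spec = _spec(("stratum",), method="permutation", n_permutations=4000, seed=1)

    # oracle: enumerate all within-stratum assignments of the 1s
    z_arr, g_arr, y_arr = np.array(z, float), np.array(g), np.array(y)
    X0 = (g_arr == 1).astype(float)[:, None]
    yc = y_arr.astype(int) - 1
    from surveyiv.ordinal import compress_codes
    yc = compress_codes(yc)
    ll0 = fit_proportional_odds(yc, X0).loglik

    def stat(zv):
        return max(0.0, 2 * (fit_proportional_odds(
            yc, np.column_stack([X0, zv])).loglik - ll0))

    obs = stat(z_arr)
    idx0, idx1 = np.flatnonzero(g_arr == 0), np.flatnonzero(g_arr == 1)
    k0, k1 = int(z_arr[idx0].sum()), int(z_arr[idx1].sum())
    stats_all = []
    for c0 in combinations(range(len(idx0)), k0):
        for c1 in combinations(range(len(idx1)), k1):
            zv = np.zeros(12)
            zv[idx0[list(c0)]] = 1
            zv[idx1[list(c1)]] = 1
            stats_all.append(stat(zv))
    stats_all = np.array(stats_all)
    exact_p = (stats_all >= obs - 1e-12).mean()

    res = ci_perm(t, spec)
    assert res.statistic == pytest.approx(obs, abs=1e-8)
    # Monte-Carlo permutation p converges to the exhaustive enumeration value
    assert res.p_value == pytest.approx(exact_p, abs=0.03)


def test_permutation_empty_conditioning_is_unconditional():
    rng = np.random.default_rng(3)
    z = rng.integers(0, 2, 60)
    y = 1 + rng.integers(0, 5, 60)
    t = make_table({"encouraged": z.tolist(), "portal_use": [0] * 60,
                    "confidence": y.tolist()})
    res = ci_perm(t, _spec((), method="permutation",
                                       n_permutations=300, seed=5))
    assert 0.0 < res.p_value <= 1.0


def test_permutation_deterministic_given_seed():
    rng = np.random.default_rng(8)
    z = rng.integers(0, 2, 80)
    y = 1 + rng.integers(0, 5, 80)
    t = make_table({"encouraged": z.tolist(), "portal_use": [0] * 80,
                    "confidence": y.tolist()})
    spec = _spec((), method="permutation", n_permutations=200, seed=11)
    assert ci_perm(t, spec).p_value == ci_perm(t, spec).p_value


def test_pair_uses_identical_rows_and_nested_conditioning(forward_table):
    table, _ = forward_table
    res_a, res_b = run_test_pair(table, "confidence", seed=0)
    assert res_a.n_used == res_b.n_used
    assert set(res_b.spec.conditioning) | {table.treatment} == set(res_a.spec.conditioning)


def test_forward_scenario_test_b_rejects_more_than_a():
    """With Z -> D -> Y and no hidden confounding, B carries the signal."""
    cfg = scenario_presets()["forward_strong"].with_updates(missing_rates={}, n=2000)
    rng = np.random.default_rng(99)
    rej_a = rej_b = 0
    for _ in range(30):
        table, _ = generate(cfg, seed=int(rng.integers(2 ** 31 - 1)))
        res_a, res_b = run_test_pair(table, "confidence")
        rej_a += res_a.p_value < 0.05
        rej_b += res_b.p_value < 0.05
    assert rej_b >= rej_a + 15


def test_reverse_scenario_collider_power():
    """Y -> D makes conditioning on D open the collider: A rejects more."""
    cfg = scenario_presets()["reverse"].with_updates(missing_rates={}, n=3000)
    rng = np.random.default_rng(7)
    rej_a = rej_b = 0
    reps = 60
    for _ in range(reps):
        table, _ = generate(cfg, seed=int(rng.integers(2 ** 31 - 1)))
        res_a, res_b = run_test_pair(table, "confidence")
        rej_a += res_a.p_value < 0.05
        rej_b += res_b.p_value < 0.05
    assert rej_a / reps - rej_b / reps >= 0.2


def test_lrt_and_permutation_agree_on_decisions():
    """The two constructions reach the same reject/retain call on most draws."""
    rng = np.random.default_rng(13)
    agree = total = 0
    for preset in ("reverse", "forward_strong"):
        cfg = scenario_presets()[preset].with_updates(missing_rates={}, n=1200)
        for _ in range(5):
            seed = int(rng.integers(2 ** 31 - 1))
            table, _ = generate(cfg, seed=seed)
            lrt_a, lrt_b = run_test_pair(table, "confidence", method="ordinal-lrt")
            per_a, per_b = run_test_pair(table, "confidence", method="permutation",
                                         seed=seed, n_permutations=400)
            for l, p in ((lrt_a, per_a), (lrt_b, per_b)):
                agree += (l.p_value < 0.05) == (p.p_value < 0.05)
                total += 1
    assert agree / total >= 0.9


def test_monotone_power_in_effect_size():
    """Test B rejection rate is nondecreasing in the treatment effect."""
    rng = np.random.default_rng(21)
    base = scenario_presets()["forward_null"].with_updates(missing_rates={}, n=1500)
    rates = []
    reps = 25
    for tau in (0.0, 0.1, 0.2, 0.4):
        cfg = base.with_updates(tau=tau)
        rej = 0
        for _ in range(reps):
            table, _ = generate(cfg, seed=int(rng.integers(2 ** 31 - 1)))
            _, res_b = run_test_pair(table, "confidence")
            rej += res_b.p_value < 0.05
        rates.append(rej / reps)
    slack = 2 * np.sqrt(0.25 / reps)  # binomial MC noise allowance
    assert all(b >= a - slack for a, b in zip(rates, rates[1:]))
    assert rates[-1] > rates[0]
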