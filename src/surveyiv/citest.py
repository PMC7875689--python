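"""Paired conditional-independence tests for causal-direction discovery.

The direction of causality between an ordinal treatment D and an ordinal
outcome Y is probed with two tests of the binary instrument Z against Y:

* Test A: Z independent of Y given the observed confounders X *and* D.
  Rejection indicates a path from Y into D (conditioning on the collider D
  opens Z -> D <- Y when Y causes D).
* Test B: Z independent of Y given X alone. Rejection indicates the
  Z -> D -> Y chain is active, i.e. D causes Y.

Two constructions of the test are provided. The default is a 1-df
likelihood-ratio test nested in a proportional-odds model of Y on the
conditioning set (confounders one-hot, D as a linear 0-4 score); the
robustness alternative permutes Z within strata of the conditioning set and
compares the same statistic to its permutation distribution.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .data import SurveyTable
from . import ordinal

logger = logging.getLogger(__name__)

__all__ = ["CITestSpec", "CITestResult", "test_ci_ordinal_lrt",
           "test_ci_permutation", "run_test_pair"]


@dataclass(frozen=True)
class CITestSpec:
    """One conditional-independence test: Z _||_ target | conditioning."""

    instrument: str
    target: str
    conditioning: tuple
    method: str = "ordinal-lrt"
    alpha: float = 0.05
    n_permutations: int = 2000
    seed: int | None = None
    treatment_coding: str = "score"  # "score" (linear 0-4) or "dummies"

    def __post_init__(self):
        object.__setattr__(self, "conditioning", tuple(self.conditioning))
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.method not in ("ordinal-lrt", "permutation"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.treatment_coding not in ("score", "dummies"):
            raise ValueError("treatment_coding must be 'score' or 'dummies'")


@dataclass(frozen=True)
class CITestResult:
    p_value: float
    statistic: float
    df: int | None
    method: str
    n_used: int
    spec: CITestSpec
    fallback: bool = False

    @property
    def rejected(self) -> bool:
        return self.p_value < self.spec.alpha


def _conditioning_design(table: SurveyTable, rows: np.ndarray, spec: CITestSpec) -> np.ndarray:
    """Design matrix for the conditioning set on the selected rows.

    The treatment enters as a linear ordinal score under the default coding;
    every other conditioning variable is one-hot over observed levels with a
    first-level reference (the intercept lives in the ordinal thresholds).
    """
    cols = []
    for name in spec.conditioning:
        v = table.column(name)[rows]
        if name == table.treatment and spec.treatment_coding == "score":
            cols.append(v[:, np.newaxis])
            continue
        levels = np.unique(v)
        for lev in levels[1:]:
            cols.append((v == lev).astype(float)[:, np.newaxis])
    if not cols:
        return np.empty((int(rows.sum()), 0))
    return np.hstack(cols)


def _prepare(table: SurveyTable, spec: CITestSpec):
    needed = [spec.instrument, spec.target, *spec.conditioning]
    rows = table.complete_mask(needed)
    n_used = int(rows.sum())
    n_dropped = table.n - n_used
    if n_dropped:
        logger.info("CI test %s: excluded %d incomplete rows", spec.target, n_dropped)
    y = table.column(spec.target)[rows].astype(int)
    if np.unique(y).size < 2:
        raise ValueError("outcome collapses to a single observed level")
    z = table.column(spec.instrument)[rows]
    X0 = _conditioning_design(table, rows, spec)
    return y, z, X0, n_used


def test_ci_ordinal_lrt(table: SurveyTable, spec: CITestSpec) -> CITestResult:
    """Proportional-odds likelihood-ratio test of Z _||_ Y | conditioning."""
    y, z, X0, n_used = _prepare(table, spec)
    stat, p, fallback = ordinal.likelihood_ratio_test(y, X0, z)
    if fallback:
        logger.warning("LRT fit did not converge; reporting score test on the same nesting")
    return CITestResult(p, stat, 1, "ordinal-lrt", n_used, spec, fallback)


def _strata(z: np.ndarray, X0: np.ndarray, seed) -> np.ndarray:
    """Stratum labels for the permutation null.

    Exact joint-level strata when the conditioning set is coarse enough;
    otherwise deciles of an estimated propensity of Z given the conditioning
    design. All-singleton strata are an error (no permutation possible).
    """
    n = len(z)
    if X0.shape[1] == 0:
        return np.zeros(n, dtype=int)
    _, joint = np.unique(X0, axis=0, return_inverse=True)
    sizes = np.bincount(joint)
    if sizes.min() >= 2 and sizes.size <= max(2, n // 10):
        return joint
    lr = LogisticRegression(max_iter=1000, random_state=0)
    prop = lr.fit(X0, z).predict_proba(X0)[:, 1]
    # decile bins of the propensity; duplicate edges collapse sparse bins
    edges = np.unique(np.quantile(prop, np.linspace(0, 1, 11)))
    bins = np.clip(np.searchsorted(edges, prop, side="right") - 1, 0, len(edges) - 2)
    sizes = np.bincount(bins)
    if sizes.max() < 2:
        raise ValueError("all permutation strata are singletons; coarsen the conditioning set")
    return bins


def test_ci_permutation(table: SurveyTable, spec: CITestSpec) -> CITestResult:
    """Stratified-permutation version of the same test.

    The statistic is the LRT statistic; its null distribution is built by
    permuting Z within strata of the conditioning set, so the conditional law
    of the conditioning variables is held fixed. p = (1 + #{perm >= obs}) /
    (1 + B), add-one corrected.
    """
    y, z, X0, n_used = _prepare(table, spec)
    rng = np.random.default_rng(spec.seed)
    y = ordinal.compress_codes(y)
    if np.ptp(z) == 0:
        return CITestResult(1.0, 0.0, None, "permutation", n_used, spec)
    fit0 = ordinal.fit_proportional_odds(y, X0)
    warm = np.concatenate([fit0.raw_params, [0.0]])

    def stat_for(zperm: np.ndarray) -> float:
        fit1 = ordinal.fit_proportional_odds(y, np.column_stack([X0, zperm]), start=warm)
        return max(0.0, 2.0 * (fit1.loglik - fit0.loglik))

    obs = stat_for(z)
    strata = _strata(z, X0, spec.seed)
    groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    n_ge = 0
    zp = z.copy()
    for _ in range(spec.n_permutations):
        for idx in groups:
            zp[idx] = z[idx][rng.permutation(len(idx))]
        if stat_for(zp) >= obs - 1e-12:
            n_ge += 1
    p = (1.0 + n_ge) / (1.0 + spec.n_permutations)
    return CITestResult(p, obs, None, "permutation", n_used, spec)


_METHODS = {"ordinal-lrt": test_ci_ordinal_lrt, "permutation": test_ci_permutation}


def run_ci_test(table: SurveyTable, spec: CITestSpec) -> CITestResult:
    return _METHODS[spec.method](table, spec)


def run_test_pair(table: SurveyTable, outcome: str, alpha: float = 0.05,
                  method: str = "ordinal-lrt", seed: int | None = None,
                  n_permutations: int = 2000, treatment_coding: str = "score"):
    """Run Test A (condition on X and D) and Test B (condition on X).

    Both tests run on the identical row set — rows complete in Z, D, Y and
    every confounder — so their p-values are comparable.

    Returns ``(result_A, result_B)``.
    """
    if outcome not in table.outcomes:
        raise ValueError(f"{outcome!r} is not a declared outcome")
    z, d, X = table.instrument, table.treatment, table.confounders
    rows = table.complete_mask([z, d, outcome, *X])
    sub = SurveyTable(table.df.loc[rows].reset_index(drop=True), table.schema)
    common = dict(instrument=z, target=outcome, alpha=alpha, method=method,
                  seed=seed, n_permutations=n_permutations,
                  treatment_coding=treatment_coding)
    spec_a = CITestSpec(conditioning=tuple(X) + (d,), **common)
    spec_b = CITestSpec(conditioning=tuple(X), **common)
    return run_ci_test(sub, spec_a), run_ci_test(sub, spec_b)
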