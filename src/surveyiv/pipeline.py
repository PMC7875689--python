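"""End-to-end analysis pipeline and Monte-Carlo experiment harness.

``run_pipeline`` chains the full survey analysis: read -> missing policy ->
chained-equation imputation -> descriptive tables -> conditional-independence
test pair -> direction verdict -> TSLS (gated on the verdict by default).
``run_calibration_experiment`` repeats generation + testing + estimation over
many seeded replicates to measure type-I error, power, verdict recovery, and
confidence-interval coverage for a named scenario preset.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict

import numpy as np

from .data import (SurveyTable, read_survey_csv, apply_missing_policy, crosstab)
from .descriptives import chi_square_independence, conditional_percentages, format_p
from .impute import ImputationConfig, impute_confounders
from .citest import run_test_pair
from .direction import decide_direction, VERDICTS
from .late import estimate_tsls, estimate_compliance_weights
from .scm import scenario_presets, generate

__all__ = ["run_pipeline", "run_calibration_experiment", "render_table1",
           "ExperimentReport"]


def _round(x, k=10):
    return float(np.round(float(x), k))


@dataclass(frozen=True)
class ExperimentReport:
    """Aggregated Monte-Carlo rates for one scenario preset."""

    scenario: str
    reps: int
    n: int
    method: str
    alpha: float
    reject_rate_A: float
    reject_rate_B: float
    mc_se_A: float
    mc_se_B: float
    verdict_frequencies: dict
    late_mean: float
    late_sd: float
    ci_coverage: float | None
    target_effect: float | None
    seed: int
    runtime_s: float

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(source, schema=None, outcomes=None, alpha: float = 0.05,
                 method: str = "ordinal-lrt", seed: int | None = None,
                 covariates="all", force_late: bool = False,
                 imputation: ImputationConfig | None = None,
                 n_permutations: int = 2000) -> dict:
    """Execute the full causal analysis and return a JSON-serializable report.

    ``source`` is a CSV path (``schema`` then required) or a ``SurveyTable``.
    Every row-count change is recorded in the report's audit trail. The TSLS
    estimate is reported only for outcomes whose verdict is
    ``treatment_causes_outcome`` unless ``force_late`` is set.
    """
    if isinstance(source, SurveyTable):
        table = source
    else:
        if schema is None:
            raise ValueError("reading from CSV requires a schema")
        table = read_survey_csv(source, schema)
    outcomes = list(outcomes or table.outcomes)
    imputation = imputation or ImputationConfig(seed=seed)

    report = {
        "config": {
            "alpha": alpha, "method": method, "seed": seed,
            "covariates": covariates if isinstance(covariates, str) else list(covariates),
            "force_late": force_late, "outcomes": outcomes,
            "imputation": {"n_sweeps": imputation.n_sweeps,
                           "n_datasets": imputation.n_datasets,
                           "seed": imputation.seed},
        },
        "audit": {"rows_in": table.n,
                  "validation_warnings": dict(table.validation_warnings)},
        "outcomes": {},
    }

    imputed = impute_confounders(table, imputation)
    report["audit"]["confounder_cells_imputed"] = int(
        sum(table.df[c].isna().sum() for c in table.confounders))

    for outcome in outcomes:
        filtered, policy_counts = apply_missing_policy(imputed, outcome)
        entry = {"missing_policy": policy_counts, "rows_analysis": filtered.n}

        ct = crosstab(filtered, filtered.instrument, outcome).drop_empty_margins()
        chi = chi_square_independence(ct)
        entry["encouragement_table"] = {
            "counts": ct.counts.tolist(),
            "row_labels": list(ct.row_labels),
            "col_labels": list(ct.col_labels),
            "column_pct_by_row": np.round(conditional_percentages(ct, "rows"), 4).tolist(),
            "chi2": _round(chi.statistic), "df": chi.df,
            "p": _round(chi.p_value), "p_formatted": format_p(chi.p_value),
        }

        res_a, res_b = run_test_pair(filtered, outcome, alpha=alpha, method=method,
                                     seed=seed, n_permutations=n_permutations)
        verdict = decide_direction(res_a.p_value, res_b.p_value, alpha, outcome)
        entry["ci_tests"] = {
            "test_A": {"p": _round(res_a.p_value), "statistic": _round(res_a.statistic),
                       "n_used": res_a.n_used, "conditioning": list(res_a.spec.conditioning)},
            "test_B": {"p": _round(res_b.p_value), "statistic": _round(res_b.statistic),
                       "n_used": res_b.n_used, "conditioning": list(res_b.spec.conditioning)},
        }
        entry["verdict"] = verdict.to_dict()

        weights = estimate_compliance_weights(filtered)
        entry["compliance_weights"] = {
            "omega": np.round(weights.omega, 6).tolist(),
            "raw_diffs": np.round(weights.raw_diffs, 6).tolist(),
            "steps": list(weights.steps),
        }

        if force_late or verdict.verdict == "treatment_causes_outcome":
            late = estimate_tsls(filtered, outcome, covariates=covariates)
            entry["late"] = {
                "estimate": _round(late.estimate), "std_error": _round(late.std_error),
                "ci_low": _round(late.ci_low), "ci_high": _round(late.ci_high),
                "p_value": _round(late.p_value),
                "first_stage_coef": _round(late.first_stage_coef),
                "first_stage_F": _round(late.first_stage_F),
                "n_used": late.n_used, "se_method": late.se_method,
            }
        else:
            entry["late"] = None

        report["outcomes"][outcome] = entry
    return report


def pipeline_report_json(report: dict) -> str:
    """Canonical (byte-stable) JSON rendering of a pipeline report."""
    return json.dumps(report, sort_keys=True, indent=2)


def run_calibration_experiment(preset: str, reps: int, seed: int,
                               n: int | None = None, alpha: float = 0.05,
                               method: str = "ordinal-lrt",
                               complete_data: bool = True) -> ExperimentReport:
    """Monte-Carlo rates for a scenario preset over ``reps`` replicates.

    Each replicate generates a fresh survey, runs the Test A / Test B pair on
    the outcome, forms the verdict, and estimates TSLS with all covariates.
    ``complete_data`` (default) zeroes the missingness rates so the measured
    rates isolate the behavior of the tests and estimator. Coverage is
    reported against the preset's constant effect when it has one.
    """
    presets = scenario_presets()
    if preset not in presets:
        raise KeyError(f"unknown preset {preset!r}; have {sorted(presets)}")
    cfg = presets[preset]
    if n is not None:
        cfg = cfg.with_updates(n=n)
    if complete_data:
        cfg = cfg.with_updates(missing_rates={})
    taus = cfg.per_step_effects()
    target = taus[0] if (len(set(taus)) == 1 and cfg.delta_YD == 0) else None

    t0 = time.time()
    rng = np.random.default_rng(seed)
    rej_a = rej_b = 0
    verdict_counts = dict.fromkeys(VERDICTS, 0)
    estimates, covered = [], []
    for _ in range(reps):
        rep_seed = int(rng.integers(2 ** 31 - 1))
        table, _ = generate(cfg, seed=rep_seed)
        res_a, res_b = run_test_pair(table, table.outcomes[0], alpha=alpha,
                                     method=method, seed=rep_seed,
                                     n_permutations=500)
        verdict = decide_direction(res_a.p_value, res_b.p_value, alpha)
        verdict_counts[verdict.verdict] += 1
        rej_a += res_a.p_value < alpha
        rej_b += res_b.p_value < alpha
        late = estimate_tsls(table, table.outcomes[0], covariates="all")
        estimates.append(late.estimate)
        if target is not None:
            covered.append(late.ci_low <= target <= late.ci_high)
    runtime = time.time() - t0

    estimates = np.asarray(estimates)
    rate_a, rate_b = rej_a / reps, rej_b / reps

    def mc_se(p):
        return float(np.sqrt(p * (1 - p) / reps))

    return ExperimentReport(
        scenario=preset, reps=reps, n=cfg.n, method=method, alpha=alpha,
        reject_rate_A=rate_a, reject_rate_B=rate_b,
        mc_se_A=mc_se(rate_a), mc_se_B=mc_se(rate_b),
        verdict_frequencies={k: v / reps for k, v in verdict_counts.items()},
        late_mean=float(estimates.mean()), late_sd=float(estimates.std(ddof=1)),
        ci_coverage=(float(np.mean(covered)) if covered else None),
        target_effect=target, seed=seed, runtime_s=runtime,
    )


def render_table1(table: SurveyTable, outcomes=None) -> str:
    """Text rendering of the encouragement-by-outcome descriptive table.

    Per outcome: counts with column percentages by encouragement arm and the
    Pearson chi-square p-value in journal format.
    """
    outcomes = list(outcomes or table.outcomes)
    lines = ["Outcome distributions by encouragement arm",
             "=" * 60]
    z = table.instrument
    for outcome in outcomes:
        ct = crosstab(table, z, outcome).drop_empty_margins()
        chi = chi_square_independence(ct)
        pct = conditional_percentages(ct, axis="rows")
        lines.append(f"\n{outcome}  (n={ct.total}, P value {format_p(chi.p_value)})")
        header = "  level".ljust(28) + "".join(str(r).rjust(22) for r in ct.row_labels)
        lines.append(header)
        for j, lab in enumerate(ct.col_labels):
            row = f"  {lab}".ljust(28)
            for i in range(ct.counts.shape[0]):
                row += f"{ct.counts[i, j]} ({pct[i, j]:.1f})".rjust(22)
            lines.append(row)
    return "\n".join(lines)
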