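"""Chained-equation imputation of missing categorical confounders.

Each sweep visits the incomplete confounders in ascending order of
missingness and refits a multinomial logistic model of that confounder on
the instrument and the other confounders (one-hot encoded), using the rows
where the target was originally observed. Missing cells are then redrawn
from the fitted conditional distribution — stochastic draws, not modal
classes, per standard chained-equations methodology. Observed cells are
never altered, and runs are reproducible given the seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .data import SurveyTable

logger = logging.getLogger(__name__)

__all__ = ["ImputationConfig", "impute_confounders"]


@dataclass(frozen=True)
class ImputationConfig:
    """Settings for the chained-equation imputer.

    ``predictor_roles`` lists the variable roles used as predictors; the
    default (instrument + confounders) deliberately excludes the treatment
    and the outcomes so imputation cannot leak the quantities under test.
    """

    n_sweeps: int = 10
    n_datasets: int = 1
    seed: int | None = None
    predictor_roles: tuple = ("instrument", "confounder")

    def __post_init__(self):
        if self.n_sweeps < 1 or self.n_datasets < 1:
            raise ValueError("n_sweeps and n_datasets must be >= 1")


def _onehot(df: pd.DataFrame, cols) -> np.ndarray:
    blocks = []
    for c in cols:
        v = df[c].to_numpy(dtype=float)
        for lev in np.unique(v)[1:]:
            blocks.append((v == lev).astype(float))
    if not blocks:
        return np.zeros((len(df), 1))
    return np.column_stack(blocks)


def _impute_once(table: SurveyTable, config: ImputationConfig,
                 rng: np.random.Generator) -> SurveyTable:
    df = table.df.copy()
    predictors = [s.name for s in table.schema if s.role in config.predictor_roles]
    targets = [c for c in table.confounders if df[c].isna().any()]
    if not targets:
        return table.copy()

    obs_mask = {c: df[c].notna().to_numpy() for c in targets}
    single_level = {}
    for c in targets:
        if not obs_mask[c].any():
            raise ValueError(f"confounder {c!r} is entirely missing; no model can be fit")
        observed_levels = df.loc[obs_mask[c], c].unique()
        if len(observed_levels) == 1:
            logger.warning("%s: single observed level; filling deterministically", c)
            single_level[c] = int(observed_levels[0])

    # initial fill: draw from each variable's observed marginal
    work = df.astype("Float64").astype(float)
    for c in targets:
        obs = work[c][obs_mask[c]].to_numpy()
        miss = ~obs_mask[c]
        work.loc[miss, c] = rng.choice(obs, size=int(miss.sum()))
    other_missing = [c for c in predictors if c not in targets and df[c].isna().any()]
    for c in other_missing:  # non-confounder predictors with holes: marginal fill
        obs = work[c][df[c].notna()].to_numpy()
        miss = df[c].isna()
        work.loc[miss, c] = rng.choice(obs, size=int(miss.sum()))

    order = sorted(targets, key=lambda c: (~obs_mask[c]).mean())
    for _ in range(config.n_sweeps):
        for c in order:
            miss = ~obs_mask[c]
            if c in single_level:
                work.loc[miss, c] = single_level[c]
                continue
            others = [p for p in predictors if p != c]
            X = _onehot(work, others)
            y_obs = work[c][obs_mask[c]].to_numpy().astype(int)
            model = LogisticRegression(max_iter=500, random_state=0)
            model.fit(X[obs_mask[c]], y_obs)
            probs = model.predict_proba(X[miss])
            draws = np.array([
                rng.choice(model.classes_, p=p / p.sum()) for p in probs
            ])
            work.loc[miss, c] = draws

    out = df.copy()
    for c in targets:
        filled = work[c].round().astype("Int64")
        out[c] = df[c].where(obs_mask[c], filled)
    return SurveyTable(out, table.schema, dict(table.validation_warnings))


def impute_confounders(table: SurveyTable, config: ImputationConfig | None = None):
    """Complete every missing confounder cell by chained equations.

    Returns a single completed ``SurveyTable`` when ``config.n_datasets`` is 1
    (the pipeline default) or a list of independently completed tables
    otherwise. Observed cells are preserved exactly; identical seeds give
    identical completions.
    """
    config = config or ImputationConfig()
    rng = np.random.default_rng(config.seed)
    completed = [_impute_once(table, config, rng) for _ in range(config.n_datasets)]
    return completed[0] if config.n_datasets == 1 else completed
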