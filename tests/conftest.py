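import numpy as np
import pandas as pd
import pytest

from surveyiv.data import (SurveyTable, VariableSpec, instrument_spec,
                           treatment_spec, outcome_spec)


def make_schema(confounders=()):
    """Minimal schema: Z, D, one Likert outcome, plus named multi-level confounders."""
    confs = tuple(
        VariableSpec(name, "confounder", tuple(range(k)))
        for name, k in confounders
    )
    return (instrument_spec(), treatment_spec(), outcome_spec("confidence")) + confs


def make_table(columns: dict, confounders=()) -> SurveyTable:
    """Build a SurveyTable from plain column lists (None = missing)."""
    df = pd.DataFrame({k: pd.array(v, dtype="Int64") for k, v in columns.items()})
    return SurveyTable(df, make_schema(confounders))


@pytest.fixture(scope="session")
def forward_table():
    """One seeded forward-causal draw (tau=0.3, complete data, n=3000)."""
    from surveyiv.scm import scenario_presets, generate
    cfg = scenario_presets()["forward_strong"].with_updates(n=3000, missing_rates={})
    table, truth = generate(cfg, seed=1234)
    return table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
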