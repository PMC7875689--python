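"""Survey data model, CSV I/O, recoding, and the missing-data policy.

The analysis table is respondent-level with four variable roles: a binary
instrument Z (provider encouragement, 0/1), an ordinal treatment D (portal
accesses in the last 12 months, coded 0-4 for the answer bands
0 / 1-2 / 3-5 / 6-9 / 10+), one or more 5-point Likert outcomes Y
(1 = "Not confident at all" ... 5 = "Completely confident"), and categorical
confounders X. Missing cells are pandas NA; validation flags out-of-range
codes as missing rather than failing.

Missing-data policy (applied before any test or estimate): respondents
missing the analysed outcome are discarded; a missing instrument response is
recoded as "no encouragement" (0); confounder missingness is left for the
chained-equation imputer; respondents missing the treatment are retained
through descriptives but excluded (with a logged count) from conditional
independence tests and TSLS.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptives import ContingencyTable

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSpec",
    "SurveyTable",
    "read_survey_csv",
    "write_survey_csv",
    "apply_missing_policy",
    "crosstab",
    "collapse_treatment",
    "TREATMENT_LABELS",
    "LIKERT_LABELS",
    "DEFAULT_MISSING_SENTINELS",
]

ROLES = ("instrument", "treatment", "outcome", "confounder")

TREATMENT_LABELS = ("0", "1 to 2 times", "3 to 5 times", "6 to 9 times", "10 or more times")
LIKERT_LABELS = (
    "Not confident at all",
    "A little confident",
    "Somewhat confident",
    "Very confident",
    "Completely confident",
)
#: Default strings parsed as missing; numeric sentinels cover public-use
#: survey exports that encode nonresponse as negative codes.
DEFAULT_MISSING_SENTINELS = ("", "NA", "-9")


@dataclass(frozen=True)
class VariableSpec:
    """Declares one analysis column: its role, admissible codes, and labels."""

    name: str
    role: str
    levels: tuple
    labels: tuple | None = None
    ordered: bool = False

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")
        levels = tuple(int(v) for v in self.levels)
        if not levels or len(set(levels)) != len(levels):
            raise ValueError(f"{self.name}: levels must be non-empty and unique")
        object.__setattr__(self, "levels", levels)
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != len(levels):
                raise ValueError(f"{self.name}: one label per level required")
            object.__setattr__(self, "labels", labels)

    def label_of(self, code) -> str:
        if self.labels is None:
            return str(code)
        return self.labels[self.levels.index(code)]


def instrument_spec(name: str = "encouraged") -> VariableSpec:
    return VariableSpec(name, "instrument", (0, 1), ("no", "yes"))


def treatment_spec(name: str = "portal_use") -> VariableSpec:
    return VariableSpec(name, "treatment", (0, 1, 2, 3, 4), TREATMENT_LABELS, ordered=True)


def outcome_spec(name: str) -> VariableSpec:
    return VariableSpec(name, "outcome", (1, 2, 3, 4, 5), LIKERT_LABELS, ordered=True)


@dataclass
class SurveyTable:
    """Respondent-level survey data bound to a validated schema.

    ``df`` holds one nullable-integer column per schema variable; helper
    properties expose columns by role. Row order is meaningful (ground-truth
    alignment for synthetic tables) and preserved by every recode.
    """

    df: pd.DataFrame
    schema: tuple
    validation_warnings: dict = field(default_factory=dict)

    def __post_init__(self):
        self.schema = tuple(self.schema)
        names = [s.name for s in self.schema]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")
        missing = [n for n in names if n not in self.df.columns]
        if missing:
            raise ValueError(f"schema columns absent from data: {missing}")
        n_inst = sum(s.role == "instrument" for s in self.schema)
        n_trt = sum(s.role == "treatment" for s in self.schema)
        if n_inst != 1 or n_trt != 1:
            raise ValueError("exactly one instrument and one treatment required")
        if not any(s.role == "outcome" for s in self.schema):
            raise ValueError("at least one outcome required")
        self.df = self.df.loc[:, names].astype("Int64").reset_index(drop=True)

    # ---- role accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.df)

    def spec(self, name: str) -> VariableSpec:
        for s in self.schema:
            if s.name == name:
                return s
        raise KeyError(name)

    def _names(self, role: str) -> list:
        return [s.name for s in self.schema if s.role == role]

    @property
    def instrument(self) -> str:
        return self._names("instrument")[0]

    @property
    def treatment(self) -> str:
        return self._names("treatment")[0]

    @property
    def outcomes(self) -> list:
        return self._names("outcome")

    @property
    def confounders(self) -> list:
        return self._names("confounder")

    def copy(self) -> "SurveyTable":
        return SurveyTable(self.df.copy(), self.schema, dict(self.validation_warnings))

    def complete_mask(self, columns) -> np.ndarray:
        """Boolean mask of rows non-missing in every named column."""
        return self.df[list(columns)].notna().all(axis=1).to_numpy()

    def column(self, name: str) -> np.ndarray:
        """Column as float array with NaN for missing."""
        return self.df[name].astype("Float64").to_numpy(dtype=float, na_value=np.nan)


def _validate_levels(df: pd.DataFrame, schema) -> tuple:
    """Mark out-of-range codes as missing; return (df, per-column counts)."""
    warnings = {}
    for spec in schema:
        col = df[spec.name]
        bad = col.notna() & ~col.isin(spec.levels)
        n_bad = int(bad.sum())
        if n_bad:
            logger.warning("%s: %d value(s) outside declared levels set to missing", spec.name, n_bad)
            warnings[spec.name] = n_bad
            df.loc[bad, spec.name] = pd.NA
    return df, warnings


def read_survey_csv(path, schema, missing_sentinels=DEFAULT_MISSING_SENTINELS) -> SurveyTable:
    """Read a respondent-level CSV against a declared schema.

    The header must contain every schema column (extra columns are ignored).
    Sentinel strings parse as missing; any non-integer or out-of-range value
    is flagged missing with a logged warning count kept on the returned table.
    """
    schema = tuple(schema)
    try:
        raw = pd.read_csv(
            path,
            dtype=str,
            na_values=list(missing_sentinels),
            keep_default_na=False,
            skipinitialspace=True,
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"could not parse survey CSV {path!r}: {exc}") from exc
    absent = [s.name for s in schema if s.name not in raw.columns]
    if absent:
        raise ValueError(f"CSV is missing schema column(s): {absent}")
    df = pd.DataFrame(index=raw.index)
    unparseable = {}
    for spec in schema:
        num = pd.to_numeric(raw[spec.name], errors="coerce")
        n_unparse = int((num.isna() & raw[spec.name].notna()).sum())
        if n_unparse:
            unparseable[spec.name] = n_unparse
            logger.warning("%s: %d non-numeric value(s) set to missing", spec.name, n_unparse)
        df[spec.name] = num.round().astype("Int64")
    df, warnings = _validate_levels(df, schema)
    for k, v in unparseable.items():
        warnings[k] = warnings.get(k, 0) + v
    return SurveyTable(df, schema, warnings)


def write_survey_csv(table: SurveyTable, path) -> None:
    """Write the table in the same dialect ``read_survey_csv`` accepts."""
    table.df.to_csv(path, index=False, na_rep="")


def apply_missing_policy(table: SurveyTable, outcome: str):
    """Apply the survey missing-data rules for one analysed outcome.

    Rows missing the named outcome are dropped; missing instrument responses
    are recoded to 0 ("no encouragement"); confounder (and treatment)
    missingness is left untouched for the imputer / downstream exclusion.

    Returns ``(new_table, counts)`` where counts reports rows affected per
    rule. Idempotent: applying the policy twice equals applying it once.
    """
    if outcome not in table.outcomes:
        raise ValueError(f"{outcome!r} is not a declared outcome column")
    df = table.df.copy()
    keep = df[outcome].notna()
    n_dropped = int((~keep).sum())
    df = df.loc[keep].reset_index(drop=True)
    z = table.instrument
    z_missing = df[z].isna()
    n_z = int(z_missing.sum())
    df.loc[z_missing, z] = 0
    counts = {"outcome_dropped": n_dropped, "instrument_recoded_to_no": n_z}
    if n_dropped or n_z:
        logger.info("missing policy for %s: %s", outcome, counts)
    return SurveyTable(df, table.schema, dict(table.validation_warnings)), counts


def crosstab(table: SurveyTable, row_var: str, col_var: str,
             include_empty_levels: bool = True) -> ContingencyTable:
    """Observed counts of ``row_var`` by ``col_var``.

    Rows missing either variable are excluded from the counts, so the grand
    total plus the excluded-for-missingness count equals the table row count.
    With ``include_empty_levels`` the grid covers every declared level (zero
    rows/columns possible); otherwise only observed levels appear.
    """
    rs, cs = table.spec(row_var), table.spec(col_var)
    sub = table.df[[row_var, col_var]].dropna()
    ct = pd.crosstab(sub[row_var], sub[col_var])
    ct = ct.reindex(index=list(rs.levels), columns=list(cs.levels), fill_value=0)
    out = ContingencyTable(
        ct.to_numpy(),
        tuple(rs.label_of(l) for l in rs.levels),
        tuple(cs.label_of(l) for l in cs.levels),
    )
    return out if include_empty_levels else out.drop_empty_margins()


def collapse_treatment(table: SurveyTable) -> SurveyTable:
    """Pool the two highest usage bands (6-9 and 10+) into a single ">5 times"
    level, yielding the 4-level coding (0 / 1-2 / 3-5 / >5) used in pooled
    usage summaries. Explicit and logged; never applied implicitly."""
    d = table.treatment
    df = table.df.copy()
    n_pooled = int((df[d] == 4).sum())
    df.loc[df[d] == 4, d] = 3
    logger.info("collapse_treatment: pooled %d rows from '10 or more times' into '>5 times'", n_pooled)
    new_spec = VariableSpec(d, "treatment", (0, 1, 2, 3),
                            ("0", "1 to 2 times", "3 to 5 times", "more than 5 times"),
                            ordered=True)
    schema = tuple(new_spec if s.name == d else s for s in table.schema)
    return SurveyTable(df, schema, dict(table.validation_warnings))
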