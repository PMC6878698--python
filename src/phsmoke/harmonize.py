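"""Harmonize raw survey records into the model's covariate scheme.

Raw records follow a BRFSS-like schema (age in years, free-coded race and
ethnicity, household income in USD, sex, marital status, children at home,
employment status, blindness, residential environment, state). Harmonization
maps them onto the closed categorical scheme in :mod:`phsmoke.categories`:

* a disability proxy — true when employment status is "unable to work" or
  the respondent is blind / has serious difficulty seeing;
* a composite gender/marital-status/children variable (married dominates
  sex: both sexes map onto the two married levels);
* a composite age/disability variable with the 65-year cut (age exactly 65
  is assigned to the under-65 arm, a documented convention);
* age and income bins with inclusive caps (income $10,000 falls in <$10k,
  $10,001 starts the next bin);
* race/ethnicity with Hispanic taking precedence over any race code, and
  Asian merged with Native Hawaiian/Pacific Islander;
* the state excise tax joined on as the single numeric covariate.

Scalar per-record operations are the reference semantics; the vectorized
:func:`harmonize_survey` applies the same rules to a whole DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import (
    AGE_BIN_LEVELS,
    COVARIATE_LEVELS,
    COVARIATE_ORDER,
    DEFAULT_REFERENCE_LEVELS,
    INCOME_BIN_LEVELS,
    validate_levels,
)
from .errors import TaxLookupError, ValidationError

# Raw code lists (lower-cased before lookup).
UNABLE_TO_WORK = "unable to work"
BLIND_LABEL = "blind or serious difficulty seeing, even when wearing glasses"

EMPLOYMENT_CODES = [
    "employed",
    "self-employed",
    "unemployed",
    "homemaker",
    "student",
    "retired",
    UNABLE_TO_WORK,
]
BLINDNESS_CODES = ["no", "yes", BLIND_LABEL]
#: Blindness codes that trigger the disability proxy.
BLIND_POSITIVE = {"yes", BLIND_LABEL}

SEX_CODES = {"female": "Female", "male": "Male"}
MARRIED_CODES = {"married"}
NOT_MARRIED_CODES = {"never married", "divorced", "widowed", "separated", "unmarried couple"}

RESIDENCE_CODE_MAP = {"city": "City", "suburb": "Suburb", "rural": "Rural"}

#: Raw race code -> race level, before Hispanic precedence is applied.
RACE_CODE_MAP = {
    "white": "White",
    "black": "Black/African American",
    "black or african american": "Black/African American",
    "american indian or alaskan native": "American Indian/Alaskan Native",
    "asian": "Asian and Native Hawaiian/Pacific Islander",
    "native hawaiian or other pacific islander": "Asian and Native Hawaiian/Pacific Islander",
    "other": "Other/multiracial",
    "multiracial": "Other/multiracial",
}
HISPANIC_POSITIVE = {"yes", "hispanic"}

RAW_COLUMNS = [
    "age_years",
    "race_ethnicity",
    "hispanic",
    "household_income_usd",
    "sex",
    "marital_status",
    "children_at_home",
    "employment_status",
    "blindness",
    "residence",
    "state",
]


def _norm(label) -> str:
    return str(label).strip().lower()


def derive_disability(employment_status: str, blindness: str) -> bool:
    """Disability proxy: unable to work, or blind/serious difficulty seeing."""
    emp = _norm(employment_status)
    bl = _norm(blindness)
    if emp not in EMPLOYMENT_CODES:
        raise ValidationError(
            f"unknown employment status {employment_status!r}; accepted: {EMPLOYMENT_CODES}"
        )
    if bl not in BLINDNESS_CODES:
        raise ValidationError(
            f"unknown blindness code {blindness!r}; accepted: {BLINDNESS_CODES}"
        )
    return emp == UNABLE_TO_WORK or bl in BLIND_POSITIVE


def combine_gender_marital_children(
    sex: str, marital_status: str, children_at_home: bool
) -> str:
    """Composite gender/marital/children level; married dominates sex."""
    s = _norm(sex)
    m = _norm(marital_status)
    if s not in SEX_CODES:
        raise ValidationError(f"unknown sex code {sex!r}; accepted: {sorted(SEX_CODES)}")
    if m not in MARRIED_CODES | NOT_MARRIED_CODES:
        raise ValidationError(
            f"unknown marital status {marital_status!r}; "
            f"accepted: {sorted(MARRIED_CODES | NOT_MARRIED_CODES)}"
        )
    child = "with children" if children_at_home else "no children"
    if m in MARRIED_CODES:
        return f"Two spouses/married/{child}"
    return f"{SEX_CODES[s]}/not married/{child}"


def combine_age_disability(age_years: int, disabled: bool) -> str:
    """Composite age/disability level; age 65 exactly maps to the <65 arm."""
    if age_years < 18:
        raise ValidationError(f"age {age_years} below 18; adults only")
    arm = "Age <65" if age_years <= 65 else "Age >65"
    return f"{arm} {'with disability' if disabled else 'no disability'}"


def bin_age(age_years: int) -> str:
    """Map age in years onto the five closed age bins (inclusive bounds)."""
    if age_years < 18:
        raise ValidationError(f"age {age_years} below 18; adults only")
    if age_years <= 24:
        return "18-24"
    if age_years <= 49:
        return "25-49"
    if age_years <= 59:
        return "50-59"
    if age_years <= 79:
        return "60-79"
    return "80+"


def bin_income(income_usd: float) -> str:
    """Income bins with caps at $10k/$15k/$20k, lower bounds exclusive of the cap."""
    if income_usd < 0:
        raise ValidationError(f"negative household income {income_usd}")
    if income_usd <= 10_000:
        return "<$10k"
    if income_usd <= 15_000:
        return "$10,001-$15k"
    if income_usd <= 20_000:
        return "$15,001-$20k"
    return ">=$20,001"


def map_race(race_ethnicity: str, hispanic: str = "no") -> str:
    """Race level with Hispanic precedence over the race code."""
    if _norm(hispanic) in HISPANIC_POSITIVE:
        return "Hispanic"
    code = _norm(race_ethnicity)
    if code not in RACE_CODE_MAP:
        raise ValidationError(
            f"unknown race/ethnicity code {race_ethnicity!r}; accepted: {sorted(RACE_CODE_MAP)}"
        )
    return RACE_CODE_MAP[code]


def map_residence(residence: str) -> str:
    code = _norm(residence)
    if code in RESIDENCE_CODE_MAP:
        return RESIDENCE_CODE_MAP[code]
    raise ValidationError(
        f"unknown residential environment {residence!r}; accepted: {sorted(RESIDENCE_CODE_MAP)}"
    )


def bin_covariates(record: dict) -> dict:
    """Harmonize one raw record (without tax). Idempotent on harmonized levels.

    Returns a dict with the six categorical covariates, plus ``state`` and,
    when present in the input, ``smokes``.
    """
    disabled = derive_disability(record["employment_status"], record["blindness"])
    age = int(record["age_years"])
    out = {
        "residence": map_residence(record["residence"]),
        "race": map_race(record["race_ethnicity"], record.get("hispanic", "no")),
        "age_bin": bin_age(age),
        "income_bin": bin_income(float(record["household_income_usd"])),
        "gen_ma_ch": combine_gender_marital_children(
            record["sex"], record["marital_status"], bool(record["children_at_home"])
        ),
        "age_dis": combine_age_disability(age, disabled),
        "state": str(record["state"]).upper(),
    }
    if "smokes" in record and record["smokes"] is not None:
        out["smokes"] = int(record["smokes"])
    return out


def attach_tax_rate(record: dict, tax_table: dict[str, float]) -> dict:
    """Return a copy of the record with ``tax`` set from its state; other fields untouched."""
    state = str(record["state"]).upper()
    if state not in tax_table:
        raise TaxLookupError(f"state {state!r} missing from the excise-tax table")
    out = dict(record)
    out["tax"] = float(tax_table[state])
    return out


def harmonize_survey(
    raw: pd.DataFrame,
    tax_table: dict[str, float],
    *,
    drop_invalid: bool = False,
) -> pd.DataFrame:
    """Vectorized harmonization of a raw survey DataFrame.

    Applies the same rules as the scalar operations row-wise, attaches the
    state tax, and returns a harmonized DataFrame. Rows with missing fields
    are dropped (count reported via logging) when ``drop_invalid`` is set,
    otherwise missingness raises :class:`ValidationError`.
    """
    df = raw.copy()
    needed = [c for c in RAW_COLUMNS if c != "hispanic"]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValidationError(f"survey table missing column(s) {missing_cols}")
    if "hispanic" not in df.columns:
        df["hispanic"] = "no"

    na_mask = df[RAW_COLUMNS].isna().any(axis=1)
    if na_mask.any():
        if not drop_invalid:
            raise ValidationError(
                f"{int(na_mask.sum())} record(s) have missing fields "
                "(pass drop_invalid=True to drop them)"
            )
        import logging

        logging.getLogger(__name__).info(
            "dropping %d record(s) with missing fields", int(na_mask.sum())
        )
        df = df.loc[~na_mask]

    age = df["age_years"].astype(int).to_numpy()
    if (age < 18).any():
        bad = np.flatnonzero(age < 18)[:5].tolist()
        raise ValidationError(f"age below 18 at row index(es) {bad}")

    emp = df["employment_status"].map(_norm)
    bl = df["blindness"].map(_norm)
    for col, accepted, name in [
        (emp, set(EMPLOYMENT_CODES), "employment_status"),
        (bl, set(BLINDNESS_CODES), "blindness"),
    ]:
        bad = sorted(set(col) - accepted)
        if bad:
            raise ValidationError(f"unknown {name} code(s) {bad}")
    disabled = (emp == UNABLE_TO_WORK).to_numpy() | bl.isin(BLIND_POSITIVE).to_numpy()

    sex = df["sex"].map(_norm)
    marital = df["marital_status"].map(_norm)
    bad_sex = sorted(set(sex) - set(SEX_CODES))
    if bad_sex:
        raise ValidationError(f"unknown sex code(s) {bad_sex}")
    bad_mar = sorted(set(marital) - (MARRIED_CODES | NOT_MARRIED_CODES))
    if bad_mar:
        raise ValidationError(f"unknown marital status code(s) {bad_mar}")
    married = marital.isin(MARRIED_CODES).to_numpy()
    children = df["children_at_home"].map(
        lambda v: _norm(v) in {"true", "yes", "1"} if not isinstance(v, (bool, np.bool_)) else bool(v)
    ).to_numpy()
    child_txt = np.where(children, "with children", "no children")
    gen_ma_ch = np.where(
        married,
        np.char.add("Two spouses/married/", child_txt.astype(str)),
        np.char.add(
            np.char.add(sex.map(SEX_CODES).to_numpy(dtype=str), "/not married/"),
            child_txt.astype(str),
        ),
    )

    hispanic = df["hispanic"].map(_norm).isin(HISPANIC_POSITIVE).to_numpy()
    race_code = df["race_ethnicity"].map(_norm)
    bad_race = sorted(set(race_code[~hispanic]) - set(RACE_CODE_MAP))
    if bad_race:
        raise ValidationError(f"unknown race/ethnicity code(s) {bad_race}")
    race = np.where(hispanic, "Hispanic", race_code.map(lambda c: RACE_CODE_MAP.get(c, "")))

    residence = df["residence"].map(_norm)
    bad_res = sorted(set(residence) - set(RESIDENCE_CODE_MAP))
    if bad_res:
        raise ValidationError(f"unknown residential environment code(s) {bad_res}")

    income = df["household_income_usd"].astype(float).to_numpy()
    if (income < 0).any():
        raise ValidationError("negative household income")
    income_bin = np.select(
        [income <= 10_000, income <= 15_000, income <= 20_000],
        INCOME_BIN_LEVELS[:3],
        default=INCOME_BIN_LEVELS[3],
    )
    age_bin = np.select(
        [age <= 24, age <= 49, age <= 59, age <= 79],
        AGE_BIN_LEVELS[:4],
        default=AGE_BIN_LEVELS[4],
    )
    arm = np.where(age <= 65, "Age <65", "Age >65")
    age_dis = np.char.add(
        arm.astype(str),
        np.where(disabled, " with disability", " no disability").astype(str),
    )

    state = df["state"].astype(str).str.upper()
    unknown_states = sorted(set(state) - set(tax_table))
    if unknown_states:
        raise TaxLookupError(f"state(s) {unknown_states} missing from the excise-tax table")

    out = pd.DataFrame(
        {
            "residence": residence.map(RESIDENCE_CODE_MAP).to_numpy(),
            "race": race,
            "age_bin": age_bin,
            "income_bin": income_bin,
            "gen_ma_ch": gen_ma_ch,
            "age_dis": age_dis,
            "state": state.to_numpy(),
            "tax": state.map(tax_table).astype(float).to_numpy(),
        },
        index=df.index,
    )
    if "smokes" in df.columns and df["smokes"].notna().all():
        out["smokes"] = df["smokes"].astype(int).to_numpy()
    return out


@dataclass
class DesignMatrix:
    """Dummy-coded design: intercept column, one numeric tax column, and one
    indicator per non-reference level of each categorical covariate."""

    X: pd.DataFrame
    reference_levels: dict[str, str]
    y: pd.Series | None = None
    column_order: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.column_order:
            self.column_order = list(self.X.columns)

    @property
    def n(self) -> int:
        return len(self.X)


def design_columns(reference_levels: dict[str, str] | None = None) -> list[str]:
    """Deterministic design-matrix column order: const, tax, then dummies in
    covariate/level printed order skipping each reference level."""
    refs = dict(DEFAULT_REFERENCE_LEVELS, **(reference_levels or {}))
    cols = ["const", "tax"]
    for cov in COVARIATE_ORDER:
        for lev in COVARIATE_LEVELS[cov]:
            if lev != refs[cov]:
                cols.append(f"{cov}[T.{lev}]")
    return cols


def build_design_matrix(
    records: pd.DataFrame,
    reference_levels: dict[str, str] | None = None,
    *,
    require_outcome: bool = False,
) -> DesignMatrix:
    """Build the dummy-coded design matrix from harmonized records."""
    if len(records) == 0:
        raise ValidationError("cannot build a design matrix from zero records")
    refs = dict(DEFAULT_REFERENCE_LEVELS, **(reference_levels or {}))
    for cov, ref in refs.items():
        if cov not in COVARIATE_LEVELS:
            raise ValidationError(f"reference level given for unknown covariate {cov!r}")
        if ref not in COVARIATE_LEVELS[cov]:
            raise ValidationError(f"reference level {ref!r} not a level of {cov!r}")
    X = pd.DataFrame(index=records.index)
    X["const"] = 1.0
    X["tax"] = records["tax"].astype(float)
    for cov in COVARIATE_ORDER:
        validate_levels(cov, records[cov])
        for lev in COVARIATE_LEVELS[cov]:
            if lev == refs[cov]:
                continue
            X[f"{cov}[T.{lev}]"] = (records[cov] == lev).astype(float)
    y = None
    if "smokes" in records.columns:
        y = records["smokes"].astype(int)
    elif require_outcome:
        raise ValidationError("outcome column 'smokes' required but absent")
    return DesignMatrix(X=X, reference_levels=refs, y=y)


def decode_design_matrix(design: DesignMatrix) -> pd.DataFrame:
    """Invert dummy coding back to levels (round-trip check of the encoding)."""
    X = design.X
    out = pd.DataFrame(index=X.index)
    out["tax"] = X["tax"]
    for cov in COVARIATE_ORDER:
        ref = design.reference_levels[cov]
        level = pd.Series(ref, index=X.index, dtype=object)
        for lev in COVARIATE_LEVELS[cov]:
            if lev == ref:
                continue
            col = f"{cov}[T.{lev}]"
            level = level.mask(X[col] == 1.0, lev)
        out[cov] = level
    return out
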