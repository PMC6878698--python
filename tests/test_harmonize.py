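"""Unit tests for covariate harmonization and design-matrix construction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phsmoke.categories import COVARIATE_LEVELS, COVARIATE_ORDER
from phsmoke.errors import TaxLookupError, ValidationError
from phsmoke.harmonize import (
    BLIND_LABEL,
    RACE_CODE_MAP,
    UNABLE_TO_WORK,
    attach_tax_rate,
    bin_age,
    bin_covariates,
    bin_income,
    build_design_matrix,
    combine_age_disability,
    combine_gender_marital_children,
    decode_design_matrix,
    derive_disability,
    harmonize_survey,
    map_race,
)

TAX = {"GA": 0.37, "NY": 4.35}


class TestDisabilityProxy:
    @pytest.mark.parametrize(
        "employment, blindness, expected",
        [
            (UNABLE_TO_WORK, "no", True),
            ("employed", BLIND_LABEL, True),
            ("employed", "yes", True),
            ("employed", "no", False),
            ("retired", "no", False),
        ],
    )
    def test_truth_table(self, employment, blindness, expected):
        assert derive_disability(employment, blindness) is expected

    def test_unknown_codes_rejected_with_accepted_list(self):
        with pytest.raises(ValidationError, match="employment"):
            derive_disability("astronaut", "no")
        with pytest.raises(ValidationError, match="blindness"):
            derive_disability("employed", "maybe")


class TestGenderMaritalChildren:
    # exhaustive truth table written independently of the implementation
    ORACLE = {}
    for sex, sex_lab in (("female", "Female"), ("male", "Male")):
        for marital in ("married", "never married", "divorced", "widowed", "separated"):
            for child in (True, False):
                ct = "with children" if child else "no children"
                if marital == "married":
                    ORACLE[(sex, marital, child)] = f"Two spouses/married/{ct}"
                else:
                    ORACLE[(sex, marital, child)] = f"{sex_lab}/not married/{ct}"

    def test_exhaustive_truth_table(self):
        for (sex, marital, child), expected in self.ORACLE.items():
            assert combine_gender_marital_children(sex, marital, child) == expected

    def test_married_dominates_sex(self):
        assert (
            combine_gender_marital_children("male", "married", True)
            == combine_gender_marital_children("female", "married", True)
            == "Two spouses/married/with children"
        )

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            combine_gender_marital_children("female", "engaged", True)


class TestAgeDisability:
    @pytest.mark.parametrize(
        "age, disabled, expected",
        [
            (40, True, "Age <65 with disability"),
            (80, False, "Age >65 no disability"),
            (65, True, "Age <65 with disability"),  # boundary convention
            (66, True, "Age >65 with disability"),
            (64, False, "Age <65 no disability"),
        ],
    )
    def test_levels(self, age, disabled, expected):
        assert combine_age_disability(age, disabled) == expected

    def test_minors_rejected(self):
        with pytest.raises(ValidationError):
            combine_age_disability(17, False)


class TestBins:
    @pytest.mark.parametrize(
        "age, expected",
        [(18, "18-24"), (24, "18-24"), (25, "25-49"), (49, "25-49"),
         (50, "50-59"), (59, "50-59"), (60, "60-79"), (79, "60-79"), (80, "80+")],
    )
    def test_age_bins_inclusive_bounds(self, age, expected):
        assert bin_age(age) == expected

    @pytest.mark.parametrize(
        "income, expected",
        [(0, "<$10k"), (10_000, "<$10k"), (10_001, "$10,001-$15k"),
         (15_000, "$10,001-$15k"), (15_001, "$15,001-$20k"),
         (20_000, "$15,001-$20k"), (20_001, ">=$20,001")],
    )
    def test_income_bins_exclusive_lower_bounds(self, income, expected):
        assert bin_income(income) == expected

    def test_hispanic_precedence_over_race(self):
        assert map_race("white", "yes") == "Hispanic"
        assert map_race("white", "no") == "White"
        assert map_race("asian", "no") == "Asian and Native Hawaiian/Pacific Islander"


class TestAttachTax:
    RECORD = {"state": "GA", "age_years": 30}

    def test_lookup(self):
        assert attach_tax_rate(self.RECORD, TAX)["tax"] == 0.37

    def test_unknown_state(self):
        with pytest.raises(TaxLookupError, match="ZZ"):
            attach_tax_rate({"state": "ZZ"}, TAX)

    def test_other_fields_untouched(self):
        out = attach_tax_rate(self.RECORD, TAX)
        assert out["age_years"] == 30 and self.RECORD.get("tax") is None


def _reference_record(tax=0.0):
    return pd.DataFrame(
        {
            "residence": ["City"],
            "race": ["White"],
            "age_bin": ["18-24"],
            "income_bin": ["<$10k"],
            "gen_ma_ch": ["Two spouses/married/with children"],
            "age_dis": ["Age <65 with disability"],
            "tax": [tax],
        }
    )


class TestDesignMatrix:
    def test_reference_row_is_intercept_only(self):
        design = build_design_matrix(_reference_record(tax=0.0))
        row = design.X.iloc[0]
        assert row["const"] == 1.0
        assert (row.drop("const") == 0.0).all()

    def test_k_minus_one_dummy_columns(self):
        design = build_design_matrix(_reference_record())
        gen_cols = [c for c in design.X.columns if c.startswith("gen_ma_ch")]
        assert len(gen_cols) == 5
        expected = 2 + sum(len(v) - 1 for v in COVARIATE_LEVELS.values())
        assert design.X.shape[1] == expected

    def test_indicator_exclusivity(self, harmonized):
        design = build_design_matrix(harmonized.head(500))
        for cov in COVARIATE_ORDER:
            cols = [c for c in design.X.columns if c.startswith(f"{cov}[")]
            sums = design.X[cols].sum(axis=1)
            assert set(sums.unique()) <= {0.0, 1.0}

    def test_decode_round_trip(self, harmonized):
        sample = harmonized.head(200)
        design = build_design_matrix(sample)
        decoded = decode_design_matrix(design)
        for cov in COVARIATE_ORDER:
            assert (decoded[cov].to_numpy() == sample[cov].to_numpy()).all()

    def test_unknown_level_rejected(self):
        df = _reference_record()
        df.loc[0, "race"] = "Martian"
        with pytest.raises(ValidationError, match="race"):
            build_design_matrix(df)

    def test_custom_reference_levels(self):
        design = build_design_matrix(_reference_record(), {"race": "Hispanic"})
        assert "race[T.White]" in design.X.columns
        assert "race[T.Hispanic]" not in design.X.columns


raw_record = st.fixed_dictionaries(
    {
        "age_years": st.integers(18, 94),
        "race_ethnicity": st.sampled_from(sorted(RACE_CODE_MAP)),
        "hispanic": st.sampled_from(["yes", "no"]),
        "household_income_usd": st.integers(0, 90_000),
        "sex": st.sampled_from(["female", "male"]),
        "marital_status": st.sampled_from(
            ["married", "never married", "divorced", "widowed", "separated"]
        ),
        "children_at_home": st.booleans(),
        "employment_status": st.sampled_from(["employed", "retired", UNABLE_TO_WORK]),
        "blindness": st.sampled_from(["no", "yes", BLIND_LABEL]),
        "residence": st.sampled_from(["city", "suburb", "rural"]),
        "state": st.sampled_from(["GA", "NY"]),
        "smokes": st.integers(0, 1),
    }
)


@given(record=raw_record)
def test_harmonization_total_on_valid_records(record):
    """Every valid raw record maps to exactly one known level per covariate."""
    out = bin_covariates(record)
    for cov in COVARIATE_ORDER:
        assert out[cov] in COVARIATE_LEVELS[cov]


@given(records=st.lists(raw_record, min_size=1, max_size=8))
def test_vectorized_harmonization_matches_scalar(records):
    """harmonize_survey row-wise agrees with the scalar reference semantics."""
    raw = pd.DataFrame(records)
    vec = harmonize_survey(raw, TAX)
    for i, rec in enumerate(records):
        scalar = attach_tax_rate(bin_covariates(rec), TAX)
        for cov in COVARIATE_ORDER + ["state", "tax"]:
            assert vec.iloc[i][cov] == scalar[cov]


def test_harmonize_survey_drops_incomplete_records():
    raw = pd.DataFrame(
        [
            dict(age_years=30, race_ethnicity="white", hispanic="no",
                 household_income_usd=5000, sex="female", marital_status="married",
                 children_at_home=True, employment_status="employed", blindness="no",
                 residence="city", state="GA", smokes=1),
            dict(age_years=np.nan, race_ethnicity="white", hispanic="no",
                 household_income_usd=5000, sex="female", marital_status="married",
                 children_at_home=True, employment_status="employed", blindness="no",
                 residence="city", state="GA", smokes=0),
        ]
    )
    with pytest.raises(ValidationError):
        harmonize_survey(raw, TAX)
    assert len(harmonize_survey(raw, TAX, drop_invalid=True)) == 1
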