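"""Closed categorical scheme for the smoking model covariates.

Six categorical covariates describe a public-housing adult: residential
environment, race/ethnicity, age bin, household income bin, a composite
gender/marital-status/children variable, and a composite age/disability
variable. The state cigarette excise tax (USD per 20-pack) enters the model
as the single numeric covariate. Level lists are closed: every harmonized
record carries exactly one level per covariate, and the design matrix dummy
codes the non-reference levels in the fixed order below.
"""

from __future__ import annotations

import numpy as np

from .errors import ValidationError

RESIDENCE_LEVELS = ["City", "Suburb", "Rural"]

RACE_LEVELS = [
    "White",
    "Black/African American",
    "American Indian/Alaskan Native",
    "Asian and Native Hawaiian/Pacific Islander",
    "Hispanic",
    "Other/multiracial",
]

AGE_BIN_LEVELS = ["18-24", "25-49", "50-59", "60-79", "80+"]

INCOME_BIN_LEVELS = ["<$10k", "$10,001-$15k", "$15,001-$20k", ">=$20,001"]

GEN_MA_CH_LEVELS = [
    "Two spouses/married/with children",
    "Two spouses/married/no children",
    "Female/not married/with children",
    "Female/not married/no children",
    "Male/not married/with children",
    "Male/not married/no children",
]

AGE_DIS_LEVELS = [
    "Age <65 with disability",
    "Age <65 no disability",
    "Age >65 with disability",
    "Age >65 no disability",
]

#: Covariate name -> ordered closed level list. Iteration order here defines
#: design-matrix column order and CSV column order everywhere in the package.
COVARIATE_LEVELS: dict[str, list[str]] = {
    "residence": RESIDENCE_LEVELS,
    "race": RACE_LEVELS,
    "age_bin": AGE_BIN_LEVELS,
    "income_bin": INCOME_BIN_LEVELS,
    "gen_ma_ch": GEN_MA_CH_LEVELS,
    "age_dis": AGE_DIS_LEVELS,
}

COVARIATE_ORDER = list(COVARIATE_LEVELS)

#: Default reference level per covariate: the first level of each list.
#: Configurable wherever a design matrix is built.
DEFAULT_REFERENCE_LEVELS = {cov: levels[0] for cov, levels in COVARIATE_LEVELS.items()}

#: Age/disability levels on the under-65 arm; ages of exactly 65 fall here.
UNDER65_AGE_DIS = {"Age <65 with disability", "Age <65 no disability"}
#: Age bins compatible with the under-65 arm (60-79 straddles the cut).
UNDER65_AGE_BINS = ["18-24", "25-49", "50-59", "60-79"]
#: Age bins compatible with the over-65 arm.
OVER65_AGE_BINS = ["60-79", "80+"]


def validate_levels(covariate: str, values) -> None:
    """Raise :class:`ValidationError` if any value is not a known level."""
    if covariate not in COVARIATE_LEVELS:
        raise ValidationError(f"unknown covariate {covariate!r}")
    known = set(COVARIATE_LEVELS[covariate])
    bad = sorted(set(map(str, values)) - known)
    if bad:
        raise ValidationError(
            f"unknown level(s) {bad} for covariate {covariate!r}; "
            f"accepted levels: {COVARIATE_LEVELS[covariate]}"
        )


def validate_marginals(marginals: dict, *, atol: float = 1e-6) -> None:
    """Check a covariate -> probability-vector mapping against the scheme.

    Every covariate must be present, each vector must have one entry per
    level, be non-negative and sum to 1 within ``atol``.
    """
    for cov, levels in COVARIATE_LEVELS.items():
        if cov not in marginals:
            raise ValidationError(f"marginals missing covariate {cov!r}")
        vec = np.asarray(marginals[cov], dtype=float)
        if vec.shape != (len(levels),):
            raise ValidationError(
                f"marginal for {cov!r} has {vec.size} entries, expected {len(levels)}"
            )
        if (vec < -atol).any():
            raise ValidationError(f"marginal for {cov!r} has negative mass")
        if abs(vec.sum() - 1.0) > atol:
            raise ValidationError(
                f"marginal for {cov!r} sums to {vec.sum():.9f}, not 1"
            )
    extra = set(marginals) - set(COVARIATE_LEVELS)
    if extra:
        raise ValidationError(f"marginals contain unknown covariate(s) {sorted(extra)}")


def age_bin_conditional(
    age_dis_level: str,
    age_marginal,
    over65_80plus_fraction: float | None = None,
) -> tuple[list[str], np.ndarray]:
    """Conditional age-bin law given the age/disability arm.

    Under-65 composite levels co-occur only with bins 18-24 through 60-79;
    over-65 levels only with 60-79 or 80+. The conditional distribution is
    the population age marginal restricted to the allowed bins and
    renormalized. ``over65_80plus_fraction`` overrides the 80+ share on the
    over-65 arm; either arm falls back to a uniform law if the restricted
    marginal carries zero mass.
    """
    age_marginal = np.asarray(age_marginal, dtype=float)
    if age_dis_level in UNDER65_AGE_DIS:
        allowed = UNDER65_AGE_BINS
        idx = [AGE_BIN_LEVELS.index(b) for b in allowed]
        probs = age_marginal[idx]
    else:
        allowed = OVER65_AGE_BINS
        if over65_80plus_fraction is not None:
            return list(allowed), np.array(
                [1.0 - over65_80plus_fraction, over65_80plus_fraction]
            )
        idx = [AGE_BIN_LEVELS.index(b) for b in allowed]
        probs = age_marginal[idx]
    total = probs.sum()
    if total <= 0:
        probs = np.full(len(allowed), 1.0 / len(allowed))
    else:
        probs = probs / total
    return list(allowed), probs
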