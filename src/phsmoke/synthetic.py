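"""Known-truth synthetic data: survey records and PHD aggregate tables.

The generator emulates the two inputs of the pipeline with a single logistic
data-generating process so every downstream stage can be checked against
ground truth:

* a national survey (BRFSS-like schema) whose raw records harmonize exactly
  back to the categorical levels they were drawn from, with smoking status
  drawn Bernoulli(logistic(linear predictor)) under known true coefficients;
* a table of public housing developments whose marginal fractions are the
  exact empirical marginals of a hidden individual roster of the stated
  size; the hidden roster's realized Bernoulli smoker count is the truth the
  small-area estimator is judged against.

All randomness flows from one seed: stream [seed, 0] drives the survey,
stream [seed, 1] drives the PHD tables, each with a documented draw order,
so either artifact can be regenerated independently and bit-identically.
The default intercept is solved numerically (exact enumeration of the joint
categorical law) so the true national smoking prevalence equals the target
(one third, the prevalence observed among U.S. public-housing adults).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .categories import (
    COVARIATE_LEVELS,
    COVARIATE_ORDER,
    UNDER65_AGE_DIS,
    age_bin_conditional,
    validate_marginals,
)
from .errors import ValidationError
from .harmonize import BLIND_LABEL, UNABLE_TO_WORK
from .microsim import PHDRecord, sample_covariates
from .model import ModelCoefficients

# 2015 state cigarette excise taxes, USD per 20-pack.
DEFAULT_TAX_BY_STATE = {
    "GA": 0.37,
    "NY": 4.35,
    "CA": 0.87,
    "NC": 0.45,
    "TX": 1.41,
    "WA": 3.025,
}

# (county FIPS choices, base latitude, base longitude) per state.
STATE_GEO = {
    "GA": (["13089", "13121"], 33.75, -84.39),
    "NY": (["36047", "36061"], 40.71, -74.01),
    "CA": (["06037", "06075"], 34.05, -118.24),
    "NC": (["37119", "37183"], 35.78, -78.64),
    "TX": (["48113", "48201"], 29.76, -95.37),
    "WA": (["53033", "53053"], 47.61, -122.33),
}

#: Marginal level probabilities representative of adult public-housing
#: residents (city-skewed, low-income, majority female-headed households).
DEFAULT_MARGINALS: dict[str, list[float]] = {
    "residence": [0.70, 0.20, 0.10],
    "race": [0.30, 0.40, 0.02, 0.05, 0.18, 0.05],
    "age_bin": [0.10, 0.40, 0.20, 0.25, 0.05],
    "income_bin": [0.40, 0.25, 0.15, 0.20],
    "gen_ma_ch": [0.10, 0.10, 0.30, 0.25, 0.05, 0.20],
    "age_dis": [0.20, 0.55, 0.10, 0.15],
}


def default_true_coefficients(intercept: float = -1.0) -> ModelCoefficients:
    """Ground-truth coefficients of realistic sign and size (log-odds scale)."""
    return ModelCoefficients(
        intercept=intercept,
        tax_slope=-0.12,
        level_coefficients={
            ("residence", "Suburb"): -0.10,
            ("residence", "Rural"): 0.20,
            ("race", "Black/African American"): 0.15,
            ("race", "American Indian/Alaskan Native"): 0.50,
            ("race", "Asian and Native Hawaiian/Pacific Islander"): -0.60,
            ("race", "Hispanic"): -0.40,
            ("race", "Other/multiracial"): 0.30,
            ("age_bin", "25-49"): 0.30,
            ("age_bin", "50-59"): 0.25,
            ("age_bin", "60-79"): -0.20,
            ("age_bin", "80+"): -1.00,
            ("income_bin", "$10,001-$15k"): -0.10,
            ("income_bin", "$15,001-$20k"): -0.20,
            ("income_bin", ">=$20,001"): -0.50,
            ("gen_ma_ch", "Two spouses/married/no children"): 0.10,
            ("gen_ma_ch", "Female/not married/with children"): 0.40,
            ("gen_ma_ch", "Female/not married/no children"): 0.30,
            ("gen_ma_ch", "Male/not married/with children"): 0.50,
            ("gen_ma_ch", "Male/not married/no children"): 0.60,
            ("age_dis", "Age <65 no disability"): -0.50,
            ("age_dis", "Age >65 with disability"): -0.30,
            ("age_dis", "Age >65 no disability"): -0.80,
        },
    )


@dataclass
class PopulationSpec:
    """Full description of the synthetic study population."""

    n_individuals: int
    category_marginals: dict[str, list[float]]
    true_coefficients: ModelCoefficients
    tax_by_state: dict[str, float]
    n_phds: int
    phd_size_range: tuple[int, int]
    rng_seed: int
    state_probabilities: dict[str, float] | None = None
    over65_80plus_fraction: float | None = None

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValidationError("n_individuals must be positive")
        if self.n_phds < 1:
            raise ValidationError("n_phds must be positive")
        lo, hi = self.phd_size_range
        if lo < 1 or hi < lo:
            raise ValidationError(f"empty or invalid phd_size_range {self.phd_size_range}")
        validate_marginals(self.category_marginals, atol=1e-9)
        for cov, levels in COVARIATE_LEVELS.items():
            if len(self.category_marginals[cov]) != len(levels):
                raise ValidationError(f"marginal for {cov!r} does not match its level set")
        if not self.tax_by_state:
            raise ValidationError("tax_by_state is empty")
        probs = self.states_and_probs()[1]
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValidationError("state probabilities do not sum to 1")

    def states_and_probs(self) -> tuple[list[str], np.ndarray]:
        states = sorted(self.tax_by_state)
        if self.state_probabilities is None:
            p = np.full(len(states), 1.0 / len(states))
        else:
            missing = set(states) ^ set(self.state_probabilities)
            if missing:
                raise ValidationError(
                    f"state_probabilities keys differ from tax_by_state: {sorted(missing)}"
                )
            p = np.array([self.state_probabilities[s] for s in states], dtype=float)
        return states, p


@dataclass
class TruthBundle:
    """Ground truth retained for validation of the downstream estimators."""

    true_coefficients: ModelCoefficients
    per_individual_probability: np.ndarray
    true_smoker_count_by_phd: dict[str, int] = field(default_factory=dict)
    hidden_rosters: dict[str, pd.DataFrame] = field(default_factory=dict)


def _enumerate_joint(spec: PopulationSpec):
    """Exact joint law of (covariates, state): per-combination weight and
    intercept-free linear predictor. Mirrors the sampling scheme exactly,
    including the conditional age-bin rule."""
    coefs = spec.true_coefficients
    beta = {("const",): 0.0}
    weights, etas = [], []
    states, sp = spec.states_and_probs()

    def coef(cov, lev):
        return coefs.level_coefficients.get((cov, lev), 0.0)

    m = {c: np.asarray(spec.category_marginals[c], dtype=float) for c in COVARIATE_ORDER}
    age_pairs = []  # (age_dis, age_bin, joint prob)
    for i, ad in enumerate(COVARIATE_LEVELS["age_dis"]):
        allowed, probs = age_bin_conditional(
            ad, m["age_bin"], spec.over65_80plus_fraction
        )
        for ab, pr in zip(allowed, probs):
            if pr > 0:
                age_pairs.append((ad, ab, m["age_dis"][i] * pr))
    for ri, res in enumerate(COVARIATE_LEVELS["residence"]):
        for ci, race in enumerate(COVARIATE_LEVELS["race"]):
            for ii, inc in enumerate(COVARIATE_LEVELS["income_bin"]):
                for gi, gen in enumerate(COVARIATE_LEVELS["gen_ma_ch"]):
                    base_w = m["residence"][ri] * m["race"][ci] * m["income_bin"][ii] * m["gen_ma_ch"][gi]
                    if base_w == 0:
                        continue
                    base_eta = (
                        coef("residence", res)
                        + coef("race", race)
                        + coef("income_bin", inc)
                        + coef("gen_ma_ch", gen)
                    )
                    for ad, ab, pw in age_pairs:
                        eta_ad = base_eta + coef("age_dis", ad) + coef("age_bin", ab)
                        for s, ps in zip(states, sp):
                            weights.append(base_w * pw * ps)
                            etas.append(eta_ad + coefs.tax_slope * spec.tax_by_state[s])
    return np.asarray(weights), np.asarray(etas)


def solve_intercept_for_prevalence(spec: PopulationSpec, target: float) -> float:
    """Intercept making the population mean smoking probability equal target."""
    w, eta = _enumerate_joint(spec)
    w = w / w.sum()

    def f(b0):
        return float(w @ expit(b0 + eta)) - target

    return float(brentq(f, -30.0, 30.0, xtol=1e-12))


def default_population_spec(
    n_individuals: int = 50_000,
    n_phds: int = 30,
    rng_seed: int = 2015,
    *,
    target_prevalence: float = 0.33,
    phd_size_range: tuple[int, int] = (500, 2500),
) -> PopulationSpec:
    """Study-condition defaults with the intercept solved for the target prevalence."""
    spec = PopulationSpec(
        n_individuals=n_individuals,
        category_marginals={k: list(v) for k, v in DEFAULT_MARGINALS.items()},
        true_coefficients=default_true_coefficients(),
        tax_by_state=dict(DEFAULT_TAX_BY_STATE),
        n_phds=n_phds,
        phd_size_range=phd_size_range,
        rng_seed=rng_seed,
    )
    b0 = solve_intercept_for_prevalence(spec, target_prevalence)
    spec.true_coefficients.intercept = b0
    spec.validate()
    return spec


# -- de-harmonization: harmonized categories -> raw survey codes -----------

_AGE_RANGES = {
    ("18-24", "u"): (18, 24),
    ("25-49", "u"): (25, 49),
    ("50-59", "u"): (50, 59),
    ("60-79", "u"): (60, 65),  # age 65 sits on the under-65 arm
    ("60-79", "o"): (66, 79),
    ("80+", "o"): (80, 94),
}
_INCOME_RANGES = {
    "<$10k": (0, 10_000),
    "$10,001-$15k": (10_001, 15_000),
    "$15,001-$20k": (15_001, 20_000),
    ">=$20,001": (20_001, 80_000),
}
_RACE_CODES = {
    "White": ["white"],
    "Black/African American": ["black"],
    "American Indian/Alaskan Native": ["american indian or alaskan native"],
    "Asian and Native Hawaiian/Pacific Islander": [
        "asian",
        "native hawaiian or other pacific islander",
    ],
    "Hispanic": ["white", "other"],  # hispanic flag carries the ethnicity
    "Other/multiracial": ["other", "multiracial"],
}
_NOT_MARRIED = ["never married", "divorced", "widowed", "separated"]
_EMPLOYED_CODES = ["employed", "self-employed", "unemployed", "homemaker", "student", "retired"]


def _deharmonize(harm: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Invent raw survey codes consistent with harmonized categories.

    Draw order per column block is fixed: age, income, race, sex/marital,
    disability route, for reproducibility.
    """
    n = len(harm)
    under = harm["age_dis"].isin(UNDER65_AGE_DIS).to_numpy()
    arm = np.where(under, "u", "o")
    lo = np.empty(n, dtype=int)
    hi = np.empty(n, dtype=int)
    for (bin_, a), (l, h) in _AGE_RANGES.items():
        mask = (harm["age_bin"].to_numpy() == bin_) & (arm == a)
        lo[mask], hi[mask] = l, h
    age = rng.integers(lo, hi + 1)

    ilo = np.empty(n, dtype=int)
    ihi = np.empty(n, dtype=int)
    for bin_, (l, h) in _INCOME_RANGES.items():
        mask = harm["income_bin"].to_numpy() == bin_
        ilo[mask], ihi[mask] = l, h
    income = rng.integers(ilo, ihi + 1)

    race_draw = rng.random(n)
    race_code = np.empty(n, dtype=object)
    hispanic = np.full(n, "no", dtype=object)
    for level, codes in _RACE_CODES.items():
        mask = harm["race"].to_numpy() == level
        picks = (race_draw[mask] * len(codes)).astype(int)
        race_code[mask] = np.asarray(codes, dtype=object)[picks]
        if level == "Hispanic":
            hispanic[mask] = "yes"

    gen = harm["gen_ma_ch"].astype(str)
    married = gen.str.startswith("Two spouses").to_numpy()
    children = gen.str.endswith("with children").to_numpy()
    sex_draw = rng.random(n)
    sex = np.where(
        married,
        np.where(sex_draw < 0.5, "female", "male"),
        np.where(gen.str.startswith("Female").to_numpy(), "female", "male"),
    )
    marital_draw = rng.integers(0, len(_NOT_MARRIED), size=n)
    marital = np.where(
        married, "married", np.asarray(_NOT_MARRIED, dtype=object)[marital_draw]
    )

    disabled = harm["age_dis"].str.endswith("with disability").to_numpy()
    route = rng.random(n) < 0.8  # most disability flows through employment status
    emp_draw = rng.integers(0, len(_EMPLOYED_CODES), size=n)
    employment = np.asarray(_EMPLOYED_CODES, dtype=object)[emp_draw]
    blindness = np.full(n, "no", dtype=object)
    employment[disabled & route] = UNABLE_TO_WORK
    blindness[disabled & ~route] = BLIND_LABEL

    return pd.DataFrame(
        {
            "age_years": age,
            "race_ethnicity": race_code,
            "hispanic": hispanic,
            "household_income_usd": income,
            "sex": sex,
            "marital_status": marital,
            "children_at_home": children,
            "employment_status": employment,
            "blindness": blindness,
            "residence": harm["residence"].str.lower().to_numpy(),
            "state": harm["state"].to_numpy(),
        }
    )


def generate_survey(spec: PopulationSpec) -> tuple[pd.DataFrame, TruthBundle]:
    """Generate the raw national survey plus its ground truth.

    Stream [rng_seed, 0]; draw order: covariates (see sample_covariates),
    state, raw-code de-harmonization, smoking status.
    """
    spec.validate()
    rng = np.random.default_rng([spec.rng_seed, 0])
    harm = sample_covariates(
        spec.category_marginals,
        spec.n_individuals,
        rng,
        spec.over65_80plus_fraction,
    )
    states, sp = spec.states_and_probs()
    idx = rng.choice(len(states), size=spec.n_individuals, p=sp)
    harm["state"] = np.asarray(states, dtype=object)[idx]
    harm["tax"] = harm["state"].map(spec.tax_by_state).astype(float)
    raw = _deharmonize(harm, rng)
    p = expit(spec.true_coefficients.linear_predictor(harm))
    raw["smokes"] = rng.binomial(1, p)
    truth = TruthBundle(
        true_coefficients=spec.true_coefficients,
        per_individual_probability=p,
    )
    return raw, truth


def _empirical_marginals(harm: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    n = len(harm)
    for cov, levels in COVARIATE_LEVELS.items():
        counts = harm[cov].value_counts()
        out[cov] = np.array([counts.get(lev, 0) / n for lev in levels])
    return out


def generate_phd_aggregates(
    spec: PopulationSpec,
) -> tuple[list[PHDRecord], TruthBundle]:
    """Generate PHD aggregate records whose marginals are exact empirical
    marginals of hidden individual rosters, plus realized true smoker counts.

    Stream [rng_seed, 1]; per PHD, draw order: size, state, county, lat/lon
    jitter, hidden covariates, smoking statuses.
    """
    spec.validate()
    rng = np.random.default_rng([spec.rng_seed, 1])
    lo, hi = spec.phd_size_range
    states, sp = spec.states_and_probs()
    phds: list[PHDRecord] = []
    truth = TruthBundle(
        true_coefficients=spec.true_coefficients,
        per_individual_probability=np.empty(0),
    )
    probs_all = []
    for k in range(spec.n_phds):
        size = int(rng.integers(lo, hi + 1))
        state = states[int(rng.choice(len(states), p=sp))]
        counties, lat0, lon0 = STATE_GEO.get(state, (["99999"], 40.0, -95.0))
        county = counties[int(rng.integers(0, len(counties)))]
        lat = lat0 + float(rng.normal(0, 0.15))
        lon = lon0 + float(rng.normal(0, 0.15))
        hidden = sample_covariates(
            spec.category_marginals, size, rng, spec.over65_80plus_fraction
        )
        hidden["state"] = state
        hidden["tax"] = float(spec.tax_by_state[state])
        p = expit(spec.true_coefficients.linear_predictor(hidden))
        smokes = rng.binomial(1, p)
        hidden["smokes"] = smokes
        phd_id = f"PHD{k + 1:04d}"
        phds.append(
            PHDRecord(
                phd_id=phd_id,
                name=f"Development {k + 1:04d}",
                state=state,
                county_fips=county,
                latitude=lat,
                longitude=lon,
                n_residents=size,
                marginals=_empirical_marginals(hidden),
            )
        )
        truth.true_smoker_count_by_phd[phd_id] = int(smokes.sum())
        truth.hidden_rosters[phd_id] = hidden
        probs_all.append(p)
    truth.per_individual_probability = np.concatenate(probs_all)
    return phds, truth


def write_truth_file(path, spec: PopulationSpec, truth: TruthBundle) -> int:
    """Key=value text dump of the ground truth; returns the line count."""
    lines = []
    series = spec.true_coefficients.to_series()
    for name, val in series.items():
        lines.append(f"coef[{name}]={val!r}")
    for cov, ref in spec.true_coefficients.reference_levels.items():
        lines.append(f"ref[{cov}]={ref}")
    for phd_id in sorted(truth.true_smoker_count_by_phd):
        lines.append(f"true_smokers[{phd_id}]={truth.true_smoker_count_by_phd[phd_id]}")
    Path(path).write_text("\n".join(lines) + "\n")
    return len(lines)


def read_truth_file(path) -> dict:
    """Parse the key=value truth file into coefficient/reference/count dicts."""
    out = {"coef": {}, "ref": {}, "true_smokers": {}}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, val = line.rsplit("=", 1)  # keys may themselves contain '='
        group, _, inner = key.partition("[")
        inner = inner[:-1] if inner.endswith("]") else inner
        if group == "coef":
            out["coef"][inner] = float(val)
        elif group == "ref":
            out["ref"][inner] = val
        elif group == "true_smokers":
            out["true_smokers"][inner] = int(val)
    return out


def write_fixture_bundle(directory, spec: PopulationSpec) -> dict:
    """Write survey, PHD, tax, economic-config and truth files; return a manifest."""
    from . import io as io_mod
    from .economics import default_economic_config, write_economic_config

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    raw, survey_truth = generate_survey(spec)
    phds, phd_truth = generate_phd_aggregates(spec)
    phd_truth.true_coefficients = spec.true_coefficients

    files = {}
    io_mod.write_survey_csv(directory / "survey.csv", raw)
    files["survey.csv"] = len(raw)
    io_mod.write_phd_csv(directory / "phds.csv", phds)
    files["phds.csv"] = len(phds)
    io_mod.write_tax_csv(directory / "tax.csv", spec.tax_by_state)
    files["tax.csv"] = len(spec.tax_by_state)
    cost_model, interventions = default_economic_config()
    write_economic_config(directory / "economics.yaml", cost_model, interventions)
    files["economics.yaml"] = len(interventions)
    files["truth.txt"] = write_truth_file(directory / "truth.txt", spec, phd_truth)
    return {"directory": str(directory), "files": files, "seed": spec.rng_seed}
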