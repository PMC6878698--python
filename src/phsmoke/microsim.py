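"""Small-area estimation of smoker counts per public housing development.

A development (PHD) is known only through aggregate marginals: its resident
count and, for each model covariate, the fraction of residents at each
level. The estimator (i) simulates an individual resident roster consistent
with those marginals, (ii) classifies each simulated resident with the
fitted, threshold-calibrated smoking model, and (iii) bootstrap-resamples
the roster (default 50 times, with replacement, roster size each time),
recording the classified smoker count of each resample. The estimate is the
mean of the bootstrap counts, with the bootstrap SD and a 2.5–97.5
percentile interval as uncertainty.

Covariates are sampled independently across marginals — the aggregate data
carry no joint structure — except that the stand-alone age bin is drawn
conditionally on the age side of the age/disability draw, so the two
age-bearing covariates never contradict each other. County-level figures
are sums of PHD-level means over the county's developments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import (
    COVARIATE_LEVELS,
    COVARIATE_ORDER,
    UNDER65_AGE_DIS,
    age_bin_conditional,
    validate_marginals,
)
from .errors import TaxLookupError, ValidationError


@dataclass
class PHDRecord:
    """One development's aggregate description."""

    phd_id: str
    name: str
    state: str
    county_fips: str
    latitude: float
    longitude: float
    n_residents: int
    #: covariate -> probability vector aligned with the closed level lists
    marginals: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_residents < 1:
            raise ValidationError(f"{self.phd_id}: n_residents must be >= 1")
        validate_marginals(self.marginals)


@dataclass
class SmokerEstimate:
    """Bootstrap-averaged smoker-count estimate for one PHD."""

    phd_id: str
    n_residents: int
    estimated_smokers_mean: float
    estimated_smokers_sd: float
    bootstrap_counts: np.ndarray
    percentile_interval: tuple[float, float]

    @property
    def estimated_proportion(self) -> float:
        return self.estimated_smokers_mean / self.n_residents


@dataclass
class CountyEstimate:
    """County roll-up: total estimated smokers among the county's PHD residents."""

    county_fips: str
    total_phd_residents: int
    estimated_smokers: float

    @property
    def estimated_proportion(self) -> float:
        return self.estimated_smokers / self.total_phd_residents


def sample_covariates(
    marginals: dict[str, np.ndarray],
    n: int,
    rng: np.random.Generator,
    over65_80plus_fraction: float | None = None,
) -> pd.DataFrame:
    """Draw n individuals' categorical covariates from marginal distributions.

    Independent draws per covariate, except age_bin which is drawn from the
    age marginal conditioned on the age/disability arm (see module docstring).
    Draw order is fixed: residence, race, income_bin, gen_ma_ch, age_dis,
    then age_bin — determinism depends on this order.
    """
    validate_marginals(marginals)
    out = {}
    for cov in ("residence", "race", "income_bin", "gen_ma_ch", "age_dis"):
        levels = COVARIATE_LEVELS[cov]
        p = np.asarray(marginals[cov], dtype=float)
        idx = rng.choice(len(levels), size=n, p=p / p.sum())
        out[cov] = np.asarray(levels, dtype=object)[idx]
    age_dis = out["age_dis"]
    age_bin = np.empty(n, dtype=object)
    under = np.isin(age_dis, list(UNDER65_AGE_DIS))
    for arm_mask, arm_level in ((under, "Age <65 no disability"), (~under, "Age >65 no disability")):
        k = int(arm_mask.sum())
        if k == 0:
            continue
        allowed, probs = age_bin_conditional(
            arm_level, marginals["age_bin"], over65_80plus_fraction
        )
        idx = rng.choice(len(allowed), size=k, p=probs)
        age_bin[arm_mask] = np.asarray(allowed, dtype=object)[idx]
    out["age_bin"] = age_bin
    return pd.DataFrame({cov: out[cov] for cov in COVARIATE_ORDER})


def simulate_residents(
    phd: PHDRecord,
    tax_table: dict[str, float],
    rng: np.random.Generator,
    over65_80plus_fraction: float | None = None,
) -> pd.DataFrame:
    """Simulate an individual resident roster consistent with the PHD's marginals."""
    phd.validate()
    if phd.state not in tax_table:
        raise TaxLookupError(f"state {phd.state!r} of {phd.phd_id} missing from tax table")
    roster = sample_covariates(
        phd.marginals, phd.n_residents, rng, over65_80plus_fraction
    )
    roster["state"] = phd.state
    roster["tax"] = float(tax_table[phd.state])
    return roster


def estimate_phd_smokers(
    phd: PHDRecord,
    results,
    tax_table: dict[str, float],
    n_boot: int = 50,
    rng: np.random.Generator | None = None,
    *,
    roster_mode: str = "resample",
    count_mode: str = "classify",
    over65_80plus_fraction: float | None = None,
) -> SmokerEstimate:
    """Bootstrap smoker-count estimate for one PHD.

    ``roster_mode="resample"`` (default) simulates one roster and resamples
    it with replacement n_boot times; ``"redraw"`` draws n_boot independent
    rosters from the marginals instead. ``count_mode="classify"`` counts
    residents whose predicted probability clears the calibrated threshold;
    ``"probability"`` sums predicted probabilities (soft counts).
    """
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if roster_mode not in ("resample", "redraw"):
        raise ValidationError("roster_mode must be 'resample' or 'redraw'")
    if count_mode not in ("classify", "probability"):
        raise ValidationError("count_mode must be 'classify' or 'probability'")
    rng = np.random.default_rng() if rng is None else rng
    n = phd.n_residents

    def _scores(roster: pd.DataFrame) -> np.ndarray:
        if count_mode == "classify":
            return results.classify(roster).astype(float)
        return results.predict_proba(roster)

    counts = np.empty(n_boot, dtype=float)
    if roster_mode == "resample":
        roster = simulate_residents(phd, tax_table, rng, over65_80plus_fraction)
        per_resident = _scores(roster)
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            counts[b] = per_resident[idx].sum()
    else:
        for b in range(n_boot):
            roster = simulate_residents(phd, tax_table, rng, over65_80plus_fraction)
            counts[b] = _scores(roster).sum()
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if n_boot > 1 else 0.0
    lo, hi = np.percentile(counts, [2.5, 97.5])
    return SmokerEstimate(
        phd_id=phd.phd_id,
        n_residents=n,
        estimated_smokers_mean=mean,
        estimated_smokers_sd=sd,
        bootstrap_counts=counts,
        percentile_interval=(float(lo), float(hi)),
    )


def aggregate_to_county(
    estimates: list[SmokerEstimate], phds: list[PHDRecord]
) -> list[CountyEstimate]:
    """Roll PHD estimates up to counties (sorted by FIPS); conserves totals."""
    county_of = {p.phd_id: p.county_fips for p in phds}
    orphans = [e.phd_id for e in estimates if e.phd_id not in county_of]
    if orphans:
        raise ValidationError(f"estimate(s) with no matching PHD record: {orphans}")
    residents: dict[str, int] = {}
    smokers: dict[str, float] = {}
    for e in estimates:
        fips = county_of[e.phd_id]
        residents[fips] = residents.get(fips, 0) + e.n_residents
        smokers[fips] = smokers.get(fips, 0.0) + e.estimated_smokers_mean
    return [
        CountyEstimate(fips, residents[fips], smokers[fips])
        for fips in sorted(residents)
    ]
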