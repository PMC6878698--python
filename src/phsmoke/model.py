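"""Logistic smoking-status model with prevalence-matched threshold calibration.

The model is an ordinary logistic regression of individual cigarette-smoking
status on the state excise tax and the six categorical covariates of the
harmonized scheme:

    logit P(smokes) = b0 + b_tax * tax + sum_j b_j * 1[level_j]

Because the model is used as a classifier inside the small-area estimator,
the decision threshold is not 0.5 but is calibrated so that the fraction of
a national reference sample classified as smokers matches an external
prevalence target (roughly one third of public-housing adults smoke). The
calibration searches the finite set of observed scores exactly, with the
>= convention at the boundary; it can operate on the probability scale
(default) or on the log-odds scale.

Fitting is maximum likelihood via :class:`statsmodels.api.Logit`; Wald
standard errors and p-values come from the same fit. Collinearity is
diagnosed up front (rank check naming the offending columns, condition
number reported) rather than silently dropping columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit as logit_fn
from scipy.stats import rankdata

from .categories import COVARIATE_LEVELS, COVARIATE_ORDER, DEFAULT_REFERENCE_LEVELS
from .errors import (
    CalibrationError,
    FittingError,
    PredictionError,
    StateError,
    ValidationError,
)
from .harmonize import DesignMatrix, build_design_matrix, design_columns


@dataclass
class ModelCoefficients:
    """Coefficient vector on the named-level scale.

    ``level_coefficients`` maps ``(covariate, non-reference level)`` to its
    log-odds coefficient; reference levels carry an implicit zero.
    """

    intercept: float
    tax_slope: float
    level_coefficients: dict[tuple[str, str], float]
    reference_levels: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_LEVELS)
    )

    def to_series(self) -> pd.Series:
        """Flatten to the design-matrix column order."""
        cols = design_columns(self.reference_levels)
        values = {"const": self.intercept, "tax": self.tax_slope}
        for (cov, lev), beta in self.level_coefficients.items():
            name = f"{cov}[T.{lev}]"
            if name not in cols:
                raise ValidationError(
                    f"coefficient for {(cov, lev)} does not match the design "
                    f"(reference levels {self.reference_levels})"
                )
            values[name] = float(beta)
        missing = [c for c in cols if c not in values]
        if missing:
            raise ValidationError(f"coefficients missing design column(s) {missing}")
        return pd.Series([values[c] for c in cols], index=cols, dtype=float)

    @classmethod
    def from_series(
        cls, series: pd.Series, reference_levels: dict[str, str]
    ) -> "ModelCoefficients":
        levels = {}
        for name, val in series.items():
            if name in ("const", "tax"):
                continue
            cov, lev = name.split("[T.", 1)
            levels[(cov, lev.rstrip("]"))] = float(val)
        return cls(
            intercept=float(series["const"]),
            tax_slope=float(series["tax"]),
            level_coefficients=levels,
            reference_levels=dict(reference_levels),
        )

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        """b0 + b_tax * tax + dummy terms, for harmonized records."""
        design = build_design_matrix(records, self.reference_levels)
        return design.X.to_numpy() @ self.to_series().to_numpy()


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name a minimal set of columns that complete a dependency
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
        raise FittingError(
            f"design matrix is rank deficient (rank {rank} < {arr.shape[1]}); "
            f"collinear column(s): {bad}"
        )


class SmokingModel:
    """Logistic model of smoking status, built from harmonized records.

    Parameters
    ----------
    design : DesignMatrix
        Dummy-coded design with the 0/1 smoking outcome attached.
    """

    def __init__(self, design: DesignMatrix):
        if design.y is None:
            raise ValidationError("design matrix has no outcome; cannot build a model")
        self.design = design

    @classmethod
    def from_dataframe(
        cls,
        records: pd.DataFrame,
        reference_levels: dict[str, str] | None = None,
    ) -> "SmokingModel":
        """Build from a harmonized DataFrame carrying a ``smokes`` column."""
        design = build_design_matrix(records, reference_levels, require_outcome=True)
        return cls(design)

    def fit(self, *, maxiter: int = 100) -> "SmokingModelResults":
        """Maximum-likelihood fit with Wald standard errors.

        Raises :class:`FittingError` on a single-class outcome, perfect
        separation, rank deficiency, or non-convergence.
        """
        y = self.design.y.to_numpy()
        classes = np.unique(y)
        if classes.size < 2:
            raise FittingError(
                f"outcome has a single class ({classes.tolist()}); perfect separation"
            )
        X = self.design.X
        constant = [
            c for c in X.columns if c != "const" and X[c].nunique(dropna=False) == 1
        ]
        if constant:
            raise FittingError(f"column(s) constant across all rows: {constant}")
        _check_rank(X)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=maxiter)
        except Exception as exc:  # statsmodels raises several separation/LA errors
            raise FittingError(f"logistic fit failed: {exc}") from exc
        if not res.mle_retvals.get("converged", False):
            raise FittingError("logistic fit did not converge")
        if not np.all(np.isfinite(res.bse)):
            raise FittingError("non-finite standard errors (quasi-separation)")
        return SmokingModelResults(self, res)


class SmokingModelResults:
    """Fitted smoking model: estimates, Wald inference, threshold, prediction.

    Attributes
    ----------
    params, bse, pvalues : pandas.Series indexed by design column.
    threshold : float or None — classification cut-off, unset until
        :meth:`calibrate_threshold` or :meth:`set_threshold` is called.
    threshold_scale : "probability" or "log_odds".
    """

    def __init__(self, model: SmokingModel, smres=None, *, params=None, bse=None,
                 pvalues=None, n_train=None, converged=True, cond_number=None):
        self.model = model
        if smres is not None:
            self.params = pd.Series(smres.params, index=model.design.X.columns)
            self.bse = pd.Series(smres.bse, index=model.design.X.columns)
            self.pvalues = pd.Series(smres.pvalues, index=model.design.X.columns)
            self.n_train = int(smres.nobs)
            self.converged = bool(smres.mle_retvals.get("converged", True))
            self.cond_number = float(np.linalg.cond(model.design.X.to_numpy()))
            self.llf = float(smres.llf)
        else:
            self.params, self.bse, self.pvalues = params, bse, pvalues
            self.n_train = n_train
            self.converged = converged
            self.cond_number = cond_number
            self.llf = float("nan")
        self.reference_levels = dict(
            model.design.reference_levels if model is not None else {}
        )
        self.threshold: float | None = None
        self.threshold_scale: str = "probability"

    @classmethod
    def from_coefficients(
        cls, coefs: ModelCoefficients, threshold: float | None = None
    ) -> "SmokingModelResults":
        """Results object with externally supplied coefficients (no fit).

        Standard errors and p-values are NaN; useful for scoring a known
        coefficient vector (e.g. a synthetic ground truth).
        """
        series = coefs.to_series()
        obj = cls.__new__(cls)
        obj.model = None
        obj.params = series
        obj.bse = pd.Series(np.nan, index=series.index)
        obj.pvalues = pd.Series(np.nan, index=series.index)
        obj.reference_levels = dict(coefs.reference_levels)
        obj.threshold = threshold
        obj.threshold_scale = "probability"
        obj.n_train = 0
        obj.converged = True
        obj.cond_number = float("nan")
        obj.llf = float("nan")
        return obj

    # -- coefficients ------------------------------------------------------
    @property
    def coefficients(self) -> ModelCoefficients:
        return ModelCoefficients.from_series(self.params, self.reference_levels)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Wald confidence intervals, one row per coefficient."""
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    # -- prediction --------------------------------------------------------
    def _design_for(self, records: pd.DataFrame) -> pd.DataFrame:
        try:
            design = build_design_matrix(records, self.reference_levels)
        except ValidationError as exc:
            raise PredictionError(str(exc)) from exc
        return design.X[self.params.index]

    def linear_predictor(self, records: pd.DataFrame) -> np.ndarray:
        return self._design_for(records).to_numpy() @ self.params.to_numpy()

    def predict_proba(self, records: pd.DataFrame) -> np.ndarray:
        """P(smokes) per record; strictly inside (0, 1)."""
        p = expit(self.linear_predictor(records))
        eps = np.finfo(float).tiny
        return np.clip(p, eps, 1 - eps)

    # -- threshold ---------------------------------------------------------
    def set_threshold(self, threshold: float, scale: str = "probability") -> None:
        """Fix the classification threshold (e.g. the conventional 0.33)."""
        if scale == "probability" and not (0.0 < threshold < 1.0):
            raise ValidationError("probability threshold must lie in (0, 1)")
        if scale not in ("probability", "log_odds"):
            raise ValidationError("scale must be 'probability' or 'log_odds'")
        self.threshold = float(threshold)
        self.threshold_scale = scale

    def calibrate_threshold(
        self,
        records: pd.DataFrame,
        target_prevalence: float,
        tolerance: float | None = None,
        scale: str = "probability",
    ) -> float:
        """Choose the cut-off whose classified prevalence best matches the target.

        Searches the finite set of observed scores; the fraction of records
        with score >= t is matched to ``target_prevalence`` as closely as
        possible, ties broken toward the larger t. With ``tolerance`` set, a
        best-achievable gap above it raises :class:`CalibrationError`.
        """
        if not (0.0 < target_prevalence <= 1.0):
            raise ValidationError("target_prevalence must lie in (0, 1]")
        scores = self.predict_proba(records)
        if scale == "log_odds":
            scores = logit_fn(scores)
        elif scale != "probability":
            raise ValidationError("scale must be 'probability' or 'log_odds'")
        t = calibrate_threshold_values(scores, target_prevalence, tolerance)
        self.threshold = float(t)
        self.threshold_scale = scale
        return self.threshold

    def classify(self, records: pd.DataFrame) -> np.ndarray:
        """0/1 classification: 1 iff score >= threshold (>= convention)."""
        if self.threshold is None:
            raise StateError("threshold unset; calibrate or set it before classify()")
        if self.threshold_scale == "log_odds":
            scores = self.linear_predictor(records)
        else:
            scores = self.predict_proba(records)
        return (scores >= self.threshold).astype(int)

    # -- reporting / persistence ------------------------------------------
    def summary(self) -> str:
        """Plain-text coefficient table with Wald inference and threshold."""
        ci = self.conf_int()
        lines = [
            "Logistic smoking-status model",
            f"n_train = {self.n_train}   converged = {self.converged}   "
            f"cond(X) = {self.cond_number:.1f}",
            f"threshold = {self.threshold}   scale = {self.threshold_scale}",
            "-" * 78,
            f"{'term':<48}{'coef':>9}{'se':>8}{'p':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<48}{self.params[name]:>9.4f}{self.bse[name]:>8.4f}"
                f"{self.pvalues[name]:>10.2e}"
            )
        lines.append("-" * 78)
        lines.append(
            "reference levels: "
            + ", ".join(f"{c}={self.reference_levels[c]}" for c in COVARIATE_ORDER)
        )
        return "\n".join(lines)

    def save(self, path) -> None:
        """Serialize to a human-readable JSON file."""
        doc = {
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "pvalues": {k: float(v) for k, v in self.pvalues.items()},
            "reference_levels": self.reference_levels,
            "threshold": self.threshold,
            "threshold_scale": self.threshold_scale,
            "n_train": self.n_train,
            "cond_number": self.cond_number,
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path) -> "SmokingModelResults":
        doc = json.loads(Path(path).read_text())
        cols = design_columns(doc["reference_levels"])
        obj = cls.__new__(cls)
        obj.model = None
        obj.params = pd.Series({c: doc["params"][c] for c in cols})
        obj.bse = pd.Series({c: doc["bse"][c] for c in cols})
        obj.pvalues = pd.Series({c: doc["pvalues"][c] for c in cols})
        obj.reference_levels = dict(doc["reference_levels"])
        obj.threshold = doc["threshold"]
        obj.threshold_scale = doc["threshold_scale"]
        obj.n_train = doc["n_train"]
        obj.converged = True
        obj.cond_number = doc["cond_number"]
        obj.llf = float("nan")
        return obj


def calibrate_threshold_values(
    scores: np.ndarray, target_prevalence: float, tolerance: float | None = None
) -> float:
    """Exact threshold search over the observed score set.

    Returns the observed score t minimizing |mean(scores >= t) − target|,
    ties broken toward the larger t. The classified prevalence at the
    returned t is then within 1/n of the best attainable match.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n == 0:
        raise ValidationError("no scores to calibrate on")
    uniq = np.unique(scores)  # ascending
    # fraction >= uniq[i]: count of scores >= that value
    counts = n - np.searchsorted(np.sort(scores), uniq, side="left")
    frac = counts / n
    gaps = np.abs(frac - target_prevalence)
    best = gaps.min()
    if uniq.size == 1 and best > 1e-12:
        raise CalibrationError(
            f"all scores equal ({uniq[0]:.6g}); attainable prevalence set is {{1.0}}, "
            f"target {target_prevalence} unreachable"
        )
    if tolerance is not None and best > tolerance:
        raise CalibrationError(
            f"best attainable |prevalence − target| is {best:.4g} > tolerance {tolerance}"
        )
    # ties toward the larger threshold
    idx = np.flatnonzero(gaps == best).max()
    return float(uniq[idx])


def compute_auc(scores, labels) -> float:
    """ROC AUC via the Mann–Whitney U statistic; ties contribute 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have the same length")
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)  # midranks handle ties
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class CVReport:
    """Aggregate of repeated random-split cross-validation."""

    n_repeats: int
    train_fraction: float
    auc_mean: float
    auc_sd: float
    false_positive_rate_mean: float
    sensitivity_mean: float
    specificity_mean: float
    n_redrawn_splits: int = 0
    per_repeat: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_repeats": [self.n_repeats],
                "train_fraction": [self.train_fraction],
                "auc_mean": [self.auc_mean],
                "auc_sd": [self.auc_sd],
                "false_positive_rate_mean": [self.false_positive_rate_mean],
                "sensitivity_mean": [self.sensitivity_mean],
                "specificity_mean": [self.specificity_mean],
                "n_redrawn_splits": [self.n_redrawn_splits],
            }
        )


def cross_validate(
    records: pd.DataFrame,
    train_fraction: float = 0.75,
    repeats: int = 100,
    seed: int | None = None,
    *,
    target_prevalence: float = 0.33,
    fixed_threshold: float | None = None,
    stratified: bool = False,
    reference_levels: dict[str, str] | None = None,
) -> CVReport:
    """Repeated random-split validation of the smoking model.

    Per repeat: split the harmonized records (default 75% train / 25% test),
    fit on the train split, calibrate the threshold on the train split
    (or apply ``fixed_threshold``), then score AUC and threshold-based
    confusion rates on the test split. A split missing a class in either
    part is redrawn and counted. ``train_fraction == 1`` makes the test
    split the training data (in-sample metrics).
    """
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    if not (0.0 < train_fraction <= 1.0):
        raise ValidationError("train_fraction must lie in (0, 1]")
    if records["smokes"].nunique() < 2:
        raise ValidationError("need both smoking classes to cross-validate")
    rng = np.random.default_rng(seed)
    n = len(records)
    n_train = int(round(train_fraction * n)) if train_fraction < 1.0 else n
    y_all = records["smokes"].to_numpy()
    rows = []
    redrawn = 0
    for _ in range(repeats):
        for _attempt in range(100):
            if train_fraction >= 1.0:
                train_idx = np.arange(n)
                test_idx = np.arange(n)
            elif stratified:
                train_parts = []
                for cls in (0, 1):
                    cls_idx = np.flatnonzero(y_all == cls)
                    k = int(round(train_fraction * cls_idx.size))
                    train_parts.append(rng.permutation(cls_idx)[:k])
                train_idx = np.sort(np.concatenate(train_parts))
                test_idx = np.setdiff1d(np.arange(n), train_idx)
            else:
                perm = rng.permutation(n)
                train_idx, test_idx = perm[:n_train], perm[n_train:]
            if (
                np.unique(y_all[train_idx]).size == 2
                and np.unique(y_all[test_idx]).size == 2
            ):
                break
            redrawn += 1
        train = records.iloc[train_idx]
        test = records.iloc[test_idx]
        res = SmokingModel.from_dataframe(train, reference_levels).fit()
        if fixed_threshold is not None:
            res.set_threshold(fixed_threshold)
        else:
            res.calibrate_threshold(train, target_prevalence)
        p_test = res.predict_proba(test)
        y_test = test["smokes"].to_numpy()
        yhat = (p_test >= res.threshold).astype(int)
        tp = int(((yhat == 1) & (y_test == 1)).sum())
        fp = int(((yhat == 1) & (y_test == 0)).sum())
        tn = int(((yhat == 0) & (y_test == 0)).sum())
        fn = int(((yhat == 0) & (y_test == 1)).sum())
        rows.append(
            {
                "auc": compute_auc(p_test, y_test),
                "sensitivity": tp / (tp + fn),
                "specificity": tn / (tn + fp),
                "false_positive_rate": fp / (fp + tn),
            }
        )
    per = pd.DataFrame(rows)
    return CVReport(
        n_repeats=repeats,
        train_fraction=train_fraction,
        auc_mean=float(per["auc"].mean()),
        auc_sd=float(per["auc"].std(ddof=1)) if repeats > 1 else 0.0,
        false_positive_rate_mean=float(per["false_positive_rate"].mean()),
        sensitivity_mean=float(per["sensitivity"].mean()),
        specificity_mean=float(per["specificity"].mean()),
        n_redrawn_splits=redrawn,
        per_repeat=per,
    )
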