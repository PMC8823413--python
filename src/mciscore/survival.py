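"""Cox proportional-hazards fitting and Kaplan–Meier survival estimation.

The Cox fit is backed by statsmodels ``PHReg`` (Efron tie correction by
default, Breslow available — ties are guaranteed here by the 6-month visit
grid); the product-limit estimator is backed by lifelines.  Both are wrapped
in light containers that carry exactly what downstream point-scoring needs:
coefficients, standard errors, covariate means, and a baseline survival
step function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .cohort import SurvivalRecord
from .exceptions import ConvergenceError, DegenerateCovariateError, InputError

__all__ = ["CoxModel", "SurvivalCurve", "fit_cox", "univariate_screen", "km_survival"]

#: Coefficients beyond this magnitude are treated as monotone-likelihood
#: divergence (perfect separation) and capped with a warning.
BETA_CAP = 20.0


@dataclass
class CoxModel:
    """A fitted Cox proportional-hazards model.

    ``means`` holds the arithmetic mean of each covariate over the fitting
    cohort (the proportion, for 0/1 covariates); the point system's
    absolute-risk map centres its linear predictor there.
    """

    covariates: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    means: np.ndarray
    loglik: float
    ties: str
    n: int
    n_events: int
    converged: bool = True

    def __post_init__(self):
        k = len(self.covariates)
        if not (len(self.coef) == len(self.se) == len(self.means) == k):
            raise InputError("coef, se and means must align with covariate names")

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    def p_values(self) -> np.ndarray:
        z = self.coef / self.se
        return 2 * stats.norm.sf(np.abs(z))

    def confidence_intervals(self, alpha: float = 0.05) -> np.ndarray:
        """Hazard-ratio CI, one (low, high) row per covariate."""
        z = stats.norm.ppf(1 - alpha / 2)
        return np.exp(np.column_stack([self.coef - z * self.se, self.coef + z * self.se]))

    def beta(self, name: str) -> float:
        return float(self.coef[self.covariates.index(name)])

    def mean(self, name: str) -> float:
        return float(self.means[self.covariates.index(name)])

    def linear_predictor(self, values: dict[str, float], centered: bool = True) -> float:
        """Σ βᵢ·(xᵢ − Mᵢ) over the model covariates (or uncentred Σ βᵢ·xᵢ)."""
        x = np.array([values[c] for c in self.covariates], dtype=float)
        if centered:
            x = x - self.means
        return float(self.coef @ x)

    def summary(self) -> pd.DataFrame:
        ci = self.confidence_intervals()
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coef,
                "se": self.se,
                "hr": self.hazard_ratios,
                "hr_ci_low": ci[:, 0],
                "hr_ci_high": ci[:, 1],
                "p": self.p_values(),
                "mean": self.means,
            }
        )


@dataclass
class SurvivalCurve:
    """Kaplan–Meier product-limit curve as a right-continuous step function."""

    times: np.ndarray  # distinct event times, increasing
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray
    events: np.ndarray
    last_observed: float | None = None  # end of follow-up incl. censorings

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if np.any(np.diff(self.survival) > 1e-12):
            raise InputError("survival function must be non-increasing")

    def survival_at(self, t) -> float | np.ndarray:
        """S(t): 1 before the first event, stepping down at each event time."""
        if self.times.size == 0:
            return 1.0 if np.isscalar(t) else np.ones_like(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right") - 1
        s = np.where(idx < 0, 1.0, self.survival[np.clip(idx, 0, None)])
        return float(s) if np.isscalar(t) else s

    @property
    def max_time(self) -> float:
        if self.last_observed is not None:
            return float(self.last_observed)
        return float(self.times[-1]) if self.times.size else 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "survival": self.survival,
             "at_risk": self.at_risk, "events": self.events}
        )


def _design(records: list[SurvivalRecord], covariates: tuple[str, ...]):
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=float)
    try:
        X = np.array([[float(r.covariates[c]) for c in covariates] for r in records])
    except KeyError as err:
        raise InputError(f"record missing covariate {err.args[0]!r}") from None
    if np.isnan(X).any():
        raise InputError("missing covariate values; complete-case records required for fitting")
    return time, event, X


def fit_cox(
    records: list[SurvivalRecord],
    covariates: list[str],
    ties: str = "efron",
    forced: tuple[str, ...] = (),
) -> CoxModel:
    """Maximise the Cox partial likelihood over the given covariates.

    ``forced`` covariates are prepended to the list if absent (used to keep
    age in every multivariable model regardless of screening).  Requires at
    least two events; zero-variance covariates are rejected up front, and
    coefficients escaping past ``BETA_CAP`` (monotone likelihood under
    perfect separation) are capped with a warning.
    """
    names = tuple(list(forced) + [c for c in covariates if c not in forced])
    time, event, X = _design(records, names)
    if event.sum() < 2:
        raise InputError(f"need at least 2 events to fit, got {int(event.sum())}")
    sd = X.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            raise DegenerateCovariateError(f"covariate {names[j]!r} has zero variance")
    if ties not in ("efron", "breslow"):
        raise InputError(f"ties must be 'efron' or 'breslow', got {ties!r}")

    # fit on standardized covariates for conditioning; the partial likelihood
    # is invariant under the affine reparameterization, so rescale back after
    mu = X.mean(axis=0)
    Xs = (X - mu) / sd
    model_s = PHReg(time, Xs, status=event, ties=ties)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # BFGS first (robust to the flat/ill-conditioned starts on which
            # plain Newton diverges), then a Newton polish from its optimum
            # for sharp convergence
            res = model_s.fit(method="bfgs", maxiter=500, disp=False)
            try:
                polished = model_s.fit(method="newton", start_params=res.params,
                                       maxiter=100, disp=False)
                if model_s.loglike(polished.params) >= model_s.loglike(res.params):
                    res = polished
            except np.linalg.LinAlgError:
                pass
    except Exception as err:
        raise ConvergenceError(f"Cox fit failed: {err}") from err
    coef = np.asarray(res.params, dtype=float) / sd
    se = np.asarray(res.bse, dtype=float) / sd
    model = PHReg(time, X - mu, status=event, ties=ties)  # for the loglik value
    if not np.all(np.isfinite(coef)):
        raise ConvergenceError("Cox fit produced non-finite coefficients")
    # monotone likelihood (perfect separation) shows up as an absurd effect
    # or standard error on the standardized scale
    diverged = (np.abs(coef * sd) > 10) | (se * sd > 10) | (np.abs(coef) > BETA_CAP)
    if np.any(diverged):
        warnings.warn(
            "coefficient diverging (monotone partial likelihood, e.g. perfect "
            f"separation) for {[names[j] for j in np.flatnonzero(diverged)]}; "
            f"capping |beta| at {BETA_CAP}",
            stacklevel=2,
        )
        coef = np.clip(coef, -BETA_CAP, BETA_CAP)
    return CoxModel(
        covariates=names,
        coef=coef,
        se=se,
        means=X.mean(axis=0),
        loglik=float(model.loglike(coef)),
        ties=ties,
        n=len(records),
        n_events=int(event.sum()),
    )


def univariate_screen(
    records: list[SurvivalRecord],
    covariates: list[str],
    ties: str = "efron",
) -> pd.DataFrame:
    """One single-covariate Cox fit per factor, order preserved.

    Per-factor fit failures do not abort the screen; the offending row
    carries NaNs and the error message.
    """
    rows = []
    for name in covariates:
        try:
            m = fit_cox(records, [name], ties=ties)
            s = m.summary().iloc[0].to_dict()
            s["error"] = ""
        except Exception as err:
            s = {"covariate": name, "coef": np.nan, "se": np.nan, "hr": np.nan,
                 "hr_ci_low": np.nan, "hr_ci_high": np.nan, "p": np.nan,
                 "mean": np.nan, "error": str(err)}
        rows.append(s)
    return pd.DataFrame(rows)


def km_survival(records: list[SurvivalRecord]) -> SurvivalCurve:
    """Kaplan–Meier product-limit estimate of the overall survival function.

    Subjects censored at t leave the risk set after the events at t.  With
    no events the curve is identically 1 (with a warning).
    """
    if not records:
        raise InputError("need at least one record")
    time = np.array([r.time for r in records], dtype=float)
    event = np.array([r.event for r in records], dtype=bool)
    if not event.any():
        warnings.warn("no events observed; survival is 1 everywhere", stacklevel=2)
        return SurvivalCurve(np.array([]), np.array([]), np.array([]), np.array([]),
                             last_observed=float(time.max()))
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    table = kmf.event_table
    mask = table["observed"] > 0
    times = table.index.to_numpy(dtype=float)[mask]
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(dtype=float)
    return SurvivalCurve(
        times=times,
        survival=surv,
        at_risk=table.loc[mask, "at_risk"].to_numpy(dtype=float),
        events=table.loc[mask, "observed"].to_numpy(dtype=float),
        last_observed=float(time.max()),
    )
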