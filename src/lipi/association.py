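"""Per-feature infection-risk estimation and explanatory-model selection.

Risk is summarized as a risk ratio (RR) with a log-scale Wald 95% CI.  The
default regression link is log-binomial (coefficients exponentiate to RRs
per unit); when the log-binomial fit does not converge — common with
continuous covariates — the modified-Poisson estimator (Poisson working
model with a robust sandwich variance) is used instead, which targets the
same RR.  Logistic regression (odds ratios) is available behind the
``link`` flag; all three preserve the effect direction and magnitude
ranking the scoring stage needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2, norm

from .cohort import Cohort
from .errors import (DegenerateDataError, NonConvergenceError,
                     UndefinedEstimateError, ValidationError)

#: Absolute standardized-coefficient bound beyond which a fit is treated as
#: separated / divergent.
_SEPARATION_BOUND = 15.0


@dataclass(frozen=True)
class RiskEstimate:
    """Risk (or odds) ratio for one feature with Wald 95% CI and p-value."""

    feature: str
    rr: float
    ci_low: float
    ci_high: float
    p: float
    dataset: str = "baseline"          # "baseline" | "nested"
    scale: str = "per-unit"            # "per-unit" | "binary"
    measure: str = "rr"                # "rr" | "or"

    def __post_init__(self):
        if not (self.ci_low <= self.rr <= self.ci_high):
            raise ValidationError(
                f"{self.feature}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket estimate {self.rr}")
        if not (0 <= self.p <= 1):
            raise ValidationError(f"{self.feature}: p={self.p} outside [0, 1]")

    @property
    def magnitude(self) -> float:
        """Effect magnitude max(rr, 1/rr); direction-free ranking key."""
        return max(self.rr, 1.0 / self.rr)


@dataclass
class ModelFit:
    """A fitted risk model: log-likelihood, AIC, and per-feature estimates."""

    features: tuple[str, ...]
    loglik: float
    k: int
    estimates: list[RiskEstimate] = field(default_factory=list)
    link: str = "log-binomial"

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.loglik


def rr_from_2x2(exposed: tuple[int, int], unexposed: tuple[int, int],
                alpha: float = 0.05, continuity: bool = False,
                feature: str = "exposure", dataset: str = "baseline",
                ) -> RiskEstimate:
    """Risk ratio from a 2x2 table of (events, total) per arm.

    The CI is the log-scale Wald interval
    exp(ln RR +/- z * sqrt(1/a - 1/n1 + 1/c - 1/n0)).  Zero event cells are
    undefined unless ``continuity=True`` adds 0.5 to all four cells.
    """
    a, n1 = exposed
    c, n0 = unexposed
    if n1 <= 0 or n0 <= 0 or a > n1 or c > n0 or a < 0 or c < 0:
        raise ValidationError("invalid 2x2 counts")
    b, d = n1 - a, n0 - c
    if continuity and (a == 0 or c == 0 or b == 0 or d == 0):
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        n1, n0 = a + b, c + d
    if a == 0 or c == 0:
        raise UndefinedEstimateError(
            "zero event cell; enable continuity correction for a finite RR")
    rr = (a / n1) / (c / n0)
    se = np.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    z = norm.ppf(1 - alpha / 2)
    log_rr = np.log(rr)
    p = 2 * norm.sf(abs(log_rr) / se) if se > 0 else 1.0
    return RiskEstimate(feature=feature, rr=float(rr),
                        ci_low=float(np.exp(log_rr - z * se)),
                        ci_high=float(np.exp(log_rr + z * se)),
                        p=float(min(p, 1.0)), dataset=dataset, scale="binary")


def _glm_fit(X: np.ndarray, y: np.ndarray, link: str):
    """Fit one GLM; returns (params, cov, llf) on the given design."""
    if link == "log-binomial":
        start = np.zeros(X.shape[1])
        start[0] = np.log(max(y.mean(), 1e-6))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GLM(y, X,
                           family=sm.families.Binomial(sm.families.links.Log()))
            res = model.fit(start_params=start, maxiter=200)
        mu = res.mu
        if not res.converged or np.any(~np.isfinite(res.params)) or np.any(mu >= 1.0):
            raise NonConvergenceError("log-binomial fit did not converge")
        return res.params, res.cov_params(), float(res.llf)
    if link == "modified-poisson":
        model = sm.GLM(y, X, family=sm.families.Poisson())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(cov_type="HC0", maxiter=200)
        if not res.converged or np.any(~np.isfinite(res.params)):
            raise NonConvergenceError("modified-Poisson fit did not converge")
        return res.params, res.cov_params(), float(res.llf)
    if link == "logistic":
        model = sm.GLM(y, X, family=sm.families.Binomial())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
        if not res.converged or np.any(~np.isfinite(res.params)):
            raise NonConvergenceError("logistic fit did not converge")
        return res.params, res.cov_params(), float(res.llf)
    raise ValueError(f"unknown link {link!r}")


def fit_risk_model(X: pd.DataFrame, y, link: str = "log-binomial",
                   fallback: bool = True, alpha: float = 0.05,
                   dataset: str = "baseline") -> ModelFit:
    """Fit a risk model of a binary outcome on the columns of ``X``.

    Continuous covariates are standardized internally for numerical
    stability and the coefficients mapped back to per-unit scale (an affine
    recoding; the likelihood is unchanged).  With the default link, a
    non-converging log-binomial fit falls back to modified Poisson unless
    ``fallback=False``.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise DegenerateDataError("outcome is constant")
    mask = ~(X.isna().any(axis=1).to_numpy() | np.isnan(y))
    X, y = X.loc[mask], y[mask]
    n, p = X.shape
    if n <= p + 1:
        raise DegenerateDataError(f"n={n} too small for {p} covariates")

    scales = np.ones(p)
    for j, col in enumerate(X.columns):
        sd = X[col].std()
        uniq = X[col].nunique()
        if uniq < 2:
            raise NonConvergenceError(f"covariate {col!r} is constant",
                                      feature=str(col))
        if uniq > 2 and sd > 0:
            scales[j] = sd
    design = sm.add_constant(X.to_numpy() / scales, prepend=True)

    used_link = link
    try:
        params, cov, llf = _glm_fit(design, y, link)
    except (NonConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
        if link == "log-binomial" and fallback:
            params, cov, llf = _glm_fit(design, y, "modified-poisson")
            used_link = "modified-poisson"
        else:
            raise NonConvergenceError(str(exc)) from exc

    se_std = np.sqrt(np.diag(np.asarray(cov)))
    for j, col in enumerate(X.columns):
        if abs(params[j + 1]) > _SEPARATION_BOUND:
            raise NonConvergenceError(
                f"separation detected for covariate {col!r}", feature=str(col))

    # Per-feature p: likelihood-ratio (drop-one refit), which stays calibrated
    # for heavily skewed covariates where the Wald statistic is
    # anti-conservative.  The robust-Poisson fallback has no true likelihood
    # and its fits condition on exactly the samples where log-binomial
    # inference breaks down, so its p comes from the logistic LRT (same null
    # hypothesis, always well-defined); Wald remains the last resort.
    lrt_link = used_link if used_link in ("log-binomial", "logistic") else "logistic"
    lrt_p: dict[int, float] = {}
    try:
        llf_full = llf if lrt_link == used_link else _glm_fit(design, y, lrt_link)[2]
        for j in range(p):
            reduced = np.delete(design, j + 1, axis=1)
            llf0 = _glm_fit(reduced, y, lrt_link)[2]
            lrt_p[j] = float(chi2.sf(max(2 * (llf_full - llf0), 0.0), df=1))
    except (NonConvergenceError, np.linalg.LinAlgError, ValueError):
        pass  # Wald fallback below

    z = norm.ppf(1 - alpha / 2)
    measure = "or" if link == "logistic" else "rr"
    estimates = []
    for j, col in enumerate(X.columns):
        b = params[j + 1] / scales[j]
        se = se_std[j + 1] / scales[j]
        pval = lrt_p.get(j)
        if pval is None:
            pval = 2 * norm.sf(abs(b) / se) if se > 0 else 1.0
        estimates.append(RiskEstimate(
            feature=str(col), rr=float(np.exp(b)),
            ci_low=float(np.exp(b - z * se)), ci_high=float(np.exp(b + z * se)),
            p=float(min(pval, 1.0)), dataset=dataset,
            scale="binary" if X[col].nunique() == 2 else "per-unit",
            measure=measure))
    return ModelFit(features=tuple(str(c) for c in X.columns), loglik=llf,
                    k=p + 1, estimates=estimates, link=used_link)


def _analysis_frame(cohort: Cohort, dataset: str,
                    binary_drugs: tuple[str, ...] = ("cyclophosphamide",)):
    """Feature frame plus binary outcome for the requested dataset."""
    if dataset == "baseline":
        frame = cohort.baseline_frame(binary_drugs=binary_drugs)
        y = frame.pop("infected").astype(float).to_numpy()
        return frame, y
    if dataset == "nested":
        from .synthetic import generate_nested_case_control
        frame = generate_nested_case_control(cohort, binary_drugs=binary_drugs)
        y = frame.pop("case").astype(float).to_numpy()
        return frame.drop(columns=["day"]), y
    raise ValueError(f"unknown dataset {dataset!r}")


def univariate_screen(cohort: Cohort, features, dataset: str = "baseline",
                      link: str = "log-binomial", alpha: float = 0.05,
                      ) -> list[RiskEstimate]:
    """One single-feature risk fit per feature, sorted by p-value.

    Features whose fit fails (constant value, separation) are skipped with
    a warning rather than aborting the screen.
    """
    frame, y = _analysis_frame(cohort, dataset)
    if len(np.unique(y[~np.isnan(y)])) < 2:
        raise DegenerateDataError("outcome has a single class")
    estimates = []
    for feat in features:
        if feat not in frame.columns:
            warnings.warn(f"feature {feat!r} absent from {dataset} frame; skipped",
                          stacklevel=2)
            continue
        try:
            fit = fit_risk_model(frame[[feat]], y, link=link, alpha=alpha,
                                 dataset=dataset)
        except (NonConvergenceError, DegenerateDataError) as exc:
            warnings.warn(f"feature {feat!r} skipped: {exc}", stacklevel=2)
            continue
        estimates.append(fit.estimates[0])
    estimates.sort(key=lambda e: e.p)
    return estimates


def select_model_by_aic(candidates, cohort: Cohort, dataset: str = "baseline",
                        link: str = "logistic") -> ModelFit:
    """Fit each candidate feature subset and return the lowest-AIC model.

    Candidates are compared on the logistic likelihood by default: AIC is
    only meaningful across fits of the same likelihood family, which rules
    out the log-binomial/modified-Poisson fallback pair (the Poisson working
    likelihood is not comparable to a binomial one).  Ties break toward
    fewer parameters, then lexicographically smaller sorted feature names.
    If every candidate fails, the per-candidate causes are aggregated into
    one error.
    """
    frame, y = _analysis_frame(cohort, dataset)
    fits = []
    failures = []
    for cand in candidates:
        cand = list(cand)
        try:
            fits.append(fit_risk_model(frame[cand], y, link=link,
                                       fallback=False, dataset=dataset))
        except Exception as exc:  # noqa: BLE001 - aggregated below
            failures.append(f"{cand}: {exc}")
    if not fits:
        raise NonConvergenceError(
            "all candidate models failed:\n" + "\n".join(failures))
    return min(fits, key=lambda f: (f.aic, f.k, tuple(sorted(f.features))))


def screen_to_frame(estimates: list[RiskEstimate]) -> pd.DataFrame:
    """Screen results as a table with the published column layout."""
    return pd.DataFrame([{
        "feature": e.feature,
        "RR" if e.measure == "rr" else "OR": e.rr,
        "ci_low": e.ci_low, "ci_high": e.ci_high,
        "p": e.p, "dataset": e.dataset,
    } for e in estimates])
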