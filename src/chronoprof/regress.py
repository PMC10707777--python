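"""Association models: median (τ = 0.5) quantile regression and binary
logistic regression, each with backward AIC factor-block selection.

Median regression minimizes the pinball loss Σ ρ_τ(yᵢ − xᵢβ) with
ρ_τ(u) = u(τ − 1{u<0}); the problem is solved exactly as a linear program
(HiGHS), and 95% confidence intervals come from a pairs bootstrap.  The AIC
for a quantile fit uses the asymmetric-Laplace working likelihood,
AIC = 2p + 2n·log(mean pinball loss).  Goodness of fit is the quantile
pseudo-R² R1 = 1 − V_full / V_intercept-only.

Logistic models are fitted by maximum likelihood through statsmodels with
Wald intervals; odds ratios are exponentiated coefficients.

Categorical predictors enter as treatment-coded factor blocks with explicit
reference levels, and backward selection drops whole blocks at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linprog

__all__ = ["Term", "ModelSpec", "MedianRegression", "LogisticModel",
           "RegressionResults", "backward_select", "pinball_loss",
           "median_fit_lp", "default_model_spec"]


def pinball_loss(resid: np.ndarray, tau: float = 0.5) -> float:
    """Σ ρ_τ(u), ρ_τ(u) = u(τ − 1{u<0})."""
    u = np.asarray(resid, dtype=float)
    return float(np.sum(u * (tau - (u < 0))))


@dataclass(frozen=True)
class Term:
    """One predictor: a continuous column or a treatment-coded factor."""

    name: str
    is_factor: bool = False
    reference: str | None = None
    levels: tuple | None = None       # full level order incl. reference


@dataclass
class ModelSpec:
    """Outcome, family and the full predictor list for backward selection."""

    outcome: str
    family: str                       # "median" | "logistic"
    terms: list[Term]
    tau: float = 0.5

    def __post_init__(self) -> None:
        if self.family not in ("median", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "median" and not 0 < self.tau < 1:
            raise ValueError("tau must be in (0, 1)")


def design_matrix(data: pd.DataFrame, terms: list[Term],
                  ) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Intercept-first design matrix plus the term → column block map."""
    X = pd.DataFrame({"(Intercept)": np.ones(len(data))}, index=data.index)
    blocks: dict[str, list[str]] = {}
    for t in terms:
        s = data[t.name]
        if t.is_factor:
            levels = list(t.levels) if t.levels else sorted(s.dropna().unique())
            ref = t.reference if t.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"{t.name}: reference {ref!r} not a level")
            observed = set(s.dropna().unique())
            cols = []
            for lev in levels:
                if lev == ref or lev not in observed:
                    continue
                col = f"{t.name}[{lev}]"
                X[col] = (s == lev).astype(float)
                cols.append(col)
            blocks[t.name] = cols
        else:
            X[t.name] = s.astype(float)
            blocks[t.name] = [t.name]
    return X, blocks


def _check_rank(X: pd.DataFrame) -> None:
    M = X.to_numpy()
    if np.linalg.matrix_rank(M) < M.shape[1]:
        _, R = np.linalg.qr(M)
        bad = [X.columns[j] for j in range(M.shape[1])
               if abs(R[j, j]) < 1e-8 * max(1.0, abs(R[0, 0]))]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")


def median_fit_lp(X: np.ndarray, y: np.ndarray, tau: float = 0.5) -> np.ndarray:
    """Exact pinball-loss minimizer via the primal LP (HiGHS).

    Variables (β, u⁺, u⁻) with Xβ + u⁺ − u⁻ = y; minimize τ·Σu⁺ + (1−τ)·Σu⁻.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    c = np.concatenate([np.zeros(p), np.full(n, tau), np.full(n, 1 - tau)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"quantile LP failed: {res.message}")
    return res.x[:p]


@dataclass
class RegressionResults:
    """Coefficients, intervals and diagnostics of one fitted model."""

    model: object
    spec: ModelSpec
    params: pd.Series
    conf_int: pd.DataFrame            # columns lo95, hi95
    aic: float
    nobs: int
    loglik: float | None = None
    pseudo_r1: float | None = None
    selection_trace: list[dict] = field(default_factory=list)

    @property
    def odds_ratios(self) -> pd.DataFrame | None:
        if self.spec.family != "logistic":
            return None
        return pd.DataFrame({
            "OR": np.exp(self.params),
            "lo95": np.exp(self.conf_int["lo95"]),
            "hi95": np.exp(self.conf_int["hi95"]),
        })

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"estimate": self.params,
                           "lo95": self.conf_int["lo95"],
                           "hi95": self.conf_int["hi95"]})
        if self.spec.family == "logistic":
            df["OR"] = np.exp(self.params)
        return df

    def summary(self) -> str:
        label = ("median regression (tau=0.5)" if self.spec.family == "median"
                 else "logistic regression")
        lines = [f"{self.spec.outcome} ~ {label},  n = {self.nobs}",
                 f"AIC = {self.aic:.2f}"
                 + (f",  R1 = {self.pseudo_r1:.3f}"
                    if self.pseudo_r1 is not None else "")]
        df = self.to_frame()
        with pd.option_context("display.float_format", "{:0.3f}".format):
            lines.append(df.to_string())
        return "\n".join(lines)


class MedianRegression:
    """τ = 0.5 quantile regression model for one outcome.

    Use :meth:`from_dataframe` to build the design from a cohort table and a
    term list; ``fit`` solves the LP and (optionally) bootstraps intervals.
    """

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame,
                 spec: ModelSpec | None = None, tau: float = 0.5):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = exog
        self.tau = spec.tau if spec else tau
        self.spec = spec or ModelSpec("y", "median", [], tau=tau)
        if len(self.endog) <= exog.shape[1]:
            raise ValueError("need more observations than parameters")
        _check_rank(exog)

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec,
                       ) -> "MedianRegression":
        X, _ = design_matrix(data, spec.terms)
        return cls(data[spec.outcome].to_numpy(), X, spec=spec)

    def _loss(self, beta: np.ndarray) -> float:
        return pinball_loss(self.endog - self.exog.to_numpy() @ beta, self.tau)

    def fit(self, boot_ci: bool = False, n_boot: int = 999,
            seed: int | None = None) -> RegressionResults:
        X = self.exog.to_numpy()
        beta = median_fit_lp(X, self.endog, self.tau)
        n, p = X.shape
        loss = self._loss(beta)
        aic = 2 * p + 2 * n * np.log(max(loss / n, 1e-300))
        # intercept-only null for pseudo-R1
        null_beta = median_fit_lp(np.ones((n, 1)), self.endog, self.tau)
        v_null = pinball_loss(self.endog - null_beta[0], self.tau)
        r1 = 1.0 - loss / v_null if v_null > 0 else 1.0
        ci = pd.DataFrame(np.nan, index=self.exog.columns,
                          columns=["lo95", "hi95"])
        if boot_ci:
            rng = np.random.default_rng(seed)
            draws = np.empty((n_boot, p))
            for b in range(n_boot):
                idx = rng.integers(0, n, n)
                draws[b] = median_fit_lp(X[idx], self.endog[idx], self.tau)
            ci["lo95"] = np.percentile(draws, 2.5, axis=0)
            ci["hi95"] = np.percentile(draws, 97.5, axis=0)
        return RegressionResults(self, self.spec,
                                 pd.Series(beta, index=self.exog.columns),
                                 ci, float(aic), n, pseudo_r1=float(r1))


class LogisticModel:
    """Binary logistic regression via statsmodels maximum likelihood."""

    def __init__(self, endog: np.ndarray, exog: pd.DataFrame,
                 spec: ModelSpec | None = None):
        y = np.asarray(endog, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("logistic outcome must be binary 0/1")
        if len(y) <= exog.shape[1]:
            raise ValueError("need more observations than parameters")
        _check_rank(exog)
        self.endog, self.exog = y, exog
        self.spec = spec or ModelSpec("y", "logistic", [])

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec,
                       ) -> "LogisticModel":
        X, _ = design_matrix(data, spec.terms)
        return cls(data[spec.outcome].to_numpy(), X, spec=spec)

    def fit(self, **kw) -> RegressionResults:
        sm_fit = sm.Logit(self.endog, self.exog).fit(disp=0, maxiter=100)
        if not sm_fit.mle_retvals.get("converged", True):
            raise RuntimeError("logistic fit did not converge in 100 iterations")
        if np.abs(sm_fit.params).max() > 15:
            import warnings
            warnings.warn("possible quasi-separation: |beta| > 15")
        ci = sm_fit.conf_int()
        ci.columns = ["lo95", "hi95"]
        return RegressionResults(self, self.spec, sm_fit.params, ci,
                                 float(sm_fit.aic), int(sm_fit.nobs),
                                 loglik=float(sm_fit.llf))


def _fit_for_terms(data: pd.DataFrame, spec: ModelSpec,
                   terms: list[Term]) -> RegressionResults:
    sub = ModelSpec(spec.outcome, spec.family, terms, tau=spec.tau)
    cls = MedianRegression if spec.family == "median" else LogisticModel
    return cls.from_dataframe(data, sub).fit()


def backward_select(spec: ModelSpec, data: pd.DataFrame,
                    boot_ci: bool = True, n_boot: int = 999,
                    seed: int | None = None) -> RegressionResults:
    """Backward AIC selection dropping whole factor blocks.

    Starting from the full model, repeatedly remove the term whose removal
    most reduces AIC (ties → the term declared earliest); stop when no
    removal improves.  The returned fit carries the full selection trace and,
    for median fits, bootstrap intervals.
    """
    rows = data.dropna(subset=[spec.outcome] + [t.name for t in spec.terms])
    terms = list(spec.terms)
    current = None
    while terms:
        try:
            current = _fit_for_terms(rows, spec, terms)
            break
        except (ValueError, RuntimeError):
            terms = terms[:-1]           # full model unfittable (e.g. separation)
    if current is None:
        current = _fit_for_terms(rows, spec, [])
    trace = [{"step": 0, "dropped": None, "aic": current.aic,
              "terms": [t.name for t in terms]}]
    step = 0
    while terms:
        candidates = []
        for i, t in enumerate(terms):
            reduced = terms[:i] + terms[i + 1:]
            try:
                fit = _fit_for_terms(rows, spec, reduced)
            except (ValueError, RuntimeError):
                continue
            candidates.append((fit.aic, i, t, fit, reduced))
        if not candidates:
            break
        best = min(candidates, key=lambda c: (c[0], c[1]))
        if best[0] >= current.aic:
            break
        step += 1
        current, terms = best[3], best[4]
        trace.append({"step": step, "dropped": best[2].name, "aic": best[0],
                      "terms": [t.name for t in terms]})
    final_spec = ModelSpec(spec.outcome, spec.family, terms, tau=spec.tau)
    if spec.family == "median" and boot_ci:
        final = MedianRegression.from_dataframe(rows, final_spec).fit(
            boot_ci=True, n_boot=n_boot, seed=seed)
    else:
        final = _fit_for_terms(rows, spec, terms)
        final.spec = final_spec
    final.selection_trace = trace
    return final


#: Full-model predictor blocks (reference levels follow the published tables).
_BASE_TERMS = [
    Term("gender", is_factor=True, reference="F", levels=("F", "M")),
    Term("age"),
    Term("education", is_factor=True, reference="middle",
         levels=("middle", "high", "degree+")),
    Term("physical_activity"),
    Term("alcohol"),
    Term("smoking"),
    Term("BMI_tertile", is_factor=True, reference=1, levels=(1, 2, 3)),
    Term("profile_label", is_factor=True, reference=1, levels=(1, 2, 3, 4)),
]
_COMORBIDITY_TERMS = [
    Term("hypertension"),
    Term("diabetes", is_factor=True, reference="no", levels=("no", "pre", "yes")),
    Term("dyslipidemia"),
]

PSYCH_OUTCOMES = ("SCL90_GSI", "SF36_PH", "SF36_MH", "YFAS", "EAT26",
                  "BIS11", "BES")
BINARY_OUTCOMES = ("hypertension", "dyslipidemia", "diabetes_bin")
METABOLIC_OUTCOMES = ("HDL", "TG", "HOMA")


def default_model_spec(outcome: str) -> ModelSpec:
    """Full-model template for one outcome.

    Comorbidity outcomes are logistic; metabolic and psychometric scores are
    median fits.  Only psychometric scores include the comorbidity
    indicators among their predictors.
    """
    if outcome in BINARY_OUTCOMES:
        terms = [t for t in _BASE_TERMS]
        real = "diabetes_bin" if outcome == "diabetes_bin" else outcome
        return ModelSpec(real, "logistic", terms)
    if outcome in METABOLIC_OUTCOMES:
        return ModelSpec(outcome, "median", list(_BASE_TERMS))
    if outcome in PSYCH_OUTCOMES:
        return ModelSpec(outcome, "median", _BASE_TERMS + _COMORBIDITY_TERMS)
    raise ValueError(f"no default template for outcome {outcome!r}")
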