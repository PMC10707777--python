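"""Synthetic cohort generator.

Emulates the statistical structure the profiling pipeline assumes for a
severe-obesity cohort assessed before bariatric surgery:

* a 4-component mixture of chrono-nutritional eating profiles with weights
  80/173, 11/173, 55/173, 27/173 and per-profile Bernoulli meal-contact
  probabilities set to the exact published count ratios (e.g. Profile-1
  breakfast 74/80), so large-n prevalences reproduce the printed percentages
  without rounding ambiguity;
* covariate marginals: 68% female; age from a truncated skew-normal
  calibrated to median 46, IQR [39, 55], support [17, 71]; BMI from a
  truncated log-normal calibrated to median 43 with tertile cuts 40.2/46.2
  on [32.9, 80.3]; education 42/43/15%; lifestyle Bernoullis;
* clinical and psychometric outcomes driven by the published regression
  point estimates (logistic inverse-link for comorbidities; linear predictor
  plus median-zero right-skewed noise for continuous scores, so that median
  regression — not least squares — recovers the generating coefficients);
* missing-at-random masking whose probability follows a logistic model in
  age and gender, with the intercept solved so the realized marginal rates
  hit the published missing-data percentages.

True profile labels and linear predictors are returned separately from the
cohort table so downstream stages never see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .schema import SLOT_NAMES, MASKABLE_COLUMNS

__all__ = [
    "GeneratorConfig", "generate_cohort", "sample_profiles", "sample_contacts",
    "sample_covariates", "sample_outcomes", "inject_missingness",
    "PROFILE_WEIGHTS", "CONTACT_PROB",
]


class ConfigError(ValueError):
    """Generator configuration violates its contract."""


#: Mixture weights: cluster sizes 80/11/55/27 of 173.
PROFILE_WEIGHTS: tuple[Fraction, ...] = tuple(
    Fraction(k, 173) for k in (80, 11, 55, 27))

#: Per-slot, per-profile contact probabilities as exact count ratios
#: (rows follow ``SLOT_NAMES`` order; columns are Profiles 1-4).
CONTACT_PROB: dict[str, tuple[Fraction, ...]] = {
    "breakfast":           (Fraction(74, 80), Fraction(11, 11), Fraction(44, 55), Fraction(25, 27)),
    "morning_nibbling":    (Fraction(0, 80),  Fraction(0, 11),  Fraction(8, 55),  Fraction(9, 27)),
    "morning_snack":       (Fraction(34, 80), Fraction(11, 11), Fraction(26, 55), Fraction(17, 27)),
    "lunch":               (Fraction(80, 80), Fraction(11, 11), Fraction(52, 55), Fraction(25, 27)),
    "afternoon_nibbling":  (Fraction(0, 80),  Fraction(0, 11),  Fraction(22, 55), Fraction(16, 27)),
    "afternoon_snack":     (Fraction(44, 80), Fraction(11, 11), Fraction(32, 55), Fraction(21, 27)),
    "dinner":              (Fraction(80, 80), Fraction(11, 11), Fraction(55, 55), Fraction(27, 27)),
    "evening_nibbling":    (Fraction(0, 80),  Fraction(0, 11),  Fraction(7, 55),  Fraction(18, 27)),
    "evening_snack":       (Fraction(0, 80),  Fraction(11, 11), Fraction(26, 55), Fraction(15, 27)),
    "night_nibbling":      (Fraction(0, 80),  Fraction(0, 11),  Fraction(6, 55),  Fraction(0, 27)),
    "night_snack":         (Fraction(0, 80),  Fraction(0, 11),  Fraction(7, 55),  Fraction(1, 27)),
}

# Truncated skew-normal for age: calibrated offline so that, after truncation
# to [17, 71], the quartiles are 39 / 46 / 55.
AGE_SKEWNORM = {"a": 21.07742585, "loc": 32.4793155, "scale": 22.27821612,
                "lo": 17.0, "hi": 71.0}
# Truncated log-normal for BMI: calibrated so the truncated tertile cuts are
# 40.2 / 46.2 on [32.9, 80.3] (median 43.0, mean 44.0).
BMI_LOGNORM = {"mu": 3.74600765, "sigma": 0.17426691, "lo": 32.9, "hi": 80.3}

DEFAULT_COVARIATE_PARAMS: dict = {
    "p_female": 0.68,
    "education": (0.42, 0.43, 0.15),      # middle / high / degree+
    "p_activity": 0.17,
    "p_alcohol": 0.14,
    "p_smoking": 0.19,
    "p_shift": 0.18,
    "p_statins": 0.10,
    "age": AGE_SKEWNORM,
    "bmi": BMI_LOGNORM,
    # mean height by gender (m); weight is back-computed from BMI.
    "height": {"F": (1.63, 0.065), "M": (1.76, 0.07)},
    # optional profile-dependent smoking (less frequent in profiles 3-4)
    "smoking_by_profile": None,
}

# Fixed BMI tertile cut points used inside the generator's linear predictors.
BMI_CUTS = (40.2, 46.2)

# Covariate vocabulary usable in outcome linear predictors.
_PREDICTORS = (
    "male", "age", "alcohol", "smoking", "physical_activity",
    "edu_high", "edu_degree", "bmi_t2", "bmi_t3",
    "profile_2", "profile_3", "profile_4",
    "hypertension", "dyslipidemia", "pre_diabetes", "diabetes_yes",
)


def _log(x: float) -> float:
    return float(np.log(x))


#: Outcome models.  Binary families use a logistic inverse link on the linear
#: predictor; continuous ("median") families add right-skewed noise
#: scale·(exp(sigma·Z) − 1) whose median is exactly zero, so τ=0.5 quantile
#: regression recovers the coefficients.  Point estimates are the published
#: odds ratios (logged) and median-regression coefficients.
DEFAULT_OUTCOME_PARAMS: dict[str, dict] = {
    "hypertension": {
        "family": "logistic", "intercept": _log(0.01),
        "coef": {"age": _log(1.09), "male": _log(2.21), "alcohol": _log(0.34)},
    },
    "dyslipidemia": {
        "family": "logistic", "intercept": _log(0.77),
        "coef": {"male": _log(11.7), "physical_activity": _log(2.07),
                 "smoking": _log(0.48)},
    },
    "diabetes_yes": {
        "family": "logistic", "intercept": _log(0.01),
        "coef": {"age": _log(1.05), "male": _log(2.99),
                 "physical_activity": _log(0.31),
                 "bmi_t2": _log(1.61), "bmi_t3": _log(3.12)},
    },
    # pre-diabetes among the non-diabetic: marginal rates 40% pre / 18% yes.
    "pre_diabetes_given_not_yes": {"family": "bernoulli", "p": 0.40 / 0.82},
    "HDL": {
        "family": "median", "intercept": 1.15,
        "coef": {"age": 0.00, "male": -0.22, "smoking": 0.14,
                 "bmi_t2": -0.16, "bmi_t3": -0.16},
        "noise_scale": 0.30, "noise_sigma": 0.7,
    },
    "TG": {
        "family": "median", "intercept": 0.44,
        "coef": {"age": 0.01, "alcohol": 0.16, "bmi_t2": 0.05, "bmi_t3": 0.29,
                 "profile_2": 0.01, "profile_3": 0.19, "profile_4": -0.10},
        "noise_scale": 0.50, "noise_sigma": 0.8,
    },
    "HOMA": {
        "family": "median", "intercept": 2.31,
        "coef": {"male": 1.86, "bmi_t2": 1.51, "bmi_t3": 2.82},
        "noise_scale": 2.0, "noise_sigma": 0.8,
    },
    "TC": {"family": "median", "intercept": 4.59, "coef": {},
           "noise_scale": 1.5, "noise_sigma": 0.45},
    "FPG": {"family": "median", "intercept": 5.6, "coef": {},
            "noise_scale": 1.2, "noise_sigma": 0.5},
    "SF36_PH": {
        "family": "median", "intercept": 69.37,
        "coef": {"male": 8.47, "age": -0.60, "edu_high": 8.51, "edu_degree": 4.46,
                 "physical_activity": 6.15, "alcohol": 9.59,
                 "bmi_t2": 13.35, "bmi_t3": 2.88,
                 "profile_2": -1.27, "profile_3": -9.75, "profile_4": -12.40,
                 "pre_diabetes": 6.50, "diabetes_yes": 8.79, "dyslipidemia": -6.31},
        "noise_scale": 15.0, "noise_sigma": 0.6,
    },
    "SF36_MH": {
        "family": "median", "intercept": 60.07,
        "coef": {"physical_activity": 8.33, "alcohol": 6.60, "smoking": -11.77,
                 "bmi_t2": -0.10, "bmi_t3": 7.63,
                 "profile_2": 0.90, "profile_3": -12.87, "profile_4": -3.60,
                 "dyslipidemia": -3.83},
        "noise_scale": 18.0, "noise_sigma": 0.6,
    },
    "SCL90_GSI": {
        "family": "median", "intercept": 65.45,
        "coef": {"smoking": 4.30, "bmi_t2": -5.02, "bmi_t3": -5.38,
                 "profile_2": -6.81, "profile_3": 13.62, "profile_4": 6.45,
                 "pre_diabetes": -8.24, "diabetes_yes": -7.89},
        "noise_scale": 15.0, "noise_sigma": 0.6,
    },
    "EAT26": {
        "family": "median", "intercept": 7.00,
        "coef": {"male": -3.33, "smoking": 4.67, "bmi_t2": -1.67, "bmi_t3": -3.33,
                 "profile_2": 1.00, "profile_3": 2.67, "profile_4": 4.67,
                 "hypertension": 1.67, "dyslipidemia": 2.00},
        "noise_scale": 6.0, "noise_sigma": 0.7,
    },
    "BIS11": {
        "family": "median", "intercept": 61.00,
        "coef": {"male": 3.25, "bmi_t2": -3.00, "bmi_t3": -5.50,
                 "profile_2": 1.25, "profile_3": 4.00, "profile_4": 4.50,
                 "hypertension": 3.25, "physical_activity": -3.75,
                 "pre_diabetes": -2.75, "diabetes_yes": -1.00},
        "noise_scale": 8.0, "noise_sigma": 0.5,
    },
    "BES": {
        "family": "median", "intercept": 19.83,
        "coef": {"age": -0.13, "bmi_t2": -4.93, "bmi_t3": -4.01,
                 "profile_2": 1.66, "profile_3": 5.48, "profile_4": 8.42,
                 "dyslipidemia": 1.94, "physical_activity": -4.93,
                 "pre_diabetes": -2.93, "diabetes_yes": -4.09},
        "noise_scale": 8.0, "noise_sigma": 0.6,
    },
    "YFAS": {
        "family": "median", "intercept": 2.00,
        "coef": {"alcohol": -1.00, "profile_2": 0.00, "profile_3": 1.00,
                 "profile_4": 1.00},
        "noise_scale": 2.0, "noise_sigma": 0.6,
    },
}

#: Published marginal missing-data rates.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "dyslipidemia": 0.145, "shift_work": 0.006, "BIS11": 0.029,
    "TC": 0.145, "HDL": 0.150, "LDL": 0.150, "TG": 0.145, "HOMA": 0.150,
}


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort."""

    n: int = 173
    seed: int = 0
    mixture_weights: tuple = PROFILE_WEIGHTS
    contact_prob: dict = field(default_factory=lambda: dict(CONTACT_PROB))
    covariate_params: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_PARAMS))
    outcome_params: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_PARAMS))
    missing_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSING_RATES))
    # MAR slopes on standardized age and on male gender
    mar_slopes: tuple = (0.3, 0.2)

    def validate(self) -> None:
        w = np.asarray([float(x) for x in self.mixture_weights])
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError(f"mixture weights sum to {w.sum()!r}, not 1")
        if (w < 0).any():
            raise ConfigError("negative mixture weight")
        for slot, ps in self.contact_prob.items():
            if slot not in SLOT_NAMES:
                raise ConfigError(f"unknown slot {slot!r} in contact_prob")
            if any(not 0 <= float(p) <= 1 for p in ps):
                raise ConfigError(f"contact probability out of [0,1] for {slot!r}")
        for name, spec in self.outcome_params.items():
            for cov in spec.get("coef", {}):
                if cov not in _PREDICTORS:
                    raise ConfigError(f"outcome {name!r}: unknown covariate {cov!r}")
        known = set(MASKABLE_COLUMNS)
        for col in self.missing_rates:
            if col not in known:
                raise ConfigError(f"missing rate for non-maskable column {col!r}")
            if not 0 <= self.missing_rates[col] <= 1:
                raise ConfigError(f"missing rate out of [0,1] for {col!r}")


def sample_profiles(n: int, weights, rng: np.random.Generator) -> np.ndarray:
    """Draw i.i.d. profile labels 1..K from the mixture weights."""
    w = np.asarray([float(x) for x in weights])
    if abs(w.sum() - 1.0) > 1e-9:
        raise ConfigError("weights must sum to 1")
    return rng.choice(np.arange(1, len(w) + 1), size=n, p=w / w.sum())


def sample_contacts(labels: np.ndarray, contact_prob: dict,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Per-slot Bernoulli contact flags, independent across slots and patients."""
    n = len(labels)
    out = {}
    for slot in SLOT_NAMES:
        p = np.asarray([float(x) for x in contact_prob[slot]])[labels - 1]
        out[slot] = (rng.random(n) < p).astype(int)
    return pd.DataFrame(out)


def _truncated_rvs(dist, lo: float, hi: float, n: int,
                   rng: np.random.Generator) -> np.ndarray:
    plo, phi = dist.cdf(lo), dist.cdf(hi)
    return dist.ppf(rng.uniform(plo, phi, n))


def bmi_tertile_fixed(bmi: np.ndarray, cuts=BMI_CUTS) -> np.ndarray:
    """Tertile category 1/2/3 with right-closed intervals at fixed cut points."""
    return 1 + (bmi > cuts[0]).astype(int) + (bmi > cuts[1]).astype(int)


def sample_covariates(labels: np.ndarray, params: dict,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Demographic / anthropometric / lifestyle columns.

    Covariates are independent of profile membership by default; smoking can
    optionally be made profile-dependent through ``smoking_by_profile``.
    """
    n = len(labels)
    gender = np.where(rng.random(n) < params["p_female"], "F", "M")
    a = params["age"]
    age = _truncated_rvs(stats.skewnorm(a["a"], loc=a["loc"], scale=a["scale"]),
                         a["lo"], a["hi"], n, rng)
    b = params["bmi"]
    bmi = _truncated_rvs(stats.lognorm(s=b["sigma"], scale=np.exp(b["mu"])),
                         b["lo"], b["hi"], n, rng)
    pe = params["education"]
    education = rng.choice(["middle", "high", "degree+"], size=n, p=pe)
    smoking_p = np.full(n, params["p_smoking"])
    if params.get("smoking_by_profile"):
        smoking_p = np.asarray(params["smoking_by_profile"])[labels - 1]
    hmu = np.where(gender == "F", params["height"]["F"][0], params["height"]["M"][0])
    hsd = np.where(gender == "F", params["height"]["F"][1], params["height"]["M"][1])
    height = rng.normal(hmu, hsd)
    df = pd.DataFrame({
        "gender": gender,
        "age": age,
        "education": education,
        "physical_activity": (rng.random(n) < params["p_activity"]).astype(int),
        "alcohol": (rng.random(n) < params["p_alcohol"]).astype(int),
        "smoking": (rng.random(n) < smoking_p).astype(int),
        "shift_work": (rng.random(n) < params["p_shift"]).astype(int),
        "height": np.round(height, 2),
        "BMI": bmi,
        "statins": (rng.random(n) < params["p_statins"]).astype(int),
    })
    df["weight"] = df["BMI"] * df["height"] ** 2
    df["BMI_tertile"] = bmi_tertile_fixed(bmi)
    return df


def _design(cov: pd.DataFrame, labels: np.ndarray,
            extra: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    X = pd.DataFrame(index=cov.index)
    X["male"] = (cov["gender"] == "M").astype(float)
    X["age"] = cov["age"].astype(float)
    X["alcohol"] = cov["alcohol"].astype(float)
    X["smoking"] = cov["smoking"].astype(float)
    X["physical_activity"] = cov["physical_activity"].astype(float)
    X["edu_high"] = (cov["education"] == "high").astype(float)
    X["edu_degree"] = (cov["education"] == "degree+").astype(float)
    X["bmi_t2"] = (cov["BMI_tertile"] == 2).astype(float)
    X["bmi_t3"] = (cov["BMI_tertile"] == 3).astype(float)
    for k in (2, 3, 4):
        X[f"profile_{k}"] = (labels == k).astype(float)
    if extra:
        for k, v in extra.items():
            X[k] = np.asarray(v, dtype=float)
    return X


def median_zero_noise(n: int, scale: float, sigma: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Right-skewed noise scale·(exp(sigma·Z) − 1), Z ~ N(0,1); median exactly 0."""
    return scale * (np.exp(sigma * rng.standard_normal(n)) - 1.0)


def _linpred(X: pd.DataFrame, spec: dict) -> np.ndarray:
    eta = np.full(len(X), float(spec["intercept"]))
    for cov, beta in spec.get("coef", {}).items():
        eta += float(beta) * X[cov].to_numpy()
    return eta


def sample_outcomes(cov: pd.DataFrame, labels: np.ndarray, outcome_params: dict,
                    rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clinical and psychometric outcome columns plus their truth records.

    Comorbidity indicators come first (they feed the psychometric linear
    predictors); LDL is derived from TC/HDL/TG by the Friedewald relation and
    fasting insulin is back-computed from HOMA and FPG so the derived-variable
    arithmetic is internally consistent.
    """
    n = len(cov)
    X = _design(cov, labels)
    out = pd.DataFrame(index=cov.index)
    truth = pd.DataFrame(index=cov.index)

    for name in ("hypertension", "dyslipidemia", "diabetes_yes"):
        eta = _linpred(X, outcome_params[name])
        out[name] = (rng.random(n) < special.expit(eta)).astype(int)
        truth[f"eta_{name}"] = eta
    p_pre = outcome_params["pre_diabetes_given_not_yes"]["p"]
    pre = ((out["diabetes_yes"] == 0) & (rng.random(n) < p_pre)).astype(int)
    out["diabetes"] = np.select([out["diabetes_yes"] == 1, pre == 1],
                                ["yes", "pre"], default="no")
    X = _design(cov, labels, extra={
        "hypertension": out["hypertension"], "dyslipidemia": out["dyslipidemia"],
        "pre_diabetes": pre, "diabetes_yes": out["diabetes_yes"]})

    for name, spec in outcome_params.items():
        if spec.get("family") != "median":
            continue
        eta = _linpred(X, spec)
        noise = median_zero_noise(n, spec["noise_scale"], spec["noise_sigma"], rng)
        out[name] = eta + noise
        truth[f"eta_{name}"] = eta
    out = out.drop(columns="diabetes_yes")

    # Derived clinical chemistry, kept internally consistent.
    out["HDL"] = out["HDL"].clip(lower=0.3)
    out["TG"] = out["TG"].clip(lower=0.2)
    out["HOMA"] = out["HOMA"].clip(lower=0.2)
    out["LDL"] = out["TC"] - out["HDL"] - out["TG"] / 2.2
    out["FPG"] = out["FPG"].clip(lower=3.0)
    out["insulin"] = out["HOMA"] * 22.5 / out["FPG"]
    treated = (out["diabetes"] == "yes") & (rng.random(n) < 0.25)
    out["insulin_treated"] = treated.astype(int)
    out.loc[treated, "HOMA"] = np.nan    # index not defined under insulin therapy
    return out, truth


def inject_missingness(cohort: pd.DataFrame, missing_rates: dict,
                       rng: np.random.Generator,
                       slopes: tuple = (0.3, 0.2)) -> pd.DataFrame:
    """Mask cells missing-at-random.

    P(missing) follows a logistic model in standardized age and male gender;
    the intercept is solved per column so the expected marginal rate over the
    realized cohort equals the target rate.  Because the drivers are always
    observed, the mechanism is MAR by construction.
    """
    df = cohort.copy()
    if not missing_rates:
        return df
    z_age = (df["age"] - df["age"].mean()) / max(df["age"].std(ddof=0), 1e-12)
    male = (df["gender"] == "M").astype(float)
    eta0 = slopes[0] * z_age.to_numpy() + slopes[1] * male.to_numpy()
    for col, rate in missing_rates.items():
        if col not in df.columns:
            raise ConfigError(f"missing rate for absent column {col!r}")
        if rate <= 0:
            continue
        if rate >= 1:
            df[col] = np.nan
            continue
        c = optimize.brentq(lambda c: special.expit(c + eta0).mean() - rate,
                            -30, 30)
        mask = rng.random(len(df)) < special.expit(c + eta0)
        df.loc[mask, col] = np.nan
    return df


def generate_cohort(config: GeneratorConfig | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort table plus its truth records.

    Returns ``(cohort, truth)``; the cohort carries no profile labels (the
    pipeline has to recover them), the truth table carries ``true_profile``
    and the generating linear predictors.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = sample_profiles(config.n, config.mixture_weights, rng)
    contacts = sample_contacts(labels, config.contact_prob, rng)
    cov = sample_covariates(labels, config.covariate_params, rng)
    out, truth_eta = sample_outcomes(cov, labels, config.outcome_params, rng)

    cohort = pd.concat([cov, out, contacts], axis=1)
    cohort.insert(0, "patient_id", [f"P{i:06d}" for i in range(config.n)])
    cohort = inject_missingness(cohort, config.missing_rates, rng,
                                config.mar_slopes)

    truth = pd.concat(
        [pd.DataFrame({"patient_id": cohort["patient_id"],
                       "true_profile": labels}), truth_eta], axis=1)
    # keep pre-masking values for MAR recovery checks
    for col in config.missing_rates:
        if col in out.columns:
            truth[f"hidden_{col}"] = out[col].to_numpy()
        elif col in cov.columns:
            truth[f"hidden_{col}"] = cov[col].to_numpy()
    return cohort, truth
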