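"""Derived clinical quantities and the descriptive test battery.

Covers BMI, HOMA-IR, Friedewald LDL, BMI tertiles, and the group-comparison
tests used in cohort tables: Pearson chi-squared, Monte-Carlo Fisher exact
for r×c tables (engaged when any expected cell count is below 10),
Kruskal-Wallis, and the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupTestResult", "compute_bmi", "compute_homa", "friedewald_ldl",
    "bmi_tertiles", "chi_square_test", "fisher_exact_mc", "kruskal_wallis",
    "wilcoxon_rank_sum", "categorical_group_test", "summary_table",
    "FRIEDEWALD_TG_BOUND",
]

#: Friedewald validity bound: 400 mg/dL triglycerides = 400/88.57 ≈ 4.52 mmol/L.
FRIEDEWALD_TG_BOUND = 4.52

#: Expected-count threshold below which the Monte-Carlo Fisher test replaces
#: the chi-squared test.
EXPECTED_COUNT_SWITCH = 10.0


@dataclass(frozen=True)
class GroupTestResult:
    method: str                  # chi2 | fisher_mc | kruskal_wallis | wilcoxon
    statistic: float
    p_value: float
    df: float | None = None
    mc_reps: int | None = None


def compute_bmi(weight_kg, height_m):
    """Body-mass index: weight (kg) / height (m) squared."""
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_m, dtype=float)
    if (w <= 0).any() or (h <= 0).any():
        raise ValueError("weight and height must be positive")
    return w / h ** 2


def compute_homa(insulin_uU_ml, fpg_mmol_l, insulin_treated=0):
    """HOMA-IR = fasting insulin (μU/mL) × FPG (mmol/L) / 22.5.

    Not defined under insulin therapy: treated patients get NaN.
    """
    ins = np.asarray(insulin_uU_ml, dtype=float)
    fpg = np.asarray(fpg_mmol_l, dtype=float)
    if (ins < 0).any() or (fpg < 0).any():
        raise ValueError("inputs must be non-negative")
    homa = ins * fpg / 22.5
    treated = np.asarray(insulin_treated, dtype=float)
    return np.where(treated > 0, np.nan, homa)


def friedewald_ldl(tc, hdl, tg, tg_bound: float = FRIEDEWALD_TG_BOUND):
    """Friedewald LDL (mmol/L): TC − HDL − TG/2.2; NaN above the TG bound."""
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    ldl = tc - hdl - tg / 2.2
    return np.where(tg > tg_bound, np.nan, ldl)


def bmi_tertiles(bmi_values, fixed_cuts: tuple[float, float] | None = None,
                 ) -> tuple[np.ndarray, tuple[float, float]]:
    """Tertile category (1/2/3) per patient, intervals closed on the right.

    Cuts default to the empirical 1/3 and 2/3 quantiles; fixed cut points can
    be supplied instead (e.g. the published 40.2 / 46.2 kg/m²).
    """
    x = np.asarray(bmi_values, dtype=float)
    obs = x[~np.isnan(x)]
    if fixed_cuts is None:
        if obs.size < 3:
            raise ValueError("need at least 3 BMI values")
        if np.ptp(obs) == 0:
            import warnings
            warnings.warn("degenerate BMI distribution: single tertile")
            return np.where(np.isnan(x), np.nan, 1.0), (obs[0], obs[0])
        cuts = tuple(np.quantile(obs, [1 / 3, 2 / 3]))
    else:
        cuts = tuple(fixed_cuts)
    cat = 1.0 + (x > cuts[0]) + (x > cuts[1])
    return np.where(np.isnan(x), np.nan, cat), cuts


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("contingency table must be a non-negative 2-D array")
    return t


def expected_counts(table) -> np.ndarray:
    t = _as_table(table)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def chi_square_test(table) -> GroupTestResult:
    """Pearson X² = Σ(O−E)²/E without continuity correction."""
    t = _as_table(table)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("contingency table has a zero margin")
    e = expected_counts(t)
    x2 = float(((t - e) ** 2 / e).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(x2, df)) if df > 0 else 1.0
    return GroupTestResult("chi2", x2, p, df=df)


def fisher_exact_mc(table, reps: int = 100_000,
                    rng: np.random.Generator | None = None) -> GroupTestResult:
    """Monte-Carlo Fisher exact test for r×c tables.

    Tables are drawn conditional on both margins (Patefield's algorithm via
    scipy) and compared on the X² statistic; p = (1 + #{X²ₛᵢₘ ≥ X²ₒᵦₛ}) /
    (reps + 1).
    """
    rng = rng or np.random.default_rng()
    t = _as_table(table)
    r, c = t.sum(axis=1), t.sum(axis=0)
    e = np.outer(r, c) / t.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        obs = np.nansum(np.where(e > 0, (t - e) ** 2 / e, 0.0))
    sim = stats.random_table(r.astype(int), c.astype(int)).rvs(
        reps, random_state=rng)
    with np.errstate(divide="ignore", invalid="ignore"):
        x2s = np.nansum(np.where(e > 0, (sim - e) ** 2 / e, 0.0), axis=(1, 2))
    p = (1.0 + np.sum(x2s >= obs - 1e-12)) / (reps + 1.0)
    return GroupTestResult("fisher_mc", float(obs), float(p), mc_reps=reps)


def categorical_group_test(table, reps: int = 10_000,
                           rng: np.random.Generator | None = None,
                           ) -> GroupTestResult:
    """Chi-squared, switching to Monte-Carlo Fisher when any expected < 10."""
    t = _as_table(table)
    if (expected_counts(t) < EXPECTED_COUNT_SWITCH).any():
        return fisher_exact_mc(t, reps=reps, rng=rng)
    return chi_square_test(t)


def kruskal_wallis(*groups) -> GroupTestResult:
    """Kruskal-Wallis rank test with mid-rank tie correction."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return GroupTestResult("kruskal_wallis", 0.0, 1.0, df=len(groups) - 1)
    h, p = stats.kruskal(*groups)
    return GroupTestResult("kruskal_wallis", float(h), float(p),
                           df=len(groups) - 1)


def wilcoxon_rank_sum(a, b) -> GroupTestResult:
    """Two-sample Wilcoxon (Mann-Whitney) rank-sum test, normal approximation."""
    a = np.asarray(a, dtype=float); a = a[~np.isnan(a)]
    b = np.asarray(b, dtype=float); b = b[~np.isnan(b)]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return GroupTestResult("wilcoxon", 0.0, 1.0)
    stat, p = stats.ranksums(a, b)
    return GroupTestResult("wilcoxon", float(stat), float(p))


CATEGORICAL_LEVELS = {
    "gender": ["F", "M"],
    "education": ["middle", "high", "degree+"],
    "diabetes": ["no", "pre", "yes"],
}


def _is_categorical(s: pd.Series) -> bool:
    if s.name in CATEGORICAL_LEVELS or s.dtype == object:
        return True
    vals = s.dropna().unique()
    return len(vals) <= 3 and set(vals) <= {0, 1, 2, 3}


def summary_table(cohort: pd.DataFrame, group_by: str | None = None,
                  variables: list[str] | None = None,
                  rng: np.random.Generator | None = None,
                  mc_reps: int = 10_000, alpha: float = 0.05) -> pd.DataFrame:
    """Cohort characteristics table: median (IQR) / count (%) with group tests.

    One row per variable level; columns for overall and each group; the
    per-row test is Kruskal-Wallis (Wilcoxon for 2 groups) for continuous
    variables and chi-squared / Monte-Carlo Fisher for categorical ones.
    With no grouping column only the overall column is produced.
    """
    rng = rng or np.random.default_rng()
    if variables is None:
        skip = {"patient_id", group_by}
        variables = [c for c in cohort.columns if c not in skip]
    groups = []
    if group_by is not None:
        levels = sorted(cohort[group_by].dropna().unique())
        groups = [(lev, cohort[cohort[group_by] == lev]) for lev in levels]

    def _cont_cell(s: pd.Series) -> str:
        s = s.dropna()
        if s.empty:
            return "NA"
        q1, q2, q3 = np.percentile(s, [25, 50, 75])
        return f"{q2:.2f} ({q1:.2f}, {q3:.2f})"

    def _cat_cell(s: pd.Series, level) -> str:
        n = (s == level).sum()
        tot = s.notna().sum()
        pct = 100 * n / tot if tot else float("nan")
        return f"{n} ({pct:.0f}%)"

    rows = []
    for var in variables:
        s = cohort[var]
        if _is_categorical(s):
            levels = CATEGORICAL_LEVELS.get(var) or sorted(s.dropna().unique())
            if not levels:               # nothing observed at all
                row = {"variable": var, "level": "", "overall": "NA",
                       "p_value": np.nan, "significant": False}
                for gl, _g in groups:
                    row[f"group_{gl}"] = "NA"
                rows.append(row)
                continue
            p = np.nan
            if groups:
                tab = np.array([[ (g[var] == lev).sum() for lev in levels]
                                for _, g in groups])
                tab = tab[:, tab.sum(axis=0) > 0]
                if tab.shape[1] >= 2 and (tab.sum(axis=1) > 0).all():
                    p = categorical_group_test(tab, reps=mc_reps, rng=rng).p_value
            for j, lev in enumerate(levels):
                row = {"variable": var, "level": str(lev),
                       "overall": _cat_cell(s, lev)}
                for gl, g in groups:
                    row[f"group_{gl}"] = _cat_cell(g[var], lev)
                row["p_value"] = p if j == 0 else np.nan
                row["significant"] = (p < alpha) if j == 0 and np.isfinite(p) else False
                rows.append(row)
        else:
            p = np.nan
            if groups:
                vals = [g[var].dropna().to_numpy() for _, g in groups]
                vals = [v for v in vals if len(v)]
                try:
                    if len(vals) == 2:
                        p = wilcoxon_rank_sum(*vals).p_value
                    elif len(vals) > 2:
                        p = kruskal_wallis(*vals).p_value
                except ValueError:
                    p = np.nan
            row = {"variable": var, "level": "", "overall": _cont_cell(s)}
            for gl, g in groups:
                row[f"group_{gl}"] = _cont_cell(g[var])
            row["p_value"] = p
            row["significant"] = bool(p < alpha) if np.isfinite(p) else False
            rows.append(row)
    return pd.DataFrame(rows)
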