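"""End-to-end pipeline: generate → impute → smooth → cluster → summarize → regress.

Each stage writes its output as CSV/JSON under the run directory; a fixed
(config, seed) pair reproduces every file bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import descriptives as _desc
from . import generate as _gen
from . import impute as _imp
from . import regress as _reg
from . import smooth as _smooth
from .config import PipelineConfig
from .schema import SLOT_NAMES, expand_contacts_to_series, records_from_frame, \
    write_cohort_csv, MealSlotSchema

log = logging.getLogger("chronoprof")

__all__ = ["run_pipeline", "contact_matrix"]


def contact_matrix(cohort: pd.DataFrame,
                   schema: MealSlotSchema | None = None) -> np.ndarray:
    """N × 24 step-function matrix from the cohort's flag columns."""
    records = records_from_frame(cohort)
    return np.array([expand_contacts_to_series(r, schema).y for r in records])


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            log.info("stage %s: start", name)
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage and return the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.model_dump_json(indent=2))
    seeds = np.random.SeedSequence(config.seed).spawn(4)

    cohort, truth = _stage("generate")(_run_generate)(config, out)
    completed = _stage("impute")(_run_impute)(config, cohort, out, seeds[0])
    smres = _stage("smooth")(_run_smooth)(config, completed, out)
    best, labels = _stage("cluster")(_run_cluster)(config, completed, smres, out)
    completed = completed.assign(profile_label=labels)
    _stage("summarize")(_run_summarize)(completed, out, seeds[2])
    _stage("regress")(_run_regress)(config, completed, out, seeds[3])
    log.info("pipeline complete: %s", out)
    return out


def _run_generate(config, out):
    gcfg = _gen.GeneratorConfig(n=config.generator.n, seed=config.seed)
    cohort, truth = _gen.generate_cohort(gcfg)
    write_cohort_csv(cohort, out / "cohort.csv")
    truth.to_csv(out / "truth.csv", index=False)
    log.info("generated %d patients", len(cohort))
    return cohort, truth


def _run_impute(config, cohort, out, seed):
    plan = _imp.default_plan(cohort, n_iter=config.imputation.n_iter,
                             k_donors=config.imputation.k_donors)
    res = _imp.ChainedImputer(plan).impute(
        cohort, rng=np.random.default_rng(seed))
    write_cohort_csv(res.data, out / "completed.csv")
    res.trace.to_csv(out / "imputation_trace.csv", index=False)
    return res.data


def _run_smooth(config, cohort, out):
    Y = contact_matrix(cohort)
    s = config.smoothing
    grid = np.logspace(np.log10(s.lambda_grid_min), np.log10(s.lambda_grid_max),
                       s.lambda_grid_size)
    smoother = _smooth.PenalizedFourierSmoother(lambda_grid=grid)
    res = smoother.fit(Y, patient_ids=cohort["patient_id"].tolist(),
                       lam=s.fixed_lambda)
    res.to_frame().to_csv(out / "coefficients.csv", index=False)
    diag = {"selected_lambda": res.lam, "edf": res.edf,
            "residual_variance": res.residual_variance()}
    if res.gcv_table is not None:
        diag["gcv"] = res.gcv_table.to_dict(orient="list")
    (out / "smoothing.json").write_text(json.dumps(diag, indent=2))
    return res


def _run_cluster(config, cohort, smres, out):
    Z = _cluster.embed_curves(smres.coefficients, smres.model.basis)
    c = config.clustering
    best, tab = _cluster.select_k_by_bic(
        Z, range(c.k_min, c.k_max + 1), random_state=config.seed,
        scree_threshold=c.scree_threshold, tol=c.tol,
        max_iter=c.max_iter, n_init=c.n_init)
    labels = best.assignments
    payload = {"bic_table": tab.drop(columns="dims").to_dict(orient="list"),
               "selected_K": best.n_clusters,
               "mixing": best.pi.tolist(),
               "assignments": labels.tolist()}
    (out / "clusters.json").write_text(json.dumps(payload, indent=2))
    flags = cohort[list(SLOT_NAMES)]
    table = _cluster.profile_contact_table(
        flags, labels, rng=np.random.default_rng(config.seed))
    table.to_csv(out / "profile_table.csv", index=False)
    return best, labels


def _run_summarize(cohort, out, seed):
    tert, cuts = _desc.bmi_tertiles(cohort["BMI"])
    df = cohort.assign(BMI_tertile=tert)
    tab = _desc.summary_table(
        df, group_by="BMI_tertile",
        variables=[c for c in df.columns
                   if c not in ("patient_id", "BMI_tertile") and
                   c not in SLOT_NAMES],
        rng=np.random.default_rng(seed))
    tab.to_csv(out / "summary_by_bmi.csv", index=False)


def _run_regress(config, cohort, out, seed):
    rng = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    rows, traces = [], {}
    data = cohort.copy()
    data["diabetes_bin"] = (data["diabetes"] == "yes").astype(float)
    for outcome, sub in zip(config.regression.outcomes,
                            rng.spawn(len(config.regression.outcomes))):
        spec = _reg.default_model_spec(outcome)
        fit = _reg.backward_select(spec, data, n_boot=config.regression.n_boot,
                                   seed=int(sub.generate_state(1)[0] % 2**31))
        tab = fit.to_frame().reset_index(names="term")
        tab.insert(0, "outcome", outcome)
        tab["aic"] = fit.aic
        if fit.pseudo_r1 is not None:
            tab["R1"] = fit.pseudo_r1
        rows.append(tab)
        traces[outcome] = fit.selection_trace
    pd.concat(rows, ignore_index=True).to_csv(out / "regressions.csv", index=False)
    (out / "selection_traces.json").write_text(json.dumps(traces, indent=2))
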