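"""Model-based clustering of smoothed curves in coefficient space.

The smoothed curves are represented by their Fourier coefficients; applying
the square root of the basis Gram matrix maps them into a Euclidean space in
which the L² distance between curves equals the distance between vectors.
In that space a parsimonious Gaussian subspace mixture in the
high-dimensional data clustering (HDDC) family is fitted by EM: each cluster
k has mean μ_k, an orthonormal basis Q_k of a d_k-dimensional signal
subspace with variances a_k1 ≥ … ≥ a_kd, and an isotropic residual variance
b_k outside it.  Intrinsic dimensions d_k are chosen by the Cattell scree
test on each cluster's eigenvalue spectrum.

The family has six standard members, named by which variance parameters are
cluster-specific (subscript k) versus shared: AkjBkQkDk (the general model),
AkjBQkDk, AkBkQkDk, AkBQkDk, ABkQkDk and ABQkDk.  Model choice matters for
discrete diary data: distinct patients frequently carry *identical*
coefficient vectors, so members with a free per-cluster noise b_k can chase
degenerate solutions in which a component collapses onto a duplicated point
(the Gaussian likelihood is unbounded there).  Members that share variance
parameters across clusters pool the residual spread instead and remain
well-posed, which is why both K and the parsimony level are selected jointly
by minimizing BIC = −2·loglik + m·log N over the whole family — the same
strategy mature mixture-model software applies across its covariance
families.  An absolute variance floor (``noise_floor``) additionally guards
the degenerate members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .schema import SLOT_NAMES
from .descriptives import categorical_group_test

__all__ = ["embed_curves", "FunHDDC", "FunHDDCResults", "select_k_by_bic",
           "profile_contact_table", "MODEL_FAMILY"]

LOG2PI = np.log(2 * np.pi)

#: The six standard parsimonious members, most general first.
MODEL_FAMILY = ("AkjBkQkDk", "AkjBQkDk", "AkBkQkDk",
                "AkBQkDk", "ABkQkDk", "ABQkDk")


class FitError(RuntimeError):
    """All EM restarts degenerated."""


def embed_curves(coefficients: np.ndarray, basis) -> np.ndarray:
    """Map basis coefficients γ to z = W^{1/2} γ (functional L² metric).

    ‖z_i − z_j‖² then equals ∫ (f_i − f_j)² dt over the period.
    """
    G = np.atleast_2d(np.asarray(coefficients, dtype=float))
    W = basis.gram
    # W is diagonal under the full-period convention; use a general sqrt anyway
    evals, evecs = np.linalg.eigh(W)
    Whalf = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T
    return G @ Whalf


@dataclass
class _Component:
    pi: float
    mu: np.ndarray
    Q: np.ndarray          # p × d orthonormal
    d: int
    a: np.ndarray          # d within-subspace variances
    b: float               # residual variance


def _cattell_d(evals: np.ndarray, threshold: float, d_max: int) -> int:
    """Scree-test dimension: last eigenvalue gap at least threshold × max gap."""
    diffs = evals[:-1] - evals[1:]
    top = diffs.max()
    if top <= 0:
        return 1
    keep = np.nonzero(diffs >= threshold * top)[0]
    d = int(keep.max()) + 1 if keep.size else 1
    return int(np.clip(d, 1, d_max))


class FunHDDC:
    """Parsimonious Gaussian subspace mixture fitted by EM.

    Parameters
    ----------
    n_clusters : int
    model : str
        Family member, one of :data:`MODEL_FAMILY` (default the general
        ``"AkjBkQkDk"``).
    scree_threshold : float
        Cattell threshold for intrinsic-dimension selection (default 0.2).
    noise_floor : float
        Absolute variance floor for a and b (default 1e-6).
    tol, max_iter : EM stopping rule on |Δloglik|.
    n_init : int
        Independent k-means-seeded restarts; best final log-likelihood wins.
    """

    def __init__(self, n_clusters: int, model: str = "AkjBkQkDk",
                 scree_threshold: float = 0.2, noise_floor: float = 1e-6,
                 tol: float = 1e-6, max_iter: int = 200, n_init: int = 25):
        if n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if model not in MODEL_FAMILY:
            raise ValueError(f"unknown model {model!r}")
        self.n_clusters = n_clusters
        self.model = model
        self.scree_threshold = scree_threshold
        self.noise_floor = max(noise_floor, 1e-12)
        self.tol = tol
        self.max_iter = max_iter
        self.n_init = n_init

    # ------------------------------------------------------------------
    def _log_density(self, Z: np.ndarray, comps: list[_Component]) -> np.ndarray:
        """N × K matrix of log(π_k φ_k(z))."""
        N, p = Z.shape
        out = np.empty((N, len(comps)))
        for k, c in enumerate(comps):
            delta = Z - c.mu
            u = delta @ c.Q                                  # N × d
            sq = np.einsum("ij,ij->i", delta, delta)
            proj = np.einsum("ij,ij->i", u, u)
            cost = (np.sum(u * u / c.a, axis=1)
                    + (sq - proj) / c.b
                    + np.sum(np.log(c.a)) + (p - c.d) * np.log(c.b)
                    + p * LOG2PI)
            out[:, k] = np.log(c.pi) - 0.5 * cost
        return out

    def _m_step(self, Z: np.ndarray, R: np.ndarray,
                forced_d: list[int] | None = None) -> list[_Component]:
        N, p = Z.shape
        d_max = p - 1
        nk = R.sum(axis=0)
        spectra, comps = [], []
        for k in range(R.shape[1]):
            w = R[:, k]
            mu = (w @ Z) / nk[k]
            delta = Z - mu
            S = (delta.T * w) @ delta / nk[k]
            evals, evecs = np.linalg.eigh(S)
            order = np.argsort(evals)[::-1]
            evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
            d = (forced_d[k] if forced_d is not None
                 else _cattell_d(evals, self.scree_threshold, d_max))
            spectra.append((evals, d))
            comps.append(_Component(pi=nk[k] / N, mu=mu, Q=evecs[:, :d],
                                    d=d, a=evals[:d].copy(), b=0.0))

        a_kind, b_kind = self.model[:-4].split("B")      # "Akj"/"Ak"/"A", "k"/""
        # noise variance(s)
        if b_kind == "k":
            for c, (ev, d) in zip(comps, spectra):
                rest = ev[d:]
                c.b = max(float(rest.mean()) if rest.size else 0.0,
                          self.noise_floor)
        else:
            num = sum(n * ev[d:].sum() for n, (ev, d) in zip(nk, spectra))
            den = sum(n * (p - d) for n, (ev, d) in zip(nk, spectra))
            b = max(num / max(den, 1e-12), self.noise_floor)
            for c in comps:
                c.b = b
        # subspace variance(s)
        if a_kind == "Ak":
            for c, (ev, d) in zip(comps, spectra):
                c.a = np.full(d, ev[:d].mean())
        elif a_kind == "A":
            num = sum(n * ev[:d].sum() for n, (ev, d) in zip(nk, spectra))
            den = sum(n * d for n, (ev, d) in zip(nk, spectra))
            A = num / max(den, 1e-12)
            for c, (ev, d) in zip(comps, spectra):
                c.a = np.full(d, A)
        for c in comps:
            c.a = np.maximum(np.maximum(c.a, self.noise_floor), c.b)
        return comps

    def _run_em(self, Z: np.ndarray, R0: np.ndarray):
        R = R0
        loglik_path: list[float] = []
        comps = None
        prev = -np.inf
        prev_d: list[int] | None = None
        for _ in range(self.max_iter):
            if (R.sum(axis=0) < 1.0 - 1e-9).any():
                return None                                  # degenerate restart
            comps = self._m_step(Z, R)
            logd = self._log_density(Z, comps)
            loglik = float(logsumexp(logd, axis=1).sum())
            # generalized-EM guard: re-selecting d each iteration can lower
            # the objective; in that case keep the previous dimensions, whose
            # exact M-step cannot decrease it
            if prev_d is not None and loglik < prev and \
                    [c.d for c in comps] != prev_d:
                alt = self._m_step(Z, R, forced_d=prev_d)
                alt_logd = self._log_density(Z, alt)
                alt_ll = float(logsumexp(alt_logd, axis=1).sum())
                if alt_ll > loglik:
                    comps, logd, loglik = alt, alt_logd, alt_ll
            norm = logsumexp(logd, axis=1)
            R = np.exp(logd - norm[:, None])
            loglik_path.append(loglik)
            prev_d = [c.d for c in comps]
            if abs(loglik - prev) < self.tol:
                break
            prev = loglik
        return comps, R, loglik_path

    def fit(self, Z: np.ndarray, random_state: int | None = None) -> "FunHDDCResults":
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        N, p = Z.shape
        if N <= self.n_clusters:
            raise ValueError("need more observations than clusters")
        ss = np.random.SeedSequence(random_state)
        seeds = ss.generate_state(self.n_init)
        best = None
        for s in seeds:
            if self.n_clusters == 1:
                R0 = np.ones((N, 1))
            else:
                km = KMeans(self.n_clusters, n_init=1,
                            random_state=int(s % (2 ** 31)))
                lab = km.fit_predict(Z)
                if len(np.unique(lab)) < self.n_clusters:
                    continue
                R0 = np.zeros((N, self.n_clusters))
                R0[np.arange(N), lab] = 1.0
            run = self._run_em(Z, R0)
            if run is None:
                continue
            comps, R, path = run
            if best is None or path[-1] > best[2][-1]:
                best = (comps, R, path)
        if best is None:
            raise FitError("all EM restarts degenerated")
        comps, R, path = best
        return FunHDDCResults(self, Z, comps, R, path)

    def bic_params(self, comps: list[_Component], p: int) -> int:
        """Free-parameter count m: mixing + means + orientations + variances."""
        K = len(comps)
        m = (K - 1) + K * p
        for c in comps:
            m += c.d * (p - (c.d + 1) / 2)    # Stiefel orientation dof
        a_kind, b_kind = self.model[:-4].split("B")
        if a_kind == "Akj":
            m += sum(c.d for c in comps)
        elif a_kind == "Ak":
            m += K
        else:
            m += 1
        m += K if b_kind == "k" else 1
        return int(round(m))


@dataclass
class FunHDDCResults:
    model: FunHDDC
    Z: np.ndarray = field(repr=False)
    components: list[_Component] = field(repr=False)
    responsibilities: np.ndarray = field(repr=False)
    loglik_path: list[float] = field(repr=False)

    @property
    def n_clusters(self) -> int:
        return len(self.components)

    @property
    def model_name(self) -> str:
        return self.model.model

    @property
    def loglik(self) -> float:
        return self.loglik_path[-1]

    @property
    def pi(self) -> np.ndarray:
        return np.array([c.pi for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mu for c in self.components])

    @property
    def intrinsic_dims(self) -> list[int]:
        return [c.d for c in self.components]

    @property
    def assignments(self) -> np.ndarray:
        """Hard labels 1..K by maximum posterior (ties → lower index)."""
        return np.argmax(self.responsibilities, axis=1) + 1

    @property
    def bic(self) -> float:
        N, p = self.Z.shape
        m = self.model.bic_params(self.components, p)
        return -2.0 * self.loglik + m * np.log(N)

    def summary(self) -> str:
        sizes = np.bincount(self.assignments, minlength=self.n_clusters + 1)[1:]
        lines = [
            f"Gaussian subspace mixture {self.model_name}, K = {self.n_clusters}",
            f"  log-likelihood: {self.loglik:.3f}",
            f"  BIC:            {self.bic:.3f}",
            f"  mixing weights: {np.round(self.pi, 3).tolist()}",
            f"  cluster sizes:  {sizes.tolist()}",
            f"  intrinsic dims: {self.intrinsic_dims}",
        ]
        return "\n".join(lines)


def select_k_by_bic(Z: np.ndarray, k_range=range(2, 7),
                    models: str | tuple = "AkjBkQkDk",
                    random_state: int | None = None,
                    **model_kw) -> tuple[FunHDDCResults, pd.DataFrame]:
    """Fit every (model, K) pair; return the BIC minimizer + the full table.

    By default only the general member is fitted; pass
    ``models=MODEL_FAMILY`` to select the parsimony level jointly with K.
    Ties resolve to the smaller K and then to the more parsimonious model;
    pairs whose restarts all degenerate are recorded with NaN and skipped.
    """
    k_range = list(k_range)
    if not k_range:
        raise ValueError("empty K range")
    if isinstance(models, str):
        models = (models,)
    rows, results = [], {}
    for K in k_range:
        for model in models:
            try:
                res = FunHDDC(K, model=model, **model_kw).fit(
                    Z, random_state=random_state)
                results[(K, model)] = res
                rows.append({"K": K, "model": model, "loglik": res.loglik,
                             "bic": res.bic, "dims": res.intrinsic_dims})
            except (FitError, ValueError):
                rows.append({"K": K, "model": model, "loglik": np.nan,
                             "bic": np.nan, "dims": None})
    tab = pd.DataFrame(rows)
    if not results:
        raise FitError("no (model, K) pair produced a valid fit")
    order = {m: i for i, m in enumerate(MODEL_FAMILY)}
    best_key = min(results, key=lambda km: (results[km].bic, km[0],
                                            -order.get(km[1], 0)))
    return results[best_key], tab


def profile_contact_table(flags: pd.DataFrame, assignments: np.ndarray,
                          rng: np.random.Generator | None = None,
                          mc_reps: int = 10_000) -> pd.DataFrame:
    """Per-profile contact frequency table with per-slot association tests.

    One row per meal slot; columns report count (%) overall and per cluster,
    clusters ordered by decreasing size.  The test is chi-squared, or
    Monte-Carlo Fisher when any expected cell count is below 10; a slot
    with no variation (all patients identical) gets no test.
    """
    rng = rng or np.random.default_rng()
    assignments = np.asarray(assignments)
    labels, counts = np.unique(assignments, return_counts=True)
    order = labels[np.argsort(-counts, kind="stable")]
    rows = []
    for slot in SLOT_NAMES:
        x = flags[slot].to_numpy()
        row = {"slot": slot,
               "overall": f"{int(x.sum())} ({100 * x.mean():.0f}%)"}
        tab = []
        for lab in order:
            sub = x[assignments == lab]
            row[f"profile_{lab}"] = f"{int(sub.sum())} ({100 * sub.mean():.0f}%)"
            tab.append([sub.sum(), len(sub) - sub.sum()])
        tab = np.asarray(tab, dtype=float)
        if (tab.sum(axis=0) > 0).all():
            row["p_value"] = categorical_group_test(tab, reps=mc_reps,
                                                    rng=rng).p_value
        else:
            row["p_value"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
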