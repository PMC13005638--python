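"""Group-based trajectory modeling of binary adherence series.

The model is a K-component finite mixture: patient *i* belongs to latent
class *k* with probability ``π_k``; given the class, the per-bin adherence
indicators are independent Bernoulli with

    p_kt = logistic( β_k0 + β_k1 t + ... + β_kd t^d ),

where *t* is the bin index standardized to [−1, 1].  Parameters are fitted
by EM: the E-step computes posterior class memberships, the M-step updates
``π`` in closed form and each class's polynomial by weighted logistic
regression (Newton–Raphson on the T aggregated bins, which is exact because
the class log-likelihood depends on the data only through per-bin weighted
success counts).  Multiple restarts (k-means and random initializations)
guard against local optima; the number of classes is chosen by BIC subject
to a minimum class share.  Classes are labeled A, B, C, … by descending
class-mean MPR.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp
from sklearn.cluster import KMeans

@dataclass(frozen=True)
class GbtmConfig:
    k_min: int = 2
    k_max: int = 9
    degree: int = 2
    max_iter: int = 500
    tol: float = 1e-7
    n_restarts: int = 10
    seed: int = 0
    min_class_share: float = 0.02

    def __post_init__(self) -> None:
        if self.degree < 0:
            raise ValueError("degree must be >= 0")
        if self.n_restarts < 1:
            raise ValueError("need at least one restart")
        if self.k_min < 1 or self.k_max < self.k_min:
            raise ValueError("invalid candidate K range")


@dataclass
class TrajectoryModel:
    """A fitted mixture of polynomial-logit adherence trajectories."""

    k: int
    weights: np.ndarray  # (K,)
    coefficients: np.ndarray  # (K, degree+1), logit scale over standardized t
    log_likelihood: float
    n_parameters: int
    bic: float
    posteriors: np.ndarray  # (N, K), rows sum to 1
    assignments: np.ndarray  # (N,) hard class indices
    loglik_trace: np.ndarray
    degenerate: bool = False
    labels: list[str] | None = None  # per class, after labeling
    label_of_patient: np.ndarray | None = None

    def class_curves(self, n_bins: int) -> np.ndarray:
        """Fitted per-bin adherence probabilities, one row per class."""
        t = np.linspace(-1.0, 1.0, n_bins)
        design = np.vander(t, self.coefficients.shape[1], increasing=True)
        return expit(self.coefficients @ design.T)

    def class_sizes(self) -> np.ndarray:
        return np.bincount(self.assignments, minlength=self.k)


def _design(n_bins: int, degree: int) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, n_bins)
    return np.vander(t, degree + 1, increasing=True)


def _binomial_loglik(design, successes, totals, beta) -> float:
    eta = design @ beta
    # log p = -softplus(-eta), log(1-p) = -softplus(eta)
    return float(successes @ eta - totals @ np.logaddexp(0.0, eta))


def _weighted_logistic(
    design: np.ndarray,
    successes: np.ndarray,
    totals: np.ndarray,
    beta0: np.ndarray,
    max_iter: int = 50,
    tol: float = 1e-10,
) -> np.ndarray:
    """Newton–Raphson for a binomial GLM on T aggregated bins.

    Step-halving keeps every update an ascent step, which in turn keeps the
    outer EM's observed-data log-likelihood monotone.
    """
    beta = beta0.copy()
    ll = _binomial_loglik(design, successes, totals, beta)
    for _ in range(max_iter):
        eta = design @ beta
        mu = expit(eta)
        grad = design.T @ (successes - totals * mu)
        w = totals * mu * (1.0 - mu)
        hess = design.T @ (design * w[:, None]) + 1e-10 * np.eye(design.shape[1])
        step = np.linalg.solve(hess, grad)
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            cand_ll = _binomial_loglik(design, successes, totals, cand)
            if cand_ll >= ll:
                break
            scale *= 0.5
        else:
            break
        if cand_ll - ll < tol * max(1.0, abs(ll)) and np.max(np.abs(scale * step)) < 1e-8:
            beta, ll = cand, cand_ll
            break
        beta, ll = cand, cand_ll
    return beta


def _loglik_matrix(y: np.ndarray, coef: np.ndarray, design: np.ndarray) -> np.ndarray:
    """(N, K) matrix of per-patient, per-class Bernoulli log-likelihoods.

    Uses the softplus form, which is exact for extreme logits (no
    probability clipping is needed)."""
    eta = coef @ design.T  # (K, T)
    logp = -np.logaddexp(0.0, -eta)
    log1mp = -np.logaddexp(0.0, eta)
    return y @ logp.T + (1.0 - y) @ log1mp.T


def _em(
    y: np.ndarray,
    k: int,
    config: GbtmConfig,
    resp0: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray]:
    n, t = y.shape
    design = _design(t, config.degree)
    resp = resp0
    coef = np.zeros((k, config.degree + 1))
    # Initial M-step from the provided responsibilities.
    for j in range(k):
        w = resp[:, j]
        coef[j] = _weighted_logistic(design, y.T @ w, w.sum() + np.zeros(t), coef[j])
    weights = np.maximum(resp.mean(axis=0), 1e-12)
    weights /= weights.sum()

    trace = []
    prev = -np.inf
    for _ in range(config.max_iter):
        ll = _loglik_matrix(y, coef, design) + np.log(weights)[None, :]
        norm = logsumexp(ll, axis=1)
        loglik = float(norm.sum())
        trace.append(loglik)
        resp = np.exp(ll - norm[:, None])
        weights = np.maximum(resp.mean(axis=0), 1e-12)
        weights /= weights.sum()
        for j in range(k):
            w = resp[:, j]
            coef[j] = _weighted_logistic(design, y.T @ w, w.sum() + np.zeros(t), coef[j])
        if loglik - prev < config.tol * max(1.0, abs(loglik)) and len(trace) > 1:
            break
        prev = loglik
    # Final E-step so posteriors match the returned parameters.
    ll = _loglik_matrix(y, coef, design) + np.log(weights)[None, :]
    norm = logsumexp(ll, axis=1)
    trace.append(float(norm.sum()))
    resp = np.exp(ll - norm[:, None])
    return coef, weights, float(norm.sum()), np.array(trace), resp


def _initial_responsibilities(
    y: np.ndarray, k: int, rng: np.random.Generator, restart: int
) -> np.ndarray:
    n = y.shape[0]
    if restart == 0 and n >= k:
        km = KMeans(
            n_clusters=k,
            n_init=3,
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(y.astype(float))
        resp = np.full((n, k), 0.05 / max(k - 1, 1))
        resp[np.arange(n), km.labels_] = 0.95
    else:
        resp = rng.dirichlet(np.ones(k), size=n)
    return resp / resp.sum(axis=1, keepdims=True)


def fit_gbtm(y: np.ndarray, k: int, config: GbtmConfig = GbtmConfig()) -> TrajectoryModel:
    """Fit the K-class mixture, keeping the best of ``n_restarts`` EM runs.

    ``y`` is an N×T binary matrix with no missing entries.  The observed-data
    log-likelihood is non-decreasing across EM iterations (up to numerical
    tolerance), posteriors row-normalize to 1, and a fixed seed yields an
    identical fit.  A class whose share falls below ``min_class_share`` marks
    the model as degenerate (flagged, not fatal).
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ValueError("y must be an N x T matrix")
    if np.any((y != 0) & (y != 1)) or np.isnan(y).any():
        raise ValueError("y must be binary with no missing entries")
    n = y.shape[0]
    if k > n:
        raise ValueError(f"K={k} exceeds the number of series N={n}")

    rng = np.random.default_rng(config.seed)
    best = None
    for restart in range(config.n_restarts):
        resp0 = _initial_responsibilities(y, k, rng, restart)
        coef, weights, loglik, trace, resp = _em(y, k, config, resp0)
        if best is None or loglik > best[2]:
            best = (coef, weights, loglik, trace, resp)
    coef, weights, loglik, trace, resp = best

    n_params = (k - 1) + k * (config.degree + 1)
    bic = -2.0 * loglik + n_params * np.log(n)
    assignments = np.argmax(resp, axis=1)
    shares = np.bincount(assignments, minlength=k) / n
    degenerate = bool(np.any(shares < config.min_class_share))
    if degenerate:
        warnings.warn(
            f"K={k}: a class share fell below {config.min_class_share:.2%}",
            stacklevel=2,
        )
    return TrajectoryModel(
        k=k,
        weights=weights,
        coefficients=coef,
        log_likelihood=loglik,
        n_parameters=n_params,
        bic=float(bic),
        posteriors=resp,
        assignments=assignments,
        loglik_trace=trace,
        degenerate=degenerate,
    )


def select_k(
    y: np.ndarray, config: GbtmConfig = GbtmConfig()
) -> tuple[TrajectoryModel, pd.DataFrame]:
    """Fit every candidate K and pick the BIC minimizer among non-degenerate fits.

    Returns the selected model and the full K-vs-BIC table.  If every
    candidate is degenerate the overall BIC minimizer is returned with a
    warning.
    """
    rows = []
    models: dict[int, TrajectoryModel] = {}
    for k in range(config.k_min, config.k_max + 1):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_gbtm(y, k, replace(config, seed=config.seed + k))
        models[k] = model
        rows.append(
            {
                "k": k,
                "bic": model.bic,
                "log_likelihood": model.log_likelihood,
                "degenerate": model.degenerate,
            }
        )
    table = pd.DataFrame(rows)
    admissible = table[~table["degenerate"]]
    if admissible.empty:
        warnings.warn("all candidate K are degenerate; returning overall BIC best")
        best_k = int(table.loc[table["bic"].idxmin(), "k"])
    else:
        best_k = int(admissible.loc[admissible["bic"].idxmin(), "k"])
    return models[best_k], table


def label_clusters(model: TrajectoryModel, mpr: np.ndarray) -> TrajectoryModel:
    """Label classes A, B, C… by strictly descending class-mean MPR.

    Ties are broken by larger class size, then by original class index.  The
    input model is not mutated; the returned copy carries per-class labels
    and a per-patient label vector.
    """
    mpr = np.asarray(mpr, dtype=float)
    if len(mpr) != model.posteriors.shape[0]:
        raise ValueError("mpr must align with the fitted series")
    sizes = model.class_sizes()
    means = np.array(
        [
            mpr[model.assignments == j].mean() if sizes[j] else -np.inf
            for j in range(model.k)
        ]
    )
    order = sorted(range(model.k), key=lambda j: (-means[j], -sizes[j], j))
    letters = list(string.ascii_uppercase)
    labels_by_class = [""] * model.k
    for rank, j in enumerate(order):
        labels_by_class[j] = letters[rank]
    out = replace(model)
    out.labels = labels_by_class
    out.label_of_patient = np.array([labels_by_class[j] for j in model.assignments])
    return out


def cluster_profile(model: TrajectoryModel, mpr: np.ndarray) -> pd.DataFrame:
    """Per-cluster table: label, n, share % and mean MPR % (A first)."""
    if model.labels is None:
        model = label_clusters(model, mpr)
    mpr = np.asarray(mpr, dtype=float)
    n = model.posteriors.shape[0]
    rows = []
    for j in range(model.k):
        members = model.assignments == j
        rows.append(
            {
                "label": model.labels[j],
                "n": int(members.sum()),
                "share_pct": 100.0 * members.sum() / n,
                "mean_mpr_pct": 100.0 * mpr[members].mean() if members.any() else np.nan,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("label", kind="stable").reset_index(drop=True)
    )
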