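"""Model-based clustering of binary pixel vectors.

Each standardized head pattern is a binary vector over the J in-mask
consensus-frame pixels.  Individuals are clustered with a multivariate
Bernoulli (latent class) mixture,

    p(y_n) = sum_k pi_k prod_j theta_kj^{y_nj} (1 - theta_kj)^{1 - y_nj},

fitted by EM with multiple random starts.  Model selection uses the
Integrated Completed Likelihood (ICL) criterion in its entropy-penalized
(soft) form, ICL = BIC + 2H with H the responsibility entropy; the MAP
(complete-data) variant is recovered in the hard-assignment limit, where
ICL = BIC exactly.  Smaller ICL is better.

Supervised partitions (species, population, habitat, or the unsupervised MAP
partition itself) are scored by a single M-step under one-hot
responsibilities, and compared on the Delta-ICL / accuracy scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2_contingency

from .morphometrics import PixelMatrix

__all__ = [
    "MixtureFit",
    "ClusterScore",
    "mixture_loglik",
    "fit_bernoulli_mixture",
    "icl_score",
    "select_k_unsupervised",
    "supervised_fit",
    "classification_accuracy",
    "compare_partitions",
    "chi_square_association",
]

#: Laplace pseudo-counts used in every theta estimate (prevents +-inf logliks
#: when a pixel is pure within a class).
SMOOTH_A = 0.5
SMOOTH_B = 1.0

ICL_VARIANT = "soft-entropy (ICL = BIC + 2H)"


@dataclass
class MixtureFit:
    """A fitted K-component Bernoulli mixture."""

    K: int
    pi: np.ndarray          # (K,) cluster weights
    theta: np.ndarray       # (K, J) per-pixel Bernoulli parameters
    tau: np.ndarray         # (n, K) responsibilities
    loglik: float
    map_labels: np.ndarray  # (n,) MAP cluster per individual (ties -> lowest index)
    n_iter: int = 0
    loglik_trace: np.ndarray | None = None
    icl_variant: str = ICL_VARIANT

    @property
    def n_params(self) -> int:
        """nu = (K - 1) mixture weights + K*J Bernoulli parameters."""
        return (self.K - 1) + self.K * self.theta.shape[1]


@dataclass
class ClusterScore:
    K: int
    loglik: float
    bic: float
    entropy: float
    icl: float
    icl_variant: str = ICL_VARIANT


def _as_matrix(data: PixelMatrix | np.ndarray) -> np.ndarray:
    Y = data.values if isinstance(data, PixelMatrix) else np.asarray(data)
    if not np.isin(Y, (0, 1)).all():
        raise ValueError("pixel matrix must be binary")
    return Y.astype(float)


def _log_components(Y: np.ndarray, pi: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(n, K) matrix of log(pi_k) + log Bernoulli(y_n | theta_k)."""
    lt = np.log(theta)
    lt1 = np.log1p(-theta)
    with np.errstate(divide="ignore"):  # pi_k = 0 -> -inf, handled by logsumexp
        lp = np.log(pi)
    return Y @ (lt - lt1).T + lt1.sum(axis=1) + lp


def mixture_loglik(data: PixelMatrix | np.ndarray, pi: np.ndarray, theta: np.ndarray) -> float:
    """Observed-data log-likelihood, computed with per-row log-sum-exp."""
    Y = _as_matrix(data)
    pi = np.asarray(pi, float)
    theta = np.asarray(theta, float)
    if np.any(theta <= 0) or np.any(theta >= 1):
        raise ValueError("theta must lie strictly inside (0, 1)")
    return float(logsumexp(_log_components(Y, pi, theta), axis=1).sum())


def _m_step(Y: np.ndarray, tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nk = tau.sum(axis=0)
    pi = nk / len(Y)
    theta = (tau.T @ Y + SMOOTH_A) / (nk[:, None] + SMOOTH_B)
    return pi, theta


def _e_step(Y: np.ndarray, pi: np.ndarray, theta: np.ndarray) -> tuple[np.ndarray, float]:
    logc = _log_components(Y, pi, theta)
    norm = logsumexp(logc, axis=1)
    tau = np.exp(logc - norm[:, None])
    return tau, float(norm.sum())


def fit_bernoulli_mixture(
    data: PixelMatrix | np.ndarray,
    K: int,
    starts: int = 10,
    seed: int | np.random.Generator | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> MixtureFit:
    """Fit a K-component Bernoulli mixture by multi-start EM.

    Each start draws random soft responsibilities (Dirichlet rows), runs one
    M-step and iterates EM until the relative log-likelihood change is below
    ``tol`` or ``max_iter`` sweeps.  The best-log-likelihood run wins; ties
    are broken by the earlier start.  Theta estimates use Laplace
    pseudo-counts 0.5/1.0 throughout.
    """
    Y = _as_matrix(data)
    n = len(Y)
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= n:
        raise ValueError(f"K = {K} must be smaller than n = {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if K == 1:
        tau = np.ones((n, 1))
        pi, theta = _m_step(Y, tau)
        ll = mixture_loglik(Y, pi, theta)
        return MixtureFit(
            K=1, pi=pi, theta=theta, tau=tau, loglik=ll,
            map_labels=np.zeros(n, dtype=int), n_iter=1, loglik_trace=np.array([ll]),
        )

    best: MixtureFit | None = None
    for _ in range(max(starts, 1)):
        tau = rng.dirichlet(np.ones(K), size=n)
        pi, theta = _m_step(Y, tau)
        trace = []
        prev = -np.inf
        for it in range(1, max_iter + 1):
            tau, ll = _e_step(Y, pi, theta)
            trace.append(ll)
            if np.isfinite(prev) and abs(ll - prev) <= tol * abs(prev):
                break
            prev = ll
            pi, theta = _m_step(Y, tau)
        fit = MixtureFit(
            K=K, pi=pi, theta=theta, tau=tau, loglik=trace[-1],
            map_labels=tau.argmax(axis=1), n_iter=it, loglik_trace=np.array(trace),
        )
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def icl_score(fit: MixtureFit, n: int | None = None) -> ClusterScore:
    """BIC, responsibility entropy and ICL of a fitted mixture.

    BIC = -2 loglik + nu ln n; H = -sum tau ln tau; ICL = BIC + 2H (the
    soft-entropy variant).  Smaller ICL is better; K = 1 or hard
    responsibilities give ICL = BIC.
    """
    n = n if n is not None else len(fit.tau)
    bic = -2.0 * fit.loglik + fit.n_params * np.log(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(fit.tau > 0, fit.tau * np.log(fit.tau), 0.0)
    entropy = float(-plogp.sum())
    return ClusterScore(K=fit.K, loglik=fit.loglik, bic=float(bic), entropy=entropy, icl=float(bic + 2 * entropy))


def select_k_unsupervised(
    data: PixelMatrix | np.ndarray,
    k_range: range = range(2, 7),
    starts: int = 10,
    seed: int | None = None,
) -> tuple[int, pd.DataFrame, dict[int, MixtureFit]]:
    """Fit every K in ``k_range`` and pick the ICL minimizer.

    Returns (best K, a score table with one row per K, the fits by K).
    """
    Y = _as_matrix(data)
    n = len(Y)
    if min(k_range) <= 1 or max(k_range) >= n:
        raise ValueError("k_range must lie strictly inside (1, n)")
    rng = np.random.default_rng(seed)
    rows = []
    fits: dict[int, MixtureFit] = {}
    for K in k_range:
        fit = fit_bernoulli_mixture(Y, K, starts=starts, seed=rng)
        score = icl_score(fit)
        fits[K] = fit
        rows.append(
            {"K": K, "loglik": score.loglik, "BIC": score.bic, "entropy": score.entropy, "ICL": score.icl}
        )
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["ICL"].idxmin(), "K"])
    return best_k, table, fits


def supervised_fit(
    data: PixelMatrix | np.ndarray,
    labels: np.ndarray,
) -> tuple[MixtureFit, ClusterScore]:
    """Score a given partition as a mixture model (single M-step).

    Classes get pi_k = n_k/n and smoothed class-mean thetas from one-hot
    responsibilities; the log-likelihood is the mixture likelihood under
    those parameters, and the ICL entropy term uses the model's own
    (recomputed) posterior responsibilities.  Class order follows the sorted
    unique labels.
    """
    Y = _as_matrix(data)
    labels = np.asarray(labels)
    if len(labels) != len(Y):
        raise ValueError("labels length must match the number of individuals")
    if np.issubdtype(labels.dtype, np.integer):
        # integer labels name classes 0..max explicitly; all must be populated
        K = int(labels.max()) + 1
        enc = labels.astype(int)
        if enc.min() < 0:
            raise ValueError("integer labels must be non-negative")
    else:
        levels, enc = np.unique(labels, return_inverse=True)
        K = len(levels)
    counts = np.bincount(enc, minlength=K)
    if (counts == 0).any():
        raise ValueError(f"every class must be non-empty (missing: {np.flatnonzero(counts == 0).tolist()})")
    onehot = np.eye(K)[enc]
    pi, theta = _m_step(Y, onehot)
    tau, ll = _e_step(Y, pi, theta)
    fit = MixtureFit(K=K, pi=pi, theta=theta, tau=tau, loglik=ll, map_labels=tau.argmax(axis=1), n_iter=1)
    return fit, icl_score(fit)


def classification_accuracy(fit: MixtureFit, labels: np.ndarray) -> float:
    """Fraction of individuals whose MAP class equals their given label.

    Labels are encoded by sorted unique value, matching the class order used
    by :func:`supervised_fit`.
    """
    labels = np.asarray(labels)
    if len(labels) != len(fit.map_labels):
        raise ValueError("labels length must match the fit")
    _, enc = np.unique(labels, return_inverse=True)
    return float(np.mean(fit.map_labels == enc))


def compare_partitions(
    data: PixelMatrix | np.ndarray,
    partitions: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Supervised comparison of candidate partitions (Delta-ICL / accuracy table).

    Each named partition is scored with :func:`supervised_fit`; the table is
    sorted by ICL with Delta-ICL relative to the best and the classification
    accuracy of each model against its own defining labels.
    """
    rows = []
    for name, labels in partitions.items():
        fit, score = supervised_fit(data, labels)
        rows.append(
            {
                "partition": name,
                "K": fit.K,
                "ICL": score.icl,
                "accuracy": classification_accuracy(fit, labels),
            }
        )
    table = pd.DataFrame(rows).sort_values("ICL", kind="stable").reset_index(drop=True)
    table["delta_ICL"] = table["ICL"] - table["ICL"].iloc[0]
    return table[["partition", "K", "ICL", "delta_ICL", "accuracy"]]


def chi_square_association(labels_a: np.ndarray, labels_b: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of association between two label vectors.

    No continuity correction; df = (r - 1)(c - 1).  Returns (chi2, df, p).
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must have the same length")
    if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
        raise ValueError("both factors need at least 2 levels")
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    res = chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
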