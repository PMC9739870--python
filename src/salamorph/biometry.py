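"""Candidate mixed models for the biometric data, ranked by AICc.

Body size (AG, the axilla–groin distance) and the eight other body features
are modelled with linear models carrying at most one categorical fixed factor
(species or site typology — never both), optionally AG as a covariate, and a
population random intercept:

    y = X beta + b_pop + eps,   b_pop ~ N(0, sigma_b^2),  eps ~ N(0, sigma^2).

Because the five population codes are globally unique, "population nested in
species/site" is the same likelihood as a plain population intercept, which
is how the random term is encoded.  All fits are maximum likelihood (ML), not
REML, so that AICc is comparable across different fixed-effect structures;
fixed-effect p-values come from likelihood-ratio chi-square tests against the
model with the factor removed.  An optional REML fit is available for
variance/SE reporting.

Random-intercept models are fitted by profiling the likelihood over the
variance ratio lambda = sigma_b^2 / sigma^2 (Brent search on log10 lambda in
[-8, 8]): for fixed lambda, the GLS beta-hat and sigma-hat^2 are closed form
per population block, so the profile is one-dimensional and the boundary
lambda -> 0 (ordinary least squares) is handled exactly.

The multivariate ("shape") candidate set scores each model structure as the
sum of eight independent per-feature fits on z-scored responses, with summed
log-likelihoods and parameter counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic import SHAPE_FEATURES

__all__ = [
    "CandidateModel",
    "LmmFit",
    "build_candidate_set",
    "fit_lmm",
    "aicc",
    "akaike_weights",
    "lrt_fixed_effect",
    "rank_models",
    "collinearity_screen",
    "SHAPE_FEATURES",
]


@dataclass(frozen=True)
class CandidateModel:
    """One candidate structure: a fixed factor and/or AG covariate and/or
    a population random intercept.  ``name`` matches the ranking-table row
    labels ("site typology:population", "species*AG", ...)."""

    name: str
    fixed: str | None = None          # None, "species" or "site_typology"
    ag_covariate: bool = False
    random_population: bool = True

    def __post_init__(self) -> None:
        if self.fixed not in (None, "species", "site_typology"):
            raise ValueError(f"unknown fixed factor {self.fixed!r}")


#: Five candidates for body size (AG): species and site typology are never
#: crossed; population enters as a random intercept or not at all.
AG_CANDIDATES: tuple[CandidateModel, ...] = (
    CandidateModel("site typology:population", fixed="site_typology"),
    CandidateModel("species:population", fixed="species"),
    CandidateModel("population"),
    CandidateModel("site typology", fixed="site_typology", random_population=False),
    CandidateModel("species", fixed="species", random_population=False),
)

#: Eleven candidates for the multivariate shape set: the five AG-style
#: structures, the same five with AG as covariate (marked "*AG"), and AG alone.
SHAPE_CANDIDATES: tuple[CandidateModel, ...] = (
    CandidateModel("population*AG", ag_covariate=True),
    CandidateModel("species*AG:population", fixed="species", ag_covariate=True),
    CandidateModel("site typology*AG:population", fixed="site_typology", ag_covariate=True),
    CandidateModel("species*AG", fixed="species", ag_covariate=True, random_population=False),
    CandidateModel("site typology*AG", fixed="site_typology", ag_covariate=True, random_population=False),
    CandidateModel("AG", ag_covariate=True, random_population=False),
    CandidateModel("population"),
    CandidateModel("site typology:population", fixed="site_typology"),
    CandidateModel("species:population", fixed="species"),
    CandidateModel("site typology", fixed="site_typology", random_population=False),
    CandidateModel("species", fixed="species", random_population=False),
)


def build_candidate_set(response: str) -> list[CandidateModel]:
    """Candidate models for ``response`` = "AG" (5 models) or "shape" (11)."""
    if response == "AG":
        return list(AG_CANDIDATES)
    if response == "shape":
        return list(SHAPE_CANDIDATES)
    raise ValueError(f"response must be 'AG' or 'shape', got {response!r}")


@dataclass
class LmmFit:
    beta: np.ndarray
    beta_names: list[str]
    cov_beta: np.ndarray       # GLS covariance of beta at the fitted variances
    sigma2_b: float            # population-intercept variance
    sigma2: float              # residual variance
    loglik: float
    n: int
    k: int                     # fixed coefficients + variance components
    reml: bool = False

    def se(self, name: str) -> float:
        return float(np.sqrt(self.cov_beta[self.beta_names.index(name), self.beta_names.index(name)]))


def _design(df: pd.DataFrame, model: CandidateModel, response: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    if model.fixed is not None:
        levels = sorted(df[model.fixed].unique())
        if len(levels) < 2:
            raise ValueError(f"fixed factor {model.fixed} has a single level")
        for lev in levels[1:]:
            cols.append((df[model.fixed] == lev).to_numpy(float))
            names.append(f"{model.fixed}[{lev}]")
    if model.ag_covariate:
        if response == "AG":
            raise ValueError("AG cannot be both response and covariate")
        cols.append(df["AG"].to_numpy(float))
        names.append("AG")
    X = np.column_stack(cols)
    y = df[response].to_numpy(float)
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values in the rows used for fitting")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(f"singular fixed-effect design for model {model.name!r} (columns {names})")
    return X, y, names


def _profile_loglik(lam: float, X: np.ndarray, y: np.ndarray, groups: list[np.ndarray], reml: bool):
    """Profile ML (or REML) log-likelihood at variance ratio lambda.

    V = I + lambda * ZZ' is block diagonal per population, so V^-1 and ln|V|
    have closed forms per block.
    """
    n, p = X.shape
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdet = 0.0
    blocks = []
    for idx in groups:
        m = len(idx)
        Xg, yg = X[idx], y[idx]
        c = lam / (1.0 + lam * m)
        sx = Xg.sum(axis=0)
        sy = yg.sum()
        XtViX += Xg.T @ Xg - c * np.outer(sx, sx)
        XtViy += Xg.T @ yg - c * sx * sy
        ytViy += yg @ yg - c * sy * sy
        logdet += np.log1p(lam * m)
        blocks.append((Xg, yg, c, sx, sy))
    beta = np.linalg.solve(XtViX, XtViy)
    quad = ytViy - 2 * beta @ XtViy + beta @ XtViX @ beta
    if reml:
        dof = n - p
        sigma2 = quad / dof
        ll = -0.5 * (
            dof * np.log(2 * np.pi * sigma2) + logdet + np.linalg.slogdet(XtViX)[1] + dof
        )
    else:
        sigma2 = quad / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)
    return float(ll), beta, float(sigma2), XtViX


def fit_lmm(df: pd.DataFrame, model: CandidateModel, response: str, reml: bool = False) -> LmmFit:
    """Fit one candidate model to one response feature by (profiled) ML.

    Models without the random term are ordinary least squares with the
    Normal ML log-likelihood.  k counts fixed coefficients plus variance
    components (1 for OLS, 2 with the random intercept).
    """
    data = df.dropna(subset=[response] + (["AG"] if model.ag_covariate else []))
    X, y, names = _design(data, model, response)
    n, p = X.shape

    if not model.random_population:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        if reml:
            sigma2 = float(resid @ resid) / (n - p)
            ll = -0.5 * (
                (n - p) * np.log(2 * np.pi * sigma2)
                + np.linalg.slogdet(X.T @ X)[1]
                + (n - p)
            )
        else:
            sigma2 = float(resid @ resid) / n
            ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return LmmFit(beta=beta, beta_names=names, cov_beta=cov, sigma2_b=0.0,
                      sigma2=sigma2, loglik=float(ll), n=n, k=p + 1, reml=reml)

    pops = data["population"].to_numpy()
    codes = sorted(set(pops))
    if len(codes) < 2:
        raise ValueError("random intercept needs at least 2 populations")
    groups = [np.flatnonzero(pops == c) for c in codes]

    def neg(log10lam: float) -> float:
        return -_profile_loglik(10.0**log10lam, X, y, groups, reml)[0]

    res = optimize.minimize_scalar(neg, bounds=(-8.0, 8.0), method="bounded",
                                   options={"xatol": 1e-10})
    # compare against the lambda -> 0 boundary (pure OLS within the LMM parameterization)
    ll_zero = _profile_loglik(0.0, X, y, groups, reml)[0]
    if ll_zero >= -res.fun:
        lam = 0.0
    else:
        lam = 10.0**res.x
    ll, beta, sigma2, XtViX = _profile_loglik(lam, X, y, groups, reml)
    cov = sigma2 * np.linalg.inv(XtViX)
    return LmmFit(beta=beta, beta_names=names, cov_beta=cov, sigma2_b=lam * sigma2,
                  sigma2=sigma2, loglik=ll, n=n, k=p + 2, reml=reml)


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with the small-sample correction:
    -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n = {n} <= k + 1 = {k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)."""
    v = np.asarray(aicc_values, dtype=float)
    if v.size == 0 or not np.isfinite(v).all():
        raise ValueError("AICc values must be a non-empty finite list")
    delta = v - v.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def _null_model(model: CandidateModel) -> CandidateModel:
    if model.fixed is None:
        raise ValueError(f"model {model.name!r} has no fixed factor to test")
    return CandidateModel(
        name=f"{model.name} (null)", fixed=None,
        ag_covariate=model.ag_covariate, random_population=model.random_population,
    )


def lrt_fixed_effect(df: pd.DataFrame, model: CandidateModel, response: str) -> float:
    """Likelihood-ratio p-value for the categorical fixed factor.

    Compares the ML fit against the same model with the factor removed;
    the reference is chi-square with df = #levels - 1.
    """
    full = fit_lmm(df, model, response)
    null = fit_lmm(df, _null_model(model), response)
    dof = len(full.beta) - len(null.beta)
    lr = max(2.0 * (full.loglik - null.loglik), 0.0)
    return float(stats.chi2.sf(lr, dof))


def _fit_structure(df: pd.DataFrame, model: CandidateModel, response: str):
    """(loglik, k, n_obs, p_value or nan) of one structure on one response set."""
    if response == "AG":
        fit = fit_lmm(df, model, "AG")
        p = lrt_fixed_effect(df, model, "AG") if model.fixed else np.nan
        return fit.loglik, fit.k, fit.n, p
    # multivariate shape set: 8 independent per-feature fits on z-scored
    # responses, summed logliks and parameter counts
    z = df.copy()
    for f in SHAPE_FEATURES:
        col = z[f].astype(float)
        z[f] = (col - col.mean()) / col.std(ddof=1)
    ll = k = n = 0
    lr_sum = 0.0
    df_sum = 0
    for f in SHAPE_FEATURES:
        fit = fit_lmm(z, model, f)
        ll += fit.loglik
        k += fit.k
        n += fit.n
        if model.fixed:
            null = fit_lmm(z, _null_model(model), f)
            lr_sum += max(2.0 * (fit.loglik - null.loglik), 0.0)
            df_sum += len(fit.beta) - len(null.beta)
    p = float(stats.chi2.sf(lr_sum, df_sum)) if model.fixed else np.nan
    return ll, k, n, p


def rank_models(
    df: pd.DataFrame,
    models: list[CandidateModel] | None = None,
    response: str = "AG",
) -> pd.DataFrame:
    """Rank a candidate set by AICc with Akaike weights and fixed-factor p-values.

    ``response`` is "AG" (or any single feature name) for the univariate set,
    or "shape" for the 8-feature multivariate set.  Rows are sorted by AICc;
    weights are computed over the full candidate set.
    """
    if models is None:
        models = build_candidate_set("shape" if response == "shape" else "AG")
    rows = []
    for m in models:
        resp = response if response != "shape" else "shape"
        ll, k, n, p = _fit_structure(df, m, resp)
        rows.append({"model": m.name, "loglik": ll, "k": k, "n": n,
                     "AICc": aicc(ll, k, n), "p_value": p})
    table = pd.DataFrame(rows)
    table["delta"] = table["AICc"] - table["AICc"].min()
    table["weight"] = akaike_weights(table["AICc"].to_numpy())
    table = table.sort_values("AICc", kind="stable").reset_index(drop=True)
    return table[["model", "AICc", "delta", "weight", "p_value", "loglik", "k", "n"]]


def collinearity_screen(
    df: pd.DataFrame,
    pairs: list[tuple[str, str]] = (("SVL", "AG"), ("TL", "AG")),
    threshold: float = 0.85,
) -> pd.DataFrame:
    """Pearson correlation screen for size proxies to exclude as collinear.

    Returns one row per pair with r, the two-sided t-test p-value and a flag
    for |r| above ``threshold``.
    """
    rows = []
    for a, b in pairs:
        sub = df[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"pair ({a}, {b}): need at least 3 complete rows")
        if sub[a].std(ddof=1) == 0 or sub[b].std(ddof=1) == 0:
            raise ValueError(f"pair ({a}, {b}): zero-variance column")
        r, p = stats.pearsonr(sub[a], sub[b])
        rows.append({"x": a, "y": b, "r": float(r), "p_value": float(p),
                     "flagged": bool(abs(r) > threshold)})
    return pd.DataFrame(rows)
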