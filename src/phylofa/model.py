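"""Bayesian hierarchical regression with a phylogenetic random effect.

The model for a response :math:`y_i` observed on species :math:`i` is

.. math::

    \\text{beta family:}\\quad y_i \\sim \\mathrm{Beta}(\\mu_i\\phi,\\,(1-\\mu_i)\\phi),
    \\qquad \\operatorname{logit}\\mu_i = x_i'\\beta + u_i,

.. math::

    \\text{Gaussian family:}\\quad y_i \\sim \\mathcal N(x_i'\\beta + u_i,\\,\\sigma_e^2),

with species effects :math:`u \\sim \\mathcal N(0, \\sigma_p^2 C)` where
:math:`C` is the normalized Brownian-motion correlation matrix of the
phylogeny.  The beta family uses the mean-precision parameterization with a
logit link, the natural model for molar proportions strictly inside (0, 1).

Priors are weakly informative and configurable: improper flat priors on the
fixed effects, half-Student-t(3, 0, 2.5) on sigma_p and sigma_e, and
Gamma(0.01, 0.01) on the beta precision phi.  Inference is by adaptive
Metropolis-within-Gibbs (see :mod:`phylofa._sampler`); convergence is judged
by the Gelman-Rubin potential scale reduction factor with the conventional
1.01 threshold, and effects are summarised as posterior means of average
marginal effects with equal-tailed 95% credible intervals — an effect is
"significant" when its interval excludes zero.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import expit
from scipy.stats import beta as beta_dist

from ._sampler import run_chain
from .phylogeny import PhyloCovariance

__all__ = [
    "Predictor",
    "MCMCSettings",
    "PUBLISHED_MCMC",
    "PriorSettings",
    "ModelSpec",
    "PreparedDesign",
    "Posterior",
    "EffectSummary",
    "prepare_design",
    "fit",
    "beta_loglik",
    "phylo_prior_loglik",
    "rhat",
    "credible_interval",
    "average_marginal_effect",
    "squeeze_proportions",
]

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.01


@dataclass(frozen=True)
class Predictor:
    """One fixed-effect column: optionally log-transformed, then z-standardized."""

    name: str
    log: bool = False
    standardize: bool = True


@dataclass(frozen=True)
class MCMCSettings:
    """Chain geometry.  Retained draws = chains x (iterations - burn_in) / thinning."""

    chains: int = 4
    iterations: int = 4000
    burn_in: int = 1000
    thinning: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.chains < 1 or self.iterations <= self.burn_in:
            raise ValueError("need chains >= 1 and iterations > burn_in")
        if (self.iterations - self.burn_in) % self.thinning != 0:
            raise ValueError("(iterations - burn_in) must be divisible by thinning")

    @property
    def n_retained(self) -> int:
        return self.chains * (self.iterations - self.burn_in) // self.thinning


#: The chain geometry used for the published analysis: 25 chains of 6,000
#: iterations with 2,000 burn-in and thinning 10.
PUBLISHED_MCMC = MCMCSettings(chains=25, iterations=6000, burn_in=2000, thinning=10)


@dataclass(frozen=True)
class PriorSettings:
    """Weakly-informative defaults; all configurable."""

    sigma_p_df: float = 3.0
    sigma_p_scale: float = 2.5
    sigma_e_df: float = 3.0
    sigma_e_scale: float = 2.5
    phi_shape: float = 0.01
    phi_rate: float = 0.01


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model definition.

    ``response_scale`` applies to the beta family only: ``"percent"`` divides
    mol% responses by 100; ``"fraction"`` takes values as given.
    ``standardize_response`` applies to the Gaussian family only.
    """

    response: str
    family: str  # "beta" or "gaussian"
    predictors: tuple[Predictor, ...]
    include_phylo: bool = True
    response_scale: str = "percent"
    log_response: bool = False
    standardize_response: bool = True
    priors: PriorSettings = PriorSettings()
    mcmc: MCMCSettings = MCMCSettings()

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gaussian"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.response_scale not in ("percent", "fraction"):
            raise ValueError(f"unknown response_scale {self.response_scale!r}")
        object.__setattr__(self, "predictors", tuple(self.predictors))


@dataclass
class PreparedDesign:
    """Response, design matrix and aligned correlation matrix ready to sample.

    ``X`` carries an intercept as its first column; ``coef_names`` are the
    design column names.  ``scaling`` stores (mean, sd) per standardized
    column so effects can be mapped back to natural units.
    """

    y: np.ndarray
    X: np.ndarray
    coef_names: list[str]
    species: list[str]
    C: Optional[np.ndarray]
    family: str
    scaling: dict[str, tuple[float, float]]
    response_scaling: Optional[tuple[float, float]]
    n_dropped: int
    squeezed: bool


@dataclass
class EffectSummary:
    """Posterior summary of one average marginal effect."""

    predictor: str
    mean: float
    lower: float
    upper: float
    significant: bool


@dataclass
class Posterior:
    """Retained MCMC draws (per chain) with convergence diagnostics.

    Arrays are shaped (chains, draws_per_chain, ...).  ``u`` and ``sigma_p``
    are ``None`` when the model had no phylogenetic effect.  ``dispersion``
    is phi for the beta family and sigma_e for the Gaussian family.
    """

    beta: np.ndarray
    u: Optional[np.ndarray]
    sigma_p: Optional[np.ndarray]
    dispersion: np.ndarray
    family: str
    coef_names: list[str]
    species: list[str]
    rhat: dict[str, float]
    settings: MCMCSettings

    @property
    def dispersion_name(self) -> str:
        return "phi" if self.family == "beta" else "sigma_e"

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat <= RHAT_THRESHOLD

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0] * self.beta.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """All retained draws of one scalar parameter, chains concatenated."""
        if name in self.coef_names:
            j = self.coef_names.index(name)
            return self.beta[:, :, j].ravel()
        if name == "sigma_p" and self.sigma_p is not None:
            return self.sigma_p.ravel()
        if name == self.dispersion_name:
            return self.dispersion.ravel()
        raise KeyError(name)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior mean, equal-tailed interval and R-hat per parameter."""
        rows = []
        names = list(self.coef_names) + (
            ["sigma_p"] if self.sigma_p is not None else []
        ) + [self.dispersion_name]
        for name in names:
            d = self.stacked(name)
            lo, hi = credible_interval(d, level)
            rows.append((name, d.mean(), lo, hi, self.rhat[name]))
        return pd.DataFrame(rows, columns=["parameter", "mean", "lower", "upper",
                                           "rhat"]).set_index("parameter")

    def to_csv(self, path) -> None:
        """Export stacked draws of the non-latent parameters as CSV."""
        cols = {n: self.stacked(n) for n in self.coef_names}
        if self.sigma_p is not None:
            cols["sigma_p"] = self.stacked("sigma_p")
        cols[self.dispersion_name] = self.stacked(self.dispersion_name)
        pd.DataFrame(cols).to_csv(path, index=False)


def squeeze_proportions(y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Pull exact 0/1 proportions into the open interval.

    Applies y' = (y*(n-1) + 0.5)/n to the whole vector, but only when exact
    boundary values occur (the beta density has open support).  Returns the
    possibly-adjusted vector and whether the adjustment was applied.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError("proportions outside [0, 1]")
    if np.any((y == 0.0) | (y == 1.0)):
        n = y.size
        logger.info("boundary proportions present; squeeze transform applied (n=%d)", n)
        return (y * (n - 1) + 0.5) / n, True
    return y, False


def _zscore(x: np.ndarray, name: str) -> tuple[np.ndarray, float, float]:
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError(f"zero-variance column {name!r}; cannot standardize")
    return (x - mu) / sd, mu, sd


def prepare_design(
    traits: pd.DataFrame,
    covariance: Optional[PhyloCovariance],
    spec: ModelSpec,
) -> PreparedDesign:
    """Assemble (y, X, C) for a model, applying the declared transforms.

    Species with missing values in any used column are dropped (count
    logged).  Predictors are log-transformed where flagged and then
    z-standardized; Gaussian responses are z-standardized; beta responses are
    converted to (0, 1) fractions and boundary-squeezed if needed.
    """
    cols = [spec.response] + [p.name for p in spec.predictors]
    missing = [c for c in cols if c not in traits.columns]
    if missing:
        raise KeyError(f"columns not in trait table: {missing}")
    sub = traits[cols].dropna()
    n_dropped = len(traits) - len(sub)
    if n_dropped:
        logger.info("dropped %d species with missing values for response %r",
                    n_dropped, spec.response)
    if spec.include_phylo:
        if covariance is None:
            raise ValueError("include_phylo=True requires a covariance")
        keep = [s for s in sub.index if s in set(covariance.labels)]
        lost = len(sub) - len(keep)
        if lost:
            logger.info("dropped %d species absent from the phylogeny", lost)
            n_dropped += lost
        sub = sub.loc[keep]
    species = list(sub.index.astype(str))
    if len(species) < len(spec.predictors) + 2:
        raise ValueError(f"too few complete cases ({len(species)})")

    y = sub[spec.response].to_numpy(dtype=float)
    response_scaling = None
    squeezed = False
    if spec.family == "beta":
        if spec.response_scale == "percent":
            y = y / 100.0
        y, squeezed = squeeze_proportions(y)
    else:
        if spec.log_response:
            if np.any(y <= 0):
                raise ValueError("log response requires strictly positive values")
            y = np.log(y)
        if spec.standardize_response:
            y, mu, sd = _zscore(y, spec.response)
            response_scaling = (mu, sd)

    columns = [np.ones(len(species))]
    names = ["intercept"]
    scaling: dict[str, tuple[float, float]] = {}
    for p in spec.predictors:
        x = sub[p.name].to_numpy(dtype=float)
        if p.log:
            if np.any(x <= 0):
                raise ValueError(f"log transform of {p.name!r} requires positive values")
            x = np.log(x)
        if p.standardize:
            x, mu, sd = _zscore(x, p.name)
            scaling[p.name] = (mu, sd)
        columns.append(x)
        names.append(p.name)
    X = np.column_stack(columns)

    C = None
    if spec.include_phylo:
        C = covariance.align_to(species).matrix
        if not covariance.normalized:
            d = np.sqrt(np.diag(C))
            C = C / np.outer(d, d)
    return PreparedDesign(y=y, X=X, coef_names=names, species=species, C=C,
                          family=spec.family, scaling=scaling,
                          response_scaling=response_scaling,
                          n_dropped=n_dropped, squeezed=squeezed)


def beta_loglik(y: np.ndarray, X: np.ndarray, beta: np.ndarray,
                u: np.ndarray, phi: float) -> float:
    """Beta log-likelihood in the mean-precision parameterization.

    logit(mu_i) = x_i' beta + u_i; y_i ~ Beta(mu_i phi, (1 - mu_i) phi).
    """
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("beta responses must lie strictly in (0, 1)")
    if phi <= 0:
        raise ValueError("phi must be positive")
    mu = expit(X @ np.asarray(beta, dtype=float) + np.asarray(u, dtype=float))
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(beta_dist.logpdf(y, mu * phi, (1.0 - mu) * phi).sum())


_CHOL_CACHE: dict[bytes, tuple[np.ndarray, float]] = {}


def _cached_chol(C: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of C and log|C|, cached on the matrix bytes."""
    key = hashlib.sha1(np.ascontiguousarray(C).tobytes()).digest()
    hit = _CHOL_CACHE.get(key)
    if hit is not None:
        return hit
    try:
        L = scipy.linalg.cholesky(C, lower=True)
    except scipy.linalg.LinAlgError:
        try:
            L = scipy.linalg.cholesky(C + 1e-8 * np.eye(C.shape[0]), lower=True)
        except scipy.linalg.LinAlgError as err:
            raise ValueError("covariance not positive definite after jitter") from err
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    if len(_CHOL_CACHE) > 64:
        _CHOL_CACHE.clear()
    _CHOL_CACHE[key] = (L, logdet)
    return L, logdet


def phylo_prior_loglik(u: np.ndarray, sigma_p: float, C: np.ndarray) -> float:
    """MVN(0, sigma_p^2 C) log-density of the species effects.

    Uses a cached Cholesky factorization of C, so repeated evaluations on the
    same tree cost one triangular solve.
    """
    if sigma_p <= 0:
        raise ValueError("sigma_p must be positive")
    u = np.asarray(u, dtype=float)
    n = u.size
    L, logdet = _cached_chol(np.asarray(C, dtype=float))
    z = scipy.linalg.solve_triangular(L, u, lower=True)
    quad = float(z @ z) / sigma_p**2
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + 2.0 * n * np.log(sigma_p) + quad)


def rhat(draws: np.ndarray) -> float:
    """Classic Gelman-Rubin potential scale reduction factor.

    ``draws`` has shape (chains, draws_per_chain).  Degenerate chains (zero
    within- and between-chain variance) return exactly 1.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("rhat requires >= 2 chains of equal length")
    m, n = x.shape
    if n < 2:
        raise ValueError("rhat requires >= 2 draws per chain")
    W = float(x.var(axis=1, ddof=1).mean())
    B_over_n = float(x.mean(axis=1).var(ddof=1))
    if W == 0.0:
        return 1.0 if B_over_n == 0.0 else np.inf
    var_plus = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_plus / W))


def credible_interval(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval via linearly interpolated quantiles."""
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 100:
        raise ValueError("credible_interval requires at least 100 draws")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a], method="linear")
    return float(lo), float(hi)


def _precision(C: np.ndarray) -> np.ndarray:
    L, _ = _cached_chol(C)
    n = C.shape[0]
    Linv = scipy.linalg.solve_triangular(L, np.eye(n), lower=True)
    return Linv.T @ Linv


def fit(spec: ModelSpec, design: PreparedDesign) -> Posterior:
    """Draw from the joint posterior by adaptive Metropolis-within-Gibbs.

    Chains are initialized from overdispersed starting points with distinct
    seeds derived from ``spec.mcmc.seed``; burn-in is discarded and thinning
    applied, so the retained draw count is chains x (iterations - burn_in) /
    thinning.  If any parameter's Gelman-Rubin statistic exceeds 1.01 the
    result is flagged (not raised) via ``Posterior.converged``.
    """
    mc = spec.mcmc
    y = np.ascontiguousarray(design.y, dtype=float)
    X = np.ascontiguousarray(design.X, dtype=float)
    n, p = X.shape
    is_beta = spec.family == "beta"
    use_phylo = design.C is not None

    if is_beta:
        logy = np.log(y)
        log1my = np.log1p(-y)
    else:
        logy = np.zeros(n)
        log1my = np.zeros(n)

    if use_phylo:
        Q0 = np.ascontiguousarray(_precision(design.C))
        Lc, _ = _cached_chol(design.C)
        Lc = np.ascontiguousarray(Lc)
    else:
        Q0 = np.zeros((1, 1))
        Lc = np.zeros((1, 1))
    XtXinv = np.linalg.inv(X.T @ X)
    XtXinv_chol = np.linalg.cholesky(XtXinv)

    ss = np.random.SeedSequence(mc.seed)
    children = ss.spawn(mc.chains)
    nkeep = (mc.iterations - mc.burn_in) // mc.thinning

    beta_all = np.empty((mc.chains, nkeep, p))
    u_all = np.empty((mc.chains, nkeep, n)) if use_phylo else None
    sp_all = np.empty((mc.chains, nkeep)) if use_phylo else None
    disp_all = np.empty((mc.chains, nkeep))

    for c, child in enumerate(children):
        rng = np.random.default_rng(child)
        kernel_seed = int(child.generate_state(1, np.uint32)[0] % (2**31 - 1))
        beta0 = rng.normal(0.0, 0.5, p)
        sp0 = float(np.exp(rng.normal(np.log(0.5), 0.4))) if use_phylo else 1.0
        if use_phylo:
            u0 = sp0 * (Lc @ rng.normal(0.0, 1.0, n))
        else:
            u0 = np.zeros(n)
        if is_beta:
            disp0 = float(np.exp(rng.normal(np.log(20.0), 0.5)))
        else:
            disp0 = float(np.exp(rng.normal(np.log(max(np.std(y), 0.1)), 0.3)))
        b_dr, u_dr, sp_dr, d_dr = run_chain(
            is_beta, use_phylo, y, X, Q0, Lc, XtXinv, XtXinv_chol,
            logy, log1my, mc.iterations, mc.burn_in, mc.thinning, kernel_seed,
            spec.priors.sigma_p_df, spec.priors.sigma_p_scale,
            spec.priors.sigma_e_df, spec.priors.sigma_e_scale,
            spec.priors.phi_shape, spec.priors.phi_rate,
            beta0, u0, sp0, disp0,
        )
        beta_all[c] = b_dr
        disp_all[c] = d_dr
        if use_phylo:
            u_all[c] = u_dr
            sp_all[c] = sp_dr

    rhats: dict[str, float] = {}
    for j, name in enumerate(design.coef_names):
        rhats[name] = rhat(beta_all[:, :, j]) if mc.chains > 1 else np.nan
    disp_name = "phi" if is_beta else "sigma_e"
    if mc.chains > 1:
        rhats[disp_name] = rhat(disp_all)
        if use_phylo:
            rhats["sigma_p"] = rhat(sp_all)
            for i, sp_name in enumerate(design.species):
                rhats[f"u[{sp_name}]"] = rhat(u_all[:, :, i])
    post = Posterior(beta=beta_all, u=u_all, sigma_p=sp_all, dispersion=disp_all,
                     family=spec.family, coef_names=list(design.coef_names),
                     species=list(design.species), rhat=rhats, settings=mc)
    if mc.chains > 1 and not post.converged:
        warnings.warn(
            f"fit for {spec.response!r} flagged non-converged "
            f"(max R-hat {post.max_rhat:.3f})",
            stacklevel=2,
        )
    return post


def average_marginal_effect(
    posterior: Posterior,
    design: PreparedDesign,
    predictor: str,
    level: float = 0.95,
    include_species_effects: bool = True,
) -> EffectSummary:
    """Posterior of the average marginal effect of one predictor.

    Per draw the AME is the mean over species of d mu_i / d x_ij: for the
    Gaussian family this is just beta_j; for the beta family it is
    beta_j * mean_i[ mu_i (1 - mu_i) ] with mu_i evaluated at that draw
    (including the species effects u_i by default, since they are part of
    each species' fitted mean; set ``include_species_effects=False`` to
    average at u = 0 instead).
    """
    if predictor not in design.coef_names:
        raise KeyError(f"predictor {predictor!r} not in design columns "
                       f"{design.coef_names}")
    j = design.coef_names.index(predictor)
    chains, nkeep, p = posterior.beta.shape
    beta_flat = posterior.beta.reshape(-1, p)
    if posterior.family == "gaussian":
        ame = beta_flat[:, j]
    else:
        eta = beta_flat @ design.X.T
        if include_species_effects and posterior.u is not None:
            eta = eta + posterior.u.reshape(-1, len(design.species))
        mu = expit(eta)
        ame = beta_flat[:, j] * (mu * (1.0 - mu)).mean(axis=1)
    lo, hi = credible_interval(ame, level)
    return EffectSummary(predictor=predictor, mean=float(ame.mean()),
                         lower=lo, upper=hi,
                         significant=bool(lo > 0.0 or hi < 0.0))
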