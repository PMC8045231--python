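"""Phylogenetic generalized least squares and residual correlation structure.

PGLS is ordinary least squares with error covariance proportional to the
Brownian-motion matrix C of the phylogeny:

    beta_hat = (X' C^-1 X)^-1 X' C^-1 y,   residuals = y - X beta_hat.

The residual-correlation analysis regresses every variable on log body mass
by PGLS (after a logit transform for proportions and a log transform for the
anti-inflammatory index) and reports the Pearson correlation matrix of the
residuals — the correlation structure of fatty-acid composition once body
mass and phylogeny are partialled out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.special import logit

from .model import squeeze_proportions
from .phylogeny import PhyloCovariance

__all__ = ["PGLSFit", "pgls_fit", "residual_correlations"]


@dataclass
class PGLSFit:
    """Coefficients, species-aligned residuals and the C matrix used."""

    params: np.ndarray
    residuals: np.ndarray
    C: np.ndarray
    coef_names: Optional[list[str]] = None


def pgls_fit(y: np.ndarray, X: np.ndarray, C: np.ndarray,
             coef_names: Optional[list[str]] = None) -> PGLSFit:
    """Generalized least squares under Brownian covariance C.

    Solved via the Cholesky whitening of C; a singular X' C^-1 X raises a
    ``LinAlgError``.  With C = I this reduces exactly to OLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = y.size
    if X.shape[0] != n or C.shape != (n, n):
        raise ValueError("y, X, C are not species-aligned")
    L = scipy.linalg.cholesky(C, lower=True)
    Xw = scipy.linalg.solve_triangular(L, X, lower=True)
    yw = scipy.linalg.solve_triangular(L, y, lower=True)
    A = Xw.T @ Xw
    cond = np.linalg.cond(A)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"X' C^-1 X is singular or near-singular (cond={cond:.2e})"
        )
    params = np.linalg.solve(A, Xw.T @ yw)
    return PGLSFit(params=params, residuals=y - X @ params, C=C,
                   coef_names=coef_names)


def _transform(values: np.ndarray, how: str) -> np.ndarray:
    if how == "none":
        return values.astype(float)
    if how == "log":
        if np.any(values <= 0):
            raise ValueError("log transform requires strictly positive values")
        return np.log(values)
    if how == "logit":
        y = np.asarray(values, dtype=float)
        if y.max() > 1.0:  # mol% scale
            y = y / 100.0
        y, _ = squeeze_proportions(y)
        return logit(y)
    raise ValueError(f"unknown transform {how!r}")


def residual_correlations(
    table: pd.DataFrame,
    covariance: PhyloCovariance,
    transforms: Mapping[str, str],
    body_mass_col: str = "body_mass_g",
) -> pd.DataFrame:
    """Pairwise Pearson correlations of PGLS residuals on log body mass.

    Each variable named in ``transforms`` (values: "logit", "log" or "none";
    proportions on the mol% scale are converted to fractions and
    boundary-squeezed before the logit) is regressed on an intercept and log
    body mass by PGLS; correlations are computed between the residual vectors
    on the species complete for each pair.
    """
    if body_mass_col not in table.columns:
        raise KeyError(f"{body_mass_col!r} not in table")
    variables = list(transforms)
    resids: dict[str, pd.Series] = {}
    for var in variables:
        sub = table[[var, body_mass_col]].dropna()
        species = [s for s in sub.index if s in set(covariance.labels)]
        sub = sub.loc[species]
        y = _transform(sub[var].to_numpy(), transforms[var])
        X = np.column_stack([np.ones(len(sub)), np.log(sub[body_mass_col].to_numpy())])
        C = covariance.align_to(list(sub.index)).matrix
        fit = pgls_fit(y, X, C, coef_names=["intercept", "log_body_mass"])
        resids[var] = pd.Series(fit.residuals, index=sub.index)

    out = pd.DataFrame(np.eye(len(variables)), index=variables, columns=variables)
    for i, a in enumerate(variables):
        for b in variables[i + 1:]:
            joint = pd.concat([resids[a], resids[b]], axis=1, join="inner").dropna()
            r = float(np.corrcoef(joint.iloc[:, 0], joint.iloc[:, 1])[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out


def plot_correlation_heatmap(corr: pd.DataFrame, path=None):
    """Convenience heatmap of a residual-correlation matrix."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(0.5 * len(corr) + 2,) * 2)
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr)), corr.columns, rotation=90)
    ax.set_yticks(range(len(corr)), corr.index)
    fig.colorbar(im, ax=ax, label="Pearson r (PGLS residuals)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
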