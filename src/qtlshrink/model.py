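"""Variance-component model, priors and density utilities.

The phenotypes of n offspring in independent full-sib families follow

    y = X beta + sum_j a_j + g + e,       a_j ~ N(0, sigma2_j Pi_j),
    g ~ N(0, sigma2_A A),                 e ~ N(0, sigma2_e I),

so that  V = sum_j sigma2_j Pi_j + sigma2_A A + sigma2_e I  is block-diagonal
over families.  Pi_j is the expected-IBD matrix at the j-th QTL position and
A the additive relationship matrix; in a genome-wide scan the polygenic term
is dropped (all QTL are in the model).

Priors: the scale-invariant Jeffreys prior 1/(sigma2_j + delta) on each QTL
variance — the shrinkage engine that drives zero-effect QTL variances toward
zero (delta = 0 by default); scaled inverse chi-square (omega, s2) on the
polygenic and residual variances; N(beta0, V0) on the covariate effects; and
a uniform prior on QTL positions.

The scaled inverse chi-square convention used throughout:
density proportional to x^(-nu/2 - 1) exp(-nu s2 / (2 x)), with mean
nu s2 / (nu - 2) for nu > 2 and mode nu s2 / (nu + 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = [
    "ModelSpec", "ChainState", "max_qtl_number", "build_covariance",
    "loglik", "scaled_inv_chisq_logpdf", "scaled_inv_chisq_rvs", "log_priors",
]


def max_qtl_number(q0: float) -> int:
    """Maximum QTL number from the expected number: q = q0 + 3 sqrt(q0)."""
    if q0 <= 0:
        raise ValueError("expected QTL number must be positive")
    return int(round(q0 + 3.0 * math.sqrt(q0)))


@dataclass
class ModelSpec:
    """Model dimensions and prior hyper-parameters.

    ``s2_A``/``s2_e`` default (when left ``None``) to prior-mean matching of
    the empirical phenotypic variance: s2 = Vp (omega - 2) / omega, which
    makes the prior expectation of the variance equal Vp; with omega = 3 the
    prior is weak, so the exact value has little influence.
    """

    q: int = 6
    include_polygenic: bool = True
    omega_A: float = 3.0
    s2_A: float = None
    omega_e: float = 3.0
    s2_e: float = None
    delta: float = 0.0
    beta0: np.ndarray = None
    V0: np.ndarray = None

    def __post_init__(self):
        if self.q < 1:
            raise ValueError("maximum QTL number must be >= 1")
        if self.omega_A <= 0 or self.omega_e <= 0:
            raise ValueError("prior degrees of freedom must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")

    def resolve(self, y: np.ndarray, k: int) -> "ModelSpec":
        """Fill data-dependent defaults from the phenotype vector."""
        vp = float(np.var(y))
        out = ModelSpec(**{**self.__dict__})
        if out.s2_A is None:
            out.s2_A = vp * (out.omega_A - 2.0) / out.omega_A \
                if out.omega_A > 2 else vp
        if out.s2_e is None:
            out.s2_e = vp * (out.omega_e - 2.0) / out.omega_e \
                if out.omega_e > 2 else vp
        if out.beta0 is None:
            out.beta0 = np.zeros(k)
        if out.V0 is None:
            out.V0 = np.eye(k) * 1e6 * max(vp, 1.0)
        return out


@dataclass
class ChainState:
    """Current parameter values of the Markov chain."""

    beta: np.ndarray          # (k,)
    sigma2: np.ndarray        # (q,) QTL variances
    pos: np.ndarray           # (q,) QTL positions, global cM
    sigma2_A: float
    sigma2_e: float

    def copy(self) -> "ChainState":
        return ChainState(self.beta.copy(), self.sigma2.copy(),
                          self.pos.copy(), self.sigma2_A, self.sigma2_e)


# ----------------------------------------------------------------------
# likelihood (reference, per-family dense blocks)
# ----------------------------------------------------------------------
def build_covariance(state: ChainState, ibd_blocks, a_blocks,
                     include_polygenic: bool = True):
    """Per-family covariance blocks V_f = sum_j s2_j Pi_jf + s2_A A_f + s2_e I.

    ``ibd_blocks[j][f]`` is the IBD matrix of family f at the j-th QTL
    position; ``a_blocks[f]`` the family's additive-relationship block.
    Raises if a block is not numerically positive definite.
    """
    nfam = len(a_blocks)
    out = []
    for f in range(nfam):
        s = a_blocks[f].shape[0]
        V = state.sigma2_e * np.eye(s)
        if include_polygenic:
            V += state.sigma2_A * a_blocks[f]
        for j in range(len(state.sigma2)):
            V += state.sigma2[j] * ibd_blocks[j][f]
        try:
            scipy.linalg.cholesky(V, lower=True)
        except scipy.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"covariance block of family {f} is not positive definite"
            ) from exc
        out.append(V)
    return out


def loglik(y, X, state: ChainState, blocks) -> float:
    """Gaussian log-likelihood, computed family-wise by Cholesky."""
    yc = np.asarray(y, dtype=float) - np.asarray(X, dtype=float) @ state.beta
    total = 0.0
    start = 0
    for V in blocks:
        s = V.shape[0]
        r = yc[start:start + s]
        c, low = scipy.linalg.cho_factor(V, lower=True)
        z = scipy.linalg.solve_triangular(c, r, lower=True)
        total += -0.5 * (s * math.log(2 * math.pi)
                         + 2.0 * np.sum(np.log(np.diag(c)))
                         + z @ z)
        start += s
    return float(total)


# ----------------------------------------------------------------------
# densities and priors
# ----------------------------------------------------------------------
def scaled_inv_chisq_logpdf(x, df, scale):
    """Log-density of the scaled inverse chi-square distribution."""
    x = np.asarray(x, dtype=float)
    if df <= 0 or scale <= 0:
        raise ValueError("df and scale must be positive")
    if np.any(x <= 0):
        raise ValueError("x must be positive")
    h = 0.5 * df
    return (h * np.log(h * scale) - math.lgamma(h)
            - (h + 1.0) * np.log(x) - h * scale / x)


def scaled_inv_chisq_rvs(df, scale, size=None, rng=None):
    """Draw from the scaled inverse chi-square: df * scale / chi2_df."""
    rng = np.random.default_rng() if rng is None else rng
    return df * scale / rng.chisquare(df, size=size)


def log_priors(state: ChainState, spec: ModelSpec) -> float:
    """Joint log-prior of a chain state (positions contribute a constant)."""
    lp = -np.sum(np.log(state.sigma2 + spec.delta))
    if spec.include_polygenic:
        lp += float(scaled_inv_chisq_logpdf(state.sigma2_A,
                                            spec.omega_A, spec.s2_A))
    lp += float(scaled_inv_chisq_logpdf(state.sigma2_e,
                                        spec.omega_e, spec.s2_e))
    d = state.beta - spec.beta0
    V0 = np.atleast_2d(spec.V0)
    c, low = scipy.linalg.cho_factor(V0, lower=True)
    z = scipy.linalg.solve_triangular(c, d, lower=True)
    lp += -0.5 * (len(d) * math.log(2 * math.pi)
                  + 2.0 * np.sum(np.log(np.diag(c))) + z @ z)
    return float(lp)
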