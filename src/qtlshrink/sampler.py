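"""MCMC engine: Gibbs update of covariate effects, random-walk
Metropolis-Hastings on every variance component, and uniform random-walk
position moves.

Variance proposals follow Browne's scheme: a new value sigma2* is drawn from
a scaled inverse chi-square with degrees of freedom nu and scale
sigma2 (nu - 2) / nu, so the proposal's expectation equals the current value
(nu is the tuning parameter: larger nu means a tighter proposal and a higher
acceptance rate).  The asymmetric proposal requires the Hastings ratio
q(old | new) / q(new | old) in the acceptance probability.  Position
proposals add a uniform(-k, k) cM perturbation, reflected at the chromosome
ends, with Hastings ratio 1.

Per iteration the order is: beta, each QTL variance, the polygenic variance
(when in the model), the residual variance, then each QTL position.
Post-burn-in states are saved every ``thin`` iterations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .ibd import IbdEngine
from .model import ChainState, ModelSpec

__all__ = [
    "McmcConfig", "SampleStore", "MappingContext", "propose_variance",
    "mh_update_variance", "gibbs_update_beta", "mh_update_position",
    "run_chain",
]


@dataclass
class McmcConfig:
    """Chain length and proposal tuning.

    ``variance_floor`` truncates the support of every variance component:
    under the Jeffreys prior the log-variance of a zero-effect QTL performs
    an unbounded random walk toward zero, so proposals below the floor are
    rejected (a reflecting barrier). The floor depth also sets how quickly
    a shrunk component can be re-activated when it wanders onto an
    undiscovered QTL — the walk back up is O((log floor)^2) iterations —
    so it is kept as shallow as scientific irrelevance allows: 1e-6 is
    four orders of magnitude below any detectable QTL variance.
    """

    n_iter: int = 21_000
    burnin: int = 1_000
    thin: int = 10
    nu: float = 10.0
    nu_A: float = 10.0
    nu_e: float = 10.0
    k_cm: float = 1.0
    seed: int = 0
    variance_floor: float = 1e-6
    rebuild_every: int = 1_000

    def __post_init__(self):
        if not (0 <= self.burnin < self.n_iter):
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")
        for nu in (self.nu, self.nu_A, self.nu_e):
            if nu <= 2:
                raise ValueError("proposal df must exceed 2 "
                                 "(mean-matched scale undefined otherwise)")
        if self.k_cm <= 0:
            raise ValueError("position tuning k must be positive")
        if max(self.nu, self.nu_A, self.nu_e) > 200:
            warnings.warn("proposal df > 200: the shrinkage character of the "
                          "sampler is hardly held", stacklevel=2)

    @property
    def n_samples(self) -> int:
        return (self.n_iter - self.burnin) // self.thin


@dataclass
class SampleStore:
    """Thinned post-burn-in draws plus acceptance accounting."""

    beta: np.ndarray          # (S, k)
    sigma2: np.ndarray        # (S, q)
    pos: np.ndarray           # (S, q) global cM
    sigma2_A: np.ndarray      # (S,)
    sigma2_e: np.ndarray      # (S,)
    accept: dict              # name -> [accepted, proposed]
    spec: ModelSpec = None
    config: McmcConfig = None
    genome: object = None

    @property
    def n_samples(self) -> int:
        return self.beta.shape[0]

    @property
    def q(self) -> int:
        return self.sigma2.shape[1]

    def acceptance_rates(self) -> dict:
        out = {}
        for k, v in self.accept.items():
            v = np.atleast_2d(v)
            with np.errstate(invalid="ignore"):
                out[k] = v[:, 0] / np.where(v[:, 1] > 0, v[:, 1], np.nan)
        return out

    def mean_variance_acceptance(self) -> float:
        """Average M-H acceptance rate over all variance components."""
        acc = prop = 0
        for k, v in self.accept.items():
            if k.startswith("sigma2"):
                v = np.asarray(v)
                acc += int(v[..., 0].sum())
                prop += int(v[..., 1].sum())
        return acc / prop if prop else np.nan


class MappingContext:
    """Mutable sampler state bound to one dataset.

    Keeps the flattened per-family covariance blocks V and the current IBD
    blocks of every QTL, so each Metropolis step costs one block Cholesky
    sweep.  ``q = 0`` is allowed (no QTL in the model) for reduced models.
    """

    def __init__(self, dataset, spec: ModelSpec, engine: IbdEngine = None,
                 config: McmcConfig = None, state: ChainState = None):
        self.dataset = dataset
        self.genome = dataset.genome
        self.y = dataset.y
        self.X = dataset.X
        self.spec = spec.resolve(self.y, self.X.shape[1])
        self.config = config or McmcConfig()
        self.sizes = dataset.family_sizes
        self.yoff = np.concatenate([[0], np.cumsum(self.sizes)])[:-1]
        self.boff = np.concatenate(
            [[0], np.cumsum(self.sizes.astype(np.int64) ** 2)])[:-1]
        self.n_block = int(np.sum(self.sizes.astype(np.int64) ** 2))
        self.engine = engine
        if engine is None and self.spec.q > 0:
            self.engine = IbdEngine(dataset)

        # flat block templates
        self.diag_flat = np.zeros(self.n_block)
        self.a_flat = np.zeros(self.n_block)
        for f, s in enumerate(self.sizes):
            b = self.boff[f]
            blk = np.full((s, s), 0.5) + 0.5 * np.eye(s)
            self.a_flat[b:b + s * s] = blk.ravel()
            self.diag_flat[b:b + s * s] = np.eye(s).ravel()

        self.state = state or self._initial_state()
        q = len(self.state.sigma2)
        self.Pi = np.empty((q, self.n_block))
        for j in range(q):
            self.Pi[j] = self.engine.blocks_at(self.state.pos[j])
        self.yc = self.y - self.X @ self.state.beta
        self.V = np.empty(self.n_block)
        self.rebuild()

        self.accept = {"sigma2_qtl": np.zeros((max(q, 1), 2), dtype=np.int64),
                       "sigma2_A": np.zeros(2, dtype=np.int64),
                       "sigma2_e": np.zeros(2, dtype=np.int64),
                       "position": np.zeros((max(q, 1), 2), dtype=np.int64)}
        self._scratch = np.empty(self.n_block)
        self._posbuf = np.empty(self.n_block)

    def _initial_state(self) -> ChainState:
        """Overdispersed but legal starting values."""
        q = self.spec.q
        vp = float(np.var(self.y))
        k = self.X.shape[1]
        beta = np.zeros(k)
        if np.allclose(self.X[:, 0], 1.0):
            beta[0] = float(np.mean(self.y))
        total = self.genome.total_length
        pos = (np.arange(q) + 0.5) / q * total
        return ChainState(
            beta=beta,
            sigma2=np.full(q, vp / (2.0 * max(q, 1))),
            pos=pos,
            sigma2_A=vp / 2.0 if self.spec.include_polygenic else 0.0,
            sigma2_e=vp / 2.0,
        )

    # -- covariance bookkeeping ----------------------------------------
    def rebuild(self):
        st = self.state
        V = st.sigma2_e * self.diag_flat
        if self.spec.include_polygenic:
            V += st.sigma2_A * self.a_flat
        for j in range(len(st.sigma2)):
            V += st.sigma2[j] * self.Pi[j]
        self.V = V
        self.ll = self.loglik_of(V)

    def loglik_of(self, V) -> float:
        return _kernels.chol_loglik(V, self.yc, self.sizes, self.yoff,
                                    self.boff)


# ----------------------------------------------------------------------
# updates
# ----------------------------------------------------------------------
def _sichi2_logpdf(x: float, nu: float, s2: float) -> float:
    """Scalar scaled-inverse-chi-square log-density (fast path)."""
    h = 0.5 * nu
    return (h * math.log(h * s2) - math.lgamma(h)
            - (h + 1.0) * math.log(x) - h * s2 / x)


def propose_variance(current: float, nu: float, rng) -> tuple:
    """Mean-matched scaled inverse chi-square proposal and log Hastings ratio.

    The proposal sigma2* ~ ScaledInvChi2(nu, current (nu-2)/nu) has
    expectation equal to ``current``.  Returns ``(proposal, log_hr)`` with
    log_hr = log q(current | proposal) - log q(proposal | current).
    """
    if nu <= 2:
        raise ValueError("nu must exceed 2")
    if current <= 0:
        raise ValueError("current variance must be positive")
    prop = current * (nu - 2.0) / rng.chisquare(nu)
    log_hr = (_sichi2_logpdf(current, nu, prop * (nu - 2.0) / nu)
              - _sichi2_logpdf(prop, nu, current * (nu - 2.0) / nu))
    return float(prop), float(log_hr)


def mh_update_variance(ctx: MappingContext, component, rng) -> bool:
    """One Metropolis-Hastings update of a variance component.

    ``component`` is ``("qtl", j)``, ``"polygenic"`` or ``"residual"``.
    Acceptance probability min(1, exp(dloglik + dlogprior + log_hr)).
    """
    st, spec, cfg = ctx.state, ctx.spec, ctx.config
    if isinstance(component, tuple):
        _, j = component
        cur = st.sigma2[j]
        nu = cfg.nu
        block = ctx.Pi[j]
        counter = ctx.accept["sigma2_qtl"][j]
    elif component == "polygenic":
        cur = st.sigma2_A
        nu = cfg.nu_A
        block = ctx.a_flat
        counter = ctx.accept["sigma2_A"]
    elif component == "residual":
        cur = st.sigma2_e
        nu = cfg.nu_e
        block = ctx.diag_flat
        counter = ctx.accept["sigma2_e"]
    else:
        raise ValueError(f"unknown component {component!r}")

    counter[1] += 1
    prop, log_hr = propose_variance(cur, nu, rng)
    if prop < cfg.variance_floor:
        return False
    if isinstance(component, tuple):
        dprior = (math.log(cur + spec.delta) - math.log(prop + spec.delta))
    elif component == "polygenic":
        dprior = (_sichi2_logpdf(prop, spec.omega_A, spec.s2_A)
                  - _sichi2_logpdf(cur, spec.omega_A, spec.s2_A))
    else:
        dprior = (_sichi2_logpdf(prop, spec.omega_e, spec.s2_e)
                  - _sichi2_logpdf(cur, spec.omega_e, spec.s2_e))
    ll_new = _kernels.chol_loglik_delta(ctx.V, block, prop - cur, ctx.yc,
                                        ctx.sizes, ctx.yoff, ctx.boff)
    log_r = (ll_new - ctx.ll) + dprior + log_hr
    if math.log(rng.random()) < log_r:
        ctx.V += (prop - cur) * block
        ctx.ll = ll_new
        if isinstance(component, tuple):
            st.sigma2[component[1]] = prop
        elif component == "polygenic":
            st.sigma2_A = prop
        else:
            st.sigma2_e = prop
        counter[0] += 1
        return True
    return False


def gibbs_update_beta(ctx: MappingContext, rng) -> np.ndarray:
    """Draw beta from its full conditional N(C (X'V^-1 y + V0^-1 b0), C)."""
    k = ctx.X.shape[1]
    XtViX = np.empty((k, k))
    XtViy = np.empty(k)
    bad = _kernels.beta_suffstats(ctx.V, ctx.X, ctx.y, ctx.sizes, ctx.yoff,
                                  ctx.boff, XtViX, XtViy)
    if bad:
        raise np.linalg.LinAlgError("non-positive-definite covariance block")
    V0inv = np.linalg.inv(np.atleast_2d(ctx.spec.V0))
    prec = XtViX + V0inv
    C = np.linalg.inv(prec)
    mean = C @ (XtViy + V0inv @ ctx.spec.beta0)
    beta = mean + np.linalg.cholesky(C) @ rng.standard_normal(k)
    ctx.state.beta = beta
    ctx.yc = ctx.y - ctx.X @ beta
    ctx.ll = ctx.loglik_of(ctx.V)
    return beta


def _reflect(x, lo, hi):
    width = hi - lo
    if width <= 0:
        return lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        if x > hi:
            x = 2 * hi - x
    return x


def mh_update_position(ctx: MappingContext, j: int, rng) -> bool:
    """Uniform random-walk move of QTL position j, reflected at the
    chromosome ends; accepted with min(1, likelihood ratio)."""
    st, cfg = ctx.state, ctx.config
    genome = ctx.genome
    c, _ = genome.to_local_scalar(float(st.pos[j]))
    lo = float(genome.chrom_offsets[c])
    hi = lo + genome.lengths[c]
    ctx.accept["position"][j][1] += 1
    new = _reflect(st.pos[j] + rng.uniform(-cfg.k_cm, cfg.k_cm), lo, hi)
    new_row = ctx.engine.blocks_at(new, out=ctx._posbuf)
    sig = st.sigma2[j]
    ll_new = _kernels.chol_loglik_swap(ctx.V, ctx.Pi[j], new_row, sig,
                                       ctx.yc, ctx.sizes, ctx.yoff, ctx.boff)
    if math.log(rng.random()) < ll_new - ctx.ll:
        old = ctx.Pi[j]
        ctx._scratch[:] = new_row
        ctx._scratch -= old
        ctx._scratch *= sig
        ctx.V += ctx._scratch
        ctx.ll = ll_new
        ctx.Pi[j] = new_row
        st.pos[j] = new
        ctx.accept["position"][j][0] += 1
        return True
    return False


# ----------------------------------------------------------------------
# chain driver
# ----------------------------------------------------------------------
def run_chain(dataset, spec: ModelSpec, config: McmcConfig = None,
              engine: IbdEngine = None, progress=None) -> SampleStore:
    """Run one complete chain and return the thinned post-burn-in draws.

    ``progress``, if given, is called as ``progress(iteration, ctx)`` every
    1,000 iterations.
    """
    config = config or McmcConfig()
    rng = np.random.default_rng(config.seed)
    ctx = MappingContext(dataset, spec, engine=engine, config=config)
    q = len(ctx.state.sigma2)
    S = config.n_samples
    k = ctx.X.shape[1]
    out = SampleStore(
        beta=np.empty((S, k)), sigma2=np.empty((S, q)), pos=np.empty((S, q)),
        sigma2_A=np.empty(S), sigma2_e=np.empty(S),
        accept=ctx.accept, spec=ctx.spec, config=config, genome=ctx.genome)
    row = 0
    for it in range(1, config.n_iter + 1):
        gibbs_update_beta(ctx, rng)
        for j in range(q):
            mh_update_variance(ctx, ("qtl", j), rng)
        if ctx.spec.include_polygenic:
            mh_update_variance(ctx, "polygenic", rng)
        mh_update_variance(ctx, "residual", rng)
        for j in range(q):
            mh_update_position(ctx, j, rng)
        if it % config.rebuild_every == 0:
            ctx.rebuild()
            if progress is not None:
                progress(it, ctx)
        if it > config.burnin and (it - config.burnin) % config.thin == 0:
            st = ctx.state
            out.beta[row] = st.beta
            out.sigma2[row] = st.sigma2
            out.pos[row] = st.pos
            out.sigma2_A[row] = st.sigma2_A
            out.sigma2_e[row] = st.sigma2_e
            row += 1
    assert row == S
    return out
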