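"""Spike-and-slab hierarchical Bayesian model for GWAS, fit by Gibbs sampling.

Model
-----
    y = X beta + W b + e,        e ~ N(0, sigma_e^2 I_n)
    b_j | I_j = 1  ~ N(0, sigma_b^2)
    b_j | I_j = 0  =  0            (or N(0, spike_sd^2) when spike_sd > 0)
    I_j ~ Bernoulli(p) independently across the N SNPs

with conjugate hyperpriors  p ~ Beta(1, 1),  sigma_b^2 ~ IG(0.001, 0.001),
sigma_e^2 ~ IG(0.001, 0.001), and independent N(0, sigma_a^2) priors on the
fixed effects with sigma_a = 1e5.  W is the column-standardized genotype
matrix, so under linkage equilibrium the genetic variance is approximately
sigma_b^2 times the number of slab SNPs, and

    PVE = sigma_g^2 / (sigma_g^2 + sigma_e^2),   sigma_g^2 = sigma_b^2 * k.

Sampler
-------
Each sweep updates, in order: (I_j, b_j) per SNP, then beta, then the two
variances, then p.  The indicator is drawn from its full conditional with
b_j integrated out (collapsed update): with partial residual r_j (the
residual with SNP j's contribution added back), s_j = w_j'w_j and
m_j = w_j'r_j,

    v1   = 1 / (s_j/sigma_e^2 + 1/sigma_b^2)
    mu1  = v1 * m_j / sigma_e^2
    logBF = 0.5*log(v1/sigma_b^2) + mu1^2/(2 v1)
    odds(I_j=1) = p/(1-p) * exp(logBF)

then b_j | I_j=1 ~ N(mu1, v1) and b_j | I_j=0 = 0 (or the analogous spike
conditional).  Because only the active columns enter the likelihood, the
cost per sweep is O(nN) regardless of how many SNPs are active, which is
what makes the sampler practical at N ~ 1e5.  An optional joint redraw of
the active block uses an exact n-rank sampler (Woodbury identity) when the
active set is larger than the sample count.

Two engines produce the same chain law: a pure-numpy reference built from
the exposed full-conditional operations, and a numba kernel used by default
for long chains.  The two engines consume different RNG streams, so draws
agree in distribution, not bit-for-bit across engines; each engine is
bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from numba import njit

logger = logging.getLogger("hbmix")

_TINY_GAMMA = 1e-300  # underflow guard for inverse-gamma draws


@dataclass
class HBMPriors:
    """Hyperparameters of the hierarchical model (Methods defaults)."""

    p_alpha: float = 1.0
    p_beta: float = 1.0
    a1: float = 0.001  # sigma_b^2 ~ IG(a1, b1)
    b1: float = 0.001
    a2: float = 0.001  # sigma_e^2 ~ IG(a2, b2)
    b2: float = 0.001
    beta_prior_sd: float = 1e5  # sigma_a; prior s.d. of each fixed effect
    spike_sd: float = 0.0  # 0 = exact point mass; 0.01 = mixture-normal spike

    def __post_init__(self) -> None:
        for name in ("p_alpha", "p_beta", "a1", "b1", "a2", "b2",
                     "beta_prior_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"prior parameter {name} must be positive")
        if self.spike_sd < 0:
            raise ValueError("spike_sd must be >= 0")


@dataclass
class ChainConfig:
    """MCMC settings.  Defaults follow the 5,000-burn-in / 2,000-retained
    schedule; scaled-down studies shorten both."""

    n_burnin: int = 5000
    n_keep: int = 2000
    thinning: int = 1
    seed: int = 0
    engine: Literal["numba", "numpy"] = "numba"
    scan_order: Literal["sequential", "random"] = "sequential"
    update_hyperparams: bool = True  # freeze (p, sigma_b2, sigma_e2) if False
    update_beta: bool = True
    block_refresh: bool = False  # joint active-block redraw each sweep (numpy engine)
    init_p: float = 0.01
    init_sigma_b2: float = 0.1
    init_sigma_e2: float | None = None  # None -> Var(y)/2

    def __post_init__(self) -> None:
        if self.n_burnin < 0 or self.n_keep < 1 or self.thinning < 1:
            raise ValueError("need n_burnin >= 0, n_keep >= 1, thinning >= 1")
        if not 0.0 < self.init_p < 1.0:
            raise ValueError("init_p must be in (0,1)")


@dataclass
class GibbsState:
    """Current sampler state plus cached data references."""

    y: np.ndarray
    X: np.ndarray
    W: np.ndarray
    beta: np.ndarray
    b: np.ndarray
    I: np.ndarray
    p: float
    sigma_b2: float
    sigma_e2: float
    r: np.ndarray  # residual cache y - X beta - W b
    col_ss: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.col_ss is None:
            self.col_ss = np.einsum("ij,ij->j", self.W, self.W)

    @property
    def k_active(self) -> int:
        return int(self.I.sum())

    def residual_drift(self) -> float:
        """Max abs deviation of the residual cache from its definition."""
        exact = self.y - self.X @ self.beta - self.W @ self.b
        return float(np.max(np.abs(self.r - exact)))

    def refresh_residual(self) -> None:
        self.r = self.y - self.X @ self.beta - self.W @ self.b


@dataclass
class PosteriorSamples:
    """Retained draws, draw-major, plus derived summaries."""

    beta: np.ndarray  # (T, q)
    b: np.ndarray  # (T, N)
    I: np.ndarray  # (T, N) uint8
    p: np.ndarray  # (T,)
    sigma_b2: np.ndarray
    sigma_e2: np.ndarray
    var_g_empirical: np.ndarray  # per-draw Var(W b)
    covariate_names: list[str] | None = None

    @property
    def n_draws(self) -> int:
        return self.p.size

    @property
    def n_snps(self) -> int:
        return self.b.shape[1]

    def pip(self) -> np.ndarray:
        return compute_pip(self)

    def pve_draws(self, method: Literal["model", "empirical"] = "model",
                  ) -> np.ndarray:
        """Per-draw PVE.  'model': sigma_g^2 = sigma_b^2 * k_active (the
        slab-count convention); 'empirical': sigma_g^2 = Var(W b)."""
        if method == "model":
            sg2 = self.sigma_b2 * self.I.sum(axis=1)
        elif method == "empirical":
            sg2 = self.var_g_empirical
        else:
            raise ValueError(f"unknown PVE method {method!r}")
        return sg2 / (sg2 + self.sigma_e2)

    def pve(self, method: Literal["model", "empirical"] = "model",
            ) -> tuple[float, float]:
        d = self.pve_draws(method)
        return float(d.mean()), float(d.std(ddof=0))


# ---------------------------------------------------------------------------
# full-conditional operations (pure-numpy reference path)
# ---------------------------------------------------------------------------

def _slab_conditional(m: float, s: float, sigma2: float, sigma_e2: float,
                      ) -> tuple[float, float, float]:
    """Posterior (mean, var) of one effect with prior N(0, sigma2) given
    sufficient statistics (m, s), plus the log marginal-likelihood gain of
    that prior over a point mass at zero."""
    v = 1.0 / (s / sigma_e2 + 1.0 / sigma2)
    mu = v * m / sigma_e2
    log_ml_gain = 0.5 * (np.log(v) - np.log(sigma2)) + 0.5 * mu * mu / v
    return mu, v, log_ml_gain


def sample_indicator_and_effect(j: int, state: GibbsState, priors: HBMPriors,
                                rng: np.random.Generator) -> None:
    """Collapsed update of (I_j, b_j): draw I_j from its full conditional
    with b_j integrated out, then b_j from its conditional given I_j.
    Updates the residual cache incrementally in O(n)."""
    wj = state.W[:, j]
    if state.b[j] != 0.0:
        state.r += wj * state.b[j]  # add SNP j's contribution back
    m = float(wj @ state.r)
    s = float(state.col_ss[j])
    mu1, v1, log_bf = _slab_conditional(m, s, state.sigma_b2, state.sigma_e2)
    spike_var = priors.spike_sd ** 2
    if spike_var > 0.0:
        mu0, v0, gain0 = _slab_conditional(m, s, spike_var, state.sigma_e2)
        log_bf -= gain0
    log_odds = np.log(state.p) - np.log1p(-state.p) + log_bf
    pr1 = 1.0 / (1.0 + np.exp(-log_odds))
    if rng.random() < pr1:
        state.I[j] = 1
        new_b = mu1 + np.sqrt(v1) * rng.standard_normal()
    else:
        state.I[j] = 0
        if spike_var > 0.0:
            new_b = mu0 + np.sqrt(v0) * rng.standard_normal()
        else:
            new_b = 0.0
    state.b[j] = new_b
    if new_b != 0.0:
        state.r -= wj * new_b


def _active_posterior_direct(WA: np.ndarray, v: np.ndarray, sigma_b2: float,
                             sigma_e2: float) -> tuple[np.ndarray, np.ndarray]:
    """Mean and covariance of the active-block conditional via the k x k
    normal equations."""
    k = WA.shape[1]
    Q = WA.T @ WA / sigma_e2 + np.eye(k) / sigma_b2
    cov = np.linalg.inv(Q)
    mean = cov @ (WA.T @ v) / sigma_e2
    return mean, cov


def _active_posterior_woodbury(WA: np.ndarray, v: np.ndarray, sigma_b2: float,
                               sigma_e2: float) -> tuple[np.ndarray, np.ndarray]:
    """Same conditional computed through the Woodbury identity, so the only
    factorization is n x n (rank = number of observations)."""
    n = WA.shape[0]
    k = WA.shape[1]
    M = sigma_b2 * (WA @ WA.T) + sigma_e2 * np.eye(n)
    Minv_WA = np.linalg.solve(M, WA)
    cov = sigma_b2 * np.eye(k) - sigma_b2 ** 2 * (WA.T @ Minv_WA)
    mean = sigma_b2 * (WA.T @ np.linalg.solve(M, v))
    return mean, cov


def sample_active_block(state: GibbsState, priors: HBMPriors,
                        rng: np.random.Generator) -> None:
    """Joint redraw of all active effects from their multivariate normal
    full conditional.  Uses a direct k x k Cholesky when k <= n; otherwise
    the exact n-rank sampler of the Woodbury/Matheron form, so the
    factorized matrix never exceeds rank min(n, k)."""
    if priors.spike_sd > 0.0:
        raise NotImplementedError("block refresh requires the point-mass spike")
    active = np.flatnonzero(state.I == 1)
    if active.size == 0:
        raise ValueError("active set is empty")
    WA = state.W[:, active]
    v = state.r + WA @ state.b[active]  # residual excluding active block
    n, k = WA.shape
    sb2, se2 = state.sigma_b2, state.sigma_e2
    if k <= n:
        Q = WA.T @ WA / se2 + np.eye(k) / sb2
        try:
            L = np.linalg.cholesky(Q)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(Q + 1e-8 * np.eye(k))
        mean = np.linalg.solve(Q, WA.T @ v / se2)
        draw = mean + np.linalg.solve(L.T, rng.standard_normal(k))
    else:
        # Matheron-rule sampler: exact draw with one n x n factorization
        u = rng.standard_normal(k) * np.sqrt(sb2)
        delta = rng.standard_normal(n) * np.sqrt(se2)
        M = sb2 * (WA @ WA.T) + se2 * np.eye(n)
        try:
            w = np.linalg.solve(M, v - WA @ u - delta)
        except np.linalg.LinAlgError:
            w = np.linalg.solve(M + 1e-8 * np.eye(n), v - WA @ u - delta)
        draw = u + sb2 * (WA.T @ w)
    state.b[active] = draw
    state.r = v - WA @ draw


def sample_fixed_effects(state: GibbsState, priors: HBMPriors,
                         rng: np.random.Generator) -> None:
    """Draw beta from its normal full conditional given y - W b, with the
    independent N(0, sigma_a^2) prior on each coefficient."""
    X = state.X
    q = X.shape[1]
    v = state.r + X @ state.beta  # = y - W b
    Q = X.T @ X / state.sigma_e2 + np.eye(q) / priors.beta_prior_sd ** 2
    try:
        L = np.linalg.cholesky(Q)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular fixed-effect precision; X appears collinear") from exc
    mean = np.linalg.solve(Q, X.T @ v / state.sigma_e2)
    new_beta = mean + np.linalg.solve(L.T, rng.standard_normal(q))
    state.r = v - X @ new_beta
    state.beta = new_beta


def sample_variances(state: GibbsState, priors: HBMPriors,
                     rng: np.random.Generator) -> None:
    """Conjugate inverse-gamma updates of sigma_b^2 and sigma_e^2.

    With no active SNPs, sigma_b^2 is drawn from its prior (the fallback
    keeps the chain ergodic when the model visits the null configuration).
    """
    active = state.I == 1
    k = int(active.sum())
    if k > 0:
        shape = priors.a1 + 0.5 * k
        rate = priors.b1 + 0.5 * float(state.b[active] @ state.b[active])
    else:
        shape, rate = priors.a1, priors.b1
    g = max(rng.gamma(shape, 1.0), _TINY_GAMMA)
    state.sigma_b2 = rate / g
    n = state.y.size
    sse = float(state.r @ state.r)
    g = max(rng.gamma(priors.a2 + 0.5 * n, 1.0), _TINY_GAMMA)
    state.sigma_e2 = (priors.b2 + 0.5 * sse) / g


def sample_mixture_probability(state: GibbsState, priors: HBMPriors,
                               rng: np.random.Generator) -> None:
    """Conjugate Beta update: p ~ Beta(alpha + k, beta + N - k)."""
    k = state.k_active
    N = state.I.size
    state.p = float(rng.beta(priors.p_alpha + k, priors.p_beta + N - k))


# ---------------------------------------------------------------------------
# numba kernel (default engine)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _chain_kernel(Wt, y, X, XtX, col_ss, n_burnin, n_keep, thinning, seed,
                  a1, b1, a2, b2, sigma_a2, spike_var, p_alpha, p_beta,
                  beta0, p0, sb20, se20,
                  update_hyper, update_beta, random_scan,
                  out_beta, out_b, out_I, out_p, out_sb2, out_se2, out_varg):
    np.random.seed(seed)
    N, n = Wt.shape
    q = X.shape[1]
    beta = beta0.copy()
    b = np.zeros(N)
    I = np.zeros(N, dtype=np.uint8)
    p = p0
    sb2 = sb20
    se2 = se20
    r = y - X @ beta
    total = n_burnin + n_keep * thinning
    kept = 0
    for t in range(total):
        log_prior_odds = np.log(p) - np.log(1.0 - p)
        if random_scan:
            order = np.random.permutation(N)
        else:
            order = np.arange(N)
        k_active = 0
        for idx in range(N):
            j = order[idx]
            wj = Wt[j]
            bj = b[j]
            if bj != 0.0:
                for i2 in range(n):
                    r[i2] += wj[i2] * bj
            m = 0.0
            for i2 in range(n):
                m += wj[i2] * r[i2]
            s = col_ss[j]
            v1 = 1.0 / (s / se2 + 1.0 / sb2)
            mu1 = v1 * m / se2
            log_bf = 0.5 * (np.log(v1) - np.log(sb2)) + 0.5 * mu1 * mu1 / v1
            v0 = 0.0
            mu0 = 0.0
            if spike_var > 0.0:
                v0 = 1.0 / (s / se2 + 1.0 / spike_var)
                mu0 = v0 * m / se2
                log_bf -= (0.5 * (np.log(v0) - np.log(spike_var))
                           + 0.5 * mu0 * mu0 / v0)
            lo = log_prior_odds + log_bf
            pr1 = 1.0 / (1.0 + np.exp(-lo))
            new_b = 0.0
            if np.random.random() < pr1:
                I[j] = 1
                new_b = mu1 + np.sqrt(v1) * np.random.standard_normal()
                k_active += 1
            else:
                I[j] = 0
                if spike_var > 0.0:
                    new_b = mu0 + np.sqrt(v0) * np.random.standard_normal()
            b[j] = new_b
            if new_b != 0.0:
                for i2 in range(n):
                    r[i2] -= wj[i2] * new_b
        if update_beta:
            v = r + X @ beta  # = y - W b
            rhs = (X.T @ v) / se2
            Q = XtX / se2
            for d in range(q):
                Q[d, d] += 1.0 / sigma_a2
            L = np.linalg.cholesky(Q)
            mean = np.linalg.solve(Q, rhs)
            z = np.random.standard_normal(q)
            beta = mean + np.linalg.solve(L.T, z)
            r = v - X @ beta
        if update_hyper:
            if k_active > 0:
                ssb = 0.0
                for j in range(N):
                    if I[j] == 1:
                        ssb += b[j] * b[j]
                g1 = np.random.gamma(a1 + 0.5 * k_active, 1.0)
                if g1 < 1e-300:
                    g1 = 1e-300
                sb2 = (b1 + 0.5 * ssb) / g1
            else:
                g1 = np.random.gamma(a1, 1.0)
                if g1 < 1e-300:
                    g1 = 1e-300
                sb2 = b1 / g1
            sse = 0.0
            for i2 in range(n):
                sse += r[i2] * r[i2]
            g2 = np.random.gamma(a2 + 0.5 * n, 1.0)
            if g2 < 1e-300:
                g2 = 1e-300
            se2 = (b2 + 0.5 * sse) / g2
            p = np.random.beta(p_alpha + k_active, p_beta + (N - k_active))
        if not (np.isfinite(se2) and np.isfinite(sb2) and np.isfinite(p)):
            return -1
        if (t + 1) % 100 == 0:
            # exact refresh against floating-point drift of the cache
            r = y - X @ beta
            for j in range(N):
                if b[j] != 0.0:
                    bj = b[j]
                    wj = Wt[j]
                    for i2 in range(n):
                        r[i2] -= wj[i2] * bj
        if t >= n_burnin and (t - n_burnin) % thinning == 0:
            for d in range(q):
                out_beta[kept, d] = beta[d]
            for j in range(N):
                out_b[kept, j] = b[j]
                out_I[kept, j] = I[j]
            out_p[kept] = p
            out_sb2[kept] = sb2
            out_se2[kept] = se2
            # genetic value g = y - X beta - r
            xb = X @ beta
            gm = 0.0
            for i2 in range(n):
                gm += y[i2] - xb[i2] - r[i2]
            gm /= n
            vg = 0.0
            for i2 in range(n):
                d2 = y[i2] - xb[i2] - r[i2] - gm
                vg += d2 * d2
            out_varg[kept] = vg / n
            kept += 1
    return 0


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def _init_state(y, X, W, cfg: ChainConfig) -> GibbsState:
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    N = W.shape[1]
    return GibbsState(
        y=y, X=X, W=W,
        beta=beta0,
        b=np.zeros(N),
        I=np.zeros(N, dtype=np.uint8),
        p=cfg.init_p,
        sigma_b2=cfg.init_sigma_b2,
        sigma_e2=(cfg.init_sigma_e2 if cfg.init_sigma_e2 is not None
                  else float(np.var(y)) / 2.0 or 1.0),
        r=y - X @ beta0,
    )


def run_gibbs(y: np.ndarray, X: np.ndarray, W: np.ndarray,
              priors: HBMPriors | None = None,
              cfg: ChainConfig | None = None,
              covariate_names: list[str] | None = None) -> PosteriorSamples:
    """Run the Gibbs sampler and return the retained draws.

    ``W`` must be the standardized genotype matrix (samples x SNPs) and
    ``X`` a full-rank fixed-effect design (include an intercept column).
    Deterministic given ``cfg.seed`` for a fixed engine.
    """
    priors = priors or HBMPriors()
    cfg = cfg or ChainConfig()
    y = np.ascontiguousarray(y, dtype=float).ravel()
    X = np.ascontiguousarray(np.atleast_2d(X), dtype=float)
    W = np.asarray(W, dtype=float)
    n = y.size
    if X.shape[0] != n or W.shape[0] != n:
        raise ValueError("y, X, W row counts disagree")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    N = W.shape[1]
    T = cfg.n_keep
    out = dict(
        beta=np.empty((T, X.shape[1])),
        b=np.empty((T, N)),
        I=np.empty((T, N), dtype=np.uint8),
        p=np.empty(T), sigma_b2=np.empty(T), sigma_e2=np.empty(T),
        var_g_empirical=np.empty(T),
    )
    state = _init_state(y, X, W, cfg)
    if cfg.engine == "numba":
        if cfg.block_refresh:
            raise ValueError("block_refresh is available on the numpy engine")
        Wt = np.ascontiguousarray(W.T)
        status = _chain_kernel(
            Wt, y, X, X.T @ X, state.col_ss,
            cfg.n_burnin, cfg.n_keep, cfg.thinning, cfg.seed % (2 ** 31),
            priors.a1, priors.b1, priors.a2, priors.b2,
            priors.beta_prior_sd ** 2, priors.spike_sd ** 2,
            priors.p_alpha, priors.p_beta,
            state.beta, cfg.init_p, cfg.init_sigma_b2, state.sigma_e2,
            cfg.update_hyperparams, cfg.update_beta,
            cfg.scan_order == "random",
            out["beta"], out["b"], out["I"], out["p"], out["sigma_b2"],
            out["sigma_e2"], out["var_g_empirical"],
        )
        if status != 0:
            raise RuntimeError(
                "non-finite likelihood during sampling; check that W is "
                "standardized and y is finite")
    elif cfg.engine == "numpy":
        _run_numpy(state, priors, cfg, out)
    else:
        raise ValueError(f"unknown engine {cfg.engine!r}")
    return PosteriorSamples(covariate_names=covariate_names, **out)


def _run_numpy(state: GibbsState, priors: HBMPriors, cfg: ChainConfig,
               out: dict) -> None:
    """Reference engine: the exposed full-conditional ops, in sweep order."""
    rng = np.random.default_rng(cfg.seed)
    N = state.b.size
    n = state.y.size
    total = cfg.n_burnin + cfg.n_keep * cfg.thinning
    kept = 0
    for t in range(total):
        order = rng.permutation(N) if cfg.scan_order == "random" else range(N)
        for j in order:
            sample_indicator_and_effect(int(j), state, priors, rng)
        if cfg.block_refresh and state.k_active > 0:
            sample_active_block(state, priors, rng)
        if cfg.update_beta:
            sample_fixed_effects(state, priors, rng)
        if cfg.update_hyperparams:
            sample_variances(state, priors, rng)
            sample_mixture_probability(state, priors, rng)
        if not (np.isfinite(state.sigma_e2) and np.isfinite(state.sigma_b2)):
            raise RuntimeError(
                f"non-finite state at sweep {t}: sigma_e2={state.sigma_e2}, "
                f"sigma_b2={state.sigma_b2}, k_active={state.k_active}")
        if (t + 1) % 100 == 0:
            state.refresh_residual()
        if t >= cfg.n_burnin and (t - cfg.n_burnin) % cfg.thinning == 0:
            out["beta"][kept] = state.beta
            out["b"][kept] = state.b
            out["I"][kept] = state.I
            out["p"][kept] = state.p
            out["sigma_b2"][kept] = state.sigma_b2
            out["sigma_e2"][kept] = state.sigma_e2
            g = state.y - state.X @ state.beta - state.r
            out["var_g_empirical"][kept] = float(np.var(g))
            kept += 1


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def compute_pip(samples: PosteriorSamples) -> np.ndarray:
    """Posterior inclusion probability: fraction of draws with I_j = 1."""
    if samples.n_draws == 0:
        raise ValueError("no retained draws")
    return samples.I.mean(axis=0)


def select_association_snps(samples: PosteriorSamples, threshold: float = 0.5,
                            snps: list[str] | None = None) -> list:
    """SNPs with PIP >= threshold, sorted by PIP descending.

    Returns SNP IDs if ``snps`` is given, else column indices.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0,1]")
    pip = compute_pip(samples)
    hits = np.flatnonzero(pip >= threshold)
    hits = hits[np.argsort(-pip[hits], kind="stable")]
    if snps is not None:
        return [snps[j] for j in hits]
    return hits.tolist()


def estimate_pve_hbm(samples: PosteriorSamples,
                     method: Literal["model", "empirical"] = "model",
                     ) -> tuple[float, float]:
    """Posterior mean and s.d. of PVE = sigma_g^2/(sigma_g^2 + sigma_e^2),
    with sigma_g^2(t) = sigma_b^2(t) * k_active(t) by default."""
    return samples.pve(method)
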