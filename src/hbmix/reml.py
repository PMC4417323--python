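"""Mixed-linear-model baseline: AI-REML variance components on a GRM.

The model is  y ~ N(X beta, V),  V = sigma_g^2 A + sigma_e^2 I,  where A is
the genomic relationship matrix.  This is the all-SNPs-causal special case
(mixture probability p = 1) of the spike-and-slab model, estimated by
restricted maximum likelihood with average-information (AI) updates and EM
fallback steps whenever an AI step leaves the parameter space or decreases
the restricted likelihood.  Standard errors come from the inverse AI matrix
at convergence; PVE and its delta-method standard error follow.

Per-SNP effects are recovered as BLUP:  b_hat = (sigma_g^2 / N) W' V^-1
(y - X beta_hat), the posterior mean of the random effects given the
estimated variance components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .qc import GRM

logger = logging.getLogger("hbmix")

_BOUNDARY = 1e-8  # variance clamp, as a fraction of Var(y)


@dataclass
class REMLFit:
    """Converged (or boundary/non-converged) REML solution."""

    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    beta_se: np.ndarray
    se_sigma_g2: float
    se_sigma_e2: float
    ai_inv: np.ndarray  # 2x2 inverse average-information matrix (g, e order)
    loglik: float
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    n_snps: int | None = None  # SNP count behind the GRM, for sigma_b2
    boundary: float = 0.0  # variance clamp value used during fitting

    @property
    def sigma_b2(self) -> float:
        """Per-SNP variance under the all-causal model: sigma_g^2 / N."""
        if not self.n_snps:
            raise ValueError("SNP count unknown; set n_snps on the fit")
        return self.sigma_g2 / self.n_snps


def _reml_loglik(theta: np.ndarray, y: np.ndarray, X: np.ndarray,
                 A: np.ndarray) -> float:
    """Restricted log-likelihood at variance components theta = (g, e)."""
    n, q = X.shape
    V = theta[0] * A + theta[1] * np.eye(n)
    L = np.linalg.cholesky(V)
    logdet_V = 2.0 * np.log(np.diag(L)).sum()
    Vinv_X = np.linalg.solve(V, X)
    XtVinvX = X.T @ Vinv_X
    sign, logdet_X = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return -np.inf
    Vinv_y = np.linalg.solve(V, y)
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    return -0.5 * (logdet_V + logdet_X + float(y @ Py))


def _projection_pieces(theta, y, X, A):
    """P y, P A P y, traces tr(PA), tr(P) and the fixed-effect solve."""
    n, q = X.shape
    V = theta[0] * A + theta[1] * np.eye(n)
    Vinv = np.linalg.inv(V)
    Vinv_X = Vinv @ X
    XtVinvX = X.T @ Vinv_X
    XtVinvX_inv = np.linalg.inv(XtVinvX)
    P = Vinv - Vinv_X @ XtVinvX_inv @ Vinv_X.T
    Py = P @ y
    return P, Py, Vinv, XtVinvX_inv


def fit_mlm_reml(y: np.ndarray, X: np.ndarray, A: GRM | np.ndarray,
                 tol: float = 1e-8, max_iter: int = 100,
                 n_snps: int | None = None) -> REMLFit:
    """AI-REML with EM fallback for y ~ N(X beta, A sigma_g^2 + I sigma_e^2).

    Accepted iterations never decrease the restricted likelihood (the EM
    step guarantees ascent when the AI step fails).  Variances are clamped
    at a small positive boundary; a fit that exhausts ``max_iter`` is
    returned with ``converged=False``.
    """
    grm = A if isinstance(A, GRM) else None
    A = A.A if isinstance(A, GRM) else np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n or A.shape != (n, n):
        raise ValueError("y, X, A dimensions disagree")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design X is rank deficient")
    vy = float(np.var(y))
    bound = _BOUNDARY * vy
    theta = np.array([vy / 2.0, vy / 2.0])  # (sigma_g2, sigma_e2)
    ll = _reml_loglik(theta, y, X, A)
    trace = [ll]
    converged = False
    ai = np.eye(2)
    it = 0
    for it in range(1, max_iter + 1):
        P, Py, _, _ = _projection_pieces(theta, y, X, A)
        APy = A @ Py
        PAPy = P @ APy
        PPy = P @ Py
        # scores: dl/dtheta_i = -0.5 [tr(P V_i) - y'P V_i P y]
        score = np.array([
            -0.5 * (np.trace(P @ A) - float(Py @ APy)),
            -0.5 * (np.trace(P) - float(Py @ Py)),
        ])
        # average information: AI_ij = 0.5 y'P V_i P V_j P y
        ai = 0.5 * np.array([[float(APy @ PAPy), float(APy @ PPy)],
                             [float(APy @ PPy), float(Py @ PPy)]])
        new_theta = None
        try:
            step = np.linalg.solve(ai, score)
            cand = np.maximum(theta + step, bound)
            cand_ll = _reml_loglik(cand, y, X, A)
            if np.isfinite(cand_ll) and cand_ll >= ll - 1e-10:
                new_theta, new_ll = cand, cand_ll
        except np.linalg.LinAlgError:
            pass
        if new_theta is None:
            # EM fallback: guaranteed-ascent update
            em = np.array([
                theta[0] + theta[0] ** 2 * (float(Py @ APy) - np.trace(P @ A)) / n,
                theta[1] + theta[1] ** 2 * (float(Py @ Py) - np.trace(P)) / n,
            ])
            new_theta = np.maximum(em, bound)
            new_ll = _reml_loglik(new_theta, y, X, A)
        delta = np.max(np.abs(new_theta - theta)) / max(vy, 1e-12)
        theta, ll = new_theta, new_ll
        trace.append(ll)
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("AI-REML did not converge in %d iterations", max_iter)
    # final quantities at the optimum
    P, Py, Vinv, XtVinvX_inv = _projection_pieces(theta, y, X, A)
    APy = A @ Py
    PAPy = P @ APy
    PPy = P @ Py
    ai = 0.5 * np.array([[float(APy @ PAPy), float(APy @ PPy)],
                         [float(APy @ PPy), float(Py @ PPy)]])
    try:
        ai_inv = np.linalg.inv(ai)
    except np.linalg.LinAlgError:
        logger.warning("near-singular information matrix; variance "
                       "components may be unidentifiable (e.g. A close to I)")
        ai_inv = np.linalg.pinv(ai)
    beta = XtVinvX_inv @ (X.T @ (Vinv @ y))
    fit = REMLFit(
        sigma_g2=float(theta[0]), sigma_e2=float(theta[1]),
        beta=beta, beta_se=np.sqrt(np.diag(XtVinvX_inv)),
        se_sigma_g2=float(np.sqrt(max(ai_inv[0, 0], 0.0))),
        se_sigma_e2=float(np.sqrt(max(ai_inv[1, 1], 0.0))),
        ai_inv=ai_inv, loglik=float(ll), loglik_trace=trace,
        converged=converged, n_iter=it,
        n_snps=n_snps or (grm.n_snps_used if grm is not None else None),
        boundary=bound,
    )
    return fit


def estimate_pve_mlm(fit: REMLFit) -> tuple[float, float]:
    """PVE = sigma_g^2/(sigma_g^2 + sigma_e^2) with delta-method s.e."""
    g, e = fit.sigma_g2, fit.sigma_e2
    tot = g + e
    if tot <= 0 or (g <= 1.01 * fit.boundary and e <= 1.01 * fit.boundary):
        raise ValueError("both variance components at the boundary; "
                         "PVE undefined")
    pve = g / tot
    grad = np.array([e, -g]) / tot ** 2
    var = float(grad @ fit.ai_inv @ grad)
    return float(pve), float(np.sqrt(max(var, 0.0)))


def blup_snp_effects(fit: REMLFit, W: np.ndarray, y: np.ndarray,
                     X: np.ndarray, A: GRM | np.ndarray | None = None,
                     ) -> np.ndarray:
    """BLUP of per-SNP effects: b_hat = (sigma_g^2/N) W' V^-1 (y - X beta).

    ``A`` defaults to W W'/N, which must match the GRM used in the fit for
    the individual-level identity g_hat = W b_hat to hold.
    """
    W = np.asarray(W, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, N = W.shape
    if A is None:
        A = W @ W.T / N
    else:
        A = A.A if isinstance(A, GRM) else np.asarray(A, dtype=float)
    V = fit.sigma_g2 * A + fit.sigma_e2 * np.eye(n)
    resid = y - X @ fit.beta
    try:
        Vinv_r = np.linalg.solve(V, resid)
    except np.linalg.LinAlgError:
        Vinv_r = np.linalg.solve(V + 1e-8 * np.eye(n), resid)
    return (fit.sigma_g2 / N) * (W.T @ Vinv_r)
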