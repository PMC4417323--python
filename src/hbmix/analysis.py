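"""Secondary analyses: single-SNP scan, multi-scale PVE, model comparison.

The marginal scan regresses the phenotype on one SNP at a time (raw allele
counts, covariates included) and reports the Wald p-value of the SNP slope.
The multi-scale procedure then varies a p-value inclusion threshold, refits
the all-SNP mixed model on each retained subset, and tracks how the PVE
estimate shrinks as fewer small-effect SNPs are allowed in - the diagnostic
that many tiny effects, not a few large ones, drive an inflated all-SNP
heritability estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genio import GenotypeMatrix
from .gibbs import PosteriorSamples, estimate_pve_hbm
from .qc import compute_grm
from .reml import REMLFit, estimate_pve_mlm, fit_mlm_reml
from .simulate import SimTruth

logger = logging.getLogger("hbmix")

#: Table-6-style default threshold grid, loosest to tightest.
DEFAULT_THRESHOLDS = [10.0 ** -k for k in range(1, 8)]


@dataclass
class MarginalScanResult:
    """Per-SNP OLS slope, s.e. and Wald p-value (covariates partialled out)."""

    snps: list[str]
    slope: np.ndarray
    se: np.ndarray
    p_value: np.ndarray
    constant_flag: np.ndarray  # True where the SNP column was constant

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "snp": self.snps, "slope": self.slope, "se": self.se,
            "p_value": self.p_value, "constant": self.constant_flag,
        })


@dataclass
class MultiScaleReport:
    """One row per p-value threshold: SNP count, variance components, PVE."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def marginal_scan(y: np.ndarray, X: np.ndarray, W_raw: np.ndarray,
                  snps: list[str] | None = None) -> MarginalScanResult:
    """OLS of y on [X, snp_j] for each SNP j; Wald p-value for the slope.

    Implemented by Frisch-Waugh-Lovell: project the covariates out of both
    y and the SNP columns, then each slope is a simple regression on the
    residualized SNP.  Missing genotype entries are mean-imputed.  Constant
    SNP columns get p-value 1 and a flag.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = np.array(W_raw, dtype=float)
    n, N = W.shape
    if snps is None:
        snps = [f"snp{j}" for j in range(N)]
    miss = np.isnan(W)
    if miss.any():
        col_mean = np.nanmean(W, axis=0)
        W[miss] = np.broadcast_to(col_mean, W.shape)[miss]
    # annihilator of X applied to y and all SNP columns at once
    Q, _ = np.linalg.qr(X)
    y_res = y - Q @ (Q.T @ y)
    W_res = W - Q @ (Q.T @ W)
    ss = np.einsum("ij,ij->j", W_res, W_res)
    constant = ss <= 1e-12 * n
    ss_safe = np.where(constant, 1.0, ss)
    slope = (W_res.T @ y_res) / ss_safe
    df = n - X.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough samples for the covariate-adjusted scan")
    rss = (y_res @ y_res) - slope ** 2 * ss_safe
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(sigma2 / ss_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slope / se, np.inf * np.sign(slope))
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    pval[constant] = 1.0
    slope[constant] = 0.0
    se[constant] = np.nan
    if constant.any():
        logger.warning("%d constant SNP column(s) flagged in marginal scan",
                       int(constant.sum()))
    return MarginalScanResult(snps=list(snps), slope=slope, se=se,
                              p_value=pval, constant_flag=constant)


def multiscale_pve(scan: MarginalScanResult, y: np.ndarray, X: np.ndarray,
                   g: GenotypeMatrix,
                   thresholds: list[float] | None = None) -> MultiScaleReport:
    """Refit the mixed model on the SNPs passing each p-value threshold.

    Thresholds must be sorted loosest (largest) to tightest; retained SNP
    counts are therefore monotone non-increasing.  A subset with fewer than
    2 SNPs is recorded as not estimable.
    """
    thresholds = list(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    if any(t2 >= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    report = MultiScaleReport()
    prev_n = np.inf
    for thr in thresholds:
        idx = np.flatnonzero(scan.p_value < thr)
        assert idx.size <= prev_n, "SNP counts must be non-increasing"
        prev_n = idx.size
        row = {"threshold": thr, "n_snps": int(idx.size)}
        if idx.size < 2:
            row.update(estimable=False, sigma_g2=np.nan, sigma_e2=np.nan,
                       total_var=np.nan, pve=np.nan, se_pve=np.nan)
        else:
            sub = g.subset(snp_idx=idx)
            grm = compute_grm(sub)
            fit = fit_mlm_reml(y, X, grm)
            pve, se = estimate_pve_mlm(fit)
            row.update(estimable=True, sigma_g2=fit.sigma_g2,
                       sigma_e2=fit.sigma_e2,
                       total_var=fit.sigma_g2 + fit.sigma_e2,
                       pve=pve, se_pve=se,
                       se_sigma_g2=fit.se_sigma_g2,
                       se_sigma_e2=fit.se_sigma_e2)
        report.rows.append(row)
    return report


def compare_models(hbm: PosteriorSamples, mlm: REMLFit,
                   truth: SimTruth | None = None) -> pd.DataFrame:
    """Side-by-side scalar summary of the two fits (plus truth if known).

    Rows: mixture probability p, per-SNP variance sigma_b^2, genetic
    variance sigma_g^2, residual variance sigma_e^2, PVE.  The mixed model
    has no mixture probability (it assumes p = 1).
    """
    k = hbm.I.sum(axis=1)
    hbm_sg2 = hbm.sigma_b2 * k
    hbm_pve_mean, hbm_pve_sd = estimate_pve_hbm(hbm)
    mlm_pve, mlm_pve_se = estimate_pve_mlm(mlm)
    rows = [
        ("p", hbm.p.mean(), hbm.p.std(ddof=0), np.nan, np.nan),
        ("sigma_b2", hbm.sigma_b2.mean(), hbm.sigma_b2.std(ddof=0),
         mlm.sigma_b2 if mlm.n_snps else np.nan, np.nan),
        ("sigma_g2", hbm_sg2.mean(), hbm_sg2.std(ddof=0),
         mlm.sigma_g2, mlm.se_sigma_g2),
        ("sigma_e2", hbm.sigma_e2.mean(), hbm.sigma_e2.std(ddof=0),
         mlm.sigma_e2, mlm.se_sigma_e2),
        ("pve", hbm_pve_mean, hbm_pve_sd, mlm_pve, mlm_pve_se),
    ]
    df = pd.DataFrame(rows, columns=["parameter", "hbm", "hbm_se",
                                     "mlm", "mlm_se"])
    if truth is not None and truth.config is not None:
        cfg = truth.config
        true_sg2 = cfg.slab_var * cfg.n_causal
        truth_col = {"p": cfg.mixture_p, "sigma_b2": cfg.slab_var,
                     "sigma_g2": true_sg2, "sigma_e2": truth.sigma_e2_used,
                     "pve": cfg.target_pve}
        df["truth"] = df["parameter"].map(truth_col)
        for m in ("hbm", "mlm"):
            df[f"{m}_abs_error"] = (df[m] - df["truth"]).abs()
    return df


def per_snp_effect_table(hbm: PosteriorSamples, mlm_effects: np.ndarray,
                         snps: list[str],
                         truth: SimTruth | None = None) -> pd.DataFrame:
    """Per-SNP posterior-mean effects under both models (Table-5 shape)."""
    df = pd.DataFrame({
        "snp": snps,
        "pip": hbm.pip(),
        "effect_hbm": hbm.b.mean(axis=0),
        "effect_mlm": np.asarray(mlm_effects, dtype=float),
    })
    if truth is not None:
        df["effect_true"] = truth.b_true
        df["is_associative"] = truth.I_true.astype(bool)
    return df
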