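"""Synthetic genotype/phenotype engine with known ground truth.

Genotypes are drawn under Hardy-Weinberg and linkage equilibrium: per SNP a
minor allele frequency is drawn uniformly on ``maf_range`` (default
U(0.05, 0.5)) and counts are Binomial(2, MAF) i.i.d. across samples.  An
optional LD-block mode couples neighbouring SNPs through a first-order
autoregressive latent allele process, to probe robustness to local
correlation; it is not a population-genetic simulation.

Phenotypes follow  y = W b + e  on the standardized genotype matrix W.
Effects come in two flavours:

* Case 1 - exactly round(p*N) SNPs carry slab effects N(0, sigma_b^2); the
  rest are exactly zero (point mass).
* Case 2 - as Case 1, but every non-associative SNP instead carries a small
  N(0, spike_sd^2) "noisy" effect (spike_sd = 0.01 by default), the
  misspecification scenario under which the all-causal mixed model inflates
  its PVE estimate.

The residual variance is calibrated to a target PVE from the empirical
variance of the *slab* genetic values:  sigma_e^2 = Var(W_slab b_slab) *
(1 - PVE)/PVE.  Under this convention "true PVE" refers to the point-mass
model's genetic variance (sigma_b^2 times the slab count), so in Case 2 the
spike effects are excess signal on top of the nominal PVE - exactly the
regime in which the mixed model overshoots.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .genio import GenotypeMatrix, StandardizedGenotypes, standardize_genotypes


@dataclass
class SimConfig:
    """Study-design parameters for one simulated dataset."""

    n_samples: int = 500
    n_snps: int = 2000
    mixture_p: float = 0.01
    slab_var: float = 0.1  # sigma_b^2
    spike_sd: float = 0.0  # 0 -> Case 1; e.g. 0.01 -> Case 2
    target_pve: float = 0.5
    maf_low: float = 0.05
    maf_high: float = 0.5
    ld_rho: float = 0.0  # >0 enables AR(1) allele coupling within the panel
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mixture_p < 1.0:
            raise ValueError("mixture_p must be in (0,1)")
        if not 0.0 < self.target_pve < 1.0:
            raise ValueError("target_pve must be in (0,1)")
        if self.slab_var <= 0:
            raise ValueError("slab_var must be positive")
        if not 0.0 < self.maf_low <= self.maf_high <= 0.5:
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")

    @property
    def case(self) -> int:
        return 1 if self.spike_sd == 0.0 else 2

    @property
    def n_causal(self) -> int:
        return int(round(self.mixture_p * self.n_snps))


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated phenotype."""

    b_true: np.ndarray
    I_true: np.ndarray  # uint8; 1 marks slab (associative) SNPs
    sigma_e2_used: float
    realized_pve: float
    genetic_values: np.ndarray  # W b (all effects, slab + spike)
    slab_genetic_values: np.ndarray  # W restricted to slab SNPs times b
    config: SimConfig | None = None

    @property
    def causal_idx(self) -> np.ndarray:
        return np.flatnonzero(self.I_true == 1)

    def to_json(self, path: str | Path) -> None:
        d = {
            "b_true": self.b_true.tolist(),
            "I_true": self.I_true.astype(int).tolist(),
            "sigma_e2_used": self.sigma_e2_used,
            "realized_pve": self.realized_pve,
            "config": asdict(self.config) if self.config else None,
        }
        Path(path).write_text(json.dumps(d) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        cfg = SimConfig(**d["config"]) if d.get("config") else None
        return cls(b_true=np.asarray(d["b_true"], dtype=float),
                   I_true=np.asarray(d["I_true"], dtype=np.uint8),
                   sigma_e2_used=float(d["sigma_e2_used"]),
                   realized_pve=float(d["realized_pve"]),
                   genetic_values=np.empty(0), slab_genetic_values=np.empty(0),
                   config=cfg)


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator,
                       ) -> GenotypeMatrix:
    """HWE/linkage-equilibrium genotype counts; AR(1) allele coupling when
    ``cfg.ld_rho`` > 0."""
    n, N = cfg.n_samples, cfg.n_snps
    maf = rng.uniform(cfg.maf_low, cfg.maf_high, size=N)
    if cfg.ld_rho == 0.0:
        counts = rng.binomial(2, maf[None, :], size=(n, N)).astype(float)
    else:
        # two latent Gaussian haplotypes with AR(1) correlation along the
        # panel, thresholded at the MAF quantile -> locally correlated alleles
        rho = cfg.ld_rho
        counts = np.zeros((n, N))
        from scipy.stats import norm
        thresh = norm.ppf(maf)
        for _hap in range(2):
            z = np.empty((n, N))
            z[:, 0] = rng.standard_normal(n)
            innov = rng.standard_normal((n, N - 1))
            for j in range(1, N):
                z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho ** 2) * innov[:, j - 1]
            counts += (z < thresh[None, :]).astype(float)
    samples = [f"S{i:05d}" for i in range(n)]
    snps = [f"snp{j:05d}" for j in range(N)]
    return GenotypeMatrix(samples=samples, snps=snps, counts=counts)


def simulate_effects(cfg: SimConfig, rng: np.random.Generator,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (b_true, I_true): exactly round(p*N) slab effects N(0, slab_var),
    chosen uniformly; the rest zero (Case 1) or N(0, spike_sd^2) (Case 2)."""
    N = cfg.n_snps
    k = cfg.n_causal
    if k == 0:
        raise ValueError(
            f"round(p*N) = 0 with p={cfg.mixture_p}, N={N}: no signal to simulate")
    I_true = np.zeros(N, dtype=np.uint8)
    causal = rng.choice(N, size=k, replace=False)
    I_true[causal] = 1
    b = np.zeros(N)
    b[causal] = rng.normal(0.0, np.sqrt(cfg.slab_var), size=k)
    if cfg.spike_sd > 0.0:
        null = np.flatnonzero(I_true == 0)
        b[null] = rng.normal(0.0, cfg.spike_sd, size=null.size)
    return b, I_true


def error_variance_for_target_pve(genetic_values: np.ndarray,
                                  target_pve: float) -> float:
    """sigma_e^2 = Var(g) * (1 - PVE)/PVE from realized genetic values."""
    if not 0.0 < target_pve < 1.0:
        raise ValueError("target_pve must be in (0,1)")
    var_g = float(np.var(np.asarray(genetic_values, dtype=float)))
    if var_g <= 0.0:
        raise ValueError("zero genetic variance; cannot calibrate residual")
    return var_g * (1.0 - target_pve) / target_pve


def simulate_phenotype(W: np.ndarray, b: np.ndarray, sigma_e2: float,
                       rng: np.random.Generator,
                       X: np.ndarray | None = None,
                       beta: np.ndarray | None = None) -> np.ndarray:
    """y = W b + e with e ~ N(0, sigma_e2 I); optional fixed-effect term."""
    W = np.asarray(W, dtype=float)
    y = W @ np.asarray(b, dtype=float)
    if X is not None:
        y = y + np.atleast_2d(X) @ np.asarray(beta, dtype=float)
    if sigma_e2 > 0:
        y = y + rng.normal(0.0, np.sqrt(sigma_e2), size=W.shape[0])
    return y


def simulate_dataset(cfg: SimConfig,
                     ) -> tuple[GenotypeMatrix, StandardizedGenotypes,
                                np.ndarray, SimTruth]:
    """Full study generator: genotypes, W, phenotype and truth manifest.

    All randomness flows through one generator seeded by ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    g = simulate_genotypes(cfg, rng)
    std = standardize_genotypes(g)
    b, I_true = simulate_effects(cfg, rng)
    slab = I_true == 1
    slab_g = std.W[:, slab] @ b[slab]
    sigma_e2 = error_variance_for_target_pve(slab_g, cfg.target_pve)
    y = simulate_phenotype(std.W, b, sigma_e2, rng)
    full_g = std.W @ b
    realized = float(np.var(slab_g) / (np.var(slab_g) + sigma_e2))
    truth = SimTruth(b_true=b, I_true=I_true, sigma_e2_used=sigma_e2,
                     realized_pve=realized, genetic_values=full_g,
                     slab_genetic_values=slab_g, config=cfg)
    return g, std, y, truth


def benchmark_detection(selected, truth: SimTruth) -> dict:
    """Detection cross-table against ground truth.

    ``selected`` holds SNP column indices (as from
    :func:`hbmix.gibbs.select_association_snps` without IDs).  Rates are
    fractions in [0,1]: TPR/FNR over the truly associative SNPs, FPR/TNR
    over the null SNPs.
    """
    true_set = set(int(i) for i in truth.causal_idx)
    if not true_set:
        raise ValueError("truth contains no associative SNPs")
    sel = set(int(i) for i in selected)
    N = truth.I_true.size
    null_set = set(range(N)) - true_set
    tp = len(sel & true_set)
    fp = len(sel & null_set)
    tpr = tp / len(true_set)
    fpr = fp / len(null_set) if null_set else 0.0
    return {
        "n_true": len(true_set), "n_null": len(null_set),
        "n_selected": len(sel), "tp": tp, "fp": fp,
        "tpr": tpr, "fnr": 1.0 - tpr, "fpr": fpr, "tnr": 1.0 - fpr,
    }
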