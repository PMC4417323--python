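"""Genotype/phenotype ingest and the standardized genotype matrix W.

Genotypes are additive minor-allele counts in {0, 1, 2} with an explicit
missing marker, held sample-by-row, SNP-by-column.  Standardization follows
the usual GWAS convention: missing entries are imputed to the column mean
2*p_i, then column i is transformed to (x - 2*p_i) / sqrt(2*p_i*(1 - p_i)),
where p_i is the empirical allele frequency.  Under Hardy-Weinberg
equilibrium each standardized column has mean 0 and variance approaching 1,
which is what the mixed-model and Bayesian machinery downstream assume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("hbmix")

#: Tokens accepted as missing genotype values in text inputs.
MISSING_TOKENS = {"NA", "na", "NaN", "nan", "-9", ""}

#: Leading metadata columns of a PLINK .raw file, in order.
PLINK_RAW_META = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class GenotypeParseError(ValueError):
    """Raised when a genotype file contains an entry outside {0,1,2,missing}."""


@dataclass
class GenotypeMatrix:
    """Raw additive genotype calls plus per-SNP allele frequencies.

    ``counts`` is an n_samples x n_snps float array with ``np.nan`` marking
    missing calls.  ``allele_freq[i]`` is the empirical frequency of the
    counted (minor) allele at SNP i, computed from non-missing calls as
    mean(count)/2.
    """

    samples: list[str]
    snps: list[str]
    counts: np.ndarray
    allele_freq: np.ndarray = field(default=None)  # type: ignore[assignment]
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            i, j = np.argwhere(~valid)[0]
            raise GenotypeParseError(
                f"genotype entry {self.counts[i, j]!r} at sample "
                f"{self.samples[i]!r}, SNP {self.snps[j]!r} not in {{0,1,2,missing}}"
            )
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("duplicate SNP IDs in genotype matrix")
        if self.allele_freq is None:
            self.allele_freq = self._compute_freq()

    def _compute_freq(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.counts, axis=0) / 2.0

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_fraction_per_sample(self) -> np.ndarray:
        return np.isnan(self.counts).mean(axis=1)

    def call_rate_per_snp(self) -> np.ndarray:
        return 1.0 - np.isnan(self.counts).mean(axis=0)

    def maf(self) -> np.ndarray:
        """Minor allele frequency: min(p, 1-p) of the counted allele."""
        p = self.allele_freq
        return np.minimum(p, 1.0 - p)

    def subset(self, sample_idx: Sequence[int] | None = None,
               snp_idx: Sequence[int] | None = None) -> "GenotypeMatrix":
        """Row/column subset with allele frequencies recomputed."""
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        sj = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.iloc[si].reset_index(drop=True)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in si],
            snps=[self.snps[j] for j in sj],
            counts=self.counts[np.ix_(si, sj)],
            sample_meta=meta,
        )


@dataclass
class StandardizedGenotypes:
    """The standardized genotype matrix W with provenance."""

    W: np.ndarray
    snps: list[str]
    samples: list[str]
    allele_freq: np.ndarray
    denominator: str = "hwe"

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]

    @property
    def n_snps(self) -> int:
        return self.W.shape[1]


@dataclass
class PhenotypeTable:
    """Phenotype vector y and fixed-effect design X keyed by sample ID."""

    samples: list[str]
    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        if self.X.shape[0] != self.y.size or self.y.size != len(self.samples):
            raise ValueError("phenotype/covariate/sample dimensions disagree")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("covariate matrix X is rank deficient")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_count_frame(df: pd.DataFrame, path: str) -> np.ndarray:
    """Convert a string/object frame of genotype tokens to float counts."""
    arr = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        s = df[col].astype(str).str.strip()
        missing = s.isin(MISSING_TOKENS)
        vals = pd.to_numeric(s.where(~missing), errors="coerce")
        bad = (~missing) & (~vals.isin([0.0, 1.0, 2.0]))
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise GenotypeParseError(
                f"{path}: entry {s.iloc[i]!r} at row {i + 1}, column {col!r} "
                "is not in {0,1,2} or a missing token"
            )
        arr[:, j] = vals.to_numpy()
    return arr


def read_genotypes(path: str | Path,
                   dialect: Literal["plink_raw", "tsv"] = "tsv") -> GenotypeMatrix:
    """Read genotypes from a PLINK .raw export or a plain sample x SNP TSV.

    ``plink_raw``: whitespace-delimited with the six PLINK metadata columns
    (FID IID PAT MAT SEX PHENOTYPE) followed by one dosage column per SNP
    named ``rsID_allele``; sample IDs are taken from IID.  ``tsv``: tab
    separated, first column holds sample IDs, remaining header names are
    SNP IDs.  Row and column order are preserved.
    """
    path = Path(path)
    if dialect == "plink_raw":
        df = pd.read_csv(path, sep=r"\s+", dtype=str)
        missing_meta = [c for c in PLINK_RAW_META if c not in df.columns]
        if missing_meta:
            raise ValueError(f"{path}: PLINK .raw missing columns {missing_meta}")
        meta = df[PLINK_RAW_META].copy()
        geno = df.drop(columns=PLINK_RAW_META)
        samples = meta["IID"].tolist()
        # strip the "_allele" suffix PLINK appends to each SNP column
        snps = [c.rsplit("_", 1)[0] if "_" in c else c for c in geno.columns]
    elif dialect == "tsv":
        df = pd.read_csv(path, sep="\t", dtype=str)
        meta = None
        samples = df.iloc[:, 0].astype(str).tolist()
        geno = df.iloc[:, 1:]
        snps = list(geno.columns)
    else:  # pragma: no cover - guarded by Literal type
        raise ValueError(f"unknown dialect {dialect!r}")
    counts = _parse_count_frame(geno, str(path))
    return GenotypeMatrix(samples=samples, snps=snps, counts=counts,
                          sample_meta=meta)


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Inverse of ``read_genotypes(..., dialect='tsv')``."""
    df = pd.DataFrame(g.counts, columns=g.snps)
    df = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    df.insert(0, "sample_id", g.samples)
    df.to_csv(path, sep="\t", index=False)


def write_genotypes_plink_raw(g: GenotypeMatrix, path: str | Path,
                              allele: str = "A") -> None:
    """Write a minimal PLINK .raw export (dosage columns named rsID_allele)."""
    cols = {"FID": g.samples, "IID": g.samples, "PAT": "0", "MAT": "0",
            "SEX": "0", "PHENOTYPE": "-9"}
    df = pd.DataFrame(cols)
    geno = pd.DataFrame(g.counts, columns=[f"{s}_{allele}" for s in g.snps])
    geno = geno.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    pd.concat([df, geno], axis=1).to_csv(path, sep=" ", index=False)


def read_phenotypes(path: str | Path, phenotype: str = "y",
                    covariates: Sequence[str] | None = None,
                    add_intercept: bool = True) -> PhenotypeTable:
    """Read a phenotype/covariate CSV keyed by a ``sample_id`` column."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: no 'sample_id' column")
    if phenotype not in df.columns:
        raise ValueError(f"{path}: no phenotype column {phenotype!r}")
    cov_names = list(covariates) if covariates else [
        c for c in df.columns if c not in ("sample_id", phenotype)
    ]
    X_cols = [df[c].to_numpy(dtype=float) for c in cov_names]
    names = list(cov_names)
    if add_intercept:
        X_cols.insert(0, np.ones(len(df)))
        names.insert(0, "(Intercept)")
    X = np.column_stack(X_cols) if X_cols else np.ones((len(df), 1))
    return PhenotypeTable(samples=df["sample_id"].astype(str).tolist(),
                          y=df[phenotype].to_numpy(dtype=float),
                          X=X, covariate_names=names)


# ---------------------------------------------------------------------------
# standardization and alignment
# ---------------------------------------------------------------------------

def standardize_genotypes(g: GenotypeMatrix,
                          denominator: Literal["hwe", "empirical"] = "hwe",
                          ) -> StandardizedGenotypes:
    """Mean-impute missing calls and column-standardize to the W matrix.

    With ``denominator='hwe'`` column i is scaled by sqrt(2 p_i (1-p_i)),
    the binomial variance under Hardy-Weinberg equilibrium; ``'empirical'``
    uses the observed column standard deviation instead.  Monomorphic SNPs
    (p_i at 0 or 1, or all calls missing) have no defined scale and must be
    removed by QC first.
    """
    p = g.allele_freq
    bad = ~np.isfinite(p) | (p <= 0.0) | (p >= 1.0)
    if bad.any():
        offenders = [g.snps[j] for j in np.flatnonzero(bad)[:5]]
        raise ValueError(
            f"{int(bad.sum())} monomorphic or all-missing SNP(s), e.g. "
            f"{offenders}; filter with hbmix.qc.filter_snps before standardizing"
        )
    X = g.counts.copy()
    miss = np.isnan(X)
    if miss.any():
        logger.info("imputing %d missing genotype calls to column mean 2p",
                    int(miss.sum()))
        X[miss] = np.broadcast_to(2.0 * p, X.shape)[miss]
    centered = X - 2.0 * p
    if denominator == "hwe":
        scale = np.sqrt(2.0 * p * (1.0 - p))
    elif denominator == "empirical":
        scale = centered.std(axis=0, ddof=0)
        if np.any(scale == 0):
            raise ValueError("zero-variance column under empirical scaling")
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return StandardizedGenotypes(W=centered / scale, snps=list(g.snps),
                                 samples=list(g.samples),
                                 allele_freq=p.copy(), denominator=denominator)


def align_samples(g: GenotypeMatrix, ph: PhenotypeTable,
                  ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Restrict both objects to their common sample IDs, genotype order."""
    common = set(g.samples) & set(ph.samples)
    if not common:
        raise ValueError("no common sample IDs between genotypes and phenotypes")
    keep_g = [i for i, s in enumerate(g.samples) if s in common]
    order = [g.samples[i] for i in keep_g]
    ph_index = {s: i for i, s in enumerate(ph.samples)}
    keep_p = [ph_index[s] for s in order]
    dropped = (g.n_samples - len(keep_g)) + (len(ph.samples) - len(keep_p))
    if dropped:
        logger.info("align_samples dropped %d unmatched sample rows", dropped)
    g2 = g.subset(sample_idx=keep_g)
    ph2 = PhenotypeTable(samples=order, y=ph.y[keep_p], X=ph.X[keep_p],
                         covariate_names=list(ph.covariate_names))
    return g2, ph2


# ---------------------------------------------------------------------------
# posterior report serialization
# ---------------------------------------------------------------------------

def write_posterior_report(samples, snps: Sequence[str], path_prefix: str | Path,
                           ) -> tuple[Path, Path]:
    """Write per-SNP and scalar-parameter posterior summaries as TSV.

    ``samples`` is a :class:`hbmix.gibbs.PosteriorSamples`.  Produces
    ``<prefix>.snps.tsv`` (SNP ID, PIP, posterior-mean effect) and
    ``<prefix>.params.tsv`` (posterior mean and s.d. of p, sigma_b2,
    sigma_e2, each fixed effect, and PVE).
    """
    if samples.n_draws == 0:
        raise ValueError("empty posterior chain")
    prefix = Path(path_prefix)
    snp_path = prefix.with_suffix(".snps.tsv")
    par_path = prefix.with_suffix(".params.tsv")
    pip = samples.pip()
    eff = samples.b.mean(axis=0)
    pd.DataFrame({"snp": list(snps), "pip": pip, "posterior_mean_effect": eff}
                 ).to_csv(snp_path, sep="\t", index=False)

    pve_mean, pve_sd = samples.pve()
    rows = [("p", samples.p.mean(), samples.p.std(ddof=0)),
            ("sigma_b2", samples.sigma_b2.mean(), samples.sigma_b2.std(ddof=0)),
            ("sigma_e2", samples.sigma_e2.mean(), samples.sigma_e2.std(ddof=0))]
    for i in range(samples.beta.shape[1]):
        name = samples.covariate_names[i] if samples.covariate_names else f"beta{i}"
        rows.append((name, samples.beta[:, i].mean(),
                     samples.beta[:, i].std(ddof=0)))
    rows.append(("PVE", pve_mean, pve_sd))
    pd.DataFrame(rows, columns=["parameter", "mean", "sd"]
                 ).to_csv(par_path, sep="\t", index=False)
    return snp_path, par_path


def read_posterior_report(path_prefix: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    prefix = Path(path_prefix)
    snp = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t")
    par = pd.read_csv(prefix.with_suffix(".params.tsv"), sep="\t")
    return snp, par
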