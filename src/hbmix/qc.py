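"""Quality control and the genomic relationship matrix (GRM).

The filters mirror standard GWAS preprocessing: drop samples with >=5%
missing genotypes, drop SNPs with call rate <=0.99 or MAF <=0.01 (all
thresholds inclusive on the removal side), then prune one member of every
sample pair whose estimated genetic relationship exceeds 0.025 so the
remaining cohort is effectively unrelated.

The relationship between individuals j and k is the average over SNPs of

    (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)),

i.e. A = W W' / N on the standardized, mean-imputed genotype matrix.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, standardize_genotypes

DEFAULT_SAMPLE_MISSINGNESS = 0.05
DEFAULT_MIN_CALL_RATE = 0.99
DEFAULT_MIN_MAF = 0.01
DEFAULT_RELATEDNESS = 0.025


@dataclass
class QCReport:
    """Counts of removed samples/SNPs per filter, with thresholds used."""

    steps: list[dict] = dc_field(default_factory=list)

    def add(self, filter_name: str, axis: str, n_in: int, n_removed: int,
            threshold: float) -> None:
        self.steps.append({
            "filter": filter_name, "axis": axis, "input": n_in,
            "removed": n_removed, "retained": n_in - n_removed,
            "threshold": threshold,
        })

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.steps, indent=2) + "\n")


@dataclass
class GRM:
    """Symmetric n x n genetic relationship matrix."""

    A: np.ndarray
    samples: list[str]
    n_snps_used: int

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        n = len(self.samples)
        if self.A.shape != (n, n):
            raise ValueError("GRM shape inconsistent with sample list")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("GRM is not symmetric")
        if not np.isfinite(self.A).all():
            raise ValueError("GRM contains non-finite entries")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


def filter_sample_missingness(g: GenotypeMatrix,
                              max_missing: float = DEFAULT_SAMPLE_MISSINGNESS,
                              report: QCReport | None = None,
                              ) -> tuple[GenotypeMatrix, QCReport]:
    """Remove samples whose missing-call fraction is >= ``max_missing``."""
    if not 0.0 < max_missing < 1.0:
        raise ValueError("max_missing must be in (0,1)")
    report = report or QCReport()
    frac = g.missing_fraction_per_sample()
    keep = np.flatnonzero(frac < max_missing)  # ">= threshold" removed
    report.add("sample_missingness", "samples", g.n_samples,
               g.n_samples - keep.size, max_missing)
    if keep.size == 0:
        raise ValueError("sample missingness filter removed every sample")
    return g.subset(sample_idx=keep), report


def filter_snps(g: GenotypeMatrix,
                min_call_rate: float = DEFAULT_MIN_CALL_RATE,
                min_maf: float = DEFAULT_MIN_MAF,
                report: QCReport | None = None,
                ) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs with call rate <= ``min_call_rate`` or MAF <= ``min_maf``."""
    if not (0.0 < min_call_rate < 1.0 and 0.0 < min_maf < 1.0):
        raise ValueError("thresholds must be in (0,1)")
    report = report or QCReport()
    call = g.call_rate_per_snp()
    with np.errstate(invalid="ignore"):
        maf = g.maf()
    bad = (call <= min_call_rate) | ~(maf > min_maf)  # NaN MAF (all missing) removed
    keep = np.flatnonzero(~bad)
    report.add("snp_call_rate_maf", "snps", g.n_snps, int(bad.sum()),
               min_maf)
    if keep.size == 0:
        raise ValueError("SNP filter removed every SNP")
    return g.subset(snp_idx=keep), report


def standard_qc(g: GenotypeMatrix,
                max_missing: float = DEFAULT_SAMPLE_MISSINGNESS,
                min_call_rate: float = DEFAULT_MIN_CALL_RATE,
                min_maf: float = DEFAULT_MIN_MAF,
                ) -> tuple[GenotypeMatrix, QCReport]:
    """Sample-missingness filter followed by the SNP call-rate/MAF filter."""
    g1, report = filter_sample_missingness(g, max_missing)
    g2, report = filter_snps(g1, min_call_rate, min_maf, report)
    return g2, report


def compute_grm(g: GenotypeMatrix) -> GRM:
    """GRM from mean-imputed standardized genotypes: A = W W' / N.

    Allele frequencies are recomputed from the (possibly filtered) input
    before standardization, since frequencies shift as samples are removed.
    """
    if g.n_snps < 2:
        raise ValueError("need at least 2 SNPs to estimate relationships")
    # recompute frequencies on current data before standardizing
    fresh = GenotypeMatrix(samples=list(g.samples), snps=list(g.snps),
                           counts=g.counts, sample_meta=g.sample_meta)
    std = standardize_genotypes(fresh)
    A = std.W @ std.W.T / std.n_snps
    return GRM(A=A, samples=list(g.samples), n_snps_used=std.n_snps)


def prune_related(A: GRM | np.ndarray,
                  threshold: float = DEFAULT_RELATEDNESS) -> np.ndarray:
    """Greedy relatedness pruning; returns indices of retained samples.

    While any off-diagonal relationship exceeds ``threshold``, take the
    currently worst (largest) offending pair and delete the member with the
    larger number of above-threshold partners (ties resolved by removing the
    smaller index).  The returned index set contains no offending pair.
    """
    M = A.A if isinstance(A, GRM) else np.asarray(A, dtype=float)
    n = M.shape[0]
    off = M.copy()
    np.fill_diagonal(off, -np.inf)
    alive = np.ones(n, dtype=bool)
    viol = off > threshold
    degree = viol.sum(axis=1)
    while True:
        sub = np.where(alive[:, None] & alive[None, :], off, -np.inf)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= threshold:
            break
        # drop the member with more offending partners; ties drop the smaller index
        if degree[i] > degree[j]:
            drop = i
        elif degree[j] > degree[i]:
            drop = j
        else:
            drop = min(i, j)
        alive[drop] = False
        degree[viol[drop] & alive] -= 1
    return np.flatnonzero(alive)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_grm_tsv(grm: GRM, path_prefix: str | Path) -> None:
    """Write the GRM as a dense TSV plus a GCTA-style .grm.id file."""
    prefix = Path(path_prefix)
    pd.DataFrame(grm.A, index=grm.samples, columns=grm.samples
                 ).to_csv(prefix.with_suffix(".grm.tsv"), sep="\t")
    pd.DataFrame({"fid": grm.samples, "iid": grm.samples}
                 ).to_csv(prefix.with_suffix(".grm.id"), sep="\t",
                          index=False, header=False)


def read_grm_tsv(path_prefix: str | Path) -> GRM:
    prefix = Path(path_prefix)
    df = pd.read_csv(prefix.with_suffix(".grm.tsv"), sep="\t", index_col=0)
    # SNP count used is not recoverable from the TSV alone
    return GRM(A=df.to_numpy(), samples=[str(s) for s in df.index],
               n_snps_used=-1)
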