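"""Quality-control filters: sample call rate, MAF, Hardy-Weinberg equilibrium.

Thresholds are strict inequalities: a sample at exactly the minimum call rate
is retained, a SNP at exactly the minimum MAF is retained, and a SNP at
exactly the HWE alpha is retained. The canonical filter order is
samples -> MAF -> HWE (see :func:`run_qc`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


class EmptyCohortError(ValueError):
    pass


@dataclass
class QCReport:
    n_samples_removed: int = 0
    n_snps_removed_maf: int = 0
    n_snps_removed_hwe: int = 0
    n_snps_removed_chrom: int = 0
    thresholds: dict = field(default_factory=dict)

    def merge(self, other: "QCReport") -> "QCReport":
        return QCReport(
            self.n_samples_removed + other.n_samples_removed,
            self.n_snps_removed_maf + other.n_snps_removed_maf,
            self.n_snps_removed_hwe + other.n_snps_removed_hwe,
            self.n_snps_removed_chrom + other.n_snps_removed_chrom,
            {**self.thresholds, **other.thresholds},
        )


def _genotype_counts(geno: GenotypeMatrix):
    c = geno.calls
    n_aa = (c == 0).sum(axis=0)
    n_ab = (c == 1).sum(axis=0)
    n_bb = (c == 2).sum(axis=0)
    return n_aa, n_ab, n_bb


def filter_sample_call_rate(geno: GenotypeMatrix, min_rate: float = 0.98):
    """Drop samples whose non-missing call fraction is strictly below min_rate."""
    if not 0 < min_rate <= 1:
        raise ValueError("min_rate must be in (0, 1]")
    rate = (geno.calls != MISSING).mean(axis=1)
    keep = rate >= min_rate
    if not keep.any():
        raise EmptyCohortError("all samples fail the call-rate filter")
    report = QCReport(
        n_samples_removed=int((~keep).sum()),
        thresholds={"min_call_rate": min_rate},
    )
    if report.n_samples_removed:
        logger.info("call-rate filter removed %d samples", report.n_samples_removed)
    return geno.take_samples(keep), report


def minor_allele_freq(geno: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor allele frequency over non-missing calls (NaN if all missing)."""
    n_aa, n_ab, n_bb = _genotype_counts(geno)
    n_chrom = 2 * (n_aa + n_ab + n_bb)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_chrom > 0, (2 * n_bb + n_ab) / np.maximum(n_chrom, 1), np.nan)
    return np.minimum(p, 1 - p)


def filter_maf(geno: GenotypeMatrix, min_maf: float = 0.01):
    """Drop SNPs with MAF strictly below min_maf (all-missing SNPs dropped too)."""
    maf = minor_allele_freq(geno)
    keep = maf >= min_maf  # NaN compares False -> removed
    report = QCReport(
        n_snps_removed_maf=int((~keep).sum()),
        thresholds={"min_maf": min_maf},
    )
    return geno.take_variants(keep), report


def hwe_exact_pvalue(n_ab: int, n_aa: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test p-value from genotype counts.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities not exceeding that of the observed
    configuration (two-sided exact test on the heterozygote distribution).
    """
    n = n_aa + n_ab + n_bb
    if n == 0:
        return float("nan")
    n_minor = 2 * min(n_aa, n_bb) + n_ab  # minor allele copies (ties fine)
    # enumerate heterozygote counts with the same parity as n_minor
    het_max = min(n_minor, 2 * n - n_minor)
    hets = np.arange(n_minor % 2, het_max + 1, 2)
    # unnormalized log-probabilities of each configuration
    from scipy.special import gammaln

    rare_hom = (n_minor - hets) // 2
    common_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(common_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    p_obs = prob[hets == n_ab]
    if p_obs.size == 0:  # parity mismatch cannot happen with valid counts
        return float("nan")
    return float(prob[prob <= p_obs[0] * (1 + 1e-12)].sum())


def hwe_chisq_pvalue(n_ab: int, n_aa: int, n_bb: int) -> float:
    """1-df chi-square HWE p-value (no continuity correction)."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return float("nan")
    p = (2 * n_bb + n_ab) / (2 * n)
    exp = np.array([(1 - p) ** 2 * n, 2 * p * (1 - p) * n, p * p * n])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    if np.any(exp == 0):
        return 1.0  # monomorphic: no departure testable
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def hwe_pvalues(geno: GenotypeMatrix, method: str = "exact") -> np.ndarray:
    n_aa, n_ab, n_bb = _genotype_counts(geno)
    fn = hwe_exact_pvalue if method == "exact" else hwe_chisq_pvalue
    if method not in ("exact", "chisq"):
        raise ValueError("method must be 'exact' or 'chisq'")
    return np.array([fn(int(ab), int(aa), int(bb)) for aa, ab, bb in zip(n_aa, n_ab, n_bb)])


def filter_hwe(geno: GenotypeMatrix, alpha: float = 1e-3, method: str = "exact"):
    """Drop SNPs whose HWE p-value is strictly below alpha.

    SNPs with no genotyped samples are skipped from testing and retained.
    """
    p = hwe_pvalues(geno, method=method)
    untestable = np.isnan(p)
    if untestable.any():
        logger.info("HWE: %d SNPs untestable (no calls), retained", int(untestable.sum()))
    keep = ~(p < alpha)  # NaN -> keep
    report = QCReport(
        n_snps_removed_hwe=int((~keep).sum()),
        thresholds={"hwe_alpha": alpha, "hwe_method": method},
    )
    return geno.take_variants(keep), report


def filter_autosomes(geno: GenotypeMatrix, allow: set[str] | None = None):
    """Keep only SNPs on allowed chromosomes (default: numeric labels, with or
    without a 'chr' prefix)."""
    labels = geno.variants.chrom
    if allow is not None:
        keep = np.isin(labels, list(allow))
    else:
        keep = np.array(
            [str(c).removeprefix("chr").isdigit() for c in labels], dtype=bool
        )
    report = QCReport(
        n_snps_removed_chrom=int((~keep).sum()),
        thresholds={"chrom_allowlist": "numeric" if allow is None else sorted(allow)},
    )
    return geno.take_variants(keep), report


def run_qc(
    geno: GenotypeMatrix,
    min_call_rate: float = 0.98,
    min_maf: float = 0.01,
    hwe_alpha: float = 1e-3,
    hwe_method: str = "exact",
    autosomes_only: bool = True,
):
    """Full QC chain in the fixed order: autosomes -> samples -> MAF -> HWE."""
    report = QCReport(thresholds={"order": "autosomes,samples,maf,hwe"})
    if autosomes_only:
        geno, r = filter_autosomes(geno)
        report = report.merge(r)
    geno, r = filter_sample_call_rate(geno, min_call_rate)
    report = report.merge(r)
    geno, r = filter_maf(geno, min_maf)
    report = report.merge(r)
    geno, r = filter_hwe(geno, hwe_alpha, hwe_method)
    report = report.merge(r)
    return geno, report
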