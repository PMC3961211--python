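"""Population-structure statistics.

PCA on standardized genotypes, multinomial group-prediction accuracy from
leading principal components, pairwise genomic-control inflation factors,
Hudson and inbreeding-robust Fst estimators (ratio of averages, block
jackknife CIs, permutation p-values), per-sample genomic inbreeding
coefficients, and Welch group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

#: median of the 1-df chi-square distribution
CHI2_1DF_MEDIAN = 0.4549364231195724


@dataclass
class PCAResult:
    scores: np.ndarray       # n_samples x k
    eigenvalues: np.ndarray  # k, non-increasing
    n_snps_used: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-9 * max(1.0, abs(self.eigenvalues[0]))):
            raise ValueError("eigenvalues must be non-increasing")


@dataclass
class FstResult:
    estimate: float
    numerator_sum: float
    denominator_sum: float
    ci_low: float
    ci_high: float
    p_value: float | None
    p_value_label: str | None
    estimator_name: str
    n_snps_used: int


@dataclass
class SampleStats:
    sample_id: str
    f_hat: float
    o_hom: float
    e_hom: float
    n_snps_used: int


# ---------------------------------------------------------------------------
# PCA


def _standardized_calls(geno: GenotypeMatrix):
    """Center each SNP by 2*p_hat and scale by sqrt(2*p_hat*(1-p_hat)).

    Missing entries contribute 0 after centering. Monomorphic SNPs (p_hat in
    {0, 1}) are excluded; the mask of SNPs used is returned.
    """
    c = geno.calls.astype(np.float64)
    miss = geno.calls == MISSING
    c[miss] = np.nan
    with np.errstate(invalid="ignore"):
        p_hat = np.nanmean(c, axis=0) / 2.0
    keep = np.isfinite(p_hat) & (p_hat > 0) & (p_hat < 1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("pca: excluded %d monomorphic/all-missing SNPs", n_dropped)
    c = c[:, keep]
    p = p_hat[keep]
    x = (c - 2 * p[None, :]) / np.sqrt(2 * p * (1 - p))[None, :]
    x[np.isnan(x)] = 0.0
    return x, keep


def pca(geno: GenotypeMatrix, k: int = 10) -> PCAResult:
    """Principal components of the standardized genotype matrix.

    Scores are eigenvectors of the sample-sample covariance scaled by the
    singular values, so Euclidean geometry among samples is preserved.
    """
    x, keep = _standardized_calls(geno)
    m = x.shape[1]
    if k > min(geno.n_samples, m):
        raise ValueError("k exceeds matrix rank bound")
    # n x n eigen-decomposition (n_samples << n_snps in the intended regime)
    gram = x @ x.T / m
    w, v = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1][:k]
    eigvals = w[order]
    scores = v[:, order] * np.sqrt(np.maximum(eigvals, 0.0))[None, :]
    # deterministic sign: largest-magnitude loading positive
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] = -scores[:, j]
    return PCAResult(scores=scores, eigenvalues=eigvals, n_snps_used=m)


def predict_group_accuracy(
    pcs: np.ndarray,
    labels,
    n_iter: int = 100,
    seed: int = 0,
    n_components: int = 4,
) -> dict:
    """Multinomial-logistic prediction accuracy of group labels from leading PCs.

    Each iteration refits the model on a stratified bootstrap resample and
    scores the most-probable predicted group against the true label on the
    full cohort. Returns {'min','max','mean','accuracies'}.
    """
    from sklearn.linear_model import LogisticRegression

    labels = np.asarray(labels, dtype=object)
    x = np.asarray(pcs)[:, :n_components]
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"group with fewer than 2 samples: {small[0]}")
    rng = np.random.default_rng(seed)
    n = len(labels)
    accs = np.empty(n_iter)
    for it in range(n_iter):
        # stratified bootstrap: resample within each group
        idx = np.concatenate([
            rng.choice(np.flatnonzero(labels == g), size=(labels == g).sum(), replace=True)
            for g in uniq
        ])
        model = LogisticRegression(max_iter=1000)
        model.fit(x[idx], labels[idx])
        accs[it] = float((model.predict(x) == labels).mean())
    return {
        "min": float(accs.min()),
        "max": float(accs.max()),
        "mean": float(accs.mean()),
        "accuracies": accs,
    }


# ---------------------------------------------------------------------------
# genomic control


def _allele_counts(calls: np.ndarray):
    """Counted-allele copies and called chromosome count per SNP."""
    miss = calls == MISSING
    alt = np.where(miss, 0, calls).sum(axis=0)
    n_chrom = 2 * (~miss).sum(axis=0)
    return alt.astype(np.float64), n_chrom.astype(np.float64)


def allelic_chisq(geno: GenotypeMatrix, mask_a, mask_b) -> np.ndarray:
    """Per-SNP 1-df allelic chi-square from the 2x2 group x allele table.

    SNPs with zero variance in the pooled pair are NaN.
    """
    a1, n1 = _allele_counts(geno.calls[np.asarray(mask_a)])
    a2, n2 = _allele_counts(geno.calls[np.asarray(mask_b)])
    tot_alt = a1 + a2
    tot = n1 + n2
    with np.errstate(invalid="ignore", divide="ignore"):
        p_pool = tot_alt / tot
        # chi2 = sum (O-E)^2/E over the 4 cells of the allele-count table
        e11 = n1 * p_pool
        e12 = n1 * (1 - p_pool)
        e21 = n2 * p_pool
        e22 = n2 * (1 - p_pool)
        chi2 = (
            (a1 - e11) ** 2 / e11
            + ((n1 - a1) - e12) ** 2 / e12
            + (a2 - e21) ** 2 / e21
            + ((n2 - a2) - e22) ** 2 / e22
        )
    chi2[(tot_alt == 0) | (tot_alt == tot) | (n1 == 0) | (n2 == 0)] = np.nan
    return chi2


def lambda_gc(geno: GenotypeMatrix, labels, group_a: str, group_b: str) -> float:
    """Genomic-control inflation factor between two groups.

    median of the per-SNP allelic chi-squares divided by the 1-df chi-square
    median 0.4549364. Returns 0.0 (degenerate) when every statistic is zero.
    """
    labels = np.asarray(labels, dtype=object)
    mask_a = labels == group_a
    mask_b = labels == group_b
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both groups must be non-empty")
    chi2 = allelic_chisq(geno, mask_a, mask_b)
    chi2 = chi2[np.isfinite(chi2)]
    if chi2.size == 0:
        raise ValueError("no testable SNPs for lambda_GC")
    if chi2.size < 100:
        logger.warning("lambda_gc: only %d testable SNPs", chi2.size)
    lam = float(np.median(chi2) / CHI2_1DF_MEDIAN)
    if lam == 0.0:
        logger.warning("lambda_gc: degenerate (all chi-square zero)")
    return lam


# ---------------------------------------------------------------------------
# Fst


def _hudson_components(calls_a: np.ndarray, calls_b: np.ndarray):
    """Per-SNP Hudson numerator/denominator from sample allele frequencies."""
    a1, m1 = _allele_counts(calls_a)
    a2, m2 = _allele_counts(calls_b)
    n1 = m1  # chromosomes
    n2 = m2
    ok = (n1 >= 4) & (n2 >= 4)  # n_i >= 2 diploid samples
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = a1 / n1
        p2 = a2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den, ok


def _reich_components(hap_a: np.ndarray, hap_b: np.ndarray):
    """Count-based unbiased Fst components from haploidized allele calls.

    ``hap_*`` are (n_ind x m) arrays of 0/1 sampled alleles with MISSING for
    no-calls.
    """
    miss_a = hap_a == MISSING
    miss_b = hap_b == MISSING
    a1 = np.where(miss_a, 0, hap_a).sum(axis=0).astype(float)
    a2 = np.where(miss_b, 0, hap_b).sum(axis=0).astype(float)
    n1 = (~miss_a).sum(axis=0).astype(float)
    n2 = (~miss_b).sum(axis=0).astype(float)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        h1 = a1 * (n1 - a1) / (n1 * (n1 - 1))
        h2 = a2 * (n2 - a2) / (n2 * (n2 - 1))
        num = (a1 / n1 - a2 / n2) ** 2 - h1 / n1 - h2 / n2
        den = num + h1 + h2
    return num, den, ok


def _ratio_jackknife(num: np.ndarray, den: np.ndarray, block_size: int):
    """Block-jackknife 95% CI for sum(num)/sum(den) over contiguous blocks."""
    m = num.size
    n_blocks = max(1, int(np.ceil(m / block_size)))
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    tot_n, tot_d = num.sum(), den.sum()
    theta = tot_n / tot_d
    if n_blocks < 2:
        return theta, theta, theta
    loo = np.empty(n_blocks)
    for b in range(n_blocks):
        s, e = edges[b], edges[b + 1]
        loo[b] = (tot_n - num[s:e].sum()) / (tot_d - den[s:e].sum())
    # weighted (equal-block) jackknife variance
    var = (n_blocks - 1) / n_blocks * ((loo - loo.mean()) ** 2).sum()
    se = np.sqrt(var)
    return theta, theta - 1.96 * se, theta + 1.96 * se


def _perm_pvalue(calls, mask_a, mask_b, observed, components_fn, n_perm, rng):
    """One-sided permutation p: fraction of label permutations with an
    estimate >= observed."""
    both = np.flatnonzero(mask_a | mask_b)
    n_a = int(mask_a.sum())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(both)
        ia, ib = perm[:n_a], perm[n_a:]
        num, den, ok = components_fn(calls[ia], calls[ib])
        est = num[ok].sum() / den[ok].sum()
        if est >= observed:
            count += 1
    p = (count + 1) / (n_perm + 1)
    label = f"<{1 / n_perm:.3g}" if count == 0 else f"{p:.3g}"
    return p, label


def fst_hudson(
    geno: GenotypeMatrix,
    labels,
    group_a: str,
    group_b: str,
    block_size: int = 5000,
    n_perm: int = 0,
    seed: int = 0,
) -> FstResult:
    """Hudson Fst between two groups as a genome-wide ratio of averages.

    Per SNP: num = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and
    den = p1(1-p2) + p2(1-p1), with n_i counted in chromosomes. The estimate
    is sum(num)/sum(den); the CI is a block jackknife over contiguous SNP
    blocks; the p-value (optional) is by label permutation.
    """
    labels = np.asarray(labels, dtype=object)
    mask_a = labels == group_a
    mask_b = labels == group_b
    num, den, ok = _hudson_components(geno.calls[mask_a], geno.calls[mask_b])
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("fst_hudson: skipped %d SNPs with <2 samples in a group", n_skip)
    num, den = num[ok], den[ok]
    if den.sum() == 0:
        raise ValueError("degenerate input: zero Hudson denominator sum")
    est, lo, hi = _ratio_jackknife(num, den, block_size)
    p_value = p_label = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        p_value, p_label = _perm_pvalue(
            geno.calls, mask_a, mask_b, est, _hudson_components, n_perm, rng
        )
    return FstResult(
        estimate=float(est), numerator_sum=float(num.sum()), denominator_sum=float(den.sum()),
        ci_low=float(lo), ci_high=float(hi), p_value=p_value, p_value_label=p_label,
        estimator_name="hudson", n_snps_used=int(ok.sum()),
    )


def haploidize(calls: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one allele per individual per SNP, removing within-individual
    allele correlation (heterozygotes contribute a fair coin)."""
    out = np.where(calls == 2, 1, calls).astype(np.int8)
    het = calls == 1
    out[het] = (rng.random(int(het.sum())) < 0.5).astype(np.int8)
    out[calls == MISSING] = MISSING
    return out


def fst_inbreeding_corrected(
    geno: GenotypeMatrix,
    labels,
    group_a: str,
    group_b: str,
    seed: int = 0,
    block_size: int = 5000,
    n_perm: int = 0,
) -> FstResult:
    """Inbreeding-robust Fst: haploidize individuals, then apply the
    count-based unbiased estimator.

    With derived counts a over n haploid chromosomes per group and
    h = a(n-a)/(n(n-1)): num = (a1/n1 - a2/n2)^2 - h1/n1 - h2/n2 and
    den = num + h1 + h2, accumulated genome-wide as sum(num)/sum(den).
    Haploidization makes the estimator insensitive to within-individual
    allele correlation (inbreeding).
    """
    labels = np.asarray(labels, dtype=object)
    mask_a = labels == group_a
    mask_b = labels == group_b
    rng = np.random.default_rng(seed)
    haps = haploidize(geno.calls, rng)
    num, den, ok = _reich_components(haps[mask_a], haps[mask_b])
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("fst_inbreeding_corrected: skipped %d SNPs", n_skip)
    num, den = num[ok], den[ok]
    if den.sum() == 0:
        raise ValueError("degenerate input: zero denominator sum")
    est, lo, hi = _ratio_jackknife(num, den, block_size)
    p_value = p_label = None
    if n_perm > 0:
        p_value, p_label = _perm_pvalue(
            haps, mask_a, mask_b, est, _reich_components, n_perm, rng
        )
    return FstResult(
        estimate=float(est), numerator_sum=float(num.sum()), denominator_sum=float(den.sum()),
        ci_low=float(lo), ci_high=float(hi), p_value=p_value, p_value_label=p_label,
        estimator_name="inbreeding_corrected", n_snps_used=int(ok.sum()),
    )


def fst_naive_genotype(geno: GenotypeMatrix, labels, group_a: str, group_b: str) -> float:
    """Naive genotype-frequency Fst (no sample-size or inbreeding correction);
    biased upward under inbreeding. Provided for comparison only."""
    labels = np.asarray(labels, dtype=object)
    a1, n1 = _allele_counts(geno.calls[labels == group_a])
    a2, n2 = _allele_counts(geno.calls[labels == group_b])
    with np.errstate(invalid="ignore", divide="ignore"):
        p1, p2 = a1 / n1, a2 / n2
    pbar = (p1 + p2) / 2
    h_t = 2 * pbar * (1 - pbar)
    h_s = p1 * (1 - p1) + p2 * (1 - p2)
    ok = np.isfinite(h_t) & (h_t > 0)
    return float((h_t - h_s)[ok].sum() / h_t[ok].sum())


# ---------------------------------------------------------------------------
# inbreeding coefficient


def inbreeding_coefficient(geno: GenotypeMatrix) -> list[SampleStats]:
    """Per-sample genomic inbreeding from observed vs expected homozygosity.

    F_hat = (O_hom - E_hom) / (L - E_hom), where E_hom sums, over the
    sample's non-missing SNPs, 1 - 2*p*(1-p) * 2n/(2n-1) with p the cohort
    allele frequency and n the cohort's called sample count at the SNP.
    """
    calls = geno.calls
    miss = calls == MISSING
    n_called = (~miss).sum(axis=0).astype(float)
    alt = np.where(miss, 0, calls).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2 * n_called)
        e_site = 1 - 2 * p * (1 - p) * (2 * n_called / (2 * n_called - 1))
    e_site[n_called < 1] = np.nan
    testable = np.isfinite(e_site)

    out = []
    for i, sid in enumerate(geno.samples):
        use = testable & ~miss[i]
        n_used = int(use.sum())
        o_hom = float(((calls[i] == 0) | (calls[i] == 2))[use].sum())
        e_hom = float(e_site[use].sum())
        denom = n_used - e_hom
        if denom == 0:
            logger.warning("inbreeding undefined for sample %s", sid)
            f_hat = float("nan")
        else:
            f_hat = (o_hom - e_hom) / denom
        out.append(SampleStats(sid, f_hat, o_hom, e_hom, n_used))
    return out


# ---------------------------------------------------------------------------
# group comparison


def compare_groups(values, labels, reference_group: str) -> pd.DataFrame:
    """Per-group mean/SE and two-sided Welch t-test p versus the reference.

    Groups with a single sample are excluded with a warning. The reference
    group's own p-value is 1 at t=0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if reference_group not in labels:
        raise ValueError(f"reference group {reference_group!r} not present")
    ref = values[labels == reference_group]
    if ref.size < 2:
        raise ValueError("reference group needs at least 2 samples")
    rows = []
    for g in pd.unique(labels):
        v = values[labels == g]
        if v.size < 2:
            logger.warning("compare_groups: excluding single-sample group %s", g)
            continue
        if g == reference_group:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(v, ref, equal_var=False)
        rows.append(
            {
                "group": g,
                "n": int(v.size),
                "mean": float(v.mean()),
                "se": float(v.std(ddof=1) / np.sqrt(v.size)),
                "t_vs_reference": float(t),
                "p_vs_reference": float(p),
            }
        )
    return pd.DataFrame(rows)
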