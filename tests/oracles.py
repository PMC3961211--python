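"""Independent brute-force oracles used by the test suite.

These deliberately re-derive each statistic from first principles (explicit
enumeration, pairwise comparison, direct accumulation) and share no code with
the package implementations they check.
"""

from __future__ import annotations

from itertools import combinations
from math import comb, factorial

import numpy as np

MISSING = -1


def hwe_exact_bruteforce(n_ab: int, n_aa: int, n_bb: int) -> float:
    """Exact HWE p by full enumeration of heterozygote configurations.

    Conditional probability of het count h given allele counts is
    proportional to 2^h * n! / (n_rare_hom! n_het! n_common_hom!).
    """
    n = n_aa + n_ab + n_bb
    n_minor = 2 * min(n_aa, n_bb) + n_ab
    weights = {}
    for h in range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2):
        rare = (n_minor - h) // 2
        common = n - h - rare
        weights[h] = 2.0**h * factorial(n) / (
            factorial(rare) * factorial(h) * factorial(common)
        )
    total = sum(weights.values())
    p_obs = weights[n_ab] / total
    return sum(w for w in weights.values() if w / total <= p_obs * (1 + 1e-12)) / total


def roh_call_bruteforce(calls, pos, window_snps, window_span_kb_cap,
                        max_het, max_missing, threshold, min_kb, min_snps):
    """Exhaustive single-chromosome RoH caller materializing every window.

    Returns inclusive (start_idx, end_idx) pairs.
    """
    m = len(calls)
    windows = []
    for i in range(m - window_snps + 1):
        j = i + window_snps - 1
        if pos[j] - pos[i] > window_span_kb_cap * 1000:
            continue
        seg = calls[i:j + 1]
        het = int(np.sum(np.asarray(seg) == 1))
        mis = int(np.sum(np.asarray(seg) == MISSING))
        windows.append((i, j, het <= max_het and mis <= max_missing))
    in_run = []
    for s in range(m):
        covering = [w for w in windows if w[0] <= s <= w[1]]
        if not covering:
            in_run.append(False)
            continue
        prop = sum(1 for w in covering if w[2]) / len(covering)
        in_run.append(prop > threshold)
    runs = []
    s = None
    for i, flag in enumerate(in_run + [False]):
        if flag and s is None:
            s = i
        elif not flag and s is not None:
            e = i - 1
            if pos[e] - pos[s] >= min_kb * 1000 and e - s + 1 >= min_snps:
                runs.append((s, e))
            s = None
    return runs


def ehh_bruteforce(haps: np.ndarray, pos: np.ndarray, core: int, bit: int):
    """EHH curve by direct all-pairs comparison of carrier haplotypes.

    Returns (positions, ehh) over the whole chromosome, core included.
    """
    carriers = [h for h in range(haps.shape[0]) if haps[h, core] == bit]
    n_pairs = comb(len(carriers), 2)
    m = haps.shape[1]
    out_pos, out_ehh = [], []
    for x in range(m):
        lo, hi = (x, core) if x <= core else (core, x)
        identical = 0
        for a, b in combinations(carriers, 2):
            if np.array_equal(haps[a, lo:hi + 1], haps[b, lo:hi + 1]):
                identical += 1
        out_pos.append(pos[x])
        out_ehh.append(identical / n_pairs)
    return np.asarray(out_pos), np.asarray(out_ehh)


def hudson_fst_bruteforce(calls_a, calls_b):
    """Hudson Fst by explicit per-SNP accumulation (ratio of averages)."""
    num_sum = 0.0
    den_sum = 0.0
    m = calls_a.shape[1]
    for j in range(m):
        ga = [int(c) for c in calls_a[:, j] if c != MISSING]
        gb = [int(c) for c in calls_b[:, j] if c != MISSING]
        n1, n2 = 2 * len(ga), 2 * len(gb)
        if n1 < 4 or n2 < 4:
            continue
        p1 = sum(ga) / n1
        p2 = sum(gb) / n2
        num_sum += (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den_sum += p1 * (1 - p2) + p2 * (1 - p1)
    return num_sum / den_sum
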