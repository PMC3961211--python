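"""EHH / iHS selection scan on phased, ancestral-coded haplotypes.

Distances are physical (bp). Raw scores are ln(iHH_ancestral / iHH_derived),
so negative standardized scores mark unusually long derived-allele
haplotypes. Standardization is within derived-allele-frequency bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import HaplotypeMatrix

logger = logging.getLogger(__name__)

EHH_CUTOFF_DEFAULT = 0.05
MAX_GAP_BP_DEFAULT = 200_000


@dataclass
class EHHCurve:
    core_index: int
    allele: str  # "ancestral" or "derived"
    positions: np.ndarray  # bp, ascending, includes the core position
    ehh: np.ndarray        # same length, ehh[core]=1, non-increasing outward
    core_position: int


try:  # compiled walk kernel; the numpy path below is the reference fallback
    from numba import njit

    @njit(cache=True)
    def _ehh_walk_jit(haps, carriers, order, stop_below, out):  # pragma: no cover
        c = carriers.size
        denom = c * (c - 1)
        group = np.zeros(c, dtype=np.int64)
        n_groups = 1
        n = 0
        for oi in range(order.size):
            j = order[oi]
            counts = np.zeros(2 * n_groups, dtype=np.int64)
            for t in range(c):
                key = group[t] * 2 + haps[carriers[t], j]
                group[t] = key
                counts[key] += 1
            s = 0
            for k in range(counts.size):
                s += counts[k] * (counts[k] - 1)
            e = s / denom
            out[n] = e
            n += 1
            if e == 0.0 or e < stop_below:
                break
            relabel = np.empty(counts.size, dtype=np.int64)
            ng = 0
            for k in range(counts.size):
                if counts[k] > 0:
                    relabel[k] = ng
                    ng += 1
            for t in range(c):
                group[t] = relabel[group[t]]
            n_groups = ng
        return n

except ImportError:  # pragma: no cover
    _ehh_walk_jit = None


def _ehh_one_side(haps: np.ndarray, carriers: np.ndarray, order: np.ndarray, stop_below: float):
    """EHH values walking outward over column indices ``order``.

    ``carriers`` are haplotype row indices sharing the core allele. Returns
    one EHH value per visited column; stops after the first value <
    stop_below or when EHH reaches 0.
    """
    if _ehh_walk_jit is not None and order.size:
        out = np.empty(order.size)
        n = _ehh_walk_jit(
            haps, carriers.astype(np.int64), order.astype(np.int64),
            float(stop_below), out,
        )
        return list(out[:n])
    c = carriers.size
    denom = c * (c - 1)  # 2 * C(c, 2)
    group = np.zeros(c, dtype=np.int64)
    n_groups = 1
    out = []
    for j in order:
        key = group * 2 + haps[carriers, j]
        counts = np.bincount(key, minlength=2 * n_groups)
        occupied = counts > 0
        sizes = counts[occupied]
        ehh = float((sizes * (sizes - 1)).sum()) / denom
        out.append(ehh)
        if ehh == 0.0 or ehh < stop_below:
            break
        relabel = np.cumsum(occupied) - 1
        group = relabel[key]
        n_groups = sizes.size
    return out


def ehh(haps: HaplotypeMatrix, core_index: int, allele: str, stop_below: float = 0.0) -> EHHCurve:
    """Extended haplotype homozygosity of one core allele.

    EHH at marker x is the probability that two random carriers of the core
    allele are identical over every marker between the core and x inclusive:
    sum over identity groups g of C(e_g, 2), divided by C(c, 2). Computed
    separately left and right; restricted to the core's chromosome.
    """
    if allele not in ("ancestral", "derived"):
        raise ValueError("allele must be 'ancestral' or 'derived'")
    bit = 1 if allele == "derived" else 0
    H = haps.haplotypes
    carriers = np.flatnonzero(H[:, core_index] == bit)
    if carriers.size < 2:
        raise ValueError(f"fewer than 2 carriers of the {allele} allele at core {core_index}")
    chrom = haps.variants.chrom[core_index]
    on_chrom = np.flatnonzero(haps.variants.chrom == chrom)
    k = int(np.searchsorted(on_chrom, core_index))
    left = on_chrom[:k][::-1]
    right = on_chrom[k + 1:]
    ehh_left = _ehh_one_side(H, carriers, left, stop_below)
    ehh_right = _ehh_one_side(H, carriers, right, stop_below)
    pos = haps.variants.pos
    core_pos = int(pos[core_index])
    positions = np.concatenate(
        (pos[left[: len(ehh_left)]][::-1], [core_pos], pos[right[: len(ehh_right)]])
    )
    values = np.concatenate((ehh_left[::-1], [1.0], ehh_right))
    return EHHCurve(core_index, allele, positions, values, core_pos)


def ihh(
    curve: EHHCurve,
    ehh_cutoff: float = EHH_CUTOFF_DEFAULT,
    max_gap_bp: int = MAX_GAP_BP_DEFAULT,
) -> float:
    """Integrated EHH: trapezoid area of (EHH - cutoff)+ vs position, summed
    over both sides of the core.

    Integration on a side stops at the first marker with EHH < cutoff (that
    marker still closes its trapezoid with a clipped value of 0) or at a
    gap wider than max_gap_bp (the gap contributes nothing), or at the
    chromosome end.
    """
    pos = np.asarray(curve.positions, dtype=float)
    val = np.asarray(curve.ehh, dtype=float)
    core = int(np.flatnonzero(pos == curve.core_position)[0])

    def side(idx: np.ndarray) -> float:
        area = 0.0
        prev_p, prev_v = float(pos[core]), float(val[core])
        for i in idx:
            p, v = float(pos[i]), float(val[i])
            gap = abs(p - prev_p)
            if gap > max_gap_bp:
                break
            a = max(prev_v - ehh_cutoff, 0.0)
            b = max(v - ehh_cutoff, 0.0)
            area += 0.5 * (a + b) * gap
            if v < ehh_cutoff:
                break
            prev_p, prev_v = p, v
        return area

    total = side(np.arange(core - 1, -1, -1)) + side(np.arange(core + 1, len(pos)))
    if total == 0.0:
        logger.debug("iHH zero at core %d (%s)", curve.core_index, curve.allele)
    return total


@dataclass
class IHSParams:
    min_maf: float = 0.05
    ehh_cutoff: float = EHH_CUTOFF_DEFAULT
    max_gap_bp: int = MAX_GAP_BP_DEFAULT
    bin_width: float = 0.025
    min_bin_snps: int = 20


def _merge_small_bins(bin_ids: np.ndarray, n_bins: int, min_count: int) -> np.ndarray:
    """Relabel frequency bins so every occupied bin has >= min_count members,
    merging small bins into their left neighbour (leftmost merges right)."""
    ids = bin_ids.copy()
    merged = 0
    for b in range(n_bins):
        count = (ids == b).sum()
        if 0 < count < min_count:
            target = b - 1
            while target >= 0 and (ids == target).sum() == 0:
                target -= 1
            if target < 0:
                candidates = [t for t in range(b + 1, n_bins) if (ids == t).sum() > 0]
                if not candidates:
                    break
                target = candidates[0]
            ids[ids == b] = target
            merged += 1
    if merged:
        logger.info("ihs_scan: merged %d small frequency bins", merged)
    return ids


def ihs_scan(haps: HaplotypeMatrix, params: IHSParams = IHSParams()) -> pd.DataFrame:
    """Per-SNP iHS table.

    raw = ln(iHH_ancestral / iHH_derived); standardized within
    derived-allele-frequency bins (width ``bin_width``, small bins merged).
    SNPs with derived frequency outside [min_maf, 1-min_maf], fewer than two
    carriers of either allele, or a zero iHH are reported with NaN scores.
    """
    n_hap, m = haps.haplotypes.shape
    freq = haps.derived_freq()
    ihh_a = np.full(m, np.nan)
    ihh_d = np.full(m, np.nan)
    usable = (freq >= params.min_maf) & (freq <= 1 - params.min_maf)
    usable &= (freq * n_hap >= 2) & ((1 - freq) * n_hap >= 2)
    n_zero = 0
    for j in np.flatnonzero(usable):
        ca = ehh(haps, j, "ancestral", stop_below=params.ehh_cutoff)
        cd = ehh(haps, j, "derived", stop_below=params.ehh_cutoff)
        ia = ihh(ca, params.ehh_cutoff, params.max_gap_bp)
        idv = ihh(cd, params.ehh_cutoff, params.max_gap_bp)
        if ia > 0 and idv > 0:
            ihh_a[j] = ia
            ihh_d[j] = idv
        else:
            n_zero += 1
    if n_zero:
        logger.info("ihs_scan: dropped %d SNPs with a zero iHH", n_zero)

    with np.errstate(invalid="ignore", divide="ignore"):
        raw = np.log(ihh_a / ihh_d)

    n_bins = int(np.ceil(1.0 / params.bin_width))
    bin_ids = np.minimum((freq / params.bin_width).astype(int), n_bins - 1)
    scored = np.isfinite(raw)
    work = np.where(scored, bin_ids, -1)
    work[scored] = _merge_small_bins(work[scored], n_bins, params.min_bin_snps)
    ihs = np.full(m, np.nan)
    for b in np.unique(work[scored]):
        sel = work == b
        mu = raw[sel].mean()
        sd = raw[sel].std(ddof=0)
        if sd > 0:
            ihs[sel] = (raw[sel] - mu) / sd
    return pd.DataFrame(
        {
            "chrom": haps.variants.chrom,
            "pos": haps.variants.pos,
            "id": haps.variants.ids,
            "derived_freq": freq,
            "ihh_a": ihh_a,
            "ihh_d": ihh_d,
            "raw_ihs": raw,
            "ihs": ihs,
            "freq_bin": work,
        }
    )


# ---------------------------------------------------------------------------
# region scan


@dataclass
class SelectionRegion:
    chrom: str
    start_bp: int
    end_bp: int
    size_kb: float
    n_snps: int
    n_extreme: int
    max_abs_ihs: float
    max_snp_id: str
    max_ihs: float
    p_nominal: float
    p_empirical: float
    p_empirical_label: str


def region_scan(
    ihs_table: pd.DataFrame,
    window_bp: int = 100_000,
    extreme_threshold: float = 4.0,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[SelectionRegion]:
    """Windows enriched in extreme |iHS|, with permutation family-wise p-values.

    The genome is tiled in non-overlapping windows of ``window_bp``. Per
    window, p_nominal is the upper binomial tail P(X >= n_extreme) with
    X ~ Binomial(n_snps_in_window, genome-wide extreme fraction). The
    family-wise empirical p compares each window's nominal p with the minimum
    nominal p over all windows under ``n_perm`` random reassignments of the
    scores to SNP positions. Adjacent windows with p_empirical < alpha merge
    into one region, trimmed to the first/last member SNP.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    tbl = ihs_table.loc[np.isfinite(ihs_table["ihs"].to_numpy(float))].reset_index(drop=True)
    n = len(tbl)
    if n == 0:
        logger.info("region_scan: no scored SNPs")
        return []
    abs_ihs = np.abs(tbl["ihs"].to_numpy(float))
    extreme = abs_ihs > extreme_threshold
    k_total = int(extreme.sum())
    frac = k_total / n
    if frac == 0:
        logger.info("region_scan: no SNP exceeds |iHS| > %g; nothing to scan", extreme_threshold)
        return []

    # window ids: per chromosome, floor((pos - first_pos) / window_bp)
    chroms = tbl["chrom"].to_numpy(object)
    pos = tbl["pos"].to_numpy(np.int64)
    win_id = np.empty(n, dtype=np.int64)
    win_key: list[tuple[str, int]] = []
    offset = 0
    for c in pd.unique(chroms):
        sel = np.flatnonzero(chroms == c)
        local = (pos[sel] - pos[sel].min()) // window_bp
        uniq, inv = np.unique(local, return_inverse=True)
        win_id[sel] = offset + inv
        win_key += [(str(c), int(u)) for u in uniq]
        offset += uniq.size
    n_win = offset
    win_n = np.bincount(win_id, minlength=n_win)
    win_k = np.bincount(win_id[extreme], minlength=n_win)

    # nominal p lookup per window for every possible extreme count
    sf_table = np.empty((n_win, k_total + 1))
    for w in range(n_win):
        ks = np.arange(k_total + 1)
        sf_table[w] = stats.binom.sf(ks - 1, win_n[w], frac)
    p_nom = sf_table[np.arange(n_win), np.minimum(win_k, k_total)]

    rng = np.random.default_rng(seed)
    min_p = np.empty(n_perm)
    for t in range(n_perm):
        idx = rng.choice(n, size=k_total, replace=False)
        counts = np.bincount(win_id[idx], minlength=n_win)
        min_p[t] = sf_table[np.arange(n_win), counts].min()
    p_emp = (1 + (min_p[None, :] <= p_nom[:, None]).sum(axis=1)) / (n_perm + 1)
    emp_label = np.where(
        (min_p[None, :] <= p_nom[:, None]).sum(axis=1) == 0,
        f"<{1 / n_perm:g}",
        [f"{v:g}" for v in p_emp],
    )

    sig = p_emp < alpha
    regions: list[SelectionRegion] = []
    order = sorted(range(n_win), key=lambda w: win_key[w])
    # group adjacent significant windows on the same chromosome
    run: list[int] = []

    def flush(run_windows: list[int]) -> None:
        if not run_windows:
            return
        member = np.isin(win_id, run_windows)
        sel = np.flatnonzero(member)
        sub_abs = abs_ihs[sel]
        imax = sel[int(np.argmax(sub_abs))]
        regions.append(
            SelectionRegion(
                chrom=str(chroms[sel[0]]),
                start_bp=int(pos[sel].min()),
                end_bp=int(pos[sel].max()),
                size_kb=float((pos[sel].max() - pos[sel].min()) / 1000.0),
                n_snps=int(sel.size),
                n_extreme=int(extreme[sel].sum()),
                max_abs_ihs=float(sub_abs.max()),
                max_snp_id=str(tbl["id"].iloc[imax]),
                max_ihs=float(tbl["ihs"].iloc[imax]),
                p_nominal=float(min(p_nom[w] for w in run_windows)),
                p_empirical=float(min(p_emp[w] for w in run_windows)),
                p_empirical_label=str(
                    emp_label[min(run_windows, key=lambda w: p_emp[w])]
                ),
            )
        )

    prev: tuple[str, int] | None = None
    for w in order:
        if not sig[w]:
            continue
        key = win_key[w]
        if prev is not None and key[0] == prev[0] and key[1] == prev[1] + 1:
            run.append(w)
        else:
            flush(run)
            run = [w]
        prev = key
    flush(run)
    regions.sort(key=lambda r: (-r.max_abs_ihs,))
    return regions


def regions_to_frame(regions: list[SelectionRegion]) -> pd.DataFrame:
    """Region list as a report table (position, size, extreme counts, max
    score, nominal and empirical p, genes placeholder)."""
    rows = [
        {
            "position": f"chr{r.chrom}: {r.start_bp:,}-{r.end_bp:,}",
            "size_kb": r.size_kb,
            "n_extreme": r.n_extreme,
            "n_snps": r.n_snps,
            "max_abs_ihs": r.max_abs_ihs,
            "max_snp_id": r.max_snp_id,
            "p_nominal": r.p_nominal,
            "p_empirical": r.p_empirical_label,
            "genes": "",
        }
        for r in regions
    ]
    cols = [
        "position", "size_kb", "n_extreme", "n_snps", "max_abs_ihs",
        "max_snp_id", "p_nominal", "p_empirical", "genes",
    ]
    return pd.DataFrame(rows, columns=cols)
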