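"""Runs-of-Homozygosity: sliding-window caller, length classes, F_RoH summaries.

The caller follows the classic genotype-array sliding-window scheme: windows
of a fixed SNP count (span-capped in kb) are flagged homozygous when they
contain at most ``max_het_per_window`` heterozygous and
``max_missing_per_window`` missing calls; a SNP joins a run when the
proportion of homozygous windows covering it exceeds the hit threshold; runs
are kept above minimum physical length and SNP count. Segments never span
chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import MISSING, GenotypeMatrix
from .structure import compare_groups

logger = logging.getLogger(__name__)

#: default accessible autosomal genome size (bp) used as the F_RoH denominator
ACCESSIBLE_GENOME_BP = 2_840_000_000

#: half-open RoH length classes in Mb; the last class is [16, inf)
LENGTH_CLASSES_MB: list[tuple[float, float]] = [
    (0.5, 1.0), (1.0, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 16.0), (16.0, float("inf")),
]


def class_label(lo: float, hi: float) -> str:
    return f"{lo:g}-{hi:g}Mb" if np.isfinite(hi) else f">{lo:g}Mb"


@dataclass(frozen=True)
class RoHParams:
    window_snps: int = 50
    window_span_kb_cap: float = 5000.0
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    hit_proportion_threshold: float = 0.05
    min_segment_kb: float = 500.0
    min_segment_snps: int = 50

    def __post_init__(self) -> None:
        if min(self.window_snps, self.min_segment_snps) < 1:
            raise ValueError("window/segment SNP counts must be positive")
        if min(self.window_span_kb_cap, self.min_segment_kb) <= 0:
            raise ValueError("kb parameters must be positive")
        if not 0 < self.hit_proportion_threshold < 1:
            raise ValueError("hit_proportion_threshold must be in (0, 1)")
        if self.max_het_per_window < 0 or self.max_missing_per_window < 0:
            raise ValueError("per-window tolerances must be non-negative")


@dataclass(frozen=True)
class RoHSegment:
    sample_id: str
    chrom: str
    start_bp: int  # 1-based position of first member SNP
    end_bp: int    # 1-based position of last member SNP
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp

    def __post_init__(self) -> None:
        if self.end_bp < self.start_bp:
            raise ValueError("segment end before start")
        if self.n_het + self.n_missing > self.n_snps:
            raise ValueError("het+missing exceeds SNP count")


def _runs_from_flags(in_run: np.ndarray):
    """Start/stop index pairs (inclusive) of maximal True runs."""
    if not in_run.any():
        return []
    padded = np.concatenate(([False], in_run, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts, ends))


def _call_sample_chrom(
    calls: np.ndarray, pos: np.ndarray, params: RoHParams
):
    """Hit-proportion run finding for one sample on one chromosome.

    Returns (start_idx, end_idx) inclusive pairs of member SNPs.
    """
    m = calls.size
    w = params.window_snps
    if m < w:
        return []
    het = (calls == 1).astype(np.int32)
    mis = (calls == MISSING).astype(np.int32)
    chet = np.concatenate(([0], np.cumsum(het)))
    cmis = np.concatenate(([0], np.cumsum(mis)))
    starts = np.arange(m - w + 1)
    span_ok = (pos[starts + w - 1] - pos[starts]) <= params.window_span_kb_cap * 1000
    hom = (
        span_ok
        & ((chet[starts + w] - chet[starts]) <= params.max_het_per_window)
        & ((cmis[starts + w] - cmis[starts]) <= params.max_missing_per_window)
    )
    # windows containing SNP j start at i in [j-w+1, j] intersected with the
    # enumerated (span-eligible) window start range
    elig = span_ok.astype(np.int64)
    homn = (span_ok & hom).astype(np.int64)
    celig = np.concatenate(([0], np.cumsum(elig)))
    chom = np.concatenate(([0], np.cumsum(homn)))
    j = np.arange(m)
    lo = np.maximum(j - w + 1, 0)
    hi = np.minimum(j, m - w)
    denom = np.where(hi >= lo, celig[hi + 1] - celig[lo], 0)
    num = np.where(hi >= lo, chom[hi + 1] - chom[lo], 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(denom > 0, num / np.maximum(denom, 1), 0.0)
    in_run = prop > params.hit_proportion_threshold
    out = []
    for s, e in _runs_from_flags(in_run):
        if pos[e] - pos[s] < params.min_segment_kb * 1000:
            continue
        if e - s + 1 < params.min_segment_snps:
            continue
        out.append((int(s), int(e)))
    return out


def call_roh(geno: GenotypeMatrix, params: RoHParams = RoHParams()) -> list[RoHSegment]:
    """Call RoH segments for every sample, sorted by (sample, chrom, start)."""
    segments: list[RoHSegment] = []
    chroms = pd.unique(geno.variants.chrom)
    chrom_idx = {c: np.flatnonzero(geno.variants.chrom == c) for c in chroms}
    for c, idx in chrom_idx.items():
        if idx.size < params.window_snps:
            logger.info("chromosome %s has %d SNPs < window size, skipped", c, idx.size)
    for i, sid in enumerate(geno.samples):
        for c in chroms:
            idx = chrom_idx[c]
            calls = geno.calls[i, idx]
            pos = geno.variants.pos[idx]
            for s, e in _call_sample_chrom(calls, pos, params):
                seg_calls = calls[s:e + 1]
                segments.append(
                    RoHSegment(
                        sample_id=sid,
                        chrom=str(c),
                        start_bp=int(pos[s]),
                        end_bp=int(pos[e]),
                        n_snps=int(e - s + 1),
                        n_het=int((seg_calls == 1).sum()),
                        n_missing=int((seg_calls == MISSING).sum()),
                    )
                )
    segments.sort(key=lambda s: (s.sample_id, s.chrom, s.start_bp))
    return segments


def classify_segments(segments: list[RoHSegment]) -> pd.DataFrame:
    """Per-sample per-class segment counts and summed lengths (Mb classes are
    half-open [lo, hi), last class unbounded)."""
    labels = [class_label(lo, hi) for lo, hi in LENGTH_CLASSES_MB]
    samples = sorted({s.sample_id for s in segments})
    rows = {
        sid: {f"n_{lab}": 0 for lab in labels} | {f"mb_{lab}": 0.0 for lab in labels}
        for sid in samples
    }
    for seg in segments:
        mb = seg.length_bp / 1e6
        for (lo, hi), lab in zip(LENGTH_CLASSES_MB, labels):
            if lo <= mb < hi:
                rows[seg.sample_id][f"n_{lab}"] += 1
                rows[seg.sample_id][f"mb_{lab}"] += mb
                break
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "sample_id"
    return df.reset_index()


def froh(
    segments: list[RoHSegment],
    samples: list[str],
    min_mb: float = 0.5,
    accessible_bp: int = ACCESSIBLE_GENOME_BP,
) -> pd.DataFrame:
    """Per-sample F_RoH% = 100 * summed length of segments >= min_mb / accessible_bp.

    ``samples`` fixes the output rows so segment-free samples report 0.
    """
    if accessible_bp <= 0:
        raise ValueError("accessible_bp must be positive")
    total = {sid: 0.0 for sid in samples}
    nseg = {sid: 0 for sid in samples}
    for seg in segments:
        if seg.length_bp / 1e6 >= min_mb and seg.sample_id in total:
            total[seg.sample_id] += seg.length_bp
            nseg[seg.sample_id] += 1
    return pd.DataFrame(
        {
            "sample_id": list(samples),
            "froh_pct": [100.0 * total[s] / accessible_bp for s in samples],
            "sum_mb": [total[s] / 1e6 for s in samples],
            "n_segments": [nseg[s] for s in samples],
        }
    )


def summarize_groups(
    segments: list[RoHSegment],
    samples: list[str],
    labels,
    reference_group: str | None = None,
    accessible_bp: int = ACCESSIBLE_GENOME_BP,
) -> dict[str, pd.DataFrame]:
    """Group-level RoH summary tables.

    Returns ``{"froh": ..., "classes": ...}``: per-group mean/SE of
    F_RoH%>=0.5 and >=5 (with Welch p vs the reference when given), and per
    length class the percentage of the accessible genome plus mean/SE of the
    per-sample summed lengths.
    """
    labels = np.asarray(labels, dtype=object)
    froh05 = froh(segments, samples, 0.5, accessible_bp)
    froh5 = froh(segments, samples, 5.0, accessible_bp)
    per_class = classify_segments(segments)
    per_class = (
        pd.DataFrame({"sample_id": samples})
        .merge(per_class, on="sample_id", how="left")
        .fillna(0.0)
    )

    def group_stats(values: np.ndarray) -> pd.DataFrame:
        if reference_group is not None:
            return compare_groups(values, labels, reference_group)
        rows = []
        for g in pd.unique(labels):
            v = values[labels == g]
            rows.append(
                {
                    "group": g,
                    "n": int(v.size),
                    "mean": float(v.mean()),
                    "se": float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else float("nan"),
                }
            )
        return pd.DataFrame(rows)

    f_tables = []
    for name, tbl in (("froh_pct_ge_0.5", froh05), ("froh_pct_ge_5", froh5)):
        t = group_stats(tbl["froh_pct"].to_numpy())
        t.insert(0, "measure", name)
        f_tables.append(t)
        t2 = group_stats(tbl["sum_mb"].to_numpy())
        t2.insert(0, "measure", name.replace("froh_pct", "sum_mb"))
        f_tables.append(t2)

    c_tables = []
    for lo, hi in LENGTH_CLASSES_MB:
        lab = class_label(lo, hi)
        v = per_class[f"mb_{lab}"].to_numpy(dtype=float)
        t = group_stats(v)
        t.insert(0, "class", lab)
        # percent of accessible genome occupied, averaged over individuals
        pct = []
        for g in t["group"]:
            vg = v[labels == g]
            pct.append(100.0 * float(vg.mean()) * 1e6 / accessible_bp)
        t.insert(2, "pct_accessible", pct)
        c_tables.append(t)

    return {
        "froh": pd.concat(f_tables, ignore_index=True),
        "classes": pd.concat(c_tables, ignore_index=True),
        "per_sample_froh05": froh05,
        "per_sample_froh5": froh5,
        "per_sample_classes": per_class,
    }
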