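"""Domain types and readers/writers for the standard formats the pipeline touches.

Genotype calls count copies of ``allele_b`` (ALT for VCF input, second-seen
allele for PLINK text input) and live in ``{0, 1, 2, MISSING}``. Coordinates
are 1-based inclusive internally (VCF convention); BED output converts to
0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: sentinel for a missing genotype call, never conflated with 0 copies
MISSING: int = -1

UNKNOWN_ANCESTRAL = "unknown"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


class PhasingError(FormatError):
    """Raised when phased input is required but an unphased genotype is found."""


@dataclass(frozen=True)
class Variant:
    """A single biallelic SNP."""

    chrom: str
    pos: int  # 1-based
    id: str
    allele_a: str
    allele_b: str
    ancestral: str = UNKNOWN_ANCESTRAL

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.allele_a == self.allele_b:
            raise ValueError(f"alleles must differ at {self.chrom}:{self.pos}")
        if self.ancestral not in (self.allele_a, self.allele_b, UNKNOWN_ANCESTRAL):
            raise ValueError(
                f"ancestral allele {self.ancestral!r} is neither observed allele "
                f"at {self.chrom}:{self.pos}"
            )


class VariantTable:
    """Array-backed, ordered collection of :class:`Variant` records.

    Within each chromosome positions must be strictly increasing.
    """

    def __init__(
        self,
        chrom: Sequence[str],
        pos: Sequence[int],
        ids: Sequence[str],
        allele_a: Sequence[str],
        allele_b: Sequence[str],
        ancestral: Sequence[str] | None = None,
    ) -> None:
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ids = np.asarray(ids, dtype=object)
        self.allele_a = np.asarray(allele_a, dtype=object)
        self.allele_b = np.asarray(allele_b, dtype=object)
        if ancestral is None:
            ancestral = [UNKNOWN_ANCESTRAL] * len(self.pos)
        self.ancestral = np.asarray(ancestral, dtype=object)
        n = len(self.pos)
        for arr in (self.chrom, self.ids, self.allele_a, self.allele_b, self.ancestral):
            if len(arr) != n:
                raise ValueError("variant table columns have unequal lengths")
        if np.any(self.pos < 1):
            raise ValueError("variant positions must be >= 1")
        self._check_sorted()

    def _check_sorted(self) -> None:
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(
                    f"variant positions not strictly increasing on chromosome {c}"
                )

    def __len__(self) -> int:
        return len(self.pos)

    def __getitem__(self, i):
        if isinstance(i, (int, np.integer)):
            return Variant(
                chrom=str(self.chrom[i]),
                pos=int(self.pos[i]),
                id=str(self.ids[i]),
                allele_a=str(self.allele_a[i]),
                allele_b=str(self.allele_b[i]),
                ancestral=str(self.ancestral[i]),
            )
        return VariantTable(
            self.chrom[i], self.pos[i], self.ids[i],
            self.allele_a[i], self.allele_b[i], self.ancestral[i],
        )

    def __iter__(self) -> Iterator[Variant]:
        for i in range(len(self)):
            yield self[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "id": self.ids,
                "allele_a": self.allele_a,
                "allele_b": self.allele_b,
                "ancestral": self.ancestral,
            }
        )


@dataclass
class GenotypeMatrix:
    """samples x variants diploid calls in {0, 1, 2, MISSING} counting allele_b."""

    samples: list[str]
    variants: VariantTable
    calls: np.ndarray  # int8, shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype calls must be in {0, 1, 2, MISSING}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def take_variants(self, index) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.variants[index], self.calls[:, index])

    def take_samples(self, index) -> "GenotypeMatrix":
        idx = np.asarray(index)
        samples = [self.samples[i] for i in np.flatnonzero(idx)] if idx.dtype == bool \
            else [self.samples[i] for i in idx]
        return GenotypeMatrix(samples, self.variants, self.calls[np.flatnonzero(idx) if idx.dtype == bool else idx, :])


@dataclass
class SampleInfo:
    """Per-sample group labels drawn from a declared finite set."""

    sample_ids: list[str]
    groups: list[str]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.groups):
            raise ValueError("sample_ids and groups differ in length")

    @property
    def group_set(self) -> list[str]:
        return sorted(set(self.groups))

    def labels_for(self, samples: Sequence[str]) -> np.ndarray:
        lut = dict(zip(self.sample_ids, self.groups))
        missing = [s for s in samples if s not in lut]
        if missing:
            raise KeyError(f"samples without group label: {missing[:5]}")
        return np.asarray([lut[s] for s in samples], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"sample_id": self.sample_ids, "group": self.groups})

    @classmethod
    def read_tsv(cls, path) -> "SampleInfo":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"sample_id", "group"} <= set(df.columns):
            raise FormatError(f"{path}: expected columns sample_id, group")
        return cls(list(df["sample_id"]), list(df["group"]))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class HaplotypeMatrix:
    """Phased 2N x M binary matrix coded ancestral=0 / derived=1.

    Every variant must have a known ancestral allele; there are exactly two
    rows per sample (rows 2i and 2i+1 are the haplotypes of sample i).
    """

    samples: list[str]
    variants: VariantTable
    haplotypes: np.ndarray  # uint8, shape (2*n_samples, n_variants)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2 * len(self.samples), len(self.variants)):
            raise ValueError(
                f"haplotypes shape {self.haplotypes.shape} does not match "
                f"2x{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if not np.isin(self.haplotypes, (0, 1)).all():
            raise ValueError("haplotype entries must be binary")
        if (self.variants.ancestral == UNKNOWN_ANCESTRAL).any():
            raise ValueError("all HaplotypeMatrix variants need a known ancestral allele")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def derived_freq(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


# ---------------------------------------------------------------------------
# allele frequencies


def allele_freq_table(geno: GenotypeMatrix, labels: np.ndarray | None = None) -> pd.DataFrame:
    """Per-variant (optionally per-group) counted-allele frequency and genotype counts.

    Returns a frame with columns group, variant_index, n_aa, n_ab, n_bb,
    n_chrom, p where p is the frequency of allele_b among non-missing calls.
    """
    if labels is None:
        labels = np.asarray(["all"] * geno.n_samples, dtype=object)
    labels = np.asarray(labels, dtype=object)
    rows = []
    for g in pd.unique(labels):
        sub = geno.calls[labels == g]
        n_aa = (sub == 0).sum(axis=0)
        n_ab = (sub == 1).sum(axis=0)
        n_bb = (sub == 2).sum(axis=0)
        n_chrom = 2 * (n_aa + n_ab + n_bb)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_chrom > 0, (2 * n_bb + n_ab) / np.maximum(n_chrom, 1), np.nan)
        rows.append(
            pd.DataFrame(
                {
                    "group": g,
                    "variant_index": np.arange(geno.n_variants),
                    "n_aa": n_aa,
                    "n_ab": n_ab,
                    "n_bb": n_bb,
                    "n_chrom": n_chrom,
                    "p": p,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# VCF


def _is_snp(ref: str, alts: Sequence[str]) -> bool:
    return len(alts) == 1 and len(ref) == 1 and len(alts[0]) == 1 and ref != alts[0]


def read_vcf(path, require_phased: bool = False, ancestral_tsv=None):
    """Read a VCF into a :class:`GenotypeMatrix` or, if ``require_phased``, a
    :class:`HaplotypeMatrix`.

    Multi-allelic and non-SNP records are skipped (count logged). The
    ancestral allele comes from INFO/AA when present, else from
    ``ancestral_tsv`` (columns chrom, pos, ancestral), else is unknown.
    When ``require_phased``, variants whose ancestral allele remains unknown
    are dropped (logged) because the haplotype coding needs an orientation.
    """
    from cyvcf2 import VCF

    anc_lut = {}
    if ancestral_tsv is not None:
        adf = pd.read_csv(ancestral_tsv, sep="\t", dtype={"chrom": str, "pos": int, "ancestral": str})
        anc_lut = {(c, p): a for c, p, a in zip(adf["chrom"], adf["pos"], adf["ancestral"])}

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    chrom, pos, ids, a_a, a_b, anc = [], [], [], [], [], []
    geno_cols: list[np.ndarray] = []
    hap_cols: list[np.ndarray] = []
    n_skipped = 0
    n_unknown_anc = 0
    for rec in vcf:
        if not _is_snp(rec.REF, rec.ALT):
            n_skipped += 1
            continue
        gts = np.array(rec.genotypes, dtype=object)  # rows [a0, a1, phased]
        if require_phased:
            unphased = [k for k, g in enumerate(gts) if not g[2]]
            if unphased:
                raise PhasingError(
                    f"unphased genotype for sample {samples[unphased[0]]} at "
                    f"{rec.CHROM}:{rec.POS} while phased input is required"
                )
        aa = rec.INFO.get("AA")
        if aa is None:
            aa = anc_lut.get((str(rec.CHROM), int(rec.POS)), UNKNOWN_ANCESTRAL)
        aa = str(aa).upper() if aa != UNKNOWN_ANCESTRAL else aa
        if aa not in (rec.REF, rec.ALT[0]):
            aa = UNKNOWN_ANCESTRAL
        if require_phased and aa == UNKNOWN_ANCESTRAL:
            n_unknown_anc += 1
            continue
        chrom.append(str(rec.CHROM))
        pos.append(int(rec.POS))
        ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
        a_a.append(rec.REF)
        a_b.append(rec.ALT[0])
        anc.append(aa)
        if require_phased:
            col = np.empty(2 * len(samples), dtype=np.int16)
            for k, g in enumerate(gts):
                col[2 * k] = g[0]
                col[2 * k + 1] = g[1]
            hap_cols.append(col)
        else:
            gt = np.asarray(rec.gt_types, dtype=np.int8)  # 0,1,2 alt copies; 3 unknown
            gt[gt == 3] = MISSING
            geno_cols.append(gt)
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", n_skipped)
    if n_unknown_anc:
        logger.info("read_vcf: dropped %d phased variants lacking ancestral allele", n_unknown_anc)

    variants = VariantTable(chrom, pos, ids, a_a, a_b, anc)
    if require_phased:
        alt_bits = (
            np.stack(hap_cols, axis=1) if hap_cols else np.empty((2 * len(samples), 0), dtype=np.int16)
        )
        # recode ALT-carrier bit -> derived bit: flip columns where ALT is ancestral
        anc_is_alt = np.asarray([a == b for a, b in zip(anc, a_b)], dtype=bool)
        haps = np.where(anc_is_alt[None, :], 1 - alt_bits, alt_bits).astype(np.uint8)
        return HaplotypeMatrix(samples, variants, haps)
    calls = (
        np.stack(geno_cols, axis=1) if geno_cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, variants, calls)


def write_vcf(geno: GenotypeMatrix, path, phased_haps: HaplotypeMatrix | None = None) -> None:
    """Write a GenotypeMatrix (or a HaplotypeMatrix via ``phased_haps``) as VCF text.

    For haplotype output the ancestral allele is emitted as INFO/AA and GT uses
    the phased separator.
    """
    if phased_haps is not None:
        hm = phased_haps
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">\n')
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(hm.samples) + "\n")
            for j in range(hm.n_variants):
                ref = hm.variants.allele_a[j]
                alt = hm.variants.allele_b[j]
                aa = hm.variants.ancestral[j]
                # derived bit -> ALT-copy bit
                flip = aa == alt
                bits = hm.haplotypes[:, j]
                alt_bits = 1 - bits if flip else bits
                gts = "\t".join(
                    f"{alt_bits[2 * k]}|{alt_bits[2 * k + 1]}" for k in range(len(hm.samples))
                )
                fh.write(
                    f"{hm.variants.chrom[j]}\t{hm.variants.pos[j]}\t{hm.variants.ids[j]}\t"
                    f"{ref}\t{alt}\t.\t.\tAA={aa}\tGT\t{gts}\n"
                )
        return

    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(geno.samples) + "\n")
        for j in range(geno.n_variants):
            info = "."
            aa = geno.variants.ancestral[j]
            if aa != UNKNOWN_ANCESTRAL:
                info = f"AA={aa}"
            gts = "\t".join(code[int(c)] for c in geno.calls[:, j])
            fh.write(
                f"{geno.variants.chrom[j]}\t{geno.variants.pos[j]}\t{geno.variants.ids[j]}\t"
                f"{geno.variants.allele_a[j]}\t{geno.variants.allele_b[j]}\t.\t.\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)


def read_plink_text(ped_path, map_path) -> GenotypeMatrix:
    """Read PLINK text files into a GenotypeMatrix.

    '0' alleles decode to missing. The counted allele (allele_b) is the second
    distinct allele observed per marker scanning samples in file order; a
    monomorphic marker keeps a placeholder second allele so that alleles stay
    distinct.
    """
    map_df = pd.read_csv(
        map_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos"], dtype={"chrom": str, "id": str},
    )
    m = len(map_df)

    samples: list[str] = []
    rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}: line {lineno} has {len(parts)} fields, "
                    f"expected {6 + 2 * m} for {m} markers"
                )
            samples.append(parts[1])
            rows.append(parts[6:])

    n = len(samples)
    calls = np.full((n, m), MISSING, dtype=np.int8)
    allele_a = np.empty(m, dtype=object)
    allele_b = np.empty(m, dtype=object)
    alleles = np.array([[r[2 * j] for r in rows] for j in range(m)], dtype=object)
    alleles2 = np.array([[r[2 * j + 1] for r in rows] for j in range(m)], dtype=object)
    for j in range(m):
        seen: list[str] = []
        for i in range(n):
            for a in (alleles[j][i], alleles2[j][i]):
                if a != "0" and a not in seen:
                    seen.append(a)
            if len(seen) == 2:
                break
        if not seen:
            seen = ["A"]
        if len(seen) == 1:
            seen.append("N" if seen[0] != "N" else "X")
        a1, a2 = seen[0], seen[1]
        allele_a[j], allele_b[j] = a1, a2
        for i in range(n):
            x, y = alleles[j][i], alleles2[j][i]
            if x == "0" or y == "0":
                continue
            calls[i, j] = (x == a2) + (y == a2)

    order = np.lexsort((map_df["pos"].to_numpy(), map_df["chrom"].to_numpy()))
    variants = VariantTable(
        map_df["chrom"].to_numpy()[order],
        map_df["pos"].to_numpy()[order],
        map_df["id"].to_numpy()[order],
        allele_a[order],
        allele_b[order],
    )
    return GenotypeMatrix(samples, variants, calls[:, order])


def write_plink_text(geno: GenotypeMatrix, ped_path, map_path) -> None:
    """Write a GenotypeMatrix as PLINK .ped/.map text; missing encodes as '0 0'."""
    with open(map_path, "w") as fh:
        for j in range(geno.n_variants):
            fh.write(
                f"{geno.variants.chrom[j]}\t{geno.variants.ids[j]}\t0\t{geno.variants.pos[j]}\n"
            )
    with open(ped_path, "w") as fh:
        for i, s in enumerate(geno.samples):
            fields = [s, s, "0", "0", "0", "-9"]
            for j in range(geno.n_variants):
                a, b = geno.variants.allele_a[j], geno.variants.allele_b[j]
                c = int(geno.calls[i, j])
                if c == MISSING:
                    fields += ["0", "0"]
                elif c == 0:
                    fields += [a, a]
                elif c == 1:
                    fields += [a, b]
                else:
                    fields += [b, b]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# BED / TSV output


BED_HEADER = "#chrom\tchromStart\tchromEnd\tname\tscore"


def write_roh_bed(segments, path) -> None:
    """Write RoH segments as BED (0-based half-open; name=sample, score=n_snps).

    Segments must arrive sorted by (sample, chrom, start).
    """
    key = [(s.sample_id, s.chrom, s.start_bp) for s in segments]
    if key != sorted(key):
        raise ValueError("segments must be sorted by sample, chrom, start")
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start_bp - 1}\t{s.end_bp}\t{s.sample_id}\t{s.n_snps}\n")


def read_roh_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment=None, skiprows=1, header=None,
        names=["chrom", "chromStart", "chromEnd", "name", "score"],
        dtype={"chrom": str, "name": str},
    )
    df["start_bp"] = df["chromStart"] + 1
    df["end_bp"] = df["chromEnd"]
    return df


def write_table(rows: pd.DataFrame, schema: Sequence[str], path) -> None:
    """Write a TSV with one header line; floats at 6 significant digits.

    ``schema`` is the required ordered column set; extra or missing columns are
    a contract error. Rows are written in a deterministic order (input order).
    """
    if list(rows.columns) != list(schema):
        if set(rows.columns) == set(schema):
            rows = rows[list(schema)]
        else:
            raise ValueError(
                f"table columns {list(rows.columns)} do not match schema {list(schema)}"
            )
    rows.to_csv(path, sep="\t", index=False, float_format="%.6g")


SELECTION_REGION_SCHEMA = [
    "position", "size_kb", "n_extreme", "n_snps", "max_abs_ihs", "max_snp_id",
    "p_nominal", "p_empirical", "genes",
]
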