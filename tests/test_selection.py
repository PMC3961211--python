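import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isletpop.core_io import HaplotypeMatrix, VariantTable
from isletpop.selection import (
    EHHCurve,
    IHSParams,
    ehh,
    ihh,
    ihs_scan,
    region_scan,
)
from isletpop.synthetic_data import SimConfig, SweepSpec, gen_sweep_haplotypes

from oracles import ehh_bruteforce


def make_haps(matrix, pos=None, chrom="1"):
    matrix = np.asarray(matrix, dtype=np.uint8)
    n, m = matrix.shape
    assert n % 2 == 0
    if pos is None:
        pos = (np.arange(m) + 1) * 10_000
    v = VariantTable([chrom] * m, pos, [f"snp{j + 1}" for j in range(m)],
                     ["A"] * m, ["G"] * m, ["A"] * m)
    return HaplotypeMatrix([f"s{i + 1}" for i in range(n // 2)], v, matrix)


def neutral_haps(seed, n_hap=60, m=4000, spacing=3000):
    rng = np.random.default_rng(seed)
    freq = rng.uniform(0.05, 0.95, size=m)
    mat = (rng.random((n_hap, m)) < freq).astype(np.uint8)
    pos = np.cumsum(rng.integers(500, 2 * spacing, size=m)).astype(np.int64)
    v = VariantTable(["1"] * m, pos, [f"snp{j}" for j in range(m)],
                     ["A"] * m, ["G"] * m, ["A"] * m)
    return HaplotypeMatrix([f"s{i}" for i in range(n_hap // 2)], v, mat)


class TestEhh:
    def test_core_is_one(self):
        h = make_haps([[1, 0, 1], [1, 1, 1], [0, 0, 0], [0, 1, 0]])
        c = ehh(h, 1, "derived")
        assert c.ehh[list(c.positions).index(c.core_position)] == 1.0

    def test_four_carriers_split_211(self):
        # 4 derived carriers at the core (column 0); one marker away their
        # extensions are (0, 0, 1, 2nd distinct) -> groups {2,1,1}:
        # EHH = C(2,2)/C(4,2) = 1/6
        mat = np.array([
            [1, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 1, 1],
        ], dtype=np.uint8)
        h = make_haps(mat)
        c = ehh(h, 0, "derived")
        # two markers away prefixes are 100,100,110,111 -> groups {2,1,1}
        assert c.ehh[2] == pytest.approx(1 / 6)
        # one marker away prefixes 10,10,11,11 -> groups {2,2}: EHH = 2/6
        assert c.ehh[1] == pytest.approx(2 / 6)

    def test_all_distinct_zero(self):
        mat = np.array([
            [1, 0, 0],
            [1, 0, 1],
            [1, 1, 0],
            [1, 1, 1],
        ], dtype=np.uint8)
        h = make_haps(mat)
        c = ehh(h, 0, "derived")
        assert c.ehh[2] == 0.0

    def test_too_few_carriers(self):
        mat = np.array([[1, 0], [0, 0], [0, 0], [0, 1]], dtype=np.uint8)
        h = make_haps(mat)
        with pytest.raises(ValueError, match="fewer than 2"):
            ehh(h, 0, "derived")

    def test_monotone_non_increasing(self):
        h = neutral_haps(seed=41, n_hap=30, m=200)
        for core in (50, 100, 150):
            for allele in ("ancestral", "derived"):
                c = ehh(h, core, allele)
                i = list(c.positions).index(c.core_position)
                left = c.ehh[: i + 1]
                right = c.ehh[i:]
                assert (np.diff(left) >= -1e-12).all()   # increasing toward core
                assert (np.diff(right) <= 1e-12).all()   # decreasing away

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n_hap = int(rng.integers(2, 25)) * 2
        m = int(rng.integers(3, 40))
        mat = rng.integers(0, 2, size=(n_hap, m)).astype(np.uint8)
        core = int(rng.integers(0, m))
        bit = int(rng.integers(0, 2))
        if min((mat[:, core] == bit).sum(), 2) < 2:
            mat[:2, core] = bit
        h = make_haps(mat)
        c = ehh(h, core, "derived" if bit else "ancestral")
        o_pos, o_ehh = ehh_bruteforce(mat, h.variants.pos, core, bit)
        lut = dict(zip(c.positions.tolist(), c.ehh.tolist()))
        for p, e in zip(o_pos, o_ehh):
            if int(p) in lut:
                assert lut[int(p)] == pytest.approx(e, abs=1e-12)
        # implementation may stop early only after reaching EHH == 0
        covered = set(c.positions.tolist())
        i_core = int(np.flatnonzero(o_pos == h.variants.pos[core])[0])
        for side in (o_pos[:i_core][::-1], o_pos[i_core + 1:]):
            for p in side:
                if int(p) not in covered:
                    break


class TestIhh:
    def test_hand_trapezoid(self):
        # flank of EHH 1 for 100 kb each side, then a drop to 0 at +/-200 kb;
        # per side: 0.95*100000 + 0.5*(0.95+0)*100000 = 142500; both: 285000
        positions = np.array([0, 100_000, 200_000, 300_000, 400_000])
        values = np.array([0.0, 1.0, 1.0, 1.0, 0.0])
        curve = EHHCurve(2, "derived", positions, values, 200_000)
        assert ihh(curve, ehh_cutoff=0.05, max_gap_bp=10**9) == pytest.approx(285_000.0)

    def test_identical_curves_zero_raw(self):
        positions = np.array([0, 50_000, 100_000])
        values = np.array([0.4, 1.0, 0.4])
        c = EHHCurve(1, "derived", positions, values, 50_000)
        a = ihh(c)
        assert np.log(a / a) == 0.0

    def test_gap_truncates(self):
        positions = np.array([100_000, 400_000, 500_000])
        values = np.array([0.9, 1.0, 0.9])
        c = EHHCurve(1, "derived", positions, values, 400_000)
        # left gap is 300 kb > 200 kb cap: only the right side contributes
        got = ihh(c, ehh_cutoff=0.05, max_gap_bp=200_000)
        assert got == pytest.approx(0.5 * (0.95 + 0.85) * 100_000)

    def test_cutoff_already_crossed(self):
        positions = np.array([90_000, 100_000, 110_000])
        values = np.array([0.01, 1.0, 0.01])
        c = EHHCurve(1, "derived", positions, values, 100_000)
        got = ihh(c, ehh_cutoff=0.05)
        assert got == pytest.approx(2 * 0.5 * 0.95 * 10_000)


class TestIhsScan:
    def test_neutral_standardization(self):
        h = neutral_haps(seed=43, n_hap=80, m=4000)
        tbl = ihs_scan(h)
        ok = np.isfinite(tbl["ihs"])
        for b, grp in tbl[ok].groupby("freq_bin"):
            if len(grp) < 20:
                continue
            assert abs(grp["ihs"].mean()) < 1e-9
            assert grp["ihs"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)
        # symmetric generator: raw scores centred at zero
        raw = tbl["raw_ihs"][np.isfinite(tbl["raw_ihs"])]
        se = raw.std() / np.sqrt(len(raw))
        assert abs(raw.mean()) < 4 * se + 0.01

    def test_allele_swap_antisymmetry(self):
        h = neutral_haps(seed=44, n_hap=40, m=600)
        tbl = ihs_scan(h)
        flipped = HaplotypeMatrix(
            h.samples,
            VariantTable(h.variants.chrom, h.variants.pos, h.variants.ids,
                         h.variants.allele_a, h.variants.allele_b,
                         h.variants.allele_b),  # ancestral is now the other allele
            1 - h.haplotypes,
        )
        tbl2 = ihs_scan(flipped)
        a = tbl["raw_ihs"].to_numpy()
        b = tbl2["raw_ihs"].to_numpy()
        ok = np.isfinite(a) & np.isfinite(b)
        np.testing.assert_allclose(b[ok], -a[ok], rtol=1e-12)

    def test_planted_sweep_core_extreme(self):
        cfg = SimConfig(seed=45, samples_per_pop=50, n_snps=10_000,
                        snp_spacing_bp=3000, maf_range=(0.05, 0.95))
        sweep = SweepSpec(5000, 0.7, 500_000, 20_000)
        h, truth = gen_sweep_haplotypes(cfg, sweep)
        tbl = ihs_scan(h)
        core_score = abs(tbl["ihs"].iloc[5000])
        scores = tbl["ihs"].abs()[np.isfinite(tbl["ihs"])]
        # the sweep's own hitchhikers occupy much of the extreme tail, so rank
        # the core against the distribution excluding the swept interval
        outside = np.abs(tbl["pos"] - truth["core_pos"]) > 1_500_000
        neutral = tbl["ihs"].abs()[outside & np.isfinite(tbl["ihs"])]
        assert core_score >= np.quantile(neutral, 0.99)
        assert core_score >= np.quantile(scores, 0.975)

    def test_low_maf_skipped(self):
        rng = np.random.default_rng(46)
        mat = rng.integers(0, 2, size=(20, 50)).astype(np.uint8)
        mat[:, 10] = 0
        mat[0, 10] = 1  # derived freq 0.05 at 20 haplotypes -> 1 carrier
        h = make_haps(mat)
        tbl = ihs_scan(h, IHSParams(min_maf=0.10))
        assert not np.isfinite(tbl["raw_ihs"].iloc[10])


class TestRegionScan:
    def synthetic_table(self, ihs, pos=None, chrom=None):
        m = len(ihs)
        if pos is None:
            pos = (np.arange(m) + 1) * 3000
        if chrom is None:
            chrom = ["1"] * m
        return pd.DataFrame({
            "chrom": chrom, "pos": pos, "id": [f"snp{j}" for j in range(m)],
            "derived_freq": np.full(m, 0.5), "ihh_a": np.ones(m),
            "ihh_d": np.ones(m), "raw_ihs": ihs, "ihs": ihs,
            "freq_bin": np.zeros(m, dtype=int),
        })

    def test_no_extremes_no_scan(self):
        tbl = self.synthetic_table(np.zeros(500))
        assert region_scan(tbl, n_perm=1000, seed=0) == []

    def test_clustered_extremes_detected(self):
        rng = np.random.default_rng(47)
        ihs = rng.normal(size=5000)
        ihs[2000:2012] = 6.0  # 12 extreme SNPs in ~36 kb
        tbl = self.synthetic_table(ihs)
        regions = region_scan(tbl, window_bp=100_000, n_perm=1000, seed=1)
        assert len(regions) >= 1
        r = regions[0]
        assert r.start_bp <= tbl["pos"][2000] and r.end_bp >= tbl["pos"][2011]
        assert r.p_nominal < 1e-10
        assert r.p_empirical < 0.05

    def test_table5_shaped_enrichment(self):
        # strongest published region shape: 12 extreme of 69 SNPs in one
        # window against a genome-wide extreme fraction of ~1e-3
        rng = np.random.default_rng(48)
        m = 20_000
        ihs = rng.normal(size=m) * 0.8
        ihs[np.abs(ihs) > 3.9] = 3.9
        # make 8 scattered extremes (fraction 4e-4) plus 12 clustered in 69 SNPs
        scatter = rng.choice(np.setdiff1d(np.arange(m), np.arange(5000, 5069)), 8, replace=False)
        ihs[scatter] = 4.5
        block = np.arange(5000, 5069)
        ihs[rng.choice(block, 12, replace=False)] = 5.5
        pos = (np.arange(m) + 1) * 3000  # 69 SNPs ~ 207 kb
        tbl = self.synthetic_table(ihs, pos=pos)
        regions = region_scan(tbl, window_bp=250_000, n_perm=10_000, seed=2)
        assert regions
        r = regions[0]
        assert r.p_nominal < 1e-15
        assert r.p_empirical_label == "<0.0001"

    def test_scattered_extremes_no_region(self):
        rng = np.random.default_rng(49)
        m = 5000
        ihs = rng.normal(size=m) * 0.5
        # one extreme per 500-SNP stretch: no window enrichment
        for k in range(10):
            ihs[k * 500 + 250] = 4.5
        tbl = self.synthetic_table(ihs)
        regions = region_scan(tbl, window_bp=100_000, n_perm=1000, seed=3)
        assert regions == []

    def test_detection_of_planted_sweep(self):
        cfg = SimConfig(seed=50, samples_per_pop=40, n_snps=6000,
                        snp_spacing_bp=3000, maf_range=(0.05, 0.95))
        sweep = SweepSpec(3000, 0.7, 500_000, 20_000)
        h, truth = gen_sweep_haplotypes(cfg, sweep)
        tbl = ihs_scan(h)
        regions = region_scan(tbl, window_bp=200_000, n_perm=1000, seed=4)
        assert any(r.start_bp <= truth["core_pos"] <= r.end_bp for r in regions)
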