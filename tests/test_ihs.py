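"""EHH, iHH integration, map interpolation, and iHS standardization."""

import numpy as np
import pandas as pd
import pytest

from admixscan.ihs import (
    QC_EDGE,
    QC_OK,
    EHHCurve,
    ehh,
    ihh,
    ihs_scan,
    interpolate_genetic_map,
    standardize_ihs,
)
from admixscan.panel import GeneticMap

from conftest import brute_force_ehh


class TestMapInterpolation:
    @pytest.fixture()
    def simple_map(self):
        return GeneticMap(
            positions_bp=[0, 1_000_000],
            rates_cM_per_Mb=[1.0, 1.0],
            cum_cM=[0.0, 1.0],
        )

    def test_midpoint(self, simple_map):
        assert interpolate_genetic_map([500_000], simple_map)[0] == pytest.approx(0.5)

    def test_map_nodes_exact(self, simple_map):
        got = interpolate_genetic_map([0, 1_000_000], simple_map)
        assert got[0] == 0.0 and got[1] == 1.0

    def test_terminal_rate_extension(self, simple_map):
        assert interpolate_genetic_map([1_500_000], simple_map)[0] == pytest.approx(1.5)
        assert interpolate_genetic_map([-500_000], simple_map)[0] == pytest.approx(-0.5)

    def test_decreasing_map_rejected(self):
        with pytest.raises(ValueError, match="decreases"):
            GeneticMap([0, 10, 20], [1, 1, 1], [0.0, 0.5, 0.4])


class TestEhh:
    def _curve_right(self, hap, core, allele, gpos):
        c = ehh(np.asarray(hap, dtype=np.uint8), core, allele, genetic_pos_cM=gpos)
        return c.right[:, 1]

    def test_hand_counted_splits(self):
        # 4 carriers of allele 1 at core 0; flanking columns split them
        hap = np.array(
            [
                [1, 1, 0, 0],
                [1, 1, 0, 1],
                [1, 1, 1, 0],
                [1, 1, 0, 0],
            ],
            dtype=np.uint8,
        )
        gpos = np.array([0.0, 0.1, 0.2, 0.3])
        e = self._curve_right(hap, 0, 1, gpos)
        assert e[0] == 1.0  # core
        assert e[1] == 1.0  # all identical at first marker: 6/6
        assert e[2] == pytest.approx(0.5)  # {3,1} split: 3/6
        assert e[3] == pytest.approx(1 / 6)  # {2,1,1}: 1/6

    def test_matches_brute_force_pairwise(self, neutral_panel):
        hap = neutral_panel.haplotypes[:50, :80]
        gpos = neutral_panel.genetic_pos_cM[:80]
        rng = np.random.default_rng(12)
        cores = rng.choice(80, size=6, replace=False)
        for core in cores:
            for allele in (0, 1):
                carriers = np.nonzero(hap[:, core] == allele)[0]
                if carriers.size < 2:
                    continue
                curve = ehh(hap, int(core), allele, genetic_pos_cM=gpos)
                for k, m in enumerate(range(core + 1, 80)):
                    if k + 1 >= curve.right.shape[0]:
                        break
                    expect = brute_force_ehh(hap, carriers, int(core), m)
                    assert curve.right[k + 1, 1] == pytest.approx(expect, abs=1e-12)
                for k, m in enumerate(range(core - 1, -1, -1)):
                    if k + 1 >= curve.left.shape[0]:
                        break
                    expect = brute_force_ehh(hap, carriers, int(core), m)
                    assert curve.left[k + 1, 1] == pytest.approx(expect, abs=1e-12)

    def test_curves_non_increasing_from_one(self, neutral_panel):
        hap = neutral_panel.haplotypes
        gpos = neutral_panel.genetic_pos_cM
        for core in (10, 100, 190):
            for allele in (0, 1):
                if (hap[:, core] == allele).sum() < 2:
                    continue
                c = ehh(hap, core, allele, genetic_pos_cM=gpos)
                for flank in (c.left, c.right):
                    assert flank[0, 1] == 1.0
                    assert np.all(np.diff(flank[:, 1]) <= 1e-12)
                    assert np.all((flank[:, 1] >= 0) & (flank[:, 1] <= 1))

    def test_single_carrier_rejected(self):
        hap = np.array([[1, 0], [0, 0], [0, 1]], dtype=np.uint8)
        with pytest.raises(ValueError, match="carrier"):
            ehh(hap, 0, 1, genetic_pos_cM=np.array([0.0, 0.1]))


class TestIhh:
    def _curve(self, pts, bp=None):
        pts = np.asarray(pts, dtype=float)
        bp = np.arange(pts.shape[0]) if bp is None else np.asarray(bp)
        core_only = np.array([[pts[0, 0], 1.0]])
        return EHHCurve(
            core_site=0,
            allele=1,
            n_core=4,
            left=core_only,
            right=pts,
            left_bp=bp[:1],
            right_bp=bp,
        )

    def test_hand_trapezoid(self):
        # (EHH - 0)+ over {(0,1),(0.1,0.5),(0.2,0)} = 0.075 + 0.025 = 0.1 cM
        curve = self._curve([(0.0, 1.0), (0.1, 0.5), (0.2, 0.0)])
        area, flag = ihh(curve, cutoff=0.0)
        assert area == pytest.approx(0.1)
        assert flag == QC_EDGE  # left flank is a bare core: chromosome edge

    def test_edge_truncation_flag(self):
        curve = self._curve([(0.0, 1.0), (0.1, 1.0), (0.2, 1.0)])
        area, flag = ihh(curve, cutoff=0.05)
        assert area == pytest.approx(0.2 * 0.95)
        assert flag == QC_EDGE

    def test_truncates_after_first_below_cutoff(self):
        curve = self._curve([(0.0, 1.0), (0.1, 0.02), (0.2, 0.9)])
        area, _ = ihh(curve, cutoff=0.05)
        # only the first trapezoid counts; the rebound past the cutoff is ignored
        assert area == pytest.approx(0.1 * (0.95 + 0.0) / 2.0)

    def test_gap_flag(self):
        curve = self._curve(
            [(0.0, 1.0), (0.1, 0.5), (0.2, 0.01)], bp=[0, 300_000, 310_000]
        )
        _, flag = ihh(curve, cutoff=0.05, max_gap_bp=200_000)
        assert flag == "gap"


class TestIhsScan:
    def test_log_ratio_and_symmetry(self, small_panel):
        df = ihs_scan(small_panel.to_haplotype_panel(), drop_truncated=False)
        ok = df[df.QC.isin([QC_OK, QC_EDGE]) & df.IHS_UNSTD.notna()]
        assert len(ok) > 0
        for rec in ok.itertuples():
            assert rec.IHS_UNSTD == pytest.approx(np.log(rec.IHH_A / rec.IHH_D), abs=1e-12)

    def test_maf_filter(self, small_panel):
        df = ihs_scan(small_panel.to_haplotype_panel(), min_maf=0.05)
        low = df[np.minimum(df.DAF, 1 - df.DAF) <= 0.05]
        assert (low.QC == "low_maf").all()
        assert low.IHS_STD.isna().all()

    def test_unpolarized_sites_excluded(self, small_panel):
        panel = small_panel.to_haplotype_panel()
        sites = panel.sites.copy()
        sites.loc[3, "polarized"] = False
        panel2 = type(panel)(panel.haplotypes, sites, panel.sample_ids, panel.genetic_pos_cM)
        df = ihs_scan(panel2, drop_truncated=False)
        assert df.loc[3, "QC"] == "unpolarized"
        assert np.isnan(df.loc[3, "IHS_STD"])


class TestStandardize:
    @staticmethod
    def _records(values, dafs, qc=QC_OK):
        return pd.DataFrame(
            {
                "CHROM": "1",
                "POS": np.arange(1, len(values) + 1),
                "DAF": dafs,
                "IHH_A": 1.0,
                "IHH_D": 1.0,
                "IHS_UNSTD": values,
                "QC": qc,
            }
        )

    def test_population_variance_zscores(self):
        df = self._records([-1.0, 0.0, 1.0], [0.205, 0.201, 0.209])
        out = standardize_ihs(df, bin_width=0.01)
        expect = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(out.IHS_STD.to_numpy(), expect, atol=1e-12)
        np.testing.assert_allclose(out.ABS_IHS.to_numpy(), np.abs(expect), atol=1e-12)

    def test_bin_mean_zero_variance_one(self):
        rng = np.random.default_rng(3)
        df = self._records(rng.normal(size=40), np.r_[np.full(20, 0.105), np.full(20, 0.507)])
        out = standardize_ihs(df, bin_width=0.01)
        for lo in (0.10, 0.50):
            z = out.IHS_STD[(out.DAF >= lo) & (out.DAF < lo + 0.01)]
            assert abs(z.mean()) < 1e-10
            assert abs(np.std(z.to_numpy(), ddof=0) - 1.0) < 1e-10

    def test_bins_are_independent(self):
        rng = np.random.default_rng(4)
        v1, v2 = rng.normal(size=10), rng.normal(size=10)
        daf = np.r_[np.full(10, 0.105), np.full(10, 0.505)]
        a = standardize_ihs(self._records(np.r_[v1, v2], daf), bin_width=0.01)
        b = standardize_ihs(self._records(np.r_[v1, 5 * v2 + 3], daf), bin_width=0.01)
        np.testing.assert_allclose(
            a.IHS_STD.to_numpy()[:10], b.IHS_STD.to_numpy()[:10], atol=1e-12
        )

    def test_sparse_bin_left_unscored_with_warning(self):
        df = self._records([0.3, -0.2, 0.1], [0.105, 0.106, 0.309])
        with pytest.warns(UserWarning, match="unstandardized"):
            out = standardize_ihs(df, bin_width=0.01)
        assert np.isnan(out.IHS_STD.iloc[2])
        assert out.IHS_STD.iloc[:2].notna().all()

    def test_reference_standardization(self):
        ref = self._records([0.0, 2.0, 4.0, 6.0], np.full(4, 0.205))
        df = self._records([2.0], [0.201])
        out = standardize_ihs(df, bin_width=0.01, reference=ref)
        # reference bin mean 3, population sd sqrt(5)
        assert out.IHS_STD.iloc[0] == pytest.approx((2.0 - 3.0) / np.sqrt(5.0))
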