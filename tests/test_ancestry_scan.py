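"""Block-frequency tails, Fst outlier scan, regions and gene overlap."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from hybridtrace import ancestry_scan as sc
from hybridtrace import genotype_io as gio
from hybridtrace import local_ancestry as la
from hybridtrace import simdata as sd


def toy_callset(call_matrix, chrom=None):
    """BlockCallSet from an explicit (haps x windows) call matrix."""
    call_matrix = np.asarray(call_matrix, dtype=np.int8)
    H, W = call_matrix.shape
    chrom = chrom if chrom is not None else [1] * W
    tab = pd.DataFrame({"chrom": chrom,
                        "i0": np.arange(W) * 20,
                        "i1": (np.arange(W) + 1) * 20,
                        "bp0": np.arange(W) * 20000 + 1,
                        "bp1": (np.arange(W) + 1) * 20000,
                        "cm_mid": np.arange(W, dtype=float),
                        "cm_span": np.ones(W)})
    windows = la.WindowSet(tab, 20)
    post = np.where(call_matrix == sd.WC, 1.0,
                    np.where(call_matrix == sd.DC, 0.0, np.nan))
    return la.BlockCallSet(windows, post, call_matrix,
                           [f"H{i}" for i in range(H // 2)],
                           np.ones(W, dtype=bool))


class TestBlockFrequencies:
    def test_unanimous_window(self):
        cs = toy_callset(np.full((4, 3), sd.DC))
        bf = sc.block_ancestry_frequencies(cs)
        assert np.all(bf["f_dc"] == 1.0)

    def test_single_call_fraction(self):
        calls = np.full((90, 1), sd.WC)
        calls[0, 0] = sd.DC
        bf = sc.block_ancestry_frequencies(toy_callset(calls))
        assert bf["f_dc"].iloc[0] == pytest.approx(1 / 90)

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(0)
        calls = rng.choice([sd.WC, sd.DC, -1], size=(10, 25),
                           p=[0.5, 0.3, 0.2])
        bf = sc.block_ancestry_frequencies(toy_callset(calls))
        j_out = 0
        for j in range(25):
            col = calls[:, j]
            n_dc = (col == sd.DC).sum()
            n_wc = (col == sd.WC).sum()
            if n_dc + n_wc == 0:
                continue
            assert bf["f_dc"].iloc[j_out] == pytest.approx(n_dc / (n_dc + n_wc))
            j_out += 1
        assert j_out == len(bf)

    def test_zero_call_windows_excluded(self):
        calls = np.full((4, 3), -1)
        calls[:, 0] = sd.WC
        bf = sc.block_ancestry_frequencies(toy_callset(calls))
        assert len(bf) == 1
        assert bf.attrs["n_windows_zero_calls"] == 2


class TestTailSelection:
    def continuous_freqs(self, W, seed=0):
        rng = np.random.default_rng(seed)
        f_dc = rng.permutation(np.linspace(0.01, 0.99, W))
        return pd.DataFrame({"chrom": np.repeat(np.arange(1, 11), W // 10),
                             "bp0": np.tile(np.arange(W // 10) * 1000 + 1, 10),
                             "bp1": np.tile((np.arange(W // 10) + 1) * 1000, 10),
                             "f_dc": f_dc, "f_wc": 1 - f_dc})

    def test_one_percent_of_thousand(self):
        freqs = self.continuous_freqs(1000)
        regions = sc.select_outlier_blocks(freqs, tail=0.01)
        per_dir = regions.regions.groupby("direction").size()
        # 10 windows per direction before merging; merged count <= 10
        assert per_dir["domestic-like"] <= 10
        assert per_dir["wildcat-like"] <= 10
        # reconstruct selected window count from the frequency table
        thr = np.sort(freqs["f_dc"])[::-1][9]
        assert (freqs["f_dc"] >= thr).sum() == 10

    def test_zero_tail_empty(self):
        freqs = self.continuous_freqs(500)
        assert len(sc.select_outlier_blocks(freqs, tail=0.0)) == 0

    def test_degenerate_distribution_warns_empty(self):
        freqs = self.continuous_freqs(200)
        freqs["f_dc"] = 0.5
        freqs["f_wc"] = 0.5
        with pytest.warns(UserWarning, match="degenerate"):
            regions = sc.select_outlier_blocks(freqs, tail=0.01)
        assert len(regions) == 0

    def test_selected_windows_exceed_cohort_mean(self, small_model,
                                                 small_map, small_panels):
        spec = sd.PedigreeSpec("BC4", mating="hybrid_isolation", m=0.25)
        haps, truth = sd.simulate_cohort(small_model, small_map,
                                         [spec] * 30, seed=3)
        windows = la.partition_windows(small_map, 20)
        calls = la.assign_window_ancestry(small_panels.wc_haps,
                                          small_panels.dc_haps, haps,
                                          small_map, windows,
                                          sample_ids=truth.sample_ids)
        bf = sc.block_ancestry_frequencies(calls)
        regions = sc.select_outlier_blocks(bf, tail=0.01)
        dom = regions.regions.query("direction == 'domestic-like'")
        assert len(dom) > 0
        thr = np.sort(bf["f_dc"])[::-1][int(0.01 * len(bf)) - 1]
        assert thr > bf["f_dc"].mean()


class TestFstOutlierScan:
    def make_groups(self, model, gmap, seed, spike=None):
        pan = sd.sample_reference_genotypes(model, gmap, 40, 1, seed=seed)
        Gwc = pan.genotype_matrix()
        Gwc = Gwc.subset_samples(Gwc.samples["label"].to_numpy() == "WC")
        anc, alleles, _ = sd.simulate_hybrid_isolation_cohort(
            model, gmap, 30, 6, 0.15, seed=seed + 1)
        dosage = (alleles[0::2] + alleles[1::2]).astype(float)
        if spike is not None:
            dosage[:, spike] = 2.0  # fixed difference injected
        Ghyb = gio.GenotypeMatrix(dosage, Gwc.snps, pd.DataFrame(
            {"id": [f"H{i}" for i in range(30)], "label": "HYB"}))
        return Ghyb, Gwc

    def test_neutral_admixture_yields_fdr_consistent_false_positives(
            self, small_model, small_map):
        Ghyb, Gwc = self.make_groups(small_model, small_map, 11)
        res = sc.fst_outlier_scan(Ghyb, Gwc, n_null=20000, seed=0)
        assert res["outlier"].mean() <= 0.05

    def test_spiked_fixed_difference_flagged(self, small_model, small_map):
        spike = 100
        # spike a SNP that is monomorphic reference-0 in WC
        model = small_model
        idx = int(np.argmin(model.p_wc))
        Ghyb, Gwc = self.make_groups(model, small_map, 13, spike=idx)
        res = sc.fst_outlier_scan(Ghyb, Gwc, n_null=100_000, seed=1)
        row = res[res["id"] == f"snp{idx}"]
        assert len(row) == 1 and bool(row["outlier"].iloc[0])

    def test_fdr_zero_empty(self, small_model, small_map):
        Ghyb, Gwc = self.make_groups(small_model, small_map, 17)
        res = sc.fst_outlier_scan(Ghyb, Gwc, fdr=0.0, n_null=5000, seed=2)
        assert res["outlier"].sum() == 0

    def test_indistinguishable_groups_abort(self, small_model, small_map):
        pan = sd.sample_reference_genotypes(small_model, small_map, 40, 1,
                                            seed=19)
        G = pan.genotype_matrix()
        G = G.subset_samples(G.samples["label"].to_numpy() == "WC")
        a = G.subset_samples(np.arange(20))
        b = G.subset_samples(np.arange(20, 40))
        with pytest.raises(ValueError, match="indistinguishable"):
            sc.fst_outlier_scan(a, b, n_null=2000, seed=3)

    @given(st.lists(st.floats(1e-6, 1.0), min_size=5, max_size=40))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_bh_qvalues_monotone_in_pvalue_rank(self, pvals):
        p = np.array(pvals)
        _, q, _, _ = multipletests(p, method="fdr_bh")
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestRegions:
    def test_flank_and_clipping(self):
        snps = pd.DataFrame({"chrom": [1, 1], "bp": [500_000, 50_000]})
        regions = sc.build_regions(snps, flank_bp=100_000).regions
        regions = regions.sort_values("start").reset_index(drop=True)
        assert (regions.loc[0, "start"], regions.loc[0, "end"]) == (1, 150_000)
        assert (regions.loc[1, "start"], regions.loc[1, "end"]) == (400_000, 600_000)

    def test_nearby_snps_merge(self):
        snps = pd.DataFrame({"chrom": [1, 1], "bp": [1_000_000, 1_120_000]})
        regions = sc.build_regions(snps, flank_bp=100_000)
        assert len(regions) == 1
        assert regions.regions.loc[0, "end"] == 1_220_000

    def test_merge_idempotent_and_disjoint(self):
        rng = np.random.default_rng(4)
        snps = pd.DataFrame({"chrom": rng.integers(1, 4, 30),
                             "bp": rng.integers(1, 5_000_000, 30)})
        regions = sc.build_regions(snps, flank_bp=100_000).regions
        again = sc.build_regions(
            pd.DataFrame({"chrom": regions["chrom"],
                          "bp": (regions["start"] + regions["end"]) // 2}),
            flank_bp=0).regions
        assert len(again) == len(regions)
        for c, sub in regions.groupby("chrom"):
            s = sub.sort_values("start")
            assert np.all(s["start"].to_numpy()[1:] > s["end"].to_numpy()[:-1])


class TestGeneOverlap:
    def write_bed(self, tmp_path):
        path = tmp_path / "genes.bed"
        pd.DataFrame([
            ["1", 99, 500, "inside"],      # 1-based 100-500
            ["1", 900, 1000, "abutting"],  # ends exactly where region starts
            ["2", 0, 50, "other_chrom"],
        ]).to_csv(path, sep="\t", header=False, index=False)
        return str(path)

    def region_set(self):
        return sc.OutlierRegionSet(pd.DataFrame(
            [("1", 200, 900, "domestic-like", "block-tail")],
            columns=sc.REGION_COLUMNS))

    def test_bed_overlap_semantics(self, tmp_path):
        mapped, flat = sc.map_genes(self.region_set(), self.write_bed(tmp_path))
        assert mapped["genes"].iloc[0] == ["inside"]
        assert list(flat["gene"]) == ["inside"]

    def test_gff3_one_based_inclusive(self, tmp_path):
        path = tmp_path / "genes.gff3"
        path.write_text(
            "##gff-version 3\n"
            "1\tsrc\tgene\t850\t950\t.\t+\t.\tID=gene:G1;Name=OVER\n"
            "1\tsrc\tgene\t901\t950\t.\t+\t.\tID=gene:G2\n"
            "1\tsrc\texon\t100\t200\t.\t+\t.\tID=exon1\n")
        regions = sc.OutlierRegionSet(pd.DataFrame(
            [("1", 200, 900, "wildcat-like", "fst-outlier")],
            columns=sc.REGION_COLUMNS))
        mapped, flat = sc.map_genes(regions, str(path))
        assert mapped["genes"].iloc[0] == ["OVER"]  # G2 starts after the region

    def test_unknown_format_rejected(self, tmp_path):
        path = tmp_path / "genes.txt"
        path.write_text("x")
        with pytest.raises(ValueError, match="bed"):
            sc.map_genes(self.region_set(), str(path))

    def test_duplicate_genes_deduplicated(self, tmp_path):
        path = tmp_path / "genes.bed"
        pd.DataFrame([["1", 99, 500, "dup"], ["1", 300, 600, "dup"]]).to_csv(
            path, sep="\t", header=False, index=False)
        mapped, flat = sc.map_genes(self.region_set(), str(path))
        assert mapped["genes"].iloc[0] == ["dup"]
        assert len(flat) == 1
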