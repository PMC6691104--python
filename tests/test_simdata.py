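"""Simulator calibration: frequency divergence, tract bookkeeping,
pedigree expectations and dataset serialization."""

import numpy as np
import pytest
from scipy import stats

from hybridtrace import genotype_io as gio
from hybridtrace import simdata as sd


class TestParentalFrequencies:
    def test_zero_divergence_gives_identical_frequencies(self):
        m = sd.generate_parental_frequencies(500, 0.0, seed=0)
        assert np.array_equal(m.p_wc, m.p_dc)
        assert sd.hudson_fst(m.p_wc, m.p_dc) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_realized_fst_matches_target(self, seed):
        # oracle: Hudson ratio-of-means Fst over the simulated frequencies
        m = sd.generate_parental_frequencies(50_000, 0.9, seed=seed)
        assert abs(sd.hudson_fst(m.p_wc, m.p_dc) - 0.9) < 0.05

    def test_fst_calibration_monotone(self):
        realized = [sd.hudson_fst(*(lambda mm: (mm.p_wc, mm.p_dc))(
            sd.generate_parental_frequencies(20_000, f, seed=3)))
            for f in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert np.all(np.diff(realized) > 0)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            sd.generate_parental_frequencies(0, 0.5)
        with pytest.raises(ValueError):
            sd.generate_parental_frequencies(100, 1.0)
        with pytest.raises(ValueError):
            sd.generate_parental_frequencies(100, -0.1)


class TestReferencePanels:
    def test_fixed_allele_gives_dosage_two(self, small_map):
        n = small_map.n_snps
        model = sd.PopulationModel(np.full(n, 0.5), np.ones(n), np.zeros(n), 0.9)
        pan = sd.sample_reference_genotypes(model, small_map, 5, 5, seed=0)
        assert np.all(pan.genotypes(sd.WC) == 2)
        assert np.all(pan.genotypes(sd.DC) == 0)

    def test_panel_shapes_match_reference_counts(self, small_model, small_map):
        pan = sd.sample_reference_genotypes(small_model, small_map, 57, 44, seed=1)
        assert pan.genotypes(sd.WC).shape == (57, small_map.n_snps)
        assert pan.genotypes(sd.DC).shape == (44, small_map.n_snps)

    def test_heterozygosity_at_half_frequency(self, small_map):
        n = small_map.n_snps
        model = sd.PopulationModel(np.full(n, 0.5), np.full(n, 0.5),
                                   np.full(n, 0.5), 0.0)
        pan = sd.sample_reference_genotypes(model, small_map, 40, 1, seed=2)
        het = (pan.genotypes(sd.WC) == 1).mean()
        assert het == pytest.approx(0.5, abs=0.01)

    def test_misaligned_map_raises(self, small_model):
        gmap = sd.GeneticMap.uniform(100, 18, 30.0, seed=0)
        with pytest.raises(ValueError):
            sd.sample_reference_genotypes(small_model, gmap, 2, 2)


class TestAdmixedIndividuals:
    def test_f1_structure(self, small_model, small_map):
        ind = sd.simulate_admixed_individual(small_model, small_map,
                                             sd.PedigreeSpec("F1"), 0)
        assert ind.m_true == 0.5
        assert ind.n_junctions == 0
        anc0 = ind.tracts[0].ancestry_at(small_map)
        anc1 = ind.tracts[1].ancestry_at(small_map)
        assert len(np.unique(anc0)) == 1 and len(np.unique(anc1)) == 1

    def test_first_backcross_junctions_and_fraction(self, small_model, small_map):
        # pedigree oracle: one meiosis of an F1 gives ~L junctions on the
        # transmitted haplotype; E[m] = 0.25 after one backcross
        rng = np.random.default_rng(5)
        ms, js = [], []
        for _ in range(1000):
            ind = sd.simulate_admixed_individual(
                small_model, small_map, sd.PedigreeSpec("BC2"), rng)
            ms.append(ind.m_true)
            js.append(ind.n_junctions)
        assert np.mean(js) == pytest.approx(small_map.length_morgans, rel=0.1)
        assert np.mean(ms) == pytest.approx(0.25, abs=0.01)

    @pytest.mark.parametrize("g", [1, 2, 3, 4])
    def test_backcross_fraction_halves_each_generation(self, small_model,
                                                       small_map, g):
        rng = np.random.default_rng(g)
        design = "F1" if g == 1 else f"BC{g}"
        ms = [sd.simulate_admixed_individual(
            small_model, small_map, sd.PedigreeSpec(design), rng).m_true
            for _ in range(300)]
        expect = 0.5 ** g
        se = np.std(ms) / np.sqrt(len(ms)) + 1e-9
        assert abs(np.mean(ms) - expect) < 3 * se + 1e-3

    def test_tract_tiling(self, small_model, small_map):
        rng = np.random.default_rng(9)
        ind = sd.simulate_admixed_individual(
            small_model, small_map, sd.PedigreeSpec("BC4"), rng)
        for hap in ind.tracts:
            for c in small_map.chromosomes:
                breaks, anc = hap.segments[c]
                assert breaks[-1] == pytest.approx(small_map.span_cm[c])
                assert np.all(np.diff(breaks) > 0)
                assert len(breaks) == len(anc)
                # adjacent segments always differ in ancestry (compressed)
                assert np.all(np.diff(anc.astype(int)) != 0)

    def test_junction_count_grows_with_generations(self, small_model, small_map):
        # hybrid isolation at fixed ancestry fraction: junction density is
        # proportional to g (under backcrossing the domestic fraction
        # dilutes, so monotone growth only holds at fixed m)
        rng = np.random.default_rng(17)
        means = []
        for g in range(1, 16):
            spec = sd.PedigreeSpec(f"BC{g}" if g > 1 else "F1",
                                   mating="hybrid_isolation", m=0.25)
            js = [sd.simulate_admixed_individual(
                small_model, small_map, spec, rng).n_junctions
                for _ in range(300)]
            means.append(np.mean(js))
        rho = stats.spearmanr(np.arange(1, 16), means).statistic
        assert rho > 0.99

    def test_hybrid_isolation_junction_density(self, small_model, small_map):
        # closed-form oracle: E[diploid junctions] = 4 L g m (1 - m)
        rng = np.random.default_rng(31)
        g, m = 6, 0.25
        spec = sd.PedigreeSpec("BC6", mating="hybrid_isolation", m=m)
        js = [sd.simulate_admixed_individual(small_model, small_map, spec,
                                             rng).n_junctions
              for _ in range(500)]
        expect = 4 * small_map.length_morgans * g * m * (1 - m)
        assert np.mean(js) == pytest.approx(expect, rel=0.05)

    def test_invalid_design_raises(self):
        with pytest.raises(ValueError):
            sd.PedigreeSpec("BC0").g


class TestVectorizedCohort:
    def test_matches_exact_simulator_moments(self, small_model, small_map):
        g, m = 5, 0.3
        anc, alleles, m_true = sd.simulate_hybrid_isolation_cohort(
            small_model, small_map, 200, g, m, seed=0)
        assert anc.shape == (400, small_map.n_snps)
        assert m_true.mean() == pytest.approx(m, abs=0.03)
        # SNP-resolution ancestry switches approximate junction density
        switches = 0
        for c in small_map.chromosomes:
            sl = small_map.chrom_slice(c)
            switches += (np.diff(anc[:, sl], axis=1) != 0).sum()
        per_ind = switches / 200
        expect = 4 * small_map.length_morgans * g * m * (1 - m)
        assert per_ind == pytest.approx(expect, rel=0.15)

    def test_alleles_follow_local_ancestry_frequencies(self, small_map):
        n = small_map.n_snps
        model = sd.PopulationModel(np.full(n, 0.5), np.ones(n), np.zeros(n), 0.9)
        anc, alleles, _ = sd.simulate_hybrid_isolation_cohort(
            model, small_map, 50, 4, 0.4, seed=1)
        # with p_wc = 1 and p_dc = 0 the allele equals 1 - ancestry code
        assert np.array_equal(alleles, 1 - anc)


class TestWriter:
    def test_round_trip_and_truth_bed(self, small_model, small_map, tmp_path):
        specs = [sd.PedigreeSpec("BC2")] * 3
        haps, truth = sd.simulate_cohort(small_model, small_map, specs, seed=4)
        G = gio.GenotypeMatrix(
            (haps[0::2] + haps[1::2]).astype(float),
            small_map.snp_frame(),
            __import__("pandas").DataFrame({"id": truth.sample_ids,
                                            "label": "HYB"}))
        prefix = str(tmp_path / "sim")
        sd.write_dataset(G, truth, small_map, prefix, hap_alleles=haps)
        G2 = gio.read_plink(prefix, labels_path=f"{prefix}.labels.tsv")
        assert np.array_equal(G.dosage, G2.dosage, equal_nan=True)
        assert list(G2.samples["label"]) == ["HYB"] * 3
        bed = __import__("pandas").read_csv(f"{prefix}.truth.bed", sep="\t",
                                            header=None)
        # one BED segment per tract: junctions + one per chromosome per hap
        expect = truth.junction_counts().sum() + \
            2 * 3 * len(small_map.chromosomes)
        assert len(bed) == expect

    def test_empty_cohort_writes_valid_files(self, small_model, small_map,
                                             tmp_path):
        import pandas as pd
        haps, truth = sd.simulate_cohort(small_model, small_map, [], seed=0)
        G = gio.GenotypeMatrix(np.empty((0, small_map.n_snps)),
                               small_map.snp_frame(),
                               pd.DataFrame({"id": [], "label": []}))
        prefix = str(tmp_path / "empty")
        sd.write_dataset(G, truth, small_map, prefix, hap_alleles=haps)
        G2 = gio.read_plink(prefix)
        assert G2.n_samples == 0 and G2.n_snps == small_map.n_snps
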