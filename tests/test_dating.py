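"""Switch-count and weighted-LD admixture dating."""

import warnings

import numpy as np
import pytest
from scipy import stats

from hybridtrace import dating as dt
from hybridtrace import local_ancestry as la
from hybridtrace import simdata as sd


@pytest.fixture(scope="module")
def windows_small(small_map):
    return la.partition_windows(small_map, 20)


@pytest.fixture(scope="module")
def hi_model_small(small_map, windows_small):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return dt.build_switch_model(0.25, windows_small, small_map,
                                     g_grid=range(1, 13), n_sims=200, seed=0)


class TestSwitchModel:
    def test_pedigree_f1_degenerate_at_zero(self, small_map, windows_small):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = dt.build_switch_model(0.5, windows_small, small_map,
                                          g_grid=[1], n_sims=100,
                                          mating_model="pedigree", seed=1)
        assert np.all(model.draws[1] == 0)

    def test_means_increase_with_g(self, hi_model_small):
        means = hi_model_small.mean_counts()
        rho = stats.spearmanr(hi_model_small.g_grid, means).statistic
        assert rho > 0.99

    def test_deterministic_given_seed(self, small_map, windows_small):
        kw = dict(g_grid=[3, 4], n_sims=50, seed=5)
        a = dt.build_switch_model(0.25, windows_small, small_map, **kw)
        b = dt.build_switch_model(0.25, windows_small, small_map, **kw)
        assert all(np.array_equal(a.draws[g], b.draws[g]) for g in (3, 4))

    def test_conditioning_matches_m_hat(self, small_map, windows_small,
                                        hi_model_small):
        assert hi_model_small.m_hat == 0.25

    def test_invalid_m_hat_raises(self, small_map, windows_small):
        with pytest.raises(ValueError):
            dt.build_switch_model(0.0, windows_small, small_map)

    def test_matches_exact_tract_simulator(self, small_model, small_map,
                                           windows_small):
        # oracle: the exact tract-level engine, pushed through the same
        # windows, should give the same switch-count distribution
        g, m = 5, 0.3
        rng = np.random.default_rng(7)
        spec = sd.PedigreeSpec("BC5", mating="hybrid_isolation", m=m)
        S_exact = []
        while len(S_exact) < 150:
            ind = sd.simulate_admixed_individual(small_model, small_map,
                                                 spec, rng)
            if abs(ind.m_true - m) <= 0.05:
                anc = np.array([h.ancestry_at(small_map)
                                for h in ind.tracts])
                calls = la.truth_window_calls(anc, windows_small)
                s = la.switches_per_hap(calls, windows_small)
                S_exact.append(int(s.sum()))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = dt.build_switch_model(m, windows_small, small_map,
                                          g_grid=[g], n_sims=400, seed=11)
        fast = model.draws[g]
        assert np.mean(S_exact) == pytest.approx(fast.mean(), rel=0.10)


class TestDateFromSwitches:
    def test_zero_switches_dates_to_first_generation(self, small_map,
                                                     windows_small):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            model = dt.build_switch_model(0.5, windows_small, small_map,
                                          g_grid=range(1, 8), n_sims=100,
                                          mating_model="pedigree", seed=2)
        assert dt.date_from_switches(0, model).g_hat == 1

    def test_saturation_flag(self, hi_model_small):
        big = int(max(d.max() for d in hi_model_small.draws.values())) + 50
        res = dt.date_from_switches(big, hi_model_small)
        assert res.saturated and res.g_hat == hi_model_small.g_grid.max()

    def test_interval_brackets_estimate(self, hi_model_small):
        res = dt.date_from_switches(100, hi_model_small)
        assert res.ci_low <= res.g_hat <= res.ci_high

    def test_closed_form_hand_arithmetic(self):
        assert dt.closed_form_generations(135, 0.25, 30) == 6.0

    def test_closed_form_matches_hybrid_isolation_mean(self, small_model,
                                                       small_map):
        # forward-simulation oracle for the junction-density estimator
        rng = np.random.default_rng(3)
        for g, m in [(4, 0.25), (8, 0.4)]:
            spec = sd.PedigreeSpec(f"BC{g}", mating="hybrid_isolation", m=m)
            S = [sd.simulate_admixed_individual(small_model, small_map, spec,
                                                rng).n_junctions
                 for _ in range(300)]
            est = dt.closed_form_generations(float(np.mean(S)), m,
                                             small_map.length_morgans)
            assert est == pytest.approx(g, rel=0.10)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            dt.closed_form_generations(-1, 0.2, 30)
        with pytest.raises(ValueError):
            dt.closed_form_generations(10, 0.0, 30)
        with pytest.raises(ValueError):
            dt.closed_form_generations(10, 0.2, 0)


class TestYearsConversion:
    def test_mean_ld_date_in_years(self):
        years, _ = dt.generations_to_years(5.02, 2)
        assert years == pytest.approx(10.04)

    def test_oldest_event_calendar_year(self):
        years, cal = dt.generations_to_years(22, 2, sampling_year=2006)
        assert years == 44 and cal == 1962

    def test_zero_generations(self):
        years, cal = dt.generations_to_years(0, 2, sampling_year=2000)
        assert years == 0 and cal == 2000

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            dt.generations_to_years(-1)


class TestWeightedLD:
    def test_pure_cohort_flat_curve(self, small_model, small_map):
        pan = sd.sample_reference_genotypes(small_model, small_map, 60, 1,
                                            seed=8)
        G = pan.genotypes(sd.WC).astype(float)
        curve = dt.weighted_ld_curve(G, small_model.p_wc, small_model.p_dc,
                                     small_map)
        tab = curve.aggregate()
        amp_scale = np.abs(small_model.p_wc - small_model.p_dc).mean() ** 2 / 4
        assert np.nanmean(np.abs(tab["a"])) < 0.05 * amp_scale

    def test_admixed_cohort_positive_and_decaying(self, small_model,
                                                  small_map):
        _, alleles, _ = sd.simulate_hybrid_isolation_cohort(
            small_model, small_map, 80, 10, 0.25, seed=9)
        G = (alleles[0::2] + alleles[1::2]).astype(float)
        curve = dt.weighted_ld_curve(G, small_model.p_wc, small_model.p_dc,
                                     small_map)
        tab = curve.aggregate().dropna()
        third = len(tab) // 3
        early = tab["a"].iloc[:third].mean()
        late = tab["a"].iloc[-third:].mean()
        assert early > 0
        assert early > 3 * abs(late)

    def test_noiseless_exponential_recovered_exactly(self):
        # closed-form oracle: feed the fitter an exact exponential curve
        edges = 0.005 + 0.001 * np.arange(201)
        d = 0.5 * (edges[:-1] + edges[1:])
        a = 0.3 * np.exp(-7.0 * d) + 0.01
        # five chromosomes, 1000 pairs per bin each, all carrying the
        # exact curve (per-chromosome sums = a * pair count)
        curve = dt.WeightedLDCurve(edges, np.tile(a * 1000, (5, 1)),
                                   np.full((5, 200), 1000), list(range(5)))
        fit = dt.fit_ld_decay(curve)
        assert fit.n_hat == pytest.approx(7.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.3, abs=1e-6)
        assert fit.affine == pytest.approx(0.01, abs=1e-8)

    def test_noise_curve_rarely_significant(self):
        rng = np.random.default_rng(10)
        n_sig = 0
        reps = 20
        for _ in range(reps):
            edges = 0.005 + 0.001 * np.arange(101)
            noise = rng.normal(0, 1e-4, size=(6, 100))
            curve = dt.WeightedLDCurve(edges, noise,
                                       np.full((6, 100), 500),
                                       list(range(6)))
            try:
                fit = dt.fit_ld_decay(curve)
            except ValueError:
                continue
            if fit.significant:
                n_sig += 1
        assert n_sig <= 0.1 * reps + 1

    def test_doubling_cohort_reduces_bin_noise(self, small_model, small_map):
        amps = {}
        for n in (30, 120):
            _, alleles, _ = sd.simulate_hybrid_isolation_cohort(
                small_model, small_map, n, 30, 0.25, seed=12)
            G = (alleles[0::2] + alleles[1::2]).astype(float)
            curve = dt.weighted_ld_curve(G, small_model.p_wc,
                                         small_model.p_dc, small_map)
            tab = curve.aggregate().dropna()
            # at g = 30 the signal at d > 0.15 M is negligible: variance
            # there is Monte-Carlo noise
            tail = tab[tab["d"] > 0.15]["a"]
            amps[n] = tail.var()
        assert amps[120] < amps[30]
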