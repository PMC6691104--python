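"""Simulate a wildcat x domestic study: parental panels plus backcrosses.

Builds two parental pools diverged at Fst 0.9 on an 18-autosome, 30-Morgan
map, samples phased reference panels (57 wildcats, 44 domestic cats), and
simulates backcrossed individuals with exactly known ancestry tracts.
"""

import numpy as np

from hybridtrace import simdata as sd

model = sd.generate_parental_frequencies(n_snps=5000, f_target=0.9, seed=1)
gmap = sd.GeneticMap.uniform(5000, n_chromosomes=18, length_morgans=30.0,
                             seed=2)
panels = sd.sample_reference_genotypes(model, gmap, n_wc=57, n_dc=44, seed=3)

print(f"realized parental Fst : {sd.hudson_fst(model.p_wc, model.p_dc):.3f}")
print(f"map                   : {len(gmap.chromosomes)} chromosomes, "
      f"{gmap.length_morgans:.0f} Morgans, {gmap.n_snps} SNPs")

# one second-generation backcross to wildcat: expect ~25% domestic ancestry
# and about one ancestry junction per Morgan
ind = sd.simulate_admixed_individual(model, gmap, sd.PedigreeSpec("BC2"),
                                     rng=4)
print(f"BC2 individual        : m_true = {ind.m_true:.3f} "
      f"(expected 0.25), junctions = {ind.n_junctions} (expected ~30)")

# a cohort of old backcrosses, 6 generations since hybridization
specs = [sd.PedigreeSpec("BC6")] * 20
haps, truth = sd.simulate_cohort(model, gmap, specs, seed=5)
print(f"BC6 cohort            : mean m_true = {truth.m_true().mean():.4f} "
      f"(expected {0.5 ** 6:.4f}), mean junctions = "
      f"{truth.junction_counts().mean():.1f}")
# m_true is the fraction of map length with domestic ancestry; junctions
# are true ancestry switch points accumulated over the pedigree.
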