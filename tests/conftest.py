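"""Shared simulated fixtures.

Everything is generated at test time from fixed seeds; the heavier
"study-scale" fixtures (20k SNPs, reference panel sizes matching a
realistic array study) are session-scoped so the acceptance-style tests
share one simulation.
"""

import numpy as np
import pandas as pd
import pytest

from hybridtrace import genotype_io as gio
from hybridtrace import simdata as sd


@pytest.fixture(scope="session")
def small_model():
    return sd.generate_parental_frequencies(3000, 0.9, seed=11)


@pytest.fixture(scope="session")
def small_map():
    return sd.GeneticMap.uniform(3000, 18, 30.0, seed=12)


@pytest.fixture(scope="session")
def small_panels(small_model, small_map):
    return sd.sample_reference_genotypes(small_model, small_map, 30, 30, seed=13)


@pytest.fixture(scope="session")
def study_model():
    """Divergent parental pools at array scale (20k SNPs, Fst 0.9)."""
    return sd.generate_parental_frequencies(20_000, 0.9, seed=21)


@pytest.fixture(scope="session")
def study_map():
    """18 autosomes, 30 Morgans, 20k SNPs."""
    return sd.GeneticMap.uniform(20_000, 18, 30.0, seed=22)


@pytest.fixture(scope="session")
def study_panels(study_model, study_map):
    """Reference panels at the study's sizes: 57 WC, 44 DC."""
    return sd.sample_reference_genotypes(study_model, study_map, 57, 44, seed=23)


@pytest.fixture(scope="session")
def study_admixed(study_model, study_map):
    """45 admixed individuals, backcrosses of 1-6 generations (ancestry
    fractions spanning roughly 0.016-0.5, as in a mixed field cohort)."""
    specs = [sd.PedigreeSpec("F1" if g == 1 else f"BC{g}")
             for g in np.resize(np.arange(1, 7), 45)]
    hap_alleles, truth = sd.simulate_cohort(study_model, study_map, specs, seed=24)
    return hap_alleles, truth


def combine_matrices(panels, hyb_haps, truth):
    """Reference + admixed GenotypeMatrix with WC/DC/HYB labels."""
    Gref = panels.genotype_matrix()
    hyb = pd.DataFrame({"id": truth.sample_ids, "label": "HYB"})
    dosage = np.vstack([Gref.dosage,
                        (hyb_haps[0::2] + hyb_haps[1::2]).astype(float)])
    return gio.GenotypeMatrix(dosage, Gref.snps,
                              pd.concat([Gref.samples, hyb], ignore_index=True))


@pytest.fixture(scope="session")
def study_matrix(study_panels, study_admixed):
    hyb_haps, truth = study_admixed
    return combine_matrices(study_panels, hyb_haps, truth)
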