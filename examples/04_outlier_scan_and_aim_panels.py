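"""Ancestry-excess scans and ancestry-informative marker (AIM) panels.

Ranks windows by domestic/wildcat block frequency in the admixed cohort
and takes the 1% tails; runs the calibrated Fst-outlier scan (expected
empty under neutral admixture); then designs 48/96/192-SNP AIM panels
ranked by Weir-Cockerham Fst and evaluates their power to detect old
backcrosses.
"""

import warnings

import numpy as np
import pandas as pd

from hybridtrace import aim_panel as ap
from hybridtrace import ancestry_scan as sc
from hybridtrace import genotype_io as gio
from hybridtrace import local_ancestry as la
from hybridtrace import simdata as sd

warnings.simplefilter("ignore")

model = sd.generate_parental_frequencies(5000, 0.9, seed=1)
gmap = sd.GeneticMap.uniform(5000, 18, 30.0, seed=2)
panels = sd.sample_reference_genotypes(model, gmap, 57, 44, seed=3)
specs = [sd.PedigreeSpec(f"BC{g}") for g in np.resize(np.arange(6, 21), 45)]
haps, truth = sd.simulate_cohort(model, gmap, specs, seed=4)

Gref = panels.genotype_matrix()
G = gio.GenotypeMatrix(
    np.vstack([Gref.dosage, (haps[0::2] + haps[1::2]).astype(float)]),
    Gref.snps,
    pd.concat([Gref.samples,
               pd.DataFrame({"id": truth.sample_ids, "label": "HYB"})],
              ignore_index=True))

# 1% tails of the block ancestry-frequency distribution
windows = la.partition_windows(gmap, 20)
calls = la.assign_window_ancestry(panels.wc_haps, panels.dc_haps, haps,
                                  gmap, windows,
                                  sample_ids=truth.sample_ids)
bf = sc.block_ancestry_frequencies(calls)
tails = sc.select_outlier_blocks(bf, tail=0.01)
counts = tails.regions.groupby("direction").size().to_dict()
print(f"1% tails over {len(bf)} windows -> regions: {counts}")

# Fst outlier scan: neutral admixture, so no outliers expected
Gwc = G.subset_samples(G.samples["label"].to_numpy() == "WC")
Ghyb = G.subset_samples(G.samples["label"].to_numpy() == "HYB")
scan = sc.fst_outlier_scan(Ghyb, Gwc, fdr=0.05, n_null=50_000, seed=5)
print(f"Fst outlier scan: {scan['outlier'].sum()} outliers among "
      f"{len(scan)} SNPs (neutral simulation; the scan is FDR-controlled)")

# AIM panels ranked by Fst
scores = ap.score_markers(G)
r, p = ap.rank_correlation(scores)
print(f"Spearman r(Fst, I_N) = {r:.3f}")
full = None
for size in (192, 96, 48):
    panel = ap.select_panel(scores, size, criterion="fst")
    ev = ap.evaluate_panel(panel, G, full, seed=6)
    print(f"top-{size:3d} panel: Fst = {ev.panel_fst:.2f}, "
          f"min WC q_w = {ev.min_wc_qw:.3f}, "
          f"hybrids misclassified = {ev.n_hyb_misclassified}/{ev.n_hyb_total} "
          f"({ev.pct_hyb_identified:.0f}% detected), "
          f"PID = {ev.pid_wc:.2e}, PIDsib = {ev.pid_sib_wc:.2e}")
# smaller panels misclassify more old backcrosses as pure wildcats:
# the price of genotyping fewer markers.
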