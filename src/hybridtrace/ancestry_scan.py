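"""Ancestry-excess and Fst-outlier scans with gene overlap.

Two routes flag candidate regions of non-random inheritance in admixed
genomes:

* Block tails — windows are ranked by the fraction of admixed haplotypes
  carrying domestic (or wildcat) ancestry and the top 1% per direction is
  selected, adjacent selected windows merging into regions.
* Fst outliers — per-SNP Weir–Cockerham Fst between admixed and parental
  groups is compared to a parametric null calibrated to the genome-wide
  mean divergence (Balding–Nichols frequency draws with the observed
  sample sizes), with Benjamini–Hochberg FDR control.  Flagged SNPs expand
  into +/-100 kb regions (the scale of background LD), which are merged
  when overlapping.

Regions can be intersected with a BED or GFF3 gene annotation to recover
per-region gene lists.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from statsmodels.stats.multitest import multipletests

from .aim_panel import group_snp_stats, weir_cockerham_fst
from .genotype_io import GenotypeMatrix
from .local_ancestry import BlockCallSet
from .simdata import DC, WC

REGION_COLUMNS = ["chrom", "start", "end", "direction", "source"]


# ---------------------------------------------------------------------------
# block ancestry frequencies and tails
# ---------------------------------------------------------------------------

def block_ancestry_frequencies(callset: BlockCallSet,
                               admixed_ids=None) -> pd.DataFrame:
    """Per-window fraction of admixed haplotypes called DC and WC.

    No-calls are excluded from the denominator; windows with zero calls
    are dropped (their count is retained in the ``attrs`` of the result).
    """
    if admixed_ids is not None:
        keep = [i for i, s in enumerate(callset.sample_ids) if s in set(admixed_ids)]
        if not keep:
            raise ValueError("no admixed individuals selected")
        rows = np.array([r for i in keep for r in (2 * i, 2 * i + 1)])
        calls = callset.calls[rows]
    else:
        calls = callset.calls
    n_dc = (calls == DC).sum(axis=0)
    n_wc = (calls == WC).sum(axis=0)
    n_called = n_dc + n_wc
    tab = callset.windows.table.copy()
    with np.errstate(invalid="ignore"):
        tab["f_dc"] = np.where(n_called > 0, n_dc / np.maximum(n_called, 1), np.nan)
        tab["f_wc"] = np.where(n_called > 0, n_wc / np.maximum(n_called, 1), np.nan)
    tab["n_called"] = n_called
    out = tab[n_called > 0].reset_index(drop=True)
    out.attrs["n_windows_zero_calls"] = int((n_called == 0).sum())
    return out


def _merge_adjacent(sel: pd.DataFrame, direction, source) -> list:
    """Merge runs of adjacent selected windows (same chromosome) into
    regions (1-based inclusive bp)."""
    regions = []
    prev_key = None
    for _, row in sel.iterrows():
        key = (row["chrom"], row["window_index"])
        if (prev_key is not None and key[0] == prev_key[0]
                and key[1] == prev_key[1] + 1):
            regions[-1][2] = int(row["bp1"])
        else:
            regions.append([row["chrom"], int(row["bp0"]), int(row["bp1"])])
        prev_key = key
    return [(c, s, e, direction, source) for c, s, e in regions]


@dataclass
class OutlierRegionSet:
    regions: pd.DataFrame  # REGION_COLUMNS (+ genes after map_genes)

    def __len__(self):
        return len(self.regions)

    def to_bed_frame(self) -> pd.DataFrame:
        r = self.regions
        return pd.DataFrame({"chrom": r["chrom"], "start": r["start"] - 1,
                             "end": r["end"],
                             "name": r["direction"] + "|" + r["source"]})


def select_outlier_blocks(freqs: pd.DataFrame, tail=0.01) -> OutlierRegionSet:
    """Top-``tail`` windows per direction of the block-frequency table.

    Windows at or above the (1 - tail) empirical quantile of f_DC are
    domestic-like; symmetrically for f_WC.  Ties at the boundary are all
    included; adjacent selected windows merge into regions.
    """
    freqs = freqs.reset_index(drop=True).assign(window_index=lambda d: d.index)
    W = len(freqs)
    rows = []
    for col, direction in (("f_dc", "domestic-like"), ("f_wc", "wildcat-like")):
        k = int(np.floor(tail * W))
        if k == 0:
            continue
        vals = freqs[col].to_numpy()
        if np.nanmax(vals) == np.nanmin(vals):
            warnings.warn(f"degenerate {col} distribution; no outlier windows")
            continue
        thr = np.sort(vals)[::-1][k - 1]
        sel = freqs[vals >= thr].sort_values(["chrom", "window_index"])
        rows.extend(_merge_adjacent(sel, direction, "block-tail"))
    return OutlierRegionSet(pd.DataFrame(rows, columns=REGION_COLUMNS))


# ---------------------------------------------------------------------------
# Fst outlier scan
# ---------------------------------------------------------------------------

def _null_fst_draws(mean_fst, p_pool, n1, n2, n_null, rng):
    """Parametric Balding–Nichols null: frequency pairs around resampled
    ancestral frequencies at divergence ``mean_fst``, genotype counts under
    HWE at the observed sample sizes, then per-draw WC Fst."""
    p_anc = rng.choice(p_pool, size=n_null, replace=True)
    ratio = (1.0 - mean_fst) / mean_fst
    a = np.clip(p_anc * ratio, 1e-3, None)
    b = np.clip((1.0 - p_anc) * ratio, 1e-3, None)
    stats = []
    for n in (n1, n2):
        p = rng.beta(a, b)
        p_het = np.clip(2 * p * (1 - p), 0, 1)
        n_het = rng.binomial(n, p_het)
        rest = n - n_het
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(p_het < 1, p ** 2 / np.maximum(p ** 2 + (1 - p) ** 2, 1e-12), 0.5)
        n_hom_alt = rng.binomial(rest, w)
        phat = (2 * n_hom_alt + n_het) / (2.0 * n)
        stats.append((phat, n_het / n, np.full(n_null, float(n))))
    (p1, h1, nn1), (p2, h2, nn2) = stats
    return weir_cockerham_fst(p1, h1, nn1, p2, h2, nn2)


def fst_outlier_scan(G_admixed: GenotypeMatrix, G_parental: GenotypeMatrix,
                     fdr=0.05, n_null=100_000, seed=0) -> pd.DataFrame:
    """Per-SNP Fst outlier test of admixed vs parental samples.

    The null distribution comes from ``n_null`` Balding–Nichols draws
    calibrated to the genome-wide (ratio-of-sums) mean Fst and the observed
    sample sizes; per-SNP upper-tail p-values get Benjamini–Hochberg
    q-values and outliers satisfy q <= ``fdr``.
    """
    if G_admixed.n_snps != G_parental.n_snps:
        raise ValueError("SNP sets differ between groups")
    if min(G_admixed.n_samples, G_parental.n_samples) < 5:
        raise ValueError("both groups need at least 5 samples")
    rng = np.random.default_rng(seed)
    p1, h1, n1 = group_snp_stats(G_admixed, np.arange(G_admixed.n_samples))
    p2, h2, n2 = group_snp_stats(G_parental, np.arange(G_parental.n_samples))
    theta, a, d = weir_cockerham_fst(p1, h1, n1, p2, h2, n2,
                                     return_components=True)
    ok = np.isfinite(theta)
    mean_fst = float(np.nansum(a[ok]) / np.nansum(d[ok]))
    if mean_fst <= 0:
        raise ValueError("genome-wide mean Fst <= 0: groups indistinguishable")
    p_pool = np.clip(0.5 * (p1[ok] + p2[ok]), 0.02, 0.98)
    null = _null_fst_draws(mean_fst, p_pool,
                           int(np.median(n1[ok])), int(np.median(n2[ok])),
                           n_null, rng)
    null = np.sort(null[np.isfinite(null)])
    n_eff = len(null)
    # upper-tail p with add-one correction
    rank = np.searchsorted(null, theta[ok], side="left")
    pvals = (n_eff - rank + 1.0) / (n_eff + 1.0)
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")[0:4]
    out = G_admixed.snps.loc[ok, ["id", "chrom", "bp"]].reset_index(drop=True)
    out["fst"] = np.clip(theta[ok], 0.0, 1.0)
    out["p"] = pvals
    out["q"] = qvals
    out["outlier"] = qvals <= fdr
    return out


def build_regions(outlier_snps: pd.DataFrame, flank_bp=100_000,
                  chrom_ends=None, direction="na",
                  source="fst-outlier") -> OutlierRegionSet:
    """Expand outlier SNPs to +/-``flank_bp`` regions, clip at chromosome
    bounds, and merge overlapping regions."""
    rows = []
    snps = outlier_snps.sort_values(["chrom", "bp"])
    for _, s in snps.iterrows():
        start = max(1, int(s["bp"]) - flank_bp)
        end = int(s["bp"]) + flank_bp
        if chrom_ends is not None and s["chrom"] in chrom_ends:
            end = min(end, int(chrom_ends[s["chrom"]]))
        if rows and rows[-1][0] == s["chrom"] and start <= rows[-1][2]:
            rows[-1][2] = max(rows[-1][2], end)
        else:
            rows.append([s["chrom"], start, end])
    return OutlierRegionSet(pd.DataFrame(
        [(c, s, e, direction, source) for c, s, e in rows],
        columns=REGION_COLUMNS))


# ---------------------------------------------------------------------------
# gene overlap
# ---------------------------------------------------------------------------

def _gff_gene_name(attr: str) -> str:
    # Name preferred over ID over gene_id
    for key in ("Name", "ID", "gene_id"):
        m = re.search(rf"(?:^|;)\s*{key}=([^;]+)", attr)
        if m:
            return m.group(1).removeprefix("gene:")
    return "unknown"


def _read_annotation(path) -> pd.DataFrame:
    """Gene spans as 1-based inclusive intervals from BED or GFF3."""
    path = str(path)
    if path.endswith((".bed", ".bed.txt")):
        bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                          usecols=[0, 1, 2, 3],
                          names=["chrom", "start0", "end0", "gene"])
        return pd.DataFrame({"chrom": bed["chrom"],
                             "start": bed["start0"] + 1,  # 0-based half-open -> 1-based
                             "end": bed["end0"],
                             "gene": bed["gene"]})
    if path.endswith((".gff", ".gff3")):
        gff = pd.read_csv(path, sep="\t", header=None, comment="#",
                          names=["chrom", "source", "type", "start", "end",
                                 "score", "strand", "phase", "attr"])
        genes = gff[gff["type"] == "gene"]
        names = genes["attr"].map(_gff_gene_name)
        return pd.DataFrame({"chrom": genes["chrom"], "start": genes["start"],
                             "end": genes["end"], "gene": names})
    raise ValueError("unknown annotation format: expected .bed, .gff or .gff3")


def map_genes(regions: OutlierRegionSet, annotation_path):
    """Overlap regions with gene annotation (>= 1 bp, convention-aware).

    Returns (regions DataFrame with a ``genes`` list column, flat
    DataFrame of unique gene ids with the count of regions hitting each).
    Coordinates must share the assembly of the genotype data.
    """
    ann = _read_annotation(annotation_path)
    trees = {}
    for c, sub in ann.groupby("chrom", sort=False):
        t = IntervalTree()
        for _, g in sub.iterrows():
            if g["end"] >= g["start"]:
                t.addi(int(g["start"]), int(g["end"]) + 1, g["gene"])
        trees[str(c)] = t  # chromosome names compared as strings
    out = regions.regions.copy()
    gene_lists = []
    for _, r in out.iterrows():
        t = trees.get(str(r["chrom"]), IntervalTree())
        hits = sorted({iv.data for iv in t.overlap(int(r["start"]), int(r["end"]) + 1)})
        gene_lists.append(hits)
    out["genes"] = gene_lists
    flat = pd.Series([g for lst in gene_lists for g in lst])
    flat_tab = (flat.value_counts().rename_axis("gene")
                .reset_index(name="n_regions")
                if len(flat) else pd.DataFrame(columns=["gene", "n_regions"]))
    return out, flat_tab
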