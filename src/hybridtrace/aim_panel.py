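"""Ancestry-informative marker (AIM) panel design and evaluation.

SNPs are scored by wild-vs-domestic divergence (per-SNP Weir–Cockerham
Fst), Rosenberg's informativeness for assignment I_N, and pooled expected
heterozygosity; reduced panels (192 / 96 / 48 and combinations) take the
top-ranked LD-independent markers.  Panels are evaluated by refitting the
supervised K = 2 admixture model on the panel alone: minimum reference-WC
q_w, misclassified hybrids (panel q_w at or above that minimum), percent
hybrids detected, agreement with the full-panel q_w, and the panel's
probability-of-identity statistics PID and PIDsib (the chance that two
random, or two sibling, individuals share a multilocus genotype).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotype_io import GenotypeMatrix
from .global_ancestry import QW_ROUNDING_TOL, fit_admixture


# ---------------------------------------------------------------------------
# divergence statistics
# ---------------------------------------------------------------------------

def group_snp_stats(G: GenotypeMatrix, rows):
    """Per-SNP (allele frequency, observed het fraction, called n) for a
    sample subset."""
    sub = G.dosage[np.asarray(rows)]
    called = ~np.isnan(sub)
    n = called.sum(axis=0).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nansum(sub, axis=0) / (2.0 * n)
        h = np.nansum(sub == 1, axis=0) / n
    p[n == 0] = np.nan
    h[n == 0] = np.nan
    return p, h, n


def weir_cockerham_fst(p1, h1, n1, p2, h2, n2, return_components=False):
    """Two-population per-SNP Weir–Cockerham theta from sample frequencies,
    observed heterozygosities and diploid sample counts (vectorized).

    Returns theta (NaN where undefined); with ``return_components`` also
    the numerator a and denominator a + b + c, whose ratio of sums gives
    the multi-locus (panel-level) estimate.
    """
    p1, h1, n1, p2, h2, n2 = map(np.asarray, (p1, h1, n1, p2, h2, n2))
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2
                                     - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0
        denom = a + b + c
        theta = np.where(denom != 0, a / denom, np.nan)
    bad = (n1 < 1) | (n2 < 1) | ~np.isfinite(denom)
    theta = np.where(bad, np.nan, theta)
    if return_components:
        return theta, np.where(bad, np.nan, a), np.where(bad, np.nan, denom)
    return theta


def rosenberg_in(p1, p2) -> np.ndarray:
    """Rosenberg informativeness for assignment I_N for biallelic SNPs,
    natural log, two populations with unweighted mean frequencies;
    0 * ln 0 := 0.  Maximum ln 2 at a fixed difference."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    out = np.zeros(np.broadcast(p1, p2).shape)
    for q1, q2 in ((p1, p2), (1 - p1, 1 - p2)):
        qbar = 0.5 * (q1 + q2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = -np.where(qbar > 0, qbar * np.log(qbar), 0.0)
            for q in (q1, q2):
                t = t + np.where(q > 0, (q / 2.0) * np.log(q), 0.0)
        out = out + t
    return out


@dataclass
class MarkerScores:
    """Per-SNP divergence scores between the WC and DC reference sets."""

    table: pd.DataFrame  # id, chrom, bp, fst, i_n, h_e + ranks (1 = best)

    def __len__(self):
        return len(self.table)


def score_markers(G: GenotypeMatrix, wc_rows=None, dc_rows=None) -> MarkerScores:
    """Score every SNP by WC-vs-DC Fst (clipped at 0), I_N and pooled H_E.

    ``wc_rows`` / ``dc_rows`` default to samples labelled "WC" / "DC"
    (reference sets as selected by the q_w thresholds).  SNPs with an
    undefined frequency in either group are dropped with a warning.
    """
    if wc_rows is None:
        wc_rows = G.samples_with_label("WC")
    if dc_rows is None:
        dc_rows = G.samples_with_label("DC")
    p1, h1, n1 = group_snp_stats(G, wc_rows)
    p2, h2, n2 = group_snp_stats(G, dc_rows)
    fst = np.clip(weir_cockerham_fst(p1, h1, n1, p2, h2, n2), 0.0, 1.0)
    i_n = rosenberg_in(p1, p2)
    pbar = 0.5 * (p1 + p2)
    h_e = 2.0 * pbar * (1.0 - pbar)
    tab = G.snps[["id", "chrom", "bp"]].copy()
    tab["fst"] = fst
    tab["i_n"] = i_n
    tab["h_e"] = h_e
    bad = tab["fst"].isna() | tab["i_n"].isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} SNPs skipped (undefined frequency)")
        tab = tab[~bad]
    tab["map_order"] = np.arange(len(tab))
    for col in ("fst", "i_n", "h_e"):
        tab[f"rank_{col}"] = tab[col].rank(ascending=False, method="min")
    return MarkerScores(tab.reset_index(drop=True))


def rank_correlation(scores: MarkerScores, pair=("fst", "i_n")):
    """Spearman rank correlation (and p-value) between two score columns."""
    a = scores.table[pair[0]]
    b = scores.table[pair[1]]
    if len(a) < 10:
        raise ValueError("need at least 10 scored SNPs")
    if a.nunique() == 1 or b.nunique() == 1:
        raise ValueError("constant ranks: correlation undefined")
    r, p = sps.spearmanr(a, b)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# panels
# ---------------------------------------------------------------------------

@dataclass
class AIMPanel:
    snp_ids: list
    criterion: str

    def __post_init__(self):
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicate SNP ids in panel")

    @property
    def size(self) -> int:
        return len(self.snp_ids)


def select_panel(scores: MarkerScores, n, criterion="fst",
                 ld_keep_ids=None) -> AIMPanel:
    """Top-``n`` SNPs by a score column, restricted to LD-independent SNPs.

    Ties at the cutoff break by the other criterion's rank, then by map
    order — deterministic panels.
    """
    tab = scores.table
    if ld_keep_ids is not None:
        tab = tab[tab["id"].isin(set(ld_keep_ids))]
    if len(tab) < n:
        raise ValueError(f"only {len(tab)} scored SNPs; cannot select {n}")
    secondary = "i_n" if criterion == "fst" else "fst"
    order = np.lexsort((tab["map_order"].to_numpy(),
                        tab[f"rank_{secondary}"].to_numpy(),
                        -tab[criterion].to_numpy()))
    chosen = tab.iloc[order[:n]]
    return AIMPanel(list(chosen["id"]), criterion)


def combine_panels(a: AIMPanel, b: AIMPanel) -> AIMPanel:
    """Union with deduplication, a's order first."""
    seen = set()
    ids = [s for s in list(a.snp_ids) + list(b.snp_ids)
           if not (s in seen or seen.add(s))]
    return AIMPanel(ids, f"{a.criterion}+{b.criterion}")


# ---------------------------------------------------------------------------
# probability of identity
# ---------------------------------------------------------------------------

def pid(p) -> float:
    """Probability of identity for unrelated individuals over biallelic
    loci with counted-allele frequencies ``p``: product of
    p^4 + q^4 + (2pq)^2 per locus."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    return float(np.prod(p ** 4 + q ** 4 + (2 * p * q) ** 2))


def pid_sib(p) -> float:
    """Probability of identity for full siblings: product per locus of
    0.25 + 0.5 * sum(p_i^2) + 0.5 * (sum p_i^2)^2 - 0.25 * sum(p_i^4)."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    s2 = p ** 2 + q ** 2
    s4 = p ** 4 + q ** 4
    return float(np.prod(0.25 + 0.5 * s2 + 0.5 * s2 ** 2 - 0.25 * s4))


# ---------------------------------------------------------------------------
# panel evaluation
# ---------------------------------------------------------------------------

@dataclass
class PanelEvaluation:
    panel_size: int
    panel_fst: float
    h_obs_wc: float
    h_obs_dc: float
    q_w: pd.Series               # per-sample panel q_w
    mean_wc_qw: float
    min_wc_qw: float
    n_wc_misclassified: int      # reference WC with panel q_w < 1.000
    n_hyb_misclassified: int     # hybrids with panel q_w >= min WC q_w
    n_hyb_total: int
    pct_hyb_identified: float
    pid_wc: float
    pid_sib_wc: float
    r2_vs_full: float


def evaluate_panel(panel: AIMPanel, G: GenotypeMatrix, full_model,
                   seed=0, hyb_label="HYB", supervised=False) -> PanelEvaluation:
    """Refit the K = 2 model on the panel SNPs alone and score the panel.

    The refit is unsupervised by default: pinning the reference rows would
    force every reference wildcat to q_w = 1.000 exactly and void the
    minimum-reference misclassification rule (an admixed individual is
    confused with a parental wildcat when its panel q_w reaches the
    minimum q_w of the reference wildcats).  The wild cluster is oriented
    by the WC-labelled samples afterwards.
    """
    if panel.size < 10:
        raise ValueError("panel too small for a K = 2 refit (< 10 SNPs)")
    ids = G.snps["id"].to_numpy()
    pos = {s: i for i, s in enumerate(ids)}
    missing = [s for s in panel.snp_ids if s not in pos]
    if missing:
        raise ValueError(f"{len(missing)} panel SNPs absent from the data")
    idx = np.array([pos[s] for s in panel.snp_ids])
    Gp = G.subset_snps(idx)
    model = fit_admixture(
        Gp, 2, supervised_labels={"WC": 0, "DC": 1} if supervised else None,
        seed=seed)
    q_w = pd.Series(model.q_w, index=G.samples["id"].to_numpy())
    labels = G.samples["label"].to_numpy()
    wc_rows = np.flatnonzero(labels == "WC")
    dc_rows = np.flatnonzero(labels == "DC")
    hyb_rows = np.flatnonzero(labels == hyb_label)
    min_wc = float(q_w.iloc[wc_rows].min())
    p1, h1, n1 = group_snp_stats(Gp, wc_rows)
    p2, h2, n2 = group_snp_stats(Gp, dc_rows)
    _, a, d = weir_cockerham_fst(p1, h1, n1, p2, h2, n2, return_components=True)
    panel_fst = float(np.nansum(a) / np.nansum(d))
    n_hyb_mis = int((q_w.iloc[hyb_rows] >= min_wc).sum())
    n_hyb = len(hyb_rows)
    full_qw = np.asarray(full_model.q_w) if full_model is not None else None
    if full_qw is not None:
        r = np.corrcoef(q_w.to_numpy(), full_qw)[0, 1]
        r2 = float(r ** 2)
    else:
        r2 = np.nan
    p_wc_panel = p1[~np.isnan(p1)]
    return PanelEvaluation(
        panel_size=panel.size,
        panel_fst=panel_fst,
        h_obs_wc=float(np.nanmean(h1)),
        h_obs_dc=float(np.nanmean(h2)),
        q_w=q_w,
        mean_wc_qw=float(q_w.iloc[wc_rows].mean()),
        min_wc_qw=min_wc,
        n_wc_misclassified=int((q_w.iloc[wc_rows] < 1.0 - QW_ROUNDING_TOL).sum()),
        n_hyb_misclassified=n_hyb_mis,
        n_hyb_total=n_hyb,
        pct_hyb_identified=100.0 * (1.0 - n_hyb_mis / n_hyb) if n_hyb else np.nan,
        pid_wc=pid(p_wc_panel),
        pid_sib_wc=pid_sib(p_wc_panel),
        r2_vs_full=r2,
    )
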