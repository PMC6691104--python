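"""Windowed local-ancestry assignment on phased haplotypes.

The genome is partitioned into blocks of 20 consecutive SNPs per
chromosome.  In each window a PCA is fit on the pooled parental reference
haplotypes (0/1 alleles, centered); each reference class is summarized by a
Gaussian (mean, diagonal covariance) on the leading PC scores, and query
haplotypes are scored by the two class likelihoods.  A two-state
forward–backward pass along each chromosome (transition probability
1 - exp(-rate * dcM) between adjacent windows) smooths the per-window
evidence into posteriors; hard calls are the posterior argmax with a
no-call margin.  Per-individual summaries give the proportion of wild /
domestic blocks (q_w_blocks / q_d_blocks) and the diploid ancestry-switch
count S, the substrate of the switch-count admixture dater.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import DC, WC, GeneticMap


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

@dataclass
class WindowSet:
    """Ordered non-overlapping SNP windows, each within one chromosome."""

    table: pd.DataFrame  # chrom, i0, i1 (global SNP idx, half-open), bp0, bp1, cm_mid, cm_span
    size_snps: int

    @property
    def n_windows(self) -> int:
        return len(self.table)

    def chrom_groups(self):
        """Yield (chrom, window index array) in map order."""
        ch = self.table["chrom"].to_numpy()
        for c in pd.unique(ch):
            yield c, np.flatnonzero(ch == c)


def partition_windows(gmap: GeneticMap, size_snps=20) -> WindowSet:
    """Blocks of ``size_snps`` consecutive SNPs per chromosome.

    A trailing remainder shorter than ``size_snps / 2`` is dropped;
    otherwise it is kept as one short window.  Chromosomes with fewer than
    ``size_snps / 2`` SNPs yield no windows (with a warning).
    """
    rows = []
    half = size_snps / 2.0
    for c in gmap.chromosomes:
        sl = gmap.chrom_slice(c)
        n = sl.stop - sl.start
        if n < half:
            warnings.warn(f"chromosome {c} has {n} SNPs; no windows formed")
            continue
        bounds = list(range(0, (n // size_snps) * size_snps + 1, size_snps))
        if n - bounds[-1] >= half:
            bounds.append(n)
        for a, b in zip(bounds[:-1], bounds[1:]):
            i0, i1 = sl.start + a, sl.start + b
            cm = gmap.cm[i0:i1]
            rows.append((c, i0, i1, int(gmap.bp[i0]), int(gmap.bp[i1 - 1]),
                         float(0.5 * (cm[0] + cm[-1])), float(cm[-1] - cm[0])))
    return WindowSet(pd.DataFrame(rows, columns=["chrom", "i0", "i1", "bp0",
                                                 "bp1", "cm_mid", "cm_span"]),
                     size_snps)


# ---------------------------------------------------------------------------
# block calls
# ---------------------------------------------------------------------------

@dataclass
class BlockCallSet:
    """Per-haplotype window posteriors and hard calls.

    post_wc : (n_haps, n_windows) posterior of WC ancestry (NaN where the
        window was skipped).
    calls : (n_haps, n_windows) int8; 0 = WC, 1 = DC, -1 = no-call.
    """

    windows: WindowSet
    post_wc: np.ndarray
    calls: np.ndarray
    sample_ids: list        # one per individual; haplotypes interleaved
    valid_windows: np.ndarray

    @property
    def n_haps(self) -> int:
        return self.calls.shape[0]

    def summary(self) -> pd.DataFrame:
        """Per-individual q_w_blocks, q_d_blocks, no-call fraction and S."""
        W = self.windows.n_windows
        S = count_switches(self)
        rec = []
        for i, sid in enumerate(self.sample_ids):
            sub = self.calls[2 * i:2 * i + 2]
            qw = (sub == WC).sum() / (2 * W)
            qd = (sub == DC).sum() / (2 * W)
            rec.append((sid, qw, qd, 1.0 - qw - qd, int(S[i])))
        return pd.DataFrame(rec, columns=["sample", "q_w_blocks",
                                          "q_d_blocks", "nocall_fraction", "S"])

    def to_frame(self) -> pd.DataFrame:
        """Long-format block-call table (sample, hap, window coords, call)."""
        w = self.windows.table
        rec = []
        names = {WC: "WC", DC: "DC", -1: "nocall"}
        for i, sid in enumerate(self.sample_ids):
            for hap in (0, 1):
                row = 2 * i + hap
                for j in range(len(w)):
                    rec.append((sid, hap, w["chrom"].iat[j], w["bp0"].iat[j],
                                w["bp1"].iat[j], self.post_wc[row, j],
                                names[int(self.calls[row, j])]))
        return pd.DataFrame(rec, columns=["sample", "hap", "chrom", "bp0",
                                          "bp1", "p_WC", "call"])


def _forward_backward(log_e, trans):
    """Two-state forward-backward; log_e (W, 2), trans (W-1,) switch probs."""
    W = log_e.shape[0]
    e = np.exp(log_e - log_e.max(axis=1, keepdims=True))
    e /= e.sum(axis=1, keepdims=True)
    fwd = np.empty((W, 2))
    bwd = np.empty((W, 2))
    f = np.array([0.5, 0.5]) * e[0]
    fwd[0] = f / f.sum()
    for t in range(1, W):
        s = trans[t - 1]
        pred = fwd[t - 1] @ np.array([[1 - s, s], [s, 1 - s]])
        f = pred * e[t]
        fwd[t] = f / f.sum()
    bwd[-1] = 1.0
    for t in range(W - 2, -1, -1):
        s = trans[t]
        b = np.array([[1 - s, s], [s, 1 - s]]) @ (e[t + 1] * bwd[t + 1])
        bwd[t] = b / b.sum()
    post = fwd * bwd
    return post / post.sum(axis=1, keepdims=True)


def assign_window_ancestry(ref_wc_haps, ref_dc_haps, query_haps,
                           gmap: GeneticMap, windows: WindowSet,
                           hmm_switch_per_cm=0.01, n_pcs=2,
                           nocall_margin=0.1, sample_ids=None,
                           emission="haplotype") -> BlockCallSet:
    """Window ancestry from reference panels with HMM smoothing.

    All haplotype matrices are (n_haps, n_snps) 0/1 arrays aligned to the
    map.  Reference panels should hold >= 10 haplotypes each.

    Two emission models are available.  The default, ``"haplotype"``, is
    the composite Bernoulli likelihood of the query window under each
    class's Laplace-smoothed allele frequencies — well calibrated even in
    weakly divergent or near-fixed windows, so that isolated ambiguous
    windows are resolved by the HMM instead of flipping.  ``"pca"`` fits a
    per-window PCA on the pooled references and scores queries with a
    homoscedastic Gaussian on the leading ``n_pcs`` scores; windows with
    zero allelic variance in the pooled references are then skipped
    (flagged).
    """
    ref_wc_haps = np.asarray(ref_wc_haps, dtype=float)
    ref_dc_haps = np.asarray(ref_dc_haps, dtype=float)
    query_haps = np.asarray(query_haps, dtype=float)
    if min(len(ref_wc_haps), len(ref_dc_haps)) < 10:
        warnings.warn("reference panels hold fewer than 10 haplotypes")
    H = query_haps.shape[0]
    W = windows.n_windows
    if sample_ids is None:
        sample_ids = [f"Q{i:03d}" for i in range(H // 2)]
    tab = windows.table
    log_lik = np.full((H, W, 2), np.nan)
    valid = np.zeros(W, dtype=bool)
    n_wc = ref_wc_haps.shape[0]
    if emission not in ("haplotype", "pca"):
        raise ValueError("emission must be 'haplotype' or 'pca'")
    for j in range(W):
        i0, i1 = int(tab["i0"].iat[j]), int(tab["i1"].iat[j])
        if emission == "haplotype":
            Q = query_haps[:, i0:i1]
            ll = np.zeros((H, 2))
            for cls, panel in ((0, ref_wc_haps), (1, ref_dc_haps)):
                sub = panel[:, i0:i1]
                p_tilde = (sub.sum(axis=0) + 1.0) / (sub.shape[0] + 2.0)
                ll[:, cls] = (Q @ np.log(p_tilde)
                              + (1.0 - Q) @ np.log1p(-p_tilde))
            log_lik[:, j] = ll
            valid[j] = True
            continue
        R = np.vstack([ref_wc_haps[:, i0:i1], ref_dc_haps[:, i0:i1]])
        mu = R.mean(axis=0)
        Rc = R - mu
        if not Rc.any():
            continue
        k = min(n_pcs, min(Rc.shape) - 1, np.linalg.matrix_rank(Rc))
        if k < 1:
            continue
        _, _, vt = np.linalg.svd(Rc, full_matrices=False)
        load = vt[:k]
        scores = Rc @ load.T
        qs = (query_haps[:, i0:i1] - mu) @ load.T
        ll = np.zeros((H, 2))
        degenerate = False
        # Diagonal covariance from the binomial sampling noise of a
        # haplotype drawn at Laplace-smoothed class frequencies (robust
        # where a panel is fixed in the window), pooled across the two
        # classes: a homoscedastic Gaussian keeps the call monotone in
        # the distance to the class means.
        variances = []
        means = []
        for rows, alleles in ((scores[:n_wc], R[:n_wc]),
                              (scores[n_wc:], R[n_wc:])):
            means.append(rows.mean(axis=0))
            n_cls = alleles.shape[0]
            p_tilde = (alleles.sum(axis=0) + 1.0) / (n_cls + 2.0)
            variances.append((load ** 2) @ (p_tilde * (1.0 - p_tilde)))
        v = 0.5 * (variances[0] + variances[1]) + 1e-6
        for cls, m in enumerate(means):
            ll[:, cls] = (-0.5 * (np.log(2 * np.pi * v)
                                  + (qs - m) ** 2 / v)).sum(axis=1)
            if not np.isfinite(ll[:, cls]).all():
                degenerate = True
        if degenerate:
            continue
        log_lik[:, j] = ll
        valid[j] = True

    post_wc = np.full((H, W), np.nan)
    calls = np.full((H, W), -1, dtype=np.int8)
    cm_mid = tab["cm_mid"].to_numpy()
    for c, widx in windows.chrom_groups():
        widx = widx[valid[widx]]
        if len(widx) == 0:
            continue
        dcm = np.diff(cm_mid[widx])
        trans = 1.0 - np.exp(-hmm_switch_per_cm * dcm)
        trans = np.clip(trans, 1e-12, 0.5)
        for h in range(H):
            post = _forward_backward(log_lik[h, widx], trans)
            post_wc[h, widx] = post[:, 0]
    margin = np.abs(2.0 * post_wc - 1.0)
    with np.errstate(invalid="ignore"):
        calls = np.where(np.isnan(post_wc), -1,
                         np.where(margin < nocall_margin, -1,
                                  np.where(post_wc > 0.5, WC, DC))).astype(np.int8)
    return BlockCallSet(windows, post_wc, calls, sample_ids, valid)


# ---------------------------------------------------------------------------
# switch counting
# ---------------------------------------------------------------------------

def switches_per_hap(calls: np.ndarray, windows: WindowSet) -> np.ndarray:
    """Ancestry switches per haplotype row: adjacent same-chromosome window
    pairs with differing hard calls, no-calls bridged."""
    H = calls.shape[0]
    out = np.zeros(H, dtype=int)
    for _, widx in windows.chrom_groups():
        sub = calls[:, widx]
        for h in range(H):
            seq = sub[h][sub[h] >= 0]
            if len(seq) > 1:
                out[h] += int((np.diff(seq) != 0).sum())
    return out


def count_switches(callset: BlockCallSet) -> np.ndarray:
    """Diploid switch count S per individual (sum over both haplotypes)."""
    per_hap = switches_per_hap(callset.calls, callset.windows)
    return per_hap[0::2] + per_hap[1::2]


def truth_window_calls(hap_ancestry: np.ndarray, windows: WindowSet) -> np.ndarray:
    """Majority-ancestry window calls from per-SNP truth (ties -> no-call)."""
    H = hap_ancestry.shape[0]
    W = windows.n_windows
    calls = np.full((H, W), -1, dtype=np.int8)
    tab = windows.table
    for j in range(W):
        frac_dc = hap_ancestry[:, tab["i0"].iat[j]:tab["i1"].iat[j]].mean(axis=1)
        calls[:, j] = np.where(frac_dc > 0.5, DC,
                               np.where(frac_dc < 0.5, WC, -1))
    return calls


# ---------------------------------------------------------------------------
# reference self-check
# ---------------------------------------------------------------------------

def reference_self_check(ref_wc_haps, ref_dc_haps, gmap: GeneticMap,
                         windows: WindowSet, n_per_pop=20, seed=0,
                         **assign_kwargs) -> pd.DataFrame:
    """Reassign held-out reference individuals as putative hybrids.

    ``n_per_pop`` individuals per panel are each removed from their own
    reference panel and re-assigned; a clean reference set shows zero
    switches and zero foreign-block fraction for all of them.
    """
    rng = np.random.default_rng(seed)
    rec = []
    for pop, haps, other in (("WC", np.asarray(ref_wc_haps), np.asarray(ref_dc_haps)),
                             ("DC", np.asarray(ref_dc_haps), np.asarray(ref_wc_haps))):
        n_ind = haps.shape[0] // 2
        if n_per_pop > n_ind - 5:
            raise ValueError("panel too small to hold out n_per_pop individuals")
        if n_per_pop == 0:
            continue
        chosen = rng.choice(n_ind, size=n_per_pop, replace=False)
        for ind in chosen:
            rows = [2 * ind, 2 * ind + 1]
            keep = np.setdiff1d(np.arange(haps.shape[0]), rows)
            query = haps[rows]
            wc_panel = haps[keep] if pop == "WC" else other
            dc_panel = other if pop == "WC" else haps[keep]
            cs = assign_window_ancestry(wc_panel, dc_panel, query, gmap,
                                        windows, sample_ids=[f"{pop}{ind}"],
                                        **assign_kwargs)
            s = int(count_switches(cs)[0])
            foreign = DC if pop == "WC" else WC
            frac = float((cs.calls == foreign).mean())
            rec.append((f"{pop}{ind}", pop, s, frac))
    return pd.DataFrame(rec, columns=["sample", "pop", "switches",
                                      "foreign_fraction"])
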