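"""Genome-wide ancestry: PCA, model-based clustering, q-thresholds, f3 test.

The clustering model is the standard K-cluster admixture likelihood: each
individual i has ancestry proportions q_i (summing to 1) and each cluster k
has allele frequencies f_k; genotypes are binomial with success probability
sum_k q_ik f_kj.  It is maximised by alternating EM updates of Q and F
(monotone in log-likelihood).  Supervised mode pins reference individuals'
Q rows to indicator vectors, the usual way parental panels anchor a K = 2
wild/domestic model.

The f3 admixture test follows the three-population statistic
f3(target; A, B) = E[(p_t - p_A)(p_t - p_B)] with the small-sample
correction for target allele-frequency noise, and a leave-one-block-out
jackknife over consecutive SNP blocks for the standard error; strongly
negative z indicates the target is admixed between sources related to A
and B.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .genotype_io import GenotypeMatrix, allele_frequencies

Q_SUM_TOL = 1e-6
QW_ROUNDING_TOL = 5e-4  # printed q_w values are 3-decimal rounded


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    scores: np.ndarray          # (n_samples, n_components)
    variance_fraction: np.ndarray
    sample_ids: list


def run_pca(G: GenotypeMatrix, n_components=10) -> PCAResult:
    """PCA on dosages centered by 2*p and scaled by sqrt(2*p*(1-p)).

    Missing dosages are mean-imputed per SNP; monomorphic SNPs are skipped.
    """
    if G.n_samples < 2 or G.n_snps < 2:
        raise ValueError("need at least 2 samples and 2 SNPs")
    X = G.dosage.copy()
    n_called = (~np.isnan(X)).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nansum(X, axis=0) / (2.0 * np.maximum(n_called, 1))
    keep = (p > 0) & (p < 1) & (n_called > 0)
    X = X[:, keep]
    p = p[keep]
    inds = np.where(np.isnan(X))
    X[inds] = (2.0 * p)[inds[1]]
    X = (X - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    max_c = min(G.n_samples, X.shape[1])
    if n_components > max_c:
        warnings.warn(f"n_components clipped to {max_c}")
        n_components = max_c
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PCAResult(scores, pca.explained_variance_ratio_,
                     list(G.samples["id"]))


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

@dataclass
class AncestryModel:
    K: int
    Q: np.ndarray               # (n, K)
    F: np.ndarray               # (K, S)
    loglik: float
    converged: bool
    wild_cluster: int | None
    sample_ids: list
    cv_error: dict = field(default_factory=dict)
    loglik_history: list = field(default_factory=list)

    @property
    def q_w(self) -> np.ndarray:
        if self.wild_cluster is None:
            raise ValueError("no wild cluster designated")
        return self.Q[:, self.wild_cluster]


def _admixture_loglik(Gm, mask, Q, F):
    P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
    with np.errstate(invalid="ignore"):
        ll = np.where(mask, Gm * np.log(P) + (2.0 - Gm) * np.log1p(-P), 0.0)
    return float(ll.sum())


def _em_fit(Gm, mask, K, rng, pinned=None, tol=1e-4, max_iter=500):
    n, S = Gm.shape
    G0 = np.where(mask, Gm, 0.0)
    M = np.where(mask, 1.0, 0.0)
    Q = rng.dirichlet(np.ones(K), size=n)
    F = np.clip(rng.uniform(0.05, 0.95, size=(K, S)), 1e-3, 1 - 1e-3)
    if pinned is not None:
        rows = pinned["rows"]
        Q[rows] = pinned["Q"]
        # seed cluster frequencies from the pinned groups
        for k in range(K):
            w = pinned["Q"][:, k]
            if w.sum() > 0:
                sub = rows[w > 0.5]
                denom = 2.0 * M[sub].sum(axis=0)
                ok = denom > 0
                F[k, ok] = np.clip(G0[sub].sum(axis=0)[ok] / denom[ok], 1e-3, 1 - 1e-3)
    ll_prev = -np.inf
    converged = False
    history = []
    for _ in range(max_iter):
        P = np.clip(Q @ F, 1e-12, 1 - 1e-12)
        A_sum = np.zeros_like(Q)
        F_num = np.zeros_like(F)
        F_den = np.zeros_like(F)
        ratio_a = G0 / P
        ratio_b = (2.0 * M - G0) / (1.0 - P)
        for k in range(K):
            a_k = Q[:, k:k + 1] * F[k] * ratio_a       # expected counted alleles
            b_k = Q[:, k:k + 1] * (1.0 - F[k]) * ratio_b
            A_sum[:, k] = (a_k + b_k).sum(axis=1)
            F_num[k] = a_k.sum(axis=0)
            F_den[k] = (a_k + b_k).sum(axis=0)
        Q = A_sum / A_sum.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            F = np.where(F_den > 0, F_num / F_den, F)
        F = np.clip(F, 1e-6, 1 - 1e-6)
        if pinned is not None:
            Q[pinned["rows"]] = pinned["Q"]
        ll = _admixture_loglik(Gm, mask, Q, F)
        history.append(ll)
        if ll < ll_prev - 1e-6:
            warnings.warn("EM log-likelihood decreased; stopping")
            break
        if ll - ll_prev < tol:
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
    return Q, F, ll_prev, converged, history


def fit_admixture(G: GenotypeMatrix, K, supervised_labels=None, seed=0,
                  tol=1e-4, max_iter=500, n_starts=3) -> AncestryModel:
    """Fit the K-cluster admixture model by EM, best of ``n_starts`` starts.

    supervised_labels : optional dict label -> cluster index; samples whose
        population label appears in the dict get their Q row pinned to the
        indicator of that cluster.  The cluster holding the "WC" label (or,
        unsupervised, the cluster most frequent among WC-labelled samples)
        is designated the wild cluster for q_w.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Gm = G.dosage
    mask = ~np.isnan(Gm)
    n = G.n_samples
    pinned = None
    if supervised_labels:
        labels = G.samples["label"].to_numpy()
        rows = np.flatnonzero(np.isin(labels, list(supervised_labels)))
        if len(rows) == 0:
            raise ValueError("no samples carry the supervised labels")
        used = {supervised_labels[l] for l in labels[rows]}
        if supervised_labels and not set(range(K)) <= set(supervised_labels.values()) | used:
            pass  # partial supervision is allowed
        Qp = np.zeros((len(rows), K))
        for i, r in enumerate(rows):
            Qp[i, supervised_labels[labels[r]]] = 1.0
        pinned = {"rows": rows, "Q": Qp}
    if K == 1:
        Q = np.ones((n, 1))
        n_called = np.maximum(mask.sum(axis=0), 1)
        F = (np.where(mask, Gm, 0.0).sum(axis=0) / (2.0 * n_called))[None, :]
        ll = _admixture_loglik(Gm, mask, Q, np.clip(F, 1e-12, 1 - 1e-12))
        return AncestryModel(1, Q, F, ll, True, 0, list(G.samples["id"]))
    best = None
    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        fit = _em_fit(Gm, mask, K, rng, pinned=pinned, tol=tol, max_iter=max_iter)
        if best is None or fit[2] > best[2]:
            best = fit
    Q, F, ll, converged, history = best
    wild = None
    labels = G.samples["label"].to_numpy()
    if supervised_labels and "WC" in supervised_labels:
        wild = supervised_labels["WC"]
    elif (labels == "WC").any():
        wild = int(np.argmax(Q[labels == "WC"].mean(axis=0)))
    model = AncestryModel(K, Q, F, ll, converged, wild, list(G.samples["id"]))
    model.loglik_history = history
    return model


def cross_validation_error(G: GenotypeMatrix, K_range, folds=5, seed=0,
                           **fit_kwargs) -> dict:
    """Entry-masking cross-validation of the admixture model.

    Non-missing genotype entries are split into ``folds`` random parts; each
    part is masked in turn, the model refit, and masked entries scored by
    the squared deviation between observed dosage and 2 * sum_k q_ik f_kj.
    Returns {K: mean error}.
    """
    K_range = list(K_range)
    if not K_range:
        raise ValueError("K_range is empty")
    rng = np.random.default_rng(seed)
    obs = np.argwhere(~np.isnan(G.dosage))
    perm = rng.permutation(len(obs))
    out = {}
    for K in K_range:
        errs = []
        for f in range(folds):
            test = obs[perm[f::folds]]
            if len(test) == 0:
                warnings.warn("fold with no masked entries skipped")
                continue
            dosage = G.dosage.copy()
            dosage[test[:, 0], test[:, 1]] = np.nan
            Gf = GenotypeMatrix(dosage, G.snps, G.samples)
            model = fit_admixture(Gf, K, seed=int(rng.integers(2 ** 31)),
                                  **fit_kwargs)
            pred = 2.0 * (model.Q @ model.F)
            err = (G.dosage[test[:, 0], test[:, 1]]
                   - pred[test[:, 0], test[:, 1]]) ** 2
            errs.append(err.mean())
        out[K] = float(np.mean(errs))
    return out


def classify_by_qw(q_w, dc_max=0.090, wc_min=1.0, tol=QW_ROUNDING_TOL):
    """Classify samples by wild-cluster proportion.

    q_w < dc_max -> "reference_DC"; q_w >= wc_min (within ``tol`` for
    3-decimal rounding) -> "reference_WC"; else "admixed".
    """
    q_w = np.asarray(q_w, dtype=float)
    out = np.where(q_w < dc_max, "reference_DC",
                   np.where(q_w >= wc_min - tol, "reference_WC", "admixed"))
    return out


# ---------------------------------------------------------------------------
# f3 admixture test
# ---------------------------------------------------------------------------

@dataclass
class F3Result:
    f3: float
    se: float
    z: float
    block_snps: int
    n_blocks: int


def f3_test(G: GenotypeMatrix, target_label, refA_label, refB_label,
            block_snps=20) -> F3Result:
    """f3(target; A, B) with block-jackknife standard error.

    Per SNP: (p_t - p_A)(p_t - p_B) - p_t(1 - p_t)/(a_t - 1), where a_t is
    the target's called allele count (the unbiased correction for sampling
    noise in p_t).  SE by leave-one-block-out jackknife over consecutive
    ``block_snps``-SNP blocks; z = f3 / SE.
    """
    freqs = allele_frequencies(G)
    cols = {lab: (f"p_{lab}", f"n_{lab}") for lab in
            (target_label, refA_label, refB_label)}
    for lab, (pc, nc) in cols.items():
        if pc not in freqs:
            raise ValueError(f"no samples labelled {lab!r}")
    pt = freqs[cols[target_label][0]].to_numpy()
    pa = freqs[cols[refA_label][0]].to_numpy()
    pb = freqs[cols[refB_label][0]].to_numpy()
    at = 2.0 * freqs[cols[target_label][1]].to_numpy()
    ok = ~(np.isnan(pt) | np.isnan(pa) | np.isnan(pb)) & (at > 1)
    pt, pa, pb, at = pt[ok], pa[ok], pb[ok], at[ok]
    vals = (pt - pa) * (pt - pb) - pt * (1 - pt) / (at - 1)
    n_blocks = len(vals) // block_snps
    if n_blocks < 2:
        raise ValueError("fewer than 2 jackknife blocks")
    vals = vals[: n_blocks * block_snps]
    f3 = float(vals.mean())
    block_means = vals.reshape(n_blocks, block_snps).mean(axis=1)
    # delete-one-block estimates
    jack = (vals.sum() - block_means * block_snps) / (len(vals) - block_snps)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * ((jack - jack.mean()) ** 2).sum()))
    if se <= 0:
        raise ValueError("degenerate jackknife SE")
    return F3Result(f3, se, f3 / se, block_snps, n_blocks)
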