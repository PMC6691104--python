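"""Admixture dating: ancestry-switch counts and weighted-LD decay.

Two complementary daters are provided.

Switch-count dating.  Recombination accumulates ancestry junctions at a
rate proportional to the number of generations since admixture.  The
empirical method simulates, for every candidate g, the distribution of
diploid window-level switch counts for individuals whose ancestry fraction
matches the observed one, and reads off the g that makes the observed
count most likely.  A closed-form junction-density estimator
g = S / (4 * L * m * (1 - m)) (S diploid switches, L map length in
Morgans, m admixed fraction) is exact in expectation under
hybrid-isolation admixture.

Weighted-LD dating.  Admixture creates covariance between pairs of sites
that decays as exp(-g * d) with genetic distance d (Morgans).  Weighting
each pair's dosage covariance by the product of parental allele-frequency
differences and fitting A * exp(-n * d) + c to the binned curve estimates
the admixture time n in generations; uncertainty comes from a
leave-one-chromosome-out jackknife.

Generations convert to years via the generation time (2 years for cats).

For speed the per-g switch-count distributions are simulated at reduced
resolution: under both mating models the ancestry process restricted to an
ordered set of points is exactly Markov, so states at a few points per
window can be propagated vectorized over replicates and turned into
majority window calls; a test verifies the distributions agree with the
exact tract-level simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genotype_io import GenotypeMatrix
from .local_ancestry import WindowSet
from .simdata import GeneticMap


# ---------------------------------------------------------------------------
# switch-count dating
# ---------------------------------------------------------------------------

@dataclass
class SwitchDatingModel:
    """Per-g empirical switch-count distributions conditioned on m_hat."""

    g_grid: np.ndarray
    draws: dict                 # g -> int array of diploid switch counts
    m_hat: float
    mating_model: str
    tolerance: float            # conditioning half-width actually used

    def mean_counts(self) -> np.ndarray:
        return np.array([self.draws[g].mean() for g in self.g_grid])


POINTS_PER_WINDOW = 3  # odd; majority over points approximates span-majority


def _window_layout(windows: WindowSet, gmap: GeneticMap,
                   points=POINTS_PER_WINDOW):
    """Per chromosome: ordered cM sample points (``points`` per window,
    evenly spaced within the window span) and window span weights."""
    tab = windows.table
    layout = []
    offs = (np.arange(points) + 0.5) / points
    for c, widx in windows.chrom_groups():
        w0 = tab["i0"].to_numpy()[widx]
        w1 = tab["i1"].to_numpy()[widx]
        cm0 = gmap.cm[w0]
        cm1 = gmap.cm[w1 - 1]
        spans = np.maximum(cm1 - cm0, 1e-9)
        pts = (cm0[:, None] + spans[:, None] * offs[None, :]).ravel()
        layout.append((c, pts, spans))
    return layout


def _majority_calls(states, n_windows, points=POINTS_PER_WINDOW):
    """(n, W * points) point states -> (n, W) majority window calls."""
    s = states.reshape(states.shape[0], n_windows, points)
    return (s.mean(axis=2) > 0.5).astype(np.uint8)


def _hi_point_states(layout, g, m, n_haps, rng):
    """Hybrid-isolation ancestry at the layout's points (exact Markov)."""
    cols = []
    for _, pts, _ in layout:
        block = np.empty((n_haps, len(pts)), dtype=np.uint8)
        col = (rng.random(n_haps) < m).astype(np.uint8)
        block[:, 0] = col
        pr = 1.0 - np.exp(-g * np.diff(pts) / 100.0)
        for j, p in enumerate(pr):
            redraw = rng.random(n_haps) < p
            col = np.where(redraw, (rng.random(n_haps) < m).astype(np.uint8), col)
            block[:, j + 1] = col
        cols.append(block)
    return cols


def _meiosis_points(hapA_blocks, hapB_blocks, layout, spans_cm, rng):
    """Vectorized meiosis at point resolution for a batch of parents."""
    out = []
    for (c, pts, _), A, B in zip(layout, hapA_blocks, hapB_blocks):
        n = A.shape[0]
        span = spans_cm[c]
        k = rng.poisson(span / 100.0, size=n)
        kmax = max(int(k.max()) if n else 0, 1)
        pos = rng.uniform(0.0, span, size=(n, kmax))
        pos[np.arange(kmax)[None, :] >= k[:, None]] = np.inf  # ragged padding
        first = rng.integers(2, size=n)
        parity = (pos[:, :, None] < pts[None, None, :]).sum(axis=1)
        src = (first[:, None] + parity) % 2
        out.append(np.where(src == 0, A, B).astype(np.uint8))
    return out


def _pedigree_point_individuals(layout, spans_cm, g, recurrent_dc, n, rng):
    """BCg admixed haplotype at the layout's points (other hap is pure)."""
    pure_rec = [np.full((n, len(p)), recurrent_dc, dtype=np.uint8)
                for _, p, _ in layout]
    pure_don = [np.full((n, len(p)), 1 - recurrent_dc, dtype=np.uint8)
                for _, p, _ in layout]
    if g == 1:
        return pure_don  # F1: one pure donor haplotype, zero junctions
    hap = _meiosis_points(pure_rec, pure_don, layout, spans_cm, rng)
    for _ in range(g - 2):
        hap = _meiosis_points(hap, pure_rec, layout, spans_cm, rng)
    return hap


def _switches_and_m(states_h0, states_h1, layout):
    """Diploid switch counts (on majority window calls) and span-weighted
    DC fraction per individual."""
    n = states_h0[0].shape[0]
    S = np.zeros(n, dtype=int)
    num = np.zeros(n)
    den = 0.0
    for (c, pts, spans), A, B in zip(layout, states_h0, states_h1):
        for st in (A, B):
            calls = _majority_calls(st, len(spans))
            S += (np.diff(calls, axis=1) != 0).sum(axis=1)
            num += 0.5 * (calls * spans[None, :]).sum(axis=1)
        den += spans.sum()
    return S, num / den


def build_switch_model(m_hat, windows: WindowSet, gmap: GeneticMap,
                       g_grid=None, n_sims=1000, mating_model="hybrid_isolation",
                       seed=0, cond_tol=0.05, max_oversample=50) -> SwitchDatingModel:
    """Simulate per-g switch-count distributions conditioned on m_hat.

    For each g in the grid, individuals are simulated under ``mating_model``
    and kept when their realized (window-span-weighted) ancestry fraction
    falls within ``cond_tol`` of ``m_hat``; if the oversampling cap is hit
    the tolerance is doubled with a warning.
    """
    if not (0 < m_hat < 1):
        raise ValueError("m_hat must lie strictly between 0 and 1")
    if g_grid is None:
        g_grid = np.arange(1, 31)
    g_grid = np.asarray(list(g_grid), dtype=int)
    layout = _window_layout(windows, gmap)
    rng = np.random.default_rng(seed)
    draws = {}
    tol_used = cond_tol
    for g in g_grid:
        tol = cond_tol
        accepted = []
        simulated = 0
        while len(accepted) < n_sims:
            batch = max(n_sims, 256)
            if mating_model == "hybrid_isolation":
                h0 = _hi_point_states(layout, g, m_hat, batch, rng)
                h1 = _hi_point_states(layout, g, m_hat, batch, rng)
            elif mating_model == "pedigree":
                adm = _pedigree_point_individuals(
                    layout, gmap.span_cm, int(g), recurrent_dc=0, n=batch, rng=rng)
                h0 = adm
                h1 = [np.zeros_like(b) for b in adm]  # pure recurrent (WC)
            else:
                raise ValueError(f"unknown mating model {mating_model!r}")
            S, m_real = _switches_and_m(h0, h1, layout)
            ok = np.abs(m_real - m_hat) <= tol
            accepted.extend(S[ok].tolist())
            simulated += batch
            if simulated > max_oversample * n_sims and len(accepted) < n_sims:
                tol *= 2.0
                warnings.warn(f"g={g}: conditioning cap exceeded; "
                              f"tolerance widened to {tol:.3f}")
                simulated = 0
        draws[int(g)] = np.array(accepted[:n_sims], dtype=int)
        tol_used = max(tol_used, tol)
    return SwitchDatingModel(g_grid, draws, float(m_hat), mating_model, tol_used)


@dataclass
class DatingResult:
    method: str
    g_hat: float
    ci_low: float | None = None
    ci_high: float | None = None
    se: float | None = None
    years: float | None = None
    calendar_year: float | None = None
    saturated: bool = False
    p_value: float | None = None
    significant: bool | None = None


def date_from_switches(S, model: SwitchDatingModel, generation_time=2.0,
                       sampling_year=None, kernel=1) -> DatingResult:
    """Empirical-likelihood dating of an observed diploid switch count.

    The likelihood of g is the fraction of simulated counts within
    ``kernel`` of S (widened automatically if S sits between supports);
    g_hat maximizes it and the interval is the central 95% of the
    normalized likelihood over the grid.
    """
    if S < 0:
        raise ValueError("S must be >= 0")
    gs = model.g_grid
    max_support = max(d.max() for d in model.draws.values())
    if S > max_support:
        g_hat = int(gs.max())
        years, cal = generations_to_years(g_hat, generation_time, sampling_year)
        return DatingResult("switches_empirical", float(g_hat),
                            years=years, calendar_year=cal, saturated=True)
    k = kernel
    while True:
        lik = np.array([(np.abs(model.draws[int(g)] - S) <= k).mean() for g in gs])
        if lik.sum() > 0:
            break
        k *= 2
    post = lik / lik.sum()
    g_hat = float(gs[int(np.argmax(lik))])
    cdf = np.cumsum(post)
    ci_low = float(gs[int(np.searchsorted(cdf, 0.025))])
    ci_high = float(gs[min(int(np.searchsorted(cdf, 0.975)), len(gs) - 1)])
    years, cal = generations_to_years(g_hat, generation_time, sampling_year)
    return DatingResult("switches_empirical", g_hat, ci_low, ci_high,
                        years=years, calendar_year=cal)


def closed_form_generations(S, m_hat, L_morgans) -> float:
    """Junction-density estimator g = S / (4 * L * m * (1 - m)), 1 decimal."""
    if S < 0:
        raise ValueError("S must be >= 0")
    if L_morgans <= 0:
        raise ValueError("map length must be positive")
    if not (0 < m_hat < 1):
        raise ValueError("m_hat must lie strictly between 0 and 1")
    return round(S / (4.0 * L_morgans * m_hat * (1.0 - m_hat)), 1)


def generations_to_years(g, generation_time=2.0, sampling_year=None):
    """years = g * generation_time; calendar year if sampling year known.

    Rounding happens only at presentation; values are returned unrounded.
    """
    if g < 0:
        raise ValueError("g must be >= 0")
    years = g * generation_time
    cal = sampling_year - years if sampling_year is not None else None
    return years, cal


# ---------------------------------------------------------------------------
# weighted-LD decay
# ---------------------------------------------------------------------------

@dataclass
class WeightedLDCurve:
    """Binned weighted-LD curve with per-chromosome components."""

    bin_edges: np.ndarray        # Morgans, len B + 1
    chrom_sums: np.ndarray       # (C, B) sum of w_x w_y cov(x, y)
    chrom_counts: np.ndarray     # (C, B) pair counts
    chromosomes: list

    def aggregate(self, exclude_chrom=None) -> pd.DataFrame:
        keep = np.ones(len(self.chromosomes), dtype=bool)
        if exclude_chrom is not None:
            keep[self.chromosomes.index(exclude_chrom)] = False
        s = self.chrom_sums[keep].sum(axis=0)
        n = self.chrom_counts[keep].sum(axis=0)
        d = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        with np.errstate(invalid="ignore", divide="ignore"):
            a = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        return pd.DataFrame({"d": d, "a": a, "n_pairs": n.astype(int)})


def weighted_ld_curve(G_admixed, p_wc, p_dc, gmap: GeneticMap = None,
                      bin_m=0.001, d_min=0.005, d_max=0.3) -> WeightedLDCurve:
    """Two-reference weighted LD: for every same-chromosome SNP pair with
    genetic distance d in [d_min, d_max] Morgans, accumulate
    w_x * w_y * cov(x, y) where w = p_WC - p_DC and cov is the sample
    covariance of dosages across the admixed cohort; bin-average by d."""
    if isinstance(G_admixed, GenotypeMatrix):
        dosage = G_admixed.dosage
        gmap = G_admixed.genetic_map() if gmap is None else gmap
    else:
        dosage = np.asarray(G_admixed, dtype=float)
        if gmap is None:
            raise ValueError("a genetic map is required")
    n = dosage.shape[0]
    if n < 2:
        raise ValueError("need at least 2 admixed samples")
    w_all = np.asarray(p_wc, dtype=float) - np.asarray(p_dc, dtype=float)
    n_bins = int(np.ceil((d_max - d_min) / bin_m))
    edges = d_min + bin_m * np.arange(n_bins + 1)
    chroms = list(gmap.chromosomes)
    sums = np.zeros((len(chroms), n_bins))
    counts = np.zeros((len(chroms), n_bins), dtype=np.int64)
    for ci, c in enumerate(chroms):
        sl = gmap.chrom_slice(c)
        X = dosage[:, sl]
        w = w_all[sl]
        ok = ~np.isnan(w)
        X, w = X[:, ok], w[ok]
        cm = gmap.cm[sl][ok]
        if X.shape[1] < 2:
            continue
        if np.isnan(X).any():
            mu = np.nanmean(X, axis=0)
            inds = np.where(np.isnan(X))
            X = X.copy()
            X[inds] = mu[inds[1]]
        Xc = X - X.mean(axis=0)
        C = (Xc.T @ Xc) / (n - 1)
        D = np.abs(cm[:, None] - cm[None, :]) / 100.0
        iu = np.triu_indices(len(w), k=1)
        d = D[iu]
        sel = (d >= d_min) & (d <= d_max)
        if not sel.any():
            continue
        vals = (np.outer(w, w) * C)[iu][sel]
        b = np.minimum(((d[sel] - d_min) / bin_m).astype(int), n_bins - 1)
        sums[ci] = np.bincount(b, weights=vals, minlength=n_bins)
        counts[ci] = np.bincount(b, minlength=n_bins)
    return WeightedLDCurve(edges, sums, counts, chroms)


@dataclass
class WeightedLDFit:
    amplitude: float
    n_hat: float
    affine: float
    se: float | None
    p_value: float | None
    significant: bool | None
    success: bool
    jackknife: np.ndarray = field(default_factory=lambda: np.array([]))
    se_amplitude: float | None = None


def _fit_exp(d, a, sigma, p0):
    popt, _ = optimize.curve_fit(
        lambda x, A, n, c: A * np.exp(-n * x) + c, d, a, p0=p0,
        sigma=sigma, bounds=([0.0, 0.0, -np.inf], [np.inf, np.inf, np.inf]),
        maxfev=20000)
    return popt


def fit_ld_decay(curve: WeightedLDCurve, alpha=0.01, min_pairs=10) -> WeightedLDFit:
    """Fit a(d) = A * exp(-n * d) + c; jackknife SE over chromosomes.

    Bins with fewer than ``min_pairs`` pairs are excluded.  One-sided
    normal p-values are formed for both n_hat > 0 and A > 0 from the
    delete-one-chromosome jackknife (the rate is unidentifiable when the
    amplitude vanishes, so a significant decay requires both); the
    reported p-value is the larger of the two and the fit is declared
    significant at ``p < alpha``.
    """
    tab = curve.aggregate()
    use = (tab["n_pairs"] >= min_pairs) & tab["a"].notna()
    if use.sum() < 5:
        raise ValueError("fewer than 5 usable bins")
    d = tab.loc[use, "d"].to_numpy()
    a = tab.loc[use, "a"].to_numpy()
    npairs = tab.loc[use, "n_pairs"].to_numpy()
    sigma = 1.0 / np.sqrt(npairs)
    c0 = a[-max(5, len(a) // 10):].mean()
    p0 = (max(a[0] - c0, 1e-9), max(1.0 / max(d[0], 1e-4), 1.0), c0)
    try:
        A, n_hat, c = _fit_exp(d, a, sigma, p0)
    except RuntimeError:
        return WeightedLDFit(np.nan, np.nan, np.nan, None, None, None, False)
    present = curve.chrom_counts.sum(axis=1) > 0
    jack_n, jack_a = [], []
    if present.sum() >= 3:
        for c_ex, has in zip(curve.chromosomes, present):
            if not has:
                continue
            t = curve.aggregate(exclude_chrom=c_ex)
            u = (t["n_pairs"] >= min_pairs) & t["a"].notna()
            try:
                aj, nj, _ = _fit_exp(t.loc[u, "d"].to_numpy(),
                                     t.loc[u, "a"].to_numpy(),
                                     1.0 / np.sqrt(t.loc[u, "n_pairs"].to_numpy()),
                                     (A, n_hat, c))
                jack_n.append(nj)
                jack_a.append(aj)
            except RuntimeError:
                continue
    if len(jack_n) >= 3:
        jack_n = np.array(jack_n)
        jack_a = np.array(jack_a)
        J = len(jack_n)
        fac = (J - 1) / J
        se = float(np.sqrt(fac * ((jack_n - jack_n.mean()) ** 2).sum()))
        se_a = float(np.sqrt(fac * ((jack_a - jack_a.mean()) ** 2).sum()))
        p_n = float(stats.norm.sf(n_hat / se)) if se > 0 else (
            0.0 if n_hat > 0 else 1.0)
        p_a = float(stats.norm.sf(A / se_a)) if se_a > 0 else (
            0.0 if A > 0 else 1.0)
        p = max(p_n, p_a)
        return WeightedLDFit(float(A), float(n_hat), float(c), se, p,
                             p < alpha, True, jack_n, se_a)
    return WeightedLDFit(float(A), float(n_hat), float(c), None, None,
                         None, True)
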