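"""Synthetic hybrid-genome simulator.

Generates two divergent parental cat populations (a "wildcat" WC and a
"domestic" DC pool) under a Balding–Nichols allele-frequency model, a
multi-chromosome genetic map, and admixed individuals with exactly known
ancestry tracts.  Every downstream analysis stage (global ancestry, local
ancestry, admixture dating, outlier scans, AIM panels) can therefore be
exercised and validated against simulated truth without any external data.

Model summary
-------------
* Parental divergence: per-SNP frequencies for WC and DC are drawn
  independently from a Beta distribution with mean ``p_anc`` and variance
  ``F * p_anc * (1 - p_anc)`` (Balding–Nichols), so the Hudson-style
  ratio-of-means Fst between the two pools equals ``F`` in expectation.
* Recombination: Poisson crossovers at rate 1 per Morgan, positions uniform
  on the cM scale, no interference, chromosomes independent.
* Two mating designs:
  - ``pedigree``: F1 (g = 1) followed by g - 1 backcrosses to a recurrent
    parent (BCg), or an F2 cross; ancestry of every transmitted segment is
    tracked exactly through each meiosis.
  - ``hybrid_isolation``: a single admixture pulse (haplotype-level mixed
    founding pool, DC fraction m) followed by g generations of random
    mating in a large population; along a sampled gamete, ancestry-redraw
    events accumulate at rate g per Morgan and each redraw is an independent
    Bernoulli(m) draw.  Expected diploid junction count is
    4 * L * m * (1 - m) * g for a map of L Morgans.

Ancestry codes: 0 = WC (wildcat), 1 = DC (domestic).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WC = 0
DC = 1
ANCESTRY_NAMES = {WC: "WC", DC: "DC"}


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

class GeneticMap:
    """SNP coordinates (chromosome, bp, cM) on a multi-chromosome map.

    Parameters
    ----------
    chrom : array of int, chromosome label per SNP (sorted blocks).
    bp : array of int, 1-based physical positions, strictly increasing
        within a chromosome.
    cm : array of float, genetic positions, non-decreasing within a
        chromosome.
    span_cm : optional mapping chrom -> total cM span; defaults to the last
        SNP's cM position per chromosome.
    """

    def __init__(self, chrom, bp, cm, span_cm=None):
        self.chrom = np.asarray(chrom)
        self.bp = np.asarray(bp, dtype=np.int64)
        self.cm = np.asarray(cm, dtype=float)
        if not (len(self.chrom) == len(self.bp) == len(self.cm)):
            raise ValueError("chrom, bp and cm must have equal length")
        self.chromosomes = list(pd.unique(self.chrom))
        self._slices = {}
        for c in self.chromosomes:
            idx = np.flatnonzero(self.chrom == c)
            if np.any(np.diff(idx) != 1):
                raise ValueError(f"SNPs of chromosome {c} are not contiguous")
            sl = slice(idx[0], idx[-1] + 1)
            self._slices[c] = sl
            if np.any(np.diff(self.bp[sl]) <= 0):
                raise ValueError(f"bp not strictly increasing on chromosome {c}")
            if np.any(np.diff(self.cm[sl]) < 0):
                raise ValueError(f"cM not monotone on chromosome {c}")
        if span_cm is None:
            span_cm = {c: float(self.cm[self._slices[c]][-1]) for c in self.chromosomes}
        self.span_cm = {c: float(span_cm[c]) for c in self.chromosomes}
        self.bp_end = {c: int(self.bp[self._slices[c]][-1]) for c in self.chromosomes}

    @property
    def n_snps(self) -> int:
        return len(self.bp)

    @property
    def length_morgans(self) -> float:
        """Total haploid map length L in Morgans (sum of cM spans / 100)."""
        return sum(self.span_cm.values()) / 100.0

    def chrom_slice(self, c) -> slice:
        return self._slices[c]

    def chrom_cm(self, c) -> np.ndarray:
        return self.cm[self._slices[c]]

    def cm_to_bp(self, c, cm_pos) -> np.ndarray:
        """Linear cM -> bp conversion on chromosome ``c``."""
        scale = self.bp_end[c] / max(self.span_cm[c], 1e-12)
        return np.maximum(1, np.rint(np.asarray(cm_pos, dtype=float) * scale)).astype(np.int64)

    @classmethod
    def uniform(cls, n_snps, n_chromosomes=18, length_morgans=30.0, seed=0,
                bp_per_cm=1_000_000):
        """Equal-length chromosomes with uniformly scattered SNPs.

        SNP counts are allocated proportionally to chromosome length (equal
        here), cM positions are sorted uniforms on (0, span), and bp
        positions follow a constant bp-per-cM scale.
        """
        if n_snps < n_chromosomes:
            raise ValueError("need at least one SNP per chromosome")
        rng = np.random.default_rng(seed)
        span = length_morgans * 100.0 / n_chromosomes
        if span < 100.0:
            raise ValueError("chromosomes must span at least 1 Morgan")
        counts = np.full(n_chromosomes, n_snps // n_chromosomes)
        counts[: n_snps % n_chromosomes] += 1
        chrom, bp, cm = [], [], []
        for c in range(1, n_chromosomes + 1):
            pos = np.sort(rng.uniform(0.0, span, counts[c - 1]))
            b = np.rint(pos * bp_per_cm).astype(np.int64) + 1
            b = np.maximum.accumulate(b)  # enforce strict increase
            b += np.arange(len(b))
            chrom.append(np.full(counts[c - 1], c))
            bp.append(b)
            cm.append(pos)
        return cls(np.concatenate(chrom), np.concatenate(bp), np.concatenate(cm),
                   span_cm={c: span for c in range(1, n_chromosomes + 1)})

    def snp_frame(self, ids=None) -> pd.DataFrame:
        if ids is None:
            ids = [f"snp{i}" for i in range(self.n_snps)]
        return pd.DataFrame({"id": ids, "chrom": self.chrom, "bp": self.bp, "cm": self.cm})


# ---------------------------------------------------------------------------
# parental populations
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Parental allele-frequency contrast between the WC and DC pools."""

    p_anc: np.ndarray
    p_wc: np.ndarray
    p_dc: np.ndarray
    f_target: float

    @property
    def n_snps(self) -> int:
        return len(self.p_anc)

    def freq(self, ancestry: int) -> np.ndarray:
        return self.p_wc if ancestry == WC else self.p_dc


def hudson_fst(p1, p2) -> float:
    """Hudson-style ratio-of-means Fst from two population frequency vectors.

    1 - mean within-pop heterozygosity / mean between-pop heterozygosity;
    unbiased for the Balding–Nichols divergence parameter.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    hw = p1 * (1 - p1) + p2 * (1 - p2)
    hb = p1 * (1 - p2) + p2 * (1 - p1)
    denom = hb.sum()
    if denom <= 0:
        return 0.0
    return float(1.0 - hw.sum() / denom)


def generate_parental_frequencies(n_snps, f_target, seed=0,
                                  p_anc_range=(0.05, 0.95)) -> PopulationModel:
    """Draw WC and DC allele frequencies around uniform ancestral frequencies.

    Each population's frequency is an independent Beta draw with mean
    ``p_anc`` and variance ``f_target * p_anc * (1 - p_anc)``.
    """
    if not (0 <= f_target < 1):
        raise ValueError("f_target must lie in [0, 1)")
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = p_anc_range
    p_anc = rng.uniform(lo, hi, n_snps)
    if f_target == 0:
        return PopulationModel(p_anc, p_anc.copy(), p_anc.copy(), 0.0)
    ratio = (1.0 - f_target) / f_target
    a = p_anc * ratio
    b = (1.0 - p_anc) * ratio
    p_wc = rng.beta(a, b)
    p_dc = rng.beta(a, b)
    return PopulationModel(p_anc, p_wc, p_dc, float(f_target))


@dataclass
class ReferencePanels:
    """Phased reference haplotypes for the two parental pools (0/1 alleles)."""

    wc_haps: np.ndarray  # (2 * n_wc, S)
    dc_haps: np.ndarray  # (2 * n_dc, S)
    model: PopulationModel
    gmap: GeneticMap

    @property
    def n_wc(self) -> int:
        return self.wc_haps.shape[0] // 2

    @property
    def n_dc(self) -> int:
        return self.dc_haps.shape[0] // 2

    def genotypes(self, pop: int) -> np.ndarray:
        haps = self.wc_haps if pop == WC else self.dc_haps
        return haps[0::2] + haps[1::2]

    def genotype_matrix(self):
        """Assemble a labelled GenotypeMatrix of both reference panels."""
        from .genotype_io import GenotypeMatrix
        gwc = self.genotypes(WC)
        gdc = self.genotypes(DC)
        dosage = np.vstack([gwc, gdc]).astype(float)
        samples = pd.DataFrame({
            "id": [f"WC{i:03d}" for i in range(self.n_wc)]
                  + [f"DC{i:03d}" for i in range(self.n_dc)],
            "label": ["WC"] * self.n_wc + ["DC"] * self.n_dc,
        })
        return GenotypeMatrix(dosage, self.gmap.snp_frame(), samples)


def sample_reference_genotypes(model: PopulationModel, gmap: GeneticMap,
                               n_wc, n_dc, seed=0) -> ReferencePanels:
    """Draw phased parental panels at Hardy–Weinberg / linkage equilibrium."""
    if model.n_snps != gmap.n_snps:
        raise ValueError("model and map disagree on SNP count")
    rng = np.random.default_rng(seed)
    wc = (rng.random((2 * n_wc, model.n_snps)) < model.p_wc).astype(np.uint8)
    dc = (rng.random((2 * n_dc, model.n_snps)) < model.p_dc).astype(np.uint8)
    return ReferencePanels(wc, dc, model, gmap)


# ---------------------------------------------------------------------------
# ancestry tracts and meiosis
# ---------------------------------------------------------------------------

class HaplotypeTracts:
    """Ancestry mosaic of one haplotype: per chromosome, segment end points
    (cM, increasing, last equals the chromosome span) and segment ancestries.
    Segments are half-open on the cM scale and tile the chromosome."""

    def __init__(self, segments):
        # segments: dict chrom -> (breaks: float array, anc: uint8 array)
        self.segments = segments

    @classmethod
    def pure(cls, gmap: GeneticMap, ancestry: int):
        return cls({c: (np.array([gmap.span_cm[c]]),
                        np.array([ancestry], dtype=np.uint8))
                    for c in gmap.chromosomes})

    def n_junctions(self) -> int:
        return sum(len(a) - 1 for _, a in self.segments.values())

    def dc_cm(self) -> float:
        total = 0.0
        for breaks, anc in self.segments.values():
            starts = np.concatenate([[0.0], breaks[:-1]])
            total += float(((breaks - starts) * (anc == DC)).sum())
        return total

    def ancestry_at(self, gmap: GeneticMap) -> np.ndarray:
        """Ancestry code at every SNP of the map."""
        out = np.empty(gmap.n_snps, dtype=np.uint8)
        for c in gmap.chromosomes:
            sl = gmap.chrom_slice(c)
            breaks, anc = self.segments[c]
            idx = np.minimum(np.searchsorted(breaks, gmap.cm[sl], side="right"),
                             len(anc) - 1)
            out[sl] = anc[idx]
        return out


def _compress(bounds, anc):
    if len(anc) <= 1:
        return bounds, anc
    keep = np.append(anc[:-1] != anc[1:], True)
    return bounds[keep], anc[keep]


def _gamete_chrom(bA, aA, bB, aB, span, rng):
    """One meiosis on one chromosome: recombine two parental haplotypes with
    Poisson(span/100) crossovers uniform on the cM scale."""
    k = rng.poisson(span / 100.0)
    cuts = np.sort(rng.uniform(0.0, span, k))
    first = int(rng.integers(2))
    bounds = np.unique(np.concatenate([cuts, bA, bB]))
    starts = np.concatenate([[0.0], bounds[:-1]])
    mids = 0.5 * (starts + bounds)
    src = (first + np.searchsorted(cuts, mids)) % 2
    ia = np.minimum(np.searchsorted(bA, mids, side="right"), len(aA) - 1)
    ib = np.minimum(np.searchsorted(bB, mids, side="right"), len(aB) - 1)
    anc = np.where(src == 0, aA[ia], aB[ib]).astype(np.uint8)
    return _compress(bounds, anc)


def meiosis(hap_a: HaplotypeTracts, hap_b: HaplotypeTracts,
            gmap: GeneticMap, rng) -> HaplotypeTracts:
    """Form a gamete from a parent's two haplotypes."""
    segs = {}
    for c in gmap.chromosomes:
        bA, aA = hap_a.segments[c]
        bB, aB = hap_b.segments[c]
        segs[c] = _gamete_chrom(bA, aA, bB, aB, gmap.span_cm[c], rng)
    return HaplotypeTracts(segs)


# ---------------------------------------------------------------------------
# pedigree designs
# ---------------------------------------------------------------------------

@dataclass
class PedigreeSpec:
    """Admixture design.

    design : "F1", "F2" or "BC<g>"; g counts generations since the founding
        hybridization (F1 has g = 1; BCg is an F1 followed by g - 1
        backcrosses to the recurrent parent).
    recurrent : recurrent parent for backcrosses, "WC" or "DC".
    mating : "pedigree" or "hybrid_isolation".
    m : founding DC haplotype fraction for hybrid-isolation mating
        (defaults to 0.5 ** g, the pedigree expectation).
    """

    design: str = "F1"
    recurrent: str = "WC"
    mating: str = "pedigree"
    m: float | None = None
    seed: int = 0

    @property
    def g(self) -> int:
        if self.design == "F1":
            return 1
        if self.design == "F2":
            return 2
        if self.design.startswith("BC"):
            g = int(self.design[2:])
            if g < 1:
                raise ValueError("g must be >= 1")
            return g
        raise ValueError(f"unknown design {self.design!r}")

    @property
    def mixture_fraction(self) -> float:
        if self.m is not None:
            return self.m
        m = 0.5 ** self.g
        return m if self.recurrent == "WC" else 1.0 - m


@dataclass
class TruthTracts:
    """True ancestry mosaics for a set of simulated individuals."""

    individuals: list  # list of (HaplotypeTracts, HaplotypeTracts)
    gmap: GeneticMap
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        if not self.sample_ids:
            self.sample_ids = [f"HYB{i:03d}" for i in range(len(self.individuals))]

    def m_true(self) -> np.ndarray:
        """Diploid DC-ancestry fraction by map length, per individual."""
        total = self.gmap.length_morgans * 100.0
        return np.array([(h0.dc_cm() + h1.dc_cm()) / (2 * total)
                         for h0, h1 in self.individuals])

    def junction_counts(self) -> np.ndarray:
        return np.array([h0.n_junctions() + h1.n_junctions()
                         for h0, h1 in self.individuals])

    def hap_ancestry_matrix(self) -> np.ndarray:
        """(2n, S) ancestry codes at SNP positions, haplotypes interleaved."""
        rows = []
        for h0, h1 in self.individuals:
            rows.append(h0.ancestry_at(self.gmap))
            rows.append(h1.ancestry_at(self.gmap))
        return np.array(rows, dtype=np.uint8)

    def to_bed_frame(self) -> pd.DataFrame:
        """Truth tracts as 0-based half-open BED records with ancestry names."""
        rec = []
        for sid, (h0, h1) in zip(self.sample_ids, self.individuals):
            for hap, tracts in enumerate((h0, h1)):
                for c in self.gmap.chromosomes:
                    breaks, anc = tracts.segments[c]
                    bp = self.gmap.cm_to_bp(c, breaks)
                    start = 0
                    for end, a in zip(bp, anc):
                        rec.append((c, start, int(end),
                                    f"{sid}|hap{hap}|{ANCESTRY_NAMES[int(a)]}"))
                        start = int(end)
        return pd.DataFrame(rec, columns=["chrom", "start", "end", "name"])


def _simulate_tracts(gmap: GeneticMap, spec: PedigreeSpec, rng) -> tuple:
    """One individual's pair of ancestry mosaics under the given design."""
    g = spec.g
    if spec.mating == "hybrid_isolation":
        m = spec.mixture_fraction
        haps = []
        for _ in range(2):
            segs = {}
            for c in gmap.chromosomes:
                span = gmap.span_cm[c]
                k = rng.poisson(g * span / 100.0)
                cuts = np.sort(rng.uniform(0.0, span, k))
                bounds = np.append(cuts, span)
                anc = (rng.random(len(bounds)) < m).astype(np.uint8)
                segs[c] = _compress(bounds, anc)
            haps.append(HaplotypeTracts(segs))
        return haps[0], haps[1]
    if spec.mating != "pedigree":
        raise ValueError(f"unknown mating model {spec.mating!r}")
    rec_anc = WC if spec.recurrent == "WC" else DC
    don_anc = DC if rec_anc == WC else WC
    pure_rec = HaplotypeTracts.pure(gmap, rec_anc)
    pure_don = HaplotypeTracts.pure(gmap, don_anc)
    f1 = (pure_rec, pure_don)
    if spec.design == "F1":
        return f1
    if spec.design == "F2":
        rng2 = np.random.default_rng(rng.integers(2 ** 31))
        return (meiosis(*f1, gmap, rng), meiosis(*f1, gmap, rng2))
    ind = f1
    for _ in range(g - 1):
        gam = meiosis(ind[0], ind[1], gmap, rng)
        ind = (gam, HaplotypeTracts.pure(gmap, rec_anc))
    return ind


@dataclass
class AdmixedIndividual:
    hap_alleles: np.ndarray  # (2, S) 0/1
    tracts: tuple            # (HaplotypeTracts, HaplotypeTracts)
    m_true: float
    n_junctions: int

    @property
    def genotype(self) -> np.ndarray:
        return self.hap_alleles.sum(axis=0)


def simulate_admixed_individual(model: PopulationModel, gmap: GeneticMap,
                                spec: PedigreeSpec, rng=None) -> AdmixedIndividual:
    """Simulate one admixed individual: exact ancestry tracts plus alleles
    drawn from the parental frequency of the local ancestry at each SNP."""
    if spec.g < 1:
        raise ValueError("g must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    h0, h1 = _simulate_tracts(gmap, spec, rng)
    total = gmap.length_morgans * 100.0
    alleles = np.empty((2, gmap.n_snps), dtype=np.uint8)
    for row, hap in enumerate((h0, h1)):
        anc = hap.ancestry_at(gmap)
        p = np.where(anc == WC, model.p_wc, model.p_dc)
        alleles[row] = rng.random(gmap.n_snps) < p
    m_true = (h0.dc_cm() + h1.dc_cm()) / (2 * total)
    return AdmixedIndividual(alleles, (h0, h1), float(m_true),
                             h0.n_junctions() + h1.n_junctions())


def simulate_cohort(model: PopulationModel, gmap: GeneticMap,
                    specs, seed=0, prefix="HYB"):
    """Simulate a cohort of admixed individuals.

    ``specs`` is either a single PedigreeSpec (replicated) with an ``n``
    given as int, or a list of PedigreeSpec.  Returns (hap_alleles (2n, S),
    TruthTracts).
    """
    rng = np.random.default_rng(seed)
    if isinstance(specs, tuple) and len(specs) == 2:
        spec, n = specs
        specs = [spec] * n
    inds, haps, ids = [], [], []
    for i, spec in enumerate(specs):
        ind = simulate_admixed_individual(model, gmap, spec, rng)
        inds.append(ind.tracts)
        haps.append(ind.hap_alleles)
        ids.append(f"{prefix}{i:03d}")
    hap_alleles = (np.concatenate(haps, axis=0) if haps
                   else np.empty((0, gmap.n_snps), dtype=np.uint8))
    return hap_alleles, TruthTracts(inds, gmap, ids)


def simulate_hybrid_isolation_cohort(model: PopulationModel, gmap: GeneticMap,
                                     n, g, m, seed=0):
    """Vectorized hybrid-isolation cohort at SNP resolution.

    Ancestry along each haplotype is a Markov redraw process (rate g per
    Morgan, redraw ~ Bernoulli(m)), evaluated exactly at the SNP positions
    and vectorized over all 2n haplotypes.  Returns (hap_ancestry (2n, S),
    hap_alleles (2n, S), m_true (n,)); m_true is the cM-span-weighted DC
    fraction at marker resolution.
    """
    if g < 1:
        raise ValueError("g must be >= 1")
    rng = np.random.default_rng(seed)
    H = 2 * n
    S = gmap.n_snps
    anc = np.empty((H, S), dtype=np.uint8)
    weights = np.empty(S)
    for c in gmap.chromosomes:
        sl = gmap.chrom_slice(c)
        cm = gmap.cm[sl]
        span = gmap.span_cm[c]
        edges = np.concatenate([[0.0], 0.5 * (cm[:-1] + cm[1:]), [span]])
        weights[sl] = np.diff(edges)
        col = (rng.random(H) < m).astype(np.uint8)
        block = np.empty((H, len(cm)), dtype=np.uint8)
        block[:, 0] = col
        p_redraw = 1.0 - np.exp(-g * np.diff(cm) / 100.0)
        for j, pr in enumerate(p_redraw):
            redraw = rng.random(H) < pr
            col = np.where(redraw, (rng.random(H) < m).astype(np.uint8), col)
            block[:, j + 1] = col
        anc[:, sl] = block
    alleles = np.where(anc == WC,
                       rng.random((H, S)) < model.p_wc,
                       rng.random((H, S)) < model.p_dc).astype(np.uint8)
    w = weights / weights.sum()
    hap_m = (anc * w).sum(axis=1)
    m_true = 0.5 * (hap_m[0::2] + hap_m[1::2])
    return anc, alleles, m_true


# ---------------------------------------------------------------------------
# dataset writer
# ---------------------------------------------------------------------------

def write_dataset(genotypes, tracts: TruthTracts | None, gmap: GeneticMap,
                  out_prefix, hap_alleles=None):
    """Write a simulated dataset as PLINK .ped/.map text plus companions.

    Emits ``<prefix>.ped`` / ``<prefix>.map`` (cM in column 3, bp in column
    4), ``<prefix>.labels.tsv`` (sample, label), optionally
    ``<prefix>.haps.tsv`` (sample, hap, allele string) and
    ``<prefix>.truth.bed`` (0-based half-open truth tracts with ancestry in
    the name field).
    """
    from .genotype_io import write_plink
    write_plink(genotypes, out_prefix)
    genotypes.samples[["id", "label"]].to_csv(
        f"{out_prefix}.labels.tsv", sep="\t", header=False, index=False)
    if hap_alleles is not None:
        with open(f"{out_prefix}.haps.tsv", "w") as fh:
            for i, sid in enumerate(genotypes.samples["id"]):
                for hap in (0, 1):
                    row = hap_alleles[2 * i + hap]
                    fh.write(f"{sid}\t{hap}\t{''.join(map(str, row))}\n")
    if tracts is not None:
        tracts.to_bed_frame().to_csv(
            f"{out_prefix}.truth.bed", sep="\t", header=False, index=False)
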