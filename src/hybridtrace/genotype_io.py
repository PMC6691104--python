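"""Genotype container, PLINK/VCF text I/O, QC filters and LD pruning.

The central container is :class:`GenotypeMatrix`: a samples x SNPs dosage
table (values 0/1/2, ``NaN`` for missing) carrying per-SNP coordinates
(chromosome, bp 1-based, cM) and per-sample population labels.

QC follows the conventional filter order: SNP missingness (GENO), then
sample missingness (MIND), then invariant SNPs.  LD pruning is the sliding
50-SNP / 5-step greedy r^2 filter computed on genotype dosages
(composite LD, phase-free), with the later SNP of an offending pair
removed — deterministic and idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import GeneticMap


class GenotypeMatrix:
    """Diploid dosage matrix with SNP and sample metadata.

    dosage : (n_samples, n_snps) float array with values {0, 1, 2, NaN}.
    snps : DataFrame with columns id, chrom, bp, cm (and optional a1, a2).
    samples : DataFrame with columns id, label (label may be "unknown").
    """

    def __init__(self, dosage, snps: pd.DataFrame, samples: pd.DataFrame):
        self.dosage = np.asarray(dosage, dtype=float)
        self.snps = snps.reset_index(drop=True)
        self.samples = samples.reset_index(drop=True)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise ValueError("dosage shape does not match metadata")
        if "a1" not in self.snps:
            self.snps = self.snps.assign(a1="1", a2="2")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def genetic_map(self) -> GeneticMap:
        return GeneticMap(self.snps["chrom"].to_numpy(),
                          self.snps["bp"].to_numpy(),
                          self.snps["cm"].to_numpy())

    def subset_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(self.dosage[:, index],
                              self.snps.iloc[index], self.samples)

    def subset_samples(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(self.dosage[index],
                              self.snps, self.samples.iloc[index])

    def samples_with_label(self, label) -> np.ndarray:
        return np.flatnonzero(self.samples["label"].to_numpy() == label)

    def snp_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        return np.isnan(self.dosage).mean(axis=1)


# ---------------------------------------------------------------------------
# QC report and filters
# ---------------------------------------------------------------------------

@dataclass
class QCStage:
    name: str
    axis: str          # "snps" or "samples"
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class QCReport:
    stages: list = field(default_factory=list)

    def add(self, name, axis, n_in, n_removed):
        self.stages.append(QCStage(name, axis, int(n_in), int(n_removed)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([(s.name, s.axis, s.n_in, s.n_removed, s.n_out)
                             for s in self.stages],
                            columns=["stage", "axis", "n_in", "n_removed", "n_out"])

    def check_arithmetic(self) -> bool:
        """in - removed = out at every stage, and stages chain per axis."""
        last = {}
        for s in self.stages:
            if s.n_out != s.n_in - s.n_removed or s.n_removed < 0:
                return False
            if s.axis in last and s.n_in != last[s.axis]:
                return False
            last[s.axis] = s.n_out
        return True


@dataclass
class ArrayAccounting:
    """Pre-genotyping array accounting: positions lost to mapping filters."""

    n_total: int = 62_897
    n_unmapped: int = 704
    n_x_linked: int = 2_724

    @property
    def n_autosomal(self) -> int:
        return self.n_total - self.n_unmapped - self.n_x_linked


def snp_array_accounting(n_total=62_897, n_unmapped=704, n_x_linked=2_724) -> ArrayAccounting:
    """Report utility: autosomal SNP count after removing unmapped and
    X-linked array positions (defaults are the 63k cat array's counts)."""
    acc = ArrayAccounting(n_total, n_unmapped, n_x_linked)
    if acc.n_autosomal < 0:
        raise ValueError("removed more SNPs than the array contains")
    return acc


def filter_qc(G: GenotypeMatrix, geno=0.2, mind=0.2, drop_invariant=True):
    """Apply SNP-missingness, sample-missingness and invariant filters.

    Returns (filtered GenotypeMatrix, QCReport).  SNPs with missing
    fraction > ``geno`` go first, then samples with missing fraction >
    ``mind``, then SNPs with a single observed allele.
    """
    for t in (geno, mind):
        if not (0 <= t <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
    report = QCReport()
    keep_snp = G.snp_missing_rate() <= geno
    report.add("GENO", "snps", G.n_snps, (~keep_snp).sum())
    G = G.subset_snps(np.flatnonzero(keep_snp))

    keep_sample = G.sample_missing_rate() <= mind
    report.add("MIND", "samples", G.n_samples, (~keep_sample).sum())
    G = G.subset_samples(np.flatnonzero(keep_sample))

    if drop_invariant:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mn = np.nanmin(G.dosage, axis=0) if G.n_samples else np.zeros(G.n_snps)
            mx = np.nanmax(G.dosage, axis=0) if G.n_samples else np.zeros(G.n_snps)
        # single observed allele: all calls 0 or all calls 2
        variant = ~((mn == mx) & np.isin(mn, (0.0, 2.0))) & ~np.isnan(mn)
        report.add("invariant", "snps", G.n_snps, (~variant).sum())
        G = G.subset_snps(np.flatnonzero(variant))
    if G.n_snps == 0:
        raise ValueError("QC removed every SNP")
    return G, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _r2_matrix(X) -> np.ndarray:
    """Squared Pearson correlation of dosage columns, pairwise-complete."""
    if np.isnan(X).any():
        r = pd.DataFrame(X).corr(min_periods=2).to_numpy()
    else:
        sd = X.std(axis=0)
        ok = sd > 0
        r = np.zeros((X.shape[1], X.shape[1]))
        if ok.any():
            r[np.ix_(ok, ok)] = np.corrcoef(X[:, ok], rowvar=False)
    return np.nan_to_num(r) ** 2


def ld_prune(G: GenotypeMatrix, r2_max=0.5, window=50, step=5) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns kept SNP indices.

    Within each ``window``-SNP window (never spanning a chromosome
    boundary) the later SNP of any pair with r^2 > ``r2_max`` is removed;
    windows slide by ``step`` and passes repeat until stable.
    """
    if not (window > step >= 1):
        raise ValueError("require window > step >= 1")
    kept_all = []
    chroms = G.snps["chrom"].to_numpy()
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        changed = True
        while changed:
            changed = False
            snap = idx.copy()
            alive = np.ones(len(snap), dtype=bool)
            for start in range(0, max(len(snap) - 1, 1), step):
                sel = np.flatnonzero(alive[start:start + window]) + start
                if len(sel) < 2:
                    continue
                r2 = _r2_matrix(G.dosage[:, snap[sel]])
                for i in range(len(sel)):
                    if not alive[sel[i]]:
                        continue
                    for j in range(i + 1, len(sel)):
                        if alive[sel[j]] and r2[i, j] > r2_max:
                            alive[sel[j]] = False
                            changed = True
            idx = snap[alive]
        kept_all.append(idx)
    return np.concatenate(kept_all)


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def allele_frequencies(G: GenotypeMatrix, by_label=True) -> pd.DataFrame:
    """Per-population counted-allele frequencies.

    p = dosage sum / (2 * non-missing count); SNPs with zero non-missing
    calls in a population get NaN (undefined, to be excluded downstream).
    Returns a DataFrame indexed like G.snps with columns ``p_<label>`` and
    ``n_<label>`` (diploid sample counts used).
    """
    out = {}
    groups = ([(lab, G.samples_with_label(lab))
               for lab in pd.unique(G.samples["label"])]
              if by_label else [("all", np.arange(G.n_samples))])
    for lab, rows in groups:
        sub = G.dosage[rows]
        n_called = (~np.isnan(sub)).sum(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            p = np.nansum(sub, axis=0) / (2.0 * n_called)
        p[n_called == 0] = np.nan
        out[f"p_{lab}"] = p
        out[f"n_{lab}"] = n_called
    return pd.DataFrame(out, index=G.snps["id"])


# ---------------------------------------------------------------------------
# PLINK text dialect
# ---------------------------------------------------------------------------

def write_plink(G: GenotypeMatrix, prefix):
    """Write .ped/.map text files (map: chrom, id, cM, bp).

    Genotypes are written with the SNP's allele pair; missing is "0 0";
    the counted allele is ``a2``.
    """
    self_snps = G.snps
    with open(f"{prefix}.map", "w") as fh:
        for _, s in self_snps.iterrows():
            fh.write(f"{s['chrom']}\t{s['id']}\t{s['cm']:.6f}\t{s['bp']}\n")
    a1 = self_snps["a1"].to_numpy().astype(str)
    a2 = self_snps["a2"].to_numpy().astype(str)
    with open(f"{prefix}.ped", "w") as fh:
        for i, sid in enumerate(G.samples["id"]):
            row = G.dosage[i]
            geno = np.empty(len(row), dtype=object)
            geno[np.isnan(row)] = "0 0"
            geno[row == 0] = [f"{a} {a}" for a in a1[row == 0]]
            geno[row == 1] = [f"{a} {b}" for a, b in zip(a1[row == 1], a2[row == 1])]
            geno[row == 2] = [f"{b} {b}" for b in a2[row == 2]]
            fh.write(f"{sid} {sid} 0 0 0 -9 " + " ".join(geno) + "\n")


def _read_labels(labels_path, sample_ids):
    labels = pd.read_csv(labels_path, sep="\t", header=None,
                         names=["id", "label"], dtype=str)
    lut = dict(zip(labels["id"], labels["label"]))
    out = []
    for sid in sample_ids:
        if sid not in lut:
            warnings.warn(f"sample {sid!r} missing from label file; labelled 'unknown'")
        out.append(lut.get(sid, "unknown"))
    return out


def read_plink(prefix, labels_path=None) -> GenotypeMatrix:
    """Read a .ped/.map pair.  The counted allele per SNP is the
    lexicographically later of the two observed alleles (so "1"/"2" coding
    counts allele 2); "0 0" is missing."""
    snps = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None,
                       names=["chrom", "id", "cm", "bp"])
    n_snps = len(snps)
    sample_ids, rows = [], []
    with open(f"{prefix}.ped") as fh:
        for ln, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(f"{prefix}.ped line {ln}: expected "
                                 f"{6 + 2 * n_snps} fields, got {len(parts)}")
            sample_ids.append(parts[1])
            rows.append(parts[6:])
    alleles = np.array(rows, dtype=object).reshape(len(rows), n_snps, 2) \
        if rows else np.empty((0, n_snps, 2), dtype=object)
    dosage = np.full((len(rows), n_snps), np.nan)
    a1_list, a2_list = [], []
    for j in range(n_snps):
        col = alleles[:, j, :] if len(rows) else np.empty((0, 2), dtype=object)
        obs = sorted(a for a in pd.unique(col.ravel()) if a != "0")
        if len(obs) == 2:
            a1, a2 = obs
        elif len(obs) == 1:
            # monomorphic: keep the observed allele on the side it was seen
            a1, a2 = ("1", obs[0]) if obs[0] != "1" else ("1", "2")
        else:
            a1, a2 = "1", "2"
        a1_list.append(a1)
        a2_list.append(a2)
        if len(rows):
            miss = (col == "0").any(axis=1)
            d = (col == a2).sum(axis=1).astype(float)
            d[miss] = np.nan
            dosage[:, j] = d
    snps = snps.assign(a1=a1_list, a2=a2_list)
    samples = pd.DataFrame({"id": sample_ids})
    samples["label"] = (_read_labels(labels_path, sample_ids)
                        if labels_path else "unknown")
    return GenotypeMatrix(dosage, snps, samples)


def read_vcf(path, labels_path=None, cm_per_mb=1.0) -> GenotypeMatrix:
    """Read a (plain or bgzipped) VCF; dosage counts the first ALT allele.

    VCFs carry no genetic-map column, so cM is derived from bp at a
    constant ``cm_per_mb`` rate (override or attach a real map upstream).
    """
    from cyvcf2 import VCF
    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    ids, chroms, bps, rows = [], [], [], []
    for v in vcf:
        gts = np.array([[a, b] for a, b, *_ in v.genotypes], dtype=float)
        dos = (gts == 1).sum(axis=1).astype(float)
        dos[(gts < 0).any(axis=1)] = np.nan
        rows.append(dos)
        ids.append(v.ID if v.ID else f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        bps.append(v.POS)
    dosage = np.array(rows).T if rows else np.empty((len(sample_ids), 0))
    chrom_arr = pd.Series(chroms)
    chrom_num = pd.to_numeric(chrom_arr.str.replace("chr", "", regex=False),
                              errors="coerce")
    snps = pd.DataFrame({
        "id": ids,
        "chrom": chrom_num.fillna(0).astype(int) if chrom_num.notna().all() else chroms,
        "bp": bps,
    })
    snps["cm"] = snps["bp"] * cm_per_mb / 1e6
    samples = pd.DataFrame({"id": sample_ids})
    samples["label"] = (_read_labels(labels_path, sample_ids)
                        if labels_path else "unknown")
    return GenotypeMatrix(dosage, snps, samples)


def load_genotypes(path, format="plink", labels_path=None) -> GenotypeMatrix:
    """Dispatch loader: ``format`` is "plink" (path = prefix) or "vcf"."""
    if format == "plink":
        return read_plink(path, labels_path)
    if format == "vcf":
        return read_vcf(path, labels_path)
    raise ValueError("format must be 'plink' or 'vcf'")
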