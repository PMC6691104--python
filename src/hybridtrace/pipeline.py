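"""End-to-end pipeline: one configuration, one run directory, one summary.

Stages run in the fixed order qc -> global ancestry (K sweep + supervised
K = 2) -> q-threshold classification -> f3 -> local ancestry -> dating
(switch counts and weighted LD) -> ancestry scans -> AIM panels.  A single
seed fans out to per-stage seeds by fixed offsets so each stage is
individually reproducible; identical config + seed yields byte-identical
summary tables.

Input is either a simulated study (the built-in generator) or a PLINK/VCF
dataset with a label file; phased haplotypes for local ancestry come from
the simulator's truth phase (real data must be pre-phased upstream).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (aim_panel, ancestry_scan, dating, genotype_io,
               global_ancestry, local_ancestry, simdata)

_STAGE_SEED_OFFSETS = {"simulate": 1, "qc": 2, "global": 3, "local": 4,
                       "dating": 5, "scan": 6, "panel": 7}


@dataclass
class RunConfig:
    """Typed run configuration; unknown keys are rejected on parse."""

    out_dir: str = "hybridtrace_run"
    seed: int = 0
    # simulated-study parameters
    simulate: bool = True
    n_snps: int = 5000
    fst: float = 0.9
    n_chromosomes: int = 18
    map_morgans: float = 30.0
    n_wc: int = 57
    n_dc: int = 44
    n_hyb: int = 45
    g_min: int = 1
    g_max: int = 6
    # real-data input
    input_prefix: str = ""
    input_format: str = "plink"
    labels_path: str = ""
    # qc
    geno: float = 0.2
    mind: float = 0.2
    ld_r2: float = 0.5
    ld_window: int = 50
    ld_step: int = 5
    # global ancestry
    k_max: int = 3
    cv_folds: int = 5
    f3_block_snps: int = 20
    # local ancestry
    window_snps: int = 20
    n_pcs: int = 2
    hmm_switch_per_cm: float = 0.01
    self_check_n: int = 5
    # dating
    g_grid_max: int = 30
    n_sims: int = 300
    generation_time: float = 2.0
    sampling_year: float | None = None
    # scan
    tail: float = 0.01
    fdr: float = 0.05
    n_null: int = 20000
    flank_bp: int = 100000
    annotation: str = ""
    # panels
    panel_sizes: tuple = (192, 96, 48)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain-text key = value configuration file."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"line {ln}: expected key = value")
            key, val = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"line {ln}: unknown configuration key {key!r}")
            typ = fields[key].type
            if key == "panel_sizes":
                kwargs[key] = tuple(int(x) for x in val.split(","))
            elif typ == "bool":
                kwargs[key] = val.lower() in ("1", "true", "yes")
            elif typ == "int":
                kwargs[key] = int(val)
            elif typ in ("float", "float | None"):
                kwargs[key] = float(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def stage_seed(self, stage) -> int:
        return (int(self.seed) * 131 + _STAGE_SEED_OFFSETS[stage]) % (2 ** 31)


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_full(config: RunConfig) -> dict:
    """Execute the whole analysis; returns the machine-readable summary
    (also written to ``<out_dir>/summary.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {"seed": int(config.seed)}
    log = [f"seed={config.seed}"]
    stage = "simulate"
    try:
        # --- input ------------------------------------------------------
        if config.simulate:
            rng_seed = config.stage_seed("simulate")
            model = simdata.generate_parental_frequencies(
                config.n_snps, config.fst, seed=rng_seed)
            gmap = simdata.GeneticMap.uniform(
                config.n_snps, config.n_chromosomes, config.map_morgans,
                seed=rng_seed + 1)
            panels = simdata.sample_reference_genotypes(
                model, gmap, config.n_wc, config.n_dc, seed=rng_seed + 2)
            designs = [simdata.PedigreeSpec(
                design="F1" if g == 1 else f"BC{g}", recurrent="WC")
                for g in np.resize(np.arange(config.g_min, config.g_max + 1),
                                   config.n_hyb)]
            hyb_haps, truth = simdata.simulate_cohort(
                model, gmap, designs, seed=rng_seed + 3)
            Gref = panels.genotype_matrix()
            hyb_dosage = (hyb_haps[0::2] + hyb_haps[1::2]).astype(float)
            hyb_samples = pd.DataFrame({"id": truth.sample_ids,
                                        "label": "HYB"})
            G = genotype_io.GenotypeMatrix(
                np.vstack([Gref.dosage, hyb_dosage]), Gref.snps,
                pd.concat([Gref.samples, hyb_samples], ignore_index=True))
            summary["m_true_mean"] = float(truth.m_true().mean())
        else:
            G = genotype_io.load_genotypes(config.input_prefix,
                                           config.input_format,
                                           config.labels_path or None)
            gmap = G.genetic_map()
            panels = truth = hyb_haps = None

        # --- qc ---------------------------------------------------------
        stage = "qc"
        G, qc_report = genotype_io.filter_qc(G, config.geno, config.mind)
        _write(qc_report.to_frame(), out / "qc_report.tsv")
        kept = genotype_io.ld_prune(G, config.ld_r2, config.ld_window,
                                    config.ld_step)
        summary["n_snps_qc"] = int(G.n_snps)
        summary["n_snps_ld_pruned"] = int(len(kept))
        G_ld = G.subset_snps(kept)

        # --- global ancestry ---------------------------------------------
        stage = "global"
        seed_g = config.stage_seed("global")
        pca = global_ancestry.run_pca(G, n_components=2)
        _write(pd.DataFrame({"sample": pca.sample_ids,
                             "PC1": pca.scores[:, 0], "PC2": pca.scores[:, 1]}),
               out / "pca_scores.tsv")
        summary["pca_var_pc1_pc2"] = float(pca.variance_fraction[:2].sum())
        cv = global_ancestry.cross_validation_error(
            G_ld, range(1, config.k_max + 1), folds=config.cv_folds,
            seed=seed_g, n_starts=1, max_iter=100)
        _write(pd.DataFrame({"K": list(cv), "cv_error": list(cv.values())}),
               out / "cv_error.tsv")
        summary["best_K"] = int(min(cv, key=cv.get))
        model2 = global_ancestry.fit_admixture(
            G_ld, 2, supervised_labels={"WC": 0, "DC": 1}, seed=seed_g)
        qw = model2.q_w
        classes = global_ancestry.classify_by_qw(qw)
        _write(pd.DataFrame({"sample": G_ld.samples["id"], "q_w": qw,
                             "class": classes}), out / "global_qw.tsv")
        summary["n_admixed"] = int((classes == "admixed").sum())
        f3 = global_ancestry.f3_test(G, "HYB", "WC", "DC",
                                     block_snps=config.f3_block_snps) \
            if (G.samples["label"] == "HYB").any() else None
        if f3:
            summary["f3_z"] = float(f3.z)

        # --- local ancestry ----------------------------------------------
        stage = "local"
        if panels is None:
            raise ValueError("local ancestry requires phased input "
                             "(simulate mode provides truth phase)")
        windows = local_ancestry.partition_windows(gmap, config.window_snps)
        calls = local_ancestry.assign_window_ancestry(
            panels.wc_haps, panels.dc_haps, hyb_haps, gmap, windows,
            hmm_switch_per_cm=config.hmm_switch_per_cm, n_pcs=config.n_pcs,
            sample_ids=truth.sample_ids)
        local_summary = calls.summary()
        _write(local_summary, out / "local_summary.tsv")
        summary["q_d_blocks_mean"] = float(local_summary["q_d_blocks"].mean())
        check = local_ancestry.reference_self_check(
            panels.wc_haps, panels.dc_haps, gmap, windows,
            n_per_pop=config.self_check_n, seed=config.stage_seed("local"))
        _write(check, out / "self_check.tsv")
        summary["self_check_max_switches"] = int(check["switches"].max()) \
            if len(check) else 0

        # --- dating -------------------------------------------------------
        stage = "dating"
        m_hat = float(np.clip(local_summary["q_d_blocks"].median(), 0.01, 0.99))
        sw_model = dating.build_switch_model(
            m_hat, windows, gmap, g_grid=range(1, config.g_grid_max + 1),
            n_sims=config.n_sims, mating_model="pedigree",
            seed=config.stage_seed("dating"))
        dates = [dating.date_from_switches(
            int(s), sw_model, config.generation_time, config.sampling_year)
            for s in local_summary["S"]]
        date_tab = pd.DataFrame({
            "sample": local_summary["sample"],
            "S": local_summary["S"],
            "g_hat": [d.g_hat for d in dates],
            "g_low": [d.ci_low for d in dates],
            "g_high": [d.ci_high for d in dates],
            "years": [d.years for d in dates],
            "g_closed_form": [dating.closed_form_generations(
                int(s), max(q, 0.01), gmap.length_morgans)
                for s, q in zip(local_summary["S"], local_summary["q_d_blocks"])],
        })
        _write(date_tab, out / "dating_switches.tsv")
        summary["g_hat_median"] = float(date_tab["g_hat"].median())
        hyb_dosage_full = (hyb_haps[0::2] + hyb_haps[1::2]).astype(float)
        freqs = genotype_io.allele_frequencies(panels.genotype_matrix())
        curve = dating.weighted_ld_curve(
            hyb_dosage_full, freqs["p_WC"].to_numpy(),
            freqs["p_DC"].to_numpy(), gmap)
        try:
            fit = dating.fit_ld_decay(curve)
            summary["ld_n_hat"] = float(fit.n_hat)
            summary["ld_p"] = fit.p_value
        except ValueError:
            summary["ld_n_hat"] = None

        # --- scans --------------------------------------------------------
        stage = "scan"
        bf = ancestry_scan.block_ancestry_frequencies(calls)
        tails = ancestry_scan.select_outlier_blocks(bf, tail=config.tail)
        tails.to_bed_frame().to_csv(out / "block_tail_regions.bed", sep="\t",
                                    header=False, index=False)
        summary["n_tail_regions"] = int(len(tails))
        scan = ancestry_scan.fst_outlier_scan(
            G.subset_samples(G.samples["label"].to_numpy() == "HYB"),
            G.subset_samples(G.samples["label"].to_numpy() == "WC"),
            fdr=config.fdr, n_null=config.n_null,
            seed=config.stage_seed("scan"))
        summary["n_fst_outliers"] = int(scan["outlier"].sum())
        regions = ancestry_scan.build_regions(scan[scan["outlier"]],
                                              flank_bp=config.flank_bp)
        regions.to_bed_frame().to_csv(out / "fst_outlier_regions.bed",
                                      sep="\t", header=False, index=False)
        if config.annotation:
            both = ancestry_scan.OutlierRegionSet(
                pd.concat([tails.regions, regions.regions], ignore_index=True))
            mapped, flat = ancestry_scan.map_genes(both, config.annotation)
            _write(flat, out / "outlier_genes.tsv")
            summary["n_outlier_genes"] = int(len(flat))

        # --- panels -------------------------------------------------------
        stage = "panel"
        scores = aim_panel.score_markers(G)
        _write(scores.table, out / "marker_scores.tsv")
        kept_ids = set(G.snps["id"].to_numpy()[kept])
        evals = {}
        for size in sorted(config.panel_sizes):
            if len(scores) < size:
                continue
            panel = aim_panel.select_panel(scores, size, "fst",
                                           ld_keep_ids=kept_ids)
            ev = aim_panel.evaluate_panel(panel, G, model2,
                                          seed=config.stage_seed("panel"))
            evals[size] = ev
        if evals:
            _write(pd.DataFrame([{
                "size": s, "panel_fst": e.panel_fst,
                "mean_wc_qw": e.mean_wc_qw, "min_wc_qw": e.min_wc_qw,
                "wc_misclassified": e.n_wc_misclassified,
                "hyb_misclassified": e.n_hyb_misclassified,
                "pct_hyb_identified": e.pct_hyb_identified,
                "pid_wc": e.pid_wc, "pid_sib_wc": e.pid_sib_wc,
                "r2_vs_full": e.r2_vs_full} for s, e in evals.items()]),
                out / "panel_evaluation.tsv")
            summary["panel_sizes_evaluated"] = sorted(evals)
    except Exception as err:
        (out / "run.log").write_text("\n".join(log + [f"FAILED at {stage}: {err}"]))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    (out / "run.log").write_text("\n".join(
        log + [f"{k}={v}" for k, v in dataclasses.asdict(config).items()]))
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
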