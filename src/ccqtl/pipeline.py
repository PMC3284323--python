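"""End-to-end orchestration: simulate -> infer -> scan -> narrow -> phylo
-> strain stats, with deterministic per-stage seeding and a JSON report."""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, io, narrow, phylo, scan, simulate, strain_stats
from .core import DEFAULT_FOUNDERS, FounderPanel, PhenotypeTable, QtlSpec


@dataclass
class RunConfig:
    """Everything a full synthetic run needs; round-trips through JSON."""

    seed: int = 1
    n_snps: int = 4000
    n_lines: int = 80
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"1": 60_000_000, "2": 60_000_000}
    )
    trait: str = "MCV"
    qtl_chrom: str = "1"
    qtl_pos: int = 30_000_000
    qtl_group: list[str] = field(
        default_factory=lambda: ["C57BL6J", "NODShiLtJ", "NZOHlLtJ"]
    )
    qtl_effect: float = 8.0
    qtl_dominance: float = 0.5
    qtl_h2: float = 0.4
    ibd_block_kb: float = 1000.0
    baseline: float = 50.0
    n_perm: int = 200
    alpha: float = 0.05
    lod_drop: float = 1.5
    identity_threshold: float = 0.98
    min_snps: int = 20
    n_bootstraps: int = 100
    error_rate: float = 0.002
    switch_rate: float = 1e-7
    use_hmm_ancestry: bool = True
    # per-stage seeds; derived from `seed` when left at None
    stage_seeds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        stages = ["founders", "lines", "genotyping", "phenotypes",
                  "permutation", "bootstrap", "strains"]
        if not self.stage_seeds:
            ss = np.random.SeedSequence(self.seed)
            children = ss.spawn(len(stages))
            self.stage_seeds = {
                name: int(child.generate_state(1)[0] % (2**31 - 1))
                for name, child in zip(stages, children)
            }

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def write_dosages_tsv(path, dosage_matrices, founder_names) -> None:
    frames = []
    for dm in dosage_matrices:
        df = dm.intervals.copy()
        df.insert(0, "line", dm.line_id)
        for k, name in enumerate(founder_names):
            df[name] = dm.dosages[:, k]
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_dosages_tsv(path, founder_names):
    """Returns (line_ids, intervals DataFrame, (N, I, 8) array)."""
    df = pd.read_csv(path, sep="\t")
    line_ids = list(dict.fromkeys(df["line"]))
    first = df[df["line"] == line_ids[0]]
    intervals = first[["chrom", "start", "end"]].reset_index(drop=True)
    intervals["chrom"] = intervals["chrom"].astype(str)
    X = np.stack([
        df[df["line"] == lid][list(founder_names)].to_numpy(dtype=float)
        for lid in line_ids
    ])
    return line_ids, intervals, X


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run the whole synthetic analysis and write all artifacts to
    ``outdir``.  Returns the report dict (also written as report.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds
    report: dict = {"config": config.to_dict(), "stages": []}

    def stage(name):
        report["stages"].append(name)

    # --- simulate -----------------------------------------------------
    stage("simulate")
    panel = simulate.simulate_founders(
        config.n_snps, chrom_lengths=config.chrom_lengths, seed=seeds["founders"]
    )
    if config.ibd_block_kb > 0:
        half = int(config.ibd_block_kb * 500)
        panel = simulate.plant_ibd_block(
            panel, config.qtl_chrom,
            max(1, config.qtl_pos - half), config.qtl_pos + half,
            set(config.qtl_group),
        )
    gmap = simulate.GeneticMap(chrom_lengths=dict(panel.chrom_lengths))
    mosaics = simulate.simulate_panel_lines(
        panel, config.n_lines, gmap, seed=seeds["lines"]
    )
    qtl = QtlSpec(
        chrom=config.qtl_chrom,
        pos=config.qtl_pos,
        functional_group=frozenset(config.qtl_group),
        effect_size=config.qtl_effect,
        dominance=config.qtl_dominance,
        h2_target=config.qtl_h2,
    )
    phenos = simulate.assign_phenotypes(
        panel, mosaics, [qtl], baseline=config.baseline,
        trait=config.trait, units="fL", seed=seeds["phenotypes"],
    )
    geno = simulate.genotype_lines(panel, mosaics, seed=seeds["genotyping"])
    line_ids = [m.line_id for m in mosaics]

    io.write_vcf(outdir / "founders.vcf", panel.founder_names, panel.chrom,
                 panel.pos, panel.genotypes, panel.chrom_lengths)
    io.write_vcf(outdir / "lines.vcf", line_ids, panel.chrom, panel.pos,
                 geno, panel.chrom_lengths, diploid_codes=True)
    io.write_phenotypes_csv(outdir / "phenotypes.csv", phenos)

    # --- ancestry ------------------------------------------------------
    stage("ancestry")
    if config.use_hmm_ancestry:
        dms, map_states = ancestry.infer_ancestry_all(
            geno, panel, line_ids=line_ids,
            error_rate=config.error_rate, switch_rate=config.switch_rate,
        )
        iset, collapsed = ancestry.collapse_intervals(dms, map_states, panel)
    else:
        iset, X_true = simulate.true_dosages(panel, mosaics)
        collapsed = [
            ancestry.DosageMatrix(line_id=lid, intervals=iset.intervals,
                                  dosages=X_true[i])
            for i, lid in enumerate(line_ids)
        ]
    X = ancestry.dosage_stack(collapsed)
    intervals = collapsed[0].intervals
    write_dosages_tsv(outdir / "dosages.tsv", collapsed, panel.founder_names)
    report["n_intervals"] = int(len(intervals))

    # --- scan ----------------------------------------------------------
    stage("scan")
    y = phenos.trait(config.trait)
    curve = scan.scan_trait(X, intervals, y, line_ids)
    threshold = scan.permutation_threshold(
        X, intervals, y, line_ids, n_perm=config.n_perm,
        alpha=config.alpha, seed=seeds["permutation"],
    )
    peak = curve.peak_index
    ci_start, ci_end = scan.lod_drop_interval(curve, peak, drop=config.lod_drop)
    effects = scan.allele_effects(X[:, peak, :], y, line_ids)
    qtl_result = scan.QtlResult(
        trait=config.trait,
        name=f"{config.trait.lower()}q1",
        chrom=str(intervals["chrom"].iloc[peak]),
        peak_pos=int(intervals["start"].iloc[peak]),
        peak_lod=float(curve.lod[peak]),
        ci_start=ci_start,
        ci_end=ci_end,
        threshold_95=threshold,
        allele_effects=effects,
    )
    pd.DataFrame({
        "chrom": intervals["chrom"], "start": intervals["start"],
        "end": intervals["end"], "lod": curve.lod,
    }).to_csv(outdir / "lod_curve.tsv", sep="\t", index=False)
    io.write_qtl_table(outdir / "qtl_table.tsv", [qtl_result])
    report["qtl"] = {
        "name": qtl_result.name,
        "chrom": qtl_result.chrom,
        "peak_pos": qtl_result.peak_pos,
        "peak_lod": round(qtl_result.peak_lod, 2),
        "threshold_95": round(threshold, 2),
        "ci_start": ci_start,
        "ci_end": ci_end,
        "ci_size_mb": qtl_result.ci_size_mb,
        "significant": bool(qtl_result.peak_lod >= threshold),
        "allele_effects": {
            n: round(float(e), 3)
            for n, e in zip(panel.founder_names, effects)
        },
    }

    # --- narrow ---------------------------------------------------------
    stage("narrow")
    grouping = narrow.group_alleles(effects, panel.founder_names)
    ci = (qtl_result.chrom, ci_start, ci_end)
    regions = {}
    for label, grp in (("high", grouping.group_a), ("low", grouping.group_b)):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            regions[label] = narrow.shared_ancestry_regions(
                panel, ci, grp,
                identity_threshold=config.identity_threshold,
                min_snps=config.min_snps,
            )
    all_regions = [r for rs in regions.values() for r in rs]
    io.write_regions_bed(outdir / "shared_regions.bed", all_regions)
    exclusive = [r for r in all_regions if r.exclusive]
    report["grouping"] = {
        "high": sorted(grouping.group_a),
        "low": sorted(grouping.group_b),
        "ambiguous": sorted(grouping.ambiguous),
        "split_gap": round(grouping.split_gap, 3),
    }
    candidate = None
    if exclusive:
        candidate = max(exclusive, key=lambda r: r.n_snps)
        rep = narrow.reduction_report((ci_start, ci_end),
                                      (candidate.start, candidate.end))
        report["reduction"] = {
            "full_size_mb": rep.full_size_mb,
            "candidate_size_mb": rep.candidate_size_mb,
            "candidate_start": candidate.start,
            "candidate_end": candidate.end,
            "percent_reduction": rep.percent_reduction,
        }

    # --- phylo ----------------------------------------------------------
    stage("phylo")
    if candidate is not None:
        region = (candidate.chrom, candidate.start, candidate.end)
    else:
        region = ci
    aln = phylo.build_alignment(panel, region)
    tree = phylo.bootstrap_support(aln, n=config.n_bootstraps,
                                   seed=seeds["bootstrap"])
    io.write_tree(outdir / "candidate_region.nwk", tree.newick)
    report["tree"] = {
        "n_sites": aln.n_sites,
        "n_bootstraps": tree.n_bootstraps,
        "newick": tree.newick,
    }

    # --- strain stats ----------------------------------------------------
    stage("strain_stats")
    group_idx = {panel.founder_index(n) for n in qtl.functional_group}
    strain_means = {
        name: config.baseline + (qtl.effect_size if i in group_idx else 0.0)
        for i, name in enumerate(panel.founder_names)
    }
    noise_sd = float(np.std(phenos.data["value"])) * 0.3
    samples = strain_stats.simulate_strain_samples(
        strain_means, sigma_within=max(noise_sd, 1e-6),
        n_replicates=8, seed=seeds["strains"],
    )
    anova = strain_stats.strain_anova(samples)
    herit = strain_stats.heritability(samples)
    classes = []
    for m in mosaics:
        fa, fb = m.founders_at(qtl.chrom, qtl.pos)
        copies = (fa in group_idx) + (fb in group_idx)
        classes.append(("low", "het", "high")[copies])
    r2 = strain_stats.variance_explained(
        np.array(classes), phenos.trait(config.trait).to_numpy()
    )
    report["strain_stats"] = {
        "anova_F": round(anova.f_stat, 2),
        "anova_p": float(anova.p_value),
        "r1": round(herit.r1, 3),
        "g2": round(herit.g2, 3),
        "qtl_variance_explained_pct": round(100.0 * r2, 1),
        "realized_h2": round(phenos.realized_h2[config.trait], 3),
    }

    # --- manifest --------------------------------------------------------
    manifest = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "report.json" or p.is_dir():
            continue
        manifest[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    report["manifest"] = manifest
    io.write_params_json(outdir / "report.json", report)
    return report
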