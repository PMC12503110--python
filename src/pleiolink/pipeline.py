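"""End-to-end orchestration: simulate → structure → de → gsea → organismal →
correlate, with a validated config, per-stage seeds, manifests, and
deterministic outputs.

A single master seed deterministically derives one seed per stage (keyed by
stage name), so any stage can be rerun in isolation and reproduce its
output bit for bit. Every output table carries a commented metadata header
echoing the thresholds that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import crosslevel, gsea, organismal, simulate, transcriptome
from . import structures as structmod
from ._util import stage_seed, write_table

log = logging.getLogger("pleiolink")


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    min_rowsum: int = 10
    lfc_thresh: float = 1.0
    alpha: float = 0.05
    gate_r2: float = 0.3
    gate_fdr: float = 0.05
    n_perm_permanova: int = 9999
    n_perm_gsea: int = 1000
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    negligible_band: float = 0.5
    na_rep_atom: str = "C1'"
    t_max_h: float = 24.0
    min_intersection: int = 5
    link_slope: float = 8.0
    link_r2_true: float = 0.9

    def thresholds(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name not in ("out_dir", "seed")}


def validate_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> PipelineConfig:
    """Load and validate a YAML config; errors are aggregated, not first-failure."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
    raw.update(overrides or {})
    known = {f.name: f for f in fields(PipelineConfig)}
    errors = []
    for key, value in raw.items():
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    checks = {
        "alpha": lambda v: 0 < v < 1,
        "gate_fdr": lambda v: 0 < v < 1,
        "gate_r2": lambda v: 0 <= v < 1,
        "min_rowsum": lambda v: v >= 0,
        "lfc_thresh": lambda v: v >= 0,
        "n_perm_permanova": lambda v: v >= 1,
        "n_perm_gsea": lambda v: v >= 100,
        "negligible_band": lambda v: v > 0,
        "t_max_h": lambda v: v > 0,
    }
    cfg_kwargs = {}
    for key, value in raw.items():
        if key not in known:
            continue
        expected = known[key].type
        try:
            if expected in ("int", int):
                value = int(value)
            elif expected in ("float", float):
                value = float(value)
        except (TypeError, ValueError):
            errors.append(f"config key {key!r}: bad type {type(value).__name__}")
            continue
        if key in checks and not checks[key](value):
            errors.append(f"config key {key!r}: value {value!r} out of range")
            continue
        cfg_kwargs[key] = value
    if errors:
        raise ValueError("invalid config:\n  " + "\n  ".join(errors))
    return PipelineConfig(**cfg_kwargs)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _manifest(stage_dir: Path, stage: str, seed: int, cfg: PipelineConfig,
              inputs: list[Path], row_counts: dict) -> None:
    manifest = {
        "stage": stage,
        "seed": seed,
        "thresholds": cfg.thresholds(),
        "inputs": {str(p.name): _checksum(p) for p in inputs if p.is_file()},
        "row_counts": row_counts,
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("stage %s: rows %s", stage, row_counts)


@dataclass
class PipelineResult:
    run_dir: Path
    bundle: simulate.LinkedBundle
    profile: structmod.DistanceProfile
    stability: structmod.StabilityTable
    deg_summaries: dict
    de_results: dict
    permanova: transcriptome.PermanovaResult
    updown_t: tuple
    gsea_results: dict
    fitness_delta: pd.DataFrame
    screen: list
    links: pd.DataFrame
    metrics: crosslevel.MetricTable = None


def run_all(config: PipelineConfig) -> PipelineResult:
    """Execute all stages in dependency order on a simulated linked scenario.

    Each stage writes its tables plus a JSON manifest under
    ``out_dir/<stage>/``; a stage failure propagates with the stage name.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    meta = {"master_seed": config.seed, **config.thresholds()}

    # --- simulate ------------------------------------------------------
    sim_dir = run_dir / "inputs"
    bundle = simulate.gen_linked_scenario(
        config.seed, slope=config.link_slope, r2_true=config.link_r2_true,
        out_dir=sim_dir)

    # --- structure -----------------------------------------------------
    stage_dir = run_dir / "structure"
    stage_dir.mkdir(exist_ok=True)
    pdb_paths = sorted((sim_dir / "structures").glob("*.pdb"))
    models = [structmod.read_pdb(p) for p in pdb_paths]
    role_map = structmod.load_role_map(sim_dir / "structures" / "roles.tsv")
    sites = structmod.load_mutations(sim_dir / "structures" / "mutations.tsv")
    profile = structmod.distance_profile(
        models, role_map, sites, list(bundle.scenario.roles),
        na_rep_atom=config.na_rep_atom)
    structmod.write_profile(profile, stage_dir, meta)
    anova_rows = []
    for role in bundle.scenario.roles:
        F, df1, df2, p = structmod.anova_by_mutant(profile, role)
        anova_rows.append((role, F, df1, df2, p))
    anova_table = pd.DataFrame(anova_rows, columns=["role", "F", "df_between",
                                                    "df_within", "p"])
    write_table(anova_table, stage_dir / "distance_anova.tsv", meta)
    stability = structmod.load_and_classify_ddg(
        sim_dir / "structures" / "ddg.tsv", config.negligible_band)
    write_table(stability.aggregates, stage_dir / "stability.tsv",
                {**meta, "negligible_band": config.negligible_band})
    _manifest(stage_dir, "structure", stage_seed(config.seed, "structures"),
              config, pdb_paths, {"distance_records": len(profile.records)})

    # --- differential expression --------------------------------------
    stage_dir = run_dir / "de"
    stage_dir.mkdir(exist_ok=True)
    counts = transcriptome.filter_genes(bundle.counts.counts,
                                        config.min_rowsum)
    factors = transcriptome.size_factors(counts)
    de_results: dict[str, transcriptome.DEResult] = {}
    deg_summaries: dict[str, transcriptome.DEGSummary] = {}
    for genotype in bundle.scenario.genotypes:
        contrast = transcriptome.Contrast("temp_within_genotype", genotype)
        res = transcriptome.nb_wald_contrast(counts, bundle.counts.design,
                                             contrast, factors)
        de_results[genotype] = res
        deg_summaries[genotype] = transcriptome.call_degs(
            res, config.lfc_thresh, config.alpha)
        write_table(res.table.reset_index(),
                    stage_dir / f"de_{contrast.label()}.tsv", meta)
    deg_table = pd.DataFrame(
        [(g, s.n_up, s.n_down, s.n_total)
         for g, s in sorted(deg_summaries.items())],
        columns=["genotype", "n_up", "n_down", "n_total"])
    write_table(deg_table, stage_dir / "deg_summary.tsv", meta)
    mutant_sets = {g: set(deg_summaries[g].up) | set(deg_summaries[g].down)
                   for g in bundle.scenario.mutants}
    exclusive, pairwise = transcriptome.exclusive_intersections(
        mutant_sets, config.min_intersection)
    write_table(exclusive, stage_dir / "intersections_exclusive.tsv", meta)
    write_table(pairwise, stage_dir / "intersections_pairwise.tsv", meta)
    mutant_updown = {g: (deg_summaries[g].n_up, deg_summaries[g].n_down)
                     for g in sorted(deg_summaries)}
    t_stat, t_df, t_p = transcriptome.updown_paired_t(mutant_updown)
    write_table(pd.DataFrame([{"t": t_stat, "df": t_df, "p": t_p}]),
                stage_dir / "updown_t.tsv", meta)
    norm = transcriptome.normalize(counts, factors)
    dist = transcriptome.bray_curtis(norm)
    write_table(dist.reset_index(), stage_dir / "bray_curtis.tsv", meta)
    perm = transcriptome.permanova(
        dist, bundle.counts.design, n_perm=config.n_perm_permanova,
        seed=stage_seed(config.seed, "permanova"))
    write_table(perm.table, stage_dir / "permanova.tsv",
                {**meta, "n_permutations": perm.n_permutations,
                 "dropped_terms": ",".join(perm.dropped_terms)})
    _manifest(stage_dir, "de", stage_seed(config.seed, "permanova"), config,
              [], {"genes_tested": len(counts),
                   "contrasts": len(de_results)})

    # --- gsea ----------------------------------------------------------
    stage_dir = run_dir / "gsea"
    stage_dir.mkdir(exist_ok=True)
    gsea_results: dict[str, gsea.GSEAResult] = {}
    for genotype in bundle.scenario.mutants:
        ranked = gsea.rank_genes(de_results[genotype].table)
        res = gsea.gsea_preranked(
            ranked, bundle.gene_sets, n_perm=config.n_perm_gsea,
            min_size=config.gsea_min_size, max_size=config.gsea_max_size,
            seed=stage_seed(config.seed, f"gsea_{genotype}"))
        gsea_results[genotype] = res
        write_table(res.table, stage_dir / f"gsea_{genotype}_42v37.tsv", meta)
    _manifest(stage_dir, "gsea", stage_seed(config.seed, "gsea"), config, [],
              {"genotypes": len(gsea_results)})

    # --- organismal ----------------------------------------------------
    stage_dir = run_dir / "organismal"
    stage_dir.mkdir(exist_ok=True)
    fitness = organismal.summarize_fitness(bundle.curves, config.t_max_h)
    write_table(fitness, stage_dir / "fitness.tsv", meta)
    fitness_delta = organismal.delta_with_error(fitness, "mean_auc")
    write_table(fitness_delta, stage_dir / "fitness_delta.tsv", meta)
    trait_tables = []
    for assay in sorted(bundle.traits["assay"].unique()):
        summary = organismal.summarize_traits(bundle.traits, assay)
        delta = organismal.delta_with_error(summary, "mean_value")
        delta.insert(0, "assay", assay)
        trait_tables.append(delta)
        sub = bundle.traits[bundle.traits["assay"] == assay]
        F, df1, df2, p = organismal.anova_phenotype(sub)
        write_table(pd.DataFrame([{"assay": assay, "F": F, "df1": df1,
                                   "df2": df2, "p": p}]),
                    stage_dir / f"anova_{assay}.tsv", meta)
        write_table(organismal.per_genotype_temp_test(sub),
                    stage_dir / f"welch_{assay}.tsv", meta)
    write_table(pd.concat(trait_tables, ignore_index=True),
                stage_dir / "trait_deltas.tsv", meta)
    _manifest(stage_dir, "organismal", stage_seed(config.seed, "growth"),
              config, [], {"wells": bundle.curves.od.shape[1]})

    # --- correlate -----------------------------------------------------
    stage_dir = run_dir / "correlate"
    stage_dir.mkdir(exist_ok=True)
    metrics = build_metric_table(bundle.scenario.mutants, profile, stability,
                                 deg_summaries, fitness_delta)
    write_table(metrics.values.reset_index(), stage_dir / "metrics.tsv", meta)
    write_table(pd.DataFrame(sorted(metrics.levels.items()),
                             columns=["metric", "level"]),
                stage_dir / "metric_levels.tsv", meta)
    screen = crosslevel.correlation_screen(metrics, gate_r2=config.gate_r2,
                                           gate_fdr=config.gate_fdr)
    write_table(crosslevel.screen_table(screen), stage_dir / "screen.tsv",
                meta)
    links = crosslevel.link_report(screen, metrics.levels)
    write_table(links, stage_dir / "links.tsv", meta)
    _manifest(stage_dir, "correlate", 0, config, [],
              {"pairs_tested": len(screen),
               "significant": int(sum(r.significant for r in screen))})

    return PipelineResult(run_dir=run_dir, bundle=bundle, profile=profile,
                          stability=stability, deg_summaries=deg_summaries,
                          de_results=de_results, permanova=perm,
                          updown_t=(t_stat, t_df, t_p),
                          gsea_results=gsea_results,
                          fitness_delta=fitness_delta, screen=screen,
                          links=links, metrics=metrics)


def build_metric_table(mutants, profile: structmod.DistanceProfile,
                       stability: structmod.StabilityTable,
                       deg_summaries: dict,
                       fitness_delta: pd.DataFrame) -> crosslevel.MetricTable:
    """Assemble the per-genotype cross-level metric table.

    Structural metrics: per-role ensemble-mean distance, per-role
    per-structure distance, mean ΔΔG. Transcriptomic: DEG counts (total, up,
    down) of the 42 vs 37 °C contrast. Organismal: ΔAUC (42 − 37 °C).
    """
    mutants = list(mutants)
    values = pd.DataFrame(index=pd.Index(mutants, name="genotype"))
    levels: dict[str, str] = {}
    for (genotype, role), sub in profile.aggregates.groupby(
            ["genotype", "role"]):
        name = f"dist_{role}_mean"
        values.loc[genotype, name] = float(sub["mean"].iloc[0])
        levels[name] = "structural"
    for row in profile.records.itertuples(index=False):
        name = f"dist_{row.role}_{row.structure_id}"
        values.loc[row.genotype, name] = row.min_distance
        levels[name] = "structural"
    agg = stability.aggregates.set_index("genotype")
    for genotype in mutants:
        if genotype in agg.index:
            values.loc[genotype, "ddg_mean"] = agg.loc[genotype, "mean"]
    levels["ddg_mean"] = "structural"
    for genotype in mutants:
        s = deg_summaries[genotype]
        values.loc[genotype, "n_deg_total_42v37"] = s.n_total
        values.loc[genotype, "n_deg_up_42v37"] = s.n_up
        values.loc[genotype, "n_deg_down_42v37"] = s.n_down
    levels.update({"n_deg_total_42v37": "transcriptomic",
                   "n_deg_up_42v37": "transcriptomic",
                   "n_deg_down_42v37": "transcriptomic"})
    fd = fitness_delta.set_index("genotype")
    for genotype in mutants:
        if genotype in fd.index:
            values.loc[genotype, "delta_auc"] = fd.loc[genotype, "delta"]
    levels["delta_auc"] = "organismal"
    values = values.loc[mutants]
    return crosslevel.MetricTable(values=values, levels=levels)
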