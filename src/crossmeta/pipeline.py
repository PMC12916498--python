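"""End-to-end orchestration: simulate -> harmonize -> nested meta ->
concordance -> loci -> gene-based -> mapping/prioritization -> enrichment
-> heritability partition -> polygenic scores, with a run manifest.

A run is configured by one YAML-able mapping (see :class:`RunConfig`),
executes its stages in dependency order, writes every table as
tab-delimited text under the output directory, and records a manifest
(config, seed, package version, content hash of every output) that is
bit-identical across runs of the same config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from crossmeta import __version__, enrichment, genes, heritability, loci, \
    mapping, meta, pgs, simulate
from crossmeta.errors import ConfigError

log = logging.getLogger(__name__)

ALL_STAGES = ("meta", "concordance", "loci", "genes", "mapping",
              "enrichment", "h2", "pgs")


@dataclass
class RunConfig:
    """One auditable home for every pipeline constant.

    Defaults mirror the analysis conventions: genome-wide significance at
    5e-8, lead r2 < 0.1, locus border r2 > 0.6, 250-kb locus merging,
    +-10-kb positional mapping, 2-Mb loop span, interaction score 0.7,
    1.645-SE expression labeling and a 10% top-score group.
    """

    seed: int = 0
    n_populations: int = 1
    sim: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)
    gws_p: float = meta.GWS_P
    lead_r2: float = loci.LEAD_R2
    border_r2: float = loci.BORDER_R2
    merge_gap_bp: int = loci.MERGE_GAP_BP
    ld_window_bp: int = loci.LD_WINDOW_BP
    gene_margin_bp: int = genes.GENE_MARGIN_BP
    loop_span_bp: int = mapping.LOOP_MAX_SPAN_BP
    interaction_score: float = mapping.INTERACTION_SCORE_MIN
    top_fraction: float = pgs.TOP_FRACTION
    n_mc: int = 20_000
    min_shared: int = 1000
    panel_size: int = 500
    target_sizes: tuple[int, ...] = (4000, 2000)
    n_genes: int = 60
    expression_shift: float = 30.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def stage_enabled(self, name: str) -> bool:
        return bool(self.stages.get(name, True))

    def sim_config(self, seed_offset: int = 0) -> simulate.SimConfig:
        kwargs = dict(self.sim)
        kwargs["seed"] = self.seed + seed_offset
        if "overlap_matrix" in kwargs:
            kwargs["overlap_matrix"] = np.asarray(kwargs["overlap_matrix"])
        return simulate.SimConfig(**kwargs)

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        out["sim"] = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                      for k, v in out["sim"].items()}
        out["target_sizes"] = list(self.target_sizes)
        return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False)
    manifest["files"][path.name] = _sha256(path)


class PipelineRun:
    """Mutable state shared across stages of one run."""

    def __init__(self, config: RunConfig, outdir):
        self.config = config
        self.outdir = Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: dict = {
            "config": config.to_jsonable(), "seed": config.seed,
            "version": __version__, "stages_run": [], "files": {},
            "counts": {},
        }


def _simulate_stage(run: PipelineRun):
    cfg = run.config
    pops = {}
    for p in range(cfg.n_populations):
        sim_cfg = cfg.sim_config(seed_offset=1000 * p)
        coll = simulate.simulate_collection(sim_cfg)
        pops[f"pop{p}"] = coll
        run.manifest["counts"][f"pop{p}_individuals"] = int(
            coll.genotypes.n_individuals)
    truth = next(iter(pops.values())).truth
    tt = truth.to_frame()
    _write(tt, run.outdir / "truth_table.tsv", run.manifest)
    return pops


def _meta_stage(run: PipelineRun, pops):
    cfg = run.config
    node_results = {}
    pop_models = {}
    for pop_name, coll in pops.items():
        studies = coll.studies
        # pre-combine duplicated traits before the cross-trait node
        by_trait: dict[int, list[str]] = {}
        for s, name in enumerate(studies):
            by_trait.setdefault(coll.config.study_traits[s], []).append(name)
        plan: dict[str, list[str]] = {}
        cross_inputs = []
        for t, names in sorted(by_trait.items()):
            if len(names) > 1:
                node = f"{pop_name}_trait{t}_combined"
                plan[node] = names
                cross_inputs.append(node)
            else:
                cross_inputs.append(names[0])
        plan[pop_name] = cross_inputs
        results = meta.nested_meta(plan, studies, min_shared=cfg.min_shared)
        node_results.update(results)
        model = meta.estimate_z_correlation(
            {n: (studies[n] if n in studies else results[n])
             for n in cross_inputs}, min_shared=cfg.min_shared)
        pop_models[pop_name] = model
        n_eff = meta.effective_sample_size(
            [float((studies[n] if n in studies else results[n])["N"].mean())
             for n in cross_inputs], model)
        run.manifest["counts"][f"{pop_name}_n_eff"] = round(n_eff, 1)
    if len(pops) > 1:
        cross = meta.nested_meta(
            {"cross_pop": list(pops)},
            {p: node_results[p] for p in pops}, min_shared=cfg.min_shared)
        node_results.update(cross)
    for name, df in node_results.items():
        _write(df, run.outdir / f"meta_{name}.tsv", run.manifest)
    report = {p: {"labels": m.labels, "C": m.C.round(4).tolist()}
              for p, m in pop_models.items()}
    path = run.outdir / "overlap_models.json"
    path.write_text(json.dumps(report, indent=1, sort_keys=True))
    run.manifest["files"][path.name] = _sha256(path)
    return node_results


def _concordance_stage(run: PipelineRun, pops, node_results):
    analyses = {}
    for pop_name in pops:
        analyses[pop_name] = meta.concordance_filter(node_results[pop_name])
    if len(pops) > 1:
        cross = node_results["cross_pop"]
        sign_frames = [cross.set_index("SNP")]
        for pop_name in pops:
            signs = node_results[pop_name].set_index("SNP")
            cols = meta.sign_columns(signs)
            sign_frames.append(signs[cols].add_prefix(f"{pop_name}."))
        wide = pd.concat(sign_frames, axis=1, join="inner").reset_index()
        analyses["cross_pop"] = meta.concordance_filter(wide)
    for name, df in analyses.items():
        _write(df, run.outdir / f"concordant_{name}.tsv", run.manifest)
        run.manifest["counts"][f"concordant_{name}"] = int(len(df))
    return analyses


def _loci_stage(run: PipelineRun, pops, analyses, annotations):
    cfg = run.config
    panel_geno = next(iter(pops.values())).genotypes
    panel = simulate.GenotypeMatrix(
        dosages=panel_geno.dosages[:cfg.panel_size],
        variants=panel_geno.variants)
    all_loci = []
    leads_frames = []
    for name, result in analyses.items():
        gws = result[result["P"] < cfg.gws_p]
        if gws.empty:
            continue
        ld = loci.compute_ld(panel, gws["SNP"].tolist(), cfg.ld_window_bp)
        leads = loci.select_leads(result, ld, cfg.gws_p)
        if leads.empty:
            continue
        locs = loci.define_loci(leads, result, ld, cfg.gws_p)
        locs = loci.merge_loci(locs, cfg.merge_gap_bp)
        locs.insert(0, "ANALYSIS", name)
        leads = leads.copy()
        leads.insert(0, "ANALYSIS", name)
        all_loci.append(locs)
        leads_frames.append(leads)
    if not all_loci:
        empty = pd.DataFrame(columns=["ANALYSIS", "CHR", "START", "END"])
        _write(empty, run.outdir / "loci.tsv", run.manifest)
        return empty, panel
    pooled = pd.concat(all_loci, ignore_index=True)
    merged = loci.merge_loci(pooled.drop(columns="ANALYSIS"),
                             cfg.merge_gap_bp)
    merged = loci.annotate_novel(merged, annotations["known_loci"])
    out = merged.copy()
    for col in ("LEADS", "LEAD_Z", "LEAD_P"):
        out[col] = ["|".join(str(v) for v in t) for t in out[col]]
    _write(out, run.outdir / "loci.tsv", run.manifest)
    _write(loci.loci_to_bed(merged), run.outdir / "loci.bed", run.manifest)
    _write(pd.concat(leads_frames, ignore_index=True),
           run.outdir / "leads.tsv", run.manifest)
    run.manifest["counts"]["n_loci"] = int(len(merged))
    run.manifest["counts"]["n_novel_loci"] = int(merged["NOVEL"].sum())
    return merged, panel


def _genes_stage(run: PipelineRun, analyses, annotations, panel, rng):
    cfg = run.config
    gene_table = annotations["genes"]
    n_genes = len(gene_table)
    tissue = simulate.generate_expression(
        n_genes, 13, planted_set=[], planted_shift=0.0,
        seed=cfg.seed + 71, gene_ids=gene_table["GENE"].tolist())
    tissue.iloc[-max(2, n_genes // 20):, :] = 0.0  # some non-brain genes
    expressed = set(genes.brain_expressed_filter(
        gene_table["GENE"].tolist(), tissue))
    per_pop = {}
    for name, result in analyses.items():
        if name == "cross_pop":
            continue
        ld = loci.compute_ld(panel, result["SNP"].tolist(), cfg.ld_window_bp)
        table = genes.gene_scan(result, gene_table, ld, expressed=expressed,
                                seed=cfg.seed + 17, n_mc=cfg.n_mc,
                                margin_bp=cfg.gene_margin_bp)
        per_pop[name] = table
        _write(table, run.outdir / f"genes_{name}.tsv", run.manifest)
    if len(per_pop) > 1:
        n_eff = {name: float(analyses[name]["N"].mean())
                 for name in per_pop}
        cross = genes.gene_meta(per_pop, n_eff)
        _write(cross, run.outdir / "genes_cross_population.tsv", run.manifest)
        per_pop["cross_population"] = cross
    return per_pop, expressed


def _mapping_stage(run: PipelineRun, analyses, locus_table, annotations,
                   gene_results, expressed):
    cfg = run.config
    pieces = []
    for name, result in analyses.items():
        gws = result[result["P"] < cfg.gws_p]
        pieces.append(gws)
    if pieces:
        sig = pd.concat(pieces).drop_duplicates("SNP")
    else:
        sig = pd.DataFrame(columns=["SNP", "CHR", "BP"])
    if len(locus_table) and "START" in locus_table.columns:
        keep = np.zeros(len(sig), dtype=bool)
        for row in locus_table.itertuples(index=False):
            if hasattr(row, "LD_SUPPORTED") and not row.LD_SUPPORTED:
                continue
            keep |= ((sig["CHR"].astype(str) == str(row.CHR))
                     & (sig["BP"] >= row.START)
                     & (sig["BP"] <= row.END)).to_numpy()
        sig = sig[keep]
    gene_table = annotations["genes"]
    mapped = pd.concat([
        mapping.map_positional(sig, gene_table, cfg.gene_margin_bp),
        mapping.map_eqtl(sig, annotations["eqtls"]),
        mapping.map_chromatin(sig, annotations["loops"], gene_table,
                              cfg.loop_span_bp),
    ], ignore_index=True)
    _write(mapped, run.outdir / "variant_gene_map.tsv", run.manifest)
    gene_based = gene_results.get("cross_population")
    if gene_based is None and gene_results:
        gene_based = next(iter(gene_results.values()))
    if gene_based is None:
        gene_based = pd.DataFrame(columns=["GENE", "P"])
    candidates = mapping.candidate_genes(mapped, gene_based,
                                         expressed=expressed)
    tables = mapping.EvidenceTables(
        pathways=annotations["pathways"],
        families=annotations["families"],
        interactions=annotations["interactions"],
        trait_classes=annotations["trait_classes"])
    prioritized = mapping.prioritize(candidates, tables)
    out = prioritized.copy()
    out["REASONS"] = ["|".join(r) for r in out["REASONS"]]
    _write(out, run.outdir / "prioritized_genes.tsv", run.manifest)
    run.manifest["counts"]["n_candidate_genes"] = int(len(candidates))
    run.manifest["counts"]["n_prioritized_genes"] = int(
        prioritized["PRIORITIZED"].sum())
    return prioritized


def _enrichment_stage(run: PipelineRun, annotations, prioritized):
    cfg = run.config
    prio = prioritized.loc[prioritized["PRIORITIZED"], "GENE"].tolist()
    if not prio:
        log.warning("no prioritized genes; enrichment skipped")
        return None
    gene_ids = annotations["genes"]["GENE"].tolist()
    planted = [gene_ids.index(g) for g in prio]
    dissections = simulate.generate_expression(
        len(gene_ids), 20, planted, cfg.expression_shift,
        seed=cfg.seed + 91, gene_ids=gene_ids)
    cells = simulate.generate_expression(
        len(gene_ids), 30, planted, cfg.expression_shift,
        seed=cfg.seed + 92, gene_ids=gene_ids)
    table = enrichment.run_enrichment_analyses(dissections, cells, prio)
    _write(table, run.outdir / "enrichment.tsv", run.manifest)
    return table


def _h2_stage(run: PipelineRun, pops, analyses, panel):
    cfg = run.config
    pop_name, coll = next(iter(pops.items()))
    concordant = set(analyses[pop_name]["SNP"])
    rows = []
    for study_name, stats in coll.studies.items():
        try:
            res = heritability.h2_fraction(stats, concordant & set(
                stats["SNP"]), panel, cfg.ld_window_bp)
        except Exception as exc:
            log.warning("h2 stage failed for %s: %s", study_name, exc)
            continue
        rows.append({
            "STUDY": study_name,
            "H2_ALL": res["h2_all"].h2, "H2_ALL_SE": res["h2_all"].h2_se,
            "H2_CONCORDANT": res["h2_concordant"].h2,
            "FRACTION": res["fraction"],
            "INTERCEPT": res["h2_all"].intercept,
        })
    table = pd.DataFrame(rows)
    _write(table, run.outdir / "h2_partition.tsv", run.manifest)
    return table


def _pgs_stage(run: PipelineRun, pops, analyses, panel):
    cfg = run.config
    pop_name, coll = next(iter(pops.items()))
    result = analyses[pop_name]
    ld = loci.compute_ld(panel, result["SNP"].tolist(), cfg.ld_window_bp)
    weights = pgs.fallback_weights(result, ld)
    pgs.write_weights(weights, run.outdir / "pgs_weights.tsv")
    run.manifest["files"]["pgs_weights.tsv"] = _sha256(
        run.outdir / "pgs_weights.tsv")
    if weights.empty:
        log.warning("no variants survived clumping; PGS stage skipped")
        return None
    sim_cfg = coll.config
    rows = []
    cohort_results = []
    for k, size in enumerate(cfg.target_sizes):
        rng = np.random.default_rng(cfg.seed + 500 + k)
        geno = simulate.simulate_genotypes(sim_cfg, size, rng)
        labels, _ = simulate.simulate_phenotypes(geno, coll.truth, sim_cfg,
                                                 rng)
        any_case = labels.any(axis=1).astype(int)
        covs = pd.DataFrame({
            "sex": rng.integers(0, 2, size=size),
            "age": rng.normal(50, 10, size=size).round(1),
        })
        for pc in range(10):
            covs[f"PC{pc + 1}"] = rng.normal(size=size)
        cohort = pgs.CohortData(
            dosages=geno.dosages.astype(float), variants=geno.variants,
            phenotype=any_case, covariates=covs, label=f"target{k}")
        scores = pgs.score(cohort, weights)
        per_cohort = []
        for stratum in ("combined", 0, 1):
            try:
                res = pgs.top_decile_or(scores, cohort, stratum=stratum,
                                        top_fraction=cfg.top_fraction)
            except Exception as exc:
                log.warning("pgs stratum %r failed on %s: %s", stratum,
                            cohort.label, exc)
                continue
            per_cohort.append(res)
            rows.append(dataclasses.asdict(res))
        cohort_results.append(per_cohort)
    combined = [rs[0] for rs in cohort_results
                if rs and rs[0].stratum == "combined"]
    if len(combined) >= 2:
        rows.append(dataclasses.asdict(pgs.meta_or(combined)))
    table = pd.DataFrame(rows)
    _write(table, run.outdir / "pgs_results.tsv", run.manifest)
    return table


def run(config: RunConfig, outdir) -> dict:
    """Execute the pipeline; returns the manifest (also written to disk).

    Stage failures abort with the failing stage named; outputs written by
    earlier stages are retained.
    """
    state = PipelineRun(config, outdir)
    stage = "simulate"
    try:
        pops = _simulate_stage(state)
        state.manifest["stages_run"].append(stage)
        rng = np.random.default_rng(config.seed + 7)
        annotations = simulate.generate_annotations(
            config.sim_config(), next(iter(pops.values())).truth,
            next(iter(pops.values())).genotypes.variants,
            n_genes=config.n_genes, rng=rng)
        node_results = analyses = None
        if config.stage_enabled("meta"):
            stage = "meta"
            node_results = _meta_stage(state, pops)
            state.manifest["stages_run"].append(stage)
        if node_results is not None:
            if config.stage_enabled("concordance"):
                stage = "concordance"
                analyses = _concordance_stage(state, pops, node_results)
                state.manifest["stages_run"].append(stage)
            else:
                analyses = {p: node_results[p] for p in pops}
                if len(pops) > 1:
                    analyses["cross_pop"] = node_results["cross_pop"]
                state.manifest["counts"]["concordance_skipped"] = True
        locus_table = panel = None
        if analyses is not None and config.stage_enabled("loci"):
            stage = "loci"
            locus_table, panel = _loci_stage(state, pops, analyses,
                                             annotations)
            state.manifest["stages_run"].append(stage)
        gene_results, expressed = {}, None
        if analyses is not None and panel is not None \
                and config.stage_enabled("genes"):
            stage = "genes"
            gene_results, expressed = _genes_stage(state, analyses,
                                                   annotations, panel, rng)
            state.manifest["stages_run"].append(stage)
        prioritized = None
        if analyses is not None and locus_table is not None \
                and config.stage_enabled("mapping"):
            stage = "mapping"
            prioritized = _mapping_stage(state, analyses, locus_table,
                                         annotations, gene_results,
                                         expressed)
            state.manifest["stages_run"].append(stage)
        if prioritized is not None and config.stage_enabled("enrichment"):
            stage = "enrichment"
            _enrichment_stage(state, annotations, prioritized)
            state.manifest["stages_run"].append(stage)
        if analyses is not None and panel is not None \
                and config.stage_enabled("h2"):
            stage = "h2"
            _h2_stage(state, pops, analyses, panel)
            state.manifest["stages_run"].append(stage)
        if analyses is not None and panel is not None \
                and config.stage_enabled("pgs"):
            stage = "pgs"
            _pgs_stage(state, pops, analyses, panel)
            state.manifest["stages_run"].append(stage)
    except Exception as exc:
        raise ConfigError(f"pipeline stage {stage!r} failed: {exc}") from exc
    path = state.outdir / "manifest.json"
    path.write_text(json.dumps(state.manifest, indent=1, sort_keys=True))
    return state.manifest


def demo_config(seed: int = 0) -> RunConfig:
    """A small single-population reference configuration.

    Four traits observed by five studies (one trait contributed by two
    overlapping cohorts, exercising the pre-combination step), planted
    shared/discordant/specific causal variants, and a liability-threshold
    prevalence of 10%.
    """
    return RunConfig(
        seed=seed,
        n_populations=1,
        sim=dict(
            n_variants=1200, n_blocks=120, block_rho=0.6,
            n_traits=4, cohort_sizes=(6000, 6000, 4000, 4000, 6000),
            study_traits=(0, 1, 2, 2, 3),
            overlap_matrix=_demo_overlap(),
            n_shared_causal=12, n_discordant_causal=6, n_specific_causal=4,
            effect_size_sd=0.12, prevalence=0.1,
        ),
        n_mc=20_000, panel_size=500, target_sizes=(4000, 2000),
    )


def _demo_overlap():
    om = np.zeros((5, 5), dtype=int)
    om[2, 3] = om[3, 2] = 2000   # the two cohorts of the duplicated trait
    om[0, 1] = om[1, 0] = 1500   # partially shared biobank participants
    return om
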