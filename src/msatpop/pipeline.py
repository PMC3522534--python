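"""End-to-end analysis pipeline.

Runs the full workflow on a Genepop file plus metadata: summary
statistics, temporal-stability tests (with optional pooling), pairwise
and hierarchical F-statistics, clustering and migrant assignment,
sex-biased dispersal tests, isolation-by-distance regression with
dispersal parameters, and effective/census population size.  Each stage
writes its tables under the output directory and records its parameters
and seed in a JSON manifest, so a rerun with the same configuration
reproduces every number.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import (demography, differentiation, genotype_io, ibd_dispersal,
               sex_bias, structure_assignment, summary_stats)
from .genotype_io import Dataset, Grouping

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ["summary", "temporal", "fst", "hierf", "clusters", "assign",
          "sexbias", "ibd", "dispersal", "ne", "census"]


@dataclass
class PipelineConfig:
    genepop_path: str
    output_dir: str
    metadata_path: str | None = None
    seed: int = 0
    # groupings: name -> {population: label}
    groupings: dict = field(default_factory=dict)
    cluster_grouping: str | None = None      # grouping used for cluster stats
    temporal_pools: dict = field(default_factory=dict)
    require_temporal_nonsignificance: bool = True
    n_permutations: int = 10_000             # F_ST permutations
    mc_replicates: int = 100_000             # exact-test tables
    fdr_q: float = 0.05
    pcrit: float = 0.02
    # dispersal inputs (no defaults in science terms: must be supplied)
    habitat: dict = field(default_factory=dict)    # group -> area km^2 (2D) / length km (1D)
    epsilon: dict = field(default_factory=dict)    # group -> inter-deme distance km
    ibd_model: str = "2D"
    temporal_pairs: list = field(default_factory=list)  # [(pop0, popt, t_gens), ...]
    census_survey_path: str | None = None
    census_n_max: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _grouping(cfg: PipelineConfig, name: str) -> Grouping:
    return Grouping(name, dict(cfg.groupings[name]))


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in canonical order; returns the manifest."""
    stages = STAGES if stages is None else [s for s in STAGES if s in stages]
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    stage_seeds = {name: int(child.generate_state(1)[0] % 2 ** 31)
                   for name, child in zip(STAGES, ss.spawn(len(STAGES)))}
    manifest: dict = {"config": asdict(cfg), "stage_seeds": stage_seeds,
                      "stages": {}}

    ds = genotype_io.read_genepop(cfg.genepop_path)
    if cfg.metadata_path:
        ds = genotype_io.attach_metadata(ds, cfg.metadata_path)

    temporal_ok = not cfg.require_temporal_nonsignificance

    def record(name, **info):
        manifest["stages"][name] = {"seed": stage_seeds[name], **info}

    for stage in stages:
        logger.info("pipeline stage: %s", stage)
        try:
            if stage == "summary":
                table = summary_stats.summary_statistics(ds)
                table.means.to_csv(out / "summary_table1.csv")
                record(stage, output="summary_table1.csv",
                       rarefaction_g=table.rarefaction_g)

            elif stage == "temporal":
                results = {}
                ok_all = True
                for new_label, parts in cfg.temporal_pools.items():
                    res = summary_stats.exact_differentiation_test(
                        ds, parts, scope="genic", B=min(cfg.mc_replicates, 20_000),
                        seed=stage_seeds[stage])
                    results[new_label] = {"p": res.p_value,
                                          "per_locus": res.per_locus}
                    if res.p_value is not None and res.p_value < 0.05:
                        ok_all = False
                        logger.warning("temporal samples %s differ (p=%.4f)",
                                       parts, res.p_value)
                temporal_ok = temporal_ok or ok_all
                if cfg.temporal_pools and (ok_all or not cfg.require_temporal_nonsignificance):
                    ds = genotype_io.pool_temporal(ds, cfg.temporal_pools)
                with open(out / "temporal_tests.json", "w") as fh:
                    json.dump(results, fh, indent=1, default=float)
                record(stage, output="temporal_tests.json", pooled=bool(results))

            elif stage == "fst":
                pw = differentiation.fst_permutation_test(
                    ds, None, n_perm=cfg.n_permutations,
                    seed=stage_seeds[stage])
                pw.to_tsv(out / "pairwise_fst_populations.tsv")
                if cfg.cluster_grouping:
                    pwc = differentiation.fst_permutation_test(
                        ds, _grouping(cfg, cfg.cluster_grouping),
                        n_perm=cfg.n_permutations, seed=stage_seeds[stage])
                    pwc.to_tsv(out / "pairwise_fst_clusters.tsv")
                record(stage, n_perm=cfg.n_permutations,
                       output="pairwise_fst_*.tsv")

            elif stage == "hierf":
                if not cfg.groupings:
                    record(stage, skipped="no groupings configured")
                    continue
                levels = [_grouping(cfg, n) for n in cfg.groupings]
                res = differentiation.hierarchical_fstats(ds, levels)
                pvals = {}
                for g in levels:
                    t = differentiation.hierf_permutation_test(
                        ds, levels, g.name, n_perm=min(cfg.n_permutations, 2000),
                        seed=stage_seeds[stage])
                    pvals[g.name] = t["p_value"]
                res.p_values = {(g.name, "enclosing"): p for g, p in
                                zip(levels, pvals.values())}
                with open(out / "hierarchical_fstats.json", "w") as fh:
                    json.dump(res.to_json_dict(), fh, indent=1, default=float)
                record(stage, output="hierarchical_fstats.json")

            elif stage == "clusters":
                fc = structure_assignment.find_clusters(
                    ds, seed=stage_seeds[stage])
                model = structure_assignment.dapc_fit(
                    ds, fc["assignments"], seed=stage_seeds[stage])
                model.scatter_frame(ds).to_csv(out / "dapc_scatter.tsv",
                                               sep="\t", index=False)
                record(stage, k=fc["k"], bic={str(k): v for k, v in fc["bic"].items()},
                       n_pcs=model.n_pcs, output="dapc_scatter.tsv")

            elif stage == "assign":
                if not cfg.cluster_grouping:
                    record(stage, skipped="no cluster grouping configured")
                    continue
                g = _grouping(cfg, cfg.cluster_grouping)
                ll = structure_assignment.assignment_loglik(ds, g.assignment)
                calls, counts = structure_assignment.detect_migrants(ll)
                counts.to_csv(out / "migrant_counts.csv", index=False)
                with open(out / "migrants.json", "w") as fh:
                    json.dump([{"id": c.individual_id, "home": c.home,
                                "lambda": c.lam,
                                "flagged_at": c.flagged_at} for c in calls
                               if c.flagged_at], fh, indent=1, default=float)
                record(stage, output="migrants.json")

            elif stage == "sexbias":
                if not cfg.cluster_grouping:
                    record(stage, skipped="no cluster grouping configured")
                    continue
                g = _grouping(cfg, cfg.cluster_grouping)
                res = sex_bias.sex_bias_tests(
                    ds, g, n_perm=min(cfg.n_permutations, 2000),
                    seed=stage_seeds[stage])
                res.to_csv(out / "sex_bias_table3.csv")
                record(stage, output="sex_bias_table3.csv",
                       p_values=res.p_values)

            elif stage == "ibd":
                pw, _ = differentiation.wc_fst(ds)
                pairs = ibd_dispersal.linearized_fst_matrix(pw, ds.site_coords)
                fit = ibd_dispersal.ibd_regression(
                    pairs, model=cfg.ibd_model,
                    n_perm=min(cfg.n_permutations, 5000),
                    seed=stage_seeds[stage])
                pairs.to_csv(out / "ibd_pairs.tsv", sep="\t", index=False)
                manifest["ibd_fit"] = {"slope": fit.slope,
                                       "intercept": fit.intercept,
                                       "mantel_p": fit.mantel_p}
                record(stage, slope=fit.slope, mantel_p=fit.mantel_p,
                       output="ibd_pairs.tsv")

            elif stage == "dispersal":
                if "ibd_fit" not in manifest or not cfg.habitat:
                    record(stage, skipped="needs ibd stage and habitat config")
                    continue
                ne_stage = manifest["stages"].get("ne", {})
                results = {}
                for group, area in cfg.habitat.items():
                    ne_val = ne_stage.get("ld_point", {}).get(group)
                    if ne_val is None or not np.isfinite(ne_val):
                        logger.warning("no finite N_E for %s; dispersal skipped",
                                       group)
                        continue
                    fit = ibd_dispersal.IBDFit(
                        model=cfg.ibd_model, pairs=None,
                        slope=manifest["ibd_fit"]["slope"],
                        intercept=manifest["ibd_fit"]["intercept"],
                        mantel_p=manifest["ibd_fit"]["mantel_p"],
                        n_perm=0, seed=None)
                    est = ibd_dispersal.derive_dispersal(
                        fit, ne_val, area, cfg.epsilon.get(group), group=group)
                    results[group] = asdict(est)
                with open(out / "dispersal_table4.json", "w") as fh:
                    json.dump(results, fh, indent=1, default=float)
                record(stage, output="dispersal_table4.json")

            elif stage == "ne":
                ld_points = {}
                if cfg.cluster_grouping:
                    g = _grouping(cfg, cfg.cluster_grouping)
                    units = {lab: g.members(lab) for lab in g.labels()}
                else:
                    units = {p: [p] for p in ds.populations}
                rows = {}
                for lab, pops in units.items():
                    try:
                        est = demography.ldne_estimate(ds, pops, pcrit=cfg.pcrit)
                    except ValueError as exc:
                        logger.warning("LD N_E failed for %s: %s", lab, exc)
                        continue
                    rows[lab] = {"point": est.point, "ci": est.ci}
                    ld_points[lab] = est.point
                temporal = {}
                for pop0, popt, t in cfg.temporal_pairs:
                    est = demography.temporal_moment_ne(
                        ds, ds, t, population_0=pop0, population_t=popt)
                    temporal[f"{pop0}->{popt}"] = {"point": est.point,
                                                   "ci": est.ci}
                with open(out / "ne_estimates.json", "w") as fh:
                    json.dump({"LD": rows, "temporal_moment": temporal},
                              fh, indent=1, default=float)
                record(stage, ld_point=ld_points, output="ne_estimates.json")

            elif stage == "census":
                if not cfg.census_survey_path:
                    record(stage, skipped="no removal survey configured")
                    continue
                survey = demography.RemovalSurvey.from_csv(cfg.census_survey_path)
                post = demography.removal_census_posterior(
                    survey, n_max=cfg.census_n_max)
                np.savetxt(out / "census_posterior.tsv",
                           np.column_stack([post.n_grid, post.marginal_n]),
                           header="N\tposterior", delimiter="\t", comments="")
                record(stage, mean_n=post.mean_n, hpd=list(post.hpd),
                       output="census_posterior.tsv")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
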