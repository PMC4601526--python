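"""End-to-end orchestration of the DDR-miRNA analysis on synthetic inputs.

One seeded configuration drives every stage: count simulation, differential
expression against the 0 h controls, the robustness filter with redundancy
resolution and kinetic clustering, genomic-context classification with
category enrichment, cross-species p53 motif ranking of synthetic promoters,
preranked GSEA of the DDR sets on that ranking, and p53-dependence calls
from the TP53-null contrast. Outputs are plain TSV/JSON tables, each run
carrying the configuration hash, and are byte-identical across re-runs at
the same seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import context as ctx
from . import diffexpr as de
from . import gsea as gs
from . import motifs as mo
from . import selection as sel
from . import simulate as sim
from .ingest import InputError

logger = logging.getLogger("mirddr")

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed or a dependency was unmet; message is stage-tagged."""


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run; defaults reproduce the study settings.

    The thresholds (|M| >= 0.75, A >= 5, corrected p < 0.05; pseudocount 1;
    aggregate-count floor 100; <10 kb locus clustering; promoter windows) are
    the published analysis parameters; the simulation block controls the
    synthetic inputs. ``stages`` toggles individual stages; disabling one
    that a later stage needs raises a stage-tagged error.
    """

    seed: int = 0
    sim: sim.SimulationConfig = field(default_factory=sim.SimulationConfig)
    norm: de.NormalizationConfig = field(default_factory=de.NormalizationConfig)
    thresholds: de.SignificanceThresholds = field(
        default_factory=de.SignificanceThresholds)
    method: str = "exact_fisher"
    control_time: int = 0
    max_gap: int = 10_000
    crm_window: int = 500
    hit_floor: float = 0.0
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    cluster_presets: dict = field(default_factory=lambda: {
        "MCF10A": "mcf10a", "HCT116": "hct116"})
    stages: dict = field(default_factory=lambda: {
        "counts": True, "diffexpr": True, "selection": True,
        "context": True, "motif": True, "gsea": True, "p53": True,
    })

    def __post_init__(self) -> None:
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict[str, Any] = {}
        for key, cls in (("sim", sim.SimulationConfig),
                         ("norm", de.NormalizationConfig),
                         ("thresholds", de.SignificanceThresholds)):
            if key in raw:
                sub = raw.pop(key)
                for nested, ncls in (("spikes", sim.SpikeConfig),
                                     ("geometry", sim.GeometryConfig),
                                     ("motif_plant", sim.MotifPlantConfig)):
                    if isinstance(sub.get(nested), dict):
                        sub[nested] = ncls(**sub[nested])
                if "times" in sub:
                    sub["times"] = tuple(sub["times"])
                if "cell_lines" in sub:
                    sub["cell_lines"] = tuple(tuple(c) for c in sub["cell_lines"])
                kwargs[key] = cls(**sub)
        kwargs.update(raw)
        return PipelineConfig(**kwargs)


def _require(config: PipelineConfig, stage: str, *deps: str) -> None:
    if not config.stages.get(stage, True):
        raise StageError(f"{stage}: stage disabled")
    for dep in deps:
        if not config.stages.get(dep, True):
            raise StageError(f"{stage}: unmet dependency {dep!r}")


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> dict[str, Any]:
    """Run every enabled stage and return the report bundle as a dict.

    When ``outdir`` is given, tables are also written there as TSV/JSON plus
    a plain-text ``summary.txt``; every file carries the configuration hash
    in a header comment.
    """
    bundle: dict[str, Any] = {"config_hash": config.config_hash(),
                              "log": []}

    def log(stage: str, msg: str) -> None:
        line = f"[{stage}] {msg}"
        bundle["log"].append(line)
        logger.info(line)

    # ----- counts ---------------------------------------------------------
    _require(config, "counts")
    table, truth = sim.simulate_counts(config.sim)
    bundle["counts"] = table
    bundle["truth"] = truth
    log("counts", f"{len(table.mirna_ids)} miRNAs x {len(table.sample_ids)} samples")

    # ----- differential expression ---------------------------------------
    _require(config, "diffexpr", "counts")
    results = de.differential_expression(
        table, config.norm, config.thresholds,
        control_time=config.control_time, method=config.method, merge=True)
    per_rep = de.differential_expression(
        table, config.norm, config.thresholds,
        control_time=config.control_time, method=config.method, merge=False)
    bundle["diffexpr"] = results
    bundle["diffexpr_per_replicate"] = per_rep
    log("diffexpr", f"{len(results)} records, "
        f"{int(results['significant'].sum())} significant calls")

    wt = results[results["genotype"] == "WT"]
    wt_rep = per_rep[per_rep["genotype"] == "WT"]

    # ----- selection ------------------------------------------------------
    _require(config, "selection", "diffexpr")
    induced = sel.robust_filter(wt, "induced", per_replicate=wt_rep)
    repressed = sel.robust_filter(wt, "repressed", per_replicate=wt_rep)
    coverage = table.counts.sum(axis=1).to_dict()
    cons_ind, removed_ind = sel.resolve_redundancy(
        induced.members, truth.reference, coverage)
    cons_rep, removed_rep = sel.resolve_redundancy(
        repressed.members, truth.reference, coverage)
    ddr_by_cell = {
        cell: set(results.loc[
            (results["cell_line"] == cell) & (results["genotype"] == "WT")
            & results["significant"], "mirna"])
        for cell, geno in {(c, g) for c, g in config.sim.cell_lines if g == "WT"}
    }
    venn = sel.compare_sets(ddr_by_cell) if len(ddr_by_cell) >= 2 else None
    clusters = {}
    for cell in ddr_by_cell:
        cell_wt = wt[(wt["cell_line"] == cell)
                     & wt["mirna"].isin(ddr_by_cell[cell])]
        if not cell_wt.empty:
            clusters[cell] = sel.assign_clusters(
                cell_wt, preset=config.cluster_presets.get(cell, "mcf10a"))
    bundle.update({
        "induced": induced, "repressed": repressed,
        "ddr_induced": cons_ind, "ddr_repressed": cons_rep,
        "removed_redundant": removed_ind + removed_rep,
        "venn": venn, "clusters": clusters,
    })
    log("selection", f"{len(induced.members)} induced candidates -> "
        f"{len(cons_ind)} after redundancy; {len(repressed.members)} repressed"
        f" -> {len(cons_rep)}")

    # ----- genomic context ------------------------------------------------
    _require(config, "context", "selection")
    loci, transcripts, truth.context = sim.simulate_annotation(config.sim)
    truth.loci, truth.transcripts = loci, transcripts
    labels = ctx.label_loci(loci, transcripts, max_gap=config.max_gap)
    ddr_union = set().union(*ddr_by_cell.values()) if ddr_by_cell else set()
    all_ids = set(table.mirna_ids)
    enrichment = (ctx.category_enrichment(ddr_union, all_ids, labels)
                  if ddr_union else None)
    bundle["context_labels"] = labels
    bundle["context_enrichment"] = enrichment
    log("context", f"{len(labels)} loci labelled; DDR union {len(ddr_union)}")

    # ----- motif ranking --------------------------------------------------
    _require(config, "motif", "counts")
    pwms = sim.demo_pwms(seed=config.seed + 1)
    # plant motifs in the promoters of the functional representatives of the
    # p53-dependent induced spikes (arms of one stem-loop share a promoter)
    planted = sim.functional_representatives(
        truth.mirnas.index[
            truth.mirnas["archetype"].isin(["A", "B"])
            & truth.mirnas["p53_dependent"]],
        truth.reference,
    )
    regions, truth.planted_motifs = sim.simulate_promoters(
        config.sim, pwms, features=table.mirna_ids,
        planted_features=planted)
    scores = {}
    for species, feats in regions.items():
        bg = mo.estimate_background(feats.values())
        scores[species] = mo.score_species(
            {fid: [seq] for fid, seq in feats.items()}, pwms, background=bg,
            window=config.crm_window, hit_floor=config.hit_floor)
    per_species = pd.DataFrame(scores)
    ranking = mo.aggregate_ranking(per_species)
    bundle["motif_scores"] = per_species
    bundle["motif_ranking"] = ranking
    log("motif", f"{len(ranking)} features ranked over "
        f"{per_species.shape[1]} species; {len(planted)} planted")

    # ----- GSEA -----------------------------------------------------------
    _require(config, "gsea", "motif", "selection")
    ranked = gs.RankedList.from_frame(ranking)
    gene_sets = {}
    if cons_ind:
        gene_sets["ddr_induced"] = set(cons_ind)
    if cons_rep:
        gene_sets["ddr_repressed"] = set(cons_rep)
    if not gene_sets:
        raise StageError("gsea: no non-empty DDR gene sets")
    gsea_results = gs.nes_and_fdr(
        ranked, gene_sets, n_perm=config.gsea_n_perm, seed=config.seed,
        p=config.gsea_weight)
    bundle["gsea"] = gsea_results
    for set_id, res in gsea_results.items():
        log("gsea", f"{set_id}: ES={res.ES:.3f} NES={res.NES:.2f} "
            f"p={res.p_nominal:.4f} q={res.fdr_q:.4f} "
            f"leading edge {len(res.leading_edge)}/{len(res.hits)}")

    # ----- p53 dependence -------------------------------------------------
    _require(config, "p53", "diffexpr", "selection")
    ko_cells = {c for c, g in config.sim.cell_lines if g == "TP53KO"}
    p53_calls = None
    dep_fracs = None
    if ko_cells:
        cell = sorted(ko_cells)[0]
        wt_cell = results[(results["cell_line"] == cell)
                          & (results["genotype"] == "WT")]
        ko_cell = results[(results["cell_line"] == cell)
                          & (results["genotype"] == "TP53KO")]
        p53_calls = sel.p53_dependence(
            wt_cell, ko_cell, m_thresh=config.thresholds.m_thresh)
        if cell in clusters:
            dep_fracs = sel.dependence_fractions(p53_calls, clusters[cell])
        n_dep = int((p53_calls == "p53_dependent").sum())
        log("p53", f"{n_dep} p53-dependent calls of {len(p53_calls)} assessed")
    bundle["p53_calls"] = p53_calls
    bundle["p53_fractions"] = dep_fracs

    if outdir is not None:
        _write_bundle(bundle, config, Path(outdir))
    return bundle


def _write_bundle(bundle: dict[str, Any], config: PipelineConfig,
                  outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    h = bundle["config_hash"]

    def tsv(frame: pd.DataFrame, name: str, index: bool = True,
            index_label: str | None = None) -> None:
        path = outdir / name
        with open(path, "w") as fh:
            fh.write(f"# mirddr config_hash={h}\n")
            frame.to_csv(fh, sep="\t", index=index, index_label=index_label,
                         lineterminator="\n")

    tsv(bundle["counts"].counts, "counts_raw.tsv", index_label="mirna")
    tsv(bundle["diffexpr"], "diffexpr.tsv", index=False)
    tsv(bundle["diffexpr_per_replicate"], "diffexpr_per_replicate.tsv",
        index=False)
    if bundle["context_enrichment"] is not None:
        tsv(bundle["context_enrichment"], "context_enrichment.tsv")
    tsv(bundle["motif_scores"], "motif_scores.tsv", index_label="feature")
    tsv(bundle["motif_ranking"], "motif_ranking.tsv", index_label="feature")
    if bundle["p53_fractions"] is not None:
        tsv(bundle["p53_fractions"], "p53_fractions.tsv")
    gsea_frame = gs.results_to_frame(bundle["gsea"])
    tsv(gsea_frame, "gsea_results.tsv")

    report = {
        "config_hash": h,
        "config": config.to_dict(),
        "ddr_induced": sorted(bundle["ddr_induced"]),
        "ddr_repressed": sorted(bundle["ddr_repressed"]),
        "removed_redundant": bundle["removed_redundant"],
        "venn": ({"sizes": bundle["venn"]["sizes"],
                  "union": bundle["venn"]["union"],
                  "intersections": {f"{a}&{b}": v for (a, b), v in
                                    bundle["venn"]["intersections"].items()},
                  "shared": bundle["venn"]["shared"]}
                 if bundle["venn"] else None),
        "gsea": {k: {"ES": r.ES, "NES": r.NES, "p_nominal": r.p_nominal,
                     "fdr_q": r.fdr_q,
                     "leading_edge": r.leading_edge}
                 for k, r in bundle["gsea"].items()},
        "p53_calls": (bundle["p53_calls"].to_dict()
                      if bundle["p53_calls"] is not None else None),
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    with open(outdir / "summary.txt", "w") as fh:
        fh.write(f"mirddr run (config_hash={h})\n")
        fh.write("\n".join(bundle["log"]) + "\n")
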