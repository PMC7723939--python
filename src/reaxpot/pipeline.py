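"""End-to-end, config-driven pipeline: preprocess -> DE -> rate potentials ->
enrichment -> network graphs, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import call_significant, moderated_t_test, significance_counts
from .enrichment import ora
from .graph import export_graph, global_view
from .network import load_network
from .potential import (
    bootstrap_ranking_scores,
    call_significant_reactions,
    compute_reaction_potentials,
    reaction_enzyme_log2fc,
    results_to_frame,
)
from .preprocess import (
    AbundanceMatrix,
    aggregate_enzyme_activity,
    filter_missing,
    impute_min,
    log_transform,
    pca_summary,
    quantile_normalize,
)

__all__ = ["RunConfig", "run_pipeline", "check_inputs", "load_abundance_matrix"]

log = logging.getLogger("reaxpot")


@dataclass
class RunConfig:
    """All inputs and tunables of one pipeline run (YAML-serializable)."""

    metabolites: str
    genes: str
    design: str
    reactions: str
    enzymes: str
    pathways: str
    out_dir: str
    seed: int = 0
    quantile_normalize: bool = True
    pseudo_count: float = 1.0
    pca_top_fraction: float = 0.10
    alpha: float = 0.05
    fc_cutoff: float = 0.5
    score_cutoff: float = 0.05
    n_boot: int = 500
    allow_missing_enzyme: bool = False
    ora_min_size: int = 3
    graph_hops: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_design(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValueError("design file needs columns sample_id, group")
    return dict(zip(df["sample_id"], df["group"]))


def load_abundance_matrix(path: str | Path, groups: dict[str, str]) -> AbundanceMatrix:
    """Read a delimited matrix (first column feature id, header sample ids).

    Empty cells or "NA" are treated as missing.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0, na_values=["NA", ""])
    df.columns = [str(c) for c in df.columns]
    return AbundanceMatrix(data=df.astype(float), groups=groups, state="raw")


def check_inputs(cfg: RunConfig) -> list[str]:
    """Validate files, design, and id overlap; returns diagnostics (warnings)."""
    diagnostics: list[str] = []
    for name in ("metabolites", "genes", "design", "reactions", "enzymes", "pathways"):
        p = Path(getattr(cfg, name))
        if not p.exists():
            diagnostics.append(f"error: {name} file not found: {p}")
    if any(d.startswith("error") for d in diagnostics):
        return diagnostics
    groups = load_design(cfg.design)
    net = load_network(cfg.reactions, cfg.enzymes, cfg.pathways)
    metab = load_abundance_matrix(cfg.metabolites, groups)
    genes = load_abundance_matrix(cfg.genes, groups)
    mapped = len(set(metab.feature_ids) & set(net.compounds))
    if mapped < 0.10 * len(metab.feature_ids):
        diagnostics.append(
            f"warning: only {mapped}/{len(metab.feature_ids)} metabolites map to network compounds"
        )
    all_genes = {g for e in net.enzymes.values() for g in e.gene_ids}
    g_mapped = len(set(genes.feature_ids) & all_genes)
    if g_mapped == 0:
        diagnostics.append("warning: no gene/protein ids map to enzyme subunits")
    return diagnostics


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write all outputs; returns the run manifest.

    Reruns with the same config and seed are bit-identical.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "reaxpot_version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "counts": {},
        "stages": [],
    }

    def stage(name: str) -> None:
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("load")
        groups = load_design(cfg.design)
        net = load_network(cfg.reactions, cfg.enzymes, cfg.pathways)
        metab = load_abundance_matrix(cfg.metabolites, groups)
        genes = load_abundance_matrix(cfg.genes, groups)
        manifest["counts"]["metabolites_input"] = len(metab.feature_ids)
        manifest["counts"]["genes_input"] = len(genes.feature_ids)

        stage("preprocess")
        metab = impute_min(filter_missing(metab))
        genes = impute_min(filter_missing(genes))
        manifest["counts"]["metabolites_post_filter"] = len(metab.feature_ids)
        manifest["counts"]["genes_post_filter"] = len(genes.feature_ids)
        if cfg.quantile_normalize:
            metab = quantile_normalize(metab)
            genes = quantile_normalize(genes)
        activity = aggregate_enzyme_activity(genes, net.enzymes)
        metab_log = log_transform(metab, cfg.pseudo_count)
        genes_log = log_transform(genes, cfg.pseudo_count)
        metab_log.data.to_csv(out / "metabolites_log2.tsv", sep="\t")
        genes_log.data.to_csv(out / "genes_log2.tsv", sep="\t")
        mapped = [c for c in metab_log.feature_ids if c in net.compounds]
        manifest["counts"]["metabolites_kegg_mapped"] = len(mapped)
        manifest["counts"]["enzymes_measured"] = len(activity.feature_ids)

        stage("pca")
        for label, matrix, frac in (
            ("metabolites", metab_log, 1.0),
            ("genes", genes_log, cfg.pca_top_fraction),
        ):
            try:
                scores, evr = pca_summary(matrix, top_fraction=frac)
                scores["explained_1"] = evr[0]
                scores["explained_2"] = evr[1] if len(evr) > 1 else float("nan")
                scores.to_csv(out / f"pca_{label}.tsv", sep="\t")
            except ValueError as exc:
                log.warning("pca skipped for %s: %s", label, exc)

        stage("de_metabolites")
        metab_fc = call_significant(
            moderated_t_test(metab_log), alpha=cfg.alpha, fc_cutoff=cfg.fc_cutoff
        )
        metab_fc.to_csv(out / "metabolite_de.tsv", sep="\t")
        manifest["counts"]["metabolites_de"] = significance_counts(metab_fc)

        stage("reaction_potentials")
        enzyme_fc = reaction_enzyme_log2fc(net, activity, cfg.pseudo_count)
        mapped_fc = metab_fc.loc[metab_fc.index.isin(set(net.compounds))]
        results = compute_reaction_potentials(
            net, mapped_fc, enzyme_fc, cfg.allow_missing_enzyme
        )
        results = bootstrap_ranking_scores(
            results, mapped_fc, enzyme_fc, n_boot=cfg.n_boot, seed=cfg.seed
        )
        results = call_significant_reactions(results, cfg.score_cutoff, cfg.fc_cutoff)
        rxn_frame = results_to_frame(results)
        rxn_frame.to_csv(out / "reaction_potentials.tsv", sep="\t")
        with open(out / "reaction_breakdown.json", "w") as fh:
            json.dump(
                {r.reaction_id: dict(r.breakdown) for r in results}, fh, indent=1, sort_keys=True
            )
        manifest["counts"]["reactions_testable"] = len(results)
        manifest["counts"]["reactions_significant"] = int(rxn_frame["significant"].sum())

        stage("enrichment")
        sig_metab = set(mapped_fc.index[mapped_fc["significant"]])
        ora(sig_metab, set(mapped_fc.index), net.pathways, "compound", cfg.ora_min_size).to_csv(
            out / "ora_metabolites.tsv", sep="\t"
        )
        sig_rxn = {r.reaction_id for r in results if r.significant}
        ora(
            sig_rxn, {r.reaction_id for r in results}, net.pathways, "reaction", cfg.ora_min_size
        ).to_csv(out / "ora_reactions.tsv", sep="\t")

        stage("graphs")
        g = global_view(net, mapped_fc, results, hops=cfg.graph_hops)
        for fmt, suffix in (("graphml", "graphml"), ("cytoscape-json", "json"), ("html", "html")):
            export_graph(g, out / f"global_view.{suffix}", fmt)
        manifest["counts"]["global_view_nodes"] = g.number_of_nodes()
    except Exception as exc:
        manifest["failed_stage"] = manifest["stages"][-1] if manifest["stages"] else "init"
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise RuntimeError(f"stage {manifest['failed_stage']!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
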