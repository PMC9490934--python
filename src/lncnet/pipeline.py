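"""End-to-end orchestration: simulate/load -> DE -> network -> module-trait
-> hubs -> enrichment, with every intermediate written as TSV plus a JSON
run report.

The pipeline consumes either a synthetic block (the generator provides
expression, annotation, samples, interaction graph and gene sets with
planted ground truth) or paths to real input files. Identical config and
seed produce byte-identical outputs; all stage parameters live in one
config object whose defaults are the package defaults documented in
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment, hubs, io, network, synthetic, traits

logger = logging.getLogger(__name__)


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """All inputs and stage parameters for one run.

    Either ``synthetic`` or ``expression_path``/``annotation_path``/
    ``samples_path`` must be provided.
    """

    # inputs
    synthetic: synthetic.SyntheticConfig | None = None
    expression_path: str | None = None
    annotation_path: str | None = None
    samples_path: str | None = None
    ppi_path: str | None = None
    gmt_path: str | None = None
    # synthetic-input extras
    within_module_edge_p: float = 0.3
    background_edge_p: float = 0.01
    n_gene_sets: int = 20
    enriched_fraction: float = 0.9
    # differential expression
    baseline_day: int | None = None
    p_cut: float = 0.05
    fc_cut: float = 2.0
    # network
    beta: int | str = "auto"
    r2_cut: float = 0.85
    min_module_size: int = 20
    cut_height: float | None = None
    # module-trait
    trait_mode: str = "numeric_day"
    # hub funnel
    gs_cut: float = 0.5
    mm_cut: float = 0.9
    k_mrna: int = 20
    k_lncrna: int = 10
    r_threshold: float = 0.9
    p_threshold: float = 0.05
    # enrichment
    min_overlap: int = 5
    # bookkeeping
    seed: int = 0
    out_dir: str = "lncnet_out"

    def validate(self) -> None:
        file_mode = all(
            p is not None
            for p in (self.expression_path, self.annotation_path, self.samples_path)
        )
        if self.synthetic is None and not file_mode:
            raise PipelineError(
                "config needs either a synthetic block or expression/"
                "annotation/samples paths"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**raw)
        if syn is not None:
            if "membership_range" in syn:
                syn["membership_range"] = tuple(syn["membership_range"])
            cfg.synthetic = synthetic.SyntheticConfig(**syn)
        return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def collapse_to_symbols(
    expr: pd.DataFrame,
    annotation: pd.DataFrame,
    universe: diffexpr.DEUniverse,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symbol-level expression for the united DE genes.

    Each symbol is represented by its chosen probe's expression row; the
    returned annotation is symbol-indexed.
    """
    symbols = sorted(universe.symbols)
    probes = [universe.probe_of_symbol[s] for s in symbols]
    sub = expr.loc[probes]
    sub.index = pd.Index(symbols, name="symbol")
    ann = pd.DataFrame(
        {
            "symbol": symbols,
            "biotype": [annotation.loc[p, "biotype"] for p in probes],
        },
        index=pd.Index(symbols, name="symbol"),
    )
    return sub, ann


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order; returns the run report (also written as
    ``report.json`` in the output directory)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # ---- stage 0: inputs -------------------------------------------------
    truth = None
    if config.synthetic is not None:
        syn_cfg = dataclasses.replace(config.synthetic, seed=config.seed)
        ds = synthetic.generate_dataset(syn_cfg)
        expr, annotation, samples, truth = (
            ds.expression, ds.annotation, ds.samples, ds.truth,
        )
        ppi = synthetic.generate_ppi(
            truth, annotation, config.within_module_edge_p,
            config.background_edge_p, config.seed,
        )
        gene_sets = synthetic.generate_gene_sets(
            truth, annotation, config.n_gene_sets, config.enriched_fraction,
            config.seed,
        )
        io.write_expression(expr, out / "expression.tsv")
        io.write_annotation(annotation, out / "annotation.tsv")
        io.write_samples(samples, out / "samples.tsv")
        io.write_edge_list(ppi, out / "ppi_edges.tsv")
        io.write_gmt(gene_sets, out / "gene_sets.gmt")
        truth_table = pd.DataFrame(
            {"module": truth.module_of, "u": truth.u}
        )
        truth_table.to_csv(out / "truth.tsv", sep="\t", index_label="gene_id")
    else:
        expr = io.read_expression(config.expression_path)
        annotation = io.read_annotation(config.annotation_path)
        samples = io.read_samples(config.samples_path, expr)
        ppi = (
            io.read_edge_list(config.ppi_path)
            if config.ppi_path
            else pd.DataFrame(columns=["gene_a", "gene_b"])
        )
        gene_sets = io.read_gmt(config.gmt_path) if config.gmt_path else None
    samples = samples.loc[expr.columns]
    report["n_genes_input"] = int(expr.shape[0])
    report["n_samples"] = int(expr.shape[1])

    # ---- stage 1: differential expression --------------------------------
    days = sorted(samples["day"].unique())
    baseline = config.baseline_day if config.baseline_day is not None else days[0]
    th = diffexpr.DEThresholds(p_cut=config.p_cut, fc_cut=config.fc_cut)
    de_tables = {}
    for d in days:
        if d == baseline:
            continue
        table = diffexpr.differential_probesets(expr, samples, baseline, d, th)
        de_tables[(baseline, d)] = table
        table.to_csv(out / f"de_day{baseline}_vs_day{d}.tsv", sep="\t",
                     index_label="gene_id")
    universe = diffexpr.unite_de(de_tables, annotation)
    report["de"] = {
        "baseline_day": baseline,
        "comparisons": [f"{a}_vs_{b}" for a, b in de_tables],
        "n_de_probes_lncrna": universe.n_probes_lncrna,
        "n_de_probes_mrna": universe.n_probes_mrna,
        "n_de_symbols_lncrna": len(universe.de_lncrna),
        "n_de_symbols_mrna": len(universe.de_mrna),
    }
    if not universe.symbols:
        raise PipelineError("differential expression: no passing genes")

    sym_expr, sym_ann = collapse_to_symbols(expr, annotation, universe)
    io.write_expression(sym_expr, out / "de_symbol_expression.tsv")

    # ---- stage 2: network and modules ------------------------------------
    cor = network.correlation_matrix(sym_expr)
    override = None if config.beta == "auto" else int(config.beta)
    beta, fit_table = network.pick_soft_threshold(
        cor, r2_cut=config.r2_cut, override=override
    )
    fit_table.to_csv(out / "soft_threshold_fits.tsv", sep="\t")
    adj = network.soft_adjacency(cor, beta)
    tom = network.topological_overlap(adj)
    dissim = 1.0 - tom
    np.fill_diagonal(dissim.values, 0.0)
    dend = network.average_linkage(dissim)
    modules = network.hybrid_tree_cut(
        dend, dissim, min_module_size=config.min_module_size,
        cut_height=config.cut_height,
    )
    merge_table = pd.DataFrame(
        dend.merges, columns=["left", "right", "height", "n_leaves"]
    )
    merge_table.to_csv(out / "dendrogram_merges.tsv", sep="\t", index_label="step")
    modules.labels.to_frame().to_csv(out / "modules.tsv", sep="\t",
                                     index_label="symbol")
    eig = network.module_eigengenes(sym_expr, modules)
    eig.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t", index_label="module")

    comp = module_composition(modules, sym_ann)
    comp.to_csv(out / "module_composition.tsv", sep="\t")
    report["network"] = {
        "beta": beta,
        "beta_mode": "auto" if override is None else "override",
        "n_modules": len(modules.modules),
        "module_sizes": modules.sizes(),
        "n_unassigned": int((modules.labels == network.UNASSIGNED).sum()),
        "cut_height": modules.cut_height,
    }
    if not modules.modules:
        raise PipelineError("module detection: no modules found")

    # ---- stage 3: module-trait relationships -----------------------------
    design = traits.encode_traits(samples, config.trait_mode)
    mt = traits.module_trait_table(eig, design)
    mt.to_csv(out / "module_trait.tsv", sep="\t")
    indicator = traits.encode_traits(samples, "stage_indicator")
    traits.module_trait_table(eig, indicator).to_csv(
        out / "module_stage_indicator.tsv", sep="\t"
    )
    key_module = traits.select_key_module(mt, modules.sizes())
    r_key, p_key = mt.loc[(key_module, design.vectors.index[0])]
    scores = traits.gene_scores(sym_expr, modules, eig, design.primary)
    scores.to_csv(out / "gene_scores.tsv", sep="\t", index_label="symbol")
    gsmm_r, gsmm_p = traits.gs_mm_relation(scores, key_module)
    report["module_trait"] = {
        "key_module": key_module,
        "key_module_r": float(r_key),
        "key_module_p": float(p_key),
        "gs_mm_r": float(gsmm_r),
        "gs_mm_p": float(gsmm_p),
    }

    # ---- stage 4: hub funnel ---------------------------------------------
    key = hubs.filter_key_genes(
        scores, sym_ann, key_module, gs_cut=config.gs_cut, mm_cut=config.mm_cut
    )
    key.key_mrna.to_csv(out / "key_mrna.tsv", sep="\t")
    key.key_lncrna.to_csv(out / "key_lncrna.tsv", sep="\t")
    if len(ppi):
        sub_ppi = hubs.induced_subgraph(ppi, key.key_mrna.index)
        bt = hubs.betweenness(sub_ppi).reindex(key.key_mrna.index).fillna(0.0)
        bt.to_csv(out / "betweenness.tsv", sep="\t", index_label="symbol")
        top_mrnas = hubs.top_k(bt, config.k_mrna) if len(bt) else []
    else:
        logger.warning("no interaction graph given: all key mRNAs enter the "
                       "co-expression step")
        sub_ppi = ppi
        bt = pd.Series(dtype=float)
        top_mrnas = sorted(key.key_mrna.index)
    top_lncs = hubs.top_lncrnas_by_p(key, config.k_lncrna)
    net = hubs.coexpression_network(
        sym_expr, top_lncs, top_mrnas,
        r_threshold=config.r_threshold, p_threshold=config.p_threshold,
    )
    io.write_sif(net.edges, out / "coexpression_network.sif")
    net.edges.to_csv(out / "coexpression_edges.tsv", sep="\t", index=False)
    hub_set = hubs.final_hubs(net, top_mrnas, top_lncs,
                              betweenness_table=bt if len(bt) else None, key=key)
    hub_set.provenance.to_csv(out / "hub_provenance.tsv", sep="\t")
    report["hubs"] = {
        "n_key_lncrna": len(key.key_lncrna),
        "n_key_mrna": len(key.key_mrna),
        "ppi_nodes_in_module": int(len(set(sub_ppi["gene_a"]) | set(sub_ppi["gene_b"]))),
        "ppi_edges_in_module": int(len(sub_ppi)),
        "top_mrnas": top_mrnas,
        "top_lncrnas": top_lncs,
        "n_coexpression_edges": int(len(net.edges)),
        "hub_mrna": hub_set.hub_mrna,
        "hub_lncrna": hub_set.hub_lncrna,
    }

    # ---- stage 5: enrichment ---------------------------------------------
    if gene_sets is not None and len(gene_sets):
        module_symbols = sorted(modules.members(key_module))
        univ = sorted(modules.labels.index)
        enr = enrichment.hypergeom_enrich(
            module_symbols, univ, gene_sets, min_overlap=config.min_overlap
        )
        enr.to_csv(out / "enrichment.tsv", sep="\t")
        report["enrichment"] = {
            "n_sets_tested": int(len(enr)),
            "n_significant_fdr05": int((enr["fdr"] < 0.05).sum()),
            "top_set": str(enr.index[0]) if len(enr) else None,
        }

    if truth is not None:
        report["truth"] = {
            "planted_modules": list(truth.trajectories.index),
            "planted_sizes": {
                m: int((truth.module_of == m).sum())
                for m in truth.trajectories.index
            },
        }

    params = {
        f.name: getattr(config, f.name)
        for f in dataclasses.fields(config)
        if f.name not in ("synthetic", "out_dir")
    }
    if config.synthetic is not None:
        params["synthetic"] = dataclasses.asdict(config.synthetic)
    with open(out / "parameters.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(params), fh, indent=2, sort_keys=True)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report


def module_composition(
    modules: "network.ModuleAssignment", annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-module lncRNA/mRNA/total bookkeeping table.

    One row per module (decreasing total size) plus a ``total`` row;
    the row sums satisfy lncRNAs + mRNAs = all.
    """
    rows = []
    for m in modules.modules:
        members = modules.members(m)
        bt = annotation.reindex(members)["biotype"]
        n_lnc = int((bt == "lncRNA").sum())
        n_mrna = int((bt == "mRNA").sum())
        rows.append({"module": m, "lncRNAs": n_lnc, "mRNAs": n_mrna,
                     "all": n_lnc + n_mrna})
    table = pd.DataFrame(rows, columns=["module", "lncRNAs", "mRNAs", "all"])
    table = table.sort_values(["all", "module"], ascending=[False, True],
                              kind="mergesort").set_index("module")
    table.loc["total"] = table.sum()
    return table
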