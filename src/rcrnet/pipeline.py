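"""End-to-end orchestration: parse -> contextualize -> score -> agree -> extract.

A run consumes the curated interaction table (packaged by default), a set
of knockdown differential-expression tables, a drug-by-gene expression
matrix and a per-drug growth (GRmax) table, and writes the contextualized
network, filtering report, per-drug perturbation results, agreement tables
at the drug / node / path / cell-line aggregation levels with their KS D+
statistics against random baselines, the ranked target paths, the
extracted top-coherent model, and a machine-readable manifest.  Reruns
with identical inputs and seeds are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from .agreement import binarize, coherence, concordance, ks_dplus, random_baseline, subnetworks
from .bel import BackboneGraph, build_backbone, parse_statement
from .contextualize import contextualize
from .io import (
    read_drug_matrix,
    read_growth,
    read_knockdown_manifest,
    split_drug_column,
    write_results_json,
    write_results_tsv,
)
from .npa import uncertainty
from .paths import extract_model, paths_to, rank_paths
from .resources import load_aliases, load_backbone, load_roles

__all__ = ["RunConfig", "filter_drugs", "run", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run.

    Thresholds default to the pipeline's documented conventions: edge
    filtering and inference at |log2FC| > 1, p < 0.05; terminal layer at
    |log2FC| > 0.5, p < 0.01; knockdown efficiency log2FC < -1, p < 0.05;
    drug efficacy GRmax < 1; path extraction coherence > 0.6 over the top
    five paths.
    """

    seed: int
    # inputs (None -> packaged curated table / stage skipped)
    interactions: str | None = None
    kd_manifest: str | None = None
    drug_matrix: str | None = None
    growth: str | None = None
    # thresholds
    edge_fc: float = 1.0
    edge_p: float = 0.05
    terminal_fc: float = 0.5
    terminal_p: float = 0.01
    efficiency_fc: float = -1.0
    efficiency_p: float = 0.05
    grmax_threshold: float = 1.0
    min_coherence: float = 0.6
    top_k: int = 5
    max_len: int = 4
    lam: float = 1.0
    n_boot: int = 200
    n_perm: int = 100
    n_baseline: int = 1000
    zero_policy: str = "exclude"
    target: str = "PEBP1"

    def __post_init__(self):
        if not 0 <= self.edge_p <= 1 or not 0 <= self.terminal_p <= 1:
            raise ValueError("p-value thresholds must be in [0, 1]")
        if not 0 <= self.min_coherence <= 1:
            raise ValueError("min_coherence must be in [0, 1]")
        if self.max_len < 1 or self.top_k < 1:
            raise ValueError("max_len and top_k must be >= 1")


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def filter_drugs(growth: pd.DataFrame, threshold: float = 1.0) -> list[str]:
    """Drugs with at least one effective dose (min GRmax strictly < threshold).

    Drugs with no dose rows are excluded with a warning.
    """
    if growth.empty:
        raise ValueError("growth table is empty")
    kept = []
    for drug, grp in growth.groupby("drug", sort=True):
        doses = grp["grmax"].dropna()
        if doses.empty:
            log.warning("drug %s has no dose measurements; excluded", drug)
            continue
        if doses.min() < threshold:
            kept.append(str(drug))
    return kept


def _load_interactions_tsv(path: str | Path) -> BackboneGraph:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    aliases = load_aliases()
    statements = [
        parse_statement(row.statement, evidence=row.reference, aliases=aliases)
        for row in df.itertuples()
    ]
    return build_backbone(statements, roles=load_roles(), on_conflict="keep_direct")


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages and write every report table under ``outdir``."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # fail early on missing inputs
    for name in ("interactions", "kd_manifest", "drug_matrix", "growth"):
        p = getattr(config, name)
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"{name} input not found: {p}")

    counts: dict[str, object] = {}

    # stage 1: backbone
    backbone = (
        _load_interactions_tsv(config.interactions)
        if config.interactions
        else load_backbone()
    )
    counts["backbone_nodes"] = len(backbone)
    counts["backbone_edges"] = backbone.n_edges
    log.info("backbone: %d nodes, %d edges", len(backbone), backbone.n_edges)

    # stage 2: contextualization
    if config.kd_manifest is None:
        raise ValueError("a knockdown manifest is required to contextualize")
    kds = read_knockdown_manifest(config.kd_manifest)
    ctx = contextualize(
        backbone,
        kds,
        edge_fc=config.edge_fc,
        edge_p=config.edge_p,
        terminal_fc=config.terminal_fc,
        terminal_p=config.terminal_p,
        efficiency_fc=config.efficiency_fc,
        efficiency_p=config.efficiency_p,
    )
    net = ctx.network
    counts["edges_removed"] = int(len(ctx.removed))
    counts["edges_added"] = len(ctx.added)
    counts["inefficient_knockdowns"] = list(ctx.inefficient)
    log.info("contextualized: %d removed, %d added, %d inefficient knockdowns",
             len(ctx.removed), len(ctx.added), len(ctx.inefficient))

    net.backbone.to_graphml(outdir / "network.graphml")
    net.backbone.to_sif(outdir / "network.sif")
    net.terminal.to_frame().to_csv(outdir / "terminal_layer.tsv", sep="\t", index=False)
    report = ctx.removed.copy()
    report["action"] = "removed"
    added = pd.DataFrame(
        [{"source": e.source, "target": e.target, "sign": e.sign,
          "log2fc": float("nan"), "pvalue": float("nan"), "action": "added"}
         for e in ctx.added]
    )
    pd.concat([report, added], ignore_index=True).to_csv(
        outdir / "filtering_report.tsv", sep="\t", index=False
    )

    # stage 3: drug filtering and scoring
    if config.drug_matrix is None:
        raise ValueError("a drug matrix is required to score the network")
    profiles = read_drug_matrix(config.drug_matrix)
    if config.growth is not None:
        effective = set(filter_drugs(read_growth(config.growth), config.grmax_threshold))
        profiles = [p for p in profiles if split_drug_column(p.drug)[0] in effective]
        counts["effective_drugs"] = sorted(effective)
    counts["scored_profiles"] = len(profiles)
    if not profiles:
        raise ValueError("no drug profile passed the efficacy filter")

    results = [
        uncertainty(net, p, n_boot=config.n_boot, n_perm=config.n_perm,
                    seed=config.seed + 1000 + i, lam=config.lam)
        for i, p in enumerate(profiles)
    ]
    write_results_tsv(results, outdir / "perturbation_results.tsv")
    write_results_json(results, outdir / "perturbation_results.json")

    # stage 4: agreement at four aggregation levels
    subs = subnetworks(net.backbone)
    states = [binarize(r, zero_policy=config.zero_policy) for r in results]
    all_paths = paths_to(net.backbone, config.target, max_len=config.max_len)
    counts["paths_enumerated"] = len(all_paths)

    rows = []
    for st in states:
        drug, cell = split_drug_column(st.drug)
        for sub in subs:
            res = concordance(sub, st)
            if res is not None:
                rows.append({"measure": "concordance", "drug": drug, "cell_line": cell,
                             "unit_id": sub.upstream, "rate": res.rate,
                             "kappa": res.kappa, "n_comparisons": res.n_comparisons})
        for p in all_paths:
            res = coherence(p, st)
            if res is not None:
                rows.append({"measure": "coherence", "drug": drug, "cell_line": cell,
                             "unit_id": p.label(), "rate": res.rate,
                             "kappa": res.kappa, "n_comparisons": res.n_comparisons})
    agree_df = pd.DataFrame(
        rows, columns=["measure", "drug", "cell_line", "unit_id",
                       "rate", "kappa", "n_comparisons"]
    )
    agree_df.to_csv(outdir / "agreement_long.tsv", sep="\t", index=False)

    summary = {}
    levels = [
        ("drug", "concordance", "drug"), ("node", "concordance", "unit_id"),
        ("cell_line", "concordance", "cell_line"),
        ("drug_coherence", "coherence", "drug"), ("path", "coherence", "unit_id"),
        ("cell_line_coherence", "coherence", "cell_line"),
    ]
    agg_frames = []
    for level, measure, key in levels:
        part = agree_df[agree_df["measure"] == measure]
        if part.empty:
            continue
        grouped = part.groupby(key, sort=True).agg(
            rate=("rate", "mean"), kappa=("kappa", "mean"), n=("rate", "size")
        ).reset_index(names="unit_id")
        grouped.insert(0, "level", level)
        agg_frames.append(grouped)
        structures = subs if measure == "concordance" else all_paths
        baseline = random_baseline(structures, n_rep=max(1, config.n_baseline // max(1, len(structures))),
                                  seed=config.seed + 2000)
        ks = ks_dplus(grouped["rate"].tolist(), baseline, scaled=True)
        summary[level] = {
            "mean_rate": float(grouped["rate"].mean()),
            "mean_kappa": float(grouped["kappa"].mean()),
            "d_plus_scaled": ks.d_plus,
            "ks_pvalue": ks.pvalue,
            "n_units": int(len(grouped)),
        }
    if agg_frames:
        pd.concat(agg_frames, ignore_index=True).to_csv(
            outdir / "agreement_aggregated.tsv", sep="\t", index=False
        )
    with open(outdir / "agreement_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)

    # stage 5: path ranking and model extraction
    ranked = rank_paths(all_paths, results, zero_policy=config.zero_policy)
    ranked_rows = [
        {"path": rp.path.label(),
         "signs": ",".join(f"{s:+d}" for s in rp.path.signs),
         "mean_coherence": rp.mean_coherence,
         **{f"rate[{d}]": r for d, r in rp.per_drug}}
        for rp in ranked
    ]
    pd.DataFrame(ranked_rows).to_csv(outdir / "ranked_paths.tsv", sep="\t", index=False)
    model = extract_model(ranked, min_coherence=config.min_coherence,
                          top_k=config.top_k, backbone=net.backbone)
    counts["model_edges"] = model.n_edges
    model.to_sif(outdir / "model.sif")
    if model.n_edges:
        model.to_graphml(outdir / "model.graphml")
    _write_dot(model, outdir / "model.dot")

    manifest = {
        "config": asdict(config),
        "version": __version__,
        "counts": counts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


def _write_dot(model: BackboneGraph, path: Path) -> None:
    """Minimal Graphviz export; edge penwidth scales with path coherence."""
    lines = ["digraph model {"]
    for n in model.nodes:
        lines.append(f'  "{n}";')
    for e in model.edges():
        coh = model.g[e.source][e.target].get("coherence", 0.0)
        style = "normal" if e.sign > 0 else "tee"
        lines.append(
            f'  "{e.source}" -> "{e.target}" '
            f'[arrowhead={style}, penwidth={1 + 4 * coh:.2f}, label="{coh:.2f}"];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")
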