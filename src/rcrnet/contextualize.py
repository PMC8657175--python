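"""Contextualize the curated backbone with knockdown differential expression.

Knocking a gene down lowers its own product, so a curated edge ``u -> v``
with sign *s* predicts that *v* moves in direction ``-s`` when *u* is
knocked down.  Three uses are made of the knockdown tables:

* **conflict filtering** — curated edges whose target moves significantly
  in the *wrong* direction are removed;
* **edge inference** — significant movements of backbone nodes with no
  curated edge from the knocked-down gene become new data-driven edges;
* **terminal layer** — significant movements of non-backbone genes define
  each backbone node's signed downstream (terminal) gene set, the
  measurable proxy for the node's activity.

Filtering and edge inference use |log2FC| > 1 at p < 0.05; the terminal
layer uses the more permissive |log2FC| > 0.5 at p < 0.01.  Raw p-values
are thresholded (no multiplicity correction by default, matching the
upstream differential-expression convention this pipeline consumes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .bel import BackboneGraph, SignedEdge

__all__ = [
    "KnockdownDataset",
    "TranscriptLayer",
    "TwoLayerNetwork",
    "adjust_pvalues",
    "check_efficiency",
    "filter_conflicts",
    "infer_edges",
    "build_terminal",
    "contextualize",
    "ContextualizeResult",
]

log = logging.getLogger(__name__)

_REQUIRED_COLS = ("gene", "log2fc", "pvalue")


@dataclass
class KnockdownDataset:
    """Differential expression of one knockdown vs control.

    ``records`` has columns ``gene``, ``log2fc``, ``pvalue`` with one row
    per gene; the knocked-down ``target`` must itself appear among the
    records (its own fold-change is the efficiency check).
    """

    target: str
    records: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in _REQUIRED_COLS if c not in self.records.columns]
        if missing:
            raise ValueError(f"knockdown table for {self.target} lacks columns {missing}")
        if not (self.records["pvalue"].between(0, 1)).all():
            raise ValueError(f"p-values outside [0, 1] in knockdown of {self.target}")
        if not np.isfinite(self.records["log2fc"]).all():
            raise ValueError(f"non-finite log2FC in knockdown of {self.target}")

    def lookup(self, gene: str) -> tuple[float, float] | None:
        rows = self.records.loc[self.records["gene"] == gene]
        if rows.empty:
            return None
        r = rows.iloc[0]
        return float(r["log2fc"]), float(r["pvalue"])


@dataclass
class TranscriptLayer:
    """Signed terminal gene sets per backbone node.

    ``sets`` maps each backbone node to ``{gene: sign}``; ``missing`` lists
    backbone nodes with no knockdown data (their terminal set is empty).
    """

    sets: dict[str, dict[str, int]]
    missing: tuple[str, ...] = ()

    def genes(self, node: str) -> dict[str, int]:
        return self.sets.get(node, {})

    def size(self, node: str) -> int:
        return len(self.sets.get(node, {}))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"backbone_node": n, "gene": g, "sign": s}
            for n in sorted(self.sets)
            for g, s in sorted(self.sets[n].items())
        ]
        return pd.DataFrame(rows, columns=["backbone_node", "gene", "sign"])


@dataclass
class TwoLayerNetwork:
    """The scoring model: signed backbone plus terminal transcript layer."""

    backbone: BackboneGraph
    terminal: TranscriptLayer

    def __post_init__(self):
        stray = [n for n in self.terminal.sets if n not in self.backbone]
        if stray:
            raise ValueError(f"terminal layer keys not in backbone: {stray}")


def check_efficiency(kd: KnockdownDataset, fc_max: float = -1.0, p_max: float = 0.05) -> bool:
    """Did the knockdown actually lower its target?

    True iff the target's own log2FC is below ``fc_max`` (default -1) with
    p-value below ``p_max`` (default 0.05).
    """
    hit = kd.lookup(kd.target)
    if hit is None:
        raise ValueError(f"target {kd.target} absent from its own knockdown table")
    log2fc, pvalue = hit
    return log2fc < fc_max and pvalue < p_max


def adjust_pvalues(kd: KnockdownDataset, method: str = "bh") -> KnockdownDataset:
    """Return a copy with multiplicity-adjusted p-values (Benjamini-Hochberg).

    Off by default everywhere: the pipeline thresholds raw p-values, as the
    upstream differential-expression convention does; this helper supports
    the stricter variant.
    """
    if method != "bh":
        raise ValueError(f"unknown adjustment method {method!r}")
    from scipy import stats

    rec = kd.records.copy()
    rec["pvalue"] = stats.false_discovery_control(rec["pvalue"].to_numpy(), method="bh")
    return KnockdownDataset(target=kd.target, records=rec)


class FilterResult(NamedTuple):
    graph: BackboneGraph
    removed: pd.DataFrame  # source, target, sign, log2fc, pvalue


def filter_conflicts(
    backbone: BackboneGraph,
    kds: Iterable[KnockdownDataset],
    fc_abs: float = 1.0,
    p_max: float = 0.05,
) -> FilterResult:
    """Remove curated edges contradicted by the knockdown of their source.

    For edge ``u -> v`` with sign *s*, knockdown of *u* predicts *v* moves
    with sign ``-s``; the edge is removed iff *v* instead moved with sign
    ``+s``, significantly (|log2FC| > ``fc_abs``, p < ``p_max``).  Edges
    whose source has no knockdown data are kept unchanged.  Never adds
    edges.
    """
    by_target = {kd.target: kd for kd in kds}
    out = backbone.copy()
    removed = []
    for e in backbone.edges():
        kd = by_target.get(e.source)
        if kd is None:
            continue
        hit = kd.lookup(e.target)
        if hit is None:
            continue
        log2fc, pvalue = hit
        contradicts = (
            np.sign(log2fc) == e.sign and abs(log2fc) > fc_abs and pvalue < p_max
        )
        if contradicts:
            out.g.remove_edge(e.source, e.target)
            removed.append(
                {"source": e.source, "target": e.target, "sign": e.sign,
                 "log2fc": log2fc, "pvalue": pvalue}
            )
            log.info("removed contradicted edge %s -> %s (sign %+d, observed log2FC %.3g)",
                     e.source, e.target, e.sign, log2fc)
    report = pd.DataFrame(removed, columns=["source", "target", "sign", "log2fc", "pvalue"])
    return FilterResult(out, report)


def infer_edges(
    backbone: BackboneGraph,
    kds: Iterable[KnockdownDataset],
    fc_abs: float = 1.0,
    p_max: float = 0.05,
) -> list[SignedEdge]:
    """Infer data-driven edges between backbone nodes from knockdowns.

    Knockdown of *u* moving backbone node *v* significantly, with no
    curated ``u -> v`` edge, implies an edge with sign ``-sign(log2FC)``
    (*v* falling when *u* falls means *u* activates *v*).  Inferred edges
    are typed direct, provenance ``data_driven``.  Never removes edges.
    """
    new_edges = []
    nodes = set(backbone.nodes)
    for kd in kds:
        if kd.target not in nodes:
            continue
        for v in sorted(nodes - {kd.target}):
            if backbone.g.has_edge(kd.target, v):
                continue
            hit = kd.lookup(v)
            if hit is None:
                continue
            log2fc, pvalue = hit
            if abs(log2fc) > fc_abs and pvalue < p_max:
                new_edges.append(
                    SignedEdge(
                        source=kd.target,
                        target=v,
                        sign=-int(np.sign(log2fc)),
                        direct=True,
                        provenance="data_driven",
                        evidence=(f"knockdown:{kd.target}",),
                    )
                )
    return new_edges


def build_terminal(
    backbone: BackboneGraph,
    kds: Iterable[KnockdownDataset],
    fc_abs: float = 0.5,
    p_max: float = 0.01,
) -> TranscriptLayer:
    """Derive the terminal layer from the knockdowns of backbone nodes.

    Terminal genes of node *u* are the non-backbone genes moving
    significantly (|log2FC| > ``fc_abs``, p < ``p_max``) under knockdown
    of *u*, with sign ``-sign(log2FC)``.  Backbone nodes without knockdown
    data get an empty set and are reported in ``missing``.
    """
    by_target = {kd.target: kd for kd in kds}
    backbone_nodes = set(backbone.nodes)
    sets: dict[str, dict[str, int]] = {}
    missing = []
    for u in backbone.nodes:
        kd = by_target.get(u)
        if kd is None:
            sets[u] = {}
            missing.append(u)
            continue
        rec = kd.records
        mask = (
            (~rec["gene"].isin(backbone_nodes))
            & (rec["log2fc"].abs() > fc_abs)
            & (rec["pvalue"] < p_max)
        )
        hits = rec.loc[mask]
        sets[u] = {
            str(g): -int(np.sign(fc)) for g, fc in zip(hits["gene"], hits["log2fc"])
        }
    if missing:
        log.info("no knockdown data for %d backbone node(s): %s", len(missing), missing)
    return TranscriptLayer(sets=sets, missing=tuple(missing))


@dataclass
class ContextualizeResult:
    network: TwoLayerNetwork
    removed: pd.DataFrame
    added: list[SignedEdge] = field(default_factory=list)
    inefficient: tuple[str, ...] = ()


def contextualize(
    backbone: BackboneGraph,
    kds: Iterable[KnockdownDataset],
    edge_fc: float = 1.0,
    edge_p: float = 0.05,
    terminal_fc: float = 0.5,
    terminal_p: float = 0.01,
    efficiency_fc: float = -1.0,
    efficiency_p: float = 0.05,
    require_efficiency: bool = True,
    p_adjust: str | None = None,
) -> ContextualizeResult:
    """Full contextualization: efficiency gate, filter, infer, terminal layer.

    Inefficient knockdowns (target not convincingly lowered) are excluded
    from edge filtering and inference when ``require_efficiency`` is set
    (the default), and reported either way.  ``p_adjust='bh'`` applies
    Benjamini-Hochberg adjustment to each table's p-values first (off by
    default; thresholds are calibrated for raw p-values).
    """
    kds = list(kds)
    if p_adjust is not None:
        kds = [adjust_pvalues(kd, p_adjust) for kd in kds]
    inefficient = tuple(
        kd.target for kd in kds
        if not check_efficiency(kd, fc_max=efficiency_fc, p_max=efficiency_p)
    )
    if inefficient:
        log.warning("inefficient knockdowns: %s", ", ".join(inefficient))
    usable = [kd for kd in kds if kd.target not in inefficient] if require_efficiency else kds

    filtered, removed = filter_conflicts(backbone, usable, fc_abs=edge_fc, p_max=edge_p)
    added = infer_edges(filtered, usable, fc_abs=edge_fc, p_max=edge_p)
    for e in added:
        filtered.add_edge(e)
    terminal = build_terminal(filtered, usable, fc_abs=terminal_fc, p_max=terminal_p)
    net = TwoLayerNetwork(backbone=filtered, terminal=terminal)
    return ContextualizeResult(network=net, removed=removed, added=added,
                               inefficient=inefficient)
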