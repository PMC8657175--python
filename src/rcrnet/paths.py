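"""Directed-path enumeration to a target node and coherence-based ranking.

Regulatory hypotheses about a target (PEBP1 by default) are expressed as
simple directed paths ending at it.  Paths are ranked by their mean
coherence across drug perturbations, and the union of the top coherent
paths forms the extracted regulatory model.  The number of simple paths
grows combinatorially with the length bound on hub-rich graphs, so the
bound is an explicit parameter (default 4 edges).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .agreement import BinarizedState, DirectedPath, binarize, coherence
from .bel import BackboneGraph, SignedEdge
from .npa import PerturbationResult

__all__ = ["RankedPath", "paths_to", "rank_paths", "extract_model"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedPath:
    path: DirectedPath
    mean_coherence: float
    per_drug: tuple[tuple[str, float], ...]

    def per_drug_dict(self) -> dict[str, float]:
        return dict(self.per_drug)


def paths_to(backbone: BackboneGraph, target: str, max_len: int = 4) -> list[DirectedPath]:
    """All simple directed paths of <= max_len edges ending at ``target``.

    Enumerated by depth-bounded reverse traversal; the target appears only
    as the terminal node.  Returned in deterministic lexicographic order
    by node sequence.
    """
    if target not in backbone:
        raise KeyError(f"target {target!r} not in backbone")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    g = backbone.g
    found: list[DirectedPath] = []

    def extend(suffix: list[str], signs: list[int]) -> None:
        head = suffix[0]
        for pred in g.predecessors(head):
            if pred in suffix:
                continue  # simple paths only; also keeps target terminal
            sign = g[pred][head]["sign"]
            new_suffix = [pred] + suffix
            new_signs = [sign] + signs
            found.append(DirectedPath(nodes=tuple(new_suffix), signs=tuple(new_signs)))
            if len(new_signs) < max_len:
                extend(new_suffix, new_signs)

    extend([target], [])
    return sorted(found, key=lambda p: p.nodes)


def rank_paths(
    paths: list[DirectedPath],
    results: list[PerturbationResult],
    zero_policy: str = "exclude",
) -> list[RankedPath]:
    """Rank paths by mean coherence across drugs.

    Coefficients are binarized per drug; a path's score is the mean of its
    defined per-drug coherence rates.  Paths undefined for every drug are
    dropped (logged).  Sort order: descending mean coherence, then shorter
    path, then lexicographic node sequence.
    """
    if not results:
        raise ValueError("at least one drug result is required")
    states: list[BinarizedState] = [binarize(r, zero_policy=zero_policy) for r in results]
    ranked = []
    for p in paths:
        per_drug = []
        for st in states:
            res = coherence(p, st)
            if res is not None:
                per_drug.append((st.drug, res.rate))
        if not per_drug:
            log.info("path %s undefined for all drugs; dropped", p.label())
            continue
        mean = sum(r for _, r in per_drug) / len(per_drug)
        ranked.append(RankedPath(path=p, mean_coherence=mean, per_drug=tuple(per_drug)))
    ranked.sort(key=lambda rp: (-rp.mean_coherence, len(rp.path), rp.path.nodes))
    return ranked


def extract_model(
    ranked: list[RankedPath],
    min_coherence: float = 0.6,
    top_k: int = 5,
    backbone: BackboneGraph | None = None,
) -> BackboneGraph:
    """Union of the edges of the top coherent paths, as a graph.

    Keeps the ``top_k`` highest-ranked paths with mean coherence strictly
    above ``min_coherence``; each retained edge is annotated with the
    maximum mean coherence over the retained paths traversing it (the
    natural edge-thickness weight for export).  Edge metadata is copied
    from ``backbone`` when given.  An empty selection yields an empty
    graph with a warning.
    """
    if not ranked:
        raise ValueError("ranked path list is empty")
    keep = [rp for rp in ranked[:top_k] if rp.mean_coherence > min_coherence]
    model = BackboneGraph()
    if not keep:
        log.warning("no path exceeds coherence %.2f; extracted model is empty", min_coherence)
        return model
    for rp in keep:
        p = rp.path
        for i, s in enumerate(p.signs):
            u, v = p.nodes[i], p.nodes[i + 1]
            if backbone is not None and backbone.g.has_edge(u, v):
                d = backbone.g[u][v]
                edge = SignedEdge(source=u, target=v, sign=d["sign"], direct=d["direct"],
                                  provenance=d.get("provenance", "curated"),
                                  evidence=tuple(d.get("evidence", ())))
            else:
                edge = SignedEdge(source=u, target=v, sign=s, provenance="model")
            model.add_edge(edge)
            prev = model.g[u][v].get("coherence", 0.0)
            model.g[u][v]["coherence"] = max(prev, rp.mean_coherence)
    return model
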