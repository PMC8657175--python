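"""Synthetic knockdown tables, drug profiles and growth data with ground truth.

The generator emulates the statistical structure the pipeline assumes, on
an arbitrary signed backbone (the packaged curated network by default):

* **knockdowns** — one differential-expression table per backbone node.
  The target falls by ``knockdown_depth`` log2 units; curated downstream
  nodes move opposite to the edge sign by ``effect_size``; each node's
  planted terminal genes move consistently with their signs; null genes
  are pure noise.  P-values come from a two-sided z-test against the known
  Gaussian noise model, so the pipeline's raw-p thresholds are calibrated.
* **drug profiles** — each drug activates or represses a few backbone
  nodes (+/-1); activity propagates one step along backbone edges with
  attenuation 0.5; terminal genes respond as node activity times terminal
  sign times ``effect_size``, plus noise.
* **growth** — GRmax values per drug and dose in [-1, 1.3], with a
  configurable fraction of drugs ineffective at every dose (GRmax >= 1)
  to exercise the efficacy filter.

Every output is deterministic given the configuration seed, and every
planted quantity is recorded in a :class:`TruthRecord` so recovery can be
checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bel import BackboneGraph
from .contextualize import KnockdownDataset
from .npa import DrugProfile

__all__ = [
    "GeneratorConfig",
    "TruthRecord",
    "gen_knockdowns",
    "gen_drug_profiles",
    "gen_growth",
]

# fixed offsets carving independent RNG streams out of one user seed
_STREAM_TERMINAL = 0
_STREAM_KNOCKDOWN = 1
_STREAM_DRUGS = 2
_STREAM_GROWTH = 3


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic world.

    Defaults mirror the scale of the real inputs the pipeline was designed
    around: a curated backbone of a few dozen nodes, knockdowns that lower
    their target by about two log2 units, true regulatory responses of
    about 1.5 log2 units (knockdown responses in real data span several
    log2 units, and effects must clear the |log2FC| > 1 edge-filter cutoff
    to be observable at all), and measurement noise an order of magnitude
    smaller than the effects.
    """

    seed: int
    backbone: BackboneGraph | None = None  # defaults to the packaged curated network
    genes_per_node: int = 20
    n_null_genes: int = 100
    effect_size: float = 1.5
    noise_sd: float = 0.1
    knockdown_depth: float = -2.0
    attenuation: float = 0.5
    # edges whose knockdown response is generated with the WRONG direction
    # (curation-error emulation); (source, target) pairs
    inverted_edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.backbone is None:
            from .resources import load_backbone

            self.backbone = load_backbone()
        if self.genes_per_node < 0 or self.n_null_genes < 0:
            raise ValueError("gene counts must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class TruthRecord:
    """Everything that was planted, for recovery checks."""

    terminal: dict[str, dict[str, int]] = field(default_factory=dict)
    drug_effects: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)
    effective: dict[str, bool] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "terminal": self.terminal,
            "drug_effects": {
                d: [[n, s, m] for n, s, m in eff] for d, eff in self.drug_effects.items()
            },
            "effective": self.effective,
        }


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def terminal_truth(cfg: GeneratorConfig) -> dict[str, dict[str, int]]:
    """Planted signed terminal gene sets, deterministic from the seed alone."""
    rng = _rng(cfg, _STREAM_TERMINAL)
    truth = {}
    for node in cfg.backbone.nodes:
        signs = rng.integers(0, 2, size=cfg.genes_per_node) * 2 - 1
        truth[node] = {
            f"T_{node}_{j:03d}": int(s) for j, s in enumerate(signs)
        }
    return truth


def _null_genes(cfg: GeneratorConfig) -> list[str]:
    return [f"N_{j:04d}" for j in range(cfg.n_null_genes)]


def _pvalues(observed: np.ndarray, true_mean: np.ndarray, noise_sd: float) -> np.ndarray:
    """Two-sided z-test of each observation against the pure-noise null."""
    if noise_sd > 0:
        return 2.0 * stats.norm.sf(np.abs(observed) / noise_sd)
    return np.where(true_mean != 0.0, 0.0, 1.0)


def gen_knockdowns(cfg: GeneratorConfig) -> tuple[list[KnockdownDataset], TruthRecord]:
    """One knockdown differential-expression table per backbone node."""
    rng = _rng(cfg, _STREAM_KNOCKDOWN)
    truth = TruthRecord(terminal=terminal_truth(cfg))
    backbone = cfg.backbone
    nulls = _null_genes(cfg)
    all_terminal = [g for node in backbone.nodes for g in truth.terminal[node]]
    genes = list(backbone.nodes) + all_terminal + nulls
    idx = {g: i for i, g in enumerate(genes)}

    datasets = []
    for u in backbone.nodes:
        mean = np.zeros(len(genes))
        mean[idx[u]] = cfg.knockdown_depth
        for v, s in backbone.successors(u):
            flip = -1.0 if (u, v) in cfg.inverted_edges else 1.0
            mean[idx[v]] = -s * cfg.effect_size * flip
        for g, t in truth.terminal[u].items():
            mean[idx[g]] = -t * cfg.effect_size
        noise = rng.normal(0.0, cfg.noise_sd, size=len(genes)) if cfg.noise_sd > 0 else 0.0
        observed = mean + noise
        records = pd.DataFrame(
            {
                "gene": genes,
                "log2fc": observed,
                "pvalue": _pvalues(np.asarray(observed), mean, cfg.noise_sd),
            }
        )
        datasets.append(KnockdownDataset(target=u, records=records))
    return datasets, truth


def gen_drug_profiles(
    cfg: GeneratorConfig,
    n_drugs: int,
    nodes_per_drug: int = 3,
    planted: dict[str, Sequence[tuple[str, int]]] | None = None,
) -> tuple[list[DrugProfile], TruthRecord]:
    """Drug expression profiles from planted node activations.

    Each drug perturbs ``nodes_per_drug`` random backbone nodes with +/-1
    effects (or exactly the ``planted`` map when given: drug -> [(node,
    sign), ...]).  Activity propagates one step along backbone edges with
    the configured attenuation, then each active node's terminal genes
    respond proportionally, plus Gaussian noise everywhere.
    """
    if n_drugs < 1 or nodes_per_drug < 1:
        raise ValueError("n_drugs and nodes_per_drug must be >= 1")
    rng = _rng(cfg, _STREAM_DRUGS)
    backbone = cfg.backbone
    nodes = backbone.nodes
    terminal = terminal_truth(cfg)
    truth = TruthRecord(terminal=terminal)
    nulls = _null_genes(cfg)

    drug_names = (
        sorted(planted) if planted is not None else [f"drug_{i:02d}" for i in range(n_drugs)]
    )
    profiles = []
    for drug in drug_names:
        if planted is not None:
            effects = [(n, int(s)) for n, s in planted[drug]]
        else:
            picked = rng.choice(len(nodes), size=min(nodes_per_drug, len(nodes)), replace=False)
            signs = rng.integers(0, 2, size=len(picked)) * 2 - 1
            effects = [(nodes[i], int(s)) for i, s in zip(picked, signs)]
        truth.drug_effects[drug] = [(n, s, 1.0) for n, s in effects]

        activity = {n: 0.0 for n in nodes}
        for n, s in effects:
            activity[n] += float(s)
        for n, s in effects:  # one-step signed propagation, attenuated
            for v, es in backbone.successors(n):
                activity[v] += cfg.attenuation * es * s

        values = {}
        for n in nodes:
            a = activity[n]
            values[n] = a * cfg.effect_size
            for g, t in terminal[n].items():
                values[g] = a * t * cfg.effect_size
        for g in nulls:
            values[g] = 0.0
        if cfg.noise_sd > 0:
            keys = list(values)
            noise = rng.normal(0.0, cfg.noise_sd, size=len(keys))
            values = {k: values[k] + e for k, e in zip(keys, noise)}
        profiles.append(DrugProfile(drug=drug, values=values))
    return profiles, truth


def gen_growth(
    cfg: GeneratorConfig,
    n_drugs: int,
    n_doses: int = 4,
    fraction_ineffective: float = 0.2,
) -> tuple[pd.DataFrame, TruthRecord]:
    """Per-drug, per-dose GRmax values straddling the efficacy threshold.

    Exactly ``round(fraction_ineffective * n_drugs)`` drugs have GRmax >= 1
    at every dose (no growth inhibition); every other drug has at least one
    dose with GRmax < 1.
    """
    if n_drugs < 1 or n_doses < 1:
        raise ValueError("n_drugs and n_doses must be >= 1")
    if not 0 <= fraction_ineffective <= 1:
        raise ValueError("fraction_ineffective must be in [0, 1]")
    rng = _rng(cfg, _STREAM_GROWTH)
    n_ineff = round(fraction_ineffective * n_drugs)
    drugs = [f"drug_{i:02d}" for i in range(n_drugs)]
    ineffective = set(rng.choice(n_drugs, size=n_ineff, replace=False).tolist())

    rows = []
    truth = TruthRecord()
    for i, drug in enumerate(drugs):
        if i in ineffective:
            vals = rng.uniform(1.0, 1.3, size=n_doses)
        else:
            vals = rng.uniform(-1.0, 1.3, size=n_doses)
            if vals.min() >= 1.0:  # guarantee one effective dose
                vals[rng.integers(0, n_doses)] = rng.uniform(-1.0, 1.0)
        truth.effective[drug] = i not in ineffective
        for d, v in enumerate(vals):
            rows.append({"drug": drug, "dose": d, "grmax": float(v)})
    return pd.DataFrame(rows), truth
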