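"""Agreement between expected and observed perturbation directions.

Two statistics compare a signed causal model against binarized perturbation
coefficients:

* **concordance** — for one upstream node *u* and its one-edge subnetwork,
  the expected downstream sign is ``u * e`` (binarized upstream state times
  edge sign); the concordance rate is the fraction of downstream nodes
  whose observed sign matches.
* **coherence** — the same per-edge comparison averaged along a directed
  path, except the upstream state is *re-read from the observations* at
  every step as we move one edge down the path.

Both are reported as Cohen's kappa with chance agreement fixed at 50%
(binary outcomes), so kappa = 2 * rate - 1.  Distributions of agreement
rates are compared to random +/-1 baselines with the one-sided
Kolmogorov-Smirnov statistic D+.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bel import BackboneGraph
from .npa import PerturbationResult

__all__ = [
    "BinarizedState",
    "Subnetwork",
    "DirectedPath",
    "AgreementResult",
    "KSResult",
    "binarize",
    "subnetworks",
    "concordance",
    "coherence",
    "cohens_kappa",
    "ks_dplus",
    "random_baseline",
    "aggregate",
]

CHANCE_AGREEMENT = 0.5


@dataclass(frozen=True)
class BinarizedState:
    """Per-node direction of perturbation for one drug.

    ``states`` holds only nodes with a defined direction (+1 activation,
    -1 repression); excluded nodes (zero or undefined coefficient) are
    simply absent.
    """

    drug: str
    states: Mapping[str, int]

    def __post_init__(self):
        bad = {n: v for n, v in self.states.items() if v not in (-1, +1)}
        if bad:
            raise ValueError(f"binarized states must be +/-1, got {bad}")

    def __getitem__(self, node: str) -> int:
        return self.states[node]

    def __contains__(self, node: str) -> bool:
        return node in self.states


@dataclass(frozen=True)
class Subnetwork:
    """One upstream node and its signed one-edge downstream neighbours."""

    upstream: str
    downstream: tuple[tuple[str, int], ...]

    @property
    def nodes(self) -> tuple[str, ...]:
        return (self.upstream,) + tuple(v for v, _ in self.downstream)


@dataclass(frozen=True)
class DirectedPath:
    """A simple directed path v_0 -> ... -> v_k with edge signs s_1..s_k."""

    nodes: tuple[str, ...]
    signs: tuple[int, ...]

    def __post_init__(self):
        if len(self.nodes) < 2 or len(self.signs) != len(self.nodes) - 1:
            raise ValueError("path needs k >= 1 edges with one sign per edge")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path nodes must be distinct (simple path)")
        if any(s not in (-1, +1) for s in self.signs):
            raise ValueError("edge signs must be +/-1")

    def __len__(self) -> int:
        return len(self.signs)

    def label(self) -> str:
        return ">".join(self.nodes)


@dataclass(frozen=True)
class AgreementResult:
    """One agreement rate with its kappa and unit of aggregation."""

    unit: str  # drug | node | path | cell_line
    unit_id: str
    rate: float
    kappa: float
    n_comparisons: int

    def __post_init__(self):
        if self.n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")


@dataclass(frozen=True)
class KSResult:
    d_plus: float
    pvalue: float
    scaled: bool


def binarize(result: PerturbationResult, zero_policy: str = "exclude") -> BinarizedState:
    """Binarize coefficients: > 0 -> +1, < 0 -> -1.

    An exactly-zero coefficient carries no direction; the default policy
    excludes the node, ``zero_policy='positive'`` maps it to +1.
    """
    if zero_policy not in ("exclude", "positive"):
        raise ValueError(f"unknown zero_policy {zero_policy!r}")
    states = {}
    for node, c in result.coefficients.items():
        if node in result.undefined_nodes:
            continue
        if c > 0:
            states[node] = +1
        elif c < 0:
            states[node] = -1
        elif zero_policy == "positive":
            states[node] = +1
    return BinarizedState(drug=result.drug, states=states)


def subnetworks(backbone: BackboneGraph) -> list[Subnetwork]:
    """One-edge subnetworks for every backbone node with outgoing edges."""
    out = []
    for u in backbone.nodes:
        down = tuple(backbone.successors(u))
        if down:
            out.append(Subnetwork(upstream=u, downstream=down))
    return out


def concordance(sub: Subnetwork, state: BinarizedState) -> AgreementResult | None:
    """Agreement of observed downstream signs with ``u * e`` expectations.

    Returns None (undefined) when the upstream or every downstream node is
    excluded from the binarized state; undefined results are skipped in
    aggregation, never counted as zeros.
    """
    if sub.upstream not in state:
        return None
    u = state[sub.upstream]
    hits, n = 0, 0
    for v, e in sub.downstream:
        if v not in state:
            continue
        n += 1
        if u * e == state[v]:
            hits += 1
    if n == 0:
        return None
    rate = hits / n
    return AgreementResult(unit="node", unit_id=sub.upstream, rate=rate,
                           kappa=cohens_kappa(rate), n_comparisons=n)


def coherence(
    path: DirectedPath,
    state: BinarizedState,
    root_anchored: bool = False,
) -> AgreementResult | None:
    """Stepwise agreement along a path, re-reading the upstream observation.

    For each edge (v_{i-1}, v_i) with sign s_i, the expected sign of v_i is
    the *observed* state of v_{i-1} times s_i; edges with either endpoint
    excluded are unusable.  ``root_anchored=True`` instead propagates the
    root's state through the product of edge signs (sensitivity variant).
    Returns None when no edge is usable.
    """
    hits, n = 0, 0
    running = 1
    for i, s in enumerate(path.signs):
        prev, cur = path.nodes[i], path.nodes[i + 1]
        running *= s
        if cur not in state:
            continue
        if root_anchored:
            if path.nodes[0] not in state:
                continue
            expected = state[path.nodes[0]] * running
        else:
            if prev not in state:
                continue
            expected = state[prev] * s
        n += 1
        if expected == state[cur]:
            hits += 1
    if n == 0:
        return None
    rate = hits / n
    return AgreementResult(unit="path", unit_id=path.label(), rate=rate,
                           kappa=cohens_kappa(rate), n_comparisons=n)


def cohens_kappa(observed: float, expected: float = CHANCE_AGREEMENT) -> float:
    """Chance-corrected agreement (observed - expected) / (1 - expected)."""
    if not 0 <= observed <= 1:
        raise ValueError("observed agreement must be in [0, 1]")
    if not 0 <= expected < 1:
        raise ValueError("expected agreement must be in [0, 1)")
    return (observed - expected) / (1 - expected)


def ks_dplus(sample: Sequence[float], baseline: Sequence[float], scaled: bool = False) -> KSResult:
    """One-sided two-sample KS statistic D+ = sup(ECDF_baseline - ECDF_sample).

    Positive D+ means the sample is stochastically larger than the
    baseline.  The p-value uses the asymptotic one-sided bound
    exp(-2 D^2 nm/(n+m)) on the unscaled statistic; ``scaled=True``
    multiplies the reported D+ by sqrt(nm/(n+m)), the normalization under
    which the null distribution is sample-size free.
    """
    sample = np.asarray(sample, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if sample.size == 0 or baseline.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = sample.size, baseline.size
    ts = np.union1d(sample, baseline)
    f_s = np.searchsorted(np.sort(sample), ts, side="right") / n
    f_b = np.searchsorted(np.sort(baseline), ts, side="right") / m
    d = max(float(np.max(f_b - f_s)), 0.0)
    pvalue = math.exp(-2.0 * d * d * n * m / (n + m))
    if scaled:
        d = d * math.sqrt(n * m / (n + m))
    return KSResult(d_plus=d, pvalue=pvalue, scaled=scaled)


def random_baseline(
    structures: Sequence[Subnetwork | DirectedPath],
    n_rep: int,
    seed: int,
) -> list[float]:
    """Agreement rates under i.i.d. uniform +/-1 node states.

    For each replicate, every node involved in any structure gets an
    independent random sign and all structure rates are recomputed;
    undefined results cannot occur (all nodes get states).  Returns the
    flat list of n_rep * len(structures) rates; deterministic given seed.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    involved = sorted({n for s in structures for n in s.nodes})
    rates: list[float] = []
    for _ in range(n_rep):
        draw = rng.integers(0, 2, size=len(involved)) * 2 - 1
        state = BinarizedState(drug="random", states=dict(zip(involved, draw.tolist())))
        for s in structures:
            res = (
                concordance(s, state)
                if isinstance(s, Subnetwork)
                else coherence(s, state)
            )
            if res is not None:
                rates.append(res.rate)
    return rates


def aggregate(
    results: Iterable[tuple[str, AgreementResult]],
    unit: str,
) -> list[AgreementResult]:
    """Mean rate and kappa grouped by a unit key.

    ``results`` yields (group key, AgreementResult) pairs; undefined
    results must already have been dropped by the caller.  kappa is
    averaged over per-unit kappas (equivalently recomputed from the mean
    rate, since kappa is affine in the rate at fixed chance level).
    """
    groups: dict[str, list[AgreementResult]] = {}
    for key, res in results:
        groups.setdefault(key, []).append(res)
    out = []
    for key in sorted(groups):
        rs = groups[key]
        rate = sum(r.rate for r in rs) / len(rs)
        out.append(
            AgreementResult(unit=unit, unit_id=key, rate=rate,
                            kappa=cohens_kappa(rate), n_comparisons=len(rs))
        )
    return out
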