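"""Concordance, coherence, Cohen's kappa and the one-sided KS statistic."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcrnet.agreement import (
    BinarizedState,
    DirectedPath,
    Subnetwork,
    binarize,
    cohens_kappa,
    coherence,
    concordance,
    ks_dplus,
    random_baseline,
)
from rcrnet.npa import PerturbationResult


def state(**nodes):
    return BinarizedState(drug="d", states=nodes)


class TestBinarize:
    def _result(self, coeffs, undefined=()):
        return PerturbationResult(drug="d", coefficients=coeffs,
                                  undefined_nodes=tuple(undefined))

    def test_signs_of_nonzero_coefficients(self):
        st_ = binarize(self._result({"A": 0.12, "B": -0.05}))
        assert st_.states == {"A": +1, "B": -1}

    def test_zero_excluded_by_default(self):
        assert "A" not in binarize(self._result({"A": 0.0}))

    def test_zero_positive_policy(self):
        st_ = binarize(self._result({"A": 0.0}), zero_policy="positive")
        assert st_["A"] == +1

    def test_undefined_nodes_always_excluded(self):
        st_ = binarize(self._result({"A": 0.3}, undefined=["A"]))
        assert "A" not in st_


class TestConcordance:
    def test_perfect_agreement(self):
        sub = Subnetwork("U", (("V", +1), ("W", -1)))
        res = concordance(sub, state(U=+1, V=+1, W=-1))
        assert res.rate == 1.0 and res.kappa == 1.0 and res.n_comparisons == 2

    def test_chance_level(self):
        sub = Subnetwork("U", (("V", +1), ("W", +1)))
        res = concordance(sub, state(U=+1, V=+1, W=-1))
        assert res.rate == 0.5 and res.kappa == 0.0

    def test_full_disagreement(self):
        sub = Subnetwork("U", (("V", +1),))
        res = concordance(sub, state(U=-1, V=+1))
        assert res.rate == 0.0 and res.kappa == -1.0

    def test_excluded_upstream_or_downstream_undefined(self):
        sub = Subnetwork("U", (("V", +1),))
        assert concordance(sub, state(V=+1)) is None
        assert concordance(sub, state(U=+1)) is None

    def test_invariant_under_global_negation(self):
        sub = Subnetwork("U", (("V", +1), ("W", -1), ("X", +1)))
        s1 = state(U=+1, V=-1, W=-1, X=+1)
        s2 = BinarizedState(drug="d", states={n: -v for n, v in s1.states.items()})
        assert concordance(sub, s1).rate == concordance(sub, s2).rate


class TestCoherence:
    def test_stepwise_sign_product_all_hits(self):
        p = DirectedPath(("R", "S", "T"), (-1, -1))
        res = coherence(p, state(R=+1, S=-1, T=+1))
        assert res.rate == 1.0 and res.kappa == 1.0

    def test_upstream_state_reread_at_each_step(self):
        # edge1 expects S = R*(-1) = -1 (miss); edge2 re-reads the OBSERVED
        # S = +1, expecting T = -1 (miss): both edges disagree
        p = DirectedPath(("R", "S", "T"), (-1, -1))
        res = coherence(p, state(R=+1, S=+1, T=+1))
        assert res.rate == 0.0 and res.kappa == -1.0
        # flipping the middle observation makes both steps consistent
        assert coherence(p, state(R=+1, S=-1, T=+1)).rate == 1.0

    def test_length_one_path_equals_single_edge_concordance(self):
        p = DirectedPath(("U", "V"), (-1,))
        sub = Subnetwork("U", (("V", -1),))
        s = state(U=+1, V=-1)
        assert coherence(p, s).rate == concordance(sub, s).rate

    def test_no_usable_edges_undefined(self):
        p = DirectedPath(("A", "B", "C"), (+1, +1))
        assert coherence(p, state(A=+1)) is None

    def test_root_anchored_variant_propagates_sign_product(self):
        p = DirectedPath(("R", "S", "T"), (-1, -1))
        s = state(R=+1, S=+1, T=+1)
        # root-anchored: T expected = R * (-1)(-1) = +1 -> hit; S expected -1 -> miss
        res = coherence(p, s, root_anchored=True)
        assert res.rate == 0.5

    def test_matches_exhaustive_enumeration_oracle(self):
        """All paths (len <= 3) of random signed graphs, all +/-1 states."""
        checked = 0
        for graph_seed in range(5):
            rng = np.random.default_rng(17 + graph_seed)
            nodes = list("ABCDEF")
            edges = {}
            for u in nodes:
                for v in nodes:
                    if u != v and rng.random() < 0.4:
                        edges[(u, v)] = int(rng.integers(0, 2)) * 2 - 1

            # enumerate simple paths of length <= 3 by brute force
            paths = []
            for k in (2, 3, 4):
                for combo in itertools.permutations(nodes, k):
                    if all((combo[i], combo[i + 1]) in edges for i in range(k - 1)):
                        signs = tuple(
                            edges[(combo[i], combo[i + 1])] for i in range(k - 1)
                        )
                        paths.append(DirectedPath(tuple(combo), signs))

            for p in paths:
                k = len(p.nodes)
                for assign in itertools.product((-1, +1), repeat=k):
                    s = BinarizedState(drug="d", states=dict(zip(p.nodes, assign)))
                    # independent oracle: literal per-edge expectation count
                    hits = sum(
                        1
                        for i in range(k - 1)
                        if assign[i] * p.signs[i] == assign[i + 1]
                    )
                    expected_rate = hits / (k - 1)
                    res = coherence(p, s)
                    assert res.rate == pytest.approx(expected_rate)
                    assert res.kappa == pytest.approx(2 * expected_rate - 1)
                    checked += 1
        assert checked >= 1000


class TestKappa:
    @pytest.mark.parametrize(
        "obs, exp, expected",
        [(0.75, 0.5, 0.5), (1.0, 0.5, 1.0), (0.5, 0.5, 0.0), (0.25, 0.5, -0.5)],
    )
    def test_formula(self, obs, exp, expected):
        assert cohens_kappa(obs, exp) == pytest.approx(expected)

    def test_expected_one_is_an_error(self):
        with pytest.raises(ValueError):
            cohens_kappa(0.5, 1.0)

    @given(rate=st.floats(min_value=0, max_value=1))
    @settings(derandomize=True, max_examples=50)
    def test_affine_relation_at_chance_half(self, rate):
        assert cohens_kappa(rate) == pytest.approx(2 * rate - 1)


class TestKS:
    def test_identical_samples_give_zero(self):
        res = ks_dplus([1, 2, 3], [1, 2, 3])
        assert res.d_plus == 0.0 and res.pvalue == 1.0

    def test_disjoint_supports_give_one(self):
        res = ks_dplus([1.0] * 5, [0.0] * 5)
        assert res.d_plus == 1.0

    def test_one_sided_direction_clamped(self):
        # sample stochastically SMALLER than baseline -> D+ = 0
        res = ks_dplus([0.0] * 5, [1.0] * 5)
        assert res.d_plus == 0.0

    def test_scaled_statistic_can_exceed_one(self):
        res = ks_dplus([1.0] * 50, [0.0] * 50, scaled=True)
        assert res.d_plus == pytest.approx(math.sqrt(50 * 50 / 100))
        assert res.d_plus > 1

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            ks_dplus([], [1.0])

    @pytest.mark.parametrize("trial", range(100))
    def test_matches_brute_force_ecdf_difference(self, trial):
        rng = np.random.default_rng(trial)
        sample = rng.normal(size=rng.integers(3, 30))
        baseline = rng.normal(loc=rng.normal(), size=rng.integers(3, 30))
        res = ks_dplus(sample, baseline)
        # brute force over all breakpoints
        pts = np.concatenate([sample, baseline])
        best = 0.0
        for t in pts:
            fb = np.mean(baseline <= t)
            fs = np.mean(sample <= t)
            best = max(best, fb - fs)
        assert res.d_plus == pytest.approx(max(best, 0.0), abs=1e-12)


class TestRandomBaseline:
    def test_mean_rate_approaches_half(self):
        subs = [
            Subnetwork("U", (("V", +1), ("W", -1))),
            Subnetwork("X", (("Y", +1),)),
        ]
        rates = random_baseline(subs, n_rep=10_000, seed=1)
        assert abs(np.mean(rates) - 0.5) < 0.02

    def test_single_downstream_rates_are_binary(self):
        sub = Subnetwork("U", (("V", +1),))
        rates = random_baseline([sub], n_rep=200, seed=2)
        assert set(rates) <= {0.0, 1.0}

    def test_seed_determinism(self):
        p = DirectedPath(("A", "B", "C"), (+1, -1))
        assert random_baseline([p], 50, seed=9) == random_baseline([p], 50, seed=9)
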