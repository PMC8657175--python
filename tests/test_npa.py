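"""NPA-style scoring: terminal scores, backbone inference, amplitude, uncertainty."""

import numpy as np
import pytest
from scipy import optimize

from rcrnet.npa import (
    DrugProfile,
    infer_backbone,
    network_amplitude,
    terminal_score,
    terminal_scores,
    uncertainty,
)

from conftest import make_net


def profile(name="d", **values):
    return DrugProfile(drug=name, values=values)


class TestTerminalScore:
    def test_uniform_activation(self):
        net = make_net([], {"U": {"g1": +1, "g2": +1, "g3": +1}})
        assert terminal_score(net, profile(g1=2, g2=2, g3=2), "U") == pytest.approx(2.0)

    def test_mixed_signs_average(self):
        net = make_net([], {"U": {"g1": +1, "g2": +1, "g3": +1}})
        assert terminal_score(net, profile(g1=1, g2=1, g3=-1), "U") == pytest.approx(1 / 3)

    def test_terminal_sign_multiplies(self):
        net = make_net([], {"U": {"g1": -1}})
        assert terminal_score(net, profile(g1=2.0), "U") == pytest.approx(-2.0)

    def test_null_profile_scores_zero(self):
        net = make_net([], {"U": {"g1": +1, "g2": -1}})
        assert terminal_score(net, profile(g1=0.0, g2=0.0), "U") == 0.0

    def test_missing_genes_skipped_and_all_missing_undefined(self):
        net = make_net([], {"U": {"g1": +1, "g2": +1}})
        assert terminal_score(net, profile(g1=3.0), "U") == pytest.approx(3.0)
        assert terminal_score(net, profile(other=1.0), "U") is None

    def test_empty_terminal_set_is_undefined_not_an_exception(self):
        net = make_net([("U", "V", +1)], {"U": {"g1": +1}})
        assert terminal_score(net, profile(g1=1.0), "V") is None


class TestInferBackbone:
    def test_single_node_returns_its_anchor(self):
        net = make_net([], {"U": {"g1": +1}})
        f = infer_backbone(net, profile(g1=0.5))
        assert f["U"] == pytest.approx(0.5)

    def test_consistent_input_is_a_fixed_point(self):
        net = make_net([("A", "B", +1)], {"A": {"ga": +1}, "B": {"gb": +1}})
        f = infer_backbone(net, profile(ga=1.0, gb=1.0))
        assert f["A"] == pytest.approx(1.0) and f["B"] == pytest.approx(1.0)

    def test_repressive_edge_fixed_point(self):
        net = make_net([("A", "B", -1)], {"A": {"ga": +1}, "B": {"gb": +1}})
        f = infer_backbone(net, profile(ga=1.0, gb=-1.0))
        assert f["A"] == pytest.approx(1.0) and f["B"] == pytest.approx(-1.0)

    def test_unanchored_component_zeroed(self):
        net = make_net(
            [("A", "B", +1), ("C", "D", +1)],
            {"A": {"ga": +1}, "B": {"gb": +1}, "C": {}, "D": {}},
        )
        f = infer_backbone(net, profile(ga=1.0, gb=1.0))
        assert f["C"] == 0.0 and f["D"] == 0.0

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_generic_quadratic_minimizer(self, trial):
        """Closed-form solve equals an independent numerical minimizer to 1e-8."""
        rng = np.random.default_rng(100 + trial)
        nodes = [f"n{i}" for i in range(5)]
        edges = []
        for i in range(5):
            for j in range(5):
                if i != j and rng.random() < 0.4:
                    edges.append((nodes[i], nodes[j], int(rng.integers(0, 2)) * 2 - 1))
        terminal = {
            n: {f"g_{n}_{k}": int(rng.integers(0, 2)) * 2 - 1
                for k in range(int(rng.integers(1, 5)))}
            for n in nodes
        }
        net = make_net(edges, terminal)
        values = {g: float(rng.normal()) for n in nodes for g in terminal[n]}
        prof = DrugProfile("rand", values)
        lam = float(rng.uniform(0.3, 3.0))

        f = infer_backbone(net, prof, lam=lam)

        # independent oracle: generic minimization of the stated objective
        anchors = {
            n: (float(np.mean([s * values[g] for g, s in terminal[n].items()])),
                len(terminal[n]))
            for n in nodes
        }
        sign = {(u, v): s for u, v, s in edges}

        def residuals(x):
            fx = dict(zip(nodes, x))
            smooth = [fx[u] - s * fx[v] for (u, v), s in sign.items()]
            data = [np.sqrt(lam * w) * (fx[n] - t) for n, (t, w) in anchors.items()]
            return np.array(smooth + data)

        res = optimize.least_squares(residuals, np.zeros(len(nodes)),
                                     xtol=1e-15, ftol=1e-15, gtol=1e-15)
        ours = np.array([f[n] for n in sorted(net.backbone.nodes)])
        theirs = np.array([dict(zip(nodes, res.x))[n] for n in sorted(net.backbone.nodes)])
        assert np.max(np.abs(ours - theirs)) < 1e-8


class TestAmplitude:
    def test_null_coefficients_give_zero(self, chain_net):
        f = {n: 0.0 for n in chain_net.backbone.nodes}
        assert network_amplitude(f, chain_net) == 0.0

    def test_single_coherent_edge(self):
        net = make_net([("A", "B", +1)], {"A": {"g": +1}})
        assert network_amplitude({"A": 1.0, "B": 1.0}, net) == pytest.approx(1.0)

    def test_incoherent_edge_vanishes(self):
        net = make_net([("A", "B", +1)], {"A": {"g": +1}})
        assert network_amplitude({"A": 1.0, "B": -1.0}, net) == 0.0

    def test_no_edges_is_zero(self):
        net = make_net([], {"A": {"g": +1}})
        assert network_amplitude({"A": 3.0}, net) == 0.0

    def test_even_under_global_sign_flip(self, chain_net):
        f = {"A": 0.7, "B": -0.2, "C": 0.4}
        neg = {n: -v for n, v in f.items()}
        assert network_amplitude(f, chain_net) == pytest.approx(
            network_amplitude(neg, chain_net)
        )


class TestInvariants:
    def test_linearity_and_antisymmetry(self, chain_net):
        rng = np.random.default_rng(7)
        genes = [g for n in chain_net.terminal.sets.values() for g in n]
        values = {g: float(rng.normal()) for g in genes}
        base = infer_backbone(chain_net, DrugProfile("d", values))
        scaled = infer_backbone(
            chain_net, DrugProfile("d", {g: 3.5 * v for g, v in values.items()})
        )
        negated = infer_backbone(
            chain_net, DrugProfile("d", {g: -v for g, v in values.items()})
        )
        for n in base:
            assert scaled[n] == pytest.approx(3.5 * base[n], rel=1e-12, abs=1e-12)
            assert negated[n] == pytest.approx(-base[n], rel=1e-12, abs=1e-12)
        amp = network_amplitude(base, chain_net)
        assert network_amplitude(scaled, chain_net) == pytest.approx(
            3.5**2 * amp, rel=1e-10
        )
        assert network_amplitude(negated, chain_net) == pytest.approx(amp, rel=1e-10)


class TestUncertainty:
    def test_seed_determinism(self, chain_net):
        rng = np.random.default_rng(3)
        genes = [g for n in chain_net.terminal.sets.values() for g in n]
        prof = DrugProfile("d", {g: float(rng.normal()) for g in genes})
        a = uncertainty(chain_net, prof, n_boot=100, n_perm=19, seed=11)
        b = uncertainty(chain_net, prof, n_boot=100, n_perm=19, seed=11)
        assert a == b

    def test_small_bootstrap_rejected(self, chain_net):
        prof = DrugProfile("d", {"gA1": 1.0})
        with pytest.raises(ValueError, match="n_boot"):
            uncertainty(chain_net, prof, n_boot=1, n_perm=10, seed=1)

    def test_ci_contains_coefficient(self, chain_net):
        rng = np.random.default_rng(5)
        genes = [g for n in chain_net.terminal.sets.values() for g in n]
        prof = DrugProfile("d", {g: float(rng.normal()) for g in genes})
        res = uncertainty(chain_net, prof, n_boot=100, n_perm=19, seed=2)
        for n, c in res.coefficients.items():
            assert res.ci_low[n] <= c <= res.ci_high[n]

    def test_ci_width_shrinks_with_terminal_set_size(self):
        rng = np.random.default_rng(9)
        widths = []
        for size in (10, 160):
            terminal = {"U": {f"g{k}": +1 for k in range(size)}}
            net = make_net([], terminal)
            values = {f"g{k}": 1.0 + float(rng.normal(0, 0.5)) for k in range(size)}
            res = uncertainty(net, DrugProfile("d", values), n_boot=400, n_perm=1, seed=4)
            widths.append(res.ci_high["U"] - res.ci_low["U"])
        assert widths[1] < widths[0] / 2

    def test_permutation_pvalues_uniform_under_null(self):
        """On exchangeable (null) profiles the permutation p-value is uniform."""
        from scipy import stats

        terminal = {
            "A": {f"a{k}": (+1 if k % 2 else -1) for k in range(6)},
            "B": {f"b{k}": (+1 if k % 3 else -1) for k in range(6)},
        }
        net = make_net([("A", "B", +1)], terminal)
        genes = [g for d in terminal.values() for g in d]
        rng = np.random.default_rng(42)
        n_perm = 39
        pvals = []
        for rep in range(200):
            prof = DrugProfile("null", {g: float(rng.normal()) for g in genes})
            res = uncertainty(net, prof, n_boot=100, n_perm=n_perm, seed=10_000 + rep)
            pvals.append(res.pvalue)
        # p-values live on the lattice {1/(n+1), ..., 1}; compare to U(0,1]
        d, p = stats.kstest(pvals, "uniform")
        assert p > 0.01
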