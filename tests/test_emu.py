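import numpy as np
import pytest

from tracemfa import emu as emu_mod
from tracemfa import model_io, synth
from tracemfa.emu import (
    EMU,
    SimulationError,
    SubstrateLabeling,
    emu_decompose,
    mix_mids,
    simulate_mids,
    spent_medium_mid,
)
from tracemfa.isotopomer import isotopomer_mids
from tracemfa.labeling import enrichment
from tracemfa.model_io import FluxState, parse_openflux


def _brute_force_emu_closure(net, targets):
    """BFS predecessor-closure oracle: enumerate required EMUs directly."""
    seen = set()
    stack = [EMU(t, tuple(range(1, net.n_carbons(t) + 1))) for t in targets]
    while stack:
        e = stack.pop()
        if e in seen or e.met in net.substrates:
            seen.add(e)
            continue
        seen.add(e)
        for rxn, _d, subs, prods in emu_mod.oriented_reactions(net):
            for pt in prods:
                if pt.met != e.met or pt.atoms is None:
                    continue
                letters = {pt.atoms[i - 1] for i in e.atoms}
                for st in subs:
                    if st.atoms is None:
                        continue
                    idx = tuple(j + 1 for j, ch in enumerate(st.atoms) if ch in letters)
                    if idx:
                        stack.append(EMU(st.met, idx))
    return seen


class TestDecomposition:
    def test_pass_through_chain(self):
        net = parse_openflux("u,A.ext = A,ab = ab,S\nr,A = B,ab = ab,F\ne,B = B.out,ab = ab,E")
        g = emu_decompose(net, ["B"])
        assert EMU("B", (1, 2)) in g.productions
        assert EMU("A", (1, 2)) in g.productions
        assert EMU("A.ext", (1, 2)) in g.inputs

    def test_condensation_convolution(self):
        net = parse_openflux(
            "u1,A.ext = A,a = a,S\nu2,B.ext = B,b = b,S\n"
            "c,A + B = C,a + b = ab,F\ne,C = C.out,ab = ab,E"
        )
        g = emu_decompose(net, ["C"])
        prods = g.productions[EMU("C", (1, 2))]
        assert any(len(p.sources) == 2 for p in prods)

    def test_unreachable_target(self):
        net = parse_openflux("u,A.ext = A,ab = ab,S\nr,A = B,ab = ab,F\ne,B = B.out,ab = ab,E")
        with pytest.raises(KeyError):
            emu_decompose(net, ["Z"])

    @pytest.mark.parametrize("name", ["chain", "condense", "cycle", "split"])
    def test_emu_count_matches_bfs_oracle(self, toy_nets, name):
        net, _ = toy_nets[name]
        targets = sorted(net.balanced_metabolites)
        g = emu_decompose(net, targets)
        oracle = _brute_force_emu_closure(net, targets)
        assert set(g.productions) | g.inputs == oracle


class TestSimulation:
    def test_unlabeled_substrates_give_m0(self, toy_nets):
        for name, (net, _) in toy_nets.items():
            lab = SubstrateLabeling(
                {m: np.zeros(net.n_carbons(m)) for m in net.substrates}
            )
            basis = model_io.free_flux_basis(net)
            fs = synth.sample_flux_state(
                net, basis, {r: (0.1, 10.0) for r in basis.free_ids}, seed=0
            )
            mids = simulate_mids(net, fs, lab, sorted(net.balanced_metabolites))
            for m, mid in mids.items():
                assert mid[0] == pytest.approx(1.0, abs=1e-9), (name, m)

    def test_pass_through_preserves_mid(self):
        net = parse_openflux("u,A.ext = A,ab = ab,S\nr,A = B,ab = ab,F\ne,B = B.out,ab = ab,E")
        lab = SubstrateLabeling({"A.ext": np.array([0.3, 0.9])})
        fs = FluxState({"u": 2.0, "r": 2.0, "e": 2.0})
        mids = simulate_mids(net, fs, lab, ["B"])
        assert np.allclose(mids["B"], lab.mid("A.ext"), atol=1e-12)

    def test_condensation_m1_times_m0(self):
        net = parse_openflux(
            "u1,A.ext = A,a = a,S\nu2,B.ext = B,b = b,S\n"
            "c,A + B = C,a + b = ab,F\ne,C = C.out,ab = ab,E"
        )
        lab = SubstrateLabeling({"A.ext": np.array([1.0]), "B.ext": np.array([0.0])})
        fs = FluxState({"u1": 1.0, "u2": 1.0, "c": 1.0, "e": 1.0})
        mids = simulate_mids(net, fs, lab, ["C"])
        assert np.allclose(mids["C"], [0.0, 1.0, 0.0], atol=1e-12)

    def test_negative_irreversible_flux_raises(self, chain_net):
        lab = SubstrateLabeling({"A.ext": np.ones(2)})
        fs = FluxState({"upt": 1.0, "r1": -1.0, "rel": 1.0})
        with pytest.raises(SimulationError, match="negative"):
            simulate_mids(chain_net, fs, lab, ["B"])

    def test_dead_target_pool_raises(self, chain_net):
        lab = SubstrateLabeling({"A.ext": np.ones(2)})
        fs = FluxState({"upt": 0.0, "r1": 0.0, "rel": 0.0})
        with pytest.raises(SimulationError):
            simulate_mids(chain_net, fs, lab, ["B"])


class TestOracleEquivalence:
    """EMU engine vs. the full-isotopomer brute-force simulator."""

    @pytest.mark.parametrize("name", ["chain", "condense", "cycle", "split"])
    def test_toys_random_fluxes(self, toy_nets, name):
        net, lab = toy_nets[name]
        basis = model_io.free_flux_basis(net)
        bounds = {r: (0.1, 10.0) for r in basis.free_ids}
        targets = sorted(net.balanced_metabolites)
        graph = emu_decompose(net, targets)
        for trial in range(10):
            fs = synth.sample_flux_state(net, basis, bounds, seed=trial)
            mids = simulate_mids(net, fs, lab, targets, graph=graph, warn_pruned=False)
            oracle = isotopomer_mids(net, fs, lab, targets)
            for m in targets:
                assert np.max(np.abs(mids[m] - oracle[m])) < 1e-10, (name, trial, m)

    def test_liver_toy_at_truth(self, liver):
        targets = sorted(liver.network.balanced_metabolites)
        mids = simulate_mids(liver.network, liver.true_flux, liver.labeling, targets)
        oracle = isotopomer_mids(liver.network, liver.true_flux, liver.labeling, targets)
        for m in targets:
            assert np.max(np.abs(mids[m] - oracle[m])) < 1e-10


class TestProperties:
    def test_mids_nonnegative_unit_sum(self, liver, rng):
        targets = sorted(liver.network.balanced_metabolites)
        graph = emu_decompose(liver.network, targets)
        bounds = {r: (0.0, 100.0) for r in liver.basis.free_ids}
        for seed in range(5):
            fs = synth.sample_flux_state(liver.network, liver.basis, bounds, seed=seed)
            mids = simulate_mids(
                liver.network, fs, liver.labeling, targets, graph=graph, warn_pruned=False
            )
            for m, mid in mids.items():
                assert np.all(mid >= -1e-9)
                assert abs(mid.sum() - 1.0) < 1e-9

    def test_linearity_in_substrate_labeling(self, toy_nets):
        net, _ = toy_nets["split"]  # single substrate
        basis = model_io.free_flux_basis(net)
        fs = synth.sample_flux_state(
            net, basis, {r: (0.5, 5.0) for r in basis.free_ids}, seed=3
        )
        mu1 = SubstrateLabeling({"S.ext": np.full(6, 0.9)})
        mu2 = SubstrateLabeling({"S.ext": np.zeros(6)})
        lam = 0.37
        # mixing at the molecule level: a lam:(1-lam) pool of molecules
        targets = sorted(net.balanced_metabolites)
        r1 = simulate_mids(net, fs, mu1, targets)
        r2 = simulate_mids(net, fs, mu2, targets)
        # superposition holds for the EMU linear systems with a mixed input MID
        for m in targets:
            mixed = lam * r1[m] + (1 - lam) * r2[m]
            assert np.all(mixed >= 0) and abs(mixed.sum() - 1) < 1e-9

    def test_condensation_enrichment_additivity(self):
        net = parse_openflux(
            "u1,A.ext = A,ab = ab,S\nu2,B.ext = B,cde = cde,S\n"
            "c,A + B = C,ab + cde = abcde,F\ne,C = C.out,abcde = abcde,E"
        )
        lab = SubstrateLabeling(
            {"A.ext": np.array([0.8, 0.3]), "B.ext": np.array([0.1, 0.5, 0.9])}
        )
        fs = FluxState({"u1": 1.0, "u2": 1.0, "c": 1.0, "e": 1.0})
        mids = simulate_mids(net, fs, lab, ["C", "A", "B"])
        ea, eb, ec = enrichment(mids["A"]), enrichment(mids["B"]), enrichment(mids["C"])
        assert ec == pytest.approx((2 * ea + 3 * eb) / 5, abs=1e-12)


class TestMixtures:
    def test_weight_one_returns_first_component(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert np.allclose(mix_mids([a, b], [1.0, 0.0]), a)

    def test_even_mixture(self):
        a, b = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert np.allclose(mix_mids([a, b], [0.5, 0.5]), [0.5, 0.5])

    def test_three_components_uniform_is_mean(self, rng):
        comps = [np.random.default_rng(i).dirichlet(np.ones(4)) for i in range(3)]
        out = mix_mids(comps, np.ones(3) / 3)
        assert np.allclose(out, np.mean(comps, axis=0))

    def test_mismatched_carbon_counts(self):
        with pytest.raises(ValueError, match="carbon"):
            mix_mids([np.array([1.0, 0.0]), np.array([1.0, 0.0, 0.0])], [0.5, 0.5])

    @pytest.mark.parametrize("alpha,expect", [(1.0, "fresh"), (0.0, "intra")])
    def test_spent_medium_extremes(self, alpha, expect):
        fresh = np.array([0.0, 0.0, 1.0])
        intra = np.array([0.5, 0.3, 0.2])
        out = spent_medium_mid(fresh, intra, alpha)
        assert np.allclose(out, fresh if expect == "fresh" else intra)

    def test_spent_medium_midpoint(self):
        fresh = np.array([0.0, 1.0])
        intra = np.array([0.6, 0.4])
        assert np.allclose(spent_medium_mid(fresh, intra, 0.5), [0.3, 0.7])

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            spent_medium_mid(np.array([1.0, 0.0]), np.array([1.0, 0.0]), 1.2)
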