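import numpy as np
import pytest
from scipy.stats import chi2

from tracemfa import mfa, synth
from tracemfa.emu import SubstrateLabeling
from tracemfa.mfa import (
    FitProblem,
    MeasurementTable,
    assemble_measurements,
    chi2_threshold,
    fit,
    label_free_fva,
    profile_ci,
    residual_influence,
)
from tracemfa.model_io import parse_openflux


class TestAssemble:
    def test_sd_flooring(self):
        t = assemble_measurements(mi_rows=[("GLC", 0, 0.5, 0.001)])
        assert t.rows[0].sd_floored == 0.03

    def test_large_sd_not_floored(self):
        t = assemble_measurements(mi_rows=[("GLC", 0, 0.5, 0.2)])
        assert t.rows[0].sd_floored == 0.2

    def test_exchange_rows_not_floored(self):
        t = assemble_measurements(exchange_rows=[("v1", 10.0, 0.001)])
        assert t.rows[0].sd_floored == 0.001

    def test_empty_mids_gives_exchange_only(self):
        t = assemble_measurements(exchange_rows=[("v1", 1.0, 0.1), ("v2", 2.0, 0.1)])
        assert t.n == 2
        assert all(r.kind == "exchange_flux" for r in t.rows)

    def test_unknown_target_rejected(self, liver):
        with pytest.raises(KeyError, match="NOPE"):
            assemble_measurements(
                mi_rows=[("NOPE", 0, 0.5, 0.1)], model=liver.network
            )

    def test_frame_roundtrip(self, noise_free_dataset):
        table, _ = noise_free_dataset
        df = table.to_frame()
        back = MeasurementTable.from_frame(df)
        assert back.n == table.n
        for a, b in zip(table.rows, back.rows):
            assert a.kind == b.kind and a.mean == pytest.approx(b.mean)
            assert a.coeffs == b.coeffs


class TestChi2Threshold:
    def test_paper_scale_threshold(self):
        assert chi2_threshold(149, 69, 0.90) == pytest.approx(96.6, abs=0.05)

    def test_one_dof(self):
        assert chi2_threshold(2, 1, 0.90) == pytest.approx(2.706, abs=1e-3)

    def test_no_dof_error(self):
        with pytest.raises(ValueError):
            chi2_threshold(5, 5)

    def test_matches_scipy_oracle(self):
        assert chi2_threshold(30, 10, 0.95) == pytest.approx(chi2.ppf(0.95, 20))


class TestFit:
    def test_noise_free_recovery(self, liver, noise_free_dataset):
        table, truth = noise_free_dataset
        problem = liver.fit_problem(table)
        res = fit(problem, n_starts=3, seed=0)
        assert res.ssr < 1e-6
        for rxn in liver.identifiable:
            est = res.flux_state.net_flux[rxn]
            assert est == pytest.approx(truth["net_flux"][rxn], rel=1e-3, abs=1e-3)

    def test_perturbed_measurement_raises_ssr_quadratically(self, liver, noise_free_dataset):
        table, _ = noise_free_dataset
        problem = liver.fit_problem(table)
        base = fit(problem, n_starts=2, seed=0)
        # perturb one exchange measurement by 10 sd; in the linear regime the
        # SSR increase is bounded by 100 (equality when unadjustable)
        import dataclasses

        rows = [dataclasses.replace(r) for r in table.rows]
        k = next(i for i, r in enumerate(rows) if r.target == "urea_rel")
        rows[k].mean += 10 * rows[k].sd
        problem2 = liver.fit_problem(MeasurementTable(rows))
        res2 = fit(problem2, n_starts=2, seed=0, x0=base.theta)
        assert 10.0 < res2.ssr - base.ssr < 110.0

    def test_best_of_n_monotone(self, liver, noise_free_dataset):
        table, _ = noise_free_dataset
        problem = liver.fit_problem(table)
        r1 = fit(problem, n_starts=1, seed=5)
        r3 = fit(problem, n_starts=3, seed=5)
        assert r3.ssr <= r1.ssr + 1e-12
        assert r3.ssr <= min(r3.per_start_ssr) + 1e-12

    def test_deterministic_given_seed(self, liver, noise_free_dataset):
        table, _ = noise_free_dataset
        problem = liver.fit_problem(table)
        a = fit(problem, n_starts=2, seed=9)
        b = fit(problem, n_starts=2, seed=9)
        assert np.array_equal(a.theta, b.theta)


class TestResidualInfluence:
    def test_perfect_fit_zero_residuals(self, liver, noise_free_dataset):
        table, _ = noise_free_dataset
        problem = liver.fit_problem(table)
        res = fit(problem, n_starts=2, seed=0)
        df = residual_influence(res)
        assert df["residual_sq"].max() < 1e-6

    def test_sum_equals_ssr_and_sorted(self, liver):
        exp = synth.SyntheticExperiment(liver, noise_sd=0.03, seed=3)
        table, _ = synth.generate_dataset(exp)
        problem = liver.fit_problem(table)
        res = fit(problem, n_starts=2, seed=0)
        df = residual_influence(res)
        assert df["residual_sq"].sum() == pytest.approx(res.ssr, abs=1e-9)
        assert (df["residual_sq"].diff().dropna() <= 1e-12).all()

    def test_perturbed_measurement_ranks_first(self, liver, noise_free_dataset):
        table, _ = noise_free_dataset
        import dataclasses

        rows = [dataclasses.replace(r) for r in table.rows]
        k = next(i for i, r in enumerate(rows) if r.target == "arg_upt")
        rows[k].mean += 10 * rows[k].sd
        problem = liver.fit_problem(MeasurementTable(rows))
        res = fit(problem, n_starts=2, seed=0)
        df = residual_influence(res)
        assert df.iloc[0]["target"] == "arg_upt"


class TestProfileCI:
    def test_point_estimate_inside_ci(self, liver, noise_free_dataset):
        table, _ = noise_free_dataset
        problem = liver.fit_problem(table)
        res = fit(problem, n_starts=2, seed=0)
        for rxn in ("glycogen", "ala_upt"):
            ci = profile_ci(problem, res, rxn)
            assert ci.lower - 1e-6 <= ci.estimate <= ci.upper + 1e-6

    def test_directly_measured_flux_matches_linear_gaussian(self):
        # single measured uptake, no labeling info: CI ~ estimate +/- 1.645 sd
        net = parse_openflux(
            "u,A.ext = A,ab = ab,S\nr,A = B,ab = ab,F\ne,B = B.out,ab = ab,E"
        )
        lab = SubstrateLabeling({"A.ext": np.ones(2)})
        table = assemble_measurements(exchange_rows=[("u", 10.0, 2.0)], model=net)
        problem = FitProblem(net, lab, table, default_bound=100.0)
        res = fit(problem, n_starts=2, seed=0)
        ci = profile_ci(problem, res, "e")
        assert ci.estimate == pytest.approx(10.0, abs=1e-4)
        half = 1.645 * 2.0
        assert ci.lower == pytest.approx(10.0 - half, abs=0.05)
        assert ci.upper == pytest.approx(10.0 + half, abs=0.05)

    def test_unidentifiable_cycle_open_ended(self):
        # an identity-mapped futile pair leaves every measurement invariant,
        # so its flux CI spans the configured bounds
        net = parse_openflux(
            "u,A.ext = A,ab = ab,S\n"
            "f1,A = B,ab = ab,F\nf2,B = A,ab = ab,F\n"
            "e1,A = A.out,ab = ab,E\n"
        )
        lab = SubstrateLabeling({"A.ext": np.ones(2)})
        table = assemble_measurements(exchange_rows=[("u", 10.0, 1.0)], model=net)
        problem = FitProblem(net, lab, table, default_bound=100.0)
        res = fit(problem, n_starts=2, seed=0)
        ci = profile_ci(problem, res, "f1")
        assert ci.open_upper  # cycle flux indistinguishable at any level
        assert ci.upper > 99.0


class TestCarbonFlow:
    def test_single_chain_conservation(self):
        net = parse_openflux(
            "u,A.ext = A,ab = ab,S\nr,A = B,ab = ab,F\ne,B = B.out,ab = ab,E"
        )
        from tracemfa.model_io import FluxState

        flux = FluxState({"u": 5.0, "r": 5.0, "e": 5.0})
        cf = mfa.carbon_flow(net, flux, discount_exchange=False)
        assert cf.flow.loc["A.ext", "B.out"] == pytest.approx(10.0)  # 5 umol * 2 C
        assert cf.total_uptake_carbon == pytest.approx(10.0)

    def test_two_substrates_proportional_shares(self):
        net = parse_openflux(
            "u1,A.ext = A,a = a,S\nu2,B.ext = B,b = b,S\n"
            "r1,A = C,a = a,F\nr2,B = C,b = b,F\n"
            "e,C = C.out,a = a,E\n"
        )
        from tracemfa.model_io import FluxState

        flux = FluxState({"u1": 3.0, "u2": 1.0, "r1": 3.0, "r2": 1.0, "e": 4.0})
        cf = mfa.carbon_flow(net, flux, discount_exchange=False)
        assert cf.flow.loc["A.ext", "C.out"] == pytest.approx(3.0)
        assert cf.flow.loc["B.ext", "C.out"] == pytest.approx(1.0)

    def test_liver_toy_conservation_no_discount(self, liver):
        cf = mfa.carbon_flow(liver.network, liver.true_flux, discount_exchange=False)
        total_flow = cf.flow.to_numpy().sum()
        assert total_flow == pytest.approx(cf.total_uptake_carbon, rel=1e-6)

    def test_exchanged_metabolite_column_zeroed(self, liver):
        # glucose is both taken up (glc_upt) and released (glc_rel)
        cf = mfa.carbon_flow(liver.network, liver.true_flux, discount_exchange=True)
        assert "GLC.rel" in cf.discounted
        assert np.allclose(cf.flow["GLC.rel"], 0.0)
        assert np.allclose(cf.enrichments["GLC.rel"], 0.0)

    def test_shares_sum_to_one(self, liver):
        cf = mfa.carbon_flow(liver.network, liver.true_flux, discount_exchange=False)
        assert cf.product_shares.sum() == pytest.approx(1.0, rel=1e-6)


class TestLabelFreeFVA:
    def test_determined_chain(self):
        net = parse_openflux(
            "u,A.ext = A,ab = ab,S\nr,A = B,ab = ab,F\ne,B = B.out,ab = ab,E"
        )
        df = label_free_fva(net, [("u", 5.0, np.nan)])
        row = df.set_index("reaction").loc["r"]
        assert row["min"] == pytest.approx(5.0, abs=1e-6)
        assert row["max"] == pytest.approx(5.0, abs=1e-6)

    def test_internal_cycle_unbounded(self):
        net = parse_openflux(
            "u,A.ext = A,ab = ab,S\n"
            "f1,A = B,ab = ab,F\nf2,B = A,ab = ab,F\n"
            "e,B = B.out,ab = ab,E\n"
        )
        df = label_free_fva(net, [("u", 5.0, np.nan)]).set_index("reaction")
        assert not df.loc["f1", "bounded_high"]

    def test_infeasible_constraints_raise(self):
        net = parse_openflux(
            "u,A.ext = A,ab = ab,S\nr,A = B,ab = ab,F\ne,B = B.out,ab = ab,E"
        )
        with pytest.raises(ValueError, match="infeasible"):
            label_free_fva(net, [("u", 5.0, np.nan), ("e", 8.0, np.nan)])

    def test_futile_cycle_fva_wider_than_profile_ci(self, liver, noise_free_dataset):
        """Labeling resolves the glucose futile cycle; label-free FVA cannot."""
        table, truth = noise_free_dataset
        ex = [(r.target, r.mean, r.sd) for r in table.by_kind("exchange_flux")]
        lit = [(r.coeffs, r.mean, r.sd, r.source) for r in table.by_kind("literature")]
        fva = label_free_fva(liver.network, ex, lit).set_index("reaction")
        assert not fva.loc["gk", "bounded_high"]  # futile cycle is free

        problem = liver.fit_problem(table)
        res = fit(problem, n_starts=2, seed=0)
        ci = profile_ci(problem, res, "gk")
        assert not ci.open_upper
        width = ci.upper - ci.lower
        assert np.isfinite(width)
        assert ci.lower <= truth["net_flux"]["gk"] <= ci.upper
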