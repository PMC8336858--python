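"""Kinetic fixtures: steady states, exact elasticities, adaptations."""

import math

import numpy as np
import pytest

from mcainfer import fixtures as fx
from mcainfer.mca import compute_control_matrix
from mcainfer.network import build_initial_domains


class TestSteadyState:
    def test_two_step_mass_action_closed_form(self):
        """k1*S - k2*x with S=1, k1=k2=1 settles at x=1, J=1."""
        model = fx.KineticModel(
            name="toy", metabolites=["x"],
            stoichiometry={"R1": {"x": 1.0}, "R2": {"x": -1.0}},
            rate_laws={"R1": fx.mass_action(1.0, {"S": 1.0}),
                       "R2": fx.mass_action(1.0, {"x": 1.0})},
            externals={"S": 1.0},
        )
        x, J = model.solve_steady_state(np.array([0.2]))
        assert x[0] == pytest.approx(1.0, rel=1e-10)
        assert np.allclose(J, 1.0, rtol=1e-10)

    def test_residuals_below_tolerance_on_all_topologies(self, solved_topologies):
        for name, d in solved_topologies.items():
            model, x = d["model"], d["x"]
            resid = np.abs(model.odes(x)).max()
            scale = np.abs(d["J"]).max()
            assert resid < 1e-10 * scale, name
            assert np.all(x > 0), name

    def test_moiety_total_conserved_at_steady_state(self, solved_topologies):
        d = solved_topologies["moiety_cycle"]
        model, x = d["model"], d["x"]
        _, members, total = model.moieties[0]
        idx = [model.metabolites.index(m) for m in members]
        assert x[idx].sum() == pytest.approx(total, rel=1e-12)

    def test_branch_fluxes_sum_to_upstream(self, solved_topologies):
        d = solved_topologies["glycolysis_ppp"]
        J = dict(zip(d["model"].reaction_ids, d["J"]))
        assert J["HK"] == pytest.approx(J["GPI"] + J["G6PD"], rel=1e-10)

    def test_inconsistent_moiety_initial_condition_rejected(self):
        model = fx.moiety_cycle()
        x0 = fx.default_x0(model)
        x0[model.metabolites.index("A")] += 1.0
        with pytest.raises(ValueError, match="conserved total"):
            model.solve_steady_state(x0)


class TestExactElasticities:
    def test_irreversible_mm_half_saturation(self):
        """MM substrate elasticity is Km/(Km+S); at S=Km it equals 0.5."""
        model = fx.KineticModel(
            name="mm", metabolites=["s"],
            stoichiometry={"R": {"s": -1.0}},
            rate_laws={"R": fx.irreversible_mm(1.0, {"s": 2.0})},
        )
        sample = model.exact_elasticities(np.array([2.0]))
        assert sample.net[("R", "s")] == pytest.approx(0.5, rel=1e-6)

    def test_hill_far_below_half_saturation_approaches_h(self):
        model = fx.KineticModel(
            name="hill", metabolites=["s"],
            stoichiometry={"R": {"s": -1.0}},
            rate_laws={"R": fx.hill(1.0, "s", k_half=10.0, h=2.0)},
        )
        sample = model.exact_elasticities(np.array([0.01]))
        assert sample.net[("R", "s")] == pytest.approx(2.0, abs=1e-4)

    def test_first_order_mass_action_is_exactly_one(self):
        model = fx.KineticModel(
            name="ma", metabolites=["s"],
            stoichiometry={"R": {"s": -1.0}},
            rate_laws={"R": fx.mass_action(3.0, {"s": 1.0})},
        )
        sample = model.exact_elasticities(np.array([0.7]))
        assert sample.net[("R", "s")] == pytest.approx(1.0, abs=1e-9)

    def test_reversible_rho_matches_rate_decomposition(self, solved_topologies):
        d = solved_topologies["reversible_chain"]
        model, x = d["model"], d["x"]
        sample = model.exact_elasticities(x)
        c = model._conc_dict(x)
        for rid in ("R2", "R3"):
            vf, vr = model.rate_laws[rid].rates(c, 1.0)
            assert sample.rho_used[rid] == pytest.approx(vr / vf, rel=1e-12)
            assert 0.0 < sample.rho_used[rid] < 1.0

    def test_forward_reverse_linkage_of_reversible_mm(self, solved_topologies):
        """The uni-uni reversible law obeys eps^vf - eps^vr = +-1 exactly."""
        d = solved_topologies["reversible_chain"]
        sample = d["model"].exact_elasticities(d["x"])
        assert sample.forward[("R2", "x1")] - sample.reverse[("R2", "x1")] == (
            pytest.approx(1.0, abs=1e-5)
        )
        assert sample.forward[("R2", "x2")] - sample.reverse[("R2", "x2")] == (
            pytest.approx(-1.0, abs=1e-5)
        )


class TestAdaptation:
    def test_identity_perturbation_changes_nothing(self, solved_topologies):
        d = solved_topologies["glycolysis_ppp"]
        truth, _ = fx.simulate_adaptation(d["model"], d["x"], {})
        assert all(abs(v) < 1e-8 for v in truth.dlog_x.values())
        assert all(abs(v) < 1e-8 for v in truth.dlog_J.values())

    def test_uniform_doubling_scales_fluxes_not_concentrations(
        self, solved_topologies
    ):
        """Doubling every limiting rate doubles every flux (dlog2 J = 1)
        and leaves the steady-state concentrations unchanged."""
        d = solved_topologies["glycolysis_ppp"]
        model = d["model"]
        pert = {r: 2.0 for r in model.reaction_ids}
        truth, _ = fx.simulate_adaptation(model, d["x"], pert)
        assert all(v == pytest.approx(1.0, abs=1e-7) for v in truth.dlog_J.values())
        assert all(abs(v) < 1e-7 for v in truth.dlog_x.values())

    def test_small_perturbation_direction_matches_control_sign(
        self, solved_topologies
    ):
        d = solved_topologies["glycolysis_ppp"]
        model, net = d["model"], d["network"]
        C = compute_control_matrix(net, model.exact_elasticities(d["x"]))
        truth, _ = fx.simulate_adaptation(model, d["x"], {"HK": 1.2})
        for rid in model.reaction_ids:
            c = C.flux.loc[rid, "HK"]
            if abs(c) > 1e-6:
                assert math.copysign(1, truth.dlog_J[rid]) == math.copysign(1, c)

    def test_linearization_error_is_second_order(self, solved_topologies):
        """Halving the perturbation roughly quarters the prediction error."""
        d = solved_topologies["glycolysis_ppp"]
        model = d["model"]
        C = compute_control_matrix(d["network"], model.exact_elasticities(d["x"]))
        errs = []
        for h in (0.4, 0.2):
            pert = {"HK": 2.0 ** h, "G6PD": 2.0 ** (-h)}
            truth, _ = fx.simulate_adaptation(model, d["x"], pert)
            pred = C.flux.to_numpy() @ np.array(
                [truth.dlog_v[r] for r in model.reaction_ids]
            )
            actual = np.array([truth.dlog_J[r] for r in model.reaction_ids])
            errs.append(np.abs(pred - actual).max())
        ratio = errs[0] / errs[1]
        assert 4.0 * 0.8 < ratio < 4.0 * 1.3

    def test_noiseless_measurements_bracket_truth(self, solved_topologies):
        d = solved_topologies["glycolysis_ppp"]
        truth, ms = fx.simulate_adaptation(d["model"], d["x"], {"HK": 1.3},
                                           interval_halfwidth=0.1)
        for m in ms.measurements:
            lo = math.log2(m.after_lo) - math.log2(m.before)
            hi = math.log2(m.after_hi) - math.log2(m.before)
            true = (truth.dlog_J if m.kind == "flux" else truth.dlog_x)[m.id]
            assert lo - 1e-9 <= true <= hi + 1e-9
            assert hi - lo == pytest.approx(0.2, abs=1e-9)

    def test_noisy_measurements_are_seed_reproducible(self, solved_topologies):
        d = solved_topologies["glycolysis_ppp"]
        _, ms1 = fx.simulate_adaptation(d["model"], d["x"], {"HK": 1.3},
                                        noise_cv_flux=0.1, noise_cv_conc=0.2,
                                        seed=4)
        _, ms2 = fx.simulate_adaptation(d["model"], d["x"], {"HK": 1.3},
                                        noise_cv_flux=0.1, noise_cv_conc=0.2,
                                        seed=4)
        assert ms1.to_frame().equals(ms2.to_frame())

    def test_nonpositive_perturbation_factor_rejected(self, solved_topologies):
        d = solved_topologies["glycolysis_ppp"]
        with pytest.raises(ValueError):
            fx.simulate_adaptation(d["model"], d["x"], {"HK": 0.0})


class TestNetworkExport:
    def test_exported_network_is_steady_state_consistent(self, solved_topologies):
        for name, d in solved_topologies.items():
            net = d["network"]  # construction validates N.J = 0
            assert net.m == len(d["model"].reaction_ids), name

    def test_moiety_ratios_match_steady_state(self, solved_topologies):
        d = solved_topologies["glycolysis_ppp"]
        net, model, x = d["network"], d["model"], d["x"]
        grp = net.moiety_groups[0]
        rel = grp.relative_concentrations()
        i_a = model.metabolites.index(grp.members[0])
        i_b = model.metabolites.index(grp.members[1])
        assert rel[grp.members[0]] / rel[grp.members[1]] == pytest.approx(
            x[i_a] / x[i_b], rel=1e-9
        )

    def test_hill_step_exports_elasticity_upper(self, solved_topologies):
        net = solved_topologies["glycolysis_ppp"]["network"]
        assert net.reaction("PFK").elasticity_upper == {"F6P": 2.0}

    def test_end_to_end_domains_from_simulated_measurements(self, solved_topologies):
        d = solved_topologies["glycolysis_ppp"]
        _, ms = fx.simulate_adaptation(d["model"], d["x"], {"HK": 1.3})
        domains = build_initial_domains(d["network"], ms)
        assert len(domains.entries) == d["network"].n + 2 * d["network"].m
        assert domains[("flux", "HK")].restricted
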