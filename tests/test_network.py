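"""Network model, validation, measurement-to-domain conversion, TSV I/O."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mcainfer.network import (
    ConsistencyError,
    DomainError,
    DomainTable,
    MeasurementSet,
    MetabolicNetwork,
    Metabolite,
    MoietyGroup,
    NetworkError,
    Reaction,
    build_initial_domains,
    load_network,
)

from conftest import make_chain_network


CHAIN_JSON = {
    "metabolites": [{"id": m} for m in ("A", "B", "C")],
    "reactions": [
        {"id": "R1", "stoichiometry": {"A": 1}, "net_flux": 1.0},
        {"id": "R2", "stoichiometry": {"A": -1, "B": 1}, "net_flux": 1.0},
        {"id": "R3", "stoichiometry": {"B": -1, "C": 1}, "net_flux": 1.0},
        {"id": "R4", "stoichiometry": {"C": -1}, "net_flux": 1.0},
    ],
}


class TestLoadAndValidate:
    def test_linear_chain_loads_and_balances(self, tmp_path):
        path = tmp_path / "chain.json"
        path.write_text(json.dumps(CHAIN_JSON))
        net = load_network(path)
        assert net.n == 3 and net.m == 4
        assert np.allclose(net.stoichiometric_matrix() @ net.net_fluxes(), 0.0)

    def test_flux_imbalance_names_offending_metabolite(self):
        data = json.loads(json.dumps(CHAIN_JSON))
        data["reactions"][2]["net_flux"] = 2.0  # B: 1 in, 2 out
        with pytest.raises(ConsistencyError, match="B"):
            MetabolicNetwork.from_dict(data)

    def test_missing_field_named_in_error(self):
        with pytest.raises(NetworkError, match="stoichiometry"):
            MetabolicNetwork.from_dict(
                {"metabolites": [{"id": "A"}], "reactions": [{"id": "R1"}]}
            )

    def test_negative_flux_reaction_is_flipped(self):
        net = MetabolicNetwork(
            metabolites=[Metabolite(id="A")],
            reactions=[
                Reaction(id="Rin", stoichiometry={"A": 1}, net_flux=1.0),
                Reaction(id="Rout", stoichiometry={"A": 1}, net_flux=-1.0),
            ],
        )
        rout = net.reaction("Rout")
        assert rout.net_flux == 1.0 and rout.stoichiometry == {"A": -1.0}

    @pytest.mark.parametrize("rho", [1.0, 1.5, -0.1])
    def test_rho_outside_unit_interval_rejected(self, rho):
        with pytest.raises(NetworkError, match="rho"):
            make_chain_network(rhos=[rho, 0, 0, 0])

    def test_zero_flux_internal_reaction_rejected(self):
        with pytest.raises(NetworkError, match="zero net flux"):
            make_chain_network(fluxes=(0.0, 0.0, 0.0, 0.0))

    def test_zero_flux_boundary_reaction_allowed(self):
        net = MetabolicNetwork(
            metabolites=[Metabolite(id="A")],
            reactions=[
                Reaction(id="Rin", stoichiometry={"A": 1}, net_flux=1.0),
                Reaction(id="Rout", stoichiometry={"A": -1}, net_flux=1.0),
                Reaction(id="Rx", stoichiometry={"A": -1}, net_flux=0.0,
                         boundary=True),
            ],
        )
        assert net.m == 3

    def test_competitive_pair_must_link_substrate_and_product(self):
        with pytest.raises(NetworkError, match="competitive pair"):
            MetabolicNetwork(
                metabolites=[Metabolite(id="A"), Metabolite(id="B")],
                reactions=[
                    Reaction(id="R0", stoichiometry={"A": 1, "B": 1}, net_flux=1.0),
                    Reaction(id="R1", stoichiometry={"A": -1, "B": -1},
                             net_flux=1.0, competitive_pairs=[("A", "B")]),
                ],
            )

    def test_undeclared_moiety_pool_rejected(self):
        # x1 and x2 are not jointly conserved in a chain
        with pytest.raises(NetworkError, match="not conserved"):
            net = make_chain_network()
            MetabolicNetwork(
                metabolites=net.metabolites,
                reactions=net.reactions,
                moiety_groups=[MoietyGroup(id="g", members=["x1", "x2"],
                                           concentration_ratios={"x1/x2": 2.0})],
            )

    def test_moiety_ratio_graph_must_connect(self):
        grp = MoietyGroup(id="g", members=["A", "B", "C"],
                          concentration_ratios={"A/B": 2.0})
        with pytest.raises(NetworkError, match="connect"):
            grp.relative_concentrations()

    def test_moiety_relative_concentrations_resolved_through_graph(self):
        grp = MoietyGroup(id="g", members=["A", "B", "C"],
                          concentration_ratios={"A/B": 8.0, "B/C": 0.5})
        rel = grp.relative_concentrations()
        assert math.isclose(rel["A"] / rel["B"], 8.0)
        assert math.isclose(rel["B"] / rel["C"], 0.5)


class TestInitialDomains:
    def test_unmeasured_variables_get_enclosure(self):
        net = make_chain_network()
        table = build_initial_domains(net, None, enclosure=3.0)
        e = table[("conc", "x1")]
        assert (e.lb, e.ub, e.restricted) == (-3.0, 3.0, False)
        assert len(table.entries) == net.n + 2 * net.m

    @pytest.mark.parametrize(
        "before,lo,hi,expected",
        [
            (2.0, 2.0, 2.0, (0.0, 0.0)),       # no change
            (1.0, 2.0, 8.0, (1.0, 3.0)),       # log2 of 2 and 8
        ],
    )
    def test_measured_interval_log2(self, before, lo, hi, expected):
        net = make_chain_network()
        ms = MeasurementSet()
        ms.add("conc", "x1", before, lo, hi)
        table = build_initial_domains(net, ms)
        e = table[("conc", "x1")]
        assert e.restricted
        assert (e.lb, e.ub) == pytest.approx(expected)

    def test_interval_clipped_to_enclosure_with_warning(self, caplog):
        net = make_chain_network()
        ms = MeasurementSet()
        ms.add("conc", "x1", 1.0, 2.0, 1000.0)  # log2(1000) ~ 9.97
        with caplog.at_level("WARNING"):
            table = build_initial_domains(net, ms, enclosure=3.0)
        assert table[("conc", "x1")].ub == 3.0
        assert any("clipped" in r.message for r in caplog.records)

    def test_nonpositive_measurement_is_domain_error(self):
        net = make_chain_network()
        ms = MeasurementSet()
        ms.add("conc", "x1", 0.0, 1.0, 2.0)
        with pytest.raises(DomainError, match="positive"):
            build_initial_domains(net, ms)

    def test_interval_fully_outside_enclosure_is_infeasible(self):
        net = make_chain_network()
        ms = MeasurementSet()
        ms.add("conc", "x1", 1.0, 512.0, 1024.0)
        with pytest.raises(DomainError, match="enclosure"):
            build_initial_domains(net, ms)

    def test_boundary_activity_copies_flux_domain(self):
        net = MetabolicNetwork(
            metabolites=[Metabolite(id="A")],
            reactions=[
                Reaction(id="Rin", stoichiometry={"A": 1}, net_flux=1.0,
                         boundary=True),
                Reaction(id="Rout", stoichiometry={"A": -1}, net_flux=1.0),
            ],
        )
        ms = MeasurementSet()
        ms.add("flux", "Rin", 1.0, 2.0, 4.0)
        table = build_initial_domains(net, ms)
        act = table[("act", "Rin")]
        assert (act.lb, act.ub, act.restricted) == (1.0, 2.0, True)
        # non-boundary activity stays at the enclosure
        assert table[("act", "Rout")].restricted is False

    @given(
        before=st.floats(0.1, 10),
        lo=st.floats(0.1, 10),
        widen=st.floats(0, 5),
        sigma=st.floats(-1, 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_measurement_and_sigma_shift(self, before, lo, widen, sigma):
        """Widening the measured interval never narrows the domain, and
        sigma shifts measurement-derived bounds by exactly sigma (until
        clipping)."""
        net = make_chain_network()
        hi = lo * (1.0 + widen)
        ms1, ms2 = MeasurementSet(), MeasurementSet()
        ms1.add("flux", "R1", before, lo, hi)
        ms2.add("flux", "R1", before, lo * 0.9, hi * 1.1)  # wider
        E = 30.0  # large enclosure: no clipping, pure log arithmetic
        t1 = build_initial_domains(net, ms1, enclosure=E)
        t2 = build_initial_domains(net, ms2, enclosure=E)
        e1, e2 = t1[("flux", "R1")], t2[("flux", "R1")]
        assert e2.lb <= e1.lb + 1e-12 and e2.ub >= e1.ub - 1e-12
        ts = build_initial_domains(net, ms1, enclosure=E, sigma=sigma)
        es = ts[("flux", "R1")]
        assert es.lb == pytest.approx(e1.lb + sigma, abs=1e-12)
        assert es.ub == pytest.approx(e1.ub + sigma, abs=1e-12)
        # generic enclosure bounds are untouched by sigma
        assert ts[("conc", "x1")].lb == -E


class TestDomainTSV:
    def test_round_trip_identity(self, tmp_path):
        net = make_chain_network()
        ms = MeasurementSet()
        ms.add("flux", "R1", 1.0, 2.0, 4.0)
        table = build_initial_domains(net, ms)
        path = tmp_path / "domains.tsv"
        table.write_tsv(path)
        back = DomainTable.read_tsv(path, network=net)
        for key, e in table.entries.items():
            b = back[key]
            assert (b.lb, b.ub, b.restricted) == (e.lb, e.ub, e.restricted)

    def test_inverted_bounds_rejected_with_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("kind\tid\tlb\tub\trestricted\nflux\tR1\t2.0\t1.0\t1\n")
        with pytest.raises(DomainError, match="line 2"):
            DomainTable.read_tsv(path)

    def test_missing_variable_defaults_to_enclosure(self, tmp_path, caplog):
        net = make_chain_network()
        path = tmp_path / "partial.tsv"
        path.write_text("kind\tid\tlb\tub\trestricted\nflux\tR1\t0.0\t1.0\t1\n")
        with caplog.at_level("WARNING"):
            table = DomainTable.read_tsv(path, network=net, enclosure=3.0)
        assert table[("conc", "x1")].lb == -3.0
        assert any("defaulting" in r.message for r in caplog.records)

    def test_measurement_tsv_round_trip(self, tmp_path):
        ms = MeasurementSet()
        ms.add("flux", "R1", 1.0, 2.0, 4.0)
        ms.add("conc", "x1", 0.5, 0.4, 0.6)
        path = tmp_path / "ms.tsv"
        ms.write_tsv(path)
        back = MeasurementSet.read_tsv(path)
        assert back.to_frame().equals(ms.to_frame())
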