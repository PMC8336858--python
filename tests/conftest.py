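"""Shared fixtures: solved kinetic models, their exported networks, and a
vertex-enumeration oracle for the LP projections."""

from itertools import combinations

import numpy as np
import pytest

from mcainfer import fixtures as fx
from mcainfer.mca import compute_control_matrix
from mcainfer.network import MetabolicNetwork, Metabolite, Reaction


@pytest.fixture(scope="session")
def solved_topologies():
    """Every shipped topology solved to steady state, with exported network."""
    out = {}
    for model in fx.fixture_topologies():
        x0 = fx.default_x0(model)
        x, J = model.solve_steady_state(x0)
        out[model.name] = {
            "model": model,
            "x": x,
            "J": J,
            "network": model.to_network(x, J),
        }
    return out


@pytest.fixture(scope="session")
def glyco(solved_topologies):
    """The glycolysis/PPP-style branch fixture with exact control matrix."""
    d = dict(solved_topologies["glycolysis_ppp"])
    d["elasticities"] = d["model"].exact_elasticities(d["x"])
    d["control"] = compute_control_matrix(d["network"], d["elasticities"])
    return d


def make_chain_network(fluxes=(1.0, 1.0, 1.0, 1.0), rhos=None):
    """Linear chain -> x1 -> x2 -> ... -> with len(fluxes) reactions."""
    m = len(fluxes)
    n = m - 1
    rhos = rhos or [0.0] * m
    mets = [Metabolite(id=f"x{i+1}") for i in range(n)]
    rxns = []
    for j in range(m):
        st = {}
        if j > 0:
            st[f"x{j}"] = -1.0
        if j < m - 1:
            st[f"x{j+1}"] = 1.0
        rxns.append(Reaction(id=f"R{j+1}", stoichiometry=st,
                             net_flux=fluxes[j], rho=rhos[j]))
    return MetabolicNetwork(metabolites=mets, reactions=rxns)


def vertex_contract(problem, tol=1e-9):
    """Independent oracle: exhaustive vertex enumeration of the constraint
    polytope projected onto the activity coordinates.

    The equalities express concentrations/fluxes as linear images of the
    activity vector u, so the polytope is {u : G u <= h} with two
    inequality rows per variable's box bound.  Vertices are intersections
    of m active rows; per-variable minima/maxima over the vertex set equal
    the LP projections.  Only valid for problems without coupling rows.
    """
    variables = problem.variables
    n = sum(1 for k, _ in variables if k == "conc")
    m = sum(1 for k, _ in variables if k == "flux")
    assert problem.A_eq.shape[0] == n + m, "oracle does not support couplings"

    # expression of each variable as a row over u (the activity block)
    expr = np.zeros((len(variables), m))
    for i in range(n + m):
        expr[i] = problem.A_eq[i, n + m:]
    for k in range(m):
        expr[n + m + k, k] = 1.0

    G, h = [], []
    for i in range(len(variables)):
        lb, ub = problem.bounds[i]
        G.append(expr[i]); h.append(ub)
        G.append(-expr[i]); h.append(-lb)
    G, h = np.array(G), np.array(h)

    vertices = []
    for rows in combinations(range(len(h)), m):
        A = G[list(rows)]
        if np.linalg.matrix_rank(A, tol=1e-10) < m:
            continue
        u = np.linalg.lstsq(A, h[list(rows)], rcond=None)[0]
        if np.all(G @ u <= h + tol):
            vertices.append(u)
    if not vertices:
        return None  # infeasible polytope
    V = np.array(vertices)
    vals = V @ expr.T        # (n_vertices, n_variables)
    return np.column_stack([vals.min(axis=0), vals.max(axis=0)])
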