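"""Scaled control-coefficient matrices and MCA theorem checks.

Given a network at steady state and one set of scaled net-rate
elasticities, the scaled concentration control matrix ``C_x`` (n x m) and
flux control matrix ``C_J`` (m x m) are computed with a link-matrix
formulation written entirely in log coordinates, so only *ratios* of
fluxes and of moiety-partner concentrations enter:

* mass balance, perturbed and scaled:  ``N_R diag(J) dlog v = 0`` over the
  independent metabolite rows ``N_R`` of the stoichiometric matrix;
* moiety conservation in log coordinates: for a conserved pool the
  dependent member's log-deviation is a ratio-weighted combination of the
  independent members' (scaled link matrix ``L``);
* local rates: ``dlog v = dlog a + E L dlog x_ind`` with ``E`` the scaled
  elasticity matrix and ``a`` the activities.

Solving for ``dlog x_ind`` as a linear function of ``dlog a`` gives

    C_x = -L (N_R diag(J) E L)^{-1} N_R diag(J),      C_J = I + E C_x

which satisfy the summation theorems (flux rows sum to 1, concentration
rows to 0), the generalized connectivity identities ``C_J E L = 0`` and
``C_x E L = -L``, the moiety row dependencies, and the stoichiometric flux
dependencies ``N diag(J) C_J = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .elasticities import ElasticitySample
from .network import MetabolicNetwork

__all__ = [
    "ControlMatrix",
    "SingularSampleError",
    "TheoremReport",
    "compute_control_matrix",
    "check_theorems",
    "filter_by_magnitude",
    "response_coefficients",
    "linearized_prediction",
]

CONDITION_LIMIT = 1e12


class SingularSampleError(RuntimeError):
    """The sampled elasticities give a (near-)singular system matrix."""


@dataclass
class ControlMatrix:
    """Scaled concentration (n x m) and flux (m x m) control coefficients."""

    conc: pd.DataFrame        # rows: internal metabolites, cols: reactions
    flux: pd.DataFrame        # rows: fluxes, cols: reactions (activities)
    provenance: dict = field(default_factory=dict)

    @property
    def max_abs(self) -> float:
        return float(max(np.abs(self.conc.to_numpy()).max(initial=0.0),
                         np.abs(self.flux.to_numpy()).max(initial=0.0)))

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.conc.index)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.flux.index)

    def write_csv(self, conc_path, flux_path) -> None:
        self.conc.to_csv(conc_path)
        self.flux.to_csv(flux_path)

    @classmethod
    def read_csv(cls, conc_path, flux_path) -> "ControlMatrix":
        return cls(
            conc=pd.read_csv(conc_path, index_col=0),
            flux=pd.read_csv(flux_path, index_col=0),
        )


def _link_structure(network: MetabolicNetwork):
    """Dependent-metabolite bookkeeping for moiety groups.

    Returns ``(independent_idx, L)`` where ``L`` (n x n_ind) maps
    independent log-deviations to all metabolites.  The last member of each
    moiety group is the dependent one; its row carries ``-x_i/x_dep`` for
    every independent member ``i`` of the group (only concentration ratios
    are needed).
    """
    mids = network.metabolite_ids
    idx = {mid: i for i, mid in enumerate(mids)}
    dependent: dict[int, list[tuple[int, float]]] = {}
    for grp in network.moiety_groups:
        rel = grp.relative_concentrations()
        dep = grp.members[-1]
        dep_i = idx[dep]
        dependent[dep_i] = [
            (idx[m], rel[m] / rel[dep]) for m in grp.members[:-1]
        ]
    independent = [i for i in range(len(mids)) if i not in dependent]
    col_of = {i: c for c, i in enumerate(independent)}
    L = np.zeros((len(mids), len(independent)))
    for c, i in enumerate(independent):
        L[i, c] = 1.0
    for dep_i, terms in dependent.items():
        for ind_i, ratio in terms:
            L[dep_i, col_of[ind_i]] = -ratio
    return independent, L


def compute_control_matrix(
    network: MetabolicNetwork,
    sample: ElasticitySample,
    condition_limit: float = CONDITION_LIMIT,
) -> ControlMatrix:
    """Scaled control coefficients for one elasticity sample.

    Raises :class:`SingularSampleError` when the system matrix is
    structurally or numerically singular (condition number above
    ``condition_limit``); such samples are discarded upstream and counted
    in the generation tally.
    """
    N = network.stoichiometric_matrix()
    J = network.net_fluxes()
    E = sample.matrix(network)
    independent, L = _link_structure(network)

    M = N[independent, :] * J[np.newaxis, :]       # N_R diag(J)
    A = M @ E @ L
    if A.size:
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > condition_limit:
            raise SingularSampleError(
                f"system matrix condition number {cond:.3e} exceeds "
                f"{condition_limit:.1e} (sample seed={sample.seed})"
            )
        C_ind = -np.linalg.solve(A, M)
    else:
        C_ind = np.zeros((0, network.m))
    C_x = L @ C_ind
    C_J = np.eye(network.m) + E @ C_x

    return ControlMatrix(
        conc=pd.DataFrame(C_x, index=network.metabolite_ids,
                          columns=network.reaction_ids),
        flux=pd.DataFrame(C_J, index=network.reaction_ids,
                          columns=network.reaction_ids),
        provenance={"seed": sample.seed},
    )


@dataclass
class TheoremReport:
    """Max residuals of the MCA identities for one control matrix."""

    summation_flux: float
    summation_conc: float
    connectivity_flux: float
    connectivity_conc: float
    connectivity_classical: float
    moiety_rows: float
    flux_dependencies: float
    skipped_classical: list[str] = field(default_factory=list)

    def max_residual(self) -> float:
        return max(
            self.summation_flux, self.summation_conc, self.connectivity_flux,
            self.connectivity_conc, self.connectivity_classical,
            self.moiety_rows, self.flux_dependencies,
        )

    def ok(self, tol: float = 1e-8) -> bool:
        return self.max_residual() <= tol


def check_theorems(
    C: ControlMatrix,
    sample: ElasticitySample,
    network: MetabolicNetwork,
) -> TheoremReport:
    """Verify summation, connectivity, moiety and flux-dependency identities.

    The classical single-metabolite connectivity ``sum_k C^J_k eps_k = 0``
    only applies to metabolites outside moiety groups; for pool members it
    is skipped (with a note) in favour of the generalized link-matrix form
    ``C_J E L = 0`` which covers all metabolites.
    """
    C_x = C.conc.to_numpy()
    C_J = C.flux.to_numpy()
    E = sample.matrix(network)
    _, L = _link_structure(network)
    N = network.stoichiometric_matrix()
    J = network.net_fluxes()

    summation_flux = float(np.abs(C_J.sum(axis=1) - 1.0).max(initial=0.0))
    summation_conc = float(np.abs(C_x.sum(axis=1)).max(initial=0.0))
    connectivity_flux = float(np.abs(C_J @ E @ L).max(initial=0.0))
    connectivity_conc = float(np.abs(C_x @ E @ L + L).max(initial=0.0))

    in_moiety = set()
    for grp in network.moiety_groups:
        in_moiety.update(grp.members)
    free_cols = [i for i, mid in enumerate(network.metabolite_ids)
                 if mid not in in_moiety]
    classical = C_J @ E
    connectivity_classical = (
        float(np.abs(classical[:, free_cols]).max(initial=0.0)) if free_cols else 0.0
    )
    skipped = sorted(in_moiety & set(network.metabolite_ids))

    moiety_res = 0.0
    midx = {mid: i for i, mid in enumerate(network.metabolite_ids)}
    for grp in network.moiety_groups:
        rel = grp.relative_concentrations()
        # total pool conserved: sum_i (x_i/x_ref) * C_x[i, :] = 0
        combo = sum(rel[m] * C_x[midx[m], :] for m in grp.members)
        moiety_res = max(moiety_res, float(np.abs(combo).max(initial=0.0)))

    flux_dep = float(np.abs((N * J[np.newaxis, :]) @ C_J).max(initial=0.0))

    return TheoremReport(
        summation_flux=summation_flux,
        summation_conc=summation_conc,
        connectivity_flux=connectivity_flux,
        connectivity_conc=connectivity_conc,
        connectivity_classical=connectivity_classical,
        moiety_rows=moiety_res,
        flux_dependencies=flux_dep,
        skipped_classical=skipped,
    )


def filter_by_magnitude(C: ControlMatrix, bound: float = 3.5) -> bool:
    """Accept a matrix only if every control coefficient lies in [-bound, bound].

    Screens out samples with unrealistically large sensitivities.
    """
    if bound <= 0:
        raise ValueError("bound must be > 0")
    return C.max_abs <= bound


def response_coefficients(
    C: ControlMatrix, parameter_elasticities: dict[str, float]
) -> tuple[pd.Series, pd.Series]:
    """Concentration and flux response coefficients to a parameter p.

    ``R_p^x = C_x . eps_p``, ``R_p^J = C_J . eps_p`` where ``eps_p`` holds
    the parameter elasticities of each activity (missing reactions -> 0).
    """
    eps = np.array([float(parameter_elasticities.get(rid, 0.0))
                    for rid in C.reaction_ids])
    if not np.all(np.isfinite(eps)):
        raise ValueError("parameter elasticities must be finite")
    R_x = pd.Series(C.conc.to_numpy() @ eps, index=C.metabolite_ids)
    R_J = pd.Series(C.flux.to_numpy() @ eps, index=C.reaction_ids)
    return R_x, R_J


def linearized_prediction(
    C: ControlMatrix, dlog_v: dict[str, float] | np.ndarray
) -> tuple[pd.Series, pd.Series]:
    """First-order prediction of log-fold changes from activity changes.

    ``dlog x = C_x . dlog v`` and ``dlog J = C_J . dlog v``: valid in the
    proximity of the reference state, increasingly approximate for large
    perturbations.
    """
    if isinstance(dlog_v, dict):
        v = np.array([float(dlog_v.get(rid, 0.0)) for rid in C.reaction_ids])
    else:
        v = np.asarray(dlog_v, dtype=float)
    dlog_x = pd.Series(C.conc.to_numpy() @ v, index=C.metabolite_ids)
    dlog_J = pd.Series(C.flux.to_numpy() @ v, index=C.reaction_ids)
    return dlog_x, dlog_J
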