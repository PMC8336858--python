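"""LP bound contraction over log2-fold-change variables.

The inference core: given a fixed control-coefficient matrix, the measured
adaptation is expressed through equality constraints linking the
log2-fold changes of concentrations, fluxes and individual activities,

    -dlog x_i + sum_k C^x_ik dlog v_k = 0      (one row per metabolite)
    -dlog J_j + sum_k C^J_jk dlog v_k = 0      (one row per flux)
    dlog v_a - dlog v_b = 0                    (activity couplings)

with box bounds from the initial domain table.  Each of the ``n + 2m``
variables is minimised and then maximised by linear programming (2n + 4m
solves in total), yielding the tightest *final* interval consistent with
every constraint.  Final intervals containing only negative or only
positive values mark changes that are *required* (though not sufficient)
to explain the adaptation.

:class:`BoundContraction` is the model object; :meth:`BoundContraction.fit`
returns a :class:`ContractionResults` carrying the per-variable intervals,
percent gains, signs, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .mca import ControlMatrix
from .network import DomainEntry, DomainTable, MetabolicNetwork

__all__ = [
    "LPProblem",
    "BoundContraction",
    "ContractionResults",
    "build_problem",
    "check_feasible",
    "contract_bounds",
    "classify_sign",
    "percentage_gain",
]

DEFAULT_SIGN_EPS = 1e-6


class LPSolverError(RuntimeError):
    """The LP backend failed for a reason other than infeasibility."""


@dataclass
class LPProblem:
    """Standardised problem: equality system + box bounds.

    ``variables`` is the ordered list of ``(kind, id)`` of length
    ``n + 2m`` (concentrations, fluxes, activities); ``A_eq x = 0`` holds
    the control-coefficient rows and the coupling rows; ``bounds`` is an
    ``(n+2m, 2)`` array of initial lower/upper bounds.
    """

    variables: list[tuple[str, str]]
    A_eq: np.ndarray
    bounds: np.ndarray

    @property
    def n_conc(self) -> int:
        return sum(1 for k, _ in self.variables if k == "conc")

    @property
    def n_react(self) -> int:
        return sum(1 for k, _ in self.variables if k == "flux")


def build_problem(
    C: ControlMatrix,
    domains: DomainTable,
    couplings: list[list[str]] | None = None,
) -> LPProblem:
    """Assemble the equality matrix and box bounds for one problem."""
    mids, rids = C.metabolite_ids, C.reaction_ids
    n, m = len(mids), len(rids)
    variables = (
        [("conc", x) for x in mids]
        + [("flux", r) for r in rids]
        + [("act", r) for r in rids]
    )
    col = {v: i for i, v in enumerate(variables)}

    couplings = couplings or []
    c_rows = sum(len(grp) - 1 for grp in couplings)
    A = np.zeros((n + m + c_rows, n + 2 * m))
    C_x, C_J = C.conc.to_numpy(), C.flux.to_numpy()
    for i in range(n):
        A[i, i] = -1.0
        A[i, n + m:] = C_x[i, :]
    for j in range(m):
        A[n + j, n + j] = -1.0
        A[n + j, n + m:] = C_J[j, :]
    row = n + m
    for grp in couplings:
        for other in grp[1:]:
            try:
                A[row, col[("act", grp[0])]] = 1.0
                A[row, col[("act", other)]] = -1.0
            except KeyError as exc:
                raise ValueError(f"coupling references unknown reaction {exc}") from exc
            row += 1

    bounds = np.empty((n + 2 * m, 2))
    for i, key in enumerate(variables):
        try:
            entry = domains[key]
        except KeyError as exc:
            raise ValueError(f"domain table missing variable {key}") from exc
        bounds[i] = (entry.lb, entry.ub)
    return LPProblem(variables=variables, A_eq=A, bounds=bounds)


def _solve(problem: LPProblem, c: np.ndarray, method: str = "highs"):
    res = linprog(
        c,
        A_eq=problem.A_eq,
        b_eq=np.zeros(problem.A_eq.shape[0]),
        bounds=problem.bounds,
        method=method,
    )
    return res


def check_feasible(problem: LPProblem, method: str = "highs") -> bool:
    """Phase-1 feasibility of the shared constraint polytope."""
    res = _solve(problem, np.zeros(len(problem.variables)), method)
    if res.status == 0:
        return True
    if res.status == 2:
        return False
    raise LPSolverError(f"LP solver failure (status {res.status}): {res.message}")


def classify_sign(interval: tuple[float, float], eps: float = DEFAULT_SIGN_EPS) -> str:
    """'positive' if lb > eps, 'negative' if ub < -eps, else 'none'.

    A required change must exclude zero, so bounds exactly at zero
    classify as 'none'.
    """
    lb, ub = interval
    if lb > eps:
        return "positive"
    if ub < -eps:
        return "negative"
    return "none"


def percentage_gain(initial: tuple[float, float], final: tuple[float, float]) -> float:
    """100 * (initial width - final width) / initial width.

    A point-valued initial domain (width 0) cannot contract: gain 0.
    """
    w0 = initial[1] - initial[0]
    w1 = final[1] - final[0]
    if w0 <= 0:
        return 0.0
    return 100.0 * (w0 - w1) / w0


@dataclass
class ContractionResults:
    """Final domains, gains and signs for one bound-contraction problem."""

    frame: pd.DataFrame
    feasible: bool
    lp_count: int
    eps_sign: float = DEFAULT_SIGN_EPS

    @property
    def signs(self) -> dict[tuple[str, str], str]:
        return {
            (row["kind"], row["id"]): row["sign"]
            for _, row in self.frame.iterrows()
        }

    def final_domains(self, enclosure: float = 3.0, sigma: float = 0.0) -> DomainTable:
        """Final intervals repackaged as a domain table (e.g. to re-contract)."""
        table = DomainTable(enclosure=enclosure, sigma=sigma)
        for _, row in self.frame.iterrows():
            table.entries[(row["kind"], row["id"])] = DomainEntry(
                row["lb_final"], row["ub_final"], bool(row["restricted"])
            )
        return table

    def write_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        lines = [
            "Bound contraction results (log2-fold changes)",
            "=" * 72,
            f"feasible: {self.feasible}    LP solves: {self.lp_count}    "
            f"sign tolerance: {self.eps_sign:g}",
            "-" * 72,
        ]
        if self.feasible:
            lines.append(
                f"{'variable':<18}{'initial':>18}{'final':>20}{'gain%':>8}  sign"
            )
            for _, r in self.frame.iterrows():
                lines.append(
                    f"{r['kind'] + ':' + r['id']:<18}"
                    f"[{r['lb_init']:7.3f},{r['ub_init']:7.3f}]"
                    f"  [{r['lb_final']:7.3f},{r['ub_final']:7.3f}]"
                    f"{r['gain_pct']:8.1f}  {r['sign']}"
                )
            n_signs = int((self.frame["sign"] != "none").sum())
            lines.append("-" * 72)
            lines.append(
                f"fixed-sign variables: {n_signs}    "
                f"mean gain: {self.frame['gain_pct'].mean():.1f}%"
            )
        else:
            lines.append("problem infeasible: initial domains and constraints "
                         "are incompatible; formulation discarded")
        return "\n".join(lines)


def contract_bounds(
    problem: LPProblem,
    eps_sign: float = DEFAULT_SIGN_EPS,
    method: str = "highs",
    duplicate_groups: list[list[tuple[str, str]]] | None = None,
    restricted: dict[tuple[str, str], bool] | None = None,
) -> ContractionResults:
    """Minimise and maximise every variable over the constraint polytope.

    Runs exactly ``2(n + 2m)`` LPs on a feasible problem.  When
    ``duplicate_groups`` lists variables constrained equal (coupled
    activities), members after the first reuse the representative's
    interval instead of being re-solved, and ``lp_count`` reports the LPs
    actually executed.
    """
    nvar = len(problem.variables)
    restricted = restricted or {}

    if not check_feasible(problem, method):
        frame = pd.DataFrame(
            columns=["kind", "id", "lb_init", "ub_init", "lb_final", "ub_final",
                     "gain_pct", "sign", "restricted"]
        )
        return ContractionResults(frame=frame, feasible=False, lp_count=0,
                                  eps_sign=eps_sign)

    col = {v: i for i, v in enumerate(problem.variables)}
    rep: dict[int, int] = {}
    for grp in duplicate_groups or []:
        first = col[grp[0]]
        for other in grp[1:]:
            rep[col[other]] = first

    lp_count = 0
    finals = np.empty((nvar, 2))
    cache: dict[int, tuple[float, float]] = {}
    for i in range(nvar):
        if i in rep and rep[i] in cache:
            # identical by the equality constraint; intersect with own box
            lb0, ub0 = cache[rep[i]]
            finals[i] = (max(lb0, problem.bounds[i, 0]),
                         min(ub0, problem.bounds[i, 1]))
            continue
        c = np.zeros(nvar)
        c[i] = 1.0
        lo = _solve(problem, c, method)
        hi = _solve(problem, -c, method)
        lp_count += 2
        for res, what in ((lo, "min"), (hi, "max")):
            if res.status == 3:
                raise LPSolverError(
                    f"unbounded LP for {problem.variables[i]} ({what}): box "
                    "bounds should preclude this"
                )
            if res.status != 0:
                raise LPSolverError(
                    f"LP solver failure on {problem.variables[i]} ({what}), "
                    f"status {res.status}: {res.message}"
                )
        lb = max(float(lo.fun), problem.bounds[i, 0])
        ub = min(float(-hi.fun), problem.bounds[i, 1])
        if lb > ub:  # numerical crossover on a point domain
            lb = ub = 0.5 * (lb + ub)
        finals[i] = (lb, ub)
        cache[i] = (lb, ub)

    rows = []
    for i, (kind, vid) in enumerate(problem.variables):
        init = tuple(problem.bounds[i])
        fin = tuple(finals[i])
        rows.append(
            {
                "kind": kind,
                "id": vid,
                "lb_init": init[0],
                "ub_init": init[1],
                "lb_final": fin[0],
                "ub_final": fin[1],
                "gain_pct": percentage_gain(init, fin),
                "sign": classify_sign(fin, eps_sign),
                "restricted": int(restricted.get((kind, vid), False)),
            }
        )
    frame = pd.DataFrame(rows)
    return ContractionResults(frame=frame, feasible=True, lp_count=lp_count,
                              eps_sign=eps_sign)


class BoundContraction:
    """Model object for one bound-contraction problem.

    Parameters
    ----------
    control
        Fixed control-coefficient matrix (the "model description").
    domains
        Initial log2-fold-change intervals for every variable.
    couplings
        Activity-coupling groups (lists of reaction ids whose
        ``dlog v`` are constrained equal), e.g. the two transketolase
        half-reactions or a transcription-factor-coordinated block.
    """

    def __init__(
        self,
        control: ControlMatrix,
        domains: DomainTable,
        couplings: list[list[str]] | None = None,
    ):
        self.control = control
        self.domains = domains
        self.couplings = couplings or []
        self.problem = build_problem(control, domains, self.couplings)

    @classmethod
    def from_network(
        cls,
        network: MetabolicNetwork,
        control: ControlMatrix,
        domains: DomainTable,
    ) -> "BoundContraction":
        """Build with the network's own coupling groups."""
        return cls(control, domains, couplings=network.couplings)

    def check_feasible(self, method: str = "highs") -> bool:
        return check_feasible(self.problem, method)

    def fit(
        self,
        eps_sign: float = DEFAULT_SIGN_EPS,
        method: str = "highs",
        dedupe: bool = False,
    ) -> ContractionResults:
        """Contract every variable's domain.

        ``dedupe`` skips the redundant LPs of coupled activities (their
        projections coincide by construction); off by default so the
        reported count is the full ``2n + 4m`` accounting.
        """
        restricted = {
            key: self.domains[key].restricted for key in self.problem.variables
        }
        groups = None
        if dedupe:
            groups = [[("act", rid) for rid in grp] for grp in self.couplings]
        return contract_bounds(
            self.problem, eps_sign=eps_sign, method=method,
            duplicate_groups=groups, restricted=restricted,
        )
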