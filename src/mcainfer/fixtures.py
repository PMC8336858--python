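"""Synthetic kinetic models with known steady states and sensitivities.

Small ODE models (mass action, reversible Michaelis-Menten, Hill) used to
produce ground truth for the inference pipeline: exact steady states,
exact scaled elasticities, finite-difference control coefficients, and
simulated "measured" adaptations (before/after states with an optional
lognormal noise model).  The shipped glycolysis/PPP-style model replicates
a classic topology — five metabolites, six reactions, an upper-glycolysis
backbone with one oxidative-branch ramification and one NADP/NADPH moiety
cycle — with package-chosen parameters.

All fold changes are reported in log2 units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .elasticities import ElasticitySample
from .network import (
    Metabolite,
    MetabolicNetwork,
    MeasurementSet,
    MoietyGroup,
    Reaction,
)

__all__ = [
    "KineticModel",
    "GroundTruthAdaptation",
    "SteadyStateError",
    "mass_action",
    "reversible_mm",
    "irreversible_mm",
    "hill",
    "linear_chain",
    "reversible_chain",
    "branched_pathway",
    "moiety_cycle",
    "glycolysis_ppp",
    "fixture_topologies",
]

STEADY_STATE_TOL = 1e-11


class SteadyStateError(RuntimeError):
    """Steady-state solver failed to converge."""


# ---------------------------------------------------------------------------
# rate laws: callables (concentrations dict, activity scale) -> (vf, vr)
# ---------------------------------------------------------------------------

@dataclass
class RateLaw:
    """A kinetic rate law split into forward and reverse components.

    ``fn(conc) -> (vf, vr)`` with both rates >= 0; the net rate is
    ``activity * (vf - vr)`` where ``activity`` is the multiplicative
    limiting-rate scale perturbed in adaptations.
    """

    kind: str
    params: dict
    fn: object  # callable(dict) -> (float, float)

    def rates(self, conc: dict[str, float], activity: float = 1.0):
        vf, vr = self.fn(conc)
        return activity * vf, activity * vr

    def net(self, conc: dict[str, float], activity: float = 1.0) -> float:
        vf, vr = self.rates(conc, activity)
        return vf - vr


def mass_action(kf: float, substrates: dict[str, float],
                kr: float = 0.0, products: dict[str, float] | None = None) -> RateLaw:
    """v = kf * prod(S^order) - kr * prod(P^order)."""
    products = products or {}

    def fn(c):
        vf = kf * math.prod(c[s] ** o for s, o in substrates.items())
        vr = kr * math.prod(c[p] ** o for p, o in products.items()) if kr else 0.0
        return vf, vr

    return RateLaw("mass_action", {"kf": kf, "kr": kr,
                                   "substrates": substrates, "products": products}, fn)


def reversible_mm(vmax: float, s: str, p: str, ks: float, kp: float,
                  keq: float) -> RateLaw:
    """Uni-uni reversible Michaelis-Menten (Haldane form)."""

    def fn(c):
        denom = 1.0 + c[s] / ks + c[p] / kp
        vf = vmax * (c[s] / ks) / denom
        vr = vmax * (c[p] / (ks * keq)) / denom
        return vf, vr

    return RateLaw("reversible_mm",
                   {"vmax": vmax, "s": s, "p": p, "ks": ks, "kp": kp, "keq": keq}, fn)


def irreversible_mm(vmax: float, km: dict[str, float],
                    inhibitors: dict[str, float] | None = None) -> RateLaw:
    """Irreversible MM, multiplicative in substrates, with optional
    noncompetitive inhibitors (Ki per inhibitor)."""
    inhibitors = inhibitors or {}

    def fn(c):
        vf = vmax
        for s, k in km.items():
            vf *= c[s] / (k + c[s])
        for i, ki in inhibitors.items():
            vf *= ki / (ki + c[i])
        return vf, 0.0

    return RateLaw("irreversible_mm",
                   {"vmax": vmax, "km": km, "inhibitors": inhibitors}, fn)


def hill(vmax: float, s: str, k_half: float, h: float) -> RateLaw:
    """Irreversible Hill kinetics with coefficient h."""

    def fn(c):
        x = c[s] ** h
        return vmax * x / (k_half ** h + x), 0.0

    return RateLaw("hill", {"vmax": vmax, "s": s, "k_half": k_half, "h": h}, fn)


# ---------------------------------------------------------------------------
# kinetic model
# ---------------------------------------------------------------------------

@dataclass
class KineticModel:
    """A small ODE model: stoichiometry + rate laws + conserved totals."""

    name: str
    metabolites: list[str]
    stoichiometry: dict[str, dict[str, float]]      # reaction -> {met: coef}
    rate_laws: dict[str, RateLaw]
    moieties: list[tuple[str, list[str], float]] = field(default_factory=list)
    #: (group id, members, conserved total)
    externals: dict[str, float] = field(default_factory=dict)
    competitive_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    couplings: list[list[str]] = field(default_factory=list)
    boundary: set[str] = field(default_factory=set)

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.stoichiometry)

    def _conc_dict(self, x: np.ndarray) -> dict[str, float]:
        c = dict(zip(self.metabolites, x))
        c.update(self.externals)
        return c

    def rates(self, x: np.ndarray, activities: dict[str, float] | None = None
              ) -> np.ndarray:
        activities = activities or {}
        c = self._conc_dict(x)
        return np.array([
            self.rate_laws[r].net(c, activities.get(r, 1.0))
            for r in self.reaction_ids
        ])

    def stoich_matrix(self) -> np.ndarray:
        N = np.zeros((len(self.metabolites), len(self.reaction_ids)))
        midx = {m: i for i, m in enumerate(self.metabolites)}
        for j, r in enumerate(self.reaction_ids):
            for mid, coef in self.stoichiometry[r].items():
                if mid in midx:
                    N[midx[mid], j] = coef
        return N

    def odes(self, x: np.ndarray, activities=None) -> np.ndarray:
        return self.stoich_matrix() @ self.rates(x, activities)

    # -- steady state ------------------------------------------------------
    def _reduction(self):
        """Moiety-aware reduction: dependent metabolite per group is
        eliminated via its conserved total."""
        midx = {m: i for i, m in enumerate(self.metabolites)}
        dep = {}
        for gid, members, total in self.moieties:
            d = members[-1]
            dep[midx[d]] = ([midx[m] for m in members[:-1]], total)
        free = [i for i in range(len(self.metabolites)) if i not in dep]
        return free, dep

    def _expand(self, x_free: np.ndarray, free, dep) -> np.ndarray:
        x = np.empty(len(self.metabolites))
        x[free] = x_free
        for d, (others, total) in dep.items():
            x[d] = total - x[others].sum()
        return x

    def solve_steady_state(
        self,
        x0: np.ndarray | dict[str, float],
        activities: dict[str, float] | None = None,
        tol: float = STEADY_STATE_TOL,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Find (x, J) with ||N v(x)|| below ``tol`` relative to the rates.

        Newton (via scipy root/hybr) from ``x0``, with an ODE-integration
        fallback to enter the basin of attraction.  Deterministic given x0.
        """
        if isinstance(x0, dict):
            x0 = np.array([x0[m] for m in self.metabolites], dtype=float)
        free, dep = self._reduction()
        for gid, members, total in self.moieties:
            midx = {m: i for i, m in enumerate(self.metabolites)}
            got = sum(x0[midx[m]] for m in members)
            if not math.isclose(got, total, rel_tol=1e-6):
                raise ValueError(
                    f"initial condition violates conserved total of {gid} "
                    f"({got:g} != {total:g})"
                )

        def reduced(x_free):
            x = self._expand(np.asarray(x_free), free, dep)
            return self.odes(x, activities)[free]

        def attempt(x_start):
            sol = root(reduced, x_start[free], method="hybr", tol=1e-13)
            return self._expand(sol.x, free, dep)

        x = attempt(x0)
        scale = max(np.abs(self.rates(x, activities)).max(), 1e-12)
        if (np.abs(self.odes(x, activities)).max() > tol * scale
                or np.any(x <= 0)):
            # integrate towards the attractor, then polish
            ivp = solve_ivp(
                lambda t, y: self.odes(np.maximum(y, 1e-12), activities),
                (0.0, 1e4), x0, method="LSODA", rtol=1e-10, atol=1e-12,
            )
            x = attempt(np.maximum(ivp.y[:, -1], 1e-12))
            scale = max(np.abs(self.rates(x, activities)).max(), 1e-12)
            resid = np.abs(self.odes(x, activities)).max()
            if resid > tol * scale or np.any(x <= 0):
                raise SteadyStateError(
                    f"{self.name}: no positive steady state found "
                    f"(residual {resid:.2e}, trajectory end {ivp.y[:, -1]})"
                )
        J = self.rates(x, activities)
        return x, J

    # -- exact sensitivities ----------------------------------------------
    def exact_elasticities(
        self, x: np.ndarray, activities: dict[str, float] | None = None,
        rel_step: float = 1e-7,
    ) -> ElasticitySample:
        """Scaled elasticities d log v / d log x at the given state.

        Central log-space finite differences on the rate laws (exact to
        O(step^2); the shipped laws are smooth).  Forward and reverse
        components are differentiated separately so the sample carries
        the full (vf, vr) decomposition.
        """
        activities = activities or {}
        sample = ElasticitySample(seed=None)
        c0 = self._conc_dict(x)
        for rid in self.reaction_ids:
            law = self.rate_laws[rid]
            a = activities.get(rid, 1.0)
            vf0, vr0 = law.rates(c0, a)
            v0 = vf0 - vr0
            sample.rho_used[rid] = vr0 / vf0 if vf0 > 0 else 0.0
            for mid in self.metabolites:
                def limits(sign):
                    c = dict(c0)
                    c[mid] = c0[mid] * math.exp(sign * rel_step)
                    return law.rates(c, a)
                vf_p, vr_p = limits(+1.0)
                vf_m, vr_m = limits(-1.0)
                dvf = (vf_p - vf_m) / (2 * rel_step)
                dvr = (vr_p - vr_m) / (2 * rel_step)
                if abs(dvf) < 1e-12 * max(vf0, 1e-300) and abs(dvr) < 1e-12 * max(vr0, 1e-300):
                    continue
                key = (rid, mid)
                if vf0 > 0:
                    sample.forward[key] = dvf / vf0
                if vr0 > 0:
                    sample.reverse[key] = dvr / vr0
                if v0 != 0:
                    sample.net[key] = (dvf - dvr) / v0
        return sample

    def control_coefficients_fd(
        self, x: np.ndarray, activities: dict[str, float] | None = None,
        rel_step: float = 1e-6,
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Brute-force control coefficients d log(x, J)/d log(Vmax).

        Centred finite differences re-solving the steady state at
        activity scalings ``exp(+-rel_step)``; the independent oracle the
        matrix computation is validated against.
        """
        base = dict(activities or {})
        C_x = np.zeros((len(self.metabolites), len(self.reaction_ids)))
        C_J = np.zeros((len(self.reaction_ids), len(self.reaction_ids)))
        x_ref = np.asarray(x, dtype=float)
        for k, rid in enumerate(self.reaction_ids):
            states = []
            for sign in (+1.0, -1.0):
                act = dict(base)
                act[rid] = act.get(rid, 1.0) * math.exp(sign * rel_step)
                states.append(self.solve_steady_state(x_ref, act))
            (x_p, J_p), (x_m, J_m) = states
            C_x[:, k] = (np.log(x_p) - np.log(x_m)) / (2 * rel_step)
            C_J[:, k] = (np.log(J_p) - np.log(J_m)) / (2 * rel_step)
        return (
            pd.DataFrame(C_x, index=self.metabolites, columns=self.reaction_ids),
            pd.DataFrame(C_J, index=self.reaction_ids, columns=self.reaction_ids),
        )

    # -- export to the inference-side network format -----------------------
    def to_network(
        self, x: np.ndarray, J: np.ndarray,
        modifiers: dict[str, list[tuple[str, str]]] | None = None,
    ) -> MetabolicNetwork:
        """Build the inference-side network: stoichiometry, steady-state
        fluxes and disequilibrium ratios read off the rate laws."""
        modifiers = modifiers or {}
        c = self._conc_dict(x)
        in_moiety = {}
        for gid, members, _ in self.moieties:
            for mname in members:
                in_moiety[mname] = gid
        mets = [Metabolite(id=mid, internal=True, moiety_group=in_moiety.get(mid))
                for mid in self.metabolites]
        rxns = []
        for j, rid in enumerate(self.reaction_ids):
            vf, vr = self.rate_laws[rid].rates(c, 1.0)
            rho = min(vr / vf, 1.0 - 1e-9) if vf > 0 else 0.0
            law = self.rate_laws[rid]
            upper = {}
            if law.kind == "hill":
                upper[law.params["s"]] = law.params["h"]
            stoich = {mid: coef for mid, coef in self.stoichiometry[rid].items()
                      if mid in set(self.metabolites)}
            rxns.append(Reaction(
                id=rid, stoichiometry=stoich, net_flux=float(J[j]), rho=float(rho),
                modifiers=modifiers.get(rid, []),
                competitive_pairs=self.competitive_pairs.get(rid, []),
                elasticity_upper=upper,
                boundary=rid in self.boundary,
            ))
        groups = []
        midx = {m: i for i, m in enumerate(self.metabolites)}
        for gid, members, total in self.moieties:
            ratios = {
                f"{members[i]}/{members[i + 1]}":
                    float(x[midx[members[i]]] / x[midx[members[i + 1]]])
                for i in range(len(members) - 1)
            }
            groups.append(MoietyGroup(id=gid, members=list(members),
                                      concentration_ratios=ratios))
        return MetabolicNetwork(metabolites=mets, reactions=rxns,
                                moiety_groups=groups, couplings=self.couplings)


@dataclass
class GroundTruthAdaptation:
    """Before/after steady states for a known activity perturbation."""

    perturbation: dict[str, float]          # reaction -> multiplicative factor
    x_before: np.ndarray
    J_before: np.ndarray
    x_after: np.ndarray
    J_after: np.ndarray
    dlog_x: dict[str, float]                # log2
    dlog_J: dict[str, float]
    dlog_v: dict[str, float]

    def truth_frame(self) -> pd.DataFrame:
        rows = (
            [{"kind": "conc", "id": k, "dlog2": v} for k, v in self.dlog_x.items()]
            + [{"kind": "flux", "id": k, "dlog2": v} for k, v in self.dlog_J.items()]
            + [{"kind": "act", "id": k, "dlog2": v} for k, v in self.dlog_v.items()]
        )
        return pd.DataFrame(rows)


def simulate_adaptation(
    model: KineticModel,
    x0: np.ndarray | dict[str, float],
    perturbation: dict[str, float],
    noise_cv_flux: float = 0.0,
    noise_cv_conc: float = 0.0,
    seed: int | None = None,
    interval_halfwidth: float = 0.1,
    n_replicates: int = 3,
    measured_conc: list[str] | None = None,
    measured_flux: list[str] | None = None,
) -> tuple[GroundTruthAdaptation, MeasurementSet]:
    """Simulate a measured metabolic adaptation.

    Scales the limiting rates by ``perturbation`` factors, re-solves the
    steady state, and emits (i) the exact ground truth in log2 units and
    (ii) a measurement set consumable by :func:`build_initial_domains`.

    Noise-free measurements (CV = 0) still carry an after-state interval
    of half-width ``interval_halfwidth`` in log2 units, representing
    instrument precision (with exact point values the first-order
    constraint system is generically incompatible with the re-solved
    nonlinear steady state).  With noise, the after-state point value is
    the geometric mean of ``n_replicates`` lognormal draws at the given
    CV (measurements are replicate averages), and intervals are built
    from the assay CV around that mean: mean +- 1 SD for concentrations
    and a 95% CI for fluxes.
    """
    for rid, f in perturbation.items():
        if f <= 0:
            raise ValueError(f"perturbation factor for {rid} must be > 0")
    x_b, J_b = model.solve_steady_state(x0)
    activities = {rid: perturbation.get(rid, 1.0) for rid in model.reaction_ids}
    x_a, J_a = model.solve_steady_state(x_b, activities)

    log2 = math.log(2.0)
    dlog_x = {m: float(np.log(x_a[i] / x_b[i]) / log2)
              for i, m in enumerate(model.metabolites)}
    dlog_J = {r: float(np.log(J_a[j] / J_b[j]) / log2)
              for j, r in enumerate(model.reaction_ids)}
    dlog_v = {r: math.log2(activities[r]) for r in model.reaction_ids}
    truth = GroundTruthAdaptation(
        perturbation=dict(perturbation),
        x_before=x_b, J_before=J_b, x_after=x_a, J_after=J_a,
        dlog_x=dlog_x, dlog_J=dlog_J, dlog_v=dlog_v,
    )

    rng = np.random.default_rng(seed)
    ms = MeasurementSet()
    measured_flux = model.reaction_ids if measured_flux is None else measured_flux
    measured_conc = model.metabolites if measured_conc is None else measured_conc

    def emit(kind, vid, before, after, cv, ci_factor):
        if cv > 0:
            sd_ln = math.sqrt(math.log(1.0 + cv * cv))
            reps = after * np.exp(sd_ln * rng.standard_normal(n_replicates))
            obs = math.exp(float(np.mean(np.log(reps))))
            lo = obs * math.exp(-ci_factor * sd_ln)
            hi = obs * math.exp(+ci_factor * sd_ln)
        else:
            half = interval_halfwidth * log2          # log2 -> natural
            lo = after * math.exp(-half)
            hi = after * math.exp(+half)
        ms.add(kind, vid, before, lo, hi)

    midx = {m: i for i, m in enumerate(model.metabolites)}
    jidx = {r: j for j, r in enumerate(model.reaction_ids)}
    for r in measured_flux:
        emit("flux", r, float(J_b[jidx[r]]), float(J_a[jidx[r]]),
             noise_cv_flux, 1.96)
    for mname in measured_conc:
        emit("conc", mname, float(x_b[midx[mname]]), float(x_a[midx[mname]]),
             noise_cv_conc, 1.0)
    return truth, ms


# ---------------------------------------------------------------------------
# shipped fixture topologies (parameters are package-chosen)
# ---------------------------------------------------------------------------

def linear_chain(n_internal: int = 2, k: float = 1.0) -> KineticModel:
    """Irreversible mass-action chain S -> x1 -> ... -> sink (S external)."""
    mets = [f"x{i}" for i in range(1, n_internal + 1)]
    stoich, laws = {}, {}
    stoich["R1"] = {mets[0]: 1.0}
    laws["R1"] = mass_action(k, {"S": 1.0})
    for i in range(1, n_internal):
        rid = f"R{i + 1}"
        stoich[rid] = {mets[i - 1]: -1.0, mets[i]: 1.0}
        laws[rid] = mass_action(k * (1.0 + 0.2 * i), {mets[i - 1]: 1.0})
    rid = f"R{n_internal + 1}"
    stoich[rid] = {mets[-1]: -1.0}
    laws[rid] = mass_action(k * 0.8, {mets[-1]: 1.0})
    return KineticModel(
        name=f"linear_chain_{n_internal}", metabolites=mets,
        stoichiometry=stoich, rate_laws=laws, externals={"S": 1.0},
    )


def reversible_chain() -> KineticModel:
    """3-metabolite chain with two reversible MM steps (nonzero rho)."""
    mets = ["x1", "x2", "x3"]
    stoich = {
        "R1": {"x1": 1.0},
        "R2": {"x1": -1.0, "x2": 1.0},
        "R3": {"x2": -1.0, "x3": 1.0},
        "R4": {"x3": -1.0},
    }
    laws = {
        "R1": irreversible_mm(2.0, {"S": 1.0}, inhibitors={"x1": 2.0}),
        "R2": reversible_mm(6.0, "x1", "x2", ks=1.0, kp=1.2, keq=2.0),
        "R3": reversible_mm(5.0, "x2", "x3", ks=0.8, kp=1.0, keq=1.5),
        "R4": irreversible_mm(3.0, {"x3": 0.6}),
    }
    return KineticModel(name="reversible_chain", metabolites=mets,
                        stoichiometry=stoich, rate_laws=laws,
                        externals={"S": 1.0})


def branched_pathway() -> KineticModel:
    """One input splitting into two competing branches (3 metabolites)."""
    mets = ["x1", "x2", "x3"]
    stoich = {
        "R1": {"x1": 1.0},
        "R2": {"x1": -1.0, "x2": 1.0},
        "R3": {"x1": -1.0, "x3": 1.0},
        "R4": {"x2": -1.0},
        "R5": {"x3": -1.0},
    }
    laws = {
        "R1": irreversible_mm(3.0, {"S": 1.0}, inhibitors={"x1": 1.5}),
        "R2": irreversible_mm(4.0, {"x1": 1.0}),
        "R3": hill(2.5, "x1", 0.8, 2.0),
        "R4": irreversible_mm(3.5, {"x2": 0.7}),
        "R5": mass_action(1.2, {"x3": 1.0}),
    }
    return KineticModel(name="branched_pathway", metabolites=mets,
                        stoichiometry=stoich, rate_laws=laws,
                        externals={"S": 1.0})


def moiety_cycle() -> KineticModel:
    """Minimal conserved-pool toy: substrate oxidation cycling A/AH."""
    mets = ["x1", "A", "AH"]
    stoich = {
        "R1": {"x1": 1.0},
        "R2": {"x1": -1.0, "A": -1.0, "AH": 1.0},
        "R3": {"AH": -1.0, "A": 1.0},
    }
    laws = {
        "R1": irreversible_mm(2.0, {"S": 1.0}, inhibitors={"x1": 1.0}),
        "R2": irreversible_mm(3.0, {"x1": 0.5, "A": 0.2}),
        "R3": mass_action(4.0, {"AH": 1.0}),
    }
    return KineticModel(
        name="moiety_cycle", metabolites=mets, stoichiometry=stoich,
        rate_laws=laws, moieties=[("A_pool", ["A", "AH"], 1.0)],
        externals={"S": 1.0},
    )


def glycolysis_ppp() -> KineticModel:
    """Glycolysis/PPP-style branch: 5 metabolites, 6 reactions, one moiety.

    Topology: hexose input -> G6P; G6P <-> F6P (reversible, near
    equilibrium); F6P -> FBP (Hill, h=2); FBP -> sink; oxidative branch
    G6P + NADP -> NADPH; NADPH re-oxidation closing the moiety cycle.
    Parameters are package-chosen to give a well-conditioned positive
    steady state; they are NOT taken from any published model.
    """
    mets = ["G6P", "F6P", "FBP", "NADP", "NADPH"]
    stoich = {
        "HK": {"G6P": 1.0},
        "GPI": {"G6P": -1.0, "F6P": 1.0},
        "PFK": {"F6P": -1.0, "FBP": 1.0},
        "ALD": {"FBP": -1.0},
        "G6PD": {"G6P": -1.0, "NADP": -1.0, "NADPH": 1.0},
        "NADPase": {"NADPH": -1.0, "NADP": 1.0},
    }
    laws = {
        "HK": irreversible_mm(2.0, {"Glc": 1.0}, inhibitors={"G6P": 0.9}),
        "GPI": reversible_mm(8.0, "G6P", "F6P", ks=0.8, kp=1.0, keq=0.45),
        "PFK": hill(2.8, "F6P", 0.55, 2.0),
        "ALD": irreversible_mm(3.2, {"FBP": 0.6}),
        "G6PD": irreversible_mm(1.4, {"G6P": 0.7, "NADP": 0.05}),
        "NADPase": mass_action(6.0, {"NADPH": 1.0}),
    }
    return KineticModel(
        name="glycolysis_ppp", metabolites=mets, stoichiometry=stoich,
        rate_laws=laws, moieties=[("NADP_pool", ["NADP", "NADPH"], 0.3)],
        externals={"Glc": 1.0},
    )


def fixture_topologies() -> list[KineticModel]:
    """The five shipped topologies used across the validation suites."""
    return [
        linear_chain(2),
        reversible_chain(),
        branched_pathway(),
        moiety_cycle(),
        glycolysis_ppp(),
    ]


def default_x0(model: KineticModel) -> np.ndarray:
    """A deterministic positive starting point respecting conserved totals."""
    x0 = np.full(len(model.metabolites), 0.5)
    midx = {m: i for i, m in enumerate(model.metabolites)}
    for gid, members, total in model.moieties:
        for mname in members:
            x0[midx[mname]] = total / len(members)
    return x0
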