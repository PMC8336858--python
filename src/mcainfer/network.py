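"""Metabolic network data model, validation and file I/O.

A :class:`MetabolicNetwork` holds the structural information that the
control-coefficient machinery consumes: reaction stoichiometry over the
``n`` internal metabolites, steady-state net fluxes for the ``m`` transport
and reaction processes, per-reaction disequilibrium ratios ``rho = vr/vf``,
allosteric modifiers, competitive substrate/product pairs, moiety-conserved
pools with literature concentration ratios, and activity-coupling groups
(sets of reactions whose log-fold activity changes are constrained equal).

Measured metabolic adaptations enter through a :class:`MeasurementSet`
(before-state point values and after-state intervals) which
:func:`build_initial_domains` converts to per-variable log2-fold-change
intervals (:class:`DomainTable`).

All logarithms are base 2 throughout the package.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: variable kinds used throughout: metabolite concentration, reaction flux,
#: individual (transporter/enzyme) activity
KINDS = ("conc", "flux", "act")

STEADY_STATE_RTOL = 1e-9


class NetworkError(ValueError):
    """Schema or invariant violation in a network definition."""


class ConsistencyError(NetworkError):
    """Steady-state (flux balance) violation."""


class DomainError(ValueError):
    """Invalid log-fold-change domain (e.g. log of a non-positive value)."""


class InfeasibleDomainError(DomainError):
    """A measurement-derived interval is empty after clipping."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    internal: bool = True
    moiety_group: str | None = None


@dataclass
class Reaction:
    """One transport or enzyme-catalysed process.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = substrate).  ``rho`` is the disequilibrium ratio
    ``vr/vf = Gamma/Keq`` in ``[0, 1)`` for the net-flux-positive
    orientation; the equilibrium constant and mass-action ratio are never
    stored separately.  ``elasticity_upper`` holds per-reactant Hill-type
    saturation bounds ``h`` (default 1, Michaelis-Menten).  ``boundary``
    marks simplified boundary processes whose activity domain is slaved to
    the flux domain.
    """

    id: str
    stoichiometry: dict[str, float]
    net_flux: float = 1.0
    rho: float = 0.0
    modifiers: list[tuple[str, str]] = field(default_factory=list)
    competitive_pairs: list[tuple[str, str]] = field(default_factory=list)
    elasticity_upper: dict[str, float] = field(default_factory=dict)
    boundary: bool = False

    @property
    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    @property
    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]

    def flipped(self) -> "Reaction":
        """Return the reaction re-oriented so the net flux is positive."""
        return Reaction(
            id=self.id,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            net_flux=-self.net_flux,
            rho=self.rho,
            modifiers=list(self.modifiers),
            competitive_pairs=[(p, s) for (s, p) in self.competitive_pairs],
            elasticity_upper=dict(self.elasticity_upper),
            boundary=self.boundary,
        )


@dataclass
class MoietyGroup:
    """A conserved pool (e.g. NADP + NADPH = const).

    ``concentration_ratios`` maps ``"A/B"`` strings to positive reals; the
    ratio graph must connect all members so a single composition is defined.
    """

    id: str
    members: list[str]
    concentration_ratios: dict[str, float]

    def relative_concentrations(self) -> dict[str, float]:
        """Concentrations of all members relative to the first member.

        Resolved by walking the ratio graph; raises :class:`NetworkError`
        if the graph is disconnected or inconsistent.
        """
        adj: dict[str, list[tuple[str, float]]] = {m: [] for m in self.members}
        for key, r in self.concentration_ratios.items():
            try:
                a, b = key.split("/")
            except ValueError as exc:
                raise NetworkError(
                    f"moiety {self.id}: ratio key {key!r} is not 'A/B'"
                ) from exc
            if a not in adj or b not in adj:
                raise NetworkError(
                    f"moiety {self.id}: ratio {key!r} references a non-member"
                )
            if r <= 0:
                raise NetworkError(f"moiety {self.id}: ratio {key!r} must be > 0")
            adj[a].append((b, 1.0 / r))  # x_b = x_a / r
            adj[b].append((a, r))
        rel: dict[str, float] = {self.members[0]: 1.0}
        stack = [self.members[0]]
        while stack:
            cur = stack.pop()
            for nxt, factor in adj[cur]:
                val = rel[cur] * factor
                if nxt in rel:
                    if not math.isclose(rel[nxt], val, rel_tol=1e-9):
                        raise NetworkError(
                            f"moiety {self.id}: inconsistent ratio cycle at {nxt}"
                        )
                else:
                    rel[nxt] = val
                    stack.append(nxt)
        missing = set(self.members) - set(rel)
        if missing:
            raise NetworkError(
                f"moiety {self.id}: ratio graph does not connect members {sorted(missing)}"
            )
        return rel


@dataclass
class MetabolicNetwork:
    """Validated network: stoichiometry, fluxes, rho, moieties, couplings."""

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    moiety_groups: list[MoietyGroup] = field(default_factory=list)
    couplings: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- convenience views -------------------------------------------------
    @property
    def internal_metabolites(self) -> list[Metabolite]:
        return [m for m in self.metabolites if m.internal]

    @property
    def n(self) -> int:
        return len(self.internal_metabolites)

    @property
    def m(self) -> int:
        return len(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.internal_metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def stoichiometric_matrix(self) -> np.ndarray:
        """n x m matrix over internal metabolites."""
        idx = {mid: i for i, mid in enumerate(self.metabolite_ids)}
        N = np.zeros((self.n, self.m))
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                if mid in idx:
                    N[idx[mid], j] = coef
        return N

    def net_fluxes(self) -> np.ndarray:
        return np.array([r.net_flux for r in self.reactions], dtype=float)

    def variables(self) -> list[tuple[str, str]]:
        """Canonical variable ordering: concentrations, fluxes, activities."""
        return (
            [("conc", mid) for mid in self.metabolite_ids]
            + [("flux", rid) for rid in self.reaction_ids]
            + [("act", rid) for rid in self.reaction_ids]
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise NetworkError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise NetworkError("duplicate reaction ids")
        met_set = set(met_ids)
        group_ids = {g.id for g in self.moiety_groups}

        for met in self.metabolites:
            if met.moiety_group is not None and met.moiety_group not in group_ids:
                raise NetworkError(
                    f"metabolite {met.id}: unknown moiety_group {met.moiety_group!r}"
                )

        # orient every reaction so net flux >= 0 (one code path for the
        # thermodynamic transform, which assumes v > 0 and 0 <= rho < 1)
        for i, rxn in enumerate(self.reactions):
            if rxn.net_flux < 0:
                logger.info("reaction %s: negative net flux, flipping orientation", rxn.id)
                self.reactions[i] = rxn.flipped()

        for rxn in self.reactions:
            if not 0.0 <= rxn.rho < 1.0:
                raise NetworkError(
                    f"reaction {rxn.id}: rho={rxn.rho} outside [0, 1)"
                )
            if rxn.net_flux == 0 and not rxn.boundary:
                raise NetworkError(
                    f"reaction {rxn.id}: zero net flux on a non-boundary reaction "
                    "(scaled control coefficients undefined)"
                )
            unknown = set(rxn.stoichiometry) - met_set
            if unknown:
                raise NetworkError(
                    f"reaction {rxn.id}: unknown metabolites {sorted(unknown)}"
                )
            subs, prods = set(rxn.substrates), set(rxn.products)
            participants = subs | prods | {m for m, _ in rxn.modifiers}
            for mid, role in rxn.modifiers:
                if role not in ("activator", "inhibitor"):
                    raise NetworkError(
                        f"reaction {rxn.id}: modifier role {role!r} invalid"
                    )
                if mid not in met_set:
                    raise NetworkError(
                        f"reaction {rxn.id}: unknown modifier metabolite {mid!r}"
                    )
            for s, p in rxn.competitive_pairs:
                if s not in subs or p not in prods:
                    raise NetworkError(
                        f"reaction {rxn.id}: competitive pair ({s}, {p}) must pair "
                        "one substrate with one product"
                    )
            for mid, h in rxn.elasticity_upper.items():
                if mid not in participants:
                    raise NetworkError(
                        f"reaction {rxn.id}: elasticity_upper for non-participant {mid!r}"
                    )
                if h <= 0:
                    raise NetworkError(
                        f"reaction {rxn.id}: elasticity_upper[{mid!r}] must be > 0"
                    )

        for grp in self.moiety_groups:
            if len(grp.members) < 2:
                raise NetworkError(f"moiety {grp.id}: needs >= 2 members")
            unknown = set(grp.members) - met_set
            if unknown:
                raise NetworkError(
                    f"moiety {grp.id}: unknown members {sorted(unknown)}"
                )
            grp.relative_concentrations()  # validates ratio graph

        rxn_set = set(rxn_ids)
        for group in self.couplings:
            if len(group) < 2:
                raise NetworkError("coupling group needs >= 2 reactions")
            unknown = set(group) - rxn_set
            if unknown:
                raise NetworkError(f"coupling references unknown reactions {sorted(unknown)}")

        self._check_steady_state()
        self._check_moiety_structure()

    def _check_steady_state(self) -> None:
        N = self.stoichiometric_matrix()
        J = self.net_fluxes()
        residual = N @ J
        scale = np.maximum(np.abs(N) @ np.abs(J), 1.0)
        bad = np.where(np.abs(residual) > STEADY_STATE_RTOL * scale)[0]
        if bad.size:
            mids = self.metabolite_ids
            detail = ", ".join(f"{mids[i]}: {residual[i]:.3e}" for i in bad)
            raise ConsistencyError(
                f"steady-state violation N.J != 0 for internal metabolites ({detail})"
            )

    def _check_moiety_structure(self) -> None:
        """Each declared conserved pool must be an actual left-null vector of N."""
        N = self.stoichiometric_matrix()
        idx = {mid: i for i, mid in enumerate(self.metabolite_ids)}
        for grp in self.moiety_groups:
            rows = [idx[m] for m in grp.members if m in idx]
            if len(rows) != len(grp.members):
                raise NetworkError(
                    f"moiety {grp.id}: members must all be internal metabolites"
                )
            total = N[rows, :].sum(axis=0)
            if np.max(np.abs(total)) > 1e-9:
                raise NetworkError(
                    f"moiety {grp.id}: member stoichiometry rows do not sum to zero "
                    "(pool is not conserved by the network)"
                )
        if self.moiety_groups:
            rank = np.linalg.matrix_rank(N, tol=1e-9)
            expected = self.n - len(self.moiety_groups)
            if rank > expected:
                raise NetworkError(
                    "declared moiety conservations exceed the actual rank "
                    f"deficiency of N (rank {rank}, expected <= {expected})"
                )
            if rank < expected:
                logger.warning(
                    "stoichiometric matrix has extra rank deficiency beyond the "
                    "declared moiety groups (rank %d < %d)", rank, expected,
                )

    # -- (de)serialisation -------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict) -> "MetabolicNetwork":
        def _req(d: dict, key: str, ctx: str):
            if key not in d:
                raise NetworkError(f"{ctx}: missing required field {key!r}")
            return d[key]

        mets = []
        for md in _req(data, "metabolites", "network"):
            mets.append(
                Metabolite(
                    id=str(_req(md, "id", "metabolite")),
                    name=str(md.get("name", "")),
                    internal=bool(md.get("internal", True)),
                    moiety_group=md.get("moiety_group"),
                )
            )
        rxns = []
        for rd in _req(data, "reactions", "network"):
            rid = str(_req(rd, "id", "reaction"))
            stoich = _req(rd, "stoichiometry", f"reaction {rid}")
            if not isinstance(stoich, dict) or not stoich:
                raise NetworkError(f"reaction {rid}: stoichiometry must be a non-empty map")
            rxns.append(
                Reaction(
                    id=rid,
                    stoichiometry={str(k): float(v) for k, v in stoich.items()},
                    net_flux=float(rd.get("net_flux", 1.0)),
                    rho=float(rd.get("rho", 0.0)),
                    modifiers=[tuple(x) for x in rd.get("modifiers", [])],
                    competitive_pairs=[tuple(x) for x in rd.get("competitive_pairs", [])],
                    elasticity_upper={
                        str(k): float(v) for k, v in rd.get("elasticity_upper", {}).items()
                    },
                    boundary=bool(rd.get("boundary", False)),
                )
            )
        groups = [
            MoietyGroup(
                id=str(_req(gd, "id", "moiety")),
                members=[str(x) for x in _req(gd, "members", "moiety")],
                concentration_ratios={
                    str(k): float(v)
                    for k, v in gd.get("concentration_ratios", {}).items()
                },
            )
            for gd in data.get("moieties", [])
        ]
        couplings = [[str(r) for r in grp] for grp in data.get("couplings", [])]
        return cls(metabolites=mets, reactions=rxns, moiety_groups=groups, couplings=couplings)

    def to_dict(self) -> dict:
        return {
            "schema": "mcainfer-network/1",
            "metabolites": [
                {
                    "id": m.id,
                    "name": m.name,
                    "internal": m.internal,
                    "moiety_group": m.moiety_group,
                }
                for m in self.metabolites
            ],
            "reactions": [
                {
                    "id": r.id,
                    "stoichiometry": r.stoichiometry,
                    "net_flux": r.net_flux,
                    "rho": r.rho,
                    "modifiers": [list(x) for x in r.modifiers],
                    "competitive_pairs": [list(x) for x in r.competitive_pairs],
                    "elasticity_upper": r.elasticity_upper,
                    "boundary": r.boundary,
                }
                for r in self.reactions
            ],
            "moieties": [
                {
                    "id": g.id,
                    "members": g.members,
                    "concentration_ratios": g.concentration_ratios,
                }
                for g in self.moiety_groups
            ],
            "couplings": self.couplings,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def load_network(path) -> MetabolicNetwork:
    """Load and validate a network from the package JSON format."""
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise NetworkError(f"{path}: invalid JSON ({exc})") from exc
    return MetabolicNetwork.from_dict(data)


# ---------------------------------------------------------------------------
# measurements and log2-fold-change domains
# ---------------------------------------------------------------------------

@dataclass
class Measurement:
    """Before-state point value and after-state interval for one variable."""

    kind: str
    id: str
    before: float
    after_lo: float
    after_hi: float


@dataclass
class MeasurementSet:
    measurements: list[Measurement] = field(default_factory=list)

    def add(self, kind: str, id: str, before: float, after_lo: float, after_hi: float):
        self.measurements.append(Measurement(kind, id, before, after_lo, after_hi))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "kind": m.kind,
                    "id": m.id,
                    "before": m.before,
                    "after_lo": m.after_lo,
                    "after_hi": m.after_hi,
                }
                for m in self.measurements
            ]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "MeasurementSet":
        df = pd.read_csv(path, sep="\t")
        ms = cls()
        for _, row in df.iterrows():
            ms.add(row["kind"], row["id"], float(row["before"]),
                   float(row["after_lo"]), float(row["after_hi"]))
        return ms


@dataclass
class DomainEntry:
    lb: float
    ub: float
    restricted: bool = False


@dataclass
class DomainTable:
    """Per-variable log2-fold-change intervals.

    ``enclosure`` is the generic bound E applied to unmeasured variables
    (and used to clip measured ones); ``sigma`` is the additive volume
    correction that was applied to measurement-derived bounds.
    """

    entries: dict[tuple[str, str], DomainEntry] = field(default_factory=dict)
    enclosure: float = 3.0
    sigma: float = 0.0

    def __getitem__(self, key: tuple[str, str]) -> DomainEntry:
        return self.entries[key]

    def __contains__(self, key) -> bool:
        return key in self.entries

    def validate(self) -> None:
        for (kind, vid), e in self.entries.items():
            if kind not in KINDS:
                raise DomainError(f"({kind}, {vid}): unknown variable kind")
            if e.lb > e.ub:
                raise DomainError(f"({kind}, {vid}): lb {e.lb} > ub {e.ub}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": k, "id": v, "lb": e.lb, "ub": e.ub, "restricted": int(e.restricted)}
            for (k, v), e in self.entries.items()
        ]
        return pd.DataFrame(rows, columns=["kind", "id", "lb", "ub", "restricted"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, network: MetabolicNetwork | None = None,
                 enclosure: float = 3.0, sigma: float = 0.0) -> "DomainTable":
        df = pd.read_csv(path, sep="\t")
        table = cls(enclosure=enclosure, sigma=sigma)
        for i, row in df.iterrows():
            try:
                lb, ub = float(row["lb"]), float(row["ub"])
                restricted = bool(int(row["restricted"]))
                kind, vid = str(row["kind"]), str(row["id"])
            except (KeyError, ValueError) as exc:
                raise DomainError(f"{path}: malformed row at line {i + 2}: {exc}") from exc
            if lb > ub:
                raise DomainError(f"{path}: line {i + 2}: lb {lb} > ub {ub}")
            table.entries[(kind, vid)] = DomainEntry(lb, ub, restricted)
        if network is not None:
            for key in network.variables():
                if key not in table.entries:
                    logger.warning(
                        "domain table %s missing %s; defaulting to enclosure bounds",
                        path, key,
                    )
                    table.entries[key] = DomainEntry(-enclosure, enclosure, False)
        table.validate()
        return table


def build_initial_domains(
    network: MetabolicNetwork,
    measurements: MeasurementSet | None = None,
    enclosure: float = 3.0,
    sigma: float = 0.0,
) -> DomainTable:
    """Initial log2-fold-change domains for every variable of the network.

    Unmeasured variables get the generic enclosure ``[-E, +E]``.  Measured
    variables get ``[log2(after_lo) - log2(before) + sigma,
    log2(after_hi) - log2(before) + sigma]`` clipped to the enclosure.
    Activities of boundary reactions copy their reaction's flux domain
    (simplified boundary processes are slaved to their fluxes).
    """
    table = DomainTable(enclosure=enclosure, sigma=sigma)
    for key in network.variables():
        table.entries[key] = DomainEntry(-enclosure, enclosure, False)

    if measurements is not None:
        for meas in measurements.measurements:
            key = (meas.kind, meas.id)
            if key not in table.entries:
                raise DomainError(f"measurement for unknown variable {key}")
            if meas.before <= 0 or meas.after_lo <= 0 or meas.after_hi <= 0:
                raise DomainError(
                    f"measurement {key}: values must be positive (log undefined)"
                )
            if meas.after_lo > meas.after_hi:
                raise DomainError(f"measurement {key}: after_lo > after_hi")
            lb = math.log2(meas.after_lo) - math.log2(meas.before) + sigma
            ub = math.log2(meas.after_hi) - math.log2(meas.before) + sigma
            if lb > enclosure or ub < -enclosure:
                raise InfeasibleDomainError(
                    f"measurement {key}: interval [{lb:.3g}, {ub:.3g}] lies "
                    f"entirely outside the enclosure [-{enclosure}, {enclosure}]"
                )
            if lb < -enclosure or ub > enclosure:
                logger.warning(
                    "measurement %s: interval [%.3g, %.3g] clipped to enclosure",
                    key, lb, ub,
                )
            table.entries[key] = DomainEntry(
                max(lb, -enclosure), min(ub, enclosure), True
            )

    # boundary reactions: activity domain slaved to the flux domain
    for rxn in network.reactions:
        if rxn.boundary:
            fe = table.entries[("flux", rxn.id)]
            table.entries[("act", rxn.id)] = DomainEntry(fe.lb, fe.ub, fe.restricted)

    table.validate()
    return table
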