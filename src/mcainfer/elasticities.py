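"""Constrained random sampling of scaled metabolite elasticities.

For every reaction, elasticities of the *forward* rate with respect to its
reactants are sampled inside saturation bounds (``0 < eps_S^vf < h`` for a
substrate, ``-h < eps_P^vf < 0`` for a product; ``h`` is 1 for
Michaelis-Menten saturation, the Hill coefficient for cooperative steps).
Elasticities of the *net* rate then follow from the displacement from
equilibrium via the disequilibrium ratio ``rho = vr/vf``:

    substrate:  eps^v =  rho/(1-rho) + eps^vf
    product:    eps^v = -rho/(1-rho) + eps^vf

The thermodynamic term ``rho/(1-rho)`` blows up as the reaction approaches
equilibrium (rho -> 1), reproducing the unbounded sensitivity of net rates
near equilibrium.  Reverse-rate elasticities are never sampled: they are
fixed by the forward/reverse linkage ``eps^vf - eps^vr = +1`` (substrate)
and ``-1`` (product) valid for 0 < rho < 1.

Additional constraints:

* declared competitive substrate/product pairs must satisfy
  ``0 < eps_S^v + eps_P^v < 1`` (the thermodynamic terms cancel in the sum,
  so the constraint is imposed on the forward elasticities directly);
* allosteric modifiers get net-rate elasticities in ``(0, 1)`` (activator)
  or ``(-1, 0)`` (inhibitor), added to any reactant contribution of the
  same metabolite.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import MetabolicNetwork

__all__ = [
    "ElasticitySample",
    "SamplerExhaustedError",
    "forward_reverse_split",
    "net_elasticity_from_forward",
    "sample_elasticities",
]


class SamplerExhaustedError(RuntimeError):
    """Rejection budget exhausted for some reaction's constraints."""


def forward_reverse_split(net_flux: float, rho: float) -> tuple[float, float]:
    """Split a positive net flux into forward and reverse rates.

    ``vf = v/(1-rho)``, ``vr = rho*v/(1-rho)``; ``vf - vr = v`` exactly.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"rho={rho} outside [0, 1)")
    vf = net_flux / (1.0 - rho)
    vr = rho * net_flux / (1.0 - rho)
    return vf, vr


def net_elasticity_from_forward(eps_f: float, rho: float, role: str) -> float:
    """Net-rate elasticity from a forward-rate elasticity.

    The regulatory (saturation) term is the sampled forward elasticity; the
    thermodynamic (mass-action) term is ``+rho/(1-rho)`` for substrates and
    ``-rho/(1-rho)`` for products.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(
            f"rho={rho} outside [0, 1): net elasticity indeterminate at equilibrium"
        )
    if role == "substrate":
        if eps_f <= 0:
            raise ValueError("substrate forward elasticity must be > 0")
        return rho / (1.0 - rho) + eps_f
    if role == "product":
        if eps_f >= 0:
            raise ValueError("product forward elasticity must be < 0")
        return -rho / (1.0 - rho) + eps_f
    raise ValueError(f"role must be 'substrate' or 'product', got {role!r}")


@dataclass
class ElasticitySample:
    """One complete set of scaled elasticities for a network.

    ``forward``/``reverse`` map ``(reaction_id, metabolite_id)`` to the
    forward/reverse-rate elasticity of reactants; ``net`` maps to the
    net-rate elasticity and additionally covers allosteric modifiers.
    """

    forward: dict[tuple[str, str], float] = field(default_factory=dict)
    reverse: dict[tuple[str, str], float] = field(default_factory=dict)
    net: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int | None = None
    rho_used: dict[str, float] = field(default_factory=dict)

    def matrix(self, network: MetabolicNetwork) -> np.ndarray:
        """m x n matrix of net elasticities over internal metabolites."""
        midx = {mid: i for i, mid in enumerate(network.metabolite_ids)}
        E = np.zeros((network.m, network.n))
        for (rid, mid), val in self.net.items():
            if mid in midx:
                E[network.reaction_ids.index(rid), midx[mid]] = val
        return E

    def to_frame(self) -> pd.DataFrame:
        keys = sorted(set(self.net) | set(self.forward) | set(self.reverse))
        rows = [
            {
                "reaction": r,
                "metabolite": x,
                "eps_forward": self.forward.get((r, x), np.nan),
                "eps_reverse": self.reverse.get((r, x), np.nan),
                "eps_net": self.net.get((r, x), np.nan),
            }
            for r, x in keys
        ]
        return pd.DataFrame(rows, columns=["reaction", "metabolite",
                                           "eps_forward", "eps_reverse", "eps_net"])

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "ElasticitySample":
        df = pd.read_csv(path)
        sample = cls()
        for _, row in df.iterrows():
            key = (str(row["reaction"]), str(row["metabolite"]))
            if np.isfinite(row["eps_forward"]):
                sample.forward[key] = float(row["eps_forward"])
            if np.isfinite(row["eps_reverse"]):
                sample.reverse[key] = float(row["eps_reverse"])
            if np.isfinite(row["eps_net"]):
                sample.net[key] = float(row["eps_net"])
        return sample


def _reaction_rng(seed: int, rid: str, stream: int = 0) -> np.random.Generator:
    """Independent substream per reaction: stable hash of the reaction id,
    so adding a reaction does not perturb other reactions' draws."""
    key = zlib.crc32(rid.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream, key)))


def _uniform_open(rng: np.random.Generator, lo: float, hi: float, margin: float) -> float:
    """Uniform draw on (lo, hi) kept away from the endpoints by ``margin``
    (absolute, scaled down if the interval is narrow)."""
    pad = min(margin, 0.25 * (hi - lo))
    return float(rng.uniform(lo + pad, hi - pad))


def sample_elasticities(
    network: MetabolicNetwork,
    seed: int,
    margin: float = 1e-3,
    rejection_budget: int = 10_000,
    competitive_method: str = "direct",
    stream: int = 0,
) -> ElasticitySample:
    """Draw one complete elasticity sample satisfying all constraints.

    Parameters
    ----------
    seed
        Root seed; per-reaction substreams are derived from it, so two
        calls with the same seed produce identical samples.
    margin
        Open-interval margin keeping draws away from exact saturation.
    competitive_method
        ``"direct"`` constructs competitive-pair elasticities from a
        uniform draw of their sum (never rejects); ``"rejection"``
        resamples the pair until the sum constraint holds, as an
        independent cross-check backend.
    stream
        Extra substream index used by the ensemble driver to draw many
        samples from one root seed.
    """
    sample = ElasticitySample(seed=seed)
    for rxn in network.reactions:
        rng = _reaction_rng(seed, rxn.id, stream)
        rho = rxn.rho
        sample.rho_used[rxn.id] = rho
        thermo = rho / (1.0 - rho)
        internal = set(network.metabolite_ids)
        paired = {s for s, _ in rxn.competitive_pairs} | {
            p for _, p in rxn.competitive_pairs
        }

        # competitive substrate/product pairs: 0 < eps_S^vf + eps_P^vf < 1
        for s, p in rxn.competitive_pairs:
            if competitive_method == "direct":
                total = _uniform_open(rng, 0.0, 1.0, margin)
                # eps_S^vf in (total, 1) so that eps_P^vf = total - eps_S^vf in (-1, 0)
                eps_s = _uniform_open(rng, total, 1.0, margin)
                eps_p = total - eps_s
            elif competitive_method == "rejection":
                for _ in range(rejection_budget):
                    eps_s = _uniform_open(rng, 0.0, 1.0, margin)
                    eps_p = -_uniform_open(rng, 0.0, 1.0, margin)
                    if 0.0 < eps_s + eps_p < 1.0:
                        break
                else:
                    raise SamplerExhaustedError(
                        f"reaction {rxn.id}: competitive pair ({s}, {p}) "
                        f"constraint unsatisfied after {rejection_budget} draws"
                    )
            else:
                raise ValueError(f"unknown competitive_method {competitive_method!r}")
            sample.forward[(rxn.id, s)] = eps_s
            sample.forward[(rxn.id, p)] = eps_p

        # remaining reactants: independent uniforms inside saturation bounds
        for mid in rxn.substrates:
            if mid in paired or mid not in internal:
                continue
            h = rxn.elasticity_upper.get(mid, 1.0)
            sample.forward[(rxn.id, mid)] = _uniform_open(rng, 0.0, h, margin)
        for mid in rxn.products:
            if mid in paired or mid not in internal:
                continue
            h = rxn.elasticity_upper.get(mid, 1.0)
            sample.forward[(rxn.id, mid)] = -_uniform_open(rng, 0.0, h, margin)

        # net and reverse elasticities follow deterministically
        for mid in rxn.substrates:
            key = (rxn.id, mid)
            if key not in sample.forward:
                continue
            eps_f = sample.forward[key]
            sample.reverse[key] = eps_f - 1.0
            sample.net[key] = thermo + eps_f
        for mid in rxn.products:
            key = (rxn.id, mid)
            if key not in sample.forward:
                continue
            eps_f = sample.forward[key]
            sample.reverse[key] = eps_f + 1.0
            sample.net[key] = -thermo + eps_f

        # allosteric modifiers act on the net rate directly; a metabolite
        # that is both reactant and modifier gets the sum of both terms
        for mid, role in rxn.modifiers:
            if role == "activator":
                term = _uniform_open(rng, 0.0, 1.0, margin)
            else:
                term = -_uniform_open(rng, 0.0, 1.0, margin)
            key = (rxn.id, mid)
            sample.net[key] = sample.net.get(key, 0.0) + term

    return sample
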