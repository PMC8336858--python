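"""Ensemble inference: sampled control matrices -> aggregated signs.

Under uncertainty about the kinetics, a single control-coefficient matrix
is not defensible: an ensemble of matrices is generated by constrained
random sampling of metabolite elasticities, each accepted matrix defines
one bound-contraction problem, and the per-variable sign calls are
aggregated over the solved problems.  Repeated signs across the ensemble
mark changes that are robust to the sampling; interval unions and
intersections of the final domains summarise the magnitudes and the
sampling dependence (union == intersection means no dependence at all).

:class:`EnsembleBoundContraction` is the model object;
:meth:`EnsembleBoundContraction.fit` returns an :class:`EnsembleResults`
with the summary table, counts, and driver scoring against expected gene
expression directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contraction import BoundContraction, ContractionResults, DEFAULT_SIGN_EPS
from .elasticities import sample_elasticities
from .mca import SingularSampleError, compute_control_matrix, filter_by_magnitude
from .network import DomainTable, MetabolicNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "EnsembleBoundContraction",
    "EnsembleResults",
    "DriverVerdict",
    "aggregate",
    "score_driver",
]


class EnsembleGenerationError(RuntimeError):
    """Matrix acceptance rate fell below the configured floor."""


@dataclass
class DriverVerdict:
    """Support classification of one gene's expected activity change."""

    gene: str
    expected_direction: str       # "-" or "+"
    activity: str
    pct_same: float
    pct_opposite: float
    verdict: str


def score_driver(
    gene: str,
    expected_direction: str,
    pct_negative: float,
    pct_positive: float,
    activity: str = "",
    strong: float = 80.0,
    opposite_max: float = 0.0,
) -> DriverVerdict:
    """Classify ensemble sign percentages against an expected direction.

    ``supported`` needs the same-direction percentage at or above
    ``strong`` with essentially no opposite calls; percentages below that
    (or any opposite calls short of ``strong``) are sampling-dependent;
    an opposite-direction percentage at or above ``strong`` contradicts
    the expectation.
    """
    if expected_direction not in ("-", "+"):
        raise ValueError("expected_direction must be '-' or '+'")
    same = pct_negative if expected_direction == "-" else pct_positive
    opposite = pct_positive if expected_direction == "-" else pct_negative
    if same >= strong and opposite <= opposite_max:
        verdict = "supported"
    elif opposite >= strong:
        verdict = "contradicted"
    elif same > opposite_max and opposite <= opposite_max:
        verdict = "supported, but sampling dependent"
    else:
        verdict = "not supported, but sampling dependent"
    return DriverVerdict(
        gene=gene, expected_direction=expected_direction, activity=activity,
        pct_same=same, pct_opposite=opposite, verdict=verdict,
    )


def aggregate(
    results: list[ContractionResults],
    variables: list[tuple[str, str]],
) -> pd.DataFrame:
    """Per-variable sign percentages and interval unions/intersections.

    Percentages are over solved (feasible) problems; the union and
    intersection are coordinatewise over the solved problems' final
    domains.
    """
    solved = [r for r in results if r.feasible]
    if not solved:
        raise ValueError("no feasible problems to aggregate")
    rows = []
    frames = [
        r.frame.set_index(["kind", "id"]) for r in solved
    ]
    n_solved = len(solved)
    for key in variables:
        lbs = np.array([f.loc[key, "lb_final"] for f in frames])
        ubs = np.array([f.loc[key, "ub_final"] for f in frames])
        signs = [f.loc[key, "sign"] for f in frames]
        rows.append(
            {
                "kind": key[0],
                "id": key[1],
                "pct_negative": 100.0 * sum(s == "negative" for s in signs) / n_solved,
                "pct_positive": 100.0 * sum(s == "positive" for s in signs) / n_solved,
                "union_lb": float(lbs.min()),
                "union_ub": float(ubs.max()),
                "inter_lb": float(lbs.max()),
                "inter_ub": float(ubs.min()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EnsembleResults:
    """Aggregated ensemble outcome."""

    summary_frame: pd.DataFrame
    per_problem: list[ContractionResults]
    n_formulated: int
    n_solved: int
    n_discarded_infeasible: int
    n_generated_matrices: int
    n_accepted_matrices: int
    mean_gain_pct: float
    config: dict = field(default_factory=dict)

    @property
    def fixed_sign_always(self) -> dict[str, list[str]]:
        """Variables fixed-sign in *every* solved problem, by kind."""
        out: dict[str, list[str]] = {}
        for _, r in self.summary_frame.iterrows():
            if r["pct_negative"] == 100.0 or r["pct_positive"] == 100.0:
                out.setdefault(r["kind"], []).append(r["id"])
        return out

    @property
    def fixed_sign_any(self) -> dict[str, list[str]]:
        """Variables fixed-sign in at least one solved problem, by kind."""
        out: dict[str, list[str]] = {}
        for _, r in self.summary_frame.iterrows():
            if r["pct_negative"] > 0.0 or r["pct_positive"] > 0.0:
                out.setdefault(r["kind"], []).append(r["id"])
        return out

    def score_driver(
        self, gene: str, expected_direction: str, activity: str,
        strong: float = 80.0, opposite_max: float = 0.0,
    ) -> DriverVerdict:
        row = self.summary_frame[
            (self.summary_frame["kind"] == "act")
            & (self.summary_frame["id"] == activity)
        ]
        if row.empty:
            raise KeyError(f"activity {activity!r} not in summary")
        return score_driver(
            gene, expected_direction,
            float(row["pct_negative"].iloc[0]), float(row["pct_positive"].iloc[0]),
            activity=activity, strong=strong, opposite_max=opposite_max,
        )

    def driver_report(
        self, genes: list[tuple[str, str, str]],
        strong: float = 80.0, opposite_max: float = 0.0,
    ) -> pd.DataFrame:
        """Verdict table for (gene, expected_direction, activity) triples."""
        rows = []
        for gene, expected, activity in genes:
            v = self.score_driver(gene, expected, activity,
                                  strong=strong, opposite_max=opposite_max)
            rows.append(
                {
                    "gene": v.gene,
                    "affected_activity": v.activity,
                    "expected": v.expected_direction,
                    "pct_same": v.pct_same,
                    "pct_opposite": v.pct_opposite,
                    "verdict": v.verdict,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame
        lines = [
            "Ensemble bound contraction (log2-fold changes)",
            "=" * 78,
            f"problems formulated: {self.n_formulated}   solved: {self.n_solved}   "
            f"discarded infeasible: {self.n_discarded_infeasible}",
            f"control matrices generated: {self.n_generated_matrices}   "
            f"accepted (|C| filter): {self.n_accepted_matrices}",
            f"mean % gain over all variables and formulated problems: "
            f"{self.mean_gain_pct:.1f}%",
            "-" * 78,
            f"{'variable':<16}{'% -':>6}{'% +':>6}{'union':>20}{'intersection':>22}",
        ]
        for _, r in df.iterrows():
            lines.append(
                f"{r['kind'] + ':' + r['id']:<16}"
                f"{r['pct_negative']:6.0f}{r['pct_positive']:6.0f}"
                f"  [{r['union_lb']:7.3f},{r['union_ub']:7.3f}]"
                f"  [{r['inter_lb']:7.3f},{r['inter_ub']:7.3f}]"
            )
        return "\n".join(lines)

    def write_tsv(self, path) -> None:
        self.summary_frame.to_csv(path, sep="\t", index=False)

    def plot_intervals(self, kind: str = "act", ax=None):
        """Union (light) and intersection (dark) bars of the final domains."""
        import matplotlib.pyplot as plt

        df = self.summary_frame[self.summary_frame["kind"] == kind]
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 0.4 * max(len(df), 4) + 1))
        y = np.arange(len(df))
        ax.barh(y, df["union_ub"] - df["union_lb"], left=df["union_lb"],
                color="lightsteelblue", label="union")
        ax.barh(y, df["inter_ub"] - df["inter_lb"], left=df["inter_lb"],
                height=0.4, color="steelblue", label="intersection")
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_yticks(y, df["id"])
        ax.set_xlabel("log2-fold change")
        ax.legend(loc="best", fontsize=8)
        return ax


class EnsembleBoundContraction:
    """Ensemble model: elasticity sampling -> matrix screen -> contraction.

    Parameters
    ----------
    network
        Validated metabolic network (fluxes, rho, moieties, couplings).
    domains
        Initial log2-fold-change domains (measured restrictions included).
    n_problems
        Number of accepted control matrices / formulated problems.
    cc_bound
        Magnitude screen: only matrices with every control coefficient in
        ``[-cc_bound, cc_bound]`` are accepted.
    max_generation_factor
        Abort if more than ``n_problems * max_generation_factor`` matrices
        must be generated (acceptance-rate floor).
    """

    def __init__(
        self,
        network: MetabolicNetwork,
        domains: DomainTable,
        n_problems: int = 100,
        cc_bound: float = 3.5,
        max_generation_factor: int = 500,
        sampler_kwargs: dict | None = None,
    ):
        self.network = network
        self.domains = domains
        self.n_problems = n_problems
        self.cc_bound = cc_bound
        self.max_generation_factor = max_generation_factor
        self.sampler_kwargs = sampler_kwargs or {}

    def fit(
        self,
        seed: int,
        eps_sign: float = DEFAULT_SIGN_EPS,
        method: str = "highs",
        dedupe: bool = False,
    ) -> EnsembleResults:
        """Run the full ensemble, reproducibly from ``seed``.

        Samples are drawn on independent substreams indexed by attempt
        number, so problems are order-independent and the run is
        deterministic.
        """
        accepted = []
        n_generated = 0
        budget = self.n_problems * self.max_generation_factor
        while len(accepted) < self.n_problems:
            if n_generated >= budget:
                raise EnsembleGenerationError(
                    f"generated {n_generated} matrices but accepted only "
                    f"{len(accepted)}/{self.n_problems}; acceptance rate below "
                    f"1/{self.max_generation_factor} — check cc_bound and rho values"
                )
            stream = n_generated
            n_generated += 1
            sample = sample_elasticities(
                self.network, seed, stream=stream, **self.sampler_kwargs
            )
            try:
                C = compute_control_matrix(self.network, sample)
            except SingularSampleError:
                continue
            if filter_by_magnitude(C, self.cc_bound):
                C.provenance.update({"stream": stream})
                accepted.append(C)

        results: list[ContractionResults] = []
        for C in accepted:
            model = BoundContraction.from_network(self.network, C, self.domains)
            results.append(model.fit(eps_sign=eps_sign, method=method, dedupe=dedupe))

        n_solved = sum(r.feasible for r in results)
        if n_solved == 0:
            raise EnsembleGenerationError(
                "all formulated problems were infeasible: initial domains are "
                "incompatible with the constraint systems"
            )
        summary = aggregate(results, self.network.variables())
        # mean gain over all variables and all *formulated* problems;
        # infeasible problems contract nothing and contribute zero gain
        gains = [
            r.frame["gain_pct"].mean() if r.feasible else 0.0 for r in results
        ]
        return EnsembleResults(
            summary_frame=summary,
            per_problem=results,
            n_formulated=len(results),
            n_solved=n_solved,
            n_discarded_infeasible=len(results) - n_solved,
            n_generated_matrices=n_generated,
            n_accepted_matrices=len(accepted),
            mean_gain_pct=float(np.mean(gains)),
            config={
                "seed": seed,
                "n_problems": self.n_problems,
                "cc_bound": self.cc_bound,
                "eps_sign": eps_sign,
                "enclosure": self.domains.enclosure,
                "sigma": self.domains.sigma,
                "log_base": 2,
            },
        )
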