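"""Model/Results interface for maximum-likelihood paralog mapping.

`ParalogMatchingModel` holds the data side of the problem — the two
aligned families, their species-constrained matching graph and the table
of unit-of-coevolution log scores. `fit()` maximises the matching log
likelihood, either exactly (enumeration, small instances) or by the
Lagrangian relaxation with certified upper/lower bounds, and returns a
`ParalogMatchingResults` carrying the estimate, its bounds, diagnostics
and a `summary()` table.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

from . import io as cio
from .errors import CoevomapError, TooLargeError
from .evaluation import EvalReport, evaluate
from .io import AlignedFamily
from .lagrangian import SolverConfig, SolverResult, solve
from .matching import (
    Matching,
    best_matching_by_enumeration,
    build_graph,
    log_likelihood,
)
from .scoring import build_score_table, coevolution_degree


class ParalogMatchingModel:
    """Maximum-likelihood one-to-one mapping between two protein families.

    Parameters
    ----------
    family_a, family_b : AlignedFamily
        The two alignments with species labels. Only same-species pairings
        are allowed; the fitted matching always has the maximum cardinality
        ``n = sum_t min(|A_t|, |B_t|)``.
    offset_margin : float
        Safety margin added to the positivity offset K of the score table.
    """

    def __init__(
        self,
        family_a: AlignedFamily,
        family_b: AlignedFamily,
        offset_margin: float = 1.0,
    ) -> None:
        self.family_a = family_a
        self.family_b = family_b
        self.graph = build_graph(family_a, family_b)
        self.table = build_score_table(
            family_a, family_b, self.graph, offset_margin=offset_margin
        )

    @classmethod
    def from_files(
        cls,
        fasta_a: str | Path,
        fasta_b: str | Path,
        species_a: str | Path | Mapping[str, str] | None = None,
        species_b: str | Path | Mapping[str, str] | None = None,
        parse_mode: str = "auto",
    ) -> "ParalogMatchingModel":
        fam_a = cio.read_family(fasta_a, species_a, parse_mode=parse_mode, name="A")
        fam_b = cio.read_family(fasta_b, species_b, parse_mode=parse_mode, name="B")
        return cls(fam_a, fam_b)

    # -- inference -------------------------------------------------------

    @property
    def n(self) -> int:
        return self.graph.n

    def loglike(self, matching: Matching) -> float:
        return log_likelihood(matching, self.table)

    def fit(
        self,
        method: str = "lagrangian",
        enumeration_cap: int = 10**6,
        auto_threshold: int = 5000,
        **solver_options,
    ) -> "ParalogMatchingResults":
        """Maximise the matching log likelihood.

        ``method`` is ``"lagrangian"`` (bounded relaxation, the default),
        ``"exact"`` (brute-force enumeration; raises on instances beyond
        ``enumeration_cap``) or ``"auto"`` (exact below ``auto_threshold``
        matchings, relaxation otherwise). Solver options (``time_limit``,
        ``gap_tol``, ``max_iter``, ``seed``, ...) are forwarded to
        :class:`~coevomap.lagrangian.SolverConfig`.
        """
        if method == "auto":
            method = (
                "exact"
                if self.graph.count_max_matchings() <= auto_threshold
                else "lagrangian"
            )
        if method == "exact":
            matching, ll = best_matching_by_enumeration(
                self.graph, self.table, cap=enumeration_cap
            )
            solver = SolverResult(
                matching=matching,
                lower_bound=ll,
                upper_bound=ll,
                relative_gap=0.0,
                proved_optimal=True,
                iterations=0,
                trace=[(ll, ll)],
            )
        elif method == "lagrangian":
            config = SolverConfig(**solver_options)
            solver = solve(self.graph, self.table, config)
        else:
            raise CoevomapError(f"unknown fit method {method!r}")
        return ParalogMatchingResults(self, solver, method)


class ParalogMatchingResults:
    """Fitted paralog mapping with likelihood bounds and diagnostics."""

    def __init__(
        self, model: ParalogMatchingModel, solver: SolverResult, method: str
    ) -> None:
        self.model = model
        self.solver_result = solver
        self.method = method
        self.matching = solver.matching
        self.llf = solver.lower_bound
        self.upper_bound = solver.upper_bound
        self.relative_gap = solver.relative_gap
        self.proved_optimal = solver.proved_optimal
        self.iterations = solver.iterations
        self.trace = solver.trace

    @property
    def nobs(self) -> int:
        return len(self.matching)

    @property
    def n_units(self) -> int:
        return math.comb(len(self.matching), 2)

    def avg_unit_loglik(self) -> float:
        if self.n_units == 0:
            raise CoevomapError("no units of coevolution in a matching of size < 2")
        return self.llf / self.n_units

    def coevolution_degrees(self) -> dict[tuple[str, str], float]:
        """Per-pair degree of coevolution: mean unit log score of each pair."""
        return {
            pair: coevolution_degree(pair, self.matching, self.model.table)
            for pair in self.matching
        }

    def evaluate_against(self, reference: Matching) -> EvalReport:
        return evaluate(
            self.matching,
            reference,
            table=self.model.table,
            relative_gap=self.relative_gap,
        )

    def save_matching(self, path: str | Path) -> None:
        cio.write_matching(self.matching, path, self.model.family_a.species_of)

    def report(self, seed: int | None = None) -> dict:
        cfg = self.solver_result.config
        return {
            "method": self.method,
            "n": self.model.n,
            "matching_size": self.nobs,
            "log_likelihood": self.llf,
            "upper_bound": self.upper_bound,
            "relative_gap": self.relative_gap,
            "proved_optimal": self.proved_optimal,
            "iterations": self.iterations,
            "wall_time_s": self.solver_result.wall_time,
            "seed": seed if seed is not None else (cfg.seed if cfg else None),
            "config": cfg.as_dict() if cfg else None,
            "trace": [[lo, up] for lo, up in self.trace],
        }

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Maximum-likelihood paralog mapping",
            "=" * 50,
            f"families:            {self.model.family_a.name} / {self.model.family_b.name}",
            f"species shared:      {len(self.model.graph.species_parts)}",
            f"candidate edges:     {len(self.model.graph.edges)}",
            f"matching size n:     {self.nobs}",
            f"units of coevolution: {self.n_units}",
            f"method:              {self.method}",
            f"log likelihood:      {self.llf:.6f}",
            f"upper bound:         {self.upper_bound:.6f}",
            f"relative gap:        {self.relative_gap:.3e}",
            f"proved optimal:      {self.proved_optimal}",
            f"iterations:          {self.iterations}",
        ]
        if self.n_units:
            lines.append(f"avg unit log lik.:   {self.avg_unit_loglik():.6f}")
        lines.append("-" * 50)
        lines.append(f"{'family_A_id':<20}{'family_B_id':<20}{'species':<12}{'coevo_degree':>14}")
        degrees = self.coevolution_degrees() if self.n_units else {}
        sp = self.model.family_a.species_of
        for a, b in sorted(self.matching.pairs, key=lambda p: (sp[p[0]], p[0])):
            d = f"{degrees[(a, b)]:.4f}" if degrees else "--"
            lines.append(f"{a:<20}{b:<20}{sp[a]:<12}{d:>14}")
        return "\n".join(lines)
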