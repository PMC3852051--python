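"""Species-constrained bipartite matching graph and matching likelihoods.

The matching graph connects every family-A member to every family-B member
of the same species, so it decomposes into one complete bipartite component
per species and every maximal matching has the same cardinality
``n = sum_t min(|A_t|, |B_t|)``. The search space is the set of matchings
of that maximum cardinality; the log likelihood of a matching is the sum of
unit log scores over all unordered pairs of its edges.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Iterator

from .errors import CardinalityError, CoevomapError, InfeasibleError, TooLargeError
from .io import AlignedFamily

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import UnitScoreTable


@dataclass(frozen=True)
class Matching:
    """A set of (family_A_id, family_B_id) pairs, no node used twice."""

    pairs: tuple[tuple[str, str], ...]

    def __init__(self, pairs: Iterable[tuple[str, str]]) -> None:
        object.__setattr__(self, "pairs", tuple(sorted(pairs)))
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise CoevomapError("matching uses a node more than once")

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.pairs)

    def intersection_size(self, other: "Matching") -> int:
        return len(set(self.pairs) & set(other.pairs))


class MatchingGraph:
    """Bipartite graph of allowed same-species pairings between two families.

    Attributes
    ----------
    nodes_a, nodes_b : tuple of str
        Sequence ids in family order; ``index_a``/``index_b`` invert them.
    edges : tuple of (int, int)
        All same-species index pairs, sorted lexicographically.
    species_parts : dict
        species -> (A indices, B indices) for species present in both
        families. Species present in only one family contribute no edges.
    n : int
        The common cardinality of all maximal matchings.
    """

    def __init__(self, fam_a: AlignedFamily, fam_b: AlignedFamily) -> None:
        self.family_a = fam_a
        self.family_b = fam_b
        self.nodes_a = fam_a.ids
        self.nodes_b = fam_b.ids
        self.index_a = {sid: i for i, sid in enumerate(self.nodes_a)}
        self.index_b = {sid: i for i, sid in enumerate(self.nodes_b)}
        self.species_a = tuple(fam_a.species_of[sid] for sid in self.nodes_a)
        self.species_b = tuple(fam_b.species_of[sid] for sid in self.nodes_b)

        parts: dict[str, tuple[list[int], list[int]]] = {}
        for i, sp in enumerate(self.species_a):
            parts.setdefault(sp, ([], []))[0].append(i)
        for k, sp in enumerate(self.species_b):
            parts.setdefault(sp, ([], []))[1].append(k)
        self.species_parts = {
            sp: (tuple(ai), tuple(bi))
            for sp, (ai, bi) in sorted(parts.items())
            if ai and bi
        }
        if not self.species_parts:
            raise InfeasibleError(
                f"families {fam_a.name!r} and {fam_b.name!r} share no species"
            )
        self.edges = tuple(
            sorted(
                (i, k)
                for ai, bi in self.species_parts.values()
                for i in ai
                for k in bi
            )
        )
        self.edge_set = frozenset(self.edges)
        self.n = sum(min(len(ai), len(bi)) for ai, bi in self.species_parts.values())

    def matching_from_indices(self, index_pairs: Iterable[tuple[int, int]]) -> Matching:
        return Matching((self.nodes_a[i], self.nodes_b[k]) for i, k in index_pairs)

    def indices_of(self, matching: Matching) -> tuple[tuple[int, int], ...]:
        try:
            idx = tuple(
                (self.index_a[a], self.index_b[b]) for a, b in matching.pairs
            )
        except KeyError as exc:
            raise CoevomapError(f"matching refers to unknown id {exc.args[0]!r}")
        for e in idx:
            if e not in self.edge_set:
                a, b = self.nodes_a[e[0]], self.nodes_b[e[1]]
                raise CoevomapError(
                    f"pair ({a!r}, {b!r}) joins different species: not a graph edge"
                )
        return idx

    def count_max_matchings(self) -> int:
        total = 1
        for ai, bi in self.species_parts.values():
            p, q = sorted((len(ai), len(bi)))
            total *= math.perm(q, p)
        return total


def build_graph(fam_a: AlignedFamily, fam_b: AlignedFamily) -> MatchingGraph:
    """Construct the species-constrained matching graph of two families."""
    return MatchingGraph(fam_a, fam_b)


def log_likelihood(matching: Matching, table: "UnitScoreTable") -> float:
    """Sum of unit log scores over unordered pairs of matching edges.

    A size-1 matching contains no units, so its log likelihood is 0
    (an empty product of probabilities).
    """
    if len(matching) < 1:
        raise CoevomapError("log likelihood requires a non-empty matching")
    idx = table.graph.indices_of(matching)
    total = 0.0
    for e1, e2 in itertools.combinations(idx, 2):
        total += table.unit_value(e1, e2)
    return total


def bqp2_objective(matching: Matching, table: "UnitScoreTable") -> float:
    """Offset-shifted quadratic objective: sum of (f + K) minus C(n,2)*K.

    For every maximum-cardinality matching this equals the log likelihood
    exactly — the shift by K adds K per unit and a maximum-cardinality
    matching always contains C(n,2) units, which the constant removes.
    """
    n = table.graph.n
    if len(matching) != n:
        raise CardinalityError(
            f"matching has size {len(matching)}, maximum cardinality is {n}"
        )
    idx = table.graph.indices_of(matching)
    total = 0.0
    for e1, e2 in itertools.combinations(idx, 2):
        total += table.unit_value(e1, e2) + table.offset_K
    return total - math.comb(n, 2) * table.offset_K


def enumerate_max_matchings(
    graph: MatchingGraph, cap: int = 10**6
) -> Iterator[Matching]:
    """Yield every maximum-cardinality matching exactly once.

    Per species the smaller side is injected into the larger in all
    possible ways; the full search space is the cross product over species.
    Raises :class:`TooLargeError` (advising the Lagrangian solver) when the
    total count exceeds ``cap``.
    """
    total = graph.count_max_matchings()
    if total > cap:
        raise TooLargeError(
            f"{total} maximum matchings exceed cap {cap}; use the Lagrangian solver"
        )

    per_species: list[list[tuple[tuple[int, int], ...]]] = []
    for ai, bi in graph.species_parts.values():
        options: list[tuple[tuple[int, int], ...]] = []
        if len(ai) <= len(bi):
            for chosen in itertools.permutations(bi, len(ai)):
                options.append(tuple(zip(ai, chosen)))
        else:
            for chosen in itertools.permutations(ai, len(bi)):
                options.append(tuple(zip(chosen, bi)))
        per_species.append(options)
    for combo in itertools.product(*per_species):
        yield graph.matching_from_indices(
            [e for component in combo for e in component]
        )


def best_matching_by_enumeration(
    graph: MatchingGraph, table: "UnitScoreTable", cap: int = 10**6
) -> tuple[Matching, float]:
    """Exact optimum over the search space by brute-force enumeration."""
    best: Matching | None = None
    best_ll = -math.inf
    for m in enumerate_max_matchings(graph, cap=cap):
        ll = log_likelihood(m, table)
        if ll > best_ll:
            best, best_ll = m, ll
    assert best is not None
    return best, best_ll
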