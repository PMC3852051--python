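"""Hypergeometric scoring of units of coevolution.

A *unit of coevolution* is a pair of mapped protein pairs
``((a, b), (a', b'))``. Under the hypothesis H of equal evolutionary rates,
the mismatch count Delta_A(a, a') between the two family-A members, given
the comparable-column counts ell_A, ell_B and the total mismatch count
T = Delta_A + Delta_B, follows a hypergeometric distribution:

    f = C(ell_A, Delta_A) * C(ell_B, Delta_B) / C(ell_A + ell_B, T)

Columns where either sequence carries a gap are excluded from both counts.
All scores are computed and stored in log space via log-gamma.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, NamedTuple

import numpy as np
from scipy.special import gammaln

from .errors import CoevomapError, InputError, UnknownIdError
from .io import GAP_CHARS, AlignedFamily

if TYPE_CHECKING:  # pragma: no cover
    from .matching import Matching, MatchingGraph

#: quadruple key: (i, j, k, l) with i < j by family-A index and k != l
Quad = tuple[int, int, int, int]


class PairCounts(NamedTuple):
    """Mismatch and comparable-column counts for one sequence pair.

    ``delta`` counts columns where the two residues differ; ``ell`` counts
    matches + mismatches. Gap columns contribute to neither, so
    ``0 <= delta <= ell`` always holds.
    """

    delta: int
    ell: int


def _check_counts(c: PairCounts, label: str) -> None:
    if not (0 <= c.delta <= c.ell):
        raise InputError(f"{label}: invalid counts delta={c.delta}, ell={c.ell}")


def pair_counts(family: AlignedFamily, id1: str, id2: str) -> PairCounts:
    """Count mismatches (delta) and comparable columns (ell) for two rows."""
    r1, r2 = family.row(id1), family.row(id2)
    delta = ell = 0
    for x, y in zip(r1, r2):
        if x in GAP_CHARS or y in GAP_CHARS:
            continue
        ell += 1
        if x != y:
            delta += 1
    return PairCounts(delta, ell)


def pair_count_matrices(family: AlignedFamily) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (delta, ell) matrices in family order, via broadcasting."""
    n = len(family)
    rows = np.array(
        [np.frombuffer(row.encode("ascii"), dtype=np.uint8) for _, row in family.sequences]
    )
    gap = (rows == ord("-")) | (rows == ord("."))
    valid = ~gap[:, None, :] & ~gap[None, :, :]
    ell = valid.sum(axis=2).astype(np.int64)
    diff = (rows[:, None, :] != rows[None, :, :]) & valid
    delta = diff.sum(axis=2).astype(np.int64)
    assert delta.shape == (n, n)
    return delta, ell


def unit_log_score(cA: PairCounts, cB: PairCounts) -> float:
    """Log hypergeometric probability of a unit of coevolution.

    Symmetric in its two arguments and always finite and <= 0: the observed
    split (Delta_A, Delta_B) of T = Delta_A + Delta_B lies inside the
    hypergeometric support by construction.
    """
    cA, cB = PairCounts(*cA), PairCounts(*cB)
    _check_counts(cA, "family A pair")
    _check_counts(cB, "family B pair")
    return _log_score(cA.delta, cA.ell, cB.delta, cB.ell)


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def _log_score(dA: int, lA: int, dB: int, lB: int) -> float:
    return _log_binom(lA, dA) + _log_binom(lB, dB) - _log_binom(lA + lB, dA + dB)


@dataclass
class UnitScoreTable:
    """Log scores for every unit of coevolution of a matching graph.

    ``log_f`` is keyed by quadruples ``(i, j, k, l)`` — family indices of
    two distinct graph edges ``(i, k)`` and ``(j, l)`` oriented so that
    ``i < j`` — covering every pair of edges that can co-occur in a
    matching (``i != j``, ``k != l``), including cross-species units.
    ``offset_K`` makes every shifted weight ``f + K`` strictly positive;
    ``w(quad) = (f + K) / 2`` is the half-weight used by the Lagrangian
    decomposition, where each unit is counted once in each of its two local
    subproblems.
    """

    graph: "MatchingGraph"
    log_f: dict[Quad, float]
    offset_K: float

    def __post_init__(self) -> None:
        if self.log_f:
            worst = min(self.log_f.values())
            if not np.isfinite(worst):
                raise CoevomapError("non-finite unit score in table")
            if worst + self.offset_K <= 0:
                raise CoevomapError(
                    f"offset K={self.offset_K} does not make all weights positive"
                )
        elif self.offset_K <= 0:
            raise CoevomapError("offset K must be positive")

    @property
    def shifted_w(self) -> dict[Quad, float]:
        return {q: (f + self.offset_K) / 2.0 for q, f in self.log_f.items()}

    def quad_of(self, e1: tuple[int, int], e2: tuple[int, int]) -> Quad:
        """Oriented quadruple key for an unordered pair of distinct edges."""
        (i, k), (j, l) = e1, e2
        if i == j or k == l:
            raise CoevomapError(f"edges {e1} and {e2} share a node: no unit")
        return (i, j, k, l) if i < j else (j, i, l, k)

    def unit_value(self, e1: tuple[int, int], e2: tuple[int, int]) -> float:
        return self.log_f[self.quad_of(e1, e2)]

    def w(self, quad: Quad) -> float:
        return (self.log_f[quad] + self.offset_K) / 2.0


def build_score_table(
    fam_a: AlignedFamily,
    fam_b: AlignedFamily,
    graph: "MatchingGraph",
    offset_margin: float = 1.0,
) -> UnitScoreTable:
    """Score every unit of coevolution induced by the graph's edges.

    The offset is ``K = -min(log_f) + offset_margin`` (``K = offset_margin``
    when there are no units at all), which makes every shifted weight
    strictly positive without changing the optimal matching.
    """
    dA, lA = pair_count_matrices(fam_a)
    dB, lB = pair_count_matrices(fam_b)
    memo: dict[tuple[int, int, int, int], float] = {}
    log_f: dict[Quad, float] = {}
    edges = graph.edges
    for idx1 in range(len(edges)):
        i, k = edges[idx1]
        for idx2 in range(idx1 + 1, len(edges)):
            j, l = edges[idx2]
            if i == j or k == l:
                continue
            if i < j:
                quad = (i, j, k, l)
            else:
                quad = (j, i, l, k)
            counts = (dA[quad[0], quad[1]], lA[quad[0], quad[1]],
                      dB[quad[2], quad[3]], lB[quad[2], quad[3]])
            val = memo.get(counts)
            if val is None:
                val = _log_score(*counts)
                memo[counts] = val
            log_f[quad] = val
    if log_f:
        offset_K = -min(log_f.values()) + offset_margin
    else:
        offset_K = offset_margin
    return UnitScoreTable(graph=graph, log_f=log_f, offset_K=offset_K)


def coevolution_degree(
    pair: tuple[str, str], matching: "Matching", table: UnitScoreTable
) -> float:
    """Mean unit log score over the n-1 units containing ``pair``.

    This is the log of the per-pair coevolution degree: the geometric mean
    of the unit probabilities the pair participates in, a per-pair summary
    of how well it coevolves with the rest of the matching.
    """
    if pair not in matching.pairs:
        raise UnknownIdError(f"pair {pair!r} not in matching")
    n = len(matching.pairs)
    if n < 2:
        raise CoevomapError("coevolution degree undefined for |matching| < 2")
    g = table.graph
    e1 = (g.index_a[pair[0]], g.index_b[pair[1]])
    total = 0.0
    for other in matching.pairs:
        if other == pair:
            continue
        e2 = (g.index_a[other[0]], g.index_b[other[1]])
        total += table.unit_value(e1, e2)
    return total / (n - 1)
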