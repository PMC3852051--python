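"""Lagrangian relaxation solver for the maximum-likelihood matching program.

The quadratic matching program is decomposed edge-wise: each unit of
coevolution (a pair of co-selectable edges) gets half its shifted weight
``w = (f + K) / 2`` in each of the two *local* subproblems it belongs to,
and a multiplier ``lambda`` shifts weight between the two copies
(``w + lambda`` on the lexicographically first edge's side, ``w - lambda``
on the other). Each local subproblem and the master problem are maximum
weight bipartite matchings, so for any multiplier vector the master value
is a valid upper bound on the optimum; feasible master matchings provide
lower bounds. Multipliers are tuned by Held–Karp style subgradient steps
interleaved with an undamped equalisation step, and extracted matchings are
polished by a swap/move local search.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import CoevomapError, InfeasibleError
from .matching import Matching, MatchingGraph, log_likelihood
from .scoring import Quad, UnitScoreTable

_EPS = 1e-12


@dataclass
class SolverConfig:
    """Tuning knobs for the subgradient/dual-descent hybrid.

    ``time_limit`` (seconds) and ``gap_tol`` (relative gap for a proof of
    optimality) are the user-facing controls; the rest are standard
    subgradient parameters. The solver is deterministic for a fixed config
    whenever the time limit is not the binding stop criterion.
    """

    time_limit: float = 300.0
    gap_tol: float = 1e-6
    max_iter: int = 500
    mu0: float = 2.0
    mu_halve_after: int = 10
    mu_min: float = 1e-8
    dual_descent_every: int = 5
    local_search: bool = True
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "time_limit": self.time_limit,
            "gap_tol": self.gap_tol,
            "max_iter": self.max_iter,
            "mu0": self.mu0,
            "mu_halve_after": self.mu_halve_after,
            "mu_min": self.mu_min,
            "dual_descent_every": self.dual_descent_every,
            "local_search": self.local_search,
            "seed": self.seed,
        }


@dataclass
class SolverResult:
    """Outcome of a solver run, on the log-likelihood scale."""

    matching: Matching
    lower_bound: float
    upper_bound: float
    relative_gap: float
    proved_optimal: bool
    iterations: int
    trace: list[tuple[float, float]] = field(repr=False)
    wall_time: float = 0.0
    config: SolverConfig | None = field(default=None, repr=False)


def _relative_gap(lower: float, upper: float) -> float:
    gap = upper - lower
    if gap <= _EPS:
        return 0.0
    if abs(lower) > _EPS:
        return gap / abs(lower)
    return math.inf


class _Decomposition:
    """Precomputed index structure shared by all solver iterations."""

    def __init__(self, graph: MatchingGraph, table: UnitScoreTable) -> None:
        if table.graph is not graph and table.graph.edges != graph.edges:
            raise CoevomapError("score table was built for a different graph")
        self.graph = graph
        self.table = table
        self.edges: Sequence[tuple[int, int]] = graph.edges
        self.edge_index = {e: idx for idx, e in enumerate(self.edges)}
        self.n = graph.n
        self.K = table.offset_K
        self.const = math.comb(self.n, 2) * self.K

        self.quads: list[Quad] = sorted(table.log_f)
        self.quad_index = {q: m for m, q in enumerate(self.quads)}
        self.w = np.array([table.w(q) for q in self.quads], dtype=float)
        self.m = len(self.quads)

        # Per edge: partner bookkeeping for its local assignment problem.
        # sign +1 when the edge is the smaller-A-index side of the quad.
        partners: list[list[tuple[int, int, int]]] = [[] for _ in self.edges]
        for q in self.quads:
            i, j, k, l = q
            m_idx = self.quad_index[q]
            a = self.edge_index[(i, k)]
            b = self.edge_index[(j, l)]
            partners[a].append((b, m_idx, +1))
            partners[b].append((a, m_idx, -1))

        self.local: list[dict] = []
        for e_idx, plist in enumerate(partners):
            rows: dict[int, int] = {}
            cols: dict[int, int] = {}
            pos_r, pos_c, q_idx, sign, partner_edge = [], [], [], [], []
            for b, m_idx, s in plist:
                j, l = self.edges[b]
                r = rows.setdefault(j, len(rows))
                c = cols.setdefault(l, len(cols))
                pos_r.append(r)
                pos_c.append(c)
                q_idx.append(m_idx)
                sign.append(s)
                partner_edge.append(b)
            self.local.append(
                {
                    "shape": (len(rows), len(cols)),
                    "pos_r": np.array(pos_r, dtype=np.intp),
                    "pos_c": np.array(pos_c, dtype=np.intp),
                    "q": np.array(q_idx, dtype=np.intp),
                    "sign": np.array(sign, dtype=float),
                    "partner": np.array(partner_edge, dtype=np.intp),
                }
            )

    # -- Lagrangian subproblems ------------------------------------------

    def local_solution(self, e_idx: int, lam: np.ndarray) -> tuple[float, np.ndarray]:
        """Solve the local subproblem of one edge.

        Returns ``(v, picked)`` where ``v`` is the optimal profit over
        matchings of strictly-positive adjusted partner weights and
        ``picked`` holds the indices (into this edge's partner arrays) of
        the units the optimum uses.
        """
        loc = self.local[e_idx]
        nr, nc = loc["shape"]
        if nr == 0 or nc == 0:
            return 0.0, np.empty(0, dtype=np.intp)
        adj = self.w[loc["q"]] + loc["sign"] * lam[loc["q"]]
        mat = np.zeros((nr, nc))
        lookup = np.full((nr, nc), -1, dtype=np.intp)
        np.maximum.at(mat, (loc["pos_r"], loc["pos_c"]), np.maximum(adj, 0.0))
        lookup[loc["pos_r"], loc["pos_c"]] = np.arange(len(adj))
        rr, cc = linear_sum_assignment(mat, maximize=True)
        vals = mat[rr, cc]
        used = vals > _EPS
        v = float(vals[used].sum())
        picked = lookup[rr[used], cc[used]]
        return v, picked

    def dual_iteration(self, lam: np.ndarray):
        """One evaluation of the relaxation at ``lam``.

        Returns ``(upper_ll, x_edges, picks)``: the bound translated to the
        log-likelihood scale, the master matching (edge indices), and per
        edge the partner-array indices its local optimum picked.
        """
        v = np.empty(len(self.edges))
        picks: list[np.ndarray] = []
        for e_idx in range(len(self.edges)):
            val, picked = self.local_solution(e_idx, lam)
            v[e_idx] = val
            picks.append(picked)

        x_edges: list[int] = []
        master_value = 0.0
        for ai, bi in self.graph.species_parts.values():
            mat = np.empty((len(ai), len(bi)))
            for r, i in enumerate(ai):
                for c, k in enumerate(bi):
                    mat[r, c] = v[self.edge_index[(i, k)]]
            rr, cc = linear_sum_assignment(mat, maximize=True)
            master_value += float(mat[rr, cc].sum())
            for r, c in zip(rr, cc):
                x_edges.append(self.edge_index[(ai[r], bi[c])])
        return master_value - self.const, sorted(x_edges), picks

    def subgradient(self, x_edges: Sequence[int], picks: list[np.ndarray]) -> np.ndarray:
        """Disagreement vector between the two local copies of each unit,
        restricted to edges selected by the master problem."""
        g = np.zeros(self.m)
        selected = set(x_edges)
        for e_idx in selected:
            loc = self.local[e_idx]
            p = picks[e_idx]
            if len(p):
                g[loc["q"][p]] += loc["sign"][p]
        return g

    # -- primal side -----------------------------------------------------

    def matching_loglik(self, edge_idxs: Sequence[int]) -> float:
        total = 0.0
        edges = [self.edges[e] for e in edge_idxs]
        for a in range(len(edges)):
            for b in range(a + 1, len(edges)):
                total += self.table.unit_value(edges[a], edges[b])
        return total

    def improve_matching(self, edge_idxs: list[int], max_passes: int = 25) -> list[int]:
        """Swap/move local search within species components.

        Tries exchanging the partners of two matched A nodes of a species
        and re-pointing a matched A node at an unmatched B node (and
        symmetrically), accepting strict improvements until a local
        optimum or the pass cap.
        """
        current = list(edge_idxs)

        def unit(e1: int, e2: int) -> float:
            return self.table.unit_value(self.edges[e1], self.edges[e2])

        def gain_replace(old_pair: list[int], new_pair: list[int]) -> float:
            rest = [e for e in current if e not in old_pair]
            g = 0.0
            for e in rest:
                for ne in new_pair:
                    g += unit(ne, e)
                for oe in old_pair:
                    g -= unit(oe, e)
            if len(new_pair) == 2:
                g += unit(new_pair[0], new_pair[1]) - unit(old_pair[0], old_pair[1])
            return g

        for _ in range(max_passes):
            improved = False
            by_species: dict[str, list[int]] = {}
            for e in current:
                i, _ = self.edges[e]
                by_species.setdefault(self.graph.species_a[i], []).append(e)
            for sp, comp_edges in by_species.items():
                ai, bi = self.graph.species_parts[sp]
                used_b = {self.edges[e][1] for e in comp_edges}
                free_b = [k for k in bi if k not in used_b]
                used_a = {self.edges[e][0] for e in comp_edges}
                free_a = [i for i in ai if i not in used_a]
                # partner swaps between two matched A nodes
                for x in range(len(comp_edges)):
                    for y in range(x + 1, len(comp_edges)):
                        e1, e2 = comp_edges[x], comp_edges[y]
                        (i1, k1), (i2, k2) = self.edges[e1], self.edges[e2]
                        ne1 = self.edge_index[(i1, k2)]
                        ne2 = self.edge_index[(i2, k1)]
                        if gain_replace([e1, e2], [ne1, ne2]) > 1e-10:
                            current[current.index(e1)] = ne1
                            current[current.index(e2)] = ne2
                            comp_edges[x], comp_edges[y] = ne1, ne2
                            improved = True
                # re-point a matched A node at an unmatched B node
                for x in range(len(comp_edges)):
                    e1 = comp_edges[x]
                    i1, k1 = self.edges[e1]
                    for k_new in list(free_b):
                        ne1 = self.edge_index[(i1, k_new)]
                        if gain_replace([e1], [ne1]) > 1e-10:
                            current[current.index(e1)] = ne1
                            comp_edges[x] = ne1
                            free_b.remove(k_new)
                            free_b.append(k1)
                            k1 = k_new
                            e1 = ne1
                            improved = True
                # re-point a matched B node at an unmatched A node
                for x in range(len(comp_edges)):
                    e1 = comp_edges[x]
                    i1, k1 = self.edges[e1]
                    for i_new in list(free_a):
                        ne1 = self.edge_index[(i_new, k1)]
                        if gain_replace([e1], [ne1]) > 1e-10:
                            current[current.index(e1)] = ne1
                            comp_edges[x] = ne1
                            free_a.remove(i_new)
                            free_a.append(i1)
                            i1 = i_new
                            e1 = ne1
                            improved = True
            if not improved:
                break
        return sorted(current)

    def lambda_array(self, lam: Mapping[Quad, float] | np.ndarray | None) -> np.ndarray:
        if lam is None:
            return np.zeros(self.m)
        if isinstance(lam, np.ndarray):
            if lam.shape != (self.m,):
                raise CoevomapError(f"lambda has shape {lam.shape}, expected ({self.m},)")
            return lam.astype(float)
        arr = np.zeros(self.m)
        for q, val in lam.items():
            arr[self.quad_index[q]] = val
        return arr


# -- spec-level operations ------------------------------------------------


def local_profit(
    i: int,
    k: int,
    lam: Mapping[Quad, float] | np.ndarray | None,
    table: UnitScoreTable,
) -> float:
    """Profit v_ik(lambda) of selecting edge (i, k): the optimal matching of
    its positively-weighted partner edges under the current multipliers."""
    graph = table.graph
    if (i, k) not in graph.edge_set:
        raise CoevomapError(f"({i}, {k}) is not an edge of the matching graph")
    dec = _Decomposition(graph, table)
    v, _ = dec.local_solution(dec.edge_index[(i, k)], dec.lambda_array(lam))
    return v


def dual_bound(
    lam: Mapping[Quad, float] | np.ndarray | None,
    table: UnitScoreTable,
    graph: MatchingGraph,
):
    """Evaluate the Lagrangian upper bound at ``lam``.

    Returns ``(value, x, y)``: the bound on the log-likelihood scale (the
    constant C(n,2)*K already removed), the master matching, and the local
    solutions as a map edge -> tuple of partner edges.
    """
    dec = _Decomposition(graph, table)
    upper, x_edges, picks = dec.dual_iteration(dec.lambda_array(lam))
    x = graph.matching_from_indices([dec.edges[e] for e in x_edges])
    y = {
        dec.edges[e_idx]: tuple(
            dec.edges[b] for b in dec.local[e_idx]["partner"][picks[e_idx]]
        )
        for e_idx in range(len(dec.edges))
    }
    return upper, x, y


def primal_from_dual(x: Matching, table: UnitScoreTable) -> tuple[Matching, float]:
    """Score a feasible master matching; its log likelihood is a lower bound."""
    n = table.graph.n
    if len(x) != n:
        raise CoevomapError(f"master matching has size {len(x)}, expected n={n}")
    table.graph.indices_of(x)  # validates edges
    return x, log_likelihood(x, table)


def solve(
    graph: MatchingGraph,
    table: UnitScoreTable,
    config: SolverConfig | None = None,
    **kwargs,
) -> SolverResult:
    """Run the subgradient / dual-descent hybrid.

    Maintains the best lower bound (score of the best feasible matching
    seen, after local search) and best upper bound (smallest relaxation
    value seen); stops on proof of optimality (relative gap below
    ``gap_tol``), the iteration cap, or the time limit.
    """
    if config is None:
        config = SolverConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a SolverConfig or keyword options, not both")
    if not graph.edges:
        raise InfeasibleError("matching graph has no edges; nothing to solve")

    start = time.monotonic()
    dec = _Decomposition(graph, table)
    lam = np.zeros(dec.m)

    best_lower = -math.inf
    best_upper = math.inf
    best_edges: list[int] | None = None
    trace: list[tuple[float, float]] = []
    mu = config.mu0
    stall = 0
    iteration = 0

    while iteration < config.max_iter:
        iteration += 1
        upper, x_edges, picks = dec.dual_iteration(lam)

        if upper < best_upper - 1e-12:
            best_upper = upper
            stall = 0
        else:
            stall += 1
            if stall >= config.mu_halve_after:
                mu = max(mu / 2.0, config.mu_min)
                stall = 0

        cand = dec.improve_matching(x_edges) if config.local_search else list(x_edges)
        lower = dec.matching_loglik(cand)
        if lower > best_lower + 1e-12 or best_edges is None:
            best_lower = lower
            best_edges = cand

        trace.append((best_lower, best_upper))

        rel = _relative_gap(best_lower, best_upper)
        if rel <= config.gap_tol:
            break
        if time.monotonic() - start > config.time_limit:
            break

        g = dec.subgradient(x_edges, picks)
        norm2 = float(g @ g)
        if norm2 <= _EPS:
            # consistent local/master solutions: the bound is exact here
            best_upper = min(best_upper, dec.matching_loglik(x_edges))
            best_upper = max(best_upper, best_lower)
            trace[-1] = (best_lower, best_upper)
            break
        gap = best_upper - best_lower
        if not math.isfinite(gap) or gap <= 0:
            gap = abs(best_lower) + 1.0
        if config.dual_descent_every and iteration % config.dual_descent_every == 0:
            step = gap / norm2  # undamped equalisation round
        else:
            step = mu * gap / norm2
        lam -= step * g

    assert best_edges is not None
    matching = graph.matching_from_indices([dec.edges[e] for e in best_edges])
    rel = _relative_gap(best_lower, best_upper)
    proved = rel <= config.gap_tol
    return SolverResult(
        matching=matching,
        lower_bound=best_lower,
        upper_bound=best_upper,
        relative_gap=rel,
        proved_optimal=proved,
        iterations=iteration,
        trace=trace,
        wall_time=time.monotonic() - start,
        config=config,
    )
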