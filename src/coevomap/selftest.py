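"""Built-in sanity checks runnable from the command line.

Covers the worked unit-score examples, hypergeometric normalisation, the
offset-shift identity between the quadratic objective and the log
likelihood, weak duality of the relaxation, and table-invariant
enforcement. Intended as a fast post-install smoke test.
"""

from __future__ import annotations

import math

import numpy as np

from .errors import CoevomapError
from .lagrangian import solve
from .matching import enumerate_max_matchings, log_likelihood, bqp2_objective
from .model import ParalogMatchingModel
from .scoring import PairCounts, UnitScoreTable, unit_log_score
from .simulate import SynthConfig, generate


def _check_worked_examples() -> None:
    p1 = math.exp(unit_log_score(PairCounts(11, 12), PairCounts(15, 19)))
    if abs(p1 - 0.274) > 5e-4:
        raise CoevomapError(f"unit score example 1: got {p1:.6f}, expected ~0.274")
    p2 = math.exp(unit_log_score(PairCounts(11, 12), PairCounts(3, 19)))
    if abs(p2 - 4.4e-5) > 5e-7:
        raise CoevomapError(f"unit score example 2: got {p2:.3e}, expected ~4.4e-5")


def _check_normalisation() -> None:
    for lA, lB in [(12, 19), (30, 7), (50, 50)]:
        for T in (0, 5, lA // 2 + lB // 2, lA + lB):
            lo, hi = max(0, T - lB), min(lA, T)
            total = sum(
                math.exp(unit_log_score(PairCounts(dA, lA), PairCounts(T - dA, lB)))
                for dA in range(lo, hi + 1)
            )
            if abs(total - 1.0) > 1e-9:
                raise CoevomapError(
                    f"hypergeometric pmf sums to {total} for lA={lA}, lB={lB}, T={T}"
                )


def _check_shift_identity_and_duality() -> None:
    fam_a, fam_b, _ = generate(
        SynthConfig(n_species=2, paralogs_per_species=(2, 3), seq_length=60, seed=7)
    )
    model = ParalogMatchingModel(fam_a, fam_b)
    table = model.table
    if any(table.w(q) <= 0 for q in table.log_f):
        raise CoevomapError("shifted weights are not strictly positive")
    opt = -math.inf
    for m in enumerate_max_matchings(model.graph):
        ll = log_likelihood(m, table)
        opt = max(opt, ll)
        if abs(bqp2_objective(m, table) - ll) > 1e-9:
            raise CoevomapError("shifted objective disagrees with log likelihood")
    res = solve(model.graph, table, max_iter=100, time_limit=30.0)
    if not (res.lower_bound - 1e-9 <= opt <= res.upper_bound + 1e-9):
        raise CoevomapError(
            f"bound sandwich violated: {res.lower_bound} / {opt} / {res.upper_bound}"
        )
    lows = [lo for lo, _ in res.trace]
    ups = [up for _, up in res.trace]
    if any(b < a - 1e-12 for a, b in zip(lows, lows[1:])):
        raise CoevomapError("best lower bound not monotone")
    if any(b > a + 1e-12 for a, b in zip(ups, ups[1:])):
        raise CoevomapError("best upper bound not monotone")


def _check_invariant_enforcement() -> None:
    fam_a, fam_b, _ = generate(
        SynthConfig(n_species=1, paralogs_per_species=(2, 2), seq_length=30, seed=1)
    )
    model = ParalogMatchingModel(fam_a, fam_b)
    try:
        UnitScoreTable(model.graph, dict(model.table.log_f), offset_K=-1.0)
    except CoevomapError:
        return
    raise CoevomapError("corrupted score table (negative K) was not rejected")


CHECKS = [
    ("worked unit-score examples", _check_worked_examples),
    ("hypergeometric normalisation", _check_normalisation),
    ("offset-shift identity & weak duality", _check_shift_identity_and_duality),
    ("score-table invariant enforcement", _check_invariant_enforcement),
]


def run_selftest() -> list[tuple[str, bool, str]]:
    """Run all checks; returns (name, passed, detail) per check."""
    results = []
    for name, fn in CHECKS:
        try:
            fn()
            results.append((name, True, "ok"))
        except Exception as exc:  # noqa: BLE001 - report, don't crash
            results.append((name, False, str(exc)))
    return results
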