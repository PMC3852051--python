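"""Evaluation of predicted matchings against a reference.

Recall is the percentage of reference pairings recovered; precision is the
percentage of predicted pairings that are correct. The average unit log
likelihood normalises a matching's log likelihood by its C(n, 2) units so
matchings of different sizes become comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

from .errors import CoevomapError
from .matching import Matching, log_likelihood
from .scoring import UnitScoreTable


@dataclass(frozen=True)
class EvalReport:
    recall: float
    precision: float
    predicted_size: int
    reference_size: int
    correct: int
    avg_unit_loglik_predicted: float | None = None
    avg_unit_loglik_reference: float | None = None
    relative_gap: float | None = None

    def as_dict(self) -> dict:
        return asdict(self)


def recall_precision(predicted: Matching, reference: Matching) -> EvalReport:
    """Recall and precision (in percent) of a prediction vs a reference."""
    if len(reference) == 0:
        raise CoevomapError("recall undefined for an empty reference matching")
    if len(predicted) == 0:
        raise CoevomapError("precision undefined for an empty predicted matching")
    correct = predicted.intersection_size(reference)
    return EvalReport(
        recall=100.0 * correct / len(reference),
        precision=100.0 * correct / len(predicted),
        predicted_size=len(predicted),
        reference_size=len(reference),
        correct=correct,
    )


def avg_unit_loglik(matching: Matching, table: UnitScoreTable) -> float:
    """Log likelihood per unit of coevolution: log L / C(|matching|, 2)."""
    if len(matching) < 2:
        raise CoevomapError("average unit log likelihood undefined for size < 2")
    return log_likelihood(matching, table) / math.comb(len(matching), 2)


def evaluate(
    predicted: Matching,
    reference: Matching,
    table: UnitScoreTable | None = None,
    relative_gap: float | None = None,
) -> EvalReport:
    """Full per-instance report; unit log likelihoods when a table is given."""
    base = recall_precision(predicted, reference)
    avg_pred = avg_ref = None
    if table is not None:
        if len(predicted) >= 2:
            avg_pred = avg_unit_loglik(predicted, table)
        if len(reference) >= 2:
            avg_ref = avg_unit_loglik(reference, table)
    return EvalReport(
        recall=base.recall,
        precision=base.precision,
        predicted_size=base.predicted_size,
        reference_size=base.reference_size,
        correct=base.correct,
        avg_unit_loglik_predicted=avg_pred,
        avg_unit_loglik_reference=avg_ref,
        relative_gap=relative_gap,
    )
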