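"""Synthetic coevolving family pairs with a planted ground-truth matching.

The generator realises the scoring model's own assumptions: every family
member diverges from a family-wide virtual ancestor by i.i.d. per-column
substitutions, and the two members of a planted pair share the same
substitution rate (the equal-rates hypothesis H). Pairwise mismatch counts
between any two members of a family are therefore Bernoulli sums whose
rate is a function of the two per-sequence rates — identical, for planted
pairs, across the two families. Distinct paralog slots within a species are
separated in rate by ``decoy_rate_jitter``; at jitter 0 paralogs of a
species are statistically exchangeable and the planted matching carries no
signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .errors import InputError
from .io import AlignedFamily
from .matching import Matching

_AMINO = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generator.

    ``paralogs_per_species`` is an inclusive (lo, hi) range; a count is
    drawn per species *and per family*, so families may be unbalanced and
    surplus sequences act as unmatched decoys. ``shared_rate_range`` bounds
    the per-pair substitution rates; ``decoy_rate_jitter`` is the rate
    separation between paralog slots of the same species.
    """

    n_species: int = 4
    paralogs_per_species: tuple[int, int] = (3, 3)
    seq_length: int = 200
    shared_rate_range: tuple[float, float] = (0.05, 0.45)
    decoy_rate_jitter: float = 0.3
    indel_rate: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise InputError("n_species must be >= 1")
        if self.seq_length < 1:
            raise InputError("seq_length must be >= 1")
        lo, hi = self.paralogs_per_species
        if not (1 <= lo <= hi):
            raise InputError("paralogs_per_species must be 1 <= lo <= hi")
        for r in (*self.shared_rate_range, self.indel_rate):
            if not 0.0 <= r <= 1.0:
                raise InputError("rates must lie in [0, 1]")
        if self.shared_rate_range[0] > self.shared_rate_range[1]:
            raise InputError("shared_rate_range must be (lo, hi) with lo <= hi")
        if self.decoy_rate_jitter < 0:
            raise InputError("decoy_rate_jitter must be >= 0")

    def as_dict(self) -> dict:
        return asdict(self)


def _mutate(ancestor: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each column independently with probability ``rate``."""
    seq = ancestor.copy()
    hit = rng.random(seq.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # replace by a uniformly chosen *different* residue
        shift = rng.integers(1, len(_AMINO), size=n_hit)
        seq[hit] = (seq[hit] + shift) % len(_AMINO)
    return seq


def _slot_rates(
    n_slots: int, cfg: SynthConfig, rng: np.random.Generator
) -> list[float]:
    """Per-pair substitution rates for the paralog slots of one species.

    Each slot draws its own rate from ``shared_rate_range`` — the two
    members of a planted pair share it exactly (hypothesis H) — and
    ``decoy_rate_jitter`` stacks an extra offset per slot so paralogs of
    the same species diverge at increasingly different rates.
    """
    lo, hi = cfg.shared_rate_range
    rates = []
    for m in range(n_slots):
        r = float(rng.uniform(lo, hi)) + m * cfg.decoy_rate_jitter
        rates.append(float(min(max(r, 0.01), 0.95)))
    return rates


def generate(config: SynthConfig) -> tuple[AlignedFamily, AlignedFamily, Matching]:
    """Simulate two aligned families and return them with the planted truth.

    Per species ``t`` each family gets its own paralog count from the
    configured range; the first ``min`` paralog slots of the two families
    form planted pairs whose members mutate from the respective family
    ancestor at the same slot rate. Gap columns are inserted i.i.d. per
    sequence at ``indel_rate``. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    anc_a = rng.integers(0, len(_AMINO), size=L)
    anc_b = rng.integers(0, len(_AMINO), size=L)

    seqs_a: list[tuple[str, str]] = []
    seqs_b: list[tuple[str, str]] = []
    species_a: dict[str, str] = {}
    species_b: dict[str, str] = {}
    truth_pairs: list[tuple[str, str]] = []

    lo, hi = config.paralogs_per_species
    for t in range(config.n_species):
        sp = f"SP{t:02d}"
        count_a = int(rng.integers(lo, hi + 1))
        count_b = int(rng.integers(lo, hi + 1))
        n_slots = max(count_a, count_b)
        rates = _slot_rates(n_slots, config, rng)

        def emit(idx: int, family: str, rate: float) -> tuple[str, np.ndarray]:
            sid = f"{family}{t:02d}p{idx}_{sp}"
            anc = anc_a if family == "A" else anc_b
            return sid, _mutate(anc, rate, rng)

        for m in range(count_a):
            sid, seq = emit(m, "A", rates[m])
            row = _with_gaps(seq, config.indel_rate, rng)
            seqs_a.append((sid, row))
            species_a[sid] = sp
        for m in range(count_b):
            sid, seq = emit(m, "B", rates[m])
            row = _with_gaps(seq, config.indel_rate, rng)
            seqs_b.append((sid, row))
            species_b[sid] = sp
        for m in range(min(count_a, count_b)):
            truth_pairs.append((f"A{t:02d}p{m}_{sp}", f"B{t:02d}p{m}_{sp}"))

    fam_a = AlignedFamily("synthA", tuple(seqs_a), species_a)
    fam_b = AlignedFamily("synthB", tuple(seqs_b), species_b)
    return fam_a, fam_b, Matching(truth_pairs)


def _with_gaps(seq: np.ndarray, indel_rate: float, rng: np.random.Generator) -> str:
    chars = [_AMINO[c] for c in seq]
    if indel_rate > 0:
        gaps = rng.random(len(chars)) < indel_rate
        for pos in np.nonzero(gaps)[0]:
            chars[pos] = "-"
    return "".join(chars)
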