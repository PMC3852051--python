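"""Reading family alignments and species labels; writing matchings and reports.

Input is one aligned FASTA per protein family. Species labels come either
from a two-column TSV (``sequence_id<TAB>species``, no header) or from
SwissProt-style ``NAME_SPECIES`` header suffixes. Gap characters ``-`` and
``.`` are equivalent; residues are uppercased on read.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping

from Bio import SeqIO

from .errors import (
    DuplicateIdError,
    InputError,
    MissingSpeciesError,
    RaggedAlignmentError,
    UnknownIdError,
)

GAP_CHARS = frozenset("-.")

#: regex for SwissProt-style entry names, e.g. ``RL3_YEAST`` -> ``YEAST``
_SUFFIX_RE = re.compile(r"_([A-Za-z0-9]+)$")


@dataclass(frozen=True)
class AlignedFamily:
    """A multiple sequence alignment with per-sequence species labels.

    Parameters
    ----------
    name : str
        Family identifier (used in error messages and reports).
    sequences : tuple of (str, str)
        Ordered ``(id, aligned_row)`` pairs. Rows are uppercase with ``-``
        as the only gap character, all of equal width.
    species_of : mapping
        Sequence id -> species label; exactly one label per sequence.
    """

    name: str
    sequences: tuple[tuple[str, str], ...]
    species_of: Mapping[str, str] = field(hash=False)

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.sequences]
        seen: set[str] = set()
        for sid in ids:
            if sid in seen:
                raise DuplicateIdError(
                    f"family {self.name!r}: duplicate sequence id {sid!r}"
                )
            seen.add(sid)
        widths = {len(row) for _, row in self.sequences}
        if len(widths) > 1:
            ref = len(self.sequences[0][1])
            for sid, row in self.sequences:
                if len(row) != ref:
                    raise RaggedAlignmentError(
                        f"family {self.name!r}: sequence {sid!r} has width "
                        f"{len(row)}, expected {ref}"
                    )
        for sid in ids:
            if sid not in self.species_of:
                raise MissingSpeciesError(
                    f"family {self.name!r}: sequence {sid!r} has no species label"
                )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.sequences)

    @property
    def width(self) -> int:
        return len(self.sequences[0][1]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)

    def row(self, sid: str) -> str:
        for s, r in self.sequences:
            if s == sid:
                return r
        raise UnknownIdError(f"family {self.name!r}: unknown sequence id {sid!r}")

    def species_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for sid, _ in self.sequences:
            sp = self.species_of[sid]
            counts[sp] = counts.get(sp, 0) + 1
        return counts


def _normalise_row(row: str) -> str:
    return row.upper().replace(".", "-")


def read_species_tsv(source: str | Path | IO[str]) -> dict[str, str]:
    """Parse a two-column ``id<TAB>species`` file (no header)."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        lines = Path(source).read_text().splitlines()
    mapping: dict[str, str] = {}
    for ln, line in enumerate(lines, 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise InputError(f"species map line {ln}: expected 'id<TAB>species'")
        mapping[parts[0]] = parts[1]
    return mapping


def species_from_header(seq_id: str) -> str | None:
    """Extract the species from a ``NAME_SPECIES`` style identifier."""
    m = _SUFFIX_RE.search(seq_id)
    return m.group(1) if m else None


def read_family(
    alignment_source: str | Path | IO[str],
    species_source: str | Path | IO[str] | Mapping[str, str] | None = None,
    parse_mode: str = "auto",
    name: str | None = None,
) -> AlignedFamily:
    """Read an aligned FASTA file into an :class:`AlignedFamily`.

    ``species_source`` may be a TSV path/handle or a ready mapping; when
    absent (or ``parse_mode="suffix"``) species are parsed from
    ``NAME_SPECIES`` header suffixes. An explicit mapping wins over header
    parsing when both are available.
    """
    if parse_mode not in ("auto", "suffix", "tsv"):
        raise InputError(f"unknown parse_mode {parse_mode!r}")
    if name is None:
        name = Path(str(alignment_source)).stem if not hasattr(
            alignment_source, "read"
        ) else "family"

    records = list(SeqIO.parse(alignment_source, "fasta"))
    if not records:
        raise InputError(f"family {name!r}: no FASTA records found")
    sequences = tuple((rec.id, _normalise_row(str(rec.seq))) for rec in records)

    mapping: Mapping[str, str] | None = None
    if species_source is not None:
        if isinstance(species_source, Mapping):
            mapping = dict(species_source)
        else:
            mapping = read_species_tsv(species_source)
    if parse_mode == "tsv" and mapping is None:
        raise InputError("parse_mode='tsv' requires a species_source")

    species_of: dict[str, str] = {}
    for sid, _ in sequences:
        if mapping is not None and sid in mapping:
            species_of[sid] = mapping[sid]
        elif mapping is None or parse_mode != "tsv":
            sp = species_from_header(sid)
            if sp is not None:
                species_of[sid] = sp
    return AlignedFamily(name=name, sequences=sequences, species_of=species_of)


def write_matching(matching, path: str | Path, species_of: Mapping[str, str]) -> None:
    """Write a matching as TSV: ``family_A_id  family_B_id  species``.

    Rows are sorted by (species, family_A_id) so output is deterministic.
    """
    rows = sorted(
        ((a, b, species_of[a]) for a, b in matching.pairs),
        key=lambda r: (r[2], r[0]),
    )
    with open(path, "w") as fh:
        fh.write("family_A_id\tfamily_B_id\tspecies\n")
        for a, b, sp in rows:
            fh.write(f"{a}\t{b}\t{sp}\n")


def read_matching(path: str | Path):
    """Read a matching TSV written by :func:`write_matching`."""
    from .matching import Matching

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["family_A_id", "family_B_id"]:
        raise InputError(f"{path}: not a matching TSV (missing header)")
    pairs = []
    for ln, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise InputError(f"{path} line {ln}: expected at least two columns")
        pairs.append((parts[0], parts[1]))
    return Matching(pairs)


def write_report(report: Mapping, path: str | Path) -> None:
    """Dump a JSON run report (bounds, gap, iterations, seed, config echo)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


def write_fasta(family: AlignedFamily, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, row in family.sequences:
            fh.write(f">{sid}\n{row}\n")


def write_species_tsv(family: AlignedFamily, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, _ in family.sequences:
            fh.write(f"{sid}\t{family.species_of[sid]}\n")
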