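"""Species-labelled alignment I/O.

Records live in plain multi-FASTA.  The species label is the header field
after the *last* ``|`` (GenBank-style ids contain pipes themselves), or it
comes from a two-column ``id<TAB>species`` map that overrides headers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .errors import AlignmentShapeError, AlphabetError, LabellingError

logger = logging.getLogger(__name__)

#: IUPAC-DNA characters accepted on input (after uppercasing; U is folded to T).
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")

#: Unambiguous bases.
BASES = ("A", "C", "G", "T")

#: IUPAC code -> set of unambiguous bases it stands for.  ``N`` is the full
#: set for sequence semantics; modules that must treat N conservatively
#: (e.g. the PCR binding model) special-case it themselves.
IUPAC_SETS: Mapping[str, frozenset] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
    "-": frozenset(),
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-",
    "TGCAYRSWMKVHDBN-",
)


def validate_dna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase *seq*, fold U->T, and verify the IUPAC-DNA alphabet.

    Raises :class:`AlphabetError` naming the first offending position
    (1-based).
    """
    s = seq.upper()
    if "U" in s:
        logger.warning("converted U to T in %s", context)
        s = s.replace("U", "T")
    for i, ch in enumerate(s):
        if ch not in IUPAC_DNA:
            raise AlphabetError(
                f"illegal character {ch!r} at position {i + 1} in {context}"
            )
    return s


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement over the full IUPAC alphabet.

    Gaps are preserved; ambiguity codes map to their complement codes.
    """
    s = validate_dna(seq)
    return s.translate(_COMPLEMENT)[::-1]


def ungap(seq: str) -> str:
    """Strip alignment gaps from *seq*."""
    return seq.replace("-", "")


@dataclass(frozen=True)
class SequenceRecord:
    """One DNA sequence tagged with a species label."""

    id: str
    species: str
    seq: str

    def __post_init__(self) -> None:
        if not self.seq:
            raise AlphabetError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "seq", validate_dna(self.seq, context=f"record {self.id!r}"))

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class SpeciesAlignment:
    """An equal-length collection of :class:`SequenceRecord`.

    The species-label set is available without re-parsing headers via
    :attr:`species` / :meth:`records_for`.
    """

    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentShapeError("alignment has no records")
        length = len(self.records[0].seq)
        for rec in self.records:
            if len(rec.seq) != length:
                raise AlignmentShapeError(
                    f"record {rec.id!r} has length {len(rec.seq)}, expected {length}"
                )
        seen = set()
        for rec in self.records:
            if rec.id in seen:
                raise LabellingError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def species(self) -> tuple:
        """Distinct species labels, in first-appearance order."""
        out = []
        for rec in self.records:
            if rec.species not in out:
                out.append(rec.species)
        return tuple(out)

    def records_for(self, species: str) -> list:
        return [r for r in self.records if r.species == species]

    def column(self, position: int) -> str:
        """Column characters at a 1-based *position*, in record order."""
        if not 1 <= position <= self.length:
            raise IndexError(
                f"position {position} outside alignment [1, {self.length}]"
            )
        i = position - 1
        return "".join(rec.seq[i] for rec in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_species_map(path) -> dict:
    """Parse a two-column ``id<TAB>species`` TSV (no header, UTF-8)."""
    mapping: dict = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise LabellingError(f"{path}:{lineno}: expected 'id<TAB>species'")
        mapping[parts[0].strip()] = parts[1].strip()
    return mapping


def _split_header(header: str) -> tuple:
    """Return (id, species-or-None) from a FASTA header line (sans '>')."""
    h = header.strip()
    if "|" in h:
        rec_id, species = h.rsplit("|", 1)
        return rec_id.strip(), species.strip() or None
    return h.split()[0], None


def read_alignment_fasta(path, species_map=None) -> SpeciesAlignment:
    """Read a species-labelled alignment from multi-FASTA.

    *species_map* (path to an ``id<TAB>species`` TSV) overrides header
    labels.  Without a map, the label is the header field after the last
    ``|``; a record that ends up unlabelled raises :class:`LabellingError`.
    """
    mapping = read_species_map(species_map) if species_map is not None else {}
    records = []
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        rec_id, species = _split_header(bio_rec.description)
        if mapping:
            # the map keys on either the full pre-pipe id or the bare header id
            species = mapping.get(rec_id, mapping.get(bio_rec.id, species))
        if species is None:
            raise LabellingError(f"no species label for record {rec_id!r}")
        records.append(SequenceRecord(id=rec_id, species=species, seq=str(bio_rec.seq)))
    if not records:
        raise AlignmentShapeError(f"no FASTA records found in {path}")
    return SpeciesAlignment(records=records)


def write_fasta(aln: SpeciesAlignment, path) -> None:
    """Write *aln* as 60-column-wrapped multi-FASTA with ``id|species`` headers.

    Round-trips exactly through :func:`read_alignment_fasta`.
    """
    lines = []
    for rec in aln.records:
        lines.append(f">{rec.id}|{rec.species}")
        for i in range(0, len(rec.seq), 60):
            lines.append(rec.seq[i : i + 60])
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_species_map(aln: SpeciesAlignment, path) -> None:
    """Write the ``id<TAB>species`` TSV for *aln*."""
    Path(path).write_text(
        "".join(f"{r.id}\t{r.species}\n" for r in aln.records), encoding="utf-8"
    )
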