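"""Discovery of species-diagnostic alignment columns (fixed differences).

A column is diagnostic for a target species when every non-missing target
record carries one base and that base occurs in zero non-target records.
Ambiguity codes and ``N`` count as missing, never as a match; columns
containing an alignment gap are never diagnostic (the method is SNP-based).
All coordinates are 1-based.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError, LabellingError
from .seqio import BASES, SpeciesAlignment

__all__ = [
    "ColumnProfile",
    "DiagnosticSite",
    "profile_column",
    "find_diagnostic_sites",
    "write_sites_tsv",
    "sites_to_json",
]


@dataclass(frozen=True)
class ColumnProfile:
    """Per-species base counts for one alignment column (1-based)."""

    position: int
    counts_by_species: dict
    n_missing: int

    @property
    def n_records(self) -> int:
        return sum(sum(c.values()) for c in self.counts_by_species.values()) + self.n_missing


@dataclass(frozen=True)
class DiagnosticSite:
    """A column fixed in the target species for a base absent elsewhere."""

    position: int
    target_species: str
    target_base: str
    nontarget_bases: frozenset
    strict: bool

    def __post_init__(self) -> None:
        if self.target_base in self.nontarget_bases:
            raise ValueError(
                f"site {self.position}: target base {self.target_base} "
                "also present in non-target records"
            )


def profile_column(aln: SpeciesAlignment, position: int) -> ColumnProfile:
    """Exact per-species base counts at *position* (1-based).

    ``N``, IUPAC ambiguity codes, and gaps are tallied as missing.
    """
    if not 1 <= position <= aln.length:
        raise IndexError(f"position {position} outside alignment [1, {aln.length}]")
    i = position - 1
    counts: dict = {}
    n_missing = 0
    for rec in aln.records:
        ch = rec.seq[i]
        if ch in BASES:
            counts.setdefault(rec.species, Counter())[ch] += 1
        else:
            n_missing += 1
    return ColumnProfile(position=position, counts_by_species=counts, n_missing=n_missing)


def find_diagnostic_sites(
    aln: SpeciesAlignment,
    target_species: str,
    max_missing_frac: float = 0.0,
    require_strict: bool = True,
) -> list:
    """All columns diagnostic for *target_species*, in ascending position order.

    A column qualifies when (a) all non-missing target records share one
    base, (b) that base appears in zero non-target records, and (c) the
    missing fraction is at most *max_missing_frac*.  With
    *require_strict* any missing character disqualifies the column.
    Columns containing a gap are always excluded.
    """
    if target_species not in aln.species:
        raise LabellingError(f"unknown species {target_species!r}")
    if len(aln.species) < 2:
        raise ConfigurationError(
            "diagnostic-site discovery needs at least 2 species in the alignment"
        )
    if not 0.0 <= max_missing_frac < 1.0:
        raise ConfigurationError(f"max_missing_frac {max_missing_frac} not in [0, 1)")

    n = len(aln.records)
    sites = []
    for pos in range(1, aln.length + 1):
        col = aln.column(pos)
        if "-" in col:
            continue
        prof = profile_column(aln, pos)
        if require_strict and prof.n_missing > 0:
            continue
        if prof.n_missing / n > max_missing_frac:
            continue
        target_counts = prof.counts_by_species.get(target_species, Counter())
        if len(target_counts) != 1:
            continue  # no base, or more than one base, in the target
        (target_base,) = target_counts
        nontarget = Counter()
        for sp, c in prof.counts_by_species.items():
            if sp != target_species:
                nontarget.update(c)
        if not nontarget or target_base in nontarget:
            continue
        sites.append(
            DiagnosticSite(
                position=pos,
                target_species=target_species,
                target_base=target_base,
                nontarget_bases=frozenset(nontarget),
                strict=prof.n_missing == 0,
            )
        )
    return sites


def _site_row(site: DiagnosticSite, aln: SpeciesAlignment) -> dict:
    prof = profile_column(aln, site.position)
    counts = {sp: dict(c) for sp, c in prof.counts_by_species.items()}
    return {
        "position": site.position,
        "target_species": site.target_species,
        "target_base": site.target_base,
        "nontarget_bases": "".join(sorted(site.nontarget_bases)),
        "strict": site.strict,
        "counts": counts,
    }


def write_sites_tsv(sites, aln: SpeciesAlignment, path) -> None:
    """TSV report: position, target_base, nontarget_bases, strict flag,
    per-species counts (JSON-encoded cell)."""
    lines = ["position\ttarget_species\ttarget_base\tnontarget_bases\tstrict\tcounts"]
    for site in sites:
        row = _site_row(site, aln)
        lines.append(
            "\t".join(
                [
                    str(row["position"]),
                    row["target_species"],
                    row["target_base"],
                    row["nontarget_bases"],
                    str(row["strict"]).lower(),
                    json.dumps(row["counts"], sort_keys=True),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def sites_to_json(sites, aln: SpeciesAlignment) -> str:
    return json.dumps([_site_row(s, aln) for s in sites], indent=2, sort_keys=True)
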