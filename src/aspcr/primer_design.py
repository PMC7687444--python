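"""Allele-specific (ARMS) primer construction and pairing.

The allele-specific primer anchors its 3'-terminal base on a diagnostic
allele; a single engineered mismatch is then introduced near the 3' end
(antepenultimate base by default) to further destabilize extension on
near-match templates.  A conventional companion primer is chosen on the
opposite side under product-size / length / Tm / GC constraints.

Coordinates are 1-based inclusive template positions throughout.  A
minus-strand primer's 3'-terminal base pairs with the template base at
``template_start``; a plus-strand primer's with the base at
``template_end``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

from .diagnostics import DiagnosticSite
from .errors import ConfigurationError, GapError, GeometryError
from .seqio import BASES, IUPAC_SETS, reverse_complement, validate_dna
from .thermo import gc_content, tm_nearest_neighbor, tm_wallace

__all__ = [
    "MismatchEdit",
    "Primer",
    "AssayDesign",
    "perfect_match_primer",
    "introduce_destabilizing_mismatch",
    "design_allele_specific_primer",
    "design_companion_primer",
    "design_assay",
    "amplicon_size",
    "default_destabilizing_replacement",
    "validate_design",
    "design_to_dict",
    "design_from_dict",
    "write_design_json",
    "write_design_tsv",
]

_PURINES = frozenset("AG")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

_MIN_PRIMER_LEN = 15


@dataclass(frozen=True)
class MismatchEdit:
    """One engineered base substitution, located from the 3' end (1 = terminal)."""

    offset_from_3prime: int
    original_base: str
    replacement_base: str

    def __post_init__(self) -> None:
        if self.offset_from_3prime < 1:
            raise GeometryError("offset_from_3prime must be >= 1")
        if self.original_base == self.replacement_base:
            raise ConfigurationError("edit replaces a base with itself")


@dataclass(frozen=True)
class Primer:
    """A 5'->3' oligo bound to a template footprint.

    ``strand`` is relative to the alignment's sense strand: a ``plus``
    primer copies the template; a ``minus`` primer is the reverse
    complement of its footprint.
    """

    name: str
    seq: str
    strand: str
    template_start: int
    template_end: int
    edits: tuple = ()
    tm_c: float = 0.0
    gc_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.strand not in ("plus", "minus"):
            raise ConfigurationError(f"strand must be plus/minus, got {self.strand!r}")
        if self.template_end - self.template_start + 1 != len(self.seq):
            raise GeometryError(
                f"primer {self.name!r}: footprint span "
                f"[{self.template_start},{self.template_end}] does not match "
                f"sequence length {len(self.seq)}"
            )
        object.__setattr__(self, "seq", validate_dna(self.seq, context=f"primer {self.name!r}"))

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def three_prime_base(self) -> str:
        return self.seq[-1]

    def base_at_offset(self, offset_from_3prime: int) -> str:
        """Primer base at the given 3'-anchored offset (1 = terminal base)."""
        if not 1 <= offset_from_3prime <= len(self.seq):
            raise GeometryError(f"offset {offset_from_3prime} outside primer")
        return self.seq[len(self.seq) - offset_from_3prime]

    def template_position_of_offset(self, offset_from_3prime: int) -> int:
        """Template position paired with the base at a 3'-anchored offset."""
        if self.strand == "minus":
            return self.template_start + offset_from_3prime - 1
        return self.template_end - offset_from_3prime + 1


def _thermo_fields(seq: str, tm_method: str) -> tuple:
    if tm_method == "wallace":
        return tm_wallace(seq), gc_content(seq)
    if tm_method == "nn":
        return tm_nearest_neighbor(seq), gc_content(seq)
    raise ConfigurationError(f"unknown tm method {tm_method!r}")


def perfect_match_primer(
    template: str,
    anchor_pos: int,
    length: int,
    strand: str,
    name: str = "",
    tm_method: str = "nn",
) -> Primer:
    """Primer whose 3'-terminal base sits on *anchor_pos*, fully matching
    the template footprint.

    For strand ``minus`` the footprint is [anchor_pos, anchor_pos+length-1]
    and the sequence is its reverse complement; for ``plus`` the footprint
    is [anchor_pos-length+1, anchor_pos] copied directly.
    """
    template = validate_dna(template, context="template")
    if length < _MIN_PRIMER_LEN:
        raise GeometryError(f"primer length {length} < minimum {_MIN_PRIMER_LEN}")
    if strand == "minus":
        start, end = anchor_pos, anchor_pos + length - 1
    elif strand == "plus":
        start, end = anchor_pos - length + 1, anchor_pos
    else:
        raise ConfigurationError(f"strand must be plus/minus, got {strand!r}")
    if start < 1 or end > len(template):
        raise GeometryError(
            f"footprint [{start},{end}] outside template [1,{len(template)}]"
        )
    footprint = template[start - 1 : end]
    if "-" in footprint:
        raise GapError(f"gap inside primer footprint [{start},{end}]")
    seq = reverse_complement(footprint) if strand == "minus" else footprint
    tm, gc = _thermo_fields(seq, tm_method)
    return Primer(
        name=name or f"pm_{strand}_{anchor_pos}",
        seq=seq,
        strand=strand,
        template_start=start,
        template_end=end,
        edits=(),
        tm_c=tm,
        gc_frac=gc,
    )


def default_destabilizing_replacement(perfect_base: str, template_base: str) -> str:
    """Base chosen by the shipped destabilization rule.

    Among the two transversions of the perfect-match base, keep the one
    that forms a same-class mispair with the template base (purine-purine
    or pyrimidine-pyrimidine) while differing from the template base
    itself; this is always unique.  For a perfect-match G opposite
    template C the rule yields T.
    """
    if perfect_base not in BASES or template_base not in BASES:
        raise ConfigurationError("destabilization rule needs unambiguous bases")
    if _COMPLEMENT[template_base] != perfect_base:
        raise ConfigurationError(
            f"{perfect_base} does not pair with template base {template_base}"
        )
    transversions = [
        b
        for b in BASES
        if b != perfect_base and (b in _PURINES) != (perfect_base in _PURINES)
    ]
    same_class = [
        b
        for b in transversions
        if (b in _PURINES) == (template_base in _PURINES) and b != template_base
    ]
    assert len(same_class) == 1
    return same_class[0]


def introduce_destabilizing_mismatch(
    p: Primer,
    template: str,
    offset_from_3prime: int,
    replacement: str = None,
    tm_method: str = "nn",
) -> Primer:
    """Return a copy of *p* with one engineered mismatch at the given
    3'-anchored offset.

    Offset 1 is refused (it would destroy the diagnostic anchor).  The
    base at the offset must currently match the template; *replacement*
    defaults to the shipped weakest-mismatch rule.
    """
    template = validate_dna(template, context="template")
    if offset_from_3prime == 1:
        raise GeometryError("refusing to edit the 3'-terminal (anchor) base")
    original = p.base_at_offset(offset_from_3prime)
    tpos = p.template_position_of_offset(offset_from_3prime)
    template_base = template[tpos - 1]
    if template_base not in BASES:
        raise GapError(f"template base at {tpos} is not an unambiguous base")
    expected = _COMPLEMENT[template_base] if p.strand == "minus" else template_base
    if original != expected:
        raise ConfigurationError(
            f"base at offset {offset_from_3prime} ({original}) already mismatches "
            f"the template (expected {expected})"
        )
    pair_base = _COMPLEMENT[template_base] if p.strand == "minus" else template_base
    if replacement is None:
        # the rule reasons about the primer base vs the strand it anneals to
        annealed = template_base if p.strand == "minus" else _COMPLEMENT[template_base]
        replacement = default_destabilizing_replacement(pair_base, annealed)
    replacement = replacement.upper()
    if replacement == original:
        raise ConfigurationError(f"replacement {replacement} equals the original base")
    if replacement not in BASES:
        raise ConfigurationError(f"replacement must be one of {BASES}")
    idx = len(p.seq) - offset_from_3prime
    new_seq = p.seq[:idx] + replacement + p.seq[idx + 1 :]
    tm, gc = _thermo_fields(new_seq, tm_method)
    edit = MismatchEdit(
        offset_from_3prime=offset_from_3prime,
        original_base=original,
        replacement_base=replacement,
    )
    return replace(p, seq=new_seq, edits=p.edits + (edit,), tm_c=tm, gc_frac=gc)


def design_allele_specific_primer(
    template: str,
    site: DiagnosticSite,
    length: int,
    strand: str = "minus",
    mismatch_offset: int = 3,
    replacement: str = None,
    name: str = "",
    tm_method: str = "nn",
) -> Primer:
    """Allele-specific primer: 3' base on the diagnostic allele, then one
    destabilizing edit at *mismatch_offset* (2-5; default antepenultimate).

    Deterministic given its inputs.
    """
    template = validate_dna(template, context="template")
    if not 2 <= mismatch_offset <= 5:
        raise ConfigurationError(f"mismatch offset {mismatch_offset} outside [2, 5]")
    if not 1 <= site.position <= len(template):
        raise GeometryError(f"site position {site.position} outside template")
    if template[site.position - 1] != site.target_base:
        raise ConfigurationError(
            f"template carries {template[site.position - 1]!r} at position "
            f"{site.position}, expected diagnostic allele {site.target_base!r}"
        )
    p = perfect_match_primer(
        template,
        site.position,
        length,
        strand,
        name=name or f"AS_{site.position}_{strand}",
        tm_method=tm_method,
    )
    return introduce_destabilizing_mismatch(
        p, template, mismatch_offset, replacement, tm_method=tm_method
    )


def _three_prime_clamp_ok(candidate: str, other: str, k: int = 5) -> bool:
    """Reject candidates whose 3' *k*-mer can anneal to itself or *other*."""
    tail_rc = reverse_complement(candidate[-k:])
    return tail_rc not in candidate and tail_rc not in other


def design_companion_primer(
    template: str,
    as_primer: Primer,
    product_range: tuple = (100, 1000),
    length_range: tuple = (18, 25),
    tm_window_c: tuple = (55.0, 65.0),
    gc_range: tuple = (0.35, 0.65),
    tm_method: str = "nn",
) -> list:
    """Candidate companion primers on the opposite side of *as_primer*.

    Every window on the opposite strand side satisfying product-size,
    length, Tm-window, GC, and the 3' clamp guard is returned, ranked by
    |Tm - Tm(as_primer)| ascending, ties broken by position ascending.
    An empty list (not an error) means no feasible window.
    """
    template = validate_dna(template, context="template")
    lo_bp, hi_bp = product_range
    candidates = []
    lengths = range(length_range[0], length_range[1] + 1)
    if as_primer.strand == "minus":
        # companion is a plus-strand (forward) primer upstream
        amp_end = as_primer.template_end
        for L in lengths:
            for start in range(1, as_primer.template_start - L + 1):
                product = amp_end - start + 1
                if not lo_bp <= product <= hi_bp:
                    continue
                window = template[start - 1 : start + L - 1]
                cand = _companion_from_window(
                    window, "plus", start, start + L - 1, as_primer,
                    tm_window_c, gc_range, tm_method,
                )
                if cand is not None:
                    candidates.append(cand)
    elif as_primer.strand == "plus":
        amp_start = as_primer.template_start
        for L in lengths:
            for start in range(as_primer.template_end + 1, len(template) - L + 2):
                end = start + L - 1
                product = end - amp_start + 1
                if not lo_bp <= product <= hi_bp:
                    continue
                window = template[start - 1 : end]
                cand = _companion_from_window(
                    reverse_complement(window) if "-" not in window else None,
                    "minus", start, end, as_primer,
                    tm_window_c, gc_range, tm_method,
                )
                if cand is not None:
                    candidates.append(cand)
    candidates.sort(key=lambda p: (abs(p.tm_c - as_primer.tm_c), p.template_start))
    return candidates


def _companion_from_window(seq, strand, start, end, as_primer, tm_window, gc_range, tm_method):
    if seq is None or "-" in seq or any(c not in BASES for c in seq):
        return None
    if not _three_prime_clamp_ok(seq, as_primer.seq):
        return None
    tm, gc = _thermo_fields(seq, tm_method)
    if not tm_window[0] <= tm <= tm_window[1]:
        return None
    if not gc_range[0] <= gc <= gc_range[1]:
        return None
    return Primer(
        name=f"companion_{strand}_{start}",
        seq=seq,
        strand=strand,
        template_start=start,
        template_end=end,
        edits=(),
        tm_c=tm,
        gc_frac=gc,
    )


def amplicon_size(forward: Primer, reverse: Primer) -> int:
    """Product size spanned by a plus-strand forward and minus-strand
    reverse primer: reverse.template_end - forward.template_start + 1."""
    if forward.strand != "plus" or reverse.strand != "minus":
        raise GeometryError("amplicon needs a plus forward and minus reverse primer")
    if forward.template_start > reverse.template_end:
        raise GeometryError("forward primer lies beyond the reverse footprint")
    return reverse.template_end - forward.template_start + 1


@dataclass(frozen=True)
class AssayDesign:
    """A designed forward + allele-specific reverse pair."""

    forward: Primer
    reverse: Primer
    target_species: str
    anchor_site: DiagnosticSite
    product_bp: int

    def __post_init__(self) -> None:
        if self.forward.template_end >= self.reverse.template_start:
            raise GeometryError("primer footprints overlap or are out of order")
        if self.product_bp != amplicon_size(self.forward, self.reverse):
            raise GeometryError("product_bp inconsistent with primer footprints")
        if self.product_bp < len(self.forward.seq) + len(self.reverse.seq):
            raise GeometryError("product shorter than the two primers combined")


def design_assay(
    template: str,
    site: DiagnosticSite,
    as_length: int = 26,
    mismatch_offset: int = 3,
    replacement: str = None,
    product_range: tuple = (100, 1000),
    length_range: tuple = (18, 25),
    tm_window_c: tuple = (55.0, 65.0),
    gc_range: tuple = (0.35, 0.65),
    tm_method: str = "nn",
) -> AssayDesign:
    """Full assay: minus-strand AS primer on *site*, best-ranked companion.

    Raises :class:`GeometryError` when no companion window is feasible.
    """
    as_primer = design_allele_specific_primer(
        template, site, as_length, "minus", mismatch_offset, replacement,
        tm_method=tm_method,
    )
    companions = design_companion_primer(
        template, as_primer, product_range, length_range, tm_window_c,
        gc_range, tm_method,
    )
    if not companions:
        raise GeometryError("no feasible companion primer window")
    forward = companions[0]
    return AssayDesign(
        forward=forward,
        reverse=as_primer,
        target_species=site.target_species,
        anchor_site=site,
        product_bp=amplicon_size(forward, as_primer),
    )


def validate_design(design: AssayDesign, aln) -> dict:
    """Re-check every design invariant against the alignment.

    Returns ``{"passed": bool, "checks": [{"name", "passed", "detail"}]}``.
    """
    checks = []

    def check(name, ok, detail=""):
        checks.append({"name": name, "passed": bool(ok), "detail": detail})

    f, r, site = design.forward, design.reverse, design.anchor_site
    check("strands", f.strand == "plus" and r.strand == "minus")
    check("ordering", f.template_end < r.template_start,
          f"forward ends {f.template_end}, reverse starts {r.template_start}")
    expected_bp = r.template_end - f.template_start + 1
    check("geometry", design.product_bp == expected_bp,
          f"product_bp={design.product_bp}, footprint span={expected_bp}")
    check("product_contains_primers",
          design.product_bp >= len(f.seq) + len(r.seq))

    targets = aln.records_for(design.target_species)
    check("target_present", bool(targets),
          f"species {design.target_species!r} in alignment")
    if targets:
        template = targets[0].seq
        allele = template[site.position - 1]
        check("template_allele", allele == site.target_base,
              f"template carries {allele} at {site.position}")
        check("anchor_position", r.template_start == site.position,
              "reverse primer 3' end sits on the diagnostic site")
        check("anchor_base", r.three_prime_base == _COMPLEMENT.get(site.target_base),
              f"3' base {r.three_prime_base} vs allele {site.target_base}")
        check("one_edit", len(r.edits) == 1, f"{len(r.edits)} edits")
        if len(r.edits) == 1:
            edit = r.edits[0]
            check("edit_not_at_anchor", edit.offset_from_3prime != 1)
            check("edit_applied",
                  r.base_at_offset(edit.offset_from_3prime) == edit.replacement_base)
            tpos = r.template_position_of_offset(edit.offset_from_3prime)
            perfect = _COMPLEMENT.get(template[tpos - 1])
            check("edit_original_matches_template", edit.original_base == perfect,
                  f"perfect-match base at offset {edit.offset_from_3prime} is {perfect}")
            check("edit_mismatches_template",
                  r.base_at_offset(edit.offset_from_3prime) != perfect)
    check("forward_unedited", len(f.edits) == 0)
    return {"passed": all(c["passed"] for c in checks), "checks": checks}


# --- serialization -------------------------------------------------------

def _primer_to_dict(p: Primer) -> dict:
    return {
        "name": p.name,
        "seq": p.seq,
        "strand": p.strand,
        "template_start": p.template_start,
        "template_end": p.template_end,
        "edits": [
            {
                "offset_from_3prime": e.offset_from_3prime,
                "original_base": e.original_base,
                "replacement_base": e.replacement_base,
            }
            for e in p.edits
        ],
        "tm_nn_c": round(tm_nearest_neighbor(p.seq), 2) if len(p.seq) >= 8 else None,
        "tm_wallace_c": tm_wallace(p.seq),
        "gc_frac": round(p.gc_frac, 4),
    }


def _primer_from_dict(d: dict) -> Primer:
    edits = tuple(
        MismatchEdit(e["offset_from_3prime"], e["original_base"], e["replacement_base"])
        for e in d.get("edits", [])
    )
    return Primer(
        name=d["name"],
        seq=d["seq"],
        strand=d["strand"],
        template_start=d["template_start"],
        template_end=d["template_end"],
        edits=edits,
        tm_c=d.get("tm_nn_c") or d["tm_wallace_c"],
        gc_frac=d["gc_frac"],
    )


def design_to_dict(design: AssayDesign) -> dict:
    return {
        "target_species": design.target_species,
        "anchor_site": {
            "position": design.anchor_site.position,
            "target_species": design.anchor_site.target_species,
            "target_base": design.anchor_site.target_base,
            "nontarget_bases": "".join(sorted(design.anchor_site.nontarget_bases)),
            "strict": design.anchor_site.strict,
        },
        "forward": _primer_to_dict(design.forward),
        "reverse": _primer_to_dict(design.reverse),
        "product_bp": design.product_bp,
    }


def design_from_dict(d: dict) -> AssayDesign:
    sd = d["anchor_site"]
    site = DiagnosticSite(
        position=sd["position"],
        target_species=sd["target_species"],
        target_base=sd["target_base"],
        nontarget_bases=frozenset(sd["nontarget_bases"]),
        strict=sd["strict"],
    )
    return AssayDesign(
        forward=_primer_from_dict(d["forward"]),
        reverse=_primer_from_dict(d["reverse"]),
        target_species=d["target_species"],
        anchor_site=site,
        product_bp=d["product_bp"],
    )


def write_design_json(design: AssayDesign, path) -> None:
    Path(path).write_text(json.dumps(design_to_dict(design), indent=2) + "\n",
                          encoding="utf-8")


def write_design_tsv(design: AssayDesign, path) -> None:
    header = ("role\tname\tseq_5to3\tstrand\ttemplate_start\ttemplate_end"
              "\tedits\ttm_nn_c\ttm_wallace_c\tgc_frac\tproduct_bp")
    rows = [header]
    for role, p in (("forward", design.forward), ("reverse", design.reverse)):
        d = _primer_to_dict(p)
        edits = ";".join(
            f"{e['original_base']}>{e['replacement_base']}@-{e['offset_from_3prime']}"
            for e in d["edits"]
        )
        rows.append("\t".join([
            role, d["name"], d["seq"], d["strand"],
            str(d["template_start"]), str(d["template_end"]),
            edits or ".", str(d["tm_nn_c"]), str(d["tm_wallace_c"]),
            str(d["gc_frac"]), str(design.product_bp),
        ]))
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")
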