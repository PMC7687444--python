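"""In silico PCR: primer binding-site scanning and amplicon prediction.

Extension blocking at the 3' end is the mechanism that makes an
allele-specific assay specific, so the binding model counts mismatches
both in total and within the last five 3' bases, and can refuse extension
outright on a 3'-terminal mismatch.  Amplification is binary; no
efficiency modelling.

Templates are gap-stripped before scanning, so binding-site coordinates
are 1-based positions on the ungapped template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .primer_design import AssayDesign, Primer
from .seqio import IUPAC_SETS, SequenceRecord, SpeciesAlignment, reverse_complement, ungap, validate_dna

__all__ = [
    "BindingModel",
    "BindingSite",
    "AmpliconPrediction",
    "SpecificityMatrix",
    "find_binding_sites",
    "predict_amplicons",
    "specificity_screen",
    "write_matrix_tsv",
    "virtual_gel",
]

# bitmask encoding: a template character's set of compatible primer bases.
# N deliberately matches nothing (conservative); gaps are stripped upstream.
_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
_CODE = np.zeros(256, dtype=np.uint8)
for _ch, _set in IUPAC_SETS.items():
    _CODE[ord(_ch)] = 0 if _ch in "N-" else sum(_BIT[b] for b in _set)


@dataclass(frozen=True)
class BindingModel:
    """Thresholds deciding whether an imperfect primer site still extends."""

    max_total_mismatches: int = 3
    max_mismatches_last5: int = 1
    block_on_3prime_mismatch: bool = True
    product_min_bp: int = 50
    product_max_bp: int = 2000

    def __post_init__(self) -> None:
        if self.max_mismatches_last5 > self.max_total_mismatches:
            raise ConfigurationError(
                "max_mismatches_last5 cannot exceed max_total_mismatches"
            )
        if self.product_min_bp > self.product_max_bp:
            raise ConfigurationError("product_min_bp > product_max_bp")


@dataclass(frozen=True)
class BindingSite:
    """One primer footprint on a template, with 3'-anchored mismatch offsets."""

    template_id: str
    footprint: tuple  # (start, end), 1-based inclusive on the ungapped template
    strand: str
    mismatch_offsets: tuple
    extendable: bool


@dataclass(frozen=True)
class AmpliconPrediction:
    template_id: str
    product_bp: int
    forward_footprint: tuple
    reverse_footprint: tuple


@dataclass
class SpecificityMatrix:
    """Per-template amplification predictions for one assay."""

    target_species: str
    rows: list  # dicts: template_id, species, amplified, product_bp, n_products

    @property
    def specific(self) -> bool:
        """True iff all target templates amplify and no non-target does."""
        target = [r for r in self.rows if r["species"] == self.target_species]
        other = [r for r in self.rows if r["species"] != self.target_species]
        return (
            bool(target)
            and all(r["amplified"] for r in target)
            and not any(r["amplified"] for r in other)
        )


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _exact_bits(seq: str) -> np.ndarray:
    """Primer bases as single bits (primers must be unambiguous)."""
    arr = np.array([_BIT.get(c, 0) for c in seq], dtype=np.uint8)
    if (arr == 0).any():
        raise ConfigurationError(f"primer sequence {seq!r} contains non-ACGT characters")
    return arr


def _scan(primer_bits: np.ndarray, t_codes: np.ndarray, offsets_3prime) -> list:
    """(start0, sorted mismatch offsets) for every window; vectorized."""
    L = len(primer_bits)
    if L > len(t_codes):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(t_codes, L)
    mism = (windows & primer_bits[None, :]) == 0  # (n_windows, L)
    out = []
    for start0 in range(windows.shape[0]):
        row = np.flatnonzero(mism[start0])
        out.append((start0, tuple(sorted(offsets_3prime[i] for i in row))))
    return out


def find_binding_sites(
    primer: Primer, template: SequenceRecord, model: BindingModel = BindingModel()
) -> list:
    """Exhaustive both-strand scan for footprints within the mismatch budget.

    Sites are ordered by position, plus strand before minus at a tie.
    ``extendable`` encodes the 3' rules: a blocked 3'-terminal mismatch or
    more than ``max_mismatches_last5`` mismatches in the last five bases
    prevents extension.
    """
    t = ungap(validate_dna(template.seq, context=f"template {template.id!r}"))
    if not t:
        return []
    t_codes = _encode(t)
    L = len(primer.seq)
    sites = []

    # plus: primer read as-is against the sense template; 3' end rightmost.
    plus_offsets = [L - i for i in range(L)]
    for start0, offs in _scan(_exact_bits(primer.seq), t_codes, plus_offsets):
        sites.append(_make_site(template.id, start0, L, "plus", offs, model))
    # minus: primer binds the sense strand; its revcomp must match the
    # template, and the 3' end is leftmost (offset = template index + 1).
    minus_offsets = [i + 1 for i in range(L)]
    for start0, offs in _scan(_exact_bits(reverse_complement(primer.seq)), t_codes, minus_offsets):
        sites.append(_make_site(template.id, start0, L, "minus", offs, model))

    sites = [s for s in sites if s is not None]
    sites.sort(key=lambda s: (s.footprint[0], s.strand != "plus"))
    return sites


def _make_site(template_id, start0, L, strand, offsets, model):
    if len(offsets) > model.max_total_mismatches:
        return None
    last5 = sum(1 for o in offsets if o <= 5)
    extendable = last5 <= model.max_mismatches_last5
    if model.block_on_3prime_mismatch and 1 in offsets:
        extendable = False
    return BindingSite(
        template_id=template_id,
        footprint=(start0 + 1, start0 + L),
        strand=strand,
        mismatch_offsets=tuple(offsets),
        extendable=extendable,
    )


def predict_amplicons(
    forward: Primer,
    reverse: Primer,
    template: SequenceRecord,
    model: BindingModel = BindingModel(),
) -> list:
    """All products from an extendable plus-strand site of one primer and
    an extendable minus-strand site of the other, converging, with size
    inside the model's product window."""
    sites_f = find_binding_sites(forward, template, model)
    sites_r = find_binding_sites(reverse, template, model)
    preds = set()
    for left_sites, right_sites in ((sites_f, sites_r), (sites_r, sites_f)):
        for sp in left_sites:
            if sp.strand != "plus" or not sp.extendable:
                continue
            for sm in right_sites:
                if sm.strand != "minus" or not sm.extendable:
                    continue
                if sp.footprint[0] > sm.footprint[1]:
                    continue
                size = sm.footprint[1] - sp.footprint[0] + 1
                if model.product_min_bp <= size <= model.product_max_bp:
                    preds.add((template.id, size, sp.footprint, sm.footprint))
    return [
        AmpliconPrediction(*p)
        for p in sorted(preds, key=lambda x: (x[1], x[2], x[3]))
    ]


def specificity_screen(
    design: AssayDesign,
    templates: SpeciesAlignment,
    model: BindingModel = BindingModel(),
) -> SpecificityMatrix:
    """Run :func:`predict_amplicons` over every (gap-stripped) template."""
    if not len(templates):
        raise ConfigurationError("no templates to screen")
    rows = []
    for rec in templates:
        preds = predict_amplicons(design.forward, design.reverse, rec, model)
        rows.append(
            {
                "template_id": rec.id,
                "species": rec.species,
                "amplified": bool(preds),
                "product_bp": preds[0].product_bp if preds else None,
                "n_products": len(preds),
            }
        )
    return SpecificityMatrix(target_species=design.target_species, rows=rows)


def write_matrix_tsv(matrix: SpecificityMatrix, path) -> None:
    from pathlib import Path

    lines = ["template_id\tspecies\tamplified\tproduct_bp\tn_products"]
    for r in matrix.rows:
        lines.append(
            "\t".join(
                [
                    r["template_id"],
                    r["species"],
                    str(r["amplified"]).lower(),
                    "." if r["product_bp"] is None else str(r["product_bp"]),
                    str(r["n_products"]),
                ]
            )
        )
    lines.append(f"# specific\t{str(matrix.specific).lower()}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def virtual_gel(matrix: SpecificityMatrix, width: int = 40) -> str:
    """ASCII gel: one lane per template, a band at the predicted size."""
    sizes = [r["product_bp"] for r in matrix.rows if r["product_bp"]]
    hi = max(sizes) if sizes else 1000
    lo = min(sizes + [100]) if sizes else 100
    span = max(hi * 1.2 - lo / 1.2, 1)
    name_w = max(len(r["template_id"]) for r in matrix.rows) + 2
    lines = [f"virtual gel (band position ~ product size, {lo}-{hi} bp window)"]
    for r in matrix.rows:
        lane = [" "] * width
        if r["product_bp"]:
            frac = (r["product_bp"] - lo / 1.2) / span
            lane[min(width - 1, max(0, int(frac * width)))] = "#"
        marker = "*" if r["species"] == matrix.target_species else " "
        label = f"{r['template_id']} ({r['species']})"
        lines.append(f"{marker}{label.ljust(name_w + 20)}|{''.join(lane)}|")
    lines.append(f"specific: {matrix.specific}")
    return "\n".join(lines)
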