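"""Melting temperature and base-composition estimates for primers.

Two Tm estimators are provided: the Wallace rule (closed-form, exact for
tests) and nearest-neighbor thermodynamics with the unified duplex
parameter set (SantaLucia 1998), salt-corrected.  The NN table is shipped
here as data so callers and tests can sum it independently.
"""

from __future__ import annotations

import math

from .errors import AlphabetError
from .seqio import BASES, validate_dna

__all__ = [
    "NN_PARAMS",
    "NN_INITIATION",
    "gc_content",
    "tm_wallace",
    "tm_nearest_neighbor",
    "nn_sums",
]

# Unified nearest-neighbor parameters, 5'->3' top-strand dinucleotides:
# dinucleotide -> (dH kcal/mol, dS cal/(mol*K)).  Only ten stacks are
# independent; the reverse-complement stack shares its parameters.
_NN_CORE = {
    "AA": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7),
    "GT": (-8.4, -22.4),
    "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}

_RC = str.maketrans("ACGT", "TGCA")


def _revcomp2(dinuc: str) -> str:
    return dinuc.translate(_RC)[::-1]


#: Full 16-entry stack table (kcal/mol, cal/(mol*K)).
NN_PARAMS = {
    d: _NN_CORE.get(d, _NN_CORE.get(_revcomp2(d)))
    for d in (a + b for a in "ACGT" for b in "ACGT")
}

#: Duplex initiation terms per terminal base pair: (dH, dS).
NN_INITIATION = {
    "G": (0.1, -2.8), "C": (0.1, -2.8),
    "A": (2.3, 4.1), "T": (2.3, 4.1),
}

_R_GAS = 1.987  # cal/(mol*K)


def _require_unambiguous(seq: str, min_len: int = 1) -> str:
    s = validate_dna(seq)
    if len(s) < min_len:
        raise AlphabetError(f"sequence shorter than {min_len} nt")
    bad = set(s) - set(BASES)
    if bad:
        raise AlphabetError(f"ambiguous characters {sorted(bad)} not allowed here")
    return s


def gc_content(seq: str) -> float:
    """(G+C) / length over unambiguous bases only.

    Ambiguity codes and gaps are excluded from numerator and denominator.
    """
    s = validate_dna(seq)
    counted = [c for c in s if c in BASES]
    if not counted:
        raise AlphabetError("no unambiguous bases in sequence")
    return sum(c in "GC" for c in counted) / len(counted)


def tm_wallace(seq: str) -> float:
    """Wallace rule: 2*(A+T) + 4*(G+C), in degrees C."""
    s = _require_unambiguous(seq)
    at = sum(c in "AT" for c in s)
    gc = len(s) - at
    return 2.0 * at + 4.0 * gc


def nn_sums(seq: str) -> tuple:
    """(dH kcal/mol, dS cal/(mol*K)) duplex sums, including initiation."""
    s = _require_unambiguous(seq, min_len=2)
    dh, ds = 0.0, 0.0
    for end in (s[0], s[-1]):
        h, v = NN_INITIATION[end]
        dh += h
        ds += v
    for i in range(len(s) - 1):
        h, v = NN_PARAMS[s[i : i + 2]]
        dh += h
        ds += v
    return dh, ds


def tm_nearest_neighbor(seq: str, na_mM: float = 50.0, primer_uM: float = 0.5) -> float:
    """Nearest-neighbor Tm (degrees C) at the given Na+ and primer strand
    concentrations, for a non-self-complementary primer in excess over
    template (Ct/4 convention), with the 16.6*log10[Na+] salt term."""
    s = _require_unambiguous(seq, min_len=8)
    dh, ds = nn_sums(s)
    ct = primer_uM * 1e-6
    tm_k = dh * 1000.0 / (ds + _R_GAS * math.log(ct / 4.0))
    return tm_k - 273.15 + 16.6 * math.log10(na_mM / 1000.0)
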