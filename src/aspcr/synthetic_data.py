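"""Species-structured synthetic alignments with planted diagnostic sites.

The generator draws a random root sequence, evolves one consensus per
species, copies each consensus with per-copy intraspecific noise (planted
positions protected), and finally writes the planted alleles — target
species receive the target base, everyone else the background base — so
the ground truth is exact by construction.

By default the generator also repairs *accidental* diagnostic columns:
any non-planted column where a species' consensus base is unique across
species is reassigned to the column's majority base.  With zero
intraspecific noise the planted sites are then the only diagnostic
columns, which is what the planted-recovery properties assume.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .seqio import BASES, SequenceRecord, SpeciesAlignment

__all__ = [
    "PlantedSite",
    "SyntheticSpec",
    "GroundTruth",
    "mutate_sequence",
    "generate_alignment",
    "paper_shaped_spec",
    "write_ground_truth_json",
]

#: Species labels for the default eight-taxon fixture.
DEFAULT_SPECIES = (
    "Cervus nippon",
    "Cervus elaphus",
    "Axis porcinus",
    "Dama dama",
    "Elaphurus davidianus",
    "Elaphodus cephalophus",
    "Rusa unicolor",
    "Rangifer tarandus",
)

_BASE_ARR = np.frombuffer("ACGT".encode(), dtype=np.uint8)


@dataclass(frozen=True)
class PlantedSite:
    position: int  # 1-based
    target_species: str
    target_base: str
    background_base: str

    def __post_init__(self) -> None:
        if self.target_base == self.background_base:
            raise ConfigurationError(
                f"planted site {self.position}: background equals target base"
            )
        if self.target_base not in BASES or self.background_base not in BASES:
            raise ConfigurationError("planted bases must be unambiguous A/C/G/T")


@dataclass
class SyntheticSpec:
    n_species: int
    seqs_per_species: object  # int or per-species sequence of ints
    length: int
    planted_sites: tuple = ()
    interspecies_divergence: float = 0.05
    intraspecific_noise: float = 0.0
    seed: int = 0
    species_names: tuple = None
    repair_accidental_sites: bool = True

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ConfigurationError("need at least 2 species")
        if isinstance(self.seqs_per_species, int):
            self.seqs_per_species = (self.seqs_per_species,) * self.n_species
        else:
            self.seqs_per_species = tuple(self.seqs_per_species)
        if len(self.seqs_per_species) != self.n_species:
            raise ConfigurationError("per-species counts do not match n_species")
        if self.species_names is None:
            if self.n_species <= len(DEFAULT_SPECIES):
                self.species_names = DEFAULT_SPECIES[: self.n_species]
            else:
                self.species_names = tuple(f"Species{i+1}" for i in range(self.n_species))
        self.species_names = tuple(self.species_names)
        if len(set(self.species_names)) != self.n_species:
            raise ConfigurationError("species names must be unique")
        for rate, what in (
            (self.interspecies_divergence, "interspecies_divergence"),
            (self.intraspecific_noise, "intraspecific_noise"),
        ):
            if not 0.0 <= rate < 0.75:
                raise ConfigurationError(f"{what} {rate} outside [0, 0.75)")
        self.planted_sites = tuple(
            s if isinstance(s, PlantedSite) else PlantedSite(*s)
            for s in self.planted_sites
        )
        positions = [s.position for s in self.planted_sites]
        if len(set(positions)) != len(positions):
            raise ConfigurationError("planted positions must be unique")
        for s in self.planted_sites:
            if not 1 <= s.position <= self.length:
                raise ConfigurationError(f"planted position {s.position} outside [1, {self.length}]")
            if s.target_species not in self.species_names:
                raise ConfigurationError(f"unknown planted target species {s.target_species!r}")


@dataclass
class GroundTruth:
    planted_sites: tuple
    mutation_log: dict  # record_id -> list of (position, from_base, to_base)


def _as_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def mutate_sequence(seq: str, rate: float, seed, protected=frozenset()) -> str:
    """Independently substitute each unprotected position with probability
    *rate*; the new base is uniform over the other three.  *seed* may be
    an int or a ``numpy.random.Generator``."""
    if not 0.0 <= rate <= 1.0:
        raise ConfigurationError(f"rate {rate} outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    arr = _as_array(seq)
    hit = rng.random(arr.size) < rate
    for pos in protected:
        hit[pos - 1] = False
    idx = np.flatnonzero(hit)
    for i in idx:
        choices = _BASE_ARR[_BASE_ARR != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _repair_unique_columns(consensus: dict, spec: SyntheticSpec) -> None:
    """Remove accidental single-species bases at non-planted columns."""
    planted = {s.position for s in spec.planted_sites}
    names = list(consensus)
    for pos in range(1, spec.length + 1):
        if pos in planted:
            continue
        while True:
            bases = {sp: consensus[sp][pos - 1] for sp in names}
            counts = Counter(bases.values())
            unique_sp = [sp for sp, b in bases.items() if counts[b] == 1]
            if not unique_sp or len(names) < 2:
                break
            sp = unique_sp[0]
            others = Counter(b for s, b in bases.items() if s != sp)
            consensus[sp][pos - 1] = others.most_common(1)[0][0]


def generate_alignment(spec: SyntheticSpec) -> tuple:
    """Build a (:class:`SpeciesAlignment`, :class:`GroundTruth`) pair.

    Reproducible per ``spec.seed``; every planted site is realized exactly
    as specified because planting happens after noise.
    """
    rng = np.random.default_rng(spec.seed)
    root = rng.choice(_BASE_ARR, size=spec.length)
    consensus = {}
    for name in spec.species_names:
        arr = _as_array(mutate_sequence(root.tobytes().decode("ascii"),
                                        spec.interspecies_divergence, rng))
        consensus[name] = arr
    if spec.repair_accidental_sites:
        _repair_unique_columns(consensus, spec)

    planted_positions = frozenset(s.position for s in spec.planted_sites)
    records = []
    mutation_log = {}
    for name, count in zip(spec.species_names, spec.seqs_per_species):
        base_seq = consensus[name].tobytes().decode("ascii")
        slug = name.replace(" ", "_")
        for k in range(count):
            seq = mutate_sequence(base_seq, spec.intraspecific_noise, rng,
                                  protected=planted_positions)
            arr = _as_array(seq)
            for site in spec.planted_sites:
                allele = (site.target_base if name == site.target_species
                          else site.background_base)
                arr[site.position - 1] = ord(allele)
            seq = arr.tobytes().decode("ascii")
            rec_id = f"{slug}_{k + 1}"
            mutation_log[rec_id] = [
                (pos + 1, base_seq[pos], seq[pos])
                for pos in range(spec.length)
                if seq[pos] != base_seq[pos]
            ]
            records.append(SequenceRecord(id=rec_id, species=name, seq=seq))
    aln = SpeciesAlignment(records=records)
    truth = GroundTruth(planted_sites=spec.planted_sites, mutation_log=mutation_log)
    return aln, truth


def paper_shaped_spec(seed: int = 0, intraspecific_noise: float = 0.0) -> SyntheticSpec:
    """The default fixture: 8 species, 19+5 records, 574 bp, two sites
    planted at positions 480 and 505 (C in the first species vs T
    elsewhere).  A structural stand-in, not real barcode data."""
    return SyntheticSpec(
        n_species=8,
        seqs_per_species=(4, 3, 2, 2, 3, 2, 3, 5),
        length=574,
        planted_sites=(
            PlantedSite(480, DEFAULT_SPECIES[0], "C", "T"),
            PlantedSite(505, DEFAULT_SPECIES[0], "C", "T"),
        ),
        interspecies_divergence=0.05,
        intraspecific_noise=intraspecific_noise,
        seed=seed,
    )


def write_ground_truth_json(truth: GroundTruth, path) -> None:
    payload = {
        "planted_sites": [
            {
                "position": s.position,
                "target_species": s.target_species,
                "target_base": s.target_base,
                "background_base": s.background_base,
            }
            for s in truth.planted_sites
        ],
        "mutation_log": {
            rid: [{"position": p, "from": a, "to": b} for p, a, b in muts]
            for rid, muts in truth.mutation_log.items()
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")
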