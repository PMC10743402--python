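"""Otoferlin annotation layers and the nine ConStruct predictor variables.

Otoferlin (the 1979-residue long isoform of the OTOF gene product) is
annotated with four interval layers in protein coordinates — C2 domains,
intrinsically disordered regions ("regions"), composition-biased
(low-complexity) stretches, and a coiled coil — plus a 46-exon map.  A
single amino-acid variant (SAV) is encoded as nine predictors:

=================  =========================================================
position           residue index of the substitution (1-based)
exon_number        exon containing the variant, 1-46
blosum_score       BLOSUM80 score of the ref->alt substitution
domain_code        C2 domain number 1-7, or 0 outside all domains
region_code        disordered-region number 1-4, or 0 outside
comp_bias_flag     1 if inside a composition-biased interval
coiled_coil_flag   1 if inside the coiled coil
phylop100          phyloP conservation, 100-vertebrate alignment
phylop30           phyloP conservation, 30-primate alignment
=================  =========================================================

All intervals are 1-based and closed on both ends.  Conservation values
travel with the variant record (they are per-nucleotide quantities that
cannot be derived from protein coordinates); encoding fails loudly when
they are absent.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

from Bio.Align import substitution_matrices

__all__ = [
    "ProteinInterval",
    "AnnotationMap",
    "SubstitutionMatrix",
    "FeatureVector",
    "FEATURE_NAMES",
    "AMINO_ACIDS",
    "load_annotation_config",
    "default_otoferlin_annotation",
    "load_blosum80",
    "domain_of",
    "region_of",
    "comp_bias_flag",
    "coiled_coil_flag",
    "exon_of",
    "blosum_score",
    "encode_variant",
]

#: The 20 standard amino acids, one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Canonical predictor ordering used for model features.
FEATURE_NAMES = (
    "position",
    "exon_number",
    "blosum_score",
    "domain_code",
    "region_code",
    "comp_bias_flag",
    "coiled_coil_flag",
    "phylop100",
    "phylop30",
)

OTOFERLIN_LENGTH = 1979


@dataclass(frozen=True)
class ProteinInterval:
    """A coded interval of protein residues, 1-based and closed."""

    start: int
    end: int
    code: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}] for {self.name!r}"
            )

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


def _check_layer(name: str, intervals: Sequence[ProteinInterval], length: int) -> None:
    ordered = sorted(intervals, key=lambda iv: iv.start)
    for iv in ordered:
        if iv.end > length:
            raise ValueError(f"{name} interval {iv} exceeds protein length {length}")
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError(f"{name} intervals overlap: {a} and {b}")


@dataclass(frozen=True)
class AnnotationMap:
    """Interval layers over the otoferlin sequence.

    ``exon_map`` must partition ``[1, protein_length]`` exactly; domain and
    region codes must be unique; every layer must be internally
    non-overlapping.  Validation happens at construction so downstream
    lookups can assume a consistent map.
    """

    protein_length: int = OTOFERLIN_LENGTH
    domains: tuple[ProteinInterval, ...] = ()
    regions: tuple[ProteinInterval, ...] = ()
    comp_bias: tuple[ProteinInterval, ...] = ()
    coiled_coil: tuple[ProteinInterval, ...] = ()
    exon_map: tuple[ProteinInterval, ...] = ()

    def __post_init__(self) -> None:
        for name in ("domains", "regions", "comp_bias", "coiled_coil", "exon_map"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
            _check_layer(name, getattr(self, name), self.protein_length)
        for name in ("domains", "regions"):
            codes = [iv.code for iv in getattr(self, name)]
            if len(set(codes)) != len(codes):
                raise ValueError(f"duplicate codes in {name}: {codes}")
        if self.exon_map:
            exons = sorted(self.exon_map, key=lambda iv: iv.start)
            if exons[0].start != 1 or exons[-1].end != self.protein_length:
                raise ValueError("exon_map must cover [1, protein_length]")
            for a, b in zip(exons, exons[1:]):
                if b.start != a.end + 1:
                    raise ValueError(f"exon_map gap between {a} and {b}")

    def _check_position(self, position: int) -> None:
        if not (1 <= position <= self.protein_length):
            raise ValueError(
                f"position {position} outside [1, {self.protein_length}]"
            )


def _load_layer(raw: Iterable[dict]) -> tuple[ProteinInterval, ...]:
    return tuple(
        ProteinInterval(d["start"], d["end"], d.get("code", 1), d.get("name", ""))
        for d in raw
    )


def load_annotation_config(path) -> AnnotationMap:
    """Load an :class:`AnnotationMap` from a JSON annotation config.

    The config carries layers ``domains``, ``regions``, ``comp_bias``,
    ``coiled_coil`` and ``exons``, each a list of
    ``{start, end, code, name}`` objects, plus ``protein_length``.
    """
    with open(path) as fh:
        cfg = json.load(fh)
    return AnnotationMap(
        protein_length=cfg.get("protein_length", OTOFERLIN_LENGTH),
        domains=_load_layer(cfg.get("domains", [])),
        regions=_load_layer(cfg.get("regions", [])),
        comp_bias=_load_layer(cfg.get("comp_bias", [])),
        coiled_coil=_load_layer(cfg.get("coiled_coil", [])),
        exon_map=_load_layer(cfg.get("exons", [])),
    )


def default_otoferlin_annotation() -> AnnotationMap:
    """The packaged otoferlin annotation.

    Domains are the seven published C2-domain intervals (codes 1-7 in
    N-to-C order); regions are the four disordered-region intervals
    (codes 1-4).  The packaged comp_bias and coiled_coil layers are empty
    (their curated coordinates are not bundled), and the exon map is a
    synthetic near-uniform 46-interval partition of 1-1979 — both are
    replaceable via :func:`load_annotation_config`.
    """
    ref = resources.files("construct_otof.data") / "otoferlin_annotation.json"
    with resources.as_file(ref) as path:
        return load_annotation_config(path)


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric integer substitution scores over the 20 standard residues."""

    scores: dict = field(repr=False)
    name: str = "BLOSUM80"

    def __post_init__(self) -> None:
        for x in AMINO_ACIDS:
            for y in AMINO_ACIDS:
                if (x, y) not in self.scores:
                    raise ValueError(f"missing score for pair ({x}, {y})")
                if self.scores[(x, y)] != self.scores[(y, x)]:
                    raise ValueError(f"asymmetric scores for ({x}, {y})")

    @classmethod
    def from_ncbi_file(cls, path, name: str | None = None) -> "SubstitutionMatrix":
        """Read an NCBI-format matrix file ('#' comments, residue header row)."""
        arr = substitution_matrices.read(str(path))
        scores = {
            (x, y): int(arr[x, y]) for x in AMINO_ACIDS for y in AMINO_ACIDS
        }
        return cls(scores=scores, name=name or "substitution matrix")


def load_blosum80() -> SubstitutionMatrix:
    """The packaged NCBI BLOSUM80 matrix (1/3-bit scale)."""
    ref = resources.files("construct_otof.data") / "blosum80.txt"
    with resources.as_file(ref) as path:
        return SubstitutionMatrix.from_ncbi_file(path, name="BLOSUM80")


@dataclass(frozen=True)
class FeatureVector:
    """The nine ConStruct predictors for one variant, in canonical order."""

    position: int
    exon_number: int
    blosum_score: int
    domain_code: int
    region_code: int
    comp_bias_flag: int
    coiled_coil_flag: int
    phylop100: float
    phylop30: float

    def as_tuple(self) -> tuple:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


def _code_of(position: int, layer: Sequence[ProteinInterval]) -> int:
    for iv in layer:
        if position in iv:
            return iv.code
    return 0


def domain_of(position: int, amap: AnnotationMap) -> int:
    """C2-domain code (1-7) containing ``position``, else 0."""
    amap._check_position(position)
    return _code_of(position, amap.domains)


def region_of(position: int, amap: AnnotationMap) -> int:
    """Disordered-region code (1-4) containing ``position``, else 0."""
    amap._check_position(position)
    return _code_of(position, amap.regions)


def comp_bias_flag(position: int, amap: AnnotationMap) -> int:
    """1 iff ``position`` lies in a composition-biased interval."""
    amap._check_position(position)
    return int(_code_of(position, amap.comp_bias) != 0)


def coiled_coil_flag(position: int, amap: AnnotationMap) -> int:
    """1 iff ``position`` lies in the coiled coil."""
    amap._check_position(position)
    return int(_code_of(position, amap.coiled_coil) != 0)


def exon_of(position: int, amap: AnnotationMap) -> int:
    """Exon code of the unique exon-map interval containing ``position``."""
    amap._check_position(position)
    exons = sorted(amap.exon_map, key=lambda iv: iv.start)
    if not exons:
        raise ValueError("annotation map has no exon layer")
    starts = [iv.start for iv in exons]
    idx = bisect_right(starts, position) - 1
    iv = exons[idx]
    if position not in iv:  # partition is validated, but guard anyway
        raise ValueError(f"position {position} not covered by exon map")
    return iv.code


def blosum_score(ref: str, alt: str, matrix: SubstitutionMatrix) -> int:
    """Substitution-matrix score for replacing ``ref`` with ``alt``."""
    try:
        return matrix.scores[(ref, alt)]
    except KeyError:
        raise KeyError(f"unknown residue pair ({ref!r}, {alt!r})") from None


class MissingConservationError(ValueError):
    """A variant record lacks the phyloP value(s) needed for encoding."""


def encode_variant(record, amap: AnnotationMap, matrix: SubstitutionMatrix) -> FeatureVector:
    """Compute the nine-predictor :class:`FeatureVector` for one SAV.

    The exon number is taken from the record when present, otherwise
    derived from the exon map.  phyloP values must be present on the
    record — they are never imputed.
    """
    if record.phylop100 is None or record.phylop30 is None:
        raise MissingConservationError(
            f"variant {record.ref_aa}{record.position}{record.alt_aa} lacks "
            "phyloP conservation values"
        )
    exon = record.exon_number if record.exon_number is not None else exon_of(
        record.position, amap
    )
    return FeatureVector(
        position=record.position,
        exon_number=int(exon),
        blosum_score=blosum_score(record.ref_aa, record.alt_aa, matrix),
        domain_code=domain_of(record.position, amap),
        region_code=region_of(record.position, amap),
        comp_bias_flag=comp_bias_flag(record.position, amap),
        coiled_coil_flag=coiled_coil_flag(record.position, amap),
        phylop100=float(record.phylop100),
        phylop30=float(record.phylop30),
    )
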