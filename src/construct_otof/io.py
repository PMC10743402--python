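"""Tabular I/O for variant tables and per-method score tables.

Variant tables are tab-separated with a header; a variant is given either
as a notation string (``Leu1504Pro``) in a ``variant`` column or as
explicit ``position`` / ``ref_aa`` / ``alt_aa`` columns.  Missing optional
values are written as ``-`` and preserved as missing on read.  The variant
identity key is ``(position, ref_aa, alt_aa)``; duplicate keys are an
error, never a silent dedupe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqUtils import seq1

from .annotation import AMINO_ACIDS

__all__ = [
    "SAVRecord",
    "MethodConfig",
    "MethodScoreTable",
    "parse_protein_variant",
    "format_protein_variant",
    "read_variant_table",
    "write_variant_table",
    "read_method_scores",
    "read_method_config",
    "phylop_from_bigwig",
    "MISSING",
]

MISSING = "-"

LABELS = ("pathogenic", "benign", "vus")

VARIANT_COLUMNS = (
    "position",
    "ref_aa",
    "alt_aa",
    "label",
    "rs_id",
    "allele_frequency",
    "phylop100",
    "phylop30",
    "exon_number",
)


@dataclass(frozen=True)
class SAVRecord:
    """One single amino-acid variant with label and optional annotations."""

    position: int
    ref_aa: str
    alt_aa: str
    label: str = "vus"
    rs_id: str | None = None
    allele_frequency: float | None = None
    phylop100: float | None = None
    phylop30: float | None = None
    exon_number: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AMINO_ACIDS:
                raise ValueError(f"unknown residue code {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise ValueError(
                f"ref and alt residues are identical at position {self.position}"
            )
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.allele_frequency is not None and not (
            0.0 <= self.allele_frequency <= 1.0
        ):
            raise ValueError(f"allele frequency {self.allele_frequency} not in [0,1]")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_aa, self.alt_aa)

    def with_conservation(self, phylop100: float, phylop30: float) -> "SAVRecord":
        return replace(self, phylop100=phylop100, phylop30=phylop30)


def parse_protein_variant(text: str) -> tuple[int, str, str]:
    """Parse ``Leu1504Pro``-style notation into ``(1504, 'L', 'P')``."""
    text = text.strip()
    if len(text) < 7 or not text[3:-3].isdigit():
        raise ValueError(f"malformed protein variant notation: {text!r}")
    ref3, pos, alt3 = text[:3], int(text[3:-3]), text[-3:]
    ref, alt = seq1(ref3), seq1(alt3)
    for three, one in ((ref3, ref), (alt3, alt)):
        if one not in AMINO_ACIDS:
            raise ValueError(f"unknown three-letter residue code {three!r} in {text!r}")
    return pos, ref, alt


_ONE_TO_THREE = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr",
}


def format_protein_variant(position: int, ref_aa: str, alt_aa: str) -> str:
    """Inverse of :func:`parse_protein_variant`: ``(1504,'L','P') -> 'Leu1504Pro'``."""
    return f"{_ONE_TO_THREE[ref_aa]}{position}{_ONE_TO_THREE[alt_aa]}"


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", na_values=[MISSING], keep_default_na=False, dtype=str
    )


def _opt(value, cast):
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    return cast(value)


def read_variant_table(path) -> list[SAVRecord]:
    """Read a variant TSV into :class:`SAVRecord` objects.

    Rows that fail to parse are collected and reported together with
    their 1-based data line numbers; duplicate variant keys are an error.
    """
    df = _read_tsv(path)
    has_notation = "variant" in df.columns
    if not has_notation and not {"position", "ref_aa", "alt_aa"} <= set(df.columns):
        raise ValueError(
            "variant table needs a 'variant' column or position/ref_aa/alt_aa columns"
        )
    records: list[SAVRecord] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            if has_notation:
                position, ref, alt = parse_protein_variant(row["variant"])
            else:
                position, ref, alt = int(row["position"]), row["ref_aa"], row["alt_aa"]
            records.append(
                SAVRecord(
                    position=position,
                    ref_aa=ref,
                    alt_aa=alt,
                    label=_opt(row.get("label"), str) or "vus",
                    rs_id=_opt(row.get("rs_id"), str),
                    allele_frequency=_opt(row.get("allele_frequency"), float),
                    phylop100=_opt(row.get("phylop100"), float),
                    phylop30=_opt(row.get("phylop30"), float),
                    exon_number=_opt(row.get("exon_number"), int),
                )
            )
        except (ValueError, KeyError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError("unparseable variant rows:\n" + "\n".join(errors))
    seen: dict[tuple, int] = {}
    for j, rec in enumerate(records):
        if rec.key in seen:
            raise ValueError(
                f"duplicate variant {format_protein_variant(*rec.key)} at data "
                f"lines {seen[rec.key] + 2} and {j + 2}"
            )
        seen[rec.key] = j
    return records


def _fmt(value) -> str:
    if value is None:
        return MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_variant_table(records: Iterable[SAVRecord], path) -> None:
    """Write records as TSV with ``-`` for missing optional fields."""
    rows = [
        {col: _fmt(getattr(rec, col)) for col in VARIANT_COLUMNS} for rec in records
    ]
    pd.DataFrame(rows, columns=list(VARIANT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


@dataclass(frozen=True)
class MethodConfig:
    """How one prediction method's scores translate into calls."""

    name: str
    cutoff: float
    direction: str  # higher_is_pathogenic | lower_is_pathogenic
    rankscore_column: str | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("higher_is_pathogenic", "lower_is_pathogenic"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def call(self, score: float | None) -> str | None:
        """Binary call from a raw score; ``None`` propagates (absence is not benign)."""
        if score is None or pd.isna(score):
            return None
        if self.direction == "higher_is_pathogenic":
            return "P" if score >= self.cutoff else "B"
        return "P" if score <= self.cutoff else "B"


def read_method_config(path) -> list[MethodConfig]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        MethodConfig(
            name=m["name"],
            cutoff=m["cutoff"],
            direction=m["direction"],
            rankscore_column=m.get("rankscore_column"),
        )
        for m in raw
    ]


@dataclass
class MethodScoreTable:
    """Per-variant method scores, rank scores and calls.

    ``frame`` is indexed by the ``(position, ref_aa, alt_aa)`` key and has
    per-method columns ``<name>_score``, ``<name>_rankscore`` and
    ``<name>_call`` (any subset per method, calls derived from score +
    cutoff + direction when the call column is absent).
    """

    frame: pd.DataFrame
    methods: list[MethodConfig]

    def __post_init__(self) -> None:
        for m in self.methods:
            rs = f"{m.name}_rankscore"
            if rs in self.frame.columns:
                vals = self.frame[rs].dropna()
                if ((vals <= 0) | (vals > 1)).any():
                    raise ValueError(f"{rs} values outside (0, 1]")

    def calls(self, method: str) -> pd.Series:
        return self.frame[f"{method}_call"]

    def rank_scores(self, method: str) -> pd.Series:
        col = f"{method}_rankscore"
        if col in self.frame.columns:
            return self.frame[col]
        return pd.Series(pd.NA, index=self.frame.index, dtype="float64")


def read_method_scores(path, methods: Sequence[MethodConfig]) -> MethodScoreTable:
    """Read a method-score TSV and derive missing call columns.

    Every configured method must contribute at least one column; call
    columns may only contain ``P``, ``B`` or missing.
    """
    df = _read_tsv(path)
    if "variant" in df.columns:
        parsed = df["variant"].map(parse_protein_variant)
        df["position"] = [p for p, _, _ in parsed]
        df["ref_aa"] = [r for _, r, _ in parsed]
        df["alt_aa"] = [a for _, _, a in parsed]
    df["position"] = df["position"].astype(int)
    for m in methods:
        cols = [f"{m.name}_{kind}" for kind in ("score", "rankscore", "call")]
        present = [c for c in cols if c in df.columns]
        if not present:
            raise ValueError(f"method {m.name!r} has no columns in {path}")
        for c in present:
            if c.endswith("_call"):
                bad = set(df[c].dropna()) - {"P", "B"}
                if bad:
                    raise ValueError(f"invalid call values {bad} in column {c}")
            else:
                df[c] = df[c].astype(float)
        call_col = f"{m.name}_call"
        if call_col not in df.columns:
            df[call_col] = df[f"{m.name}_score"].map(m.call)
    # numeric pass-through columns not owned by a configured method
    for col in df.columns:
        if col == "construct_probability" or (
            col.endswith(("_score", "_rankscore")) and df[col].dtype == object
        ):
            df[col] = df[col].astype(float)
    df = df.set_index(["position", "ref_aa", "alt_aa"])
    return MethodScoreTable(frame=df, methods=list(methods))


def phylop_from_bigwig(path, chrom: str, genomic_positions: Sequence[int]) -> list[float]:
    """Convenience reader: per-base phyloP values from a bigWig track.

    ``genomic_positions`` are 1-based genomic coordinates supplied by the
    caller (protein-to-genome mapping is out of scope).  Imported lazily so
    the core package never needs the binary-format dependency.
    """
    import pyBigWig  # local import keeps the dependency optional

    bw = pyBigWig.open(str(path))
    try:
        return [bw.values(chrom, p - 1, p)[0] for p in genomic_positions]
    finally:
        bw.close()
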