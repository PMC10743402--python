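"""Consensus prioritization of VUS and mean-RankScore ordering.

A variant of uncertain significance is nominated as probably pathogenic
when (1) the ConStruct probability strictly exceeds a threshold (default
0.85) and (2) every required external method calls it pathogenic.  The
required panel defaults to the eight dbNSFP-derived methods with balanced
accuracy above 0.8 on the otoferlin benchmark, plus SAV-Pred; the
mean-RankScore panel is those nine plus ConStruct itself.  Both panels are
configurable — the published consensus wording admits either reading of
where SAV-Pred sits.

Rank scores follow the dbNSFP convention (rank fraction of a method's raw
score among all scored variants, oriented so higher means more damaging);
:func:`rank_scores_from_raw` is an explicit local approximation for when
precomputed rank scores are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import MISSING, SAVRecord, format_protein_variant, parse_protein_variant

__all__ = [
    "DEFAULT_REQUIRED_METHODS",
    "DEFAULT_RANKSCORE_PANEL",
    "ConsensusCriteria",
    "PrioritizationRecord",
    "rank_scores_from_raw",
    "mean_rank_score",
    "consensus_select",
    "load_ranked_candidates",
    "packaged_candidate_table",
    "write_prioritization_table",
]

DEFAULT_REQUIRED_METHODS = (
    "MetaLR",
    "MetaSVM",
    "MutationAssessor",
    "PolyPhen2_HDIV",
    "PROVEAN",
    "SIFT_4G",
    "MutPred",
    "LIST_S2",
    "SAV_Pred",
)

DEFAULT_RANKSCORE_PANEL = DEFAULT_REQUIRED_METHODS + ("ConStruct",)


@dataclass(frozen=True)
class ConsensusCriteria:
    construct_threshold: float = 0.85
    required_methods: tuple[str, ...] = DEFAULT_REQUIRED_METHODS
    require_all: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.construct_threshold <= 1.0):
            raise ValueError("construct_threshold must lie in [0, 1]")
        if not self.required_methods:
            raise ValueError("required_methods must be non-empty")


@dataclass
class PrioritizationRecord:
    variant: SAVRecord
    construct_probability: float
    method_calls: dict = field(default_factory=dict)
    mean_rank_score: float | None = None
    n_rank_scores: int = 0
    selected: bool = False

    @property
    def notation(self) -> str:
        return format_protein_variant(*self.variant.key)


def rank_scores_from_raw(scores: Sequence[float], direction: str) -> np.ndarray:
    """Rank fractions in (0, 1] from raw scores; ties get the mean rank.

    Scores are first oriented so that higher means more damaging; missing
    values stay missing and do not consume ranks.
    """
    arr = np.asarray(scores, dtype=float)
    mask = ~np.isnan(arr)
    if not mask.any():
        raise ValueError("all scores missing; cannot rank")
    oriented = arr if direction == "higher_is_pathogenic" else -arr
    out = np.full(arr.shape, np.nan)
    out[mask] = rankdata(oriented[mask], method="average") / mask.sum()
    return out


def mean_rank_score(rank_scores: Mapping[str, float | None]) -> tuple[float | None, int]:
    """Arithmetic mean over non-missing rank scores, with contributor count."""
    vals = [
        v for v in rank_scores.values() if v is not None and not pd.isna(v)
    ]
    if not vals:
        return None, 0
    return float(np.mean(vals)), len(vals)


def _is_pathogenic_call(value) -> bool:
    # a missing call is never a pathogenic call (absence is not evidence)
    return value is not None and not pd.isna(value) and value == "P"


def consensus_select(
    vus_records: Sequence[SAVRecord],
    construct_probs: Mapping[tuple, float],
    method_calls: pd.DataFrame,
    rank_scores: pd.DataFrame,
    criteria: ConsensusCriteria = ConsensusCriteria(),
) -> list[PrioritizationRecord]:
    """Apply the consensus criteria and order by mean RankScore, descending.

    ``method_calls`` and ``rank_scores`` are indexed by the variant key
    ``(position, ref_aa, alt_aa)`` with one column per method (calls in
    {P, B, missing}; rank scores in (0, 1] or missing).  A missing call
    from a required method blocks selection when ``require_all`` is set.
    Output order: mean rank score descending, ties broken by variant key;
    the result is a permutation of the input.
    """
    out: list[PrioritizationRecord] = []
    for rec in vus_records:
        key = rec.key
        if key not in construct_probs:
            raise KeyError(
                f"no ConStruct probability for {format_protein_variant(*key)}"
            )
        prob = float(construct_probs[key])
        calls = {
            m: method_calls.at[key, m]
            for m in method_calls.columns
            if key in method_calls.index
        }
        rs = {
            m: rank_scores.at[key, m]
            for m in rank_scores.columns
            if key in rank_scores.index
        }
        mean_rs, n_rs = mean_rank_score(rs)
        required_ok = [
            _is_pathogenic_call(calls.get(m)) for m in criteria.required_methods
        ]
        methods_pass = all(required_ok) if criteria.require_all else any(required_ok)
        selected = prob > criteria.construct_threshold and methods_pass
        out.append(
            PrioritizationRecord(
                variant=rec,
                construct_probability=prob,
                method_calls=calls,
                mean_rank_score=mean_rs,
                n_rank_scores=n_rs,
                selected=selected,
            )
        )
    out.sort(
        key=lambda r: (
            -(r.mean_rank_score if r.mean_rank_score is not None else -np.inf),
            r.variant.key,
        )
    )
    return out


def load_ranked_candidates(path) -> pd.DataFrame:
    """Read a ranked candidate table (variant notation + mean RankScore).

    Returns a frame with parsed ``position``/``ref_aa``/``alt_aa`` columns
    alongside ``rs_id``, ``allele_frequency`` and ``mean_rank_score``,
    sorted by mean rank score descending.
    """
    df = pd.read_csv(
        path, sep="\t", na_values=[MISSING], keep_default_na=False,
        dtype={"variant": str, "rs_id": str},
    )
    parsed = df["variant"].map(parse_protein_variant)
    df["position"] = [p for p, _, _ in parsed]
    df["ref_aa"] = [r for _, r, _ in parsed]
    df["alt_aa"] = [a for _, _, a in parsed]
    df["mean_rank_score"] = df["mean_rank_score"].astype(float)
    if "allele_frequency" in df.columns:
        df["allele_frequency"] = df["allele_frequency"].astype(float)
    return df.sort_values(
        ["mean_rank_score", "position", "ref_aa", "alt_aa"],
        ascending=[False, True, True, True],
        kind="stable",
    ).reset_index(drop=True)


def packaged_candidate_table() -> pd.DataFrame:
    """The packaged 16-variant otoferlin candidate-pathogenic VUS table."""
    ref = resources.files("construct_otof.data") / "otof_candidate_vus.tsv"
    with resources.as_file(ref) as path:
        return load_ranked_candidates(path)


def write_prioritization_table(records: Sequence[PrioritizationRecord], path) -> None:
    """Serialize prioritization results as a ranked TSV."""
    rows = []
    for r in records:
        rows.append(
            {
                "variant": r.notation,
                "rs_id": r.variant.rs_id if r.variant.rs_id is not None else MISSING,
                "allele_frequency": (
                    repr(r.variant.allele_frequency)
                    if r.variant.allele_frequency is not None
                    else MISSING
                ),
                "construct_probability": repr(r.construct_probability),
                "mean_rank_score": (
                    repr(r.mean_rank_score) if r.mean_rank_score is not None else MISSING
                ),
                "n_rank_scores": r.n_rank_scores,
                "selected": int(r.selected),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
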