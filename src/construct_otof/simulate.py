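"""Synthetic otoferlin variant benchmarks.

The published benchmark tables (270 labelled single amino-acid variants
and 1302 VUS) live in supplementary material that is not machine-readable,
so this module generates stand-ins with the same class structure: 93
pathogenic / 177 benign training variants whose pathogenic class is
enriched in C2 domains 2-7, skewed toward high positions (hence high exon
numbers), biased to negative BLOSUM80 substitution scores and high phyloP
conservation; and a VUS set with per-method scores driven by a shared
latent pathogenicity plus method noise, including a planted subset built
to satisfy the consensus criteria so the prioritization stage has known
positives to recover.

All distributional parameters are invented defaults collected in
:class:`SimulationConfig`; every draw flows from one seeded generator so a
given seed reproduces a run byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import AMINO_ACIDS, AnnotationMap, SubstitutionMatrix
from .io import MethodConfig, MethodScoreTable, SAVRecord
from .prioritization import DEFAULT_REQUIRED_METHODS, rank_scores_from_raw

__all__ = ["SimulationConfig", "SimulatedVUS", "simulate_training_set", "simulate_vus_set"]

# plausible track bounds used to clip sampled conservation values
_P100_RANGE = (-20.0, 10.0)
_P30_RANGE = (-20.0, 1.25)


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator, with the benchmark's class sizes as defaults."""

    n_pathogenic: int = 93
    n_benign: int = 177
    n_vus: int = 1302
    seed: int = 17

    # class-conditional structure of the training set
    domain_enrichment: float = 0.8  # P(pathogenic position in domains 2-7)
    benign_domain_prob: float = 0.25  # P(benign position in any domain)
    blosum_negative_prob: float = 0.8  # P(pathogenic substitution scores < 0)
    benign_negative_prob: float = 0.2
    phylop100_pathogenic: tuple[float, float] = (6.0, 1.5)  # mean, sd
    phylop100_benign: tuple[float, float] = (0.0, 1.5)
    phylop30_pathogenic: tuple[float, float] = (0.8, 0.3)
    phylop30_benign: tuple[float, float] = (0.0, 0.3)

    # VUS / method-score generation
    n_planted: int = 16
    latent_pathogenic_rate: float = 0.05  # base rate among non-planted VUS
    method_names: tuple[str, ...] = DEFAULT_REQUIRED_METHODS
    method_cutoff: float = 0.5
    method_noise_sd: float = 0.12  # per-method noise around the latent signal
    missingness: float = 0.05  # P(a method score is missing for a variant)

    def __post_init__(self) -> None:
        for name in ("n_pathogenic", "n_benign", "n_vus", "n_planted"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in (
            "domain_enrichment",
            "benign_domain_prob",
            "blosum_negative_prob",
            "benign_negative_prob",
            "latent_pathogenic_rate",
            "missingness",
        ):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_planted > self.n_vus:
            raise ValueError("n_planted cannot exceed n_vus")


def _layer_positions(amap: AnnotationMap, codes) -> np.ndarray:
    out = []
    for iv in amap.domains:
        if iv.code in codes:
            out.extend(range(iv.start, iv.end + 1))
    return np.array(sorted(out))


def _draw_positions(
    rng: np.random.Generator,
    n_inside: int,
    n_outside: int,
    inside_pool: np.ndarray,
    outside_pool: np.ndarray,
    available: set,
    weight_outside_by_position: bool,
) -> list[int]:
    positions: list[int] = []
    pool = np.array([p for p in inside_pool if p in available])
    if n_inside > len(pool):
        raise ValueError(
            f"cannot place {n_inside} variants in a layer with only "
            f"{len(pool)} free residues"
        )
    chosen = rng.choice(pool, size=n_inside, replace=False)
    positions.extend(int(p) for p in chosen)
    available.difference_update(positions)
    pool = np.array([p for p in outside_pool if p in available])
    if n_outside > len(pool):
        raise ValueError("not enough free residues outside the layer")
    if weight_outside_by_position and n_outside:
        w = pool.astype(float)
        chosen = rng.choice(pool, size=n_outside, replace=False, p=w / w.sum())
    elif n_outside:
        chosen = rng.choice(pool, size=n_outside, replace=False)
    else:
        chosen = np.array([], dtype=int)
    positions.extend(int(p) for p in chosen)
    available.difference_update(positions)
    return positions


def _substitution_pools(matrix: SubstitutionMatrix):
    neg, nonneg = {}, {}
    for ref in AMINO_ACIDS:
        neg[ref] = [a for a in AMINO_ACIDS if a != ref and matrix.scores[(ref, a)] < 0]
        nonneg[ref] = [
            a for a in AMINO_ACIDS if a != ref and matrix.scores[(ref, a)] >= 0
        ]
    return neg, nonneg


def _draw_substitution(rng, matrix_pools, negative_prob: float) -> tuple[str, str]:
    neg, nonneg = matrix_pools
    ref = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]
    want_negative = rng.random() < negative_prob
    pool = neg[ref] if want_negative else nonneg[ref]
    if not pool:  # a residue may lack non-negative exchanges; fall back
        pool = neg[ref] or nonneg[ref]
    return ref, pool[rng.integers(len(pool))]


def _clipped_normal(rng, mean_sd, bounds, size) -> np.ndarray:
    vals = rng.normal(mean_sd[0], mean_sd[1], size=size)
    return np.clip(vals, bounds[0], bounds[1])


def simulate_training_set(
    config: SimulationConfig,
    amap: AnnotationMap,
    matrix: SubstitutionMatrix,
) -> list[SAVRecord]:
    """A labelled training set with the benchmark's class-conditional structure.

    Positions are sampled without replacement across the whole run, so
    every variant key is unique.  Pathogenic positions fall in C2 domains
    2-7 with probability ``domain_enrichment`` and otherwise favour the
    C-terminal part of the sequence; pathogenic substitutions favour
    negative BLOSUM80 scores and high phyloP values.
    """
    rng = np.random.default_rng(config.seed)
    if config.n_pathogenic + config.n_benign > amap.protein_length:
        raise ValueError("more variants requested than free residues")
    domain27 = _layer_positions(amap, codes=range(2, 8))
    if config.n_pathogenic and config.domain_enrichment > 0 and len(domain27) == 0:
        raise ValueError("domain enrichment requested but domains 2-7 are empty")
    all_domains = _layer_positions(amap, codes=range(1, 8))
    everything = np.arange(1, amap.protein_length + 1)
    outside_domains = np.setdiff1d(everything, all_domains)
    available = set(range(1, amap.protein_length + 1))
    pools = _substitution_pools(matrix)

    records: list[SAVRecord] = []
    for label, n in (("pathogenic", config.n_pathogenic), ("benign", config.n_benign)):
        if n == 0:
            continue
        if label == "pathogenic":
            n_inside = int(rng.binomial(n, config.domain_enrichment))
            inside_pool, weight_high = domain27, True
            neg_prob = config.blosum_negative_prob
            p100, p30 = config.phylop100_pathogenic, config.phylop30_pathogenic
        else:
            n_inside = int(rng.binomial(n, config.benign_domain_prob))
            inside_pool, weight_high = all_domains, False
            neg_prob = config.benign_negative_prob
            p100, p30 = config.phylop100_benign, config.phylop30_benign
        positions = _draw_positions(
            rng, n_inside, n - n_inside, inside_pool, outside_domains,
            available, weight_outside_by_position=weight_high,
        )
        phylop100 = _clipped_normal(rng, p100, _P100_RANGE, n)
        phylop30 = _clipped_normal(rng, p30, _P30_RANGE, n)
        for i, pos in enumerate(positions):
            ref, alt = _draw_substitution(rng, pools, neg_prob)
            records.append(
                SAVRecord(
                    position=pos,
                    ref_aa=ref,
                    alt_aa=alt,
                    label=label,
                    phylop100=round(float(phylop100[i]), 3),
                    phylop30=round(float(phylop30[i]), 3),
                )
            )
    records.sort(key=lambda r: r.key)
    return records


@dataclass
class SimulatedVUS:
    """A VUS set, its method-score table, and the planted positive keys."""

    records: list[SAVRecord]
    scores: MethodScoreTable
    planted: list[tuple[int, str, str]] = field(default_factory=list)


def simulate_vus_set(
    config: SimulationConfig,
    amap: AnnotationMap,
    matrix: SubstitutionMatrix,
) -> SimulatedVUS:
    """A VUS table plus per-method scores driven by latent pathogenicity.

    ``n_planted`` variants are constructed to satisfy the default
    consensus criteria outright (ConStruct probability above 0.85 and a
    pathogenic call from every required method); the remaining variants
    carry latent pathogenicity at ``latent_pathogenic_rate`` and noisy
    method scores, with scores missing at rate ``missingness`` (planted
    rows keep their required-method scores, by construction).
    """
    rng = np.random.default_rng(config.seed + 1)
    n = config.n_vus
    if n > amap.protein_length:
        raise ValueError("more VUS requested than residues available")
    positions = rng.choice(
        np.arange(1, amap.protein_length + 1), size=n, replace=False
    )
    pools = _substitution_pools(matrix)
    latent = rng.random(n) < config.latent_pathogenic_rate
    planted_idx = rng.choice(n, size=config.n_planted, replace=False)
    latent[planted_idx] = True
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted_idx] = True

    records: list[SAVRecord] = []
    p100_p = _clipped_normal(rng, config.phylop100_pathogenic, _P100_RANGE, n)
    p100_b = _clipped_normal(rng, config.phylop100_benign, _P100_RANGE, n)
    p30_p = _clipped_normal(rng, config.phylop30_pathogenic, _P30_RANGE, n)
    p30_b = _clipped_normal(rng, config.phylop30_benign, _P30_RANGE, n)
    for i in range(n):
        neg_prob = (
            config.blosum_negative_prob if latent[i] else config.benign_negative_prob
        )
        ref, alt = _draw_substitution(rng, pools, neg_prob)
        records.append(
            SAVRecord(
                position=int(positions[i]),
                ref_aa=ref,
                alt_aa=alt,
                label="vus",
                phylop100=round(float(p100_p[i] if latent[i] else p100_b[i]), 3),
                phylop30=round(float(p30_p[i] if latent[i] else p30_b[i]), 3),
            )
        )

    construct = np.where(
        planted_mask,
        rng.uniform(0.86, 0.995, size=n),
        np.where(
            latent,
            rng.uniform(0.40, 0.97, size=n),
            rng.beta(2.0, 8.0, size=n),
        ),
    )

    frame = pd.DataFrame(
        {
            "position": [r.position for r in records],
            "ref_aa": [r.ref_aa for r in records],
            "alt_aa": [r.alt_aa for r in records],
            "construct_probability": np.round(construct, 6),
        }
    )
    configs = [
        MethodConfig(name=m, cutoff=config.method_cutoff,
                     direction="higher_is_pathogenic")
        for m in config.method_names
    ]
    for m in config.method_names:
        signal = np.where(latent, 0.8, 0.25)
        score = signal + rng.normal(0.0, config.method_noise_sd, size=n)
        # planted rows must clear the cutoff for every required method
        score = np.where(
            planted_mask, rng.uniform(0.75, 0.99, size=n), score
        )
        missing = rng.random(n) < config.missingness
        missing &= ~planted_mask
        score = np.where(missing, np.nan, np.round(score, 6))
        frame[f"{m}_score"] = score
        if np.isnan(score).all():  # a fully missing method cannot be ranked
            frame[f"{m}_rankscore"] = np.nan
        else:
            frame[f"{m}_rankscore"] = np.round(
                rank_scores_from_raw(score, "higher_is_pathogenic"), 6
            )
        frame[f"{m}_call"] = [
            c.call(s) for c, s in zip([cfg for cfg in configs if cfg.name == m] * n, score)
        ]
    frame["ConStruct_rankscore"] = np.round(
        rank_scores_from_raw(frame["construct_probability"].to_numpy(),
                             "higher_is_pathogenic"),
        6,
    )
    frame = frame.set_index(["position", "ref_aa", "alt_aa"])
    planted_keys = sorted(records[i].key for i in planted_idx)
    return SimulatedVUS(
        records=sorted(records, key=lambda r: r.key),
        scores=MethodScoreTable(frame=frame, methods=configs),
        planted=planted_keys,
    )
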