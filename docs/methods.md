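# Methods

## Scope and model

`construct-otof` classifies single amino-acid variants (SAVs) of human
otoferlin (UniProt Q9HC10, long isoform, 1979 residues) as pathogenic or
benign for OTOF-related auditory neuropathy, and prioritizes variants of
uncertain significance (VUS) by consensus with external predictors. The
classifier is a random forest over nine protein-centric predictors
(position, exon number, BLOSUM80 substitution score, C2-domain code,
disordered-region code, composition-bias flag, coiled-coil flag, and two
phyloP conservation values). The forest contract is a bagged ensemble of
decision trees with random feature subsetting; defaults are 500 trees,
`sqrt` feature subsetting, minimum leaf size 1, seed 17. These are
recorded in every trained model's metadata and are configurable — the
defaults are ordinary random-forest practice, not fitted values.

## Annotation layers

Intervals are 1-based and closed on both ends, matching the "positions
1–98" convention of protein feature databases. The packaged map carries:

* **Domains** — the seven C2-domain intervals 1–98, 236–357, 400–531,
  944–1069, 1115–1242, 1464–1593, 1714–1865, coded 1–7 in N→C order. The
  C-terminal transmembrane anchor is not a coded domain: only the seven C2
  intervals have published coordinates, and code 7 is assigned to the
  printed seventh interval.
* **Regions** — four intrinsically disordered regions 128–171, 642–694,
  1299–1324, 1343–1405, coded 1–4.
* **Composition bias and coiled coil** — shipped *empty* by default. Their
  curated coordinates are not bundled with the package; both layers are
  config-driven (`load_annotation_config`) and the membership flags are
  exercised in tests with toy configs. With the default map these two
  features are constant 0, which a forest simply ignores.
* **Exon map** — a *synthetic* near-uniform partition of 1–1979 into 46
  intervals (45 of 43 residues, the last of 44). True exon boundaries in
  protein coordinates are transcript-specific and not bundled; users
  doing real analyses should supply a transcript-derived map via the
  config. The exon number of a record takes precedence over the map when
  present, so real exon assignments pass through unchanged.

Layers are validated at load: non-overlap within each layer, unique
domain/region codes, and exact exon coverage of the sequence.

## Substitution scores

The packaged BLOSUM80 matrix is the NCBI-scale (1/3-bit) matrix in NCBI
text format, parsed with Biopython. Off-diagonal entries are frequently
negative — the "negative BLOSUM80 score" tendency of pathogenic variants
is meaningful only on this standard scale.

## Conservation

phyloP values (100-vertebrate and 30-primate tracks) are per-nucleotide
quantities and travel with each variant record; encoding raises rather
than imputing when they are missing. A thin optional reader
(`phylop_from_bigwig`) extracts values from bigWig tracks given caller-
supplied genomic coordinates; genomic↔protein coordinate mapping is out
of scope.

## Cross-validation

Folds follow the position-ordered cyclic rule: records sorted by
(position, ref, alt) — the substitution letters break ties, since the
published rule orders by position only — receive fold labels 1…k
cyclically. Fold sizes therefore differ by at most one (270 variants give
exactly 54 per fold), and the assignment is independent of input row
order. Out-of-fold probabilities are pooled before computing metrics
(confusion counts summing to n imply pooling rather than fold-averaging);
per-fold reports are also returned. The confusion threshold defaults to
0.5, with "predicted pathogenic" meaning probability strictly greater
than the threshold throughout the package.

## Metrics and threshold analysis

Standard definitions: sensitivity = tp/(tp+fn) with pathogenic as the
positive class, specificity = tn/(tn+fp), balanced accuracy their mean.
A metric with an empty denominator is reported as undefined (`None`),
never 0. ROC AUC equals the pairwise probability
P(score⁺ > score⁻) + ½P(tie); the implementation delegates to
scikit-learn while tests check it against an exhaustive pairwise count.
Score distributions per class are summarized with Tukey box-plot
statistics: linear-interpolation quartiles, mild outliers strictly beyond
1.5×IQR fences, extreme outliers strictly beyond 3×IQR, whisker ends at
the most extreme values inside the mild fences. The threshold sweep
reports, per threshold, confusion counts, the number of predicted
positives and the false-positive share fp/(tp+fp) as a percentage
(undefined when nothing is predicted positive).

## Consensus prioritization

A VUS is selected when its ConStruct probability strictly exceeds the
threshold (default 0.85) and all required external methods call it
pathogenic; a missing call blocks selection (absence of evidence is not a
benign call). The default required panel is the eight dbNSFP-derived
methods with balanced accuracy above 0.8 on the otoferlin benchmark plus
SAV-Pred; the mean-RankScore panel is those nine plus ConStruct (ten
methods). Both panels are explicit arguments because the published
wording ("eight other methods … and SAV-Pred prediction") is ambiguous
about whether SAV-Pred is inside or alongside the eight; we read it as
8 + SAV-Pred. Results are ordered by mean RankScore descending, ties
broken by variant key. dbNSFP rank scores are genome-wide quantities that
cannot be recomputed locally; `rank_scores_from_raw` (ascending rank
fraction after orienting scores so higher = more damaging, mean ranks for
ties) is an explicit local approximation used when they are absent.

## Synthetic benchmark generator

The generator emulates the structure of the real otoferlin benchmark:
93 pathogenic / 177 benign labelled SAVs and 1302 VUS. Class-conditional
defaults (all invented, all in `SimulationConfig`):

* pathogenic positions fall in C2 domains 2–7 with probability 0.8;
  outside-domain pathogenic positions are sampled with weight ∝ position,
  which also skews pathogenic exon numbers high; benign positions fall in
  any domain with probability 0.25, otherwise uniformly;
* pathogenic substitutions draw an alternate residue with negative
  BLOSUM80 score with probability 0.8 (benign: 0.2);
* phyloP100 ~ Normal(6, 1.5) for pathogenic vs Normal(0, 1.5) for benign;
  phyloP30 ~ Normal(0.8, 0.3) vs Normal(0, 0.3), clipped to plausible
  track ranges. These effect sizes make the classes well separated — the
  benchmark is a strong-signal recovery test of the pipeline, not a
  difficulty-calibrated imitation of real data; passing it shows the
  machinery works, not that real-data accuracy would match.
* positions are sampled without replacement within a run, so variant keys
  are unique; a run is a pure function of its seed (byte-identical
  reruns).

VUS method scores derive from a shared latent pathogenicity (base rate
0.05) plus per-method Gaussian noise (sd 0.12), with 5% missingness. A
planted subset (default 16) is constructed to satisfy the consensus
criteria outright — probability drawn above 0.86 and pathogenic calls
from every required method — so prioritization has known positives;
recovering them tests the selection and I/O logic end to end, not the
statistical difficulty of real VUS triage. The generator does not mimic
the real OTOF mutational spectrum, allele frequencies, dbSNP identifiers,
linkage between conservation and position, or realistic inter-method
correlation structure.

## Problem sizes

The test suite and the acceptance script run the benchmark at its native
sizes (270 training variants, 1302 VUS) with 500-tree forests; the
multi-seed recovery checks use 20 seeds, a size at which the whole suite
completes in a few minutes on one core.

## Known limitations

* Default comp-bias/coiled-coil layers are empty and the default exon map
  is synthetic (see above) — supply a curated config for real use.
* The Bayes/SVM/PNN comparison models and the external predictors
  themselves are out of scope; external methods enter only as score
  columns.
* Genomic coordinates, VCF and HGVS cDNA notation are out of scope; input
  is protein-level.
* Synonymous variants are not handled.
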