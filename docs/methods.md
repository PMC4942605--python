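# Methods

## Data model

A cohort row is one patient: IDs, sex, parental provinces and two alleles.
An *allele* is one inherited *SLC25A13* chromosome carrying ≥ 1 catalogued
variants in cis, or the unknown sentinel `?` when no mutation was detected.
Allele identity is the canonical variant id, `[a;b]` for a cis compound, or
`?`; genotype identity is the unordered pair of allele identities. The
variant catalogue (41 entities) is a packaged TSV keyed by systematic
cDNA-level names; legacy spellings (`IVS7-1G>C`, `c.955G>A`,
`c.933+1_c.933+2insCAGG`, `g.2T>C`, `1092-1095delT`, `r.16_212dup`) resolve
through an alias table rather than positional parsing, because sources mix
both nomenclatures for the same alleles. Variant category (missense,
nonsense, deletion, insertion, duplication, splice-site, complex,
pathogenic-SNP, aberrant-transcript) is registry metadata, never inferred
from the string — classifying a splice variant requires transcript
evidence a string does not carry.

One deliberately conventional identification: the catalogue treats
`c.933+1_c.933+2insCAGG` and `c.933_c.933+1insGCAG` as two spellings of one
insertion (they describe the same duplicated junction sequence from either
side); without this identification the packaged cohort would contain a
42nd entity.

## Geographic stratification

Provinces map to north/border/south of the Yangtze (10 + 6 + 10 = 26
provinces/municipalities, packaged as YAML). A patient's region is the
shared parental region; discordant parents give `mixed`, missing data
`unstated`. Family deduplication keeps the lexicographically smallest
patient id per family (sibling records append an `S` suffix and must carry
identical genotypes). The genotype-analysis subset drops families with any
unknown allele or mixed region, each exclusion logged with exactly one
reason.

## Count reconstruction from printed frequencies

The packaged regional count matrices are rebuilt from 2-decimal relative
frequency tables as `round(freq% × N / 100)` with round-half-away-from-zero
in exact rational arithmetic, `N = 55/81/392` alleles and `23/35/187`
families per region. Every reconstructed column is validated to sum exactly
to its margin; a residual raises an error naming the column. This rule
recovers integers exactly for all six columns, which is the evidence it is
the right inverse of the original rounding.

## Statistical tests

For each variant identity (including the unknown row) a carriers-vs-rest ×
3-region table is tested:

- **Selection rule.** Pearson χ² (via `scipy.stats.chi2_contingency`, no
  continuity correction) when every expected cell count ≥ 5, otherwise the
  Freeman–Halton exact test. The 2×2 pairwise comparisons use the same rule.
- **Freeman–Halton exact test.** Full enumeration of all tables with the
  observed margins (no Monte Carlo); two-sided p is the sum of
  multivariate-hypergeometric point probabilities ≤ that of the observed
  table, with a 1e-7 relative tolerance treating floating-point near-ties
  as ties. Probabilities are computed in log space (`gammaln`). Zero
  margins are dropped first; a table left with < 2 informative rows or
  columns has p = 1. On 2×2 tables this definition coincides with the
  classical two-sided Fisher test (scipy's `fisher_exact` is used as an
  independent oracle in the test suite, never as the implementation).
- **Post-hocs.** Pairwise north/border, north/south, border/south tests run
  only when the omnibus p < 0.05, judged at the Bonferroni-adjusted
  α = 0.05/3 ≈ 0.017.
- No correction is applied across the 41 variant rows; the scan mirrors the
  single-variant reporting convention of clinical mutation-spectrum tables.

## Homozygosity

Theoretical homozygosity (gene identity) per region is J = Σ Xᵢ², Xᵢ = m/N
in exact rationals; each undetected allele is its own allele at frequency
1/N (so u unknowns contribute u/N²). A compound allele is one identity with
one Xᵢ, keeping Σ Xᵢ = 1. Observed homozygosity is the fraction of included
families whose two allele identities are equal. Observed values are
compared between regions with the shared 2×2 machinery. For the
*theoretical* comparison no standard test exists (J is a probability, not a
count); the package's declared convention forms expected homozygote counts
`round(J × families)` and reuses the same 2×2 machinery. This is a
deterministic convention, documented as such — not a claim to reproduce any
particular published p-value for that comparison.

Known non-reproducibles, confirmed by computation and left unasserted: a
published exact p of 0.008 for a (2, 0, 0) carrier table where full
enumeration gives 0.011 (and 0.494/0.089/0.310 where enumeration gives
0.514/0.107/0.481 — most plausibly a χ² fallback in the original software);
two pairwise values (0.001, 0.005) that no single uniform convention
reproduces simultaneously (we compute 0.0004 and 0.002). None of these
affect which variants or genotypes are significant at α = 0.05.

## Synthetic cohorts

The generator emulates the sampling structure the analysis assumes: within
each region, two alleles per family drawn i.i.d. from a region-specific
frequency vector (random mating), with optional

- `homozygosity_excess` — probability the second allele copies the first,
  pushing observed homozygosity above Hardy–Weinberg J;
- `detection_failure_rate` — per-allele masking to `?`;
- `sibling_rate` — exact-genotype duplicate record with an `S`-suffixed id;
- `compound_rate` — substitution of a two-variant cis allele.

Defaults are 0; profiles built from a spectrum use its Xᵢ values, with the
unknown mass either re-expressed as a detection-failure rate or expanded
into unique 1/N pseudo-alleles (`unknown_as_unique`), matching the J
convention. Each family's generator is seeded by (global seed, region
index, family index), so output is byte-deterministic and growing a region
never reshuffles earlier families. The generator does not model migration,
mutation processes or founder-age coalescence; passing recovery tests shows
the pipeline is consistent under its own sampling assumptions, not that
real cohorts satisfy them (real data add ascertainment bias, relatedness
beyond siblings and geographically correlated detection failure).

## Problem sizes in the test suite

Calibration and recovery checks run at desk scale: 1000 null replicates of
a rare-variant carrier table at the study's regional allele totals
(55/81/392) for the type-I bound; 5000 families for frequency/J recovery
(3 binomial SE acceptance bands); 30 replicates at cohort-scale family
counts (28/40/196) for the power spot-check. The exact test's enumeration
cost is bounded by the carrier total (≤ a few thousand tables per call
throughout), so the whole suite runs in seconds.

## Limitations

- No Hardy–Weinberg testing, inbreeding-coefficient estimation or
  haplotype-based founder dating.
- No genomic-coordinate liftover or HGVS semantic validation; the registry
  is authoritative and closed.
- Region assignment for mixed-origin families' individual alleles follows
  the transmitting parent only when parental origin is stated; otherwise
  such families are simply excluded by the analysis subset, which is the
  only place regional allele counts are consumed.
- The packaged cohort table carries no per-patient provinces (its source
  prints none), so region-stratified results in the examples come from the
  reconstructed count matrices; the cohort fixture exercises parsing,
  deduplication and filtering.
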