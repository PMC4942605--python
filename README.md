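# citrinspec

Region-stratified *SLC25A13* allele-spectrum analysis for citrin-deficiency
cohorts.

Citrin deficiency (CD) is an autosomal recessive disorder caused by
biallelic mutations of *SLC25A13*; its neonatal cholestatic form (NICCD) is
diagnosed molecularly. Chinese CD cohorts show strong geographic structure
across the Yangtze boundary — a founder mutation (c.851_854del4) dominates
the south while the north carries a more heterogeneous allele pool — so
region-aware mutation screening panels matter. `citrinspec` is for clinical
geneticists and genetic epidemiologists who need to turn a table of
biallelic genotypes into:

- a parsed, registry-validated mutation catalogue (systematic cDNA names,
  legacy IVS aliases, cis-compound `[a; b]` alleles, undetected `?` alleles);
- north/border/south allele and genotype spectra with relative frequencies,
  diagnostic efficiency and screening-panel coverage;
- geographic frequency-difference tests: a 3×2 omnibus per variant
  (Pearson χ² when every expected count ≥ 5, otherwise a full-enumeration
  Freeman–Halton exact test), with Bonferroni pairwise post-hocs at
  α = 0.05/3;
- allelic-heterogeneity statistics: observed homozygosity and the gene
  identity **J = Σᵢ Xᵢ²** over allele frequencies Xᵢ = m/N, where each
  undetected allele is a unique allele of frequency 1/N;
- seeded synthetic cohorts under region-specific allele frequencies, for
  calibration and parameter-recovery studies.

The exact test uses the two-sided *probability method*: with both margins
fixed, the p-value is the sum of multivariate-hypergeometric point
probabilities of every table no more probable than the observed one.

## Worked example

The package ships a 154-patient NICCD cohort table and the published
regional frequency tables as plain-text fixtures.

```python
import citrinspec as cs

cohort = cs.load_packaged_cohort()          # 154 records
families = cs.dedupe_families(cohort)       # 151 families (3 sibling pairs)

spec = cs.build_allele_count_fixture()      # counts rebuilt from frequencies
pooled = cs.relative_frequencies(spec, "all")
print(round(pooled["c.851_854del4"], 2))    # 58.33
print(round(cs.diagnostic_efficiency(spec), 2))  # 98.86

sig = cs.significant_set(cs.scan_spectrum(spec))
print(len(sig))                              # 7

from citrinspec.homozygosity import theoretical_homozygosity
for region in ("north", "border", "south"):
    j = theoretical_homozygosity(spec, region).theoretical_J
    print(region, round(100 * j, 2))         # 15.24 / 24.31 / 44.81
```

`58.33` is the pooled relative frequency (%) of the dominant founder
deletion over 528 independent alleles; `98.86` the fraction of alleles on
which a mutation was identified; `7` the number of variants whose regional
frequencies differ significantly (omnibus p < 0.05); the final three
numbers are the theoretical homozygosity per region — the south's larger J
reflects the founder effect, the north's smaller J its higher allelic
heterogeneity.

The same surfaces are available from the shell:

```sh
citrinspec validate
citrinspec spectrum --format markdown
citrinspec geostats
citrinspec homozygosity
citrinspec simulate --seed 7 --n-families 500 --out cohort.tsv
citrinspec report-all --out-dir reports/
```

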