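# binqtl

Bin-map genotyping and QTL analysis for low-coverage sequencing of
biparental plant populations.

When every line of a mapping population is sequenced at a fraction of 1x
coverage, individual SNP genotypes are too sparse and too noisy to use
directly.  `binqtl` implements the standard rescue: slide a window of ~15
*observed* SNPs along each chromosome, call each window to the parent whose
alleles dominate its reads, place recombination breakpoints at call
transitions, genotype 100-kb intervals, and merge intervals that no line in
the population separates into *recombination bins*.  Each bin becomes a
single virtual marker (at its physical midpoint) genotyped across the whole
population — an ultra-high-density, low-error marker set built from
ultra-low-coverage data.

On top of the bin map the package provides the full analysis chain used for
intermated doubled-haploid (DH) populations such as maize B73 x Mo17
intermated lines:

- **simulation** (`binqtl.simulate`): forward-in-time breeding-scheme
  simulator (F1 → F2 → *j*−2 generations of random intermating → DH or
  selfed finish) with Poisson crossovers on the cM scale, viability
  selection by rejection sampling, additive QTL phenotypes, and a
  Poisson/binomial low-coverage read-observation model;
- **SNP filtering** (`binqtl.snpfilter`): parental candidate-SNP retention
  rules (depth in [5, 100], mappability < 1.5, allele quality ≥ 20,
  homozygous-polymorphic, uniquely placed, no two candidates within 5 bp);
- **bin maps** (`binqtl.binmap`): window calling, breakpoint detection,
  interval genotyping, bin construction and bin-length summaries;
- **linkage maps** (`binqtl.linkmap`): two-point recombination fractions and
  LODs, single-linkage grouping (LOD ≥ 9), MST + 2-opt marker ordering and
  Kosambi map distances, d = 25 ln((1+2r)/(1−2r));
- **map expansion** (`binqtl.expansion`): the expected expansion factor
  α = j/2 + (2^i − 1)/2^i for a scheme with *j* total generations
  (including the two creating the F2) and *i* inbreeding generations
  (DH ⇒ i = 1, full selfing ⇒ i = ∞), and F2-scale map adjustment by
  dividing every interval by α;
- **segregation distortion** (`binqtl.distortion`): per-marker χ² =
  (n₁−n₂)²/(n₁+n₂) against 1:1 at P = 0.01 without multiple-testing
  correction, allele-frequency envelopes 0.5 ± z·√(0.25/n), distortion
  regions (SDRs), per-line genome-composition bias, and SDR–QTL
  effect-sign orientation;
- **QTL mapping** (`binqtl.qtl`): composite interval mapping by Haley–Knott
  regression with up to 10 stepwise cofactors, a 5-cM exclusion window,
  0.5-cM steps, LOD = (n/2)·log₁₀(RSS₀/RSS₁), a 2.5 LOD call threshold and
  2-LOD support intervals mapped to physical coordinates;
- **comparison** (`binqtl.compare`): physical-position imputation for legacy
  markers from regional Mb/cM rates, QTL interval overlap, gene
  colocalization;
- **map QC** (`binqtl.mapqc`): misassembly detection from double-crossover
  excess and linkage-guided segment relocation, identity-by-descent SNP
  verification against the bin map, and integrated multi-class marker maps.

## Worked example

The bundled demo simulates a 100-line Syn10-style DH population (j = 12,
two chromosomes, 10,000 SNPs, one additive QTL of effect +1.5 at
chr1:5 Mb, residual sd 2), observes it at 0.31x coverage with 1% read
error, and runs every stage:

```bash
binqtl pipeline --out demo_run
```

prints (abridged):

```json
{
  "stages": {
    "binmap":    {"n_bins": 156, "n_breakpoints": 556},
    "linkmap":   {"n_groups": 2, "total_cm": 555.2, "mean_spacing_cm": 3.6},
    "expansion": {"alpha_expected": 6.5, "observed_cm": 555.2,
                  "adjusted_cm": 85.4, "alpha_observed": 6.5},
    "distortion": {"n_significant": 23, "pct_significant": 14.74, "n_sdrs": 2},
    "qtl":       {"n_qtls": 1}
  }
}
```

Reading the numbers: 100 lines at 0.31x yield 556 recombination
breakpoints, merged into 156 population bins; the bin-marker linkage map
totals 555.2 cM on the observed scale — the j = 12 intermated-DH scheme
expands the 90-cM F2 genome by the expected factor 6.5 — and dividing each
interval by 6.5 gives the 85.4-cM F2-scale map.  The CIM scan finds the
one simulated QTL: `demo_run/qtl_records.tsv` reports a peak of LOD 12.5
with additive effect +1.60 (truth +1.5), R² = 43.7%, and a 2-LOD support
interval of 4.78–5.01 Mb containing the true locus at 5.0 Mb.

Each stage is also available as a subcommand over TSV artifacts
(`binqtl filter-snps`, `binqtl binmap`, `binqtl linkmap`, `binqtl adjust`,
`binqtl distort`, `binqtl qtl`) or as plain library calls.

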