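# Methods

This note records the models behind `binqtl`, the defaults that matter, the
numerical choices, and what the synthetic validation does and does not show.

## Breeding-scheme simulator

Populations are simulated forward in time as ancestry mosaics: a haplotype
is a list of segments (end position, parental origin) tiling each
chromosome.  Meiosis draws a Poisson number of crossovers per chromosome
with mean equal to the F2-scale genetic length in Morgans, places them
uniformly on the cM scale, and maps them to bp through the genome's
monotone piecewise-linear bp↔cM function.  There is no crossover
interference (Haldane model) and no obligate chiasma; the map-expansion
theory the package tests is itself interference-free, so simulator and
theory share assumptions.  Mutation is ignored: all polymorphism is
parental, which is exactly the premise of biparental bin mapping.

The scheme parameter `j` counts generations *including the two that create
the F2*; `j−2` further generations of random intermating follow (random
pairing without selfing, constant census).  The census defaults to the
number of extracted lines but is configurable (`n_census`): the published
descriptions of such populations do not state the intermating census, and
the expansion formula below is an infinite-population expectation, so
closure experiments use a census several times larger than the line count
to keep co-ancestry from deflating observed recombination (measured effect
at census = 500: about −2% on adjacent-marker discordance).  A DH finish
draws one gamete per selected individual and doubles it; a selfed finish
runs `i` generations of single-seed descent (`i = inf` is capped at 30
generations, residual heterozygosity 2⁻³⁰).

Viability selection is rejection sampling at the gamete or zygote stage
with per-allele relative fitnesses (at least one allele has fitness 1).
Phenotypes are purely additive, y = Σ a_q·x_q + N(0, σ²) with x ∈ {+1
(parent 1), −1}; epistasis and dominance are out of scope.  All randomness
flows from a single seed.

The read-observation model is per line × SNP: read count ~
Poisson(coverage); each read reports the line's true allele with
probability 1 − e (heterozygous sites transmit either allele with
probability ½ first).  It does not model reference bias, mappability
variation, indels, or correlated coverage along the genome — conclusions
from synthetic data are about the calling/binning algorithm under ideal
sampling noise, not about alignment artifacts.

## Window calling and bins

The sliding window holds a fixed count (default 15) of *observed* SNPs, so
its physical span adapts to the line's read density — the practical reading
of a "dynamic" window.  A window is called to parent 1 when the parent-1
read fraction is ≥ h (default 0.7), to parent 2 when ≤ 1−h.  Heterozygous
calls require that ≥ 30% of the window's SNPs individually show *both*
parental alleles: a mixture of pure SNPs is what a breakpoint-spanning
window looks like and is left Unknown, never called H.  (An earlier
read-count-ratio heterozygosity rule misclassified breakpoint windows at
deep coverage; intra-SNP evidence is the discriminating signal.)  Isolated
single-window calls disagreeing with both flanking runs are smoothed away
(configurable) to suppress error-driven double crossovers.

Breakpoints fall at the midpoint between the last SNP of the left run's
defining window span and the first SNP of the right run's; with overlapping
windows this lands inside the transition zone, and at 0.31x coverage with
60 SNPs per 100 kb the localization error is typically under 30 kb.
Each 100-kb grid interval takes the call covering its midpoint (ties at an
exact breakpoint go to the left call); intervals beyond the outermost
informative window are Unknown.  Population bins merge adjacent intervals
between which no line changes genotype; Unknown stretches are tolerated
inside bins and forward-filled when locating change points, so a line
reading A·U·B splits at the B side.  Bin markers sit at the floor midpoint
of each bin.

## Linkage maps

For DH/RIL-coded matrices the recombination fraction between two markers is
the discordance fraction over lines informative for both (heterozygous
calls are treated as missing); r̂ is truncated to [1/(2n), 0.5] and the LOD
is evaluated at the untruncated MLE with the 0·log 0 = 0 convention.
Grouping is single-linkage on the LOD ≥ 9 graph.  Ordering uses a
minimum-spanning-tree backbone (DFS from a diameter endpoint) refined by
2-opt on the open path; orientation follows ascending physical position.
The multipoint Gibbs-sampling/simulated-annealing re-estimation used by
commercial mapping software is intentionally not reproduced: the map
contract (ordered markers with cM positions) is met by summing Kosambi
distances of adjacent r̂, and the two-point estimates at bin-map marker
densities are already near-saturated.  Adjacent r̂ is capped at 0.49 before
the Kosambi transform to keep distances finite.

Two practical limits follow from two-point estimation.  Local order is
statistically undetermined when adjacent markers show ~0–3 recombinant
lines, so validation uses spacings with ≥ ~5 expected recombinants.  And
because the simulator composes distances by Haldane while the map uses
Kosambi, summed map length underestimates truth by roughly the per-interval
discordance R (≈ 6% at R = 0.06, ≈ 1% at R = 0.01); expansion-closure
experiments therefore use markers dense on the *expanded* scale (~1 marker
per observed cM), where the bias is second-order.

## Map expansion

Expected factor: α = j/2 + (2^i − 1)/2^i, with i = ∞ giving 1.  The first
term counts accumulated intermating meioses; the second is the fraction of
residual heterozygosity removed by i selfing generations (a DH finish is
i = 1).  Printed forms of this equation sometimes carry 2^j in the
numerator of the second term; only the form above reproduces the canonical
values α(12, 1) = 6.5 and α(6, ∞) = 4, and it is the one implemented.
F2-scale adjustment divides every marker interval by α, preserving order
and proportions exactly; the observed factor is reported as the
observed/adjusted quotient rounded half-up to two decimals.  The exact
per-interval recombination-fraction transformation for intermated RILs
(used historically for selfed intermated populations) is not reproduced;
users may supply an externally adjusted map instead.

## Segregation distortion

Per marker, χ² = (n₁ − n₂)²/(n₁ + n₂) on informative lines, significant at
the 0.01 critical value 6.635, deliberately without continuity correction
and without multiple-testing correction — linked markers are dependent and
the scan is descriptive.  Markers with fewer than 50 informative lines
(configurable) are flagged untested.  SDRs are maximal runs of ≥ 3
consecutively significant markers sharing a direction, within a
chromosome; the run length and the absence of gap tolerance are package
choices (the underlying publications do not define SDR boundaries).  The
no-distortion envelope is 0.5 ± z₍₁₊c₎/₂·√(0.25/n).  Orientation analysis
calls an SDR–QTL overlap concordant when distortion favors the parent
whose allele decreases the trait.

## Composite interval mapping

The scan regresses phenotype on the Haley–Knott conditional expectation of
the coded QTL genotype given the immediate flanking markers (recombination
fractions from inverse Kosambi, composed without interference; one missing
flank falls back to single-marker decay, two missing give 0).  Background
cofactors are chosen by forward/backward stepwise regression capped at 10,
then refined by equal-size swap passes; cofactors within 5 cM of the test
position are excluded from both the null and alternative fits; LOD =
(n/2)·log₁₀(RSS₀/RSS₁), capped at 50 for singular fits.  Missing marker
genotypes are mean-imputed for the cofactor design only.

Two deliberate departures from textbook CIM, both calibration-driven:

1. **Family-wise stepwise thresholds.**  The enter/remove levels (defaults
   0.01/0.02) are divided by the number of candidate markers.  With
   per-test levels, a chance cofactor enters in ~25% of null scans and is
   re-detected at LOD ≈ 0.217·F when the window excludes it, so a
   genome-wide null scan would cross LOD 2.5 in ~13% of replicates;
   family-wise gating restores the ~5% genome-wide null rate while true
   QTL (partial F ≫ threshold) are unaffected.
2. **Peak-conditional support intervals.**  The 2-LOD support region of a
   detected peak is traced on a profile whose cofactor context is frozen
   at the peak (a standard profile-likelihood region), not on the raw CIM
   profile, whose cofactor-window edges truncate the region independent of
   evidence.  In simulation (a = 1, σ = 2, n = 194) raw-profile intervals
   cover the true locus in ~87% of replicates; peak-conditional intervals
   in ~96%, matching plain interval mapping.  Detection, peaks, effects
   and R² still come from the standard windowed CIM profile.

Support-interval endpoints are interpolated linearly between scan steps and
mapped to bp through the marker map.  The scan runs on the observed
(expanded) map scale.

## QTL comparison and map QC

Physical positions of legacy markers lacking coordinates are imputed from
the regional Mb/cM rate between flanking anchor markers, extrapolating with
the nearest region's rate and clipping to chromosome bounds.  QTL interval
overlap is physical-span intersection on the same chromosome (same trait
by default; a flag relaxes this), reported with span Jaccard.
Boundary-straddling genes are reported with a partial flag rather than
dropped.

Misassembly detection counts, per bin, the lines in which the bin lies
inside a constant-genotype run of physical span ≤ 2 Mb flanked on both
sides by a different genotype — attributing the event to every bin of the
run so multi-bin misplaced blocks are caught, not just their edges.  Bins
exceeding max(5 × genome-wide median, 10% of lines) form candidate
segments of ≥ 2 bins; the 10%-of-lines floor guards against the degenerate
5×0 threshold on clean maps and sits an order of magnitude above the real
double-crossover background and well below a misplaced block's ~50%-of-
lines signature.  Flagged-run edges with counts below 60% of the run
maximum are trimmed: bins adjacent to a misplaced block inherit elevated
counts (ordinary segments ending at the block get spurious flanks) but
stay far below the block's own signal.  Relocation finds the best-linked
bin by two-point LOD of the segment's per-line consensus genotype, then
chooses the insertion point within ±10 bins by minimizing the total
double-crossover count — the same quantity that justifies the move — and
accepts only strict reductions.

IBD verification assigns each covered SNP the expected parental allele of
its containing bin in each line (H/U bins contribute nothing); the
majority read allele verifies or contradicts it, and SNPs verified at
least once are retained (a strict mode excludes any contradiction).  Note
that SNPs sitting on the far side of a within-bin crossover legitimately
contradict the bin consensus even with perfect reads (~2% of SNPs in the
validation runs); retention-by-any-verification absorbs this.

## Validation experiment design

The test suite pins experiments at what a maize-like study would see,
scaled to desk runtimes:

- **Expansion closure**: 2 chromosomes × 150 F2-cM, 500 DH lines from a
  census of 2,000, markers at 1 per expanded cM; recovered factor
  6.35–6.68 across seeds against the expected 6.5.
- **Bin-map recovery**: 20 Mb / 5 F2-cM, 280 lines, 60 SNPs per 100 kb,
  0.31x coverage, 1% error, recombination suppressed in the terminal
  200 kb so every crossover has flanking marker support; ≥ 99% of
  line × bin genotypes match truth and all crossovers localize within
  100 kb.  The low crossover density is deliberate: two true crossovers
  < ~50 kb apart are physically invisible at this coverage.
- **CIM**: markers ~1.5 observed cM apart (the density bin maps actually
  deliver); a genome of ~1–1.5 observed Morgans for the null calibration.
  With much coarser markers the 5-cM window cannot reach a cofactor one
  marker off the QTL and localization degrades.
- **SDR recovery**: j = 4 with census 2,000 and gamete-stage fitness
  1 vs 0.5; the larger census keeps drift-born false SDRs rare.
- **Misassembly**: 2 × 10 Mb at 25 F2-cM, a 4 × 100-kb block moved across
  chromosomes; at much higher cM/Mb real short double-crossover segments
  swamp the baseline, at much lower density single-bin linkage cannot
  resolve the insertion point.

These are synthetic-data results: they demonstrate the algorithms under
the stated sampling models, not robustness to alignment bias, segmental
duplication, or genotyping batch effects in real sequencing data.
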