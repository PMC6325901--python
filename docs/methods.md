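# Methods

This note documents the models and procedures implemented in `rohkit`,
the parameter choices that matter, and the package's own design
decisions where the underlying methods are under-specified.

## Conventions

All coordinates are 1-based, inclusive, physical base pairs; the length
of any interval is `end − start + 1`. Genetic positions are carried
through the `.map` files but unused: every threshold in the pipeline is
physical. Genotype calls are stored as int8 codes (HOM_A 0, HET 1,
HOM_B 2, MISSING −1); because ROH calling only distinguishes
heterozygous from non-heterozygous calls, allele labelling is arbitrary
but stable — the first allele observed at a marker is A. Chromosomes
are the 38 dog autosomes plus X by default; synthetic genomes may use
any subset.

Chromosome X in males is hemizygous, so X "homozygosity" carries no
inbreeding signal: male X HET calls are flagged (never silently fixed),
males are excluded from X-scope F_ROH and per-breed X curves, and a
pseudoautosomal interval can be supplied to exempt/exclude the PAR.

## The scan ROH caller

Three steps per sample and chromosome:

1. **Run finding.** Maximal runs of consecutive markers containing no
   HET call; a run qualifies if its first-to-last marker span is
   ≥ 500 kb. The boundary is inclusive (≥): a run spanning exactly
   500,000 bp is kept. Under the default `BREAK` missing policy a
   missing call also terminates a run; `IGNORE` treats it as
   homozygous. The choice is moot for imputed (missing-free) data but
   matters for raw genotypes, where `BREAK` is the conservative
   default.
2. **Gap merging.** Neighbouring runs separated by strictly less than
   50 kb (`next.start − prev.end < 50,000`) are unioned, transitively.
   One or a few tightly clustered heterozygous calls between two long
   runs are characteristic of genotyping error or small CNVs
   (deletions/duplications mostly < 50 kb produce clustered
   heterozygote calls at the markers inside them); bridging them
   recovers long tracts that would otherwise be split. A sensitivity
   variant doubles the gap to 100 kb; called coverage is monotone
   non-decreasing in this parameter (tested).
3. **Marker-count filter.** Merged tracts containing fewer than 41
   array markers are dropped, guarding against spurious calls in
   marker-poor regions. The count includes *all* markers inside the
   merged span — heterozygous markers inside merged gaps included —
   since the filter is about marker support, not homozygosity.

Tract endpoints are the first/last marker positions of the merged span,
not midpoints to flanking heterozygotes, so reported lengths are
reproducible functions of the marker grid. The caller is implemented
directly from this definition rather than by emulating any particular
tool's windowed internals; its output is verified against an O(n²)
brute-force enumerate-merge-filter oracle on 1000 random chromosomes.

## The windowed ROH caller

A faithful reimplementation of the documented PLINK 1.07 algorithm at
strict settings: slide 41-SNP windows along each chromosome; a window
is a *hit* if it contains ≤ 0 HET and ≤ 0 MISSING calls; each SNP's hit
proportion is (hit windows containing it) / (windows containing it),
and the SNP qualifies if that proportion is ≥ 0.05. Maximal stretches
of qualifying SNPs, trimmed to their outermost homozygous SNPs, are
reported if they contain ≥ 41 SNPs and span ≥ 500 kb. The density
(kb/SNP) and internal-gap checks are explicitly disabled (set to `None`
in `WindowParams`); enabling them is unsupported rather than silently
defaulted. PLINK's end-trimming behaviour is under-documented, so the
caller is verified against a second, independently coded loop reference
of the same published description rather than against PLINK binaries.

With these settings a single heterozygote splits a long homozygous
region into two tracts (no window containing the HET is a hit), which
is why the scan caller's gap merging tends to be slightly more
sensitive for long tracts — the behaviour the enrichment analysis
exploits.

## F_ROH

F_ROH(j) = Σ_k length(ROH_k) / L. Two denominators are supported
because "total genome length" is ambiguous on an array: `MARKER_SPAN`
(default) sums per-chromosome first-to-last marker spans — a
self-contained choice matching the region the caller can actually see —
and `FIXED` accepts assembly lengths (e.g. canFam3.1) for comparability
across arrays. Tracts from different callers cannot be mixed in one
computation (hard error). F_ROH is monotone non-decreasing as the
minimum tract length entering the sum decreases, and the autosomal and
X scopes use disjoint tract sets.

## Disease-genotype enrichment

Tract length classes partition [0, ∞): sub-threshold < 0.5 Mb (the
caller's detection limit, equivalently "not in a called ROH"), short
[0.5, 2.5) Mb, medium [2.5, 5) Mb, long ≥ 5 Mb. The interior bounds are
left-closed/right-open; a 2,500,000 bp tract is medium. This is a
documented convention — the class labels are usually quoted without
inclusivity.

Per-dog genome composition by class is summed tract length / L with the
sub-threshold fraction as the complement; cohort values are the
*unweighted per-dog average* (not pooled tract totals), matching a
"fraction of genome averaged across dogs" reading. Each at-risk
genotype takes the class of the tract containing its locus in that
sample, or sub-threshold if none. The relative risk of class c is the
at-risk density per unit genome fraction, baselined on sub-threshold:

    RR(c) = [atrisk%(c) / genome%(c)] / [atrisk%(sub) / genome%(sub)]

so RR(sub) = 1 by construction and RR is invariant to common rescaling
of the genome fractions. No closed-form RR formula is printed alongside
the published per-class percentages; this definition reproduces all six
published relative risks from the published input percentages within
2% (the residual is rounding of the printed inputs), which is the
package's acceptance check for it. If no at-risk genotype falls outside
ROH the baseline is zero and enrichment is reported as infinite; a
class with zero genome fraction has undefined RR (NaN).

**Resampling null.** To ask whether the k tracts containing disease
homozygotes are a random sample of the cohort's tracts, 1000 sets of k
tracts are drawn uniformly *without replacement* from the full tract
set ("same sample size, sampled randomly" read as subsampling the
observed set), and each set's cumulative curve — fraction of tracts
with length ≥ x, tracts ordered longest to shortest — is evaluated on a
common grid. The envelope records the pointwise min/max and quantiles;
an observed curve "exits" if it leaves the min/max band anywhere.
Count-based curves are the default; a length-weighted variant is
available by flag since the published curves do not state which
weighting was used. No formal p-value is attached (none is defined for
the min/max band); the test is a positive/negative control comparison.

## Breed-level summaries

ROH density for a breed is, at each evaluation position, the exact
fraction of sampled dogs with a tract covering that position. The
default evaluation grid is the marker positions themselves — no
coverage is invented between markers. ROH islands are maximal intervals
with density ≥ 0.95 over ≥ 500 kb (both package parameters; no
published values exist for them). The integral of density over the grid
approximates mean per-dog ROH coverage, a consistency check against
F_ROH up to grid discretization (tested). Per-breed cumulative
ROH-by-length curves reuse the enrichment module's curve; the X-scope
variant uses females only and skips breeds without females.

## Cohort QC

**LD pruning** follows the `--indep-pairwise 200 100 0.90` scheme:
within 200-SNP windows advancing by 100 SNPs, while any retained pair
has genotype-dosage r² > 0.90, one member is removed. r² is the squared
Pearson correlation of 0/1/2 allele counts over pairwise-complete
samples (unphased semantics); monomorphic markers have undefined r²,
treated as 0, so they are never removed for LD. The removal rule —
drop the lower-MAF member, tie → later map position — is a documented
deterministic choice; pruning is idempotent and verified against an
independent greedy oracle on small panels.

**Relatedness** uses the Purcell et al. (2007) method-of-moments IBD
estimator: per pair, IBS class counts (IBS = 2 − |dosage difference|)
over non-missing informative markers are equated to their expectations
under IBD 0/1/2 given panel allele frequencies and solved sequentially
for P(IBD=0), P(IBD=1), P(IBD=2); estimates are clamped to [0, 1] and
renormalized, and PI_HAT = P(IBD=2) + ½·P(IBD=1). The finite-sample
allele-frequency correction of the original estimator is omitted — at
panel sizes of tens of samples and thousands of markers the bias is
well inside the Monte-Carlo tolerance the tests use (self-pair 1,
parent-offspring ≈ 0.5, unrelated ≈ 0). Pairs with fewer than 100
informative markers are flagged low-confidence. Relative removal at
PI_HAT > 0.45 drops the sample participating in the most over-threshold
pairs, ties broken by lexicographic id, until no pair remains — a
deterministic, near-minimal rule; published pipelines state only that
flagged pairs "were used to remove" samples.

## The synthetic-data generator

The generator emulates the data regime the pipeline targets: a dense
array (default 38 × 58 Mb autosomes at one marker per 12.8 kb ≈ 172k
markers, plus a 124 Mb X at one per 28.2 kb), genotyping error 10⁻⁴
(arrays are concordance-filtered above 99.99%) and missingness 10⁻³.
Markers are evenly spaced; real arrays are irregular, which mainly
affects the marker-count filter in marker-poor regions.

* **Founders.** Per-marker allele frequencies are Beta(a, b) (default
  a = b = 1, i.e. uniform — mean heterozygosity 1/3, so chance zero-het
  runs of ≥ 39 markers essentially never occur in outbred samples); an
  optional first-order Markov copy probability between adjacent markers
  is a crude LD stand-in, default off. No quantitative LD model of the
  real array is claimed.
* **Pedigree loops.** A loop of depth d mates two lines descending from
  a common ancestor couple after d generations of outcrossing: depth 0
  is a full-sib mating (offspring F = 1/4), depth 1 first cousins
  (F = 1/16), generally F = (1/4)^(d+1). Mixtures of depths model
  cohorts with heterogeneous inbreeding histories. Meiosis places
  Poisson(length_cM/100) crossovers uniformly in genetic distance with
  a constant 1 cM/Mb rate (no interference, no sex-specific maps), and
  every transmitted chromosome is tracked as exact bp breakpoints over
  founder haplotypes, so truth autozygosity — both homologs descending
  from the same founder haplotype copy — is recorded exactly and tiles
  each chromosome. Error is applied after truth recording.
* **Disease alleles.** A planted recessive allele lives on exactly one
  founder haplotype lineage; additional carriers (to reach the
  configured carrier frequency) are literal copies of the origin over a
  ±3 Mb window — the shared background a single ancestral mutation
  rides on — and the copied window carries the origin's lineage id, so
  a homozygote formed from two carrier copies is genuinely autozygous
  there. A second origin at a planted locus is rejected. The 3 Mb
  half-window corresponds to the expected shared haplotype around a
  variant some tens of generations old at 1 cM/Mb. A *neutral* control
  allele can instead be planted on independently chosen carriers with
  no background copying — homozygotes then arise by chance pairing of
  unrelated haplotypes.
* **Chromosome X** is transmitted like an autosome through the loop (a
  simplification — male intermediates are not forced hemizygous); final
  male offspring receive a single maternal X reported as homozygous
  calls, and no X truth is emitted for males.

What passing tests on these cohorts shows: the callers recover
pedigree-scale autozygosity from clean dense genotypes, and the
enrichment machinery separates descent-driven from chance homozygosity.
What it does not show: robustness to real-array artifacts (irregular
marker spacing, CNV-dense regions, breed-specific LD, phasing/
imputation error), which only real panels can probe.

## The control experiment for the resampling null

The packaged positive/negative control (`rohkit.experiments.
enrichment_control`) simulates a 300-offspring cohort over 8 × 32 Mb
chromosomes with loop depths mixed as 10% full-sib / 35% first-cousin /
55% second-cousin — an inbred cohort whose tract pool is dominated by
shorter tracts, with disease homozygotes arising preferentially through
the shallower loops. The disease allele is planted at carrier frequency
0.30 (single origin); the neutral allele at 0.10 with independent
origins. The frequencies reflect the regimes being contrasted: a
disease variant common enough in the (ascertained, heavily inbred)
cohort to yield tens of homozygotes through its shared background,
versus a rare neutral variant whose homozygotes — requiring two
independent copies — are few. The observed disease-tract curve is
expected to exit the 1000-replicate envelope; the neutral curve to stay
inside. Note an intrinsic asymmetry of this test: tracts containing any
*fixed* position are a size-biased sample of tracts, so the uniform-
draw null is mildly anti-conservative for position-stabbed tract sets;
with the small homozygote counts a rare neutral variant produces, the
envelope is wide enough that this bias is immaterial, but a common
neutral variant (many homozygotes) can spuriously exit. The acceptance
tests therefore require the disease curve to exit in ≥ 90% of 20 seeds
and the neutral curve to stay inside in ≥ 95%.

## Problem sizes

The test-suite and acceptance-script simulations use scaled problem
sizes chosen for single-core runtimes of seconds to a couple of
minutes while keeping ample statistical resolution: truth-recovery runs
on 200 full-sib offspring over 30 × 64 Mb chromosomes at full array
density (150k markers); pedigree-F checks use sparse marker grids
(truth geometry is marker-free); the caller-vs-oracle sweeps use 1000
random chromosomes of ≤ 200 markers; the control experiment uses the
cohort described above across 10–20 seeds.

## Known limitations

* The windowed caller is verified against an independent
  reimplementation of the documented algorithm, not against PLINK
  binaries; corner cases of PLINK's undocumented trimming may differ.
* The simulator has no coalescent background, selection, realistic
  recombination maps, or breed demography; its LD knob is a stand-in.
* PI_HAT omits the finite-sample frequency correction (see above).
* The resampling null attaches no formal p-value; it is a control
  comparison, and is mildly anti-conservative for large position-
  stabbed samples (see the control-experiment section).
* ROH islands on real data (e.g. sweep loci) can only be emulated here
  by planting common tracts; island threshold and span are package
  parameters with no published counterpart.
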