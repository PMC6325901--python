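# rohkit

Runs of homozygosity (ROH) — chromosomal segments where an individual's
two haplotypes carry no heterozygous genotype — are the genomic
footprint of inbreeding: long runs signal recent consanguinity, short
runs older coancestry, and runs of any length can expose recessive
deleterious alleles as homozygotes. `rohkit` is a toolkit for
fine-scale ROH analysis of dense SNP-array genotype panels (its design
point is canine panels with ~170k autosomal markers, one per ~12.8 kb),
aimed at population and conservation geneticists working with inbred
populations such as purebred dogs.

It provides, as a library plus a thin `rohkit` command-line tool:

* **Two ROH callers.**
  * A *scan* caller: find every maximal zero-heterozygote run spanning
    ≥ 500 kb, merge neighbouring runs separated by < 50 kb (tightly
    clustered heterozygotes between two runs are typically genotyping
    error or small CNVs), then drop merged tracts with fewer than 41
    array markers.
  * A *windowed* caller implementing the classic PLINK 1.07
    sliding-window algorithm with strict settings: 41-SNP windows, zero
    heterozygous and zero missing calls per window, per-SNP hit
    proportion ≥ 0.05, minimum 41 SNPs and 500 kb per segment, density
    and gap checks disabled.
* **Inbreeding coefficients.** F<sub>ROH</sub>(j) = Σ<sub>k</sub>
  length(ROH<sub>k</sub>) / L per individual, for autosomes and for
  chromosome X in females, with a marker-span or fixed assembly-length
  denominator L.
* **Recessive-disease enrichment.** Each observed *at-risk genotype* (a
  dog homozygous for a known recessive disease allele) is assigned the
  length class of the ROH containing its locus — sub-threshold
  (< 0.5 Mb, i.e. no called tract), short (0.5–2.5 Mb), medium
  (2.5–5 Mb) or long (> 5 Mb) — and compared with the average per-dog
  genome composition by class to give a relative risk per class,
  RR(c) = [atrisk%(c)/genome%(c)] / [atrisk%(sub)/genome%(sub)],
  plus a resampling null (1000 draws of matched size from the cohort's
  full tract set) for the cumulative tract-length curve.
* **Population summaries.** Per-breed ROH density maps (fraction of
  dogs covered at each marker position), ROH-island detection, and
  per-breed cumulative ROH-by-length curves.
* **Cohort QC.** Sliding-window LD pruning (`--indep-pairwise`-style,
  200 SNP window / 100 step / r² > 0.90) and method-of-moments
  relatedness (PI_HAT = P(IBD=2) + ½·P(IBD=1)) with greedy removal of
  pairs above 0.45.
* **A pedigree simulator with exact truth.** Synthetic genotype panels
  from consanguineous pedigree loops of configurable depth (full-sib
  F = 1/4, first-cousin F = 1/16, …), with crossovers tracked at exact
  base-pair resolution so every sample carries a tiling of truth
  autozygosity segments; recessive disease alleles can be planted on a
  single founder haplotype background, and genotyping error /
  missingness added after truth is recorded.

Genotypes are read and written in PLINK 1.x text `.ped`/`.map` format;
tract tables, truth segments, density tracks and disease tables are
plain TSV.

## Worked example

Simulate a small full-sib cohort (20 offspring, 4 × 32 Mb chromosomes
at one marker per 12.8 kb, no genotyping error), call ROH and compare
with the simulator's truth:

```python
import rohkit as rk

cfg = rk.SimConfig(seed=7, n_autosomes=4, autosome_length=32_000_000,
                   marker_spacing=12_800, x_length=None, n_offspring=20,
                   error_rate=0.0, missing_rate=0.0, pedigree="full_sib")
pool = rk.simulate_founders(cfg)
panel, truth = rk.simulate_pedigree(cfg, pool)

tracts = rk.scan_roh(panel)
print(tracts.head(4).to_string(index=False))

froh = rk.compute_froh(tracts, panel.markers, samples=panel.samples)
print("mean F_ROH: %.4f" % froh["froh"].mean())
print("detectable truth: %.4f" % rk.truth_restricted_fraction(truth, 500_000).mean())
print("precision (tracts >= 2.5 Mb): %.4f" % rk.base_precision(tracts, truth, 2_500_000))
```

Output:

```
sample chrom    start      end  length_bp  n_markers caller
 S0001     1  9030400 31993600   22963201       1795   SCAN
 S0002     1 17926400 21625600    3699201        290   SCAN
 S0003     1  1196800  9350400    8153601        638   SCAN
 S0003     1 28793600 31993600    3200001        251   SCAN
mean F_ROH: 0.2368
detectable truth: 0.2365
precision (tracts >= 2.5 Mb): 0.9987
```

Full-sib offspring have expected inbreeding F = 1/4; this cohort's
realized detectable autozygosity is 0.2365, the called mean
F<sub>ROH</sub> recovers it to within 0.0003, and 99.9% of the bases in
called tracts ≥ 2.5 Mb are truly autozygous.

The same pipeline is available from the shell:

```bash
rohkit simulate --config sim.yaml --ped cohort.ped --map cohort.map --truth truth.tsv
rohkit roh --ped cohort.ped --map cohort.map --caller scan --out tracts.tsv
rohkit froh --tracts tracts.tsv --map cohort.map --out froh.tsv
rohkit enrich --tracts tracts.tsv --disease disease.tsv --ped cohort.ped \
              --map cohort.map --out table.tsv --null-out envelope.tsv
```

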