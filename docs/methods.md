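# Methods

This note documents the models, formulas and numerical conventions behind
`felinepop`, the assumptions of its synthetic breed-panel generator, and the
design decisions taken where more than one reasonable choice existed.

## Data model

A `GenotypeDataset` is a samples × markers matrix of biallelic genotype
calls coded 0 (homozygous `allele_a`), 1 (heterozygous), 2 (homozygous
`allele_b`), −1 (missing), together with a marker map (cat chromosomes
A1–A3, B1–B4, C1–C2, D1–D4, E1–E3, F1–F2, X, plus "unknown" for unplaced
markers) and a sample-metadata table (sex, population, sire/dam, phenotype,
replicate group). Coordinates are 1-based; all region queries are inclusive
on both ends. Markers are sorted by (chromosome, position) after loading.
Numeric PLINK chromosome codes (1–18, 19 = X, 0/20 = unknown) are accepted
on input and translated to cat names.

On the X chromosome males are hemizygous: their calls are homozygous-coded
(0 or 2), they contribute a single allele to frequency computations, and a
heterozygous male X call is treated as an assay artifact — it is excluded
from allele counting and from the trio transmission test, and is instead
the signal used to detect pseudoautosomal (PAR) markers.

PLINK PED/MAP and BED/BIM/FAM (SNP-major, magic bytes `6c 1b 01`) are read
and written natively. The PED dialect cannot record which allele is
`allele_a`, so `write_dataset` emits an `.alleles.tsv` sidecar that the
loader honors; without it, `allele_a` is the first allele observed in file
order (deterministic, but a round trip through a file written by other
software may relabel alleles). Sample metadata beyond the FAM columns
travels in a `.meta.tsv` sidecar.

## Synthetic breed panels

The generator produces the statistical structure that the downstream
analyses assume, not a demographically faithful cat history. Its model:

* **Shared ancestral pool.** Per-marker ancestral allele frequencies are
  drawn from a Beta(0.8, 0.8) spectrum truncated to MAF ≥ 0.01 (a realistic
  U-shaped spectrum). All populations draw founder haplotypes from this
  pool, so they share alleles but differ by drift.
* **Breed founding.** Each population starts from `H` diploid founders
  (`founder_pool_size`) whose haplotypes are drawn site-independently from
  the pool; passes a bottleneck of `bottleneck_generations` (default 5) at
  census 2H, during which drift builds breed-specific LD in proportion to
  1/H; then expands to `expansion_census` (default 300) for the remaining
  generations, during which recombination erodes LD without regenerating it
  and sampled individuals end up only distantly related. The default of 60
  total generations matches breeds founded roughly a century ago at a
  feline generation time of a few years. This bottleneck–expansion shape is
  what makes the extent-of-LD statistic decay within the 4 Mb analysis
  window: a census locked to 2H throughout would keep sample relatedness —
  and hence the long-range r² floor — permanently above the random-bred
  reference.
* **Recombination.** Poisson crossovers per chromosome per meiosis at
  1 × 10⁻⁸ per bp (≈1 cM/Mb), placed uniformly; a crossover landing exactly
  on a marker assigns that marker to the left segment.
* **X chromosome.** One linkage group with a terminal pseudoautosomal
  segment (`par_fraction`, default 2% of the X map) in which males are
  diploid. Internally a male's "paternal X" outside the PAR is overwritten
  with his maternal haplotype at birth, which makes every downstream rule
  (hemizygous emission, sons inheriting only the dam's X, PAR recombination
  through the male line) fall out of ordinary diploid bookkeeping.
* **Marker map.** Inter-marker gaps are exponential with mean `spacing_bp`
  (default 37,741 bp, the array's mean spacing); per-chromosome counts
  default to the ~63K array apportioned by chromosome size, and desk-scale
  runs pass smaller maps.
* **Artifacts.** Four channels, applied after breeding: i.i.d. miscalls at
  `error_rate` (default 0.07%, so a replicate pair disagrees at
  ≈ 2e(1−e) ≈ 0.14% of compared genotypes); i.i.d. missingness at
  `missing_rate` (default 1%, matching a ~99% call-rate array); a small
  subpopulation of systematically failing assays (`bad_marker_rate`,
  default 1% of markers, with 20% missingness — these are what the
  10%-missingness screen catches); and a few per mille of systematically
  mis-calling assays (`error_marker_rate`, default 0.4%, with 20% miscalls
  — these are what the trio transmission screen catches). The two
  systematic channels are active only when their corresponding random
  channel is non-zero, so `missing_rate = error_rate = 0` makes
  `inject_artifacts` the identity.
* **Trios and replicates.** `simulate_trios` breeds offspring from panel
  parents by true Mendelian transmission (86 trios by default); replicate
  samples are duplicated individuals with independent artifact draws and a
  shared `replicate_group` label (20 by default).
* **Traits.** Autosomal-recessive (affected ⇔ homozygous `allele_b`, with
  penetrance) and X-linked (hemizygous carrier males, homozygous females).
  A causal variant can be withheld from the emitted map (`on_array=False`)
  for indirect-mapping scenarios.

A fixed seed yields a byte-identical dataset. What the generator does *not*
emulate: mutation during breeding, migration and admixture, selection
sweeps, intensity-level (A/B signal) artifacts, batch effects, and real
colony pedigree depth. Passing tests therefore demonstrate the correctness
and calibration of the statistics under a drift-recombination model, not
robustness to every failure mode of real array data.

## Quality control

* **Call rates.** A marker fails when its missing fraction is ≥ 10%; a
  sample passes at a call rate ≥ 90%. Both boundaries are inclusive,
  following the study's wording rather than PLINK's strictly-greater
  `--geno`; the missing fraction is computed directly from missing counts
  (not as 1 − rate) so the 10% boundary is float-exact.
* **Mendelian errors.** A trio × marker test is an error iff the child
  genotype is impossible under biallelic transmission (12 of the 27 ordered
  genotype combinations). The denominator at each marker is the number of
  trios with all required genotypes present. On X, sons are tested against
  the dam only (heterozygous sons are routed to the PAR check instead), and
  daughters are tested with the sire contributing his single hemizygous
  allele (heterozygous sires are skipped). Markers at ≥ 10% errors are
  flagged; errors are attributed to the marker, not apportioned among trio
  members, and per-trio rates use the same numerator.
* **PAR detection.** Per X marker, the fraction of heterozygous males among
  males with calls; flagged at ≥ 10%.
* **Replicate concordance.** Discordant / jointly-called genotypes per
  pair, reported on all markers and after caller-specified marker removals
  (the study's three-way reporting: all, post-call-rate, post-Mendelian).
* **Exclusions.** The union of low-call and Mendelian-flagged markers with
  reason codes LOW_CALL / MENDEL / BOTH; low-call markers are dropped from
  the analysis set while Mendelian-flagged markers are retained but
  reassigned to chromosome "unknown" (parked for potential future use, as
  in the study), which removes them from all autosomal analyses.

## Diversity summaries

Allele frequencies count two alleles per diploid call and one per
hemizygous male X call. MAF = min(p, 1−p); a marker is monomorphic iff
MAF = 0 among counted alleles (all-missing markers are reported as NaN, not
monomorphic). Per individual, over non-missing autosomal markers *L*:

    H_O  = het count / L
    E_hom = Σ_j [ 1 − 2 p_j (1 − p_j) · 2n_j / (2n_j − 1) ]
    F    = (O_hom − E_hom) / (L − E_hom)

with the PLINK-style small-sample correction 2n/(2n−1) (n_j = diploid
sample count at marker j); F is NaN when L = E_hom. X markers are excluded
from H_O and F. Two dataset-level MAF aggregations are exposed: pooling all
samples then averaging per-marker MAF, and the mean of per-population mean
MAFs — drifted populations each lose variation that pooling recovers, so
the pooled figure is systematically the larger.

## Relatedness and structure

* **DST** = (IBS2 + 0.5·IBS1)/N over jointly non-missing autosomal markers.
* **PI_HAT** is the method-of-moments IBD estimator: P(IBS | IBD = z) is
  computed per marker from pooled allele counts using without-replacement
  (falling-factorial) expectations, summed over each pair's jointly called
  markers; the moment equations are solved for P(IBD = 0, 1, 2), clamped to
  [0, 1] and renormalized; PI_HAT = P(2) + P(1)/2. Frequencies are
  recomputed on the sample set being analyzed. Digit parity with any
  particular PLINK build is not claimed; the estimator is validated by
  pedigree recovery (duplicates ≈ 1, parent–offspring ≈ 0.5).
* **MDS** is Torgerson double-centering of squared distances (distance =
  1 − DST), eigendecomposition, top-k components scaled by √eigenvalue,
  with a deterministic sign convention (the largest-magnitude loading of
  each component is positive). Negative eigenvalues are reported, never
  truncated; missing pairs are imputed with the mean distance under a
  warning.
* **Unrelated selection** is greedy: repeatedly drop the sample with the
  largest mean PI_HAT to the remaining set (ties: larger max PI_HAT, then
  the lexicographically larger id). The exhaustive optimum is intractable
  and the original study does not state its algorithm.
* **Population circles**: center = component means; radius = the larger of
  the two components' sample standard deviations (ddof = 1; 0 for
  singletons).
* **Strata fallback**: complete-linkage clustering on 1 − DST cut at a
  fixed height, for use when population labels are unavailable. The
  pairwise-population-concordance clustering used by the original study is
  not reimplemented; population labels are the default strata.

## Linkage disequilibrium

Two-locus haplotype frequencies are estimated from unphased genotypes by
EM: all genotype classes except the double heterozygote contribute known
haplotypes; the double heterozygote's two phasings are weighted by their
current likelihood. The EM is initialized at linkage equilibrium, runs
vectorized over all marker pairs with an active set (converged pairs stop
iterating), and stops at a max absolute frequency change < 1e-10 or 1,000
iterations; the two-locus likelihood has a single interior optimum almost
everywhere, so restarts are unnecessary. D = p_AB − p_A p_B and
r² = D²/(p_A(1−p_A)p_B(1−p_B)).

Pairs are restricted to same-chromosome autosomal markers with MAF ≥ 0.05
within the analyzed population, at distances up to 4 Mb. Decay curves
average r² in half-open 50-Kb bins [lo, hi); a [0, 50 Kb) bin is retained
for plotting but never enters the extent determination.

**Extent of LD.** The threshold is the maximum bin mean of a reference
(random-bred) population's curve. Scanning the 50 Kb–4 Mb bins from the
first upward, the extent is the distance — the lower edge, in Kb, of the
last bin — of the maximal initial run of bins whose mean r² stays at or
above the threshold. LD confined to the first bin reports 50; a curve
already below the threshold in its first bin reports the sentinel "<50"
(the reference compared with itself); an empty bin terminates the run.
This lower-edge convention is the one under which the three boundary cases
(extent 50, "<50", and mid-range values such as 750) are mutually
consistent on 50-Kb multiples.

Because the threshold is a maximum over ~79 noisy bin means, its value
rises with bin-level noise; extent comparisons are therefore made between
populations of equal sample size (the study reduces every population to its
25 most-unrelated members) and are meaningful only with enough marker pairs
per bin (hundreds, in the package's test configurations).

## Association

* **Allelic test**: Pearson 1-df chi-square on the 2×2 allele-count table,
  no continuity correction; males contribute one allele on X. Markers and
  samples are pre-filtered to call rate ≥ 90% and markers to MAF ≥ 0.05 on
  the phenotyped samples. Zero-margin markers are skipped and listed.
* **CMH**: the 2×2×K statistic Σ(a_k − E_k)² / ΣV_k with strata from
  population labels by default; strata without both phenotype classes drop
  out. With one stratum it equals ((N−1)/N)× the allelic chi-square, which
  the tests assert to 1e-10.
* **max-T**: R label permutations (Fisher–Yates under one seeded
  generator), within strata for CMH and optionally within sex (the
  X-linked design, preserving the male/female allele-count imbalance);
  P_genome(marker) = (1 + #{max_r ≥ observed})/(R + 1), bounded below by
  1/(R+1) and monotone in the observed statistic.
* **λ_GC** = median(χ²)/0.454936…, the 1-df chi-square median. λ is a
  median-based statistic of a discrete test: on perfectly balanced,
  fully-typed cohorts the allelic statistic takes lattice values and the
  median (hence λ) is visibly quantized; calibration checks use cohorts
  with a full MAF spectrum and some missingness, where the lattice smears
  out.
* **Haplotype blocks** are genotype-based, not phased: the maximal
  contiguous run of markers around the anchor at which every case carries
  one and the same homozygous genotype. Missing calls are tolerated (at
  least one case must be typed per marker); a heterozygote or a conflicting
  homozygote breaks the run. The anchor must be a recessive causal variant
  (all cases typed and identically homozygous). The same rule applied to a
  population's full membership gives fixed-variant runs of homozygosity.
* **Required sample size** for indirect association: n_required =
  ⌈n/r²⌉, with r² the LD between the causal variant and its nearest array
  marker (ties on distance broken toward larger MAF, then lexicographic
  id).

## Problem sizes in the test suite

The statistical tests run on reduced problem sizes chosen so the full suite
completes in minutes on one core while keeping each check well-powered:
panels of 2–4 populations × 25–250 individuals on maps of 300–1,250
markers (2–4 chromosomes at the array's native 37.7-Kb spacing);
permutation counts of 199–40,000 chosen so Monte-Carlo error is small
relative to each assertion's tolerance; 10–100 seed replicates for
sign-test and calibration properties. `scripts/acceptance.py` runs the
entire pipeline — simulation, QC, diversity, structure, LD, GWAS, blocks,
power — on one such panel and writes every headline quantity it computes.

## Known limitations

* The PED dialect relabels alleles on files written by other software
  unless the `.alleles.tsv` sidecar is present (the format itself carries
  no allele order).
* PI_HAT and the CMH strata fallback are not digit-for-digit reproductions
  of any specific PLINK build; they implement the published estimators.
* The extent-of-LD statistic is threshold-relative and sample-size
  sensitive by construction; values from populations of unequal size are
  not comparable.
* Blocks are defined on genotypes; a phased-haplotype definition would be
  narrower in regions where cases share one haplotype but vary on the
  other.
* VCF input, imputation, phasing, multi-allelic markers, Hardy–Weinberg
  tests, F_ST and admixture-proportion estimation are out of scope.
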