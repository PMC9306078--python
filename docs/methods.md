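# Methods

This note records the statistical models, default parameters, and numerical
choices behind `gras2qtl`, including the points where the underlying
methodology is underdetermined and a concrete reading had to be fixed.

## Synthetic data generator (`gras2qtl.simulate`)

**Genome and genotypes.** An F2 individual is two gametes. Each gamete is
simulated as a Markov chain along the ordered loci of a linkage group: the
first allele is a fair coin, and the parental origin flips between adjacent
loci with probability `kosambi_inverse(spacing)`. This matches the Kosambi
map function used downstream and assumes no crossover interference beyond
what Kosambi implies for adjacent intervals. Planted QTL positions are
inserted as extra unobserved loci of the same chain, so QTL genotypes
co-segregate correctly with flanking markers. Defaults: 150 individuals,
8 linkage groups of 20 markers at 5 cM spacing (a 760 cM genome).

**Read depths.** Each marker tracks the allele of one source parent
(alternating by marker index, so both phases occur). An individual's
expected depth is the class mean for its dosage of that allele — defaults
2 / 60 / 120 reads for 0 / 1 / 2 copies — times a per-marker log-normal
scale factor (log-sd 0.25) representing amplification efficiency. Counts
are gamma-mixed Poisson (negative binomial, `var = mu + 0.02 mu^2`). The
class means were chosen to give high but imperfect calling accuracy
(high 90s%), i.e. the regime where depth-based co-dominant calling is
useful; the non-zero `mu_absent` represents index hopping and mismapped
reads. Both mixture families are therefore *mis-specified* for the
generated counts, as they are for real data; neither family is given a
home-field advantage.

**Default caller emulation.** The vendor caller is emulated, not modelled:
dominant presence/absence calls threshold the count at 10 reads, and a
random 12% of markers also carry three-state calls equal to the true
genotype corrupted at rate 2% (errors drawn uniformly from the two wrong
codes). These three knobs are exposed because real defaults are unknown.

**Phenotypes.** Trait = baseline + QTL effects + Gaussian noise, with the
noise variance set so the genetic fraction equals the configured
heritability (default 0.21 for maturity, 0.154 for flowering). A
homozygote for the seed-parent allele deviates by +a, the other homozygote
by −a, the heterozygote by d. Maturity is right-censored at `censor_day`
(default 105): censored individuals keep the truncated value plus a flag.
Default planted QTLs: maturity a=−7.19, d=−3.28 on group 6 at 47.5 cM;
flowering a=−6.52, d=−0.03 on group 3.

**Seeding.** All stages draw from `np.random.default_rng([seed, k])` with a
distinct `k` per stage (genotypes, depths, default calls, phenotypes), so
the same genome can be re-dressed with different depths deterministically.

## Mixture genotyping (`gras2qtl.mixture`)

**Model.** Per locus, counts are a three-component mixture (gamma or
normal). EM initialization: weights (0.25, 0.50, 0.25); normal means at
(0, q50, q75) of the counts with common sd; gamma pre-initial shape/scale
moment-matched to means (0, q50, q75) and sds (sd/3, sd/2, sd/2), then
+1.0 added to every pre-initial shape and +0.5 to every scale. The
zero-mean component's pre-initials are taken as 0, so it starts at
shape 1.0, scale 0.5 — the only self-consistent reading of the zero-mean
case. Loci need ≥ 20 non-missing counts and positive variance.

**Numerics.** Counts are shifted by +0.5 before gamma fitting (the gamma
density is degenerate at 0 and log(0) is undefined); calls depend only on
posteriors, so the shift is never undone, and reported component means
subtract it. The gamma M-step solves `log a − psi(a) = c` by Newton
iteration in log-space from the standard closed-form starting point. EM
stops at relative log-likelihood change < 1e-8 or 5000 iterations; a
component collapsing (weight < 1/(10n), variance underflow, or shape
overflow) marks the locus non-converged rather than raising. Non-converged
loci are removed from the marker set with an explicit filter-history entry.
Whole matrices are fitted as a single vectorized batch with an active-set
mask, so 500 loci fit in seconds.

**Calls and filters.** Components are sorted by fitted mean: lowest =
homozygote lacking the source allele, middle = heterozygote, highest =
homozygous carrier; each individual gets the argmax-posterior code, and
posterior ties (within 1e-9) become missing. Both parents are called from
the same fit; the parental-consistency filter keeps markers whose parents
call as the correct opposite homozygotes (a missing parent call removes
the marker — the conservative rule). The consensus filter collapses
three-state calls to presence/absence of the source allele and keeps
markers agreeing with the default dominant calls on strictly more than 95%
of jointly observed individuals. Accuracy summaries are unweighted means
over markers. `priority_merge` resolves shared marker ids by source
priority default > gamma > normal; it is associative and idempotent.

## Marker QC and linkage maps (`gras2qtl.linkage`)

**Duplicates and distortion.** Duplicate collapse uses missing-tolerant
identity (two markers are duplicates when their non-missing calls never
conflict), greedily grouping markers in order of increasing missingness
and keeping the member with fewest missing calls. Segregation distortion is
a χ² goodness-of-fit test — 1:2:1 (df 2) for co-dominant markers, 3:1
(df 1) for dominant/morphological ones — removing markers at P < 0.001,
plus markers with under 20 informative calls.

**Recombination.** For two co-dominant F2 markers, the 3×3 joint count
table's cell probabilities follow from gamete probabilities p=(1−r)/2,
q=r/2 in coupling phase. All cells have a fixed number of recombinant
gametes except the double-heterozygote cell, which mixes 0- and
2-recombinant gamete pairs; the ML estimate runs EM on that ambiguity
(expected recombinants in the (1,1) cell = 2r²/((1−r)²+r²)). All pairs are
processed as one vectorized EM over stacked tables. Pairs involving a
dominant-coded marker (carrier class = {AA, AB}) use a generic scalar EM
over the censored cell structure. LOD is the log10 likelihood ratio against
r = 0.5.

**Grouping and ordering.** Single-linkage grouping connects markers with
r ≤ 0.35 and LOD ≥ 3. Ordering minimizes the sum of adjacent recombination
fractions via greedy double-ended seriation from a random start plus 2-opt
refinement, restarted 50 times; ties in cost break lexicographically on
the canonical orientation (first marker id ≤ last), making output
independent of input order up to reversal. Positions are cumulative Kosambi
distances, d = 25·ln((1+2r)/(1−2r)), with adjacent r capped just below 0.5
so an unlinked adjacency yields a large finite gap for the gap filter to
find. The gap filter iteratively removes, at each > 20 cM gap, the marker
on the side with fewer markers (right side on ties) until no gap exceeds
the limit; it is idempotent. Map summaries report total length and
length/markers as the average marker distance. `bridge_maps` relates two
maps by shared markers, taking the modal partner group per group and
counting markers that disagree with it as inconsistent.

## QTL scanning (`gras2qtl.qtl`)

**Genotype probabilities.** Per linkage group, a three-state hidden Markov
chain over the grid (union of marker positions and a 1 cM step grid) with
transition matrices from the Kosambi-inverse recombination fraction of each
interval and the F2 prior (0.25, 0.5, 0.25) at the start. Emissions are
one-hot for observed co-dominant calls, {AB, AA-carrier} for dominant
codes, uninformative for missing. Forward–backward with per-step
normalization gives P(BB/AB/AA) at every position.

**Scan.** Haley–Knott regression of the phenotype on x = P(AA) − P(BB) and
z = P(AB); LOD = (n/2)·log10(RSS0/RSS1). CIM adds forward-selected marker
cofactors (default 5), each coded as additive + dominance columns with
mean imputation of missing calls; cofactors within 10 cM of the scan
position on its group are dropped from the model at that position. Effects
at a peak are the regression coefficients (a, d); R² is the percentage RSS
reduction against the cofactor-only null. Peaks are local maxima above
threshold at least 20 cM apart, each annotated with a 1-LOD support
interval (the widest contiguous region within `drop` of the peak) and
flanking markers. Support-interval methodology is not standardized; 1-LOD
is the common convention and the drop is a parameter.

**Permutations.** The genome-wide threshold is the ceil((1−α)·n)-th order
statistic of the max-LOD over n phenotype permutations (α = 0.05 default).
For CIM, cofactors selected on the observed phenotype are held fixed across
permutations — re-selecting per permutation would be more conservative but
is far more expensive; fixing them is the standard compromise and is
applied consistently. Permutations are a single vectorized multi-phenotype
scan, so 1000 permutations cost roughly one scan of a 1000-column Y.
Scans require ≥ 30 phenotyped individuals and reject zero-variance
phenotypes outright (a constant trait has no mappable signal).

**Censoring policy.** Scans default to *including* censored individuals at
their truncated values (dropping them would discard a fifth of late
populations and bias effects); association summaries default to *excluding*
them (class means of truncated values are not interpretable as days).
Both policies are explicit parameters.

## Association statistics (`gras2qtl.association`)

Tukey–Kramer: MSW = Σ(n_k−1)s_k²/(N−K); q_ij = |μ_i−μ_j| /
sqrt((MSW/2)(1/n_i+1/n_j)); P from the studentized-range distribution with
K groups and N−K df (scipy's `studentized_range`). The statistic depends on
the data only through (n, mean, sd) per group, so the raw-data and
summary-triplet entry points agree exactly (tested to 1e-10). Degenerate
zero-variance inputs yield P = 0 for unequal means and NaN for equal ones.
Classes with n < 2 get NaN contrast rows rather than being dropped
silently. Significance stars: * < 0.05, ** < 0.01, *** < 0.001.

## Known limitations

- The depth model has no zero-inflation knob beyond `mu_absent` itself and
  no per-individual library-size factor; per-marker scale is the only
  efficiency axis.
- Recombination estimation assumes coupling-phase F2 tables; repulsion
  dominant-dominant pairs are handled by the generic EM but with less
  information, as in any F2 analysis.
- Single-linkage grouping at (r ≤ 0.35, LOD ≥ 3) can fuse two true groups
  through one spurious inter-group pair at n = 150 (observed in roughly
  one seed in six); raising `lod_min` trades this against fragmentation.
  Group *labels* are assigned by size and need not match any external
  numbering.
- Maps built from mixture calls are longer than truth because miscalls
  mimic double recombinants; no map-shrinking error correction is applied.
- The permutation threshold treats individuals as exchangeable; censored
  maturity values are permuted like any other value.
- `scan_cim` fixes cofactors across permutations (see above), and effect
  estimates at a peak are conditional on the selected cofactors outside the
  10 cM window.
- Tukey–Kramer assumes equal within-class variances (pooled MSW); no
  Welch-type correction is offered.
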