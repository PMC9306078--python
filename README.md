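# gras2qtl

Co-dominant genotype calling from random-amplicon read depths, and QTL
mapping in F2 populations built on those calls.

Random-amplicon genotyping-by-sequencing (e.g. GRAS-Di) yields anonymous
*dominant* markers: an amplicon tracks one parent's allele, so the standard
output only distinguishes presence from absence of that allele. The read
depth at each locus carries more information than the binary call, though —
over an F2 population the depths are trimodal, with near-zero counts for
individuals lacking the allele, intermediate counts for heterozygotes, and
high counts for homozygous carriers. `gras2qtl` recovers *co-dominant*
three-state genotypes (AA / AB / BB) by fitting a three-component mixture of
gamma (or normal) distributions to each locus's counts with EM and assigning
each individual its maximum-posterior component. The gamma family usually
wins: read counts are non-negative and right-skewed, which the normal family
has to force.

The package carries those calls through a complete mapping workflow:

- **Synthetic data generator** — seeded F2 populations with Markov-chain
  gamete simulation, negative-binomial amplicon depths, an emulated
  default (dominant) caller, planted QTLs, heritability-scaled phenotypes,
  and right-censored maturity traits. Every stage ships with matched ground
  truth, so the whole pipeline is testable end to end.
- **Mixture genotyping** — per-locus gamma/normal EM (weights initialized at
  the F2 prior 0.25/0.50/0.25, component means at 0, the median, and the
  75% quantile of the counts; at most 5000 iterations), accuracy evaluation
  against default calls, a >95% dominant-consensus filter, a parental-
  consistency filter, and priority merging of default > gamma > normal calls.
- **Marker QC and linkage maps** — duplicate collapse, χ² segregation-
  distortion filtering (P < 0.001), EM estimation of pairwise recombination
  fractions handling the F2 double-heterozygote phase ambiguity, single-
  linkage grouping, greedy seriation + 2-opt marker ordering (50 restarts),
  Kosambi map distances, a 20 cM gap filter, and cross-population map
  bridging through shared markers.
- **QTL scanning** — hidden-Markov genotype probabilities on a 1 cM grid,
  Haley–Knott regression, composite interval mapping with forward-selected
  marker cofactors, genome-wide permutation thresholds, peak tables with
  additive/dominance effects, R², and 1-LOD support intervals.
- **Association statistics** — per-marker genotype-class summaries and
  Tukey–Kramer all-pairs comparisons that accept either raw observations or
  published (n, mean, sd) triplets, with exactly identical results.

## Worked example

Simulate a 150-plant F2 population with a planted maturity QTL
(additive effect −7.19 days, dominance −3.28, on linkage group 6 at
47.5 cM), call genotypes from the read depths, build a map, and scan:

```python
from gras2qtl import (
    SimConfig, simulate_dataset, call_markers, codominant_accuracy,
    consensus_filter, parental_consistency_filter, priority_merge,
    marker_set_from_calls, collapse_duplicate_markers,
    segregation_distortion_filter, build_map, gap_filter, summarize_map,
    scan_with_permutations, class_summary,
)

data = simulate_dataset(SimConfig(seed=2))

gamma_set, _ = call_markers(data.depths, "gamma")
normal_set, _ = call_markers(data.depths, "normal")
_, gamma_acc = codominant_accuracy(gamma_set.calls, data.truth.genotypes)
_, normal_acc = codominant_accuracy(normal_set.calls, data.truth.genotypes)
print(f"gamma accuracy vs truth:  {gamma_acc:.2f}%")
print(f"normal accuracy vs truth: {normal_acc:.2f}%")

default_set = marker_set_from_calls(
    data.default_codominant, "default", data.depths.source_parent)
sets = []
for ms in (gamma_set, normal_set):
    ms = consensus_filter(ms, data.default_dominant)
    sets.append(parental_consistency_filter(ms))
merged = priority_merge(default_set, *sets)
print(f"markers after merge: {merged.n_markers}")

calls, _ = collapse_duplicate_markers(merged.calls)
calls, _ = segregation_distortion_filter(calls)
gmap = build_map(calls, seed=2)
gmap, _ = gap_filter(gmap)
print(summarize_map(gmap))

mapped = calls.loc[[m for m in calls.index if m in set(gmap.marker_ids)]]
res = scan_with_permutations(
    gmap, mapped, data.phenotypes.trait("maturity_time"),
    model="cim", n_perm=200, seed=2)
print(f"LOD threshold (alpha=0.05, 200 permutations): {res.threshold:.2f}")
print(res.peaks[["group", "peak_cM", "lod", "additive", "dominance", "r2_pct"]]
      .round(2).to_string(index=False))

peak = res.peaks.sort_values("lod", ascending=False).iloc[0]
cs = class_summary(mapped.loc[peak["marker_left"]],
                   data.phenotypes.trait("maturity_time"))
print(cs.classes.round(1).to_string())
print(cs.contrasts.round(4).to_string(index=False))
```

Output:

```text
gamma accuracy vs truth:  98.02%
normal accuracy vs truth: 97.43%
markers after merge: 157
{'n_groups': 8, 'n_markers': 156, 'total_length_cM': 1044.4, 'average_marker_distance_cM': 6.7}
LOD threshold (alpha=0.05, 200 permutations): 3.72
group  peak_cM   lod  additive  dominance  r2_pct
  LG7    67.00 10.09     -7.34     -10.62   26.64
  LG1    13.86  4.77     -0.19       7.00   13.61
      n  mean    sd
A  31.0  75.3  10.5
H  85.0  79.0  10.2
B  34.0  91.6  11.0
class_a class_b    diff      q  p_adj stars
      A       H  3.6587 2.3615 0.2203      
      A       B 16.2846 8.8803 0.0000   ***
      H       B 12.6259 8.4261 0.0000   ***
```

The top peak's group ("LG7" — map group labels are assigned by size, so they
need not match the generator's numbering) consists entirely of the true
linkage-group-6 markers, the additive effect recovers the planted −7.19
within sampling error, and plants homozygous for the seed-parent allele
mature about 16 days earlier than the other homozygote at the peak marker.
Genotype-calling noise stretches the map relative to its true 760 cM —
miscalls look like extra recombinations — which is the expected behaviour of
maps built from depth-derived calls. A permutation threshold at α = 0.05
still admits genome-wide false positives at that rate, so secondary peaks
(like LG1 here) warrant validation before any claim.

## Command-line interface

Each stage is also a subcommand (`gras2qtl --help` for details):

```bash
gras2qtl simulate --seed 2 --out run/sim
gras2qtl call --depths run/sim/depths.tsv \
    --default-dominant run/sim/default_dominant.tsv \
    --default-codominant run/sim/default_codominant.tsv --out run/calls
gras2qtl map --genotypes run/calls_genotypes.tsv --seed 2 --out run/map.tsv
gras2qtl scan --map run/map.tsv --genotypes run/calls_genotypes.tsv \
    --pheno run/sim/phenotypes.tsv --permutations 1000 --seed 2 --out run/qtl
gras2qtl assoc --genotypes run/calls_genotypes.tsv --marker LG6M010 \
    --pheno run/sim/phenotypes.tsv

gras2qtl run --seed 2 --out run/all   # the whole pipeline in one call
```

All artifacts are tab-separated text with a comment header recording the
seed; the pipeline configuration is YAML (see `gras2qtl.io.RunConfig`).

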