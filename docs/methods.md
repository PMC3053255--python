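# Methods

## Error model

The efficiency of a genetic code is measured by the mean squared change
in an amino-acid property over all single-base substitutions between
sense codons:

```
MS = Σ_ij N_ij (X_i − X_j)² / Σ_ij N_ij
```

Events are enumerated as **ordered** (codon, single-base neighbor) pairs:
every codon has 9 neighbors (3 positions × 3 alternative bases). Pairs
with a stop codon on either side are dropped; synonymous pairs are kept
(zero numerator contribution, counted in the denominator). Since
(X_i − X_j)² is symmetric, counting both directions doubles numerator and
denominator alike and leaves MS unchanged; it makes the event count
unambiguous — 526 for any code with stops at the canonical positions
(576 ordered pairs minus 54 involving a stop, plus the 4 stop–stop pairs
removed twice). The reported statistic is the mean square itself, not its
root: under the polar requirement scale the standard code scores 5.1936.

**tMS** replaces the unweighted mean by a weighted mean, with one weight
per (codon position, transition/transversion) stratum. The default
weights — transitions 1, 0.5, 1 and transversions 0.5, 0.1, 1 for bases
1–3 — encode the empirical pattern that second-position errors are
rarest (transversions there rarest of all) while third-position errors
are common. All six weights equal gives back MS exactly. tMS of the
standard code under the defaults is 2.6283.

The property scale is Woese's polar requirement, a dimensionless
water/pyrimidine partition coefficient per amino acid. Literature copies
of the scale differ in the last digit for a few residues; the embedded
variant (W = 5.2, Y = 5.4) is pinned by the test suite to reproduce the
standard code's MS of 5.19 to three significant figures. Any 20-entry
finite scale can be supplied as TSV.

## Code spaces and variation operators

**Model 1 — restrictive codes.** The 64 codons keep the standard code's
partition into 21 synonym blocks; a code is a bijection of the 20 amino
acids onto the 20 sense blocks (20! ≈ 2.43·10¹⁸ codes); the 3 stop codons
are fixed at UAA/UAG/UGA. The genotype is the length-20 permutation; the
variation operator swaps the amino acids of two blocks drawn uniformly
without replacement. Random model-1 codes are uniform permutations.

**Model 2 — codon-reassignment codes.** The genotype is the full
64-position assignment with stops fixed at the canonical positions and
every amino acid required to appear at least once. The operator models
natural codon reassignments: choose a sense codon uniformly among the 61,
choose uniformly one of its single-base neighbors that is also sense, and
copy the source's amino acid onto the neighbor — unless the neighbor's
amino acid occurs nowhere else, in which case the move is not applied and
the code is returned unchanged (the guard preserves the 20-amino-acid
invariant). Model 1's space is contained in model 2's.

Stop placement in model 2 is fixed to the canonical positions (consistent
with model 1's convention); random model-2 codes draw the 61 sense labels
i.i.d. uniform over the 20 amino acids with rejection until all 20 are
present (acceptance probability ≈ 0.39, so sampling stays cheap). This
conditioning is the natural uniform distribution on the constrained
space.

## Genetic algorithm

Fitness is MS or tMS, minimized. Defaults follow the study conditions:
population 1000; tournament selection with a window of 3% of the
population (30), drawn with replacement, ties broken toward the lowest
population index; elitism of the single best individual (first index on
ties); every non-elite offspring receives exactly one operator
application (`operator_probability` exposes a rate < 1 if wanted). A run
ends at a generation cap (default 100 for model 1, 300 for model 2 —
model 2 needs more generations to overcome the canonical values) or
earlier once the best fitness has not improved for 25 consecutive
generations. Replicates use seeds spawned from one base seed
(`numpy` SeedSequence), so runs are independent, and identical
configuration plus seed reproduces traces bit-for-bit.

Fitness evaluation is vectorized: the 526-pair event set is precomputed,
so model-2 populations score as one (n × 526) array operation, and
model-1 codes reduce further to a quadratic form over a precomputed
20×20 between-block (weighted) event-count kernel — a model-1 code's
error depends only on its block→amino-acid mapping. The test suite
checks both fast paths against independent loop-based enumerations to
1e-9; summation order is fixed by the codon enumeration order.

## Optimality measures

Percentage distance minimization:
`p.d.m. = 100·(Δ_mean − Δ_code)/(Δ_mean − Δ_low)`, with Δ_mean the mean
error of 10,000 random codes of the model under study, Δ_code the
canonical code's error, and Δ_low the minimum across the GA replicates of
the same arm. It is affine-invariant in its three inputs and requires
Δ_mean > Δ_low. The statistical measure is the fraction of sampled codes
strictly better (lower) than the canonical value; ties count as not
better. Histograms use 30 equal-width bins over the sample range by
default and report the bin containing a reference value (the canonical
score) for random-vs-evolved comparisons.

The pattern proxies quantify two regularities of optimized codes.
Pattern I (first-position similarity): mean within-group property
variance of sense codons grouped by bases 2+3 (varying base 1) minus the
same with base 2 varying; negative means the pattern is present. Groups
reduced to fewer than two sense codons by stop positions are skipped.
Pattern II (second-position pyrimidine/purine structure): over sense
codon pairs differing only at base 2, mean squared property difference of
cross-set pairs minus within-set pairs; positive means present. Both are
zero for a constant scale; the standard code scores −1.94 and +7.58.

## Serialization choices

Codons enumerate base1-major in U, C, A, G order (first base slowest,
third fastest) — the row order of NCBI translation tables with T read as
U, so the standard code serializes to the familiar `FFLLSSSS…` string.
The RNA alphabet is used internally; parsers accept T as a synonym of U
and lower case. Code-table parsing names the violated invariant (length,
illegal character, stop count, missing amino acid) in its error message.

## Problem sizes

Default experiment sizes: 10 GA replicates per arm and 10,000 random
codes per Δ_mean estimate, the sizes also used by the acceptance script.
The four-arm experiment completes in well under a minute on one CPU at
these sizes; replicates, population and sample size are flags when more
precision is wanted.

## Known limitations

* Model-1 GA runs occasionally (roughly 1 run in 10–20, seed-dependent)
  converge to a swap-local optimum near MS ≈ 4.0 rather than the usual
  3.49–3.52 plateau; once the population has collapsed onto such an
  optimum, longer plateaus do not rescue it, since escape needs two
  coordinated swaps through a worse intermediate. Means over replicate
  batches therefore sit slightly above the clean-run value for some
  seeds. All such runs still fall well below the 4.7 benchmark.
* The error model weighs all amino-acid changes by a single linear
  property scale and all codons equally: no amino-acid usage
  frequencies, codon-usage bias, tRNA abundances, or substitution-matrix
  distances.
* Only codes with exactly 3 stop codons at the canonical positions are
  generated (arbitrary 3-stop codes are accepted by the parser and
  scorable); no selenocysteine/pyrrolysine, no reading-frame effects.
* The GA characterizes reachability of better codes, not historical
  evolutionary pathways of the real code.
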