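# codeopt

A toolkit for studying the **error-minimization optimality of the genetic
code**: how well does the standard codon table buffer proteins against
point mutations and mistranslation, compared with the alternative codes it
could have been?

It is aimed at researchers in molecular evolution who want to reproduce,
extend or stress-test load-minimization analyses: the classical
random-code comparisons, the percentage-distance-minimization measure,
and a genetic-algorithm search for better-adapted hypothetical codes.

## The model

A genetic code is a mapping of the 64 codons onto the 20 amino acids plus
3 stop signals. Its **mean square error** under an amino-acid property
scale X (the Woese polar requirement by default) is

```
MS = Σ_ij N_ij (X_i − X_j)² / Σ_ij N_ij
```

where N_ij counts the single-base codon substitutions that turn amino
acid i into amino acid j. Substitutions from or to stop codons are
ignored; synonymous substitutions count in the denominator. For the
standard code this leaves 526 of the 64×9 ordered codon–neighbor pairs,
and MS = 5.19. The **tMS** variant weights each substitution by codon
position and transition/transversion class (defaults: transitions
1/0.5/1, transversions 0.5/0.1/1 for bases 1–3), modeling empirical
mistranslation biases; lower is better for both.

Two spaces of hypothetical codes are implemented:

* **Model 1 (restrictive codes)** keeps the standard code's 21 synonym
  blocks and permutes the 20 amino acids over the 20 sense blocks
  (20! ≈ 2.43·10¹⁸ codes). Its GA variation operator swaps the amino
  acids of two blocks.
* **Model 2 (codon-reassignment codes)** lets each of the 61 sense codons
  carry any amino acid (all 20 must remain encoded; stops are fixed).
  Its operator mimics natural codon reassignments: a random sense codon's
  amino acid is copied onto a random single-base sense neighbor, unless
  the neighbor's amino acid would vanish from the code.

A genetic algorithm (population 1000, tournament selection over a 3%
window, elitism of the best individual, plateau stopping) minimizes MS or
tMS in either space. Optimality of the canonical code is then quantified
two ways:

* **statistical approach** — the fraction of random codes scoring better
  than the canonical code;
* **engineering approach** — percentage distance minimization,
  `p.d.m. = 100·(Δ_mean − Δ_code)/(Δ_mean − Δ_low)`, placing the
  canonical code's error Δ_code between the random-code mean Δ_mean (0%)
  and the best code found Δ_low (100%).

## Worked example

The whole four-arm experiment (model 1/2 × MS/tMS) from one command:

```
$ codeopt report --seed 1 --out results/report
 model fitness  canonical  best_evolved  mean_best_evolved  delta_mean  pdm_percent
     1      MS     5.1936        3.4886             3.6128      9.4013        71.16
     1     TMS     2.6283        1.4874             1.6376      7.6096        81.36
     2      MS     5.1936        2.4717             2.7164     12.0389        71.55
     2     TMS     2.6283        1.2675             1.9497     12.0414        87.37
```

Reading the first row: the standard code's MS is 5.19, random restrictive
codes average 9.40, and the GA's best restrictive code reaches 3.49, so
the canonical code sits 71% of the way from an average random code to the
best code found — far better than chance (only ~2 in 10,000 random
restrictive codes beat it), yet clearly not optimal. Weighting for
mistranslation biases (TMS rows) raises the canonical code's standing in
both models.

Smaller pieces individually:

```
$ codeopt evaluate                 # MS of the standard code
MS = 5.194
$ codeopt evaluate --fitness tms
TMS = 2.628
$ codeopt evolve --model 1 --fitness ms --replicates 10 --seed 42 --out results/evo
best-of-run MS: mean 3.4995 sd 0.0141 min 3.4886
$ codeopt sample --model 1 -n 10000 --seed 7 --out results/samp   # histogram + summary
$ codeopt pdm --delta-mean 9.40 --delta-code 5.19 --delta-low 3.49
```

`evolve` writes per-replicate trace CSVs (generation, best, mean), the
best code of each run as a 64-character code-table text file, and a
`manifest.json` capturing the full configuration and derived seeds so any
run can be replayed exactly. Every flag can also come from a YAML config
file (`--config run.yaml`; command-line flags win).

File formats (all plain text): code tables are the 64-character one-letter
amino-acid string ('*' = stop) in base1-major U,C,A,G codon order with a
`# codon-order=U C A G, base1-major` header; property scales are
two-column TSV (`A<TAB>7.0`); mistranslation weights are three-column TSV
(position, class, weight).

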