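# renschkit

Comparative-phylogenetics toolkit for studying the evolution of **sexual
size dimorphism (SSD)** on time-calibrated phylogenies — built around the
question of whether a clade obeys **Rensch's rule** (male body size
evolving with positive allometry relative to female size, i.e. males are
the more evolutionarily labile sex), with companion tools for per-branch
evolutionary rates and for quantifying the complexity of male genitalia.

It is aimed at evolutionary biologists with a species-level trait table
(male and female body length in mm, optionally genital measurements) and
a dated tree (branch lengths in million years, My).

## What it computes

- **Independent contrasts (PIC).** Felsenstein's algorithm: standardized
  contrasts $(x_i - x_j)/\sqrt{v_i + v_j}$ with corrected branch lengths
  $v' = v + v_i v_j/(v_i+v_j)$, which are i.i.d. under Brownian motion.
- **Reduced major axis (type II) regression.** Standard RMA
  ($\hat\beta = \operatorname{sign}(r)\, s_y/s_x$) and the through-origin
  form for contrasts ($\hat\beta = \operatorname{sign}(\sum xy)
  \sqrt{\sum y^2 / \sum x^2}$, after positivizing the x contrasts),
  with bootstrap or analytic 95% CIs. Rensch's rule is supported when the
  slope of male on female log10 size exceeds 1 and the CI excludes 1.
- **Blomberg's K** phylogenetic signal,
  $K = \frac{\mathrm{MSE}_0/\mathrm{MSE}}
  {(\operatorname{tr} V - n/\mathbf{1}^{\top}V^{-1}\mathbf{1})/(n-1)}$,
  with a one-sided tip-permutation test. $K = 1$ matches Brownian motion.
- **Brownian-motion ancestral states.** ML/GLS reconstruction by the
  two-pass pruning algorithm (root estimate = the phylogenetic mean),
  with 95% intervals from the conditional variance scaled by the ML rate
  $\hat\sigma^2$.
- **Per-branch change metrics.** For every ancestor→descendant branch:
  arithmetic change, absolute change, and the rate in **darwins**
  ($|\ln(x_\text{final}/x_\text{initial})|$ per My); a qualitative
  +/−/= coding (changes below 5% of the initial size, or below 5% of the
  total SSD range, count as "no change"); cross-tabulations; an exact
  binomial sign test for whether SSD changes are driven by one sex; and
  male−female rate-difference regressions.
- **Fitch parsimony** for binary secondary sexual characters, with
  per-branch gain/loss lists and explicit ambiguity reporting.
- **Genital complexity.** Perimeter standardized by aedeagus length, and
  the Minkowski (box-counting) fractal dimension of binary outlines
  (|slope| of log box count vs log box size, power-of-two boxes).
- **Synthetic generators** with exact ground truth: Yule trees,
  correlated bivariate sex-specific Brownian evolution, binary gain/loss
  histories, and raster phantoms of known fractal dimension.

## Worked example

Generate a study-scale synthetic dataset (71-tip Yule tree; male Brownian
rate 1.44× the female rate, cross-sex correlation 0.9) and run the full
analysis:

```python
from renschkit import AnalysisConfig, limnebius_like, run_full_analysis

tree, male_truth, female_truth, traits = limnebius_like(seed=42)
report = run_full_analysis(AnalysisConfig(tree=tree, traits=traits, seed=42))
print(report.allometry.round(3).to_string(index=False))
print(report.k_table.round(3).to_string(index=False))
print("male-only:", report.n_male_only, "female-only:", report.n_female_only,
      "binomial p:", round(report.binomial_p, 5))
```

prints

```
group      data  n  slope  ci_low  ci_high    r2   p
  all contrasts 70  1.442   1.302    1.599 0.841 0.0
  all       raw 71  1.206   1.103    1.286 0.892 0.0
group         trait     k     p  n_perm
  all          rssd 0.637 0.001     999
  all   male_length 0.928 0.001     999
  all female_length 1.356 0.001     999
male-only: 19 female-only: 1 binomial p: 4e-05
```

Reading the output: the through-origin RMA slope of male-vs-female log10
contrasts is 1.44 with a 95% CI of [1.30, 1.60] — isometry (slope 1) is
rejected, recovering the generating rate ratio of 1.44: Rensch's rule.
Body sizes carry strong phylogenetic signal (K near or above 1) while the
dimorphism ratio rSSD does not (K = 0.64 < 1). Of the branches where SSD
changed by more than the 5% thresholds, 19 were driven by male change
alone versus 1 by female change alone; an exact binomial test rejects
equal probabilities (p ≈ 4e-5) — male size drives SSD evolution in this
regime.

The same analysis is available from a shell:

```sh
renschkit simulate --seed 42 --out sim/
renschkit run --tree sim/tree.nwk --traits sim/traits.csv --seed 42 --out report/
renschkit fractal outlines/*.png --out fd.csv
```

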