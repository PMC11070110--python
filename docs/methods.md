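# Methods

## Problem and model

The pipeline prioritizes plasma-membrane receptors whose engagement is most
likely to push a macrophage toward the pro-inflammatory (M1) transcriptional
program. It treats intracellular signaling as a directed graph whose nodes
are genes/proteins and whose edges carry a sign — +1 activation, −1
inhibition, 0 unknown — and asks, for every candidate receptor, how cheaply a
sign-consistent route reaches the phenotype-defining terminals. "Cheaply" is
defined by evidence: edges into nodes supported by the M1 transcript program
and by antibody confirmation are cheaper than edges into unsupported nodes.

## Differential expression

Input is a gene × sample intensity matrix (linear or log2 scale) with
conditions M0 (resting), M1 (LPS/IFN-γ-type), and M2 (IL-4-induced, i.e.
M2a). Two contrasts are run, M0-vs-M1 and M2-vs-M1, both oriented with M1
in the numerator so a positive logFC means up in M1:

* `logFC = log2((mean_M1 + ε)/(mean_ref + ε))` on linear intensities, with
  pseudocount ε = 1e−9 × the global mean intensity (keeps all-zero genes
  finite; configurable). Swapping conditions exactly negates logFC.
* Welch's unequal-variance two-sided t-test on log2 values. Degenerate genes
  (zero variance in both groups) get t = 0, p = 1 when the means agree, and
  the smallest positive double with a flag when they do not.
* Benjamini–Hochberg step-up adjustment: `q_(i) = min_{j≥i} m·p_(j)/j`,
  capped at 1 and floored at the raw p (the floor is mathematically implied
  but must be made explicit because `m·p/j` at j = m can round one ULP below
  p in floating point).

A gene is a hit when q < α (default 0.05) in both contrasts; by default it
must also have the same fold-change direction in both (a gene cannot be
simultaneously up and down in M1). The direction filter is a package choice
and can be disabled.

**Statistical power at the default design.** With three replicates per group
a gene-wise Welch test has only 2–4 error degrees of freedom, so even an
effect of 8 per-sample standard deviations (logFC 2.0 at noise 0.25) leaves
substantial mass of the raw p-value above the adaptive BH cutoff. Measured
over 50 simulated studies, the two-contrast intersection recovers ~47% of
planted genes at zero observed false positives; a pooled-variance t raises
this to ~93%. Recovering essentially all planted genes at this sample size
requires variance moderation across genes (an empirical-Bayes fit), which is
deliberately out of scope here. Analyses that need high per-gene sensitivity
at n = 3 should treat this module as conservative: what it calls a hit is
reliable, but its hit list is incomplete. The zero-noise limit recovers the
planted sets exactly.

## Membrane annotation and evidence

The annotation table stands in for a protein-knowledgebase query
(localization "cell membrane", function "receptor") plus an antibody
confirmation list; genes missing from the table are conservatively treated
as non-membrane, non-receptor, non-confirmed. The candidate receptor set is
the DEG intersection filtered to plasma-membrane receptors. Each node's
evidence profile is: `mrna_supported` ⇔ membership in the DEG intersection,
`mrna_direction` from the sign of the M2-vs-M1 logFC (the contrast that pits
the M1 phenotype against M2), and `mab_confirmed` copied from annotations.

## Network construction

Curated edge lists are merged as a set union; duplicate (source, target)
pairs with agreeing signs collapse, disagreeing duplicates resolve to
unknown (0) with a logged conflict count, and self-loops are dropped
(path semantics ignore them). Merging is order-independent.

Candidate (unsigned) interaction edges extend the network with signs
inferred from co-expression: Pearson r over all samples on log2 values, a
two-sided t-based p-value for r, and sign(r) if p < 0.05, else unknown.
Curated edges always take precedence over extension edges. Correlation is
pooled across conditions by default (the planted M1 shift then dominates r
for co-regulated genes); per-condition correlation is a configuration away.

Edge costs are additive on the *downstream* node's missing evidence:

```
cost(u→v) = 1.0 + 0.5·[v not mRNA-supported] + 0.5·[v not mAb-confirmed]
                + 0.5·[edge sign unknown]
```

Activation-vs-inhibition is carried by the edge sign, not the cost —
inhibition is directional information, not a confidence penalty. All costs
are ≥ 1.0 > 0, which shortest-path search requires, and pointwise increases
in evidence never increase any cost. The λ = 0.5 defaults weight each
missing evidence class equally at half the base cost; they are exposed in
`CostParams`.

## Sign-constrained minimum-cost path search

The net sign of a path is the product of its edge signs (double inhibition
activates). Unknown signs zero the product in strict mode (default); in
lenient mode they count as +1, their uncertainty having already been paid
as a cost penalty.

Search runs on a parity-layered graph: each node v becomes (v, +) and
(v, −), and an edge u→v with sign s connects (u, p)→(v, p·s). Dijkstra from
(source, +) to (target, required sign) with the positive edge costs returns
the cheapest walk with the required accumulated sign. Such a walk is almost
always simple in the base graph, in which case it is exactly the cheapest
sign-consistent simple path (any simple path is a walk, so the walk optimum
bounds the simple optimum from below). When the layered optimum revisits a
base node, an exact enumeration of simple paths up to 12 edges decides; on
networks of ≤ 9 nodes this fallback is exhaustive, which is how the search
is validated against brute-force enumeration.

## Scoring and ranking

For each receptor and each pro-inflammatory terminal (TNF, IL6, IL1B,
IL12B), the best *activating* path contributes `exp(−cost)` to the pro
score; for each anti-inflammatory terminal (TGFBR2, ADORA3, FFAR4) the best
*inhibiting* path also counts as pro (suppressing the anti-program is
M1-consistent). The mirror combinations accumulate into the anti score.
`exp(−cost)` makes shorter, better-evidenced paths dominate smoothly and
maps "no path" to exactly 0. Receptors are ranked by composite = pro − anti
(a pro-only mode exists), ties broken lexicographically so rankings are
total and reproducible; receptors that are themselves terminals are excluded
as degenerate.

## Synthetic data generator

Expression is simulated on the log2 scale: every gene has baseline mean 6.0,
planted M1-up (down) genes have their M1 mean shifted by +2.0 (−2.0) log2
units, and i.i.d. Gaussian noise (sd 0.25) is added per cell — three
conditions × three replicates, one 24-h-style timepoint. These defaults
emulate a microarray polarization study design: the effect size corresponds
to a 4-fold change, and the per-cell noise is a plain Gaussian stand-in for
probe-level intensity error. What the generator does *not* emulate:
probe-to-gene collapsing, mean–variance dependence, correlated noise between
samples, or time-course structure — so passing recovery tests demonstrate
correctness of the statistical machinery, not performance on real arrays.

Network fixtures plant signed cascades (receptor → intermediates → terminal)
inside a directed Erdős–Rényi-style background (density 0.05 over 60 nodes
by default, 20% inhibitory edges). Background edges never *target* a planted
cascade node or a phenotype terminal: the cascade is the controlled
ground-truth route, and recovery experiments are meant to measure the
ranking machinery (evidence costs, sign constraints, exp(−cost)
aggregation), not the luck of a random shortcut into a fully evidenced
terminal, which would otherwise dominate at any nontrivial density. This
protection rule, and the decoy receptors carrying no cascade, are what make
the planted-receptor recovery test a clean positive control.

## Numerical and degenerate-input choices

* BH floors q at p explicitly (see above); adjusted values are monotone in
  the p-ranks.
* Pseudocount default 1e−9 × global mean; with a configured ε = 0, an
  all-zero gene raises a named error instead of producing ±inf.
* Correlation on a zero-variance gene yields sign 0 with a warning; fewer
  samples than `min_samples_for_correlation` (default 4) is an error.
* Ties in ranking and in path enumeration break lexicographically (receptor
  symbol; node sequence), making every output deterministic byte-for-byte
  for fixed inputs.
* `source == target` path queries are rejected; ranking drops
  target-receptors as degenerate with a log message.

## Known limitations

* DEG sensitivity at n = 3 is ~47% at the default effect/noise (see power
  note above); the module is faithful to a plain gene-wise Welch+BH recipe
  and inherits its small-sample weakness.
* The additive cost formula and the λ defaults are a modeling choice; only
  the ordering they induce, not their absolute scale, is meaningful.
* The correlation sign inference pools all conditions and assumes a linear
  (Pearson) association on log2 values.
* The bounded-depth (12-edge) fallback after a non-simple layered optimum
  can, in principle, miss a longer sign-consistent simple path; in the
  evaluated regimes the fallback never had to reach its depth limit.
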