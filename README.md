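# crispr-coverage

Design-of-experiments toolkit for **multiplex CRISPR/Cas knockout screens
in plants**: how many mutant plants must be regenerated and genotyped
before *every* k-combination of gene knockouts among x target genes has
been observed at least once?

In a multiplex screen, a pool of x·g guide RNAs (g per gene) is
assembled into constructs carrying r guides each, constructs are
transformed into plant cells, and each regenerated plant ends up with a
random set of gene knockouts. To study all k-order genetic interactions,
the plant library must cover all C(x, k) knockout combinations — its
minimal size N_{x,k} is a random variable, and screens designed without
regard for E[N_{x,k}] cannot distinguish "combination absent because it
is lethal" from "combination absent because too few plants were grown".

The package answers this with two independent routes:

* **A stochastic simulator** of the full experiment. Guide abundances
  are drawn from a double-truncated normal with skew ρ = max/min
  frequency; per-guide editing efficiencies come from a bimodal mixture
  (a fraction f_act of active guides with ε_edit ≈ 0.95, the rest ≈ 0.1);
  each construct samples r guides multinomially; each guide edits with
  probability ε_edit and an edit knocks the gene out with global
  efficiency ε_KO. Plants are generated until all C(x, k) combinations
  are covered; repeating the trial yields E[N_{x,k}] and σ[N_{x,k}].

* **A coupon-collector estimator** (CCP) with unequal probabilities.
  The C(x, k) combinations are the "coupons"; each plant provides
  m = C(r, k) module draws; a draw yields gene combination J with
  probability q_J = k!·ε_KO^k·∏_{i∈J} w_i, where w_i = Σ_{guides of i}
  freq·ε_edit. The expected number of draws to complete the collection
  is the Poissonized integral

      E[T] = ∫₀^∞ ( 1 − ∏_J (1 − e^{−q_J t}) ) dt,     E[N] = E[T] / m,

  with Var(N) = Var(T) − E[T] exact for the discrete draw count. The
  same abstraction gives the probability of full coverage
  P_{x,k}(N) = ∏_J (1 − (1 − q_J)^{N·m}) and the (exact) expected
  coverage E[γ_{x,k}](N) = mean_J (1 − (1 − q_J)^{N·m}).

On top of both routes the package quantifies two design strategies:
**Split–Select–Combine** (partition the genes into disjoint subsets and
screen each separately) and **Overshoot–Select–Purify** (put r > k
guides on every construct so one plant covers up to C(r, k)
combinations), plus sensitivity sweeps over x, ε_KO, ρ, f_act and g.

## Worked example

Default design: x = 20 genes, g = 6 guides per gene, ρ = 2, f_act = 0.9,
ε_edit ≈ 0.95/0.1, ε_KO = 0.8.

```console
$ crispr-coverage simulate -k 1 --seed 11 --out results/sim1
E[N] = 111.4 plants, sigma[N] = 40.3 (500 trials)
```

About 111 plants are needed on average before each of the 20 genes has
been knocked out in at least one plant, with a standard deviation of 40
plants across repeat experiments.

```console
$ crispr-coverage ccp -k 2 --seed 11 --target-probability 0.95 --out results/ccp2
E[N] = 2911.5 plants (round up: 2912), sigma[N] = 699.8
smallest N with P(full coverage) >= 0.95: 4223
```

Covering all C(20,2) = 190 knockout pairs takes ~2,900 plants in
expectation for this guide library draw, and 4,223 plants are needed
before full pairwise coverage is 95 % certain. (Values vary by a few
hundred plants between library draws — the realised guide frequencies
and efficiencies are themselves random.)

```console
$ crispr-coverage overshoot -k 2 --r-values 2,3,4,5,6 --replicates 5 --seed 11 --out results/os
r=2: E[N] = 2469.6 plants
r=3: E[N] = 823.2 plants
r=4: E[N] = 411.6 plants
r=5: E[N] = 247.0 plants
r=6: E[N] = 164.6 plants
```

One extra guide per construct (r = 3 instead of 2) already cuts the
expected screen size by two thirds, because every triple-knockout plant
covers three pairs at once.

The same functionality is available as a library
(`crispr_coverage.estimate_min_library_size`,
`crispr_coverage.combination_probabilities`, … — see the module
docstrings), and a measured guide library can replace the sampled one
via a calibration TSV (`--library`, columns
`grna_id  gene_id  abundance  eps_edit`).

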