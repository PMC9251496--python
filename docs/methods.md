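# Methods

## The experiment being modelled

A multiplex CRISPR/Cas knockout screen in plants proceeds in stages:
(1) design g guide RNAs for each of x target genes; (2) pool them and
assemble constructs carrying r guide cassettes each; (3) transform the
construct library into plant cells (one construct per cell) and
regenerate plants; (4) genotype/phenotype the resulting plant library.
A plant's genotype is the set of genes that acquired a loss-of-function
mutation. To study all k-order genetic interactions, the library must
contain every one of the C(x, k) k-combinations of knockouts at least
once; the minimal number of plants achieving this, N_{x,k}, is the
quantity the package estimates.

## Stochastic model

**Guide abundances.** Construct libraries are never equimolar. Raw
abundances are drawn from a normal truncated to [l, u] with
μ = (l+u)/2 and σ = (u−l)/2, parameterised only by the skew
ρ = u/l ≥ 1 (the ratio of the most to the least abundant guide; the
absolute scale cancels when abundances are normalised into relative
frequencies). ρ = 1 degenerates to a uniform pool. Truncation is exact,
so the realised max/min frequency ratio never exceeds ρ.

**Editing efficiencies.** Each guide is independently "active" with
probability f_act. Active guides draw their genome-editing efficiency
from N(ε_edit,act, sd), inactive ones from N(ε_edit,inact, sd), clamped
to [0, 1]. With the default sd of 0.01 the clamp is effectively inert.
A deterministic round(f_act·n) active/inactive split would be an
alternative reading; we use the independent Bernoulli mixture, which is
what a bimodal efficiency distribution means, and expose the choice
only through the seed.

**Per-plant pipeline.** A construct draws r guide indices i.i.d. from
the frequency vector (duplicates allowed). Each guide slot induces a
mutation with probability ε_edit of that guide, and a mutation disrupts
gene function with the global knockout efficiency ε_KO. The genotype is
the *set* of genes with at least one successful knockout (duplicate
guides of one gene collapse), so a plant carries between 0 and r
knockouts. Transformation and regeneration are assumed 100 % efficient;
vector propagation, multiple integrations and regeneration failure are
out of scope.

**Coverage accounting.** A plant with j ≥ k knockouts covers all
C(j, k) k-subsets of its knocked-out genes (each combination counts
regardless of the background knockouts it sits in); plants with fewer
than k knockouts count toward N but cover nothing.

### Default parameters

| symbol | meaning | default |
|---|---|---|
| x | target genes | 20 |
| g | guides per gene | 6 |
| k | interaction order to cover | 1 (2, 3 in the examples) |
| r | guides per construct | k |
| ρ | abundance skew (max/min frequency) | 2 |
| f_act | fraction of active guides | 0.9 |
| ε_edit,act / ε_edit,inact | mean editing efficiency, active/inactive | 0.95 / 0.1 |
| sd(ε_edit) | spread of each efficiency mode | 0.01 |
| ε_KO | P(edit → loss of function) | 0.8 |
| n_trials | simulation repetitions | 500 |
| max_plants | cap per trial (guards unreachable coverage) | 10⁷ |

## Simulation route

Each trial generates plants until every combination has been seen,
returning that plant count; the estimate over n_trials trials reports
the sample mean and standard deviation. One guide library (frequencies
+ efficiencies) is sampled per estimate and shared across trials —
library resampling happens across replicates of a sweep, not across
trials — matching the fact that a real experiment fixes one construct
library. Internally plants are generated in growing chunks
(2048 → 65536) with fully vectorised sampling; per combination the
engine records the index of the first plant covering it (a colex
ranking maps k-subsets to a dense C(x, k) array), so the completion
size is exact regardless of chunk boundaries and coverage curves come
for free. Trial RNG streams are derived as (seed, purpose, trial index)
substreams, so any trial is reproducible in isolation and trials could
run in any order.

## Coupon-collector route

The screen maps onto a coupon-collector problem with unequal
probabilities: modules = the C(x, k) gene combinations, m = C(r, k)
module draws per plant, and per-draw probability

    q_J = k! · ε_KO^k · ∏_{i∈J} w_i ,   w_i = Σ_{guides of gene i} freq·ε_edit ,

obtained by enumerating the ordered k-tuples of construct slots whose
guides hit k distinct genes and succeed; the sum over guide choices
factorises per gene, which is why the expression is a product of
per-gene weights. Tuples that reuse a gene, or whose edits fail, fall
into the deficit 1 − Σq (a draw that completes no combination); this is
the same convention the simulator's multinomial assembly realises, so
at r = k the two routes estimate the *same* quantity exactly. For
r > k the m module draws of one plant are treated as independent — an
approximation (a real plant's C(r, k) slot-subsets overlap); the
simulator is the exactness reference.

Waiting-time statistics use Poissonization. With T the continuous
completion time of a unit-rate draw process,

    E[T]  = ∫₀^∞ (1 − ∏_J (1 − e^(−q_J t))) dt ,
    E[T²] = 2 ∫₀^∞ t (1 − ∏_J (1 − e^(−q_J t))) dt ,

and the discrete draw count N satisfies E[N] = E[T] and
Var(N) = Var(T) − E[T] exactly (T is a sum of N i.i.d. Exp(1) gaps
independent of N). Plant counts divide by m; E[N] is reported
unrounded and the CLI rounds up. For a single module these reduce to
the geometric mean 1/q and variance (1−q)/q²; for equal probabilities
to the classical n·H_n.

The probability of full coverage P(N) = ∏_J (1 − (1−q_J)^{N m})
additionally assumes module independence across plants; the expected
coverage E[γ](N) = mean_J (1 − (1−q_J)^{N m}) is exact by linearity.
Inverse queries (smallest N reaching a target P or γ) use doubling plus
integer bisection on these monotone curves; a coverage target of
exactly 1 is rejected since E[γ] → 1 only asymptotically.

**Numerics.** The improper integrals are evaluated with adaptive
quadrature (scipy `quad` on [0, ∞), relative tolerance 1e-10) after
rescaling time by 1/min(q) so the integrand decays on an O(1) scale;
the equal-probability closed form n·H_n is reproduced to machine
precision. Any q_J = 0 raises an error naming the unreachable
combinations (for P(N) it simply pins the result at 0). Module
enumeration is O(C(x, k)); k > 4 is refused — the design space itself
is astronomically large before that point.

## Strategies

**Split–Select–Combine.** Each gene subset is an independent
sub-experiment: its own x_subset·g guide pool with freshly sampled
frequencies and efficiencies, identical k, r, ρ and efficiency
parameters. The total is the sum of per-subset expectations and
per-subset variances add; the quantified benefit comes entirely from
C(x_subset, k) ≪ C(x, k). Subset library seeds are derived from
(replicate, subset size, occurrence), making totals invariant to
subset order. The Combine phase (crosses between subsets) and the
Purify backcrossing programme are not modelled.

**Overshoot–Select–Purify.** Sweeping r at fixed k reuses the identical
library within a replicate so the sweep isolates r. Under the CCP route
q is r-independent and E[N] = E[T]/C(r, k), which is monotonically
decreasing in r. The knockout-count distribution panel (per (ε_KO, r)
cell) shows how overshoot converts wildtype/single-knockout by-products
into multi-knockout plants. Guide competition for the Cas nuclease at
large r is not modelled, so large-r extrapolations are optimistic.

**Parameter sweeps** resample the guide library per replicate, reusing
the same replicate seeds across grid values so only the swept parameter
varies. Two sweeps isolate one noise source by design: the ρ sweep
forces all ε_edit to 1, the f_act sweep forces uniform frequencies.

## What the generator does and does not emulate

The synthetic guide model captures abundance skew and bimodal activity
— the two dominant, measurable imperfections of real construct
libraries — but not sequencing noise in the calibration data,
gene-specific knockout efficiencies (ε_KO is global), heterozygous vs
homozygous states, or off-target edits. Passing tests therefore show
that the estimators are correct *for this generative model*; for a real
screen the calibration TSV path should replace the sampled library, and
the resulting sizes remain lower bounds on what phenotyping with
biological noise requires.

A consequence of the stochastic library worth knowing: E[N_{x,k}] is a
convex functional of the realised library, dominated by the weakest
genes (those with several inactive guides), so the *library-averaged*
expectation exceeds the value of a typical single draw, increasingly so
for larger k (roughly +6 %, +16 %, +25 % at k = 1, 2, 3 under the
defaults relative to a low-heterogeneity draw). Reported averages in
the acceptance script are taken over dozens of library draws for
precisely this reason, and single-library runs (as in the README
example) can sit noticeably below or above them.

## Problem sizes used in tests and the acceptance script

Simulation estimates use 500 trials (k = 1, 2) and 100 trials (k = 3),
averaged over 6–8 library draws; coupon-collector statistics are
averaged over 25–50 draws (they cost milliseconds each). These sizes
hold Monte-Carlo standard errors on reported means to a few percent
while keeping the whole suite in the tens of seconds on one CPU.

## Known limitations

* Module independence makes P_{x,k}(N) an approximation for r > k and
  mildly optimistic near full coverage even at r = k.
* σ[N] from the CCP route assumes the same independence; it agrees with
  the simulator to within ~10 % in the regimes tested.
* The max_plants cap (default 10⁷) turns truly unreachable coverage
  (e.g. ε_KO = 0) into a diagnostic error listing uncovered
  combinations rather than a hang.
* Guide-level biology (sequence design, PAM constraints, off-target
  activity) is entirely out of scope; guides are abstract entities with
  a frequency and an efficiency.
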