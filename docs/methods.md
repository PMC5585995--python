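# Methods

## The problem

A mutation-accumulation (MA) experiment propagates replicate lines from a
single ancestor through repeated single-cell bottlenecks, letting
mutations fix nearly free of selection, then sequences each line to count
new mutations.  In ciliates such as *Tetrahymena thermophila* the
germline (micronuclear) genome is not directly sequenceable; instead,
*genomic exclusion* crosses produce lines whose somatic macronucleus
derives from a single haploid germline copy, so each descendant sample is
effectively haploid while the ancestor — sequenced as a pool of many
genomic-exclusion lines — exposes both alleles at heterozygous sites.

`macaw` implements the detection model for this design, the classical
consensus co-caller, the callable-sites denominator, and the rate
arithmetic; a simulator generates data under the same generative model so
every stage can be validated without sequencing data.

## Detection model

For one reference site the observed data are base-count 4-vectors
`R = (r_A, r_C, r_G, r_T)` for the ancestor and each of `n` descendants
(strand-split in the input, collapsed by the model; strand information is
used only by filters).  A *history* `h` assigns the ancestral diploid
genotype `G_A` (10 unordered values), a transmitted allele per line, and
each line's haploid outcome `G_i`.  The joint probability factorizes as

    P(R, h) = P(G_A; theta, pi)
              * DM(R_A | p(G_A, eps), phi_A)
              * prod_i [ P(G_i | G_A; pi, mu) * DM(R_i | p(G_i, eps), phi_D) ]

with the following components.

**Genotype prior** (finite sites, parent-independent mutation):
homozygote `{b,b}` has prior `pi_b/(1+theta) + pi_b^2 theta/(1+theta)`;
heterozygote `{b1,b2}` has `2 pi_b1 pi_b2 theta/(1+theta)`.  `1/(1+theta)`
is the autozygosity probability.

**Genotype likelihood**: Dirichlet-multinomial (DM) in
mean/overdispersion form, concentration `alpha = p * (1-phi)/phi`.
`phi = 0` is the multinomial; `phi -> 1` is maximally overdispersed.
Expected base frequencies `p` given a genotype and error rate `eps`:
`1-eps` (homozygous match), `1/2 - eps/3` (heterozygous match), `eps/3`
(mismatch).

**Transmission and mutation**: one ancestral allele is transmitted with
probability 1/2 each, then substituted under a rate-normalized F81 model,
`P[a->b] = exp(-beta*mu) delta_ab + (1-exp(-beta*mu)) pi_b` with
`beta = 1/(1 - sum pi^2)`, so the experiment-long `mu` equals the expected
number of substitutions per site to first order.  A history carries a
mutation in line `i` exactly when the transmitted allele differs from the
outcome — this makes the mutation indicator 0/1 per history.

The posterior probability of at least one (and of exactly one) mutation
is the ratio of restricted to total history sums.  The implementation
factorizes the sums per line (cost `O(10 * 4 * n)` per site) but is
tested to agree with full enumeration of all `10 * (2*4)^n` histories to
1e-10 in log probability.  All reductions are log-sum-exp; underflow
cannot occur by construction.

### Numerical notes

- The DM log-pmf uses log-gamma identities; for `omega = (1-phi)/phi >
  1e6` the gammaln differences cancel catastrophically, so the exact
  rising-factorial series over the integer counts is used instead, which
  makes the `phi -> 0` multinomial limit accurate to < 1e-6.
- Zero expected frequency with a positive count yields `-inf`, not an
  error; `phi = 1` is rejected (`omega` undefined).
- Read-count vectors repeat heavily across a genome, so likelihood
  tables and per-line history sums are computed once per distinct count
  4-vector and gathered — a ~5x speedup at genome scale with bit-exact
  results.
- Argmax ties for the mutant line/allele break lexicographically on base
  (A<C<G<T), then lowest line index.

## Calling and filters

A site is a candidate when `P(>=1 mutation) > 0.1` and passes when the
most probable mutant allele in the most probable mutant line is supported
by >= 3 reads in each orientation.  The threshold applies to `p_any`
(`p_one` is reported alongside); this is a documented choice, since at
MA-realistic parameters the two rarely disagree.  Sites where most of the
signal implies more than one mutation
(`(p_any - p_one)/p_any > 0.5`) are flagged as probable systematic error:
in an MA experiment independent double hits at one site are vanishingly
rare, while shared mismapping is not.

Two parameter profiles are shipped: `initial`
(`phi_A = phi_D = 0.001`, upstream mapping-quality contract 13) and
`final` (`phi_A = 0.03`, `phi_D = 0.01`, contract 25, strand filter on).
The larger ancestor overdispersion in the final profile lets the
heterozygous-ancestor history absorb low-level shared variants — the main
source of false positives under the initial profile.  The mapping-quality
numbers only document how the upstream pileup should be generated; they
are not applied by the model.

Defaults: `theta = 1e-4`, `mu = 1e-8` (experiment-long), `eps = 0.01`,
`pi` uniform.  The genome-matched choice for `pi` in an AT-rich ciliate
would be strongly biased; uniform is the neutral default because no
published vector is available, and `--pi` exposes it everywhere.

## Consensus co-caller

Per line, the consensus base must hold strictly more than 80% of the
line's reads with >= 3 forward and >= 3 reverse reads, else the line is
undetermined.  A mutation is called when exactly one line differs from
the unanimous consensus of all remaining lines; the ancestor participates
as a voting line by default (configurable).  Unanimity (rather than
majority) among the remaining lines is required — the stricter of the two
readings, chosen because the approach is explicitly the conservative arm
of the pair.  On clean simulations its calls are a subset of the
probabilistic caller's (tested).

## Callable sites

The rate denominator counts, per line, sites where a mutation would have
been detected.  Each line's counts are shuffled — by default the
deterministic cyclic label shift A->C->G->T->A applied to each strand —
relocating the dominant allele's reads onto a different base: a simulated
full-frequency mutation with the site's own depth and error profile.  The
posterior is recomputed with only that line shuffled; the site is missing
from the line if the shuffled `p_any < 0.1` or the most probable mutant
allele (evaluated in the focal line) lacks 3+3 strand support.  The cyclic
shift is chosen over a random permutation for reproducibility and because
it guarantees the simulated mutant allele differs from the dominant one;
a seeded random-permutation mode is provided as an alternative
interpretation.  Ancestor counts are never shuffled.

## Rate estimation

`mu_hat = sum_i n_i / sum_i L_i T_i` over lines with `n_i` validated
mutations, `L_i` callable sites and `T_i` generations;
`SE = sqrt(mu_hat / LT)` under per-line Poisson counts.  Two intervals
are reported: normal `mu_hat +/- 1.96 SE` truncated at zero, and
log-space `mu_hat * exp(+/- 1.96 SE/mu_hat)` (delta method on the log
scale).  The log-space interval is the one used for coverage testing:
at Poisson counts near 8 the normal interval's true coverage is ~89%
(standard small-count anti-conservatism) while the log interval's is
~96%.  An exact Garwood chi-square interval is available, and is the
recommended report when `n = 0` (the normal/log intervals degenerate; a
warning says so).  Genome-wide conversion multiplies by genome size
(default 104 Mb) and 1000 generations.  The expected number of missed
mutations extrapolates `mu_hat` into each line's non-callable fraction:
`mu_hat * sum_i (1-prop_i) * G * T_i`.

## Simulator

`simulate_experiment` is the generative model read forward: genotype from
the prior, transmission + F81 mutation per line, per-sample depths from a
negative binomial (mean 47x by default, matching typical MA sequencing;
size parameter `k = 20` as a realistic coverage overdispersion — variance
`m + m^2/k`), DM base counts (`phi_A` for the pooled ancestor, whose
heterozygous sites yield ~50/50 allele mixes; `phi_D` per descendant),
binomial strand split (0.5 by default).  The reference base is the
ancestor's canonical first allele, mimicking an ancestor-derived
assembly.  A truth table of all mutation events is emitted.

What the simulator does *not* emulate: mapping artifacts, indels,
reference errors, base-quality structure, or correlated errors beyond
the DM overdispersion.  A green end-to-end test therefore establishes
internal consistency of model, caller, callability and rate arithmetic —
not robustness to upstream artifacts, which the quality contracts and
strand filter address only heuristically.

## Known limitations

- Descendants are modeled as haploid (the genomic-exclusion design);
  diploid descendants would need a different transition and likelihood.
- Whether the transmission choice is marginalized inside or outside the
  F81 substitution differs only at O(mu^2); the separate-transmission
  reading is implemented.
- Counts are assumed pre-filtered for quality upstream; there is no
  per-base quality weighting.
- The published per-site interval for the *T. thermophila* data is not
  exactly reproducible from the stated formulas (see the genome-wide
  interval, which is); the package reports its own clearly labeled
  constructions.
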