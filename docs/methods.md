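# Methods

## Data model

Infinite-sites (ISM) data are binary haplotype-by-site incidence
matrices with per-haplotype counts; polarity is fixed (0 ancestral,
1 derived), so the data are rooted.  The sufficient statistic is the
gene tree: one node per segregating site plus a root, each node holding
the multiplicity of the allele whose mutation set is the node's root
path.  Non-segregating (all-zero) columns carry no information for the
likelihood and are dropped on read with a warning rather than rejected;
all-ones columns are accepted as mutations on the stem above the whole
sample.  Infinite-alleles (IAM) data are allele frequency spectra;
ISM data project onto them by forgetting the sites.

## Phylogeny tests

Both classic tests are implemented and must agree (this is
property-tested): the four-gamete test in its rooted form (a site pair
is incompatible when the gametes 01, 10, 11 all occur — carrier sets
neither disjoint nor nested) and in the classic unrooted form (all four
gametes including 00), and Gusfield's radix-sort/L-value algorithm,
linear in the number of matrix cells, which supplies the verdict used
by tree building.  When Gusfield's test fails, the witness pair is
recovered by a direct pairwise scan, so the reported pair always
violates the criterion on re-check.  Witnesses are the first violating
pair in column order, making reports deterministic.  Frequencies never
affect compatibility; only the set of distinct row patterns does.

Tree construction inserts each haplotype's mutation set along a
root-to-tip path ordered by decreasing carrier count (ties, i.e.
duplicate columns, keep input column order and become chains; the
likelihood is invariant to chain order because removal is sequential
either way).

## The exact recursion

For a configuration T with allele multiplicities n_k, sample size n,
and mutation rate θ (coalescent units, mutations at rate θ/2 per
lineage):

n(n−1+θ) P(T) = Σ_{S0} n(n_k−1) P(C_k T) + θ Σ_{S1} P(M_k T)
                + θ Σ_{S2} (n_i+1) P(M_k T),   P(MRCA) = 1.

S0: alleles with n_k ≥ 2 (coalescence, coefficient n(n_k−1) with n the
*current* sample size — the derivation conditions on the most recent
backward event: a coalescence occurs with probability (n−1)/(n−1+θ) and
the forward split reproduces T from C_k T with probability
(n_k−1)/(n−1); the mutation terms arise the same way with the uniform
lineage choice contributing 1/n or (n_i+1)/n).  S1/S2: singleton
alleles whose terminal mutation is removable, classified by whether the
parent type is absent (first kind) or present (second kind, merge
allele i).  The S1/S2 sums run over removable alleles exactly as
written, one term per allele, not over de-duplicated successors.

The engine first discovers all ancestral configurations by
breadth-first traversal from the data, de-duplicating by a canonical
key (children sorted recursively), then solves bottom-up by ascending
level.  This avoids deep call stacks and makes the per-level profile a
natural by-product.  Configurations are identified by the *labelled*
key (site identity preserved): identical shapes with different site
labels are distinct DAG nodes, so enumeration output names the actual
sites of the data.  Unlabelled (shape) keys exist separately and are
used only for matching against simulated data, whose site labels are
arbitrary.

Numerics: double precision by default; exact rational mode (Python
`Fraction`) for regression checking — the two agree to 10⁻¹⁰ relative
error on every tested dataset and the closed forms are met exactly in
rational mode.  Desk-scale inputs (tens of alleles, ~10 mutations) do
not underflow in double precision.  Counts (configurations,
genealogies) always use arbitrary-precision integers, since genealogy
numbers grow combinatorially.  A node-count cap (default 10⁷) turns
runaway inputs into a clean capped-run error; genealogy enumeration
takes an optional path cap with the same behaviour.  All output orders
(events, configurations, genealogies) are fixed by kind and
labelled-key/lexicographic tie-breaks, so repeated runs are
byte-identical.

### Labelled vs unlabelled probabilities

P(T) as computed is the probability of the *labelled* configuration.
For shapes with an automorphism the observable unlabelled pattern
frequency differs by the automorphism order: for n = 2 with one private
mutation on each lineage the recursion gives θ²/(1+θ)³ while the
probability of observing that unlabelled pattern is θ²/(2(1+θ)³); the
10⁵-replicate simulator reproduces the factor 2 (ratio ≈ 2.01
observed).  No correction factor is applied; the Monte-Carlo
comparisons used for validation are restricted to automorphism-free
shapes, where the two notions coincide.  For n = 2 the closed forms
are 1/(1+θ), θ/(1+θ)² and, for two mutations on one lineage,
θ²/(2(1+θ)³) — the chain shape has no automorphism ambiguity.

## Ewens sampling formula

P(spectrum) = n!/(θ(θ+1)⋯(θ+n−1)) × Π_j (θ/j)^{a_j} / a_j! with a_j the
number of alleles seen j times.  It is included as the analytic IAM
case; tests verify normalization over integer partitions up to n = 6
(exhaustive generator, 10⁻¹⁰) and consistency with the ISM recursion
on the n = 2 monomorphic sample (both 1/(1+θ)).

## Forward simulator

The simulator draws a standard coalescent: with k lineages the waiting
time is Exp(k(k−1)/2), a uniformly random pair merges, and mutations
fall on each lineage as Poisson(θ/2 per unit time), each creating a new
site.  This time scale makes the simulator commensurable with the
recursion (same θ), which the n = 2 closed forms confirm.  Randomness
comes from NumPy's seeded PCG64 generator; identical seeds give
byte-identical datasets, and the generator name is recorded in output
metadata.

What the simulator emulates — and what it does not: it produces exactly
the neutral, panmictic, constant-size, non-recombining ISM world the
recursion assumes, so agreement between the two validates the
implementation, not the model.  Real sequence data violate these
assumptions (recombination, population structure, size changes,
back-mutation at finite sites), and passing tests say nothing about
such effects.  Migration and recombination events are out of scope
throughout.

The Monte-Carlo oracle `mc_probability_estimate` matches simulated gene
trees to a target by unlabelled canonical key (shape and
multiplicities) and reports the hit fraction with its binomial standard
error.  Validation sizes: 10⁵ replicates per comparison, n = 2 and
n = 3 targets at θ = 1, acceptance within 3–4 standard errors;
conservation checks (counts vs enumerations vs level profiles) run on
50 simulated datasets restricted to level n + m ≤ 8, where exhaustive
genealogy enumeration stays in the thousands of paths.  These sizes
were chosen to keep the whole validation suite in the tens of seconds
while leaving standard errors around 1.5 × 10⁻³, far below the effect
sizes being checked.

## Design choices

* The recursion counts both the data configuration and the MRCA in
  "number of ancestral configurations"; other software may differ by
  up to 2.
* θ stays symbolic in event coefficients (integer factor × θ^{0,1});
  substitution happens once, in the recursion solver, which is what
  makes the exact-rational mode possible.
* The CLI is a thin layer: every subcommand maps 1:1 to a library
  function, payloads go to stdout as TSV or tree text, logs to stderr,
  and exit codes distinguish usage (2), incompatibility (3), capped
  runs (4) and domain errors (5).
* DOT and Newick exports are deterministic (canonical child order);
  Newick encodes multiplicities as a `_k` name suffix and uses no
  branch lengths, since gene-tree edges carry no time information.

## Known limitations

* Exact computation is exponential in n + m; the cap, not cleverness,
  is the guard.  The level profile exists precisely to study this
  growth.
* No missing data, multi-state characters, or imperfect-phylogeny
  repair; incompatible data are an error, not a fixable input.
* The ESF implementation uses double precision; for n beyond a few
  hundred a log-space variant would be needed.
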