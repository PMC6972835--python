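# Methods

This note documents the models, the default parameter choices and the
numerical decisions behind `clutchkin`, and what the simulation-based
validation does and does not establish.

## Exclusion paternity and minimum sibship partitioning

The analysis assumes the mother's multilocus genotype is known and
error-free enough that each hatchling shares at least one allele with her
at nearly every locus. Paternal candidate alleles are obtained by
subtraction: a hatchling allele is a candidate if its partner allele occurs
in the mother. Three cases arise per locus — a *certain* paternal allele
(exactly one resolution), an *ambiguous* pair (the hatchling's genotype is
a subset of the mother's, so either allele may be paternal), and a
*mismatch* (no shared allele), which is flagged and treated as
uninformative rather than dropped. A hatchling mismatching at more than two
loci is reported as a candidate foreign hatchling (mis-assigned nest,
contamination) and excluded with a warning.

The minimum father count is the smallest partition of the clutch into
sibships such that, at every locus, some resolution of the ambiguities
leaves at most two distinct paternal alleles per sibship — one diploid
father. Ambiguities are resolved *during* the search, not greedily
beforehand: per sibship and locus the search maintains the set of still
viable paternal allele pairs and updates it incrementally as hatchlings
join. The exact method is an iterative-deepening depth-first search
starting from the pigeonhole lower bound (max over loci of ⌈certain
alleles / 2⌉) and returning the first feasible partition in canonical
sorted-id order — deterministic and invariant to hatchling input order. A
node cap (500,000) bounds degenerate, weakly constrained instances; when
hit, the search advances to the next father count, so the result is then an
upper bound but still deterministic. A greedy first-fit method is provided
for comparison and serves as the search's sanity bound (exact ≤ greedy
always).

Multiple paternity follows the conservative rule for microsatellite clutch
data: MP requires three or more paternal alleles at two or more loci;
exactly one such locus is attributed to a germ-line mutation. Consistent
with that allowance, the partition may designate a single locus as mutated
and ignore it when doing so strictly lowers the father count
(`max_mutation_loci=1`, the default). With seven loci of 14–25 alleles this
collapses spurious two-father splits caused by one mutant allele while
leaving genuinely multi-sired clutches untouched, since the other six loci
still separate the sibships.

Reconstructed father genotypes carry only *certain* attributions: per locus
the alleles present in every feasible resolution (plus all certain
candidates). Two reconstructed fathers match when their attributed sets are
jointly consistent with a single diploid genotype (≤ 2 alleles per locus)
at all loci (optionally allowing a small number of mismatch loci); matching
is one-to-one, resolved by fewest mismatching loci then index order. This
conservative compatibility notion errs toward matching when attribution is
incomplete, which is the desired behaviour for counting *minimum* numbers
of distinct males.

This exclusion-plus-minimal-partition approach deliberately replaces
likelihood-based sibship software: at the locus diversity this panel is
designed for (combined PI ~ 10⁻¹²), exclusion is essentially decisive, and
the simulation-recovery experiments below quantify exactly how often it
matches truth.

## Mating-system classification

`p_f = (1 − f)^n` is the probability that a male with siring fraction `f`
of a well-mixed sperm store leaves no offspring among `n` independently
sampled hatchlings. For a father absent from the later clutch, `f` can be
estimated from the first clutch alone (`f_mode="first-clutch"`, the
well-mixed-store reading) or from both clutches combined
(`f_mode="combined"`). A father newly appearing in the second clutch is
always tested with the combined estimate (his offspring in both clutches
over both sample sizes) against the first clutch's sample size. The
significance level defaults to α = 0.05; `p_f < α` is labelled "unlikely
due to chance" (consistent with remating), otherwise "chance or sperm
depletion". The test is per father; no joint test for the simultaneous
disappearance of several fathers is attempted, because a well-defined joint
null would need a model of dependence between their sampling fractions.

Sampling detection power for multiple paternity is `1 − Σ f_i^n` (the
disjoint events "all n hatchlings share sire i"); with 20 hatchlings and
two even sires this exceeds 0.999998, which is why 20 is the conventional
per-clutch sample size.

The breeding sex ratio divides distinct inferred males by females, after
matching reconstructed fathers within each female across her clutches
(stored sperm counts once) and across females (a male mating with several
females counts once). Both an all-clutch and a first-clutch-only scope are
reported; the worked-example all-clutch ratio of 1.46 used in the
extrapolation example is carried as a printed input because its original
accounting is not reconstructible from the printed per-clutch counts
alone. Population extrapolation rounds to the nearest integer at each
step (females = nests / clutch frequency, males = females × BSR); this
convention reproduces all four bounds of the worked example, where
floor/ceiling conventions do not. The Fisher's-exact comparison of two BSR
estimates builds the 2×2 table from (fathers, females) of each estimate;
the construction is documented here because the original table is not
published.

## Marker-panel statistics

Per locus with allele frequencies `p_i` and `a_k = Σ p_i^k`:

- PI = `2 a₂² − a₄`; combined multiplicatively across loci.
- PE₂ (one parent known) = `1 − 2a₂ + a₃ + 2a₄ − 3a₅ − 2a₂² + 3a₂a₃`.
- PE₃ (no parent known, candidate parent pair) =
  `1 + 4a₄ − 4a₅ − 3a₆ − 8a₂² + 8a₂a₃ + 2a₃²`.
- Combined PE = `1 − Π(1 − PE_l)`.

These polynomials are treated as conjectures, not trusted identities: the
test suite checks them against a brute-force enumeration over all
mother/offspring/candidate genotype combinations weighted by
Hardy–Weinberg frequencies, to 10⁻¹², for loci of up to five alleles. The
Hardy–Weinberg test is a Monte-Carlo exact test (alleles permuted into
random diploid pairings, χ² distance from HWE proportions as the statistic,
default 10,000 replicates, seeded) rather than the asymptotic χ², because
genotype tables at 14–25 alleles are extremely sparse. The
duplicate-genotyping error rate is plain discordance — mismatched allele
calls over calls compared, with unordered pairs aligned to maximise
agreement and loci with missing calls skipped — not a maximum-likelihood
per-allele error model.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
the scale the analysis is designed for: 16 females; 2 clutches each, a
third for every fourth female; ~100 eggs per clutch with 20 sampled
(~1/5); seven loci with 14–25 alleles drawn from a symmetric Dirichlet
(concentration 1.0); adults in Hardy–Weinberg equilibrium. Fathers per
female default to 1 with probability 0.75 (the observed predominance of
single paternity) and 2–5 otherwise; siring proportions are a symmetric
Dirichlet with concentration 2.0 (moderately even contributions, matching
the 40–60% splits typical of multi-sired clutches). Remating is off by
default; when enabled, a new male enters the second clutch at a fraction
drawn uniformly from 0.3–0.7. Mutation is single-step (± one repeat unit,
equiprobable) at a default rate of 0, since no empirical rate is available
for this panel; genotyping error replaces a recorded call with a uniform
draw from the locus's allele set at a default rate of 0, a model under
which duplicate-genotyping concordance can emulate a ~2% observed
discordance rate. Nest inventories draw hatching success at 0.65 with ~2%
in-nest stragglers, giving emergence success near 0.6, typical of a hot
incubation season. All draws flow from one root seed through spawned
`numpy` SeedSequence streams, so runs are bit-reproducible.

What the generator does *not* emulate: null alleles, allelic dropout and
stutter artefacts; linkage or population structure; temporal trends in
clutch size or sex-determining incubation temperature; sperm stratification
(the store is well-mixed by construction). Passing recovery tests therefore
show the inference is correct *under its stated assumptions*, not that it
is robust to those artefacts — on real data the marker-diagnostic stage is
the guard.

## Validation experiments and problem sizes

The test suite validates the core against independent oracles: exhaustive
set-partition enumeration (minimum father count, 200 random instances of up
to 8 hatchlings, group feasibility by brute force over ambiguity
resolutions); trio enumeration for PI/PE; a numerical surface integral for
the ellipsoid area approximation (within 1.2% at adult-loggerhead scale);
and truth-labelled simulations. Recovery experiments use five simulated
seasons (~180 clutches): among clutches where every sire has at least two
sampled offspring, the inferred minimum father count matches truth in ≥
95% (observed: 100%). The remating classifier is scored on 1,000 replicates
each of a planted-remating pattern (new male at combined fraction 0.3) and
a storage-only pattern: ≥ 99% of planted events are flagged, ≤ 5% of
storage-only replicates raise any flag. These sizes keep the whole suite
under a minute while leaving the binomial error of each rate estimate well
below the margins being asserted.

## Numerical choices and degenerate inputs

- Half-ellipsoid surface area uses the Thomsen-type approximation with
  exponent 1.6, divided by two (only the dorsal surface is measured). The
  depth semi-axis `c` is recovered by numerically inverting Ramanujan's
  ellipse-perimeter approximation, pairing `c` with the length semi-axis
  `a = SCL/2` and equating the half perimeter to CCL (tolerance 10⁻⁹).
  The pairing of `c` with the length axis is a documented, swappable
  choice; CCL ≤ SCL has no positive solution and raises an
  invalid-geometry error. Surface areas are reported in cm².
- Emergence success with zero eggs, error rates with zero comparable
  calls, and Hardy–Weinberg tests on monomorphic loci are flagged
  (NaN/exception) rather than silently coerced.
- t tests report both one- and two-tailed p-values, since the tail
  convention of historical analyses is not always stated; degrees of
  freedom are always the computed ones.
- Frequency estimates are renormalised so per-locus sums are exactly 1;
  missing allele calls (coded 0) never enter denominators.

## Known limitations

- Exclusion has no error model: a genotyping error in a hatchling can
  create a spurious paternal allele. The single-mutation allowance absorbs
  one such locus per clutch; higher error rates require the duplicate-rate
  diagnostic and data cleaning upstream.
- Father matching is by compatibility of partially reconstructed
  genotypes; with few informative loci it can merge distinct males
  (deflating the BSR). At the default panel diversity the simulation
  experiments bound this risk, but panels much below ~10 alleles per locus
  deserve a dedicated sensitivity check.
- The minimum father count is a lower bound by construction; rare sires
  with a single sampled offspring are undercounted, which the eligibility
  condition of the recovery experiment makes explicit.
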