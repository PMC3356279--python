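# Methods

This note documents the models and procedures `kinnet` implements, the
choices made where the design was genuinely open, and what the synthetic
generator does and does not emulate.

## Observation model and network construction

The unit of analysis is the dyad within one group-year. Three networks are
built per group-year:

- **Association (undirected).** A focal sample records one focal animal
  and every individual within the sampling radius; the sample therefore
  defines a single spatial cluster. Co-occurrence is counted for *every*
  pair in the cluster, focal–neighbour and neighbour–neighbour alike —
  this keeps the per-dyad tallies symmetric and treats the radius as a
  property of the cluster, not of the focal. Tie weights are half-weight
  indices `HWI = X / (X + 0.5(Ya + Yb) + Yab)`. `Yab` (both seen, separate
  parties) is structurally supported but is 0 for single-group observation
  streams. A dyad in which either member was never seen has no defined
  index; it is masked, reported, and excluded downstream — never imputed
  as 0, which would conflate "unsampled" with "avoid each other".
- **Grooming (directed).** Entry (i, j) counts bouts i groomed j. A
  mutual-grooming bout increments both directions by one; the field
  protocol records mutuality without resolving initiative, and one count
  in each direction is the representation that preserves total effort.
- **Aggression (directed).** Entry (i, j) counts decided contests i won
  against j. Orientation follows the outcome (winner → loser), merging
  directed aggression with food-possession outcomes under a single winner
  definition, so the matrix expresses dominance rather than initiation.

**Centrality.** In/out-strength is the column/row sum of tie weights;
normalised strength divides by group size minus one (the number of
possible partners). Eigenvector centrality is the dominant eigenvector of
the weighted adjacency, computed on the symmetrised matrix `(M + Mᵀ)/2`
for directed input — symmetrisation guarantees a real dominant eigenpair
with a non-negative eigenvector — and max-scaled to 1. Disconnected
components are scored separately; isolates score 0. Field studies have
normalised strength in more than one way, so the raw values are always
reported alongside.

## Genetic analyses

**Allele frequencies** are counted from a reference panel, by default the
adult individuals of the population pooled across groups (adults are the
demographically stable residents; a flag widens the panel to everyone).
Loci untyped in the whole panel are dropped; monomorphic loci are flagged
uninformative.

**Pairwise relatedness** uses the Queller–Goodnight estimator. Per locus,
with reference individual x = (a, b) and partner y = (c, d):

    num_x = 0.5 (I[a=c] + I[a=d] + I[b=c] + I[b=d]) − p_a − p_b
    den_x = 1 + I[a=b] − p_a − p_b

Aggregation is ratio-of-sums: numerators and denominators are summed over
loci before dividing (stable when loci are few), then the two reference
directions are averaged, which makes the estimate symmetric. Loci whose
denominator contribution is zero for a direction (reference homozygous for
a fixed allele) carry no information in that direction and are skipped;
loci missing in either member are skipped pairwise. A dyad with no shared
informative locus is undefined and excluded from downstream means. By
default the focal pair is *not* removed from the frequency panel
(`exclude_pair_from_freqs=False`); the flag exists because some programs
apply that bias correction, and with the small panels typical of field
studies the choice is visible in the estimates.

**Maternity by exclusion.** A candidate mother mismatches an offspring at
a locus when the two share no allele there. The unique candidate with at
most `max_mismatch` mismatching loci is assigned; zero or several passers
leave the offspring unassigned (exclusion gives no likelihood ordering
among passers, so ambiguity is not broken by mismatch count). Default
`max_mismatch = 0`, because duplicate genotyping keeps error rates low; a
tolerance of 1 is available to absorb residual genotyping error.

**Predictor matrices.** The mother–offspring matrix codes 1 only for
(adult female, her *juvenile* offspring) dyads — mother–subadult dyads are
0, so the predictor captures active maternal care of dependent young.
Homophily matrices code 1 when both members are the same sex, or both
belong to a named age class.

## MRQAP with double semi-partialing

OLS is fitted over the off-diagonal dyad cells (both cells for directed
matrices, each unordered dyad once for undirected). Inference is by node
permutation because dyads sharing an individual are not independent.
For each predictor X_i: X_i is regressed on the other predictors, the
residuals are reshaped to a matrix E_i, E_i is node-permuted (rows and
columns relabelled together), the permuted residuals replace X_i, and the
full model is refitted; the p-value is the add-one-rule fraction of
permuted |slopes| reaching the observed one. Residualising before
permuting is what makes the test for one predictor robust to the others
(the double-semi-partialing property); with a single predictor it reduces
to classical dependent-matrix-permutation QAP, and the test suite verifies
that equivalence.

Numerical implementation: the permutation refits use the
Frisch–Waugh–Lovell identity — the coefficient on the permuted column
equals the simple slope between the permuted column and the dependent
variable after both are projected off the remaining predictors — so all
permutations are evaluated as vectorised array operations. The results are
mathematically identical to refitting the full model per permutation.

Choices: 2000 permutations by default (add-one p floor ≈ 0.0005);
two-tailed by default with one-tailed variants behind a flag; ties counted
with ≥ (conservative); undirected residual matrices are symmetric by
construction, preserving the exchangeability structure; dyads undefined in
any matrix are dropped listwise with a recorded count; rank-deficient
designs raise a collinearity error naming the predictors.

## Coalitionary support

The random-support null assumes each recorded event has exactly one
adult-female supporter drawn uniformly among that group-year's adult
females, mother included. The expectation of mother-support is then
`Σ_events 1/F(group-year)` when the juvenile's mother is present, which is
linear in events. The non-mother share is reported as a whole percent;
events whose supported juvenile has unassigned maternity are excluded and
logged. The supporter-relatedness comparison pools supporter–juvenile r
values against all defined within-group dyads (supporter dyads included in
the pool by default, mirroring a complete-pool comparison; excludable by
flag) and reports the one-way ANOVA F with both the parametric p and a
label-permutation p — the permutation p is the honest one, since dyadic r
values are not independent.

## Synthetic-study generator

The generator emulates a small female-philopatric society. Reference
conditions (the defaults):

| parameter | default | rationale |
|---|---|---|
| groups × years | 2 × 2 | four group-year analysis units |
| composition per group-year | 4 AF + 1 AM + 3 SA + 6 JU (n = 14) | mid-range group size; single resident male |
| loci | 15, 2–7 alleles each (uniform), Dirichlet(1) founder frequencies | realistic microsatellite richness, mean ≈ 4.5 alleles |
| focal samples per group-year | 800, baseline neighbour probability 0.15 | ≈ 2 neighbours per sample |
| association multipliers | mother–juvenile ×3, juvenile–juvenile ×2 | recoverable kin/homophily signal |
| grooming base rates (events per directed dyad) | AF 1.2, AM 0.3, SA 0.4, JU 0.2 | adult females groom most |
| grooming multipliers | mother–juvenile ×8, adult–adult ×2, adult-male recipient ×3 | strong maternal bond; male attraction |
| aggression rates | AM 2.0, JU-M 1.0, AF 0.6, SA-M 0.5, JU-F 0.4, SA-F 0.3 | class-based only, no kin terms |
| coalition events per group-year | 10, mother weight w = 3 | with 4 females, P(mother) = w/(w+3) = 0.5, twice the random 0.25 |

Pedigree: juveniles and subadults are assigned mothers uniformly among the
group's adult females; offspring inherit one maternal allele and one
paternal gamete drawn from the population frequencies — fathers are not
modelled as individuals because only maternity is analysed. Each
group-year is an independent unit with its own pedigree (no demographic
turnover or multi-year pedigree growth). A `genotyping_error` knob
(default 0) re-draws alleles at a per-allele miscall rate to exercise the
maternity mismatch tolerance. All randomness flows from one scenario seed
through named substreams per stage, so any single stage can be regenerated
independently and emitted files are byte-identical across runs.

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: spatially explicit movement (association
is i.i.d. per sample, with none of the temporal autocorrelation of real
focal streams), observation effort bias toward particular classes,
dispersal and mortality within a year, genotyping artefacts beyond simple
miscalls (null alleles, allelic dropout, linkage), and reciprocity or
exchange dynamics in grooming. Calibration results on synthetic data bound
the estimators' behaviour under the stated sampling model only.

## Problem sizes used in validation

The statistical checks run at these sizes: MRQAP type-I calibration on 500
null 12-node datasets at 500 permutations (rejection within [0.03, 0.07]
per predictor); power/confound recovery over 200 single-group-year
replicates at the default effects (maternal term ≥ 90% significant,
relatedness ≤ 20%); estimator calibration on 500 parent–offspring and 500
unrelated dyads (means within 3 SEM of 0.5 and 0); coalition null coverage
over 300 studies (≥ 93% inside the central 95% binomial envelope);
maternity recovery over 150 pedigrees (≥ 90% correct at zero mismatch
tolerance). The acceptance script repeats the same computations at
comparable sizes from a caller-supplied seed.

## Known limitations

- Published strength-centrality tables from field studies are often on a
  normalisation other than raw/(n−1); raw values are exported so any
  rescaling can be applied, but cross-study numeric comparisons of
  normalised strength are not meaningful without knowing the convention.
- Exclusion maternity is conservative: with few loci or close relatives
  among candidates it returns "unassigned-ambiguous" rather than a best
  guess; likelihood-based parentage is deliberately out of scope.
- The DSP permutation distribution treats the dyad mask as fixed;
  matrices with many undefined dyads lose power and, in the extreme, the
  listwise-dropped cell set may no longer be exchangeable.
- Relatedness estimates from small adult panels inherit panel sampling
  error; group-mean r values should be read with the panel size in mind.
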