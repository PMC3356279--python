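# kinnet

Kinship and age-sex homophily analysis of animal social networks, built for
behavioural ecologists studying small, individually recognisable social
groups (the reference system is a female-philopatric carnivore society with
resident adult females, one adult male, and cohorts of subadults and
juveniles).

The package answers one question end to end: **do kinship and age-sex class
similarity predict who associates with, grooms, and fights whom?** It takes
field observation records and microsatellite genotypes and produces
network matrices, relatedness and maternity estimates, matrix-permutation
regressions, and a coalition-support analysis — plus a synthetic-study
generator with known ground truth so every stage can be validated.

## Methods at the core

**Half-weight association index.** For a dyad (a, b) over focal samples,

```
HWI = X / (X + 0.5 * (Ya + Yb) + Yab)
```

where X counts samples with both present, Ya/Yb samples with only one, and
Yab samples where both were seen but in separate parties. The index
corrects co-sighting counts for unequal sampling effort; 1 means always
together, 0 never together. Grooming and aggression networks are directed
count matrices (aggression ties run winner → loser).

**Queller–Goodnight relatedness.** For individuals x = (a, b) and
y = (c, d) at a locus, with reference allele frequencies p,

```
num_x = 0.5 * (I[a=c] + I[a=d] + I[b=c] + I[b=d]) - p_a - p_b
den_x = 1 + I[a=b] - p_a - p_b
```

Numerators and denominators are summed across loci before dividing, the
two reference directions are averaged. Expectation: 0 for unrelated dyads,
0.25 for half-siblings, 0.5 for parent–offspring. Maternity is assigned by
exclusion (a unique candidate mother with no allele-sharing mismatch).

**MRQAP with double semi-partialing.** OLS of a dependent dyadic matrix on
predictor matrices (mother–offspring, relatedness, sex/age homophily),
with permutation inference: each predictor's residual matrix (after
regressing it on the others) is node-permuted and the full model refitted;
the two-tailed p-value uses the add-one rule. This respects the
non-independence of dyads sharing a node.

**Coalition-support null.** Observed mother-support counts are compared to
the expectation if, per event, one adult female of the juvenile's
group-year supported it uniformly at random: `E = Σ 1/F(group-year)`.
Supporter–juvenile relatedness is compared to the group dyad pool with a
one-way ANOVA F plus a label-permutation p.

## Worked example

```python
from kinnet import SyntheticScenario, run_end_to_end

scenario = SyntheticScenario(n_groups=1, years=(2003,), seed=1)
bundle = run_end_to_end(scenario, n_permutations=1000)

print(bundle["mrqap"][("G1", 2003)]["grooming"].to_frame().to_string(index=False))
cs = bundle["coalition_summary"]
print(f"coalition events: {cs.n_events}, mother-supported: {cs.n_mother_support} "
      f"(expected {bundle['expected_mother_support']:.1f} under random support), "
      f"non-mother share: {cs.nonmother_percent}%")
```

prints

```
       predictor     slope  slope_std        P
mother_offspring  5.505749   0.546845 0.000999
     relatedness  0.642979   0.072696 0.181818
             sex -0.242428  -0.048157 0.306693
           adult  2.239073   0.280268 0.001998
        subadult -0.277182  -0.019808 0.646354
        juvenile -0.548620  -0.081468 0.105894
coalition events: 10, mother-supported: 6 (expected 2.5 under random support), non-mother share: 40%
```

The generator put a maternal grooming effect into this study: the
mother–offspring predictor carries it (slope 5.5 extra grooming bouts per
dyad, p ≈ 0.001 at 1000 permutations), while pairwise relatedness — which
is collinear with motherhood but carries no independent effect — is
correctly non-significant once the mother–offspring matrix is in the
model. Mothers supported their juveniles 6 times against the 2.5 expected
under random female support (the default maternal support weight roughly
doubles the random rate).

The same stages are available from the shell:

```
kinnet simulate --seed 3 --out study/
kinnet build-nets --roster study/roster.csv --focal study/focal_samples.csv --out nets/
kinnet relatedness --roster study/roster.csv --genotypes study/genotypes.csv --out rel/
kinnet mrqap --dep nets/association_matrix.csv --pred relatedness=rel/relatedness_matrix.csv --undirected --out out/
kinnet coalitions --roster study/roster.csv --events study/coalitions.csv --maternity rel/maternity.csv --out out/
```

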