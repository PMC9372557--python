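# Methods

## Problem and pipeline

The package ranks alternative diet patterns on joint health,
environmental and socio-economic performance. Four stages are chained:
eligibility screening of candidate concepts, aggregation of study-level
evidence into a decision matrix, derivation of criterion weights from
expert pairwise comparisons (AHP), and ranking by closeness to the
ideal solution (TOPSIS). Each stage is usable on its own; `run`
executes the chain and records everything needed to reproduce the run
(input digests, seed, warnings) in a JSON report.

## Screening

A concept dossier passes through four sequential steps: region
applicability; a minimum count of implementation studies (default 5);
a per-sub-criterion quality cut-off — each of *sample size ≥ 5,000
participants*, *women and children included*, and *duration ≥ 4 years*
must be met by at least 60% of the concept's studies; and availability
of both environmental and health outcome data. Design choices:

- The 60% cut-off is applied **per sub-criterion**, not to the
  conjunction of sub-criteria within a study: each of the three
  predicates independently needs a ≥ 60% passing fraction. This is the
  most literal reading of a per-sub-criterion cut-off; applying it to
  the conjunction would be strictly stricter.
- Fractions are compared with ≥, so exactly 60% of studies passing
  (6 of 10) counts as a pass — the cut-off is attainable.
- Evaluation short-circuits at the first failing step; later steps are
  reported as not-evaluated (`None`), distinct from `False`, mirroring
  blank cells in a selection table.
- The demography predicate is a single boolean (women and children
  included), as no finer demographic rule is defined.
- Region applicability is a single user-supplied flag per concept; the
  package does not attempt to infer it from study countries.

Monotonicity holds by construction: adding a passing study can only
raise passing fractions and counts, and tightening any threshold can
only shrink the selected set.

## Evidence aggregation

Study-level outcomes are percent changes relative to the baseline
(current US) diet. Sign convention: **positive = reduction, negative =
increase** (a 17% increase in energy use is stored as −17). Cells of
the diet × criterion matrix are unweighted arithmetic means of their
observations — no inverse-variance weighting, since study variances are
not part of the input format. Missing cells are never filled silently:
under the default policy they raise an assembly error naming the cell;
under the proxy policy they may be covered by observations explicitly
flagged as proxies (values borrowed from comparable high-income
countries), which is counted and echoed into the run report.

Food-group relative risks are classified by the standard rule — RR > 1
increased risk per additional daily serving, RR < 1 decreased, RR = 1
neutral — and summarized per food group by the arithmetic mean.

### Orientation

Each criterion carries an objective (minimize or maximize) describing
the underlying quantity. The ranking stage needs a benefit/cost
orientation for the *values actually in the matrix*, which depends on
their semantics:

| objective | raw impact | percent reduction |
|-----------|-----------|-------------------|
| minimize  | cost      | benefit (larger reduction of a burden is better) |
| maximize  | benefit   | rejected as contradictory |

A maximized quantity expressed as its own reduction has no coherent
orientation, so that combination is a configuration error rather than
a guess. Ten of the eleven default criteria are minimized burdens; only
socio-economic savings is maximized, and its values must therefore be
supplied as raw impact (or the criteria set adjusted) when
percent-reduction semantics are used.

## AHP weighting

Weights are derived by the arithmetic-mean (column normalization)
method: each column of the judgment matrix is divided by its sum and
the rows of the normalized matrix are averaged. For a perfectly
consistent matrix (a\_ij = w\_i/w\_j) this recovers the generating
weights exactly; the principal-eigenvector method is implemented only
as an independent test oracle, and the two agree within L∞ ≤ 0.02 on
matrices passing the consistency gate (verified empirically over 1,000
seeded matrices).

λ\_max is estimated as the mean of (Mw)\_i / w\_i, which equals the
matrix order n exactly under consistency and is ≥ n for every
positive-reciprocal matrix (each reciprocal pair contributes
t + 1/t ≥ 2 to the sum). Consistency uses CI = (λ\_max − n)/(n − 1)
and CR = CI/RI(n) with Saaty's classical random-index table
(RI(3) = 0.58 … RI(11) = 1.51 …); the table is overridable since
published variants differ slightly for n ≥ 12. The pass rule is strict:
CR < 0.1 passes, CR = 0.1 fails. Orders 1–2 are consistent by
construction (RI = 0, CR defined as 0).

Multiple experts are combined by the element-wise geometric mean — the
only aggregation rule that preserves reciprocity — before weight
derivation; aggregated entries are clipped back to [1/9, 9] with a
logged warning if expert disagreement pushes them off-scale.

## TOPSIS ranking

Vector normalization (r\_ij = x\_ij/√Σ\_i x\_ij²) is used as stated by
the method definition, not min–max scaling. Negative entries (percent
increases) pass through with their sign preserved; the positive/negative
ideal construction (column max/min for benefit criteria, reversed for
cost criteria) is unchanged by them. Separations are exact Euclidean
distances in the weighted normalized space, and the closeness
coefficient CC\* = D⁻/(D⁻ + D⁺) is ranked descending.

Numerical conventions:

- Ties in CC\* (within 1e−12) are broken lexicographically by
  alternative id and flagged in the result.
- A single alternative makes CC\* = 0/0; it is defined as 1 with a
  warning.
- An all-zero criterion column cannot be normalized and is rejected by
  name.

CC\* is scale-invariant per column (multiplying a raw column by c > 0
cancels in normalization), equivariant under row permutation, and
preserves dominance: an alternative at least as good on every oriented
criterion never scores lower. These invariances are property-tested
over 1,000 seeded random matrices each.

## Synthetic data

The generators emulate the two empirical inputs of a real evaluation:

- **Expert matrices**: a consistent matrix a\_ij = w\_i/w\_j built from
  target priorities whose ratio spread fits the 1–9 scale, with
  log-normal multiplicative noise on the upper triangle (mirrored as
  reciprocals, clipped to scale). Because CR has no closed-form inverse
  in the noise scale, a target CR band is reached by rejection
  sampling, and the achieved CR is verified through the AHP machinery
  rather than assumed. Default noise 0.1–0.15 yields matrices that
  typically pass the 0.1 gate on the first draw.
- **Performance matrices**: percent-reduction values drawn uniformly in
  [−20, 90]% — spanning the reported range from moderate increases to
  large reductions across diet concepts — over minimized criteria, so
  every column is benefit-oriented. An optional planted alternative is
  set to the column-wise maximum of all other rows plus a margin
  (≥ noise_scale, at least 1 point), making it dominant by
  construction; dominance implies rank 1 for any positive weights,
  which is the generator's testable ground truth.
- **Study dossiers**: studies engineered so the first failing screening
  step equals a declared profile under the configured thresholds
  ("step2" → one study below the minimum count; "step3" → half the
  studies below the duration cut-off while the other sub-criteria
  pass; "step4" → no environmental outcomes). The packaged 17-concept
  profile reproduces the published selection pattern, including which
  step excluded each concept, and yields 9 selected concepts.

All generators are pure functions of their arguments and seed; repeat
calls are byte-identical. What the synthetic data does **not** emulate:
correlated criteria (real health and environmental reductions co-vary
across diets), heterogeneous study precision, non-uniform effect-size
distributions, and systematically biased expert panels. Passing tests
therefore demonstrate correctness of the decision machinery and its
invariances, not calibration against any real survey or cohort data.

## Problem sizes and tolerances

Property suites run 1,000 seeds at 3–8 criteria and 6–8 alternatives,
sizes at which every invariant is exercised (including degenerate and
tied cases) while the whole suite runs in seconds. Exact-recovery
assertions use 1e−12 (accumulated floating-point error in column
normalization); the arithmetic-mean-vs-eigenvector band of 0.02 is an
empirical tolerance valid under CR < 0.1. The consistency arithmetic at
11 criteria reproduces a reported CR of 0.091 from CI = 0.14 within
±0.005 (0.14/1.51 = 0.0927); the residual gap is consistent with the
reported CI being rounded from ≈ 0.138.

## Known limitations

- The exact survey indicator matrix and the full 9 × 11 performance
  grid live in non-redistributable supplementary material; the pipeline
  accepts such files when supplied, and the same code paths are
  validated on synthetic stand-ins with known ground truth instead.
- Rank-reversal on adding/removing alternatives — a known property of
  TOPSIS with data-dependent ideals — is not mitigated; alternative
  MCDM back-ends (ELECTRE, PROMETHEE, VIKOR) are out of scope.
- Weight derivation is limited to the arithmetic-mean method;
  fuzzy/interval judgments and incomplete matrices are not supported.
- Aggregation ignores study precision and between-study heterogeneity;
  the evidence stage consumes reported outcome values and never
  recomputes the underlying LCA footprints or cohort relative risks.
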