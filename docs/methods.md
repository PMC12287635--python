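# Methods

This note documents the models, procedures and design choices behind
`caniact`: what each stage assumes, which parameters matter and why their
defaults are what they are, what the synthetic data do and do not emulate,
and the numerical details a maintainer would otherwise have to reverse
engineer.

## The causal graph

The shipped DAG (`caniact/data/activity_dag.txt`) encodes the working
hypotheses about daily dog activity: location type and owner age influence
both which dog a household keeps (breed size) and how active it is, making
them confounders of every dog-attribute → activity relation; unhealthy
diagnoses and injury are *mediators* of age, size, weight and neuter status
rather than confounders, so they are deliberately not adjusted for when the
total effects of dog attributes are the target; daily weather is a latent
mediator between climate/season and activity; the environmental exposures
themselves (season, day type, owner age, location) have no unblocked
backdoor paths. The file is an editable modelling input: change it and the
adjustment sets and implied independences change with it.

Algorithms. d-separation is delegated to networkx's reachability-based
implementation and is verified in the test suite against an exhaustive
path-enumeration oracle (every undirected simple path, textbook blocking
rules) on hundreds of random graphs. Minimal backdoor adjustment sets are
enumerated by subset search over observed eligible nodes, pruned to the
ancestors of exposure and outcome in the exposure-outedge-cut graph — every
inclusion-minimal separator lies inside that ancestor set, so the pruning
is lossless; an explicit guard (25 observed nodes) refuses graphs where
enumeration would blow up. Minimal separating sets for implied
independences use the same ancestral pruning; the smallest-cardinality set
wins, ties broken lexicographically. Pairs connected only through a latent
mediator have no observed separator and are omitted from the testable list.

Consistency testing regresses both claim variables on the conditioning set
(ordinary least squares, drop-first indicator contrasts for categoricals)
and t-tests the correlation of the residuals. For multi-column blocks
(categoricals with more than two levels) the minimum pairwise p-value is
Bonferroni-corrected — conservative, but it reduces exactly to the plain
partial-correlation test in the scalar case, which is the case the
calibration guarantee covers. Claims with a constant column are returned
untested with a warning rather than failing the batch. When the pipeline
tests claims on its own linked table it first collapses to one randomly
chosen row per dog, because repeated rows of one dog are not independent
draws and would make the tests anti-conservative.

## The synthetic cohort

`SimulationConfig` defines the data-generating process; its defaults are
the package's standing study conditions:

| parameter | default | rationale |
|---|---|---|
| visits/dog-year | 3 | primary-care visit frequency at population scale |
| study window | 2 years | enough within-dog calendar variation |
| records/dog | mean 100, NegBin(shape 2) or fixed | heavy right skew of device wear |
| τ² (dog intercept var) | 0.2 | between-dog share ≈ half of log-scale noise |
| σ² (residual var) | 0.2 | log-scale day-to-day noise |
| anomaly_prob | 0.21 | fraction of days outside 10–600 min |
| unlinkable_prob | 0.10 | dogs whose keys disagree between sources |
| intercept | 3.40 (+0.005·latitude) | ≈ 38 active min/day for a reference dog |

Daily active minutes are generated multiplicatively: the log of minutes is
a linear predictor over age⁻², linear age, breed size, weight status, sex,
neuter status, owner age band, location type, latitude, climate, season and
day type, plus three interaction blocks (per-size age slopes, season ×
climate, weekend × owner age), plus the dog's random intercept and Gaussian
noise. Effect presets follow the sign/magnitude patterns reported for
population-scale dog-activity data; they are labelled presets, not
reproductions of any real-data fit. The breed-size × age interaction is
parameterised as per-size deviations from a global linear age slope — the
published pattern (steeper decline for larger breeds) is a linear-age
phenomenon, and a reference-level interaction coefficient only makes sense
in a per-size-slope coding. Ages are fractional years from birth date.

Two artefact channels give the cleaning stages real work: with probability
`anomaly_prob` a record is replaced by a draw outside [10, 600] minutes
(half below, half above), and a fraction of dogs get one EHR-side key field
perturbed (variant name spelling or birth month off by one), making exact
matching fail for them. Visit weights are drawn as ideal weight × 1/0.8
(BCS 4) or × 1/0.6 (BCS 5) with 3% lognormal measurement noise, so the
published weight correction inverts them in expectation.

What the generator does **not** emulate: raw accelerometer signals, real
geography or climate-zone assignment, breed text labels, within-dog changes
of weight status or neuter status over the window (both are held at the
dog's typical value so that linked-visit covariates coincide with the
generating covariates), informative visit timing, and device-wear
selection. Passing tests therefore demonstrate that the pipeline's
machinery is correct and calibrated under the stated process — not that
real dog data satisfy these assumptions.

## Linkage and cleaning

Matching is exact on the normalised key (household, species, sex, name —
lowercased, trimmed, punctuation-stripped — and birth month/year); keys
with zero or multiple candidates on either side are excluded and reported
rather than guessed. Each daily record joins the visit with the greatest
`visit_date ≤ date` within 365 days ("within one calendar year" is read as
≤365 days, resolved by day count); same-day visits qualify.

The cascade order is bounds → ratio → age window → minimum records. The
order of these stages is a documented package choice; every stage logs
rows/dogs in and out so alternative orders can be audited from the flow
report. Boundary semantics: minutes exactly 10 or 600 are kept; ages must
be strictly >1.5 and <12 years at both dates; the ratio (linked activity
rows per distinct linked visit, computed per dog when the cascade first
runs and frozen into a column) must be ≥5; dogs need strictly more than 7
surviving rows. Freezing the ratio makes the cascade idempotent even
though later stages can reduce a dog's rows below five per visit.

Dogs are assigned a breed size from the mean of BCS-corrected *adult*
(>1.5 years, matching the cohort bound) visit weights; the 9-point BCS
scale maps two-to-one onto the 5-point scale, extrapolating 1→1, 2–3→2
below the printed range. The healthy-visits subset keeps rows whose linked
visit is classified healthy (no chronic-illness diagnosis, a
preventive-care visit reason) and carries no injury/mobility code; the
code dictionary ships as an editable ruleset covering every named category.

## Mixed-model inference

The fitter is a purpose-built profiled (RE)ML routine for the
random-intercept-only case. For a variance ratio λ = τ²/σ², the GLS
normal equations, the profiled residual variance and both log-likelihoods
are closed forms in per-group sufficient statistics (X'X, per-dog column
sums, per-dog outcome sums), so each candidate λ costs O(G·p²) and the fit
is a one-dimensional bounded minimisation over log λ (`xatol` 1e-10, with
an explicit λ=0 boundary check; a fit collapsing to λ≈0 is returned with a
`singular` flag rather than raising). This makes the thousands of refits of
the resampling procedure affordable; the suite pins the fitter against
statsmodels `MixedLM` (estimates and SEs to ≲1%, variance components to
≲0.1%) and against closed-form identities. Wald 95% CIs (±1.96·SE) are
used throughout; AIC comes from a maximum-likelihood refit of λ, the form
valid for comparing fixed-effect structures, and is what the
interaction-selection step compares alongside the likelihood-ratio test
(candidates evaluated one at a time in the listed order, kept iff
LRT p < 0.05 *and* AIC decreases).

Repeated-subsample aggregation draws K records per dog without replacement
(dogs with fewer than K contribute all their records — dropping them would
fight the ≥8-records inclusion floor), refits, and repeats R times. The
default K=50 follows the procedure's final-results setting; K=30 is used
in the simulation experiments (both appear in the source procedure, and
the discrepancy is documented here rather than resolved). Reported per
term: mean estimate, mean CI endpoints, and p = fraction of repetitions
whose CI includes zero — so p is a multiple of 1/R. Repetitions whose fit
fails (e.g. a subsample losing an interaction cell) are skipped and
counted; more than 10% skipped aborts. Because repetitions reuse the same
cohort, the aggregated mean CI is *conservative* for terms that vary
little across subsamples (within-dog calendar effects cover the truth in
essentially 100% of replicates); the simulation suite measures overall
coverage ≈98% against the 90–99% acceptance band.

Diagnostics: conditional pseudo-R² = (var(Xβ)+τ²)/(var(Xβ)+τ²+σ²),
the random-effect variance share τ²/(var(Xβ)+τ²+σ²), and the log-scale
RMSE of conditional residuals (fixed effects + BLUPs). No named R²
definition is inherited from the source procedure; this one is stated so
its numbers are interpretable.

Marginal means hold other categoricals at reference levels and continuous
predictors at their data means (reference-grid semantics; population
averaging was the alternative and is intentionally not the default),
evaluate the fitted terms with zero random effect, and back-transform by
exp. When age is focal, the age⁻² column tracks the grid. The naive exp
back-transform is the default; the log-normal mean correction
exp((τ²+σ²)/2) sits behind a flag because the headline outputs are
comparisons on a common scale, which the correction rescales without
reordering. Intervals: delta-method Wald for a single fit; percentiles of
per-repetition predictions for an aggregated result.

Grouped k-fold consistency shuffles dogs into k near-equal groups (all
rows of a dog together), fits per group, and reports per-term and
per-metric standard deviations; k=1 degenerates to a flagged single fit.

## Flexible validation

The check fits a gradient-boosted tree ensemble (lightgbm; 400 trees,
learning rate 0.05, 31 leaves, single-threaded and deterministic under the
seed) to log active minutes with *all* DAG predictors — the point of the
flexible route is exactly that it needs no adjustment-set selection. The
per-dog grouping factor is emulated by backfitting in the style of
mixed-effects random forests: alternate (i) trees fitted to the outcome
minus current dog intercepts and (ii) intercepts re-estimated as per-dog
residual means shrunken by n_iτ̂²/(n_iτ̂²+σ̂²) with moment-based variance
components, for three rounds. Plain per-dog demeaning — the obvious
alternative — removes the between-dog signal of every dog-level covariate
before the trees see it, leaving their partial dependences flat, which
defeats the comparison; the backfitting scheme was adopted for that
reason. Partial dependence sets the focal column across the whole table,
averages population-level predictions on the log scale and
back-transforms. Comparisons against the LMM's marginal means report the
maximum absolute difference in minutes and the Spearman rank correlation;
level offsets between the two curves are expected (reference grid vs data
averaging) — the comparison is about trends, and it is one-way: nothing
feeds back into the linear model.

## Pipeline and reproducibility

One run seed fans out to per-stage generators by stable hashing (CRC32) of
the stage name, so any stage can be rerun in isolation and a full run is
byte-identical under a fixed configuration. The dog-attribute model's
extra covariates are not hard-coded: the pipeline computes each exposure's
minimal backdoor sets from the DAG and adjoins the union (location type
and owner age under the shipped graph). The environmental model is fitted
on the all-visits dataset only, since the graph indicates no confounding
of environmental exposures by dog attributes. A stage failure is recorded
in the report and downstream stages are skipped.

## Problem sizes in the verification suites

The simulation experiments run at desk scale, chosen once: coefficient
recovery and CI coverage use 100 replicates of 500 dogs × 100 records
(K=30, R=50); p-value behaviour sweeps the sex effect over
{0, 0.05, 0.1, 0.2, 0.4} log units at 500 dogs × 60 records; interaction
selection uses 100 seeds of 150 dogs × 20 records with a generous
(±0.1-ish per-size slope) true interaction versus a null one; the
flexible-model comparison uses 400 dogs × 50 records; independence-test
calibration uses 200 linear-Gaussian datasets of n=500 drawn from the
shipped DAG. `scripts/acceptance.py` repeats the same measurements at the
same or slightly reduced replicate counts under the caller's seed.

## Known limitations

- The fitter covers exactly one random intercept; no random slopes, no
  crossed or nested groupings, no non-Gaussian outcomes.
- The independence tests are linear; nonlinear dependence that leaves
  residual correlation at zero goes undetected, and the Bonferroni
  handling of multi-level categoricals is conservative.
- The fraction-of-CI p-value is a resampling heuristic, not a calibrated
  test statistic; its operating characteristics are established here by
  simulation only, under the generator's conditions.
- Backdoor enumeration is exponential in observed nodes and deliberately
  guarded; graphs beyond ~25 observed nodes need a smarter algorithm.
- The tree-ensemble grouping is an approximation to a joint
  trees+random-intercept posterior, adequate for trend comparison but not
  for uncertainty statements.
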