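# Methods

## Design bookkeeping

The accelerated layout is fully determined by a `DesignSchedule`:

* wave years (2001, 2003, 2012, 2015);
* nine age columns [50–53], [54–57], [58–61], [62–65], [66–69],
  [70–73], [74–77], [78–81], [82+], with nominal mean ages
  52, 55, 59, 63, 67, 71, 75, 81, 86 used as the design time-point ages;
* twelve birth-cohort bins — cohorts 1–9 ([1909–1919], [1920–1923], …,
  [1948–1951]) entering in 2001, refreshment cohorts 10–12
  ([1951–1954], [1955–1958], [1959–1962]) entering in 2012.  Bins 9 and
  10 deliberately share 1951; the entry wave disambiguates;
* column advances per wave relative to the entry column
  ({2001: 0, 2003: +1, 2012: +3, 2015: +4}; refreshment entrants
  {2012: 0, 2015: +1}) and anchor cohorts (cohort 9 occupies column 1
  in 2001, cohort 12 occupies column 1 in 2012).

Three conventions were genuinely open and are fixed as follows:

* **Cell-to-cohort rule.**  A (wave, age-column) cell of the tabulated
  panel maps to cohort `anchor(entry) − (column − offset(wave)) + 1`.
  The 2001-entrant and 2012-entrant rules give the same cohort for
  every 2012/2015 cell, so the map is well defined without knowing a
  cell's entry mix; it is the unique simple rule that redistributes the
  published wave × age-column counts into the published cohort
  staircase cell-for-cell (all 34 non-empty cells; verified in the test
  suite).
* **Person-level cohort.**  A person's cohort comes from the birth year
  implied by age at first interview and is kept at all follow-ups, even
  when the exact age drifts relative to a column's bracket: panel
  members stay on their cohort's diagonal.  Records advancing past
  column 9 leave the design (no clamping) — the oldest cohorts' rows
  terminate early, exactly as in the published staircase.
* **Coordinates.**  Columns and time points are 1-based (t = 1..9).

Printed cohort age ranges in survey documentation are sometimes
inconsistent with the birth-year bins; only the bins are used here.

## The latent class model

Ten binary items (nine household markers plus sex) at nine time points
give 90 indicators.  Given class s, all observed cells are independent
Bernoulli; under the completely equivalent (fully invariant) multigroup
specification both the class proportions and the item probabilities are
equal across cohorts, so cohort never enters the likelihood.  Planned
missingness is ignorable because it is a deterministic function of
cohort and wave schedule: each person contributes
`log Σ_s π_s Π_{observed (i,t)} p_{s,i,t}^x (1−p_{s,i,t})^{1−x}`.

EM implementation choices:

* E-step in log space (never NaN); persons with zero observed cells get
  the prior as posterior, contribute exactly 0 to the log-likelihood and
  are excluded from `n_obs_used` and from the class-proportion update.
* M-step pools all cohorts in one posterior-weighted update (this *is*
  the invariance restriction); cells observed for nobody keep their
  previous value and are reported via the missingness summary.
* Item probabilities are clamped to [1e-6, 1−1e-6] to keep the
  likelihood finite at degenerate cells.
* Initialization: item probabilities = observed cell marginals plus
  uniform(−0.15, +0.15) noise clamped to [0.05, 0.95]; uniform class
  proportions; `n_starts` = 20 by default (the large-scale tests use 5,
  which suffices for well-separated classes), relative tolerance 1e-6,
  `max_iter` 1000.  Converged chains are preferred; among them the
  highest log-likelihood wins.  A chain whose class loses essentially
  all posterior mass (< 1e-8) is abandoned.
* Label switching: classes are relabelled by descending proportion;
  recovery analyses additionally align labels to reference profiles by
  cost-minimizing (Hungarian) matching on item-probability RMSE.
* Modal-assignment ties break to the lower class index and are logged.

The invariance contract is checkable mechanically: relabelling a
person's cohort cannot change their posterior (the parameters carry no
group index), and the likelihood is identical under any cohort
aggregation — the three-birth-decade grouping G1 (cohorts 1–6), G2
(7–9), G3 (10–12) is carried as a diagnostic label only.

## Class enumeration

Per class count S the report gives −2logL; BIC = −2logL + p·ln N with
N = persons contributing at least one observed cell (the unit of
analysis is the individual, not the record); relative entropy
1 − Σ(−p ln p)/(N ln S); the range of relative class sizes; and the
range across classes of the average assigned posterior.  Parameter
counts are ambiguous in sparse designs, so both conventions are
reported: all-cells, p = (S−1) + S·90 (the default used in the BIC
column), and observed-cells, which counts only cells observed for at
least one person.  Likelihood-ratio-based enumeration tests
(Lo–Mendell–Rubin, bootstrap LRT) are deliberately out of scope.

Entropy of an *overfitted* model is not controlled by class
separation: when S exceeds the true class count the surplus class often
splits a true class near 50/50, capping relative entropy around
1 − w·ln2/ln S for a split class of mass w (≈ 0.87 for w = 0.25,
S = 4).  High entropy at every S is therefore a typical but not
guaranteed signature, which is why the enumeration checks are stated
per seed.

## Synthetic data

The generator emulates the study conditions: 8,000 baseline entrants
(2001) with birth years uniform on [1909, 1951], a 2,000-person
refreshment sample (2012) with birth years uniform on [1951, 1962]
(occupying cohorts 10–12, as in the published staircase), three latent
classes with proportions (0.40, 0.35, 0.25), and per-transition
attrition hazard 0.22 + 0.004·(age − 50), calibrated so the mean
consecutive-wave overlap matches the reported ≈57% linkage of the
design.  Marker prevalences follow logistic-in-age curves anchored at
the published marginal endpoints (e.g. partner presence 77.8% at age 52
→ 35.2% at 86; grandchildren 20.8% → 34.3%), with per-class intercept
offsets creating three well-separated household regimes: large
multigenerational households; couple-based emptying-nest households;
small, mostly unpartnered households.  Sex is item 10 with strongly
gendered class shares (0.55/0.35/0.75 probability of being a woman).

Deliberate idealizations, and hence what passing tests do and do not
show:

* Markers are drawn independently given (class, design age) — exactly
  the conditional-independence structure the model assumes — and are
  evaluated at the *nominal mean age of the design time point* a record
  maps to, so every cell is homogeneous within class.  Parameter
  recovery on these data tests the estimator, not robustness to
  within-cell age heterogeneity or residual dependence.
* By default sex, too, is drawn independently per time point given
  class.  A `sex_time_constant=True` switch replicates a single draw
  across time points, which induces within-class serial correlation the
  model does not describe; with it enabled, information criteria
  overstate the number of classes (an extra class harvests the
  replicated-item correlation), which is itself instructive about real
  panels, where sex *is* constant.
* Attrition is class-independent by default (missing at random by
  design); per-class hazard multipliers are available for robustness
  experiments.
* Birth years are uniform within ranges, so the oldest columns carry
  more mass than in a real aging panel; mortality is not distinguished
  from dropout; household size counts and within-household dyads are
  not simulated.

Determinism: a configuration (including its seed) maps to a
byte-identical panel; the pipeline derives per-stage seeds from one
root seed via SHA-256, so manifests (artifact hashes) reproduce
exactly.

## Trajectory profiles

Class profiles are posterior-weighted (default) or modal within-class
means of each observed cell, reported with per-cell effective sample
sizes; cells observed for nobody are explicit not-available entries.
The exact mixture identity — the effective-sample-size-weighted average
of class profiles equals the overall prevalence at every observed
cell — holds to machine precision and is enforced in the tests
(weighting by class proportions instead is only approximate, since
proportions are person-level while profiles are cell-level ratios).
Profiles are prevalences (shares of households with the marker);
count-valued profiles would require roster data the binary markers do
not carry, so no dichotomization inverse is invented.

## Problem sizes

The shipped checks run at desk scale by choice: class enumeration on
the 10,000-person default panel (S = 1..4, 5 starts, 10 seeds),
parameter recovery at 4,000 persons (10 seeds), grid-search
cross-validation of EM on complete-data instances of at most 10 persons
and 2 items, and Monte-Carlo checks of the generating law at 50,000
persons.  The estimator is vectorized (two dense matrix products per EM
sweep), so a full enumeration at the default scale takes seconds on one
CPU.

## Known limitations

Partial invariance (group-varying thresholds), covariates on class
membership, distal outcomes, standard errors/bootstrap intervals,
hidden-Markov transition structure, and survey weights are out of
scope.  The per-transition attrition hazard ignores interval length
(the 2003→2012 gap is nine years, 2001→2003 two), trading realism for
the simple per-wave dropout the design bookkeeping needs.
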