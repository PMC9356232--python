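# Methods

## Engagement indicators

Only two LMS log types count as learning activity: `login-attempt` (entering
the LMS; no course attached) and `course-access` (any in-course action).
Time of day and dwell time are deliberately ignored; a day is active when it
holds at least one event, using the calendar's local-date boundary.

Inclusion rules are applied before anything is computed: pass/fail courses
and courses below 2 credits are dropped (with their course-access events),
and a student-semester enters the analysis only with at least one qualifying
course. Login attempts survive the course filter because they belong to no
course; they count toward Log-Count, Log-Entropy and Access-Rate but never
toward any per-course quantity.

Definitions, per student-semester with day counts c₁…c_D over a D-day
calendar, total N = Σcᵢ, and k qualifying courses:

- Log-Count raw = N/k; descriptive tables report the raw value, models use
  ln(1 + N/k). The `ln(1+x)` form (not `ln x`) tolerates zero-activity
  students. The "per course" denominator is the count of qualifying
  enrollments, one of two defensible readings of an events-per-lecture
  definition; the alternative (mean of separately computed per-course
  counts) differs only in how course-less login events are shared out.
- Log-Entropy S = −Σ pᵢ ln pᵢ, pᵢ = cᵢ/N, 0·ln 0 := 0, natural log
  (reference values near 3.4–3.5 over a ~112-day semester are only
  consistent with nats; the base is still an argument). Zero-activity
  students have undefined entropy and propagate as missing.
- Access-Rate = #{i : cᵢ > 0}/D.
- GPA = unweighted mean of grade points over the nine levels 4.5 (A+) …
  1 (D), 0 (F). Credit weighting is not applied; the scale has no 0.5
  level.

## Survey scoring

MHC-SF (14 items, 0–5): emotional items 1–3, social 4–8, psychological
9–14. Categorical rule with high = {4,5} and low = {0,1}: flourishing needs
≥1 high emotional item and ≥6 high among the 11 social+psychological items;
languishing mirrors it on low items; otherwise moderate. Both rules can in
principle fire through disjoint item subsets; such rows are scored moderate
and logged. K-MDI: total over all 14 items; the disorder flag needs ≥1
symptom item ≥3 (of 0–4) *and* the dysfunction item ≥2 (of 0–3). The K-MDI
cutoffs are not published with the instrument, so they are top-of-scale
bands exposed in `ScoringThresholds`. Academic distress is the sum of the
4 items (0–16); a mean-scored variant exists behind a flag. Crossing the
collapsed well-being side with the disorder flag yields the four groups.

## Statistical stage

χ² tests are Pearson statistics without continuity correction (the
reference cohort's published values reproduce exactly without one).
One-way ANOVA reports η² = SS_b/(SS_b+SS_w); post-hoc pairwise tests use
the pooled within-group variance with Bonferroni family = all 6 pairs.
`anova_from_summary` exploits the exact identity SS_b = Σnᵢ(mᵢ−m̄)²,
SS_w = Σ(nᵢ−1)sᵢ², so published group summaries recover F and η²;
`reconstruct_counts` rebuilds contingency tables from row percentages and
row sizes and refuses tables whose rounded cells do not add back to the
stated margins. Descriptive/ANOVA stages treat semesters as independent
rows; only the mixed models link repeat responders.

### Mixed models

One random effect — a per-student intercept — is fit by REML. The criterion
is profiled down to the variance ratio λ = τ₀₀/σ²: given λ, GLS estimates of
β and σ² are closed-form (within-cluster inverses are rank-one updates, so
only cluster sums are touched), leaving a bounded 1-d minimisation on
λ ∈ [0, 10⁴] with tolerance 1e-10. τ₀₀ ≥ 0 is enforced by the bound; the
λ = 0 endpoint is evaluated explicitly, and all-singleton data short-circuit
there, where estimates equal OLS exactly.

Satterthwaite df for a contrast c: df = 2·g²/(∇g'A∇g) with g = Var(c'β̂) as
a function of θ = (σ², τ₀₀), ∇g by central finite differences (relative step
1e-5), and A the inverse observed information of θ, i.e. the inverse of the
numerically differentiated Hessian of the REML negative log-likelihood.
When the information is not positive definite, or at the τ₀₀ = 0 boundary,
the df fall back to the residual n − p (boundary case exact). With θ the
two group variances of independent sample means, the same formula is the
Welch–Satterthwaite df, which the tests use as a closed-form oracle;
statsmodels MixedLM is the independent cross-check for the REML estimates
themselves. All continuous variables are standardized (sample SD, n−1)
before fitting — including the income decile — so coefficients are on the
standardized scale; categorical indicators stay 0/1.

## Synthetic cohort generator

The generator states the world the analysis assumes; its defaults restate
the reference cohort: group prevalences 0.7760/0.1548/0.0426/0.0266, mean
courses per student 5.09, distress group means 4.34/7.98/6.92/11.59,
GPA group means 3.92/3.83/3.64/3.35, 13.03% repeat responders, ICC 0.6,
57.65% female, 112-day (16-week) semesters — the semester length is not
published and 16 weeks is the standard Korean university term.

Engagement: each student-semester gets an active-day indicator per day
(Bernoulli with a Beta-heterogeneous, group-specific probability) and
Dirichlet weights with group-specific concentration over the active days;
course-access day counts are Poisson with total mass
rate_g × n_courses × D × exp(0.25·z), where z is the student-semester latent
score (√ICC·u + √(1−ICC)·ε); days with activity add 1 + Poisson(0.5) login
events. A single symmetric Dirichlet over all days cannot hit the reference
Log-Entropy (≈3.5) and Access-Rate (≈0.5) simultaneously — evenness at that
entropy forces activity on ~60% of days — hence the two-stage day model.
The per-day rates (3.48/3.17/2.95/3.03 per course), active-day probabilities
(0.565/0.545/0.525/0.515) and concentrations (0.62/0.61/0.56/0.51) were
calibrated once against the reference group means of all three indicators
and then frozen.

Surveys: item vectors are drawn from group-specific response distributions
whose means track the reference scale means; languishing profiles are
constructive (≥1 low emotional and ≥6 low social/psychological items by
design) while non-languishing profiles never produce low items. Label noise
therefore enters only through the disorder rule's dysfunction tail and
symptom threshold (~2–3% of draws), which is what limits classification
round-trip agreement to ≈97–98% — deliberately above the 95% the tests
require, since real borderline cases flip too. Distress uses a second
student intercept correlated −0.35 with the engagement intercept, so
distress runs against engagement and GPA within groups as well as between.
Grades discretize a latent achievement = group mean + 0.3·0.59·z + N(0,
0.35²) to the nearest scale level (0.59 being the reference GPA SD).

What the generator does **not** emulate: course-level heterogeneity
(assignments-heavy vs. reading-heavy courses), within-semester
non-stationarity (exam-week spikes beyond what sparse Dirichlet weights
produce), joint demographic structure beyond marginals, attrition, and
item-level psychometric structure (items are conditionally independent
given group). A green round-trip test therefore establishes that the
pipeline recovers the stated world, not that the instruments behave
psychometrically like real responses.

## Numerical and design choices

- Entropy of an all-zero vector raises rather than returning 0; the
  aggregator maps it to missing so zero-activity students do not fake
  perfect cramming.
- Grade snapping is nearest-level with ties toward the lower index of
  numpy's argmin; the D→F gap (1.0 to 0.0) is respected.
- Percent rows in `reconstruct_counts` must sum to 100 ± 0.5 (printed
  rounding); cell rounding is `rint`.
- Two-sided tests, α = 0.05, no multiplicity correction across the five
  outcomes.
- The consistency report gives test statistics recomputed from rounded
  published summaries 0.3% relative slack; exact-arithmetic checks get
  absolute 5e-3.

## Limitations

- Only a random intercept is supported — no random slopes, no
  Kenward–Roger df, no ML fitting.
- The Satterthwaite information matrix is numerical; for variance
  components very near the boundary the df degrade (by design) to
  residual df rather than attempting a constrained information.
- `score_survey_table` iterates rows; it is comfortable at cohort scale
  (thousands) but not built for millions of rows.
- The pipeline assumes one calendar per semester label and drops events
  outside it with a warning count, not an error.
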