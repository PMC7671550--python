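# Methods

`fclustfd` clusters longitudinal symptom-diary data in two stages: a
*fitting step* that converts each patient's noisy daily series into a
smooth functional, and a *clustering step* that groups patients by a
fuzzy k-medoids algorithm on the functional coefficients. This note
records the models, the defaults and why they are what they are, the
numerical choices, and the limits of what the synthetic-data experiments
demonstrate.

## Scoring

Daily diary entries carry six rhinoconjunctivitis symptom intensities on
a 0–3 scale (sneezing, rhinorrhea, pruritus, nasal congestion, ocular
pruritus, lacrimation) and a rescue-medication category (0 none,
1 antihistamine, 2 nasal corticosteroid, 3 oral corticosteroid). ARTSS
is the mean of the six intensities; RMS is the daily medication
category (the highest, when several drugs were taken); CSMS = ARTSS +
RMS ∈ [0, 6] and is divided by 6 before smoothing. Pollen-count series
are divided by their in-window maximum so both kinds of curve live on
[0, 1].

Two conventions matter. A day whose six symptoms are all recorded but
whose medication cell is empty counts as "no medication taken"
(RMS = 0). A day with *any* symptom missing is a missing day: ARTSS is
the mean of exactly six features and is undefined on fewer, so partial
entry is not imputed at the scoring stage. The missing-day count is
taken *after* the RMS = 0 convention is applied.

## Filtering and imputation

Patients are excluded when more than 37.5 % of their days are missing
(inclusive comparison: a patient at exactly the cut-off is retained —
`missing_cutoff`, default 0.375). Diaries whose observed values never
vary are excluded as degenerate recorders (`drop_constant`); this single
zero-variance rule covers both the all-zero diary and the
same-value-every-day diary. Remaining gaps are filled by the scheme
y<sub>t'+t''</sub> = y<sub>t'</sub> + (y<sub>t'+w</sub> −
y<sub>t'</sub>)·t''/w for an interior gap of length w − 1, with leading
and trailing gaps carried from the nearest observation. The operation
is idempotent and never alters an observed value.

## Fitting step

Each series is represented in a B-spline basis of order m (degree + 1)
with q equally spaced interior knots, so the basis dimension is
s = q + m. Coefficients minimize the penalized least squares
SSE + λ·∫(D²x)² dt, with the curvature penalty assembled exactly by
Gauss–Legendre quadrature per inter-knot interval (the integrand is
piecewise polynomial, so m − d nodes per interval suffice at penalty
order d; d = 2 by default). λ is chosen by GCV,
GCV = v·SSE/(v − df(λ))², where v is the per-patient number of days and
df(λ) is the trace of the hat matrix. Because the clustering compares
coefficient vectors across patients, one (q, m, λ) is shared by the
cohort: for each (q, m), a single λ = 10^g minimizes
TGCV = Σᵢ GCVᵢ over the exponent grid g ∈ [−30, 20] in steps of 0.05,
and (q\*, m\*) minimizes the resulting TGCV. A parsimony tolerance
(`parsimony_tol`, default 0 = off) may instead select the simplest
model — smallest s — whose TGCV is within the tolerance of the minimum;
the override is recorded in the result. GCV ties along the λ grid break
toward the smaller λ (the smoother fit at equal score). Weights in the
least-squares criterion are fixed to the identity.

**Numerics.** The λ profile is evaluated through a
generalized-eigenvalue reparametrization: with A = ΦᵀΦ = LLᵀ and
K = L⁻¹RL⁻ᵀ = QΓQᵀ, both df(λ) = Σⱼ 1/(1 + λγⱼ) and SSE(λ) come from a
single decomposition, so the 1001-point λ grid costs one factorization
per (q, m). Eigenvalues below 10⁻¹¹ of the largest are clamped to zero;
without the clamp, round-off-level eigenvalues of the penalty nullspace
are amplified by extreme λ and the λ → ∞ limit (the ordinary
least-squares fit restricted to the nullspace — a straight line for
d = 2) is lost. A direct per-λ solve with pseudo-inverse degrees of
freedom remains as the fallback when ΦᵀΦ is rank-deficient (s > v);
an unpenalized singular system is flagged and reported with infinite
GCV. GCV is also set to +∞ whenever df ≥ v (saturated fit).

## Clustering step

Fuzzy k-medoids minimizes Σᵢ Σₗ u<sub>il</sub>^f d²(cᵢ, hₗ) subject to
membership rows on the simplex and prototypes constrained to observed
units, with d² the squared Euclidean distance on coefficient vectors.
The alternating algorithm updates each medoid as the unit minimizing
the membership-weighted total squared distance of its cluster, then
updates memberships as
u<sub>il</sub> ∝ d²(cᵢ, hₗ)^{−1/(f−1)}, units at zero distance from a
prototype being assigned crisply; iteration stops when successive
membership matrices differ by at most `tol` (default 10⁻⁶) in Frobenius
norm. Each half-step minimizes the objective in one block, so the
objective sequence is non-increasing within a run; the per-start
sequences are retained on the fitted estimator
(`objective_histories_`) and asserted in the test suite.

Defaults: f = 1.5 (medoid-based algorithms are recommended to stay at
or below 1.5; f → 1 hardens the partition, large f flattens memberships
toward 1/k), `max_iter` = 1000, `n_starts` = 30.

**Initialization.** Each start draws k distinct units uniformly at
random and initializes U as the optimal memberships to those units.
Random membership rows drawn uniformly on the simplex were tried first
and rejected: their fluctuations average out inside the weighted medoid
update, so every start flows into the same basin and the multi-start
scheme loses its purpose (on a small two-blob instance, 0 of 300
flat-simplex starts reached the enumeration optimum, against 25 of the
66 possible random-prototype starts). Medoid argmin ties break to the
smallest unit index; when two clusters select the same unit, the
cluster with the lower weighted cost keeps it and the other takes its
best not-yet-taken candidate.

Fuzzy k-means is the same machinery with the prototype constraint
dropped: centroids are the membership-weighted means
hₗ = Σᵢ u<sub>il</sub>^f cᵢ / Σᵢ u<sub>il</sub>^f. Both estimators
accept raw observed series as rows, which covers the
raw-data comparator variants without separate code.

A brute-force enumeration oracle (all k-subsets of units as medoids,
each paired with its optimal memberships; capped at n ≤ 15) serves as
the independent global-optimum reference in tests and in the
acceptance script.

## Validity and choice of k

The silhouette of unit i is s(i) = (b(i) − a(i))/max(a(i), b(i)) with
a(i) the mean distance to its own cluster's other members and b(i) the
smallest mean distance to another cluster; singleton clusters score 0
by convention. The fuzzy silhouette FS(k) weights s(i) by
(u<sub>ig</sub> − u<sub>ig'</sub>)^γ, the gap between the two largest
memberships (γ = 1 by default; γ = 0 or a hard U recovers the plain
average S(k) exactly). k is chosen by maximizing FS(k) over a range,
but the per-k table and every k within `k_tolerance` (default 0.05) of
the maximum are reported too — the strict argmax can be too blunt an
instrument, and near-optimal solutions are often the interpretable
ones. Distances for the silhouette default to squared Euclidean,
matching the clustering objective; plain Euclidean is available by
flag (which of the two the original software used is not documented).
Hardening for the silhouette and for all cluster summaries assigns each
unit to its maximum membership, ties to the lowest cluster index.
Partition agreement uses the standard adjusted Rand index.

## Pollen association (ARp)

Spearman correlations between patient and pollen curves are computed on
their B-spline coefficient vectors, the pollen curves being smoothed
with the same basis and λ as the patients. Spline coefficients are
serially dependent, so significance comes from a one-sided permutation
test (H₁: r > 0) with the add-one estimator
p = (1 + #{permuted r ≥ r})/(n_perm + 1) over `n_perm` = 10 000 seeded
permutations by default. ARp<sub>iu</sub> is 0 where p > α (α = 0.05)
and otherwise r<sub>iu</sub> normalized by the sum of the patient's
significant correlations — all positive under the one-sided test, so
ARp ∈ [0, 1] and each patient's significant entries sum to 1. Cluster
summaries weight ARp by membership degree over the patients assigned to
the cluster and report the share of patients with ARp = 1; these
cluster means need not sum to 1 across pollens. No multiple-testing
correction is applied across patients or pollens.

## Synthetic cohorts

`CohortDesign` plants known structure: per-cluster template curves on
[0, 1] (constant `flat-low` at 0.10 and `flat-high` at 0.60, an early
`peak-then-decline` flare, and `pollen-tracking` = 0.12 + 0.68 × the
normalized first pollen curve), patient-level multiplicative amplitude
jitter (sd 0.08) and additive shift (sd 0.03), Gaussian noise (sd 0.05
on the [0, 1] scale), and MCAR masking (rate 0.10). The defaults
emulate the larger study setting: a 40-day window, three clusters of
30 patients. Pollen seasons are bell-shaped bumps with peaks of 200,
400 and 60 grains/m³. Each daily value is decomposed back into an
integer-valued six-symptom + medication record whose re-scored CSMS is
within 1/12 of the target, so the whole scoring path is exercised.
The flat templates are genuinely constant: a draft gave them a gentle
rise-then-fall seasonal wiggle, which — being shaped like the pollen
bumps — made *every* cluster's coefficients rank-correlate with the
pollen curves and erased the planted association contrast. Day-to-day
variability instead comes from noise and score quantization.

What the generator does **not** emulate: informative (MNAR)
missingness, weekday/weekend entry patterns, medication feedback on
subsequent symptoms, pollen measurement error, or within-season
autocorrelated noise. Passing the recovery experiments therefore shows
the pipeline is correct and well-calibrated under clean planted
structure, not that real diary cohorts separate this cleanly.

## Experiment sizes

The packaged experiments (test suite and `scripts/acceptance.py`) use:
50 twelve-unit instances for the enumeration-oracle comparison; 20
replicates of the 90-patient design for ARI and k-selection (smoothing
fixed at q = 15, m = 4 with the full λ grid — one configuration rather
than the full eight-model table, which the grid-search tests cover
separately); 2000 null replicates at 999 permutations for test
calibration; and 999 permutations for the ARp contrast. These sizes
give stable pass/fail behaviour at interactive runtimes.

## Known limitations

* The TGCV search shares λ across patients by design; patients with
  atypical noise levels are smoothed at the cohort's λ, not their own.
* Fuzzy k-medoids is a local optimizer; the multi-start scheme makes
  missing the global optimum rare at small n but offers no guarantee.
* The permutation test is one-sided for positive association; a
  protective (negative) pollen relationship is reported as
  non-significant by construction.
* Coefficient-space squared Euclidean distance is not the L² distance
  between curves unless the basis Gram matrix is the identity; with a
  shared basis the two orderings are close but not identical.
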