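# Methods

## Growth model

Dendritic elaboration is modelled as a continuous-"time" Markov birth-death
process in which the time-like coordinate is grown length *r* (μm).  All
active tips elongate at the same constant speed; per unit grown length each
tip branches with rate *k_b* and terminates with rate *k_t* (both μm⁻¹).
With *n* active tips the total event rate is *n(k_b + k_t)* per μm, so the
Gillespie algorithm applies exactly: draw the gap
Δr = −log x₁ / (n(k_b + k_t)) with x₁ ∈ (0, 1] (the half-open interval
guards log 0), advance every tip by Δr, then branch if x₂ < k_b/(k_b+k_t)
and terminate otherwise, with x₂ ∈ [0, 1).

Assumptions worth making explicit:

* Tips are exchangeable and independent: no self-avoidance, tiling,
  resource competition or spatial interaction.  The population count n(r)
  and the termination-length distribution depend only on the rates.
* Rates are constant within a stage (linear kinetics).
* The process is purely length-indexed; there is no geometric arbor, and
  no 2-D/3-D reconstruction is attempted.

Because the count process is insensitive to *which* tip carries an event,
the engine additionally tags each tip with its birth length and picks the
event-carrying tip uniformly at random (from the same seeded stream).
This costs nothing statistically and yields per-tip segment lengths: a
tip's hazard per μm is k_b + k_t while it lives, so segment lengths are
exactly Exponential with mean 1/(k_b + k_t) — a property the test suite
checks against pooled simulation output.

A neuron starts with N₀ = 30 tips at r = 0 and runs to extinction
(n = 0), which occurs with probability 1 whenever the (final) stage has
Δk = k_t − k_b > 0.

### Radial mapping and R95

A tip wanders diffusively while elongating, so the straight-line distance
of a terminal point from the origin is taken as R = √r with an implicit
unit diffusion scale (1 μm² of mean-square displacement per μm grown).
The per-neuron field radius R95 is the 95th percentile of {√rᵢ} over that
neuron's termination lengths, with the linear-interpolation quantile
convention (numpy's default, "type 7").  R95 is computed per neuron, not
pooled over the ensemble.

### Two-stage schedules

Rates switch the first time r crosses `switch_length`.  The stage-1 event
proposal that would land at r ≥ switch_length is discarded, r is set to
the threshold, and the simulation resumes under stage-2 rates; by the
memorylessness of the exponential gap this truncation is exact, not an
approximation.  The standard presets use a growth phase (k_b = 0.42,
k_t = 0.40) switching at 100 μm to a terminating phase (k_b = 0.36 with
k_t = 0.40, or k_t = 0.42 in the second variant).

### Event caps and truncation

`max_events` bounds each run (default 10⁶).  A supercritical final stage
(k_t ≤ k_b) never goes extinct on its own and is accepted only with an
explicit cap.  Truncated neurons are flagged and excluded from ensemble
summaries.  Near criticality the total event count has a heavy
(Borel-type) tail with cutoff scale ~2k_b/Δk²; at Δk = 0.001 this is
~7×10⁵ events, so a 10⁶ cap would clip a handful of the *largest finite*
neurons per thousand and bias the mean field size down by ~0.5 μm.  The
near-critical presets (Δk ≤ 0.005) in the acceptance script therefore run
with max_events = 10⁷, at which truncation probability is negligible
(~10⁻⁶ per neuron).

### Seeding

All randomness flows through numpy Generators created as
`SeedSequence(master_seed, spawn_key=key)`, with keys built from neuron
index, grid-cell index and replicate index.  Identical seeds give
bit-identical event logs on any platform; ensembles are independent of
execution order.

## Ensemble summaries

* mean, SD (sample, n−1 denominator), median and CV (100·SD/mean) of
  per-neuron R95;
* pooled mean segment length (cross-checked against 1/(k_b+k_t));
* dendritic density, defined as the per-neuron ratio
  total dendrite length / (π·R95²), averaged over neurons, in μm/μm².
  The circular field of radius R95 is the only area the model defines.
  Note a caveat: because total length scales like N₀/Δk while the field
  area grows only like π·r95 (area is linear in the length coordinate
  under the square-root mapping), this density is *not* smaller in the
  low-rate sparse regime — arbor sparsity shows up instead in segment
  length and in terminal points per unit area.

## Parameter scan

The default grid takes 49 rate values 0.01–0.97 μm⁻¹ (step 0.02) on both
axes.  (A 50-value reading of the grid, 0.01–0.99, changes only the
resolution; the 49-value grid is the documented default.)  Cells with
k_b ≥ k_t are excluded without simulation — off-diagonal because the
population explodes, the diagonal because the critical process has
infinite expected extinction length.  Near-critical refinement cells with
Δk ∈ {0.01, 0.05, 0.025, 0.0125} are appended per k_b column; they probe
field radii beyond the coarse grid's characteristic maximum
√(1/0.02) ≈ 7 μm.  Cell seeds derive from the master seed and the cell
indices, so the whole scan is reproducible cell-by-cell.

## Dispersion tests

Both tests reduce to "sum a score over sample 1 and refer it to the
permutation null", and both use the exact finite-population moments of
that sum.  For combined n ≤ 14 the permutation null is enumerated exactly
and the two-sided p is 2·min(lower tail, upper tail), capped at 1.

* **Conover squared-ranks**: scores are squared mid-ranks of the pooled
  absolute deviations from each group's own mean.  For larger samples the
  standardised statistic is referred to Student t with N−2 df rather than
  the normal: the squared-rank score sum is noticeably right-skewed, and
  the t reference empirically calibrates the test at moderate n (measured
  type-I error 0.047 at n = 30 + 30 versus 0.052 for the normal, against
  a nominal 0.05).
* **Siegel-Tukey**: alternating extreme ranks (1 to the smallest, 2–3 to
  the two largest, 4–5 to the next two smallest, …; ties mid-ranked) are
  assigned to the pooled sorted values and the Wilcoxon rank-sum
  procedure is applied with a continuity correction.  The direction of
  ranking (rank 1 at the minimum) follows the classical convention; the
  mirrored direction is available as an option.  Because the test assumes
  equal location, each sample is shifted to zero median by default
  (`align_medians=True`).  Alignment makes the test mildly conservative
  (measured type-I error ≈0.042 at n = 30 + 30); the canonical unaligned
  form is calibrated (≈0.048) and should be preferred when locations are
  known to be equal.

Both tests are scale-invariant and symmetric under exchanging the two
samples; identical samples give p = 1.

## Synthetic measurements

The generator emulates the *structure* of per-genotype field-size tables
(label, mean, SD, sample size in dfu) so the mean/variance comparison
workflow can run without imaging data.  Values are normal by default — an
assumption of convenience, not a claim about real measurement noise; a
rounded-normal family (integers clamped at ≥ 1 dfu) is available.
Published tables print mean ± SE, so `se_to_sd` converts (SD = SE·√n)
before generating.  What passing tests show is therefore that the
pipeline detects mean and variance differences at the advertised rates
for normal data of realistic sizes (n ≈ 8–34); they say nothing about
distributional peculiarities of real dfu counts.

## Study-condition sizes

Standard runs use 100 neurons per ensemble, N₀ = 30, and 10 replicate
ensembles when a statistic's sampling spread matters; the scan default is
100 neurons per cell (20 in the quick profile).  Single-ensemble CV
estimates at n = 100 carry a sampling SD of roughly 1.5–3 percentage
points (larger near criticality), which is why replicate bands rather
than single runs are used for comparisons.

## Known limitations

* N₀-dependence: the mean R95 is not exactly flat above N₀ = 20 — more
  initial tips mean more terminal points, and the 95th-percentile
  estimator is less downward-biased on larger samples.  The drift from
  N₀ = 20 to 50 at Tm20 rates is ≈0.27 μm (~8% of the mean): small
  against kinetic effects, but statistically resolvable.
* Near-critical ensembles (Δk ≤ 0.002) have heavy-tailed per-neuron R95,
  so their ensemble means converge slowly and depend on the event-cap
  policy; the cap and exclusion rule above are part of the reported
  conditions.
* The density summary inherits the caveat noted in its definition.
* The dispersion tests' large-sample approximations are calibrated for
  n per group ≳ 15–20; between the exact threshold (combined n = 14) and
  that regime the approximation error, while small, is uncharacterised.
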