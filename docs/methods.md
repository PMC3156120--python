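# Methods

This note records the statistical model, the numerical choices and the
known limitations of `mirtraj`, in the package's own words. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Normalization model

Raw microarray intensities are non-negative fluorescence units with a
reliable-detection floor at 200. The preprocessing chain is:

1. **Mean filter** on *raw* intensities: a miR is retained iff its mean
   intensity over the samples entering the analysis is ≥ 200. Filtering on
   floored values would be vacuous — flooring makes every mean ≥ 200 by
   construction — so the filter deliberately sees raw values. The scope of
   the mean (which samples) is configurable (`filter_samples`); by default
   it is exactly the samples of the groups being co-analysed plus their
   naive references, so a wild-type-only analysis and a combined-strain
   analysis may retain different sets.
2. **Floor, ratio, natural log**: $w = \ln(\max(x,200)/\max(x_{naive},200))$
   per miR, against the *same strain's* naive (day-0) kidney. A miR that
   never clears the floor is identically 0; the reference's own vector is
   the zero vector; days are ordered ascending with the naive sample
   prepended as day 0.

Digital knockout zeroes the normalized values of a chosen miR set at every
time point, before PCA. It therefore commutes trivially with the
normalization and only interacts with the PCA refit.

## PCA conventions

One PCA is fitted to the pooled time points of all co-analysed series
(including each strain's day-0 naive point once), mean-centred per miR, no
variance scaling — log-ratios already share a scale. Components are
ordered by decreasing variance; signs are fixed by making each component's
largest-magnitude loading positive. Signs and the global rotation do not
affect any downstream statistic, since all angles are measured within a
single projection. Zero total variance (e.g. after knocking out every
retained miR) raises a degenerate-data error rather than returning an
arbitrary basis.

## Spherical statistics

Directions are formed from a center time point *through each later time
point*; points before the center (the day-0 naive point when an injured arm
is projected from day 1) are plotted but not projected. Angles use the
chord formula $2\arcsin(\lVert u-v\rVert/2)$, which is exact near 0 where
$\arccos$ of a dot product loses precision; all outputs are in degrees.

**Minimal enclosing cap.** Minimizing the maximum angle over centers on
$S^{d-1}$ is equivalent to maximizing the minimum dot product. When the
directions fit inside an open hemisphere this problem is convex: by
max–min duality over the unit ball, the optimal value equals the norm of
the minimum-norm point $u$ of the directions' convex hull, the optimal
center is $u/\lVert u\rVert$, and the radius is $\arccos\lVert u\rVert$.
The solver computes $u$ with a small simplex-constrained QP, verifies the
duality gap (≤ 1e-9 rad certifies global optimality), and runs one primal
SLSQP polish if needed. Only when the certificate does not close — the
directions do not fit a hemisphere, radius ≥ 90° — does it fall back to
multi-start constrained minimization: on $S^2$ the eight octant points
$(\pm1,\pm1,\pm1)/\sqrt3$, the normalized mean and eight seeded random
starts; in higher dimension the normalized mean, every input direction and
32 seeded random starts (octant enumeration is infeasible at $2^d$). The
primal problem is posed as max $s$ s.t. $c\cdot d_i \ge s$, $\lVert c
\rVert = 1$ (linear in $s$, hence well conditioned for tight clusters),
objective tolerance 1e-14. The reported radius is always the true maximum
angle from the returned center, so it is a valid covering radius on every
path. The test suite checks agreement with an exhaustive combinatorial
oracle (1-, 2- and 3-point supports) to 1e-6 degrees over 500 random sets.

For symmetric configurations (e.g. points on an equator) the optimal
center is not unique; the solver returns one optimizer. Such
configurations have probability zero under every model used here; no
explicit non-uniqueness flag is emitted (known limitation).

**Spherical standard deviation.** The center minimizing the RMS angular
distance is found by multi-start L-BFGS on the normalized-vector
parameterization with an analytic gradient (starts: normalized mean,
octants on $S^2$, each input direction, four seeded random vectors). The
SD is the minimized RMS with a plain $1/n$ inside the root — the statistic
is the root *mean* square, not an $n-1$ estimator. SD ≤ enclosing radius
holds by construction (RMS from the RMS-optimal center ≤ max angle from
the cap center) and is asserted property-style in the tests.

**Discrimination** = angular separation of the two groups' SD centers
divided by the larger SD; undefined (error) when both SDs are zero.

## Monte-Carlo nulls

The directionality null is a random walk from the origin with independent
unit displacements uniform on $S^{d-1}$ (normalized Gaussian draws); each
replicate records the minimal cap radius of the walk's center-projected
directions, and the P-value of an observed radius is the plain fraction of
null radii *equal or smaller* (no continuity correction — the published
values are plain fractions of 10,000).

The published analysis built a *single* ensemble of 10,000 walks of seven
displacements — matching the sham series — and evaluated both observed
radii against it. Under that ensemble the package reproduces both printed
probabilities (≈ 0.06 at 21.7° and ≈ 0.0069 at 14.6°). A null matched to
six directions, the injured arm's own count, gives ≈ 0.012 at 14.6°
instead; the pipeline's default is the matched null (each group is tested
against walks of its own length and dimension), while the acceptance
script reproduces the single-ensemble computation.

Two group-comparison nulls are documented reconstructions (their original
specifications are not public):

* **discrimination** — both groups are replaced by independent random
  walks of the observed sizes; one-sided P on large discrimination;
* **proximity** — only the test trajectory is randomized; the reference
  group's SD center is held fixed; P is the fraction of replicate angles
  no larger than observed. When several test groups share a reference, the
  product of their per-group P-values is reported alongside, as the joint
  construction is likewise not public.

Reports flag both as reconstructed. All replicate streams derive from a
single user seed through `numpy` SeedSequence children keyed by statistic,
direction count and dimension (order-independent for the symmetric
discrimination null), so reruns are byte-identical and group order only
permutes the report.

## Synthetic experiments

The generator emulates a pooled-sample two-colour-free microarray time
course: 571 miRs; one naive kidney per strain; sham and injured arms for a
wild-type strain (days 1–30) and two immunodeficient strains (days 1–14).
On the natural-log intensity scale, a sample is

baseline + strain offset + surgery jump (every post-surgery day)
+ treatment term + measurement noise,

with the injured arms drifting day-proportionally along one fixed unit
vector shared across strains (the injury response is modelled as
lymphocyte independent) and sham arms fluctuating isotropically about the
surgery state (mean-reverting, not accumulating). Baselines are a
two-component log-normal (expressed vs background). Defaults, ln-intensity
units:

| parameter | default | rationale |
|---|---|---|
| `fraction_expressed` | 0.24 | with the baseline components at ln 200 ± 2.5 (SD 1), the mean-200 filter retains ≈ 24 % of miRs, emulating 144/571 on the real platform |
| `injury_drift_magnitude` | 0.8 / day | vector norm of the daily drift; strong enough that the injured arm's 3-PC directionality is unambiguous (P ≤ 10⁻³) while day-30 per-miR changes stay within a plausible fold-change range |
| `surgery_jump_magnitude` | 6.0 | common day-1 response shared by both arms; sets the sham arm's preferred direction |
| `sham_fluctuation_sd` | 0.40 | per-miR SD about the surgery state; at this jump/fluctuation ratio the sham cap radius sits near 30° and sham directionality is non-significant, as in the study |
| `measurement_noise_sd` | 0.10 | per-value log-normal array noise |
| `baseline_shift_immunodeficient` | 2.0 | immunodeficient naive kidneys are offset from wild-type along a strain-specific direction |

The injury and surgery directions are drawn supported on the *expressed*
miRs and renormalized: a response component on a miR that never clears the
detection floor is censored to 0 by construction, so a full-space
direction is unidentifiable in principle and the floor would otherwise
rectify it (systematically biasing direction recovery regardless of noise
level).

An accumulating-walk mode (`sham_mode="walk"`) replaces the mean-reverting
fluctuation with a random walk in miR log space, for null calibration. The
calibration studies in the test suite use it with drift 0 *and* surgery
jump 0, analysed in the full retained-miR dimension: the test's null is a
walk of iid uniform unit steps, and in ~140 dimensions the generator's
Gaussian steps have nearly constant length, so the control series realizes
that null faithfully; a deterministic common surgery step is not part of
the null, and a 3-PC analysis would confound calibration with the PCA's
axis selection. Measured this way, the directionality test's type-I error
at α = 0.05 is within 0.05 ± 0.03 (200 replicates, 400-replicate nulls),
its power on default injured series exceeds 0.9 at α = 0.01 (50
replicates, 10,000-replicate null), and the full-dimension SD center
recovers the injected injury direction to < 30° in ≥ 90 % of 50
replicates; those problem sizes are the package's chosen defaults for its
own validation studies.

What the generator does **not** emulate — and hence what passing tests do
not establish about real arrays: probe-level physics (background, dye
bias, cross-hybridization, saturation); within-cell biological replicates
(the data model is one pooled sample per strain × treatment × day, as in
the deposited series); and low-rank structure in the sham response. The
last point matters: real sham fluctuations are concentrated in few
directions, which is why the study's sham cap radius was similar in 3-PC
and 144-dimension analyses, whereas the generator's isotropic fluctuation
necessarily looks much broader in full dimension than in 3 PCs. Analyses
comparing 3-PC to full-dimension spread on synthetic data therefore do not
transfer quantitatively to real data.

## Design choices on open points

* Center days default to day 0 for sham and immunodeficient injured arms
  (no initial sham response there) and day 1 for the wild-type injured arm
  (tissue damage and expression changes appear after day 1); all
  overridable per group.
* The day grids of the immunodeficient series are configurable
  ({0, 1, 3, 5, 7, 14} by default, a 14-day course); the published total
  of 29 time points over 6 series does not pin down the per-strain grids.
* Subset mode (analysing, e.g., a nine-miR signature) refits the PCA on
  the subset only. Subset and knockout are mutually exclusive flags.
* No multiple-testing adjustment is applied anywhere; all Monte-Carlo
  P-values are reported raw with their null summaries, replicate counts
  and seeds.
* The two-phase behaviour reported for the nine-miR subset trajectory
  (one direction to day 14, another thereafter) has no published test; no
  such test is implemented.

## Known limitations

* P-values are Monte-Carlo fractions; at 10,000 replicates their binomial
  SE near P = 0.006 is ≈ 0.0008, and P = 0 means "smaller than 1/reps".
* The discrimination and proximity nulls are reconstructions (flagged in
  every report); absolute agreement with the published group-comparison
  P-values is not guaranteed.
* Full-dimension Monte-Carlo nulls are expensive relative to 3-PC nulls
  (each replicate solves a cap problem in ~140 dimensions); the pipeline
  caches nulls by (statistic, size, dimension) within a run.
* Accession ingestion (downloading the deposited series) is out of scope;
  the expression matrix and sample sheet are plain TSV inputs.
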