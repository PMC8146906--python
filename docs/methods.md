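# Methods

This note documents the statistical machinery in `growthdyn`: the
models and their assumptions, the defaults and why they were chosen,
what the synthetic generator does and does not emulate, and the
numerical choices that affect results.

## Data model

Observations live in a long-format table keyed by (genotype,
treatment, replicate, imaging day, trait).  The imaging-day grid is
declared explicitly (default days 2–35 with day 30 absent, mirroring a
lost imaging day) and is *irregular by design*: downstream code always
consumes true day distances, so a one-day gap enters a POWER
covariance as distance 2 and an RGR interval across the gap divides by
Δt = 2.  Missing days are absent from the grid, never NaN rows.
Validation is strict (unique keys, positive size traits, finite
values, on-grid days) and every rejection carries a machine-readable
reason.

Long format is canonical; genotype × day matrices are derived views.
This preserves replicate-level data for the per-day ANOVA and variance
decomposition, while clustering and covariance fitting use
replicate-mean profiles.  Both access paths (replicate-level and
genotype-mean) are exposed wherever the choice is not forced.

## Growth metrics

* **RGR** uses the natural logarithm, reported per day.  Computed on
  raw daily means — no smoothing or spline fitting, since the daily
  grid is dense enough that interval log-differences are stable.
* **CV** per day is computed across genotype means by default (one
  value per genotype per day); a replicate-level option exists.  The
  default matches the convention of tracking between-genotype
  variability, not within-genotype measurement spread.
* **WUE** is ΔEBv over grams of water applied for a phase (defaults:
  drying 2→22, recovery 22→35).  Irrigation volumes are experiment
  inputs; the generator supplies a constant per-day schedule so WUE is
  computable on synthetic data, but the numbers are not calibrated to
  any real watering regime.
* **Decline metrics** search for the biomass peak in a window
  (default days 19–21) and measure the drop to the declared
  maximum-stress day (22).  Peak ties break to the *earliest* day —
  the conservative choice, giving the longest decline.  A curve still
  rising through day 22 gets a 0 % decline, not a negative one.

## Capability indices

DTO/DRC/DAD are ratios of stress-treatment biomass increments to
control increments over the drying window (9→22), the recovery window
(23→35) and the whole cycle (9→35).  They are computed on
replicate-mean curves, one value per genotype, using the curve values
at the anchor days exactly.  A window whose control increment is
non-positive yields a *missing* score — never a clipped one, since
silent clipping would bias the index correlations.  W is referenced
against C and NW against N, isolating the water effect in the combined
treatment.

Index p-values use the exact t-transform of Pearson r with n − 2
degrees of freedom; stars follow the usual convention (≤0.05, ≤0.01,
≤0.001).

## Fuzzy c-means temporal clustering

Standard alternating optimisation with fuzzifier m (default 2.0;
m → 1 approaches hard k-means), Euclidean distance, membership rows
normalised every iteration, and exact centre-coincidence handled by
crisp assignment.  The objective is non-increasing by construction;
the per-iteration history of the winning restart is retained so this
can be asserted on every run.  Initialisation is a uniform-Dirichlet
random membership matrix; 20 seed-controlled restarts by default
(fuzzy c-means is local-optimum-prone) keeping the lowest objective.

Profiles are clustered on the raw, unstandardised scale by default:
the biological groups of interest differ in overall size, and
z-scoring would erase exactly that signal.  A `standardize=True`
option provides shape-based clustering.

The number of clusters is chosen by majority vote over six validity
indices with their usual optimum conventions: partition coefficient
(max), modified partition coefficient (max), partition entropy (min),
Xie–Beni (min), Fukuyama–Sugeno (min), fuzzy silhouette (max, weight
exponent 1).  Ties break to the smallest c (parsimony).  Candidate c
values producing an empty hard cluster are excluded from the vote with
a warning.  Cluster labels are canonicalised by descending mean
trajectory level, so cluster "A" is always the larger-biomass group.

Typical curves are per-cluster means over *hard* members on the
peak-to-rebound window (days 19–23).  Differential profiles use a
per-day two-sample Welch t-test on genotype means between the two hard
clusters, reported as −log10(p) without cross-day adjustment.

## Per-day treatment tests and onset detection

Each imaging day is analysed separately with the fixed-effects model
value ~ treatment + replicate, followed by Tukey's HSD: the
studentized-range statistic on treatment means with the model's
residual mean square and degrees of freedom (harmonic-mean group size
for mild imbalance, i.e. Tukey–Kramer).  Genotype is deliberately not
in the one-day model — the test asks about the cohort-level treatment
effect and absorbs genotypic spread into the residual, which makes the
per-day test conservative.

Onset detection scans the per-day adjusted p-values of one contrast
for the first run of at least `persistence` consecutive significant
days (default 1; every maximal run is reported either way).  At
persistence 1 and α = 0.05, isolated pre-onset false positives occur
at the expected 5 % per day; persistence 2 suppresses them and is the
recommended setting when the onset day itself matters.  Days are
*not* multiplicity-adjusted across the season — per-day reporting is
the stated convention, and output headers say so.

Correlation dynamics report per-day Pearson r across genotype means
together with the exact two-sided critical value at p = 0.05, obtained
by inverting t = r√(n−2)/√(1−r²) at the 0.975 t-quantile for the
realised n.  A day where either trait is constant yields a flagged
missing value.

## Per-day variance decomposition (REML)

The per-day mixed model is y = μ + rep (fixed) + G + T + G×T + e with
genotype, treatment and interaction random.  On a balanced layout the
restricted likelihood factorises over the ANOVA strata (G, T, G×T,
residual), each stratum contributing df·(ln λ + MS/λ)/2 with λ the
stratum's expected mean square.  The implementation maximises this
factorised likelihood with non-negativity bounds (L-BFGS-B on a unit
scale, making the percentage decomposition exactly scale-invariant).
Its *unconstrained* optimum coincides with the closed-form
expected-mean-squares estimators — an independent cross-check asserted
to 1e-6 in the tests.  Negative components are truncated at zero and
percentages renormalised to sum to 100.  Unbalanced layouts fall back
to a general iterative REML over the full covariance matrix, with a
warning; the intended design is balanced.

## Covariance-structure selection

For a subjects × T response with a saturated mean (free mean per time
point), five within-subject covariance models are fitted by maximum
likelihood: uniform/compound symmetry (2 parameters), POWER
(continuous-time AR(1), 2), heterogeneous POWER (T+1), first-order
antedependence (2T−1), unstructured (T(T+1)/2).  Note the naming
trap: "UN" here means *uniform*, not unstructured.

US and UN have closed-form MLEs (sample covariance; stratum averages
of its trace and rank-one projection).  ANTE(1) is a decomposable
Gaussian graphical model with cliques {t, t+1}, so its MLE matches the
sample variances and adjacent-pair correlations exactly — also closed
form.  POWER and HETPOWER are optimised over unconstrained transforms
(log standard deviations, tanh-linked ρ), which keeps every proposal
positive definite; non-convergence is recorded in the fit's status and
excluded from selection.  BIC = −2 logL + k ln(n_subjects) with the
number of *subjects* as sample size (the common mixed-model
convention; alternatives exist, so this is stated).  The saturated
mean is common to all structures and not counted.

By default the pipeline fits genotype-mean profiles (20 subjects) per
trait × treatment with a thinned time grid (`thin`, default every 4th
day): US and ANTE on the full 33-point grid would carry 561 and 65
parameters for 20 subjects, and the model warns whenever parameters
reach the subject count.

## The synthetic generator

The generator emulates the *statistical structure* the analyses
assume, not greenhouse physics.  Per genotype g:

    EBv_g(t) = K_g / (1 + exp(−r_g (t − t0_g))) · N_g(t) · S_g(t) · ε

with lognormal unit-mean noise ε (CV 8 % per observation), a nitrogen
penalty N ramping linearly from day 15 to −8 % at day 35 (1 in C/W),
and a water-stress factor (1 in C/N)

    S_g(t) = 1 − δ_g ((t − 9)/13)^p          9 ≤ t ≤ 22
    S_g(t) = 1 − δ_g exp(−γ_g (t − 22))      t > 22.

The decline exponent p (default 9) concentrates the damage in the
final days before maximum stress.  This shape was chosen over a
cosine half-wave deliberately: a cosine's slope vanishes at the trough
day, which (against any still-growing logistic) moves the biomass
trough earlier than day 22, caps the own-peak decline at a few
percent, and lets the day-23 rebound overshoot the pre-trough peak —
all contrary to the wilting dynamics being emulated, where deep
(10–45 %) declines develop within 1–3 days of peak growth.
Accelerating damage as soil water approaches a critical level is also
the physiologically sensible picture.  The NW treatment composes the
two penalties multiplicatively with a small extra synergy ramping
after the trough, so NW falls below W from day 22 onward.

Two latent groups, sized 12 ("A") and 8 ("B"), differ in scale and
timing: A is large (K = 1.2e5 voxels) with a deeper dip (δ = 0.52), B
is half the size, relatively faster-growing (higher r, later t0) with
a shallower dip (δ = 0.48).  The group means were calibrated
*analytically* — comparing per-day logistic log-growth against per-day
stress log-drops — so that under water stress group A peaks at day 20
and B at day 21, both trough at day 22, the rebound stays below the
peak, and the cohort-mean W/C biomass ratio at day 22 is ≈ 0.49 (a
~51 % reduction).  Genotype-level dispersion around the group means
(lognormal 10 % on K, small additive jitter on r/t0/δ, 20 % on γ) is
deliberately modest so the calibrated ordering survives per genotype.

Secondary traits are links to EBv and to instantaneous stress
intensity 1 − S(t): height ∝ EBv^(1/3); surface coverage and solidity
are saturating functions of EBv with a post-trough boost for
small-plant genotypes; colour ratios and fluorescence increase with
stress intensity.

What the generator does **not** emulate: soil-water balance and
per-pot soil measurements, phenology stages, spatial/bench effects,
temporal autocorrelation of the measurement noise (observations are
independent given the genotype curve), and any association between
plant size and stress experienced.  Consequently, a green test
establishes that the *pipeline* recovers what the stated world
contains — it does not validate biological claims about real
genotypes.  One known divergence: because group A is simultaneously
larger and less tolerant, the cross-genotype correlation between
biomass at maximum stress and tolerance is confounded by size in the
default world; the direction check for that relationship therefore
uses a single-group cohort with dispersed dip depth, where the
mechanism (tolerance preserves biomass under stress) is unconfounded.

## Numerical choices

* Peak-day ties → earliest day; cluster-count ties → smallest c.
* Fuzzy c-means stops when the max absolute membership change drops
  below 1e-8 (or 300 iterations); best of 20 restarts.
* REML truncation at zero happens *after* optimisation; the
  unconstrained estimates remain available (`variances_raw`).
* ρ parameters travel through tanh links and variances through logs,
  so optimisers can never propose a non-SPD covariance.
* All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical seed ⇒ byte-identical
  pipeline CSVs (floats formatted at 10 significant digits).

## Limitations

* The general (unbalanced) REML path is O(n³) per iteration and only
  lightly exercised; the intended design is balanced.
* Covariance fitting assumes complete profiles; genotypes with missing
  cells are dropped from the subject matrix rather than imputed.
* The Tukey studentized-range tail is evaluated numerically by scipy
  and is the runtime bottleneck of per-day scans.
* Water-use efficiency is only as meaningful as the supplied watering
  schedule; the generator's schedule is a placeholder.
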