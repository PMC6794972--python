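# Methods

## Model

Tubule occlusion is modelled as logistic growth of the occluded area
percentage X(t):

    dX/dt = r X (1 − X/K),  X(0) = X₀,
    X(t) = K C e^{rt} / (1 + C e^{rt}),  C = X₀/(K − X₀).

Assumptions: occlusion is self-limiting with a hard ceiling K (taken as
100 %, i.e. complete occlusion; overridable), deposition speed is
proportional both to already-occluded area and to remaining open area, and
the process is deterministic at the group level with measurement noise on
top. X, X₀ and K are in percent of tubule area on [0, 100]; r is per day;
t is continuous (day indices are not rounded).

The right-hand side vanishes at X = 0 and X = K. Its derivative
r(1 − 2X/K) is positive at 0 and negative at K for any r > 0, so bare
dentin is an unstable equilibrium and full occlusion is the stable
attractor; trajectories started in (0, K) increase monotonically to K.
r = 0 is reported as a documented degenerate case (every state neutrally
stable); r < 0 is refused by the equilibrium analysis because a negative
remineralization rate has no interpretation in this setting.

Numerics: the closed form is evaluated as K·expit(logit(X₀/K) + r t),
which is algebraically identical to the textbook ratio but cannot
overflow for any |r t| (tested up to r t = 700); t = 0 is pinned to X₀
exactly. The time to reach a target level θ ∈ (X₀, K) is the closed-form
inversion t = (1/r)·ln[θ(K − X₀)/(X₀(K − θ))]; θ ≥ K raises an
unreachable-threshold error since K is an asymptote.

## Rate estimation

Each paste × saliva-condition group contributes one series of daily means
(days 1..7 in the bundled study, t coded as the printed day numbers, with
X₀ the latent value at t = 0, before the first brushing day is scored).
The fit minimizes the sum of squared deviations between the daily means
and the closed-form trajectory; fitting to the mean series unweighted is
the default, with inverse-variance weights (n/SD² per day) as a
sensitivity option. K is fixed, not estimated.

Because the original study does not state how X₀ was handled, the
estimator exposes an `x0_policy` and the standard analysis runs a
sensitivity sweep over it:

* `fitted` (package default): X₀ estimated jointly with r, bounded inside
  (0, K);
* `anchored`: the trajectory is constrained to pass exactly through the
  first (day, mean) point and only r is free (X₀ is the back-projection
  of that point to t = 0);
* a fixed numeric X₀.

On the bundled table the anchored policy reproduces the study's published
rate table almost exactly (four of six cells to all four printed decimals,
a fifth to 0.5 %), so we call it the replication policy and use it for the
headline rate table; the joint fit is reported alongside. The sweep also
shows why the joint policy is fragile here: two of the six series (the
proargin paste with saliva and the bioactive-glass paste without saliva)
are not sigmoid — they stay flat for days and then jump — and the joint
fit then degenerates to a tiny X₀ with a large rate, flipping the
apparent with/without-saliva ordering for those pastes. The one cell that
resists reproduction under every policy we probed (the composite paste
with saliva, published rate 0.9500/day vs 1.2354 anchored / 1.1016 joint)
is flagged in the fit report rather than hidden; its published value
cannot be regenerated from the published daily means by least squares.

Optimization is deterministic bounded multi-start: a fixed 5×5 grid of
starting points over r ∈ [10⁻⁶, 10] (five log-spaced rates) and
X₀ ∈ (0, K) (five fractions of K), ranked by initial SSE; the best-ranked
starts (five by default, all on request) are refined with L-BFGS-B using
the analytic gradient of the SSE (ftol 10⁻¹⁴, gtol 10⁻¹²), and the best
refined point is returned. The returned SSE is guaranteed not to exceed
the SSE at any grid start, and the test suite checks dominance over an
exhaustive 200×200 grid for every bundled series. Refining only the
top-ranked starts keeps a 500-replicate recovery study under a minute
without changing the estimator (the global minimum of the same objective).

Goodness of fit is reported as RMSE and R² about the series mean; R² is
undefined (NaN) for a constant series. Fewer than three observation days
raises an insufficient-data error; a K not exceeding the largest observed
mean triggers a warning.

## Group comparisons from summary statistics

Specimen-level measurements behind the bundled table were never
published, so all tests run on (mean, SD, n) summaries; no specimen-level
data are imputed for testing.

Per-day condition comparisons use Welch's unequal-variance t-test with
Satterthwaite degrees of freedom — per-day SDs in the bundled table
differ by up to threefold, so the pooled-variance test is offered only as
a sensitivity variant. Both SDs zero is degenerate: equal means return
p = 1 by convention, unequal means raise an error. The one-way ANOVA
reconstructs the between-group sum of squares Σ nᵢ(mᵢ − m̄)² and the
within-group sum Σ (nᵢ−1)SDᵢ² exactly from the summaries (balanced or
not).

The published table marks per-day differences with superscript letters
but does not state the family over which its Bonferroni correction was
applied. The comparison report therefore carries the unadjusted p-value
and a Bonferroni-over-seven-days adjustment side by side; the `significant`
flag follows the adjusted value. Empirically the published letter pattern
matches the unadjusted tests (21/21 cells at α = 0.05, the only
non-significant cell being the composite paste on day 5), while 7-way
Bonferroni would flip three borderline cells (composite days 1 and 7,
proargin day 7) — so the letters are scored against the unadjusted family.

## Synthetic data and parameter recovery

The generator emulates the study design: for each paste × condition it
draws n specimens (default 7) on days 1..7 as the closed-form trajectory
of a known parameter triple plus independent Gaussian noise on the
percent scale (default SD 3 percentage points, the middle of the 1–9
point range of the published per-day SDs; a per-day SD vector is
accepted). Values outside [0, 100] are clipped by default — the published
summaries never leave the bounds — with a reject-and-resample variant for
bias-sensitive studies. An optional per-specimen random effect on r
exists but is off by default, since the original analysis has no
specimen-level structure to match. A fixed spec (including its integer
seed) yields a byte-identical dataset; replicate k of a recovery
experiment uses seed + k.

What the generator does **not** emulate: within-specimen day-to-day
correlation (measurements are independent by assumption; the true
longitudinal covariance is unknowable from the published summaries),
non-Gaussian measurement error, and any non-logistic trajectory shape.
Passing recovery tests therefore show that the estimator recovers rates
from data that follow the model at the study's noise scale — they cannot
certify behaviour on real series that deviate from the logistic shape,
which the bundled bioactive-glass series visibly does.

The recovery harness simulates, summarizes to daily means, refits, and
reports per cell the bias, RMSE and median of the fitted rate plus
"coverage", defined here as the fraction of replicates whose fitted rate
lies within ±10 % of truth. With the published six rates as truth, noise
SD 3 and n = 7, the median recovered rate stays within 10 % of truth in
every cell over 500 replicates, and RMSE grows monotonically with the
noise SD (checked at SD 1 vs 5, 200 replicates each, shared seed
schedule). These problem sizes run the whole validation in about a
minute on one core.

## File formats and fixture

Summary CSV: `paste, condition, day, mean, sd, n` (one row per group-day);
long CSV: `paste, condition, specimen, day, occluded_pct` (aggregated on
read). Conditions accept `WS`/`S` aliases. Validation errors name the
offending row. The bundled seven-day table ships inside the package with
its published letter pattern; a checksum test pins all 84 printed numbers.
The published per-group rates are bundled as reference truth for recovery
studies.

## Known limitations

* The single-rate logistic cannot describe delayed-onset occlusion (flat
  series ending in a jump); for such series the fitted r is a poor summary
  and R² makes that visible. Richer growth laws (Gompertz, Richards) are
  deliberately out of scope.
* Summary-based tests cannot model repeated measures on the same
  specimens across days; days are treated marginally, as in the original
  analysis.
* One published rate (composite paste with saliva) is not recoverable
  from the published daily means under any least-squares policy probed;
  the package reports what the data imply.
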