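# Methods

## The estimation problem

A stationary ultrasound detector yields counts of call sequences
("passes") per night, not individuals. echodens converts such counts to
absolute density by two routes with complementary failure modes: an
encounter-rate model that uses the full pass count but needs the
detection geometry, and an abundance-mixture model that needs only
detection/nondetection data but saturates at high activity.

## Encounter-model path

### Geometry and assumptions

Animals are modeled as particles of speed v moving independently with
uniform headings and uniform positions (the ideal-gas assumption:
movement is random with respect to the detector). The detector senses a
sector of radius r and angle θ; the animal's call is audible inside a
cone of angle α centered on its heading. An encounter requires all
three conditions simultaneously. Averaging the projected width of the
joint region over headings gives the mean profile width

    p̄ = (r/π)(θ sin(α/2) − cos(α/2) + 1),   valid for θ > π, α < π,

and the encounter rate is D·v·p̄, so D = z/(v·t·p̄). We verified the
formula against two independent oracles: a quadrature over the projected
width of the sector-intersection region (agreement < 0.01%) and the
event-level gas simulation below (bias < 2% at Monte Carlo resolution).
Geometries outside the θ > π, α < π regime raise an explicit error; other
sub-model formulas are not implemented.

With mean flight height Δh above the microphone, the plane of movement
intersects the detection sphere in a disk of radius √(r² − Δh²), giving
p̄ = 2√(r² − Δh²) sin(α/2). This form is implemented as printed and
tested only for its algebraic identities (Δh = 0 and Δh = r); its
simulation behavior (the naive full-r estimator understates density for
elevated flight) is asserted as a sign, not a magnitude.

### Detection radius

The level reaching the microphone is SPL_source − 20 log₁₀(r/d₀) − a·r,
with spherical spreading from the reference distance d₀ = 0.1 m (the
bat-acoustics convention) and a the ISO 9613-1 pure-tone absorption
(classical/rotational plus O₂ and N₂ vibrational relaxation). The
detection radius is the unique root of this strictly decreasing function
at the detector threshold, bracketed by the zero-absorption bound and
solved by Brent's method (residual < 1e-6 dB).

Per-night conditions: within-night median temperature and humidity from
the site's weather series (medians for robustness to logger spikes), and
pressure from site elevation via the standard atmosphere. The absolute
detector threshold is a configuration parameter (default 20 dB SPL at
the microphone) because recorder chains publish only relative trigger
settings; `calibrate_threshold` fits a single threshold to published
detection-range spans (a one-dimensional golden-section fit on the summed
squared log-ratio of span endpoints). Against published field spans for
44/28/48 kHz callers the calibrated threshold lands near 24 dB SPL with
every span endpoint within ±25%.

Source SPL is swept over the species' plausible range (default
90–120 dB in 10 dB steps) and the resulting per-cell densities are
reported as a grid; the grid spread characterizes parameter uncertainty
and is deliberately not a confidence interval.

### Pooling conventions

One density per species × period × variant is computed as a ratio of
totals: z summed over all surveyed site-nights of the period divided by
(v × summed duration × p̄), with p̄ using the median per-night radius per
SPL grid point. The reported "average density" is the unweighted mean
over periods and grid cells; the convention is isolated in
`summarize_grem` so it can be switched. Pass counts are used as recorded
— re-entries by the same individual are separate encounters, which is
exactly what the encounter-rate theory counts.

## Abundance-model path

### Sessions

Call times are normalized by night length (0 at sunset, 1 at sunrise) and
pooled per species/variant/period; Scott's rule h = 3.49·σ·n^(−1/3)
gives the session count S = ceil(1/h), clamped to [1, 48] (≈ 10-minute
sessions on an 8-h night) so model size stays bounded. Pooling across
nights (rather than per-night S) keeps occasions aligned across sites; a
per-night variant can be slotted in by passing a different `SessionGrid`.
Bins are right-open with the final bin closed, the standard histogram
convention.

### Likelihood and fitting

The site marginal likelihood marginalizes N over 0..K with K the
smallest value leaving Poisson tail mass < 1e-8 (floor 50). The fit
maximizes the summed log marginal likelihood by L-BFGS-B with 5 random
restarts from a seeded stream; detection uses a logit link (temperature
and humidity polynomials, a session-index polynomial on the index
centered and scaled to [−1, 1] to avoid collinearity at large S, and
device dummies against the most frequent device), abundance a log link on
mean-centered site covariates. Convergence is declared when the
finite-difference gradient infinity-norm is below 1e-3 relative to the
objective and the best restarts agree; an absolute 1e-6 gradient norm is
not attainable with finite-difference gradients at this objective scale.
Wald intervals come from the central-difference observed information.

Site covariates are ranked by random-forest permutation importance
(mtry = 18 following the two-times-root-p heuristic at 73 candidate
variables; tree count doubled from 500 until successive importance
rankings correlate ≥ 0.95 by Spearman), then greedily pruned at |Pearson
r| > 0.6 keeping the higher-ranked member, and the top 5 (configurable)
enter the abundance model. The detection design is chosen first by AIC
among the nested family (temperature/humidity orders 0–2, session orders
0–4, device on/off) with intercept-only abundance, then refitted with the
selected site covariates.

### Goodness of fit

The MacKenzie–Bailey statistic sums (O_h − E_h)²/E_h over distinct
observed histories within cohorts sharing a missingness pattern, plus a
remainder cell for unobserved histories. The reference distribution is
parametric-bootstrap: simulate from the fitted model, refit, recompute;
p is the bootstrap proportion ≥ observed and ĉ the observed-to-mean
ratio. ĉ is reported but never used to inflate standard errors. For
intercept-only designs without missing data the per-site likelihood
depends only on the detection count, and all bootstrap refits are batched
through a vectorized damped-Newton solver on the two-parameter
sufficient-statistic likelihood (the observed data are refitted through
the same solver so both sides sit at comparable optima); inside this path
K uses the exact 1e-8 tail quantile without the floor. Bootstrap refits
that end on the weak-identifiability ridge keep their statistic — their
fitted history probabilities are valid, and dropping them would thin the
reference tail and inflate rejection.

Density is reported as mean λ over the median MCP home-range area, and
withheld when the GOF p-value is ≤ 0.05. Home-range areas are
user-supplied configuration constants.

## Synthetic data

The gas simulator places round(D·L²) animals uniformly on an L × L torus
(L ≥ 10r) with uniform headings. For ballistic motion the per-heading
detectable set is a union of at most two convex circular sectors, so
crossings are counted exactly: each sector is a disk intersected with two
half-planes, intersected analytically with the straight path and its
lattice of torus translates; z counts entries (including an animal
already detectable at switch-on, and re-entries). A fixed-step state
machine (step ≤ r/(4v)) backs the turning-flight variant and the
discretization cross-checks; at the coarsest allowed step it misses ~8%
of short crossings, which is why the exact counter is the default.
Elevated flight replaces r by √(r² − Δh²) and is otherwise identical
(Δh = 0 reproduces the ground simulation bit for bit).

The RN generator draws site covariates standard normal, λ by log link,
N ~ Poisson, occasion covariates standard normal, r by logit link and
y ~ Bernoulli(1 − (1 − r)^N). The survey faker stitches gas-simulation
event times into per-night call timestamps, attaches a diel temperature
curve with noise and a drifting humidity series, and writes the four CSV
files consumed by the readers (each pass appears once per identification
variant).

What the generators do not emulate: home-range-constrained or
habitat-guided movement, flight-path reuse, 3-D flight, call-rate
variation, weather-dependent activity, and identification error
differences between the strict and generous variants. Passing tests
therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to the behavioral realism of field data.

## Verification scale and numerical choices

- Gas-oracle density recovery uses 500 replicates per signal angle at
  D = 5/km², r = 30 m, v = 5.4 m/s, 8-h nights, arena 3000 m. The
  replicate count comes from a power argument: the pooled-density Monte
  Carlo error is then 1.1–1.9%, small enough to resolve a 5% bias band;
  at 50 replicates the Monte Carlo error alone (~6%) would swamp it.
  The larger arena also de-clusters encounters (more animals, shorter
  wrapped paths) at fixed expected z.
- RN recovery and interval coverage use 100 simulated surveys of 200
  sites × 15 occasions at λ = 2, r = 0.3; GOF calibration uses 200
  simulations × 500 bootstraps under the same conditions. At much
  smaller designs (e.g. 50 × 5) the parametric bootstrap is measurably
  anti-conservative (rejection ≈ 0.08 at the 5% level), a known
  small-sample limitation worth keeping in mind with few sites.
- Root solves: Brent with xtol 1e-10; likelihood truncation 1e-8; AIC
  with per-parameter penalty 2 throughout (no small-sample correction).
- Ties at session boundaries go to the right-open bin; the final bin is
  closed at 1.

## Known limitations

- Only the wide-sensor/narrow-signal profile-width regime is
  implemented; other (θ, α) regimes error out.
- The altitude-corrected width is used as printed; it omits θ, and its
  bias relative to the full sphere–plane–sector geometry is not
  characterized beyond the sign check in simulation.
- gREM densities carry no confidence intervals — only the parameter-grid
  envelope.
- The device covariate is a fixed effect; surveys with many devices and
  few sites per device will overfit.
- The RN likelihood has a λ–r ridge on saturated histories; fits there
  are flagged via the boundary/convergence machinery but the reported λ̂
  magnitude is not meaningful (the density comparison example deliberately
  stays below saturation).
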