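# Methods

This note documents the statistical model behind each processing stage, the
defaults and their rationale, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was genuinely
open.

## Signal model and detection

A dwell-resolved SP-ICP-MS trace is modelled as independent Poisson counts
per dwell: mean λ_bg from dissolved analyte and instrument noise, plus
transient particle peaks of full base width τ (~500 µs for gold, ~600 µs for
Ti/Cr/Cu particles; default 500 µs). With a dwell time of 100 µs
(600 000 dwells/minute) a peak spans ~5 dwells.

**Threshold.** Detection is a per-dwell test at false-positive probability
α = 0.05/600 000 ≈ 8.3 × 10⁻⁸ per dwell: the critical count is the smallest
integer k with Poisson CDF(k; λ) ≥ 1 − α, and a dwell is flagged iff its
count is *strictly greater* than k. The strict comparator makes the
guarantee exact under discreteness, so a full minute of pure background is
false-positive-free with ≥ 95 % probability (in practice more, because the
integer threshold overshoots the nominal level; at λ_bg = 1 the expected
clean-minute fraction is 99.4 %).

**Local background.** λ is estimated by a centred rolling mean (default
window 1001 dwells ≈ 0.1 s) over dwells *not* currently flagged as particle
signal; flags and estimate are iterated to a fixed point (≤ 10 iterations —
in practice 2–4). The window is long enough to average counting noise to
≲ 5 % at λ_bg ≥ 0.2 and short enough to track drift on the ~0.1 s scale.
Edges are handled by shrinking the window.

**Background subtraction.** Integration subtracts a rolling median, which is
robust to the particle spikes themselves. The integer median of low-mean
Poisson data is nearly uninformative (it is 0 for any mean < ln 2 and biased
by up to ~0.7 counts elsewhere), so where the rolling median is below 1 the
subtraction falls back to the exclusion-filtered rolling mean; where the
median is ≥ 1 the worst-case bias is < 0.7 counts/dwell, negligible against
peak areas of tens to hundreds of counts. (A fixed additive "median + 1/3"
correction was considered and rejected: it is exact only at means where the
distribution median sits at the top of its step, and on integer-mean Poisson
data — where the sample median is already exact — it would *introduce* a
+0.33 bias.)

**Events.** Contiguous flagged dwells form an event; events separated by
≤ ⌈τ/t_d⌉ sub-threshold dwells are merged, since one particle can straddle
dwell boundaries. Each extent is then padded by ⌈τ/t_d⌉ dwells per side
before integration: the sub-threshold tails of a peak carry real signal
(for near-threshold particles ~15 % of the area), and background subtraction
keeps the padding unbiased. Indices are 0-based, intervals half-open.

**Threshold harmonisation.** For multi-run comparisons each run's count
threshold is converted to a per-particle mass threshold and one common value
applied to all runs, so that all share a false-negative floor. Both the
"highest" (unbiased between-run comparison; the default) and "lowest"
(maximum sensitivity at matched false-negative rates) policies are
implemented as an explicit switch, since both conventions are in use.

## Calibration

Ionic standards (defaults mirror a routine gold sequence: 0.5, 1, 5 µg/L)
are fitted by unweighted OLS with a free intercept — weighting or forcing
the origin is unwarranted at three points spanning one decade. Transport
efficiency uses the particle size method: the event-intensity distribution
of a certified reference nanoparticle (e.g. 60 nm gold) is summarised by the
mode of a Gaussian KDE (Silverman bandwidth, 2048-point grid on
[0, 1.2·max]) — the mode, unlike the mean, is robust to the lower-tail
pile-up of partially missed or artefactual small events. The unit algebra is
fixed by one convention (masses ag, flow mL/min, concentrations µg/L, dwell
time s, u = 10⁹/60 ag per µg/L·mL/min·s) and validated by simulator round
trips: η values baked into simulated sensitivities are recovered within
Monte Carlo error. η outside (0, 1) raises a calibration failure rather than
propagating nonsense.

## Quantification

`C_N = n/(η·q·t_acq)·D` and `C_m = Σmᵢ/(η·q·t_acq)·D`, with `C_m/C_N` equal
to the mean per-particle mass by construction. The reported mean diameter is
the arithmetic mean of per-event mass-equivalent diameters, matching the
convention of reporting the mean of the displayed size distribution (the
alternative — diameter of the mean mass — is systematically larger for any
polydisperse sample). Events below the harmonized mass threshold are
censored before all summaries. No coincidence correction is applied inside
the working range; above the coincidence bound a warning is raised instead,
treating the bound as a range limit rather than something to correct through.

## Limits and working range

* Per-particle critical value: triangular peak of base τ and apex at the
  intensity threshold height h (counts above background), area
  `(τ/t_d)·h/2`, converted to mass and diameter. A particle at exactly this
  limit is detected ~50 % of the time (its measured area fluctuates
  symmetrically about the critical area); the package's simulations
  reproduce 50 % within sampling error, modulo the small Poisson-skewness
  deficit of order 1/√(gross counts).
* Mass-concentration LOD: pooled blank mean + 3 SD (sample SD, ddof = 1).
* Number-concentration LOD: exact Garwood (chi-square) upper bound of a
  two-sided central 99.7 % Poisson interval on the pooled mean blank count;
  "99.7 %" is read as central two-sided coverage and the chi-square form
  extends continuously to non-integer pooled means. The Garwood bound was
  chosen because it is exact under the Poisson model at any count, including
  zero (upper limit −ln 0.0015 ≈ 6.50 counts for zero observed events).
* Upper working range: 5 % coincidence with a ±τ window around each
  arrival, `λ_max = −ln(1−α)/(2τ)`; the 2τ window is the natural "another
  particle overlaps this peak" criterion. At τ = 500 µs, η ≈ 6 %,
  q = 0.346 mL/min and D = 500 this lands in the 10⁷–10⁸ particles/g decade.
* Per-day limits can be pooled conservatively by the maximum across days.

## Validation statistics

One-way ANOVA precision follows the variance-components decomposition:
s_r² = MS_within, s_between² = max(0, (MS_between − MS_within)/n₀) with n₀
the unbalanced-adjusted group size, s_IP² = s_r² + s_between². When
MS_between < MS_within the between-day component is clamped to zero, a flag
is set, and the total RSD (SD of all values / grand mean) is carried as the
reporting fallback. Monte Carlo uncertainty propagation draws all budget
components independently (normal, uniform, triangular or Poisson), evaluates
the measurand per draw (default 10⁵ draws, seeded), and reports the relative
standard uncertainty times the coverage factor (default k = 2); component
variance shares come from one-at-a-time re-evaluation about the nominal
point. No default numeric budget is shipped — budgets are measurement-
specific inputs.

## Synthetic data generator

`spq.simulate` draws exponential inter-arrival times at the detected-particle
rate, per-particle diameters from a point-mass or lognormal distribution,
and distributes each particle's expected counts (sensitivity × mass) over a
triangular (default) or Gaussian template discretised by integrating over
dwell boundaries; every dwell is then one Poisson draw, so coincident
arrivals superpose exactly as in the detector. Defaults mirror the
validation-study conditions: 100 µs dwells, 500 µs peaks, 0.346 mL/min
intake, backgrounds of order 0.2–1 counts/dwell, sensitivity 0.14 counts/ag
(consistent with η = 6 % and an ionic slope of ~4.8 counts/dwell per µg/L),
monodisperse 30 or 60 nm gold spikes at tens of particles per second.

What it deliberately does **not** emulate: nebulisation physics, ionic-cloud
expansion (and hence the size-dependent tailing artefact that can appear as
a spurious small-size population for larger particles), detector dead time,
matrix suppression, and background drift. Passing tests therefore
demonstrate the correctness of the statistical processing under its stated
model, not robustness to those instrumental effects; on real data the
matrix-induced signal suppression in particular biases sizes and mass
concentrations low unless matrix-matched standards are used.

## Problem sizes in the test suite

The suite favours parameter regimes where oracles are sharp but cheap:
single traces of 10⁵–4 × 10⁶ dwells, 300–3000 particles per trace, 8–30
seed replicates for Monte Carlo comparisons, 2 × 10⁵ draws for uncertainty
propagation, and the binomial shortcut (exact per-dwell exceedance
probability) for the 1000-minute false-positive budget check. All
stochastic tests are seeded.

## Known limitations

* The rolling-median/mean background tracks drift only on scales longer
  than the window; step changes in background are smeared over ~window/2.
* Coincident particles are merged into single events (counted once, with
  summed mass); no deconvolution is attempted.
* The size LOD assumes the triangular peak model; real peak shapes deviate,
  which shifts the critical area by the shape factor.
* Recovery/z-score machinery takes reference values as exact; reference-
  material uncertainty belongs in the Monte Carlo budget instead.
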