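# Methods

## Model

The reservoir is modelled as the surface-preserving reshaping of a
cylinder into a sphere. A harvested ileal segment of length *L* (cm) and
hemicircumference *w* (cm) is an open cylinder of circumference 2*w*, so
its lateral (mucosal) surface is A = 2wL. The finished pouch is assumed
spherical; equating 4πr² = 2wL gives r = √(wL/2π) and the capacity
V = (4/3)πr³ = √(2(wL)³/9π) in ml (1 ml ≡ 1 cm³). Solving for *L* gives
the planning form L = ∛(9πV²/2)/w, so the required length is inversely
proportional to the width at fixed target volume.

Four assumptions underlie this algebra, and each marks a limitation:

1. **All tissue reaches the pouch wall** — suture loss is treated as
   negligible. Stapled reconstructions, which consume a non-negligible
   strip of tissue, will fall short of the prediction.
2. **The pouch is a sphere.** The model applies to spheroidal
   configurations; W-, S- or U-shaped reservoirs with internal septation
   are out of scope.
3. **The segment is a cylinder of constant diameter.** The width is
   therefore taken as the mean of two readings, made 10 cm from each end
   of the segment.
4. **Wall thickness is negligible.** On the bench the opened strip
   measures 2w plus roughly 0.19 cm of thickness allowance; the model
   treats that allowance as consumed by the suture line
   (`expected_opened_width` exposes it), leaving the effective posterior
   plate 4w wide and, by area conservation, L/2 long.

The model is static: reservoir capacity is known to increase over the
months after surgery, and no time-dependence is modelled.

Sensitivity follows directly from V ∝ (wL)^{3/2}: at fixed length the
relative gain from a width change Δ is ((w+Δ)/w)^{3/2} − 1, independent of
L (83.7% for 2 → 3 cm); at fixed target the spared length between two
widths is the difference of the closed-form inverses (≈ 20 cm between 2
and 3 cm at 350 ml). The Laplace helper uses the thin-walled-sphere
convention T = Pr/2 (and P = 2T/r); only the proportionality matters for
the clinical argument, but the standard factor ½ is adopted so the units
compose.

## Parameters and conventions

| Quantity | Unit | Default | Rationale |
|---|---|---|---|
| width *w* | cm | — | hemicircumference of the closed tube, never the diameter |
| length *L* | cm | — | stretched segment length |
| capacity *V* | ml | — | 1 ml ≡ 1 cm³; no unit inference anywhere |
| width plausibility band | cm | [2.0, 3.5] | observed human range; outside → warning, never an error |
| length plausibility band | cm | (10, 80] | the span of lengths used for ileal reservoirs |
| clinical rounding | cm | ceil | never harvest less than the formula requires |
| cohort mean / SD | cm | 2.43 / 0.39 | reported human distal-ileum statistics |
| cohort truncation | cm | [2.0, 3.5] | observed range |
| bench noise `relative_sd` | — | 0 | log-scale SD of multiplicative measurement error |

Exact planned lengths are always reported at full precision alongside the
clinical value; published worked examples round the exact length either
way (34.31 → 35 but 41.41 → 41), so both are exposed and the safe ceil is
the package's single clinical convention. A 1 nm slack is subtracted
before the ceil so that a length that is an integer up to float error
(e.g. a round-tripped 60.0000000000001) is not bumped a full centimetre.

## Synthetic data

`simulate_widths` draws ileal widths from a normal distribution with the
human cohort defaults (mean 2.43 cm, SD 0.39 cm) truncated to [2.0,
3.5] cm. Only mean, SD and range of the real cohort are known, so the
distribution *shape* is an assumption; truncation is implemented by
rejection sampling (acceptance ≈ 87% at the defaults), which is exactly
bounded; an inverse-CDF transform would be the alternative if acceptance
ever became a cost. `sd_cm = 0` degenerates to a constant cohort at the
mean.

`simulate_bench` turns widths into virtual bench pouches: the effective
capacity is the model prediction perturbed multiplicatively,
`effective = V·exp(ε)`, ε ~ N(0, `relative_sd`). Multiplicative noise
keeps capacities positive and scales errors with pouch size, matching how
leak-test deviations behave; an additive component exists for sensitivity
exploration but defaults to 0. All generators take mandatory seeds and
are byte-reproducible.

What the simulator does **not** emulate: tissue viscoelasticity and
stretch under filling, peristalsis, inter-measurement correlation within
a patient, systematic (as opposed to random) measurement bias, and the
post-operative capacity increase. Passing simulation-based tests
therefore demonstrates the statistical pipeline and the model's internal
consistency, not clinical accuracy in humans — which only prospective
measurement can establish.

## Validation statistics

`validate` recomputes every prediction from the recorded (L, w) — a table
can never smuggle in its own predicted column — and reports Pearson's r,
mean absolute error (ml), mean relative error (% of effective) and the
signed bias predicted − effective (positive = overprediction). A
correlation needs n ≥ 3 and non-degenerate variance; when predicted and
effective agree elementwise the r = 1 limit is returned directly rather
than relying on a 0/0 evaluation. The five bench pairs available in print
ship as `BUILTIN_BENCH_RECORDS` (r ≈ 0.989 on those five); the full
12-pouch bench table behind the published correlation was released only
as a figure and is deliberately not transcribed.

## Numerical choices

- Closed-form identities (round trips, conservation laws) are asserted at
  relative 1e-9; the bisection oracle (`scipy.optimize.brentq` inverting
  the forward model over L ∈ (0, 500] cm) must agree with the closed form
  within 1e-6 cm across 1000 random (V, w) pairs.
- Domain errors (non-positive or non-finite lengths, widths, volumes)
  name the offending field; implausible-but-valid measurements emit a
  `PlausibilityWarning` and set `plausible=False` instead of failing, so
  unusual anatomy never blocks a computation.
- Curve grids must be strictly increasing and positive; violations are
  input errors (CLI exit 2), distinct from domain errors (exit 3).
- The two-reading width protocol keeps the exact arithmetic mean (3.0 and
  2.5 cm → 2.75 cm, not a rounded 2.8) — display rounding happens only in
  text output (whole ml, 0.1 cm).

## Problem sizes

Everything is closed-form; the heaviest pieces of the test suite are the
1000-pair bisection-oracle comparison and a 5000-draw cohort
parameter-recovery check (sample mean within 0.03 cm of the analytic
truncated-normal mean from `scipy.stats.truncnorm`). The full suite runs
in a few seconds on one CPU; the acceptance script's Monte Carlo
self-check uses a 12-pouch bench at 5% noise, mirroring the scale of the
original bench experiment.
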