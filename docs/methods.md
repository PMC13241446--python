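# Methods

## Model

`tauavrami` treats post-traumatic tau accumulation as a deterministic
KJMA (Kolmogorov–Johnson–Mehl–Avrami) nucleation-and-growth process.
Misfolded-tau seeds appear at a volumetric nucleation rate
`J(t') = J0·exp(kJ·t')`; each seed grows as a sphere with radial
velocity `v(t) = v0·exp(kv·t)`.  Exponential time modulation covers
accelerating (`k > 0`), constant (`k = 0`) and decelerating (`k < 0`)
regimes for both processes.  Summing the non-impinging spherical volumes
of all seeds born in `[0, t]` gives the extended volume `Y_e(t)`; the
classical impingement correction plus a saturation bound α give the
observable transformed percentage `X(t) = α(1 − exp(−Y_e(t)))`.

Assumptions inherited from the model class: nuclei are spherical and
grow isotropically; kinetics are deterministic (the aim is the averaged
tissue-scale burden, not realization-to-realization variability); tau is
measured in AT%-units — the percentage of histological area labelled by
the AT8 antibody — and all tau values (0.0032 … 0.35) are used as
dimensionless numbers inside exponentials, with no division by 100.
Time is in days throughout; there is no internal unit conversion.

## Parameters

| parameter | meaning | units | default / baseline |
|---|---|---|---|
| `v0` | reference growth velocity | mm/day | sensitivity baseline 1e-3 |
| `J0` | reference nucleation rate | nuclei mm⁻³ day⁻¹ | 1e-3 |
| `kv` | growth modulation | day⁻¹ | 1e-3 (any sign allowed) |
| `kJ` | nucleation modulation | day⁻¹ | 1e-3 (any sign allowed) |
| `alpha` | saturation bound on X | AT%-units | 0.35 |
| `exponent` | strain-weighting power | – | 4 |
| `A` | impact-amplitude factor (Q/Q_ref)(N/N_ref) | – | 1 |
| threshold | atrophy removal level on element tau | AT%-units | 0.7 |

α = 0.35 sits slightly above the six-month murine burden (≈ 0.25 AT%)
and keeps the global curve in the sub-percent range reported by
quantitative tau histology; it is a plain parameter, not a structural
constant.  The published unit for `J0` ("nuclei mm⁻¹ day⁻¹") is
dimensionally inconsistent with a volumetric nucleation rate; this
package uses mm⁻³ day⁻¹ and notes the discrepancy rather than guessing
an intent.  The fourth-power strain weighting is an exploratory
modelling assumption (it sharpens focality versus quadratic/cubic maps),
so the exponent is exposed as a parameter.

## Extended volume: closed form and quadrature oracle

`extended_volume` evaluates the four-term closed-form bracket scaled by
`(4π/3)·J0·(v0/kv)³`, with each term computed through `expm1` to avoid
cancellation inside the term.  Two regimes defeat the closed form and
trigger a fallback to `extended_volume_quadrature` (adaptive
`scipy.integrate.quad` of the birth-time integral, relative tolerance
1e-10), keeping `Y_e` continuous in the parameters:

- **degenerate denominators** — any of `kv`, `kJ`, `kJ+kv`, `kJ+2kv`,
  `kJ+3kv` with `|d|·t < 1e-6`.  Hand-derived series limits for all five
  degeneracy lines are error-prone; the oracle guarantees continuity at
  negligible cost at desk scale.
- **catastrophic cancellation** — when all `|k|·t` are small the four
  O(t) bracket terms cancel down to O(k³t⁴) (e.g. at
  `kv = kJ = 1e-3, t = 1` the terms are O(1) but the bracket is
  O(1e-10)).  The result is accepted only when the a-posteriori estimate
  `eps·max|term| / |bracket|` is ≤ 1e-9; otherwise quadrature is used.

The radius integral itself is evaluated in the stable form
`(v0/kv)·e^{kv·t'}·expm1(kv·(t−t'))`, which remains accurate for
negative and tiny `kv`.  Exponent arguments above 700 raise a typed
overflow error (carrying the exponent) instead of returning infinity;
the calibration objective converts such failures into a large finite
penalty (1e12) so derivative-free optimizers can continue.

## Calibration

Only the product `C = J0·v0³` (together with `kv`, `kJ`) is identifiable
from a tau time series — `J0` and `v0` never appear separately in
`Y_e`.  The optimizer therefore works in `(log C, kv, kJ)` and expands
back to four parameters by pinning `v0` to a configurable reference
(default 0.0472197 mm/day, the published growth velocity), setting
`J0 = C / v_ref³`.

The two-step procedure: (1) a seeded random exploration — log-uniform
`C ∈ [1e-14, 1e-2]`, uniform `kv, kJ ∈ [−0.1, 0.1]` day⁻¹, 5×10⁴
samples by default — ranked by mean-squared error; (2) Nelder–Mead
refinement of the top 5 candidates (`fatol` 1e-12, iteration cap 10⁴).
Refinement is kept inside the sampled box by a quadratic penalty
(objective evaluated at the clipped point): an unconstrained simplex on
the murine series walks to `kJ ≈ 3.9 day⁻¹`, which overflows
`exp(kJ·t)` at year-scale projection times.  The sampling ranges bracket
both the published parameter magnitudes and the regimes the data's shape
requires.  The seed is mandatory; identical seed, config and
observations give bit-identical results.  R² is the coefficient of
determination about the observed mean.

The built-in murine series (days 1/7/60/180; tau 0.0032/0.0048/0.0085/
0.2533) is the biological anchor.  Note that the *published* parameter
quadruple (`datasets.published_parameters`) does not reproduce the
published day-1 prediction within these equations with t in days — with
`|k|·t ≤ 6e-4` the kinetics are effectively constant-rate and give
`X(1) ≈ 4e-10`, not 0.00388; an unstated unit conversion or transformed
fitting variable is likely.  The package exposes both the printed
quadruple (for reference) and its own re-fit, and reports the re-fit's
residuals honestly (RMSE ≈ 2.9e-3 within this model family and these
parameter ranges).

## Spatial coupling

The nodal field is min–max normalized, `w = (w0−min)/(max−min)`.  A
constant raw field is the 0/0 corner; by convention it maps to `w ≡ 1`,
so the heterogeneous model degrades exactly to the homogeneous curve
(any constant would give the same tau after correction; 1 keeps `S`
interpretable).  The spatial average is the unweighted node mean, not an
element-volume-weighted mean.

`S(t)` solves `mean_i(1 − exp(−S·A⁴w_i⁴·Y_e)) = X(t)`.  The left side
is strictly increasing in `S` and saturates at the fraction of nodes
with positive weight, so the root is unique when reachable; feasibility
(`X <` positive-node fraction) is checked before solving and an
infeasible target raises a typed error naming the time, rather than
diverging silently.  The solver brackets `[0, S_hi]` by doubling, runs
Brent to machine precision, and polishes by bisection until the residual
on the *mean* is ≤ 1e-10 (the default tolerance).  At `Y_e = 0` the
equation is vacuous and `S = 1` is recorded by convention.  Because
`X(t)` is non-decreasing and the mean is strictly increasing in
`S·Y_e`, the product `S(t)·Y_e(t)` — and with it every nodal tau — is
non-decreasing in time.  Local tau is kept strictly below 1 (the
dimensionless local bound): where `exp(−S·b)` underflows, tau is capped
at the largest double below 1 (error < 1 ulp).

## Atrophy surrogate

Tau is nodal but removal is per element, so a nodal-to-element reduction
bridges the two; the default is the arithmetic mean of the element's
nodal tau (least biased; `max`/`min` available).  Elements with reduced
tau ≥ 0.7 (model AT%-units, strict `≥`) are removed; a cumulative OR
along time enforces monotone removal against rounding.  Removed volume
is tracked but never fed back into the kinetics — coupling atrophy back
into the transformation law is deliberately out of scope.

## Synthetic fields

`generate_synthetic_field` emulates the one feature of finite-element
impact output this model consumes: a smooth non-negative nodal scalar
with a focal high-strain region.  It is a Gaussian blob (default peak
0.30, background 0.02 — magnitudes typical of maximum principal strain
in moderate head impacts; sigma defaults to a quarter of the domain
extent; centre on the +x "frontal" face) plus optional seeded Gaussian
noise, clipped at zero, over a regular hexahedral grid or an icospheric
shell (for the shell, per-element "volumes" are triangle areas).  What
it does *not* emulate: anatomical geometry, tissue heterogeneity,
sulcal/gyral strain concentration, spatial noise correlation, or any
relation between strain and actual murine pathology — so passing tests
demonstrate the mathematical contracts (mean enforcement, ordering,
localization), not biological validity of predicted maps.

## Problem sizes and defaults in tests and the acceptance script

Test fields use 10³–10⁵ nodes (a 12³ grid for the focal fixtures, 10⁵
random weights for the large mean-enforcement check); calibrations in
tests use 2–4×10³ search samples with 3 restarts, which the recovery
experiment shows is already convergent (noise-free truth recovered to
~1e-11 relative).  The acceptance script uses 2×10⁴ search samples for
the murine re-fit, 200 random parameter draws × 3 times for the
closed-form/quadrature comparison, and a 15³ grid for the projection and
atrophy stages.  The parameter-recovery experiment samples its truth
trajectory at days 1, 12, 24, …, 144: past ~day 150 that trajectory
saturates to exactly α in double precision, and saturated points carry
no information about the kinetics.

## Known limitations

- Global, single-curve calibration: no regional kinetics, no repeated
  impacts, no cross-species scaling of the murine time course.
- The strain field is a single static scalar per node; no diffusion or
  connectome-mediated spreading term exists in the model.
- Four observations cannot constrain three effective parameters tightly;
  the murine re-fit is an interpolation within a flexible family, not an
  identification.
- The atrophy surrogate is a visualization of threshold exceedance, not
  a tissue-loss law.
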