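# Methods

## Scope and model structure

`marsalt` bounds the distance wind-saltating grains can carry viable
*Bacillus subtilis* endospores across Mars, treating abrasion during
grain–grain collisions as the only kill mechanism. Three coupled pieces:

1. a hop-length law giving the characteristic length of one saltation
   hop from atmosphere, gravity, wind and grain size (`physics`);
2. a survival curve giving the fraction of spores still viable after a
   tumbling time, with tumbling rotations equated one-to-one with hops
   (`survival`);
3. transport end-members converting a hop count into a distance
   bracket, deterministically and by Monte Carlo (`transport`),
   orchestrated into the headline table by `pipeline` and made testable
   end-to-end by the `synthetic` generator.

UV and other non-abrasive kill mechanisms, trajectory physics (launch
angle, drag), threshold-friction-speed modelling and suspension
transport are out of scope; shear velocities are user inputs.

## Hop-length law and its parameters

L_salt = 1091.5 · (v²/g)^(1/3) · (u★ − u★t) / √(g·d), SI units
throughout, lengths internally in metres. The typeset source of this
law is typographically garbled; the implemented form is fixed by two
requirements that leave no freedom: the stated building blocks
(v = η/ρ, g, d, u★, u★t and the 1091.5 prefactor), and reproduction of
both quoted Mars hop lengths (29 m at d = 1 mm, 81 m at d = 0.125 mm).
Unrounded, the implementation gives 28.664 m and 81.074 m. The law is
exactly linear in the shear excess (u★ − u★t) and scales as d^(−1/2);
both are asserted as machine-precision invariants in the tests.

Defaults (each overridable via the YAML config or dataclass fields):

| parameter | default | unit | note |
|---|---|---|---|
| η (dynamic viscosity) | 1.3×10⁻⁵ | kg m⁻¹ s⁻¹ | thin CO₂ atmosphere |
| ρ (fluid density) | 0.02 | kg m⁻³ | |
| g (gravity) | 3.71 | m s⁻² | source prints "m s⁻¹", an evident unit typo; only the m s⁻² reading reproduces the quoted hop lengths |
| u★ (shear velocity) | 1.45 | m s⁻¹ | midpoint of the 1.12–1.78 estimate range; no other point in the range is more defensible, so sensitivity is left to the user via config |
| u★t (impact threshold) | 1.12 | m s⁻¹ | |
| d (grain diameters) | 10⁻³, 1.25×10⁻⁴ | m | the two grain classes of the tumbling experiments |
| rotation rate | 1 | s⁻¹ | forced by the pairing of 1 minute with 60 hops |

u★ < u★t raises a below-threshold error (no sustained saltation);
u★ = u★t yields a zero hop length, which propagates to all-zero
distances.

## Survival curve

Anchors: (60 s, 0.50), (3600 s, 0.03), (86400 s, 0.005) — digitized
values from tumbling experiments; the full source figure is not
re-digitized, so intermediate times are a modelling choice, not data.

The table-reproducing model is a piecewise-linear interpolant in
(log t, log S): exact at every anchor, monotone between them, and the
natural choice when the anchors are near power-law and the argument
runs over three decades. At the geometric midpoint of two anchor times
it returns the geometric mean of their fractions (e.g.
S(√(60·3600)) = √(0.50·0.03) ≈ 0.1225). Evaluation outside
[60 s, 86400 s] raises an out-of-range error unless extrapolation is
explicitly enabled, in which case the terminal segments extend as local
power laws and CLI output is flagged `(extrapolated)`.

The Weibull form S(t) = exp(−(t/λ)^k) is fitted by least squares on the
linearisation log(−log S) = k·log t − k·log λ (optionally weighted).
It is never used for the table; it exists to (a) express the
lengthening-half-life behaviour formally — for k < 1 the time for the
surviving population to halve again strictly increases — and (b) act
as ground truth for synthetic data. On the three anchors the fit gives
k ≈ 0.285, λ ≈ 134 s. Note the pairwise log S/log t power-law
exponents between consecutive anchors (0.69, 0.56) are a different
quantity from the Weibull shape; both are < 1, consistently
sub-exponential.

## Transport end-members and the Monte Carlo validator

With n hops of length L, the prevailing-wind bound is the collinear sum
n·L (maximum) and the no-prevailing-wind bound is the RMS net
displacement of a 2-D isotropic fixed-step walk, √n·L (minimum
end-member). RMS is adopted rather than the mean displacement
((√π/2)·√n·L ≈ 0.886·√n·L in the Rayleigh limit) — the source of the
printed values does not say which convention it used, and both round to
the same one-significant-figure cells, so the ambiguity is noted here
rather than resolved. Hop counts are integers; rate×duration products
round half away from zero.

`simulate_walk` draws per-hop directions uniformly on [0, 2π) with
numpy's PCG64 generator, fully determined by the seed; the
prevailing-wind mode is exact by construction. The RMS standard error
is propagated from the sample variance of squared displacements by the
delta method. Default ensembles of 10⁴ walkers put the RMS check well
inside a 3-standard-error band; tests use 10⁴ walkers at n = 100 hops,
which runs in well under a second.

Intermediate direction distributions (partially concentrated winds) are
deliberately not modelled: the two end-members are the argument.

## Table reproduction and rounding

For each duration (1 minute, 1 hour, 1 day) and each grain class the
pipeline emits a raw row (unrounded km) and a rounded row. The raw rows
satisfy min = max/√n identically. The report rounding is
half-away-from-zero to one significant figure, except that values in
[10, 100) km keep two significant figures — a convention
reverse-engineered from the printed cells it must reproduce (0.2, 2,
0.6, 5, 100, 300, 8, 2,000, 24, 7,000) and documented as such. Under it
all fourteen numeric cells of the reference table reproduce, including
the 1 mm / 1 day linear cell: the computed 2476.6 km rounds to
2,000 km. That cell is nonetheless the coarsest rounding in the table —
the printed value sits ~19% below the computed one, and the rounded
hop length (29 m) would instead give 2505.6 km → 3,000 km — so the
pipeline attaches an explicit note to any linear-distance cell whose
rounding discards more than 15% of the value, rather than letting it
pass silently. Survival percentages are the interpolant evaluated at
the row's tumbling time, never the Weibull fit.

`run_report` wraps both table variants with a provenance block
(parameters, seed, package version) and serialises deterministically:
identical config and seed give byte-identical JSON.

## Synthetic tumbling experiments

The generator emulates the structure of a plate-count tumbling assay:
at each sampling time and replicate it draws a CFU count for the
tumbled series with mean `initial_cfu · S_true(t)` and for an untumbled
control series with mean `initial_cfu`. Poisson counting noise is the
declared plating-noise model (standard for CFU assays; the source
experiments' replicate structure and error model are not described, so
this is an assumption, not an inference). An expected-value mode
(noise "none") supports exact pipeline tests. Defaults: ground-truth
Weibull fitted to the three anchors (k ≈ 0.285, λ ≈ 134 s — synthetic,
never presented as experimental data), initial_cfu = 200, twenty
log-spaced sampling times on [10, 1000] s, three replicates.

Fitting from counts reduces each time point to the ratio of
replicate-summed tumbled counts to replicate-summed control counts
(cancelling plating-efficiency offsets), drops points outside (0, 1)
(extinct or super-control platings carry no log(−log S) information),
and weights the linearised regression by inverse delta-method
variances, var(log(−log S)) ≈ (1−S)/(N·S·(log S)²) — without the
weights the noisiest early points (S near 1) dominate. Under the
default conditions the generating (k, λ) are recovered within 10%
relative error; dilution series, plating volumes and detection limits
are not simulated, so passing tests say nothing about those effects in
real assays.

## Numerical conventions and degenerate inputs

- All parameter validation is strict-positive with finite checks;
  violations raise typed errors (`InvalidParameterError`,
  `BelowThresholdError`, `OutOfRangeError`, `FitError`,
  `ConfigurationError`), all subclasses of both `MarsaltError` and
  `ValueError`.
- Zero-hop rows report zero distances and a flagged, absent survival
  value (S is undefined at t = 0 for the interpolant).
- Weibull fitting requires ≥ 2 points with distinct times and fractions
  strictly inside (0, 1); a non-positive fitted slope (non-decaying
  data) is a fit error, not a curve.
- Scaling-law invariants are asserted at 10⁻¹² relative tolerance;
  anchor reproduction at 10⁻¹⁴.

## Known limitations

- Abrasion is the only kill mechanism; UV, desiccation and oxidants
  would lower survival further. The survival anchors derive from
  freshly crushed, sharp-edged basalt, while martian grains are likely
  rounded by long aeolian weathering — so the curve is a worst case
  for survival, and distances paired with it are conservative in that
  one direction only.
- The hop is characterized only by its length; no launch angle, drag
  or hop-length dispersion (each grain class has a single L).
- The rotation-to-hop equivalence is adopted, not derived.
- The three anchors are the only survival data; everything between
  them is the interpolation rule.
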