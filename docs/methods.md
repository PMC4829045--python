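# Methods

## Back-calculation

Carapace length at the time a growth mark was deposited is estimated
under the body proportional hypothesis (BPH). The population's mean
allometry between humerus diameter `D` (mm) and straightline carapace
length (SCL, cm) is

    f(D) = L_op + b (D − D_op)^c

with hatchling anchors `L_op = 5.1` cm and `D_op = 2.6` mm, slope
`b = 3.127` and proportionality coefficient `c = 0.928` (the published
fit for Hawaiian green turtles over 36.4–97.9 cm SCL). The BPH assumes
each individual sits a constant proportional distance from this curve
throughout life; anchoring at dead recovery (`D_final`, `L_final`)
gives

    L(D) = f(D) / f(D_final) × L_final .

The ratio is computed before multiplying by `L_final`, which makes the
identity `L(D_final) = L_final` bit-exact. Marks outside
`[D_op, D_final]` raise a domain error — the equation is never
extrapolated beyond the section edge. The analytic inverse
(`invert_length_to_diameter`) undoes the proportional anchoring and
inverts `f`; it is what realises printed SCLs as concrete diameters in
the bundled fixture and the simulator. Estimates are kept at full
precision internally and rounded half-away-from-zero to 0.1 cm (the
field reporting resolution) only at the reporting layer.

## Chronology

Double LAGs — two closely spaced lines laid down in one annual cycle —
are collapsed to their outer line before anything else; flags marking
doubles are inputs (expert reading), not detected from spacing.

Calendar years count back one per collapsed LAG from the outermost
mark. Whether the outermost LAG carries the stranding year or the
previous one follows the deposition season (spring: window closing
mid-May, nominal deposition day-of-year 91 ≈ 1 April, both
configurable):

* stranding before the nominal deposition date → previous year (that
  year's mark cannot have formed yet);
* stranding between the nominal date and the window end → stranding
  year if the final LAG sits at the bone edge (edge growth ≤ 0.05 mm,
  configurable), previous year if measurable growth separates them;
* stranding after the window closes → stranding year regardless of
  edge growth.

The nominal deposition date (1 April, the window midpoint) also
positions each LAG in time when selecting the mark nearest a tagging or
injection date; ties break toward the later LAG. When the year a
target date belongs to precedes the earliest surviving LAG, the mark
was lost to the resorption core and the caller falls back to the OTC
mark diameter. The 0.05 mm edge threshold and the 1 April nominal date
operationalise rules the source analysis states only qualitatively;
selection outcomes on the bundled fixture are insensitive to small
changes in either.

## Validation statistics

Paired differences (measured − estimated SCL) are rounded to 0.1 cm
*before* any statistic, matching how printed difference columns were
analysed. The paired Wilcoxon signed-rank test drops zero differences
(Wilcoxon's original rule — the alternative Pratt treatment would not
reproduce an effective `N` of 7 from 10 pairs on the bundled data),
ranks absolute differences with midranks for ties, and reports
`T = min(T+, T−)`. The two-sided p-value is exact: the null
distribution of the positive-rank sum over all `2^N` equiprobable sign
assignments of the observed midrank vector is built by subset-sum
convolution (identical to literal enumeration, which the tests verify
against for `N ≤ 10`), and `p = P(W ≤ T) + P(W ≥ S − T)` with
`S = N(N+1)/2`, capped at 1. Beyond `N = 25` a tie-corrected normal
approximation with continuity correction takes over. The reported
standard error is the `n−1` standard deviation of the absolute
differences over `√n`.

## OTC timing

An OTC injection time-stamps the bone. Back-calculated SCLs from the
OTC mark and from the calendar-matched LAG are compared at the 0.1 cm
reporting resolution: within 0.1 cm (configurable) they are
*coincident*; a smaller LAG SCL means the LAG predates the injection,
a larger one that it postdates it. The population window is bracketed
by the latest injection that preceded its LAG (deposition had not yet
happened then) and the latest injection coincident with its LAG
(deposition observed happening that late and not later). Injections
that postdate their LAG bound only that individual and are reported
per-turtle rather than folded into the window — individual variability
in deposition timing is surfaced, not averaged away. Bounds are
month/day positions in the annual cycle (ordered on a cycle anchored
opposite the deposition season); years are discarded because the
conclusion is seasonal. Note the coincidence class is sharp only for
animals still growing appreciably: a near-asymptotic adult adds little
bone over months, so its injection can classify as coincident with a
mark months away, widening the inferred window.

## Synthetic data

The simulator models growth on the bone axis: humerus diameter follows
`D(t) = D_op + (D_inf − D_op)(1 − e^{−kt})` and SCL is
`s · f(D(t))` with an individual lognormal proportionality factor `s`
(σ = 0.05). The BPH therefore holds exactly by construction, which is
deliberate: noise-free recovery failures can only come from pipeline
defects, not model mismatch. Defaults emulate the study conditions:
10 turtles, `k = 0.1`/yr, asymptotic SCL drawn from 75–100 cm (adult
sizes at maturation; observed sizes then span roughly the study's
44–86 cm), July–September hatching, stranding 1999–2004, one LAG per
calendar year at day-of-year ~ N(91, 10²), 10% double LAGs emitted
0.05–0.15 mm inside the annual mark, a linear resorption front
advancing 0.35 mm/yr from the core (a simulator convenience, not a
biological claim; it is capped so at least the outermost mark always
survives), OTC injection for 60% of turtles, and additive Gaussian
measurement error (0.3 cm on lengths, 0.05 mm on diameters). Tagging
coincides with a surviving LAG deposition event 1–9 years before
stranding, mirroring the design in which the mark nearest tagging is
what gets validated; observation noise is clamped (ε-margins) so
profiles never violate ordering invariants. A single integer seed
drives everything, with per-turtle counter-split streams so turtle `i`
is reproducible under a changed population size.

What the simulator does *not* model: within-year seasonal modulation of
growth, fibropapilloma growth suppression (the flag is carried only),
measurement-error correlation between observers, and any feedback of
condition on deposition timing. Passing recovery tests therefore show
the pipeline is correct under its own assumptions — not that the BPH
holds for real bones.

## Experiment configurations

The recovery experiments (tests, `analysis/02`, `scripts/acceptance.py`)
override defaults where the question demands it, and these choices are
part of the experiment design:

* *Noise-free exactness and year recovery* restrict stranding to
  day-of-year 150–365. Strandings in the few weeks right after
  deposition are where the edge-growth rule is genuinely ambiguous
  (bone laid down since the spring mark may or may not yet exceed the
  threshold); post-season strandings make year assignment exact, so
  any failure is a defect rather than an edge case of the rule.
* *Deposition-window recovery* uses 200 turtles, injections uniform
  over the at-large period, and deposition day-of-year variability 0.
  The window logic brackets a population-typical date; with individual
  spread the latest pre-deposition injection can postdate the mean, so
  synchronous deposition is the condition under which "window contains
  the true day" is the correct expectation.
* *Folded-normal propagation* uses σ = 0.5 cm SCL noise, diameters
  exact, old turtles (hatched 1975–85) tagged at their latest LAG, so
  the compared marks nearly coincide and the difference reduces to the
  gap of two independent N(0, σ) errors with mean
  `σ√2·√(2/π) ≈ 0.564` cm. The residual growth between mark and
  recovery keeps the realised ratio ~1–3% below 1; tests allow 8%,
  about three Monte-Carlo standard errors at n = 1000.
* *Exact-test calibration* draws N = 7 continuous symmetric nulls,
  10,000 replicates. The discrete null makes the largest achievable
  two-sided size 6/128 ≈ 0.047 at nominal 0.05 (and 0 at nominal
  0.01), so the observed rejection rate must sit at or below nominal.

Problem sizes (50/200/1000 turtles, 10⁴ replicates) keep every
experiment's Monte-Carlo error well below the effects being checked
while the whole suite runs in seconds.

## Degenerate inputs and numerical choices

All-zero difference vectors raise a degenerate-sample error from the
test but report a mean absolute difference of 0; the pipeline catches
the degenerate case (noise-free simulations produce it by design) and
reports `N = 0` with NaN statistics. Rounding is half-away-from-zero
with a 1e-9 epsilon absorbing binary representation of `.x5` values.
Elapsed time is day-count/365.25. The inverse back-calculation is
validated to 1e-9 cm round-trip across a property-tested grid.

## Known limitations

The bundled fixture realises bone diameters from printed SCLs because
no diameters were published; scaffold LAGs in years without printed
estimates are interpolated and carry no evidential weight. The
year-assignment rule inherits the source analysis's qualitative edge
threshold; real sections with partial marks or non-annual lines are
outside scope, as are histology, imaging and LAG detection itself —
inputs are already-measured diameters.
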