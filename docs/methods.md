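# Methods

## Scope and model structure

The package implements a one-compartment particokinetic model of the
alveolar region. Deposited poorly soluble particles are cleared by alveolar
macrophages (AM) with first-order kinetics; dissolution, where present,
acts as a parallel first-order pathway. Lymphatic/interstitial clearance is
deliberately neglected — the one-compartment simplification is conservative
(burdens at overload are over- rather than under-estimated) and avoids the
over-parameterisation of multi-compartment schemes. Inflammation biology
(BAL cytology, PMN influx) is outside the model: the package predicts
*kinetic* quantities — burdens, half-times, threshold concentrations — and
the transition to adversity enters only through the volumetric thresholds.

Unit conventions: volumes in µl (1 µl = 10⁹ µm³ = 1 mm³), densities in
g/cm³ ≡ mg/µl, concentrations in µl/m³ (volume basis) or mg/m³ (mass
basis), time in days. Display rounding is integers for µl/m² and µl/lung
anchors and two decimals for concentrations; full precision is kept
internally and in JSON output.

## Burden kinetics and clearance retardation

The daily update is operator splitting: on each exposure day the deposited
volume enters as a bolus, and the burden then decays by
`exp(−(ln2/t½(V) + k_diss))` per day, evaluated at the current burden's
half-time. Sub-daily resolution is unnecessary because exposure is 6 h/day
and all relevant half-times are tens to hundreds of days; with a fixed
half-time the scheme is *exact* for the post-exposure phase (it is the
analytic exponential sampled daily), and with retardation active the
splitting error is O(Δt) in the slowly varying rate.

The recorded burden for day *n* is the value immediately after that day's
deposition. This sampling convention makes the constant-dosing recursion
`V_n = q·V_{n−1} + d` (q = exp(−ln2/t½)) converge to the geometric-series
steady state `d/(1−q)`, which is the closed form the simulator is verified
against; sampling before the bolus would give the trough `q·d/(1−q)`
instead, about 1% lower at t½ = 80 d. Exposure days are the first
`days_per_week` consecutive days of each week (default 5), matching the
standard repeated-dose regimen.

Retardation modes for t½(V):

* **none** — constant t½ (infinity allowed, expressing absent clearance;
  used to verify deposition conservation).
* **linear** — straight-line interpolation between the anchors
  (1 µl, 80 d) and (10 µl, 365 d).
* **loglinear** (default) — log t½ linear in log V between the same
  anchors: `t½(V) = 80·(365/80)^log₁₀(V)`. Chosen as default because it is
  smooth, monotone, and respects both anchors; the true retardation curve
  is an empirical calibration whose analytic form is not published.
* **custom** — piecewise-linear over user anchors.

Below the adaptive anchor the half-time is the constant baseline; above
the exhaustion anchor the terminal slope is continued. The exhaustion
anchor defaults to 365 d ("one year"); 400 d, also quoted in the
literature for chronic studies, is selectable via `t_half_mtd`.

Known deviation: the literature's predicted 4-week half-time triple
(92/148/292 d for end burdens of 1/√10·…/10 µl) comes from that
unpublished calibration; neither provided mode reproduces it (the
loglinear default predicts 80/171/365 d). The triple is carried in
`particokinetics.reference` as a read-only reference with this deviation
documented, never as a model output or test assertion. The same applies to
the chronic MTD concentration (0.26 µl/m³ reported vs 0.57 µl/m³ from the
static threshold formalism) and the ~17-fold chronic burden
disproportionality, of which the simulator reproduces the qualitative
superlinearity only.

## Half-time estimation

`estimate_elimination_half_time` fits ln(burden) against day by unweighted
least squares over the post-exposure observations and returns
t½ = ln2/|slope| with a delta-method standard error. Unweighted log-linear
regression matches how first-order fits are conventionally reported for
such data and is robust at the 3–5 sampling days real studies use. The
estimator warns when the observation window is shorter than one estimated
half-time. Classification bands for the fitted half-time: < 60 d
dissolution-dominated, 60–90 d normal AM-mediated clearance, > 90 d
overload onset, ≥ 365 d exhausted clearance.

## Thresholds and the accumulation factor

The threshold set pins the volumetric overload constants: 4.2/42 µl per kg
body weight, 1/10 µl per lung, 60/600 µm³ per macrophage, tied by the
6% → 60% pool-fraction ratio (validated at construction). The 4.2 µl/kg
constant itself is a pinned input, not re-derived from macrophage counts.
Per-kg and per-lung scales are both kept explicit: 4.2 µl/kg over ~4.5 g
lung/kg is ≈ 0.93, *rounded to ~1 µl/lung* in the formalism — the package
exposes the full-precision conversion (`per_lung_from_per_kg`) alongside
the pinned per-lung constants so the lumping is visible rather than silent.

`f_v(x) = −0.08 + 60.6·(1 − exp(−0.083 x))` is interpreted with **x in
weeks**: this reproduces both the printed chronic NOAEL concentration
(1/(0.29·f_v(104)) = 0.057 → 0.06 µl/m³) and the 4-week MTD concentration
(10/(0.29·f_v(4)) = 2.02 ≈ the rounded 2.2 µl/m³ study pick); a day-based
reading reproduces neither. f_v lumps deposition efficiency, body-weight to
lung normalisation and the 5/7 intermittency of the standard regimen, so no
separate deposition fraction is applied in this formalism — the "dose" it
multiplies is the nominal inhaled respirable volume per kg and exposure
day. The slightly negative fitted intercept is clamped to zero and the
relationship treated as valid for durations of one week and longer
(`DurationTooShortError` below that).

A documented internal inconsistency of the source constants: at unit
density, 70–700 µm³/cell is 0.07–0.7×10⁹ µm³ per 10⁶ cells, which is
70–700 µg per 10⁶ cells, not the 7–70 µg sometimes quoted alongside; the
package computes 70–700 µg.

## Dissolution

The Nernst–Brunner equation is evaluated literally in (mg, L, m, day)
units; the 1/V_m factor in the printed form makes the prefactor a lumped
first-order coefficient rather than a strict dimensional flux, which is how
the relationship is applied to half-time reasoning. Geometry laws:
`constant_area` holds the *specific* transfer area (area per unit solid
mass) constant, S_A ∝ m, giving first-order kinetics and a well-defined
dissolution half-time — the form everything else in the package consumes;
`shrinking_sphere` uses S_A ∝ m^(2/3), giving the cube-root law under sink
conditions. Closed systems compute the dissolved concentration from the
solid mass balance, so total mass is conserved by construction.
Supersaturation (C > C_s) is reported via a warning, never integrated as
precipitation. Polydispersity is representable as a list of independent
systems summed; pH-dependent speciation, complexation and
interfacial-barrier effects are out of scope.

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-10, with an
RK45 retry; failures raise). Half-times are located by a terminal event at
m = m₀/2. No example in the source literature states D, h or V_m; test
fixtures use order-of-magnitude placeholder values chosen for exact hand
verification (powers of ten).

## Study design

The designed study brackets the overload range after `x` weeks: the low
concentration attains the adaptive burden (1 µl/lung), the high the
exhausted burden (10 µl/lung) — their ratio is exactly the pool-fraction
ratio 10 — and the mid concentration is their geometric mean, a scale-free
rule that lands within ~15% of the conventional rounded picks (0.75 µl/m³
for the 4-week design). The post-exposure window is the first day the
simulated mid-dose burden decays back to the adaptive threshold, floored at
90 days (the minimum needed to resolve normal-band half-times) and capped
at two years; the high-dose burden is verified to remain above the
threshold at that window ("no reversibility at the high dose"). Verdicts
on observed kinetics use ±30% agreement with the predicted half-time — the
qualitative source rules made quantitative; the tolerance is a named
parameter.

## OEL derivation

The rat→human chain is an explicit multiplicative ledger; every factor
carries a provenance note and is echoed in reports. The pinned preset is
7 (human overload resistance, consistent with the patrol-area ratio
140,000/22,000 ≈ 6.4 and pool-volume comparisons) × 1.353 — a **calibrated
constant**: the residual dosimetric normalisation is not recoverable from
the threshold formalism alone, so it is pinned such that the preset chain
maps the chronic rat NOAEL (0.057 µl/m³) onto the generic volumetric OEL
of 0.54 µl/m³, and it is labelled "calibrated, not mechanistically
derived" in all outputs. Expert-committee comparators (MAK 0.3×ρ,
TRGS 900 0.5×ρ) are read-only reporting constants. No regional-deposition
(HEC/RDDR) modelling is performed.

## Synthetic data

The fixture generator emulates post-exposure lung-burden sampling: a
first-order decay trajectory observed with multiplicative lognormal noise,
`observed = B₀·2^(−t/t½)·exp(ε)`, ε ~ N(0, σ_log²), σ_log defaulting to
0.15 (proportional assay CVs on positive burdens). The default design for
estimator-recovery experiments is 4 sampling days (7/28/56/90) × 5 animals,
mirroring the group sizes and sparse schedules of real repeated-dose
studies; 500-replicate recovery runs take seconds. Stochastic generation
without an explicit seed is refused. What the generator does **not**
emulate: inter-animal variability in the true half-time, deviations from
first-order decay (biphasic clearance, ongoing dissolution), censoring at
analytical detection limits, or day-0 dosimetry error — so passing recovery
tests demonstrate estimator correctness on the model's own terms, not
robustness to real-world model misspecification.

## Limitations

* Static threshold arithmetic (f_v) and the dynamic retardation simulator
  are two views of the same accumulation process and agree only
  approximately; the package keeps them separate and never calibrates one
  to the other.
* The retardation curve between the anchors is a modelling choice, not an
  identified function; predictions between 1 and 10 µl/lung inherit that
  uncertainty.
* Respirable fraction and deposition efficiency are user inputs or lumped
  constants; no aerosol-size-to-deposition modelling is included.
* Human dosimetry is represented only as far as the species-comparison
  constants require; the human preset cannot drive a burden simulation.
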