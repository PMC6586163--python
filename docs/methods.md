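# Methods

## The composite transport model and its forward solution

The root segment mounted on a pressure probe is treated as a single
effective osmometer: one pressurised compartment (the functional xylem,
volume Vx) exchanging water across the root cylinder surface Ar and coupled
to the probe through the elastic coefficient β (MPa m⁻³).  Two rate
constants govern everything:

* water exchange: kwr = Lpr·Ar·β = ln 2 / t½w,
* solute permeation: ksr = Ar·Psr/Vx = ln 2 / t½s.

For a hydrostatic step the pressure relaxes as P(t) = P_ss + ΔP₀·e^(−kwr·t).
For an osmotic step Δπ°s the linear two-compartment system (pressure–volume
coupling through β; the effective external osmotic push decaying at ksr as
the solute equilibrates) integrates in closed form to

P(t) = P₀ − σ·Δπ°s·kwr/(kwr−ksr)·(e^(−ksr·t) − e^(−kwr·t)),

with the removable singularity at ksr = kwr handled by the analytic limit
−σ·Δπ°s·kwr·t·e^(−kwr·t), not by an epsilon perturbation.  The trace has a
single interior minimum at tmin = ln(kwr/ksr)/(kwr−ksr) and the identity
(ΔPr/Δπ°s)·e^(ksr·tmin) = σ is exact under this model; the test suite
asserts it to 1 × 10⁻¹⁰ and cross-checks the closed form against an
independent ODE integration to < 0.1 % of the response amplitude.

Model assumptions worth keeping in mind: a single effective Lpr (no
decomposition into parallel apoplastic and cell-to-cell conductances — the
hydrostatic/osmotic Lpr ratio is the observable used for pathway inference),
no unstirred-layer correction (the experiment minimises it by stirring), no
active solute pumping, no growth during the measurement, full pressure
recovery after a permeating-solute step.  The simulator drives the water
phase of the osmotic response with the same kwr as hydrostatic relaxations;
a separate osmotic Lpr can be emulated by overriding the parameter set,
since measured hydrostatic and osmotic conductivities need not coincide.

Exosmotic sign convention: an osmotic step *lowers* root pressure and ΔPr is
reported as a positive depression magnitude.

## Inverse analysis

β is the least-squares slope through the origin of ΔP against ΔV over the
calibration steps.  Exponential phases are fitted as P∞ + A·e^(−kt) by
Levenberg–Marquardt, seeded from a log-linear regression of ln|P − P̂∞|
(tail-mean asymptote seed).  For biphasic traces:

* tmin is the argmin of the trace after centred moving-average smoothing
  (default window 5 samples; configurable).  Smoothing controls noise
  dimples; at the parameter scales used here its bias on ΔPr is ≪ 0.1 %.
* ΔPr is measured from the pre-step pressure P(0) (not extrapolated).
* the water phase is fitted on [0, tmin] with a free asymptote,
* the solute phase is fitted with the asymptote pinned to P(0) (the model
  recovers fully).  The fit window starts three water-phase time constants
  after tmin rather than at tmin itself: at the minimum the residual
  water-phase transient is still ksr/kwr of the signal (up to several
  per cent when the phases are poorly separated) and would bias ksr upward;
  after 3/kwr it has decayed by e⁻³.  The onset is configurable
  (`solute_onset_efolds`, 0 restores a fit from tmin) and falls back to
  tmin when the trace is too short to spare the delay.

σsr then follows from the measured (ΔPr, tmin) and the fitted ksr.  Because
the correction factor e^(ksr·tmin) is near 1 (≈ 1.04 at control values), σ
is insensitive to moderate error in ksr.  Monotone traces raise a
"no minimum" error and are treated as the impermeant-solute case.

QC follows the cut test: pass only if post-cut pressure falls below 10 % of
the pre-cut steady pressure *and* the post-cut half-time is at least 10×
shorter than pre-cut; both thresholds are parameters, the defaults encoding
"drops to zero" and "about one order of magnitude faster".

Noise-free forward–inverse round trips recover (Lpr, Psr, σ) to < 1 % over
a 3 × 2 × 3 parameter grid (discretisation only).  With Gaussian sensor
noise of sd 0.002 MPa, median relative errors over 200 replicates are < 5 %
for Lpr and < 10 % for Psr and σ (asserted in the suite at exactly those
sizes).

## Osmoticum

PEG-8000 water potential uses the empirical Michel calibration
ψ[bar] = 1.29c²T − 140c² − 4.0c with c the **w/w fraction of total
solution** and T in °C.  This concentration convention is deliberate: it is
the one under which 17.5/25.4/31.6 % map to the nominal −0.4/−0.8/−1.2 MPa
at 23 °C (computed: −0.408, −0.813, −1.228); interpreting c as g PEG per g
water instead gives −0.58 MPa for the first solution and does not reproduce
the series.  Valid range 0–0.45 w/w and 5–40 °C; the inverse lookup
bisects the strictly monotone curve.  The default temperature is 23 °C (the
daytime growth temperature).  Osmotic pressure is ideal van't Hoff,
π = R·T·Cs with 1 mOsmol kg⁻¹ ≙ 1 mol m⁻³; for half-strength Hoagland
(20 mOsmol kg⁻¹) this gives 0.049 MPa — slightly above the rounded 0.04 MPa
sometimes quoted for that medium; the computed value is reported as is.
Non-ideal osmotic coefficients and matric potential are out of scope.
Potentials are signed negative (MPa), pressures positive (MPa), never mixed.

## Suberin chemistry

Monomer labels are parsed by a small registry grammar
(`C<len>[:<unsat>] <class>` plus named aromatics); classes are the four
aliphatics (alcohols, fatty acids, diacids, ω-OH acids, chain lengths
C16–C26) and the two aromatics (coumaric, ferulic).  Odd chain lengths warn
but are accepted.  Zones are half-open relative-length intervals (chemistry:
A [0, 0.25), B [0.25, 0.50), C [0.50, 1]; narrower windows for RNA-seq
sampling); a segment is assigned by its midpoint.  Amounts are normalised to
the endodermal cylinder area A = 2π·r·L; the endodermis radius is a
per-experiment configuration scalar (synthetic default 200 μm) since it is
not tabulated in print, so absolute μg cm⁻² levels are emulated rather than
reproduced.  Replicate summaries report mean ± SD at n = 3.  Aromatic
totals carry an "interpret cautiously" flag: in grasses, wall-bound
hydroxycinnamates are not suberin-specific.

## Statistics

One-way ANOVA uses the pooled within-group MSE; Fisher-LSD pairwise t-tests
share that MSE and its df.  Letters come from the insert-absorb compact
letter display, issued in ascending-mean order from "a"; the suite checks
letter/significance agreement exhaustively against a brute-force pairwise
oracle for up to six groups.  The LSD is protected by default (pairwise
differences only declared when the omnibus F rejects at α) — the classical
convention, flagged in the result object; the unprotected mode and an
optional Holm correction are switches.  Shapiro–Wilk normality p-values are
reported per group but never gate the analysis.  The two-sample t-test is
pooled-variance, two-sided; two constant identical samples give p = 1 by
convention.  TPM is the standard length-normalised within-sample unit,
TPM_i = 10⁶(c_i/l_i)/Σ_j(c_j/l_j), which sums to 10⁶ by construction.

## Synthetic data: what it emulates, and what it does not

The trace generator draws per-root (Lpr, Psr, σ) from group means ± SD
(defaults: control 8.11 ± 2.37 × 10⁻⁸ m s⁻¹ MPa⁻¹, 2.24 ± 1.54 × 10⁻⁹
m s⁻¹, 0.38 ± 0.06; stress 3.19 ± 1.45, 0.61 ± 0.61, 0.38 ± 0.17; n = 8 per
group), truncated to physical ranges by resampling so no probability mass
piles on the bounds — note truncation shifts the realised group means of
strongly dispersed parameters (Psr under control) upward relative to the
nominal mean.  Probe/geometry defaults (β = 1.09 × 10¹⁰ MPa m⁻³,
Ar = 1.57 × 10⁻⁴ m², conductive length 0.10 m, diameter 0.5 mm, xylem
fraction 1.5 % → Vx = 2.945 × 10⁻¹⁰ m³) are chosen to give t½w ≈ 5 s and
t½s ≈ 10 min, the magnitudes such roots show; raw traces, P₀, β and Ar are
not published, so these are simulator choices.  Sensor noise is Gaussian
(sd 0.002 MPa); chemistry noise is lognormal (mean 1, CV 0.15) as befits
strictly positive amounts, applied at the class level within a replicate.

The suberin generator encodes per-area aliphatic totals of 0.6/1.5/3.3
μg cm⁻² in zones A/B/C (control) with zone-wise class shares
(A: fa 33 %, alc 9 %, diacid 9 %, ω-OH 49 %; C: 12/4/18/66 %), which yields
≈ 2-fold basipetal increases for alcohols/fatty acids and ≈ 10-fold for
diacids/ω-OH acids; stress ≥ 0.8 MPa doubles zone B, any stress doubles
zone C (peak ≈ 7 μg cm⁻² aliphatic); aromatic totals are twice the zone's
control aliphatic total and treatment-independent.

What passing tests therefore show: the estimators are unbiased and precise
*under the generating model* — single-exponential kinetics, Gaussian sensor
noise, lognormal replicate scatter, exact zone assignment.  They do not
show robustness to electrode drift, temperature transients, partially
blocked xylem, growth during measurement, GC integration error, or zone
mis-cutting: real data add systematic components the generator deliberately
omits.

## Numerical choices and problem sizes

Defaults throughout: hydrostatic traces 60 s at dt = 0.05 s; osmotic traces
3000 s at dt = 0.1 s; curve fits seeded as above with a 20 000-evaluation
cap; bisection tolerance 10⁻¹⁰ w/w.  The simulation studies in the suite use
200 noise replicates for the recovery medians, 100 seeded cohorts for the
letter-detection rate, and a 16-root cohort in the pipeline demo — sizes
chosen to estimate medians and rates stably while keeping the whole suite
around ten seconds.  Degenerate inputs are signalled, not silently patched:
constant traces, monotone "biphasic" traces, all-zero counts and all-zero
composition groups raise typed errors.

## Known limitations

Single effective-osmometer abstraction (no radial composite decomposition,
no axial conductance); ideal osmolality only; the compact letter display is
exact but not minimal in pathological significance patterns (letters remain
sound: sharing ⇔ non-significance); absolute suberin levels depend on the
configured endodermis radius and zone lengths; TPM is a within-sample unit
and the package deliberately stops short of differential-expression
modelling.
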