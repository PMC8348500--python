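# Methods

## The cell-covered electrode model

The measured quantity is the complex specific impedance Z(f) (Ω·cm²) of a
gold film microelectrode, with and without a confluent cell layer. The
package works throughout in specific impedance; whole-well ohms are obtained
by dividing by the electrode area (`ElectrodeModel.electrode_area`, cm² — a
required property of the array in use, with no hidden default).

**Naked electrode.** The cell-free electrode is modelled as a constant-phase
element in series with a solution/spreading resistance,
`Zn = R_solution + 1/(Q_cpe (iω)^n_cpe)`, the standard description of the
gold/electrolyte double layer. The packaged default
(`DEFAULT_ELECTRODE`: R_solution = 3 Ω·cm², Q_cpe = 5·10⁻⁶ Ω⁻¹·cm⁻²·sⁿ,
n_cpe = 0.95, area = 0.02 cm²) was chosen once so that, together with the
baseline monolayer below, the model reproduces the canonical ECIS readout
choices (see *Frequency selection*).

**Cell layer.** The transcellular path crosses two membranes of equal
specific capacitance Cm in series and no membrane conductance:
`Zm = 2/(iωCm)`. The covered-electrode impedance follows the Giaever–Keese
relation

    1/Zc = (1/Zn) [ Zn/(Zn+Zm) + (Zm/(Zn+Zm)) /
                    ( (s/2)·I0(s)/I1(s) + Rb·(1/Zn + 1/Zm) ) ],
    s = α √(1/Zn + 1/Zm)   (principal branch),

where I0, I1 are modified Bessel functions of the first kind evaluated at
complex argument. At s = 0 the term (s/2)·I0/I1 is taken at its limit, 1;
for |s| > 30 the ratio I0/I1 is replaced by its asymptotic form 1 + 1/(2s)
to avoid overflow. With Rb = α = 0 the relation reduces exactly to Zn, and
for f → ∞ (Zm → 0) Zc → Zn; both identities are asserted in the tests. The
onset of the high-frequency collapse scales as f ~ 1/(2π|Zn|Cm): for the
baseline Cm = 1 µF/cm² it lies just beyond the 64 kHz end of the
acquisition grid, so the grid-tail convergence test uses Cm = 8 µF/cm²,
where the roll-off happens inside the grid.

**Series readouts.** Instrument-style resistance and capacitance are the
series-RC interpretation of the whole-well impedance: R = Re Z and
C = −1/(2πf·Im Z) (reported in nF). A non-capacitive impedance
(Im Z ≥ 0) has no defined series capacitance and is returned as NaN.

## Inversion

`fit_barrier_parameters` minimises the relative-weighted residual
Σ_f |Zc(model) − Z(meas)|² / |Z(meas)|² over Rb ≥ 0, α ≥ 0, Cm > 0 with
`scipy.optimize.least_squares` (trust-region reflective, tolerances 1e-14).
The 1/|Z|² weighting makes the 250 Hz and 64 kHz points contribute
comparably. Starts: the caller-supplied warm start (the previous time point
in trajectory fitting), then a default (5, 5, 2), then a 3×3×3 log-spaced
grid; the search stops early once the residual falls below `good_enough`
(default 1e-16, i.e. effectively only for noise-free data) and otherwise
keeps the best of all starts. Non-convergence is reported in the result,
never raised.

**Rb-zero masking.** When the fitted Rb falls below ε_Rb = 10⁻³ Ω·cm² the
result reports Rb = 0 with α and Cm flagged *not calculable*: with the
paracellular path fully open the model cannot attribute the remaining
impedance between the substrate and membrane paths. Downstream, masked
values are propagated as missing — never imputed — and a trace's AUC is
integrated only up to its last calculable sample, with the effective
interval reported alongside the value.

**Identifiability.** The three parameters are not equally well determined
in all regimes. A Fisher-information analysis of the weighted residual
shows that α carries almost no impedance signature when Rb is large and α
small (the Rb·(1/Zn+1/Zm) term dominates the denominator), and conversely
Rb is weakly determined when α is large; at 1% multiplicative noise on a
9-frequency spectrum the implied relative standard errors in such corners
exceed 100%. Noise-free spectra are recovered to better than 0.1%
everywhere; noisy single-spectrum fits should be trusted only where the
parameters are of comparable influence (the physiological regime of the
packaged presets is), and trajectory fits gain robustness from
warm-starting.

## Frequency selection and confluence

`frequency_of_max_contrast` picks, over the acquisition grid, the frequency
maximising either the covered/naked series-resistance ratio or the relative
series-capacitance drop. For the packaged electrode and baseline monolayer
(Rb = 4 Ω·cm², α = 8 Ω·cm^½, Cm = 1 µF/cm²) these argmaxes are 4000 Hz and
64,000 Hz — the conventional ECIS readout frequencies — and this is a
deliberate packaged-data contract, asserted in tests. Confluence is
declared at the first sample whose whole-well 64 kHz capacitance drops
below 20 nF (the instrument convention; with the 0.02 cm² default electrode
the naked well reads ≈ 53 nF and the confluent monolayer ≈ 11 nF).

## The analysis chain

Traces are normalized by their value at the last sample at or before the
treatment time (inclusive at T = 0); that sample maps to exactly 1.
Outcomes per well and channel are the endpoint value (nearest sample to
100 h), the midpoint value (nearest sample to 24 h; exact on grids dividing
24), and the trapezoidal AUC over 0–100 h (trapezoid was chosen over
rectangular summation; on the uniform grids used the difference is
negligible for smooth traces and trapezoid is exact for the piecewise-linear
preset trajectories). Group summaries are mean ± SD over replicate wells
(n ≥ 2 required for an SD). Fitted Rb/α/Cm trajectories are normalized by
their own fitted value at T = 0.

Comparisons follow the study conventions: two groups — unpaired two-tailed
t-test with pooled variance (the era-typical software default; Welch is
deliberately not used); three or more — one-way ANOVA with Tukey's HSD
post-test (studentized-range adjusted p per pair, pooled within-group
variance). Stars map p inclusively: * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001,
**** ≤ 0.0001, else ns. Note that a Tukey-adjusted p is guaranteed to be at
least the unadjusted pairwise p *on the same pooled variance* (df = N − k);
it can occasionally undercut a two-sample pooled t that uses only the
pair's own variance. LDH cytotoxicity is the 490 nm absorbance minus the
680 nm instrument background, per well.

## The synthetic-experiment generator

The generator drives the forward model along documented ground-truth
(Rb, α, Cm) trajectories and emulates the acquisition protocol: the
9-frequency grid, 180-s sampling, a 94 h seeding-to-treatment window, a
100 h post-treatment window and 5–6 replicate wells per group. Trajectories
are piecewise linear between documented breakpoints — the simplest form
reproducing the published features. The absolute baseline
(Rb = 4 Ω·cm², α = 8 Ω·cm^½, Cm = 1 µF/cm²) is a package assumption in the
conventional epithelial range; the emulated study reports only normalized
quantities, so only relative trajectories are anchored.

Scenario highlights (all relative to that baseline):

* **fccp_10** — Rb falls linearly to 0 at 5.1 h and stays there (so fitted
  α/Cm terminate at 5.1 h); α falls steeply; Cm rises.
* **fccp_1** — Rb reaches 0 near 10 h, rebounds over hours 15–25, returns
  to 0 by 100 h; milder α and Cm changes than the high dose.
* **oligo_1 / oligo_10** — predominantly an α (substrate-attachment)
  effect, dose-ordered; Rb unchanged at low dose, moderately reduced at
  high dose. The oligo_10 64 kHz *measured* capacitance follows a
  triangular excursion peaking at 1.2× baseline at 50 h and returning to
  baseline at 100 h — exactly +10% on the 0–100 h AUC of the normalized
  curve. Because that statement lives on the measured quantity, the Cm
  trajectory is obtained by inverting the forward model per time point
  (scalar root find, increasing branch above the capacitance–Cm minimum),
  given the preset's Rb(t) and α(t); the implied Cm dips below baseline at
  the endpoint, compensating the residual barrier effect.
* **rot_2 / rot_20** — dose-dependent Rb loss, a common (non-dose-ordered)
  α loss, dose-ordered Cm rise.

With noise disabled, the 4 kHz resistance AUCs order as
control > low dose > high dose within each drug, and across drugs the
damage orders FCCP > rotenone > oligomycin.

**Spreading.** Before treatment, electrode coverage grows logistically
(rate 0.12 h⁻¹, midpoint 30 h after seeding) and the well impedance is the
area-weighted parallel combination of covered and naked patches — the
standard partial-coverage extension, confined to the generator since the
inversion model assumes confluence. Coverage is exactly 1 from T = 0 on.
The 64 kHz capacitance therefore falls monotonically and crosses 20 nF
well before treatment.

**Noise.** Multiplicative log-normal noise (σ = 1% default) on the complex
impedance, with AR(1) temporal correlation (φ = 0.9) mimicking micromotion;
a single factor scales Re and Im together. The emulated study reports only
mean ± SD bars, so the noise law is a package decision. Identical seeds
give bit-identical tables.

**LDH schedules.** Viability fold-changes versus control encode the release
pattern: at 24 h only rotenone 20 µM is elevated; at 48 h and 72 h the
three high doses are; low doses never are. Absorbances are
A490 = background + 0.25·fold + N(0, 0.008) and A680 = background +
N(0, 0.002) with background 0.05, chosen so the corrected control signal
is ≈ 0.25 and group differences are unambiguous at n = 6.

## What the synthetic data does and does not show

The generator reproduces the *structure* of real ECIS experiments —
multi-frequency acquisition, spreading, normalization anchors, masked
α/Cm segments, dose orderings, LDH timing — so a green pipeline test means
the analysis chain implements those conventions correctly. It does not
model drug pharmacokinetics, micromotion beyond AR(1) noise, well-to-well
baseline heterogeneity, or absolute ohm values of any real cell line;
passing tests therefore say nothing about ARPE-19 biology beyond what the
presets encode.

## Problem sizes and numerical choices

Tests and the acceptance script run the full 0–100 h window at 0.5 h
sampling for AUC-level quantities (trapezoid on piecewise-linear
trajectories is exact, so coarser sampling does not move them) and at the
native 180-s sampling over 0–10 h for the collapse-time recovery, where
resolution is the point. Ties in `detect_confluence` are strict
(capacitance must be *below* threshold); the normalization baseline is
inclusive at T = 0; midpoint/endpoint use nearest-sample lookup. All
randomness flows from a single integer seed per run.
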