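# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the
numerical choices a maintainer would otherwise have to reverse-engineer.

## Quantification model

A processed 1D ¹³C spectrum is reduced to a *carbon biomass density*
`ρ = A/(m·NS)` where `A` is a trapezoidal integral on the native ppm grid,
`m` the packed sample mass (mg) and `NS` the number of scans. `ρ` is
proportional to the carbon weight fraction, so only ratios of `ρ` are
meaningful across samples; time courses are therefore reported relative to
a reference day (day 2, the biomass maximum, = 1.0 by default, overridable).

Component windows are half-open `[low, high)` intervals so adjacent windows
never double-count: carbohydrates 74–105 ppm; proteins 10–29, 34–48,
106–124 and 132–160 ppm. The protein windows deliberately exclude the
29–34 and 124–132 ppm gaps where acyl-chain CH₂ and olefinic lipid carbons
sit; exclusion is purely by window choice — no peak deconvolution — so
Lorentzian tails of strong lipid signals still leak a few percent into the
protein windows (quantified below). Integration interpolates the window
endpoints, which makes integrals over adjacent windows add exactly
(machine precision) and independent of axis storage direction. No baseline
correction is applied by default (synthetic spectra are baseline-free); a
linear-endpoint baseline can be added upstream for instrument data.

The mobile fraction of a window is `ρ(DP, 2 s recycle)/ρ(DP, quantitative)`.
Values outside [0, 1] can arise from noise and are clamped with a warning
rather than silently — the warning ends up in the run report. Peak tracking
(e.g. glycerol consumption at 65.187/72.775 ppm) uses peak height within a
window by default, with an integral option; heights are robust to small
shifts of neighboring lines, and for a fixed lineshape the two are
proportional.

2D peak volumes are grouped into seven source categories
(bacteria-related, exopolysaccharides, proteins, nucleotides, N-acetyl,
lipids/biosurfactants, unknown; unmapped peaks fall into "unknown").
Absolute quantities are normalized to proteins on day 2 = 100; per-day
relative proportions sum to 100%.

## Degradation kinetics

For first-order degradation `d[S]/dt = −k[S]`, the degraded quantity over
an interval, `D = C₀(1 − e^(−kt))·V`, equals `⟨[S]⟩·k·t·V` with `⟨[S]⟩`
the time-averaged concentration — consumption is proportional to the local
substrate concentration. `⟨[S]⟩ = C₀(1 − e^(−kt))/(kt)` switches to the
series `C₀(1 − kt/2 + (kt)²/6)` below `kt = 1e−8` to avoid cancellation
(the switchover is continuous to < 1e−9 relative).

Assuming the same volume and total biomass on two consecutive intervals,
the compositional percentages of the degraded matrix satisfy a linear
4-equation system whose closed form is `p₂ = 100(1 − r_c)/(r_p − r_c)`
with `r_p`, `r_c` the protein and carbohydrate degraded-quantity ratios.
The solver is ratio-based, hence scale-invariant separately in each
component pair; the absolute units of the inputs never matter. A singular
system (`r_p = r_c` within 1e−12) and solutions outside [0, 100]% raise
errors with the raw values — clamping would fabricate a composition when
the equal-volume/equal-biomass assumption is violated. Percentages are
carried on the 0–100 scale. Estimating `k` or `C₀` from time series is out
of scope (nothing downstream needs them).

## Relaxation and dipolar dynamics

**T1.** Inversion-recovery series are fitted with the three-parameter model
`I(t) = A + B·e^(−t/T1)` (B < 0), robust to imperfect inversion, via
bounded Levenberg–Marquardt least squares with data-driven initial values
(plateau, inverted amplitude, 63%-recovery crossing). Constant series and
fits that hit the T1 search bound (default 100 s) raise errors instead of
returning garbage. At the noiseless limit the estimator is exact to the
optimizer tolerance (≥ 6 significant digits in the round-trip tests). At
2% Gaussian noise on the unit-normalized plateau with 12 delays the median
relative error is ≈ 1.6% (Monte-Carlo, 200 replicates); note the
Cramér–Rao bound for this design is ≈ 2.3% relative sd, so materially
better precision at this noise level is impossible for any fitting method.

**DIPSHIFT.** Under MAS at rotor frequency `f_r`, a C–H pair in a
crystallite with orientation (β, γ) contributes the time-modulated dipolar
frequency

    ν(t) = (δ/2)[√2·sin2β·cos(γ + ω_r t) − sin²β·cos(2γ + 2ω_r t)],

with `δ` the FSLG-scaled effective coupling (theoretical scaling 1/√3 ≈
0.577, configurable — instruments calibrate slightly different values).
The dephasing curve is the powder average of `cos Φ(t₁)` with
`Φ(t₁) = 2π∫₀^t₁ ν dt` taken in closed form (verified against numerical
quadrature of ν). CH₂ groups are the powder average of the product of the
two C–H cosine factors with tetrahedral (109.47°) inter-vector geometry;
cross-correlation between the two couplings is neglected
(independent-coupling product model). The phase integral vanishes at
integer rotor periods — the rotor echo — and the curve is symmetric about
the half rotor period; both are enforced as tests.

Powder averaging uses a sinβ-weighted angular grid: 5° steps over (β, γ)
for CH, and 10° steps over the three Euler angles for CH₂ — the coarser
CH₂ grid agrees with a 5° grid to ≤ 3.3e−4 absolute up to the rigid-limit
coupling at an eighth of the cost, and with a 2° CH grid to ≤ 1e−3.

Order parameters are fitted by simulation: a coarse scan plus bounded
scalar refinement of the effective coupling over `[0, 1.2·δ_rigid]`
(deliberately beyond the rigid limit so pathological fits surface; the
final `S = δ_eff/δ_rigid` is clamped to [0, 1] with a warning).
Defaults: rigid-limit one-bond coupling δ_rigid = 22.7 kHz (r_CH ≈ 1.1 Å);
MAS rate 7 kHz — slow spinning deepens the dephasing and hence the
coupling sensitivity, a standard choice for non-constant-time DIPSHIFT,
taken here as an explicit assumption since it is acquisition metadata the
user should override; 16 evolution-time points over one rotor period.
Noiseless round trips recover S to ≤ 2e−5; with noise at 2% of a curve's
dynamic range single-draw recovery is within ±0.03 across S ∈ [0.1, 1].
(For very mobile sites the information content collapses: at S ≈ 0.1 the
CH curve modulation depth is ~0.006, so noise specified as an absolute
fraction of the *full* intensity scale would make S unrecoverable there —
a physical sensitivity limit of slow-MAS DIPSHIFT, not an estimator
defect.)

## Sugar partition clustering

Each monosaccharide is summarized by its biofilm/medium integral ratio per
day, days 2–5 by default (day 1 is excluded because the default scenario —
like real spent-medium data — has a missing medium value there). Sugars
with any missing ratio are dropped with a logged reason, never imputed: a
sugar undetected in the medium (e.g. GlcN) has no defined partition ratio,
and a zero medium integral is an error naming the cell. Features are
z-scored with the population (divide-by-n) standard deviation — the
StandardScaler convention — then projected onto 2 principal components
(full SVD, deterministic sign: each component's largest-magnitude loading
is positive), then clustered with K-means (50 restarts, seed 0 default).
k is chosen by maximizing the silhouette score over k = 2–6; a `force_k`
override exists because cluster count is often fixed by prior knowledge
(e.g. peptidoglycan sugars forming their own class). Silhouettes that are
undefined for a candidate k (duplicate points collapsing clusters) are
reported as missing, not as zero.

## Synthetic data: what it emulates, and what it does not

The default scenario encodes the study conditions of a 5-day static
pellicle time course: total biomass peaking on day 2 and decaying to 20%
of maximum on day 5; an overall mobile fraction ≈ 0.89–0.91 early and
≈ 0.76–0.79 late, split per class (carbohydrates 0.94 → 0.71, proteins
0.87 → 0.74); mobile/rigid T1 of 0.5 s / 20 s; a category table whose
protein and exopolysaccharide declines on days 3/4 are 49.28/31.31 and
14.18/33.43 (so the kinetics stage reproduces the 79/50/21/50 solution);
a lipid/biosurfactant surge from 0.2 to 1.8 between days 3 and 4; eight
sugars in four families (a three-member galactan family partitioned into
the medium, the peptidoglycan pair GlcNAc/MurNAc, and the distinct Glc and
GlcA profiles) with GlcN absent from the medium and GlcA missing on
day 1; site T1 values 0.7–2.6 s and order parameters 0.49–1.0 over CH and
CH₂ sites.

Spectra are sums of Lorentzian lines (mobile-phase ssNMR lines are
near-Lorentzian; a Gaussian/Voigt option was deferred), stored on a
descending 0–200 ppm axis of 4096 points, with 30 mg samples and
mode-specific scan counts. Polarization weighting: quantitative DP detects
both phases fully; 2 s DP attenuates each phase by the mono-exponential
saturation factor `1 − e^(−2 s/T1)` — the simplest model consistent with
recycle-delay selection; CP carries only the rigid phase scaled by a
single global efficiency (0.4) and is flagged non-quantitative. Noise is
additive i.i.d. Gaussian per point from seeded, per-stream RNGs; identical
(config, seed) pairs reproduce every file byte for byte.

Not emulated: FIDs and their processing (the pipeline starts from
frequency-domain data), 2D spectra (consumed only as peak/integral
tables), baseline/phase artifacts, rotor-synchronized spinning sidebands,
field-dependent lineshapes, and relaxation during the DIPSHIFT evolution
period. Passing recovery tests therefore demonstrates the correctness of
the quantification and fitting machinery under the stated forward models —
not robustness to instrument artifacts those models exclude.

Two systematic biases are *expected* on synthetic data and bounded by the
recovery suite rather than hidden: short-recycle saturation bias on mobile
fractions (up to ≈ 0.015 at the 0.5 s / 20 s T1 split: the mobile phase is
~1.8% unsaturated at 2 s while the rigid phase contributes ~9.5% of its
share), and inter-window Lorentzian tail leakage (worst when the day-4
lipid spike reaches ~70% of protein biomass, biasing the protein-window
mobile fraction by up to ≈ 0.04). Hence the recovery-suite tolerances:
relative densities ±0.05, mobile fractions ±0.05, T1 ±5% relative, order
parameters ±0.02, sugar-family ARI = 1.0, solver proportions ±1
percentage point.

## Reference-table check

When a user supplies a per-sugar ratio table (CSV, rows = sugars,
columns = days), the pipeline reports the variance captured by the first
two principal components after standardization. No such reference table
ships with the package, so by default this check is reported as
`unavailable` in the run report rather than silently skipped.

## Problem sizes

Default problem sizes were chosen so a full simulate → analyze → recover
cycle completes in seconds on one core: 4096-point spectra × 5 days × 3
modes, 12-delay recovery series per site, 16-point dephasing curves per
site, 8 sugars × 5 days. The Monte-Carlo tests use 200 replicates (T1)
and the full S ∈ {0.1, …, 1.0} grid for both multiplicities.

## Known limitations

* CP spectra are qualitative by construction; the rigid phase is only
  estimable as (total − mobile).
* The CH₂ model neglects dipolar cross-correlation and any relaxation
  during t₁; order parameters for strongly coupled CH₂ sites carry the
  corresponding model error.
* The proportion solver is strictly two-component; a three-component
  generalization would need an additional constraint per interval.
* Region-based component quantification underestimates totals (carbonyl
  carbons fall outside the protein windows) — intentional, since relative
  time courses are invariant to the missing constant fraction.
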