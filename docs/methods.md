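# Methods

## Scope and design

The package compares two intraprocedural MR-thermometry readings — PRFS phase
mapping and qualitative T1-magnitude signal loss — on synthetic liver laser
ablations whose true thermal damage is known. Every simulated case produces
one temperature history, which is encoded into both modalities; the
comparison is therefore paired by construction and isolates the monitoring
physics and reading rules from lesion-to-lesion variability. Real per-patient
clinical outcomes are outside the model: the phantom's job is to expose the
*mechanism* of the accuracy asymmetry (the visibility threshold of the T1
reading corresponds to a much hotter isotherm than the lethal boundary), not
to reproduce clinical medians.

## Bioheat phantom

Temperature obeys the Pennes equation
ρc ∂T/∂t = ∇·(k∇T) + w_b(T_a − T) + Q_laser on a 3D grid: 128×128 in-plane
voxels of 2.5 mm (FOV 320 mm, the monitoring-sequence matrix), solver
z-spacing 3 mm over ±24 mm, Dirichlet boundaries at baseline. The three
monitored slices sit 9 mm apart (3 mm slice + 6 mm gap). An explicit
finite-difference scheme is used; the step must satisfy
dt ≤ 1/(2α(1/dx²+1/dy²+1/dz²) + w_b/ρc) (≈ 8.4 s at defaults; dt = 2 s is
the default, and an unstable dt raises an error naming the bound). Frames
are stored every 15 s — a stand-in for one acquisition per breathing cycle;
only the final ("peak temperature") triplet enters the lethal-zone reading,
so the exact cadence is immaterial.

Tissue defaults are literature liver values, all overridable:
ρ = 1050 kg/m³, c = 3600 J/(kg·K), k = 0.52 W/(m·K), perfusion heat sink
w_b = 3·10⁴ W/(m³·K) (≈ 0.008 1/s volumetric exchange; screening length
√(k/w_b) ≈ 4 mm), T_a = baseline = 37 °C. Properties are constant during
heating — coagulation-induced changes in conductivity and perfusion shutdown
are not modeled.

Each fiber deposits Q_laser along its 3 cm diffusor tip with radial
exponential attenuation exp(−d/δ), normalized on the grid so the volume
integral equals the absorbed power (energy conservation is exact by
construction). The absorbed fraction defaults to 0.7. The effective
attenuation length defaults to δ = 2.5 mm: with the literature constants
above, this reproduces realistic LITT behaviour — core temperatures near
80 °C and single-fiber coagulation widths of ~2.5 cm, matching the
applicator's stated maximum zone width. (Longer attenuation lengths of ~4 mm
spread the same power so widely that the core never exceeds ~60 °C and the
hot display corridors can never appear, which contradicts how these
procedures look; δ remains configurable.)

The power regimen is the standard clinical schedule: one increment of
2 W/min per full minute until 14 W (a 6 min ramp), 14 W held for 17 min,
then off — 23 min active time, 16.8 kJ per fiber. Each fiber is driven by
its own source at the full schedule (two fibers deliver 33.6 kJ, consistent
with the reported median applied energy of ~36 kJ); an optional beam-split
flag divides one source's power among fibers instead.

Cohort generation draws tumor diameters uniformly from 0.5–6.0 cm (the
clinical target range) and applies the placement rule: one applicator up to
2 cm, two up to 3.5 cm, three up to 4.8 cm, four beyond, parallel tips
spaced ≤ 20 mm so estimated 2.5 cm zones overlap by ≥ 5 mm. Biological
variability enters through the perfusion coefficient (uniform ±25 %) and the
absorbed fraction (uniform ±10 % relative) — these drive the case-to-case
spread of both predicted and true areas, which the Spearman statistics rank.
All randomness flows from a single per-case seed; cohorts are bit-for-bit
reproducible.

## Ground truth

Thermal damage is first-order Arrhenius kinetics, Ω = ∫A·exp(−Ea/(R·T_K))dt,
integrated per voxel with a left-Riemann rule on the stored cadence
(trapezoid optional); necrosis is Ω ≥ 1. Ea is fixed at the published liver
value 2.577·10⁵ J/mol. Published frequency factors put the lethal isotherm
of a ~20 min exposure in the low 40s °C, which is inconsistent with the
52–55 °C operating point of the procedure this package models, so A is
calibrated instead (`scripts/calibrate_damage.py`): on the standard
one-fiber phantom the Ω = 1 boundary is placed at a peak temperature of
≈ 52.4 °C, giving A = 2.34·10³⁸ 1/s. With this calibration the damage
integral and the peak-temperature model at ~52 °C agree almost voxel-for-
voxel (Dice > 0.85, in practice ≈ 0.95+), mirroring the equivalence of the
two damage models at this operating point.

## MR encodings

**PRFS forward model.** Phase = 2π·γ·B₀·α·TE·(T − 37) + drift(t) on top of a
proton-density map (liver 1.0, tumor 0.85, posterior muscle 1.2, background
0.05); complex Gaussian noise (i.i.d. per channel, SD 0.1 → magnitude
SNR ≈ 10 in liver) is added to M₀e^{iφ} and the result stored as magnitude +
wrapped phase. γ = 42.576 MHz/T, B₀ = 1.5 T, TE = 12 ms, α = −0.01 ppm/°C
(the water literature value; scanner vendors do not publish theirs). A 10 °C
rise shifts phase by −0.48 rad. B₀ drift is spatially uniform and linear in
time by default (3·10⁻⁴ rad/s ≈ 0.4 rad per procedure, several apparent °C
if uncorrected); a polynomial drift is configurable. A spatially uniform
term is exactly what a single-ROI correction can remove — spatially varying
drift is deliberately out of scope.

**T1-magnitude forward model.** T1(T) = T1₀(1 + c·(T − 37)) with T1₀ =
586 ms (liver, 1.5 T) and c = +1 %/°C feeds the spoiled-GRE steady-state
signal sin α(1−E1)/(1−cos α·E1), E1 = exp(−TR/T1), at TR = 100 ms and
flip 70°. The signal is strictly decreasing in temperature; the noise-free
25 % drop is reached at ≈ 76 °C (`drop_isotherm_temperature`), comfortably
above the > 60 °C presumption attached to visible signal loss and far above
the 52 °C lethal boundary — this gap *is* the mechanism behind the T1 arm's
gross underestimation. Noise is Rician (complex Gaussian before magnitude).
The T1 arm is simulated on the same 3-slice geometry as the GRE arm rather
than a separate 10–15 × 5 mm axial stack; with the largest-slice reading
rule the extra slices would be redundant.

## Reconstruction and reading rules

PRFS reconstruction: wrapped phase difference against the pre-heating
reference; temporal unwrapping (valid while true per-step changes stay below
π; voxels with apparent steps ≥ 0.9π are flagged); per-acquisition B₀
correction by subtracting the 36-voxel reference-ROI mean (the corrected
ROI mean is zero by construction); linear conversion ΔT = Δφ/(2πγB₀αTE).
Voxels whose reference magnitude falls below 3× the noise SD are flagged
invalid instead of being assigned temperatures. The display renders four
isothermal corridors ([40,55), [55,70), [70,85), ≥85 °C; 85.0 goes to the
hottest corridor) only inside the square monitoring ROI — 400 or 900 voxels
(side 20 or 30; at 2.5 mm voxels that is 25 or 56 cm² — the display's
voxel counts are taken as the operational definition). Hot tissue outside
the ROI is "thermometrically blind" and can only cause underestimation.

Lethal-zone readings, both at the final triplet: PRFS, temp ≥ 55.0 °C
(inclusive) inside the ROI; T1, fractional signal drop ≥ 0.25 with negative
drops clipped to zero, cleaned per slice by removing blobs under 2 voxels
and keeping the connected component containing an applicator (fallback:
largest) — mimicking a reader outlining one coherent blackened zone. Both
arms report the slice with the largest zone (ties → lowest index), its area
as voxel count × 6.25 mm², and the necrosis area measured on that same
slice (if that slice shows none, the largest necrotic slice, as a human
reader would measure).

## Statistics

Predictive error = (1 − estimated/necrosis)·100, positive for
underestimation; the ratio ×100 is the "percent of necrosis captured" scale
on which arms are compared. Spearman rank correlation (average ranks;
two-sided; exact permutation p over all n! pairings for n ≤ 8, t
approximation beyond) relates estimated to resulting areas within each arm.
Mann-Whitney U (average ranks; exact enumeration null for n1+n2 ≤ 14
without ties, otherwise normal approximation with tie and continuity
corrections) compares the arms on ratios and, as a negative control that
must stay non-significant in a paired phantom, on the necrosis extents. The
U statistic and both p-value branches ride on scipy.stats behind the module
surface; the exact-Spearman permutation p is computed in-package
(vectorized over all permutations) since scipy provides none. Degenerate
inputs (constant vectors, < 3 pairs) yield flagged "undefined" results at
cohort level rather than aborting the analysis. Independent brute-force
enumeration oracles in the test suite verify both tests exactly on tie-free
samples.

QC follows the dual-acquisition estimator SNR = √2·S₁/SD₁₋₂ in a 6×6-voxel
ROI of non-heated liver (sample SD, n−1, appropriate for 36 voxels;
triplets average per-slice SNRs) and the temperature SD over the same ROI on
the reconstructed map; with uncorrelated complex noise the latter scales as
1/SNR, which the acceptance checks verify across SNR 5/10/20.

## Numerical choices and degenerate inputs

Explicit Euler is kept deliberately: at the stability-bounded steps the
scheme's error is far below the physical uncertainty of the tissue
constants, and the solver stays dependency-light and exactly reproducible.
Stationarity (no source, uniform field) holds to machine precision. Left
endpoints are used for both the power schedule within a step and the damage
integral between stored frames, matching the discrete acquisition cadence.
Phase wrapping maps to (−π, π]; the 55 °C and 25 % thresholds are
inclusive; slice ties resolve to the lowest index; areas are always in-plane
voxel counts × voxel area. Temperatures above 100 °C are not clamped
(vaporization is not modeled) and label the hottest corridor.

## Problem sizes

The default analyses run at desk scale by choice: 34-case cohorts (each a
~23 min simulated procedure at dt = 2 s, stored every 15 s) complete in a
few minutes on one core; the closed-form solver checks use 5³–41³ grids; the
oracle sweeps use 200 random instances at n ≤ 7 where exact enumeration is
feasible.

## What the phantom does and does not show

Passing tests show that: the forward/inverse PRFS chain is exact to
microkelvin without noise; uniform drift is removed exactly; temperature
noise behaves as 1/SNR; the damage calibration places the lethal isotherm at
the intended operating point; and under these conditions the qualitative T1
reading underestimates necrosis far more than PRFS thermometry, with the
paired necrosis distributions indistinguishable between arms. The phantom
omits respiratory motion and deformation, susceptibility and fat-related
phase errors, spatially structured drift, coagulation-dependent tissue
properties, optical Monte-Carlo light transport, vendor display internals,
and reader variability in manual segmentation. Clinical error magnitudes
therefore differ from the synthetic ones — in vivo, motion and blind-ROI
effects push the PRFS error up — and only the direction and mechanism of
the asymmetry, not its clinical size, carry over.
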