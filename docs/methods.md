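# Methods

## Signal model

Each voxel belongs to one generative compartment: deep, middle, or
superficial gray matter (equivolume-depth terciles of the annular ribbon) or
vessel-dominated (tubes in CSF just outside the gray-matter surface). For a
stimulus of duration D, a compartment's response in contrast k ∈ {cbv, bold}
is

    r(t) = a · min( G(t − d) − G(t − d − D), c )

where G is the CDF of a gamma-variate impulse response parameterized by its
mean m and standard deviation s (shape = (m/s)², scale = s²/m), d an onset
delay, a the amplitude (fractional signal change), and c a saturation
ceiling on the convolved boxcar. The closed form makes every simulated curve
and its peak analytic ground truth. With c = ∞ the response is linear in
stimulus duration; responses to a trial sequence superpose additively.

Acquired signals per cycle i (nulled at block 2, BOLD at block 4 of the
four-block 785 ms cycle):

    S_bold(i)   = S0 · (1 + δ(t_bold,i))
    S_nulled(i) = S0 · (1 − v(t_null,i)) · (1 + g · δ(t_bold,i))

v is the CBV response (a CBV increase lowers the blood-nulled signal), δ the
BOLD response, g the contamination gain (default 1). The multiplicative T2\*
contamination of both volumes of a cycle is modelled as a single per-cycle
factor evaluated at that cycle's BOLD readout — the drift of the T2\*
weighting over one 3.14 s cycle is second order — so volume-by-volume
division (BOCO) cancels it exactly in the noise-free limit. This is the
property the exactness tests verify. Noise is i.i.d. Gaussian, equal
variance in both contrasts.

### Default generative parameters

| compartment | contrast | a (frac) | m (s) | s (s) | d (s) | ceiling |
|---|---|---|---|---|---|---|
| GM deep        | cbv  | 0.016 | 5.0 | 2.5  | 0.0 | ∞ |
| GM middle      | cbv  | 0.022 | 5.0 | 2.5  | 0.0 | ∞ |
| GM superficial | cbv  | 0.018 | 5.0 | 2.5  | 0.4 | ∞ |
| vessel         | cbv  | 0.040 | 6.5 | 3.0  | 0.5 | 0.9 × (2 s linear peak) |
| GM deep        | bold | 0.015 | 5.5 | 2.75 | 0.2 | ∞ |
| GM middle      | bold | 0.025 | 5.5 | 2.75 | 0.3 | ∞ |
| GM superficial | bold | 0.035 | 5.5 | 2.75 | 0.5 | ∞ |
| vessel         | bold | 0.080 | 5.5 | 2.75 | 0.8 | ∞ |

Rationale: CBV responses of ~0.3 % (1 s) to ~2 % (24 s) in gray matter with
a mid-depth maximum; vessel CBV about twice gray matter for brief stimuli
but saturating during a 2 s stimulus (the ceiling sits at 90 % of the 2 s
linear peak so saturation is reached *within* that stimulus); BOLD strongly
vessel-biased (8 % vs 1.5–3.5 %) and linear in duration, which keeps the
BOLD vessel/GM peak ratio flat across durations while the capped CBV makes
only the VASO ratio duration-dependent. Superficial and vessel responses are
slightly delayed relative to deep/middle gray matter. Baseline signal
S0 = 1000 a.u. for both contrasts; default noise SD S0/15 gives a VASO-like
temporal SNR of ~15. Stimulus durations {1, 2, 4, 12, 24} s; rest periods
paired to durations in sorted order ({10, 12, 14, 20, 24} s for the short
class, {20, 22, 24, 30, 40} s for the long class); long-ITI designs are
shared across runs, short-ITI designs randomized per run. Runs begin and end
with 30 s of rest to support the edge-window baseline.

The default grid is a 40×40×10-voxel annulus (inner radius 10, outer 16
voxels, nominally 0.9 mm isotropic) extruded along z — small enough that a
multi-run simulation takes seconds, thick enough (6 voxels) that 11 layers
remain meaningful.

## Event-related averaging

Trials are extracted from stimulus onset to the end of their rest period on
the 4×-upsampled grid. Because onsets are jittered over the block grid, each
trial's window contains native (non-interpolated) samples at one of four
phases. `average_trials` by default *interleaves* jitters: each time point
of the average uses only the trials whose native sample lands on it, with
per-time-point sample counts reported. This reconstructs the response on the
0.785 s effective grid without interpolation error — for noise-free input
the recovered curve matches the generative one at numerical precision, and
saturated plateaus stay exactly flat. The alternative mode
(`interleave=False`), in which every trial contributes its possibly
interpolated sample everywhere, is provided for comparison; its residual
interpolation smoothing (~0.1–0.2 percentage points near response onsets at
these curvatures, linear kernel) is the reason interleaving is the default.

Percent signal change divides by the voxel baseline (mean of the first and
final 30 s of each run) and multiplies by 100; VASO values are then
sign-inverted so a CBV increase is positive. When short- and long-ITI
sessions are combined, the samples present only in long-ITI runs are shifted
by the offset between the first long-only and the last short-covered time
point (leaving that junction pair equal), and finally the first time point
is set to zero. The step order — divide, invert, stitch, zero — is fixed and
verified by an integration test.

## Layering

Depth runs from 0 at the WM/GM boundary to 1 at the GM/CSF boundary.
Signed distances to both boundaries come from Euclidean distance transforms
(smoothed with a σ = 1.4 voxel Gaussian to suppress voxelization staircase).
Columns are traced per gray-matter voxel by marching (step 0.15 voxel) along
the gradient of the mid-surface signed distance to a subvoxel zero crossing
on each side. The equivolume depth integrates a cross-section area model
dA/ds = κ·A along the traced column, with κ the divergence of the normalized
gradient field (smoothed at σ = 2.5 voxels); the voxel's depth is the
fraction of column volume between it and the white matter. The smoothing
scales were chosen by validating against the analytic annulus, where the
equivolume depth has the closed form (r² − r_in²)/(r_out² − r_in²): maximum
absolute error ≈ 0.02 at the default grid. The area model captures one
principal curvature exactly (cylindrical geometry); strongly doubly-curved
cortex would need the Gaussian-curvature term, which the synthetic
geometries do not exercise. Columns that cannot be traced to both boundaries
are flagged NaN and excluded. Layer bins are equal-width in depth, layer 1
deepest. The disc ROI grows by within-ribbon geodesic distance (uniform-cost
wavefront over gray matter) from the cortical column through the chosen
center, so it spans all depths; an optional nearest-neighbour upsampling
factor for the label grid defaults to 1.

## GLM

One boxcar regressor per stimulus duration is convolved with a unit-area
gamma HRF (moment-matched: mean lag 6 s, sd 3 s; shape 4, scale 1.5) on the
kernel's 0.1 s grid and sampled at volume times. High-pass filtering uses
discrete-cosine drift regressors with frequencies below 0.01 Hz (periods
longer than 100 s), included in the design rather than applied to the data.
Fitting is ordinary least squares at the native volume rate of each
contrast (event-related analyses use the upsampled grid); t statistics are
converted to z by CDF matching at the residual degrees of freedom, and
voxels fitted to numerical precision (zero residual variance) are flagged
rather than assigned infinite z. Sessions combine by Stouffer fixed effects
(Σz/√k). VASO series are sign-inverted before fitting so activation yields
positive z. No prewhitening is applied; the simulator's noise is white by
construction, so OLS is exact there — a known limitation for real,
autocorrelated fMRI noise.

## Time to peak and peak ratios

TTP is the time of the highest signal change between the initial deflection
above zero and the subsequent fall below zero (truncated at the window end
when the signal never falls below zero; series that never rise above zero
are invalid). Samples within 0.1 % (relative) of the span maximum count as
ties and the earliest wins. This tie tolerance makes the peak location well
defined for saturated responses whose maximum is an exactly flat plateau —
a plain argmax there is decided by numerical ripple — while being
inconsequential for noisy data; the generator's analytic ground-truth peak
times use the same rule. The vessel/GM ratio divides the peak signal change
of vessel-dominated voxels by that of gray matter per stimulus duration,
using peaks found by the same span rule, on zeroed percent-change averages.

## What the simulator does and does not emulate

Emulated: the symmetric four-block cycle and its jittered effective
sampling; per-duration trial structure with short/long rest classes;
compartment-specific CBV and BOLD dynamics including vessel-CBV saturation;
multiplicative BOLD contamination of the nulled signal; Gaussian thermal
noise; rigid motion parameter traces (as QC input only — data are generated
in aligned space, since registration is external-tool territory).

Not emulated: EPI/k-space physics, inflow and T1-relaxation effects, CSF
volume redistribution, physiological (cardiac/respiratory) noise,
autocorrelated drift, geometric distortion, and actual image motion.
Passing recovery tests therefore demonstrates correctness of the analysis
chain under the stated signal model, not robustness to every artefact of
real acquisitions.

## Numerical choices and problem sizes

Temporal upsampling uses linear interpolation with edge-hold extrapolation
(a cubic-spline option is available); original samples are preserved
exactly at stride `factor`, which is what the BOCO exactness and
interleaving guarantees rely on. The BOCO division guards divisors below
1e−6 of a voxel's mean magnitude (NaN, not ±inf). tSNR and 1/CV maps use
the sample standard deviation (ddof = 1) and flag zero-variance voxels.
Framewise displacement converts rotations to arc length on a 50 mm head
radius; index i of the FD series is the displacement of volume i+1 with
respect to volume i.

Test and verification sizes: recovery tests simulate one noise-free
participant (default grid, 4 long-ITI runs, ≈ 250 cycles per run); GLM
calibration uses 8000 null voxels at one run's length; oracle-equivalence
checks run 100 randomized instances per operation. These sizes keep the
whole suite in the tens of seconds while leaving every statistical check
comfortably powered.
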