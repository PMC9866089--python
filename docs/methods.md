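# Methods

This note documents the models behind `cardiocal`, the defaults that matter,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was genuinely open.

## 1. Calcium forward model and its inverse chain

The simulated cardiomyocyte is a single well-mixed compartment.  Between
beats, free cytosolic calcium obeys

    dc/dt = J_leak − k_eff · (c − c_dia)

with `k_eff` the sum of the first-order extrusion rate constants active
under the current pharmacological state (SERCA2, NCX, PMCA, mitochondria).
Each spontaneous beat adds `release_amplitude` nM instantaneously; beats
arrive on a clock with normally jittered inter-beat intervals.  Protocol
events toggle the state: caffeine dumps the full SR content, nulls the
SERCA2 term (continuous release defeats net re-uptake) and stops the beat
clock; Na/Ca-free buffer nulls NCX; tetracaine nulls the leak flux; an
uncoupler nulls the mitochondrial term; washout restores everything.

This is deliberately the same model class the analysis assumes — parallel
first-order extrusion — so generator-truth recovery is a well-posed test of
the measurement chain.  It is **not** a biophysical SR model: there is no
RyR gating, no calcium-induced calcium release, no spatial waves and no
photobleaching.  Passing recovery tests therefore demonstrates that the
analysis correctly inverts a first-order world, not that real traces are
first-order.

Integration uses a fixed step at 10× the sampling rate, with the exact
exponential update of the linear ODE inside each step; noiseless decays are
mono-exponential to machine precision, and event/beat times snap to the
integration grid.

**Fura-2 encoding.** The two channels follow the standard two-state dye
mixture: with bound fraction x = c/(c + K_D), the 380 nm signal
interpolates between the free-dye level (1000 a.u. by default) and the
bound level (free level / β), the 340 nm signal between R_min and R_max
times those levels.  The noiseless ratio therefore inverts *exactly*
through [Ca²⁺] = K_D·β·(R−R_min)/(R_max−R).  Channel noise is additive
Gaussian per channel before ratioing.  The reference calibration used by
the simulations is R_min = 0.5, R_max = 3.5, β = 1, K_D = 225 nM; "3 %
channel noise" means SD 30 on the 1000-unit channel scale.

Defaults that encode the study conditions: diastolic calcium 125 nM,
per-beat release 300 nM (systolic peaks ~350–450 nM), SR content 400 nM,
leak 5 nM/s; wild-type beating 59 bpm with k_sys = 2.0 /s split
90/5/2.5/2.5 % (SERCA2/NCX/PMCA/mitochondria); knockout-like cells beat at
96 bpm with k_sys = 3.0 /s split 89/7/2/2 %.  Sampling defaults are
23 frames/s for kinetic runs and 6.6 frames/s for long blocker protocols.
The inter-beat jitter of the acceptance experiments maps the reported
group spread to interval units: jitter = 60·SD_bpm/rate².

## 2. Decay fitting under ratiometric noise

Converting noisy ratios to concentration amplifies channel noise by
dC/dR = K_D·β·(R_max−R_min)/(R_max−R)², which diverges toward saturation:
at 3 % channel noise a 450 nM peak carries ~60 nM of noise while the
diastolic baseline carries ~5 nM.  Three consequences drove the estimator
design (each validated against generator truth during development):

1. **The detected peak sample is excluded from every fit window.**  The
   peak index is the argmax of noisy samples and is biased high; fitting
   from it steepens the decay by up to tens of percent.  Windows open at
   the first sample *after* the peak at or below baseline + 90 % amplitude.
2. **Weighted least squares with data-independent-ish weights.**  Fit
   weights come from the calibration's noise propagation evaluated on a
   smoothed signal — a self-excluding neighbour average for long
   single-transient windows (fully decorrelated from each sample's own
   noise) and a 5-sample running median for the short twitch segments.
   Weights computed from the raw noisy samples correlate with the noise and
   bias τ upward; weights iteratively re-evaluated on the model prediction
   drift toward high-variance solutions because the plain weighted sum of
   squares lacks the log-σ likelihood term — both failure modes were
   measured, which is why neither is used.
3. **A shared-τ profile fit for the systolic rate.**  At 96 bpm and
   23 frames/s an individual twitch decay spans ~10 samples — too few for a
   stable 3-parameter fit.  `fit_shared_decay` gives every inter-beat
   segment its own amplitude while sharing τ and the offset across the
   trace; for fixed τ the model is linear in the remaining parameters, so τ
   is profiled by 1-D bounded minimization.  Recovery at the study noise
   level is within ~3 % for both genotypes.

Caffeine transients are fitted over the full window from the peak to
washout or the end of the trace (the long tail pins the slow τ; the free
offset absorbs the post-caffeine plateau).  The amplitude is measured from
the 10th-percentile (diastolic) level of the 5 s before the event, which is
insensitive to ongoing twitches.  Fits that refuse (fewer than 5 samples)
or do not converge are flagged and excluded from group summaries.

The decomposition ladder is exact arithmetic: k_SERCA2 = k_sys − k_caff,
k_NCX = k_caff − k_caff,0Na0Ca, k_mito = k_caff,0Na0Ca − k_unc,
k_PMCA = k_unc; components always sum to k_sys by construction, negative
components are reported as-is with a quality flag (they diagnose
inconsistent condition fits), and without an uncoupler condition the PMCA
slot carries the combined slow-system rate with `pmca_mito_combined=True`.
Group tables report mean ± SEM.

## 3. Connexin-cluster imaging

**Generator.**  Plaques are 2-D Gaussian spots whose footprint above half
their amplitude equals the drawn area (σ = √(area/(2π ln2))); areas are
log-normal (log-SD 0.55) with the log-mean solved so the 0.05–1 µm²
truncated mean equals the target group mean (0.292 µm² wild-type,
0.3352 µm² knockout; the truncated-lognormal mean has a closed form used as
the analytic oracle).  Spots sit in a 2 µm contact band across a
512×192 px image at 0.1581 µm/px, 20 per wild-type image (12 per knockout
image, the 0.6× density), with non-overlapping footprints — plaques are
distinct structures, and the per-image count is deterministic so group
density ratios are set by parameters rather than count noise.  Per-cluster
peak amplitudes are log-normal (median 64, log-SD 0.5) over a background of
30 with Gaussian noise SD 10.

The amplitude spread is load-bearing: with uniform amplitudes the
Rényi-entropy threshold hugs the background mode (the foreground histogram
is a narrow spike and the entropy criterion maximizes just above the
background), inflating every threshold-level footprint relative to the
half-max ground truth.  A brightness spread is also what real
immunofluorescence shows.  The chosen contrast places the automatic
threshold near the half-amplitude of the median cluster, making the
measured post-filter mean area track the generator law within a few
percent.

**Known limitation.**  The dim tail of the amplitude spread produces
occasional fragmented or undersized masks, and these artifacts scale with
cluster size, so they hit the larger knockout plaques slightly harder.
The measured knockout-vs-wild-type density decrease is therefore attenuated
to ≈37 ± 2 points against the 40-point generator truth over 50-image
groups.  Auto-thresholding an image that contains *no* plaques is
degenerate (a pure-noise histogram has no foreground mode); the pipeline
raises rather than returning speckle counts for structure-free images.

**Pipeline.**  Thresholding follows the three-order Rényi procedure
(optima at ρ→1, 0.5, 2 combined by the published rank-ordered weighting; an
exhaustive Kapur maximization guards the ρ→1 core in the tests) on a
256-bin histogram of the masked intensities; segmentation is 8-connected
(the particle-analysis convention, switchable); the 0.05–1 µm² size filter
is applied as nearest-integer pixel bounds (2–40 px at the default pixel
size — 2 px is 0.04998 µm², so literal µm² bounds would exclude the stated
lower pixel bound).  Size-distribution comparisons use a chi-square on the
binned contingency table without continuity correction, with 8 equal bins
across the filter window by default.  Costes colocalization fits the
channel-2-vs-1 relationship by orthogonal (total-least-squares) regression,
scans the threshold pair downward until the below-threshold Pearson
coefficient reaches ≤ 0, and reports the coefficient above both thresholds;
anti-correlated channel pairs are flagged instead of thresholded.

## 4. Dye coupling

Monolayers are jittered-grid Delaunay graphs (long border edges pruned)
with log-normal junctional permeabilities (default mean 0.005 /s, CV 0.5)
and near-normal cell areas (400 µm², CV 0.15).  Dye spread integrates the
linear compartment model with the exact matrix exponential of the weighted
graph Laplacian over 0.5 s steps; the donor source (default: constant over
the whole 300 s spread, i.e. the electrode stays in) adds mass exactly, and
total dye is conserved to machine precision once the source is off.  A
recipient counts as coupled at ≥5 % of the donor's final concentration
(visual-detectability proxy; configurable).  Carbenoxolone is modeled as a
full block at the assay dose rather than a dose-response curve, because the
assay uses it only as an on/off control.

## 5. Voltage clamp

The simulated pipette clamps the membrane through the residual
(post-compensation) series resistance; the membrane carries C_m, a linear
leak (reversal at the −90 mV holding potential) and an HH-type m³h sodium
current with Boltzmann steady states (activation V½ −34 mV / slope 5.5 mV,
inactivation V½ −68 mV / slope 6 mV) and fixed time constants (τ_m 0.3 ms,
τ_h 1.5 ms).  Gates and voltage advance by exponential (exact for frozen
coefficients) updates at 2 µs, sampled at 10 kHz; command edges land
exactly on output samples so the onset sample carries the full transient
peak.  The wild-type cell is 51.9 pF / 435.1 MΩ with a 10 MΩ pipette.

Two compensation regimes coexist deliberately: the ±10 mV capacitance test
pulses are simulated uncompensated (the transient is what compensation
circuitry is tuned on), while the step family assumes 98 % compensation.
The latter is a modeling necessity: at the peak densities these cells show
(−338 pA/pF × ~52 pF ≈ −17 nA), every megaohm of residual series
resistance shifts the command potential by ~17 mV, so only a
near-ideally-compensated recording clamps the membrane at all.  The
recovery experiment calibrates g_Na,max so the *ideal-clamp* peak density
equals the target (the peak is linear in g_Na,max under ideal clamp), then
analyzes the full artifact-laden recording; recovery is within ~1 %.

Analysis choices: capacitance integrates the leak-subtracted transient from
the pulse onset to five fitted time constants plus the analytic tail of the
fit, corrected by the (R_in+R_s)²/R_in² charge-divider factor computed from
the recording's own estimates; the ΔV/ΔI_ss input resistance deliberately
reports access + membrane resistance, as the physical measurement does;
leak subtraction scales the −20 mV pulse by ΔV/(−20); the peak-current
search window is 0.5–20 ms after the step onset (excludes any residual
capacitive spike, configurable); recordings with estimated R_s > 20 MΩ are
flagged as rejected.

## 6. Statistics

Two-group comparisons gate on a Lilliefors-corrected Kolmogorov–Smirnov
normality test per group at α = 0.05 (plain KS with estimated parameters is
anti-conservative): both normal → (paired) t-test, otherwise Mann–Whitney
(Wilcoxon signed-rank when paired).  The organ-culture time courses use
two-way ANOVA with type-II sums of squares, which tolerates the unbalanced
explant designs.  Grubbs' two-sided single-outlier test uses the exact
t-based critical value at α = 0.05.  qPCR fold changes follow the
comparative method, fold = 2^(−ΔΔCt), against a reference gene and control
group.  No multiple-testing correction is applied, matching the
per-comparison reporting convention; treat families of comparisons
accordingly.

## 7. Problem sizes of the recovery experiments

The recovery workflows run 25/27 one-minute traces for the beating-rate
groups, 30 three-condition protocol sets per genotype for the
decomposition, 50 (or 56) images per group for the cluster pipeline, and a
single deterministic voltage-clamp recording per membrane quantity; the
complete set executes in well under a minute.  All randomness derives from
a single integer seed through a deterministic sub-seed schedule.
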