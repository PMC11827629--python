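# Methods

## Two-state binding model and trace synthesis

Each immobilized protein molecule is modeled as an alternating renewal
process between *unbound* and *bound*: unbound dwells are exponential with
rate k_on·c (pseudo-first-order at free-aptamer concentration c, assumed
undepleted), bound dwells exponential with rate k_off.  The initial state
is Bernoulli with the stationary bound probability k_on·c/(k_on·c+k_off);
because first and last dwells are censored at analysis time, this choice
cannot bias the estimators.  A zero rate makes its state absorbing; both
rates zero is rejected (no stationary law exists).

Rendering integrates occupancy exactly: the bound-time fraction f of each
frame comes from interval overlap (not midpoint sampling, which would add
an avoidable discretization bias).  A frame contributes f·I of signal,
split acceptor = E·f·I, donor = (1−E)·f·I by the molecule's FRET
efficiency E, plus a constant background and i.i.d. Gaussian noise per
channel.  Per-molecule E is drawn once: Normal(0.38, 0.14) truncated to
[0,1] for site-specifically labeled targets ("2PCA mode"), Uniform(0.2,
0.8) for amine-labeled targets ("NHS mode", emulating random dye
positions).  Acceptor photophysics produces the donor-only population: a
fraction p_dark = 0.1 of molecules has no active acceptor, and an optional
exponential bleach time zeroes E from the bleach frame onward.

Defaults where no measured value exists are stated choices, not fits:
total intensity 1000, noise SD 100 (SNR 10, at which frame
misclassification by thresholding is negligible, ~2·10⁻⁴), background 100,
bleach rate 0 in kinetic benchmarks.  Assay-condition defaults are c =
5 nM, 0.1-s frames, 600-s movies, 300 molecules per field of view.

What the generator does **not** emulate: camera EM gain statistics and
shot noise (noise is homoscedastic Gaussian), spectral crosstalk and
gamma-factor corrections, donor blinking/bleaching, spot-detection and
pairing errors upstream of trace extraction, baseline drift.  Passing
recovery tests therefore demonstrate estimator correctness under the
stated model, not robustness to every instrument artifact.

## Trace analysis

*Threshold.*  A deterministic 1-D two-means on donor+acceptor: centers
initialized at the 10th/90th percentiles, assignment iterations to a fixed
point, threshold = midpoint of the centers.  A trace is declared
"no binding detected" when the converged centers are closer than 3× the
within-cluster residual MAD (normal-consistent).  The noise scale is taken
within clusters rather than over the whole signal because a genuine
two-state trace with ~50% duty cycle has a whole-signal MAD comparable to
the level separation itself, which would misflag exactly the strongest
binders.

*Segments.*  Maximal runs above threshold; runs shorter than `min_frames`
(default 4, i.e. strictly more than three consecutive frames; a ≥3 reading
is available via the parameter) are discarded, not merged, but retained as
sub-threshold runs for dwell bookkeeping.  Spans are half-open
[start, end) in 0-based frames.

*Event FRET.*  Per-frame E = I_A/(I_A+I_D) on background-subtracted
intensities (background = per-channel median of below-threshold frames),
averaged over the segment, clipped to [0,1]; frames with non-positive
total are excluded.

*Populations.*  Event efficiencies are classified with a Gaussian mixture
(1..3 components, count by BIC, components sorted by mean; events below
the donor-only cut E < 0.15 reported as the donor-only population — the
cut sits between the donor-only peak at 0 and the 0.38 peak, and is
exposed as a parameter).  Two robustness measures matter in practice:
a variance floor of 10⁻⁴ (SD 0.01, the efficiency measurement resolution)
prevents degenerate spike components on clipped values, and when molecule
ids are available the component count is selected on per-molecule mean
efficiencies — event-level BIC is wildly anti-conservative because the
hundreds of events from one molecule share its true E and are not
independent.  Even so, a mixture of Gaussians is a misspecified model for
the donor-only population (an atom at 0 plus a half-normal tail, from
clipping), and the fitted component means shift accordingly.  The
quantitative statistic for a labeling site's FRET peak is therefore
`fit_fret_peak`: a truncated-normal maximum-likelihood fit of the events
above the donor-only cut, which is the standard single-Gaussian histogram
fit expressed without binning and is unbiased by the cut.

*QC.*  Molecules with fewer than 10 surviving events are rejected;
kept/rejected counts are reported.

## Dwell-time estimation

Bound dwells are surviving-segment lengths × frame interval; unbound
dwells are the low runs between detected high runs.  Dwells touching the
first or last frame are censored and excluded (censoring fractions
reported; Kaplan–Meier correction was considered and rejected as
unnecessary complexity given per-molecule event counts of ~100).

Three systematic effects of the detection chain are handled explicitly:

1. **Segment-length filter.**  Keeping only ≥4-frame segments
   left-truncates the bound-dwell distribution.  For a discretized
   exponential the recorded frame count is geometric, and the MLE
   "mean of kept dwells − (min_frames − 0.5)·Δ" is exactly unbiased
   (verified against a sampling oracle); the half-frame term is the
   continuity correction between frame counts and continuous time.
2. **Filtered-out events between gaps.**  If unbound dwells were read as
   gaps between *surviving* segments, every discarded 1–3-frame event
   would merge its two flanking unbound dwells; at HD1-like rates ~22% of
   bound events fall under the filter and tau_ub would be overestimated
   by ~30%.  Unbound dwells are therefore split at sub-threshold runs by
   default (the merged-gap reading is available for comparison).
3. **Sub-half-frame episodes.**  Gaps (or bound blips) shorter than about
   half a frame leave no frame below (above) threshold and silently fuse
   their neighbors — a few-percent inflation of both means at fast rates.
   Both dwell means are corrected by inverting
   E[obs] = (tau + q·E[short episode])/(1−q), with q the sub-threshold
   probability of the opposite state, by fixed-point iteration.

Rates follow as k_off = 1/tau_b, k_on = 1/(tau_ub·c), K_d = k_off/k_on
(the identity holds per replicate by construction); replicates are
independent fields of view, summarized as mean ± sample SD.  K_d is
computed per replicate and then averaged — not as the ratio of the
averaged, rounded rates, which differs at the percent level.  A
histogram-based exponential fit is provided for comparison with
plotting-style analyses; the MLE is the default because it needs no
binning choices and handles truncation exactly.

## Flow-cell transport model

The cylindrical measurement chamber (height H = 0.64 mm, diameter
L = 11.1 mm) is reduced to a 2-D slice with effective width W = π/4·L, so
W·H equals the mean cross-section of the cylinder; the 1-mm inlet/outlet
bores are not resolved and the inlet condition is applied across the full
height.  Flow is prescribed plane Poiseuille, u(y) = 6U(y/H)(1−y/H) with
U = Q/(W·H) — no Navier–Stokes solve, matching the laminar, low-Reynolds
regime.  Analyte transport is ∂c/∂t + u∂c/∂x = D∇²c with D =
8.76×10⁻¹¹ m²/s (thrombin in water); the sensor floor carries Langmuir
kinetics dB/dt = k_on·c_wall·(Γ_max − B) − k_off·B with Γ_max =
2.3×10⁻⁷ mol/m².  Schedule: analyte at c_in for t_assoc = 100 s, then
buffer until t_end = 300 s.

**Numerics.**  Cell-centered finite volumes; first-order upwind advection
and central diffusion; backward Euler in time.  The y-grid is refined
geometrically toward the sensor (first cell ≈ 2 µm); default 256×64 cells,
dt = 0.05 s.  Velocities enter as exact cell averages of the parabola so
the discrete through-flux equals Q identically.  Lie splitting separates
transport (a constant operator, factorized once per run with sparse LU)
from surface exchange, which is solved per step and per floor cell as a
scalar monotone backward-Euler update by bisection — unconditionally
robust although the uptake rate constant k_on·Γ_max/h reaches ~10⁷ s⁻¹.
The scheme is an M-matrix plus a bounded exchange, so 0 ≤ c ≤ c_in and
0 ≤ B ≤ Γ_max hold to solver precision.  A running ledger (inflow,
outflow, bulk, surface, desorbed) is evaluated every step from the same
discrete fluxes as the solve; its relative residual is ~10⁻¹⁴ and a
breach of 10⁻³ aborts the run.  Refinement studies show the expected
first-order error decay.

**Desorbed analyte.**  With Γ_max = 2.3×10⁻⁷ mol/m², the surface uptake
velocity k_on·Γ_max is 0.2–23 m/s across k_on = 10⁶–10⁸ M⁻¹s⁻¹, while
transport-limited delivery through the depletion layer is ~10⁻⁶ m/s.  If
desorbed analyte re-enters the boundary layer it is recaptured with
near-certainty, making net dissociation transport-limited and effectively
zero on the 300-s scale for any k_off ≤ 1 s⁻¹ — and capture insensitive to
k_off.  Sensor-level behavior in which k_off shapes both the capture rate
and the rinse-phase release — the regime this package is built to explore,
and the one observed in real QCM rinses — corresponds to desorbed analyte
leaving the system (convected away without recapture).  That is the
default (`recapture=False`); the desorbed mass is tracked explicitly in
the ledger, so mass accounting remains exact.  `recapture=True` gives the
fully conservative two-way coupling; it is the mode validated against the
closed-form well-mixed Langmuir limit (agreement within 1%, checked
against an independent stiff ODE integration), and the mode of choice when
surface densities are low enough for rebinding to be weak.  The difference
between the modes is itself informative: it quantifies how strongly
rebinding masks intrinsic dissociation at high ligand density.

Derived metrics: capture rate (least-squares slope of B(t) over a window,
default the 5-min evaluation window), time-to-level onset times, release
fraction, and sensitivity (slope of capture rate vs concentration over a
series of runs).  Sweeps over flow (20–60 µl/min), concentration
(0.3–17 nM), k_on (10⁶–10⁸ M⁻¹s⁻¹) and k_off (0.01–1 s⁻¹) reproduce the
expected transport-limitation phenomenology: onset accelerates with flow;
capture is linear in concentration (R² > 0.99) and flat in k_on (<15%
band); k_off orders peak loading, capture rate and rinse retention, with
≥90% release at k_off = 1 s⁻¹.  With the measured aptamer rate pairs the
predicted sensitivity ranking is NU172 > RE31 > HD1, i.e. the slowest
k_off wins under flow.

## QCM processing

Frequency shifts convert to areal mass via the crystal sensitivity
constant C = 17.7 ng Hz⁻¹ cm⁻² (Δm = −C·Δf; 5 MHz AT-cut crystal);
dissipation/viscoelastic effects are out of scope.  Noise filtering is a
100-point centered moving average (edge-normalized); baseline is the mean
over a marked pre-capture interval.  Capture slopes follow the windowed
procedure: 30-s means just before onset and at onset + 5 min, differenced
per minute — invariant to any constant offset.  Onset is user-annotated by
default, with an optional 3-sigma-drop detector.  Sensitivity is an OLS
fit of capture slope vs concentration over the flagged linear range
(points below it are sub-LOQ).  Dissociation rates are regression slopes
over the first 5 min of rinse normalized by the captured shift; note a
linear fit of an exponential decay over 1.5 time constants reads ~2×
low — it is a trend indicator, as used in instrument practice, not a rate
estimator.  Regeneration recovery is the second-cycle capture shift over
the first, in percent.  The synthesizer inverts Sauerbrey on a simulated
B(t) (thrombin molar mass 36.7 kDa, a configurable literature constant),
adds drift and Gaussian noise, and annotates phases, closing the loop for
end-to-end tests (noiseless round trips agree to 10⁻⁹; slope recovery at
0.1 Hz noise is within 5% at realistic signal scale).

## Problem sizes and reproducibility

Benchmarks run at the assay scale: 300 molecules × 600-s traces (1200 s
for the slow binder NU172 so unbound statistics stay ample), three
replicate ensembles for K_d, 400 molecules for the FRET-peak recovery;
transport checks use the full 256×64 grid for the conservation run and
96×32 for sweeps, which changes trend metrics by well under the margins
tested.  Every stochastic stage draws from numpy `SeedSequence` streams
spawned from a single recorded seed; identical configs reproduce outputs
bit-for-bit, and pipeline manifests record seeds and output checksums.

## Known limitations

- Two intensity states only: no hidden-Markov multi-state kinetics, no
  multi-exponential dwell mixtures (by scope).
- The generator's noise model is simple Gaussian; see above for what that
  excludes.
- The 2-D slice cannot capture 3-D inlet jets or lateral non-uniformity;
  conclusions are about transport-limitation trends, not absolute
  COMSOL-grade fields.
- The GMM is the right classifier for well-separated Gaussian-ish
  populations but a misspecified model for the clipped donor-only
  population; quantitative peak means should come from `fit_fret_peak`.
- Kinetic estimators assume the exponential dwell model they fit; the
  merge corrections assume both dwell distributions are exponential.
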