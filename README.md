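# aptakinetics

Decoding aptamer–protein binding kinetics from single-molecule FRET
traces, and predicting what those kinetics mean for a flow-through
biosensor.

## The problem

Aptamers with near-identical equilibrium affinity (K_d) can behave very
differently as biosensor recognition elements, because the affinity hides
the underlying rate constants: a surface that captures analyte quickly but
lets it go quickly (fast k_on, fast k_off) performs worse under flow than
one that holds on (slow k_off), even at the same K_d.  Single-molecule
FRET assays resolve this: individual target proteins (e.g. thrombin) are
immobilized and transient binding of donor-labeled aptamers (e.g. the
exosite-I binders HD1, RE31, NU172) is recorded as intensity bursts at
0.1-s frames.  The dwell-time statistics of those bursts give the rates
directly:

    k_off = 1 / tau_b        k_on = 1 / (tau_ub * c)        K_d = k_off / k_on

where tau_b and tau_ub are the mean bound and unbound dwell times
(exponential under memoryless two-state kinetics) and c is the aptamer
concentration.  A companion transport simulation — laminar flow through a
QCM (quartz crystal microbalance) cell with Langmuir surface binding,
dB/dt = k_on·c_wall·(Γ_max − B) − k_off·B — then predicts which rate
constants actually limit sensor sensitivity, and QCM signal processing
(Sauerbrey mass conversion, 5-min capture slopes, sensitivity fits,
regeneration recovery) evaluates the prediction.

## What the package provides

| module | contents |
|---|---|
| `aptakinetics.traces` | ground-truthed synthetic smFRET binding traces (alternating-renewal state paths, exact frame integration, acceptor-dark/bleach photophysics, Gaussian camera noise) |
| `aptakinetics.segmentation` | deterministic two-means intensity thresholding, binding-segment detection (>3-frame filter), event FRET (E = I_A/(I_A+I_D)), Gaussian-mixture population classification, truncated-normal peak fits, molecule QC |
| `aptakinetics.kinetics` | dwell-time pooling with censoring, left-truncated exponential MLE, frame-merge corrections, rates and replicate statistics |
| `aptakinetics.transport` | 2-D finite-volume advection–diffusion solver with implicit Langmuir surface exchange, mass-balance ledger, parameter sweeps |
| `aptakinetics.qcm` | Sauerbrey conversion (17.7 ng Hz⁻¹ cm⁻²), smoothing/baseline, capture slopes, sensitivity fits, dissociation and regeneration, QCM trace synthesis |
| `aptakinetics.io` | CSV/HDF5 trace formats, run manifests, YAML-configured pipelines; a thin `aptakinetics` CLI |

All study inputs are synthesized with known ground truth, so every stage is
testable without instrument data.

## Worked example

`examples/01_recover_binding_kinetics.py` simulates a field of view of 300
molecules at the HD1–thrombin rate pair and re-estimates the rates through
the full analysis chain:

```
ground truth : k_off = 0.70 1/s, k_on = 7.00e+07 1/(M s)
recovered    : k_off = 0.700 1/s  (tau_b = 1.429 s, n = 32474 bound dwells)
               k_on  = 7.066e+07 1/(M s)  (tau_ub = 2.830 s, n = 39738 unbound dwells)
               K_d   = 9.91 nM  (= k_off / k_on)
```

The recovered k_off is the inverse of the fitted mean bound dwell after
correcting for the more-than-three-frames segment filter; k_on comes from
the unbound dwells at c = 5 nM; the ratio reproduces the programmed 10 nM
dissociation constant.

`examples/03_flow_cell_sensor.py` shows the transport result that makes
the kinetics matter — capture is transport-limited (insensitive to k_on)
but strongly shaped by k_off:

```
 k_off (1/s)   peak B (mol/m^2)   capture rate  released
        1.00          6.310e-12      6.518e-14     100%
        0.10          6.026e-11      6.383e-13     100%
        0.01          3.417e-10      2.630e-12      69%
```

The other examples cover FRET-population classification (2PCA-like narrow
peak at E = 0.38 vs NHS-like 0.2–0.8 heterogeneity) and QCM sensorgram
evaluation end to end.

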