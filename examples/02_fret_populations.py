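"""FRET-efficiency histograms distinguish labeling chemistries.

Site-specific (N-terminal, 2PCA-style) acceptor labeling puts the dye at
one defined position, so all binding events report a narrow efficiency
peak; amine-directed (NHS-ester) labeling hits random lysines, smearing
the histogram over a broad range.  This script simulates both ensembles,
classifies the event histogram with a Gaussian mixture, and fits the
binding-competent peak with a truncated-normal model that ignores the
donor-only population (events from acceptor-dark molecules, E ~ 0).
"""

import numpy as np

from aptakinetics import (
    TraceSimConfig,
    analyze_trace,
    fit_fret_peak,
    fit_fret_populations,
    qc_filter,
    simulate_ensemble,
)


def event_table(cfg, n_molecules=150):
    traces, _ = simulate_ensemble(cfg, n_molecules)
    kept, _ = qc_filter(analyze_trace(t) for t in traces)
    ids = [s.molecule_id for s in kept for _ in s.segments]
    events = [ev.mean_fret for s in kept for ev in s.segments]
    return ids, np.array(events)


# --- 2PCA-like: narrow peak at 0.38 plus donor-only events ---------------
cfg_2pca = TraceSimConfig(seed=8, fret_mode="fixed_2pca", fret_mean=0.38,
                          fret_sd=0.14, p_acceptor_dark=0.1)
ids, events = event_table(cfg_2pca)
model = fit_fret_populations(events, molecule_ids=ids)
mu, sd = fit_fret_peak(events)
print(f"2PCA-like ensemble: {len(events)} events")
print(f"  donor-only fraction (E < 0.15): {model.donor_only_fraction:.2f}")
print(f"  binding-competent peak: E = {mu:.3f} +/- {sd:.3f} (truncated-normal fit)")

# --- NHS-like: broad heterogeneity 0.2-0.8 -------------------------------
cfg_nhs = TraceSimConfig(seed=9, fret_mode="heterogeneous_nhs",
                         p_acceptor_dark=0.1)
_, events_nhs = event_table(cfg_nhs)
hi = events_nhs[events_nhs >= 0.15]
print(f"\nNHS-like ensemble: {len(events_nhs)} events")
print(f"  non-donor-only spread: {np.percentile(hi, 2):.2f} to "
      f"{np.percentile(hi, 98):.2f} (2nd-98th percentile)")
print()
print("The narrow 0.38 peak pins the aptamer binding site relative to the")
print("protein N terminus; the broad NHS histogram reflects dye-position")
print("heterogeneity, not binding heterogeneity.")
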