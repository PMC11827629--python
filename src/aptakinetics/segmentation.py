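"""Two-state segmentation of binding traces and FRET population analysis.

The detection chain mirrors the standard transient-binding analysis:

1. a deterministic two-means split of the summed donor+acceptor intensity
   gives a per-molecule threshold (midpoint of the two cluster centers);
2. maximal runs of frames above threshold become candidate binding
   segments, and runs shorter than ``min_frames`` (default 4, i.e. "more
   than three consecutive frames") are discarded;
3. each surviving segment's apparent FRET efficiency E = I_A / (I_A + I_D)
   is averaged over its frames on background-subtracted intensities;
4. event-level efficiencies are classified with a Gaussian mixture model
   (component count by BIC), with events below a donor-only cut (default
   E < 0.15) reported as the donor-only population;
5. molecules with fewer than ``min_events`` surviving segments are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.mixture import GaussianMixture

from .traces import FluorescenceTrace

__all__ = [
    "BindingSegment",
    "SegmentedTrace",
    "FretPopulationModel",
    "threshold_total_intensity",
    "segment_trace",
    "estimate_background",
    "event_fret",
    "analyze_trace",
    "fit_fret_populations",
    "qc_filter",
]

DONOR_ONLY_CUT = 0.15


@dataclass(frozen=True)
class BindingSegment:
    """One above-threshold run of frames, half-open span [start, end)."""

    start_frame: int
    end_frame: int
    mean_fret: float = float("nan")

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("segment must span at least one frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame

    @property
    def label(self) -> str:
        if np.isnan(self.mean_fret):
            return "unclassified"
        return "donor_only" if self.mean_fret < DONOR_ONLY_CUT else "fret_event"


@dataclass(frozen=True)
class SegmentedTrace:
    molecule_id: str
    threshold: float | None  # None: no binding detected (degenerate threshold)
    segments: tuple[BindingSegment, ...]
    subthreshold_runs: tuple[tuple[int, int], ...]  # high runs < min_frames
    n_frames_total: int

    def __post_init__(self) -> None:
        starts = [s.start_frame for s in self.segments]
        if starts != sorted(starts):
            raise ValueError("segments must be ordered")
        ends = [s.end_frame for s in self.segments]
        if any(e > s for s, e in zip(starts[1:], ends[:-1])):
            raise ValueError("segments must not overlap")

    @property
    def n_events(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class FretPopulationModel:
    """Gaussian mixture over event-level FRET efficiencies, sorted by mean."""

    components: tuple[tuple[float, float, float], ...]  # (weight, mean, sd)
    n_events_used: int
    donor_only_cut: float = DONOR_ONLY_CUT
    donor_only_fraction: float = 0.0

    def __post_init__(self) -> None:
        w = np.array([c[0] for c in self.components])
        if np.any(w <= 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("component weights must be positive and sum to 1")
        if any(c[2] <= 0 for c in self.components):
            raise ValueError("component sds must be positive")

    def primary_component(self) -> tuple[float, float, float]:
        """Highest-weight component whose mean lies above the donor-only cut."""
        cands = [c for c in self.components if c[1] >= self.donor_only_cut]
        if not cands:
            raise ValueError("no component above the donor-only cut")
        return max(cands, key=lambda c: c[0])


def threshold_total_intensity(trace: FluorescenceTrace) -> float | None:
    """Two-means intensity threshold on the summed donor+acceptor signal.

    A deterministic 1-D two-means: centers start at the 10th and 90th
    percentiles of the summed signal and assignments are iterated until
    stable.  Returns the midpoint of the converged centers, or None when
    the split is degenerate, which callers treat as "no binding detected".

    Degeneracy is judged against the within-cluster noise scale (the MAD
    of the residuals to the assigned centers, normal-consistent): centers
    closer than 3x that scale mean the split only partitions noise.  A
    whole-signal MAD would misfire here, because a genuine two-state trace
    spending half its time bound has a signal MAD comparable to the level
    separation itself.
    """
    s = trace.total
    if len(s) < 10:
        raise ValueError("trace too short to threshold (need >= 10 frames)")
    lo, hi = np.percentile(s, [10.0, 90.0])
    if hi <= lo:  # constant (or near-constant) signal
        return None
    assign = s > (lo + hi) / 2.0
    for _ in range(100):
        if assign.all() or not assign.any():
            break
        lo = s[~assign].mean()
        hi = s[assign].mean()
        new = s > (lo + hi) / 2.0
        if np.array_equal(new, assign):
            break
        assign = new
    if assign.all() or not assign.any():
        return None
    resid = np.where(assign, s - hi, s - lo)
    noise = 1.4826 * np.median(np.abs(resid))
    if abs(hi - lo) < 3.0 * noise:
        return None
    return float((lo + hi) / 2.0)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) spans of True runs."""
    padded = np.diff(np.concatenate([[0], mask.astype(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def segment_trace(
    trace: FluorescenceTrace,
    threshold: float | None,
    min_frames: int = 4,
) -> SegmentedTrace:
    """Split a trace into above-threshold binding segments.

    Runs shorter than ``min_frames`` are discarded (not merged) but kept as
    ``subthreshold_runs`` so dwell extraction can account for them.  With
    ``threshold=None`` the molecule is event-free.
    """
    if threshold is None:
        return SegmentedTrace(trace.molecule_id, None, (), (), trace.n_frames)
    high = trace.total > threshold
    kept, short = [], []
    for start, end in _runs(high):
        if end - start >= min_frames:
            kept.append(BindingSegment(start, end))
        else:
            short.append((start, end))
    return SegmentedTrace(
        trace.molecule_id, float(threshold), tuple(kept), tuple(short), trace.n_frames
    )


def estimate_background(
    trace: FluorescenceTrace, threshold: float | None
) -> tuple[float, float]:
    """Per-channel background: median intensity of frames below threshold."""
    if threshold is None:
        mask = np.ones(trace.n_frames, dtype=bool)
    else:
        mask = trace.total <= threshold
    if not mask.any():
        return 0.0, 0.0
    return float(np.median(trace.donor[mask])), float(np.median(trace.acceptor[mask]))


def event_fret(
    trace: FluorescenceTrace,
    segment: BindingSegment,
    background: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Mean apparent FRET efficiency E = I_A/(I_A+I_D) over a segment.

    Intensities are background-subtracted per channel; frames whose summed
    intensity is not positive are excluded; the average is clipped to [0, 1].
    """
    if segment.start_frame < 0 or segment.end_frame > trace.n_frames:
        raise ValueError("segment outside trace bounds")
    sl = slice(segment.start_frame, segment.end_frame)
    d = trace.donor[sl] - background[0]
    a = trace.acceptor[sl] - background[1]
    tot = d + a
    ok = tot > 0
    if not ok.any():
        raise ValueError("no frame in segment has positive total intensity")
    e = a[ok] / tot[ok]
    return float(np.clip(np.mean(e), 0.0, 1.0))


def analyze_trace(
    trace: FluorescenceTrace,
    min_frames: int = 4,
    threshold: float | None = ...,
) -> SegmentedTrace:
    """Threshold, segment, and compute per-segment FRET for one trace."""
    if threshold is ...:
        threshold = threshold_total_intensity(trace)
    seg = segment_trace(trace, threshold, min_frames)
    if not seg.segments:
        return seg
    bg = estimate_background(trace, seg.threshold)
    segments = tuple(
        BindingSegment(s.start_frame, s.end_frame, event_fret(trace, s, bg))
        for s in seg.segments
    )
    return SegmentedTrace(
        seg.molecule_id, seg.threshold, segments, seg.subthreshold_runs,
        seg.n_frames_total,
    )


# variance floor at the efficiency measurement resolution (sd ~0.01),
# preventing degenerate spike components on clipped E values
_REG_COVAR = 1e-4


def _fit_gmm(x: np.ndarray, k: int, random_state: int) -> GaussianMixture:
    """Best of random-init EM runs and a quantile-based deterministic init.

    One-dimensional EM is prone to poor local optima when a narrow
    population sits beside a broad one; seeding one run with quantile
    means makes the fit reliable.
    """
    gm = GaussianMixture(
        n_components=k, n_init=5, random_state=random_state, reg_covar=_REG_COVAR
    ).fit(x)
    q = np.quantile(x.ravel(), (np.arange(k) + 0.5) / k).reshape(-1, 1)
    gm_q = GaussianMixture(
        n_components=k, means_init=q, random_state=random_state,
        reg_covar=_REG_COVAR,
    ).fit(x)
    return gm_q if gm_q.lower_bound_ > gm.lower_bound_ else gm


def _bic_component_count(
    x: np.ndarray, max_components: int, random_state: int
) -> int:
    best_k, best_bic = 1, np.inf
    for k in range(1, max_components + 1):
        if k > max(len(x) // 2, 1):
            break
        bic = _fit_gmm(x, k, random_state).bic(x)
        if bic < best_bic:
            best_k, best_bic = k, bic
    return best_k


def fit_fret_populations(
    events: Sequence[float],
    max_components: int = 3,
    donor_only_cut: float = DONOR_ONLY_CUT,
    random_state: int = 0,
    molecule_ids: Sequence[str] | None = None,
) -> FretPopulationModel:
    """Classify event FRET efficiencies with a BIC-selected Gaussian mixture.

    Fits 1..max_components and keeps the component count with the lowest
    BIC.  Event efficiencies from one molecule are strongly correlated
    (they share that molecule's true FRET), which makes an event-level BIC
    overfit badly when molecules contribute many events each; when
    ``molecule_ids`` are supplied, the component count is therefore chosen
    on per-molecule mean efficiencies (approximately independent units) and
    the mixture parameters are then fitted on all events.  Components are
    reported sorted by mean; the share of events below ``donor_only_cut``
    is reported as the donor-only fraction.
    """
    e = np.asarray(events, dtype=float)
    if len(e) < 20:
        raise ValueError(f"need >= 20 events to fit populations, got {len(e)}")
    x = e.reshape(-1, 1)
    if molecule_ids is not None:
        ids = np.asarray(molecule_ids)
        if len(ids) != len(e):
            raise ValueError("molecule_ids must match events one-to-one")
        mol_means = np.array([e[ids == m].mean() for m in np.unique(ids)])
        k_sel = _bic_component_count(mol_means.reshape(-1, 1), max_components,
                                     random_state)
    else:
        k_sel = _bic_component_count(x, max_components, random_state)
    best = _fit_gmm(x, k_sel, random_state)
    order = np.argsort(best.means_.ravel())
    comps = tuple(
        (
            float(best.weights_[i]),
            float(best.means_[i, 0]),
            float(np.sqrt(best.covariances_[i].ravel()[0])),
        )
        for i in order
    )
    return FretPopulationModel(
        comps, len(e), donor_only_cut, float(np.mean(e < donor_only_cut))
    )


def fit_fret_peak(
    events: Sequence[float],
    donor_only_cut: float = DONOR_ONLY_CUT,
) -> tuple[float, float]:
    """Gaussian fit of the binding-competent FRET peak, (mean, sd).

    The donor-only population (absent or bleached acceptors) piles up
    below ``donor_only_cut`` and is an atom-plus-tail shape rather than a
    Gaussian, so the peak of interest is fitted as a normal distribution
    left-truncated at the cut: the maximum-likelihood (mu, sigma) of the
    events with E >= cut under a truncated-normal model.  This is the
    single-peak histogram fit used to quote a labeling site's mean FRET
    efficiency, and unlike a raw above-cut sample mean it is not biased by
    the truncation.
    """
    e = np.asarray(events, dtype=float)
    e = e[e >= donor_only_cut]
    if len(e) < 20:
        raise ValueError("need >= 20 events above the donor-only cut")

    from scipy.optimize import minimize
    from scipy.stats import norm

    def nll(params: np.ndarray) -> float:
        mu, log_sd = params
        sd = np.exp(log_sd)
        z = (donor_only_cut - mu) / sd
        # log of the normalizer P(X >= cut); sf is stable for z < 0 too
        log_tail = norm.logsf(z)
        return float(
            -np.sum(norm.logpdf(e, mu, sd)) + len(e) * log_tail
        )

    x0 = np.array([np.mean(e), np.log(max(np.std(e), 1e-3))])
    res = minimize(nll, x0, method="Nelder-Mead", options={"xatol": 1e-6})
    mu, sd = float(res.x[0]), float(np.exp(res.x[1]))
    return mu, sd


def qc_filter(
    segmented: Iterable[SegmentedTrace], min_events: int = 10
) -> tuple[list[SegmentedTrace], dict[str, int]]:
    """Drop molecules with fewer than ``min_events`` surviving segments."""
    kept, rejected = [], 0
    for seg in segmented:
        if seg.n_events >= min_events:
            kept.append(seg)
        else:
            rejected += 1
    return kept, {"kept": len(kept), "rejected": rejected}
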