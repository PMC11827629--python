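"""Synthetic single-molecule FRET binding traces with known ground truth.

Surface-immobilized protein targets are probed by transient binding of
donor-labeled aptamers.  Each molecule alternates between an unbound and a
bound state (an alternating renewal process with exponential dwell times:
unbound dwells at rate ``k_on * c``, bound dwells at rate ``k_off``).  A
camera integrates donor and acceptor photons over fixed frame intervals
(0.1 s by default), so a rendered trace reports, per frame, the fraction of
the frame spent bound, split between the two channels by the molecule's
FRET efficiency.

Acceptor photophysics is emulated so the donor-only population seen in real
histograms appears in synthetic data: a fraction of molecules carry no
active acceptor at all, and acceptors may bleach irreversibly at an
exponential time, after which binding events emit in the donor channel only
(apparent FRET efficiency 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal, Sequence

import numpy as np

__all__ = [
    "StatePath",
    "TraceSimConfig",
    "FluorescenceTrace",
    "MoleculeTruth",
    "GroundTruth",
    "simulate_state_path",
    "render_trace",
    "simulate_ensemble",
]


@dataclass(frozen=True)
class StatePath:
    """Alternating bound/unbound intervals covering [0, duration).

    ``states`` holds one boolean per interval (True = bound); ``edges`` has
    one more entry than ``states``, with ``edges[0] == 0`` and
    ``edges[-1] == duration``.  Intervals are contiguous and alternate.
    """

    states: np.ndarray  # bool, shape (n_intervals,)
    edges: np.ndarray  # float seconds, shape (n_intervals + 1,)

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=bool)
        edges = np.asarray(self.edges, dtype=float)
        object.__setattr__(self, "states", states)
        object.__setattr__(self, "edges", edges)
        if edges.ndim != 1 or states.ndim != 1 or len(edges) != len(states) + 1:
            raise ValueError("edges must have exactly one more entry than states")
        if len(states) == 0:
            raise ValueError("state path needs at least one interval")
        if edges[0] != 0.0:
            raise ValueError("first interval must start at t=0")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("interval lengths must be positive")
        if len(states) > 1 and np.any(states[1:] == states[:-1]):
            raise ValueError("consecutive intervals must alternate state")

    @property
    def duration(self) -> float:
        return float(self.edges[-1])

    def intervals(self) -> Iterator[tuple[bool, float, float]]:
        for s, t0, t1 in zip(self.states, self.edges[:-1], self.edges[1:]):
            yield bool(s), float(t0), float(t1)

    def bound_occupancy(self, times: np.ndarray) -> np.ndarray:
        """Cumulative bound time evaluated at ``times`` (piecewise linear)."""
        lengths = np.diff(self.edges) * self.states
        cum = np.concatenate([[0.0], np.cumsum(lengths)])
        return np.interp(times, self.edges, cum)

    def frame_occupancy(self, n_frames: int, frame_interval: float) -> np.ndarray:
        """Fraction of each frame spent bound, from exact interval overlap."""
        t = np.arange(n_frames + 1) * frame_interval
        cum = self.bound_occupancy(t)
        return np.diff(cum) / frame_interval


@dataclass(frozen=True)
class TraceSimConfig:
    """Parameters of one simulated field of view.

    Rates follow the two-state binding scheme: the unbound->bound rate is
    ``k_on * c`` (pseudo-first-order at aptamer concentration ``c``), the
    bound->unbound rate is ``k_off``.  Defaults mirror typical assay
    conditions: 5 nM labeled aptamer, 0.1-s camera frames, 600-s movies.
    """

    k_on: float = 0.7e8  # M^-1 s^-1
    c: float = 5e-9  # M
    k_off: float = 0.7  # s^-1
    frame_interval: float = 0.1  # s
    n_frames: int = 6000
    fret_mode: Literal["fixed_2pca", "heterogeneous_nhs"] = "fixed_2pca"
    fret_mean: float = 0.38
    fret_sd: float = 0.14
    total_intensity: float = 1000.0
    background_mean: float = 100.0
    noise_sd: float = 100.0
    p_acceptor_dark: float = 0.1
    acceptor_bleach_rate: float = 0.0  # s^-1, 0 disables bleaching
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k_on, self.c, self.k_off) < 0:
            raise ValueError("rates and concentration must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 <= self.fret_mean <= 1.0:
            raise ValueError("fret_mean must lie in [0, 1]")
        if not 0.0 <= self.p_acceptor_dark <= 1.0:
            raise ValueError("p_acceptor_dark must lie in [0, 1]")
        if self.total_intensity < 0 or self.background_mean < 0 or self.noise_sd < 0:
            raise ValueError("intensities must be non-negative")
        if self.acceptor_bleach_rate < 0:
            raise ValueError("acceptor_bleach_rate must be non-negative")

    @property
    def duration(self) -> float:
        return self.n_frames * self.frame_interval


@dataclass(frozen=True)
class FluorescenceTrace:
    """One molecule's donor/acceptor intensity series at fixed frame interval."""

    molecule_id: str
    frame_interval: float
    donor: np.ndarray
    acceptor: np.ndarray

    def __post_init__(self) -> None:
        donor = np.asarray(self.donor, dtype=float)
        acceptor = np.asarray(self.acceptor, dtype=float)
        object.__setattr__(self, "donor", donor)
        object.__setattr__(self, "acceptor", acceptor)
        if donor.shape != acceptor.shape or donor.ndim != 1:
            raise ValueError("donor and acceptor must be 1-D arrays of equal length")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.donor)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor


@dataclass(frozen=True)
class MoleculeTruth:
    molecule_id: str
    path: StatePath
    fret: float
    acceptor_dark: bool
    bleach_time: float  # s; inf if the acceptor never bleaches


@dataclass(frozen=True)
class GroundTruth:
    """Per-molecule hidden state for a simulated ensemble."""

    config: TraceSimConfig
    molecules: tuple[MoleculeTruth, ...]

    def __getitem__(self, molecule_id: str) -> MoleculeTruth:
        for m in self.molecules:
            if m.molecule_id == molecule_id:
                return m
        raise KeyError(molecule_id)


def simulate_state_path(
    k_on: float,
    c: float,
    k_off: float,
    duration: float,
    rng: np.random.Generator,
) -> StatePath:
    """Draw one alternating-renewal bound/unbound path truncated at ``duration``.

    The initial state is Bernoulli with the stationary bound probability
    ``k_on*c / (k_on*c + k_off)``; the first and last dwells are therefore
    censored at analysis time and the choice cannot bias dwell estimates.
    A zero rate makes the corresponding state absorbing.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if min(k_on, c, k_off) < 0:
        raise ValueError("rates must be non-negative")
    rate_bind = k_on * c
    total = rate_bind + k_off
    if total == 0:
        raise ValueError(
            "k_on*c and k_off are both zero: stationary initial state undefined"
        )
    bound = bool(rng.random() < rate_bind / total)

    states: list[bool] = []
    edges: list[float] = [0.0]
    t = 0.0
    while t < duration:
        rate = k_off if bound else rate_bind
        dwell = math.inf if rate == 0 else rng.exponential(1.0 / rate)
        t = min(t + dwell, duration)
        states.append(bound)
        edges.append(t)
        bound = not bound
    return StatePath(np.array(states, dtype=bool), np.array(edges))


def render_trace(
    path: StatePath,
    config: TraceSimConfig,
    rng: np.random.Generator,
    *,
    molecule_id: str = "mol",
    fret: float | None = None,
    acceptor_dark: bool = False,
    bleach_time: float = math.inf,
) -> FluorescenceTrace:
    """Integrate a state path into a noisy two-channel camera trace.

    Each frame contributes ``f * total_intensity`` of binding signal, where
    ``f`` is the exact fraction of the frame spent bound; the signal splits
    as ``acceptor = E * f * I`` and ``donor = (1 - E) * f * I``.  The
    apparent efficiency E is the molecule's true FRET unless the acceptor is
    dark or has bleached (frames starting at or after ``bleach_time``), in
    which case E = 0 and the full signal lands in the donor channel.
    Gaussian noise plus a constant background is added per channel.
    """
    n = config.n_frames
    if path.duration + 1e-9 < n * config.frame_interval:
        raise ValueError("state path shorter than the requested number of frames")
    e_mol = config.fret_mean if fret is None else float(fret)
    if not 0.0 <= e_mol <= 1.0:
        raise ValueError("FRET efficiency must lie in [0, 1]")

    f = path.frame_occupancy(n, config.frame_interval)
    frame_starts = np.arange(n) * config.frame_interval
    e_frames = np.full(n, e_mol)
    if acceptor_dark:
        e_frames[:] = 0.0
    else:
        e_frames[frame_starts >= bleach_time] = 0.0

    signal = f * config.total_intensity
    acceptor = e_frames * signal + config.background_mean
    donor = (1.0 - e_frames) * signal + config.background_mean
    if config.noise_sd > 0:
        donor = donor + rng.normal(0.0, config.noise_sd, n)
        acceptor = acceptor + rng.normal(0.0, config.noise_sd, n)
    return FluorescenceTrace(molecule_id, config.frame_interval, donor, acceptor)


def _draw_fret(config: TraceSimConfig, rng: np.random.Generator) -> float:
    if config.fret_mode == "heterogeneous_nhs":
        # positionally random acceptor labeling: broad uniform efficiency
        return float(rng.uniform(0.2, 0.8))
    # site-specific labeling: narrow normal, truncated to the physical range
    while True:
        e = rng.normal(config.fret_mean, config.fret_sd)
        if 0.0 <= e <= 1.0:
            return float(e)


def simulate_ensemble(
    config: TraceSimConfig,
    n_molecules: int,
) -> tuple[list[FluorescenceTrace], GroundTruth]:
    """Simulate a field of view: ``n_molecules`` traces plus their ground truth.

    Reproducible: all randomness derives from ``config.seed`` through one
    spawned stream per molecule, so the output is bit-identical across runs.
    """
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    streams = np.random.SeedSequence(config.seed).spawn(n_molecules)
    traces: list[FluorescenceTrace] = []
    records: list[MoleculeTruth] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        mol_id = f"mol{i:04d}"
        path = simulate_state_path(
            config.k_on, config.c, config.k_off, config.duration, rng
        )
        e_mol = _draw_fret(config, rng)
        dark = bool(rng.random() < config.p_acceptor_dark)
        if config.acceptor_bleach_rate > 0:
            bleach = float(rng.exponential(1.0 / config.acceptor_bleach_rate))
        else:
            bleach = math.inf
        traces.append(
            render_trace(
                path,
                config,
                rng,
                molecule_id=mol_id,
                fret=e_mol,
                acceptor_dark=dark,
                bleach_time=bleach,
            )
        )
        records.append(MoleculeTruth(mol_id, path, e_mol, dark, bleach))
    return traces, GroundTruth(config, tuple(records))
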