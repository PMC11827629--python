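"""File formats, run manifests, and pipeline assembly.

Trace ensembles are exchanged as one CSV per molecule (columns ``frame,
donor, acceptor``) plus a JSON manifest recording the simulation config and
seed; an equivalent single-container HDF5 layout
(``/molecules/<id>/donor``, ``.../acceptor``, attribute ``frame_interval``)
is also supported.  Ground truth travels as two CSVs: the per-molecule
truth table and the interval table ``(molecule_id, state, start_s, end_s)``.

``run_pipeline`` chains simulate -> analyze -> kinetics (and, or instead,
sensor -> qcm) from a single config mapping and writes a RunManifest so any
run can be reproduced bit-for-bit from its recorded seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from . import kinetics as kin
from . import segmentation as seg
from . import transport as tr
from . import qcm as qcmmod
from .traces import FluorescenceTrace, GroundTruth, TraceSimConfig, simulate_ensemble

__all__ = [
    "SchemaError",
    "RunManifest",
    "write_ensemble",
    "read_traces",
    "write_ensemble_h5",
    "read_traces_h5",
    "events_table",
    "load_config",
    "run_pipeline",
]


class SchemaError(ValueError):
    """A file does not conform to the documented schema."""


@dataclass
class RunManifest:
    config: dict[str, Any]
    seeds: dict[str, int]
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def save(self, path: Path | str) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def load(cls, path: Path | str) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_ensemble(
    out_dir: Path | str,
    traces: Iterable[FluorescenceTrace],
    truth: GroundTruth | None = None,
    config: TraceSimConfig | None = None,
) -> Path:
    """Write one CSV per molecule plus manifest and optional ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame_interval = None
    for trace in traces:
        frame_interval = trace.frame_interval
        pd.DataFrame(
            {
                "frame": np.arange(trace.n_frames),
                "donor": trace.donor,
                "acceptor": trace.acceptor,
            }
        ).to_csv(out / f"{trace.molecule_id}.csv", index=False)
    manifest = {
        "format": "aptakinetics-traces-v1",
        "frame_interval": frame_interval,
        "config": dataclasses.asdict(config) if config else None,
        "seed": config.seed if config else None,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if truth is not None:
        rows = []
        mol_rows = []
        for m in truth.molecules:
            mol_rows.append(
                {
                    "molecule_id": m.molecule_id,
                    "fret": m.fret,
                    "acceptor_dark": m.acceptor_dark,
                    "bleach_time_s": m.bleach_time,
                }
            )
            for state, t0, t1 in m.path.intervals():
                rows.append(
                    {
                        "molecule_id": m.molecule_id,
                        "state": "bound" if state else "unbound",
                        "start_s": t0,
                        "end_s": t1,
                    }
                )
        pd.DataFrame(rows).to_csv(out / "ground_truth_intervals.csv", index=False)
        pd.DataFrame(mol_rows).to_csv(out / "ground_truth_molecules.csv", index=False)
    return out


def read_traces(in_dir: Path | str) -> tuple[list[FluorescenceTrace], dict]:
    """Read a trace ensemble directory written by :func:`write_ensemble`."""
    d = Path(in_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise SchemaError(f"missing manifest.json in {d}")
    manifest = json.loads(manifest_path.read_text())
    frame_interval = manifest.get("frame_interval")
    if not frame_interval or frame_interval <= 0:
        raise SchemaError("manifest must record a positive frame_interval")
    traces = []
    files = sorted(p for p in d.glob("*.csv") if not p.name.startswith("ground_truth"))
    for path in files:
        df = pd.read_csv(path)
        for col in ("frame", "donor", "acceptor"):
            if col not in df.columns:
                raise SchemaError(f"{path.name}: missing column '{col}'")
        frames = df["frame"].to_numpy()
        if np.any(np.diff(frames) <= 0):
            bad = int(np.flatnonzero(np.diff(frames) <= 0)[0]) + 2
            raise SchemaError(f"{path.name}: non-monotone frame index at line {bad}")
        traces.append(
            FluorescenceTrace(
                path.stem, frame_interval,
                df["donor"].to_numpy(float), df["acceptor"].to_numpy(float),
            )
        )
    return traces, manifest


def write_ensemble_h5(
    path: Path | str, traces: Iterable[FluorescenceTrace]
) -> Path:
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        grp = f.create_group("molecules")
        for trace in traces:
            g = grp.create_group(trace.molecule_id)
            g.create_dataset("donor", data=trace.donor)
            g.create_dataset("acceptor", data=trace.acceptor)
            g.attrs["frame_interval"] = trace.frame_interval
    return path


def read_traces_h5(path: Path | str) -> list[FluorescenceTrace]:
    import h5py

    traces = []
    with h5py.File(path, "r") as f:
        for mol_id, g in f["molecules"].items():
            traces.append(
                FluorescenceTrace(
                    mol_id, float(g.attrs["frame_interval"]),
                    g["donor"][...], g["acceptor"][...],
                )
            )
    return traces


def events_table(
    segmented: Iterable[seg.SegmentedTrace], frame_interval: float
) -> pd.DataFrame:
    """Flatten segmented traces into the events CSV schema."""
    rows = []
    for s in segmented:
        for ev in s.segments:
            rows.append(
                {
                    "molecule_id": s.molecule_id,
                    "start_frame": ev.start_frame,
                    "end_frame": ev.end_frame,
                    "duration_s": ev.n_frames * frame_interval,
                    "mean_fret": ev.mean_fret,
                    "label": ev.label,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "molecule_id", "start_frame", "end_frame", "duration_s",
            "mean_fret", "label",
        ],
    )


def load_config(path: Path | str) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def _validate_sim_config(cfg: dict) -> TraceSimConfig:
    try:
        return TraceSimConfig(**cfg)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid simulate config: {exc}") from exc


def run_pipeline(config: dict, out_dir: Path | str) -> RunManifest:
    """Execute the configured stages and write a manifest.

    Recognized top-level keys: ``simulate`` (TraceSimConfig fields plus
    ``n_molecules``), ``analyze`` (min_frames, donor_only_cut, min_events),
    ``kinetics`` (concentration_nM, min_n), ``sensor`` (TransportScenario
    fields with unit-suffixed keys), ``qcm`` (noise_sd, drift, molar_mass,
    seed).  Config is validated before any stage runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config, seeds={})

    sim_cfg = None
    if "simulate" in config:
        c = dict(config["simulate"])
        n_molecules = int(c.pop("n_molecules", 100))
        sim_cfg = _validate_sim_config(c)
    sensor_cfg = dict(config.get("sensor", {})) if "sensor" in config else None

    traces: list[FluorescenceTrace] | None = None
    if sim_cfg is not None:
        traces, truth = simulate_ensemble(sim_cfg, n_molecules)
        write_ensemble(out / "traces", traces, truth, sim_cfg)
        manifest.seeds["simulate"] = sim_cfg.seed
        manifest.stages.append("simulate")

    segmented = None
    if "analyze" in config:
        if traces is None:
            traces, m = read_traces(config["analyze"]["traces_dir"])
        a = config["analyze"]
        min_frames = int(a.get("min_frames", 4))
        segmented = [seg.analyze_trace(t, min_frames) for t in traces]
        segmented, counts = seg.qc_filter(segmented, int(a.get("min_events", 10)))
        fi = traces[0].frame_interval
        events_table(segmented, fi).to_csv(out / "events.csv", index=False)
        manifest.stages.append("analyze")
        manifest.config.setdefault("_counts", {})["analyze"] = counts

    if "kinetics" in config:
        if segmented is None:
            raise ValueError("kinetics stage requires an analyze stage")
        kcfg = config["kinetics"]
        conc = float(kcfg["concentration_nM"]) * 1e-9
        est = kin.estimate_kinetics(
            segmented, conc, traces[0].frame_interval,
            min_n=int(kcfg.get("min_n", 50)),
        )
        (out / "kinetics.json").write_text(
            json.dumps(
                {
                    "k_off_per_s": est.k_off,
                    "k_on_per_M_s": est.k_on,
                    "K_d_M": est.K_d,
                    "tau_b_s": est.tau_b,
                    "tau_ub_s": est.tau_ub,
                    "n_bound": est.n_bound,
                    "n_unbound": est.n_unbound,
                },
                indent=2,
            )
        )
        manifest.stages.append("kinetics")

    response = None
    if sensor_cfg is not None:
        scen = tr.TransportScenario(
            Q=tr.ul_min_to_m3_s(float(sensor_cfg.get("flow_ul_min", 40.0))),
            c_in=tr.nM_to_M(float(sensor_cfg.get("c_in_nM", 10.0))),
            k_on=float(sensor_cfg.get("kon_M_s", 1e7)),
            k_off=float(sensor_cfg.get("koff_s", 0.1)),
            gamma_max=float(sensor_cfg.get("gamma_max_mol_m2", 2.3e-7)),
            t_assoc=float(sensor_cfg.get("t_assoc_s", 100.0)),
            t_end=float(sensor_cfg.get("t_end_s", 300.0)),
            nx=int(sensor_cfg.get("nx", 128)),
            ny=int(sensor_cfg.get("ny", 48)),
            dt=float(sensor_cfg.get("dt_s", 0.1)),
        )
        response = tr.run_scenario(scen)
        pd.DataFrame(
            {
                "time_s": response.times,
                "B_mol_m2": response.B,
                "residual": response.residual,
            }
        ).to_csv(out / "sensor_response.csv", index=False)
        manifest.stages.append("sensor")

    if "qcm" in config:
        if response is None:
            raise ValueError("qcm stage requires a sensor stage")
        q = config["qcm"]
        qseed = int(q.get("seed", 0))
        trace = qcmmod.synthesize_qcm(
            response,
            molar_mass=float(q.get("molar_mass", qcmmod.THROMBIN_MOLAR_MASS)),
            noise_sd=float(q.get("noise_sd", 0.0)),
            drift=float(q.get("drift_hz_min", 0.0)),
            rng=np.random.default_rng(qseed),
        )
        pd.DataFrame({"time_s": trace.times, "frequency_hz": trace.frequency}).to_csv(
            out / "qcm_trace.csv", index=False
        )
        (out / "qcm_phases.json").write_text(json.dumps(trace.phases, indent=2))
        manifest.seeds["qcm"] = qseed
        manifest.stages.append("qcm")

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "run_manifest.json":
            manifest.outputs[str(p.relative_to(out))] = _sha256(p)
    manifest.save(out / "run_manifest.json")
    return manifest
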