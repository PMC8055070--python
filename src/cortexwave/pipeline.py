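"""End-to-end driver: simulate/load -> preprocess -> flow -> patterns ->
modes -> stats, plus a planted-pattern recovery helper used for
ground-truth validation of the whole chain."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import io as cwio
from . import modes as cwmodes
from . import patterns as cwpatterns
from . import preprocess as cwpre
from . import pvf as cwpvf
from . import stats as cwstats
from . import synthgen
from .config import default_config
from .datatypes import FlowSettings, PhaseMovie, VoltageMovie

log = logging.getLogger("cortexwave")

__all__ = ["movie_from_config", "preprocess_movie", "run_all",
           "recover_pattern_kind"]


def movie_from_config(cfg: Dict) -> VoltageMovie:
    """Build the synthetic movie described by the ``simulate`` config block."""
    sim = cfg["simulate"]
    frame_rate = float(sim["frame_rate"])
    comps = []
    for c in sim["components"]:
        c = dict(c)
        freq = c.pop("freq_hz", None)
        if freq is not None:
            c["angular_frequency"] = synthgen.omega_from_hz(float(freq), frame_rate)
        if "wavevector" in c and c["wavevector"] is not None:
            c["wavevector"] = tuple(c["wavevector"])
        if "center" in c and c["center"] is not None:
            c["center"] = tuple(c["center"])
        comps.append(synthgen.WaveComponentSpec(**c))
    spec = synthgen.MovieSpec(shape=tuple(sim["shape"]), frame_rate=frame_rate,
                              components=comps, noise_sd=float(sim["noise_sd"]),
                              seed=int(cfg["seed"]))
    return synthgen.generate_movie(spec)


def preprocess_movie(movie: VoltageMovie, cfg: Dict) -> PhaseMovie:
    """Coarse-grain (optional), band-pass, artifact-mask, Hilbert phase."""
    if cfg["coarse"]["enabled"]:
        movie = cwpre.coarse_grain(movie, cfg["coarse"]["scale"])
    band = (cfg["band"]["low"], cfg["band"]["high"])
    movie = cwpre.bandpass(movie, band, cfg["cheby"]["attenuation_db"])
    movie = cwpre.mask_artifacts(movie, cfg["artifact"]["k_sd"],
                                 cfg["artifact"]["guard_s"])
    return cwpre.instantaneous_phase(movie, edge_s=1.0 / band[0])


def _flow_settings(cfg: Dict) -> FlowSettings:
    return FlowSettings(**cfg["flow"])


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(cfg: Dict, out_dir, movie: Optional[VoltageMovie] = None) -> Path:
    """Execute every stage, writing intermediates and a run manifest.

    When ``movie`` is None the synthetic movie from the config is used.
    Returns the artifact directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": cfg, "stages": {}, "version": cfg.get("version", "")}

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"][name] = {"start": time.time()}
        return time.time()

    def done(name, files):
        manifest["stages"][name]["seconds"] = time.time() - manifest["stages"][name]["start"]
        manifest["stages"][name]["outputs"] = {
            str(p.name): _checksum(p) for p in files}

    try:
        stage("simulate")
        if movie is None:
            movie = movie_from_config(cfg)
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        cwio.write_movie(sim_dir / "movie.h5", movie,
                         spec_text=yaml.safe_dump(cfg["simulate"]))
        done("simulate", [sim_dir / "movie.h5"])

        stage("preprocess")
        phase = preprocess_movie(movie, cfg)
        pre_dir = out / "preprocess"
        pre_dir.mkdir(exist_ok=True)
        cwio.write_phase(pre_dir / "phase.h5", phase)
        done("preprocess", [pre_dir / "phase.h5"])

        stage("pvf")
        fields = cwpvf.estimate_pvf_series(phase, _flow_settings(cfg))
        if not fields:
            raise RuntimeError("no valid frame pairs after masking")
        pvf_dir = out / "pvf"
        pvf_dir.mkdir(exist_ok=True)
        cwio.write_fields(pvf_dir / "pvf.h5", fields)
        done("pvf", [pvf_dir / "pvf.h5"])

        stage("patterns")
        pcfg = cfg["patterns"]
        summaries = cwpatterns.summarize_frames(fields, pcfg["plane_thresh"],
                                                pcfg["standing_k"])
        points = [cwpatterns.analyze_frame(f, pcfg["ring_agreement"])
                  for f in fields]
        tracks = cwpatterns.track_patterns(points, pcfg["link_tol"])
        pat_dir = out / "patterns"
        pat_dir.mkdir(exist_ok=True)
        rows = []
        for tid, tr in enumerate(tracks):
            for p in tr.points:
                rows.append({"t": p.t, "row": p.location[0], "col": p.location[1],
                             "type": p.type, "subtype": p.subtype, "tau": p.trace,
                             "delta": p.determinant, "index": p.poincare_index,
                             "radius": p.radius, "track_id": tid})
        pd.DataFrame(rows, columns=["t", "row", "col", "type", "subtype", "tau",
                                    "delta", "index", "radius", "track_id"]
                     ).to_csv(pat_dir / "tracks.csv", index=False)
        pd.DataFrame([{"t": s.t, "order_parameter": s.order_parameter,
                       "mean_speed": s.mean_speed,
                       "mean_direction": s.mean_direction, "label": s.label}
                      for s in summaries]).to_csv(pat_dir / "frames.csv",
                                                  index=False)
        done("patterns", [pat_dir / "tracks.csv", pat_dir / "frames.csv"])

        stage("modes")
        modeset = cwmodes.svd_modes(fields, cfg["modes"]["k"])
        mode_dir = out / "modes"
        mode_dir.mkdir(exist_ok=True)
        cwio.write_modes(mode_dir / "modes.h5", modeset)
        summary = pd.DataFrame({
            "mode": np.arange(modeset.n_modes),
            "variance_fraction": modeset.variance_fractions[:modeset.n_modes],
        })
        splits = [cwmodes.direction_split(modeset, m) for m in range(modeset.n_modes)]
        summary["p_dominant"] = [s[0] for s in splits]
        summary["p_opposite"] = [s[1] for s in splits]
        summary.to_csv(mode_dir / "modes.csv", index=False)
        done("modes", [mode_dir / "modes.h5", mode_dir / "modes.csv"])

        stage("stats")
        scfg = cfg["stats"]
        filtered = cwpatterns.filter_tracks(tracks, pcfg["d"], pcfg["r"])
        states = cwstats.direction_states(summaries, scfg["op_thresh"])
        shape = fields[0].shape
        rostral, caudal = cwstats.default_boxes(shape, scfg["box_fraction"])
        scen = cwstats.reversal_scenarios(states, filtered, rostral, caudal)
        maps = cwstats.emergence_probability_map(filtered, shape, len(fields))
        stats_dir = out / "stats"
        stats_dir.mkdir(exist_ok=True)
        scen.to_csv(stats_dir / "reversal_scenarios.csv", index=False)
        for typ, m in maps.items():
            np.savetxt(stats_dir / f"probability_{typ}.txt", m)
        pd.DataFrame({"t": states.frames, "state": states.states,
                      "theta": states.theta,
                      "order_parameter": states.order_parameter}
                     ).to_csv(stats_dir / "direction_states.csv", index=False)
        done("stats", [stats_dir / "reversal_scenarios.csv",
                       stats_dir / "direction_states.csv"])
    except Exception as exc:
        failed = [k for k, v in manifest["stages"].items() if "seconds" not in v]
        name = failed[-1] if failed else "unknown"
        raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return out


def recover_pattern_kind(movie: VoltageMovie, cfg: Optional[Dict] = None,
                         reference_speed: Optional[float] = None,
                         standing_frac: float = 0.2):
    """Classify which single planted pattern dominates a movie.

    Runs the full chain and returns ``(kind, center)`` where ``kind`` is
    one of plane, standing, source, sink, saddle and ``center`` is the
    median location of the dominant singularity track (None for
    plane/standing).  ``reference_speed`` (pixels/frame of a comparable
    travelling wave) anchors the standing decision, which is inherently
    relative: a movie with mean speed below ``standing_frac`` times the
    reference is called standing.
    """
    cfg = cfg or default_config()
    phase = preprocess_movie(movie, cfg)
    fields = cwpvf.estimate_pvf_series(phase, _flow_settings(cfg))
    if not fields:
        raise ValueError("no analysable frames")
    speeds = [cwpatterns.mean_speed(f) for f in fields]
    if reference_speed is not None and np.mean(speeds) < standing_frac * reference_speed:
        return "standing", None
    ops = [cwpatterns.order_parameter(f) if s > 0 else 0.0
           for f, s in zip(fields, speeds)]
    if np.median(ops) >= cfg["patterns"]["plane_thresh"]:
        return "plane", None
    points = [cwpatterns.analyze_frame(f, cfg["patterns"]["ring_agreement"])
              for f in fields]
    tracks = cwpatterns.track_patterns(points, cfg["patterns"]["link_tol"])
    if not tracks:
        return "other", None
    best = max(tracks, key=lambda tr: (tr.duration, tr.min_radius))
    rows = [p.location[0] for p in best.points]
    cols = [p.location[1] for p in best.points]
    return best.type, (float(np.median(rows)), float(np.median(cols)))
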