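"""End-to-end orchestration: counts -> fill -> wavelet -> tide -> patterns.

One configuration mapping drives the whole run; every source of randomness
flows from named seeds, so identical configurations give byte-identical
numeric outputs.  Each stage writes provenance-stamped artifacts under the
configured output directory and appends to a run log (config hash, seeds,
per-stage timing, artifact checksums).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from tidalflux import __version__
from tidalflux.config import merge_config, validate_config
from tidalflux.gapfill import detect_candidate_periods, harmonic_fill, linear_fill, median_fill
from tidalflux.patterns import diel_labels, hour_by_day_matrix, solar_days_for_range, stage_diel_crosstab
from tidalflux.tidal_model import ALL_CONSTITUENTS, constituent_periods, fit_tidal_model, stage_series
from tidalflux.timeseries_io import (
    bin_hourly,
    read_fish_tracks,
    read_hourly_series,
    write_hourly_series,
)
from tidalflux.wavelet import WaveletConfig, log_transform, morlet_cwt, white_noise_significance

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and partial-output manifest."""

    def __init__(self, stage: str, message: str, manifest: list[str]):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
        self.manifest = manifest


def run_pipeline(config: dict | None = None) -> dict:
    """Execute the full analysis described by ``config``; return the manifest.

    Inputs come either from files named in ``paths`` or, when a ``simulate``
    section is present, from the synthetic-data generators (optionally with
    the packaged deployment gap calendar applied).
    """
    cfg = merge_config(config or {})
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid configuration: " + "; ".join(violations))
    out_dir = Path(cfg["paths"]["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    log: dict = {
        "version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seeds": cfg["seeds"],
        "stages": {},
    }

    def _emit(name: str, writer) -> Path:
        path = out_dir / name
        writer(path)
        manifest.append(name)
        return path

    def _stage(name):
        t0 = time.perf_counter()

        def done():
            log["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}

        return done

    # ---- counts -----------------------------------------------------------
    done = _stage("counts")
    try:
        series, directions, truth_slacks = _acquire_inputs(cfg)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError("counts", str(exc), manifest) from exc
    _emit("counts.csv", lambda p: write_hourly_series(series, p))
    done()

    # ---- gap fill ---------------------------------------------------------
    done = _stage("gapfill")
    try:
        gf = cfg["gapfill"]
        if np.isnan(series.values).any():
            if gf["method"] == "median":
                filled, report = median_fill(series), None
            elif gf["method"] == "linear":
                filled, report = linear_fill(series), None
            else:
                if gf["periods"] == "auto":
                    periods = detect_candidate_periods(median_fill(series), gf["max_periods"])
                else:
                    periods = [float(p) for p in str(gf["periods"]).split(",")]
                filled, report = harmonic_fill(
                    series,
                    periods,
                    add_noise=gf["noise"],
                    seed=cfg["seeds"]["gapfill"],
                    min_window_hours=gf["min_window_hours"],
                    max_period_rule=gf["max_period_rule"],
                )
        else:
            filled, report = series.copy(), None
    except Exception as exc:
        raise PipelineError("gapfill", str(exc), manifest) from exc
    _emit("filled.csv", lambda p: write_hourly_series(filled, p))
    if report is not None:
        _emit(
            "fill_report.json",
            lambda p: p.write_text(json.dumps(report.to_dict(), indent=1, default=str)),
        )
    done()

    # ---- wavelet ----------------------------------------------------------
    done = _stage("wavelet")
    try:
        w = cfg["wavelet"]
        wconfig = WaveletConfig(
            omega0=w["omega0"],
            voices_per_octave=w["voices_per_octave"],
            n_sim=w["n_sim"],
            alpha=w["alpha"],
            seed=cfg["seeds"]["wavelet"],
            min_period=w["min_period"],
            max_period=w["max_period"],
        )
        x = log_transform(filled)
        spectrum = morlet_cwt(x, dt=1.0, config=wconfig, start=filled.start)
        spectrum = white_noise_significance(spectrum, float(np.std(x)), wconfig)
    except Exception as exc:
        raise PipelineError("wavelet", str(exc), manifest) from exc
    _emit("power.csv", lambda p: spectrum.to_long_frame("power").to_csv(p, index=False))
    _emit(
        "significance.csv",
        lambda p: spectrum.to_long_frame("significant").to_csv(p, index=False),
    )
    _emit(
        "coi.csv",
        lambda p: pd.DataFrame(
            {"time_hours": spectrum.times, "coi_period_hours": spectrum.coi}
        ).to_csv(p, index=False),
    )
    done()

    # ---- tidal model ------------------------------------------------------
    done = _stage("tide")
    stages = None
    try:
        if directions is not None:
            tide_cfg = cfg["tide"]
            names = ALL_CONSTITUENTS if tide_cfg["constituents"] == "all" else tide_cfg["constituents"]
            model = fit_tidal_model(
                directions, constituent_periods(tuple(names)), seam=tide_cfg["seam"]
            )
            stages = stage_series(
                model, filled.times, slack_halfwidth_minutes=tide_cfg["slack_halfwidth_minutes"]
            )
            _emit(
                "tidal_model.json",
                lambda p: p.write_text(json.dumps(model.to_dict(), indent=1)),
            )
            _emit(
                "stages.csv",
                lambda p: stages.to_frame().assign(
                    time_utc=lambda d: d["time_utc"].map(lambda t: t.isoformat())
                ).to_csv(p, index=False),
            )
    except Exception as exc:
        raise PipelineError("tide", str(exc), manifest) from exc
    done()

    # ---- patterns ---------------------------------------------------------
    done = _stage("patterns")
    try:
        site = cfg["site"]
        matrix, flags = hour_by_day_matrix(filled, utc_offset=site["utc_offset"])
        _emit("hour_by_day.csv", lambda p: matrix.to_csv(p))
        _emit("hour_by_day_flags.csv", lambda p: flags.to_csv(p))
        if stages is not None:
            local = filled.times + pd.Timedelta(hours=site["utc_offset"])
            solar = solar_days_for_range(
                local.min().date(),
                local.max().date(),
                lat=site["lat"],
                lon=site["lon"],
                utc_offset=site["utc_offset"],
            )
            diel = diel_labels(
                solar,
                filled.times,
                crepuscular_halfwidth_hours=cfg["patterns"]["crepuscular_halfwidth_hours"],
                utc_offset=site["utc_offset"],
            )
            crosstab = stage_diel_crosstab(filled, stages, diel)
            _emit("stage_diel_crosstab.csv", lambda p: crosstab.to_csv(p, index=False))
    except Exception as exc:
        raise PipelineError("patterns", str(exc), manifest) from exc
    done()

    log["artifacts"] = {
        name: hashlib.sha256((out_dir / name).read_bytes()).hexdigest() for name in manifest
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
    manifest.append("run_log.json")
    return {"out_dir": str(out_dir), "artifacts": manifest, "log": log}


def _acquire_inputs(cfg: dict):
    """Hourly series plus optional direction samples, from files or simulation."""
    paths = cfg["paths"]
    sim = cfg.get("simulate")
    directions = None
    truth = None
    if paths["counts"] is not None:
        series = read_hourly_series(paths["counts"])
    elif paths["tracks"] is not None:
        tracks, _ = read_fish_tracks(paths["tracks"], min_targets=cfg["thresholds"]["min_targets"])
        times = [t.mean_time for t in tracks]
        start = min(times).floor("h")
        end = max(times).floor("h") + pd.Timedelta(hours=1)
        series, _ = bin_hourly(tracks, start, end)
    elif sim is not None:
        from tidalflux.synthetic_data import (
            CountSimConfig,
            DirectionSimConfig,
            apply_gaps,
            make_deployment_fixture,
            simulate_counts,
            simulate_directions,
        )

        count_cfg = CountSimConfig(seed=cfg["seeds"]["simulate"], **(sim.get("counts") or {}))
        series = simulate_counts(count_cfg)
        if sim.get("deployment_gaps", False):
            span, layout = make_deployment_fixture()
            series = apply_gaps(series, layout)
        if sim.get("directions") is not None or sim.get("with_directions", False):
            dir_cfg = DirectionSimConfig(
                seed=cfg["seeds"]["simulate"] + 1, **(sim.get("directions") or {})
            )
            directions, truth = simulate_directions(dir_cfg)
    else:
        raise ValueError("no input: set paths.counts, paths.tracks, or a simulate section")
    if paths["directions"] is not None:
        from tidalflux.tidal_model import DirectionSample

        df = pd.read_csv(paths["directions"])
        directions = [
            DirectionSample(pd.Timestamp(t), float(h) % 360.0)
            for t, h in zip(pd.to_datetime(df["time_utc"], utc=True), df["heading_deg"])
        ]
    return series, directions, truth
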