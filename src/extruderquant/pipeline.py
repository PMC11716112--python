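"""Run orchestration: configuration, manifests and stage plumbing.

A run is described by a flat YAML/dict config naming the stages to execute
and their parameters; outputs land in a run directory together with a JSON
manifest recording package version, seeds, input digests and per-stage
status. Completed-stage outputs are retained when a later stage fails.

All default physical constants live in ``DEFAULTS``.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field
from importlib.metadata import version as _pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fcs, frap, occupancy, spotbleach, synth, traces

__all__ = ["DEFAULTS", "RunConfig", "run_pipeline", "validate_fixtures"]

#: single documented table of the package's default constants.
DEFAULTS = {
    "genome_total_mb": 15_800.0,      # 2 x 7.9 Gb hypotriploid HeLa content
    "map_contact_threshold_nm": 120.0,
    "trace_contact_threshold_nm": 100.0,
    "frap_gap_px": 14,
    "spot_bleach_window_s": 0.5,
    "sted_pixel_nm": 18.88,
    "sted_blur_sigma_px": 2.6,
    "sted_gain": 6.0,
    "sted_undercount_correction": 1.67,
    "sted_z_depth_um": 0.5,
    "qc_min_positions": 20,
    "extrusion_rate_kb_s": 1.0,
}


@dataclass
class RunConfig:
    """Validated run configuration.

    ``stages`` maps stage names to parameter dicts; every stochastic stage
    must carry an explicit seed (enforced at validation).
    """

    stages: dict[str, dict] = field(default_factory=dict)
    seed: int | None = None
    out_dir: str = "run"

    _KNOWN = {"simulate", "occupancy", "validate_tables", "fcs_fit", "frap",
              "spotbleach", "traces"}
    _STOCHASTIC = {"simulate"}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        config = cls(
            stages=raw.get("stages", {}) or {},
            seed=raw.get("seed"),
            out_dir=raw.get("out_dir", "run"),
        )
        config.validate()
        return config

    def validate(self) -> None:
        unknown = set(self.stages) - self._KNOWN
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for name in self._STOCHASTIC & set(self.stages):
            if self.seed is None and "seed" not in (self.stages[name] or {}):
                raise ValueError(f"stochastic stage {name!r} requires a seed")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _stage_occupancy(params: dict, out: Path, manifest: dict) -> None:
    table_path = params.get("table")
    table = occupancy.load_measurement_table(table_path)
    if table_path:
        manifest["inputs"][str(table_path)] = _digest(Path(table_path))
    derived = occupancy.derive_occupancy_table(table, params.get("convention"))
    derived.to_csv(out / "occupancy_derived.csv", index=False)


def _stage_validate_tables(params: dict, out: Path, manifest: dict) -> None:
    report = validate_fixtures(params.get("table"))
    report.to_csv(out / "table_validation.csv", index=False)


def _stage_fcs_fit(params: dict, out: Path, manifest: dict) -> None:
    path = Path(params["acf"])
    manifest["inputs"][str(path)] = _digest(path)
    df = pd.read_csv(path)
    curve = fcs.AutocorrelationCurve(df["lag_s"].to_numpy(), df["g"].to_numpy())
    fit = fcs.fit_diffusion(curve, params.get("kappa_fixed", 5.0))
    result = {"n_particles": fit.n_particles, "tau_d_s": fit.tau_d_s,
              "kappa": fit.kappa, "offset": fit.offset}
    if "dye_diffusion_um2_s" in params:
        vol = fcs.effective_volume(fit.tau_d_s, params["dye_diffusion_um2_s"], fit.kappa)
        result["v_eff_fl"] = vol.v_eff_fl
        result["concentration_nm"] = fcs.concentration_from_fcs(fit, vol)
    (out / "fcs_fit.json").write_text(json.dumps(result, indent=2))


def _stage_frap(params: dict, out: Path, manifest: dict) -> None:
    path = Path(params["curve"])
    manifest["inputs"][str(path)] = _digest(path)
    df = pd.read_csv(path)
    curve = frap.RecoveryCurve(
        t_s=df["t_s"].to_numpy(), f_unbleached=df["f_ub"].to_numpy(),
        f_bleached=df["f_b"].to_numpy(),
    )
    fit = frap.fit_recovery(curve.d, curve.t_s)
    (out / "frap_fit.json").write_text(json.dumps({
        "immobile_fraction": fit.immobile_fraction,
        "koff_per_s": fit.koff_per_s,
        "residence_time_s": fit.residence_time_s,
        "rmse": fit.rmse,
        "identifiable": fit.identifiable,
    }, indent=2))


def _stage_spotbleach(params: dict, out: Path, manifest: dict) -> None:
    path = Path(params["trace"])
    manifest["inputs"][str(path)] = _digest(path)
    df = pd.read_csv(path)
    trace = spotbleach.BleachTrace(
        df["t_s"].to_numpy(), df["intensity"].to_numpy(),
        window_s=params.get("window_s", DEFAULTS["spot_bleach_window_s"]),
    )
    raw = spotbleach.raw_bound_fraction(trace)
    result = {"raw_bound_pct": raw}
    if "cal_h2b" in params and "cal_megfp" in params:
        cal = spotbleach.BoundFractionCalibration(params["cal_h2b"], params["cal_megfp"])
        result["calibrated_bound_pct"] = spotbleach.calibrate_bound_fraction(raw, cal)
    (out / "spotbleach.json").write_text(json.dumps(result, indent=2))


def _stage_traces(params: dict, out: Path, manifest: dict) -> None:
    path = Path(params["traces"])
    manifest["inputs"][str(path)] = _digest(path)
    ensemble = traces.traces_from_dataframe(pd.read_csv(path))
    ensemble = traces.qc_filter(
        ensemble, params.get("min_positions", DEFAULTS["qc_min_positions"]))
    threshold = params.get("threshold_nm", DEFAULTS["map_contact_threshold_nm"])
    dist = traces.median_distance_matrix(ensemble)
    cmap = traces.contact_map(ensemble, threshold)
    np.savetxt(out / "median_distance_nm.csv", dist.median_nm, delimiter=",")
    np.savetxt(out / "contact_frequency.csv", cmap.frequency, delimiter=",")
    traces.scaling_curve(ensemble).to_csv(out / "scaling_curve.csv", index=False)
    (out / "traces_meta.json").write_text(json.dumps({
        "n_traces": len(ensemble), "threshold_nm": threshold,
    }, indent=2))


def _stage_simulate(params: dict, out: Path, manifest: dict) -> None:
    kind = params.get("kind", "frap")
    seed = params.get("seed")
    if kind == "frap":
        curve = synth.gen_frap_curve(
            params.get("a", 0.35), params.get("koff_per_s", 1.0 / 139.0),
            np.arange(0.0, params.get("span_s", 600.0) + 1, params.get("dt_s", 20.0)),
            params.get("noise_sd", 0.03), seed)
        pd.DataFrame({"t_s": curve.t_s, "f_ub": curve.f_unbleached,
                      "f_b": curve.f_bleached}).to_csv(out / "frap_curve.csv", index=False)
    elif kind == "spotbleach":
        trace = synth.gen_spot_bleach_trace(
            params.get("bound", 0.5), noise_sd=params.get("noise_sd", 0.01), seed=seed)
        pd.DataFrame({"t_s": trace.t_s, "intensity": trace.intensity}).to_csv(
            out / "bleach_trace.csv", index=False)
    elif kind == "fcs":
        curve = synth.gen_fcs_curve(
            params.get("n_particles", 10.0), params.get("tau_d_s", 30e-6),
            noise_sd=params.get("noise_sd", 0.01), seed=seed)
        pd.DataFrame({"lag_s": curve.lags, "g": curve.g}).to_csv(
            out / "fcs_acf.csv", index=False)
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")


_STAGE_RUNNERS = {
    "occupancy": _stage_occupancy,
    "validate_tables": _stage_validate_tables,
    "fcs_fit": _stage_fcs_fit,
    "frap": _stage_frap,
    "spotbleach": _stage_spotbleach,
    "traces": _stage_traces,
    "simulate": _stage_simulate,
}

#: stages run in dependency order (simulation first, analyses after)
_STAGE_ORDER = ["simulate", "occupancy", "validate_tables", "fcs_fit", "frap",
                "spotbleach", "traces"]


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Execute the configured stages and write a manifest.

    Returns the run directory. A failing stage is recorded in the manifest
    with its traceback; earlier stages' outputs are kept.
    """
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        pkg_version = _pkg_version("extruderquant")
    except Exception:  # not installed (e.g. source tree)
        pkg_version = "unknown"
    manifest: dict = {"version": pkg_version, "seed": config.seed,
                      "inputs": {}, "stages": {}}
    for name in _STAGE_ORDER:
        if name not in config.stages:
            continue
        params = dict(config.stages[name] or {})
        if config.seed is not None and "seed" not in params:
            params["seed"] = config.seed
        try:
            _STAGE_RUNNERS[name](params, out, manifest)
            manifest["stages"][name] = {"status": "ok", "params": params}
        except Exception as err:
            manifest["stages"][name] = {
                "status": "failed", "params": params,
                "error": f"{type(err).__name__}: {err}",
                "traceback": traceback.format_exc(limit=5),
            }
            break
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out


def validate_fixtures(table_path=None) -> pd.DataFrame:
    """Recompute every derivable measurement-table cell and report matches.

    Wraps :func:`extruderquant.occupancy.validate_tables` on the packaged
    (or a user-supplied) table.
    """
    table = occupancy.load_measurement_table(table_path)
    return occupancy.validate_tables(table)
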