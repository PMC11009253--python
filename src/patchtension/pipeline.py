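"""End-to-end orchestration: simulate -> detect -> fit -> report.

``run_simulate`` writes synthetic experiments to disk (TIFF + sweep CSV +
metadata sidecars); ``run_analyze`` consumes those file interfaces (or
recorded data laid out the same way) and produces an :class:`AnalysisReport`:
per-patch step tables (pressure, radius, tension, normalized current), QC
verdicts with reasons, pooled Boltzmann fits in the tension and pressure
domains, and channel energetics from the tension-domain fit.

Failures are isolated per patch: a patch whose movie cannot be read or whose
membrane cannot be traced is excluded with a recorded reason, and the run
continues. Every report carries the config hash, seed, and package version so
each number is traceable to its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import (
    InsufficientPointsError,
    InvalidArgumentError,
    InvalidGeometryError,
    NormalizationError,
    PatchTensionError,
)
from .gating_analysis import (
    channel_energetics,
    fit_boltzmann,
    fold_activation,
    normalize_currents,
    peak_current,
    qc_patch,
)
from .membrane_imaging import (
    ImageStack,
    detect_membrane_points,
    enforce_continuity,
    fit_circle_algebraic,
    frame_index_for_time,
    with_physical_radius,
)
from .synthetic_experiment import (
    ChannelModel,
    CohortJitter,
    DEFAULT_STEP_PRESSURES,
    GeometryModel,
    SimulatedPatch,
    generate_cohort,
    make_pressure_protocol,
    write_patch,
)
from .tension_calc import tension_series

__all__ = [
    "RunConfig",
    "run_simulate",
    "run_analyze",
    "analyze_cohort",
    "analyze_patch",
    "load_patch_inputs",
    "report_hash",
]

log = logging.getLogger("patchtension")


@dataclass
class RunConfig:
    """All knobs of a pipeline run, serializable to/from YAML.

    The config hash of the exact parameter set is recorded in every report.
    """

    # cohort simulation
    n_patches: int = 12
    seed: int = 0
    channel: ChannelModel = field(default_factory=ChannelModel)
    geometry: GeometryModel = field(default_factory=GeometryModel)
    jitter: CohortJitter = field(default_factory=CohortJitter)
    step_pressures: tuple = DEFAULT_STEP_PRESSURES
    step_duration_s: float = 0.5
    inter_step_s: float = 0.5
    sample_rate_hz: float = 5000.0
    image_mode: str = "peak"
    frame_shape: tuple = (120, 120)
    arc_intensity: float = 100.0
    arc_noise_frac: float = 0.2
    # detection / circle fitting
    subpixel: bool = True
    filter_method: str = "ransac_circle"
    filter_params: dict = field(default_factory=dict)
    # geometric refinement is the default: the closed-form Kåsa estimate is
    # biased low on shallow noisy arcs (large radii at low pressure)
    refine_circle: bool = True
    min_retained_frac: float = 0.5
    rms_max_px: float = 2.0
    flat_radius_um: float = 25.0
    # gating analysis
    smooth_ms: float = 25.0
    baseline_s: float = 0.100
    basal_limit: float = 0.25
    saturation_tol: float = 0.10
    fit_mode: str = "global"
    temperature_K: float = 298.15
    fold_floor_pa: float = 1.5

    def __post_init__(self):
        for name in ("basal_limit", "saturation_tol", "rms_max_px", "temperature_K"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")
        if self.fit_mode not in ("global", "per_patch"):
            raise InvalidArgumentError(f"unknown fit mode {self.fit_mode!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "channel" in kwargs and isinstance(kwargs["channel"], dict):
            kwargs["channel"] = ChannelModel(**kwargs["channel"])
        if "geometry" in kwargs and isinstance(kwargs["geometry"], dict):
            kwargs["geometry"] = GeometryModel(**kwargs["geometry"])
        if "jitter" in kwargs and isinstance(kwargs["jitter"], dict):
            kwargs["jitter"] = CohortJitter(**kwargs["jitter"])
        if "step_pressures" in kwargs:
            kwargs["step_pressures"] = tuple(kwargs["step_pressures"])
        if "frame_shape" in kwargs:
            kwargs["frame_shape"] = tuple(kwargs["frame_shape"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise InvalidArgumentError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        # round-trip through JSON so tuples become lists (YAML-safe)
        return json.loads(json.dumps(dataclasses.asdict(self)))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def protocol(self):
        return make_pressure_protocol(
            self.step_pressures,
            step_duration=self.step_duration_s,
            inter_step=self.inter_step_s,
            sample_rate=self.sample_rate_hz,
        )


# ---------------------------------------------------------------------------
# Simulation on disk


def run_simulate(config: RunConfig, out_dir) -> dict:
    """Write a synthetic cohort under ``out_dir``; returns the manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patches = generate_cohort(
        n_patches=config.n_patches,
        channel=config.channel,
        geometry=config.geometry,
        jitter=config.jitter,
        protocol=config.protocol(),
        seed=config.seed,
        image_mode=config.image_mode,
        frame_shape=config.frame_shape,
        arc_intensity=config.arc_intensity,
        arc_noise_frac=config.arc_noise_frac,
    )
    entries = [write_patch(p, out_dir) for p in patches]
    manifest = {
        "n_patches": len(entries),
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "patches": entries,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def load_patch_inputs(directory, entry: dict) -> dict:
    """Load one patch's files (TIFF, sweep CSV, acquisition metadata).

    The ground-truth sidecar is deliberately not read here.
    """
    directory = Path(directory)
    meta = json.loads((directory / entry["meta"]).read_text())
    stack = ImageStack.from_tiff(
        directory / entry["tiff"],
        frame_rate=meta["frame_rate_hz"],
        pixel_scale=meta["pixel_scale_um_per_px"],
    )
    sweep = pd.read_csv(directory / entry["sweep"])
    sfi = meta.get("step_frame_index") or None
    if sfi is not None:
        sfi = {int(k): int(v) for k, v in sfi.items()}
    return {
        "patch_id": meta["patch_id"],
        "stack": stack,
        "time_s": sweep["time_s"].to_numpy(float),
        "current_pa": sweep["current_pA"].to_numpy(float),
        "pressure_mmhg": sweep["pressure_mmHg"].to_numpy(float),
        "roi": tuple(meta["roi"]),
        "step_frame_index": sfi,
    }


def inputs_from_patch(patch: SimulatedPatch) -> dict:
    """In-memory equivalent of :func:`load_patch_inputs` for a simulated patch."""
    return {
        "patch_id": patch.patch_id,
        "stack": patch.stack,
        "time_s": patch.time_s,
        "current_pa": patch.current_pa,
        "pressure_mmhg": patch.protocol.pressure_mmhg,
        "roi": patch.roi,
        "step_frame_index": patch.step_frame_index or None,
    }


# ---------------------------------------------------------------------------
# Analysis


def find_pressure_steps(time_s, pressure_mmhg, atol: float = 1e-9):
    """Annotated (step_id, pressure, t_on, t_off) windows from a pressure trace."""
    p = np.asarray(pressure_mmhg, dtype=float)
    t = np.asarray(time_s, dtype=float)
    active = np.abs(p) > atol
    edges = np.flatnonzero(np.diff(active.astype(int)))
    starts = list(edges[~active[edges]] + 1) if edges.size else []
    stops = list(edges[active[edges]] + 1) if edges.size else []
    if active.size and active[0]:
        starts.insert(0, 0)
    if active.size and active[-1]:
        stops.append(active.size)
    steps = []
    for i, (a, b) in enumerate(zip(starts, stops)):
        steps.append(
            {
                "step_id": i,
                "pressure_mmhg": float(np.median(p[a:b])),
                "t_on": float(t[a]),
                "t_off": float(t[b - 1]),
            }
        )
    return steps


def _fit_step_circle(frame, roi, config: RunConfig):
    """Detect, filter, and circle-fit the membrane in one frame.

    Returns ``(fit_or_None, flags)``; a fit is rejected (None) when too few
    points survive continuity filtering, when fewer than
    ``min_retained_frac`` of the detected rows survive, or when the RMS radial
    residual exceeds ``rms_max_px``.
    """
    flags = []
    pts = detect_membrane_points(frame, roi, subpixel=config.subpixel)
    try:
        kept = enforce_continuity(pts, method=config.filter_method, **config.filter_params)
    except (InsufficientPointsError, InvalidArgumentError) as exc:
        return None, [f"detection-failed: {exc}"]
    retained = kept.n_points / max(pts.n_points, 1)
    if retained < config.min_retained_frac:
        return None, [f"detection-failed: only {retained:.0%} of rows retained"]
    try:
        fit = fit_circle_algebraic(kept, refine=config.refine_circle)
    except PatchTensionError as exc:
        return None, [f"circle-fit-failed: {exc}"]
    if fit.rms_residual_px > config.rms_max_px:
        return None, [f"circle-fit-failed: rms {fit.rms_residual_px:.2f} px"]
    if retained < 1.0:
        flags.append(f"outliers-removed: {pts.n_points - kept.n_points}")
    return fit, flags


def analyze_patch(inputs: dict, config: RunConfig) -> dict:
    """Analyze one patch: peaks, radii, tensions, normalization, QC."""
    time_s = inputs["time_s"]
    current = inputs["current_pa"]
    pressure = inputs["pressure_mmhg"]
    stack: ImageStack = inputs["stack"]
    roi = inputs["roi"]
    sfi = inputs.get("step_frame_index")
    steps = find_pressure_steps(time_s, pressure)
    if not steps:
        raise InvalidArgumentError("no pressure steps found in sweep")

    responses, fits, frame_indices, step_flags = [], [], [], []
    for s in steps:
        resp = peak_current(
            time_s,
            current,
            (s["t_on"], s["t_off"]),
            step_id=s["step_id"],
            baseline_s=config.baseline_s,
            smooth_ms=config.smooth_ms,
        )
        responses.append(resp)
        if sfi is not None:
            idx = sfi.get(s["step_id"])
        else:
            idx = frame_index_for_time(stack, resp.t_peak)
        frame_indices.append(idx)
        if idx is None:
            fits.append(None)
            step_flags.append(["no-frame"])
            continue
        fit, flags = _fit_step_circle(stack.frames[idx], roi, config)
        if fit is not None:
            fit = with_physical_radius(fit, stack.pixel_scale)
        fits.append(fit)
        step_flags.append(flags)

    pressures = [s["pressure_mmhg"] for s in steps]
    tpoints = tension_series(
        pressures, fits, frame_indices, flat_radius_um=config.flat_radius_um
    )

    # resting current from the window preceding the first step
    t_first = steps[0]["t_on"]
    rest_mask = (time_s >= t_first - config.baseline_s) & (time_s < t_first)
    rest_pa = float(np.median(current[rest_mask])) if rest_mask.any() else 0.0

    # I/Imax on recorded (absolute) peak currents: the per-step peak is the
    # resting current plus the baseline-subtracted deviation
    absolute = [
        dataclasses.replace(r, peak_pa=rest_pa + r.peak_pa) for r in responses
    ]
    abs_mags = np.array([abs(r.peak_pa) for r in absolute])
    i_star = int(np.argmax(abs_mags))
    basal_fraction = abs(rest_pa) / max(abs_mags[i_star], 1e-12)
    fold = fold_activation(rest_pa, absolute[i_star].peak_pa, config.fold_floor_pa)

    norm_pressure = normalize_currents(
        absolute,
        stimuli=[abs(p) for p in pressures],
        patch_id=inputs["patch_id"],
        stimulus_units="mmHg",
    )
    verdict = qc_patch(
        norm_pressure,
        basal_fraction,
        basal_limit=config.basal_limit,
        saturation_tol=config.saturation_tol,
    )

    rows = []
    for s, resp, tp, flags in zip(steps, responses, tpoints, step_flags):
        rows.append(
            {
                "patch_id": inputs["patch_id"],
                "step_id": s["step_id"],
                "dP_mmHg": tp.dp_mmhg,
                "dP_abs_mmHg": abs(tp.dp_mmhg),
                "dP_Pa": tp.dp_pa,
                "r_um": tp.r_um,
                "T_mN_per_m": tp.tension_mn_per_m,
                "peak_pA": resp.peak_pa,
                "fraction": float(norm_pressure.fraction[s["step_id"]]),
                "frame_index": tp.frame_index,
                "flags": ";".join(list(tp.flags) + flags),
            }
        )
    return {
        "patch_id": inputs["patch_id"],
        "steps": rows,
        "rest_pa": rest_pa,
        "basal_fraction": basal_fraction,
        "fold_activation": fold,
        "qc_passed": verdict.passed,
        "qc_reasons": list(verdict.reasons),
    }


def _params_dict(params) -> dict:
    return {
        "midpoint": params.midpoint,
        "slope_factor": params.slope_factor,
        "r_squared": params.r_squared,
        "ci95_midpoint": params.ci95[0],
        "ci95_slope": params.ci95[1],
        "mode": params.mode,
        "n_patches": params.n_patches,
        "n_points": params.n_points,
        "stimulus_units": params.stimulus_units,
        "identifiable": params.identifiable,
    }


def analyze_cohort(inputs_list, config: RunConfig) -> dict:
    """Analyze many patches and pool QC-passing ones into cohort fits."""
    per_patch, excluded = [], []
    for inputs in inputs_list:
        pid = inputs.get("patch_id", "?") if isinstance(inputs, dict) else "?"
        try:
            result = analyze_patch(inputs, config)
        except (PatchTensionError, NormalizationError, Exception) as exc:
            if not isinstance(exc, (PatchTensionError, ValueError, OSError)):
                raise
            log.warning("patch %s failed: %s", pid, exc)
            excluded.append({"patch_id": pid, "reason": f"error: {exc}"})
            continue
        per_patch.append(result)
        if not result["qc_passed"]:
            excluded.append(
                {"patch_id": result["patch_id"], "reason": "; ".join(result["qc_reasons"])}
            )

    passing = [r for r in per_patch if r["qc_passed"]]
    steps_df = pd.DataFrame(
        [row for r in passing for row in r["steps"]]
    )

    fits, energetics, fit_notes = {}, None, {}
    if not steps_df.empty:
        for label, col in (("tension", "T_mN_per_m"), ("pressure", "dP_abs_mmHg")):
            sub = steps_df[["patch_id", col, "fraction"]].dropna()
            pts = sub.rename(columns={col: "stimulus"})
            try:
                params = fit_boltzmann(
                    pts,
                    mode=config.fit_mode,
                    stimulus_units="mN/m" if label == "tension" else "mmHg",
                    seed=config.seed,
                )
            except PatchTensionError as exc:
                fit_notes[label] = str(exc)
                continue
            fits[label] = _params_dict(params)
            if label == "tension":
                en = channel_energetics(params, temperature_K=config.temperature_K)
                energetics = dataclasses.asdict(en)

    report = {
        "provenance": {
            "package_version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "tension_note": "stimulus-induced tension only; basal tension unaccounted",
        },
        "n_patches_analyzed": len(per_patch),
        "n_patches_passing_qc": len(passing),
        "qc_excluded": excluded,
        "per_patch": per_patch,
        "global_fits": fits,
        "fit_notes": fit_notes,
        "energetics": energetics,
    }
    return report


def run_analyze(config: RunConfig, input_dir, out_dir=None) -> dict:
    """File-based analysis run over a simulated (or equivalently laid out) cohort."""
    input_dir = Path(input_dir)
    manifest = json.loads((input_dir / "manifest.json").read_text())
    inputs_list = []
    for entry in manifest["patches"]:
        try:
            inputs_list.append(load_patch_inputs(input_dir, entry))
        except Exception as exc:
            log.warning("could not load %s: %s", entry.get("patch_id"), exc)
            inputs_list.append(
                {"patch_id": entry.get("patch_id", "?"), "load_error": str(exc)}
            )
    loadable = [i for i in inputs_list if "load_error" not in i]
    report = analyze_cohort(loadable, config)
    for i in inputs_list:
        if "load_error" in i:
            report["qc_excluded"].append(
                {"patch_id": i["patch_id"], "reason": f"error: {i['load_error']}"}
            )
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(canonical_json(report))
        rows = [row for r in report["per_patch"] for row in r["steps"]]
        if rows:
            pd.DataFrame(rows).to_csv(out_dir / "steps.csv", index=False)
    return report


def canonical_json(report: dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True, default=float)


def report_hash(report: dict) -> str:
    """Stable hash of a report's canonical JSON form (for rerun checks)."""
    return hashlib.sha256(canonical_json(report).encode()).hexdigest()
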