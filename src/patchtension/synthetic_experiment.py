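"""Synthetic patch experiments with known ground truth.

Generates complete simulated experiments — pressure protocols, macroscopic
current sweeps, and fluorescence movies of the patched membrane — so the whole
analysis chain (arc detection, circle fitting, Laplace tension, normalization,
QC, Boltzmann fitting, energetics) can be exercised and validated without
recorded data.

The forward model, in brief:

* A piecewise-constant pressure protocol drives patch curvature through a
  hyperbolic compliance fixture ``r(dP) = r_pipette * (1 + c/|dP|)``: the patch
  is effectively flat at rest (radius capped) and its radius decreases toward
  the pipette radius as |pressure| grows, which makes tension
  ``T = |dP| r / 2`` strictly increasing in |dP|. This is a fixture chosen for
  its qualitative realism, not a mechanical model of the membrane.
* Hundreds of channels gate independently with a tension-dependent Boltzmann
  open probability; the macroscopic current is
  ``n_channels * i_single * P_open(T)`` plus additive Gaussian noise. A
  resting (basal) tension adds to the stimulus-induced tension and, exactly as
  in real excised patches, is invisible to the downstream analysis.
* The membrane appears in each frame as a bright arc of the true radius,
  anchored at the pipette aperture, with a Gaussian cross-section over a dark
  background, plus a dim pipette-wall silhouette and additive noise.

All randomness flows through explicit seeds; a cohort splits one root seed
into per-patch streams with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, InvalidGeometryError
from .gating_analysis import boltzmann_fraction
from .membrane_imaging import ImageStack
from .tension_calc import MMHG_TO_PA, laplace_tension

__all__ = [
    "ChannelModel",
    "GeometryModel",
    "CohortJitter",
    "StepWindow",
    "StimulusProtocol",
    "SimulatedPatch",
    "TRAAK_CHANNEL",
    "MSCS_CHANNEL",
    "DEFAULT_STEP_PRESSURES",
    "make_pressure_protocol",
    "patch_radius_for_pressure",
    "true_tension_for_pressure",
    "simulate_currents",
    "render_patch_frame",
    "simulate_patch",
    "generate_cohort",
    "write_patch",
]


@dataclass(frozen=True)
class ChannelModel:
    """Ground-truth gating parameters for a simulated channel population.

    Defaults describe a TRAAK-like patch: midpoint tension 4.4 mN/m, slope
    factor 1.7 mN/m, ~300 channels of 1.5 pA single-channel current (patches
    contain hundreds of channels at ~1-2 pA), resting tension 0.5 mN/m (low
    end of literature estimates; patches are selected for low basal tension),
    and current noise of 5 % of the maximal macroscopic current.
    """

    t50_mn_per_m: float = 4.4
    slope_mn_per_m: float = 1.7
    n_channels: int = 300
    i_single_pa: float = 1.5
    basal_tension_mn_per_m: float = 0.5
    current_noise_sd_pa: float | None = None

    def __post_init__(self):
        if self.slope_mn_per_m <= 0:
            raise InvalidArgumentError("slope factor must be positive")
        if self.n_channels < 1:
            raise InvalidArgumentError("need at least one channel")
        if self.i_single_pa == 0:
            raise InvalidArgumentError("single-channel current must be nonzero")
        if self.basal_tension_mn_per_m < 0:
            raise InvalidArgumentError("basal tension must be >= 0")
        if self.current_noise_sd_pa is None:
            object.__setattr__(
                self,
                "current_noise_sd_pa",
                0.05 * abs(self.n_channels * self.i_single_pa),
            )
        elif self.current_noise_sd_pa < 0:
            raise InvalidArgumentError("noise SD must be >= 0")

    @property
    def max_current_pa(self) -> float:
        return self.n_channels * self.i_single_pa

    def open_probability(self, tension_mn_per_m):
        return boltzmann_fraction(
            tension_mn_per_m, self.t50_mn_per_m, self.slope_mn_per_m
        )


#: TRAAK-like defaults (outward K+ current at 0 mV in a tenfold K+ gradient).
TRAAK_CHANNEL = ChannelModel()

#: MscS-like preset: steeper, left-shifted response; tens of channels with a
#: large inward single-channel current (~12 pA at -60 mV).
MSCS_CHANNEL = ChannelModel(
    t50_mn_per_m=3.7,
    slope_mn_per_m=1.1,
    n_channels=40,
    i_single_pa=-12.0,
    basal_tension_mn_per_m=0.5,
)


@dataclass(frozen=True)
class GeometryModel:
    """Patch/pipette geometry and imaging parameters.

    ``compliance_mmhg`` sets how quickly the patch radius approaches the
    pipette radius with pressure in the hyperbolic fixture; ``flat_cap_factor``
    caps the radius of the nominally flat resting patch at
    ``flat_cap_factor * pipette_radius`` (the Laplace relation degenerates for
    perfectly flat membranes).
    """

    pipette_radius_um: float = 1.5
    compliance_mmhg: float = 20.0
    pixel_scale_um_per_px: float = 0.05
    frame_rate_hz: float = 120.0
    flat_cap_factor: float = 50.0

    def __post_init__(self):
        if self.pipette_radius_um <= 0:
            raise InvalidArgumentError("pipette radius must be positive")
        if self.frame_rate_hz <= 0:
            raise InvalidArgumentError("frame rate must be positive")
        if self.pixel_scale_um_per_px <= 0:
            raise InvalidArgumentError("pixel scale must be positive")
        if self.compliance_mmhg <= 0:
            raise InvalidArgumentError("compliance must be positive")
        if self.flat_cap_factor <= 1:
            raise InvalidArgumentError("flat cap must exceed the pipette radius")


@dataclass(frozen=True)
class StepWindow:
    step_id: int
    pressure_mmhg: float
    t_on: float
    t_off: float


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant pressure protocol with annotated step windows.

    Each step of ``step_duration`` seconds is preceded by ``inter_step``
    seconds at zero pressure (so every step has a pre-step baseline window).
    """

    sample_rate_hz: float
    time_s: np.ndarray
    pressure_mmhg: np.ndarray
    steps: tuple[StepWindow, ...]

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] + 1.0 / self.sample_rate_hz) if self.time_s.size else 0.0

    @property
    def step_pressures(self) -> np.ndarray:
        return np.array([s.pressure_mmhg for s in self.steps])


#: Default six-step suction protocol (mmHg). Spans the TRAAK-like response
#: from below midpoint tension to a saturating response.
DEFAULT_STEP_PRESSURES = (-10.0, -20.0, -35.0, -50.0, -75.0, -110.0)


def make_pressure_protocol(
    step_pressures,
    step_duration: float = 0.5,
    inter_step: float = 0.5,
    sample_rate: float = 5000.0,
) -> StimulusProtocol:
    """Build a pressure step protocol.

    An empty pressure list yields a zero-length protocol. Non-positive
    durations or rates are invalid.
    """
    if step_duration <= 0 or inter_step <= 0:
        raise InvalidArgumentError("durations must be positive")
    if sample_rate <= 0:
        raise InvalidArgumentError("sample rate must be positive")
    step_pressures = [float(p) for p in step_pressures]
    n_steps = len(step_pressures)
    total = n_steps * (step_duration + inter_step)
    n_samples = int(round(total * sample_rate))
    time = np.arange(n_samples) / sample_rate
    pressure = np.zeros(n_samples)
    windows = []
    for i, p in enumerate(step_pressures):
        t_on = inter_step + i * (step_duration + inter_step)
        t_off = t_on + step_duration
        pressure[(time >= t_on) & (time < t_off)] = p
        windows.append(StepWindow(step_id=i, pressure_mmhg=p, t_on=t_on, t_off=t_off))
    return StimulusProtocol(
        sample_rate_hz=float(sample_rate),
        time_s=time,
        pressure_mmhg=pressure,
        steps=tuple(windows),
    )


def patch_radius_for_pressure(g: GeometryModel, dp_mmhg: float) -> float:
    """Forward radius model ``r = r_p * (1 + c/|dP|)``, capped at dP = 0.

    Monotonically non-increasing in |dP|, asymptoting to the pipette radius;
    the resulting tension ``T = |dP| r / 2`` is strictly increasing in |dP|.
    At exactly zero pressure the patch is treated as flat and the radius is
    capped at ``flat_cap_factor * pipette_radius``.
    """
    cap = g.flat_cap_factor * g.pipette_radius_um
    if dp_mmhg == 0:
        return cap
    r = g.pipette_radius_um * (1.0 + g.compliance_mmhg / abs(dp_mmhg))
    return min(r, cap)


def true_tension_for_pressure(g: GeometryModel, dp_mmhg: float) -> float:
    """Stimulus-induced tension (mN/m) at a step pressure, from the true radius."""
    if dp_mmhg == 0:
        return 0.0
    r_um = patch_radius_for_pressure(g, dp_mmhg)
    return laplace_tension(dp_mmhg * MMHG_TO_PA, r_um * 1e-6)


def pressure_for_tension(g: GeometryModel, tension_mn_per_m: float) -> float:
    """Invert the forward model: suction (mmHg, negative) producing a tension.

    With ``r = r_p (1 + c/|dP|)`` the induced tension is linear in |dP|:
    ``T = k_u * r_p * (|dP| + c)`` with ``k_u = MMHG_TO_PA * 1e-3 / 2``. Only
    tensions above the ``|dP| -> 0`` limit ``k_u * r_p * c`` are reachable.
    """
    k_u = MMHG_TO_PA * 1e-3 / 2.0
    dp = tension_mn_per_m / (k_u * g.pipette_radius_um) - g.compliance_mmhg
    if dp <= 0:
        raise InvalidArgumentError(
            f"tension {tension_mn_per_m} mN/m below the reachable range of this geometry"
        )
    return -dp


def radius_for_tension(g: GeometryModel, tension_mn_per_m: float) -> float:
    """Patch radius (µm) at the pressure that produces the given tension.

    Used to emulate stimuli (e.g. ultrasound) that set membrane tension
    without an applied pressure: a patch at tension T adopts the same
    curvature regardless of how the tension was generated.
    """
    return patch_radius_for_pressure(g, pressure_for_tension(g, tension_mn_per_m))


def simulate_currents(ch: ChannelModel, tension_mn_per_m, seed=0) -> np.ndarray:
    """Macroscopic current (pA) for a tension time series.

    ``I(t) = n_channels * i_single * P_open(T(t)) + N(0, noise_sd)``;
    reproducible given the seed (an ``int`` or a :class:`numpy.random.Generator`).
    """
    tension = np.asarray(tension_mn_per_m, dtype=float)
    if not np.all(np.isfinite(tension)) or np.any(tension < 0):
        raise InvalidArgumentError("tension trace must be finite and non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mean = ch.max_current_pa * ch.open_probability(tension)
    if ch.current_noise_sd_pa > 0:
        return mean + rng.normal(scale=ch.current_noise_sd_pa, size=tension.shape)
    return mean.copy()


# ---------------------------------------------------------------------------
# Frame rendering


def arc_geometry(
    g: GeometryModel,
    r_um: float,
    shape: tuple[int, int],
    anchor_col_frac: float = 0.45,
):
    """Circle center and row band for an arc anchored at the pipette aperture.

    The membrane meets the pipette walls at two anchor points one aperture
    half-width above and below the frame midline; the arc of radius ``r`` bulges
    rightward through them. Returns ``(center_xy, half_band_px, anchor_col)``.
    """
    h, w = shape
    r_px = r_um / g.pixel_scale_um_per_px
    a_px = g.pipette_radius_um / g.pixel_scale_um_per_px
    if r_px < a_px:
        raise InvalidGeometryError(
            f"radius {r_um} um smaller than pipette aperture half-width"
        )
    cy = h / 2.0
    x_anchor = anchor_col_frac * w
    cx = x_anchor - np.sqrt(r_px**2 - a_px**2)
    return (cx, cy), a_px, x_anchor


def render_patch_frame(
    g: GeometryModel,
    r_um: float,
    arc_center: tuple[float, float],
    shape: tuple[int, int] = (120, 120),
    row_half_band: float | None = None,
    intensity: float = 100.0,
    noise_sd: float = 20.0,
    seed=0,
    cross_section_sigma_px: float = 1.2,
    noise_model: str = "gaussian",
    wall_intensity: float = 30.0,
) -> np.ndarray:
    """Render one fluorescence frame: bright membrane arc over dark background.

    The arc is the right-facing portion of the circle of radius ``r_um``
    centered at ``arc_center`` (pixel ``(x, y)``), restricted to rows within
    ``row_half_band`` of the center row, with a Gaussian cross-section of
    ``cross_section_sigma_px``. In the noise-free limit each arc row has
    exactly one brightest pixel. ``noise_model='poisson'`` replaces additive
    Gaussian noise with shot noise on the signal plus a Gaussian read floor.
    Raises :class:`InvalidGeometryError` when the arc falls outside the frame.
    """
    h, w = shape
    if r_um <= 0:
        raise InvalidArgumentError("radius must be positive")
    cx, cy = arc_center
    r_px = r_um / g.pixel_scale_um_per_px
    if row_half_band is None:
        row_half_band = min(g.pipette_radius_um / g.pixel_scale_um_per_px, 0.95 * r_px)
    b = float(row_half_band)
    if b <= 0 or b > r_px:
        raise InvalidGeometryError("row band must be positive and within the radius")
    apex_x = cx + r_px
    edge_x = cx + np.sqrt(max(r_px**2 - b**2, 0.0))
    pad = 4.0 * cross_section_sigma_px
    if not (0 <= edge_x - pad and apex_x + pad < w and cy - b - 2 >= 0 and cy + b + 2 < h):
        raise InvalidGeometryError(
            f"arc (apex x={apex_x:.1f}, rows {cy - b:.1f}..{cy + b:.1f}) outside frame {shape}"
        )
    frame = np.zeros((h, w), dtype=float)

    if intensity != 0.0:
        r0 = int(np.floor(cy - b))
        r1 = int(np.ceil(cy + b)) + 1
        c0 = max(int(np.floor(edge_x - pad)), 0)
        c1 = min(int(np.ceil(apex_x + pad)) + 1, w)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        dist = np.hypot(xx - cx, yy - cy) - r_px
        band = np.abs(yy - cy) <= b
        frame[r0:r1, c0:c1] = np.where(
            band, intensity * np.exp(-(dist**2) / (2.0 * cross_section_sigma_px**2)), 0.0
        )
        # dim pipette-wall silhouette left of the anchors
        for wall_row in (int(round(cy - b)) - 2, int(round(cy + b)) + 2):
            if 0 <= wall_row < h:
                frame[wall_row, : max(c0, 0)] = wall_intensity

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if noise_model == "gaussian":
        if noise_sd > 0:
            frame = frame + rng.normal(scale=noise_sd, size=frame.shape)
    elif noise_model == "poisson":
        frame = rng.poisson(np.clip(frame, 0.0, None)).astype(float)
        if noise_sd > 0:
            frame = frame + rng.normal(scale=noise_sd, size=frame.shape)
    else:
        raise InvalidArgumentError(f"unknown noise model {noise_model!r}")
    return frame


# ---------------------------------------------------------------------------
# Whole-patch simulation


@dataclass
class SimulatedPatch:
    """A complete synthetic experiment with its ground truth.

    ``stack`` holds either one frame per stimulus step (``image_mode='peak'``,
    with ``step_frame_index`` mapping step id to frame) or a full movie at the
    geometry's frame rate (``image_mode='full'``). Protocol, sweep, and full
    stacks share the common experiment time base.
    """

    patch_id: str
    protocol: StimulusProtocol
    time_s: np.ndarray
    current_pa: np.ndarray
    stack: ImageStack
    step_frame_index: dict[int, int]
    roi: tuple[int, int, int, int]
    channel: ChannelModel
    geometry: GeometryModel
    truth: dict
    image_mode: str = "peak"

    def sweep_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "current_pA": self.current_pa,
                "pressure_mmHg": self.protocol.pressure_mmhg,
            }
        )


def _tension_trace(ch: ChannelModel, g: GeometryModel, protocol: StimulusProtocol):
    tension = np.full_like(protocol.time_s, ch.basal_tension_mn_per_m)
    per_step = []
    for stepw in protocol.steps:
        t_ind = true_tension_for_pressure(g, stepw.pressure_mmhg)
        r_um = patch_radius_for_pressure(g, stepw.pressure_mmhg)
        mask = (protocol.time_s >= stepw.t_on) & (protocol.time_s < stepw.t_off)
        tension[mask] = ch.basal_tension_mn_per_m + t_ind
        per_step.append(
            {
                "step_id": stepw.step_id,
                "dP_mmHg": stepw.pressure_mmhg,
                "r_um": r_um,
                "T_induced_mN_per_m": t_ind,
                "T_total_mN_per_m": ch.basal_tension_mn_per_m + t_ind,
            }
        )
    return tension, per_step


def _roi_for_steps(g, per_step, shape, intensity_sigma_px=1.2):
    radii = [s["r_um"] for s in per_step if s["dP_mmHg"] != 0]
    if not radii:
        radii = [g.flat_cap_factor * g.pipette_radius_um]
    h, w = shape
    (cx_min, cy), b, x_anchor = arc_geometry(g, min(radii), shape)
    apex_max = max(
        arc_geometry(g, r, shape)[0][0] + r / g.pixel_scale_um_per_px for r in radii
    )
    r0 = int(np.ceil(cy - b)) + 2
    r1 = int(np.floor(cy + b)) - 1
    c0 = max(int(np.floor(x_anchor - 6)), 0)
    c1 = min(int(np.ceil(apex_max + 6 * intensity_sigma_px)), w)
    return (r0, r1, c0, c1)


def simulate_patch(
    channel: ChannelModel = TRAAK_CHANNEL,
    geometry: GeometryModel = GeometryModel(),
    protocol: StimulusProtocol | None = None,
    seed: int = 0,
    image_mode: str = "peak",
    frame_shape: tuple[int, int] = (120, 120),
    arc_intensity: float = 100.0,
    arc_noise_frac: float = 0.2,
    patch_id: str = "patch000",
) -> SimulatedPatch:
    """Simulate one patch: protocol -> tension -> currents -> movie.

    ``arc_noise_frac`` sets the image noise SD as a fraction of the arc peak
    intensity (default 20 %, the calibrated realistic level). With
    ``image_mode='peak'`` only the per-step analysis frames are rendered; with
    ``'full'`` the movie covers the whole protocol at the geometry frame rate.
    """
    if image_mode not in ("peak", "full"):
        raise InvalidArgumentError(f"unknown image mode {image_mode!r}")
    if protocol is None:
        protocol = make_pressure_protocol(DEFAULT_STEP_PRESSURES)
    ss = np.random.SeedSequence(seed)
    rng_current, rng_frames = (np.random.default_rng(s) for s in ss.spawn(2))

    tension, per_step = _tension_trace(channel, geometry, protocol)
    current = simulate_currents(channel, tension, rng_current)
    noise_sd = arc_noise_frac * arc_intensity

    frames = []
    step_frame_index: dict[int, int] = {}
    if image_mode == "peak":
        for s in per_step:
            center, band, _ = arc_geometry(geometry, s["r_um"], frame_shape)
            frames.append(
                render_patch_frame(
                    geometry,
                    s["r_um"],
                    center,
                    shape=frame_shape,
                    row_half_band=band,
                    intensity=arc_intensity,
                    noise_sd=noise_sd,
                    seed=rng_frames,
                )
            )
            step_frame_index[s["step_id"]] = len(frames) - 1
    else:
        n_frames = int(np.floor(protocol.duration_s * geometry.frame_rate_hz))
        frame_times = np.arange(n_frames) / geometry.frame_rate_hz
        sample_idx = np.minimum(
            (frame_times * protocol.sample_rate_hz).astype(int),
            protocol.time_s.size - 1,
        )
        dp_at_frames = protocol.pressure_mmhg[sample_idx]
        for dp in dp_at_frames:
            r_um = patch_radius_for_pressure(geometry, float(dp))
            center, band, _ = arc_geometry(geometry, r_um, frame_shape)
            frames.append(
                render_patch_frame(
                    geometry,
                    r_um,
                    center,
                    shape=frame_shape,
                    row_half_band=band,
                    intensity=arc_intensity,
                    noise_sd=noise_sd,
                    seed=rng_frames,
                )
            )

    stack = ImageStack(
        frames=np.stack(frames) if frames else np.zeros((0,) + frame_shape),
        frame_rate=geometry.frame_rate_hz,
        pixel_scale=geometry.pixel_scale_um_per_px,
    )
    roi = _roi_for_steps(geometry, per_step, frame_shape)
    truth = {
        "channel": dataclasses.asdict(channel),
        "geometry": dataclasses.asdict(geometry),
        "per_step": per_step,
        "seed": seed,
    }
    return SimulatedPatch(
        patch_id=patch_id,
        protocol=protocol,
        time_s=protocol.time_s,
        current_pa=current,
        stack=stack,
        step_frame_index=step_frame_index,
        roi=roi,
        channel=channel,
        geometry=geometry,
        truth=truth,
        image_mode=image_mode,
    )


@dataclass(frozen=True)
class CohortJitter:
    """Between-patch variability (fractions are relative SDs, sd absolute).

    Geometry varies so the same pressure yields different tensions across
    patches; gating parameters are shared unless their jitter is nonzero.
    """

    pipette_radius_frac: float = 0.15
    compliance_frac: float = 0.30
    basal_tension_sd: float = 0.25
    t50_sd: float = 0.0
    slope_sd: float = 0.0

    @classmethod
    def none(cls) -> "CohortJitter":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0)


def generate_cohort(
    n_patches: int = 12,
    channel: ChannelModel = TRAAK_CHANNEL,
    geometry: GeometryModel = GeometryModel(),
    jitter: CohortJitter = CohortJitter(),
    protocol: StimulusProtocol | None = None,
    seed: int = 0,
    image_mode: str = "peak",
    **patch_kwargs,
) -> list[SimulatedPatch]:
    """Simulate ``n_patches`` patches with between-patch variability.

    Per-patch seeds are split deterministically from the root seed. Jitter is
    multiplicative truncated-normal on geometry (so radii stay positive) and
    additive truncated-at-zero normal on basal tension.
    """
    if n_patches < 0:
        raise InvalidArgumentError("n_patches must be >= 0")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patches)
    rng_jitter = np.random.default_rng(ss.spawn(1)[0])
    patches = []
    for i in range(n_patches):
        rp = geometry.pipette_radius_um * max(
            1.0 + jitter.pipette_radius_frac * rng_jitter.standard_normal(), 0.3
        )
        comp = geometry.compliance_mmhg * max(
            1.0 + jitter.compliance_frac * rng_jitter.standard_normal(), 0.2
        )
        basal = max(
            channel.basal_tension_mn_per_m
            + jitter.basal_tension_sd * rng_jitter.standard_normal(),
            0.0,
        )
        t50 = channel.t50_mn_per_m + jitter.t50_sd * rng_jitter.standard_normal()
        slope = max(
            channel.slope_mn_per_m + jitter.slope_sd * rng_jitter.standard_normal(),
            1e-3,
        )
        ch_i = dataclasses.replace(
            channel,
            t50_mn_per_m=t50,
            slope_mn_per_m=slope,
            basal_tension_mn_per_m=basal,
        )
        g_i = dataclasses.replace(
            geometry, pipette_radius_um=rp, compliance_mmhg=comp
        )
        patches.append(
            simulate_patch(
                channel=ch_i,
                geometry=g_i,
                protocol=protocol,
                seed=int(children[i].generate_state(1)[0] % (2**31)),
                image_mode=image_mode,
                patch_id=f"patch{i:03d}",
                **patch_kwargs,
            )
        )
    return patches


# ---------------------------------------------------------------------------
# On-disk interface


def write_patch(patch: SimulatedPatch, outdir) -> dict:
    """Write one patch as TIFF stack + sweep CSV + meta and truth sidecars.

    ``meta.json`` carries acquisition metadata the analysis is allowed to use
    (pixel scale, frame rate, ROI, frame map); ``truth.json`` carries the
    ground truth and is never read by the analysis.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = outdir / patch.patch_id
    tiff_path = base.with_suffix(".tif")
    patch.stack.to_tiff(tiff_path)
    sweep_path = Path(str(base) + ".sweep.csv")
    patch.sweep_table().to_csv(sweep_path, index=False, float_format="%.6g")
    meta = {
        "patch_id": patch.patch_id,
        "pixel_scale_um_per_px": patch.geometry.pixel_scale_um_per_px,
        "frame_rate_hz": patch.geometry.frame_rate_hz,
        "roi": list(patch.roi),
        "image_mode": patch.image_mode,
        "step_frame_index": {str(k): v for k, v in patch.step_frame_index.items()},
    }
    meta_path = Path(str(base) + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=1, sort_keys=True))
    truth_path = Path(str(base) + ".truth.json")
    truth_path.write_text(json.dumps(patch.truth, indent=1, sort_keys=True))
    return {
        "patch_id": patch.patch_id,
        "tiff": tiff_path.name,
        "sweep": sweep_path.name,
        "meta": meta_path.name,
        "truth": truth_path.name,
    }
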