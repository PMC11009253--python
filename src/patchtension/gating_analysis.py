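"""Current-tension analysis: normalized responses, Boltzmann fits, energetics.

The gating model is a two-state Boltzmann in the stimulus domain,

    f(s) = 1 / (1 + exp((s50 - s) / k)),

with midpoint ``s50`` and slope factor ``k`` (both in stimulus units), fitted
with amplitude fixed at 1 because responses are normalized to each patch's
maximum evoked current. When the stimulus is membrane tension ``T`` (mN/m),
the same curve is the open probability of a channel whose opening expands its
in-plane cross-sectional area by ``dA`` against an intrinsic energy
difference ``dG``:

    P_open = 1 / (1 + exp((dG - T*dA) / (kB * T_abs)))

so ``dA = kB * T_abs / k`` and ``dG = (s50 / k) * kB * T_abs``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.optimize import least_squares
from scipy.special import expit
from scipy.stats import t as t_dist

from .errors import (
    FitFailureError,
    InvalidArgumentError,
    NormalizationError,
    OutOfRangeError,
)

__all__ = [
    "BOLTZMANN_CONSTANT",
    "StepResponse",
    "NormalizedResponse",
    "BoltzmannParams",
    "ChannelEnergetics",
    "QCVerdict",
    "boltzmann_fraction",
    "peak_current",
    "normalize_currents",
    "fold_activation",
    "qc_patch",
    "fit_boltzmann",
    "activation_range",
    "channel_energetics",
    "compare_stimulus_domains",
]

#: Boltzmann constant, J/K (2019 SI exact value).
BOLTZMANN_CONSTANT = 1.380649e-23

#: Default recording temperature (K); recordings are made at 25 degC.
DEFAULT_TEMPERATURE_K = 298.15


def boltzmann_fraction(stimulus, midpoint: float, slope_factor: float):
    """Two-state Boltzmann sigmoid ``1/(1 + exp((midpoint - s)/k))``."""
    return expit((np.asarray(stimulus, dtype=float) - midpoint) / slope_factor)


# ---------------------------------------------------------------------------
# Peak extraction and normalization


@dataclass(frozen=True)
class StepResponse:
    """Baseline-subtracted peak current for one stimulus step."""

    step_id: int
    peak_pa: float
    window: tuple[float, float]
    t_peak: float
    baseline_pa: float = 0.0


def peak_current(
    time,
    current,
    window: tuple[float, float],
    step_id: int = 0,
    polarity: str = "auto",
    baseline_s: float = 0.100,
    smooth_ms: float = 25.0,
) -> StepResponse:
    """Peak (extremum) of the baseline-subtracted current within a window.

    The baseline is the median of the ``baseline_s`` seconds preceding the
    window; the trace is boxcar-smoothed over ``smooth_ms`` before the
    extremum is taken so single-sample noise spikes do not set the peak.
    ``polarity='auto'`` picks the side with the larger |extremum - baseline|;
    ties between equal extrema resolve to the earliest time.
    """
    time = np.asarray(time, dtype=float)
    current = np.asarray(current, dtype=float)
    t0, t1 = window
    if t1 <= t0:
        raise InvalidArgumentError("window must have t_end > t_start")
    if t0 < time[0] - 1e-12 or t1 > time[-1] + 1e-12:
        raise OutOfRangeError(f"window {window} outside sweep [{time[0]}, {time[-1]}]")
    if polarity not in ("auto", "positive", "negative"):
        raise InvalidArgumentError(f"unknown polarity {polarity!r}")

    base_mask = (time >= t0 - baseline_s) & (time < t0)
    baseline = float(np.median(current[base_mask])) if base_mask.any() else 0.0

    if smooth_ms > 0 and time.size > 1:
        fs = 1.0 / float(np.median(np.diff(time)))
        width = max(int(round(smooth_ms * 1e-3 * fs)), 1)
        smoothed = uniform_filter1d(current, size=width, mode="nearest")
    else:
        smoothed = current

    in_win = (time >= t0) & (time <= t1)
    if not in_win.any():
        raise OutOfRangeError("window contains no samples")
    dev = smoothed[in_win] - baseline
    tw = time[in_win]
    i_hi = int(np.argmax(dev))
    i_lo = int(np.argmin(dev))
    if polarity == "positive":
        i = i_hi
    elif polarity == "negative":
        i = i_lo
    else:
        i = i_hi if dev[i_hi] >= -dev[i_lo] else i_lo
    return StepResponse(
        step_id=step_id,
        peak_pa=float(dev[i]),
        window=(float(t0), float(t1)),
        t_peak=float(tw[i]),
        baseline_pa=baseline,
    )


@dataclass(frozen=True)
class NormalizedResponse:
    """Per-patch normalized current (I / Imax) against a stimulus axis.

    Normalization is on peak-current magnitudes, so it applies unchanged to
    inward-current channels; exactly one point attains 1 (the maximal step,
    first occurrence on ties).
    """

    patch_id: str
    stimulus: np.ndarray
    fraction: np.ndarray
    stimulus_units: str = "mN/m"
    step_ids: np.ndarray | None = None

    def __post_init__(self):
        s = np.asarray(self.stimulus, dtype=float)
        f = np.asarray(self.fraction, dtype=float)
        if s.shape != f.shape:
            raise InvalidArgumentError("stimulus and fraction must align")
        object.__setattr__(self, "stimulus", s)
        object.__setattr__(self, "fraction", f)

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.stimulus, self.fraction])


def normalize_currents(
    responses: list[StepResponse],
    stimuli=None,
    patch_id: str = "patch",
    stimulus_units: str = "mN/m",
) -> NormalizedResponse:
    """Divide each step's peak magnitude by the patch maximum.

    ``stimuli`` aligns one stimulus value (tension, |pressure|, or acoustic
    power) with each response; step ids are used when omitted.
    """
    if not responses:
        raise InvalidArgumentError("need at least one step response")
    mags = np.array([abs(r.peak_pa) for r in responses], dtype=float)
    if np.max(mags) <= 0:
        raise NormalizationError("all peak currents are zero")
    frac = mags / np.max(mags)
    frac[np.argmax(mags)] = 1.0  # exactly one point attains the maximum
    if stimuli is None:
        stimuli = [float(r.step_id) for r in responses]
    return NormalizedResponse(
        patch_id=patch_id,
        stimulus=np.asarray(stimuli, dtype=float),
        fraction=frac,
        stimulus_units=stimulus_units,
        step_ids=np.array([r.step_id for r in responses]),
    )


def fold_activation(basal_pa: float, max_pa: float, floor_pa: float = 1.5) -> float:
    """Maximal over basal current magnitude ratio.

    The basal magnitude is floored at ``floor_pa`` (about one single-channel
    current) so near-zero baselines do not blow up the ratio.
    """
    if floor_pa <= 0:
        raise InvalidArgumentError("floor_pa must be positive")
    return abs(max_pa) / max(abs(basal_pa), floor_pa)


# ---------------------------------------------------------------------------
# Quality control


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    reasons: tuple[str, ...] = field(default_factory=tuple)


def qc_patch(
    resp: NormalizedResponse,
    basal_fraction: float,
    basal_limit: float = 0.25,
    saturation_tol: float = 0.10,
) -> QCVerdict:
    """Exclusion rules applied before any patch enters a fit.

    A patch fails when (a) its basal activity exceeds ``basal_limit`` of Imax,
    or (b) the response has not saturated: the normalized responses at the two
    largest stimuli differ by more than ``saturation_tol``.
    """
    reasons = []
    if basal_fraction > basal_limit:
        reasons.append(f"basal-activity {basal_fraction:.3f} > {basal_limit}")
    order = np.argsort(resp.stimulus)
    if order.size >= 2:
        y1, y2 = resp.fraction[order[-2]], resp.fraction[order[-1]]
        if abs(y2 - y1) > saturation_tol:
            reasons.append(f"no-saturation |{y2:.3f} - {y1:.3f}| > {saturation_tol}")
    return QCVerdict(passed=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# Boltzmann fitting


@dataclass(frozen=True)
class BoltzmannParams:
    """Fitted sigmoid parameters with diagnostics.

    ``ci95`` holds the half-widths of the 95 % confidence intervals on
    (midpoint, slope_factor). ``identifiable`` is False when the midpoint CI
    is wider than the stimulus span of the data (e.g. all points on one side
    of the midpoint).
    """

    midpoint: float
    slope_factor: float
    r_squared: float = float("nan")
    ci95: tuple[float, float] = (float("nan"), float("nan"))
    mode: str = "global"
    n_patches: int = 1
    n_points: int = 0
    stimulus_units: str = "mN/m"
    identifiable: bool = True
    amplitude: float = 1.0
    per_patch_fits: tuple = ()


def _points_frame(points, mode: str) -> pd.DataFrame:
    if isinstance(points, NormalizedResponse):
        return pd.DataFrame(
            {
                "patch_id": points.patch_id,
                "stimulus": points.stimulus,
                "fraction": points.fraction,
            }
        )
    if isinstance(points, pd.DataFrame):
        df = points.rename(
            columns={c: c.lower() for c in points.columns}
        )
        if "patch_id" not in df.columns:
            df = df.assign(patch_id="patch")
        return df[["patch_id", "stimulus", "fraction"]].copy()
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidArgumentError("points must be (n, 2) of (stimulus, fraction)")
    if mode == "per_patch":
        raise InvalidArgumentError("per_patch mode needs patch ids (pass a DataFrame)")
    return pd.DataFrame({"patch_id": "patch", "stimulus": arr[:, 0], "fraction": arr[:, 1]})


def _fit_single(x, y, free_amplitude, seed, max_nfev=2000):
    n = x.size
    if n < 4:
        raise InvalidArgumentError("Boltzmann fit needs at least 4 points")
    span = float(x.max() - x.min())
    if span <= 0:
        raise InvalidArgumentError("stimulus values must not be constant")
    k0 = max(span / 4.0, 1e-6)
    m0 = float(np.median(x))

    def residual(p):
        mid, k = p[0], p[1]
        f = expit((x - mid) / k)
        if free_amplitude:
            f = p[2] * f
        return f - y

    lower = [-np.inf, 1e-9] + ([1e-9] if free_amplitude else [])
    upper = [np.inf, np.inf] + ([np.inf] if free_amplitude else [])

    rng = np.random.default_rng(seed)
    starts = [(m0, k0)]
    for _ in range(8):
        starts.append(
            (
                m0 + span * (rng.random() - 0.5) / 2.0,
                k0 * float(np.exp(rng.normal(scale=0.7))),
            )
        )
    best = None
    tried = []
    for m_init, k_init in starts:
        x0 = [m_init, max(k_init, 1e-6)] + ([1.0] if free_amplitude else [])
        try:
            out = least_squares(
                residual, x0=x0, bounds=(lower, upper), xtol=1e-12, ftol=1e-12,
                gtol=1e-12, max_nfev=max_nfev,
            )
        except Exception as exc:  # pragma: no cover - scipy internal failures
            tried.append(str(exc))
            continue
        if not np.all(np.isfinite(out.x)):
            continue
        if best is None or out.cost < best.cost - 1e-15:
            best = out
    if best is None:
        raise FitFailureError("all fit starts failed", {"errors": tried})

    p = best.x
    res = best.fun
    dof = max(n - p.size, 1)
    s2 = float(np.sum(res**2)) / dof
    JtJ = best.jac.T @ best.jac
    try:
        cov = s2 * np.linalg.pinv(JtJ)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(p.size, np.inf)
    tcrit = float(t_dist.ppf(0.975, dof))
    ss_res = float(np.sum(res**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    ci = (tcrit * se[0], tcrit * se[1])
    # flagged when the CI exceeds the sampled span or the midpoint is
    # extrapolated outside it (e.g. all points on one side of the midpoint)
    identifiable = bool(
        np.isfinite(ci[0]) and ci[0] <= span and x.min() <= p[0] <= x.max()
    )
    amp = float(p[2]) if free_amplitude else 1.0
    return {
        "midpoint": float(p[0]),
        "slope": float(p[1]),
        "r2": r2,
        "ci": ci,
        "identifiable": identifiable,
        "amplitude": amp,
        "n": n,
    }


def fit_boltzmann(
    points,
    mode: str = "global",
    stimulus_units: str = "mN/m",
    free_amplitude: bool = False,
    seed: int = 0,
) -> BoltzmannParams:
    """Least-squares Boltzmann fit of normalized responses.

    ``mode='global'`` pools all points into one fit (the default, matching how
    cohort tension-response curves are reported); ``mode='per_patch'`` fits
    each patch separately and reports the mean with a SEM-based CI across
    patches. The amplitude is fixed at 1 unless ``free_amplitude`` (a
    sensitivity-analysis flag) is set. Initialization is multi-start (median
    stimulus / quarter-span slope plus 8 seeded jitters); non-convergence of
    every start raises :class:`FitFailureError`.
    """
    if mode not in ("global", "per_patch"):
        raise InvalidArgumentError(f"unknown fit mode {mode!r}")
    df = _points_frame(points, mode)
    n_patches = int(df["patch_id"].nunique())

    if mode == "global":
        x = df["stimulus"].to_numpy(dtype=float)
        y = df["fraction"].to_numpy(dtype=float)
        fit = _fit_single(x, y, free_amplitude, seed)
        return BoltzmannParams(
            midpoint=fit["midpoint"],
            slope_factor=fit["slope"],
            r_squared=fit["r2"],
            ci95=fit["ci"],
            mode="global",
            n_patches=n_patches,
            n_points=fit["n"],
            stimulus_units=stimulus_units,
            identifiable=fit["identifiable"],
            amplitude=fit["amplitude"],
        )

    per = []
    for pid, grp in df.groupby("patch_id", sort=True):
        x = grp["stimulus"].to_numpy(dtype=float)
        y = grp["fraction"].to_numpy(dtype=float)
        fit = _fit_single(x, y, free_amplitude, seed)
        per.append(
            BoltzmannParams(
                midpoint=fit["midpoint"],
                slope_factor=fit["slope"],
                r_squared=fit["r2"],
                ci95=fit["ci"],
                mode="per_patch",
                n_patches=1,
                n_points=fit["n"],
                stimulus_units=stimulus_units,
                identifiable=fit["identifiable"],
                amplitude=fit["amplitude"],
            )
        )
    mids = np.array([f.midpoint for f in per])
    slopes = np.array([f.slope_factor for f in per])
    npz = len(per)
    if npz > 1:
        tcrit = float(t_dist.ppf(0.975, npz - 1))
        sem_m = float(mids.std(ddof=1) / math.sqrt(npz))
        sem_k = float(slopes.std(ddof=1) / math.sqrt(npz))
        ci = (tcrit * sem_m, tcrit * sem_k)
    else:
        ci = per[0].ci95
    return BoltzmannParams(
        midpoint=float(mids.mean()),
        slope_factor=float(slopes.mean()),
        r_squared=float(np.mean([f.r_squared for f in per])),
        ci95=ci,
        mode="per_patch",
        n_patches=npz,
        n_points=int(df.shape[0]),
        stimulus_units=stimulus_units,
        identifiable=all(f.identifiable for f in per),
        per_patch_fits=tuple(per),
    )


def activation_range(
    params: BoltzmannParams, lo: float = 0.1, hi: float = 0.9
) -> tuple[float, float]:
    """Stimulus values at fractional activations ``lo`` and ``hi``.

    ``s_f = midpoint + slope_factor * ln(f / (1 - f))``; the default 10-90 %
    range has width ``2 ln(9) * slope_factor``.
    """
    if not (0.0 < lo < hi < 1.0):
        raise InvalidArgumentError("need 0 < lo < hi < 1")

    def at(f):
        return params.midpoint + params.slope_factor * math.log(f / (1.0 - f))

    return (at(lo), at(hi))


# ---------------------------------------------------------------------------
# Channel energetics


@dataclass(frozen=True)
class ChannelEnergetics:
    """In-plane area expansion and gating energy from a tension-domain fit."""

    delta_A_nm2: float
    delta_G_joules: float
    delta_G_kBT: float
    temperature_K: float


def channel_energetics(
    params: BoltzmannParams, temperature_K: float = DEFAULT_TEMPERATURE_K
) -> ChannelEnergetics:
    """Derive ``dA`` and ``dG`` from a tension-domain Boltzmann fit.

    With tension in mN/m, ``dA = kB*T_abs / slope_factor`` (converted to nm^2)
    and ``dG = (midpoint / slope_factor) * kB * T_abs``. Raises when the fit
    is not in the tension domain (no energetics are derivable from pressure or
    acoustic-power midpoints).
    """
    if params.stimulus_units not in ("mN/m", "mN m-1", "mN per m"):
        raise InvalidArgumentError(
            f"energetics need a tension-domain fit, got units {params.stimulus_units!r}"
        )
    if temperature_K <= 0:
        raise InvalidArgumentError("temperature must be positive (K)")
    kbt = BOLTZMANN_CONSTANT * temperature_K
    slope_si = params.slope_factor * 1e-3  # mN/m -> N/m
    delta_a_m2 = kbt / slope_si
    delta_g_kbt = params.midpoint / params.slope_factor
    return ChannelEnergetics(
        delta_A_nm2=delta_a_m2 * 1e18,
        delta_G_joules=delta_g_kbt * kbt,
        delta_G_kBT=delta_g_kbt,
        temperature_K=temperature_K,
    )


# ---------------------------------------------------------------------------
# Stimulus-domain comparison (tension vs pressure)


def compare_stimulus_domains(
    df: pd.DataFrame,
    domains: dict[str, str] | None = None,
    fraction_col: str = "fraction",
    seed: int = 0,
) -> dict:
    """Global fit quality and per-patch midpoint dispersion per stimulus domain.

    Patches vary in geometry, so identical pressures produce different
    tensions across patches: if tension is the gating stimulus, pooled fits in
    the tension domain should be tighter (higher R^2) and per-patch midpoints
    less dispersed (lower CV) than in the pressure domain. ``domains`` maps a
    domain label to the stimulus column name, default
    ``{"tension": "T_mN_per_m", "pressure": "dP_abs_mmHg"}``.
    """
    if domains is None:
        domains = {"tension": "T_mN_per_m", "pressure": "dP_abs_mmHg"}
    out = {}
    for label, col in domains.items():
        sub = df[["patch_id", col, fraction_col]].dropna()
        pts = sub.rename(columns={col: "stimulus", fraction_col: "fraction"})
        glob = fit_boltzmann(pts, mode="global", stimulus_units=col, seed=seed)
        mids = []
        for _, grp in pts.groupby("patch_id"):
            try:
                fit = _fit_single(
                    grp["stimulus"].to_numpy(float),
                    grp["fraction"].to_numpy(float),
                    False,
                    seed,
                )
            except (FitFailureError, InvalidArgumentError):
                continue
            mids.append(fit["midpoint"])
        mids = np.asarray(mids, dtype=float)
        cv = float(mids.std(ddof=1) / abs(mids.mean())) if mids.size > 1 else float("nan")
        out[label] = {
            "r_squared": glob.r_squared,
            "midpoint": glob.midpoint,
            "midpoint_cv": cv,
            "n_patch_fits": int(mids.size),
        }
    return out
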