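"""Young-Laplace membrane tension from applied pressure and patch radius.

For a hemispherical patch of radius of curvature ``r`` under a transmembrane
pressure difference ``dP``, membrane tension is ``T = |dP| * r / 2``. Tension
is reported as a magnitude because positive- and negative-pressure stimulation
both generate tension (with opposite curvature); curvature direction, when
known, travels separately as metadata.

Two caveats from excised-patch work are encoded as flags rather than
corrections: tensions below the smallest reliably measurable value
(0.36 mN/m) are flagged ``below-measured-range``, and fits with very large
radii (near-flat membranes, where the Laplace relation degenerates) are
flagged ``flat-patch``. Resting (basal) membrane tension is *not* added to the
computed stimulus-induced tension; the omission is recorded in output
metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidGeometryError

__all__ = [
    "MMHG_TO_PA",
    "MIN_MEASURED_TENSION_MN_PER_M",
    "FLAT_RADIUS_UM",
    "TensionPoint",
    "pressure_to_pascals",
    "laplace_tension",
    "tension_series",
    "tension_table",
]

#: Conversion factor, pascals per mmHg.
MMHG_TO_PA = 133.322

#: Smallest tension treated as reliably measurable in this assay (mN/m).
MIN_MEASURED_TENSION_MN_PER_M = 0.36

#: Default radius (µm) above which a patch is treated as effectively flat.
FLAT_RADIUS_UM = 25.0

#: Tension caveat recorded with every exported table.
BASAL_TENSION_NOTE = (
    "Stimulus-induced tension only; resting (basal) membrane tension is "
    "unaccounted for."
)


@dataclass(frozen=True)
class TensionPoint:
    """One (pressure, radius, tension) triple with provenance.

    ``tension_mn_per_m`` is ``|dP_Pa| * r_m / 2`` expressed in mN/m; ``None``
    radius marks a step whose circle fit is absent (reported, never silently
    dropped).
    """

    step_id: int
    dp_mmhg: float
    dp_pa: float
    r_um: float | None
    tension_mn_per_m: float | None
    frame_index: int | None = None
    fit_method: str | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)


def pressure_to_pascals(dp_mmhg: float) -> float:
    """Convert mmHg to Pa (1 mmHg = 133.322 Pa)."""
    return dp_mmhg * MMHG_TO_PA


def laplace_tension(dp_pa: float, r_m: float) -> float:
    """Tension ``T = |dP| * r / 2`` in mN/m from Pa and metres.

    The sign of the pressure is dropped: tension is generated by curvature of
    either polarity.
    """
    if r_m <= 0 or not math.isfinite(r_m):
        raise InvalidGeometryError(f"radius must be positive and finite, got {r_m}")
    return abs(dp_pa) * r_m / 2.0 * 1e3


def tension_flags(tension_mn_per_m: float, r_um: float, flat_radius_um: float = FLAT_RADIUS_UM):
    flags = []
    if tension_mn_per_m < MIN_MEASURED_TENSION_MN_PER_M:
        flags.append("below-measured-range")
    if r_um > flat_radius_um:
        flags.append("flat-patch")
    return tuple(flags)


def tension_series(
    pressures_mmhg,
    fits,
    frame_indices=None,
    flat_radius_um: float = FLAT_RADIUS_UM,
) -> list[TensionPoint]:
    """One :class:`TensionPoint` per stimulus step.

    Parameters
    ----------
    pressures_mmhg:
        Per-step applied pressure (mmHg), indexed by step.
    fits:
        Per-step :class:`~patchtension.membrane_imaging.CircleFit` with
        ``radius_um`` populated, or ``None`` for a step without a usable fit
        (recorded as an absent point carrying a ``missing-fit`` flag).
    frame_indices:
        Optional per-step frame index for provenance.
    """
    points: list[TensionPoint] = []
    for step_id, dp in enumerate(pressures_mmhg):
        dp = float(dp)
        dp_pa = pressure_to_pascals(dp)
        fit = fits[step_id] if step_id < len(fits) else None
        frame = None if frame_indices is None else frame_indices[step_id]
        if fit is None or fit.radius_um is None:
            points.append(
                TensionPoint(
                    step_id=step_id,
                    dp_mmhg=dp,
                    dp_pa=dp_pa,
                    r_um=None,
                    tension_mn_per_m=None,
                    frame_index=frame,
                    fit_method=None,
                    flags=("missing-fit",),
                )
            )
            continue
        r_um = fit.radius_um
        tension = laplace_tension(dp_pa, r_um * 1e-6)
        points.append(
            TensionPoint(
                step_id=step_id,
                dp_mmhg=dp,
                dp_pa=dp_pa,
                r_um=r_um,
                tension_mn_per_m=tension,
                frame_index=frame,
                fit_method=fit.method,
                flags=tension_flags(tension, r_um, flat_radius_um),
            )
        )
    return points


def tension_table(points: list[TensionPoint], patch_id: str = "patch") -> pd.DataFrame:
    """Tidy per-step table (one row per stimulus step, units in column names)."""
    df = pd.DataFrame(
        {
            "patch_id": patch_id,
            "step_id": [p.step_id for p in points],
            "dP_mmHg": [p.dp_mmhg for p in points],
            "dP_Pa": [p.dp_pa for p in points],
            "r_um": [p.r_um for p in points],
            "T_mN_per_m": [p.tension_mn_per_m for p in points],
            "flags": [";".join(p.flags) for p in points],
        }
    )
    df.attrs["note"] = BASAL_TENSION_NOTE
    return df
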