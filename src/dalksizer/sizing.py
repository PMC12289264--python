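"""Surgical recommendation layer.

Turns the DM arc-length geometry into actionable numbers: the exact punch
size that matches the retained Descemet's membrane, the nearest punch a
surgeon can actually buy (0.25-mm steps), the signed mismatch for a punch
the surgeon has already chosen, and the inverse problem (which trephine to
cut so that a punch in stock fits exactly).

A positive mismatch — DM arc longer than the graft — is the fold-forming
direction: the membrane has nowhere to go but to wrinkle under the sutured
button.  Oversizing (negative mismatch) is not flagged.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from ._constants import KINDEX_DEFAULT, PUNCH_STEP_DEFAULT, REL_TOL
from .core_geometry import diopters_to_radius, dm_arc_length
from .errors import DomainError, GeometryError

__all__ = [
    "SnapPolicy",
    "PunchRecommendation",
    "MismatchReport",
    "round_half_away",
    "snap_to_step",
    "recommend_punch",
    "assess_mismatch",
    "trephine_for_punch",
]


class SnapPolicy(str, enum.Enum):
    """How to resolve an exact size that is not an available punch size.

    ``NEAREST_UP_ON_TIE`` (default) picks the closest step and breaks exact
    ties upward — undersizing is the fold-forming direction, so a tie goes
    to the larger graft.  ``ALWAYS_UP`` never recommends below the exact
    size.
    """

    NEAREST_UP_ON_TIE = "nearest-up-on-tie"
    NEAREST_DOWN_ON_TIE = "nearest-down-on-tie"
    ALWAYS_UP = "always-up"


@dataclass(frozen=True)
class PunchRecommendation:
    exact_size: float      # unrounded DM arc length, mm
    table_size: float      # rounded to 2 decimals as printed in the grid
    snapped_size: float    # nearest available punch, mm
    step: float            # punch granularity, mm
    snap_policy: SnapPolicy


@dataclass(frozen=True)
class MismatchReport:
    dm_arc: float     # mm
    punch: float      # mm
    mismatch: float   # signed, dm_arc - punch
    fold_risk: bool   # True iff mismatch exceeds the risk threshold


def round_half_away(value: float, decimals: int = 2) -> float:
    """Round half away from zero (0.125 -> 0.13 at 2 decimals).

    Python's built-in ``round`` uses banker's rounding; clinical tables round
    halves up, so the grid uses this rule throughout.
    """
    factor = 10.0**decimals
    scaled = value * factor
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / factor


def snap_to_step(
    size: float,
    step: float = PUNCH_STEP_DEFAULT,
    policy: SnapPolicy = SnapPolicy.NEAREST_UP_ON_TIE,
) -> float:
    """Snap an exact size to the punch-availability grid.

    Idempotent: a size already on the grid is returned unchanged.
    """
    if step <= 0:
        raise DomainError(f"step must be positive (got {step})")
    policy = SnapPolicy(policy)
    ratio = size / step
    nearest = round(ratio)
    if math.isclose(nearest * step, size, rel_tol=REL_TOL, abs_tol=REL_TOL):
        return nearest * step  # already on the grid (within tolerance)
    lower = math.floor(ratio)
    frac = ratio - lower
    if policy is SnapPolicy.ALWAYS_UP:
        up = True
    elif math.isclose(frac, 0.5, rel_tol=0.0, abs_tol=REL_TOL):
        up = policy is SnapPolicy.NEAREST_UP_ON_TIE
    else:
        up = frac > 0.5
    return (lower + 1) * step if up else lower * step


def recommend_punch(
    keratometry: float,
    trephine: float,
    *,
    kindex: float = KINDEX_DEFAULT,
    step: float = PUNCH_STEP_DEFAULT,
    snap_policy: SnapPolicy = SnapPolicy.NEAREST_UP_ON_TIE,
) -> PunchRecommendation:
    """Recommend the donor punch size matching the retained DM arc.

    ``exact_size`` is the unrounded arc; ``table_size`` is the 2-decimal
    value as a printed lookup table would show it; ``snapped_size`` is the
    punch the surgeon picks from the 0.25-mm inventory.  Snapping operates on
    the exact size, not its printed rounding.
    """
    exact = dm_arc_length(keratometry, trephine, kindex=kindex)
    return PunchRecommendation(
        exact_size=exact,
        table_size=round_half_away(exact, 2),
        snapped_size=snap_to_step(exact, step, snap_policy),
        step=step,
        snap_policy=SnapPolicy(snap_policy),
    )


def assess_mismatch(
    keratometry: float,
    trephine: float,
    punch: float,
    *,
    kindex: float = KINDEX_DEFAULT,
    risk_threshold: float = 0.0,
) -> MismatchReport:
    """Signed DM-arc / graft mismatch for a chosen punch size.

    ``fold_risk`` is True when the membrane is longer than the graft by more
    than ``risk_threshold`` (default 0: any undersizing is flagged, because
    no clinically safe slack has been established).
    """
    if punch <= 0:
        raise DomainError(f"punch size must be positive (got {punch})")
    arc = dm_arc_length(keratometry, trephine, kindex=kindex)
    mismatch = arc - punch
    return MismatchReport(
        dm_arc=arc,
        punch=punch,
        mismatch=mismatch,
        fold_risk=mismatch > risk_threshold,
    )


def trephine_for_punch(
    keratometry: float, target_punch: float, *, kindex: float = KINDEX_DEFAULT
) -> float:
    """Inverse problem: trephine diameter whose DM arc equals ``target_punch``.

    Inverts x = r·α with chord = 2r·sin(α/2), i.e.
    ``chord = 2r·sin(target/(2r))``.  The arc of a cap cannot exceed the
    semicircular arc π·r, beyond which no trephine exists.
    """
    if target_punch <= 0:
        raise DomainError(f"target punch must be positive (got {target_punch})")
    radius = diopters_to_radius(keratometry, kindex)
    if target_punch > math.pi * radius:
        raise GeometryError(
            f"target punch {target_punch} mm exceeds the semicircular arc "
            f"{math.pi * radius:.4f} mm for r = {radius:.4f} mm"
        )
    return 2.0 * radius * math.sin(target_punch / (2.0 * radius))
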