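"""Closed-form geometry of the recipient corneal bed.

In deep anterior lamellar keratoplasty (DALK) the trephine cuts a circular
button out of the recipient cornea, which is modelled here as a sphere of
radius ``r``.  Connecting both ends of the trephine chord to the centre of
curvature forms an isosceles triangle with equal sides ``r`` and base equal
to the trephine diameter.  The cosine rule yields the apex angle α

    cos α = (b² + c² − a²) / 2bc   with b = c = r, a = chord
          = 1 − chord² / (2 r²)

and the arc of Descemet's membrane (DM) left on the recipient bed is the
circular arc subtended by that angle, ``x = r·α`` (α in radians).  Because
the donor cornea is flattened under the punch, the donor button diameter
equals the punch size, so the DM arc length is the punch size that avoids a
DM/graft mismatch.

All functions here are pure scalar functions; the keratometric power K (in
diopters) is converted to the radius of curvature via ``r = kindex / K``
with the standard keratometric constant 337.5 D·mm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from ._constants import (
    KINDEX_DEFAULT,
    K_PLAUSIBLE_RANGE,
    K_TABLE_RANGE,
    REL_TOL,
    TREPHINE_PLAUSIBLE_RANGE,
    TREPHINE_TABLE_RANGE,
)
from .errors import ClinicalRangeWarning, DomainError, GeometryError

__all__ = [
    "CorneaModel",
    "ChordSpec",
    "ArcSolution",
    "diopters_to_radius",
    "apex_angle_from_chord",
    "arc_length",
    "dm_arc_length",
]


@dataclass(frozen=True)
class CorneaModel:
    """Recipient cornea as a sphere of a single curvature.

    Parameters
    ----------
    keratometry : float
        Corneal power in diopters (D).
    radius : float
        Radius of curvature in mm; equals ``kindex / keratometry``.
    kindex : float
        Diopter-to-radius conversion constant in D·mm.
    """

    keratometry: float
    radius: float
    kindex: float = KINDEX_DEFAULT

    def __post_init__(self) -> None:
        if self.keratometry <= 0 or self.radius <= 0:
            raise DomainError(
                "keratometry and radius must both be positive "
                f"(got K={self.keratometry}, r={self.radius})"
            )
        if not math.isclose(
            self.radius * self.keratometry, self.kindex, rel_tol=REL_TOL
        ):
            raise DomainError(
                f"inconsistent model: radius*keratometry = "
                f"{self.radius * self.keratometry!r} but kindex = {self.kindex!r}"
            )

    @classmethod
    def from_keratometry(
        cls, keratometry: float, kindex: float = KINDEX_DEFAULT
    ) -> "CorneaModel":
        """Build the model from a keratometric power alone."""
        return cls(
            keratometry=keratometry,
            radius=diopters_to_radius(keratometry, kindex),
            kindex=kindex,
        )


@dataclass(frozen=True)
class ChordSpec:
    """Trephine diameter, the base of the isosceles triangle, in mm."""

    chord: float

    def __post_init__(self) -> None:
        if self.chord <= 0:
            raise DomainError(f"trephine diameter must be positive (got {self.chord})")


@dataclass(frozen=True)
class ArcSolution:
    """Apex angle α (radians) and DM arc length x (mm) for one chord on one
    cornea."""

    apex_angle: float
    arc_length: float


def diopters_to_radius(keratometry: float, kindex: float = KINDEX_DEFAULT) -> float:
    """Convert keratometric power (D) to radius of curvature (mm).

    Uses ``r = kindex / K``; the default constant 337.5 D·mm is the standard
    keratometric index n = 1.3375.  E.g. 45 D -> 7.5 mm.
    """
    if keratometry <= 0:
        raise DomainError(f"keratometry must be positive (got {keratometry})")
    if kindex <= 0:
        raise DomainError(f"kindex must be positive (got {kindex})")
    return kindex / keratometry


def apex_angle_from_chord(radius: float, chord: float) -> float:
    """Apex angle α (radians) subtended at the centre of curvature by a chord.

    Cosine rule on the isosceles triangle with equal sides ``radius`` and
    base ``chord``: ``α = arccos(1 − chord²/(2·radius²))``, in (0, π].

    Raises
    ------
    DomainError
        If ``radius`` or ``chord`` is non-positive.
    GeometryError
        If the chord exceeds the sphere's diameter ``2·radius``.
    """
    if radius <= 0:
        raise DomainError(f"radius must be positive (got {radius})")
    if chord <= 0:
        raise DomainError(f"chord must be positive (got {chord})")
    if chord > 2.0 * radius:
        raise GeometryError(
            f"chord {chord} mm exceeds the corneal sphere diameter "
            f"{2.0 * radius} mm"
        )
    cos_alpha = 1.0 - chord * chord / (2.0 * radius * radius)
    # clamp the ulp excursion at chord == 2r
    return math.acos(max(-1.0, min(1.0, cos_alpha)))


def arc_length(radius: float, apex_angle: float) -> float:
    """Arc length x = r·α (α in radians); the degree form 2πr(α/360) is the
    same quantity."""
    if radius <= 0:
        raise DomainError(f"radius must be positive (got {radius})")
    if apex_angle < 0 or apex_angle > 2.0 * math.pi:
        raise DomainError(f"apex angle must lie in [0, 2π] (got {apex_angle})")
    return radius * apex_angle


def _warn_if_outside_envelope(keratometry: float, trephine: float) -> None:
    k_lo, k_hi = K_TABLE_RANGE
    t_lo, t_hi = TREPHINE_TABLE_RANGE
    if k_lo <= keratometry <= k_hi and t_lo <= trephine <= t_hi:
        return
    pk_lo, pk_hi = K_PLAUSIBLE_RANGE
    pt_lo, pt_hi = TREPHINE_PLAUSIBLE_RANGE
    if pk_lo <= keratometry <= pk_hi and pt_lo <= trephine <= pt_hi:
        warnings.warn(
            f"K={keratometry} D, trephine={trephine} mm is outside the "
            f"tabulated envelope [{k_lo}, {k_hi}] D x [{t_lo}, {t_hi}] mm; "
            "the geometry is valid but clinically unvalidated",
            ClinicalRangeWarning,
            stacklevel=3,
        )
    else:
        warnings.warn(
            f"K={keratometry} D, trephine={trephine} mm is far outside the "
            "plausible range for a human cornea "
            f"([{pk_lo}, {pk_hi}] D x [{pt_lo}, {pt_hi}] mm); "
            "proceeding on geometry alone",
            ClinicalRangeWarning,
            stacklevel=3,
        )


def dm_arc_length(
    keratometry: float, trephine: float, kindex: float = KINDEX_DEFAULT
) -> float:
    """Unrounded arc length (mm) of Descemet's membrane left on the recipient
    bed after trephination.

    Composes the diopter-to-radius conversion, the cosine-rule apex angle and
    the arc formula.  The result always exceeds the trephine diameter (an arc
    is longer than its chord) and converges to it as the cornea flattens.

    Parameters
    ----------
    keratometry : float
        Recipient corneal power in diopters.
    trephine : float
        Trephine diameter in mm (the chord).
    kindex : float, optional
        Diopter-to-radius constant, default 337.5 D·mm.
    """
    radius = diopters_to_radius(keratometry, kindex)
    _warn_if_outside_envelope(keratometry, trephine)
    alpha = apex_angle_from_chord(radius, trephine)
    return arc_length(radius, alpha)


def solve_arc(
    keratometry: float, trephine: float, kindex: float = KINDEX_DEFAULT
) -> ArcSolution:
    """Like :func:`dm_arc_length` but returning the apex angle as well."""
    radius = diopters_to_radius(keratometry, kindex)
    _warn_if_outside_envelope(keratometry, trephine)
    alpha = apex_angle_from_chord(radius, trephine)
    return ArcSolution(apex_angle=alpha, arc_length=arc_length(radius, alpha))
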