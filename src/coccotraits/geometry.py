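"""Coccosphere and cell geometry.

Coccosphere volume is computed from the two axes measurable on a 2-D SEM
image (short axis *d*, long axis *h*, both in µm) using one of three
idealised shape classes assigned per taxon:

* prolate sphere      V = (π/6)·d²·h   (also used for spherical and
  ellipsoid-shaped coccospheres, whose third axis cannot be measured)
* cone + half sphere  V = (π/4)·d²·h
* double cone         V = (π/12)·d²·h  (e.g. the fusiform, tapering
  coccospheres of *Calciosolenia*)

Coccosphere size is reported as equivalent spherical diameter (ESD), the
diameter of the sphere with the same volume.  Cell size is estimated from
coccosphere size via the taxon-specific fraction ``y`` of coccosphere
volume occupied by the cell, which reduces to ``ESD · y^(1/3)``.
Multilayer coccospheres (notably *Emiliania huxleyi*) are first shrunk to
an equivalent single-layer diameter by subtracting two coccolith
thicknesses per extra layer.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

from .errors import DomainError

__all__ = [
    "ShapeClass",
    "CoccosphereGeometry",
    "coccosphere_volume",
    "equivalent_spherical_diameter",
    "cell_diameter_from_coccosphere",
    "multilayer_corrected_diameter",
    "full_length_from_partial",
]


class ShapeClass(str, enum.Enum):
    """Idealised coccosphere shape determining the volume formula."""

    PROLATE_SPHERE = "prolate_sphere"
    CONE_HALF_SPHERE = "cone_half_sphere"
    DOUBLE_CONE = "double_cone"


# volume = coefficient · d² · h
_SHAPE_COEFFICIENT = {
    ShapeClass.PROLATE_SPHERE: math.pi / 6.0,
    ShapeClass.CONE_HALF_SPHERE: math.pi / 4.0,
    ShapeClass.DOUBLE_CONE: math.pi / 12.0,
}


@dataclass(frozen=True)
class CoccosphereGeometry:
    """Measured coccosphere axes (µm) plus shape class and layer count.

    Axes are normalised defensively so ``short_axis_d <= long_axis_h``;
    ``axes_swapped`` records whether the inputs arrived reversed.
    """

    short_axis_d: float
    long_axis_h: float
    shape_class: ShapeClass = ShapeClass.PROLATE_SPHERE
    n_layers: int = 1
    axes_swapped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        d, h = self.short_axis_d, self.long_axis_h
        if not (d > 0 and h > 0):
            raise DomainError(f"coccosphere axes must be positive, got d={d}, h={h}")
        if d > h:
            object.__setattr__(self, "short_axis_d", h)
            object.__setattr__(self, "long_axis_h", d)
            object.__setattr__(self, "axes_swapped", True)
        if self.n_layers < 1:
            raise DomainError(f"n_layers must be >= 1, got {self.n_layers}")


def coccosphere_volume(geom: CoccosphereGeometry) -> float:
    """Coccosphere volume (µm³) from axes and shape class."""
    coef = _SHAPE_COEFFICIENT[ShapeClass(geom.shape_class)]
    return coef * geom.short_axis_d**2 * geom.long_axis_h


def equivalent_spherical_diameter(volume: float) -> float:
    """Diameter (µm) of the sphere with the given volume (µm³)."""
    if not volume > 0:
        raise DomainError(f"volume must be positive, got {volume}")
    return (6.0 * volume / math.pi) ** (1.0 / 3.0)


def cell_diameter_from_coccosphere(esd: float, y_fraction: float) -> float:
    """Equivalent spherical cell diameter (µm) from coccosphere ESD.

    ``y_fraction`` is the taxon-specific proportion of coccosphere volume
    occupied by the organic cell; the closed form is ``esd · y^(1/3)``.
    """
    if not esd > 0:
        raise DomainError(f"esd must be positive, got {esd}")
    if not 0 < y_fraction <= 1:
        raise DomainError(f"y_fraction must be in (0, 1], got {y_fraction}")
    return esd * y_fraction ** (1.0 / 3.0)


def multilayer_corrected_diameter(
    esd: float, n_layers: int, coccolith_thickness: float
) -> float:
    """Shrink a multilayer coccosphere diameter to its single-layer equivalent.

    Each extra coccolith layer adds one coccolith thickness on both sides of
    the sphere, so the correction is ``2 · (n_layers − 1) · thickness``.
    """
    if n_layers < 1:
        raise DomainError(f"n_layers must be >= 1, got {n_layers}")
    if not coccolith_thickness > 0:
        raise DomainError(f"thickness must be positive, got {coccolith_thickness}")
    corrected = esd - 2.0 * (n_layers - 1) * coccolith_thickness
    if not corrected > 0:
        raise DomainError(
            f"multilayer correction ({n_layers} layers, t={coccolith_thickness}) "
            f"exceeds coccosphere diameter {esd}"
        )
    return corrected


def full_length_from_partial(half_length: float) -> float:
    """Double a centre-to-rim partial coccolith measurement to a full length.

    Used when the most flat-lying coccolith is partly overlapped and only
    the distance from the central-area mid-point to the distal shield edge
    could be measured.
    """
    if not half_length > 0:
        raise DomainError(f"half_length must be positive, got {half_length}")
    return 2.0 * half_length
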