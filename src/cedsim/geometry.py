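"""Distribution shapes against the posterior dorsal putamen.

The infusion target — the posterior dorsal putamen, the region most
depleted of dopamine in Parkinson's disease — is approximated as a
rectangular box from atlas measurements: 1.92 cm long, 1.15 cm high, and
1.12 or 0.90 cm wide depending on the level at which width is measured.
Per-catheter distribution volume is projected at 0.5 mL (two catheters per
putamen over a ~1 mL volume of interest).

A reflux-resistant catheter in isotropic tissue produces a spherical Vd,

    Vd = (4/3) pi r^3;

with controlled reflux along the track the shape is instead a hemisphere
below the tip plus a cylinder of reflux length h above it,

    Vd = (2/3) pi r^3 + pi r^2 h,

with total length r + h. For a fixed Vd, total length and diameter trade
off inversely, which is what makes the cylindrical pattern attractive for
an elongated target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import InfeasibleGeometryError, ParameterError

__all__ = [
    "RoiBox",
    "CylinderModel",
    "FitReport",
    "DEFAULT_ROI",
    "CATHETER_VOLUME_ML",
    "sphere_diameter_for_vd",
    "cylinder_vd",
    "solve_cylinder",
    "check_roi_fit",
]

#: Volume occupied by a typical cannula (1 cm x 1 mm OD), mL — reported
#: informationally; negligible against a 0.5 mL Vd and never subtracted.
CATHETER_VOLUME_ML = np.pi * 0.05**2 * 1.0  # ~0.008 mL


@dataclass(frozen=True)
class RoiBox:
    """Box model of the target region (cm).

    ``width_levels`` lists the width measured at labelled dorsoventral
    levels; a shape must fit the narrowest one it spans, and each level is
    checked independently.
    """

    length: float = 1.92
    height: float = 1.15
    width_levels: tuple[float, ...] = (1.12, 0.90)

    def __post_init__(self) -> None:
        if self.length <= 0 or self.height <= 0 or any(w <= 0 for w in self.width_levels):
            raise ParameterError("all ROI dimensions must be positive")


DEFAULT_ROI = RoiBox()


@dataclass(frozen=True)
class CylinderModel:
    """Hemisphere-capped cylinder distribution: radius r, reflux length h (cm)."""

    radius: float
    reflux_length: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ParameterError(f"radius must be > 0, got {self.radius}")
        if self.reflux_length < 0:
            raise ParameterError(f"reflux_length must be >= 0, got {self.reflux_length}")

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius

    @property
    def total_length(self) -> float:
        return self.radius + self.reflux_length


@dataclass(frozen=True)
class FitReport:
    """Per-dimension clearance of a shape inside the ROI box."""

    margins: dict[str, float]
    overflow: bool

    @property
    def overflow_dimensions(self) -> list[str]:
        return [k for k, v in self.margins.items() if v < 0]


def sphere_diameter_for_vd(vd: float) -> float:
    """Diameter of the sphere holding volume ``vd`` (mL -> cm)."""
    if vd <= 0:
        raise ParameterError(f"vd must be > 0, got {vd}")
    return 2.0 * (3.0 * vd / (4.0 * np.pi)) ** (1.0 / 3.0)


def cylinder_vd(model: CylinderModel) -> float:
    """Volume of the hemisphere-capped cylinder, mL."""
    r, h = model.radius, model.reflux_length
    return (2.0 / 3.0) * np.pi * r**3 + np.pi * r**2 * h


def solve_cylinder(
    vd: float,
    diameter: float | None = None,
    total_length: float | None = None,
) -> CylinderModel:
    """Invert the cylinder volume for one fixed dimension.

    Exactly one of ``diameter`` or ``total_length`` must be given. With the
    diameter fixed the reflux length follows linearly; with the total
    length L fixed the radius solves the cubic
    (2/3) pi r^3 + pi r^2 (L - r) = vd on (0, L], found by bisection.
    The returned model reproduces ``vd`` to < 1e-9 mL.

    Raises
    ------
    InfeasibleGeometryError
        If the fixed dimension cannot enclose ``vd`` with h >= 0 (e.g. the
        hemisphere alone already exceeds the volume).
    """
    if vd <= 0:
        raise ParameterError(f"vd must be > 0, got {vd}")
    if (diameter is None) == (total_length is None):
        raise ParameterError("fix exactly one of diameter or total_length")

    if diameter is not None:
        if diameter <= 0:
            raise ParameterError("diameter must be > 0")
        r = diameter / 2.0
        hemi = (2.0 / 3.0) * np.pi * r**3
        if hemi > vd * (1 + 1e-12):
            raise InfeasibleGeometryError(
                f"hemisphere of d={diameter} cm holds {hemi:.4g} mL > vd={vd} mL"
            )
        h = max((vd - hemi) / (np.pi * r**2), 0.0)
        return CylinderModel(radius=r, reflux_length=h)

    L = total_length
    if L <= 0:
        raise ParameterError("total_length must be > 0")

    def vol_minus_vd(r: float) -> float:
        return (2.0 / 3.0) * np.pi * r**3 + np.pi * r**2 * (L - r) - vd

    # volume is increasing in r on (0, L]; r = L is the hemisphere-only limit
    if vol_minus_vd(L) < -1e-15:
        raise InfeasibleGeometryError(
            f"total length {L} cm cannot hold vd={vd} mL even as a hemisphere"
        )
    r = brentq(vol_minus_vd, 1e-12, L, xtol=1e-15, rtol=1e-15)
    return CylinderModel(radius=r, reflux_length=L - r)


def check_roi_fit(shape, roi: RoiBox = DEFAULT_ROI) -> FitReport:
    """Compare a distribution shape's extents against the ROI box.

    ``shape`` is a sphere diameter (float, cm) or a :class:`CylinderModel`
    whose axis is taken as aligned with the ROI's long axis (catheter
    inclination is out of scope). Margins are ROI dimension minus shape
    extent per dimension; any negative margin flags overflow. Width is
    checked at every measured level.
    """
    if isinstance(shape, CylinderModel):
        axial, lateral = shape.total_length, shape.diameter
    else:
        d = float(shape)
        if d < 0:
            raise ParameterError("sphere diameter must be >= 0")
        axial = lateral = d
    margins = {"length": roi.length - axial, "height": roi.height - lateral}
    for i, w in enumerate(roi.width_levels, start=1):
        margins[f"width_level_{i}"] = w - lateral
    return FitReport(margins=margins, overflow=any(v < 0 for v in margins.values()))
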