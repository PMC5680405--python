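#!/usr/bin/env python
"""Stage 4 — fitting 0.5 mL of distribution into the posterior dorsal putamen.

Solves the spherical and hemisphere-capped-cylinder shape models for the
projected per-catheter Vd of 0.5 mL and checks each against the atlas box
(1.92 x 1.15 x 1.12/0.90 cm). The sphere (0.98 cm diameter) overflows the
narrow 0.90 cm width level; a long thin cylinder does not — controlled
reflux is geometrically preferable for this elongated target.

Writes results/target_geometry.json.
"""

import json
from pathlib import Path

from cedsim.geometry import (
    CATHETER_VOLUME_ML,
    DEFAULT_ROI,
    check_roi_fit,
    solve_cylinder,
    sphere_diameter_for_vd,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"
VD_ML = 0.5


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    sphere_d = sphere_diameter_for_vd(VD_ML)
    sphere_fit = check_roi_fit(sphere_d)
    wide = solve_cylinder(VD_ML, diameter=1.12)
    thin = solve_cylinder(VD_ML, total_length=1.90)

    out = {
        "vd_ml": VD_ML,
        "roi_cm": {
            "length": DEFAULT_ROI.length,
            "height": DEFAULT_ROI.height,
            "width_levels": list(DEFAULT_ROI.width_levels),
        },
        "sphere": {
            "diameter_cm": sphere_d,
            "overflow": sphere_fit.overflow,
            "overflow_dimensions": sphere_fit.overflow_dimensions,
        },
        "cylinder_wide": {
            "diameter_cm": wide.diameter,
            "total_length_cm": wide.total_length,
            "overflow": check_roi_fit(wide).overflow,
        },
        "cylinder_thin": {
            "diameter_cm": thin.diameter,
            "total_length_cm": thin.total_length,
            "overflow": check_roi_fit(thin).overflow,
        },
        "catheter_volume_ml": CATHETER_VOLUME_ML,
    }
    (RESULTS / "target_geometry.json").write_text(json.dumps(out, indent=2) + "\n")

    print(f"projected per-catheter Vd: {VD_ML} mL")
    print(
        f"sphere: d = {sphere_d:.2f} cm -> overflow at "
        f"{', '.join(sphere_fit.overflow_dimensions)} "
        f"(ROI width level 2 = {DEFAULT_ROI.width_levels[1]} cm)"
    )
    print(
        f"wide cylinder: d = {wide.diameter:.2f} cm x L = {wide.total_length:.2f} cm, "
        f"overflow = {check_roi_fit(wide).overflow}"
    )
    print(
        f"thin cylinder: d = {thin.diameter:.2f} cm x L = {thin.total_length:.2f} cm, "
        f"overflow = {check_roi_fit(thin).overflow}"
    )
    print(f"catheter dead volume: {CATHETER_VOLUME_ML * 1000:.0f} uL (negligible)")


if __name__ == "__main__":
    main()
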