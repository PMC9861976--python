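"""CAM cRORA/iRORA size classification on the en face map.

Builds a map with one 500-um lesion (rotated 45 degrees, so its greatest
linear dimension is not horizontal) and one 150-um lesion, measures each
lesion's greatest linear dimension in microns, and applies the CAM
consensus 250-um threshold.
"""

from octga import LesionSpec, analytic_enface, analyze_map, make_geometry
from octga.enface import EnFaceMap

import numpy as np

geometry = make_geometry("spectralis")
lesions = [
    LesionSpec(2000, 2000, semi_axis_a_um=250, semi_axis_b_um=100, rotation_rad=np.pi / 4),
    LesionSpec(4500, 4500, semi_axis_a_um=75, semi_axis_b_um=60),
]
emap = EnFaceMap(analytic_enface(geometry, lesions), geometry)

report = analyze_map(emap, threshold_um=250.0)
for lesion in report.lesions:
    print(
        f"lesion {lesion.label}: GLD {lesion.gld_um:6.1f} um, "
        f"area {lesion.area_um2 / 1e6:.4f} mm^2 -> {lesion.cam_class}"
    )
print(f"GA area, all lesions:   {report.area_percent_all:.3f}% of scan")
print(f"GA area, cRORA only:    {report.area_percent_cRORA_only:.3f}% of scan")
# The 500-um lesion is cRORA (>= 250 um in its greatest, non-horizontal
# dimension); the 150-um lesion is iRORA and drops out of the cRORA-only area.
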