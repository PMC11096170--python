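"""Apply the DECT empirical conversions and read a density line profile.

Converts emulated DECT parametric maps to mass density and RSP with the
published empirical formulas and samples a line profile across a
water / bone-mimic boundary.
"""

import numpy as np

import mrproton as mp
from mrproton.evaluation import line_profile, per_phantom_report
from mrproton.synthetic_imaging import VolumeImage

tissues = mp.load_tissues()
config = mp.PhantomSceneConfig(inserts=(("45% HA bone", (0.0, 0.0)),), seed=3)
labels = mp.build_scene(config, tissues)
maps = mp.render_parametric_maps(labels, tissues, seed=3)

density = VolumeImage(
    mp.dect_empirical_density(np.asarray(maps.rho_e.grid, dtype=np.float64)),
    labels.spacing, "density-dect",
)
rsp = VolumeImage(
    mp.dect_empirical_rsp(
        np.asarray(maps.rho_e.grid, dtype=np.float64),
        np.clip(np.asarray(maps.z_eff.grid, dtype=np.float64), 0, None),
    ),
    labels.spacing, "rsp-dect",
)

truth_density, truth_rsp = mp.ground_truth_maps(labels, tissues)
mask = labels.container_mask()
for pred, truth, q in ((density, truth_density, "density"), (rsp, truth_rsp, "rsp")):
    report = per_phantom_report(pred, truth, labels, mask, "DECT empirical", q)
    print(report.to_string(index=False))

nz, ny, nx = labels.shape
profile = line_profile(density, (nz // 2, ny // 2, 10), (nz // 2, ny // 2, nx // 2), 40)
print("\ndensity along a mid-slice ray (water -> bone mimic):")
print(profile.round(3).to_string(index=False))
# The profile steps from ~1.0 g/cm^3 in water to ~1.4 g/cm^3 inside the
# hydroxyapatite insert; the report MAPEs of a percent or two reflect the
# empirical formulas' systematic error plus the parametric-map noise.
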