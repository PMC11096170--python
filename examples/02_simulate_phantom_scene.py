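"""Build a synthetic phantom cylinder and inspect its rendered channels.

Constructs a water cylinder holding two tissue inserts, renders one MR
sequence with SNR-30 noise, water-normalizes it, and emulates the DECT
parametric maps, printing per-region statistics.
"""

import numpy as np

import mrproton as mp

tissues = mp.load_tissues()
config = mp.PhantomSceneConfig(
    inserts=(("Muscle", (-28.6, -28.6)), ("45% HA bone", (28.6, 28.6))),
    seed=7,
)
labels = mp.build_scene(config, tissues)
print(f"grid {labels.shape}, legend {dict(labels.legend)}")

raw = mp.render_sequence(labels, mp.DEFAULT_SIGNAL_TABLE, "T1-D-P-W", seed=7)
normalized = mp.normalize_by_water(raw, mp.water_mask(labels))
maps = mp.render_parametric_maps(labels, tissues, seed=8)

for tid, name in labels.legend.items():
    sel = labels.grid == tid
    sig = normalized.grid[sel]
    print(f"{name:14s} signal {sig.mean():5.3f} +/- {sig.std():5.3f}   "
          f"rho_e {maps.rho_e.grid[sel].mean():5.3f}   "
          f"z_eff {maps.z_eff.grid[sel].mean():5.2f}")

water = normalized.grid[mp.water_mask(labels)]
print(f"water mean {water.mean():.9f} (normalization reference), "
      f"empirical SNR {water.mean() / water.std():.1f}")
# The per-region means recover the configured nominal contrasts; water sits
# at exactly 1 after normalization and its SNR matches the configured 30.
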