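"""Quantify per-animal fluorescent readouts for one well.

Counts animals by their pharyngeal red-head marker (robust to body
overlap), measures GFP inclusion spots over the whole well, and normalizes
to a per-animal readout — the quantity a screen compares across wells.
"""

import numpy as np

from wormhcs import (calibrate_head_gate, count_heads, detect_spots,
                     make_scene, per_animal_metrics, render_well)

rng = np.random.default_rng(2)

refs = [render_well(make_scene(20, adult_fraction=1.0, rng=rng),
                    channels=("tritc",), rng=rng).channels["tritc"]
        for _ in range(2)]
head_gate = calibrate_head_gate(refs)
print(f"head gate: area >= {head_gate.min_spot_area:.1f} px^2 and "
      f"mean intensity >= {head_gate.min_mean_intensity:.0f}")

scene = make_scene(35, frame=(320, 320), adult_fraction=1.0,
                   gfp_inclusions=(2, 5), rng=rng)
images = render_well(scene, channels=("tritc", "gfp"), rng=rng)

heads, _ = count_heads(images.channels["tritc"], head_gate)
spots, _ = detect_spots(images.channels["gfp"], intensity_threshold=1000.0)
per = per_animal_metrics(spots, heads)

print(f"animals sorted: {len(scene.worms)}, heads counted: {heads}")
print(f"whole-well spots: {spots.spot_count}, total area {spots.total_spot_area:.0f} px^2")
print(f"per-animal spot count: {per.spot_count:.2f}  "
      f"(planted mean {np.mean([w.gfp_inclusion_count for w in scene.worms]):.2f})")
print(f"per-animal spot area:  {per.spot_area:.1f} px^2/animal")
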