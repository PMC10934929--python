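"""Segment a synthetic four-egg transmission frame and extract mean spectra.

Builds a toy hyperspectral cube, thresholds the high-contrast band (band 38,
~1078 nm) with Otsu's method, labels 4-connected components, and punches each
egg's mask through all 167 bands.
"""

import numpy as np

from candlepls import (GeneratorConfig, SyntheticFrameSpec, extract_spectra,
                       generate_hypercube, segment_eggs)

cfg = GeneratorConfig(seed=4)
frame = SyntheticFrameSpec()
cube = generate_hypercube(cfg, frame)
print(f"cube shape (rows, cols, bands): {cube.shape}")

masks = segment_eggs(cube)
print(f"found {len(masks)} eggs; ROI sizes: {[m.pixel_count for m in masks]} px")

spectra = extract_spectra(cube, masks, day=cfg.day)
for egg_id, label, spec in zip(spectra.ids, spectra.y, spectra.X):
    peak_band = int(np.argmax(spec)) + 1
    peak_nm = spectra.wavelengths[peak_band - 1]
    print(f"  {egg_id}: {label:12s} peak {spec.max():.3f} at band {peak_band} "
          f"({peak_nm:.0f} nm)")
print("\nNon-fertile eggs transmit more at the peak; that amplitude gap is"
      "\nwhat the PLS classifier exploits.")
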