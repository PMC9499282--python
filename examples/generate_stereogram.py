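"""Render a dynamic anticorrelated random-dot stereogram and save it.

Builds the circle-in-annulus configuration at a crossed 28-arcmin target
disparity (9-arcmin dots, 25% coverage, 1.9 arcmin/pixel), renders five
frames (an 80 ms presentation at 60 Hz), and writes PNG image pairs plus
region masks and a JSON metadata record.
"""

from pathlib import Path

import numpy as np

import stereodepth as sd

spec = sd.preset("exp1_circle", correlation="anticorrelated",
                 target_disparity=28.0, duration_ms=80)
seq = sd.render_sequence(spec, seed=0)
outdir = sd.write_sequence(seq, Path("scratch") / "acrds_circle")

left, right = seq.frames[0]
print(f"wrote {seq.n_frames} frame pairs to {outdir}/")
print(f"frame shape: {left.shape} pixels "
      f"({left.shape[1] * spec.pixel_pitch / 60:.1f} deg across)")
print(f"luminance levels (cd/m^2): {sorted(np.unique(left))}")
tgt = seq.target_mask.sum() * spec.pixel_pitch**2
print(f"target disc area: {tgt:.0f} arcmin^2 "
      f"(printed geometry: {np.pi * 138**2:.0f})")
# Inside the target the two eyes' dots have opposite contrast polarity;
# the annulus is binocularly matched at zero disparity.
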