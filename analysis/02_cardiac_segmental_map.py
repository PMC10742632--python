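"""16-segment cardiac T2* mapping on a noisy annulus phantom.

Builds the three-slice (basal/mid/apical) wedge phantom with known
segmental T2*, runs contour-based segmentation + per-segment fitting, and
reports recovery per AHA segment.  Writes results/cardiac_recovery.csv.
"""

import numpy as np
import pandas as pd
from pathlib import Path

from ferriscope.cardiac_mapping import build_heart_map, count_low_segments, segment_masks
from ferriscope.relaxometry import roi_mean_decay
from ferriscope.synthetic_data import PhantomSpec, make_phantom

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

truth = [7.0 + 2 * k for k in range(16)]
ph = make_phantom(PhantomSpec(geometry="cardiac_annulus_16seg", t2star_ms=truth,
                              noise_sigma=2.0, seed=11, grid_shape=(128, 128)))
series = []
for s in ph.slices:
    for m in segment_masks(s.contours, s.stack.shape[1:]):
        series.append(roi_mean_decay(s.stack, m, ph.echo_times_ms, ph.noise_sigma))
hm = build_heart_map(series)

table = pd.DataFrame({
    "segment": np.arange(1, 17),
    "t2star_true_ms": truth,
    "t2star_fit_ms": hm.segment_values,
    "model": [f.model for f in hm.fits],
    "rel_error_pct": 100 * np.abs(hm.segment_values - np.asarray(truth)) / np.asarray(truth),
})
table.to_csv(OUT / "cardiac_recovery.csv", index=False)
print(table.round(3).to_string(index=False))
print(f"\nGlobal heart T2*: {hm.global_value:.2f} ms (truth {np.mean(truth):.2f}); "
      f"low segments (<= 20 ms): {hm.n_low_segments} "
      f"(truth {count_low_segments(truth)}); "
      f"worst segment error {table['rel_error_pct'].max():.2f}% at sigma/S0 = 0.02.")
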