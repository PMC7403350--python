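"""Relate pairwise letter reflectivity to decoder-space similarity.

Computes R_H, R_V and delta_R for the 325 letter pairs, embeds each letter
through a cross-validated 26-way decoder, and tests whether decoder
similarity r_IT rises with delta_R (three equal-range bins, one-tailed
tests).  With the default population (no mirror-symmetric tuning planted)
no effect is expected.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import OUT_DIR, run_config

from orthopop import pipeline

pipeline.run_pipeline(run_config(["stimuli", "simulate", "mirror"]))
m = json.loads((Path(OUT_DIR) / "mirror_stats.json").read_text())
for b in m["bins"]:
    print(f"delta_R bin [{b['delta_R_low']:.2f}, {b['delta_R_high']:.2f}]: "
          f"mean r_IT = {b['mean_r_IT']:.3f} +/- {b['se_r_IT']:.3f} "
          f"(n = {b['n_pairs']})")
print(f"right bin > 0: p = {m.get('p_right_positive', float('nan')):.3f}; "
      f"left bin > 0: p = {m.get('p_left_positive', float('nan')):.3f}; "
      f"right > left: p = {m.get('p_right_gt_left', float('nan')):.3f}")
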