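"""Single-site selectivity, topography and sparsity statistics.

Bootstrap exact tests for word selectivity per site, the binomial test of
the selective fraction against the 5% floor, the hemisphere-bias test,
Moran's I spatial autocorrelation on the electrode grids, and the sparsity
index of letter/position tuning against uniform and one-hot nulls.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import OUT_DIR, run_config

from orthopop import pipeline

pipeline.run_pipeline(run_config(["stimuli", "simulate", "sites"]))
s = json.loads((Path(OUT_DIR) / "site_stats.json").read_text())
print(f"word-selective sites: {s['n_selective']}/{s['n_sites']} "
      f"(binomial p vs 5%: {s['selective_fraction_p']:.2e})")
print(f"hemisphere bias p = {s['hemisphere_bias_p']:.3f}; "
      f"Moran's I = {s['moran_I']:.3f} (permutation p = {s['moran_p']:.2f})")
for axis in ("letters", "positions"):
    b = s[f"sparsity_{axis}"]
    print(f"sparsity over {axis}: median SI = {b['median_SI']:.3f} "
          f"(vs uniform null p = {b['vs_uniform']['p_greater']:.3f}, "
          f"vs one-hot null p = {b['vs_onehot']['p_less']:.3f})")
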