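"""Noise-adjusted consistency of the decoder with the reference pool.

Builds a decoder choice table from repeated cross-validation, bins choices
into ten bigram-frequency deciles per class, and compares the resulting d'
signature to the pooled reference behavior; the subject hold-out
distribution defines the behavioral ceiling.
"""
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import OUT_DIR, run_config

from orthopop import pipeline

pipeline.run_pipeline(run_config(["stimuli", "simulate", "consistency"]))
c = json.loads((Path(OUT_DIR) / "consistency.json").read_text())
d = c["decoder_vs_pool"]
print(f"decoder vs pool: rho_tilde = {d['rho_tilde']:.3f} "
      f"(raw {d['raw_rho']:.3f}; reliabilities {d['reliability_m']:.3f} / "
      f"{d['reliability_p']:.3f}; {d['n_undefined']} undefined resplits)")
print(f"subject hold-out ceiling: median rho_tilde = {c['holdout_median']:.3f}")
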