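"""Screen sites and run the 30-task decoding battery.

Applies the visual-drive (p < 0.001) and letter-reliability (p < 0.01)
screens, then decodes 20 letter-identification, 8 bigram-identification and
2 word-classification tasks with ten-fold cross-validated logistic readouts,
plus a site-count sweep for word classification.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from common import OUT_DIR, run_config

from orthopop import pipeline

pipeline.run_pipeline(run_config(["stimuli", "simulate", "screen", "decode"]))
screens = pd.read_csv(Path(OUT_DIR) / "site_screens.csv")
print(f"screens: {int(screens.visually_driven.sum())}/{len(screens)} visually driven, "
      f"{int(screens.reliable_letters.sum())}/{len(screens)} letter-reliable")
acc = pd.read_csv(Path(OUT_DIR) / "task_accuracies.csv")
for fam, sub in acc.groupby("family"):
    print(f"{fam}: n={len(sub)} balanced accuracy "
          f"{sub.balanced_accuracy.mean():.3f} "
          f"({sub.balanced_accuracy.min():.3f}-{sub.balanced_accuracy.max():.3f})")
sweep = pd.read_csv(Path(OUT_DIR) / "site_count_sweep.csv")
print("word classification vs site count:")
print(sweep.to_string(index=False))
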