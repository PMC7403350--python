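"""Simulate the neural population and the reference behavioral pool.

Generates a 200-site population (two 100 ms response windows, >30
repetitions per image, Poisson-like spike-count noise, 10% weakly
word-selective sites) responding to every stimulus, plus a six-subject
choice table whose errors track mean bigram frequency.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from common import OUT_DIR, run_config

from orthopop import pipeline, synth

pipeline.run_pipeline(run_config(["stimuli", "simulate"]))
tensor = synth.read_tensor(Path(OUT_DIR) / "responses.h5")
beh = pd.read_csv(Path(OUT_DIR) / "behavior.csv")
print(f"population: {tensor.n_sites} sites x {len(tensor.stimulus_ids)} stimuli "
      f"x {tensor.n_reps} repetitions, windows {tensor.window_labels}")
gt = tensor.ground_truth
print(f"planted: {int(gt.word_selective.sum())} word-selective sites "
      f"(|d'| targets within {gt.target_word_dprime.abs().max():.2f})")
print(f"behavior: {beh.subject_id.nunique()} subjects, {len(beh)} trials")
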