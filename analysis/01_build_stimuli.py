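"""Build the orthographic stimulus sets and their metadata.

Renders the word/pseudoword base set (150 + 150 strings x 3 sizes x 2 cases)
and the single-letter set (26 letters x 4 positions x 6 variations), writes
the stimulus metadata table, and summarizes the bigram-frequency spread that
the behavioral analyses bin over.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
import pandas as pd
from common import OUT_DIR, run_config

from orthopop import pipeline

pipeline.run_pipeline(run_config(["stimuli"]))
meta = pd.read_csv(Path(OUT_DIR) / "stimulus_meta.csv")
strings = meta[meta.lexical_class.isin(["word", "pseudoword"])]
print(f"stimuli: {len(meta)} total images "
      f"({len(strings)} string images over {strings.text.nunique()} strings, "
      f"{(meta.lexical_class == 'letter').sum()} letter images)")
bf = strings.drop_duplicates("text").mean_bigram_freq
print(f"mean bigram frequency across strings: median {bf.median():.0f} "
      f"(IQR {bf.quantile(0.75) - bf.quantile(0.25):.0f}) counts/million")
print(f"metadata written to {OUT_DIR}/stimulus_meta.csv")
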