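"""Shared configuration for the numbered analysis drivers.

All drivers write into results/analysis/ through the pipeline stages, which
skip work that is already done — run the scripts in order (or any later one
after its prerequisites).  The configuration below defines the study
conditions of the synthetic experiment: a 200-site population, >30
repetitions per image, a 150+150-string base set under six variations, the
full 26 x 4 x 6 letter set, and a six-subject reference behavioral pool.
"""

from orthopop import pipeline, synth

OUT_DIR = "results/analysis"


def run_config(stages) -> pipeline.RunConfig:
    return pipeline.RunConfig(
        out_dir=OUT_DIR,
        seed=0,
        n_words=150,
        n_pseudo=150,
        letter_variations=6,
        sim=synth.SimConfig(n_sites=200, n_reps=32, seed=0),
        site_counts=(10, 25, 50, 100, 200),
        n_site_samples=10,
        behavior_trials_per_stim=40,
        decoder_repeats=10,
        stages=tuple(stages),
    )
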