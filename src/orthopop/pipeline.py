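"""End-to-end orchestration: simulate -> screen -> decode -> metrics -> report.

``run_pipeline`` executes the stages in dependency order, writes one
artifact directory with per-stage outputs plus a manifest (inputs, seeds,
output hashes), and skips already-completed stages on re-runs unless forced.
The defaults are sized to run on one CPU in a few minutes; the analysis
scripts under ``analysis/`` are thin drivers around these stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, decoding, encoding, features, mirror, single_site, stimuli, synth

STAGES = ("stimuli", "simulate", "screen", "decode", "consistency", "sites",
          "encoding", "mirror")


@dataclass
class RunConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    n_words: int = 60
    n_pseudo: int = 60
    letter_variations: int = 6
    sim: synth.SimConfig = field(default_factory=lambda: synth.SimConfig(n_sites=120, n_reps=32))
    n_letter_tasks: int = 20
    n_bigram_tasks: int = 8
    invariant_words: int = 40
    invariant_pseudo: int = 40
    invariant_variations: int = 5
    site_counts: tuple[int, ...] = (10, 30, 60, 120)
    n_site_samples: int = 10
    n_behavior_subjects: int = 6
    behavior_trials_per_stim: int = 30
    decoder_repeats: int = 10
    n_boot: int = 100
    n_perm: int = 100
    stages: tuple[str, ...] = STAGES
    force: bool = False

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, default=str)


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = {"config": json.loads(config.to_json()), "stages": {}, "outputs": {}}
    if manifest_path.exists() and not config.force:
        old = json.loads(manifest_path.read_text())
        manifest["stages"] = old.get("stages", {})
        manifest["outputs"] = old.get("outputs", {})

    state: dict = {}

    def done(stage, files):
        all_exist = all((out / f).exists() for f in files)
        return (not config.force) and stage in manifest["stages"] and all_exist

    def finish(stage, files):
        manifest["stages"][stage] = {"finished_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
                                     "files": files}
        for f in files:
            manifest["outputs"][f] = _hash_file(out / f)
        manifest_path.write_text(json.dumps(manifest, indent=1))

    # --- stimuli -----------------------------------------------------------
    base = stimuli.build_base_set(n_words=config.n_words, n_pseudo=config.n_pseudo,
                                  seed=config.seed)
    letters = stimuli.build_letter_set(variations=config.letter_variations)
    full = base.concat(letters)
    state["base"], state["letters"], state["full"] = base, letters, full
    if "stimuli" in config.stages and not done("stimuli", ["stimulus_meta.csv"]):
        full.to_dataframe().to_csv(out / "stimulus_meta.csv", index=False)
        finish("stimuli", ["stimulus_meta.csv"])

    # --- simulate ----------------------------------------------------------
    tensor_file = out / "responses.h5"
    if "simulate" in config.stages and not (tensor_file.exists() and done("simulate", ["responses.h5", "behavior.csv"])):
        tensor = synth.simulate_population(full, config.sim)
        synth.write_tensor(tensor, tensor_file)
        beh = synth.simulate_reference_behavior(
            base.subset([m.stimulus_id for m in base.meta
                         if m.font_case == "upper" and m.font_size == "medium"]),
            n_subjects=config.n_behavior_subjects,
            trials_per_stim=config.behavior_trials_per_stim,
            seed=config.seed + 1,
        )
        beh.to_csv(out / "behavior.csv", index=False)
        finish("simulate", ["responses.h5", "behavior.csv"])
    downstream = set(config.stages) - {"stimuli", "simulate"}
    if not downstream:
        manifest_path.write_text(json.dumps(manifest, indent=1))
        return manifest
    if not tensor_file.exists():
        raise FileNotFoundError(
            f"missing response tensor {tensor_file}; run the simulate stage first")
    tensor = synth.read_tensor(tensor_file)
    ref_behavior = pd.read_csv(out / "behavior.csv")
    state["tensor"] = tensor

    meta_df = full.to_dataframe()
    letter_ids = [m.stimulus_id for m in letters.meta]

    # --- screen ------------------------------------------------------------
    if "screen" in config.stages and not done("screen", ["site_screens.csv"]):
        drive = features.screen_visual_drive(tensor)
        rel = features.screen_letter_reliability(tensor, letter_ids, seed=config.seed + 2)
        screens = drive.merge(rel, on="site_id", suffixes=("_drive", "_rel"))
        screens.to_csv(out / "site_screens.csv", index=False)
        finish("screen", ["site_screens.csv"])
    screens = pd.read_csv(out / "site_screens.csv")

    pf = features.average_repetitions(tensor, "both_concatenated")
    battery = decoding.build_task_battery(
        full,
        n_letter_tasks=config.n_letter_tasks,
        n_bigram_tasks=config.n_bigram_tasks,
        invariant_set=decoding.subsample_invariant_set(
            base, config.invariant_words, config.invariant_pseudo,
            config.invariant_variations, seed=config.seed),
        seed=config.seed,
    )
    state["battery"] = battery

    # --- decode ------------------------------------------------------------
    if "decode" in config.stages and not done("decode", ["task_accuracies.csv", "site_count_sweep.csv"]):
        rows = []
        for task in battery:
            res = decoding.crossval_decode(pf, task, n_site_samples=1, seed=config.seed)
            rows.append((task.task_id, task.family, len(task.stimulus_ids),
                         res.mean_accuracy))
        pd.DataFrame(rows, columns=["task_id", "family", "n_stimuli", "balanced_accuracy"]).to_csv(
            out / "task_accuracies.csv", index=False)
        word_task = [t for t in battery if t.task_id == "word_classification_base"][0]
        sweep = decoding.site_count_sweep(pf, word_task, config.site_counts,
                                          n_site_samples=config.n_site_samples,
                                          seed=config.seed)
        sweep.to_csv(out / "site_count_sweep.csv", index=False)
        finish("decode", ["task_accuracies.csv", "site_count_sweep.csv"])

    word_task = [t for t in battery if t.task_id == "word_classification_base"][0]
    base_meta = meta_df[meta_df.stimulus_id.isin(word_task.stimulus_ids)]

    # --- consistency -------------------------------------------------------
    if "consistency" in config.stages and not done("consistency", ["consistency.json"]):
        dec_trials = decoding.decoder_choice_table(pf, word_task,
                                                   n_repeats=config.decoder_repeats,
                                                   seed=config.seed + 3)
        pool = ref_behavior.drop(columns=["subject_id"])
        est = behavior.consistency(dec_trials, pool, base_meta, seed=config.seed + 4)
        holdout = behavior.pool_and_holdout_consistency(
            {s: g for s, g in ref_behavior.groupby("subject_id")}, base_meta,
            seed=config.seed + 5)
        payload = {
            "decoder_vs_pool": dataclasses.asdict(est) | {"per_resplit": est.per_resplit.tolist()},
            "subject_holdout": holdout.to_dict(orient="records"),
            "holdout_median": float(holdout.rho_tilde.median()),
        }
        (out / "consistency.json").write_text(json.dumps(payload, indent=1, default=float))
        finish("consistency", ["consistency.json"])

    # --- sites -------------------------------------------------------------
    if "sites" in config.stages and not done("sites", ["site_selectivity.csv", "site_stats.json"]):
        early = features.average_repetitions(tensor, "early_only")
        X = early.stimulus_matrix(word_task.stimulus_ids).T  # sites x stimuli
        seltab = single_site.population_selectivity_table(
            X, word_task.labels, tensor.site_ids, n_boot=config.n_boot,
            seed=config.seed + 6)
        seltab.to_csv(out / "site_selectivity.csv", index=False)
        n_sel = int(seltab.significant.sum())
        frac_p = single_site.selective_fraction_test(n_sel, len(seltab))
        hemis = tensor.site_meta.hemisphere.to_numpy()
        sel_hemis = hemis[seltab.significant.to_numpy()]
        sampling_fraction = float((hemis == "right").mean())
        hemi_p = (single_site.hemisphere_bias_test(sel_hemis, sampling_fraction)
                  if len(sel_hemis) else float("nan"))
        grids = single_site.selectivity_grids(
            tensor.site_meta, seltab.significant.to_numpy().astype(float))
        moran = single_site.morans_I_multi(grids, n_perm=config.n_perm,
                                           seed=config.seed + 7)
        lrates, lcats = single_site.category_rate_tensor(tensor, meta_df, by="letter")
        prates, pcats = single_site.category_rate_tensor(tensor, meta_df, by="position")
        def si_block(rates):
            emp, nu, no = [], [], []
            for i in range(rates.shape[0]):
                r = single_site.sparsity_nulls(rates[i], n_perm=config.n_perm,
                                               seed=config.seed + 8 + i)
                emp.append(r.SI)
                nu.append(r.null_uniform_SI)
                no.append(r.null_onehot_SI)
            emp = np.array(emp)
            return {
                "median_SI": float(np.median(emp)),
                "vs_uniform": single_site.compare_si_medians(emp, np.array(nu)),
                "vs_onehot": single_site.compare_si_medians(emp, np.array(no)),
            }
        payload = {
            "n_selective": n_sel,
            "n_sites": len(seltab),
            "selective_fraction_p": frac_p,
            "hemisphere_bias_p": hemi_p,
            "moran_I": moran.I,
            "moran_p": moran.p,
            "sparsity_letters": si_block(lrates),
            "sparsity_positions": si_block(prates),
        }
        (out / "site_stats.json").write_text(json.dumps(payload, indent=1, default=float))
        finish("sites", ["site_selectivity.csv", "site_stats.json"])

    # --- encoding ----------------------------------------------------------
    if "encoding" in config.stages and not done("encoding", ["reconstruction_fits.csv", "encoding_stats.json"]):
        fits = {m: encoding.fit_reconstruction(tensor, meta_df, meta_df, model=m,
                                               seed=config.seed + 9)
                for m in ("full_4", "best_3", "bag_of_letters")}
        pd.concat(fits.values(), ignore_index=True).to_csv(
            out / "reconstruction_fits.csv", index=False)
        stats_payload = {
            "medians": {m: float(f.rho_tilde.median()) for m, f in fits.items()},
            "full_vs_best3": encoding.compare_model_medians(fits["full_4"], fits["best_3"],
                                                            seed=config.seed + 10),
            "full_vs_bag": encoding.compare_model_medians(fits["full_4"], fits["bag_of_letters"],
                                                          seed=config.seed + 11),
        }
        (out / "encoding_stats.json").write_text(json.dumps(stats_payload, indent=1, default=float))
        finish("encoding", ["reconstruction_fits.csv", "encoding_stats.json"])

    # --- mirror ------------------------------------------------------------
    if "mirror" in config.stages and not done("mirror", ["letter_pairs.csv", "mirror_stats.json"]):
        letter_pf = features.average_repetitions(
            tensor.select_stimuli(letter_ids), "both_concatenated")
        letter_meta = meta_df[meta_df.lexical_class == "letter"]
        emb, letts, _ = mirror.letter_decoder_embedding(letter_pf, letter_meta,
                                                        seed=config.seed + 12)
        sim = mirror.pair_similarity(emb, letts)
        glyphs = stimuli.canonical_letter_glyphs(letters)
        records = stimuli.all_letter_pair_reflectivity(glyphs)
        pairs = mirror.join_reflectivity(sim, records)
        pairs.to_csv(out / "letter_pairs.csv", index=False)
        summary = mirror.deltaR_analysis(pairs)
        payload = {k: v for k, v in summary.items()
                   if k not in ("rolling_delta_R", "rolling_r_IT")}
        (out / "mirror_stats.json").write_text(json.dumps(payload, indent=1, default=float))
        finish("mirror", ["letter_pairs.csv", "mirror_stats.json"])

    return manifest


def report(results_dir) -> str:
    """Human-readable summary of a completed run."""
    out = Path(results_dir)
    if not (out / "manifest.json").exists():
        raise FileNotFoundError(f"no run manifest in {results_dir}")
    lines = [f"Pipeline report: {out}"]
    acc_file = out / "task_accuracies.csv"
    if acc_file.exists():
        acc = pd.read_csv(acc_file)
        lines.append(f"\nDecoding battery ({len(acc)} tasks):")
        for fam, sub in acc.groupby("family"):
            lines.append(f"  {fam}: n={len(sub)}, "
                         f"balanced accuracy {sub.balanced_accuracy.mean():.3f} "
                         f"(range {sub.balanced_accuracy.min():.3f}-{sub.balanced_accuracy.max():.3f})")
    sweep_file = out / "site_count_sweep.csv"
    if sweep_file.exists():
        sweep = pd.read_csv(sweep_file)
        lines.append("\nWord classification vs site count:")
        for _, r in sweep.iterrows():
            lines.append(f"  n={int(r.n_sites):4d}: {r.accuracy_mean:.3f} +/- {r.accuracy_sd:.3f}")
    cons_file = out / "consistency.json"
    if cons_file.exists():
        c = json.loads(cons_file.read_text())
        lines.append(f"\nConsistency with reference behavior: "
                     f"rho_tilde = {c['decoder_vs_pool']['rho_tilde']:.3f} "
                     f"(subject hold-out median {c['holdout_median']:.3f})")
    stats_file = out / "site_stats.json"
    if stats_file.exists():
        s = json.loads(stats_file.read_text())
        lines.append(f"\nSingle sites: {s['n_selective']}/{s['n_sites']} word-selective "
                     f"(binomial p = {s['selective_fraction_p']:.2e}); "
                     f"Moran's I = {s['moran_I']:.3f} (p = {s['moran_p']:.2f})")
        lines.append(f"  letter sparsity median SI = {s['sparsity_letters']['median_SI']:.3f}; "
                     f"position SI = {s['sparsity_positions']['median_SI']:.3f}")
    enc_file = out / "encoding_stats.json"
    if enc_file.exists():
        e = json.loads(enc_file.read_text())
        med = e["medians"]
        lines.append("\nReconstruction medians: "
                     + ", ".join(f"{k}={v:.3f}" for k, v in med.items())
                     + f"; full_4 > bag p = {e['full_vs_bag']['p_one_tailed']:.4f}")
    mir_file = out / "mirror_stats.json"
    if mir_file.exists():
        m = json.loads(mir_file.read_text())
        b = m["bins"]
        lines.append(f"\nMirror symmetry: leftmost bin r_IT = {b[0]['mean_r_IT']:.3f}, "
                     f"rightmost = {b[-1]['mean_r_IT']:.3f}, "
                     f"right>left p = {m.get('p_right_gt_left', float('nan')):.4f}")
    return "\n".join(lines)
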