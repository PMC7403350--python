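"""Task battery construction and cross-validated linear readout."""

import numpy as np
import pytest

from orthopop import decoding, features, stimuli as st, synth


def _features_from_matrix(X, n_stim=None):
    """stimuli x features array -> PopulationFeatures with one row per site."""
    X = np.asarray(X, float)
    return features.PopulationFeatures(
        matrix=X.T,
        site_ids=[f"s{i}" for i in range(X.shape[1])],
        site_of_feature=np.arange(X.shape[1]),
        stimulus_ids=[f"stim{j}" for j in range(X.shape[0])],
        window_selection="early_only",
    )


def _binary_task(labels, ids=None):
    labels = np.asarray(labels, bool)
    if ids is None:
        ids = [f"stim{j}" for j in range(len(labels))]
    ids = np.asarray(ids)
    return decoding.TaskSpec("toy", "word_classification",
                             tuple(ids[labels]), tuple(ids[~labels]))


class TestBattery:
    def test_default_battery_has_30_tasks(self, base_small):
        battery = decoding.build_task_battery(
            base_small,
            invariant_set=decoding.subsample_invariant_set(base_small, 8, 8, 3, seed=0),
            seed=0)
        assert len(battery) == 30
        fams = [t.family for t in battery]
        assert fams.count("letter_id") == 20
        assert fams.count("bigram_id") == 8
        assert fams.count("word_classification") == 1
        assert fams.count("word_classification_invariant") == 1

    def test_token_free_battery_has_two_tasks(self, base_small):
        battery = decoding.build_task_battery(
            base_small, n_letter_tasks=0, n_bigram_tasks=0,
            invariant_set=decoding.subsample_invariant_set(base_small, 6, 6, 2, seed=0))
        assert len(battery) == 2

    def test_letter_tasks_are_most_balanced_available(self, base_small):
        inv = decoding.subsample_invariant_set(base_small, 10, 10, 4, seed=1)
        battery = decoding.build_task_battery(base_small, invariant_set=inv, seed=1)
        texts = [m.text for m in inv.meta]
        chosen, imbalances = [], {}
        for c in sorted({ch for t in texts for ch in t}):
            n_pos = sum(c in t for t in texts)
            if 0 < n_pos < len(texts):
                imbalances[c] = abs(2 * n_pos - len(texts))
        for task in battery:
            if task.family == "letter_id":
                assert len(task.positive_ids) > 0 and len(task.negative_ids) > 0
                chosen.append(task.token)
        worst_chosen = max(imbalances[c] for c in chosen)
        best_unchosen = min((v for c, v in imbalances.items() if c not in chosen),
                            default=np.inf)
        assert worst_chosen <= best_unchosen

    def test_missing_token_rejected(self, base_small):
        inv = decoding.subsample_invariant_set(base_small, 6, 6, 2, seed=0)
        texts = {m.text for m in inv.meta}
        absent = next(c for c in "abcdefghijklmnopqrstuvwxyz"
                      if all(c not in t for t in texts))
        with pytest.raises(ValueError):
            decoding.build_task_battery(base_small, n_letter_tasks=1, invariant_set=inv,
                                        letter_tokens=[absent])

    def test_invariant_subsample_counts(self):
        base = st.build_base_set(n_words=50, n_pseudo=50, seed=0)
        inv = decoding.subsample_invariant_set(base, 40, 40, 5, seed=0)
        assert len(inv) == 400
        tiny = decoding.subsample_invariant_set(base, 1, 1, 1, seed=0)
        assert len(tiny) == 2

    def test_invariant_subsample_reproducible(self, base_small):
        a = decoding.subsample_invariant_set(base_small, 6, 6, 3, seed=5)
        b = decoding.subsample_invariant_set(base_small, 6, 6, 3, seed=5)
        assert a.stimulus_ids == b.stimulus_ids


class TestCrossvalDecode:
    def test_separable_features_reach_perfect_accuracy(self, rng):
        labels = np.arange(60) < 30
        X = rng.normal(0, 1, (60, 5))
        X[:, 0] += np.where(labels, 6.0, -6.0)
        out = decoding.crossval_decode(_features_from_matrix(X), _binary_task(labels),
                                       n_site_samples=1, seed=0)
        assert out.mean_accuracy == 1.0

    def test_permuted_labels_near_chance(self, rng):
        """Permutation null: accuracy distribution centred on 0.5."""
        accs = []
        for i in range(20):
            labels = rng.permutation(np.arange(40) < 20)
            X = rng.normal(0, 1, (40, 10))
            out = decoding.crossval_decode(_features_from_matrix(X), _binary_task(labels),
                                           n_site_samples=1, seed=i)
            accs.append(out.mean_accuracy)
        m = np.mean(accs)
        assert abs(m - 0.5) < 3 * np.std(accs) / np.sqrt(len(accs)) + 0.02

    def test_every_stimulus_tested_exactly_once(self, rng):
        labels = np.arange(45) < 22
        X = rng.normal(0, 1, (45, 4))
        out = decoding.crossval_decode(_features_from_matrix(X), _binary_task(labels),
                                       n_folds=9, n_site_samples=1, seed=3)
        assert sorted(np.bincount(out.fold_assignment)) == [5] * 9
        assert (out.probabilities >= 0).all() and (out.probabilities <= 1).all()

    def test_duplicating_sites_leaves_accuracy_stable(self, rng):
        labels = np.arange(50) < 25
        X = rng.normal(0, 1, (50, 6))
        X[:, 0] += np.where(labels, 1.5, -1.5)
        a = decoding.crossval_decode(_features_from_matrix(X), _binary_task(labels),
                                     n_site_samples=1, seed=0).mean_accuracy
        b = decoding.crossval_decode(_features_from_matrix(np.hstack([X, X])),
                                     _binary_task(labels),
                                     n_site_samples=1, seed=0).mean_accuracy
        assert abs(a - b) < 0.1

    def test_more_folds_than_stimuli_rejected(self, rng):
        labels = np.arange(8) < 4
        X = rng.normal(0, 1, (8, 3))
        with pytest.raises(ValueError):
            decoding.crossval_decode(_features_from_matrix(X), _binary_task(labels),
                                     n_folds=10, n_site_samples=1)

    def test_deterministic_given_seed(self, rng):
        labels = np.arange(30) < 15
        X = rng.normal(0, 1, (30, 8))
        pf = _features_from_matrix(X)
        t = _binary_task(labels)
        a = decoding.crossval_decode(pf, t, n_site_samples=3, sites_per_sample=4, seed=7)
        b = decoding.crossval_decode(pf, t, n_site_samples=3, sites_per_sample=4, seed=7)
        np.testing.assert_array_equal(a.probabilities, b.probabilities)


class TestSiteCountSweep:
    def test_full_population_sweep_matches_direct_decode(self, rng):
        labels = np.arange(40) < 20
        X = rng.normal(0, 1, (40, 6))
        X[:, 1] += np.where(labels, 2, -2)
        pf = _features_from_matrix(X)
        task = _binary_task(labels)
        sweep = decoding.site_count_sweep(pf, task, [6], n_site_samples=2, seed=0)
        direct = decoding.crossval_decode(pf, task, n_site_samples=1, seed=0)
        assert sweep.accuracy_mean.iloc[0] == pytest.approx(direct.mean_accuracy)

    def test_accuracy_grows_with_sites_on_informative_data(self):
        base = st.build_base_set(n_words=40, n_pseudo=40, seed=0)
        canon_ids = [m.stimulus_id for m in base.meta
                     if m.font_case == "upper" and m.font_size == "medium"]
        cfg = synth.SimConfig(n_sites=60, n_reps=16, seed=0)
        tensor = synth.simulate_population(base, cfg).select_stimuli(canon_ids)
        pf = features.average_repetitions(tensor)
        labels = np.array([i < 40 for i in range(80)])
        task = _binary_task(labels, ids=canon_ids)
        sweep = decoding.site_count_sweep(pf, task, [5, 60], n_site_samples=8, seed=0)
        lo, hi = sweep.accuracy_mean.to_numpy()
        sd = sweep.accuracy_sd.max()
        assert lo <= hi + 2 * sd

    def test_zero_signal_sweep_flat_at_chance(self):
        labels = np.arange(60) < 30
        means = []
        for s in range(6):  # average out single-dataset fluctuations
            X = np.random.default_rng(s).normal(0, 1, (60, 30))
            sweep = decoding.site_count_sweep(_features_from_matrix(X),
                                              _binary_task(labels),
                                              [5, 30], n_site_samples=4, seed=s)
            means.append(sweep.accuracy_mean.to_numpy())
        mean_curve = np.mean(means, axis=0)
        assert (np.abs(mean_curve - 0.5) < 0.08).all()

    def test_invalid_count_rejected(self, rng):
        X = rng.normal(0, 1, (20, 4))
        with pytest.raises(ValueError):
            decoding.site_count_sweep(_features_from_matrix(X),
                                      _binary_task(np.arange(20) < 10), [50])


class TestExternalFeatures:
    def test_shuffled_ids_rejected(self, rng):
        labels = np.arange(20) < 10
        task = _binary_task(labels)
        X = rng.normal(0, 1, (20, 5))
        with pytest.raises(ValueError):
            decoding.decode_external_features(X, [f"other{j}" for j in range(20)], task)

    def test_same_seed_shares_fold_plan(self, rng):
        labels = np.arange(30) < 15
        task = _binary_task(labels)
        X = rng.normal(0, 1, (30, 6))
        a = decoding.crossval_decode(_features_from_matrix(X), task, n_site_samples=1, seed=4)
        b = decoding.decode_external_features(X, [f"stim{j}" for j in range(30)],
                                              task, seed=4)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)

    def test_pixel_features_weaker_than_simulated_population_on_invariant_task(self):
        """Low-level pixel features generalize worse across size/case than a
        position-tolerant population on invariant word classification."""
        base = st.build_base_set(n_words=30, n_pseudo=30, seed=1)
        inv = decoding.subsample_invariant_set(base, 20, 20, 4, seed=1)
        labels = np.array([m.lexical_class == "word" for m in inv.meta])
        task = _binary_task(labels, ids=inv.stimulus_ids)
        cfg = synth.SimConfig(n_sites=80, n_reps=16, seed=1)
        tensor = synth.simulate_population(inv, cfg)
        pf = features.average_repetitions(tensor)
        neural = decoding.crossval_decode(pf, task, n_site_samples=1, seed=0).mean_accuracy
        pix = st.pixel_feature_matrix(inv, downsample=16)
        ext = decoding.decode_external_features(pix, inv.stimulus_ids, task,
                                                seed=0).mean_accuracy
        assert neural > ext
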