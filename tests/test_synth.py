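"""Synthetic population generator: determinism, planted structure, IO."""

import numpy as np
import pytest

from orthopop import stimuli as st
from orthopop import synth


def _word_dprimes(tensor, stimulus_set):
    m = tensor.rates[0].mean(axis=2)
    classes = np.array([x.lexical_class for x in stimulus_set.meta])
    iw, ip = classes == "word", classes == "pseudoword"
    num = m[:, iw].mean(1) - m[:, ip].mean(1)
    den = np.sqrt(0.5 * (m[:, iw].var(1, ddof=1) + m[:, ip].var(1, ddof=1)))
    return num / den


class TestSimulatePopulation:
    def test_seed_determinism(self, full_small):
        cfg = synth.SimConfig(n_sites=10, n_reps=3, seed=9)
        a = synth.simulate_population(full_small, cfg)
        b = synth.simulate_population(full_small, cfg)
        assert np.array_equal(a.rates, b.rates)
        assert np.array_equal(a.baseline_rates, b.baseline_rates)

    def test_string_rate_is_sum_of_letter_rates(self, base_small, letters_small):
        """Linear construction: with no conjunctive terms and no noise, the
        string response equals the sum of the four letter-at-slot responses
        minus 3x baseline."""
        word = base_small.meta[0].text
        ids = [f"{word}_upper_medium"] + [f"{word[k]}_upper_medium_pos{k+1}" for k in range(4)]
        sub = base_small.concat(letters_small).subset(ids)
        cfg = synth.SimConfig(n_sites=15, n_reps=2, nonlinearity_weight=0.0,
                              frac_word_selective=0.0, noise_model="gaussian",
                              gaussian_noise_sd=0.0, seed=1)
        t = synth.simulate_population(sub, cfg)
        r = t.rates[0, :, :, 0]
        np.testing.assert_allclose(r[:, 0], r[:, 1:].sum(axis=1) - 3 * cfg.baseline_rate,
                                   rtol=1e-5)

    def test_planted_word_dprime_in_range(self):
        base = st.build_base_set(n_words=100, n_pseudo=100, seed=1)
        canon = base.subset([m.stimulus_id for m in base.meta
                             if m.font_case == "upper" and m.font_size == "medium"])
        cfg = synth.SimConfig(n_sites=80, n_reps=30, frac_word_selective=0.25, seed=5)
        t = synth.simulate_population(canon, cfg)
        d = _word_dprimes(t, canon)
        sel = t.ground_truth.word_selective.to_numpy()
        lo, hi = cfg.word_dprime_range
        # repetition noise attenuates realized d' slightly; allow MC slack
        assert lo - 0.1 < np.abs(d[sel]).mean() < hi + 0.1
        assert abs(d[~sel].mean()) < 0.15
        assert np.abs(t.ground_truth.target_word_dprime).max() < 0.5

    def test_mirror_sites_respond_equally_to_mirror_glyphs(self, mirror_config):
        images, meta = [], []
        for c in "bd":
            images.append(st.render_string(c, "lower", "medium", mirror_config, position_slot=1))
            meta.append(st.StimulusMeta(f"{c}_pos1", c, "letter", "lower", "medium", 1))
        ss = st.StimulusSet(images, meta, mirror_config)
        cfg = synth.SimConfig(n_sites=12, n_reps=2, mirror_symmetric_fraction=1.0,
                              noise_model="gaussian", gaussian_noise_sd=0.0, seed=2)
        t = synth.simulate_population(ss, cfg)
        np.testing.assert_allclose(t.rates[0, :, 0, 0], t.rates[0, :, 1, 0], rtol=1e-6)

    def test_poisson_rates_nonnegative(self, tensor_small):
        assert tensor_small.rates.min() >= 0
        assert tensor_small.baseline_rates.min() >= 0

    def test_grid_coordinates_on_array(self, tensor_small):
        sm = tensor_small.site_meta
        assert sm.grid_row.between(0, 9).all()
        assert sm.grid_col.between(0, 9).all()
        # cells unique within each array
        assert not sm.duplicated(["array_id", "grid_row", "grid_col"]).any()

    def test_split_half_reliability_monotone_in_reps_and_gain(self, letters_small):
        """Letter-tuning reliability grows with repetitions and signal gain."""
        def mean_reliability(n_reps, gain):
            cfg = synth.SimConfig(n_sites=25, n_reps=n_reps, gain=gain, seed=3)
            t = synth.simulate_population(letters_small, cfg)
            x = t.rates[0]
            h = n_reps // 2
            m1 = x[:, :, :h].mean(2)
            m2 = x[:, :, h:].mean(2)
            rs = [np.corrcoef(m1[i], m2[i])[0, 1] for i in range(x.shape[0])]
            return np.mean(rs)

        rel = [mean_reliability(n, 10.0) for n in (2, 8, 32)]
        assert rel[0] < rel[1] < rel[2]
        relg = [mean_reliability(8, g) for g in (1.0, 5.0, 25.0)]
        assert relg[0] < relg[1] < relg[2]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            synth.SimConfig(n_reps=1)
        with pytest.raises(ValueError):
            synth.SimConfig(tuning_sparsity=1.5)
        with pytest.raises(ValueError):
            synth.SimConfig(word_dprime_range=(0.2, 0.6))
        with pytest.raises(ValueError):
            synth.SimConfig(noise_model="cauchy")


class TestReferenceBehavior:
    def test_flat_slope_gives_flat_bins(self, base_small):
        """With freq_slope = 0 the per-stimulus word probability depends only
        on lexical class, so per-bin d' is constant in expectation."""
        canon = base_small.subset([m.stimulus_id for m in base_small.meta
                                   if m.font_case == "upper" and m.font_size == "medium"])
        beh = synth.simulate_reference_behavior(canon, n_subjects=1, freq_slope=0.0,
                                                lapse=0.0, trials_per_stim=2000, seed=0)
        from orthopop.behavior import binned_signature

        sig = binned_signature(beh, canon.to_dataframe(), n_bins=3)
        assert np.ptp(sig.dprime_per_bin) < 0.25

    def test_false_alarms_increase_with_bigram_frequency(self):
        base = st.build_base_set(n_words=60, n_pseudo=60, seed=2)
        canon = base.subset([m.stimulus_id for m in base.meta
                             if m.font_case == "upper" and m.font_size == "medium"])
        beh = synth.simulate_reference_behavior(canon, n_subjects=1, freq_slope=1.5,
                                                trials_per_stim=200, seed=1)
        meta = canon.to_dataframe()
        pseudo = meta[meta.lexical_class == "pseudoword"].sort_values("mean_bigram_freq")
        merged = beh.merge(pseudo[["stimulus_id"]], on="stimulus_id")
        thirds = np.array_split(pseudo.stimulus_id.to_numpy(), 3)
        fars = [merged[merged.stimulus_id.isin(t)].choice.eq("word").mean() for t in thirds]
        assert fars[0] < fars[1] < fars[2]

    def test_identical_subjects_share_signature(self, base_small):
        canon = base_small.subset([m.stimulus_id for m in base_small.meta
                                   if m.font_case == "upper" and m.font_size == "medium"])
        beh = synth.simulate_reference_behavior(canon, n_subjects=2, trials_per_stim=800, seed=4)
        from orthopop.behavior import binned_signature

        meta = canon.to_dataframe()
        sigs = [binned_signature(g, meta, n_bins=4).dprime_per_bin
                for _, g in beh.groupby("subject_id")]
        assert np.corrcoef(sigs[0], sigs[1])[0, 1] > 0.8

    def test_missing_bigram_metadata_rejected(self, letters_small):
        with pytest.raises(ValueError):
            synth.simulate_reference_behavior(letters_small, seed=0)


class TestTensorIO:
    def test_round_trip_bit_identical(self, tensor_small, tmp_path):
        path = tmp_path / "t.h5"
        synth.write_tensor(tensor_small, path)
        back = synth.read_tensor(path)
        assert np.array_equal(back.rates, tensor_small.rates)
        assert back.stimulus_ids == tensor_small.stimulus_ids
        assert back.window_labels == tensor_small.window_labels
        for col in tensor_small.site_meta.columns:
            assert (back.site_meta[col].to_numpy() == tensor_small.site_meta[col].to_numpy()).all()

    def test_missing_window_labels_rejected(self, tensor_small, tmp_path):
        import h5py

        path = tmp_path / "bad.h5"
        synth.write_tensor(tensor_small, path)
        with h5py.File(path, "a") as f:
            del f["window_labels"]
        with pytest.raises(ValueError, match="window_labels"):
            synth.read_tensor(path)

    def test_older_minor_version_accepted_newer_major_rejected(self, tensor_small, tmp_path):
        import h5py

        path = tmp_path / "v.h5"
        synth.write_tensor(tensor_small, path)
        with h5py.File(path, "a") as f:
            f.attrs["schema_version"] = "1.0.1"
        synth.read_tensor(path)  # same major: fine
        with h5py.File(path, "a") as f:
            f.attrs["schema_version"] = "2.0"
        with pytest.raises(ValueError, match="major"):
            synth.read_tensor(path)
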