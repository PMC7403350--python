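"""Synthetic neural populations and reference behavior.

No recorded data ships with this package; every analysis is exercised on
populations generated here.  The generator plants the statistical structure
the analyses assume about high-level ventral-stream sites:

* coarse letter-identity tuning derived from glyph pixel features (so that
  visually similar letters evoke similar responses), with a sparsity knob;
* position tuning with a tolerance knob and a contralateral gain;
* string responses that are sums of letter-at-slot responses plus optional
  conjunctive adjacent-letter-pair terms (the nonlinear component);
* a small weakly word-selective subpopulation with realized |d'| below 0.5,
  calibrated against the simulated stimulus-level variability;
* optionally, sites whose letter tuning is invariant to horizontal glyph
  reflection (mirror-symmetric tuning);
* two response windows (70-170 and 170-270 ms), the late one carrying the
  same drive at half amplitude, and per-trial baseline activity;
* Poisson-like (spike-count) or Gaussian repetition noise.

Reference behavior emulates a pool of subjects classifying words versus
pseudowords whose errors depend on mean bigram frequency through a
lapse-mixed logistic choice model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from .stimuli import StimulusSet, render_string

SCHEMA_VERSION = "1.0"
WINDOW_LABELS = ("70-170 ms", "170-270 ms")
#: spike-count window length in seconds (both windows are 100 ms)
WINDOW_SEC = 0.1
N_SLOTS = 4


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the package's study conditions."""

    n_sites: int = 200
    n_reps: int = 32  # > 30 repetitions per image
    tuning_sparsity: float = 0.5
    position_tolerance: float = 0.5
    contralateral_bias: float = 1.5
    frac_word_selective: float = 0.1
    word_dprime_range: tuple[float, float] = (0.15, 0.45)
    mirror_symmetric_fraction: float = 0.0
    nonlinearity_weight: float = 0.25
    noise_model: str = "poisson_like"  # or "gaussian"
    gaussian_noise_sd: float = 3.0
    baseline_rate: float = 10.0  # spikes/s
    gain: float = 10.0  # spikes/s per unit drive
    seed: int = 0

    def __post_init__(self):
        for name in ("tuning_sparsity", "position_tolerance", "frac_word_selective",
                     "mirror_symmetric_fraction", "nonlinearity_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (split-half analyses need it)")
        if self.noise_model not in ("poisson_like", "gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        lo, hi = self.word_dprime_range
        if not (0 <= lo <= hi):
            raise ValueError("word_dprime_range must satisfy 0 <= low <= high")
        if hi >= 0.5:
            raise ValueError("planted word selectivity must keep |d'| < 0.5")


@dataclass
class ResponseTensor:
    """Firing rates: windows x sites x stimuli x repetitions (spikes/s)."""

    rates: np.ndarray
    baseline_rates: np.ndarray  # sites x stimuli x repetitions
    site_meta: pd.DataFrame  # site_id, array_id, grid_row, grid_col, hemisphere
    stimulus_ids: list[str]
    window_labels: tuple[str, ...] = WINDOW_LABELS
    ground_truth: pd.DataFrame | None = None  # planted per-site structure

    def __post_init__(self):
        if self.rates.ndim != 4 or self.rates.shape[0] != len(self.window_labels):
            raise ValueError("rates must be windows x sites x stimuli x reps")
        if self.rates.shape[2] != len(self.stimulus_ids):
            raise ValueError("stimulus axis does not match stimulus_ids")
        if len(self.site_meta) != self.rates.shape[1]:
            raise ValueError("site_meta does not match site axis")
        grid = self.site_meta[["grid_row", "grid_col"]].to_numpy()
        if grid.min() < 0 or grid.max() > 9:
            raise ValueError("grid coordinates must lie on the 10x10 array")

    @property
    def n_sites(self) -> int:
        return self.rates.shape[1]

    @property
    def n_reps(self) -> int:
        return self.rates.shape[3]

    @property
    def site_ids(self) -> list[str]:
        return list(self.site_meta["site_id"])

    def select_sites(self, index) -> "ResponseTensor":
        idx = np.asarray(index)
        return ResponseTensor(
            rates=self.rates[:, idx],
            baseline_rates=self.baseline_rates[idx],
            site_meta=self.site_meta.iloc[idx].reset_index(drop=True),
            stimulus_ids=self.stimulus_ids,
            window_labels=self.window_labels,
            ground_truth=None if self.ground_truth is None else self.ground_truth.iloc[idx].reset_index(drop=True),
        )

    def select_stimuli(self, ids) -> "ResponseTensor":
        pos = {s: i for i, s in enumerate(self.stimulus_ids)}
        idx = np.array([pos[s] for s in ids])
        return ResponseTensor(
            rates=self.rates[:, :, idx],
            baseline_rates=self.baseline_rates[:, idx],
            site_meta=self.site_meta,
            stimulus_ids=list(ids),
            window_labels=self.window_labels,
            ground_truth=self.ground_truth,
        )


# ---------------------------------------------------------------------------
# tuning construction


def _letter_similarity_matrices(letters, stimulus_set: StimulusSet | None, config=None):
    """Pairwise glyph-overlap similarity between letters.

    Returns (S_raw, S_mirror): letters x letters matrices of bounding-box
    aligned pixel IoU, where S_mirror takes the larger of the direct overlap
    and the overlap after horizontally reflecting one glyph — the similarity
    seen by a site whose tuning is invariant to left-right reflection (two
    exact mirror glyphs have identical S_mirror rows).

    Glyphs are taken from the stimulus set's letter stimuli when present
    (so test fonts propagate into the tuning; lower case preferred, since
    mirror-pair glyphs such as b/d are lower-case forms), otherwise rendered
    with the default font (lower case, medium size).
    """
    from .stimuli import aligned_overlap

    glyphs: dict[str, np.ndarray] = {}
    ranks: dict[str, int] = {}
    if stimulus_set is not None:
        for img, m in zip(stimulus_set.images, stimulus_set.meta):
            if m.lexical_class != "letter":
                continue
            rank = (0 if m.font_case == "lower" else 2) + (0 if m.font_size == "medium" else 1)
            if rank < ranks.get(m.text, 99):
                ranks[m.text] = rank
                glyphs[m.text] = img.pixels
        cfg = stimulus_set.config
    else:
        cfg = config
    masks = []
    for letter in letters:
        mask = glyphs.get(letter)
        if mask is None:
            mask = render_string(letter, "lower", "medium", cfg).pixels
        masks.append(mask)
    n = len(letters)
    S_raw = np.eye(n)
    S_flip = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            if j > i:
                S_raw[i, j] = S_raw[j, i] = aligned_overlap(masks[i], masks[j])
            f = aligned_overlap(masks[i], masks[j], flip="horizontal")
            S_flip[i, j] = S_flip[j, i] = f
    return S_raw, np.maximum(S_raw, S_flip)


def _zscore(x, axis=-1):
    m = x.mean(axis=axis, keepdims=True)
    s = x.std(axis=axis, keepdims=True)
    return (x - m) / np.where(s > 0, s, 1.0)


class PopulationModel:
    """Deterministic expected-rate model for one simulated population."""

    def __init__(self, stimulus_set: StimulusSet, config: SimConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        letters = sorted({ch for m in stimulus_set.meta for ch in m.text.lower()})
        self.letters = letters
        self.letter_index = {c: i for i, c in enumerate(letters)}
        n_sites, n_letters = config.n_sites, len(letters)

        S_raw, S_mirror = _letter_similarity_matrices(letters, stimulus_set)

        n_mirror = int(round(config.mirror_symmetric_fraction * n_sites))
        mirror = np.zeros(n_sites, dtype=bool)
        mirror[rng.choice(n_sites, size=n_mirror, replace=False)] = True
        # template-matching tuning: each site carries a sparse nonnegative
        # mixture over template letters and responds by glyph-overlap
        # similarity; mirror-symmetric sites use the reflection-invariant
        # similarity, so exact mirror-pair glyphs evoke identical responses
        n_templates = min(3, n_letters)
        w = np.zeros((n_sites, n_letters))
        for i in range(n_sites):
            tmpl = rng.choice(n_letters, size=n_templates, replace=False)
            w[i, tmpl] = rng.dirichlet(np.ones(n_templates))
        z = np.where(mirror[:, None], w @ S_mirror.T, w @ S_raw.T)  # sites x letters
        z = _zscore(z, axis=1)
        # temperature maps tuning_sparsity in [0,1] onto near-uniform..near-one-hot
        tau = 0.3 + 4.0 * (1.0 - config.tuning_sparsity)
        t = np.exp(z / tau)
        self.letter_tuning = t / t.mean(axis=1, keepdims=True)  # mean 1 per site

        # position tuning: preferred slot softened by tolerance, mean 1
        pref = rng.integers(N_SLOTS, size=n_sites)
        tol = config.position_tolerance
        posw = np.full((n_sites, N_SLOTS), tol)
        posw[np.arange(n_sites), pref] += (1.0 - tol) * N_SLOTS

        # site geometry: 10x10 arrays, half the sites per hemisphere
        n_arrays = int(np.ceil(n_sites / 100))
        array_id = np.arange(n_sites) % n_arrays
        hemi = np.where(array_id % 2 == 0, "left", "right")
        cells = np.concatenate(
            [rng.permutation(100)[: (array_id == a).sum()] for a in range(n_arrays)]
        )
        order = np.argsort(array_id, kind="stable")
        grid = np.zeros((n_sites, 2), dtype=int)
        grid[order, 0] = cells // 10
        grid[order, 1] = cells % 10
        # contralateral slots: left visual field (slots 1-2) projects to the
        # right hemisphere, slots 3-4 to the left
        contra = np.zeros((n_sites, N_SLOTS), dtype=bool)
        contra[hemi == "right", :2] = True
        contra[hemi == "left", 2:] = True
        posw = np.where(contra, posw * config.contralateral_bias, posw)
        self.position_tuning = posw

        # mild per-site sensitivity to the case/size variation
        self.variation_gain = np.clip(
            1.0 + 0.08 * rng.standard_normal((n_sites, 2, 3)), 0.5, None
        )
        # conjunctive adjacent-pair terms, mean ~1
        self.conjunctive = rng.lognormal(mean=-0.125, sigma=0.5,
                                         size=(n_sites, n_letters, n_letters, N_SLOTS - 1))
        self.mirror_site = mirror
        self.pref_slot = pref
        self.site_meta = pd.DataFrame(
            {
                "site_id": [f"site{i:04d}" for i in range(n_sites)],
                "array_id": array_id,
                "grid_row": grid[:, 0],
                "grid_col": grid[:, 1],
                "hemisphere": hemi,
            }
        )
        self._rng = rng

    def _variation_index(self, meta):
        from .stimuli import CASES, SIZES

        return CASES.index(meta.font_case), SIZES.index(meta.font_size)

    def expected_rates(self, stimulus_set: StimulusSet) -> np.ndarray:
        """Noise-free expected early-window rate, sites x stimuli."""
        cfg = self.config
        n_sites = cfg.n_sites
        rates = np.zeros((n_sites, len(stimulus_set)))
        for j, m in enumerate(stimulus_set.meta):
            ci, si = self._variation_index(m)
            gvar = self.variation_gain[:, ci, si]
            text = m.text.lower()
            if m.lexical_class == "letter":
                slot = m.position_slot - 1
                li = self.letter_index[text]
                drive = self.letter_tuning[:, li] * self.position_tuning[:, slot]
            else:
                lids = [self.letter_index[c] for c in text]
                drive = np.zeros(n_sites)
                for k, li in enumerate(lids):
                    drive += self.letter_tuning[:, li] * self.position_tuning[:, k]
                if cfg.nonlinearity_weight > 0:
                    for k in range(len(lids) - 1):
                        drive += cfg.nonlinearity_weight * self.conjunctive[:, lids[k], lids[k + 1], k]
            rates[:, j] = cfg.baseline_rate + cfg.gain * drive * gvar
        return rates

    def plant_word_selectivity(self, rates: np.ndarray, stimulus_set: StimulusSet):
        """Additive lexical-class offset calibrated to a realized d' target.

        An additive offset leaves the within-class stimulus variances
        untouched, so the offset achieving a target d' is available in
        closed form: delta = (d'_target - d'_baseline) * pooled SD of the
        noise-free stimulus means, where d'_baseline is the class separation
        the site already shows through its letter tuning (word and
        pseudoword strings differ in letter statistics).
        """
        cfg = self.config
        rng = self._rng
        classes = np.array([m.lexical_class for m in stimulus_set.meta])
        is_word = classes == "word"
        is_pseudo = classes == "pseudoword"
        n_sel = int(round(cfg.frac_word_selective * cfg.n_sites))
        selected = np.zeros(cfg.n_sites, dtype=bool)
        target = np.zeros(cfg.n_sites)
        if n_sel and is_word.any() and is_pseudo.any():
            idx = rng.choice(cfg.n_sites, size=n_sel, replace=False)
            selected[idx] = True
            lo, hi = cfg.word_dprime_range
            mag = rng.uniform(lo, hi, size=n_sel)
            sign = rng.choice([-1.0, 1.0], size=n_sel)
            target[idx] = sign * mag
            pooled_sd = np.sqrt(
                0.5 * (rates[idx][:, is_word].var(axis=1, ddof=1)
                       + rates[idx][:, is_pseudo].var(axis=1, ddof=1))
            )
            d_base = (rates[idx][:, is_word].mean(axis=1)
                      - rates[idx][:, is_pseudo].mean(axis=1)) / pooled_sd
            rates[np.ix_(idx, np.flatnonzero(is_word))] += ((target[idx] - d_base) * pooled_sd)[:, None]
        return selected, target


def simulate_population(stimulus_set: StimulusSet, config: SimConfig) -> ResponseTensor:
    """Simulate a neural population's responses to a stimulus set.

    Fully reproducible under ``config.seed``.  Returns two response windows
    plus per-trial baseline activity.
    """
    model = PopulationModel(stimulus_set, config)
    mu_early = model.expected_rates(stimulus_set)
    selected, target = model.plant_word_selectivity(mu_early, stimulus_set)
    mu_early = np.clip(mu_early, 0.0, None)
    mu_late = config.baseline_rate + 0.5 * (mu_early - config.baseline_rate)
    mu_late = np.clip(mu_late, 0.0, None)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 777]))
    shape = mu_early.shape + (config.n_reps,)

    def draw(mu):
        mu3 = np.broadcast_to(mu[..., None], shape)
        if config.noise_model == "poisson_like":
            return rng.poisson(mu3 * WINDOW_SEC).astype(np.float32) / WINDOW_SEC
        out = mu3 + rng.normal(0.0, config.gaussian_noise_sd, size=shape)
        return out.astype(np.float32)

    rates = np.stack([draw(mu_early), draw(mu_late)])
    baseline = draw(np.full_like(mu_early, config.baseline_rate))
    gt = pd.DataFrame(
        {
            "site_id": model.site_meta["site_id"],
            "word_selective": selected,
            "target_word_dprime": target,
            "mirror_symmetric": model.mirror_site,
            "preferred_slot": model.pref_slot + 1,
        }
    )
    return ResponseTensor(
        rates=rates,
        baseline_rates=baseline,
        site_meta=model.site_meta,
        stimulus_ids=stimulus_set.stimulus_ids,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# reference behavior


def simulate_reference_behavior(
    stimulus_set: StimulusSet,
    n_subjects: int = 6,
    lapse: float = 0.02,
    freq_slope: float = 0.8,
    class_weight: float = 0.9,
    trials_per_stim: int = 40,
    seed: int = 0,
) -> pd.DataFrame:
    """Choice table emulating a pool of subjects classifying words.

    P(choice = word) is a lapse-mixed logistic in lexical class and, for
    pseudowords, log mean bigram frequency: pseudowords built from frequent
    bigrams look word-like and attract more "word" responses (higher
    false-alarm rate), so the binned d' signature decreases over
    bigram-frequency bins.  The slope acts on pseudowords only — word
    difficulty varies little in the emulated task, and a slope shared by
    both classes would cancel in the per-bin d'.  Subjects share the
    generative parameters and differ only by independent trial noise.
    """
    rng = np.random.default_rng(seed)
    strings = [m for m in stimulus_set.meta if m.lexical_class in ("word", "pseudoword")]
    if not strings:
        raise ValueError("stimulus set contains no string stimuli")
    if any(m.mean_bigram_freq is None for m in strings):
        raise ValueError("string stimuli lack mean_bigram_freq metadata")
    logf = np.log10(np.array([m.mean_bigram_freq for m in strings]) + 1.0)
    logf = logf - logf.mean()
    sign = np.array([1.0 if m.lexical_class == "word" else -1.0 for m in strings])
    eta = class_weight * sign + freq_slope * logf * (sign < 0)
    p_word = lapse / 2.0 + (1.0 - lapse) / (1.0 + np.exp(-eta))
    rows = []
    for subj in range(n_subjects):
        draws = rng.random((len(strings), trials_per_stim)) < p_word[:, None]
        for i, m in enumerate(strings):
            for t in range(trials_per_stim):
                rows.append((f"subj{subj}", m.stimulus_id, t, "word" if draws[i, t] else "pseudoword"))
    return pd.DataFrame(rows, columns=["subject_id", "stimulus_id", "trial_index", "choice"])


# ---------------------------------------------------------------------------
# tensor container IO (HDF5)


def write_tensor(tensor: ResponseTensor, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.create_dataset("rates", data=tensor.rates, compression="gzip")
        f.create_dataset("baseline_rates", data=tensor.baseline_rates, compression="gzip")
        f.create_dataset("stimulus_ids", data=np.array(tensor.stimulus_ids, dtype="S"))
        f.create_dataset("window_labels", data=np.array(tensor.window_labels, dtype="S"))
        sm = f.create_group("site_meta")
        for col in tensor.site_meta.columns:
            data = tensor.site_meta[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            sm.create_dataset(col, data=data)
        if tensor.ground_truth is not None:
            gt = f.create_group("ground_truth")
            for col in tensor.ground_truth.columns:
                data = tensor.ground_truth[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                gt.create_dataset(col, data=data)


def _read_group(group) -> pd.DataFrame:
    cols = {}
    for name, ds in group.items():
        arr = ds[()]
        if arr.dtype.kind == "S":
            arr = arr.astype(str)
        cols[name] = arr
    return pd.DataFrame(cols)


def read_tensor(path) -> ResponseTensor:
    with h5py.File(path, "r") as f:
        version = f.attrs.get("schema_version")
        if version is None:
            raise ValueError("malformed container: missing schema_version")
        if str(version).split(".")[0] != SCHEMA_VERSION.split(".")[0]:
            raise ValueError(f"unsupported schema major version {version!r}")
        if "window_labels" not in f:
            raise ValueError("malformed container: missing window_labels")
        tensor = ResponseTensor(
            rates=f["rates"][()],
            baseline_rates=f["baseline_rates"][()],
            site_meta=_read_group(f["site_meta"]),
            stimulus_ids=list(f["stimulus_ids"][()].astype(str)),
            window_labels=tuple(f["window_labels"][()].astype(str)),
            ground_truth=_read_group(f["ground_truth"]) if "ground_truth" in f else None,
        )
    return tensor
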