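"""The 30-task battery and cross-validated linear readout machinery.

Each task is a binary discrimination solved by an L2-regularized logistic
regression on population features (a weighted sum plus threshold), with
ten-fold stratified cross-validation over stimuli and repeated random
sampling of neural sites.  Reported performance is always the balanced
accuracy, so class imbalance in token tasks does not inflate scores.

The battery comprises 20 invariant letter-identification tasks, 8 invariant
bigram-identification tasks and two word-classification variants (the
canonical-view base set, and an invariant subsampled set of 40 words + 40
pseudowords under five variations = 400 stimuli).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .behavior import balanced_accuracy
from .features import PopulationFeatures
from .stimuli import StimulusSet

#: L2 regularization strength, frozen once after a nested-validation sweep
#: on a synthetic pilot population (see the methods note)
DEFAULT_C = 1.0


@dataclass(frozen=True)
class TaskSpec:
    task_id: str
    family: str  # word_classification | word_classification_invariant | letter_id | bigram_id
    positive_ids: tuple[str, ...]
    negative_ids: tuple[str, ...]
    token: str | None = None

    def __post_init__(self):
        pos, neg = set(self.positive_ids), set(self.negative_ids)
        if not pos or not neg:
            raise ValueError(f"task {self.task_id}: both classes must be non-empty")
        if pos & neg:
            raise ValueError(f"task {self.task_id}: classes overlap")

    @property
    def stimulus_ids(self) -> list[str]:
        return list(self.positive_ids) + list(self.negative_ids)

    @property
    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.positive_ids), bool), np.zeros(len(self.negative_ids), bool)]
        )


@dataclass
class DecodeOutput:
    """Per-stimulus class probabilities and site-sample accuracies for a task."""

    task_id: str
    stimulus_ids: list[str]
    labels: np.ndarray
    probabilities: np.ndarray  # n_site_samples x n_stimuli
    choices: np.ndarray  # n_site_samples x n_stimuli (bool)
    fold_assignment: np.ndarray
    accuracies: np.ndarray  # balanced accuracy per site sample

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.accuracies.std(ddof=1)) if len(self.accuracies) > 1 else 0.0


def subsample_invariant_set(
    stimulus_set: StimulusSet,
    n_words: int = 40,
    n_pseudo: int = 40,
    n_variations: int = 5,
    seed: int = 0,
) -> StimulusSet:
    """Random strings x variations subset used for the invariant battery."""
    rng = np.random.default_rng(seed)
    meta = stimulus_set.to_dataframe()
    strings = meta[meta.lexical_class.isin(["word", "pseudoword"])]
    words = sorted(strings[strings.lexical_class == "word"].text.unique())
    pseudos = sorted(strings[strings.lexical_class == "pseudoword"].text.unique())
    variations = sorted(strings[["font_case", "font_size"]].drop_duplicates().itertuples(index=False))
    if len(words) < n_words or len(pseudos) < n_pseudo or len(variations) < n_variations:
        raise ValueError("base set too small for the requested invariant subset")
    sel_words = [words[i] for i in rng.choice(len(words), n_words, replace=False)]
    sel_pseudos = [pseudos[i] for i in rng.choice(len(pseudos), n_pseudo, replace=False)]
    sel_var = [variations[i] for i in rng.choice(len(variations), n_variations, replace=False)]
    texts = set(sel_words) | set(sel_pseudos)
    var = {(v.font_case, v.font_size) for v in sel_var}
    keep = strings[strings.text.isin(texts)
                   & strings.apply(lambda r: (r.font_case, r.font_size) in var, axis=1)]
    return stimulus_set.subset(list(keep.stimulus_id))


def _token_balance_ranking(texts: pd.Series, tokens) -> list[str]:
    """Tokens sorted by |n_present - n_absent| then alphabetically."""
    scores = []
    n = len(texts)
    for tok in tokens:
        n_pos = int(texts.str.contains(tok).sum())
        if n_pos == 0 or n_pos == n:
            continue
        scores.append((abs(2 * n_pos - n), tok))
    scores.sort()
    return [tok for _, tok in scores]


def build_task_battery(
    stimulus_set: StimulusSet,
    n_letter_tasks: int = 20,
    n_bigram_tasks: int = 8,
    invariant_set: StimulusSet | None = None,
    seed: int = 0,
    letter_tokens=None,
    bigram_tokens=None,
) -> list[TaskSpec]:
    """The orthographic task battery (defaults: 20 + 8 + 2 = 30 tasks).

    Letter and bigram tasks are "token present anywhere in the string"
    discriminations over the invariant stimulus subset; tokens default to
    the most label-balanced choices (deterministic, alphabetical
    tie-break), overridable explicitly.
    """
    if invariant_set is None:
        invariant_set = subsample_invariant_set(stimulus_set, seed=seed)
    inv = invariant_set.to_dataframe()
    inv_strings = inv[inv.lexical_class.isin(["word", "pseudoword"])]
    texts = inv_strings.text.str.lower()

    if letter_tokens is None:
        alphabet = sorted({c for t in texts for c in t})
        letter_tokens = _token_balance_ranking(texts, alphabet)[:n_letter_tasks]
    if len(letter_tokens) < n_letter_tasks:
        raise ValueError("not enough discriminable letter tokens in the stimulus set")
    if bigram_tokens is None:
        bigrams = sorted({t[i : i + 2] for t in texts for i in range(len(t) - 1)})
        bigram_tokens = _token_balance_ranking(texts, bigrams)[:n_bigram_tasks]
    if len(bigram_tokens) < n_bigram_tasks:
        raise ValueError("not enough discriminable bigram tokens in the stimulus set")

    tasks: list[TaskSpec] = []
    for tok in list(letter_tokens)[:n_letter_tasks]:
        present = texts.str.contains(tok)
        if not present.any() or present.all():
            raise ValueError(f"letter token {tok!r} absent (or universal) in stimuli")
        tasks.append(
            TaskSpec(
                task_id=f"letter_{tok}",
                family="letter_id",
                positive_ids=tuple(inv_strings.stimulus_id[present]),
                negative_ids=tuple(inv_strings.stimulus_id[~present]),
                token=tok,
            )
        )
    for tok in list(bigram_tokens)[:n_bigram_tasks]:
        present = texts.str.contains(tok)
        if not present.any() or present.all():
            raise ValueError(f"bigram token {tok!r} absent (or universal) in stimuli")
        tasks.append(
            TaskSpec(
                task_id=f"bigram_{tok}",
                family="bigram_id",
                positive_ids=tuple(inv_strings.stimulus_id[present]),
                negative_ids=tuple(inv_strings.stimulus_id[~present]),
                token=tok,
            )
        )

    meta = stimulus_set.to_dataframe()
    base = meta[meta.lexical_class.isin(["word", "pseudoword"])
                & (meta.font_case == "upper") & (meta.font_size == "medium")]
    if len(base):
        tasks.append(
            TaskSpec(
                task_id="word_classification_base",
                family="word_classification",
                positive_ids=tuple(base.stimulus_id[base.lexical_class == "word"]),
                negative_ids=tuple(base.stimulus_id[base.lexical_class == "pseudoword"]),
            )
        )
    tasks.append(
        TaskSpec(
            task_id="word_classification_invariant",
            family="word_classification_invariant",
            positive_ids=tuple(inv_strings.stimulus_id[inv_strings.lexical_class == "word"]),
            negative_ids=tuple(inv_strings.stimulus_id[inv_strings.lexical_class == "pseudoword"]),
        )
    )
    return tasks


def _fold_plan(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment depending only on (labels, seed)."""
    if n_folds > len(labels):
        raise ValueError("more folds than stimuli")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    assignment = np.empty(len(labels), dtype=int)
    for k, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignment[test] = k
    return assignment


def crossval_decode(
    features: PopulationFeatures,
    task: TaskSpec,
    n_folds: int = 10,
    n_site_samples: int = 10,
    sites_per_sample: int | None = None,
    seed: int = 0,
    C: float = DEFAULT_C,
) -> DecodeOutput:
    """Ten-fold cross-validated logistic readout with neuron resampling.

    Per fold, the decoder is fit on 90% of stimuli (features standardized
    with training-fold statistics only) and scored on the held-out 10%;
    folds are stratified by class.  The whole procedure repeats over
    independent random samples of ``sites_per_sample`` sites.  The fold plan
    depends only on the task labels and the seed, so external feature
    matrices are scored against identical folds.
    """
    ids = task.stimulus_ids
    labels = task.labels
    X_all = features.stimulus_matrix(ids)
    folds = _fold_plan(labels, n_folds, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 12345]))
    n_sites = features.n_sites
    if sites_per_sample is None:
        sites_per_sample = n_sites
    if sites_per_sample > n_sites:
        raise ValueError("sites_per_sample exceeds available sites")
    if sites_per_sample == n_sites:
        samples = [np.arange(n_sites) for _ in range(n_site_samples)]
    else:
        samples = [rng.choice(n_sites, sites_per_sample, replace=False)
                   for _ in range(n_site_samples)]

    probs = np.zeros((len(samples), len(ids)))
    for s, site_idx in enumerate(samples):
        rows = features.rows_for_sites(site_idx)
        X = X_all[:, rows]
        for k in range(n_folds):
            train, test = folds != k, folds == k
            if len(np.unique(labels[train])) < 2:
                raise ValueError(f"fold {k} has a single training class")
            scaler = StandardScaler().fit(X[train])
            clf = LogisticRegression(C=C, max_iter=2000)
            clf.fit(scaler.transform(X[train]), labels[train])
            p = clf.predict_proba(scaler.transform(X[test]))
            probs[s, test] = p[:, list(clf.classes_).index(True)]
    choices = probs > 0.5  # ties resolve to the negative class
    acc = np.array([balanced_accuracy(c, labels) for c in choices])
    return DecodeOutput(
        task_id=task.task_id,
        stimulus_ids=ids,
        labels=labels,
        probabilities=probs,
        choices=choices,
        fold_assignment=folds,
        accuracies=acc,
    )


def site_count_sweep(
    features: PopulationFeatures,
    task: TaskSpec,
    site_counts,
    n_site_samples: int = 100,
    n_folds: int = 10,
    seed: int = 0,
    C: float = DEFAULT_C,
) -> pd.DataFrame:
    """Accuracy mean +/- SD across site samples, per site count."""
    rows = []
    for n in site_counts:
        if not 1 <= n <= features.n_sites:
            raise ValueError(f"invalid site count {n}")
        out = crossval_decode(features, task, n_folds=n_folds,
                              n_site_samples=n_site_samples,
                              sites_per_sample=n, seed=seed, C=C)
        rows.append((n, out.mean_accuracy, out.sd_accuracy))
    return pd.DataFrame(rows, columns=["n_sites", "accuracy_mean", "accuracy_sd"])


def decode_external_features(
    feature_matrix: np.ndarray,
    stimulus_ids,
    task: TaskSpec,
    n_folds: int = 10,
    n_feature_samples: int = 10,
    features_per_sample: int | None = None,
    seed: int = 0,
    C: float = DEFAULT_C,
) -> DecodeOutput:
    """Run the identical battery machinery on an external stimulus x feature matrix.

    Rows must align with ``stimulus_ids``; every task stimulus must be
    present.  Fold plans are shared with the neural decode at equal seed.
    """
    feature_matrix = np.asarray(feature_matrix, dtype=float)
    if feature_matrix.shape[0] != len(stimulus_ids):
        raise ValueError("feature matrix rows must align with stimulus_ids")
    missing = set(task.stimulus_ids) - set(stimulus_ids)
    if missing:
        raise ValueError(f"feature matrix lacks task stimuli: {sorted(missing)[:5]}")
    pf = PopulationFeatures(
        matrix=feature_matrix.T,
        site_ids=[f"f{i}" for i in range(feature_matrix.shape[1])],
        site_of_feature=np.arange(feature_matrix.shape[1]),
        stimulus_ids=list(stimulus_ids),
        window_selection="external",
    )
    return crossval_decode(pf, task, n_folds=n_folds, n_site_samples=n_feature_samples,
                           sites_per_sample=features_per_sample, seed=seed, C=C)


def decoder_choice_table(
    features: PopulationFeatures,
    task: TaskSpec,
    n_repeats: int = 10,
    n_folds: int = 10,
    sites_per_sample: int | None = None,
    seed: int = 0,
    C: float = DEFAULT_C,
) -> pd.DataFrame:
    """Decoder choices as behavioral trials for consistency analyses.

    Decoder outputs are deterministic given folds, so repeated
    cross-validation with independent fold plans (and site samples) plays
    the role of behavioral trial repetitions.
    """
    frames = []
    for r in range(n_repeats):
        out = crossval_decode(features, task, n_folds=n_folds, n_site_samples=1,
                              sites_per_sample=sites_per_sample, seed=seed + 1000 * r + r, C=C)
        frames.append(pd.DataFrame({
            "stimulus_id": out.stimulus_ids,
            "trial_index": r,
            "choice": np.where(out.choices[0], "word", "pseudoword"),
        }))
    return pd.concat(frames, ignore_index=True)
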