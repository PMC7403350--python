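"""Behavioral metrics: balanced accuracy, d', binned signatures, consistency.

A behavioral signature is the ten-dimensional pattern of per-bin d' values
over mean-bigram-frequency bins (words and pseudowords rank-binned into
deciles separately; decile i of each class forms paired bin i).  Two
systems' signatures are compared with a noise-adjusted correlation

    rho_tilde(m, p) = rho(m, p) / sqrt(rho(m, m) * rho(p, p))

where the denominator holds each system's split-half internal reliability;
all terms are computed from the same trial split-halves, so no
Spearman-Brown extrapolation is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


def balanced_accuracy(choices, labels) -> float:
    """(HR + (1 - FAR)) / 2 for boolean positive-choice and positive-label arrays."""
    choices = np.asarray(choices, bool)
    labels = np.asarray(labels, bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    hr = choices[labels].mean()
    far = choices[~labels].mean()
    return float((hr + (1.0 - far)) / 2.0)


def dprime(hr: float, far: float, n_pos: int | None = None, n_neg: int | None = None) -> float:
    """d' = Z(HR) - Z(FAR) with a 1/(2N) correction for extreme rates.

    When trial counts are given, rates are clipped to [1/(2N), 1 - 1/(2N)];
    without counts a fallback epsilon keeps the value finite.
    """
    def clip(rate, n):
        eps = 1.0 / (2.0 * n) if n else 1e-6
        return min(max(rate, eps), 1.0 - eps)

    return float(stats.norm.ppf(clip(hr, n_pos)) - stats.norm.ppf(clip(far, n_neg)))


@dataclass
class BehavioralSignature:
    """Per-bin unbiased performance over bigram-frequency bins."""

    dprime_per_bin: np.ndarray
    bin_index_word: pd.Series  # stimulus_id -> bin (words)
    bin_index_pseudo: pd.Series  # stimulus_id -> bin (pseudowords)
    n_trials_per_bin: np.ndarray = field(default=None)
    source: str = "unknown"

    @property
    def n_bins(self) -> int:
        return len(self.dprime_per_bin)


def _rank_bins(meta: pd.DataFrame, lexical_class: str, n_bins: int) -> pd.Series:
    sub = meta[meta["lexical_class"] == lexical_class]
    if len(sub) < n_bins:
        raise ValueError(f"too few {lexical_class} stimuli ({len(sub)}) for {n_bins} bins")
    ranks = sub["mean_bigram_freq"].rank(method="first")
    bins = np.ceil(ranks * n_bins / len(sub)).astype(int) - 1
    return pd.Series(bins.to_numpy(), index=sub["stimulus_id"].to_numpy())


def binned_signature(
    choice_table: pd.DataFrame,
    stimulus_meta: pd.DataFrame,
    n_bins: int = 10,
    source: str = "unknown",
) -> BehavioralSignature:
    """Rank-matched decile signature of a choice table.

    ``choice_table`` has columns stimulus_id and choice ("word"/"pseudoword"
    or boolean); ``stimulus_meta`` has stimulus_id, lexical_class and
    mean_bigram_freq.  Words and pseudowords are independently rank-binned
    by mean bigram frequency; bin i pools word decile i (hits) with
    pseudoword decile i (false alarms), d' computed across all trials
    within the bin with the 1/(2N) clip.
    """
    wbins = _rank_bins(stimulus_meta, "word", n_bins)
    pbins = _rank_bins(stimulus_meta, "pseudoword", n_bins)
    choice = choice_table["choice"]
    if choice.dtype == object:
        choice = choice == "word"
    df = pd.DataFrame({"stimulus_id": choice_table["stimulus_id"].to_numpy(),
                       "said_word": choice.to_numpy()})
    d = np.zeros(n_bins)
    n_trials = np.zeros((n_bins, 2), dtype=int)
    for b in range(n_bins):
        wtr = df[df["stimulus_id"].isin(wbins.index[wbins == b])]["said_word"]
        ptr = df[df["stimulus_id"].isin(pbins.index[pbins == b])]["said_word"]
        if len(wtr) == 0 or len(ptr) == 0:
            raise ValueError(f"bin {b} has no trials in one class")
        d[b] = dprime(wtr.mean(), ptr.mean(), n_pos=len(wtr), n_neg=len(ptr))
        n_trials[b] = (len(wtr), len(ptr))
    return BehavioralSignature(d, wbins, pbins, n_trials, source=source)


@dataclass
class ConsistencyEstimate:
    rho_tilde: float
    raw_rho: float
    reliability_m: float
    reliability_p: float
    n_resplits: int
    per_resplit: np.ndarray = None
    n_undefined: int = 0


def _split_trials(table: pd.DataFrame, rng) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random half-split of trials within each stimulus."""
    idx = np.arange(len(table))
    perm = rng.permutation(idx)
    order_within = table.iloc[perm].groupby("stimulus_id", sort=False).cumcount()
    counts = table.iloc[perm].groupby("stimulus_id", sort=False)["stimulus_id"].transform("size")
    first_half = (order_within < counts // 2).to_numpy()
    shuffled = table.iloc[perm]
    return shuffled[first_half], shuffled[~first_half]


def consistency(
    trials_m: pd.DataFrame,
    trials_p: pd.DataFrame,
    stimulus_meta: pd.DataFrame,
    n_resplits: int = 10,
    n_bins: int = 10,
    seed: int = 0,
) -> ConsistencyEstimate:
    """Noise-adjusted correlation between two systems' signatures.

    Each resplit halves both systems' trials, computes half signatures,
    takes the mean cross-system Pearson correlation of the four half pairs
    as the raw rho, the within-system half correlations as reliabilities,
    and forms rho / sqrt(rel_m * rel_p).  Resplits with a non-positive
    reliability are reported as undefined rather than coerced.
    """
    rng = np.random.default_rng(seed)
    vals, raws, rms, rps = [], [], [], []
    n_undef = 0
    for _ in range(n_resplits):
        m1t, m2t = _split_trials(trials_m, rng)
        p1t, p2t = _split_trials(trials_p, rng)
        sigs = [binned_signature(t, stimulus_meta, n_bins).dprime_per_bin
                for t in (m1t, m2t, p1t, p2t)]
        m1, m2, p1, p2 = sigs
        raw = np.mean([stats.pearsonr(a, b)[0] for a in (m1, m2) for b in (p1, p2)])
        rel_m = stats.pearsonr(m1, m2)[0]
        rel_p = stats.pearsonr(p1, p2)[0]
        raws.append(raw)
        rms.append(rel_m)
        rps.append(rel_p)
        if rel_m <= 0 or rel_p <= 0:
            n_undef += 1
            vals.append(np.nan)
        else:
            vals.append(raw / np.sqrt(rel_m * rel_p))
    vals = np.array(vals)
    rho = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")
    return ConsistencyEstimate(
        rho_tilde=rho,
        raw_rho=float(np.mean(raws)),
        reliability_m=float(np.mean(rms)),
        reliability_p=float(np.mean(rps)),
        n_resplits=n_resplits,
        per_resplit=vals,
        n_undefined=n_undef,
    )


def pool_and_holdout_consistency(
    tables_by_subject: dict[str, pd.DataFrame],
    stimulus_meta: pd.DataFrame,
    n_resplits: int = 10,
    n_bins: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-subject-out consistency of each subject with the pool.

    The distribution of hold-out rho_tilde values defines the behavioral
    ceiling against which a model's consistency is judged.
    """
    subjects = sorted(tables_by_subject)
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for i, s in enumerate(subjects):
        pool = pd.concat([tables_by_subject[t] for t in subjects if t != s], ignore_index=True)
        est = consistency(tables_by_subject[s], pool, stimulus_meta,
                          n_resplits=n_resplits, n_bins=n_bins, seed=seed + i)
        rows.append((s, est.rho_tilde, est.raw_rho, est.reliability_m, est.reliability_p))
    return pd.DataFrame(rows, columns=["subject_id", "rho_tilde", "raw_rho",
                                       "reliability_subject", "reliability_pool"])
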