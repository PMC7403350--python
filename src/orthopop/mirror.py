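"""Mirror-symmetry analysis: reflectivity vs decoder-space letter similarity.

A 26-way multinomial logistic decoder maps the population representation of
each single-letter stimulus into a 26-dimensional class-probability vector.
For each of the 325 unordered letter pairs, r_IT is the Pearson correlation
of the two letters' embeddings at one position, averaged over the four
positions.  The analysis relates r_IT to the pairwise reflectivity contrast
delta_R = R_H - R_V: a population with horizontally mirror-symmetric tuning
confuses high-delta_R pairs, raising r_IT in the rightmost delta_R bin.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .features import PopulationFeatures


def letter_decoder_embedding(
    features: PopulationFeatures,
    letter_meta: pd.DataFrame,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[np.ndarray, list[str], list[int]]:
    """Cross-validated 26-class decoder embedding per (letter, position).

    Leave-one-position-out: the decoder that embeds position p's stimuli is
    trained on the other positions only, so no stimulus is embedded by a
    decoder trained on its own position instance.  Returns an array of shape
    (letters, positions, classes) of class probabilities (rows sum to 1),
    averaged over the case/size variations at each position.
    """
    lm = letter_meta[letter_meta.lexical_class == "letter"].copy()
    letters = sorted(lm.text.str.lower().unique())
    positions = sorted(lm.position_slot.astype(int).unique())
    pos_index = {s: i for i, s in enumerate(features.stimulus_ids)}
    missing = set(lm.stimulus_id) - set(features.stimulus_ids)
    if missing:
        raise ValueError(f"features lack letter stimuli: {sorted(missing)[:5]}")
    X = features.matrix[:, [pos_index[s] for s in lm.stimulus_id]].T
    y = lm.text.str.lower().to_numpy()
    slot = lm.position_slot.astype(int).to_numpy()

    emb = np.zeros((len(letters), len(positions), len(letters)))
    letter_row = {c: i for i, c in enumerate(letters)}
    for pi, p in enumerate(positions):
        train, test = slot != p, slot == p
        if not train.any() or not test.any():
            raise ValueError(f"position {p} lacks train or test stimuli")
        if set(y[train]) != set(letters):
            raise ValueError("training positions do not cover all letter classes")
        scaler = StandardScaler().fit(X[train])
        clf = LogisticRegression(C=C, max_iter=2000)
        clf.fit(scaler.transform(X[train]), y[train])
        proba = clf.predict_proba(scaler.transform(X[test]))
        cols = [letter_row[c] for c in clf.classes_]
        for letter in letters:
            rows = proba[y[test] == letter]
            out = np.zeros(len(letters))
            out[cols] = rows.mean(axis=0)
            emb[letter_row[letter], pi] = out
    return emb, letters, positions


def pair_similarity(embedding: np.ndarray, letters: list[str]) -> pd.DataFrame:
    """r_IT per unordered letter pair: position-wise Pearson r, averaged."""
    n_letters, n_pos, _ = embedding.shape
    rows = []
    for a, b in itertools.combinations(range(n_letters), 2):
        rs = [stats.pearsonr(embedding[a, p], embedding[b, p])[0] for p in range(n_pos)]
        rows.append((letters[a], letters[b], float(np.mean(rs))))
    return pd.DataFrame(rows, columns=["letter_a", "letter_b", "r_IT"])


def join_reflectivity(pair_sim: pd.DataFrame, records) -> pd.DataFrame:
    """Join r_IT with ReflectivityRecord values on the letter pair."""
    ref = pd.DataFrame(
        [(r.letter_a, r.letter_b, r.R_H, r.R_V, r.delta_R) for r in records],
        columns=["letter_a", "letter_b", "R_H", "R_V", "delta_R"],
    )
    merged = pair_sim.merge(ref, on=["letter_a", "letter_b"])
    if len(merged) != len(pair_sim):
        raise ValueError("reflectivity records do not cover all letter pairs")
    return merged


def deltaR_analysis(pairs: pd.DataFrame, n_bins: int = 3, boxcar: int = 5) -> dict:
    """Summary of the r_IT vs delta_R relationship.

    Pairs sorted by delta_R get a boxcar rolling average of r_IT; delta_R is
    additionally cut into ``n_bins`` equal-range bins with per-bin mean +/-
    SE (over pairs), one-tailed one-sample t-tests of positive mean r_IT in
    each extreme bin, and a one-tailed Welch two-sample t-test of
    (rightmost > leftmost).
    """
    if len(pairs) < 2 * n_bins:
        raise ValueError("too few pairs for the requested binning")
    df = pairs.sort_values("delta_R", kind="stable").reset_index(drop=True)
    roll = None
    if len(df) >= boxcar:
        roll = np.convolve(df.r_IT, np.ones(boxcar) / boxcar, mode="valid")
    edges = np.linspace(df.delta_R.min(), df.delta_R.max(), n_bins + 1)
    which = np.clip(np.searchsorted(edges, df.delta_R, side="right") - 1, 0, n_bins - 1)
    bins = []
    for b in range(n_bins):
        r = df.r_IT[which == b].to_numpy()
        bins.append({
            "bin": b,
            "delta_R_low": float(edges[b]),
            "delta_R_high": float(edges[b + 1]),
            "n_pairs": int(len(r)),
            "mean_r_IT": float(r.mean()) if len(r) else np.nan,
            "se_r_IT": float(r.std(ddof=1) / np.sqrt(len(r))) if len(r) > 1 else np.nan,
        })
    left = df.r_IT[which == 0].to_numpy()
    right = df.r_IT[which == n_bins - 1].to_numpy()
    out = {
        "bins": bins,
        "rolling_delta_R": df.delta_R.to_numpy()[boxcar - 1 :] if roll is not None else None,
        "rolling_r_IT": roll,
        "empty_bins": [b["bin"] for b in bins if b["n_pairs"] == 0],
    }
    if len(right) > 1:
        out["p_right_positive"] = float(stats.ttest_1samp(right, 0, alternative="greater").pvalue)
    if len(left) > 1:
        out["p_left_positive"] = float(stats.ttest_1samp(left, 0, alternative="greater").pvalue)
    if len(left) > 1 and len(right) > 1:
        out["p_right_gt_left"] = float(
            stats.ttest_ind(right, left, equal_var=False, alternative="greater").pvalue
        )
    return out
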