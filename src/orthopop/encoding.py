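"""Letter-to-string encoding models.

Tests whether a site's responses to four-letter strings can be linearly
reconstructed from its own responses to the constituent letters at the
corresponding positions.  Models: the full position-specific four-predictor
model (``full_4``), best-substring models (``best_1/2/3``, subset chosen on
training folds only) and a position-shuffled "bag of letters" model that
uses a fixed random permutation of slots for all strings.

Fits are cross-validated over strings and reported as a noise-adjusted
correlation: the raw correlation between predictions and measured responses
divided by the square root of the (Spearman-Brown corrected) split-half
reliability of the measured string responses, so that a fully predictive
model scores ~1 regardless of the finite repetition count.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .synth import ResponseTensor

MODELS = ("full_4", "best_3", "best_2", "best_1", "bag_of_letters")
N_SLOTS = 4


def letter_response_lookup(
    tensor: ResponseTensor,
    letter_meta: pd.DataFrame,
    font_case: str = "upper",
    font_size: str = "medium",
) -> dict[tuple[str, int], np.ndarray]:
    """(letter, slot) -> per-site repetition-averaged early-window response.

    Letter stimuli are matched at a canonical case/size; multiple matching
    stimuli (if any) are averaged.
    """
    early = tensor.rates[0].mean(axis=2)  # sites x stimuli
    pos = {s: i for i, s in enumerate(tensor.stimulus_ids)}
    sel = letter_meta[(letter_meta.lexical_class == "letter")
                      & (letter_meta.font_case == font_case)
                      & (letter_meta.font_size == font_size)]
    lookup: dict[tuple[str, int], list] = {}
    for _, row in sel.iterrows():
        if row.stimulus_id not in pos:
            continue
        lookup.setdefault((row.text.lower(), int(row.position_slot)), []).append(
            early[:, pos[row.stimulus_id]]
        )
    return {k: np.mean(v, axis=0) for k, v in lookup.items()}


def letter_predictor_matrix(
    string_texts,
    lookup: dict[tuple[str, int], np.ndarray],
    model: str = "full_4",
    bag_permutation: np.ndarray | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Predictors: sites x strings x 4 responses to the constituent letters.

    ``full_4`` (and the best_k models, which subset later) use the letter at
    slot k paired with the slot-k letter response; ``bag_of_letters``
    replaces the slot index by one fixed random permutation of slots shared
    by all strings.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if model == "bag_of_letters":
        if bag_permutation is None:
            bag_permutation = np.random.default_rng(seed).permutation(N_SLOTS)
        slots = np.asarray(bag_permutation)
        if sorted(slots.tolist()) != list(range(N_SLOTS)):
            raise ValueError("bag_permutation must be a permutation of 0..3")
    else:
        slots = np.arange(N_SLOTS)
    missing = sorted({
        (t[k], int(slots[k]) + 1)
        for t in (s.lower() for s in string_texts)
        for k in range(N_SLOTS)
        if (t[k], int(slots[k]) + 1) not in lookup
    })
    if missing:
        raise KeyError(f"missing letter-at-slot responses: {missing[:8]}")
    n_sites = next(iter(lookup.values())).shape[0]
    P = np.zeros((n_sites, len(list(string_texts)), N_SLOTS))
    for j, text in enumerate(string_texts):
        t = text.lower()
        for k in range(N_SLOTS):
            P[:, j, k] = lookup[(t[k], int(slots[k]) + 1)]
    return P


def _ols_predict(Xtr, ytr, Xte):
    A = np.column_stack([np.ones(len(Xtr)), Xtr])
    coef, *_ = np.linalg.lstsq(A, ytr, rcond=None)
    return np.column_stack([np.ones(len(Xte)), Xte]) @ coef


def _split_half_reliability(rates: np.ndarray, n_splits: int, rng) -> np.ndarray:
    """Spearman-Brown corrected split-half reliability per site.

    ``rates`` is sites x strings x reps; the correction 2r/(1+r) converts
    half-data reliability to full-data reliability, the noise ceiling of a
    deterministic model's correlation with the all-repetition average.
    """
    n_sites, n_str, n_reps = rates.shape
    rel = np.zeros(n_sites)
    for _ in range(n_splits):
        order = rng.permutation(n_reps)
        m1 = rates[:, :, order[: n_reps // 2]].mean(axis=2)
        m2 = rates[:, :, order[n_reps // 2 :]].mean(axis=2)
        for i in range(n_sites):
            r = np.corrcoef(m1[i], m2[i])[0, 1]
            rel[i] += 2 * r / (1 + r) if r > -1 else np.nan
    return rel / n_splits


def fit_reconstruction(
    tensor: ResponseTensor,
    string_meta: pd.DataFrame,
    letter_meta: pd.DataFrame,
    model: str = "full_4",
    n_folds: int = 10,
    n_reliability_splits: int = 10,
    font_case: str = "upper",
    font_size: str = "medium",
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated noise-adjusted reconstruction fit, one row per site.

    For best_k models the slot subset is chosen by exhaustive search on the
    training fold (lowest residual sum of squares, ties to the lowest slot
    indices), keeping selection and testing statistically independent.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    strings = string_meta[(string_meta.lexical_class.isin(["word", "pseudoword"]))
                          & (string_meta.font_case == font_case)
                          & (string_meta.font_size == font_size)]
    texts = list(strings.text)
    if len(texts) < n_folds:
        raise ValueError("fewer strings than folds")
    lookup = letter_response_lookup(tensor, letter_meta, font_case, font_size)
    rng = np.random.default_rng(seed)
    P = letter_predictor_matrix(texts, lookup, model=model, seed=seed)
    sub = tensor.select_stimuli(list(strings.stimulus_id))
    y_all = sub.rates[0].mean(axis=2)  # sites x strings
    reliability = _split_half_reliability(sub.rates[0], n_reliability_splits, rng)

    if model in ("full_4", "bag_of_letters"):
        subsets = [tuple(range(N_SLOTS))]
    else:
        k = int(model[-1])
        subsets = list(itertools.combinations(range(N_SLOTS), k))

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**32))
    folds = list(kf.split(texts))
    rows = []
    for i, site in enumerate(sub.site_ids):
        X = P[i]
        y = y_all[i]
        pred = np.zeros_like(y)
        chosen = []
        for train, test in folds:
            best_rss, best_subset = np.inf, subsets[0]
            for ss in subsets:
                if len(subsets) == 1:
                    break
                p_tr = _ols_predict(X[np.ix_(train, ss)], y[train], X[np.ix_(train, ss)])
                rss = ((y[train] - p_tr) ** 2).sum()
                if rss < best_rss - 1e-12:
                    best_rss, best_subset = rss, ss
            chosen.append(best_subset)
            pred[test] = _ols_predict(X[np.ix_(train, best_subset)], y[train],
                                      X[np.ix_(test, best_subset)])
        r_raw = np.corrcoef(pred, y)[0, 1]
        rel = reliability[i]
        rho = r_raw / np.sqrt(rel) if rel > 0 else np.nan
        rows.append({
            "site_id": site,
            "model": model,
            "rho_tilde": rho,
            "raw_r": r_raw,
            "reliability": rel,
            "selected_slots": ";".join(",".join(map(str, s)) for s in chosen)
            if len(subsets) > 1 else "",
            "n_folds": n_folds,
        })
    return pd.DataFrame(rows)


def compare_model_medians(
    fits_a: pd.DataFrame,
    fits_b: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """One-tailed exact test that median rho(a) > median rho(b).

    Bootstraps sites (jointly for both models) and compares the resampled
    median difference against zero.
    """
    merged = fits_a.merge(fits_b, on="site_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("fits share no sites")
    a = merged["rho_tilde_a"].to_numpy()
    b = merged["rho_tilde_b"].to_numpy()
    rng = np.random.default_rng(seed)
    idx = rng.integers(len(a), size=(n_boot, len(a)))
    diffs = np.median(a[idx], axis=1) - np.median(b[idx], axis=1)
    p = (1 + (diffs <= 0).sum()) / (n_boot + 1)
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "median_diff": float(np.median(a) - np.median(b)),
        "p_one_tailed": float(p),
        "n_boot": n_boot,
    }
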