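"""Decoder-ready feature matrices and per-site screens.

Screens follow the recording-quality criteria used for population analyses:
a visual-drive screen (evoked vs baseline activity, alpha = 0.001) and a
letter-reliability screen (split-half Pearson correlation of single-letter
response patterns, alpha = 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synth import ResponseTensor

WINDOW_SELECTIONS = ("both_concatenated", "early_only", "late_only")


@dataclass
class PopulationFeatures:
    """Feature x stimulus matrix of repetition-averaged rates.

    With ``both_concatenated`` each site contributes two rows (one per
    response window); ``site_of_feature`` maps rows back to sites.
    """

    matrix: np.ndarray  # n_features x n_stimuli
    site_ids: list[str]  # unique sites, in site order
    site_of_feature: np.ndarray  # feature row -> index into site_ids
    stimulus_ids: list[str]
    window_selection: str

    def __post_init__(self):
        if self.matrix.shape != (len(self.site_of_feature), len(self.stimulus_ids)):
            raise ValueError("feature matrix shape mismatch")
        if not np.isfinite(self.matrix).all():
            raise ValueError("feature matrix contains missing entries")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def rows_for_sites(self, site_index) -> np.ndarray:
        """Feature-row indices for the given site indices (windows grouped)."""
        wanted = set(np.asarray(site_index).tolist())
        return np.flatnonzero(np.isin(self.site_of_feature, list(wanted)))

    def select_sites(self, site_index) -> "PopulationFeatures":
        """Features restricted to the given site indices (windows kept together)."""
        keep = np.asarray(sorted(set(np.asarray(site_index).tolist())))
        rows = self.rows_for_sites(keep)
        return PopulationFeatures(
            matrix=self.matrix[rows],
            site_ids=[self.site_ids[i] for i in keep],
            site_of_feature=np.searchsorted(keep, self.site_of_feature[rows]),
            stimulus_ids=self.stimulus_ids,
            window_selection=self.window_selection,
        )

    def stimulus_matrix(self, ids) -> np.ndarray:
        """Stimuli x features design matrix for the requested stimulus ids."""
        pos = {s: i for i, s in enumerate(self.stimulus_ids)}
        idx = np.array([pos[s] for s in ids])
        return self.matrix[:, idx].T


def average_repetitions(
    tensor: ResponseTensor,
    window_selection: str = "both_concatenated",
    rep_indices=None,
) -> PopulationFeatures:
    """Repetition-averaged rates, optionally restricted to a subset of reps.

    ``both_concatenated`` stacks the two window averages site-wise (the
    decoding configuration); single-site analyses use ``early_only``.
    """
    if window_selection not in WINDOW_SELECTIONS:
        raise ValueError(f"unknown window selection {window_selection!r}")
    rates = tensor.rates if rep_indices is None else tensor.rates[..., rep_indices]
    if rates.shape[-1] == 0:
        raise ValueError("no repetitions selected")
    means = rates.mean(axis=3)  # windows x sites x stimuli
    n_sites = means.shape[1]
    if window_selection == "both_concatenated":
        matrix = np.concatenate([means[0], means[1]], axis=0)
        site_of_feature = np.concatenate([np.arange(n_sites), np.arange(n_sites)])
    else:
        w = 0 if window_selection == "early_only" else 1
        matrix = means[w]
        site_of_feature = np.arange(n_sites)
    return PopulationFeatures(
        matrix=matrix,
        site_ids=tensor.site_ids,
        site_of_feature=site_of_feature,
        stimulus_ids=list(tensor.stimulus_ids),
        window_selection=window_selection,
    )


def screen_visual_drive(tensor: ResponseTensor, alpha: float = 0.001) -> pd.DataFrame:
    """Wilcoxon signed-rank test of evoked vs baseline rate, per site.

    Trial-wise paired comparison (early-window evoked rate minus the
    simultaneous baseline-rate draw), two-sided; distribution-free on rates.
    """
    evoked = tensor.rates[0].reshape(tensor.n_sites, -1)
    baseline = tensor.baseline_rates.reshape(tensor.n_sites, -1)
    rows = []
    for i, site in enumerate(tensor.site_ids):
        diff = evoked[i] - baseline[i]
        if np.all(diff == 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(diff, zero_method="wilcox", method="approx")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append((site, stat, p, p < alpha))
    return pd.DataFrame(rows, columns=["site_id", "statistic", "p", "visually_driven"])


def screen_letter_reliability(
    tensor: ResponseTensor,
    letter_stimulus_ids,
    alpha: float = 0.01,
    n_splits: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Split-half reliability of single-letter response patterns, per site.

    The early-window repetitions are split into random halves; the Pearson
    correlation between the two half-mean response patterns over the letter
    stimuli, averaged over ``n_splits`` resplits, is the reported
    reliability.  Significance uses the one-sided Pearson p of a single
    seeded split: the resplit-averaged correlation has inflated variance
    relative to its naive null (resplits share repetitions), so testing the
    average directly would be anti-conservative, while a single split is
    exactly one independent-halves comparison and calibrates at alpha.
    """
    if tensor.n_reps < 2:
        raise ValueError("split-half reliability requires >= 2 repetitions")
    sub = tensor.select_stimuli(list(letter_stimulus_ids))
    x = sub.rates[0]  # sites x letter stimuli x reps
    n_sites, n_stim, n_reps = x.shape
    rng = np.random.default_rng(seed)

    def znorm(v):  # rows: sites, cols: stimuli
        v = v - v.mean(axis=1, keepdims=True)
        s = np.linalg.norm(v, axis=1, keepdims=True)
        return v / np.where(s > 0, s, 1.0)

    r_obs = np.zeros(n_sites)
    r_first = None
    for k in range(n_splits):
        order = rng.permutation(n_reps)
        h1, h2 = order[: n_reps // 2], order[n_reps // 2 :]
        z1 = znorm(x[:, :, h1].mean(axis=2))
        z2 = znorm(x[:, :, h2].mean(axis=2))
        r = np.einsum("ij,ij->i", z1, z2)
        r_obs += r
        if k == 0:
            r_first = r
    r_obs /= n_splits
    # one-sided p for positive correlation from the first split (t statistic
    # with n_stim - 2 degrees of freedom)
    rr = np.clip(r_first, -0.999999, 0.999999)
    t = rr * np.sqrt((n_stim - 2) / (1.0 - rr**2))
    p = stats.t.sf(t, df=n_stim - 2)
    return pd.DataFrame(
        {
            "site_id": sub.site_ids,
            "split_half_r": r_obs,
            "p": p,
            "reliable_letters": p < alpha,
        }
    )
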