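"""Single-site statistics: selectivity d', bootstrap exact tests, sparsity
index with uniform/one-hot permutation nulls, spatial topography (Moran's I)
and binomial proportion tests.

All single-site analyses operate on the early response window (70-170 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# selectivity


def selectivity_dprime(responses_x: np.ndarray, responses_y: np.ndarray) -> float:
    """d' = (mu_x - mu_y) / sqrt((sigma_x^2 + sigma_y^2) / 2).

    Means and SDs are taken across stimuli of repetition-averaged responses;
    positive values indicate a preference for class x.
    """
    x = np.asarray(responses_x, float)
    y = np.asarray(responses_y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 stimuli per class")
    pooled = 0.5 * (x.var(ddof=1) + y.var(ddof=1))
    if pooled == 0:
        raise ValueError("zero pooled variance")
    return float((x.mean() - y.mean()) / np.sqrt(pooled))


def bootstrap_selectivity_test(
    responses: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Two-tailed exact test of d' != 0 by bootstrap resampling over stimuli.

    p = 2 * min(P(boot <= 0), P(boot >= 0)), capped at 1, with add-one
    smoothing of the tail fractions (the finite bootstrap count otherwise
    makes the min-of-tails estimate anti-conservative).
    """
    if n_boot < 2:
        raise ValueError("cannot form a two-tailed p from fewer than 2 bootstrap samples")
    responses = np.asarray(responses, float)
    labels = np.asarray(labels, bool)
    rng = np.random.default_rng(seed)
    x, y = responses[labels], responses[~labels]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both classes must have >= 2 stimuli")
    ix = rng.integers(len(x), size=(n_boot, len(x)))
    iy = rng.integers(len(y), size=(n_boot, len(y)))
    bx, by = x[ix], y[iy]
    pooled = 0.5 * (bx.var(axis=1, ddof=1) + by.var(axis=1, ddof=1))
    ok = pooled > 0
    boots = np.full(n_boot, np.nan)
    boots[ok] = (bx.mean(axis=1) - by.mean(axis=1))[ok] / np.sqrt(pooled[ok])
    valid = boots[np.isfinite(boots)]
    nb = len(valid)
    p = 2.0 * min(((valid <= 0).sum() + 1) / (nb + 1), ((valid >= 0).sum() + 1) / (nb + 1))
    return {
        "dprime": selectivity_dprime(x, y),
        "boot_mean": float(valid.mean()),
        "boot_sd": float(valid.std(ddof=1)),
        "p": float(min(p, 1.0)),
        "significant": bool(min(p, 1.0) < alpha),
        "n_boot": int(len(valid)),
        "n_degenerate": int(n_boot - len(valid)),
    }


def population_selectivity_table(
    site_responses: np.ndarray,
    labels: np.ndarray,
    site_ids,
    n_boot: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap selectivity test per site (sites x stimuli matrix input)."""
    rows = []
    for i, site in enumerate(site_ids):
        res = bootstrap_selectivity_test(site_responses[i], labels,
                                         n_boot=n_boot, alpha=alpha, seed=seed + i)
        rows.append({"site_id": site, **res})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# proportion tests


def selective_fraction_test(n_selective: int, n_total: int, p0: float = 0.05) -> float:
    """Binomial tail P(X >= n_selective) under success probability p0."""
    if not 0 <= n_selective <= n_total:
        raise ValueError("invalid counts")
    return float(stats.binomtest(n_selective, n_total, p0, alternative="greater").pvalue)


def hemisphere_bias_test(hemispheres, sampling_fraction: float, reference: str = "right") -> float:
    """Two-sided binomial test of selective-site hemisphere counts.

    ``sampling_fraction`` is the fraction of all recorded sites in the
    reference hemisphere (the sampling bias the null must respect).
    """
    hemispheres = list(hemispheres)
    if not hemispheres:
        raise ValueError("no hemisphere labels")
    k = sum(h == reference for h in hemispheres)
    return float(stats.binomtest(k, len(hemispheres), sampling_fraction,
                                 alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# sparsity


def sparsity_index(response_vector: np.ndarray) -> float:
    """SI(x) = (1 - A(x)) / (1 - 1/N) with A(x) = E[x]^2 / E[x^2].

    0 for a perfectly uniform vector, 1 for a perfectly one-hot vector
    (noise-free).  Negative entries (possible after Gaussian-noise
    repetition averaging) are rectified at zero.
    """
    x = np.asarray(response_vector, float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("response vector must be 1-D with N >= 2")
    x = np.clip(x, 0.0, None)
    if not x.any():
        raise ValueError("all-zero response vector")
    n = len(x)
    a = x.mean() ** 2 / (x**2).mean()
    return float((1.0 - a) / (1.0 - 1.0 / n))


@dataclass
class SparsityResult:
    site_id: str
    SI: float
    null_uniform_SI: np.ndarray
    null_onehot_SI: np.ndarray
    axis: str
    n_categories: int


def sparsity_nulls(
    category_rates: np.ndarray,
    site_id: str = "",
    axis: str = "letters",
    n_perm: int = 100,
    seed: int = 0,
) -> SparsityResult:
    """Empirical SI plus simulated uniform and one-hot null SI distributions.

    ``category_rates`` is categories x repetitions for one site (responses
    already averaged within category over positions/variations as desired).

    Uniform null: the category label of every repetition is shuffled, which
    destroys tuning while keeping repetition noise, then SI is computed on
    the shuffled repetition average.  One-hot null: the top category is
    inferred from the first half of repetitions; on the second half, the top
    category keeps its measured trials while every other category is
    replaced by its own mean-removed residuals (rectified), simulating a
    site that responds only to one category with matched trial noise.
    """
    x = np.asarray(category_rates, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need categories x repetitions with >= 2 repetitions")
    n_cat, n_reps = x.shape
    rng = np.random.default_rng(seed)
    si_emp = sparsity_index(x.mean(axis=1))

    null_uniform = np.empty(n_perm)
    flat = x.ravel()
    for i in range(n_perm):
        shuffled = flat[rng.permutation(flat.size)].reshape(n_cat, n_reps)
        null_uniform[i] = sparsity_index(shuffled.mean(axis=1))

    half = n_reps // 2
    null_onehot = np.empty(n_perm)
    for i in range(n_perm):
        order = rng.permutation(n_reps)
        h1, h2 = order[:half], order[half:]
        top = int(np.argmax(x[:, h1].mean(axis=1)))
        sim = x[:, h2] - x[:, h2].mean(axis=1, keepdims=True)
        sim = np.clip(sim, 0.0, None)
        sim[top] = x[top, h2]
        v = sim.mean(axis=1)
        if not np.clip(v, 0, None).any():
            null_onehot[i] = np.nan
            continue
        null_onehot[i] = sparsity_index(v)
    return SparsityResult(site_id, si_emp, null_uniform, null_onehot, axis, n_cat)


def compare_si_medians(empirical_si: np.ndarray, null_si_per_site: np.ndarray) -> dict:
    """Permutation test of the across-site median SI against a simulated null.

    ``null_si_per_site`` is sites x permutations; the null median
    distribution is the per-permutation median across sites.
    """
    emp = float(np.median(empirical_si))
    null_medians = np.nanmedian(null_si_per_site, axis=0)
    n = len(null_medians)
    p_greater = (1 + (null_medians >= emp).sum()) / (n + 1)
    p_less = (1 + (null_medians <= emp).sum()) / (n + 1)
    return {
        "empirical_median": emp,
        "null_median": float(np.median(null_medians)),
        "p_greater": float(p_greater),
        "p_less": float(p_less),
    }


def category_rate_tensor(tensor, letter_meta: pd.DataFrame, by: str = "letter") -> tuple[np.ndarray, list]:
    """Sites x categories x repetitions early-window rates for letter stimuli.

    Stimuli sharing a category (same letter, or same position slot) are
    averaged within each repetition, giving the per-category trial matrix
    that the sparsity analyses consume.
    """
    lm = letter_meta[letter_meta.lexical_class == "letter"]
    if by == "letter":
        cats = sorted(lm.text.str.lower().unique())
        key = lm.text.str.lower()
    elif by == "position":
        cats = sorted(lm.position_slot.astype(int).unique())
        key = lm.position_slot.astype(int)
    else:
        raise ValueError(f"unknown grouping {by!r}")
    pos = {s: i for i, s in enumerate(tensor.stimulus_ids)}
    out = np.zeros((tensor.n_sites, len(cats), tensor.n_reps))
    for ci, c in enumerate(cats):
        ids = lm.stimulus_id[key == c]
        idx = [pos[s] for s in ids if s in pos]
        if not idx:
            raise ValueError(f"no stimuli for category {c!r}")
        out[:, ci] = tensor.rates[0][:, idx].mean(axis=1)
    return out, cats


# ---------------------------------------------------------------------------
# topography


def _grid_weights(occupied: np.ndarray, adjacency: str = "rook", row_standardize: bool = True):
    """Spatial weight matrix over occupied cells of a 10x10 grid."""
    coords = np.argwhere(occupied)
    n = len(coords)
    W = np.zeros((n, n))
    steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if adjacency == "queen":
        steps += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    elif adjacency != "rook":
        raise ValueError(f"unknown adjacency {adjacency!r}")
    index = {tuple(c): i for i, c in enumerate(coords)}
    for i, (r, c) in enumerate(coords):
        for dr, dc in steps:
            j = index.get((r + dr, c + dc))
            if j is not None:
                W[i, j] = 1.0
    if row_standardize:
        sums = W.sum(axis=1, keepdims=True)
        W = np.divide(W, sums, out=np.zeros_like(W), where=sums > 0)
    return W


def _moran_statistic(values: np.ndarray, W: np.ndarray) -> float:
    z = values - values.mean()
    denom = (z**2).sum()
    if denom == 0:
        raise ValueError("constant field: Moran's I undefined")
    return float(len(values) / W.sum() * (z @ W @ z) / denom)


@dataclass
class MoranResult:
    I: float
    p: float
    n_permutations: int
    per_array_I: list


def morans_I(
    grid_values: np.ndarray,
    adjacency: str = "rook",
    row_standardize: bool = True,
    n_perm: int = 100,
    seed: int = 0,
    alternative: str = "greater",
) -> MoranResult:
    """Moran's I spatial autocorrelation on a 10x10 electrode grid.

    ``grid_values`` is a 10x10 array with NaN marking unoccupied electrodes.
    The permutation p shuffles values across occupied cells (the chance
    distribution fixing the observed values); ``alternative='greater'`` tests for clustering.
    """
    return morans_I_multi([grid_values], adjacency=adjacency,
                          row_standardize=row_standardize, n_perm=n_perm,
                          seed=seed, alternative=alternative)


def morans_I_multi(
    grids,
    adjacency: str = "rook",
    row_standardize: bool = True,
    n_perm: int = 100,
    seed: int = 0,
    alternative: str = "greater",
) -> MoranResult:
    """Moran's I averaged over arrays, with a joint permutation null."""
    if n_perm < 100:
        raise ValueError("use at least 100 permutations")
    rng = np.random.default_rng(seed)
    per_array = []
    weights = []
    vals = []
    for g in grids:
        g = np.asarray(g, float)
        occupied = np.isfinite(g)
        v = g[occupied]
        if len(v) < 2:
            raise ValueError("need >= 2 finite values per grid")
        W = _grid_weights(occupied, adjacency, row_standardize)
        per_array.append(_moran_statistic(v, W))
        weights.append(W)
        vals.append(v)
    obs = float(np.mean(per_array))
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = np.mean([
            _moran_statistic(v[rng.permutation(len(v))], W)
            for v, W in zip(vals, weights)
        ])
    if alternative == "greater":
        p = (1 + (null >= obs).sum()) / (n_perm + 1)
    elif alternative == "less":
        p = (1 + (null <= obs).sum()) / (n_perm + 1)
    elif alternative == "two-sided":
        p = min(1.0, 2 * min((1 + (null >= obs).sum()) / (n_perm + 1),
                             (1 + (null <= obs).sum()) / (n_perm + 1)))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return MoranResult(I=obs, p=float(p), n_permutations=n_perm, per_array_I=per_array)


def selectivity_grids(site_meta: pd.DataFrame, values: np.ndarray) -> list[np.ndarray]:
    """Per-array 10x10 grids of a per-site quantity (NaN = unoccupied)."""
    grids = []
    for _, sub in site_meta.assign(v=values).groupby("array_id"):
        g = np.full((10, 10), np.nan)
        g[sub.grid_row.to_numpy(), sub.grid_col.to_numpy()] = sub.v.to_numpy()
        grids.append(g)
    return grids
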