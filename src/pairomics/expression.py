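"""Paired gene-expression statistics.

The core statistic is the SAM (significance analysis of microarrays)
two-class paired test: per gene, the mean of the per-pair relapse -
diagnosis log2 differences divided by its standard error plus a global
"fudge" constant s0, with q-values estimated from sign-flip permutations
via the median-false-positive rule. Around it sit the standard filters
(low-expression floor, variance filter), per-pair fold-change rules,
UPGMA clustering, classical multidimensional scaling, and a local
hypergeometric over-representation test for user-supplied gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class SAMResult:
    """Per-gene output of the paired SAM statistic."""

    table: pd.DataFrame  # gene, mean_diff, se, d, fold_change, q_value
    s0: float
    n_permutations: int

    def significant(self, q_cutoff: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q_value"] < q_cutoff]


def _pair_columns(matrix: pd.DataFrame, pairing: dict[str, str]) -> tuple[np.ndarray, np.ndarray]:
    diag = list(pairing)
    rel = [pairing[d] for d in diag]
    missing = [s for s in diag + rel if s not in matrix.columns]
    if missing:
        raise KeyError(f"samples not in matrix: {missing}")
    return matrix[diag].to_numpy(dtype=float), matrix[rel].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# filters

def low_expression_filter(
    matrix: pd.DataFrame,
    floor: float | None = None,
    min_samples: int | None = None,
) -> pd.DataFrame:
    """Drop genes that never rise above a low-expression floor.

    A gene is kept when its value exceeds ``floor`` in at least
    ``min_samples`` samples. Defaults: floor = 25th percentile of the
    global value distribution; min_samples = 25% of samples (>= 1).
    """
    values = matrix.to_numpy(dtype=float)
    if floor is None:
        floor = float(np.percentile(values, 25))
    if min_samples is None:
        min_samples = max(1, matrix.shape[1] // 4)
    keep = (values > floor).sum(axis=1) >= min_samples
    if not keep.any():
        warnings.warn("low-expression filter removed every gene")
    return matrix.loc[keep]


def variance_filter(matrix: pd.DataFrame, drop_fraction: float = 0.5) -> pd.DataFrame:
    """Remove the ``drop_fraction`` of genes with lowest profile variance.

    Ties are broken by gene id so the result is deterministic.
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    if drop_fraction == 0:
        return matrix.copy()
    var = matrix.var(axis=1, ddof=1)
    order = sorted(matrix.index, key=lambda g: (var[g], str(g)))
    n_drop = int(np.floor(drop_fraction * len(order)))
    keep = set(order[n_drop:])
    return matrix.loc[[g for g in matrix.index if g in keep]]


# ---------------------------------------------------------------------------
# SAM two-class paired

def _sign_matrix(n_pairs: int, n_permutations: int, seed: int) -> np.ndarray:
    if n_pairs <= 10:
        return np.array(
            [[1 if (m >> b) & 1 else -1 for b in range(n_pairs)] for m in range(2**n_pairs)],
            dtype=float,
        )
    rng = np.random.default_rng(seed)
    return rng.choice([-1.0, 1.0], size=(n_permutations, n_pairs))


def _choose_s0(mean_diff: np.ndarray, se: np.ndarray) -> float:
    """Tusher-style fudge factor: the percentile of the se distribution
    minimizing the coefficient of variation of the median absolute
    d-statistic across se-quantile bins."""
    percentiles = np.arange(0, 101, 5)
    candidates = np.percentile(se, percentiles)
    n_bins = min(10, max(2, se.size // 20))
    edges = np.quantile(se, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, se, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d = mean_diff / np.maximum(se + s0, 1e-12)
        mads = np.array(
            [np.median(np.abs(d[bins == b])) for b in range(n_bins) if np.any(bins == b)]
        )
        if mads.size < 2 or mads.mean() == 0:
            continue
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, s0
    return float(best_s0)


def sam_paired(
    matrix: pd.DataFrame,
    pairing: dict[str, str],
    n_permutations: int = 1000,
    s0: float | None = None,
    seed: int = 0,
) -> SAMResult:
    """SAM two-class paired statistic with permutation q-values.

    ``pairing`` maps diagnosis sample id -> relapse sample id. Per gene,
    z_i = relapse - diagnosis for pair i, d = mean(z) / (se(z) + s0).
    The null distribution of d comes from sign-flip permutations of the
    pair labels (all 2^n flips when n <= 10, else ``n_permutations``
    random draws). The q-value at threshold |d_g| is the median across
    permutations of the null exceedance count divided by the observed
    exceedance count, clipped to [0, 1] and monotonized in |d|.
    """
    diag, rel = _pair_columns(matrix, pairing)
    n_pairs = diag.shape[1]
    if n_pairs < 3:
        raise ValueError("paired SAM needs at least 3 pairs")
    Z = rel - diag  # genes x pairs
    n = n_pairs
    mean_diff = Z.mean(axis=1)
    sd = Z.std(axis=1, ddof=1)
    se = sd / np.sqrt(n)
    if s0 is None:
        s0 = _choose_s0(mean_diff, se)
    # guard the degenerate all-constant case (se + s0 = 0): d stays defined
    eps = s0 if s0 > 0 else max(float(se[se > 0].min()) * 1e-6 if (se > 0).any() else 1e-12, 1e-12)
    d = mean_diff / np.maximum(se + s0, eps)

    signs = _sign_matrix(n, n_permutations, seed)  # perms x pairs
    n_perm = signs.shape[0]
    sumsq = (Z**2).sum(axis=1)  # invariant under sign flips
    null_mean = Z @ signs.T / n  # genes x perms
    null_var = np.maximum(sumsq[:, None] - n * null_mean**2, 0.0) / (n - 1)
    null_se = np.sqrt(null_var / n)
    null_d = null_mean / np.maximum(null_se + s0, eps)

    abs_d = np.abs(d)
    order = np.argsort(abs_d)[::-1]
    # observed exceedance count at each gene's threshold
    sorted_abs = np.sort(abs_d)
    obs_count = abs_d.size - np.searchsorted(sorted_abs, abs_d, side="left")
    # null exceedance counts, per permutation
    null_counts = np.empty((n_perm, abs_d.size), dtype=float)
    abs_null = np.abs(null_d)
    for b in range(n_perm):
        col = np.sort(abs_null[:, b])
        null_counts[b] = abs_d.size - np.searchsorted(col, abs_d, side="left")
    med_fp = np.median(null_counts, axis=0)
    q = np.clip(med_fp / np.maximum(obs_count, 1), 0.0, 1.0)
    # monotonize: q must not decrease as |d| decreases
    q_sorted = q[order]
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_mono = np.empty_like(q)
    q_mono[order] = q_sorted

    fc = mean_diff  # log2 scale fold change
    table = pd.DataFrame(
        {
            "mean_diff": mean_diff,
            "se": se,
            "d": d,
            "fold_change": fc,
            "q_value": q_mono,
        },
        index=matrix.index,
    )
    return SAMResult(table=table, s0=float(s0), n_permutations=n_perm)


# ---------------------------------------------------------------------------
# fold changes and concordance

def fold_changes(matrix: pd.DataFrame, pairing: dict[str, str]) -> pd.DataFrame:
    """Per-gene, per-pair log2 fold change (relapse - diagnosis)."""
    diag, rel = _pair_columns(matrix, pairing)
    return pd.DataFrame(rel - diag, index=matrix.index, columns=list(pairing))


def concordance_filter(
    fc: pd.DataFrame,
    min_ratio_fc: float = 2.0,
    min_pairs: int = 5,
) -> dict[str, list[str]]:
    """Genes changed >= ``min_ratio_fc``-fold in the same direction in at
    least ``min_pairs`` pairs, partitioned into up/down lists."""
    if min_ratio_fc <= 0 or min_pairs <= 0:
        raise ValueError("thresholds must be positive")
    log_t = np.log2(min_ratio_fc)
    up_counts = (fc >= log_t).sum(axis=1)
    down_counts = (fc <= -log_t).sum(axis=1)
    up = sorted(fc.index[up_counts >= min_pairs])
    down = sorted(fc.index[down_counts >= min_pairs])
    return {"up": [str(g) for g in up], "down": [str(g) for g in down]}


# ---------------------------------------------------------------------------
# unsupervised

def hierarchical_cluster(
    matrix: pd.DataFrame, height: float | None = None
) -> tuple[np.ndarray, pd.Series | None]:
    """UPGMA (group-average, Euclidean) clustering of samples (columns).

    Returns the scipy linkage matrix and, when ``height`` is given, the
    flat cluster labels from cutting the dendrogram at that height.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least two samples")
    X = matrix.to_numpy(dtype=float).T
    link = hierarchy.linkage(X, method="average", metric="euclidean")
    labels = None
    if height is not None:
        flat = hierarchy.fcluster(link, t=height, criterion="distance")
        labels = pd.Series(flat, index=matrix.columns, name="cluster")
    return link, labels


def mds(data: pd.DataFrame | np.ndarray, n_components: int = 2, is_distance: bool = False) -> np.ndarray:
    """Classical (Torgerson) multidimensional scaling.

    Accepts a samples-in-columns matrix (Euclidean distances are computed)
    or a precomputed symmetric distance matrix with ``is_distance=True``.
    Axis orientation is fixed by making the first non-zero loading of each
    component positive.
    """
    if is_distance:
        D = np.asarray(data, dtype=float)
        if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-8):
            raise ValueError("distance matrix must be symmetric")
    else:
        X = data.to_numpy(dtype=float).T if isinstance(data, pd.DataFrame) else np.asarray(data, dtype=float)
        D = squareform(pdist(X, metric="euclidean"))
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    idx = np.argsort(evals)[::-1][:n_components]
    lam = np.clip(evals[idx], 0.0, None)
    coords = evecs[:, idx] * np.sqrt(lam)
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
    return coords


# ---------------------------------------------------------------------------
# gene-set over-representation

def ora(
    gene_list: list[str],
    universe: list[str],
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set,
    BH-adjusted across sets. Sets with no members in the universe are
    skipped (flagged in the output)."""
    uni = set(universe)
    lst = set(gene_list)
    if not lst <= uni:
        raise ValueError("gene list must be a subset of the universe")
    N, n = len(uni), len(lst)
    rows = []
    for name, members in gene_sets.items():
        K = len(uni & set(members))
        if K == 0:
            rows.append({"set": name, "overlap": 0, "set_size": 0, "p_value": np.nan, "skipped": True})
            continue
        k = len(lst & set(members))
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set": name, "overlap": k, "set_size": K, "p_value": p, "skipped": False})
    out = pd.DataFrame(rows)
    tested = ~out["skipped"]
    out["adj_p"] = np.nan
    if tested.any():
        out.loc[tested, "adj_p"] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    return out
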