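"""DNA methylation analysis for paired tiling-array data.

Three workflows are supported, mirroring common practice for two-colour
methylation tiling arrays:

1. **Peak counting** — per-sample methylated regions from probe peak
   scores (window 750 bp, >= 2 probes per peak, score cutoff 2), with
   relapse/diagnosis peak-count ratios per sample and per chromosome.
2. **DMR detection** — smoothed paired relapse-diagnosis differences on
   the methylation-fraction scale; maximal runs exceeding a 5-percentage-
   point cutoff, at least 4 probes, sign-flip permutation p-values.
3. **Promoter-window aggregation** — strand-aware mean/max methylation in
   the promoter (-2000..0 bp from TSS) and core promoter (+/-250 bp)
   windows, fed to the paired SAM statistic.

Preprocessing (quantile normalization on log ratios, ComBat-style
empirical-Bayes batch correction) lives here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import sam_paired

PEAK_WIDTH = 750
PEAK_MIN_PROBES = 2
PEAK_SCORE_CUTOFF = 2.0
DMR_MIN_PROBES = 4
DMR_DELTA_CUTOFF = 0.05
PROMOTER_UPSTREAM = 2000
CORE_HALF_WIDTH = 250


@dataclass
class PeakParams:
    width: int = PEAK_WIDTH
    min_probes: int = PEAK_MIN_PROBES
    score_cutoff: float = PEAK_SCORE_CUTOFF

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass
class DMR:
    chrom: str
    start: int
    end: int
    n_probes: int
    mean_delta: float
    p_value: float

    @property
    def direction(self) -> str:
        return "hyper" if self.mean_delta > 0 else "hypo"


# ---------------------------------------------------------------------------
# scale conversions

def fraction_to_logratio(m: np.ndarray) -> np.ndarray:
    """Logit-style log2 ratio x = log2(m / (1 - m)) for fractions in (0,1)."""
    m = np.asarray(m, dtype=float)
    return np.log2(m / (1.0 - m))


def logratio_to_fraction(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fraction_to_logratio`: m = 2^x / (1 + 2^x)."""
    x = np.asarray(x, dtype=float)
    p = np.exp2(x)
    return p / (1.0 + p)


# ---------------------------------------------------------------------------
# preprocessing

def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column to the common mean-of-sorted-columns distribution.

    Ranks within columns are preserved; ties receive the mean reference
    value of the tied ranks (rank-average convention).
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile normalization with < 2 samples is the identity")
        return matrix.copy()
    values = matrix.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    n = values.shape[0]
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        ranks = stats.rankdata(values[:, j], method="average")
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def batch_correct(
    matrix: pd.DataFrame,
    batches: pd.Series | dict,
    parametric: bool = True,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Empirical-Bayes location/scale batch adjustment (ComBat-style).

    Probes are standardized against the grand mean and pooled variance;
    per-batch location (gamma) and scale (delta) parameters are shrunk
    toward their batch-wide means using parametric method-of-moments
    priors, then removed and the data returned on the original scale.
    With ``parametric=False`` a plain per-batch mean-centering fallback is
    used (appropriate for very small cohorts).
    """
    batches = pd.Series(batches)
    batches = batches.reindex(matrix.columns)
    if batches.isna().any():
        raise ValueError("every sample needs a batch label")
    levels = batches.unique()
    if len(levels) < 2:
        return matrix.copy()
    counts = batches.value_counts()
    if (counts < 2).any() and parametric:
        warnings.warn("batches with < 2 samples: falling back to mean-centering")
        parametric = False

    X = matrix.to_numpy(dtype=float)
    n_probe, n_sample = X.shape
    design = np.stack([(batches == lv).to_numpy(dtype=float) for lv in levels], axis=1)
    n_per = design.sum(axis=0)

    grand_mean = X.mean(axis=1, keepdims=True)
    if not parametric:
        out = X.copy()
        for k, lv in enumerate(levels):
            cols = design[:, k].astype(bool)
            out[:, cols] -= out[:, cols].mean(axis=1, keepdims=True) - grand_mean
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)

    # standardize
    batch_means = (X @ design) / n_per  # probe x batch
    fitted = batch_means @ design.T
    pooled_var = ((X - fitted) ** 2).mean(axis=1, keepdims=True)
    pooled_var[pooled_var == 0] = 1e-12
    stand_mean = (batch_means * (n_per / n_sample)).sum(axis=1, keepdims=True)
    Z = (X - stand_mean) / np.sqrt(pooled_var)

    gamma_hat = (Z @ design) / n_per
    delta_hat = np.stack(
        [Z[:, design[:, k].astype(bool)].var(axis=1, ddof=1) for k in range(len(levels))],
        axis=1,
    )
    delta_hat[delta_hat == 0] = 1e-12

    # parametric EB priors (method of moments)
    gamma_bar = gamma_hat.mean(axis=0)
    tau2 = gamma_hat.var(axis=0, ddof=1)
    tau2[tau2 == 0] = 1e-12
    d_bar = delta_hat.mean(axis=0)
    s2 = delta_hat.var(axis=0, ddof=1)
    s2[s2 == 0] = 1e-12
    lam = (2 * s2 + d_bar**2) / s2          # inverse-gamma shape
    theta = (d_bar * s2 + d_bar**3) / s2    # inverse-gamma scale

    Z_adj = Z.copy()
    for k, lv in enumerate(levels):
        cols = design[:, k].astype(bool)
        nk = int(n_per[k])
        zk = Z[:, cols]
        g_star = gamma_hat[:, k]
        d_star = delta_hat[:, k]
        for _ in range(max_iter):
            g_new = (nk * tau2[k] * zk.mean(axis=1) + d_star * gamma_bar[k]) / (
                nk * tau2[k] + d_star
            )
            sse = ((zk - g_new[:, None]) ** 2).sum(axis=1)
            d_new = (theta[k] + 0.5 * sse) / (nk / 2 + lam[k] - 1)
            change = max(
                np.max(np.abs(g_new - g_star) / (np.abs(g_star) + 1e-12)),
                np.max(np.abs(d_new - d_star) / (np.abs(d_star) + 1e-12)),
            )
            g_star, d_star = g_new, d_new
            if change < tol:
                break
        Z_adj[:, cols] = (zk - g_star[:, None]) / np.sqrt(d_star[:, None])

    out = Z_adj * np.sqrt(pooled_var) + stand_mean
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# workflow 1: peaks

def peak_scores(
    positions: np.ndarray, values: np.ndarray, width: int = PEAK_WIDTH
) -> np.ndarray:
    """Per-probe methylation peak score.

    The scanner vendor's score is proprietary; the stand-in used here is
    -log10 of the one-sided rank-sum p-value of the probes within
    ``width`` bp of each probe against the sample's global log-ratio
    distribution, so a cutoff of 2 corresponds to p < 0.01.
    """
    positions = np.asarray(positions)
    values = np.asarray(values, dtype=float)
    global_ranks = stats.rankdata(values)
    n = values.size
    scores = np.empty(n)
    for i in range(n):
        lo = np.searchsorted(positions, positions[i] - width // 2)
        hi = np.searchsorted(positions, positions[i] + width // 2, side="right")
        m = hi - lo
        if m == 0 or m == n:
            scores[i] = 0.0
            continue
        # rank-sum of window probes among all probes: normal approximation
        r = global_ranks[lo:hi].sum()
        mu = m * (n + 1) / 2
        sigma = np.sqrt(m * (n - m) * (n + 1) / 12.0)
        z = (r - mu) / sigma if sigma > 0 else 0.0
        p = stats.norm.sf(z)
        scores[i] = -np.log10(max(p, 1e-300))
    return scores


def call_peaks(
    positions: np.ndarray,
    scores: np.ndarray,
    params: PeakParams | None = None,
    chrom: str = "chr1",
) -> list[tuple[str, int, int, int]]:
    """Maximal runs of qualifying probes (score >= cutoff) whose
    consecutive members lie within ``width`` bp; runs with fewer than
    ``min_probes`` qualifying probes are discarded.

    Returns (chrom, start, end, n_probes) tuples, half-open coordinates.
    """
    params = params or PeakParams()
    positions = np.asarray(positions)
    scores = np.asarray(scores, dtype=float)
    qual = np.flatnonzero(scores >= params.score_cutoff)
    peaks = []
    run: list[int] = []
    for idx in qual:
        if run and positions[idx] - positions[run[-1]] > params.width:
            if len(run) >= params.min_probes:
                peaks.append((chrom, int(positions[run[0]]), int(positions[run[-1]]) + 1, len(run)))
            run = []
        run.append(idx)
    if len(run) >= params.min_probes:
        peaks.append((chrom, int(positions[run[0]]), int(positions[run[-1]]) + 1, len(run)))
    return peaks


def count_peaks(
    probes: pd.DataFrame,
    matrix: pd.DataFrame,
    params: PeakParams | None = None,
) -> pd.DataFrame:
    """Peak counts per sample and per chromosome.

    ``probes`` holds (chrom, pos) aligned with ``matrix`` rows (log2
    ratios, probes x samples).
    """
    params = params or PeakParams()
    rows = []
    for sample in matrix.columns:
        values = matrix[sample].to_numpy(dtype=float)
        for chrom, grp_idx in probes.groupby("chrom", sort=True).indices.items():
            pos = probes["pos"].to_numpy()[grp_idx]
            vals = values[grp_idx]
            order = np.argsort(pos)
            scores = peak_scores(pos[order], vals[order], width=params.width)
            peaks = call_peaks(pos[order], scores, params=params, chrom=str(chrom))
            rows.append({"sample": sample, "chrom": chrom, "n_peaks": len(peaks)})
    return pd.DataFrame(rows)


def peak_ratio(counts: pd.DataFrame, pairing: dict[str, str], by: str = "sample") -> pd.DataFrame:
    """Relapse/diagnosis ratio of methylated-region counts.

    ``pairing`` maps diagnosis sample id -> relapse sample id. ``by`` is
    "sample" (ratio per pair, summed over chromosomes) or "chrom" (ratio
    per chromosome, summed over pairs).
    """
    total = counts.groupby(["sample", "chrom"])["n_peaks"].sum().unstack(fill_value=0)
    diag = list(pairing)
    rel = [pairing[d] for d in diag]
    if by == "sample":
        num = total.loc[rel].sum(axis=1).to_numpy(dtype=float)
        den = total.loc[diag].sum(axis=1).to_numpy(dtype=float)
        return pd.DataFrame(
            {"pair": diag, "relapse_peaks": num, "diagnosis_peaks": den,
             "ratio": np.divide(num, den, out=np.full_like(num, np.nan), where=den > 0)}
        )
    num = total.loc[rel].sum(axis=0).to_numpy(dtype=float)
    den = total.loc[diag].sum(axis=0).to_numpy(dtype=float)
    return pd.DataFrame(
        {"chrom": total.columns, "relapse_peaks": num, "diagnosis_peaks": den,
         "ratio": np.divide(num, den, out=np.full_like(num, np.nan), where=den > 0)}
    )


# ---------------------------------------------------------------------------
# workflow 2: DMRs

def _running_mean(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or x.size < 2:
        return x.copy()
    kernel = np.ones(window) / window
    pad = window // 2
    xp = np.pad(x, pad, mode="edge")
    sm = np.convolve(xp, kernel, mode="valid")
    return sm[: x.size]


def detect_dmrs(
    probes: pd.DataFrame,
    diagnosis: pd.DataFrame,
    relapse: pd.DataFrame,
    smooth_window: int = 3,
    max_gap: int = 1000,
    delta_cutoff: float = DMR_DELTA_CUTOFF,
    min_probes: int = DMR_MIN_PROBES,
    n_permutations: int = 1000,
    seed: int = 0,
    p_cutoff: float = 0.05,
) -> list[DMR]:
    """Detect differentially methylated regions from paired fraction data.

    ``diagnosis`` and ``relapse`` are probes x pairs matrices on the
    fraction scale with aligned columns (column *j* of each belongs to the
    same patient). Per-probe mean paired differences (relapse - diagnosis)
    are smoothed with a ``smooth_window``-probe running mean inside runs
    broken at inter-probe gaps > ``max_gap`` bp; candidate regions are
    maximal same-sign runs with |smoothed delta| > ``delta_cutoff``, with
    edges trimmed to probes whose raw |delta| also exceeds the cutoff (so
    noiseless regions have exact bounds). Regions with fewer than
    ``min_probes`` probes are removed; p-values come from sign-flip
    permutations of pair labels using the area statistic |sum of smoothed
    deltas| over the region.
    """
    if list(diagnosis.columns) == list(relapse.columns):
        pass
    elif len(diagnosis.columns) != len(relapse.columns):
        raise ValueError("diagnosis and relapse matrices must have paired columns")
    D = relapse.to_numpy(dtype=float) - diagnosis.to_numpy(dtype=float)  # probe x pair
    n_pairs = D.shape[1]
    rng = np.random.default_rng(seed)
    if n_pairs <= 10:
        signs = np.array(
            [[1 if (m >> b) & 1 else -1 for b in range(n_pairs)] for m in range(2**n_pairs)]
        )
    else:
        signs = rng.choice([-1, 1], size=(n_permutations, n_pairs))

    dmrs: list[DMR] = []
    for chrom, grp in probes.groupby("chrom", sort=True):
        idx = grp.sort_values("pos").index
        loc = probes.index.get_indexer(idx)
        pos = probes.loc[idx, "pos"].to_numpy()
        delta = D[loc].mean(axis=1)
        # break probe runs at large gaps
        breaks = np.flatnonzero(np.diff(pos) > max_gap)
        run_starts = np.concatenate([[0], breaks + 1])
        run_ends = np.concatenate([breaks + 1, [pos.size]])
        for rs, re_ in zip(run_starts, run_ends):
            sm = _running_mean(delta[rs:re_], smooth_window)
            raw = delta[rs:re_]
            exceed = np.abs(sm) > delta_cutoff
            sign = np.sign(sm)
            i = 0
            while i < sm.size:
                if not exceed[i]:
                    i += 1
                    continue
                j = i
                while j + 1 < sm.size and exceed[j + 1] and sign[j + 1] == sign[i]:
                    j += 1
                # trim edges to probes where the raw delta also exceeds cutoff
                lo, hi = i, j
                while lo <= hi and not (abs(raw[lo]) > delta_cutoff and np.sign(raw[lo]) == sign[i]):
                    lo += 1
                while hi >= lo and not (abs(raw[hi]) > delta_cutoff and np.sign(raw[hi]) == sign[i]):
                    hi -= 1
                if hi - lo + 1 >= min_probes:
                    region = slice(rs + lo, rs + hi + 1)
                    region_D = D[loc][region]
                    obs_area = abs(_running_mean(region_D.mean(axis=1), smooth_window).sum())
                    null_means = region_D @ signs.T / n_pairs  # probes x perms
                    null_area = np.abs(
                        np.apply_along_axis(
                            lambda v: _running_mean(v, smooth_window).sum(), 0, null_means
                        )
                    )
                    p = float((null_area >= obs_area - 1e-12).mean())
                    mean_delta = float(raw[lo : hi + 1].mean())
                    if abs(mean_delta) > delta_cutoff and p < p_cutoff:
                        dmrs.append(
                            DMR(
                                chrom=str(chrom),
                                start=int(pos[rs + lo]),
                                end=int(pos[rs + hi]) + 1,
                                n_probes=int(hi - lo + 1),
                                mean_delta=mean_delta,
                                p_value=p,
                            )
                        )
                i = j + 1
    return dmrs


# ---------------------------------------------------------------------------
# workflow 3: promoter windows

def promoter_window(tss: int, strand: str, chrom_length: int | None = None) -> tuple[int, int]:
    """Strand-aware promoter window: 2000 bp upstream of the TSS."""
    if strand == "+":
        lo, hi = tss - PROMOTER_UPSTREAM, tss
    else:
        lo, hi = tss, tss + PROMOTER_UPSTREAM
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def core_promoter_window(tss: int, chrom_length: int | None = None) -> tuple[int, int]:
    """Core promoter: +/- 250 bp around the TSS (strand-symmetric)."""
    lo = max(tss - CORE_HALF_WIDTH, 0)
    hi = tss + CORE_HALF_WIDTH
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def assign_region_to_gene(
    region: tuple[str, int, int], annotation: pd.DataFrame
) -> str | None:
    """Nearest-TSS gene assignment for a genomic region.

    Distance is measured from the region midpoint to each gene's TSS on
    the same chromosome; ties go to the gene with the smaller TSS
    coordinate (then lexicographically smaller id). Returns ``None`` when
    the chromosome carries no genes.
    """
    if annotation.empty:
        raise ValueError("empty annotation")
    chrom, start, end = region
    genes = annotation[annotation["chrom"] == chrom]
    if genes.empty:
        return None
    mid = (start + end) / 2
    dist = (genes["tss"] - mid).abs()
    cand = genes.assign(_d=dist).sort_values(["_d", "tss", "gene"])
    return str(cand.iloc[0]["gene"])


def promoter_aggregate(
    probes: pd.DataFrame,
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    chrom_lengths: dict[str, int] | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Gene x sample methylation aggregated over promoter windows.

    Returns a dict keyed by (window, aggregation) for window in
    {"promoter", "core"} and aggregation in {"mean", "max"}; genes with no
    probe in a window get NaN.
    """
    values = matrix.to_numpy(dtype=float)
    out: dict[tuple[str, str], dict[str, np.ndarray]] = {
        (w, a): {} for w in ("promoter", "core") for a in ("mean", "max")
    }
    by_chrom = {
        str(chrom): grp.sort_values("pos") for chrom, grp in probes.groupby("chrom", sort=True)
    }
    for _, gene in annotation.iterrows():
        chrom = str(gene["chrom"])
        grp = by_chrom.get(chrom)
        clen = chrom_lengths.get(chrom) if chrom_lengths else None
        windows = {
            "promoter": promoter_window(int(gene["tss"]), str(gene["strand"]), clen),
            "core": core_promoter_window(int(gene["tss"]), clen),
        }
        for wname, (lo, hi) in windows.items():
            if grp is None:
                sel = None
            else:
                pos = grp["pos"].to_numpy()
                a = np.searchsorted(pos, lo)
                b = np.searchsorted(pos, hi)
                sel = probes.index.get_indexer(grp.index[a:b]) if b > a else None
            for agg in ("mean", "max"):
                if sel is None:
                    row = np.full(matrix.shape[1], np.nan)
                else:
                    sub = values[sel]
                    row = sub.mean(axis=0) if agg == "mean" else sub.max(axis=0)
                out[(wname, agg)][str(gene["gene"])] = row
    return {
        key: pd.DataFrame.from_dict(d, orient="index", columns=matrix.columns)
        for key, d in out.items()
    }


def promoter_differential(
    gene_values: pd.DataFrame,
    pairing: dict[str, str],
    variance_drop: float = 0.5,
    **sam_kwargs,
):
    """Paired SAM on gene-level promoter methylation.

    Genes with missing values are dropped, then the lower-variance half is
    removed (standard unsupervised filter for methylation profiles) before
    the paired SAM statistic is computed.
    """
    from .expression import variance_filter

    mat = gene_values.dropna(axis=0, how="any")
    mat = variance_filter(mat, drop_fraction=variance_drop)
    return sam_paired(mat, pairing, **sam_kwargs)
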