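"""Cross-platform association screens for paired multi-omics cohorts.

Associates per-pair expression fold changes with per-pair copy-number
differences or promoter-methylation fold changes: global Pearson
correlation screens with BH-FDR (reporting rule r > 0.8 & FDR < 0.05),
DMR/differential-expression inverse-sign intersection, burden-stratified
differential expression, pair-by-pair co-occurrence counting, and a
region-wise random-intercept surrogate for region-dependent association
("SIM-surrogate" — a simplified stand-in, not the published SIM
algorithm).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import SAMResult, sam_paired
from .methylation import DMR

CNA_DELTA_THRESHOLD = 0.1     # |gain/loss| log2 call threshold
METH_DELTA_THRESHOLD = 0.05   # 5 percentage points on the fraction scale


def gene_cna_delta(
    probes: pd.DataFrame,
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    pairing: dict[str, str],
) -> pd.DataFrame:
    """Per-gene, per-pair CNA difference: probe-weighted mean log2 over
    the gene span, relapse minus diagnosis. Genes without probes get NaN.

    ``probes`` is a (chrom, pos) frame aligned row-wise with ``matrix``
    (probes x samples log2 ratios).
    """
    values = matrix.to_numpy(dtype=float)
    col = {s: j for j, s in enumerate(matrix.columns)}
    diag = list(pairing)
    rel = [pairing[d] for d in diag]
    out = np.full((len(annotation), len(diag)), np.nan)
    by_chrom = {
        str(chrom): grp.sort_values("pos") for chrom, grp in probes.groupby("chrom", sort=True)
    }
    for gi, (_, gene) in enumerate(annotation.iterrows()):
        grp = by_chrom.get(str(gene["chrom"]))
        if grp is None:
            continue
        pos = grp["pos"].to_numpy()
        a = np.searchsorted(pos, gene["start"])
        b = np.searchsorted(pos, gene["end"])
        if b <= a:
            continue
        sel = probes.index.get_indexer(grp.index[a:b])
        for pj, (d, r) in enumerate(zip(diag, rel)):
            out[gi, pj] = values[sel, col[r]].mean() - values[sel, col[d]].mean()
    return pd.DataFrame(out, index=annotation["gene"].tolist(), columns=diag)


def select_candidates(
    fc: pd.DataFrame, min_ratio_fc: float = 2.0, min_pairs: int = 3
) -> list[str]:
    """Genes whose expression changes at least ``min_ratio_fc``-fold (either
    direction) in at least ``min_pairs`` pairs — the admission rule for the
    correlation screens (2-fold for the CNA screen, 1.5-fold for the
    methylation screen)."""
    if min_ratio_fc <= 1:
        raise ValueError("min_ratio_fc must exceed 1")
    log_t = np.log2(min_ratio_fc)
    n = (fc.abs() >= log_t).sum(axis=1)
    return [str(g) for g in fc.index[n >= min_pairs]]


def correlate_fc(
    x: pd.DataFrame,
    y: pd.DataFrame,
    sign_filter: str = "any",
    fdr_cutoff: float = 0.05,
    r_cutoff: float = 0.8,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of two pair-indexed tables.

    ``x`` holds expression fold changes, ``y`` the matched platform
    deltas (CNA log2 difference or methylation FC); rows are genes,
    columns pairs. Genes present in both tables with >= 3 complete pairs
    are tested; zero-variance genes are skipped and flagged. BH-FDR is
    computed across tested genes; ``passes`` marks the reporting rule
    |r| >= ``r_cutoff`` (with the requested sign) and FDR < ``fdr_cutoff``.
    """
    if sign_filter not in {"positive", "negative", "any"}:
        raise ValueError("sign_filter must be positive/negative/any")
    genes = [g for g in x.index if g in set(y.index)]
    pairs = [p for p in x.columns if p in set(y.columns)]
    rows = []
    for g in genes:
        xv = x.loc[g, pairs].to_numpy(dtype=float)
        yv = y.loc[g, pairs].to_numpy(dtype=float)
        ok = ~(np.isnan(xv) | np.isnan(yv))
        if ok.sum() < 3:
            continue
        xv, yv = xv[ok], yv[ok]
        if np.std(xv) == 0 or np.std(yv) == 0:
            rows.append({"gene": g, "n_pairs": int(ok.sum()), "r": np.nan, "p_value": np.nan,
                         "skipped": True})
            continue
        r, p = stats.pearsonr(xv, yv)
        rows.append({"gene": g, "n_pairs": int(ok.sum()), "r": float(r), "p_value": float(p),
                     "skipped": False})
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(fdr=[], passes=[])
    tested = ~out["skipped"]
    out["fdr"] = np.nan
    if tested.any():
        out.loc[tested, "fdr"] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    sign_ok = {
        "positive": out["r"] > 0,
        "negative": out["r"] < 0,
        "any": pd.Series(True, index=out.index),
    }[sign_filter]
    out["passes"] = (
        tested & sign_ok & (out["r"].abs() > r_cutoff) & (out["fdr"] < fdr_cutoff)
    )
    return out


def dmr_deg_intersect(
    dmrs: list[tuple[DMR, str | None]],
    fc: pd.DataFrame,
    min_ratio_fc: float = 1.5,
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Inverse-association screen: DMR-bearing genes whose expression moves
    opposite to their methylation change.

    ``dmrs`` pairs each DMR with its assigned gene (``None`` entries are
    ignored). A gene qualifies when a hypermethylated DMR coincides with
    expression down >= ``min_ratio_fc``-fold in >= ``min_pairs`` pairs, or
    a hypomethylated DMR with the corresponding up-regulation.
    """
    log_t = np.log2(min_ratio_fc)
    rows = []
    for dmr, gene in dmrs:
        if gene is None or gene not in fc.index:
            continue
        v = fc.loc[gene].to_numpy(dtype=float)
        if dmr.direction == "hyper":
            n = int((v <= -log_t).sum())
            expr_dir = "down"
        else:
            n = int((v >= log_t).sum())
            expr_dir = "up"
        if n >= min_pairs:
            rows.append(
                {
                    "gene": gene,
                    "chrom": dmr.chrom,
                    "start": dmr.start,
                    "end": dmr.end,
                    "methylation": dmr.direction,
                    "expression": expr_dir,
                    "n_pairs": n,
                    "mean_delta": dmr.mean_delta,
                }
            )
    return pd.DataFrame(rows).drop_duplicates(subset=["gene"]) if rows else pd.DataFrame(
        columns=["gene", "chrom", "start", "end", "methylation", "expression", "n_pairs", "mean_delta"]
    )


def burden_stratified_de(
    matrix: pd.DataFrame,
    pairing: dict[str, str],
    burden_classes: dict[str, str],
    min_pairs: int = 3,
    **sam_kwargs,
) -> dict[str, SAMResult | None]:
    """Paired SAM within each copy-number burden stratum.

    ``burden_classes`` maps pair id (diagnosis sample id) to
    "small"/"large". Strata with fewer than ``min_pairs`` pairs are
    skipped (``None`` in the result).
    """
    out: dict[str, SAMResult | None] = {}
    for stratum in ("small", "large"):
        sub = {d: r for d, r in pairing.items() if burden_classes.get(d) == stratum}
        out[stratum] = sam_paired(matrix, sub, **sam_kwargs) if len(sub) >= min_pairs else None
    return out


def pairwise_association(
    x: pd.DataFrame,
    y: pd.DataFrame,
    platform: str = "cna",
    min_supporting_pairs: int = 3,
    expr_log2_threshold: float = 1.0,
    inverse: bool = False,
) -> pd.DataFrame:
    """Pair-by-pair co-occurrence of expression change and platform change.

    For each gene, counts the pairs where |expression log2 FC| >=
    ``expr_log2_threshold`` (2-fold) co-occurs with a same-gene platform
    delta beyond its threshold (CNA |delta| >= 0.1 log2; methylation
    |delta| >= 0.05 fraction) in the required sign relation — concordant
    for CNA dosage, discordant when ``inverse=True`` (methylation
    repression). Genes with count >= ``min_supporting_pairs`` are reported.
    """
    thresh = CNA_DELTA_THRESHOLD if platform == "cna" else METH_DELTA_THRESHOLD
    genes = [g for g in x.index if g in set(y.index)]
    pairs = [p for p in x.columns if p in set(y.columns)]
    rows = []
    for g in genes:
        xv = x.loc[g, pairs].to_numpy(dtype=float)
        yv = y.loc[g, pairs].to_numpy(dtype=float)
        ok = ~(np.isnan(xv) | np.isnan(yv))
        expr_hit = np.abs(xv) >= expr_log2_threshold
        plat_hit = np.abs(yv) >= thresh
        sign_rel = (xv * yv < 0) if inverse else (xv * yv > 0)
        n = int((ok & expr_hit & plat_hit & sign_rel).sum())
        if n >= min_supporting_pairs:
            rows.append({"gene": g, "n_supporting_pairs": n})
    return pd.DataFrame(rows) if rows else pd.DataFrame(columns=["gene", "n_supporting_pairs"])


def regionwise_random_effects(
    x: pd.DataFrame,
    y: pd.DataFrame,
    regions: dict[str, str],
    fdr_cutoff: float = 0.05,
    min_genes: int = 3,
) -> pd.DataFrame:
    """Region-wise association with a region-level random intercept
    ("SIM-surrogate").

    For each region (e.g. chromosome), a per-pair region intercept is
    estimated as the across-gene mean of the gene-centred expression FC,
    shrunk by the method-of-moments reliability tau2/(tau2 + sigma2/G),
    and removed before per-gene Pearson correlation against the platform
    delta; BH-FDR is applied within the region. This is a documented
    simplified surrogate for published region-dependent integration
    methods, not a reimplementation of any of them.
    """
    genes = [g for g in x.index if g in set(y.index) and g in regions]
    pairs = [p for p in x.columns if p in set(y.columns)]
    rows = []
    by_region: dict[str, list[str]] = {}
    for g in genes:
        by_region.setdefault(regions[g], []).append(g)
    for region, rgenes in sorted(by_region.items()):
        if len(rgenes) < min_genes:
            continue
        X = x.loc[rgenes, pairs].to_numpy(dtype=float)
        Y = y.loc[rgenes, pairs].to_numpy(dtype=float)
        centred = X - np.nanmean(X, axis=1, keepdims=True)
        pair_means = np.nanmean(centred, axis=0)  # raw region intercept per pair
        G = len(rgenes)
        sigma2 = np.nanvar(centred - pair_means[None, :], ddof=1)
        tau2 = max(0.0, np.nanvar(pair_means, ddof=1) - sigma2 / G)
        shrink = tau2 / (tau2 + sigma2 / G) if (tau2 + sigma2 / G) > 0 else 0.0
        adj = X - shrink * pair_means[None, :]
        region_rows = []
        for gi, g in enumerate(rgenes):
            xv, yv = adj[gi], Y[gi]
            ok = ~(np.isnan(xv) | np.isnan(yv))
            if ok.sum() < 3 or np.std(yv[ok]) == 0 or np.std(xv[ok]) == 0:
                continue
            r, p = stats.pearsonr(xv[ok], yv[ok])
            region_rows.append({"gene": g, "region": region, "r": float(r), "p_value": float(p)})
        if region_rows:
            sub = pd.DataFrame(region_rows)
            sub["fdr"] = multipletests(sub["p_value"], method="fdr_bh")[1]
            sub["significant"] = sub["fdr"] < fdr_cutoff
            rows.append(sub)
    if not rows:
        return pd.DataFrame(columns=["gene", "region", "r", "p_value", "fdr", "significant"])
    return pd.concat(rows, ignore_index=True)
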