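"""Random-effects gene-expression meta-analysis.

Per gene and per study, the effect size is Hedges' g (bias-corrected
standardized mean difference between the relapse and diagnosis groups).
Heterogeneity is assessed with Cochran's Q and I²; studies are pooled
with DerSimonian–Laird method-of-moments random-effects weights, with a
normal-theory 95% CI and z-test on the pooled effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class StudySummary:
    """Two-group summary statistics for one study and one gene."""

    study: str
    n1: int          # diagnosis group size
    n2: int          # relapse group size
    mean1: float
    mean2: float
    sd1: float
    sd2: float

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class MetaResult:
    """Random-effects pooling of one gene across studies."""

    studies: list[str]
    effects: np.ndarray        # g_i
    variances: np.ndarray      # v_i
    Q: float
    df: int
    Q_p_value: float
    i_squared: float           # percent
    tau_squared: float
    weights: np.ndarray        # random-effects weights, normalized to sum 1
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    z: float
    z_p_value: float

    @property
    def heterogeneous(self) -> bool:
        """Flagged heterogeneous when Q-test p < 0.05 and I² > 50%."""
        return self.Q_p_value < 0.05 and self.i_squared > 50.0


def hedges_g(summary: StudySummary) -> tuple[float, float]:
    """Hedges' g and its variance from two-group summary statistics.

    g = J * (mean2 - mean1) / s_pooled with the small-sample correction
    J = 1 - 3/(4*df - 1), df = n1 + n2 - 2; the variance is the usual
    large-sample form (n1+n2)/(n1*n2) + g²/(2(n1+n2)).
    """
    n1, n2 = summary.n1, summary.n2
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * summary.sd1**2 + (n2 - 1) * summary.sd2**2) / df
    if sp2 <= 0:
        raise ValueError("pooled standard deviation is zero: effect size undefined")
    d = (summary.mean2 - summary.mean1) / np.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    v = (n1 + n2) / (n1 * n2) + g**2 / (2.0 * (n1 + n2))
    return float(g), float(v)


def cochran_q(effects: np.ndarray, variances: np.ndarray) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity statistic with chi-square p-value."""
    g = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    if g.size < 2:
        raise ValueError("need at least 2 studies")
    if np.any(v <= 0):
        raise ValueError("variances must be positive")
    w = 1.0 / v
    g_bar = np.sum(w * g) / np.sum(w)
    Q = float(np.sum(w * (g - g_bar) ** 2))
    df = g.size - 1
    p = float(stats.chi2.sf(Q, df))
    return Q, df, p


def i_squared(Q: float, df: int) -> float:
    """I² heterogeneity percentage: max(0, (Q - df)/Q) * 100."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if Q <= 0:
        return 0.0
    return float(max(0.0, (Q - df) / Q) * 100.0)


def dl_pool(
    effects: np.ndarray,
    variances: np.ndarray,
    studies: list[str] | None = None,
    ci_z: float = 1.96,
) -> MetaResult:
    """DerSimonian–Laird random-effects pooling of study effects.

    tau² = max(0, (Q - df)/C) with C = sum(w) - sum(w²)/sum(w), w = 1/v;
    random-effects weights are 1/(v + tau²). When the studies are
    homogeneous (Q <= df) tau² = 0 and the estimate reduces to
    inverse-variance fixed-effect pooling.
    """
    g = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    Q, df, Q_p = cochran_q(g, v)
    w = 1.0 / v
    C = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float(np.sum(w_star * g) / np.sum(w_star))
    se = float(1.0 / np.sqrt(np.sum(w_star)))
    z = pooled / se
    return MetaResult(
        studies=list(studies) if studies is not None else [f"study{i+1}" for i in range(g.size)],
        effects=g,
        variances=v,
        Q=Q,
        df=df,
        Q_p_value=Q_p,
        i_squared=i_squared(Q, df),
        tau_squared=float(tau2),
        weights=w_star / np.sum(w_star),
        pooled=pooled,
        se=se,
        ci_low=pooled - ci_z * se,
        ci_high=pooled + ci_z * se,
        z=float(z),
        z_p_value=float(2.0 * stats.norm.sf(abs(z))),
    )


def meta_analyze_gene(summaries: list[StudySummary]) -> MetaResult:
    """Full chain for one gene: Hedges' g per study, then DL pooling."""
    gv = [hedges_g(s) for s in summaries]
    g = np.array([x[0] for x in gv])
    v = np.array([x[1] for x in gv])
    return dl_pool(g, v, studies=[s.study for s in summaries])


def study_summaries_from_matrix(
    study: str,
    matrix: pd.DataFrame,
    diagnosis_samples: list[str],
    relapse_samples: list[str],
    genes: list[str] | None = None,
) -> dict[str, StudySummary]:
    """Per-gene two-group summaries from a genes x samples log2 matrix.

    Groups are treated as independent (unpaired) because pairing is not
    shared across studies; mean2/sd2 describe the relapse group.
    """
    genes = list(genes) if genes is not None else list(matrix.index)
    d = matrix.loc[genes, diagnosis_samples].to_numpy(dtype=float)
    r = matrix.loc[genes, relapse_samples].to_numpy(dtype=float)
    out = {}
    for i, gene in enumerate(genes):
        out[str(gene)] = StudySummary(
            study=study,
            n1=len(diagnosis_samples),
            n2=len(relapse_samples),
            mean1=float(d[i].mean()),
            mean2=float(r[i].mean()),
            sd1=float(d[i].std(ddof=1)),
            sd2=float(r[i].std(ddof=1)),
        )
    return out


def forest_table(result: MetaResult, ci_z: float = 1.96) -> pd.DataFrame:
    """Forest-plot table: per-study g, 95% CI and percent weight, plus the
    pooled random-effects row. Percent weights sum to 100 up to rounding."""
    se_i = np.sqrt(result.variances)
    rows = [
        {
            "study": s,
            "g": float(g),
            "ci_low": float(g - ci_z * se),
            "ci_high": float(g + ci_z * se),
            "weight_pct": float(100.0 * w),
        }
        for s, g, se, w in zip(result.studies, result.effects, se_i, result.weights)
    ]
    rows.append(
        {
            "study": "pooled",
            "g": result.pooled,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "weight_pct": 100.0,
        }
    )
    return pd.DataFrame(rows)


def negative_trend_check(results: dict[str, MetaResult], alpha: float = 0.05) -> list[str]:
    """Genes whose pooled effect indicates significant underexpression at
    relapse: pooled g < 0 with z-test p below ``alpha``."""
    return sorted(
        gene for gene, r in results.items() if r.pooled < 0 and r.z_p_value < alpha
    )
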