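"""Copy-number analysis: winsorization, segmentation, CNA calling and
paired lesion evolution.

The calling rules follow the array workflow used for paired tumour
profiling: a segment is reported as a copy-number abnormality (CNA) when
its mean log2 ratio exceeds +0.1 (gain) or falls below -0.1 (loss), it
spans at least 25 markers and 100 kb, and it overlaps known copy-number
variants by less than 50% of its length. Per-sample burden is the length
of the union of all called intervals, split into "small"/"large" classes
at 100 Mb.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    Interval,
    interval_intersect,
    interval_union,
    overlap_fraction,
    total_length,
)

GAIN_THRESH = 0.1
LOSS_THRESH = -0.1
MIN_MARKERS = 25
MIN_LENGTH = 100_000
MAX_CNV_OVERLAP = 0.5
BURDEN_CUTOFF = 100_000_000


@dataclass(frozen=True)
class Segment:
    """A piecewise-constant segment of a probe-level log2-ratio profile."""

    chrom: str
    start: int
    end: int
    mean_log2: float
    n_markers: int

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"segment start {self.start} >= end {self.end}")
        if self.n_markers < 1:
            raise ValueError("segment must contain at least one marker")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self) -> Interval:
        return (self.start, self.end)


@dataclass(frozen=True)
class CNACall:
    segment: Segment
    state: str  # "gain" or "loss"
    cnv_overlap_fraction: float = 0.0


@dataclass
class CNACallParams:
    gain_thresh: float = GAIN_THRESH
    loss_thresh: float = LOSS_THRESH
    min_markers: int = MIN_MARKERS
    min_length: int = MIN_LENGTH
    max_cnv_overlap: float = MAX_CNV_OVERLAP

    def __post_init__(self):
        if not (self.loss_thresh < 0 < self.gain_thresh):
            raise ValueError("need loss_thresh < 0 < gain_thresh")
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")


@dataclass
class SampleCNAProfile:
    sample_id: str
    calls: list[CNACall]
    gained_bp: int = 0
    lost_bp: int = 0
    changed_bp: int = 0
    burden_class: str = "small"

    @classmethod
    def from_calls(
        cls, sample_id: str, calls: Sequence[CNACall], burden_cutoff: int = BURDEN_CUTOFF
    ) -> "SampleCNAProfile":
        def bp(state: str) -> int:
            by_chrom: dict[str, list[Interval]] = {}
            for c in calls:
                if c.state == state:
                    by_chrom.setdefault(c.segment.chrom, []).append(c.segment.interval)
            return sum(total_length(ivs) for ivs in by_chrom.values())

        by_chrom_all: dict[str, list[Interval]] = {}
        for c in calls:
            by_chrom_all.setdefault(c.segment.chrom, []).append(c.segment.interval)
        changed = sum(total_length(ivs) for ivs in by_chrom_all.values())
        prof = cls(
            sample_id=sample_id,
            calls=list(calls),
            gained_bp=bp("gain"),
            lost_bp=bp("loss"),
            changed_bp=changed,
        )
        prof.burden_class = classify_burden(prof, cutoff=burden_cutoff)
        return prof


@dataclass
class PairEvolution:
    """Lesion evolution within a diagnosis/relapse pair."""

    pair_id: str
    acquired: list[CNACall] = field(default_factory=list)
    lost: list[CNACall] = field(default_factory=list)
    unchanged: list[CNACall] = field(default_factory=list)


def winsorize(values: np.ndarray, k: float = 2.5) -> np.ndarray:
    """Clip outlier probe values to median +/- k*MAD (MAD scaled by 1.4826).

    When the MAD is zero (e.g. a constant-dominated vector) the input is
    returned unchanged; clipping to a zero-width band would destroy real
    outliers rather than tame them.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot winsorize an empty vector")
    med = np.median(values)
    mad = stats.median_abs_deviation(values, scale="normal")
    if mad == 0:
        return values.copy()
    return np.clip(values, med - k * mad, med + k * mad)


def segment_profile(
    positions: Sequence[int],
    values: Sequence[float],
    penalty: float,
    chrom: str = "chr1",
) -> list[Segment]:
    """Exact penalized least-squares segmentation of one chromosome.

    Minimizes sum of squared residuals around segment means plus
    ``penalty`` per breakpoint, by O(n^2) dynamic programming. Segment
    bounds run from the first member probe to one past the last member
    probe (half-open); means are plain arithmetic means of member probes.
    """
    positions = np.asarray(positions, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if positions.size != values.size:
        raise ValueError("positions and values must have equal length")
    if positions.size == 0:
        return []
    if np.any(np.diff(positions) <= 0):
        raise ValueError("probe positions must be strictly increasing")
    if penalty < 0:
        raise ValueError("penalty must be non-negative")

    n = values.size
    csum = np.concatenate([[0.0], np.cumsum(values)])
    csum2 = np.concatenate([[0.0], np.cumsum(values**2)])

    # best[j] = min cost of segmenting probes 0..j-1; a new segment adds
    # `penalty` unless it is the first one. The inner minimization over
    # the last segment's start i is vectorized.
    best = np.full(n + 1, np.inf)
    best[0] = -penalty
    back = np.zeros(n + 1, dtype=int)
    idx = np.arange(n)
    for j in range(1, n + 1):
        i = idx[:j]
        s = csum[j] - csum[i]
        sse = (csum2[j] - csum2[i]) - s * s / (j - i)
        cost = best[:j] + penalty + sse
        k = int(np.argmin(cost))
        best[j] = cost[k]
        back[j] = k
    bounds = []
    j = n
    while j > 0:
        i = back[j]
        bounds.append((i, j))
        j = i
    bounds.reverse()

    segments = []
    for i, j in bounds:
        mean = (csum[j] - csum[i]) / (j - i)
        segments.append(
            Segment(
                chrom=chrom,
                start=int(positions[i]),
                end=int(positions[j - 1]) + 1,
                mean_log2=float(mean),
                n_markers=j - i,
            )
        )
    return segments


def call_cnas(
    segments: Iterable[Segment],
    params: CNACallParams | None = None,
    cnv_mask: Mapping[str, Sequence[Interval]] | None = None,
) -> list[CNACall]:
    """Apply the CNA reporting criteria to a list of segments.

    ``cnv_mask`` maps chromosome name to known-CNV intervals; a segment
    overlapping the mask by >= ``max_cnv_overlap`` of its length is
    rejected.
    """
    params = params or CNACallParams()
    cnv_mask = cnv_mask or {}
    calls = []
    for seg in segments:
        if seg.mean_log2 > params.gain_thresh:
            state = "gain"
        elif seg.mean_log2 < params.loss_thresh:
            state = "loss"
        else:
            continue
        if seg.n_markers < params.min_markers:
            continue
        if seg.length < params.min_length:
            continue
        frac = overlap_fraction(seg.interval, list(cnv_mask.get(seg.chrom, [])))
        if frac >= params.max_cnv_overlap:
            continue
        calls.append(CNACall(segment=seg, state=state, cnv_overlap_fraction=frac))
    return calls


def classify_burden(profile: SampleCNAProfile, cutoff: int = BURDEN_CUTOFF) -> str:
    """Small/large burden split at the total-changed-DNA cutoff (100 Mb)."""
    return "large" if profile.changed_bp > cutoff else "small"


def _calls_by_chrom(calls: Iterable[CNACall], state: str) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for c in calls:
        if c.state == state:
            out.setdefault(c.segment.chrom, []).append(c.segment.interval)
    return out


def compare_pair(
    pair_id: str,
    diagnosis_calls: Sequence[CNACall],
    relapse_calls: Sequence[CNACall],
    reciprocal_overlap: float = 0.5,
) -> PairEvolution:
    """Classify each call as acquired, lost or unchanged within a pair.

    Gains and losses are compared separately. A relapse call whose overlap
    with the union of same-state diagnosis calls is below
    ``reciprocal_overlap`` of its own length is "acquired"; symmetrically a
    diagnosis call is "lost" when insufficiently covered by relapse calls.
    """
    evo = PairEvolution(pair_id=pair_id)
    for state in ("gain", "loss"):
        diag = _calls_by_chrom(diagnosis_calls, state)
        rel = _calls_by_chrom(relapse_calls, state)
        for call in relapse_calls:
            if call.state != state:
                continue
            frac = overlap_fraction(call.segment.interval, diag.get(call.segment.chrom, []))
            (evo.acquired if frac < reciprocal_overlap else evo.unchanged).append(call)
        for call in diagnosis_calls:
            if call.state != state:
                continue
            frac = overlap_fraction(call.segment.interval, rel.get(call.segment.chrom, []))
            if frac < reciprocal_overlap:
                evo.lost.append(call)
    return evo


def count_stats(
    group_a: Mapping[str, SampleCNAProfile],
    group_b: Mapping[str, SampleCNAProfile],
) -> pd.DataFrame:
    """Per-sample imbalance/gain/loss counts with Mann-Whitney U p-values.

    Returns a table with one row per count type (imbalances, gains,
    losses) and the two-sided U-test p-value between the groups. The
    exact null distribution is used when both groups have <= 8 samples
    and the data are tie-free; otherwise the tie-corrected normal
    approximation is used.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must contain at least one sample")

    def counts(profiles: Mapping[str, SampleCNAProfile], state: str | None) -> np.ndarray:
        return np.array(
            [
                sum(1 for c in p.calls if state is None or c.state == state)
                for p in profiles.values()
            ],
            dtype=float,
        )

    rows = []
    for label, state in [("imbalances", None), ("gains", "gain"), ("losses", "loss")]:
        a = counts(group_a, state)
        b = counts(group_b, state)
        has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append(
            {
                "count_type": label,
                "median_a": float(np.median(a)),
                "median_b": float(np.median(b)),
                "U": float(res.statistic),
                "p_value": float(min(1.0, res.pvalue)),
            }
        )
    return pd.DataFrame(rows)


def acquisition_vs_loss_test(evolutions: Sequence[PairEvolution]) -> float:
    """Two-sided Wilcoxon signed-rank p for per-pair (n_acquired - n_lost).

    Tests whether lesion acquisition at relapse outweighs lesion loss.
    """
    diffs = np.array([len(e.acquired) - len(e.lost) for e in evolutions], dtype=float)
    if np.all(diffs == 0):
        return 1.0
    return float(stats.wilcoxon(diffs, alternative="two-sided", zero_method="wilcox").pvalue)


def recurrent_acquisition_test(
    evolutions: Sequence[PairEvolution],
    bins: Mapping[str, Sequence[Interval]],
    chrom_lengths: Mapping[str, int],
    n_permutations: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Recurrence of acquired lesions across pairs, per genomic bin.

    For each bin and state, counts the pairs with an acquired lesion
    overlapping the bin. The null preserves each pair's acquired-lesion
    lengths but places them uniformly at random on the genome; the
    per-bin p-value is the fraction of permutations whose count reaches
    the observed one, BH-adjusted across bins.
    """
    if len(evolutions) < 2:
        raise ValueError("need at least two pairs")
    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()

    bin_list = [(c, s, e) for c in sorted(bins) for (s, e) in bins[c]]

    def bin_counts(per_pair_intervals: list[dict[str, list[Interval]]]) -> np.ndarray:
        out = np.zeros(len(bin_list), dtype=int)
        for by_chrom in per_pair_intervals:
            for k, (c, s, e) in enumerate(bin_list):
                ivs = by_chrom.get(c, [])
                if ivs and interval_intersect([(s, e)], ivs):
                    out[k] += 1
        return out

    results = []
    for state in ("gain", "loss"):
        observed_sets = []
        lesion_lengths = []  # per pair: list of lengths to re-place under the null
        for evo in evolutions:
            by_chrom = _calls_by_chrom(evo.acquired, state)
            observed_sets.append(by_chrom)
            lesion_lengths.append(
                [e - s for ivs in by_chrom.values() for (s, e) in ivs]
            )
        obs = bin_counts(observed_sets)

        exceed = np.zeros(len(bin_list), dtype=int)
        for _ in range(n_permutations):
            null_sets = []
            for lens in lesion_lengths:
                by_chrom: dict[str, list[Interval]] = {}
                for L in lens:
                    ci = rng.choice(len(chroms), p=chrom_p)
                    chrom = chroms[ci]
                    max_start = max(1, chrom_lengths[chrom] - L)
                    s = int(rng.integers(0, max_start))
                    by_chrom.setdefault(chrom, []).append((s, s + L))
                null_sets.append(by_chrom)
            null = bin_counts(null_sets)
            exceed += null >= obs
        p = (1 + exceed) / (1 + n_permutations)
        p = np.where(obs == 0, 1.0, p)
        q = _bh(p)
        for k, (c, s, e) in enumerate(bin_list):
            results.append(
                {
                    "chrom": c,
                    "start": s,
                    "end": e,
                    "state": state,
                    "n_pairs": int(obs[k]),
                    "frequency": obs[k] / len(evolutions),
                    "p_value": float(p[k]),
                    "q_value": float(q[k]),
                }
            )
    return pd.DataFrame(results)


def _bh(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def frequency_track(
    calls_per_sample: Mapping[str, Sequence[CNACall]],
    chrom_lengths: Mapping[str, int],
    grid_step: int,
) -> pd.DataFrame:
    """Per-position gain/loss frequencies across samples on a fixed grid."""
    if grid_step <= 0:
        raise ValueError("grid step must be positive")
    n_samples = len(calls_per_sample)
    rows = []
    for chrom in sorted(chrom_lengths):
        grid = np.arange(0, chrom_lengths[chrom], grid_step)
        gain = np.zeros(grid.size)
        loss = np.zeros(grid.size)
        for calls in calls_per_sample.values():
            for state, track in [("gain", gain), ("loss", loss)]:
                ivs = interval_union(
                    [
                        c.segment.interval
                        for c in calls
                        if c.state == state and c.segment.chrom == chrom
                    ]
                ) if calls else []
                for s, e in ivs:
                    track[(grid >= s) & (grid < e)] += 1
        for pos, g, l in zip(grid, gain, loss):
            rows.append(
                {
                    "chrom": chrom,
                    "pos": int(pos),
                    "gain_freq": g / n_samples if n_samples else 0.0,
                    "loss_freq": l / n_samples if n_samples else 0.0,
                }
            )
    return pd.DataFrame(rows)


def segment_sample(
    probes: pd.DataFrame,
    value_col: str,
    penalty: float = 1.0,
    winsorize_k: float | None = 2.5,
) -> list[Segment]:
    """Winsorize and segment one sample's probe table (chrom, pos, value).

    Winsorization is applied per chromosome before segmentation; pass
    ``winsorize_k=None`` to skip it.
    """
    segments: list[Segment] = []
    for chrom, grp in probes.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        vals = grp[value_col].to_numpy(dtype=float)
        if winsorize_k is not None:
            vals = winsorize(vals, k=winsorize_k)
        segments.extend(
            segment_profile(grp["pos"].to_numpy(), vals, penalty=penalty, chrom=str(chrom))
        )
    return segments


def brute_force_segment(values: Sequence[float], penalty: float) -> float:
    """Exhaustive-search optimal segmentation cost (oracle for tests).

    Enumerates all 2^(n-1) breakpoint sets; only usable for tiny n.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    best = np.inf
    for mask in itertools.product([0, 1], repeat=n - 1):
        cost = penalty * sum(mask)
        start = 0
        for i, brk in enumerate(list(mask) + [1]):
            if brk:
                seg = values[start : i + 1]
                cost += float(np.sum((seg - seg.mean()) ** 2))
                start = i + 1
        best = min(best, cost)
    return best
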