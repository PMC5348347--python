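"""Synthetic paired diagnosis/relapse cohorts with planted ground truth.

Generates a toy genome with copy-number and methylation probe grids and a
gene annotation, then simulates the three platforms for a paired cohort:

* **Copy number** — per-pair shared segments (present at both time
  points), relapse-acquired segments, and optionally diagnosis-only
  ("lost") segments, with Gaussian probe noise on the log2-ratio scale.
* **Methylation** — probe-level methylation fractions with an additive
  batch effect and planted relapse DMRs (contiguous probe runs shifted by
  a fixed delta).
* **Expression** — gene-level log2 values driven by baseline + gene
  dosage (the true CNA log2 over the gene span) + promoter methylation
  repression + direct relapse effects + noise.

Every planted feature is recorded in a :class:`GroundTruth` object so the
downstream callers can be tested for recovery. All generators are
deterministic given their seed, and zero-noise settings make every
downstream estimate exact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_N_PAIRS = 17  # expression cohort size of the study design being emulated


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; coordinates 0-based half-open."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self):
        names = [n for n, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(L <= 0 for _, L in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)


@dataclass(frozen=True)
class ProbeSet:
    """Sorted probe coordinates for one platform ("cn" or "meth")."""

    platform: str
    probes: tuple[tuple[str, int], ...]  # (chrom, pos), sorted per chromosome

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probes, columns=["chrom", "pos"])


@dataclass
class CohortDesign:
    """Paired cohort: each diagnosis sample has exactly one relapse partner."""

    n_pairs: int = DEFAULT_N_PAIRS
    n_batches: int = 2
    seed: int = 0

    @property
    def pair_ids(self) -> list[str]:
        return [f"P{i+1:02d}" for i in range(self.n_pairs)]

    @property
    def pairing(self) -> dict[str, str]:
        return {f"{p}-D": f"{p}-R" for p in self.pair_ids}

    @property
    def samples(self) -> list[str]:
        return [s for p in self.pair_ids for s in (f"{p}-D", f"{p}-R")]

    @property
    def batches(self) -> pd.Series:
        """Batch labels assigned per pair (both time points share a batch)."""
        labels = {}
        for i, p in enumerate(self.pair_ids):
            b = f"batch{i % self.n_batches + 1}"
            labels[f"{p}-D"] = b
            labels[f"{p}-R"] = b
        return pd.Series(labels)

    def sample_sheet(self) -> pd.DataFrame:
        batches = self.batches
        rows = []
        for p in self.pair_ids:
            for tp, suffix in [("diagnosis", "D"), ("relapse", "R")]:
                sid = f"{p}-{suffix}"
                rows.append(
                    {"sample_id": sid, "patient_id": p, "timepoint": tp, "batch": batches[sid]}
                )
        return pd.DataFrame(rows)


@dataclass
class GroundTruth:
    """Record of every planted feature, for recovery testing."""

    cna_segments: dict[str, list[dict]] = field(default_factory=dict)
    dmrs: list[dict] = field(default_factory=list)
    dosage_genes: list[str] = field(default_factory=list)
    meth_genes: list[str] = field(default_factory=list)
    de_genes: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def generate_genome(
    n_chrom: int = 2,
    chrom_length: int = 10_000_000,
    probe_spacing: int = 5_000,
    n_genes: int = 200,
    seed: int = 0,
    meth_probe_spacing: int | None = None,
    gene_span: int = 20_000,
) -> tuple[GenomeLayout, ProbeSet, ProbeSet, pd.DataFrame]:
    """Build a toy genome: layout, CN and methylation probe grids, genes.

    CN probes sit on a regular ``probe_spacing`` grid; methylation probes
    use ``meth_probe_spacing`` (default: same spacing, offset by half a
    step so the two platforms do not coincide). Genes are placed with
    unique TSS coordinates and random strands; an impossible placement
    (more genes than available slots) raises.
    """
    if probe_spacing <= 0:
        raise ValueError("probe spacing must be positive")
    meth_spacing = meth_probe_spacing or probe_spacing
    if meth_spacing <= 0:
        raise ValueError("methylation probe spacing must be positive")
    rng = np.random.default_rng(seed)
    layout = GenomeLayout(tuple((f"chr{i+1}", chrom_length) for i in range(n_chrom)))

    cn_probes = tuple(
        (chrom, int(pos))
        for chrom, L in layout.chromosomes
        for pos in range(0, L, probe_spacing)
    )
    offset = meth_spacing // 2
    meth_probes = tuple(
        (chrom, int(pos))
        for chrom, L in layout.chromosomes
        for pos in range(offset, L, meth_spacing)
    )

    # genes: unique TSS on a coarse grid, random strand, fixed span
    slots_per_chrom = chrom_length // gene_span - 1
    if n_genes > slots_per_chrom * n_chrom:
        raise ValueError("cannot place genes without TSS collisions")
    genes = []
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    g = 0
    for (chrom, L), k in zip(layout.chromosomes, per_chrom):
        slots = rng.choice(slots_per_chrom, size=k, replace=False)
        for slot in np.sort(slots):
            strand = "+" if rng.random() < 0.5 else "-"
            tss = int((slot + 1) * gene_span)
            start, end = (tss, tss + gene_span) if strand == "+" else (tss - gene_span, tss)
            genes.append(
                {
                    "gene": f"G{g+1:04d}",
                    "chrom": chrom,
                    "strand": strand,
                    "tss": tss,
                    "start": max(0, start),
                    "end": min(L, end),
                }
            )
            g += 1
    annotation = pd.DataFrame(genes)
    return layout, ProbeSet("cn", cn_probes), ProbeSet("meth", meth_probes), annotation


def _place_segment(
    rng: np.random.Generator, layout: GenomeLayout, length: int, taken: dict[str, list]
) -> tuple[str, int, int]:
    """Place a segment uniformly, rejecting overlaps with taken intervals."""
    chroms = [c for c, L in layout.chromosomes if L > length]
    if not chroms:
        raise ValueError("segment longer than every chromosome")
    lengths = dict(layout.chromosomes)
    for _ in range(2000):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, lengths[chrom] - length))
        end = start + length
        if all(end <= s or start >= e for s, e in taken.get(chrom, [])):
            taken.setdefault(chrom, []).append((start, end))
            return chrom, start, end
    raise ValueError("could not place segment without overlap")


def simulate_cna(
    design: CohortDesign,
    layout: GenomeLayout,
    probes: ProbeSet,
    n_shared_segments: int = 2,
    n_acquired_segments: int = 2,
    n_lost_segments: int = 0,
    n_recurrent_segments: int = 1,
    recurrent_fraction: float = 0.5,
    recurrent_log2: float = 1.0,
    high_burden_fraction: float = 0.5,
    high_burden_factor: int = 4,
    segment_length_range: tuple[int, int] = (500_000, 3_000_000),
    gain_log2: float = 0.5,
    loss_log2: float = -0.5,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate probe-level log2 copy-number ratios for a paired cohort.

    Each pair receives ``n_shared_segments`` present at both time points,
    ``n_acquired_segments`` present only at relapse, and optionally
    ``n_lost_segments`` present only at diagnosis. Two features of real
    relapse cohorts are planted on top: ``n_recurrent_segments`` lesions
    at fixed genomic locations, each acquired at relapse by a random
    ``recurrent_fraction`` of the pairs (the substrate for recurrence and
    dosage-correlation analyses), and a high-burden subgroup — the first
    ``round(high_burden_fraction * n_pairs)`` pairs carry
    ``high_burden_factor`` times as many private acquired lesions, so
    burden classes separate. Segment states are drawn gain/loss with
    equal probability; probe values are the segment mean plus
    N(0, noise_sd). Segments within a sample never overlap.
    """
    if not (loss_log2 < -0.1 < 0 < 0.1 < gain_log2):
        raise ValueError("planted log2 levels must be callable at the +/-0.1 threshold")
    rng = np.random.default_rng(seed)
    probe_df = probes.to_frame()
    lengths = layout.lengths
    for chrom, grp in probe_df.groupby("chrom"):
        if grp["pos"].max() >= lengths[chrom]:
            raise ValueError("probe outside chromosome bounds")

    truth = GroundTruth()
    n_probes = len(probe_df)
    values = np.zeros((n_probes, 2 * design.n_pairs))
    columns = design.samples
    col_idx = {s: j for j, s in enumerate(columns)}
    chrom_arr = probe_df["chrom"].to_numpy()
    pos_arr = probe_df["pos"].to_numpy()

    lo, hi = segment_length_range
    # fixed-location recurrent lesions, shared across a subset of pairs
    recurrent: list[tuple[str, int, int, str, float]] = []
    recurrent_taken: dict[str, list] = {}
    for _ in range(n_recurrent_segments):
        length = int(rng.integers(lo, hi + 1))
        chrom, start, end = _place_segment(rng, layout, length, recurrent_taken)
        state = "gain" if rng.random() < 0.5 else "loss"
        # recurrent lesions are amplification-level so dosage effects are strong
        recurrent.append(
            (chrom, start, end, state, recurrent_log2 if state == "gain" else -recurrent_log2)
        )

    n_high = round(high_burden_fraction * design.n_pairs)
    for pair_idx, pair in enumerate(design.pair_ids):
        taken = {c: list(ivs) for c, ivs in recurrent_taken.items()}
        planted = []  # (chrom, start, end, state, mean, kind)
        for chrom, start, end, state, mean in recurrent:
            if rng.random() < recurrent_fraction:
                planted.append((chrom, start, end, state, mean, "acquired"))
        n_acq = n_acquired_segments * (high_burden_factor if pair_idx < n_high else 1)
        for kind, count in [
            ("shared", n_shared_segments),
            ("acquired", n_acq),
            ("lost", n_lost_segments),
        ]:
            for _ in range(count):
                length = int(rng.integers(lo, hi + 1))
                chrom, start, end = _place_segment(rng, layout, length, taken)
                state = "gain" if rng.random() < 0.5 else "loss"
                mean = gain_log2 if state == "gain" else loss_log2
                planted.append((chrom, start, end, state, mean, kind))
        for suffix, present_kinds in [("D", {"shared", "lost"}), ("R", {"shared", "acquired"})]:
            sample = f"{pair}-{suffix}"
            truth.cna_segments[sample] = []
            for chrom, start, end, state, mean, kind in planted:
                if kind not in present_kinds:
                    continue
                mask = (chrom_arr == chrom) & (pos_arr >= start) & (pos_arr < end)
                values[mask, col_idx[sample]] += mean
                truth.cna_segments[sample].append(
                    {
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "state": state,
                        "mean_log2": mean,
                        "kind": kind,
                        "n_markers": int(mask.sum()),
                    }
                )
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)
    matrix = pd.DataFrame(values, columns=columns)
    matrix.insert(0, "chrom", chrom_arr)
    matrix.insert(1, "pos", pos_arr)
    return matrix, truth


def simulate_methylation(
    design: CohortDesign,
    probes: ProbeSet,
    n_dmrs: int = 10,
    dmr_probe_count: int = 6,
    dmr_delta: float = 0.20,
    dmr_pair_fraction: float = 0.7,
    batch_shift: float = 0.05,
    noise_sd: float = 0.03,
    baseline_beta: tuple[float, float] = (2.0, 2.0),
    seed: int = 0,
    truth: GroundTruth | None = None,
    annotation: pd.DataFrame | None = None,
    target_genes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate probe-level methylation fractions for a paired cohort.

    Baseline per-probe fractions are Beta(``baseline_beta``) draws shared
    by all samples; each planted DMR shifts ``dmr_probe_count`` contiguous
    probes by ``dmr_delta`` in the relapse sample of a random
    ``dmr_pair_fraction`` of the pairs (at least one; 1.0 means every
    pair, which is what the zero-noise oracle fixtures use);
    ``batch_shift`` is added to all samples of every even-numbered batch;
    Gaussian noise is added last and values are clipped to [0, 1].

    When ``annotation`` and ``target_genes`` are given, DMRs are planted
    on the probes inside each target gene's promoter window (2 kb
    upstream of the TSS) so methylation-repressed expression can be
    simulated downstream; remaining DMRs are placed at random probe runs.
    Baselines under planted DMRs are drawn from the mid-range so the
    shift survives clipping.
    """
    if dmr_probe_count < 1:
        raise ValueError("dmr_probe_count must be >= 1")
    rng = np.random.default_rng(seed)
    truth = truth or GroundTruth()
    probe_df = probes.to_frame()
    n_probes = len(probe_df)
    chrom_arr = probe_df["chrom"].to_numpy()
    pos_arr = probe_df["pos"].to_numpy()

    baseline = rng.beta(*baseline_beta, size=n_probes)

    dmr_probe_idx: list[np.ndarray] = []
    used = np.zeros(n_probes, dtype=bool)
    n_targeted = 0
    if annotation is not None and target_genes:
        from .methylation import promoter_window

        ann = annotation.set_index("gene")
        for gene in target_genes:
            row = ann.loc[gene]
            lo, hi = promoter_window(int(row["tss"]), str(row["strand"]))
            idx = np.flatnonzero((chrom_arr == row["chrom"]) & (pos_arr >= lo) & (pos_arr < hi))
            if idx.size == 0:
                raise ValueError(
                    f"no methylation probes in the promoter window of {gene}; "
                    "use a denser methylation probe grid"
                )
            dmr_probe_idx.append(idx)
            used[idx] = True
            n_targeted += 1
            if gene not in truth.meth_genes:
                truth.meth_genes.append(gene)
    for _ in range(max(0, n_dmrs - n_targeted)):
        for _try in range(200):
            start_i = int(rng.integers(0, n_probes - dmr_probe_count))
            idx = np.arange(start_i, start_i + dmr_probe_count)
            same_chrom = len(set(chrom_arr[idx])) == 1
            if same_chrom and not used[idx].any():
                dmr_probe_idx.append(idx)
                used[idx] = True
                break
        else:
            raise ValueError("could not place DMR without overlap")

    sign = np.ones(len(dmr_probe_idx))
    # default direction: hypermethylation at relapse; flip a subset for variety
    flip = rng.random(len(dmr_probe_idx)) < 0.3
    sign[flip] = -1.0
    carriers: list[list[str]] = []
    for idx, s in zip(dmr_probe_idx, sign):
        # mid-range baseline keeps baseline + delta inside [0, 1]
        baseline[idx] = rng.uniform(0.25, 0.55, size=idx.size)
        if dmr_pair_fraction >= 1.0:
            carry = list(design.pair_ids)
        else:
            hit = rng.random(design.n_pairs) < dmr_pair_fraction
            if not hit.any():
                hit[int(rng.integers(design.n_pairs))] = True
            carry = [p for p, h in zip(design.pair_ids, hit) if h]
        carriers.append(carry)
        truth.dmrs.append(
            {
                "chrom": str(chrom_arr[idx[0]]),
                "start": int(pos_arr[idx[0]]),
                "end": int(pos_arr[idx[-1]]) + 1,
                "n_probes": int(idx.size),
                "delta": float(s * dmr_delta),
                "pairs": carry,
            }
        )

    columns = design.samples
    values = np.tile(baseline[:, None], (1, len(columns)))
    for j, sample in enumerate(columns):
        if sample.endswith("-R"):
            pair = sample[:-2]
            for idx, s, carry in zip(dmr_probe_idx, sign, carriers):
                if pair in carry:
                    values[idx, j] += s * dmr_delta
    batches = design.batches
    shifted = {b for i, b in enumerate(sorted(batches.unique())) if i % 2 == 1}
    for j, sample in enumerate(columns):
        if batches[sample] in shifted:
            values[:, j] += batch_shift
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, 1.0)
    matrix = pd.DataFrame(values, columns=columns)
    matrix.insert(0, "chrom", chrom_arr)
    matrix.insert(1, "pos", pos_arr)
    return matrix, truth


def true_gene_cna(
    truth: GroundTruth,
    annotation: pd.DataFrame,
    samples: Sequence[str],
    probes: "ProbeSet | None" = None,
) -> pd.DataFrame:
    """Noise-free gene-level CNA log2 per sample from the planted segments.

    With ``probes`` given, the gene value is the mean planted log2 over
    the copy-number probes inside the gene span — exactly what a
    probe-weighted analysis of the noise-free matrix measures (genes
    without probes get NaN). Without probes, the planted segment mean is
    weighted by the fraction of the gene span covered.
    """
    genes = annotation["gene"].tolist()
    out = pd.DataFrame(0.0, index=genes, columns=list(samples))
    if probes is not None:
        pdf = probes.to_frame()
        chrom_arr = pdf["chrom"].to_numpy()
        pos_arr = pdf["pos"].to_numpy()
        for sample in samples:
            true_vals = np.zeros(len(pdf))
            for seg in truth.cna_segments.get(sample, []):
                mask = (chrom_arr == seg["chrom"]) & (pos_arr >= seg["start"]) & (
                    pos_arr < seg["end"]
                )
                true_vals[mask] += seg["mean_log2"]
            for _, row in annotation.iterrows():
                sel = (chrom_arr == row["chrom"]) & (pos_arr >= row["start"]) & (
                    pos_arr < row["end"]
                )
                out.loc[row["gene"], sample] = (
                    true_vals[sel].mean() if sel.any() else np.nan
                )
        return out
    for sample in samples:
        for seg in truth.cna_segments.get(sample, []):
            sel = annotation[annotation["chrom"] == seg["chrom"]]
            for _, row in sel.iterrows():
                ov = min(seg["end"], row["end"]) - max(seg["start"], row["start"])
                span = row["end"] - row["start"]
                if ov > 0 and span > 0:
                    out.loc[row["gene"], sample] += seg["mean_log2"] * ov / span
    return out


def true_promoter_methylation(
    truth: GroundTruth,
    annotation: pd.DataFrame,
    meth_matrix: pd.DataFrame,
    samples: Sequence[str],
) -> pd.DataFrame:
    """Noise-free promoter methylation shift per gene: the planted DMR
    delta for relapse samples of carrier pairs, zero otherwise."""
    genes = annotation["gene"].tolist()
    out = pd.DataFrame(0.0, index=genes, columns=list(samples))
    ann = annotation.set_index("gene")
    from .methylation import promoter_window

    for gene in truth.meth_genes:
        row = ann.loc[gene]
        lo, hi = promoter_window(int(row["tss"]), str(row["strand"]))
        hit = None
        for d in truth.dmrs:
            if d["chrom"] == row["chrom"] and d["start"] >= lo - 1 and d["end"] <= hi + 1:
                hit = d
                break
        if hit is None:
            continue
        carry = set(hit.get("pairs") or [])
        for sample in samples:
            if sample.endswith("-R") and (not carry or sample[:-2] in carry):
                out.loc[gene, sample] = hit["delta"]
    return out


def simulate_expression(
    design: CohortDesign,
    annotation: pd.DataFrame,
    truth: GroundTruth,
    dosage_slope: float = 1.0,
    meth_slope: float = -3.0,
    de_log2fc: float = -1.0,
    n_de_genes: int = 5,
    noise_sd: float = 0.03,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.5,
    seed: int = 0,
    cn_probes: ProbeSet | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a genes x samples log2 expression matrix.

    expression = baseline(gene)
               + dosage_slope * true gene-level CNA log2        (all genes in CNAs)
               + meth_slope  * true promoter methylation shift  (genes in truth.meth_genes)
               + de_log2fc at relapse for planted DE genes
               + N(0, noise_sd)

    Genes overlapping any planted CNA segment are recorded as
    ``truth.dosage_genes``; ``n_de_genes`` genes free of CNA/methylation
    effects receive the direct relapse effect and are recorded in
    ``truth.de_genes`` with their signed log2 fold change.
    """
    rng = np.random.default_rng(seed)
    genes = annotation["gene"].tolist()
    unknown = set(truth.meth_genes) - set(genes)
    if unknown:
        raise KeyError(f"ground-truth genes missing from annotation: {sorted(unknown)}")
    samples = design.samples
    baseline = rng.normal(baseline_mean, baseline_sd, size=len(genes))
    expr = pd.DataFrame(
        np.tile(baseline[:, None], (1, len(samples))), index=genes, columns=samples
    )

    # probe-weighted when the CN probe grid is known, so the dosage signal
    # is exactly what a probe-level analysis measures
    gene_cna = true_gene_cna(truth, annotation, samples, probes=cn_probes).fillna(0.0)
    expr += dosage_slope * gene_cna
    # recoverable dosage genes: CNA differs between time points in >= 1
    # pair (genes in purely shared lesions have no paired contrast)
    diag_cols = [s for s in samples if s.endswith("-D")]
    rel_cols = [s for s in samples if s.endswith("-R")]
    delta = gene_cna[rel_cols].to_numpy() - gene_cna[diag_cols].to_numpy()
    truth.dosage_genes = [str(g) for g in gene_cna.index[(delta != 0).any(axis=1)]]

    if truth.meth_genes:
        prom = true_promoter_methylation(truth, annotation, pd.DataFrame(), samples)
        expr += meth_slope * prom

    excluded = set(truth.dosage_genes) | set(truth.meth_genes)
    free = [g for g in genes if g not in excluded]
    if n_de_genes > 0:
        if len(free) < n_de_genes:
            raise ValueError("not enough effect-free genes for planted DE genes")
        de = [free[i] for i in rng.choice(len(free), size=n_de_genes, replace=False)]
        for g in de:
            truth.de_genes[str(g)] = float(de_log2fc)
            for s in samples:
                if s.endswith("-R"):
                    expr.loc[g, s] += de_log2fc
    if noise_sd > 0:
        expr += rng.normal(0.0, noise_sd, size=expr.shape)
    return expr, truth
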