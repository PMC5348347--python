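"""Methylation preprocessing, peaks, DMRs and promoter windows."""

import numpy as np
import pandas as pd
import pytest

from pairomics import methylation as meth
from pairomics.methylation import (
    DMR,
    PeakParams,
    assign_region_to_gene,
    batch_correct,
    call_peaks,
    core_promoter_window,
    detect_dmrs,
    fraction_to_logratio,
    logratio_to_fraction,
    promoter_aggregate,
    promoter_differential,
    promoter_window,
    quantile_normalize,
)


class TestScaleConversion:
    def test_round_trip_bijection(self, rng):
        m = rng.uniform(0.01, 0.99, 500)
        assert np.allclose(logratio_to_fraction(fraction_to_logratio(m)), m)
        x = rng.normal(0, 3, 500)
        assert np.allclose(fraction_to_logratio(logratio_to_fraction(x)), x)

    def test_half_maps_to_zero(self):
        assert fraction_to_logratio(np.array([0.5]))[0] == pytest.approx(0.0)


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 3.0, 2.0], "b": [1.0, 3.0, 2.0]})
        pd.testing.assert_frame_equal(quantile_normalize(m), m)

    def test_mean_of_sorted_definition(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_column_distributions_identical(self, rng):
        m = pd.DataFrame(rng.normal(size=(200, 5)) * [1, 2, 3, 4, 5])
        out = quantile_normalize(m)
        ref = np.sort(out.iloc[:, 0].to_numpy())
        for j in range(1, 5):
            assert np.allclose(np.sort(out.iloc[:, j].to_numpy()), ref)

    def test_ranks_preserved(self, rng):
        m = pd.DataFrame(rng.normal(size=(50, 3)))
        out = quantile_normalize(m)
        for c in m.columns:
            assert np.array_equal(np.argsort(m[c].to_numpy()), np.argsort(out[c].to_numpy()))

    def test_single_sample_warns_identity(self):
        m = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            out = quantile_normalize(m)
        pd.testing.assert_frame_equal(out, m)


class TestBatchCorrect:
    def make_data(self, rng, shift=0.0, n=200, per_batch=6):
        base = rng.normal(0, 1, size=(n, 2 * per_batch))
        cols = [f"s{i}" for i in range(2 * per_batch)]
        batches = pd.Series(
            {c: ("A" if i < per_batch else "B") for i, c in enumerate(cols)}
        )
        base[:, per_batch:] += shift
        return pd.DataFrame(base, columns=cols), batches

    def test_planted_shift_removed(self, rng):
        m, batches = self.make_data(rng, shift=0.5)
        out = batch_correct(m, batches)
        a = out.loc[:, batches == "A"].to_numpy().mean()
        b = out.loc[:, batches == "B"].to_numpy().mean()
        assert abs(a - b) < 0.05

    def test_null_case_nearly_identity(self, rng):
        m, batches = self.make_data(rng, shift=0.0)
        out = batch_correct(m, batches)
        # no planted effect: movement stays small relative to the unit noise
        assert np.abs(out.to_numpy() - m.to_numpy()).mean() < 0.5
        a = out.loc[:, batches == "A"].to_numpy().mean()
        b = out.loc[:, batches == "B"].to_numpy().mean()
        assert abs(a - b) < 0.05

    def test_single_batch_identity(self, rng):
        m, _ = self.make_data(rng)
        batches = pd.Series({c: "A" for c in m.columns})
        pd.testing.assert_frame_equal(batch_correct(m, batches), m)

    def test_mean_centering_fallback(self, rng):
        m, batches = self.make_data(rng, shift=0.5)
        out = batch_correct(m, batches, parametric=False)
        a = out.loc[:, batches == "A"].to_numpy().mean()
        b = out.loc[:, batches == "B"].to_numpy().mean()
        assert abs(a - b) < 1e-9


class TestPeaks:
    def test_single_qualifying_probe_no_peak(self):
        peaks = call_peaks([100], [5.0], PeakParams())
        assert peaks == []

    def test_two_probes_within_width_one_peak(self):
        peaks = call_peaks([100, 600], [5.0, 5.0], PeakParams())
        assert peaks == [("chr1", 100, 601, 2)]

    def test_two_probes_far_apart_no_peak(self):
        peaks = call_peaks([100, 2100], [5.0, 5.0], PeakParams())
        assert peaks == []

    def test_invariant_to_subthreshold_probes(self):
        base = call_peaks([100, 600], [5.0, 5.0], PeakParams())
        padded = call_peaks([50, 100, 300, 600, 900], [0.1, 5.0, 1.0, 5.0, 0.5],
                            PeakParams())
        assert base == padded

    def test_peak_scores_enriched_window(self, rng):
        pos = np.arange(100) * 300
        vals = rng.normal(0, 0.3, 100)
        vals[40:45] += 3.0  # strongly methylated run
        scores = meth.peak_scores(pos, vals, width=750)
        # interior probes of the run have fully-methylated windows
        assert scores[41:44].min() > 2.0
        assert np.median(scores[:30]) < 2.0


def paired_frames(delta_vec, n_pairs=8, noise_sd=0.0, seed=0, baseline=0.4):
    rng = np.random.default_rng(seed)
    n = delta_vec.size
    d = np.full((n, n_pairs), baseline) + rng.normal(0, noise_sd, (n, n_pairs))
    r = d + delta_vec[:, None] + rng.normal(0, noise_sd, (n, n_pairs))
    cols = [f"p{i}" for i in range(n_pairs)]
    return pd.DataFrame(d, columns=cols), pd.DataFrame(r, columns=cols)


class TestDMR:
    def probes(self, n=40, spacing=200):
        return pd.DataFrame({"chrom": "chr1", "pos": np.arange(n) * spacing})

    def test_zero_noise_exact_bounds(self):
        delta = np.zeros(40)
        delta[10:16] = 0.20  # 6-probe DMR
        diag, rel = paired_frames(delta)
        dmrs = detect_dmrs(self.probes(), diag, rel, seed=0)
        assert len(dmrs) == 1
        d = dmrs[0]
        assert (d.start, d.end) == (10 * 200, 15 * 200 + 1)
        assert d.n_probes == 6
        assert d.mean_delta == pytest.approx(0.20)
        assert d.direction == "hyper"
        assert d.p_value < 0.05

    def test_small_delta_not_reported(self):
        delta = np.zeros(40)
        delta[10:16] = 0.02  # below the 5-percentage-point rule
        diag, rel = paired_frames(delta)
        assert detect_dmrs(self.probes(), diag, rel, seed=0) == []

    def test_three_probe_run_removed(self):
        delta = np.zeros(40)
        delta[10:13] = 0.30
        diag, rel = paired_frames(delta)
        assert detect_dmrs(self.probes(), diag, rel, seed=0) == []

    def test_no_difference_no_dmrs(self, rng):
        vals = rng.uniform(0.2, 0.8, (40, 6))
        diag = pd.DataFrame(vals, columns=[f"p{i}" for i in range(6)])
        assert detect_dmrs(self.probes(), diag, diag.copy(), seed=0) == []

    def test_hypomethylation_direction(self):
        delta = np.zeros(40)
        delta[5:11] = -0.20
        diag, rel = paired_frames(delta)
        dmrs = detect_dmrs(self.probes(), diag, rel, seed=0)
        assert len(dmrs) == 1 and dmrs[0].direction == "hypo"

    def test_gap_breaks_runs(self):
        # same 8 exceeding probes, but a >1-kb gap splits them 4/4
        probes = pd.DataFrame(
            {"chrom": "chr1", "pos": [0, 200, 400, 600, 5000, 5200, 5400, 5600]}
        )
        delta = np.full(8, 0.20)
        diag, rel = paired_frames(delta)
        dmrs = detect_dmrs(probes, diag, rel, seed=0)
        assert len(dmrs) == 2
        assert all(d.n_probes == 4 for d in dmrs)


class TestRegionToGene:
    def annotation(self):
        return pd.DataFrame(
            {
                "gene": ["g1", "g2"],
                "chrom": ["chr1", "chr1"],
                "strand": ["+", "+"],
                "tss": [1000, 5000],
                "start": [1000, 5000],
                "end": [2000, 6000],
            }
        )

    def test_midpoint_at_tss(self):
        assert assign_region_to_gene(("chr1", 900, 1100), self.annotation()) == "g1"

    def test_equidistant_tie_lower_coordinate(self):
        # midpoint 3000 is 2000 from both TSSs
        assert assign_region_to_gene(("chr1", 2900, 3100), self.annotation()) == "g1"

    def test_chromosome_without_genes(self):
        assert assign_region_to_gene(("chr9", 0, 100), self.annotation()) is None

    def test_empty_annotation_raises(self):
        with pytest.raises(ValueError):
            assign_region_to_gene(("chr1", 0, 100), pd.DataFrame())


class TestPromoterWindows:
    def test_plus_strand(self):
        assert promoter_window(10_000, "+") == (8_000, 10_000)
        assert core_promoter_window(10_000) == (9_750, 10_250)

    def test_minus_strand_reflected(self):
        assert promoter_window(10_000, "-") == (10_000, 12_000)

    def test_clipped_at_chromosome_start(self):
        assert promoter_window(500, "+") == (0, 500)

    def test_aggregation_mean_and_max(self):
        probes = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [8_100, 9_900]})
        matrix = pd.DataFrame({"s1": [0.1, 0.9]})
        ann = pd.DataFrame(
            {"gene": ["g", "h"], "chrom": ["chr1", "chr2"], "strand": ["+", "+"],
             "tss": [10_000, 10_000], "start": [10_000, 10_000],
             "end": [12_000, 12_000]}
        )
        out = promoter_aggregate(probes, matrix, ann)
        assert out[("promoter", "mean")].loc["g", "s1"] == pytest.approx(0.5)
        assert out[("promoter", "max")].loc["g", "s1"] == pytest.approx(0.9)
        # only the 9900 probe falls in the core window [9750, 10250)
        assert out[("core", "mean")].loc["g", "s1"] == pytest.approx(0.9)
        # gene on a probe-free chromosome gets a missing value
        assert np.isnan(out[("promoter", "mean")].loc["h", "s1"])


class TestPromoterDifferential:
    def test_planted_hypermethylation_recovered(self, rng):
        n_genes, n_pairs = 60, 8
        cols_d = [f"P{i}-D" for i in range(n_pairs)]
        cols_r = [f"P{i}-R" for i in range(n_pairs)]
        base = rng.uniform(0.2, 0.6, (n_genes, 1))
        noise = lambda: rng.normal(0, 0.01, (n_genes, n_pairs))
        d = pd.DataFrame(base + noise(), columns=cols_d)
        r = pd.DataFrame(base + noise(), columns=cols_r)
        r.iloc[0] += 0.25  # planted promoter hypermethylation
        mat = pd.concat([d, r], axis=1)
        mat.index = [f"g{i}" for i in range(n_genes)]
        res = promoter_differential(mat, dict(zip(cols_d, cols_r)), seed=0)
        assert "g0" in res.significant(0.05).index

    def test_too_few_pairs_raises(self):
        mat = pd.DataFrame(np.ones((10, 4)), columns=["a", "b", "c", "d"])
        with pytest.raises(ValueError):
            promoter_differential(mat, {"a": "b", "c": "d"})
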