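"""End-to-end pipeline driver: simulate -> CNA -> methylation ->
expression -> integration -> meta-analysis, with a JSON run manifest.

The configuration is a nested dict (typically loaded from YAML); every
analysis threshold is a named key defaulting to the standard workflow
value. Unknown keys raise, so typos in configs fail loudly.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cna, expression, integration, meta, methylation, synthetic
from .io import write_bed, write_matrix, write_seg

log = logging.getLogger("pairomics")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {"n_pairs": 17, "n_batches": 2},
    "genome": {
        "n_chrom": 4,
        "chrom_length": 20_000_000,
        "probe_spacing": 20_000,
        "meth_probe_spacing": 400,
        "n_genes": 300,
    },
    "cna": {
        "n_shared_segments": 2,
        "n_acquired_segments": 2,
        "n_lost_segments": 0,
        "n_recurrent_segments": 1,
        "recurrent_fraction": 0.5,
        "recurrent_log2": 1.0,
        "high_burden_fraction": 0.5,
        "high_burden_factor": 4,
        "segment_length_range": [500_000, 3_000_000],
        "gain_log2": 0.5,
        "loss_log2": -0.5,
        "noise_sd": 0.1,
        "penalty": 2.0,
        "gain_thresh": 0.1,
        "loss_thresh": -0.1,
        "min_markers": 25,
        "min_length": 100_000,
        "max_cnv_overlap": 0.5,
        # the toy genome is ~1/40 of hg19; the 100-Mb burden split is
        # scaled accordingly so both classes are populated
        "burden_cutoff": 10_000_000,
    },
    "methylation": {
        "n_dmrs": 10,
        "n_promoter_dmrs": 4,
        "dmr_probe_count": 6,
        "dmr_delta": 0.20,
        "dmr_pair_fraction": 0.7,
        "batch_shift": 0.05,
        "noise_sd": 0.03,
        "dmr_min_probes": 4,
        "dmr_delta_cutoff": 0.05,
        "smooth_window": 3,
        "max_gap": 1000,
    },
    "expression": {
        "dosage_slope": 1.0,
        "meth_slope": -3.0,
        "de_log2fc": -1.0,
        "n_de_genes": 5,
        "noise_sd": 0.03,
        "sam_q_cutoff": 0.05,
        "concordance_fold": 2.0,
        "concordance_min_pairs": 5,
    },
    "integration": {
        "cna_fold": 2.0,
        "meth_fold": 1.5,
        "min_pairs": 3,
        "r_cutoff": 0.8,
        "fdr_cutoff": 0.05,
    },
    "meta": {"n_studies": 3, "study_n_pairs": [17, 10, 12]},
}


def _merge(defaults: dict, override: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in override.items():
        if key not in defaults:
            raise KeyError(f"unknown config key: {path}{key}")
        if isinstance(defaults[key], dict):
            out[key] = _merge(defaults[key], value or {}, f"{path}{key}.")
        else:
            out[key] = value
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def run_pipeline(config: dict | None = None, outdir=None, seed: int | None = None) -> dict:
    """Run the full synthetic-cohort analysis; returns a results dict and
    (if ``outdir`` is given) writes TSV/BED/JSON outputs plus a manifest.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    if seed is not None:
        cfg["seed"] = seed
    seed = int(cfg["seed"])
    t0 = time.time()
    logging.basicConfig(stream=sys.stderr, level=logging.INFO, format="%(name)s %(message)s")

    # --- simulate -----------------------------------------------------------
    g = cfg["genome"]
    layout, cn_probes, meth_probes, annotation = synthetic.generate_genome(
        n_chrom=g["n_chrom"],
        chrom_length=g["chrom_length"],
        probe_spacing=g["probe_spacing"],
        meth_probe_spacing=g["meth_probe_spacing"],
        n_genes=g["n_genes"],
        seed=seed,
    )
    design = synthetic.CohortDesign(
        n_pairs=cfg["cohort"]["n_pairs"], n_batches=cfg["cohort"]["n_batches"], seed=seed
    )
    c = cfg["cna"]
    cn_matrix, truth = synthetic.simulate_cna(
        design,
        layout,
        cn_probes,
        n_shared_segments=c["n_shared_segments"],
        n_acquired_segments=c["n_acquired_segments"],
        n_lost_segments=c["n_lost_segments"],
        n_recurrent_segments=c["n_recurrent_segments"],
        recurrent_fraction=c["recurrent_fraction"],
        recurrent_log2=c["recurrent_log2"],
        high_burden_fraction=c["high_burden_fraction"],
        high_burden_factor=c["high_burden_factor"],
        segment_length_range=tuple(c["segment_length_range"]),
        gain_log2=c["gain_log2"],
        loss_log2=c["loss_log2"],
        noise_sd=c["noise_sd"],
        seed=seed + 1,
    )
    m = cfg["methylation"]
    rng = np.random.default_rng(seed + 2)
    target_genes = [
        annotation["gene"].iloc[i]
        for i in rng.choice(len(annotation), size=m["n_promoter_dmrs"], replace=False)
    ]
    meth_matrix, truth = synthetic.simulate_methylation(
        design,
        meth_probes,
        n_dmrs=m["n_dmrs"],
        dmr_probe_count=m["dmr_probe_count"],
        dmr_delta=m["dmr_delta"],
        dmr_pair_fraction=m["dmr_pair_fraction"],
        batch_shift=m["batch_shift"],
        noise_sd=m["noise_sd"],
        seed=seed + 2,
        truth=truth,
        annotation=annotation,
        target_genes=target_genes,
    )
    e = cfg["expression"]
    expr_matrix, truth = synthetic.simulate_expression(
        design,
        annotation,
        truth,
        dosage_slope=e["dosage_slope"],
        meth_slope=e["meth_slope"],
        de_log2fc=e["de_log2fc"],
        n_de_genes=e["n_de_genes"],
        noise_sd=e["noise_sd"],
        seed=seed + 3,
        cn_probes=cn_probes,
    )
    log.info("simulated cohort: %d pairs, %d genes", design.n_pairs, len(annotation))

    # --- copy number --------------------------------------------------------
    params = cna.CNACallParams(
        gain_thresh=c["gain_thresh"],
        loss_thresh=c["loss_thresh"],
        min_markers=c["min_markers"],
        min_length=c["min_length"],
        max_cnv_overlap=c["max_cnv_overlap"],
    )
    probe_df = cn_matrix[["chrom", "pos"]]
    calls_per_sample: dict[str, list] = {}
    profiles: dict[str, cna.SampleCNAProfile] = {}
    for sample in design.samples:
        segs = cna.segment_sample(
            cn_matrix[["chrom", "pos", sample]], value_col=sample, penalty=c["penalty"]
        )
        calls = cna.call_cnas(segs, params=params)
        calls_per_sample[sample] = calls
        profiles[sample] = cna.SampleCNAProfile.from_calls(
            sample, calls, burden_cutoff=c["burden_cutoff"]
        )
    evolutions = [
        cna.compare_pair(p, calls_per_sample[f"{p}-D"], calls_per_sample[f"{p}-R"])
        for p in design.pair_ids
    ]
    diag_profiles = {s: p for s, p in profiles.items() if s.endswith("-D")}
    rel_profiles = {s: p for s, p in profiles.items() if s.endswith("-R")}
    counts = cna.count_stats(diag_profiles, rel_profiles)
    burden = {f"{p}-D": profiles[f"{p}-R"].burden_class for p in design.pair_ids}
    log.info(
        "cna: %d calls, %d/%d large-burden pairs",
        sum(len(v) for v in calls_per_sample.values()),
        sum(1 for b in burden.values() if b == "large"),
        design.n_pairs,
    )

    # --- methylation --------------------------------------------------------
    meth_probe_df = meth_matrix[["chrom", "pos"]]
    frac = meth_matrix[design.samples]
    logratio = pd.DataFrame(
        methylation.fraction_to_logratio(np.clip(frac.to_numpy(), 1e-6, 1 - 1e-6)),
        index=frac.index,
        columns=frac.columns,
    )
    norm = methylation.quantile_normalize(logratio)
    corrected = methylation.batch_correct(norm, design.batches)
    frac_corrected = pd.DataFrame(
        methylation.logratio_to_fraction(corrected.to_numpy()),
        index=corrected.index,
        columns=corrected.columns,
    )
    diag_cols = list(design.pairing)
    rel_cols = [design.pairing[d] for d in diag_cols]
    dmrs = methylation.detect_dmrs(
        meth_probe_df,
        frac_corrected[diag_cols],
        frac_corrected[rel_cols],
        smooth_window=m["smooth_window"],
        max_gap=m["max_gap"],
        delta_cutoff=m["dmr_delta_cutoff"],
        min_probes=m["dmr_min_probes"],
        seed=seed + 4,
    )
    dmr_genes = [
        (d, methylation.assign_region_to_gene((d.chrom, d.start, d.end), annotation))
        for d in dmrs
    ]
    log.info("methylation: %d DMRs detected", len(dmrs))

    # --- expression ---------------------------------------------------------
    filtered = expression.low_expression_filter(expr_matrix)
    sam = expression.sam_paired(filtered, design.pairing, seed=seed + 5)
    fc = expression.fold_changes(expr_matrix, design.pairing)
    concordant = expression.concordance_filter(
        fc, min_ratio_fc=e["concordance_fold"], min_pairs=e["concordance_min_pairs"]
    )
    log.info(
        "expression: %d genes at q<%.2f, %d up / %d down concordant",
        len(sam.significant(e["sam_q_cutoff"])),
        e["sam_q_cutoff"],
        len(concordant["up"]),
        len(concordant["down"]),
    )

    # --- integration --------------------------------------------------------
    i_cfg = cfg["integration"]
    cna_delta = integration.gene_cna_delta(
        probe_df, cn_matrix[design.samples], annotation, design.pairing
    )
    cand_cna = integration.select_candidates(fc, i_cfg["cna_fold"], i_cfg["min_pairs"])
    assoc_cna = integration.correlate_fc(
        fc.loc[[g_ for g_ in cand_cna if g_ in cna_delta.index]],
        cna_delta,
        sign_filter="positive",
        fdr_cutoff=i_cfg["fdr_cutoff"],
        r_cutoff=i_cfg["r_cutoff"],
    )
    meth_gene = methylation.promoter_aggregate(
        meth_probe_df, frac_corrected, annotation, chrom_lengths=layout.lengths
    )[("promoter", "mean")]
    meth_fc = expression.fold_changes(meth_gene.dropna(axis=0, how="any"), design.pairing)
    cand_meth = integration.select_candidates(fc, i_cfg["meth_fold"], i_cfg["min_pairs"])
    assoc_meth = integration.correlate_fc(
        fc.loc[[g_ for g_ in cand_meth if g_ in meth_fc.index]],
        meth_fc,
        sign_filter="negative",
        fdr_cutoff=i_cfg["fdr_cutoff"],
        r_cutoff=i_cfg["r_cutoff"],
    )
    inverse = integration.dmr_deg_intersect(
        dmr_genes, fc, min_ratio_fc=i_cfg["meth_fold"], min_pairs=i_cfg["min_pairs"]
    )
    strata = integration.burden_stratified_de(
        filtered, design.pairing, burden, seed=seed + 6
    )
    log.info(
        "integration: %d CNA-assoc genes, %d meth-assoc genes, %d inverse DMR/DEG",
        int(assoc_cna["passes"].sum()) if not assoc_cna.empty else 0,
        int(assoc_meth["passes"].sum()) if not assoc_meth.empty else 0,
        len(inverse),
    )

    # --- meta-analysis ------------------------------------------------------
    meta_cfg = cfg["meta"]
    de_genes = sorted(truth.de_genes)
    meta_results: dict[str, meta.MetaResult] = {}
    if de_genes:
        studies_data = []
        for si, n_pairs_s in enumerate(meta_cfg["study_n_pairs"][: meta_cfg["n_studies"]]):
            d_s = synthetic.CohortDesign(n_pairs=n_pairs_s, seed=seed + 10 + si)
            ex, _ = synthetic.simulate_expression(
                d_s,
                annotation,
                synthetic.GroundTruth(de_genes=dict(truth.de_genes)),
                n_de_genes=0,
                noise_sd=e["noise_sd"],
                seed=seed + 10 + si,
            )
            for gid, lfc in truth.de_genes.items():
                ex.loc[gid, [s for s in d_s.samples if s.endswith("-R")]] += lfc
            studies_data.append(
                meta.study_summaries_from_matrix(
                    f"study{si+1}",
                    ex,
                    [s for s in d_s.samples if s.endswith("-D")],
                    [s for s in d_s.samples if s.endswith("-R")],
                    genes=de_genes,
                )
            )
        for gid in de_genes:
            meta_results[gid] = meta.meta_analyze_gene([sd[gid] for sd in studies_data])
        flagged = meta.negative_trend_check(meta_results)
        log.info("meta-analysis: %d/%d planted genes with pooled g<0, p<0.05",
                 len(flagged), len(de_genes))

    results = {
        "config": cfg,
        "truth": truth,
        "annotation": annotation,
        "profiles": profiles,
        "evolutions": evolutions,
        "count_stats": counts,
        "burden": burden,
        "dmrs": dmrs,
        "sam": sam,
        "fold_changes": fc,
        "concordant": concordant,
        "assoc_cna": assoc_cna,
        "assoc_meth": assoc_meth,
        "inverse_dmr_deg": inverse,
        "burden_strata": strata,
        "meta": meta_results,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_seg(outdir / "cna_calls.seg", calls_per_sample)
        write_bed(
            outdir / "dmrs.bed",
            {
                chrom: [(d.start, d.end, f"{d.direction}", f"{d.p_value:.4g}")
                        for d in dmrs if d.chrom == chrom]
                for chrom in sorted({d.chrom for d in dmrs})
            },
        )
        write_matrix(outdir / "sam_table.tsv", sam.table)
        write_matrix(outdir / "fold_changes.tsv", fc)
        if not assoc_cna.empty:
            assoc_cna.to_csv(outdir / "assoc_cna.tsv", sep="\t", index=False)
        if not assoc_meth.empty:
            assoc_meth.to_csv(outdir / "assoc_meth.tsv", sep="\t", index=False)
        truth.to_json(outdir / "ground_truth.json")
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh)
        manifest = {
            "version": __version__,
            "seed": seed,
            "elapsed_s": round(time.time() - t0, 2),
            "stages": {
                "cna_calls": sum(len(v) for v in calls_per_sample.values()),
                "dmrs": len(dmrs),
                "sam_genes": int(len(sam.table)),
                "meta_genes": len(meta_results),
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return results
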