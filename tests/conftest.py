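"""Shared fixtures: small synthetic cohorts with planted ground truth."""

import numpy as np
import pandas as pd
import pytest

from pairomics import synthetic
from pairomics.cna import CNACall, Segment


@pytest.fixture(scope="session")
def small_genome():
    """Tiny 2-chromosome genome with dense methylation probes."""
    return synthetic.generate_genome(
        n_chrom=2,
        chrom_length=10_000_000,
        probe_spacing=10_000,
        meth_probe_spacing=400,
        n_genes=60,
        seed=7,
    )


@pytest.fixture(scope="session")
def zero_noise_cohort(small_genome):
    """8-pair cohort with no noise anywhere: every estimate is exact."""
    layout, cn_probes, meth_probes, annotation = small_genome
    design = synthetic.CohortDesign(n_pairs=8, seed=7)
    cn, truth = synthetic.simulate_cna(
        design, layout, cn_probes, noise_sd=0.0, seed=7,
        n_recurrent_segments=1, recurrent_fraction=0.5,
        segment_length_range=(300_000, 900_000),
    )
    target = list(annotation["gene"].iloc[[3, 11]])
    meth, truth = synthetic.simulate_methylation(
        design, meth_probes, noise_sd=0.0, batch_shift=0.0, n_dmrs=4,
        dmr_pair_fraction=1.0, seed=7, truth=truth,
        annotation=annotation, target_genes=target,
    )
    expr, truth = synthetic.simulate_expression(
        design, annotation, truth, noise_sd=0.0, seed=7, cn_probes=cn_probes
    )
    return {
        "layout": layout,
        "cn_probes": cn_probes,
        "annotation": annotation,
        "design": design,
        "cn": cn,
        "meth": meth,
        "expr": expr,
        "truth": truth,
    }


def make_call(chrom="chr1", start=0, end=1_000_000, mean_log2=0.5, n_markers=100,
              state=None):
    seg = Segment(chrom=chrom, start=start, end=end, mean_log2=mean_log2,
                  n_markers=n_markers)
    return CNACall(segment=seg, state=state or ("gain" if mean_log2 > 0 else "loss"))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
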