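"""Shared fixtures: small synthetic genomes with planted ground truth."""

from __future__ import annotations

import pytest

from mitokit.synth import (
    GeneClusterPlan,
    MtptPlan,
    PlastomeConfig,
    RepeatPlan,
    SsrPlan,
    SynthConfig,
    generate_mitogenome,
    generate_plastome,
)


@pytest.fixture(scope="session")
def small_plastome():
    cfg = PlastomeConfig(
        lsc_length=20_000, ir_length=3_000, ssc_length=4_000, n_genes=8, seed=7
    )
    return generate_plastome(cfg)


@pytest.fixture(scope="session")
def small_mito(small_plastome):
    """3-isoform mitogenome with repeats of all three size classes, two
    MTPTs, SSRs and one gene cluster planted."""
    plastome, _ = small_plastome
    cfg = SynthConfig(
        n_isoforms=3,
        isoform_length_range=(40_000, 60_000),
        gc_target=0.44,
        repeat_plan=[
            RepeatPlan(50, 98.0),
            RepeatPlan(500, 97.0),
            RepeatPlan(5000, 99.0),
            RepeatPlan(300, 96.0, strand="-"),
        ],
        mtpt_plan=[MtptPlan(1500, 90.0), MtptPlan(400, 85.0)],
        ssr_plan=[SsrPlan("A", 10), SsrPlan("AT", 6), SsrPlan("AGC", 5)],
        gene_plan=[
            GeneClusterPlan((("nad3", 300), ("rps12", 360))),
            GeneClusterPlan((("rps3", 300), ("rpl16", 300), ("rpl2", 300))),
        ],
        seed=7,
    )
    return generate_mitogenome(cfg, plastome)
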