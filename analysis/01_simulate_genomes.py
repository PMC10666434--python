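#!/usr/bin/env python
"""Generate the synthetic study system: a donor plastome and two
multi-isoform mitogenomes with planted repeats, MTPTs, SSRs and gene
clusters.

Writes FASTA genomes, GFF3 gene annotations, and JSON truth tables under
results/synthetic/.  Every downstream analysis script reads these files,
so the whole analysis chain is reproducible from this single entry point.
"""

import dataclasses
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mitokit.genome_io import write_annotations_gff3, write_fasta
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

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"

# shared gene repertoire, arranged in clusters as in plant mitogenomes
CLUSTERS = [
    GeneClusterPlan((("rps3", 300), ("rpl16", 402), ("rpl2", 300), ("rps19", 309))),
    GeneClusterPlan((("nad3", 357), ("rps12", 378))),
    GeneClusterPlan((("atp8", 480), ("nad4L", 303), ("atp4", 594))),
    GeneClusterPlan((("atp9", 225), ("rps7", 447))),
    GeneClusterPlan((("rps14", 303), ("rpl5", 555))),
]


def mito_config(name: str, seed: int) -> SynthConfig:
    return SynthConfig(
        name=name,
        n_isoforms=4,
        isoform_length_range=(45_000, 70_000),
        gc_target=0.44,
        repeat_plan=[
            RepeatPlan(35, 100.0),
            RepeatPlan(60, 98.0),
            RepeatPlan(150, 96.0),
            RepeatPlan(450, 97.0, strand="-"),
            RepeatPlan(2500, 99.0),
        ],
        mtpt_plan=[MtptPlan(300, 85.0), MtptPlan(700, 88.0), MtptPlan(1500, 92.0)],
        ssr_plan=[
            SsrPlan("A", 10),
            SsrPlan("T", 9),
            SsrPlan("AT", 6),
            SsrPlan("AG", 5),
            SsrPlan("AAT", 5),
        ],
        gene_plan=CLUSTERS,
        seed=seed,
    )


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    plastome_cfg = PlastomeConfig(
        lsc_length=30_000, ir_length=5_000, ssc_length=6_000, n_genes=12, seed=11
    )
    plastome, p_truth = generate_plastome(plastome_cfg)
    write_fasta(plastome, OUT / "plastome.fa")
    write_annotations_gff3(p_truth.genes, OUT / "plastome_genes.gff3")

    truths = {"plastome_regions": p_truth.regions}
    for name, seed in (("mito_A", 11), ("mito_B", 12)):
        genome, truth = generate_mitogenome(mito_config(name, seed), plastome)
        write_fasta(genome, OUT / f"{name}.fa")
        write_annotations_gff3(truth.genes, OUT / f"{name}_genes.gff3")
        truths[name] = {
            "repeats": [dataclasses.asdict(r) for r in truth.repeats],
            "mtpts": [dataclasses.asdict(m) for m in truth.mtpts],
            "ssrs": [dataclasses.asdict(s) for s in truth.ssrs],
            "total_length": genome.total_length,
        }
        print(
            f"{name}: {len(genome)} isoforms, {genome.total_length:,} bp, "
            f"{len(truth.repeats)} repeat pairs, {len(truth.mtpts)} MTPTs, "
            f"{len(truth.ssrs)} SSRs planted"
        )
    with open(OUT / "truth.json", "w") as fh:
        json.dump(truths, fh, indent=2)
    print(f"plastome: {plastome.total_length:,} bp, regions {p_truth.regions}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
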