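"""Inter-genome similarity, gene clusters, codon statistics and ORFs."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .align import AlignmentHit, ScoringScheme, seed_extend_align
from .genome_io import (
    GeneFeature,
    OrganelleGenome,
    interval_union_length,
    merge_intervals,
    revcomp,
)

__all__ = [
    "SimilarityResult",
    "GeneCluster",
    "OrfFeature",
    "pairwise_similarity",
    "gene_clusters",
    "shared_clusters",
    "rscu",
    "codon_boundary_summary",
    "find_orfs",
]


@dataclass
class SimilarityResult:
    """Reciprocal shared-sequence fractions between two genomes.

    Coverage is computed on merged hit intervals so overlapping hits are
    never double-counted; fractions are coverage / genome length.
    """

    genome_a: str
    genome_b: str
    covered_bp_a: int
    fraction_a: float
    covered_bp_b: int
    fraction_b: float


def _coverage_of(
    query: OrganelleGenome,
    subject: OrganelleGenome,
    min_identity: float,
    max_evalue: float,
    k: int,
    scoring: ScoringScheme | None,
    hits: Sequence[AlignmentHit] | None,
) -> int:
    by_iso: dict[str, list[tuple[int, int]]] = {}
    if hits is None:
        for qi in query:
            for si in subject:
                for h in seed_extend_align(
                    qi.sequence,
                    si.sequence,
                    k=k,
                    min_len=20,
                    min_identity=min_identity,
                    max_evalue=max_evalue,
                    scoring=scoring,
                    query_id=qi.id,
                    subject_id=si.id,
                ):
                    by_iso.setdefault(qi.id, []).append(h.q_interval)
    else:
        for h in hits:
            if h.evalue < max_evalue:
                by_iso.setdefault(h.query_id, []).append(h.q_interval)
    return sum(interval_union_length(ivs) for ivs in by_iso.values())


def pairwise_similarity(
    genome_a: OrganelleGenome,
    genome_b: OrganelleGenome,
    max_evalue: float = 1e-5,
    min_identity: float = 70.0,
    k: int = 12,
    scoring: ScoringScheme | None = None,
    hits_ab: Sequence[AlignmentHit] | None = None,
    hits_ba: Sequence[AlignmentHit] | None = None,
) -> SimilarityResult:
    """Shared-sequence fraction between two genomes, both directions.

    All hits of A against B below the E-value threshold are projected onto
    A and unioned (redundancy exclusion); ``fraction_a`` is the covered
    fraction of A.  The computation is repeated with roles swapped for B.
    Externally computed hits (BLAST outfmt 6) can be supplied instead.
    """
    cov_a = _coverage_of(genome_a, genome_b, min_identity, max_evalue, k, scoring, hits_ab)
    cov_b = _coverage_of(genome_b, genome_a, min_identity, max_evalue, k, scoring, hits_ba)
    return SimilarityResult(
        genome_a.name,
        genome_b.name,
        cov_a,
        cov_a / genome_a.total_length,
        cov_b,
        cov_b / genome_b.total_length,
    )


# ---------------------------------------------------------------------------
# Gene clusters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneCluster:
    """Two or more consecutive genes on one isoform with small gaps."""

    genes: tuple[str, ...]
    isoform_id: str
    orientations: tuple[str, ...]
    start: int
    end: int


def gene_clusters(
    annotations: Sequence[GeneFeature],
    min_genes: int = 2,
    max_gap: int = 5000,
) -> list[GeneCluster]:
    """Maximal runs of consecutive genes whose intergenic gaps are
    <= ``max_gap``; singletons are excluded."""
    clusters: list[GeneCluster] = []
    by_iso: dict[str, list[GeneFeature]] = {}
    for f in annotations:
        by_iso.setdefault(f.isoform_id, []).append(f)
    for iso_id in sorted(by_iso):
        feats = sorted(by_iso[iso_id], key=lambda f: f.start)
        run: list[GeneFeature] = []
        for f in feats + [None]:
            if f is not None and (not run or f.start - run[-1].end <= max_gap):
                run.append(f)
                continue
            if len(run) >= min_genes:
                clusters.append(
                    GeneCluster(
                        tuple(g.gene_name for g in run),
                        iso_id,
                        tuple(g.strand for g in run),
                        run[0].start,
                        run[-1].end,
                    )
                )
            run = [f] if f is not None else []
    return clusters


def shared_clusters(
    clusters_a: Sequence[GeneCluster], clusters_b: Sequence[GeneCluster]
) -> list[tuple[GeneCluster, GeneCluster]]:
    """Clusters present in both genomes.

    Two clusters match when their ordered gene-name lists are identical or
    exactly reversed (orientation-insensitive); each cluster is matched at
    most once.
    """
    matched: list[tuple[GeneCluster, GeneCluster]] = []
    used_b: set[int] = set()
    for ca in clusters_a:
        for bi, cb in enumerate(clusters_b):
            if bi in used_b:
                continue
            if ca.genes == cb.genes or ca.genes == tuple(reversed(cb.genes)):
                matched.append((ca, cb))
                used_b.add(bi)
                break
    return matched


# ---------------------------------------------------------------------------
# Codon statistics
# ---------------------------------------------------------------------------


def _synonymous_families(table_id: int) -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return fams


def rscu(
    cds_sequences: dict[str, str] | Sequence[str],
    genetic_code: int = 1,
    include_stops: bool = False,
) -> pd.DataFrame:
    """Relative synonymous codon usage over a set of CDS sequences.

    For amino acid *a* with *k* synonymous codons, ``rscu(c) = count(c) × k
    / Σ counts`` over the family; uniform usage gives 1 for every codon and
    the family sum is always *k* when the family is observed at all.
    CDS with internal stop codons are skipped with a warning; amino acids
    never observed have NaN RSCU.
    """
    if not isinstance(cds_sequences, dict):
        cds_sequences = {f"cds{i+1}": s for i, s in enumerate(cds_sequences)}
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    counts: dict[str, int] = {}
    for name, seq in cds_sequences.items():
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            warnings.warn(f"CDS {name!r} length not divisible by 3; skipped")
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        body = codons[:-1] if codons and codons[-1] in table.stop_codons else codons
        if any(c in table.stop_codons for c in body):
            warnings.warn(f"CDS {name!r} has an internal stop codon; skipped")
            continue
        use = codons if include_stops else body
        for c in use:
            if set(c) <= set("ACGT"):
                counts[c] = counts.get(c, 0) + 1
    rows = []
    for aa, fam in sorted(_synonymous_families(genetic_code).items()):
        total = sum(counts.get(c, 0) for c in fam)
        k = len(fam)
        for codon in sorted(fam):
            cnt = counts.get(codon, 0)
            rows.append(
                {
                    "amino_acid": aa,
                    "codon": codon,
                    "count": cnt,
                    "rscu": (cnt * k / total) if total else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def codon_boundary_summary(cds_sequences: dict[str, str]) -> pd.DataFrame:
    """First and last codon of each CDS, with canonical-start/stop flags."""
    rows = []
    stops = CodonTable.unambiguous_dna_by_id[1].stop_codons
    for name, seq in cds_sequences.items():
        seq = seq.upper().replace("U", "T")
        start, stop = seq[:3], seq[-3:]
        rows.append(
            {
                "gene": name,
                "start_codon": start,
                "stop_codon": stop,
                "canonical_start": start == "ATG",
                "canonical_stop": stop in stops,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ORFs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrfFeature:
    """ATG..stop open reading frame; forward-strand half-open coordinates,
    length includes the stop codon."""

    isoform_id: str
    start: int
    end: int
    strand: str
    frame: int

    @property
    def length(self) -> int:
        return self.end - self.start


def _orfs_in_strand(seq: str, min_len: int) -> list[tuple[int, int, int]]:
    """(start, end, frame) of the longest ORF per stop per frame."""
    stops = {"TAA", "TGA", "TAG"}
    out = []
    n = len(seq)
    for frame in range(3):
        first_atg: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon == "ATG" and first_atg is None:
                first_atg = pos
            elif codon in stops:
                if first_atg is not None:
                    length = pos + 3 - first_atg
                    if length > min_len:
                        out.append((first_atg, pos + 3, frame))
                first_atg = None
    return out


def find_orfs(
    genome: OrganelleGenome | str, min_len: int = 300
) -> list[OrfFeature]:
    """ORFs longer than ``min_len`` bp on both strands of every isoform.

    An ORF starts at the first ATG after the previous in-frame stop and
    runs to the next stop (nested ORFs collapse to the longest per stop per
    frame).  Minus-strand ORFs are reported in forward coordinates.
    """
    if isinstance(genome, str):
        items = [("seq", genome)]
    else:
        items = [(iso.id, iso.sequence) for iso in genome]
    orfs: list[OrfFeature] = []
    for iso_id, seq in items:
        for s, e, frame in _orfs_in_strand(seq, min_len):
            orfs.append(OrfFeature(iso_id, s, e, "+", frame))
        rc = revcomp(seq)
        n = len(seq)
        for s, e, frame in _orfs_in_strand(rc, min_len):
            orfs.append(OrfFeature(iso_id, n - e, n - s, "-", frame))
    orfs.sort(key=lambda o: (o.isoform_id, o.start, o.strand))
    return orfs
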