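"""Phylogenomic supermatrix construction with foreign-sequence masking.

Whole-mitogenome matrices are built by concatenating externally produced
per-isoform multiple sequence alignments; a second matrix excludes
plastid-derived (cp-derived) sequence by excising the detected segments
from the genome before alignment.  Columns with more than 50% missing data
(gap or N) are removed, and blocks that are mostly missing can be dropped
outright.  Writers produce inference-ready FASTA, relaxed PHYLIP and NEXUS
(with partition charsets).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .cp_transfer import CpSegment
from .genome_io import IsoformRecord, OrganelleGenome, merge_intervals

__all__ = [
    "MsaBlock",
    "Supermatrix",
    "mask_cp_derived",
    "filter_columns",
    "build_supermatrix",
    "read_msa_fasta",
    "write_supermatrix_fasta",
    "write_supermatrix_phylip",
    "write_supermatrix_nexus",
    "robinson_foulds",
]

MISSING = set("-N")


@dataclass
class MsaBlock:
    """One aligned locus: equal-length rows over {A,C,G,T,N,-} per taxon."""

    locus_id: str
    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError(f"block {self.locus_id!r}: taxa/rows mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError(f"block {self.locus_id!r}: duplicate taxa")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"block {self.locus_id!r}: unequal row lengths")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def missing_fraction(self) -> float:
        if not self.rows or not self.width:
            return 1.0
        total = sum(sum(1 for c in row if c in MISSING) for row in self.rows)
        return total / (len(self.rows) * self.width)


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: list[str]
    partitions: dict[str, tuple[int, int]]

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0


def mask_cp_derived(
    genome: OrganelleGenome, cp_segments: Sequence[CpSegment]
) -> tuple[OrganelleGenome, dict[str, list[tuple[int, int, int]]]]:
    """Excise cp-derived intervals from every isoform.

    Returns the masked genome plus, per isoform, a list of
    ``(old_start, old_end, new_start)`` records for the retained stretches
    (the old→new coordinate map).  The total removed length equals the
    merged segment union.
    """
    by_iso: dict[str, list[tuple[int, int]]] = {}
    for seg in cp_segments:
        if seg.isoform_id not in genome:
            raise ValueError(f"segment references unknown isoform {seg.isoform_id!r}")
        if seg.end > genome[seg.isoform_id].length or seg.start < 0:
            raise ValueError(f"segment outside isoform {seg.isoform_id!r}")
        by_iso.setdefault(seg.isoform_id, []).append((seg.start, seg.end))
    new_isoforms: list[IsoformRecord] = []
    coord_map: dict[str, list[tuple[int, int, int]]] = {}
    for iso in genome:
        removed = merge_intervals(by_iso.get(iso.id, []))
        kept: list[tuple[int, int]] = []
        pos = 0
        for s, e in removed:
            if s > pos:
                kept.append((pos, s))
            pos = e
        if pos < iso.length:
            kept.append((pos, iso.length))
        parts = []
        mapping = []
        new_pos = 0
        for s, e in kept:
            parts.append(iso.sequence[s:e])
            mapping.append((s, e, new_pos))
            new_pos += e - s
        coord_map[iso.id] = mapping
        if parts:
            new_isoforms.append(IsoformRecord(iso.id, "".join(parts), iso.circular))
    return OrganelleGenome(genome.name + "_cp_masked", new_isoforms), coord_map


def filter_columns(msa: MsaBlock, max_missing: float = 0.5) -> MsaBlock:
    """Remove alignment columns whose gap+N fraction exceeds ``max_missing``.

    Row order is preserved; the operation is idempotent.  When every column
    is removed an empty block is returned with a warning.
    """
    if not msa.rows:
        return msa
    mat = np.array([list(r) for r in msa.rows])
    missing = np.isin(mat, ["-", "N"])
    frac = missing.mean(axis=0)
    keep = frac <= max_missing
    if not keep.any():
        import warnings

        warnings.warn(f"block {msa.locus_id!r}: all columns removed")
    rows = ["".join(row) for row in mat[:, keep]]
    return MsaBlock(msa.locus_id, list(msa.taxa), rows)


def build_supermatrix(
    blocks: Sequence[MsaBlock], taxa_order: Sequence[str]
) -> Supermatrix:
    """Concatenate aligned blocks into a supermatrix.

    Taxa missing from a block are filled with all-gap rows; the partition
    map records each locus's half-open column range.
    """
    seen = set()
    for b in blocks:
        if b.locus_id in seen:
            raise ValueError(f"duplicate locus id {b.locus_id!r}")
        seen.add(b.locus_id)
        unknown = set(b.taxa) - set(taxa_order)
        if unknown:
            raise ValueError(f"block {b.locus_id!r} has taxa outside taxa_order: {sorted(unknown)}")
    parts: dict[str, list[str]] = {t: [] for t in taxa_order}
    partitions: dict[str, tuple[int, int]] = {}
    col = 0
    for b in blocks:
        row_of = dict(zip(b.taxa, b.rows))
        for t in taxa_order:
            parts[t].append(row_of.get(t, "-" * b.width))
        partitions[b.locus_id] = (col, col + b.width)
        col += b.width
    return Supermatrix(list(taxa_order), ["".join(parts[t]) for t in taxa_order], partitions)


def assemble_matrix(
    blocks: Sequence[MsaBlock],
    taxa_order: Sequence[str],
    max_missing: float = 0.5,
    drop_sparse_blocks: bool = True,
) -> tuple[Supermatrix, list[str]]:
    """Full pipeline: drop blocks mostly missing, filter columns, concatenate.

    Returns the matrix and a log of dropped blocks / removed column counts.
    """
    log: list[str] = []
    kept: list[MsaBlock] = []
    for b in blocks:
        if drop_sparse_blocks and b.missing_fraction() > max_missing:
            log.append(f"dropped block {b.locus_id} (missing {b.missing_fraction():.2f})")
            continue
        fb = filter_columns(b, max_missing)
        if fb.width < b.width:
            log.append(f"block {b.locus_id}: removed {b.width - fb.width} columns")
        if fb.width:
            kept.append(fb)
    return build_supermatrix(kept, taxa_order), log


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_msa_fasta(path: str | Path, locus_id: str | None = None) -> MsaBlock:
    from Bio import SeqIO

    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq).upper())
    return MsaBlock(locus_id or Path(path).stem, taxa, rows)


def write_supermatrix_fasta(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for taxon, row in zip(sm.taxa, sm.rows):
            fh.write(f">{taxon}\n{row}\n")


def read_supermatrix_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    from Bio import SeqIO

    taxa, rows = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxa.append(rec.id)
        rows.append(str(rec.seq))
    return taxa, rows


def write_supermatrix_phylip(sm: Supermatrix, path: str | Path) -> None:
    """Relaxed PHYLIP: name, two spaces, sequence."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.width}\n")
        for taxon, row in zip(sm.taxa, sm.rows):
            fh.write(f"{taxon}  {row}\n")


def write_supermatrix_nexus(sm: Supermatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.width};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=N GAP=-;\n  MATRIX\n")
        for taxon, row in zip(sm.taxa, sm.rows):
            fh.write(f"    {taxon}  {row}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for locus, (s, e) in sm.partitions.items():
            fh.write(f"  CHARSET {locus} = {s+1}-{e};\n")
        fh.write("END;\n")


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unweighted Robinson–Foulds distance between two newick topologies
    (convenience utility for comparing inferred trees)."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(t1, t2))
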