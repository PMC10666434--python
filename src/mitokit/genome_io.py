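"""Reading, writing and coordinate bookkeeping for multi-isoform organelle genomes.

Plant mitochondrial genomes are frequently multipartite: the genome is an
ordered collection of independent circular- or linear-mapping molecules
("isoforms" or chromosomes) deposited as separate FASTA records.  This module
provides the in-memory containers for such genomes, annotation I/O, and the
concatenation / offset machinery that downstream binned analyses rely on.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open, on the forward strand.
GFF3 input/output is 1-based inclusive; BED output is 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = set("ACGTN")
# IUPAC ambiguity codes that may be normalized to N in lenient mode.
AMBIGUITY_CODES = set("RYSWKMBDHV")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class IsoformRecord:
    """One molecule (chromosome) of a multipartite organelle genome."""

    id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"isoform {self.id!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class OrganelleGenome:
    """An ordered set of named isoforms composing one organelle genome."""

    name: str
    isoforms: list[IsoformRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError(f"genome {self.name!r} has no isoforms")
        ids = [iso.id for iso in self.isoforms]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate isoform ids in genome {self.name!r}")
        self._by_id = {iso.id: iso for iso in self.isoforms}

    @property
    def total_length(self) -> int:
        return sum(iso.length for iso in self.isoforms)

    def __iter__(self):
        return iter(self.isoforms)

    def __len__(self) -> int:
        return len(self.isoforms)

    def __getitem__(self, isoform_id: str) -> IsoformRecord:
        return self._by_id[isoform_id]

    def __contains__(self, isoform_id: str) -> bool:
        return isoform_id in self._by_id


@dataclass(frozen=True)
class GeneFeature:
    """A gene-level feature on one isoform (0-based half-open coordinates)."""

    gene_name: str
    isoform_id: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "protein_coding"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.gene_name!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(f"feature {self.gene_name!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class OffsetMap:
    """Mapping between per-isoform and concatenated ("global") coordinates.

    ``offsets`` is an ordered list of ``(isoform_id, global_offset)`` pairs;
    the first offset is 0 and offsets increase strictly.
    """

    offsets: list[tuple[str, int]]
    total_length: int

    def __post_init__(self) -> None:
        if not self.offsets or self.offsets[0][1] != 0:
            raise ValueError("OffsetMap must start at offset 0")
        starts = [off for _, off in self.offsets]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("OffsetMap offsets must increase strictly")
        self._starts = np.asarray(starts, dtype=np.int64)

    def to_global(self, isoform_id: str, local: int) -> int:
        for iso, off in self.offsets:
            if iso == isoform_id:
                return off + local
        raise KeyError(isoform_id)

    def to_local(self, global_pos: int) -> tuple[str, int]:
        if not (0 <= global_pos < self.total_length):
            raise IndexError(f"global position {global_pos} out of range")
        idx = int(np.searchsorted(self._starts, global_pos, side="right")) - 1
        iso, off = self.offsets[idx]
        return iso, global_pos - off


def _clean_sequence(raw: str, record_id: str, ambiguous: str) -> str:
    seq = raw.upper()
    letters = set(seq)
    bad = letters - VALID_BASES
    if not bad:
        return seq
    if ambiguous == "strict":
        raise ValueError(
            f"record {record_id!r} contains non-ACGTN characters: {sorted(bad)}"
        )
    if ambiguous == "to_n":
        unknown = bad - AMBIGUITY_CODES - {"U"}
        if unknown:
            raise ValueError(
                f"record {record_id!r} contains non-nucleotide characters: {sorted(unknown)}"
            )
        table = {c: "N" for c in bad}
        table["U"] = "T"
        return seq.translate(str.maketrans(table))
    raise ValueError(f"unknown ambiguity policy {ambiguous!r}")


def read_fasta(
    path: str | Path | io.TextIOBase,
    name: str | None = None,
    circular: bool = True,
    ambiguous: str = "strict",
) -> OrganelleGenome:
    """Read a multi-record FASTA file as an :class:`OrganelleGenome`.

    Parameters
    ----------
    ambiguous
        ``"strict"`` rejects any character outside A/C/G/T/N; ``"to_n"``
        maps IUPAC ambiguity codes to N (and U to T).
    """
    records = list(SeqIO.parse(path, "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    seen: set[str] = set()
    isoforms = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA record id {rec.id!r}")
        seen.add(rec.id)
        isoforms.append(
            IsoformRecord(rec.id, _clean_sequence(str(rec.seq), rec.id, ambiguous), circular)
        )
    if name is None:
        name = Path(path).stem if isinstance(path, (str, Path)) else "genome"
    return OrganelleGenome(name, isoforms)


def write_fasta(genome: OrganelleGenome, path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(iso.sequence), id=iso.id, description="") for iso in genome
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_annotations(
    path: str | Path,
    fmt: str = "gff3",
    genome: OrganelleGenome | None = None,
) -> list[GeneFeature]:
    """Read gene features from GFF3 (1-based inclusive) or a 5-column TSV.

    TSV columns: gene, isoform, start, end, strand — start/end 1-based
    inclusive, matching the GFF3 convention so the two inputs are
    interchangeable.  If ``genome`` is given, features referencing unknown
    isoforms or exceeding isoform bounds raise.
    """
    feats: list[GeneFeature] = []
    kind_map = {
        "gene": "protein_coding",
        "cds": "protein_coding",
        "mrna": "protein_coding",
        "trna": "tRNA",
        "rrna": "rRNA",
        "orf": "orf",
    }
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if fmt == "gff3":
                if len(cols) < 9:
                    raise ValueError(f"{path}:{line_no}: GFF3 row with <9 columns")
                iso, source, ftype, start, end, _score, strand, _phase, attrs = cols[:9]
                if ftype.lower() not in kind_map:
                    continue
                kind = kind_map[ftype.lower()]
                name = _gff3_attr(attrs, ("Name", "gene", "ID")) or f"feature_{line_no}"
            elif fmt == "tsv":
                if len(cols) < 5:
                    raise ValueError(f"{path}:{line_no}: TSV row with <5 columns")
                name, iso, start, end, strand = cols[:5]
                kind = cols[5] if len(cols) > 5 else "protein_coding"
            else:
                raise ValueError(f"unknown annotation format {fmt!r}")
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{line_no}: end {end_i} < start {start_i}")
            feats.append(GeneFeature(name, iso, start_i - 1, end_i, strand, kind))
    if genome is not None:
        unknown = sorted({f.isoform_id for f in feats if f.isoform_id not in genome})
        if unknown:
            raise ValueError(f"features reference unknown isoforms: {unknown}")
        for f in feats:
            if f.end > genome[f.isoform_id].length:
                raise ValueError(
                    f"feature {f.gene_name!r} exceeds isoform {f.isoform_id!r} length"
                )
    feats.sort(key=lambda f: (f.isoform_id, f.start))
    return feats


def _gff3_attr(attrs: str, keys: Sequence[str]) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
    )
    for key in keys:
        if key in fields:
            return fields[key]
    return None


def write_annotations_gff3(
    features: Iterable[GeneFeature], path: str | Path, source: str = "mitokit"
) -> None:
    type_map = {"protein_coding": "gene", "tRNA": "tRNA", "rRNA": "rRNA", "orf": "orf"}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    [
                        f.isoform_id,
                        source,
                        type_map.get(f.kind, "gene"),
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"Name={f.gene_name}",
                    ]
                )
                + "\n"
            )


def concatenate_isoforms(genome: OrganelleGenome) -> tuple[str, OffsetMap]:
    """Join isoforms in order with no separator; return the offset map."""
    parts: list[str] = []
    offsets: list[tuple[str, int]] = []
    pos = 0
    for iso in genome:
        offsets.append((iso.id, pos))
        parts.append(iso.sequence)
        pos += iso.length
    return "".join(parts), OffsetMap(offsets, pos)


def gc_content(sequence: str, window: int | None = None):
    """GC fraction of a sequence, or per-window fractions.

    N bases are excluded from the denominator; a window composed entirely of
    N yields NaN.  With ``window`` set, non-overlapping windows are used and a
    trailing partial window is dropped.
    """
    if not sequence:
        raise ValueError("empty sequence")
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_n = arr == ord("N")
    if window is None:
        denom = len(arr) - int(is_n.sum())
        if denom == 0:
            return float("nan")
        return float(is_gc.sum()) / denom
    n_win = len(arr) // window
    gc = is_gc[: n_win * window].reshape(n_win, window).sum(axis=1).astype(float)
    nn = is_n[: n_win * window].reshape(n_win, window).sum(axis=1).astype(float)
    denom = window - nn
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, gc / denom, np.nan)
    return out


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, returned sorted and disjoint."""
    ivs = sorted((s, e) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def interval_union_length(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))
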