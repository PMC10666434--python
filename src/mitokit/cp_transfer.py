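"""Detection and analysis of plastid-derived sequences (MTPTs) in mitogenomes.

A mitochondrial segment is called chloroplast-derived when it aligns to the
donor plastome at >80% identity over >200 bp (E < 1e−5).  Overlapping or
adjacent hits on the mitochondrial side are merged into maximal segments.
Summaries follow the conventions of comparative organelle studies: a
length histogram over fixed bins, per-isoform counts, and a binned
correlation analysis in which the concatenated mitogenome is cut into
non-overlapping 3,000 bp bins and per-bin GC content, repeat counts and
MTPT counts are correlated (Pearson).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .align import AlignmentHit, ScoringScheme, seed_extend_align
from .genome_io import (
    GeneFeature,
    OffsetMap,
    OrganelleGenome,
    concatenate_isoforms,
    gc_content,
)

__all__ = [
    "CpSegment",
    "BinTable",
    "CorrelationReport",
    "detect_cp_segments",
    "annotate_intact_genes",
    "segment_summaries",
    "binned_feature_correlation",
]

DEFAULT_LENGTH_BINS = (200, 500, 1000, 1500, 3000)


@dataclass
class CpSegment:
    """A mitochondrial interval of plastid origin with its donor interval."""

    isoform_id: str
    start: int
    end: int
    plastome_start: int
    plastome_end: int
    strand: str
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start


def detect_cp_segments(
    mitogenome: OrganelleGenome,
    plastome: OrganelleGenome,
    min_identity: float = 80.0,
    min_len: int = 200,
    max_evalue: float = 1e-5,
    k: int = 11,
    merge_gap: int = 0,
    scoring: ScoringScheme | None = None,
    hits: Sequence[AlignmentHit] | None = None,
) -> list[CpSegment]:
    """Plastid-derived segments of the mitogenome.

    Each mitochondrial isoform is aligned against the plastome (both
    strands); hits passing the identity/length/E-value thresholds are
    merged on the mitochondrial side (segments closer than ``merge_gap``
    bp, default strict overlap/adjacency, become one segment).  A merged
    segment keeps the donor interval of its longest component and the
    length-weighted mean identity of its components.

    Pre-computed hits (e.g. read from BLAST ``-outfmt 6``) may be passed
    via ``hits``; their ``query_id`` must name mitochondrial isoforms.
    """
    plast_seq = plastome.isoforms[0].sequence
    if hits is None:
        hits = []
        for iso in mitogenome:
            hits.extend(
                seed_extend_align(
                    iso.sequence,
                    plast_seq,
                    k=k,
                    min_len=min_len,
                    min_identity=min_identity,
                    max_evalue=max_evalue,
                    scoring=scoring,
                    query_id=iso.id,
                    subject_id=plastome.name,
                )
            )
    kept = [
        h
        for h in hits
        if h.aligned_length > min_len and h.identity > min_identity and h.evalue < max_evalue
    ]
    by_iso: dict[str, list[AlignmentHit]] = {}
    for h in kept:
        by_iso.setdefault(h.query_id, []).append(h)
    segments: list[CpSegment] = []
    for iso_id in sorted(by_iso):
        group = sorted(by_iso[iso_id], key=lambda h: (h.q_start, h.q_end))
        cluster: list[AlignmentHit] = []
        for h in group + [None]:
            if h is not None and (
                not cluster or h.q_start <= cluster[-1].q_end + merge_gap
            ):
                cluster.append(h)
                continue
            if cluster:
                start = min(c.q_start for c in cluster)
                end = max(c.q_end for c in cluster)
                main = max(cluster, key=lambda c: c.aligned_length)
                w = sum(c.aligned_length for c in cluster)
                ident = sum(c.identity * c.aligned_length for c in cluster) / w
                segments.append(
                    CpSegment(
                        iso_id, start, end, main.s_start, main.s_end, main.strand, ident
                    )
                )
            if h is not None:
                cluster = [h]
    return segments


def total_cp_content(
    segments: Sequence[CpSegment], genome: OrganelleGenome
) -> tuple[int, float]:
    total = sum(s.length for s in segments)
    return total, total / genome.total_length


def annotate_intact_genes(
    segments: Sequence[CpSegment],
    plastome_annotations: Sequence[GeneFeature],
) -> tuple[dict[int, list[str]], dict[int, list[str]]]:
    """Plastid genes carried by each segment.

    A gene is *intact* in a segment when its full donor interval lies
    within the segment's plastome interval; genes overlapping the segment
    edge are listed separately as fragments.  Returns
    ``(intact, fragments)`` keyed by segment index.
    """
    intact: dict[int, list[str]] = {}
    fragments: dict[int, list[str]] = {}
    for idx, seg in enumerate(segments):
        ps, pe = seg.plastome_start, seg.plastome_end
        for gene in plastome_annotations:
            if gene.start >= ps and gene.end <= pe:
                intact.setdefault(idx, []).append(gene.gene_name)
            elif gene.start < pe and gene.end > ps:
                fragments.setdefault(idx, []).append(gene.gene_name)
    return intact, fragments


def segment_summaries(
    segments: Sequence[CpSegment],
    genome: OrganelleGenome,
    length_bins: Sequence[int] = DEFAULT_LENGTH_BINS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Length histogram and per-isoform counts of cp-derived segments.

    ``length_bins`` are ascending inner edges; the default bins are
    (200,500], (500,1000], (1000,1500], (1500,3000], >3000.
    """
    edges = list(length_bins) + [math.inf]
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{lo+1}-{hi}" if hi != math.inf else f">{lo}")
    counts = [0] * len(labels)
    for seg in segments:
        for b, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            if lo < seg.length <= hi:
                counts[b] += 1
                break
    hist = pd.DataFrame({"length_bin": labels, "n_segments": counts})
    per_iso = pd.DataFrame(
        {
            "isoform_id": [iso.id for iso in genome],
            "n_segments": [
                sum(1 for s in segments if s.isoform_id == iso.id) for iso in genome
            ],
        }
    )
    return hist, per_iso


@dataclass
class BinTable:
    """Per-bin GC, repeat count and cp-segment count over the concatenated
    genome (trailing partial bin dropped)."""

    table: pd.DataFrame  # columns: bin, global_start, gc, n_repeat, n_cp
    bin_size: int
    offset_map: OffsetMap = None


@dataclass
class CorrelationReport:
    r_cp_gc: float
    p_cp_gc: float
    r_cp_repeat: float
    p_cp_repeat: float
    n_bins: int
    diagnostics: list[str] = field(default_factory=list)


def _count_overlaps(bins_n: int, bin_size: int, intervals: list[tuple[int, int]], mode: str) -> np.ndarray:
    counts = np.zeros(bins_n, dtype=int)
    for s, e in intervals:
        if mode == "overlap":
            first = s // bin_size
            last = (e - 1) // bin_size
            for b in range(first, min(last, bins_n - 1) + 1):
                if b >= 0:
                    counts[b] += 1
        else:  # "start": count the feature in its start bin only
            b = s // bin_size
            if 0 <= b < bins_n:
                counts[b] += 1
    return counts


def build_bin_table(
    genome: OrganelleGenome,
    cp_segments: Sequence[CpSegment],
    repeat_intervals: dict[str, list[tuple[int, int]]],
    bin_size: int = 3000,
    count_mode: str = "overlap",
) -> BinTable:
    """Cut the concatenated genome into non-overlapping bins and count
    features per bin.

    ``count_mode="overlap"`` increments every bin a feature overlaps;
    ``"start"`` counts a feature only in the bin containing its start.
    """
    seq, omap = concatenate_isoforms(genome)
    n_bins = len(seq) // bin_size
    gc = gc_content(seq, window=bin_size)

    def to_global(iso_id: str, s: int, e: int) -> tuple[int, int]:
        off = omap.to_global(iso_id, 0)
        return off + s, off + e

    cp_iv = [to_global(s.isoform_id, s.start, s.end) for s in cp_segments]
    rep_iv = []
    for iso_id, ivs in repeat_intervals.items():
        L = genome[iso_id].length
        for s, e in ivs:
            rep_iv.append(to_global(iso_id, s, min(e, L)))
    table = pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "global_start": np.arange(n_bins) * bin_size,
            "gc": gc[:n_bins],
            "n_repeat": _count_overlaps(n_bins, bin_size, rep_iv, count_mode),
            "n_cp": _count_overlaps(n_bins, bin_size, cp_iv, count_mode),
        }
    )
    return BinTable(table, bin_size, omap)


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook two-pass Pearson correlation (oracle implementation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mx, my = x.mean(), y.mean()
    num = float(((x - mx) * (y - my)).sum())
    den = math.sqrt(float(((x - mx) ** 2).sum()) * float(((y - my) ** 2).sum()))
    return num / den if den else float("nan")


def binned_feature_correlation(
    genome: OrganelleGenome | Sequence[OrganelleGenome],
    cp_segments: Sequence[CpSegment] | Sequence[Sequence[CpSegment]],
    repeat_intervals: dict | Sequence[dict],
    bin_size: int = 3000,
    count_mode: str = "overlap",
) -> tuple[CorrelationReport, BinTable]:
    """Pearson correlation of per-bin MTPT counts against GC and repeats.

    Passing lists of genomes/segments/repeat-interval dicts pools the bins
    of several genomes into one correlation (pooling is explicit: a single
    genome is never pooled implicitly).
    """
    if isinstance(genome, OrganelleGenome):
        genomes = [genome]
        cp_sets = [cp_segments]
        rep_sets = [repeat_intervals]
    else:
        genomes = list(genome)
        cp_sets = list(cp_segments)
        rep_sets = list(repeat_intervals)
    tables = []
    for g, cps, reps in zip(genomes, cp_sets, rep_sets):
        tables.append(build_bin_table(g, cps, reps, bin_size, count_mode).table)
    table = pd.concat(tables, ignore_index=True)
    table = table.dropna(subset=["gc"])
    if len(table) < 3:
        raise ValueError(f"need at least 3 bins, got {len(table)}")
    diagnostics: list[str] = []

    def corr(a: str, b: str) -> tuple[float, float]:
        xa, xb = table[a].to_numpy(float), table[b].to_numpy(float)
        if np.allclose(xa.std(), 0) or np.allclose(xb.std(), 0):
            diagnostics.append(f"zero variance in {a if xa.std()==0 else b}")
            return float("nan"), float("nan")
        r, p = stats.pearsonr(xa, xb)
        return float(r), float(p)

    r1, p1 = corr("n_cp", "gc")
    r2, p2 = corr("n_cp", "n_repeat")
    report = CorrelationReport(r1, p1, r2, p2, len(table), diagnostics)
    bt = BinTable(table, bin_size)
    return report, bt
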