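"""Repeat-mediated recombination frequency from long reads.

For each dispersed repeat pair, the two genomic copies define two *original*
configurations: up to 2,000 bp of single-copy flank on each side of the
copy, plus the copy itself.  Exchange between the copies produces the two
*alternative* configurations, combining the left flank of one copy with the
right flank of the other.  Long reads are assigned to the configuration
they support — a read supports a configuration only if it spans the full
repeat copy plus a minimum anchor into both flanks at sufficient identity —
and the recombination frequency of the pair is

    n_alternative / (n_original + n_alternative)

Reads that tie between classes, cover only one flank, or align poorly are
counted as ambiguous and never enter the frequency.  Pairs whose repeat copy
is too long for any read to span are reported "unassessable" rather than
frequency 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import edlib

from .genome_io import OrganelleGenome, revcomp
from .repeats import RepeatPair, repeat_intervals

__all__ = [
    "RepeatConfiguration",
    "ReadSupport",
    "RecombinationResult",
    "build_configurations",
    "assign_reads",
    "recombination_frequency",
]


@dataclass
class RepeatConfiguration:
    """One flank-repeat-flank template (original or alternative)."""

    pair_id: str
    kind: str  # original_1 | original_2 | alt_1 | alt_2
    sequence: str
    left_len: int
    repeat_len: int
    right_len: int
    provenance: str = ""
    left_truncated: bool = False
    right_truncated: bool = False


@dataclass
class ReadSupport:
    pair_id: str
    n_original: int = 0
    n_alternative: int = 0
    n_ambiguous: int = 0


@dataclass
class RecombinationResult:
    pair_id: str
    frequency: float  # NaN when no informative reads
    support: ReadSupport
    status: str = "ok"  # ok | no_informative_reads | unassessable


def _extract_flanks(
    genome: OrganelleGenome,
    interval: tuple[str, int, int],
    flank: int,
    single_copy_mask: dict[str, list[tuple[int, int]]],
    own_intervals: list[tuple[str, int, int]],
) -> tuple[str, bool, str, str, bool]:
    """Left flank, left-truncated flag, repeat copy, right flank, right flag.

    Flanks are truncated at isoform ends (or wrapped when the isoform is
    circular) and shortened to the portion that is single-copy, i.e. not
    overlapping any *other* detected repeat interval.
    """
    iso_id, start, end = interval
    iso = genome[iso_id]
    L = iso.length
    if end - start > L:
        raise ValueError(f"repeat copy longer than isoform {iso_id}")
    seq2 = iso.sequence * 2 if iso.circular else iso.sequence

    def base_at(pos: int) -> int:
        return pos % L if iso.circular else pos

    # other repeat intervals on this isoform (exclude the pair's own copies)
    own = {(s, e) for i, s, e in own_intervals if i == iso_id}
    others = [
        (s, e)
        for (s, e) in single_copy_mask.get(iso_id, [])
        if (s, e) not in own
    ]

    def overlaps_other(pos: int) -> bool:
        p = base_at(pos)
        return any(s <= p < e for s, e in others)

    # left flank: walk outward from start
    left_limit = flank if iso.circular else min(flank, start)
    left_len = 0
    while left_len < left_limit and not overlaps_other(start - left_len - 1):
        left_len += 1
    left_trunc = left_len < flank
    if iso.circular:
        ls = (start - left_len) % L
        left_seq = seq2[ls : ls + left_len]
    else:
        left_seq = iso.sequence[start - left_len : start]

    repeat_seq = seq2[start:end] if end <= len(seq2) else iso.sequence[start:end]

    right_limit = flank if iso.circular else min(flank, L - end)
    right_len = 0
    while right_len < right_limit and not overlaps_other(end + right_len):
        right_len += 1
    right_trunc = right_len < flank
    rs = end % L if iso.circular else end
    right_seq = seq2[rs : rs + right_len]
    return left_seq, left_trunc, repeat_seq, right_seq, right_trunc


def build_configurations(
    pair: RepeatPair,
    genome: OrganelleGenome,
    detected_repeats: Sequence[RepeatPair],
    flank: int = 2000,
) -> list[RepeatConfiguration]:
    """The four flank configurations of a repeat pair.

    ``original_1/2`` keep each copy's own flanks; ``alt_1`` joins the left
    flank of copy A to the right flank of copy B (and ``alt_2`` vice versa),
    which is the molecule produced by recombination between the copies.
    The repeat sequence of copy A is used in ``alt_1`` and copy B's in
    ``alt_2`` (the copies are near-identical by construction).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    mask = repeat_intervals(detected_repeats)
    own = [pair.interval_a, pair.interval_b]
    la, lta, ra_seq, rra, rta = _extract_flanks(genome, pair.interval_a, flank, mask, own)
    lb, ltb, rb_seq, rrb, rtb = _extract_flanks(genome, pair.interval_b, flank, mask, own)
    rep_a = ra_seq
    rep_b = rb_seq if pair.strand == "+" else revcomp(rb_seq)
    # On a '-' pair, copy B's local left flank corresponds to copy A's right
    # side after reverse complementing; orient everything on copy A's strand.
    if pair.strand == "-":
        lb, rrb = revcomp(rrb), revcomp(lb)
        ltb, rtb = rtb, ltb
    pid = pair.pair_id
    return [
        RepeatConfiguration(pid, "original_1", la + rep_a + rra, len(la), len(rep_a), len(rra), "A-left|A|A-right", lta, rta),
        RepeatConfiguration(pid, "original_2", lb + rep_b + rrb, len(lb), len(rep_b), len(rrb), "B-left|B|B-right", ltb, rtb),
        RepeatConfiguration(pid, "alt_1", la + rep_a + rrb, len(la), len(rep_a), len(rrb), "A-left|A|B-right", lta, rtb),
        RepeatConfiguration(pid, "alt_2", lb + rep_b + rra, len(lb), len(rep_b), len(rra), "B-left|B|A-right", ltb, rta),
    ]


def _diagnostic_region(cfg: RepeatConfiguration, min_anchor: int) -> tuple[str, int, int]:
    """The repeat copy plus ``min_anchor`` bp into both flanks.

    Returns (sequence, effective left anchor, effective right anchor); the
    anchors shrink when a flank is shorter than ``min_anchor``.
    """
    a_left = min(min_anchor, cfg.left_len)
    a_right = min(min_anchor, cfg.right_len)
    s = cfg.left_len - a_left
    e = cfg.left_len + cfg.repeat_len + a_right
    return cfg.sequence[s:e], a_left, a_right


def assign_reads(
    reads: Sequence[tuple[str, str]],
    configurations: Sequence[RepeatConfiguration],
    min_anchor: int = 100,
    min_read_identity: float = 0.8,
) -> ReadSupport:
    """Count reads supporting each configuration class of one repeat pair.

    Each read (both orientations) is aligned against the diagnostic region
    of all four configurations with an edit-distance infix alignment.  A
    read supports the class of its best-scoring configuration when (i) the
    whole-region alignment identity is at least ``min_read_identity`` and
    (ii) both of the winning configuration's flank anchors are found in the
    read at that identity — i.e. the read spans the full repeat copy plus
    ``min_anchor`` bp into both flanks.  Reads whose best original-class
    and best alternative-class distances tie, or that fail the anchor or
    identity checks, are counted as ambiguous.
    """
    if len(configurations) != 4 or {c.kind for c in configurations} != {
        "original_1",
        "original_2",
        "alt_1",
        "alt_2",
    }:
        raise ValueError("need the four configurations original_1/2 and alt_1/2")
    support = ReadSupport(configurations[0].pair_id)
    regions = {}
    for cfg in configurations:
        regions[cfg.kind] = _diagnostic_region(cfg, min_anchor)
    for _rid, seq in reads:
        seqs = (seq, revcomp(seq))
        best: dict[str, tuple[int, str]] = {}
        for kind, (region, _al, _ar) in regions.items():
            for oriented in seqs:
                res = edlib.align(region, oriented, mode="HW", task="distance")
                d = res["editDistance"]
                if d >= 0 and (kind not in best or d < best[kind][0]):
                    best[kind] = (d, oriented)
        if not best:
            support.n_ambiguous += 1
            continue
        orig_d = min(
            (best[k][0] for k in ("original_1", "original_2") if k in best),
            default=math.inf,
        )
        alt_d = min(
            (best[k][0] for k in ("alt_1", "alt_2") if k in best), default=math.inf
        )
        if orig_d == alt_d:
            support.n_ambiguous += 1
            continue
        winner = "original" if orig_d < alt_d else "alternative"
        win_kinds = ("original_1", "original_2") if winner == "original" else ("alt_1", "alt_2")
        win_kind = min((k for k in win_kinds if k in best), key=lambda k: best[k][0])
        dist, oriented = best[win_kind]
        region, a_left, a_right = regions[win_kind]
        identity = 1.0 - dist / len(region)
        max_err = 1.0 - min_read_identity
        if identity < min_read_identity:
            support.n_ambiguous += 1
            continue
        # anchor verification: each flank anchor of the winning configuration
        # must itself be present in the read, so partially spanning reads
        # (whose missing tail the infix alignment absorbs as scattered gaps)
        # never count as support
        anchors_ok = True
        for probe in (region[:a_left], region[-a_right:] if a_right else ""):
            if not probe:
                continue
            pd = edlib.align(probe, oriented, mode="HW", task="distance")["editDistance"]
            if pd < 0 or pd > max_err * len(probe):
                anchors_ok = False
                break
        if not anchors_ok:
            support.n_ambiguous += 1
            continue
        if winner == "original":
            support.n_original += 1
        else:
            support.n_alternative += 1
    return support


def recombination_frequency(
    support: ReadSupport,
    configurations: Sequence[RepeatConfiguration] | None = None,
    max_read_length: int | None = None,
    min_anchor: int = 100,
) -> RecombinationResult:
    """Apply the alt / (orig + alt) formula to read-support counts.

    With zero informative reads the frequency is NaN (never 0); if the
    repeat copy is longer than the longest read minus both anchors, the
    pair is additionally flagged "unassessable".
    """
    if min(support.n_original, support.n_alternative, support.n_ambiguous) < 0:
        raise ValueError("negative support counts")
    denom = support.n_original + support.n_alternative
    if denom == 0:
        status = "no_informative_reads"
        if (
            configurations is not None
            and max_read_length is not None
            and configurations[0].repeat_len + 2 * min_anchor > max_read_length
        ):
            status = "unassessable"
        return RecombinationResult(support.pair_id, float("nan"), support, status)
    return RecombinationResult(
        support.pair_id, support.n_alternative / denom, support, "ok"
    )
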