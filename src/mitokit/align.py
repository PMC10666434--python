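"""Self-contained local alignment for homology search within and between genomes.

Two engines live here:

``local_align_exact``
    Optimal Smith–Waterman local alignment with affine gap penalties
    (quadratic DP, numba-compiled).  This is the exact reference used to
    validate the heuristic aligner and is practical up to a few kb.

``seed_extend_align``
    A BLASTN-style heuristic: exact k-mer seeds, chaining of seeds on a
    shared diagonal, and ungapped X-drop extension, with Karlin–Altschul
    E-values and identity/length filtering.  Both strands of the query are
    searched; hit coordinates are always reported on the forward strands
    with a strand flag.

A reader/writer for BLAST tabular output (``-outfmt 6``) allows hits from an
external BLASTN run to be substituted for the internal engine when exact
replication of accession-based numbers is wanted.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from numba import njit

from .genome_io import revcomp

__all__ = [
    "AlignmentHit",
    "ScoringScheme",
    "local_align_exact",
    "seed_extend_align",
    "evalue",
    "read_blast_tabular",
    "write_blast_tabular",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch scores and affine gap penalties (penalties positive).

    Defaults are megablast-like (+1/−2, gap open 2, extend 1).  ``karlin_lambda``
    and ``karlin_k`` calibrate the E-value; the defaults are the standard
    gapped-BLASTN constants for +1/−2 scoring.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 2
    gap_extend: int = 1
    karlin_lambda: float = 1.28
    karlin_k: float = 0.46

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("require match > 0 > mismatch")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")


@dataclass
class AlignmentHit:
    """One local alignment between query and subject.

    Coordinates are 0-based half-open on the *forward* strand of both
    sequences; ``strand`` is '−' when the reverse complement of the query
    aligns to the subject.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    aligned_length: int
    identity: float
    score: float
    evalue: float = 0.0

    @property
    def q_interval(self) -> tuple[int, int]:
        return (self.q_start, self.q_end)

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)


def evalue(score: float, m: int, n: int, scoring: ScoringScheme) -> float:
    """Karlin–Altschul expectation value ``K·m·n·exp(−λ·score)``.

    ``m`` and ``n`` are the (effective) lengths of the two sequences; no
    edge-effect length adjustment is applied.
    """
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    return scoring.karlin_k * m * n * math.exp(-scoring.karlin_lambda * score)


# ---------------------------------------------------------------------------
# Exact Smith–Waterman (affine gaps) — the validation oracle scale engine.
# ---------------------------------------------------------------------------

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Encode A,C,G,T→0..3 and anything else (N)→4."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True)
def _sw_fill(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), -(10**9), dtype=np.int32)
    F = np.full((n + 1, m + 1), -(10**9), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = E[i, j - 1] - gap_extend
            eo = H[i, j - 1] - gap_open - gap_extend
            if eo > e:
                e = eo
            E[i, j] = e
            f = F[i - 1, j] - gap_extend
            fo = H[i - 1, j] - gap_open - gap_extend
            if fo > f:
                f = fo
            F[i, j] = f
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    return H, E, F, best, bi, bj


def local_align_exact(
    a: str,
    b: str,
    scoring: ScoringScheme | None = None,
    query_id: str = "query",
    subject_id: str = "subject",
) -> AlignmentHit | None:
    """Optimal local alignment of two sequences (forward strands only).

    Returns ``None`` when the best local score is 0 (no alignment).  Among
    co-optimal end cells the one with smallest (q_end, s_end) is taken and
    the traceback prefers diagonal moves, which makes the result
    deterministic.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    scoring = scoring or ScoringScheme()
    ea, eb = encode_seq(a), encode_seq(b)
    H, E, F, best, bi, bj = _sw_fill(
        ea, eb, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
    )
    if best <= 0:
        return None
    # Traceback from (bi, bj); prefer diagonal, then vertical, then horizontal.
    i, j = bi, bj
    matches = 0
    cols = 0
    state = "H"
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            s = scoring.match if (ea[i - 1] == eb[j - 1] and ea[i - 1] < 4) else scoring.mismatch
            if i > 0 and j > 0 and H[i, j] == H[i - 1, j - 1] + s:
                cols += 1
                if ea[i - 1] == eb[j - 1] and ea[i - 1] < 4:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = "F"
            elif H[i, j] == E[i, j]:
                state = "E"
            else:  # pragma: no cover - defensive
                raise RuntimeError("traceback failed")
        elif state == "F":
            cols += 1
            if F[i, j] == H[i - 1, j] - scoring.gap_open - scoring.gap_extend:
                i -= 1
                state = "H"
            else:
                i -= 1
                state = "F"
        else:  # E
            cols += 1
            if E[i, j] == H[i, j - 1] - scoring.gap_open - scoring.gap_extend:
                j -= 1
                state = "H"
            else:
                j -= 1
                state = "E"
    q_start, s_start = i, j
    ev = evalue(best, len(a), len(b), scoring)
    return AlignmentHit(
        query_id,
        subject_id,
        q_start,
        bi,
        s_start,
        bj,
        "+",
        cols,
        100.0 * matches / cols if cols else 0.0,
        float(best),
        ev,
    )


# ---------------------------------------------------------------------------
# Heuristic seed-and-extend aligner.
# ---------------------------------------------------------------------------


def _kmer_index(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _extend_ungapped(
    qa: np.ndarray,
    sa: np.ndarray,
    q0: int,
    q1: int,
    s0: int,
    match: int,
    mismatch: int,
    xdrop: int,
) -> tuple[int, int, int]:
    """Extend [q0,q1) on the diagonal (s0 aligned with q0) in both directions.

    Returns (new_q0, new_q1, n_matches).  X-drop: extension in a direction
    stops once the running score falls ``xdrop`` below its maximum, and the
    end-point is trimmed back to the score maximum.
    """
    d = s0 - q0
    n, m = qa.shape[0], sa.shape[0]
    # right extension
    best_gain, gain, best_q1 = 0, 0, q1
    j = q1
    while j < n and j + d < m:
        gain += match if (qa[j] == sa[j + d] and qa[j] < 4) else mismatch
        j += 1
        if gain > best_gain:
            best_gain, best_q1 = gain, j
        elif gain < best_gain - xdrop:
            break
    q1 = best_q1
    # left extension
    best_gain, gain, best_q0 = 0, 0, q0
    j = q0 - 1
    while j >= 0 and j + d >= 0:
        gain += match if (qa[j] == sa[j + d] and qa[j] < 4) else mismatch
        if gain > best_gain:
            best_gain, best_q0 = gain, j
        elif gain < best_gain - xdrop:
            break
        j -= 1
    q0 = best_q0
    seg_q = qa[q0:q1]
    seg_s = sa[q0 + d : q1 + d]
    n_match = int(np.sum((seg_q == seg_s) & (seg_q < 4)))
    return q0, q1, n_match


def _trim_to_identity(
    qa: np.ndarray,
    sa: np.ndarray,
    q0: int,
    q1: int,
    d: int,
    min_identity: float,
    min_len: int,
    max_trim: int = 40,
):
    """Identity-compliant sub-segment obtained by end trimming only.

    Repeatedly removes the outermost mismatch (with its flanking tail) from
    whichever end restores identity more, breaking ties toward the shorter
    trim.  At most ``max_trim`` bp may be removed from each end — trimming
    repairs end dilution caused by score-positive chance extension into the
    flanks, but must not carve compliant windows out of a homology that is
    genuinely below the identity threshold.  Returns (None, None, None)
    when no such sub-segment of at least ``min_len`` exists.
    """
    seg_q = qa[q0:q1]
    seg_s = sa[q0 + d : q1 + d]
    mism = np.flatnonzero(~((seg_q == seg_s) & (seg_q < 4))) + q0
    mism_list = mism.tolist()
    lo, hi = q0, q1
    while hi - lo >= min_len:
        n_mis = sum(1 for m in mism_list if lo <= m < hi)
        length = hi - lo
        if 100.0 * (length - n_mis) / length >= min_identity:
            return lo, hi, length - n_mis
        inner = [m for m in mism_list if lo <= m < hi]
        if not inner:
            return None, None, None
        left_cut, right_cut = inner[0] + 1, inner[-1]
        # identity after each candidate trim
        def ident_after(new_lo: int, new_hi: int) -> float:
            L = new_hi - new_lo
            if L <= 0:
                return -1.0
            k = sum(1 for m in mism_list if new_lo <= m < new_hi)
            return (L - k) / L
        can_left = left_cut - q0 <= max_trim
        can_right = q1 - right_cut <= max_trim
        if not can_left and not can_right:
            return None, None, None
        i_left = ident_after(left_cut, hi) if can_left else -1.0
        i_right = ident_after(lo, right_cut) if can_right else -1.0
        if i_left > i_right or (
            i_left == i_right and left_cut - lo < hi - right_cut
        ):
            lo = left_cut
        else:
            hi = right_cut
    return None, None, None


def seed_extend_align(
    query: str,
    subject: str,
    k: int = 13,
    min_len: int = 20,
    min_identity: float = 95.0,
    max_evalue: float = 1e-5,
    scoring: ScoringScheme | None = None,
    both_strands: bool = True,
    seed_gap: int = 50,
    xdrop: int = 20,
    query_id: str = "query",
    subject_id: str = "subject",
) -> list[AlignmentHit]:
    """Find local alignments between ``query`` and ``subject``.

    Seeds are exact k-mer matches; seeds sharing a diagonal within
    ``seed_gap`` bp are chained, each chain is extended ungapped with an
    X-drop criterion, and the resulting segments are filtered by length,
    identity and E-value.  Overlapping segments on the same diagonal are
    merged before filtering, so each homologous region is reported once.
    """
    scoring = scoring or ScoringScheme()
    if not (9 <= k <= 15):
        raise ValueError("k must be in [9, 15]")
    index = _kmer_index(subject, k)
    sa = encode_seq(subject)
    hits: list[AlignmentHit] = []
    strands = ["+", "-"] if both_strands else ["+"]
    for strand in strands:
        q = query if strand == "+" else revcomp(query)
        qa = encode_seq(q)
        # collect seed matches grouped by diagonal d = s_pos − q_pos
        by_diag: dict[int, list[int]] = {}
        for i in range(len(q) - k + 1):
            kmer = q[i : i + k]
            positions = index.get(kmer)
            if not positions:
                continue
            for s_pos in positions:
                by_diag.setdefault(s_pos - i, []).append(i)
        for d, qpos_list in by_diag.items():
            qpos_list.sort()
            # chain seeds with gaps <= seed_gap into runs
            runs: list[tuple[int, int]] = []
            r0 = qpos_list[0]
            prev = qpos_list[0]
            for p in qpos_list[1:]:
                if p - prev > seed_gap:
                    runs.append((r0, prev + k))
                    r0 = p
                prev = p
            runs.append((r0, prev + k))
            segs: list[tuple[int, int, int]] = []
            for q0, q1 in runs:
                segs.append(
                    _extend_ungapped(
                        qa, sa, q0, q1, q0 + d, scoring.match, scoring.mismatch, xdrop
                    )
                )
            # merge overlapping extended segments on this diagonal
            segs.sort()
            merged: list[list[int]] = []
            for q0, q1, _nm in segs:
                if merged and q0 <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], q1)
                else:
                    merged.append([q0, q1])
            for q0, q1 in merged:
                length = q1 - q0
                if length < min_len:
                    continue
                seg_q = qa[q0:q1]
                seg_s = sa[q0 + d : q1 + d]
                n_match = int(np.sum((seg_q == seg_s) & (seg_q < 4)))
                ident = 100.0 * n_match / length
                if ident < min_identity:
                    # the score-optimal extension may dilute a borderline
                    # homology below the identity threshold; trim outermost
                    # mismatches (whichever trim restores identity more)
                    # until the segment complies or is too short
                    q0, q1, n_match = _trim_to_identity(
                        qa, sa, q0, q1, d, min_identity, min_len
                    )
                    if q0 is None:
                        continue
                    length = q1 - q0
                    ident = 100.0 * n_match / length
                score = n_match * scoring.match + (length - n_match) * scoring.mismatch
                ev = evalue(score, len(query), len(subject), scoring)
                if ev > max_evalue:
                    continue
                if strand == "+":
                    f_q0, f_q1 = q0, q1
                else:
                    f_q0, f_q1 = len(q) - q1, len(q) - q0
                hits.append(
                    AlignmentHit(
                        query_id,
                        subject_id,
                        f_q0,
                        f_q1,
                        q0 + d,
                        q1 + d,
                        strand,
                        length,
                        ident,
                        float(score),
                        ev,
                    )
                )
    hits.sort(key=lambda h: (h.q_start, h.s_start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# BLAST tabular (-outfmt 6) interchange.
# ---------------------------------------------------------------------------

_OUTFMT6_COLS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_blast_tabular(path: str | Path) -> list[AlignmentHit]:
    """Read BLAST ``-outfmt 6`` rows as :class:`AlignmentHit` objects.

    BLAST coordinates are 1-based inclusive with subject start > end on
    minus-strand hits; they are normalized to 0-based half-open forward
    coordinates with a strand flag.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            rec = dict(zip(_OUTFMT6_COLS, row))
            qs, qe = int(rec["qstart"]), int(rec["qend"])
            ss, se = int(rec["sstart"]), int(rec["send"])
            strand = "+"
            if ss > se:
                ss, se = se, ss
                strand = "-"
            if qs > qe:
                qs, qe = qe, qs
                strand = "-"
            hits.append(
                AlignmentHit(
                    rec["qseqid"],
                    rec["sseqid"],
                    qs - 1,
                    qe,
                    ss - 1,
                    se,
                    strand,
                    int(rec["length"]),
                    float(rec["pident"]),
                    float(rec["bitscore"]),
                    float(rec["evalue"]),
                )
            )
    return hits


def write_blast_tabular(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        for h in hits:
            mismatches = round(h.aligned_length * (1 - h.identity / 100.0))
            if h.strand == "+":
                ss, se = h.s_start + 1, h.s_end
            else:
                ss, se = h.s_end, h.s_start + 1
            writer.writerow(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.identity:.3f}",
                    h.aligned_length,
                    mismatches,
                    0,
                    h.q_start + 1,
                    h.q_end,
                    ss,
                    se,
                    f"{h.evalue:.2e}",
                    f"{h.score:.1f}",
                ]
            )
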