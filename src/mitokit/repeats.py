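"""Dispersed repeats, SSRs and plastome repeat types.

Dispersed repeats are found by aligning the genome against itself (all
isoform pairs, both strands) and keeping pairs above identity/length
thresholds; they are classified into short (<100 bp), intermediate
(100–1000 bp, boundaries inclusive) and large (>1000 bp) classes.
Non-redundant repeat content is the union of all repeat intervals.

SSRs are maximal perfect tandem runs of a 1–6 bp motif (mono-nucleotide
runs of >=8 copies, longer motifs >=5 copies), reported with the motif in
canonical form (lexicographically minimal rotation of the primitive motif).

Plastome repeats follow the REPuter typology: forward, reverse, complement
and palindromic copy pairs of equal length >=20 bp within Hamming
distance 3, each reported at maximal extension.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .align import AlignmentHit, ScoringScheme, seed_extend_align
from .genome_io import OrganelleGenome, interval_union_length, merge_intervals

__all__ = [
    "RepeatPair",
    "SSRLocus",
    "PlastomeRepeat",
    "classify_repeat",
    "find_dispersed_repeats",
    "deduplicate_repeat_content",
    "find_ssrs",
    "find_plastome_repeats",
]


@dataclass(frozen=True)
class RepeatPair:
    """Two near-identical genomic intervals forming one dispersed repeat."""

    interval_a: tuple[str, int, int]
    interval_b: tuple[str, int, int]
    identity: float
    length: int
    strand: str
    size_class: str

    @property
    def pair_id(self) -> str:
        a, b = self.interval_a, self.interval_b
        return f"{a[0]}:{a[1]}-{a[2]}|{b[0]}:{b[1]}-{b[2]}|{self.strand}"


@dataclass(frozen=True)
class SSRLocus:
    isoform_id: str
    start: int
    end: int
    motif: str
    repeat_count: int


@dataclass(frozen=True)
class PlastomeRepeat:
    type: str  # forward | reverse | complement | palindromic
    start_a: int
    start_b: int
    length: int
    hamming: int


def classify_repeat(length: int) -> str:
    """Size class of a repeat: <100 short, 100–1000 intermediate, >1000 large."""
    if length <= 20:
        raise ValueError(f"repeat length must exceed 20 bp, got {length}")
    if length < 100:
        return "short"
    if length <= 1000:
        return "intermediate"
    return "large"


def _canonical_pair(
    iso_a: str, qs: int, qe: int, iso_b: str, ss: int, se: int
) -> tuple[tuple[str, int, int], tuple[str, int, int], bool]:
    a = (iso_a, qs, qe)
    b = (iso_b, ss, se)
    if b < a:
        return b, a, True
    return a, b, False


def find_dispersed_repeats(
    genome: OrganelleGenome,
    min_len: int = 20,
    min_identity: float = 95.0,
    max_evalue: float = 1e-5,
    k: int = 13,
    scoring: ScoringScheme | None = None,
    honor_circularity: bool = True,
) -> list[RepeatPair]:
    """All-vs-all self alignment of the genome, reported as repeat pairs.

    Trivial full-length self-hits and mirror duplicates (a,b)/(b,a) are
    removed; of each mirror pair the copy with lexicographically smaller
    (isoform, start) is kept first.  For circular isoforms the search runs
    on the doubled sequence and hits are normalized back to [0, L), so
    repeats spanning the deposited origin are still found; hits that are
    mere rotations of an already-reported pair are dropped.
    """
    pairs: dict[tuple, RepeatPair] = {}
    isoforms = list(genome)
    for ai in range(len(isoforms)):
        for bi in range(ai, len(isoforms)):
            iso_a, iso_b = isoforms[ai], isoforms[bi]
            dbl_a = honor_circularity and iso_a.circular
            dbl_b = honor_circularity and iso_b.circular
            seq_a = iso_a.sequence * 2 if dbl_a else iso_a.sequence
            seq_b = iso_b.sequence * 2 if dbl_b else iso_b.sequence
            hits = seed_extend_align(
                seq_a,
                seq_b,
                k=k,
                min_len=min_len,
                min_identity=min_identity,
                max_evalue=max_evalue,
                scoring=scoring,
                query_id=iso_a.id,
                subject_id=iso_b.id,
            )
            la, lb = iso_a.length, iso_b.length
            for h in hits:
                qs, qe, ss, se = h.q_start, h.q_end, h.s_start, h.s_end
                if h.aligned_length <= min_len:
                    continue  # pair contract requires length strictly > 20
                if h.aligned_length > min(la, lb):
                    continue  # longer than a full isoform: doubling artifact
                # normalize starts into the primary copy
                if dbl_a and qs >= la:
                    qs, qe = qs - la, qe - la
                if dbl_b and ss >= lb:
                    ss, se = ss - lb, se - lb
                if iso_a.id == iso_b.id and h.strand == "+" and qs == ss and qe == se:
                    continue  # trivial self-hit
                if (
                    iso_a.id == iso_b.id
                    and h.strand == "+"
                    and (qs - ss) % la == 0
                    and (qe - se) % la == 0
                ):
                    continue  # rotation of the trivial self-hit on doubled sequence
                a, b, _swapped = _canonical_pair(iso_a.id, qs, qe, iso_b.id, ss, se)
                key = (a, b, h.strand)
                cand = RepeatPair(
                    a, b, h.identity, h.aligned_length, h.strand,
                    classify_repeat(h.aligned_length),
                )
                prev = pairs.get(key)
                if prev is None or cand.length > prev.length:
                    pairs[key] = cand
    out = sorted(pairs.values(), key=lambda p: (p.interval_a, p.interval_b, p.strand))
    return out


def repeat_intervals(
    pairs: Iterable[RepeatPair],
) -> dict[str, list[tuple[int, int]]]:
    """All repeat copy intervals grouped by isoform (not yet merged)."""
    by_iso: dict[str, list[tuple[int, int]]] = {}
    for p in pairs:
        for iso, s, e in (p.interval_a, p.interval_b):
            by_iso.setdefault(iso, []).append((s, e))
    return by_iso


def deduplicate_repeat_content(
    pairs: Sequence[RepeatPair], genome: OrganelleGenome
) -> tuple[dict[str, list[tuple[int, int]]], int, float]:
    """Project all repeat copies onto the genome and union the intervals.

    Returns (merged intervals per isoform, total union bp, fraction of the
    genome covered).  Intervals extending past an isoform end (origin-
    spanning hits from circular detection) are wrapped before the union.
    """
    by_iso: dict[str, list[tuple[int, int]]] = {}
    for iso_id, ivs in repeat_intervals(pairs).items():
        L = genome[iso_id].length
        flat: list[tuple[int, int]] = []
        for s, e in ivs:
            if e <= L:
                flat.append((s, e))
            else:  # wraps the origin
                flat.append((s, L))
                flat.append((0, e - L))
        by_iso[iso_id] = merge_intervals(flat)
    total = sum(interval_union_length(ivs) for ivs in by_iso.values())
    fraction = total / genome.total_length if genome.total_length else 0.0
    return by_iso, total, fraction


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------


def canonical_motif(motif: str) -> str:
    """Lexicographically minimal rotation of a motif."""
    doubled = motif + motif
    return min(doubled[i : i + len(motif)] for i in range(len(motif)))


def _is_primitive(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif[:d] * (m // d) == motif:
            return False
    return True


def _tandem_runs(seq: str, m: int) -> list[tuple[int, int]]:
    """Maximal tandem runs of period ``m``: (start, total_run_length)."""
    n = len(seq)
    if n < 2 * m:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    match = arr[:-m] == arr[m:]
    runs: list[tuple[int, int]] = []
    i = 0
    nm = len(match)
    idx = np.flatnonzero(np.diff(np.concatenate(([0], match.view(np.int8), [0]))))
    # idx pairs: starts at even positions, ends at odd
    for s, e in zip(idx[::2], idx[1::2]):
        runs.append((int(s), int(e - s) + m))
    return runs


def find_ssrs(
    genome: OrganelleGenome | str,
    mono_min: int = 8,
    poly_min: int = 5,
    max_motif: int = 6,
) -> list[SSRLocus]:
    """Maximal perfect SSR loci over motif lengths 1..max_motif.

    A locus must contain at least ``mono_min`` copies of a 1 bp motif or
    ``poly_min`` copies of a longer motif; only whole motif copies count
    (a trailing partial unit is not included).  Runs whose motif is itself
    periodic are found at the primitive period instead.  Overlapping
    candidates are resolved by keeping the longer locus (ties: smaller
    start, shorter motif).
    """
    if isinstance(genome, str):
        items = [("seq", genome)]
    else:
        items = [(iso.id, iso.sequence) for iso in genome]
    out: list[SSRLocus] = []
    for iso_id, seq in items:
        candidates: list[SSRLocus] = []
        for m in range(1, max_motif + 1):
            threshold = mono_min if m == 1 else poly_min
            for start, run_len in _tandem_runs(seq, m):
                count = run_len // m
                if count < threshold:
                    continue
                motif = seq[start : start + m]
                if "N" in motif:
                    continue
                if not _is_primitive(motif):
                    continue
                candidates.append(
                    SSRLocus(iso_id, start, start + count * m, canonical_motif(motif), count)
                )
        # non-overlap resolution: longest first
        candidates.sort(key=lambda c: (-(c.end - c.start), c.start, len(c.motif)))
        chosen: list[SSRLocus] = []
        for c in candidates:
            if all(c.end <= o.start or c.start >= o.end for o in chosen):
                chosen.append(c)
        out.extend(sorted(chosen, key=lambda c: c.start))
    return out


# ---------------------------------------------------------------------------
# Plastome repeats (REPuter typology)
# ---------------------------------------------------------------------------

_COMP = str.maketrans("ACGTN", "TGCAN")


def _maximal_windows(
    mism: np.ndarray, length: int, max_hamming: int, min_len: int
) -> list[tuple[int, int]]:
    """Maximal half-open windows of [0, length) containing <=max_hamming
    of the (sorted) mismatch positions ``mism``, at least ``min_len`` long.

    Each maximal window is bounded by the next excluded mismatch on either
    side (or the sequence end), so with m mismatches there are at most
    m − max_hamming + 1 of them; they are enumerated vectorized and only
    those long enough are materialized.
    """
    if len(mism) <= max_hamming:
        return [(0, length)] if length >= min_len else []
    q = np.empty(len(mism) + 2, dtype=np.int64)
    q[0] = -1
    q[1:-1] = mism
    q[-1] = length
    k = max_hamming
    starts = q[: len(mism) - k + 1] + 1
    ends = q[k + 1 :]
    keep = (ends - starts) >= min_len
    return list(zip(starts[keep].tolist(), ends[keep].tolist()))


def find_plastome_repeats(
    sequence: str,
    min_len: int = 20,
    max_hamming: int = 3,
    types: Sequence[str] = ("forward", "reverse", "complement", "palindromic"),
) -> list[PlastomeRepeat]:
    """All maximal equal-length substring pairs within Hamming distance
    ``max_hamming`` under the four orientation relations.

    Copy relations, for copies ``A = s[i:i+L]`` and ``B = s[j:j+L]``:
    forward ``B ≈ A``; reverse ``B ≈ A[::-1]``; complement ``B ≈ comp(A)``;
    palindromic ``B ≈ revcomp(A)``.  Each unordered copy pair is reported
    once with ``start_a <= start_b``; the pair with identical intervals is
    excluded.
    """
    n = len(sequence)
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    comp = np.frombuffer(sequence.translate(_COMP).encode("ascii"), dtype=np.uint8)
    out: set[PlastomeRepeat] = set()

    def emit(rtype: str, i: int, j: int, L: int, ham: int) -> None:
        if L < min_len or i == j:  # identical intervals excluded
            return
        a, b = (i, j) if i <= j else (j, i)
        out.add(PlastomeRepeat(rtype, a, b, L, ham))

    # forward & complement: compare arr with (arr|comp) shifted by d
    for rtype, target in (("forward", arr), ("complement", comp)):
        if rtype not in types:
            continue
        for d in range(1, n):
            a = arr[: n - d]
            b = target[d:]
            mism = np.flatnonzero(a != b)
            for w0, w1 in _maximal_windows(mism, n - d, max_hamming, min_len):
                L = w1 - w0
                ham = int(((mism >= w0) & (mism < w1)).sum())
                emit(rtype, w0, w0 + d, L, ham)

    # reverse & palindromic: compare arr with reversed(arr) / revcomp(arr)
    rev = arr[::-1].copy()
    rc = comp[::-1].copy()
    for rtype, target in (("reverse", rev), ("palindromic", rc)):
        if rtype not in types:
            continue
        # s[i+t] vs target[p+t] where target[p] = s'[n-1-p]; a diagonal match
        # of arr[a:b] with target[a+d:b+d] maps to the s-pair
        # (a, n-(b+d), L): copy B = s[n-b-d : n-a-d] read in reverse.
        for d in range(-(n - 1), n):
            lo = max(0, -d)
            hi = min(n, n - d)
            if hi - lo < min_len:
                continue
            a_seg = arr[lo:hi]
            b_seg = target[lo + d : hi + d]
            mism = np.flatnonzero(a_seg != b_seg)
            for w0, w1 in _maximal_windows(mism, hi - lo, max_hamming, min_len):
                L = w1 - w0
                i = lo + w0
                j = n - (lo + w1 + d)
                ham = int(((mism >= w0) & (mism < w1)).sum())
                if j < 0 or j + L > n:
                    continue
                if i == j:
                    continue
                emit(rtype, i, j, L, ham)

    return sorted(out, key=lambda r: (r.type, r.start_a, r.start_b, r.length))
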