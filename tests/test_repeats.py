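"""Dispersed repeats, SSRs and plastome repeat typology, with oracles."""

import numpy as np
import pytest

from mitokit.genome_io import IsoformRecord, OrganelleGenome, revcomp
from mitokit.repeats import (
    PlastomeRepeat,
    SSRLocus,
    canonical_motif,
    classify_repeat,
    deduplicate_repeat_content,
    find_dispersed_repeats,
    find_plastome_repeats,
    find_ssrs,
)
from mitokit.synth import RepeatPlan, SynthConfig, generate_mitogenome

# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_force_ssrs(seq, mono_min=8, poly_min=5, max_motif=6):
    """Position-by-position SSR scanner (no vectorization, no regex)."""
    candidates = []
    n = len(seq)
    for m in range(1, max_motif + 1):
        threshold = mono_min if m == 1 else poly_min
        i = 0
        while i + m <= n:
            # count consecutive copies of seq[i:i+m]
            count = 1
            while seq[i + count * m : i + (count + 1) * m] == seq[i : i + m]:
                count += 1
            if count >= threshold:
                motif = seq[i : i + m]
                primitive = all(
                    not (m % d == 0 and motif[:d] * (m // d) == motif)
                    for d in range(1, m)
                )
                # maximal: not a continuation of the same run
                left_extends = i >= m and seq[i - m : i] == motif
                if primitive and "N" not in motif and not left_extends:
                    candidates.append(
                        SSRLocus("seq", i, i + count * m, canonical_motif(motif), count)
                    )
                i += count * m
            else:
                i += 1
    candidates.sort(key=lambda c: (-(c.end - c.start), c.start, len(c.motif)))
    chosen = []
    for c in candidates:
        if all(c.end <= o.start or c.start >= o.end for o in chosen):
            chosen.append(c)
    return sorted(chosen, key=lambda c: c.start)


_ORIENT = {
    "forward": lambda s: s,
    "reverse": lambda s: s[::-1],
    "complement": lambda s: s.translate(str.maketrans("ACGT", "TGCA")),
    "palindromic": revcomp,
}


def _hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def _pair_valid(seq, rtype, i, j, L, max_h=3):
    if i < 0 or j < 0 or i + L > len(seq) or j + L > len(seq):
        return False
    return _hamming(seq[i : i + L], _ORIENT[rtype](seq[j : j + L])) <= max_h


def _pair_maximal(seq, rtype, i, j, L, max_h=3):
    """Direct check: valid, and every one-step outward extension invalid."""
    if not _pair_valid(seq, rtype, i, j, L, max_h):
        return False
    if rtype in ("forward", "complement"):
        ext = [(i, j, L + 1), (i - 1, j - 1, L + 1)]
    else:  # copy B read backwards: right extension grows B leftwards
        ext = [(i, j - 1, L + 1), (i - 1, j, L + 1)]
    return not any(_pair_valid(seq, rtype, *e, max_h) for e in ext)


def brute_force_plastome_repeats(seq, min_len=20, max_h=3):
    """Independent two-pointer enumeration over explicit copy-pair offsets."""
    n = len(seq)
    found = set()
    for rtype, transform in _ORIENT.items():
        t = transform(seq)  # full-sequence transform, compared directly
        # all window pairs correspond to diagonals of seq vs t
        for d in range(-(n - 1), n):
            lo, hi = max(0, -d), min(n, n - d)
            if hi - lo < min_len:
                continue
            mism = [p for p in range(lo, hi) if seq[p] != t[p + d]]
            # two-pointer over mismatch list
            bounds = [lo - 1] + mism + [hi]
            if len(mism) <= max_h:
                windows = [(lo, hi)]
            else:
                windows = [
                    (bounds[x] + 1, bounds[x + max_h + 1])
                    for x in range(len(mism) - max_h + 1)
                ]
            for w0, w1 in windows:
                L = w1 - w0
                if L < min_len:
                    continue
                ham = sum(1 for p in mism if w0 <= p < w1)
                if rtype in ("forward", "complement"):
                    i, j = w0, w0 + d
                else:
                    i, j = w0, n - (w1 + d)
                if i == j or j < 0 or j + L > n:
                    continue
                a, b = min(i, j), max(i, j)
                found.add(PlastomeRepeat(rtype, a, b, L, ham))
    return found


# ---------------------------------------------------------------------------
# Tests
# ---------------------------------------------------------------------------


class TestClassify:
    @pytest.mark.parametrize(
        "length,expected",
        [(21, "short"), (99, "short"), (100, "intermediate"), (1000, "intermediate"), (1001, "large"), (5000, "large")],
    )
    def test_boundaries(self, length, expected):
        assert classify_repeat(length) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            classify_repeat(20)


class TestDispersedRepeats:
    def test_planted_pairs_detected_with_classes(self, small_mito):
        genome, truth = small_mito
        pairs = find_dispersed_repeats(genome)
        assert len(pairs) == len(truth.repeats)
        detected = {(p.interval_a, p.interval_b) for p in pairs}
        for rp in truth.repeats:
            a, b = sorted([rp.interval_a, rp.interval_b])
            match = [
                p
                for p in pairs
                if abs(p.interval_a[1] - a[1]) <= 13 and p.interval_a[0] == a[0]
            ]
            assert match, f"planted repeat {a} not detected"
            p = match[0]
            assert abs(p.identity - rp.identity) <= 1.0
            assert p.strand == rp.strand
        classes = sorted(p.size_class for p in pairs)
        assert classes == ["intermediate", "intermediate", "large", "short"]

    def test_low_identity_repeat_not_reported(self):
        cfg = SynthConfig(
            n_isoforms=2,
            isoform_length_range=(30_000, 40_000),
            repeat_plan=[RepeatPlan(500, 90.0)],
            seed=13,
        )
        g, _ = generate_mitogenome(cfg)
        assert find_dispersed_repeats(g, min_identity=95) == []

    def test_origin_spanning_repeat_found_on_circular_isoform(self):
        rng = np.random.default_rng(21)
        motif = "".join(rng.choice(list("ACGT"), 60))
        s = list("".join(rng.choice(list("ACGT"), 1000)))
        s[970:] = motif[:30]
        s[:30] = motif[30:]
        s[400:460] = motif
        seq = "".join(s)
        g = OrganelleGenome("c", [IsoformRecord("iso1", seq, circular=True)])
        pairs = find_dispersed_repeats(g, min_len=30, k=13)
        assert any(p.length >= 55 for p in pairs)
        g_lin = OrganelleGenome("l", [IsoformRecord("iso1", seq, circular=False)])
        pairs_lin = find_dispersed_repeats(g_lin, min_len=30, k=13)
        assert all(p.length < 55 for p in pairs_lin)

    def test_recovery_and_identity_on_seeded_genomes(self):
        for seed in (101, 102, 103):
            cfg = SynthConfig(
                n_isoforms=2,
                isoform_length_range=(25_000, 35_000),
                repeat_plan=[RepeatPlan(40, 97.5), RepeatPlan(250, 96.0), RepeatPlan(1500, 99.0)],
                seed=seed,
            )
            g, truth = generate_mitogenome(cfg)
            pairs = find_dispersed_repeats(g)
            for rp in truth.repeats:
                a, _b = sorted([rp.interval_a, rp.interval_b])
                match = [
                    p
                    for p in pairs
                    if p.interval_a[0] == a[0] and abs(p.interval_a[1] - a[1]) <= 13
                ]
                assert match, f"seed {seed}: planted {a} missed"
                assert abs(match[0].identity - rp.identity) <= 1.0


class TestDeduplicate:
    def test_overlap_counted_once(self, small_mito):
        genome, _ = small_mito
        pairs = find_dispersed_repeats(genome)
        _, total, fraction = deduplicate_repeat_content(pairs, genome)
        gross = sum(p.length * 2 for p in pairs)
        assert 0 < total <= gross
        assert fraction == pytest.approx(total / genome.total_length)

    def test_no_repeats_empty_result(self):
        g = OrganelleGenome("e", [IsoformRecord("i", "ACGT" * 100)])
        ivs, total, fraction = deduplicate_repeat_content([], g)
        assert ivs == {} and total == 0 and fraction == 0.0

    def test_manual_overlap_union(self):
        from mitokit.repeats import RepeatPair

        g = OrganelleGenome("m", [IsoformRecord("i", "A" * 10_000, circular=False)])
        pairs = [
            RepeatPair(("i", 100, 400), ("i", 5000, 5300), 99.0, 300, "+", "intermediate"),
            RepeatPair(("i", 300, 600), ("i", 7000, 7300), 99.0, 300, "+", "intermediate"),
        ]
        _, total, _ = deduplicate_repeat_content(pairs, g)
        # [100,600) union + two disjoint 300 bp copies
        assert total == 500 + 300 + 300


class TestSsrs:
    def test_mono_run_at_threshold(self):
        seq = "GCTGTC" + "A" * 8 + "CGTGCT"
        [locus] = find_ssrs(seq)
        assert (locus.motif, locus.repeat_count, locus.start) == ("A", 8, 6)

    def test_dinucleotide_run(self):
        seq = "GGC" + "AT" * 5 + "CCG"
        [locus] = find_ssrs(seq)
        assert (locus.motif, locus.repeat_count) == ("AT", 5)

    def test_below_threshold_ignored(self):
        assert find_ssrs("GCT" + "A" * 7 + "CTG") == []
        assert find_ssrs("GGC" + "AT" * 4 + "CCG") == []

    def test_canonical_motif_is_minimal_rotation(self):
        assert canonical_motif("TA") == "AT"
        assert canonical_motif("GCA") == "AGC"
        seq = "GG" + "TA" * 6 + "GG"  # TATATA... = (AT) rotated
        [locus] = find_ssrs(seq)
        assert locus.motif == "AT"

    def test_periodic_motif_collapsed_to_primitive(self):
        seq = "GC" + "AT" * 8 + "GC"
        loci = find_ssrs(seq)
        assert len(loci) == 1 and loci[0].motif == "AT" and loci[0].repeat_count == 8

    def test_matches_brute_force_scanner_on_random_strings(self):
        rng = np.random.default_rng(31)
        for trial in range(8):
            # low-complexity alphabet mix makes SSRs actually occur
            probs = [0.4, 0.3, 0.2, 0.1] if trial % 2 else [0.25] * 4
            seq = "".join(rng.choice(list("ACGT"), size=10_000, p=probs))
            got = find_ssrs(seq)
            expected = brute_force_ssrs(seq)
            assert got == expected, f"trial {trial}"

    def test_planted_ssrs_recovered(self, small_mito):
        genome, truth = small_mito
        found = {
            (s.isoform_id, s.start, s.motif, s.repeat_count) for s in find_ssrs(genome)
        }
        for s in truth.ssrs:
            assert (s.isoform_id, s.start, canonical_motif(s.motif), s.repeat_count) in found


class TestPlastomeRepeats:
    def test_planted_exact_forward_duplicate(self):
        rng = np.random.default_rng(41)
        motif = "".join(rng.choice(list("ACGT"), 30))
        bg = "".join(rng.choice(list("ACGT"), 2_000))
        seq = bg[:500] + motif + bg[500:1500] + motif + bg[1500:]
        reps = [r for r in find_plastome_repeats(seq, types=("forward",)) if r.length >= 30]
        assert any(r.start_a <= 500 <= r.start_a + 5 and r.length >= 30 for r in reps)

    def test_planted_revcomp_copy_is_palindromic(self):
        rng = np.random.default_rng(42)
        motif = "".join(rng.choice(list("ACGT"), 30))
        bg = "".join(rng.choice(list("ACGT"), 2_000))
        seq = bg[:500] + motif + bg[500:1500] + revcomp(motif) + bg[1500:]
        reps = [r for r in find_plastome_repeats(seq) if r.length >= 30]
        assert any(r.type == "palindromic" for r in reps)

    def test_matches_brute_force_all_pairs_scan(self):
        rng = np.random.default_rng(43)
        m1 = "".join(rng.choice(list("ACGT"), 40))
        m2 = "".join(rng.choice(list("ACGT"), 25))
        bg = "".join(rng.choice(list("ACGT"), 1_200))
        seq = (
            bg[:200] + m1 + bg[200:400] + m1 + bg[400:600] + revcomp(m2)
            + bg[600:800] + m2 + bg[800:1000] + m1[::-1] + bg[1000:]
        )
        got = set(find_plastome_repeats(seq))
        expected = brute_force_plastome_repeats(seq)
        assert got == expected
        # every reported pair is directly verified maximal
        for r in got:
            i, j = (r.start_a, r.start_b)
            ok = _pair_maximal(seq, r.type, i, j, r.length) or _pair_maximal(
                seq, r.type, j, i, r.length
            )
            assert ok, r
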