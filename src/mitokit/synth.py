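"""Synthetic multipartite organelle genomes and long reads with planted truth.

The generator emulates the structure of multipartite plant mitogenomes:
several circular isoforms of unequal length with a GC content around 44%,
dispersed repeat pairs in three size classes planted at controlled identity,
plastid-derived insertions (MTPTs) copied from a generated quadripartite
plastome, SSR loci, and clustered gene features.  Nanopore-like long reads
can be simulated from the genome or from repeat "configuration" templates
with a controllable fraction of repeat-recombinant molecules.

Identity of planted repeats and MTPTs is controlled by substitutions only,
so the realized identity equals the Hamming identity exactly; indels are
introduced only by the read simulator.  A single NumPy generator seeded from
the config drives every random choice, so a fixed seed yields byte-identical
output.

Default genome parameters mirror the organelle genomes this pipeline is
aimed at: 22 isoforms of 20,401–124,954 bp at GC 0.44 for the mitogenome,
and a plastome of LSC 84,962 / IR 26,128 / SSC 14,001 bp at GC 0.3752.
Tests and the bundled analyses run reduced sizes, passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genome_io import (
    GeneFeature,
    IsoformRecord,
    OrganelleGenome,
    revcomp,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_STOPS = {"TAA", "TGA", "TAG"}


@dataclass(frozen=True)
class RepeatPlan:
    """One dispersed repeat pair to plant: both copies of ``length`` bp, the
    second mutated to ``identity`` percent; ``strand`` '−' plants the second
    copy reverse-complemented."""

    length: int
    identity: float
    strand: str = "+"


@dataclass(frozen=True)
class MtptPlan:
    """One plastid-derived insertion: ``length`` bp copied from the donor
    plastome and mutated to ``identity`` percent.  ``donor_start`` pins the
    donor window (otherwise random); ``isoform_index`` pins the receiving
    isoform."""

    length: int
    identity: float
    donor_start: int | None = None
    isoform_index: int | None = None


@dataclass(frozen=True)
class SsrPlan:
    motif: str
    repeat_count: int


@dataclass(frozen=True)
class GeneClusterPlan:
    """A run of adjacent genes planted consecutively on one isoform.

    ``genes`` is a list of (name, cds_length) with cds_length divisible by 3.
    """

    genes: tuple[tuple[str, int], ...]
    max_intergenic_gap: int = 800


@dataclass
class SynthConfig:
    n_isoforms: int = 22
    isoform_length_range: tuple[int, int] = (20_401, 124_954)
    gc_target: float = 0.44
    repeat_plan: Sequence[RepeatPlan] = field(default_factory=tuple)
    mtpt_plan: Sequence[MtptPlan] = field(default_factory=tuple)
    ssr_plan: Sequence[SsrPlan] = field(default_factory=tuple)
    gene_plan: Sequence[GeneClusterPlan] = field(default_factory=tuple)
    seed: int = 0
    name: str = "synthetic_mito"
    feature_margin: int = 60  # clearance kept around planted features

    def __post_init__(self) -> None:
        if self.n_isoforms < 1:
            raise ValueError("need at least one isoform")
        lo, hi = self.isoform_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad isoform length range")
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must be in (0,1)")
        for rp in self.repeat_plan:
            if rp.length <= 0 or not (0 < rp.identity <= 100):
                raise ValueError(f"bad repeat plan {rp}")
        for mp in self.mtpt_plan:
            if mp.length <= 0 or not (0 < mp.identity <= 100):
                raise ValueError(f"bad MTPT plan {mp}")


@dataclass
class PlastomeConfig:
    lsc_length: int = 84_962
    ir_length: int = 26_128
    ssc_length: int = 14_001
    gc_target: float = 0.3752
    n_genes: int = 20
    gene_length_range: tuple[int, int] = (300, 1500)
    seed: int = 0
    name: str = "synthetic_plastome"


@dataclass(frozen=True)
class PlantedRepeat:
    interval_a: tuple[str, int, int]
    interval_b: tuple[str, int, int]
    identity: float
    length: int
    strand: str


@dataclass(frozen=True)
class PlantedMtpt:
    isoform_id: str
    start: int
    end: int
    donor_start: int
    donor_end: int
    identity: float


@dataclass(frozen=True)
class PlantedSsr:
    isoform_id: str
    start: int
    end: int
    motif: str
    repeat_count: int


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    label: str  # "original" or "alternative"
    template_id: str
    start: int
    length: int
    strand: str


@dataclass
class TruthSet:
    """Ground truth for everything planted by the generator."""

    repeats: list[PlantedRepeat] = field(default_factory=list)
    mtpts: list[PlantedMtpt] = field(default_factory=list)
    ssrs: list[PlantedSsr] = field(default_factory=list)
    genes: list[GeneFeature] = field(default_factory=list)
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    reads: list[ReadTruth] = field(default_factory=list)


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return BASES[rng.choice(4, size=n, p=p)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def _mutate_to_identity(
    rng: np.random.Generator, seq: np.ndarray, identity: float
) -> tuple[np.ndarray, float]:
    """Substitute bases so the copy has exactly round((1−id)·L) mismatches.

    Substitution sites avoid the outermost bases of the copy when possible,
    so the planted feature's boundaries — and hence its Hamming identity —
    coincide with what an end-trimming aligner reports.
    """
    L = len(seq)
    n_sub = int(round((1 - identity / 100.0) * L))
    out = seq.copy()
    if n_sub:
        margin = max(3, round(0.05 * L))
        if L - 2 * margin < n_sub:
            margin = 0
        pos = margin + rng.choice(L - 2 * margin, size=n_sub, replace=False)
        for p in pos:
            choices = BASES[BASES != out[p]]
            out[p] = choices[rng.integers(len(choices))]
    realized = 100.0 * (len(seq) - n_sub) / len(seq)
    return out, realized


class _Placer:
    """Tracks occupied intervals per isoform and draws free placements."""

    def __init__(self, lengths: list[int], margin: int, rng: np.random.Generator):
        self.lengths = lengths
        self.margin = margin
        self.rng = rng
        self.occupied: list[list[tuple[int, int]]] = [[] for _ in lengths]

    def reserve(self, iso: int, start: int, end: int) -> None:
        self.occupied[iso].append((start - self.margin, end + self.margin))

    def _is_free(self, iso: int, start: int, end: int) -> bool:
        return all(e <= start or s >= end for s, e in self.occupied[iso])

    def place(self, length: int, iso: int | None = None, tries: int = 400) -> tuple[int, int]:
        candidates = range(len(self.lengths)) if iso is None else [iso]
        for _ in range(tries):
            i = int(self.rng.choice(list(candidates)))
            if self.lengths[i] < length + 2 * self.margin:
                continue
            start = int(self.rng.integers(self.margin, self.lengths[i] - length - self.margin))
            if self._is_free(i, start, start + length):
                self.reserve(i, start, start + length)
                return i, start
        raise ValueError(
            f"could not place a {length} bp feature; plan exceeds isoform capacity"
        )


def _random_cds(rng: np.random.Generator, length: int) -> str:
    """A CDS of ``length`` bp: ATG + random non-stop codons + random stop."""
    if length % 3 or length < 9:
        raise ValueError("CDS length must be a multiple of 3 and >= 9")
    codons = ["ATG"]
    while len(codons) < length // 3 - 1:
        c = _to_str(BASES[rng.integers(0, 4, size=3)])
        if c not in _STOPS:
            codons.append(c)
    codons.append(["TAA", "TGA", "TAG"][int(rng.integers(3))])
    return "".join(codons)


def generate_plastome(config: PlastomeConfig) -> tuple[OrganelleGenome, TruthSet]:
    """A quadripartite plastome: LSC + IR_A + SSC + IR_B, IR_B = revcomp(IR_A).

    Gene features (for intact-gene annotation tests) are planted in the LSC
    at recorded positions; truth records the four region intervals.
    """
    # distinct stream per generator kind, so a mitogenome and a plastome
    # built from the same seed are statistically independent sequences
    rng = np.random.default_rng([config.seed, 17])
    lsc = _random_bases(rng, config.lsc_length, config.gc_target)
    ira = _random_bases(rng, config.ir_length, config.gc_target)
    ssc = _random_bases(rng, config.ssc_length, config.gc_target)
    truth = TruthSet()
    # plant genes in the LSC, evenly spread
    genes: list[GeneFeature] = []
    if config.n_genes:
        slot = config.lsc_length // config.n_genes
        for g in range(config.n_genes):
            lo, hi = config.gene_length_range
            glen = int(rng.integers(lo // 3, hi // 3 + 1)) * 3
            glen = max(glen, 9)
            start = g * slot + int(rng.integers(0, max(1, slot - glen)))
            if start + glen > config.lsc_length:
                continue
            cds = np.frombuffer(_random_cds(rng, glen).encode(), dtype=np.uint8)
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "-":
                cds = np.frombuffer(revcomp(_to_str(cds)).encode(), dtype=np.uint8)
            lsc[start : start + glen] = cds
            genes.append(GeneFeature(f"cpgene{g+1:02d}", "plastome", start, start + glen, strand))
    seq = _to_str(lsc) + _to_str(ira) + _to_str(ssc) + revcomp(_to_str(ira))
    a = config.lsc_length
    b = a + config.ir_length
    c = b + config.ssc_length
    truth.regions = {
        "LSC": (0, a),
        "IR_A": (a, b),
        "SSC": (b, c),
        "IR_B": (c, c + config.ir_length),
    }
    truth.genes = genes
    genome = OrganelleGenome(config.name, [IsoformRecord("plastome", seq, circular=True)])
    return genome, truth


def generate_mitogenome(
    config: SynthConfig,
    plastome: OrganelleGenome | None = None,
) -> tuple[OrganelleGenome, TruthSet]:
    """Generate a multi-isoform mitogenome with planted features.

    If the plan contains MTPT insertions and no ``plastome`` is supplied,
    a donor plastome is generated with the same seed.
    """
    rng = np.random.default_rng([config.seed, 29])
    lo, hi = config.isoform_length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_isoforms)]
    planned = sum(rp.length * 2 for rp in config.repeat_plan)
    planned += sum(mp.length for mp in config.mtpt_plan)
    planned += sum(len(sp.motif) * sp.repeat_count for sp in config.ssr_plan)
    planned += sum(sum(l for _, l in gp.genes) for gp in config.gene_plan)
    if planned > 0.5 * sum(lengths):
        raise ValueError("plan exceeds isoform capacity (planted features > 50% of genome)")
    arrays = [_random_bases(rng, n, config.gc_target) for n in lengths]
    iso_ids = [f"isoform{i+1:02d}" for i in range(config.n_isoforms)]
    placer = _Placer(lengths, config.feature_margin, rng)
    truth = TruthSet()

    if config.mtpt_plan and plastome is None:
        plastome, _ = generate_plastome(PlastomeConfig(seed=config.seed))

    # genes, planted as consecutive clusters
    for gp in config.gene_plan:
        total = sum(l for _, l in gp.genes)
        gaps = [int(rng.integers(100, gp.max_intergenic_gap + 1)) for _ in gp.genes[:-1]]
        iso, start = placer.place(total + sum(gaps))
        pos = start
        for gi, (gname, glen) in enumerate(gp.genes):
            cds = _random_cds(rng, glen)
            strand = "+" if rng.random() < 0.5 else "-"
            ins = cds if strand == "+" else revcomp(cds)
            arrays[iso][pos : pos + glen] = np.frombuffer(ins.encode(), dtype=np.uint8)
            truth.genes.append(GeneFeature(gname, iso_ids[iso], pos, pos + glen, strand))
            pos += glen + (gaps[gi] if gi < len(gaps) else 0)

    # SSR loci; flanking bases are forced to break the tandem run
    for sp in config.ssr_plan:
        motif = sp.motif.upper()
        run = motif * sp.repeat_count
        iso, start = placer.place(len(run) + 2)
        ins = np.frombuffer(run.encode(), dtype=np.uint8)
        arrays[iso][start + 1 : start + 1 + len(run)] = ins
        left_break = next(b for b in "ACGT" if b != motif[-1])
        right_break = next(b for b in "ACGT" if b != motif[0])
        arrays[iso][start] = ord(left_break)
        arrays[iso][start + 1 + len(run)] = ord(right_break)
        truth.ssrs.append(
            PlantedSsr(iso_ids[iso], start + 1, start + 1 + len(run), motif, sp.repeat_count)
        )

    # dispersed repeat pairs: copy a background segment elsewhere, mutated
    for rp in config.repeat_plan:
        iso_a, start_a = placer.place(rp.length)
        iso_b, start_b = placer.place(rp.length)
        src = arrays[iso_a][start_a : start_a + rp.length]
        copy, realized = _mutate_to_identity(rng, src, rp.identity)
        if rp.strand == "-":
            copy = np.frombuffer(revcomp(_to_str(copy)).encode(), dtype=np.uint8)
        arrays[iso_b][start_b : start_b + rp.length] = copy
        truth.repeats.append(
            PlantedRepeat(
                (iso_ids[iso_a], start_a, start_a + rp.length),
                (iso_ids[iso_b], start_b, start_b + rp.length),
                realized,
                rp.length,
                rp.strand,
            )
        )

    # MTPT insertions copied from the donor plastome
    if config.mtpt_plan:
        donor_seq = plastome.isoforms[0].sequence
        donor_len = len(donor_seq)
        used_donor: list[tuple[int, int]] = []
        for mp in config.mtpt_plan:
            if mp.donor_start is not None:
                d0 = mp.donor_start
            else:
                for _ in range(200):
                    d0 = int(rng.integers(0, donor_len - mp.length))
                    if all(e <= d0 or s >= d0 + mp.length for s, e in used_donor):
                        break
                else:
                    raise ValueError("could not find a free donor window for MTPT")
            used_donor.append((d0, d0 + mp.length))
            seg = np.frombuffer(
                donor_seq[d0 : d0 + mp.length].encode(), dtype=np.uint8
            )
            copy, realized = _mutate_to_identity(rng, seg, mp.identity)
            iso, start = placer.place(mp.length, iso=mp.isoform_index)
            arrays[iso][start : start + mp.length] = copy
            truth.mtpts.append(
                PlantedMtpt(
                    iso_ids[iso], start, start + mp.length, d0, d0 + mp.length, realized
                )
            )

    isoforms = [
        IsoformRecord(iso_ids[i], _to_str(arrays[i]), circular=True)
        for i in range(config.n_isoforms)
    ]
    return OrganelleGenome(config.name, isoforms), truth


# ---------------------------------------------------------------------------
# Long-read simulation.
# ---------------------------------------------------------------------------


@dataclass
class ReadSimConfig:
    n_reads: int = 2000
    # log-normal read lengths, Nanopore 10 kb library-like, truncated
    length_log_mean: float = np.log(9000.0)
    length_log_sigma: float = 0.45
    length_min: int = 1000
    length_max: int = 50_000
    error_rate: float = 0.05
    # error composition: substitutions / insertions / deletions
    error_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    recombinant_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.recombinant_fraction <= 1.0):
            raise ValueError("recombinant_fraction must be in [0,1]")
        if not (0.0 <= self.error_rate <= 0.2):
            raise ValueError("error_rate must be in [0, 0.2]")


def _apply_errors(rng: np.random.Generator, seq: str, rate: float, mix) -> str:
    if rate == 0:
        return seq
    out: list[str] = []
    p_sub, p_ins, p_del = (rate * m for m in mix)
    u = rng.random(len(seq))
    for i, base in enumerate(seq):
        if u[i] < p_del:
            continue
        if u[i] < p_del + p_ins:
            out.append(_to_str(BASES[rng.integers(0, 4, size=1)]))
        if u[i] < p_del + p_ins + p_sub and u[i] >= p_del + p_ins:
            alt = [b for b in "ACGT" if b != base]
            out.append(alt[int(rng.integers(3))])
        else:
            out.append(base)
    return "".join(out)


def simulate_reads(
    original_templates: dict[str, str],
    config: ReadSimConfig,
    alternative_templates: dict[str, str] | None = None,
) -> tuple[list[tuple[str, str]], TruthSet]:
    """Simulate Nanopore-like reads from template sequences.

    Each read is drawn from an original template with probability
    ``1 − recombinant_fraction`` and from an alternative template otherwise
    (templates within a class are chosen length-proportionally).  Start
    positions are uniform; a read longer than the remaining template is
    truncated.  Substitutions and indels are applied at ``error_rate``.

    Returns ``(reads, truth)`` where reads are ``(read_id, sequence)`` pairs
    and per-read truth labels record the source class and coordinates.
    """
    rng = np.random.default_rng([config.seed, 41])
    if config.recombinant_fraction > 0 and not alternative_templates:
        raise ValueError("recombinant_fraction > 0 requires alternative templates")
    classes: list[tuple[str, dict[str, str]]] = [("original", original_templates)]
    if alternative_templates:
        classes.append(("alternative", alternative_templates))
    reads: list[tuple[str, str]] = []
    truth = TruthSet()
    for r in range(config.n_reads):
        is_alt = alternative_templates is not None and rng.random() < config.recombinant_fraction
        label, pool = classes[1] if is_alt else classes[0]
        names = list(pool)
        weights = np.array([len(pool[n]) for n in names], dtype=float)
        tname = names[int(rng.choice(len(names), p=weights / weights.sum()))]
        template = pool[tname]
        raw_len = int(np.exp(rng.normal(config.length_log_mean, config.length_log_sigma)))
        length = int(np.clip(raw_len, config.length_min, config.length_max))
        if length >= len(template):
            start, length = 0, len(template)
        else:
            start = int(rng.integers(0, len(template) - length + 1))
        frag = template[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        frag = _apply_errors(rng, frag, config.error_rate, config.error_mix)
        read_id = f"read{r+1:05d}"
        reads.append((read_id, frag))
        truth.reads.append(ReadTruth(read_id, label, tname, start, length, strand))
    return reads, truth


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastx(path) -> list[tuple[str, str]]:
    """Read FASTA or FASTQ reads as (id, sequence) pairs."""
    from Bio import SeqIO

    fmt = "fastq"
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        fmt = "fasta"
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, fmt)]
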