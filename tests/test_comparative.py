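"""Similarity, gene clusters, codon statistics and ORF identification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitokit.comparative import (
    codon_boundary_summary,
    find_orfs,
    gene_clusters,
    pairwise_similarity,
    rscu,
    shared_clusters,
)
from mitokit.genome_io import GeneFeature, IsoformRecord, OrganelleGenome, revcomp
from mitokit.synth import SynthConfig, generate_mitogenome


class TestSimilarity:
    def test_genome_vs_itself_is_one(self, small_mito):
        genome, _ = small_mito
        sim = pairwise_similarity(genome, genome)
        assert sim.fraction_a == 1.0 and sim.fraction_b == 1.0

    def test_disjoint_random_genomes_share_nothing(self):
        g1, _ = generate_mitogenome(
            SynthConfig(n_isoforms=1, isoform_length_range=(30_000, 30_000), seed=5)
        )
        g2, _ = generate_mitogenome(
            SynthConfig(n_isoforms=1, isoform_length_range=(30_000, 30_000), seed=6)
        )
        sim = pairwise_similarity(g1, g2)
        assert sim.fraction_a < 0.01 and sim.fraction_b < 0.01

    def test_shared_fraction_tracks_planted_share(self):
        # build genome B carrying half of genome A's sequence
        g1, _ = generate_mitogenome(
            SynthConfig(n_isoforms=1, isoform_length_range=(40_000, 40_000), seed=7)
        )
        rng = np.random.default_rng(8)
        other = "".join(rng.choice(list("ACGT"), 20_000))
        shared = g1.isoforms[0].sequence[:20_000]
        g2 = OrganelleGenome("b", [IsoformRecord("i", shared + other, circular=False)])
        sim = pairwise_similarity(g1, g2)
        assert sim.fraction_a == pytest.approx(0.5, abs=0.02)
        assert sim.fraction_b == pytest.approx(0.5, abs=0.02)

    def test_fraction_invariant_under_isoform_reordering(self, small_mito):
        genome, _ = small_mito
        flipped = OrganelleGenome(genome.name, list(genome)[::-1])
        a = pairwise_similarity(genome, flipped)
        assert a.fraction_a == 1.0 and a.fraction_b == 1.0


class TestGeneClusters:
    def _feats(self, triples, iso="iso1"):
        return [
            GeneFeature(n, iso, s, e, "+", "protein_coding") for n, s, e in triples
        ]

    def test_small_gaps_form_one_cluster(self):
        feats = self._feats([("a", 0, 100), ("b", 500, 700), ("c", 1200, 1400)])
        [c] = gene_clusters(feats, max_gap=1000)
        assert c.genes == ("a", "b", "c")

    def test_large_gap_splits_clusters(self):
        feats = self._feats([("a", 0, 100), ("b", 200, 400), ("c", 20_000, 20_300)])
        clusters = gene_clusters(feats, max_gap=5000)
        assert [c.genes for c in clusters] == [("a", "b")]  # c is a singleton

    def test_planted_cluster_templates_recovered(self, small_mito):
        genome, truth = small_mito
        clusters = gene_clusters(truth.genes, max_gap=5000)
        got = {c.genes for c in clusters} | {tuple(reversed(c.genes)) for c in clusters}
        assert ("nad3", "rps12") in got
        assert ("rps3", "rpl16", "rpl2") in got

    def test_shared_cluster_reversal_insensitive(self):
        a = gene_clusters(self._feats([("nad3", 0, 100), ("rps12", 200, 300)]))
        b = gene_clusters(
            self._feats([("rps12", 50, 150), ("nad3", 300, 400)], iso="isoX")
        )
        assert len(shared_clusters(a, b)) == 1

    def test_different_gene_lists_not_shared(self):
        a = gene_clusters(self._feats([("atp9", 0, 100), ("rps7", 200, 300)]))
        b = gene_clusters(self._feats([("atp9", 0, 100), ("rps13", 200, 300)]))
        assert shared_clusters(a, b) == []

    def test_shared_clusters_symmetric(self, small_mito):
        _, truth = small_mito
        a = gene_clusters(truth.genes)
        b = list(reversed(gene_clusters(truth.genes)))
        assert len(shared_clusters(a, b)) == len(shared_clusters(b, a)) == len(a)


class TestRscu:
    def test_uniform_usage_gives_one_everywhere(self):
        # one of each codon of every family, as a single in-frame CDS
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        body = "".join(sorted(table.forward_table))
        df = rscu({"g": "ATG" + body + "TAA"})
        observed = df.dropna(subset=["rscu"])
        extra = {"ATG", "TGG"}  # also present as start/seeded singletons
        assert np.allclose(observed["rscu"], 1.0)

    def test_his_three_to_one(self):
        df = rscu({"g": "ATG" + "CAT" * 3 + "CAC" + "TAA"})
        his = df[df.amino_acid == "H"].set_index("codon")["rscu"]
        assert his["CAT"] == pytest.approx(1.5)
        assert his["CAC"] == pytest.approx(0.5)

    def test_family_sums_equal_family_size(self, small_mito):
        genome, truth = small_mito
        cds = {
            g.gene_name: (
                genome[g.isoform_id].sequence[g.start : g.end]
                if g.strand == "+"
                else revcomp(genome[g.isoform_id].sequence[g.start : g.end])
            )
            for g in truth.genes
        }
        df = rscu(cds)
        for aa, grp in df.groupby("amino_acid"):
            if grp["count"].sum() > 0:
                assert grp["rscu"].sum() == pytest.approx(len(grp))

    def test_matches_independent_tally(self):
        rng = np.random.default_rng(17)
        stops = {"TAA", "TGA", "TAG"}
        genes = {}
        for i in range(5):
            codons = ["ATG"]
            while len(codons) < 80:
                c = "".join(rng.choice(list("ACGT"), 3))
                if c not in stops:
                    codons.append(c)
            genes[f"g{i}"] = "".join(codons) + "TAA"
        df = rscu(genes)
        # oracle: plain dictionary tally
        from Bio.Data import CodonTable

        table = CodonTable.unambiguous_dna_by_id[1]
        tally = {}
        for seq in genes.values():
            for p in range(0, len(seq) - 3, 3):
                tally[seq[p : p + 3]] = tally.get(seq[p : p + 3], 0) + 1
        fams = {}
        for codon, aa in table.forward_table.items():
            fams.setdefault(aa, []).append(codon)
        for _, row in df.iterrows():
            fam = fams[row.amino_acid]
            total = sum(tally.get(c, 0) for c in fam)
            expected = row["count"] * len(fam) / total if total else float("nan")
            if total:
                assert row.rscu == pytest.approx(expected)
            assert row["count"] == tally.get(row.codon, 0)

    def test_internal_stop_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="internal stop"):
            df = rscu({"bad": "ATGTAACAT" + "TAA", "good": "ATGCATTAA"})
        assert df.set_index("codon").loc["CAT", "count"] == 1


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.lists(st.integers(0, 60), min_size=10, max_size=120))
def test_rscu_normalization_property(codon_indices):
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    codons = sorted(table.forward_table)
    body = "".join(codons[i % len(codons)] for i in codon_indices)
    df = rscu({"g": "ATG" + body + "TAA"})
    for aa, grp in df.groupby("amino_acid"):
        if grp["count"].sum() > 0:
            assert grp["rscu"].sum() == pytest.approx(len(grp))


class TestCodonBoundaries:
    def test_canonical_and_flagged(self):
        df = codon_boundary_summary(
            {"atp6": "ATGCATCATTAA", "mttB": "TTGCATCATTGA"}
        ).set_index("gene")
        assert df.loc["atp6", "start_codon"] == "ATG"
        assert df.loc["atp6", "canonical_stop"]
        assert not df.loc["mttB", "canonical_start"]

    def test_single_planted_noncanonical_start(self, small_mito):
        genome, truth = small_mito
        cds = {
            g.gene_name: (
                genome[g.isoform_id].sequence[g.start : g.end]
                if g.strand == "+"
                else revcomp(genome[g.isoform_id].sequence[g.start : g.end])
            )
            for g in truth.genes
        }
        cds["mttB"] = "TTG" + cds["nad3"][3:]
        df = codon_boundary_summary(cds)
        assert (~df["canonical_start"]).sum() == 1
        assert df.loc[~df["canonical_start"], "gene"].item() == "mttB"


class TestOrfs:
    def test_planted_orf_found_at_exact_coordinates(self):
        rng = np.random.default_rng(19)
        bg = "".join(rng.choice(list("ACGT"), 3000))
        orf = "ATG" + "GCT" * 132 + "TAA"  # 402 bp
        seq = bg[:500] + orf + bg[500:]
        hits = [o for o in find_orfs(seq, 300) if o.start == 500 and o.strand == "+"]
        assert hits and hits[0].end == 500 + 402

    def test_length_threshold_is_strict(self):
        filler = "GCA" * 98
        seq = "CCCC" + "ATG" + filler + "TAA" + "CCCC"  # exactly 300 bp ORF
        assert all(o.length != 300 for o in find_orfs(seq, 300))
        seq2 = "CCCC" + "ATG" + filler + "GCA" + "TAA" + "CCCC"  # 303 bp
        assert any(o.length == 303 for o in find_orfs(seq2, 300))

    def test_sequence_without_atg_has_no_orfs(self):
        assert find_orfs("GGCCTTGGCCTT" * 100, 300) == []

    def test_minus_strand_orf_reported_in_forward_coordinates(self):
        rng = np.random.default_rng(20)
        bg = "".join(rng.choice(list("ACGT"), 2000))
        orf = "ATG" + "GCT" * 132 + "TAA"
        seq = bg[:400] + revcomp(orf) + bg[400:]
        hits = [o for o in find_orfs(seq, 300) if o.strand == "-" and o.start == 400]
        assert hits and hits[0].length == 402
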