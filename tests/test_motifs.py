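import numpy as np
import pytest

from coexnet import motifs as mo
from coexnet.simulate import simulate_promoters
from oracles import sliding_window_scan


class TestScan:
    def test_literal_forward_hit(self):
        assert mo.scan_motif("AATGACGTTT", "TGACGT") == [(2, 8, "+")]

    def test_iupac_degeneracy_s_matches_c_or_g(self):
        hits = mo.scan_motif("TGACTGTGAGTG", "TGASTG")
        assert [(h[0], h[1]) for h in hits] == [(0, 6), (6, 12)]

    def test_palindrome_counted_once(self):
        hits = mo.scan_motif("ACACGTGA", "CACGTG")
        assert hits == [(1, 7, "+")]

    def test_reverse_strand_hit_reported(self):
        # ACGTGA reverse-complements to TCACGT, present in the sequence
        hits = mo.scan_motif("TTCACGTT", "ACGTGA")
        assert hits == [(1, 7, "-")]

    def test_overlapping_hits_all_reported(self):
        assert len(mo.scan_motif("AAAA", "AA")) == 3

    def test_sequence_n_matches_nothing_but_motif_n(self):
        assert mo.scan_motif("ANAT", "AA") == []
        assert (0, 2, "+") in mo.scan_motif("ANAT", "AN")

    def test_invalid_motif_character(self):
        with pytest.raises(mo.MotifValidationError):
            mo.scan_motif("ACGT", "AXGT")

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_sliding_window_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGTN"), size=400,
                                 p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        for consensus in ("TGACGT", "CACGTG", "TGASTG", "WWWW", "CNG", "RYN"):
            got = mo.scan_motif(seq, consensus)
            assert got == sliding_window_scan(seq, consensus)
            starts = [h[0] for h in got]
            assert all(0 <= s <= len(seq) - len(consensus) for s in starts)


class TestCounts:
    def test_planted_hits_sum(self):
        ps = {f"g{i}": "AATGACGTTTTTGACGTAA" for i in range(3)}  # 2 hits each
        assert mo.count_occurrences(ps, list(ps), "TGACGT") == 6

    def test_empty_gene_subset(self):
        ps = {"g1": "ACGT"}
        assert mo.count_occurrences(ps, [], "ACGT") == 0

    def test_all_n_promoter_has_no_hits(self):
        assert mo.count_occurrences({"g": "N" * 50}, ["g"], "TGACGT") == 0

    def test_unknown_gene_listed(self):
        with pytest.raises(KeyError, match="gX"):
            mo.count_occurrences({"g1": "ACGT"}, ["gX"], "AC")


class TestBackground:
    def test_identical_promoters_have_degenerate_background(self):
        ps = {f"g{i}": "AATGACGTTT" for i in range(10)}  # exactly 1 hit each
        mean, sd = mo.background_distribution(ps, 5, "TGACGT", n_sets=50,
                                              seed=0)
        assert (mean, sd) == (5.0, 0.0)

    def test_full_set_draws_are_identical(self):
        rng = np.random.default_rng(2)
        ps, _ = simulate_promoters(8, length=100, carrier_fraction=0.5, seed=2)
        mean, sd = mo.background_distribution(ps, 8, "CACGTG", n_sets=20,
                                              seed=1)
        assert sd == 0.0

    def test_seeded_reproducibility_bit_for_bit(self):
        ps, _ = simulate_promoters(50, length=300, carrier_fraction=0.3,
                                   seed=4)
        a = mo.background_distribution(ps, 10, "CACGTG", n_sets=100, seed=42)
        b = mo.background_distribution(ps, 10, "CACGTG", n_sets=100, seed=42)
        assert a == b

    def test_binomial_expectation_of_planted_carriers(self):
        # 500 promoters, ~30% carry one planted hit; background hits are
        # vanishingly rare for an 8-mer, so a 50-promoter draw expects ~15.
        ps, carriers = simulate_promoters(500, length=200, motif="TGCATGCA",
                                          carrier_fraction=0.3, seed=5)
        mean, sd = mo.background_distribution(ps, 50, "TGCATGCA",
                                              n_sets=300, seed=5)
        se = np.sqrt(50 * 0.3 * 0.7 * (450 / 499)) / np.sqrt(300)
        assert abs(mean - 15.0) < 3 * np.sqrt(50 * 0.3 * 0.7)

    def test_set_size_larger_than_collection_rejected(self):
        with pytest.raises(ValueError):
            mo.background_distribution({"g": "ACGT"}, 2, "AC", n_sets=10)


class TestZScore:
    def test_enrichment_z_and_tail(self):
        z, p = mo.motif_zscore(10, 4, 2)
        assert z == pytest.approx(3.0)
        assert p == pytest.approx(0.00135, abs=1e-4)

    def test_count_at_mean(self):
        assert mo.motif_zscore(4, 4, 1) == (0.0, pytest.approx(0.5))

    def test_depletion_is_not_significant(self):
        z, p = mo.motif_zscore(2, 4, 1)
        assert z == pytest.approx(-2.0)
        assert p == pytest.approx(0.97725, abs=1e-4)

    def test_degenerate_background(self):
        assert mo.motif_zscore(4, 4, 0) == (0.0, 0.5)
        assert mo.motif_zscore(5, 4, 0) == (float("inf"), 0.0)
        assert mo.motif_zscore(3, 4, 0) == (float("-inf"), 1.0)

    def test_constant_extra_hit_per_promoter_cancels(self):
        """Appending exactly one guaranteed hit to every promoter shifts
        query count and background mean equally, leaving z unchanged."""
        rng = np.random.default_rng(9)
        base = {f"g{i}": "".join(rng.choice(list("AT"), size=120))
                for i in range(40)}
        spiked = {g: s + "TTGGGGGTT" for g, s in base.items()}
        query = sorted(base)[:10]
        n0 = mo.count_occurrences(base, query, "GGGGG")
        n1 = mo.count_occurrences(spiked, query, "GGGGG")
        assert n1 == n0 + 10
        m0, s0 = mo.background_distribution(base, 10, "GGGGG", n_sets=200,
                                            seed=7)
        m1, s1 = mo.background_distribution(spiked, 10, "GGGGG", n_sets=200,
                                            seed=7)
        assert m1 == pytest.approx(m0 + 10) and s1 == pytest.approx(s0)
        assert mo.motif_zscore(n1, m1, s1)[0] == pytest.approx(
            mo.motif_zscore(n0, m0, s0)[0])


class TestEnrichmentPipeline:
    def test_planted_motif_flagged(self):
        ps, carriers = simulate_promoters(200, length=300, motif="CACGTG",
                                          carrier_fraction=0.05, seed=9)
        rng = np.random.default_rng(9)
        non = sorted(set(ps) - set(carriers))
        query = carriers[:18] + list(rng.choice(non, size=2, replace=False))
        # plant the motif into 90% of the query promoters
        res = mo.motif_enrichment(ps, query, [mo.Motif("GBOX", "CACGTG")],
                                  n_sets=300, seed=9)
        assert res["p_value"].iloc[0] < 0.001

    def test_empty_motif_list(self):
        ps, _ = simulate_promoters(10, length=100, seed=0)
        res = mo.motif_enrichment(ps, list(ps)[:3], [], seed=0)
        assert len(res) == 0

    def test_reproducible_given_seed(self):
        ps, _ = simulate_promoters(60, length=200, motif="CACGTG",
                                   carrier_fraction=0.2, seed=3)
        motifs = [mo.Motif("GBOX", "CACGTG"), mo.Motif("TATA", "TATAWAW")]
        a = mo.motif_enrichment(ps, sorted(ps)[:12], motifs, n_sets=100,
                                seed=11)
        b = mo.motif_enrichment(ps, sorted(ps)[:12], motifs, n_sets=100,
                                seed=11)
        assert a.equals(b)


class TestIO:
    def test_fasta_round_trip(self, tmp_path):
        ps, _ = simulate_promoters(5, length=80, seed=1)
        p = tmp_path / "prom.fasta"
        mo.write_promoters_fasta(ps, p)
        assert mo.read_promoters_fasta(p) == ps

    def test_motif_table(self, tmp_path):
        p = tmp_path / "motifs.tsv"
        p.write_text("motif_id\tconsensus\tannotation\nM1\tCACGTG\tG-box\n")
        motifs = mo.read_motif_table(p)
        assert motifs == [mo.Motif("M1", "CACGTG", "G-box")]

    def test_promoter_extraction_helper(self, tmp_path):
        genome = tmp_path / "genome.fasta"
        genome.write_text(">chr1\n" + "A" * 10 + "CACGTG" + "G" * 30 + "\n")
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t17\t40\t.\t+\t.\tID=gplus\n"     # upstream = 1..16
            "chr1\tsrc\tgene\t5\t10\t.\t-\t.\tID=gminus\n")    # upstream = 11..30 rc
        promoters = mo.extract_promoters(genome, gff, length=16)
        assert promoters["gplus"] == "A" * 10 + "CACGTG"
        assert promoters["gminus"] == ("A" * 10 + "CACGTG" + "G" * 30)[10:26][
            ::-1].translate(str.maketrans("ACGT", "TGCA"))
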