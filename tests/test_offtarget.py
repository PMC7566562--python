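"""Transcript database extraction, local alignment, and the specificity screen."""

import math

import pytest

from rrnaprobe import offtarget as ot
from rrnaprobe.candidates import FLAG_OFFTARGET, ProbeCandidate
from rrnaprobe.synthetic import FixtureRecipe, make_decoys
from rrnaprobe.thermo import reverse_complement
from conftest import random_dna


def ref_sw(q, t, match=1, mis=-3, go=5, ge=2):
    """Independent quadratic full-DP Smith-Waterman (affine gaps, gap of
    length k costs go + k*ge), written from the recurrence directly."""
    n, m = len(q), len(t)
    NEG = -10**9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if (q[i - 1] == t[j - 1] and q[i - 1] in "ACGT"
                            and t[j - 1] in "ACGT") else mis
            E[i][j] = max(E[i][j - 1] - ge, H[i][j - 1] - go - ge)
            F[i][j] = max(F[i - 1][j] - ge, H[i - 1][j] - go - ge)
            H[i][j] = max(0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestScoringScheme:
    def test_shipped_lambda_solves_karlin_altschul_identity(self):
        s = ot.ScoringScheme()
        ident = (0.25 * math.exp(s.lambda_ * s.match)
                 + 0.75 * math.exp(s.lambda_ * s.mismatch))
        assert ident == pytest.approx(1.0, abs=2e-3)

    def test_inconsistent_lambda_rejected(self):
        with pytest.raises(ValueError):
            ot.ScoringScheme(lambda_=0.5)
        with pytest.raises(ValueError):
            ot.ScoringScheme(K=1.5)


class TestBitscore:
    def test_16mer_exceeds_cutoff_15mer_does_not(self):
        s = ot.ScoringScheme()
        assert ot.bitscore(16, s) > 32.0
        assert ot.bitscore(15, s) <= 32.0

    def test_zero_raw_gives_minimal_bits(self):
        s = ot.ScoringScheme()
        assert ot.bitscore(0, s) == pytest.approx(-math.log(s.K) / math.log(2))

    def test_strictly_monotone(self):
        s = ot.ScoringScheme()
        bits = [ot.bitscore(r, s) for r in range(0, 40)]
        assert all(a < b for a, b in zip(bits, bits[1:]))

    def test_min_flagged_match_length_is_16(self):
        assert ot.min_flagged_match_length() == 16


class TestLocalAlign:
    def test_perfect_substring_scores_its_length(self, rng):
        sub = random_dna(rng, 16)
        subject = random_dna(rng, 40) + sub + random_dna(rng, 40)
        raw, qspan, sspan = ot.local_align(sub, subject)
        assert raw >= 16  # may extend by chance matches
        assert sspan[1] - sspan[0] >= 16

    def test_disjoint_alphabets_bound(self):
        raw = ot.sw_max_score("ACACACAC", "GTGTGTGT")
        assert raw <= 1

    def test_vectorized_and_traceback_match_reference_dp(self, rng):
        s = ot.ScoringScheme()
        for _ in range(200):
            q = random_dna(rng, rng.randint(5, 60))
            t = random_dna(rng, rng.randint(5, 60),
                           alphabet="ACGTN" if rng.random() < 0.2 else "ACGT")
            expected = ref_sw(q, t)
            assert ot.sw_max_score(q, t, s) == expected
            raw, _, _ = ot.local_align(q, t, s)
            assert raw == expected

    def test_empty_sequences_score_zero(self):
        assert ot.sw_max_score("", "ACGT") == 0
        assert ot.local_align("ACGT", "")[0] == 0


TOY_GENOME = None  # built in fixture below


@pytest.fixture
def toy_annotation(tmp_path, rng):
    """200-nt chromosome; plus-strand two-exon gene (exons [0,50) and
    [80,130)), a minus-strand single-exon gene, and an excluded gene."""
    genome = random_dna(rng, 200)
    gfa = tmp_path / "genome.fa"
    gfa.write_text(f">chr1\n{genome}\n")
    gff = tmp_path / "genes.gff3"
    gff.write_text("\n".join([
        "##gff-version 3",
        "chr1\t.\tgene\t1\t130\t.\t+\t.\tID=geneA",
        "chr1\t.\tmRNA\t1\t130\t.\t+\t.\tID=txA;Parent=geneA",
        "chr1\t.\texon\t1\t50\t.\t+\t.\tID=txA.e1;Parent=txA",
        "chr1\t.\texon\t81\t130\t.\t+\t.\tID=txA.e2;Parent=txA",
        "chr1\t.\tgene\t140\t180\t.\t-\t.\tID=geneB",
        "chr1\t.\tmRNA\t140\t180\t.\t-\t.\tID=txB;Parent=geneB",
        "chr1\t.\texon\t140\t180\t.\t-\t.\tID=txB.e1;Parent=txB",
        "chr1\t.\tgene\t150\t190\t.\t+\t.\tID=rRNA_gene",
        "chr1\t.\tmRNA\t150\t190\t.\t+\t.\tID=tx_rRNA;Parent=rRNA_gene",
        "chr1\t.\texon\t150\t190\t.\t+\t.\tID=tx_rRNA.e1;Parent=tx_rRNA",
    ]) + "\n")
    return genome, gfa, gff


class TestTranscriptDB:
    def test_toy_extraction(self, toy_annotation):
        genome, gfa, gff = toy_annotation
        db = ot.extract_transcript_db(gfa, gff, flank_nt=40,
                                      excluded_gene_ids={"rRNA_gene"})
        by_id = {r.record_id: r for r in db.records}
        # spliced transcript = exon concatenation
        assert by_id["txA"].sequence == genome[0:50] + genome[80:130]
        # intron record = intron [50, 80) with 40-nt flanks, clipped at 0
        intron = by_id["txA:intron:50-80"]
        assert intron.sequence == genome[10:120]
        assert intron.kind == "intron_flanked"
        # minus-strand transcript reverse-complemented
        rc = reverse_complement(genome[139:180])
        assert by_id["txB"].sequence == rc
        # excluded gene contributes nothing
        assert not any(r.gene_id == "rRNA_gene" for r in db.records)

    def test_single_exon_has_no_introns(self, toy_annotation):
        _, gfa, gff = toy_annotation
        db = ot.extract_transcript_db(gfa, gff, excluded_gene_ids={"rRNA_gene"})
        assert not any(r.record_id.startswith("txB:intron")
                       for r in db.records)

    def test_exon_beyond_chromosome_end_rejected(self, tmp_path, rng):
        (tmp_path / "g.fa").write_text(f">c\n{random_dna(rng, 50)}\n")
        (tmp_path / "a.gff3").write_text(
            "##gff-version 3\n"
            "c\t.\tgene\t1\t90\t.\t+\t.\tID=g1\n"
            "c\t.\tmRNA\t1\t90\t.\t+\t.\tID=t1;Parent=g1\n"
            "c\t.\texon\t1\t90\t.\t+\t.\tID=t1.e1;Parent=t1\n")
        with pytest.raises(ValueError):
            ot.extract_transcript_db(tmp_path / "g.fa", tmp_path / "a.gff3")

    def test_db_rejects_record_of_excluded_gene(self):
        rec = ot.TranscriptRecord("r1", "geneX", "spliced", "ACGT")
        with pytest.raises(ValueError):
            ot.TranscriptDB(records=[rec], excluded_gene_ids={"geneX"})


def _mk_cand(site, target_id="t", start=0):
    return ProbeCandidate(target_id=target_id, start=start, length=len(site),
                          target_site_seq=site,
                          probe_seq=reverse_complement(site))


class TestScreen:
    def test_planted_16mer_flagged_12mer_not(self, rng):
        recipe = FixtureRecipe(seed=77, decoy_count=6, decoy_length=800,
                               planted_match_lengths=[16, 12])
        sites = [random_dna(rng, 30), random_dna(rng, 30)]
        decoys, truth = make_decoys(sites, recipe)
        db = ot.TranscriptDB(records=[
            ot.TranscriptRecord(rid, rid, "spliced", seq)
            for rid, seq in decoys])
        cands = [_mk_cand(s, start=i * 40) for i, s in enumerate(sites)]
        ot.screen_candidates(cands, db)
        assert FLAG_OFFTARGET in cands[0].filter_flags       # 16-nt plant
        assert FLAG_OFFTARGET not in cands[1].filter_flags   # 12-nt plant
        assert cands[0].offtarget_max_bits > 32.0
        assert cands[1].offtarget_max_bits <= 32.0

    def test_empty_db_passes_everything(self, rng):
        cands = [_mk_cand(random_dna(rng, 28))]
        hits = ot.screen_candidates(cands, ot.TranscriptDB())
        assert hits == []
        assert cands[0].offtarget_max_bits is None
        assert FLAG_OFFTARGET not in cands[0].filter_flags

    def test_flags_invariant_under_record_order(self, rng):
        sites = [random_dna(rng, 30) for _ in range(5)]
        recs = [ot.TranscriptRecord(f"r{i}", f"g{i}", "spliced",
                                    random_dna(rng, 500) + sites[0][5:23]
                                    + random_dna(rng, 500))
                for i in range(4)]
        for order in (recs, recs[::-1]):
            cands = [_mk_cand(s, start=i * 40) for i, s in enumerate(sites)]
            ot.screen_candidates(cands, ot.TranscriptDB(records=list(order)))
            flags1 = [FLAG_OFFTARGET in c.filter_flags for c in cands]
            bits1 = [c.offtarget_max_bits for c in cands]
            if order is recs:
                ref_flags, ref_bits = flags1, bits1
        assert flags1 == ref_flags
        assert bits1 == pytest.approx(ref_bits)

    def test_screen_agrees_with_exhaustive_reference_dp(self, rng):
        """Flag decisions from the vectorized screen equal those from the
        independent quadratic DP, candidate by candidate."""
        s = ot.ScoringScheme()
        recipe = FixtureRecipe(seed=88, decoy_count=20, decoy_length=300,
                               planted_match_lengths=[10, 12, 14, 15, 16, 17,
                                                      18, 20])
        sites = [random_dna(rng, 30) for _ in range(8)]
        decoys, truth = make_decoys(sites, recipe)
        db = ot.TranscriptDB(records=[
            ot.TranscriptRecord(rid, rid, "spliced", seq)
            for rid, seq in decoys])
        cands = [_mk_cand(site, start=i * 40) for i, site in enumerate(sites)]
        ot.screen_candidates(cands, db, s)
        for cand in cands:
            best_ref = max(ref_sw(cand.target_site_seq, r.sequence)
                           for r in db.records)
            flagged_ref = ot.bitscore(best_ref, s) > s.bitscore_cutoff
            assert (FLAG_OFFTARGET in cand.filter_flags) == flagged_ref
            assert cand.offtarget_max_bits == pytest.approx(
                ot.bitscore(best_ref, s))

    @pytest.mark.skipif(__import__("shutil").which("blastn") is None,
                        reason="blastn not installed")
    def test_flags_agree_with_external_blastn(self, rng):
        """The internal screen's flag decisions match blastn-short with the
        same scoring and cutoff on planted-match decoys."""
        recipe = FixtureRecipe(seed=99, decoy_count=8, decoy_length=500,
                               planted_match_lengths=[12, 14, 15, 16, 17, 20])
        sites = [random_dna(rng, 30) for _ in range(6)]
        decoys, _ = make_decoys(sites, recipe)
        db = ot.TranscriptDB(records=[
            ot.TranscriptRecord(rid, rid, "spliced", seq)
            for rid, seq in decoys])
        cands = [_mk_cand(s, start=i * 40) for i, s in enumerate(sites)]
        ot.screen_candidates(cands, db)
        ref = ot.blastn_best_bits(
            {f"q{i}": s for i, s in enumerate(sites)},
            dict(decoys))
        for i, cand in enumerate(cands):
            ref_flag = ref.get(f"q{i}", 0.0) > 32.0
            assert (FLAG_OFFTARGET in cand.filter_flags) == ref_flag

    def test_contiguous_16mer_soundness(self, rng):
        """Any planted >=16-nt exact match must flag its candidate."""
        for length in (16, 17, 19):
            site = random_dna(rng, 30)
            recipe = FixtureRecipe(seed=900 + length, decoy_count=1,
                                   decoy_length=600,
                                   planted_match_lengths=[length])
            decoys, _ = make_decoys([site], recipe)
            db = ot.TranscriptDB(records=[
                ot.TranscriptRecord("d", "d", "spliced", decoys[0][1])])
            cand = _mk_cand(site)
            ot.screen_candidates([cand], db)
            assert FLAG_OFFTARGET in cand.filter_flags
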