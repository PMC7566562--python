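"""Nearest-neighbor Tm, salt correction, and structure-dG screening."""

import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rrnaprobe import thermo as T
from conftest import random_dna

# Independent oracle table for the RNA/DNA hybrid stacking parameters
# (Sugimoto et al. 1995), transcribed by hand from the publication:
# step on the RNA strand 5'->3' -> (dH kcal/mol, dS cal/(mol*K)).
ORACLE_NN = {
    "AA": (-7.8, -21.9), "AC": (-5.9, -12.3), "AG": (-9.1, -23.5),
    "AT": (-8.3, -23.9), "CA": (-9.0, -26.1), "CC": (-9.3, -23.2),
    "CG": (-16.3, -47.1), "CT": (-7.0, -19.7), "GA": (-5.5, -13.5),
    "GC": (-8.0, -17.1), "GG": (-12.8, -31.9), "GT": (-7.8, -21.6),
    "TA": (-7.8, -23.2), "TC": (-8.6, -22.9), "TG": (-10.4, -28.4),
    "TT": (-11.5, -36.4),
}
ORACLE_INIT = (1.9, -3.9)

FIXTURE_26MER = "TAGCCGATCGGTACATGCAATTGCCA"

dna = st.text(alphabet="ACGT", min_size=10, max_size=40)


def oracle_tm(seq, cfg):
    """Hand summation of the published table + salt formula, written
    independently of the package's vectorized path."""
    dh, ds = ORACLE_INIT
    for i in range(len(seq) - 1):
        h, s = ORACLE_NN[seq[i:i + 2]]
        dh += h
        ds += s
    c_eff = cfg.probe_conc_nM * 1e-9 / cfg.conc_divisor
    tm_k = dh * 1000.0 / (ds + 1.987 * math.log(c_eff))
    fgc = (seq.count("G") + seq.count("C")) / len(seq)
    inv = (1.0 / tm_k
           + (4.29 * fgc - 3.95) * 1e-5 * math.log(cfg.na_molar)
           + 9.40e-6 * math.log(cfg.na_molar) ** 2)
    return 1.0 / inv - 273.15


class TestDuplexTm:
    def test_matches_hand_summation_on_fixture(self, thermo_cfg):
        got = T.duplex_tm(FIXTURE_26MER, thermo_cfg)
        assert got == pytest.approx(oracle_tm(FIXTURE_26MER, thermo_cfg),
                                    abs=0.05)

    def test_matches_hand_summation_random(self, rng, thermo_cfg):
        for _ in range(50):
            seq = random_dna(rng, rng.randint(20, 35))
            assert T.duplex_tm(seq, thermo_cfg) == pytest.approx(
                oracle_tm(seq, thermo_cfg), abs=0.05)

    def test_matches_biopython_reference(self, rng):
        # Biopython's Tm_NN with the same published table and salt formula
        # is a fully independent implementation of the identical model
        from Bio.SeqUtils import MeltingTemp as mt

        for _ in range(20):
            seq = random_dna(rng, rng.randint(18, 35))
            ref = mt.Tm_NN(seq, nn_table=mt.R_DNA_NN1, dnac1=125, dnac2=125,
                           Na=300, saltcorr=6)
            assert T.duplex_tm(seq) == pytest.approx(ref, abs=1e-6)

    def test_salt_correction_noop_at_1M(self, rng):
        cfg = T.ThermoConfig(na_molar=1.0)
        seq = random_dna(rng, 28)
        assert T.duplex_tm(seq, cfg) == pytest.approx(T.tm_1m(seq, cfg,
                                                              T.RNA_DNA_TABLE))

    def test_increases_with_probe_concentration(self, rng):
        seq = random_dna(rng, 30)
        tms = [T.duplex_tm(seq, T.ThermoConfig(probe_conc_nM=c))
               for c in (50, 250, 1000)]
        assert tms[0] < tms[1] < tms[2]

    def test_rejects_bad_input(self):
        with pytest.raises(T.InvalidSequenceError):
            T.duplex_tm("ACGTNACGT")
        with pytest.raises(T.InvalidSequenceError):
            T.duplex_tm("A")

    @given(seq=st.text(alphabet="ACGT", min_size=10, max_size=10),
           pos=st.integers(min_value=1, max_value=8))
    @settings(max_examples=300, deadline=None)
    def test_at_to_gc_substitution_never_lowers_tm(self, seq, pos):
        """Strengthening an internal A.T pair to G.C never lowers the 1 M Tm."""
        if seq[pos] not in "AT":
            return
        repl = "G" if seq[pos] == "A" else "C"
        stronger = seq[:pos] + repl + seq[pos + 1:]
        cfg = T.ThermoConfig()
        assert (T.tm_1m(stronger, cfg, T.RNA_DNA_TABLE)
                >= T.tm_1m(seq, cfg, T.RNA_DNA_TABLE) - 1e-9)


class TestSaltCorrection:
    def test_identity_at_1M(self):
        for tm in range(60, 91, 5):
            for fgc in (0.3, 0.5, 0.7):
                assert T.salt_correct(float(tm), fgc, 1.0) == pytest.approx(tm)

    def test_lowers_tm_below_1M(self):
        assert T.salt_correct(80.0, 0.5, 0.3) < 80.0

    def test_reciprocal_space_agreement_on_grid(self):
        # independent evaluation of the published formula, compared in
        # reciprocal-kelvin space
        for tm in range(60, 91, 3):
            for fgc in (0.3, 0.4, 0.5, 0.6, 0.7):
                got = T.salt_correct(float(tm), fgc, 0.3)
                inv_expected = (1.0 / (tm + 273.15)
                                + (4.29 * fgc - 3.95) * 1e-5 * math.log(0.3)
                                + 9.40e-6 * math.log(0.3) ** 2)
                assert 1.0 / (got + 273.15) == pytest.approx(inv_expected,
                                                             abs=1e-6)

    def test_rejects_nonpositive_na(self):
        with pytest.raises(ValueError):
            T.salt_correct(80.0, 0.5, 0.0)


class TestNNTable:
    def test_shipped_table_matches_publication(self):
        assert len(T.RNA_DNA_TABLE.pair_params) == 16
        for step, vals in ORACLE_NN.items():
            assert T.RNA_DNA_TABLE.pair_params[step] == vals
        assert (T.RNA_DNA_TABLE.init_dH, T.RNA_DNA_TABLE.init_dS) == ORACLE_INIT

    def test_all_stacking_dh_negative(self):
        for table in (T.RNA_DNA_TABLE, T.DNA_DNA_TABLE):
            assert all(dh < 0 for dh, _ in table.pair_params.values())

    def test_round_trips_through_asset(self):
        reloaded = T.load_nn_table("rna_dna_nn.tsv")
        assert reloaded.pair_params == T.RNA_DNA_TABLE.pair_params
        assert reloaded.init_dH == T.RNA_DNA_TABLE.init_dH

    def test_dna_table_complement_symmetric(self):
        rc = T.reverse_complement
        for step in T.DNA_DNA_TABLE.pair_params:
            assert T.DNA_DNA_TABLE.dg37(step) == pytest.approx(
                T.DNA_DNA_TABLE.dg37(rc(step)))


class TestGcFraction:
    @given(dna)
    @settings(max_examples=100, deadline=None)
    def test_reverse_complement_invariant(self, seq):
        assert T.gc_fraction(seq) == pytest.approx(
            T.gc_fraction(T.reverse_complement(seq)))


# seeded structure panel; verdicts cross-checked against an external
# thermodynamic folding tool (ViennaRNA with DNA parameters) when available
STEMS = ["GCGCGGCC", "CCGGTACGG", "GGCCAGGC", "CGTGCCGG", "GCCGTGCA"]


def _hairpin_panel():
    rc = T.reverse_complement
    strong = ["ATA" + s + "TTAT" + rc(s) + "TCA" for s in STEMS]
    import random as _r
    r = _r.Random(42)
    weak = ["".join(r.choice("AC") for _ in range(26)) for _ in range(5)]
    return [(s, "fail") for s in strong] + [(s, "pass") for s in weak]


class TestHairpin:
    def test_no_self_complementary_stem_returns_sentinel(self):
        assert T.hairpin_dg("ACACACACACACACACACAC") == T.NO_STRUCTURE_DG

    def test_planted_stem_fails_threshold(self):
        rc = T.reverse_complement
        stem = "GCGCGGCC"
        seq = "AAA" + stem + "TTTT" + rc(stem) + "AAA"
        assert T.hairpin_dg(seq) < -3.0

    @pytest.mark.parametrize("seq,verdict", _hairpin_panel())
    def test_verdicts_on_panel(self, seq, verdict):
        dg = T.hairpin_dg(seq)
        assert ("fail" if dg < -3.0 else "pass") == verdict

    @pytest.mark.skipif(shutil.which("RNAfold") is None,
                        reason="external folding tool not installed")
    @pytest.mark.parametrize("seq,verdict", _hairpin_panel())
    def test_verdicts_agree_with_external_folder(self, seq, verdict):
        r = subprocess.run(["RNAfold", "--paramFile=DNA", "--noPS"],
                           input=seq + "\n", capture_output=True, text=True)
        line = r.stdout.strip().splitlines()[-1]
        dg = float(line[line.rindex("(") + 1:line.rindex(")")])
        assert ("fail" if dg < -3.0 else "pass") == verdict

    def test_rejects_non_dna(self):
        with pytest.raises(T.InvalidSequenceError):
            T.hairpin_dg("ACGTNACGTACG")


def _dimer_panel():
    import random as _r
    r = _r.Random(42)
    rc = T.reverse_complement
    pairs = []
    for _ in range(5):
        s = "".join(r.choice("ACGT") for _ in range(20))
        pairs.append((s, rc(s), "fail"))
    for _ in range(5):
        a = "".join(r.choice("ACG") for _ in range(30))
        b = "".join(r.choice("ACT") for _ in range(30))
        pairs.append((a, b, "pass"))
    return pairs


class TestDimer:
    def test_no_complementarity_returns_sentinel(self):
        assert T.dimer_dg("AAAAAAAAAA", "AAAAAAAAAA") == T.NO_STRUCTURE_DG

    def test_perfect_duplex_fails_threshold(self, rng):
        s = random_dna(rng, 20)
        assert T.dimer_dg(s, T.reverse_complement(s)) < -10.0

    @pytest.mark.parametrize("a,b,verdict", _dimer_panel())
    def test_verdicts_on_panel(self, a, b, verdict):
        dg = T.dimer_dg(a, b)
        assert ("fail" if dg < -10.0 else "pass") == verdict

    @pytest.mark.skipif(shutil.which("RNAduplex") is None,
                        reason="external duplex tool not installed")
    @pytest.mark.parametrize("a,b,verdict", _dimer_panel())
    def test_verdicts_agree_with_external_duplex_tool(self, a, b, verdict):
        r = subprocess.run(["RNAduplex", "--paramFile=DNA"],
                           input=f"{a}\n{b}\n", capture_output=True, text=True)
        line = r.stdout.strip().splitlines()[-1]
        dg = float(line[line.rindex("(") + 1:line.rindex(")")])
        assert ("fail" if dg < -10.0 else "pass") == verdict

    @given(a=st.text(alphabet="ACGT", min_size=8, max_size=30),
           b=st.text(alphabet="ACGT", min_size=8, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_symmetric(self, a, b):
        assert T.dimer_dg(a, b) == pytest.approx(T.dimer_dg(b, a))


class TestLoopPenalty:
    def test_interpolation_monotone_beyond_table(self):
        assert T.loop_penalty(40) > T.loop_penalty(30)
        assert T.loop_penalty(11) == pytest.approx(
            (T.loop_penalty(10) + T.loop_penalty(12)) / 2)

    def test_rejects_tight_loops(self):
        with pytest.raises(ValueError):
            T.loop_penalty(2)
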