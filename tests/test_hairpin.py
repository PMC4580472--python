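"""Folding DP, stem-loop decomposition and the 11-criterion engine."""

import numpy as np
import pytest

from dinomir import hairpin
from dinomir.hairpin import (
    SecondaryStructure,
    evaluate,
    extract_windows,
    fold,
    pairs_from_dotbracket,
    precursor_stats,
)

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


def nussinov_max_pairs(s, min_loop=3):
    """Independent maximum base-pairing count (plain Nussinov DP)."""
    s = s.upper().replace("U", "T")
    n = len(s)
    ok = lambda a, b: (a + b) in ("AT", "TA", "GC", "CG", "GT", "TG")
    dp = [[0] * n for _ in range(n)]
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i][j - 1]
            for k in range(i, j - min_loop):
                if ok(s[k], s[j]):
                    left = dp[i][k - 1] if k > i else 0
                    inner = dp[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    best = max(best, left + inner + 1)
            dp[i][j] = best
    return dp[0][n - 1]


UNIFORM = {"AT": 1.0, "GC": 1.0, "GT": 1.0}


class TestFold:
    def test_perfect_stem_pairs_exactly(self):
        # 20-bp A/T stem closed by a C-only loop: no alternative pairings
        rng = np.random.default_rng(7)
        arm = "".join(rng.choice(["A", "T"], size=20))
        seq = arm + "CCCC" + revcomp(arm)
        ss = fold(seq, length_bounds=None)
        assert ss.n_pairs == 20
        assert ss.dot_bracket == "(" * 20 + "." * 4 + ")" * 20

    def test_homopolymer_unfolded(self):
        ss = fold("A" * 60)
        assert ss.n_pairs == 0
        assert ss.energy == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_pair_count_matches_nussinov_oracle(self, seed):
        # uniform scores, no stacking bonus -> maximum base pairing
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 41))
        seq = "".join(rng.choice(list("ACGT"), size=n))
        ss = fold(seq, pair_scores=UNIFORM, stack_bonus=0.0, length_bounds=None)
        assert ss.n_pairs == nussinov_max_pairs(seq)

    @pytest.mark.parametrize("seed", range(8))
    def test_structure_validity(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 120))))
        ss = fold(seq)
        pairs = pairs_from_dotbracket(ss.dot_bracket)  # balanced or raises
        for i, j in pairs.items():
            if i < j:
                assert (seq[i] + seq[j]).replace("U", "T") in (
                    "AT", "TA", "GC", "CG", "GT", "TG",
                )
                assert j - i - 1 >= 3

    def test_stack_extension_never_raises_energy(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            arm = "".join(rng.choice(list("ACGT"), size=15))
            base = arm + "CAAC" + revcomp(arm)
            ext = "G" + base + "C"  # one more closing pair
            e_base = fold(base, length_bounds=None).energy
            e_ext = fold(ext, length_bounds=None).energy
            assert e_ext <= e_base

    def test_length_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside foldable range"):
            fold("ACGT" * 5)  # 20 nt < 50

    def test_determinism(self):
        seq = "GCATGCAAGCTTGCATGCAGCTTAAGCTGCATGCAAGCTTGCATGC" + "A" * 20
        assert fold(seq).dot_bracket == fold(seq).dot_bracket


class TestWindows:
    def test_three_windows_with_stated_flank(self):
        contig = "A" * 200
        assert extract_windows(100, 121, contig, flank=60) == [
            (40, 121), (100, 181), (40, 181),
        ]

    def test_left_truncation_at_contig_start(self):
        contig = "A" * 200
        wins = extract_windows(5, 26, contig, flank=60)
        assert wins[0] == (1, 26)
        assert wins[2] == (1, 86)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            extract_windows(10, 500, "A" * 100)


def designed_structure(s1, s2, bulge, loop, energy):
    """Hairpin with an s1-pair outer helix, a one-sided 5'-arm bulge of
    ``bulge`` nt, an s2-pair inner helix and a ``loop``-nt terminal loop."""
    db = "(" * s1 + "." * bulge + "(" * s2 + "." * loop + ")" * (s1 + s2)
    return SecondaryStructure("A" * len(db), db, energy)


class TestCriteria:
    def test_perfect_designed_precursor_passes_all(self):
        rng = np.random.default_rng(3)
        arm = "".join(rng.choice(["A", "T"], size=25))
        seq = arm + "CCCC" + revcomp(arm)
        ss = fold(seq, length_bounds=None)
        rep = evaluate(ss, (1, 20))  # mature on the 5' arm
        assert rep.overall, rep.failed()

    def test_13nt_stem_bulge_fails_c1(self):
        ss = designed_structure(s1=22, s2=8, bulge=13, loop=4, energy=-40.0)
        rep = evaluate(ss, (1, 20))
        assert not rep.criteria["c1"].passed
        assert rep.criteria["c1"].value == 13
        assert rep.criteria["c2"].passed  # 30 stem pairs

    def test_weak_energy_fails_c3(self):
        ss = designed_structure(s1=25, s2=0, bulge=0, loop=4, energy=-14.0)
        rep = evaluate(ss, (1, 20))
        assert not rep.criteria["c3"].passed
        assert rep.overall is False

    def test_no_hairpin_loop_fails_everything(self):
        ss = SecondaryStructure("A" * 60, "." * 60, 0.0)
        rep = evaluate(ss, (1, 20))
        assert not rep.overall
        assert not rep.criteria["c2"].passed

    def test_thirty_designed_hairpins_match_construction_flags(self):
        # construction-time ground truth: flags derived from the design
        # parameters by independent arithmetic
        rng = np.random.default_rng(42)
        for _ in range(30):
            s1 = int(rng.integers(20, 31))
            s2 = int(rng.integers(0, 10))
            bulge = int(rng.integers(0, 16)) if s2 > 0 else 0
            loop = int(rng.integers(4, 210))
            energy = float(rng.uniform(-60, -5))
            ss = designed_structure(s1, s2, bulge, loop, energy)
            rep = evaluate(ss, (1, 20))
            n = s1 + s2
            expected = {
                "c1": bulge <= 12,
                "c2": n >= 16,
                "c3": energy <= -15.0,
                "c4": (2 * n + bulge + loop) >= 50,
                "c5": loop <= 200,
                "c6": True,  # mature inside the perfect outer helix
                "c7": True,
                "c8": True,
                "c9": True,
                "c10": True,  # 20 paired mature positions
                "c11": True,
            }
            got = {k: rep.criteria[k].passed for k in expected}
            assert got == expected, (s1, s2, bulge, loop, energy)

    def test_mature_region_imperfections_counted(self):
        # bulge inside the mature region: 3-nt one-sided run after 10 pairs
        ss = designed_structure(s1=10, s2=12, bulge=3, loop=4, energy=-40.0)
        rep = evaluate(ss, (1, 13))  # mature spans the bulge run
        assert rep.criteria["c6"].value == 3
        assert rep.criteria["c8"].value == 1  # one biased bulge event
        assert rep.criteria["c9"].value == 0  # no mismatch-like errors
        # 5-nt version breaks the <=4 limit
        ss = designed_structure(s1=10, s2=12, bulge=5, loop=4, energy=-40.0)
        rep = evaluate(ss, (1, 15))
        assert not rep.criteria["c6"].passed

    def test_symmetric_internal_loop_counts_errors(self):
        # 2x2 internal loop inside mature: errors=2, no bulge
        db = "(" * 10 + ".." + "(" * 10 + "...." + ")" * 10 + ".." + ")" * 10
        ss = SecondaryStructure("A" * len(db), db, -40.0)
        rep = evaluate(ss, (1, 14))
        assert rep.criteria["c9"].value == 2
        assert rep.criteria["c8"].value == 0
        assert rep.criteria["c7"].value == 0  # symmetric -> not biased

    def test_evaluate_is_pure(self):
        ss = designed_structure(20, 5, 2, 6, -30.0)
        r1, r2 = evaluate(ss, (1, 18)), evaluate(ss, (1, 18))
        assert r1 == r2


class TestStats:
    def test_gc_all(self):
        ss = SecondaryStructure("GGCC", "....", 0.0)
        assert precursor_stats("GGCC", ss)[1] == 100.0

    def test_random_gc_matches_letter_count(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=100))
        ss = SecondaryStructure(seq, "." * 100, 0.0)
        length, gc, dg = precursor_stats(seq, ss)
        assert length == 100
        assert gc == round(
            100 * sum(1 for b in seq if b in "GC") / 100, 2
        )

    def test_criterion_threshold_helper(self):
        assert hairpin.criterion_passes("c3", -67.8)
        assert not hairpin.criterion_passes("c3", -14.0)
        assert hairpin.criterion_passes("c4", 96)
        assert not hairpin.criterion_passes("c4", 49)


class TestVienna:
    def test_roundtrip(self, tmp_path):
        ss = fold("GCATGCAAGCTTGCATGCAG" + "CCCC" + "CTGCATGCAAGCTTGCATGC",
                  length_bounds=None)
        path = tmp_path / "x.vienna"
        hairpin.write_vienna([("cand1", ss)], path)
        (name, back), = hairpin.read_vienna(path)
        assert name == "cand1"
        assert back.dot_bracket == ss.dot_bracket
        assert back.energy == pytest.approx(ss.energy, abs=0.01)
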