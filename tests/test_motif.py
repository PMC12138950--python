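import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaregnet.motif import (
    MotifError,
    Pwm,
    RegionSpec,
    filter_canonical_hits,
    read_jaspar_pfm,
    relative_score,
    reverse_complement,
    scan_region,
    write_jaspar_pfm,
)

# literature consensus pairs of the binding motifs used in the worked example
CONSENSUS_PAIRS = {
    "MSC": ("AACAGCTGTT", "AACAGCTGTT"),
    "SNAI2": ("CACCTG", "CAGGTG"),
    "TWIST1": ("CATCTG", "CAGATG"),
    "PRRX1": ("TAATT", "AATTA"),
    "EGR2": ("CGCCCACGC", "GCGTGGGCG"),
    "HEY1": ("CACGTG", "CACGTG"),
    "BCL6B": ("AATTCCTAGAAAGCA", "TGCTTTCTAGGAATT"),
    "MEIS3": ("TGTCA", "TGACA"),
}


class TestReverseComplement:
    @pytest.mark.parametrize("name,pair", CONSENSUS_PAIRS.items())
    def test_literature_consensus_pairs(self, name, pair):
        fwd, rev = pair
        assert reverse_complement(fwd) == rev

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=30))
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq

    def test_illegal_character(self):
        with pytest.raises(MotifError):
            reverse_complement("ACGU")


def toy_pwm(name="toy", cols=((8, 1, 1, 1), (1, 8, 1, 1), (1, 1, 8, 1))):
    return Pwm(name, np.array(cols, dtype=float).T)


class TestJasparIO:
    def test_parse_six_column_matrix(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA1123.3 TWIST1\n"
            "A [  1 90  2  1  2  1 ]\n"
            "C [ 90  2  1 90  2  1 ]\n"
            "G [  5  4  3  5  4 90 ]\n"
            "T [  4  4 94  4 92  6 ]\n"
        )
        pwms = read_jaspar_pfm(path)
        assert pwms[0].length == 6
        assert pwms[0].consensus() == "CATCTG"

    def test_round_trip_counts(self, tmp_path):
        pwm = toy_pwm()
        path = tmp_path / "rt.jaspar"
        write_jaspar_pfm([pwm], path)
        back = read_jaspar_pfm(path)[0]
        assert np.allclose(back.counts, pwm.counts)

    def test_uniform_matrix_is_degenerate(self):
        with pytest.raises(MotifError, match="degenerate"):
            Pwm("flat", np.full((4, 5), 10.0))


class TestRelativeScore:
    def test_best_window_scores_one(self):
        pwm = toy_pwm()
        assert relative_score(pwm, "ACG") == pytest.approx(1.0)

    def test_worst_window_scores_zero(self):
        pwm = toy_pwm()
        # per-column argmin base: any of the 3 non-consensus bases ties at 1
        worst = min(
            ("".join(w) for w in itertools.product("ACGT", repeat=3)),
            key=lambda w: relative_score(pwm, w),
        )
        assert relative_score(pwm, worst) == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration(self):
        pwm = toy_pwm()
        kappa, bg = pwm.pseudocount, 0.25
        for window in ("".join(w) for w in itertools.product("ACGT", repeat=3)):
            s = 0.0
            for j, b in enumerate(window):
                col = pwm.counts[:, j]
                p = (col["ACGT".index(b)] + kappa * bg) / (col.sum() + kappa)
                s += np.log2(p / bg)
            expected = (s - pwm.s_min) / (pwm.s_max - pwm.s_min)
            assert relative_score(pwm, window) == pytest.approx(expected, abs=1e-12)

    def test_n_in_window_scores_zero(self):
        assert relative_score(toy_pwm(), "ANG") == 0.0

    def test_length_mismatch(self):
        with pytest.raises(MotifError):
            relative_score(toy_pwm(), "ACGT")

    def test_agrees_with_biopython_pssm(self):
        from Bio import motifs as bio_motifs
        from Bio.Seq import Seq

        counts = {"A": [8, 1, 1], "C": [1, 8, 1], "G": [1, 1, 8], "T": [1, 1, 1]}
        m = bio_motifs.Motif(
            alphabet="ACGT",
            counts=bio_motifs.matrix.FrequencyPositionMatrix("ACGT", counts),
        )
        m.pseudocounts = {b: 0.8 * 0.25 for b in "ACGT"}
        pssm = m.pssm
        ours = Pwm("bio", np.array([counts[b] for b in "ACGT"], dtype=float))
        for window in ("ACG", "TTT", "AAG"):
            raw = ours.log_odds[
                [("ACGT").index(b) for b in window], np.arange(3)
            ].sum()
            assert raw == pytest.approx(pssm.calculate(Seq(window)), abs=1e-5)


def plant(seq_len, planted, fill="T"):
    seq = list(fill * seq_len)
    for start, s in planted:
        seq[start - 1:start - 1 + len(s)] = list(s)
    return "".join(seq)


class TestScanRegion:
    def _pwm(self, consensus):
        counts = np.full((4, len(consensus)), 2.0)
        for j, b in enumerate(consensus):
            counts["ACGT".index(b), j] = 90.0
        return Pwm(consensus, counts)

    def test_forward_planted_site_found(self):
        pwm = self._pwm("CACCTG")
        region = RegionSpec("g", "promoter", plant(300, [(100, "CACCTG")], fill="A"))
        hits = scan_region(pwm, region)
        assert any(h.start == 100 and h.strand == "+" for h in hits)

    def test_reverse_consensus_found_on_minus_strand(self):
        # forward-strand CAGGTG is the minus-strand image of consensus CACCTG
        pwm = self._pwm("CACCTG")
        region = RegionSpec("g", "promoter", plant(300, [(150, "CAGGTG")], fill="A"))
        hits = scan_region(pwm, region)
        minus = [h for h in hits if h.strand == "-"]
        assert any(h.start == 150 and h.matched_forward == "CAGGTG" for h in minus)

    def test_all_n_sequence_yields_nothing(self):
        assert scan_region(self._pwm("CACCTG"), RegionSpec("g", "promoter", "N" * 50)) == []

    def test_short_region_warns_empty(self):
        with pytest.warns(UserWarning):
            out = scan_region(self._pwm("CACCTG"), RegionSpec("g", "promoter", "ACG"))
        assert out == []

    def test_hit_count_monotone_in_threshold(self, rng):
        pwm = self._pwm("CACGTG")
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        region = RegionSpec("g", "promoter", seq)
        counts = [len(scan_region(pwm, region, t)) for t in (0.5, 0.7, 0.85, 0.95)]
        assert counts == sorted(counts, reverse=True)

    def test_strand_symmetry_of_reversed_region(self, rng):
        pwm = self._pwm("CATCTG")
        seq = "".join(rng.choice(list("ACGT"), size=400))
        fwd_hits = scan_region(pwm, RegionSpec("g", "promoter", seq), 0.8)
        rev_hits = scan_region(
            pwm, RegionSpec("g", "promoter", reverse_complement(seq)), 0.8
        )
        L, Lr = pwm.length, len(seq)
        mapped = {(Lr - h.start - L + 2, {"+": "-", "-": "+"}[h.strand]) for h in rev_hits}
        assert {(h.start, h.strand) for h in fwd_hits} == mapped


class TestCanonicalFilter:
    def _hits(self, pwm_name, matches):
        pwm = TestScanRegion()._pwm("CACCTG")
        region = RegionSpec("g", "promoter", plant(200, matches, fill="A"))
        hits = scan_region(pwm, region, threshold=0.5)
        for h in hits:
            h.pwm = pwm_name
        return hits

    def test_consensus_match_kept_and_mismatch_removed(self):
        cmap = {"SNAI2": ("CACCTG", "CAGGTG")}
        kept = filter_canonical_hits(self._hits("SNAI2", [(50, "CACCTG")]), cmap)
        assert all(h.matched_forward in cmap["SNAI2"] for h in kept)
        assert any(h.start == 50 for h in kept)
        near = filter_canonical_hits(self._hits("SNAI2", [(50, "CACGTG")]), cmap)
        assert all(h.start != 50 for h in near)

    def test_no_consensus_entry_passes_through(self):
        hits = self._hits("VENTX", [(50, "CACCTG")])
        kept = filter_canonical_hits(hits, {"VENTX": None})
        assert len(kept) == len(hits)
        assert all(h.canonical is False for h in kept)

    def test_consensus_length_mismatch_rejected(self):
        with pytest.raises(MotifError, match="length"):
            filter_canonical_hits(self._hits("SNAI2", [(50, "CACCTG")]),
                                  {"SNAI2": ("CACC", "GGTG")})
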