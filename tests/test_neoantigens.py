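"""Phasing, window enumeration, fusion junctions, scoring, abundance."""

import pytest

from sarcimmune.neoantigens import (ConstantScorer, PhasingError, ScorerContractError,
                                    SurrogateScorer, apply_phasing,
                                    build_reference_kmers, dedupe_peptides,
                                    enumerate_windows, fusion_junction_peptides,
                                    peptide_abundance, score_candidates,
                                    uniqueness_filter)
from sarcimmune.variants import FusionEvent, SomaticVariant

AA = "ACDEFGHIKLMNPQRSTVWY"


def mk_var(vid, pos, aa_ref, aa_alt, consequence="missense", phase_set="",
           fs_tail=""):
    return SomaticVariant(id=vid, chrom="1", position=1000 + pos, ref="A", alt="T",
                          n_callers=3, depth_tumor=50, depth_normal=40,
                          alt_reads_tumor=10, vaf_dna=0.3, vaf_rna=0.3,
                          consequence=consequence, phase_set=phase_set,
                          protein_id="P1", protein_pos=pos, aa_ref=aa_ref,
                          aa_alt=aa_alt, fs_tail=fs_tail)


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


class TestPhasing:
    def test_phased_pair_yields_one_doubly_edited_sequence(self, rng):
        wt = random_protein(rng, 40)
        v1 = mk_var("v1", 10, wt[9], "W" if wt[9] != "W" else "Y", phase_set="ps1")
        v2 = mk_var("v2", 12, wt[11], "W" if wt[11] != "W" else "Y", phase_set="ps1")
        out = apply_phasing(wt, [v1, v2])
        assert len(out) == 1
        seq, ids = out[0]
        assert set(ids) == {"v1", "v2"}
        assert seq[9] == v1.aa_alt and seq[11] == v2.aa_alt
        assert len(seq) == len(wt)

    def test_unphased_pair_yields_two_single_edit_sequences(self, rng):
        wt = random_protein(rng, 40)
        v1 = mk_var("v1", 10, wt[9], "W" if wt[9] != "W" else "Y")
        v2 = mk_var("v2", 12, wt[11], "W" if wt[11] != "W" else "Y")
        out = apply_phasing(wt, [v1, v2])
        assert len(out) == 2
        diffs = [sum(a != b for a, b in zip(seq, wt)) for seq, _ in out]
        assert diffs == [1, 1]

    def test_frameshift_diverges_to_stop(self, rng):
        wt = random_protein(rng, 40)
        v = mk_var("v1", 20, "", "", consequence="frameshift", fs_tail="WWYYK")
        (seq, _), = apply_phasing(wt, [v])
        assert seq == wt[:19] + "WWYYK"

    def test_conflicting_overlap_in_one_phase_set_raises(self, rng):
        wt = random_protein(rng, 40)
        v1 = mk_var("v1", 10, wt[9], "W" if wt[9] != "W" else "Y", phase_set="ps")
        v2 = mk_var("v2", 10, wt[9], "M" if wt[9] != "M" else "Y", phase_set="ps")
        with pytest.raises(PhasingError, match="overlap"):
            apply_phasing(wt, [v1, v2])

    def test_composition_identity_with_enumeration(self, rng):
        """Enumerating a jointly phased pair equals enumerating the jointly
        edited sequence directly."""
        wt = random_protein(rng, 60)
        alt1 = "W" if wt[19] != "W" else "Y"
        alt2 = "M" if wt[24] != "M" else "Y"
        v1 = mk_var("v1", 20, wt[19], alt1, phase_set="ps")
        v2 = mk_var("v2", 25, wt[24], alt2, phase_set="ps")
        (mutant, _), = apply_phasing(wt, [v1, v2])
        direct = wt[:19] + alt1 + wt[20:24] + alt2 + wt[25:]
        assert mutant == direct
        a = [(p.sequence, p.window_start) for p in enumerate_windows(mutant, wt)]
        b = [(p.sequence, p.window_start) for p in enumerate_windows(direct, wt)]
        assert a == b


def brute_force_windows(mutant, wt, lengths):
    """Independent all-window check: overlap with an altered residue plus
    difference from the aligned wild-type window (same-length case)."""
    if len(mutant) == len(wt):
        altered = {i + 1 for i, (a, b) in enumerate(zip(mutant, wt)) if a != b}
        same_len = True
    else:
        first = 0
        while first < min(len(mutant), len(wt)) and mutant[first] == wt[first]:
            first += 1
        altered = set(range(first + 1, len(mutant) + 1))
        same_len = False
    out = []
    for L in lengths:
        for s in range(1, len(mutant) - L + 2):
            if not altered & set(range(s, s + L)):
                continue
            win = mutant[s - 1:s - 1 + L]
            if same_len and win == wt[s - 1:s - 1 + L]:
                continue
            out.append((L, s, win))
    return out


class TestWindows:
    def test_interior_substitution_window_counts(self, rng):
        wt = random_protein(rng, 100)
        mut = wt[:14] + ("W" if wt[14] != "W" else "Y") + wt[15:]
        nine = enumerate_windows(mut, wt, lengths=[9])
        assert len(nine) == 9
        assert [p.window_start for p in nine] == list(range(7, 16))
        both = enumerate_windows(mut, wt, lengths=[9, 10])
        assert len(both) == 19

    def test_substitution_at_first_residue(self, rng):
        wt = random_protein(rng, 50)
        mut = ("W" if wt[0] != "W" else "Y") + wt[1:]
        wins = enumerate_windows(mut, wt, lengths=[9])
        assert len(wins) == 1 and wins[0].window_start == 1
        assert wins[0].altered_positions == (1,)

    def test_matches_bruteforce_on_random_proteins(self, rng):
        for _ in range(100):
            n = int(rng.integers(12, 200))
            wt = random_protein(rng, n)
            kind = rng.choice(["sub", "frameshift", "inframe"])
            pos = int(rng.integers(1, n + 1))
            if kind == "sub":
                alt = "W" if wt[pos - 1] != "W" else "Y"
                mut = wt[:pos - 1] + alt + wt[pos:]
            elif kind == "frameshift":
                mut = wt[:pos - 1] + random_protein(rng, int(rng.integers(9, 30)))
            else:
                mut = wt[:pos - 1] + wt[pos - 1] + random_protein(rng, 2) + wt[pos:]
            got = [(len(p.sequence), p.window_start, p.sequence)
                   for p in enumerate_windows(mut, wt)]
            assert got == brute_force_windows(mut, wt, (9, 10))

    def test_no_difference_yields_no_windows(self, rng):
        wt = random_protein(rng, 30)
        assert enumerate_windows(wt, wt) == []


class TestFusionWindows:
    def make(self, rng, n5, n3, frame):
        return FusionEvent("f1", "G5", "G3", random_protein(rng, n5),
                           random_protein(rng, n3), frame, "high")

    def test_in_frame_window_counts(self, rng):
        f = self.make(rng, 12, 12, "in_frame")
        assert len(fusion_junction_peptides(f, lengths=[9])) == 8
        assert len(fusion_junction_peptides(f, lengths=[10])) == 9

    def test_out_of_frame_novel_only(self, rng):
        f = self.make(rng, 12, 5, "out_of_frame")
        wins = fusion_junction_peptides(f, lengths=[9])
        # every window must contain >= 1 novel residue
        for w in wins:
            assert w.window_start + 8 >= 13
        assert len(wins) == 5

    def test_short_context_fewer_windows_no_error(self, rng):
        f = self.make(rng, 3, 2, "in_frame")
        assert fusion_junction_peptides(f, lengths=[9]) == []

    def test_matches_bruteforce(self, rng):
        for _ in range(100):
            n5 = int(rng.integers(1, 20))
            n3 = int(rng.integers(1, 20))
            frame = str(rng.choice(["in_frame", "out_of_frame"]))
            f = self.make(rng, n5, n3, frame)
            full = f.junction_seq5 + f.junction_seq3
            expected = []
            for L in (9, 10):
                for s in range(1, len(full) - L + 2):
                    e = s + L - 1
                    spans = s <= n5 and e >= n5 + 1
                    touches_novel = e >= n5 + 1
                    if (frame == "in_frame" and spans) or (
                            frame == "out_of_frame" and touches_novel):
                        expected.append((L, s, full[s - 1:e]))
            got = [(len(p.sequence), p.window_start, p.sequence)
                   for p in fusion_junction_peptides(f)]
            assert got == expected


class TestUniquenessAndScoring:
    def test_uniqueness_filter(self, rng):
        wt = random_protein(rng, 120)
        proteome = {"P1": wt}
        kmers = build_reference_kmers(proteome)
        mut = wt[:49] + ("W" if wt[49] != "W" else "Y") + wt[50:]
        wins = enumerate_windows(mut, wt, lengths=[9])
        assert uniqueness_filter(wins, kmers) == wins  # true mutants survive
        # a window identical to a proteome k-mer is dropped
        fake_self = enumerate_windows(wt[10:19], "W" * 9, lengths=[9])
        assert uniqueness_filter(fake_self, kmers) == []
        assert uniqueness_filter(wins, set()) == wins

    def test_score_candidates_contract(self, rng):
        wt = random_protein(rng, 60)
        mut = wt[:29] + ("W" if wt[29] != "W" else "Y") + wt[30:]
        peps = enumerate_windows(mut, wt, lengths=[9])[:3]
        alleles = ["HLA-A*02:01", "HLA-B*07:02", "HLA-C*07:01"]
        cands = score_candidates(peps, alleles, ConstantScorer(0.7))
        assert len(cands) == 6  # HLA-C excluded
        assert all(c.ap_score == 0.7 for c in cands)
        assert not any(c.hla_allele.startswith("HLA-C") for c in cands)

        class BadScorer:
            deterministic = True

            def score(self, p, a):
                return 1.5

        with pytest.raises(ScorerContractError):
            score_candidates(peps, alleles, BadScorer())

    def test_surrogate_scorer_deterministic_and_bounded(self):
        s = SurrogateScorer()
        vals = [s.score("ACDEFGHIK", "HLA-A*02:01") for _ in range(3)]
        assert vals[0] == vals[1] == vals[2]
        assert 0.0 <= vals[0] <= 1.0
        assert s.score("ACDEFGHIK", "HLA-B*07:02") != vals[0]

    def test_dedupe(self, rng):
        wt = random_protein(rng, 40)
        mut = wt[:19] + ("W" if wt[19] != "W" else "Y") + wt[20:]
        wins = enumerate_windows(mut, wt, lengths=[9])
        assert dedupe_peptides(wins + wins) == wins


@pytest.mark.parametrize("tpms,vaf,expected", [
    ({"i1": 10.0, "i2": 5.0}, 0.5, 7.5),
    ({"i1": 10.0}, 0.0, 0.0),
    ({"i1": 8.0}, 1.0, 8.0),
])
def test_peptide_abundance(tpms, vaf, expected):
    assert peptide_abundance(tpms, vaf) == pytest.approx(expected)


def test_peptide_abundance_rejects_bad_vaf():
    with pytest.raises(ValueError):
        peptide_abundance({"i": 1.0}, 1.5)
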