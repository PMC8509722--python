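"""Evidence descriptor computations."""

import math
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from varodds import (
    EvidenceContext,
    PredictorCalls,
    build_profile,
    complexity_descriptor,
    conservation_descriptor,
    find_ppxsp_motifs,
    motif_descriptor,
    predictor_damage_count,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestConservation:
    def test_identical_column_fully_conserved(self):
        assert conservation_descriptor(["R"] * 10) == (1.0, 1)

    def test_three_of_four(self):
        score, flag = conservation_descriptor(list("RRRK"))
        assert score == pytest.approx(0.75)
        assert flag == 0

    def test_all_gap_column(self):
        assert conservation_descriptor(["-", "-"]) == (0.0, 0)

    def test_unknown_symbol_rejected(self):
        with pytest.raises(ValueError, match="residue"):
            conservation_descriptor(["R", "X"])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from(AA + "-"), min_size=1, max_size=50))
    def test_matches_tally_oracle(self, column):
        score, flag = conservation_descriptor(column)
        residues = [c for c in column if c != "-"]
        expected = (
            max(Counter(residues).values()) / len(residues) if residues else 0.0
        )
        assert score == pytest.approx(expected)
        assert flag == int(expected >= 0.9 and bool(residues))

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.sampled_from(AA), min_size=1, max_size=20))
    def test_monotone_as_modal_residue_added(self, column):
        modal = Counter(column).most_common(1)[0][0]
        before, _ = conservation_descriptor(column)
        after, _ = conservation_descriptor(column + [modal])
        assert after >= before


class TestComplexity:
    def test_homopolymer_zero_entropy_low_complexity(self):
        assert complexity_descriptor("A" * 10) == (0.0, 1)

    def test_sixteen_distinct_residues_four_bits(self):
        entropy, flag = complexity_descriptor(AA[:16])
        assert entropy == pytest.approx(4.0)
        assert flag == 0

    def test_short_window_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            complexity_descriptor("ACDE")

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet=AA, min_size=5, max_size=40))
    def test_matches_frequency_sum_oracle(self, window):
        entropy, flag = complexity_descriptor(window)
        n = len(window)
        expected = -sum(
            (c / n) * math.log2(c / n) for c in Counter(window).values()
        )
        assert entropy == pytest.approx(expected)
        assert 0.0 <= entropy <= math.log2(20)
        assert flag == int(expected < 2.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.text(alphabet=AA, min_size=5, max_size=30), st.randoms())
    def test_permutation_invariant(self, window, rnd):
        shuffled = list(window)
        rnd.shuffle(shuffled)
        assert complexity_descriptor("".join(shuffled))[0] == pytest.approx(
            complexity_descriptor(window)[0]
        )


class TestMotifs:
    def test_planted_ppxsp_found(self):
        assert find_ppxsp_motifs("AAPPASPAA") == [(3, 7)]

    def test_five_planted_pppsp(self):
        tail = "".join("G" * 10 + "PPPSP" for _ in range(5)) + "GG"
        assert len(find_ppxsp_motifs(tail)) == 5

    def test_position_between_flanking_motifs_within_proximity(self):
        motifs = [(1575, 1579), (1590, 1594)]
        assert motif_descriptor(1585, motifs, proximity=5) == 1

    def test_distant_position_not_flagged(self):
        assert motif_descriptor(99, [(1520, 1524), (1590, 1600)]) == 0

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="PSAG", min_size=5, max_size=60))
    def test_matches_sliding_window_oracle(self, s):
        hits = find_ppxsp_motifs(s)
        expected = [
            (i + 1, i + 5)
            for i in range(len(s) - 4)
            if s[i] == "P" and s[i + 1] == "P" and s[i + 3] == "S" and s[i + 4] == "P"
        ]
        assert hits == expected

    @settings(derandomize=True, max_examples=50)
    @given(
        st.integers(1, 200),
        st.lists(st.tuples(st.integers(1, 180), st.integers(0, 15)), max_size=5),
        st.integers(0, 10),
    )
    def test_motif_descriptor_matches_membership_oracle(self, pos, raw, prox):
        motifs = sorted((s, s + w) for s, w in raw)
        expected = int(
            any(s - prox <= p <= e + prox for (s, e) in motifs for p in [pos])
        )
        assert motif_descriptor(pos, motifs, proximity=prox) == expected


DAMAGING = PredictorCalls("probably_damaging", "not_tolerated", "disease", -0.3)
BENIGN = PredictorCalls("benign", "tolerated", "neutral", -0.45)


class TestPredictorDamageCount:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            (DAMAGING, 3),
            (BENIGN, 0),
            (PredictorCalls("possibly_damaging", "tolerated", "neutral", -1.17), 1),
            (PredictorCalls("benign", "tolerated", "disease", -0.83), 1),
            (PredictorCalls("probably_damaging", "tolerated", "disease", -0.48), 2),
        ],
    )
    def test_counts(self, calls, expected):
        assert predictor_damage_count(calls) == expected

    def test_ddg_not_counted(self):
        a = PredictorCalls("benign", "tolerated", "neutral", -5.0)
        b = PredictorCalls("benign", "tolerated", "neutral", -0.01)
        assert predictor_damage_count(a) == predictor_damage_count(b) == 0

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError, match="polyphen"):
            PredictorCalls("damaging", "tolerated", "neutral", 0.0)


class TestBuildProfile:
    def test_empty_evidence_all_zero(self):
        prof = build_profile("p.X1Y", BENIGN, EvidenceContext())
        assert prof.as_tuple() == (0, 0, 0, 0, 0, 0, 0, 0)

    def test_motif_and_full_agreement(self):
        prof = build_profile(
            "p.S1585L", DAMAGING, EvidenceContext(on_linear_motif=True)
        )
        assert prof.d5 == 1 and prof.d6 == 1

    def test_label_mismatch_rejected(self):
        p = PredictorCalls("benign", "tolerated", "neutral", 0.0, variant="p.A1B")
        with pytest.raises(ValueError, match="mismatch"):
            build_profile("p.C2D", p, EvidenceContext())

    def test_mutually_exclusive_prior_flags_rejected(self):
        with pytest.raises(ValueError, match="exclusive"):
            EvidenceContext(
                literature_pathogenic=True, dbsnp_low_freq_no_functional=True
            )

    @settings(derandomize=True, max_examples=100)
    @given(
        st.tuples(*[st.booleans()] * 7),
        st.sampled_from(["benign", "possibly_damaging", "probably_damaging"]),
        st.sampled_from(["tolerated", "not_tolerated"]),
        st.sampled_from(["neutral", "disease"]),
    )
    def test_each_descriptor_equals_its_predicate(self, flags, pp, sf, pm):
        lit, ann, fd, sd, mot, cons, lc = flags
        e = EvidenceContext(
            literature_pathogenic=lit,
            dbsnp_low_freq_no_functional=False,
            prior_annotation_in_db=ann,
            in_functional_domain=fd,
            in_structured_domain=sd,
            on_linear_motif=mot,
            conserved_position=cons,
            low_complexity_context=lc,
        )
        p = PredictorCalls(pp, sf, pm, -0.5)
        prof = build_profile("p.X1Y", p, e)
        assert prof.as_tuple() == (
            int(cons), int(fd), int(lc), int(sd), int(mot),
            int(predictor_damage_count(p) >= 2), int(ann), int(lit),
        )
        # pure function: identical inputs give identical profiles
        assert build_profile("p.X1Y", p, e) == prof
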