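"""Feature extraction: N-grams, AAC, Active Motifs, repeats, DD, DDSM."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ddsm import (
    STANDARD_ALPHABET,
    LabeledSequenceSet,
    amino_acid_composition,
    dd_filter,
    extract_active_motifs,
    extract_dd,
    extract_ddsm,
    extract_ngrams,
    extract_repeats,
)
from ddsm.extractors import TooManyFeaturesError, segments
from conftest import WORKED_MOTIFS

seq_st = st.text(alphabet="ARNDCGGK", min_size=1, max_size=30)


def single_family(*seqs):
    return LabeledSequenceSet.from_records(
        [(f"s{i}", s, "F1" if i == 0 else "F2") for i, s in enumerate(seqs)]
    )


def one_label_set(*seqs):
    return LabeledSequenceSet.from_records(
        [(f"s{i}", s, "F1") for i, s in enumerate(seqs)]
    )


class TestNgrams:
    def test_sliding_window(self):
        assert set(extract_ngrams(one_label_set("MKLV"), 3).features) == {"MKL", "KLV"}

    def test_distinctness(self):
        assert extract_ngrams(one_label_set("AAAA"), 2).features == ("AA",)

    def test_separator_blocks_windows(self):
        assert extract_ngrams(one_label_set("MKXLV"), 3).features == ()

    def test_window_longer_than_sequences(self):
        assert extract_ngrams(one_label_set("MK"), 5).features == ()

    @settings(deadline=None, max_examples=30)
    @given(seqs=st.lists(seq_st, min_size=1, max_size=4), n=st.integers(1, 4))
    def test_size_bound_and_exact_length(self, seqs, n):
        s = one_label_set(*seqs)
        fs = extract_ngrams(s, n)
        assert len(fs) <= sum(max(0, len(q) - n + 1) for q in seqs)
        assert all(len(f) == n for f in fs.features)


class TestAAC:
    def test_pure_sequence(self):
        v = amino_acid_composition("AAAA")
        assert v[STANDARD_ALPHABET.index("A")] == 1.0
        assert v.sum() == pytest.approx(1.0)

    def test_equal_mix(self):
        v = amino_acid_composition("ARAR")
        assert v[STANDARD_ALPHABET.index("A")] == 0.5
        assert v[STANDARD_ALPHABET.index("R")] == 0.5

    def test_one_of_each(self):
        v = amino_acid_composition(STANDARD_ALPHABET)
        assert np.allclose(v, 0.05)

    def test_no_standard_residues_rejected(self):
        with pytest.raises(ValueError):
            amino_acid_composition("XXX")

    @settings(deadline=None, max_examples=30)
    @given(seq=seq_st)
    def test_sums_to_one(self, seq):
        assert amino_acid_composition(seq).sum() == pytest.approx(1.0)


def brute_force_active(seqs, min_length, activity_pct, mutations):
    """Direct substring/activity enumeration, independent of the extractor."""

    def matches(motif, seq):
        for run in segments(seq):
            k = len(motif)
            for i in range(len(run) - k + 1):
                ham = sum(a != b for a, b in zip(motif, run[i : i + k]))
                if ham <= mutations:
                    return True
        return False

    candidates = set()
    for seq in seqs:
        for run in segments(seq):
            for i in range(len(run)):
                for j in range(i + min_length, len(run) + 1):
                    candidates.add(run[i:j])
    need = activity_pct / 100 * len(seqs)
    return {m for m in candidates if sum(matches(m, s) for s in seqs) >= need}


class TestActiveMotifs:
    def test_unanimous_exact_activity(self):
        s = one_label_set("MKLVA", "MKLVC", "MKLVD")
        fs = extract_active_motifs(s, min_length=3, activity_pct=100, mutations=0)
        assert set(fs.features) == {"MKL", "KLV", "MKLV"}

    def test_min_length_one_full_activity_gives_shared_residues(self):
        s = one_label_set("ARN", "AKN", "ALN")
        fs = extract_active_motifs(s, min_length=1, activity_pct=100, mutations=0)
        shared = set("ARN") & set("AKN") & set("ALN")
        assert {f for f in fs.features if len(f) == 1} == shared

    def test_short_sequences_yield_nothing(self):
        assert extract_active_motifs(one_label_set("AAA"), min_length=5).features == ()

    def test_one_mutation_cross_match(self):
        s = one_label_set("MKL", "MRL")
        fs = extract_active_motifs(s, min_length=3, activity_pct=100, mutations=1)
        assert set(fs.features) == {"MKL", "MRL"}

    def test_feature_cap_raises(self):
        s = one_label_set("ARNDCQEGHILKMFPSTWYV")
        with pytest.raises(TooManyFeaturesError):
            extract_active_motifs(s, min_length=1, activity_pct=1, feature_cap=10)

    @settings(deadline=None, max_examples=25)
    @given(
        seqs=st.lists(seq_st, min_size=1, max_size=3),
        min_length=st.integers(1, 3),
        activity=st.sampled_from([34.0, 50.0, 100.0]),
        mutations=st.integers(0, 1),
    )
    def test_matches_brute_force(self, seqs, min_length, activity, mutations):
        s = one_label_set(*seqs)
        fs = extract_active_motifs(s, min_length, activity, mutations)
        assert set(fs.features) == brute_force_active(seqs, min_length, activity, mutations)


def brute_force_repeats(family, min_length, max_length):
    subs_per_seq = []
    for seq in family:
        subs = []
        for run in segments(seq):
            for i in range(len(run)):
                for j in range(i + min_length, min(i + max_length, len(run)) + 1):
                    subs.append(run[i:j])
        subs_per_seq.append(subs)
    out = set()
    if len(family) == 1:
        from collections import Counter

        counts = Counter(subs_per_seq[0])
        out = {m for m, c in counts.items() if c >= 2}
    else:
        for i, subs in enumerate(subs_per_seq):
            for m in set(subs):
                if any(m in set(other) for j, other in enumerate(subs_per_seq) if j != i):
                    out.add(m)
    return out


class TestRepeats:
    def test_single_sequence_family(self):
        assert extract_repeats(["ABCAB".replace("B", "R")], 2, 5) == {"AR"}

    def test_cross_sequence_repeat(self):
        assert extract_repeats(["MKL", "MKV"], 2, 10) == {"MK"}

    def test_identical_sequences(self):
        assert extract_repeats(["MKL", "MKL"], 1, 3) == {"M", "K", "L", "MK", "KL", "MKL"}

    def test_length_bounds(self):
        reps = extract_repeats(["MKLVA", "MKLVA"], 2, 3)
        assert all(2 <= len(r) <= 3 for r in reps)

    @settings(deadline=None, max_examples=30)
    @given(
        family=st.lists(seq_st, min_size=1, max_size=4),
        min_length=st.integers(1, 3),
        max_length=st.integers(3, 8),
    )
    def test_matches_brute_force(self, family, min_length, max_length):
        assert extract_repeats(family, min_length, max_length) == brute_force_repeats(
            family, min_length, max_length
        )


class TestDDFilter:
    def test_family_specific_substrings(self, two_family_set):
        repeats = {
            "F1": extract_repeats(["MKLVA", "MKLVC"], 2, 10),
            "F2": extract_repeats(["GGPQR", "GGPQS"], 2, 10),
        }
        fs = dd_filter(repeats, two_family_set, alpha=0.0, beta=0.0)
        f2_text = "GGPQRGGPQS"
        for feature in fs.features:
            if feature[0] in "MKLV":
                assert feature not in f2_text
        assert "MK" in fs.features
        assert "MKL" not in fs.features  # pruned: MK is a retained proper substring

    def test_beta_one_is_vacuous(self, two_family_set):
        repeats = {"F1": {"MK", "GG"}, "F2": {"GG"}}
        fs = dd_filter(repeats, two_family_set, alpha=0.0, beta=1.0)
        assert "GG" in fs.features  # shared motif survives when beta disables exclusivity

    def test_shared_motif_excluded_at_beta_zero(self):
        s = single_family("MKGG", "GGPQ")
        fs = dd_filter({"F1": {"GG"}, "F2": {"GG"}}, s, alpha=0.0, beta=0.0)
        assert "GG" not in fs.features

    def test_exclusivity_property(self, two_family_set):
        repeats = {
            fam: extract_repeats(two_family_set.family_sequences(fam), 2, 10)
            for fam in two_family_set.families
        }
        fs = dd_filter(repeats, two_family_set, alpha=0.0, beta=0.0)
        for feature in fs.features:
            containing = {
                fam
                for fam in two_family_set.families
                if any(feature in q for q in two_family_set.family_sequences(fam))
            }
            assert len(containing) <= 1


class TestDDSM:
    def test_worked_motif_stub_collapses_to_five(self, blosum62):
        from ddsm import cluster_motifs, filter_main_motifs

        clustering = cluster_motifs(WORKED_MOTIFS, blosum62, 0.5)
        assert len(filter_main_motifs(clustering)) == 5

    def test_t1_identity_means_dd_equals_ddsm(self, blosum62, two_family_set):
        dd = extract_dd(two_family_set, 0, 0, min_length=2)
        ddsm = extract_ddsm(two_family_set, 0, 0, blosum62, t=1.0, min_length=2)
        assert set(ddsm.features) == set(dd.features)

    def test_never_more_features_than_dd(self, blosum62, two_family_set):
        dd = extract_dd(two_family_set, 0, 0, min_length=2)
        for t in (0.0, 0.5, 0.9, 1.0):
            ddsm = extract_ddsm(two_family_set, 0, 0, blosum62, t=t, min_length=2)
            assert len(ddsm) <= len(dd)
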