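"""Allele handling, k-mer enumeration, toy predictor, DAI, binder tiers."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from neoforge.binding import (
    AMINO_ACIDS,
    HlaAllele,
    ToyPredictor,
    annotate_candidates,
    classify_binder,
    compute_dai,
    enumerate_candidate_peptides,
    get_predictor,
    lookup_method,
    method_registry,
    parse_allele,
    toy_predict,
)
from neoforge.peptides import NeoepitopeWindow


A0201 = parse_allele("HLA-A*02:01")
A1101 = parse_allele("HLA-A*11:01")


def missense_window(mut="AAAAAAAAAAWAAAAAAAAAA", wt="AAAAAAAAAAPAAAAAAAAAA",
                    idx=11, span=1, label="P29W", sample="S1"):
    return NeoepitopeWindow(sample, "G1", "T1", "missense", mut, wt, idx,
                            span, label)


class TestAlleles:
    @pytest.mark.parametrize("raw, name, cls", [
        ("HLA-A*02:01", "HLA-A*02:01", "I"),
        ("a0201", "HLA-A*02:01", "I"),
        ("B*5701", "HLA-B*57:01", "I"),
        ("DRB1*01:01", "DRB1*01:01", "II"),
        ("hla-DQB1_0302", "DQB1*03:02", "II"),
    ])
    def test_normalization(self, raw, name, cls):
        allele = parse_allele(raw)
        assert (allele.name, allele.mhc_class) == (name, cls)
        assert parse_allele(allele.name) == allele  # idempotent

    @pytest.mark.parametrize("bad", ["", "02:01", "HLA-Z*01:01", "A*2:1x"])
    def test_rejects_garbage(self, bad):
        with pytest.raises(ValueError):
            parse_allele(bad)


class TestRegistry:
    def test_class_i_has_seven_iedb_methods_plus_mhcflurry(self):
        class_i, _ = method_registry()
        iedb = [m for m in class_i if m.source == "IEDB"]
        assert len(iedb) == 7
        assert {m.name for m in class_i if m.source == "MHCflurry"} == {"MHCflurry"}

    def test_class_ii_has_four_methods(self):
        _, class_ii = method_registry()
        assert len([m for m in class_ii if not m.internal]) == 4

    def test_toy_flagged_internal_in_both_lists(self):
        class_i, class_ii = method_registry()
        assert any(m.name == "toy" and m.internal for m in class_i)
        assert any(m.name == "toy" and m.internal for m in class_ii)

    def test_lookup(self):
        assert lookup_method("NetMHCpan").mhc_class == "I"
        with pytest.raises(KeyError):
            lookup_method("NotAMethod")

    def test_external_method_needs_command_template(self):
        with pytest.raises(ValueError, match="command template"):
            get_predictor("NetMHCpan")


class TestToyPredictor:
    def test_deterministic(self):
        assert toy_predict("SIINFEKLV", A0201) == toy_predict("SIINFEKLV", A0201)

    @given(st.text(alphabet=AMINO_ACIDS, min_size=8, max_size=15))
    def test_range(self, peptide):
        value = toy_predict(peptide, A0201)
        assert 0 < value <= 50000

    def test_anchor_position_sensitivity(self):
        a = toy_predict("SIINFEKLV", A0201)
        b = toy_predict("SIINFEKLM", A0201)  # anchor (C-terminal) residue swap
        assert a != b

    def test_allele_sensitivity(self):
        assert toy_predict("SIINFEKLV", A0201) != toy_predict("SIINFEKLV", A1101)

    def test_invalid_residue_fails(self):
        with pytest.raises(ValueError):
            toy_predict("SIINFEKB", A0201)


class TestDai:
    def test_fold_change(self):
        assert compute_dai(500, 50) == 10.0
        assert compute_dai(50, 50) == 1.0

    @given(st.floats(0.01, 5e4), st.floats(0.01, 5e4))
    def test_reciprocal_identity(self, a, b):
        assert compute_dai(a, b) * compute_dai(b, a) == pytest.approx(1.0)

    def test_nonpositive_fails(self):
        with pytest.raises(ValueError):
            compute_dai(0, 10)


class TestClassifyBinder:
    @pytest.mark.parametrize("ic50, category", [
        (30, "strong"), (49.99, "strong"),
        (50, "intermediate"), (150, "intermediate"), (250, "intermediate"),
        (250.01, "weak"), (499.99, "weak"),
        (500, "non-binding"), (600, "non-binding"),
    ])
    def test_tiers(self, ic50, category):
        assert classify_binder(ic50) == category

    @given(st.floats(min_value=1e-6, max_value=1e6))
    def test_partition_of_positive_reals(self, ic50):
        assert classify_binder(ic50) in {"strong", "intermediate", "weak",
                                         "non-binding"}

    @given(st.floats(1e-3, 1e5), st.floats(1e-3, 1e5))
    def test_monotone_in_affinity(self, a, b):
        order = ["strong", "intermediate", "weak", "non-binding"]
        lo, hi = sorted([a, b])
        assert order.index(classify_binder(lo)) <= order.index(classify_binder(hi))

    def test_nonpositive_fails(self):
        with pytest.raises(ValueError):
            classify_binder(0)


class TestEnumerate:
    def test_21mer_k9_centered_mutation_gives_nine(self):
        window = missense_window()
        result = enumerate_candidate_peptides(window, 9)
        # brute-force oracle: every 9-mer of the 21-mer covering index 11
        expected = [
            (window.mut_window[o:o + 9], window.wt_window[o:o + 9], o)
            for o in range(13) if o + 1 <= 11 <= o + 9
        ]
        assert result == expected
        assert len(result) == 9

    def test_k_equal_window_length_gives_one(self):
        window = missense_window()
        assert len(enumerate_candidate_peptides(window, 21)) == 1

    def test_frameshift_window_covers_novel_tail(self):
        mut = "ACDEFGHIKLMNPQRSTVWYACDEFGHIKL"  # 30-mer
        window = NeoepitopeWindow("S1", "G1", "T1", "frameshift", mut, None,
                                  11, 20, "X11fs")
        result = enumerate_candidate_peptides(window, 9)
        expected = [(mut[o:o + 9], None, o)
                    for o in range(22) if o + 9 >= 11]  # overlap 11..30
        assert result == expected
        assert len(result) == 20

    def test_k_exceeding_window_warns_and_returns_empty(self, caplog):
        window = missense_window()
        with caplog.at_level("WARNING"):
            assert enumerate_candidate_peptides(window, 25) == []
        assert any("exceeds" in r.message for r in caplog.records)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_matches_bruteforce_on_random_windows(self, data):
        n = data.draw(st.integers(9, 30))
        idx = data.draw(st.integers(1, n))
        span = data.draw(st.integers(1, n - idx + 1))
        k = data.draw(st.integers(8, min(11, n)))
        mut = "".join(data.draw(st.sampled_from(AMINO_ACIDS)) for _ in range(n))
        window = NeoepitopeWindow("S", "G", "T", "frameshift", mut, None,
                                  idx, span, "fs")
        got = enumerate_candidate_peptides(window, k)
        altered = set(range(idx, idx + span))
        expected = [
            (mut[o:o + k], None, o) for o in range(n - k + 1)
            if altered & set(range(o + 1, o + k + 1))
        ]
        assert got == expected


class TestAnnotate:
    def test_missense_window_one_allele_length9(self):
        cands = annotate_candidates([missense_window()], [A0201], [9])
        assert len(cands) == 9
        assert all(c.dai is not None and c.ic50_wt is not None for c in cands)
        assert all(c.category == classify_binder(c.ic50_mut) for c in cands)

    def test_missense_peptides_differ_at_one_position(self):
        cands = annotate_candidates([missense_window()], [A0201], [9, 10])
        for c in cands:
            diffs = [i for i, (a, b) in enumerate(zip(c.mut_peptide, c.wt_peptide))
                     if a != b]
            assert len(diffs) == 1

    def test_frameshift_candidates_have_no_dai(self):
        window = NeoepitopeWindow("S1", "G1", "T1", "frameshift",
                                  "ACDEFGHIKLMNPQRSTVWY", None, 11, 10, "fs")
        cands = annotate_candidates([window], [A0201], [9])
        assert cands and all(c.dai is None and c.ic50_wt is None for c in cands)

    def test_empty_allele_list_gives_empty_result(self):
        assert annotate_candidates([missense_window()], [], [9]) == []

    def test_invariant_to_batch_size_and_window_order(self):
        windows = [
            missense_window(),
            missense_window(mut="CCCCCWCCCCC", wt="CCCCCPCCCCC", idx=6,
                            label="P6W", sample="S2"),
        ]
        base = annotate_candidates(windows, [A0201, A1101], [9], batch_size=64)
        small = annotate_candidates(windows, [A0201, A1101], [9], batch_size=1)
        permuted = annotate_candidates(windows[::-1], [A1101, A0201], [9],
                                       batch_size=7)
        key = lambda c: (c.window.sample_id, c.allele.name, c.mut_peptide,
                         c.ic50_mut)
        assert [key(c) for c in base] == [key(c) for c in small]
        assert [key(c) for c in base] == [key(c) for c in permuted]

    def test_failing_batches_isolated(self):
        class FlakyPredictor:
            name = "flaky"
            def predict_batch(self, peptides, allele):
                if any(p.startswith("W") for p in peptides):
                    raise RuntimeError("boom")
                return ToyPredictor().predict_batch(peptides, allele)

        cands = annotate_candidates([missense_window()], [A0201], [9],
                                    predictor=FlakyPredictor(), batch_size=1)
        # k-mers whose mutant peptide starts with W are dropped; others scored
        assert 0 < len(cands) < 9
        assert all(not c.mut_peptide.startswith("W") for c in cands)

    def test_class_specific_default_lengths(self):
        drb = parse_allele("DRB1*01:01")
        window = missense_window()
        cands = annotate_candidates([window], [A0201, drb], None)
        lengths_i = {len(c.mut_peptide) for c in cands if c.allele == A0201}
        lengths_ii = {len(c.mut_peptide) for c in cands if c.allele == drb}
        assert lengths_i == {8, 9, 10, 11}
        assert lengths_ii == {15}
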