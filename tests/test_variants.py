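"""Variant identity, multi-allelic splitting and left-alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinpool.variants import (
    INDEL,
    SNV,
    NormalizationError,
    OutOfWindowError,
    ReferenceMismatchError,
    ReferenceWindow,
    UnsupportedAlleleError,
    VariantKey,
    classify,
    normalize_record,
)


def enumerate_canonical(window: ReferenceWindow, pos: int, ref: str, alt: str):
    """Independent oracle: enumerate every equivalent (pos, ref, alt)
    representation by applying it to the window, keep the parsimonious ones,
    and return the leftmost (ties broken by shortest ref)."""
    target = window.apply(pos, ref, alt)
    bases = "ACGT"
    candidates = []
    for p in range(window.start, window.end + 1):
        for ref_len in range(1, 5):
            if p + ref_len - 1 > window.end:
                break
            r = window.fetch(p, ref_len)
            alts = [""]
            for _ in range(3):
                alts = [a + b for a in alts for b in bases]
                for a in alts:
                    if a == r:
                        continue
                    if window.apply(p, r, a) != target:
                        continue
                    trailing_trim = r[-1] == a[-1] and (len(r) > 1 or len(a) > 1)
                    leading_trim = len(r) > 1 and len(a) > 1 and r[0] == a[0]
                    if not trailing_trim and not leading_trim:
                        candidates.append((p, r, a))
    assert candidates, "oracle found no parsimonious representation"
    return min(candidates, key=lambda c: (c[0], len(c[1]), len(c[2]), c[2]))


class TestVariantKey:
    def test_identity_ignores_genotype_context(self):
        assert VariantKey("chr1", 5, "A", "T") == VariantKey("chr1", 5, "A", "T")
        assert hash(VariantKey("chr1", 5, "A", "T")) == hash(VariantKey("chr1", 5, "A", "T"))

    @pytest.mark.parametrize(
        "ref,alt,expected",
        [("A", "T", SNV), ("CA", "C", INDEL), ("C", "CTT", INDEL), ("AT", "GC", INDEL)],
    )
    def test_classify(self, ref, alt, expected):
        assert classify(VariantKey("chr1", 4, ref, alt)) == expected

    @pytest.mark.parametrize("bad", ["", "A<DEL>", "<DEL>", "*", "A]chr1:5]", "AXG"])
    def test_unsupported_alleles_rejected(self, bad):
        with pytest.raises((UnsupportedAlleleError, ValueError)):
            VariantKey("chr1", 5, "A", bad)


class TestNormalizeRecord:
    def test_snv_is_fixed_point(self):
        w = ReferenceWindow("chr1", 90, "TTTTTTTTTTAGGGG")
        assert normalize_record("chr1", 100, "A", ["G"], w) == [
            VariantKey("chr1", 100, "A", "G")
        ]

    def test_multiallelic_split_preserves_order_and_count(self):
        w = ReferenceWindow("chr1", 95, "CCCCCATTTT")
        keys = normalize_record("chr1", 100, "A", ["G", "T"], w)
        assert keys == [VariantKey("chr1", 100, "A", "G"), VariantKey("chr1", 100, "A", "T")]

    def test_left_alignment_worked_example(self):
        # deletion in a short homopolymer shifts to its leftmost anchor
        w = ReferenceWindow("chr", 1, "GGGCAAAT")
        keys = normalize_record("chr", 6, "AA", ["A"], w)
        assert keys == [VariantKey("chr", 4, "CA", "C")]
        assert keys[0].vtype == INDEL

    def test_insertion_left_shifts_through_repeat(self):
        # inserting "T" after position 7 of CCCCATTT == inserting after the A
        w = ReferenceWindow("c", 1, "CCCCATTTGG")
        keys = normalize_record("c", 7, "T", ["TT"], w)
        assert keys == [VariantKey("c", 5, "A", "AT")]

    def test_reference_mismatch_raises(self):
        w = ReferenceWindow("chr1", 1, "ACGTACGT")
        with pytest.raises(ReferenceMismatchError):
            normalize_record("chr1", 2, "A", ["G"], w)
        with pytest.raises(ReferenceMismatchError):
            normalize_record("chr2", 2, "C", ["G"], w)

    def test_shift_beyond_window_raises(self):
        # deletion in an A-run that extends to the window's first base
        w = ReferenceWindow("chr1", 5, "AAAT")
        with pytest.raises(OutOfWindowError):
            normalize_record("chr1", 5, "AA", ["A"], w)

    def test_case_folded_on_ingest(self):
        w = ReferenceWindow("chr1", 1, "ACGT")
        assert normalize_record("chr1", 2, "c", ["t"], w) == [
            VariantKey("chr1", 2, "C", "T")
        ]

    def test_no_alts_rejected(self):
        w = ReferenceWindow("chr1", 1, "ACGT")
        with pytest.raises(NormalizationError):
            normalize_record("chr1", 2, "C", [], w)


def _random_case(rng):
    seq = "".join(rng.choice(list("ACGT"), size=24))
    window = ReferenceWindow("w", 1, seq)
    pos = int(rng.integers(9, 18))
    ref_len = int(rng.integers(1, 4))
    ref = window.fetch(pos, ref_len)
    while True:
        alt = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
        if alt != ref:
            return window, pos, ref, alt


class TestNormalizationProperties:
    def test_haplotype_preserved_and_idempotent(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 300:
            window, pos, ref, alt = _random_case(rng)
            try:
                (key,) = normalize_record(window.chrom, pos, ref, [alt], window)
            except OutOfWindowError:
                continue
            checked += 1
            # haplotype preservation against the sequence-edit oracle
            assert window.apply(key.pos, key.ref, key.alt) == window.apply(pos, ref, alt)
            # idempotence
            (again,) = normalize_record(window.chrom, key.pos, key.ref, [key.alt], window)
            assert again == key

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        checked = 0
        while checked < 25:
            window, pos, ref, alt = _random_case(rng)
            try:
                (key,) = normalize_record(window.chrom, pos, ref, [alt], window)
            except OutOfWindowError:
                continue
            checked += 1
            p, r, a = enumerate_canonical(window, pos, ref, alt)
            assert (key.pos, key.ref, key.alt) == (p, r, a)

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=18, max_size=26),
        pos_frac=st.floats(0.35, 0.7),
        ref_len=st.integers(1, 3),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=3),
    )
    def test_haplotype_preserved_hypothesis(self, seq, pos_frac, ref_len, alt):
        window = ReferenceWindow("w", 1, seq)
        pos = max(2, int(len(seq) * pos_frac))
        if pos + ref_len - 1 > window.end:
            return
        ref = window.fetch(pos, ref_len)
        if alt == ref:
            return
        try:
            (key,) = normalize_record("w", pos, ref, [alt], window)
        except OutOfWindowError:
            return
        assert window.apply(key.pos, key.ref, key.alt) == window.apply(pos, ref, alt)

    def test_splitting_conserves_alt_count(self):
        w = ReferenceWindow("chr1", 1, "GGGCAAATGGG")
        keys = normalize_record("chr1", 6, "AA", ["A", "AAA", "CA"], w)
        assert len(keys) == 3
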