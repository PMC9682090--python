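import numpy as np
import pytest

from foramflow.io_formats import SequenceRecord, revcomp
from foramflow.readprep import (MergeParams, PrimerPair, length_filter,
                                merge_pair, preprocess, quality_truncate,
                                trim_primers, trim_primers_verbose)
from foramflow.synthetic_data import build_amplicon, realize_primer


def rec(seq, qual=38, rid="r"):
    if isinstance(qual, int):
        qual = (qual,) * len(seq)
    return SequenceRecord(rid, seq, tuple(qual))


def brute_force_overlap(fseq, rseq_rc, p):
    """Independent oracle: scan every overlap, min ratio, tie -> longest."""
    best = None
    for o in range(p.min_overlap, min(p.max_overlap, len(fseq), len(rseq_rc)) + 1):
        mism = sum(a != b for a, b in zip(fseq[-o:], rseq_rc[:o]))
        ratio = mism / o
        if ratio > p.max_mismatch_ratio:
            continue
        if best is None or (ratio, -o) < best:
            best = (ratio, -o)
    return None if best is None else -best[1]


class TestMergePair:
    # 16-mer whose unique zero-mismatch overlap of fwd=[:12] vs rev=[4:] is 8
    FULL = "TAAAATTGAACCGCCA"

    def test_exact_overlap(self):
        full = self.FULL
        fwd = rec(full[:12])
        rev = rec(revcomp(full[4:]))
        p = MergeParams(min_overlap=4, max_overlap=300, max_mismatch_ratio=0.0)
        merged = merge_pair(fwd, rev, p)
        assert merged.seq == full

    def test_single_mismatch_consensus_takes_higher_quality(self):
        full = self.FULL
        fwd_seq = full[:12]
        # error at position 8 on the forward read, low quality there
        fwd_err = fwd_seq[:8] + "T" + fwd_seq[9:]
        assert fwd_err != fwd_seq
        fq = [38] * 12
        fq[8] = 15
        fwd = rec(fwd_err, fq)
        rev = rec(revcomp(full[4:]))
        p = MergeParams(min_overlap=8, max_overlap=300, max_mismatch_ratio=0.2)
        merged = merge_pair(fwd, rev, p)
        # overlap is 8, one mismatch -> ratio 0.125 <= 0.2; reverse wins
        assert merged.seq == full
        assert merged.qual[8] == 38

    def test_forward_base_wins_quality_tie(self):
        full = self.FULL
        alt = "T" if full[8] != "T" else "G"
        fwd_err = full[:8] + alt + full[9:12]
        fwd = rec(fwd_err, 30)
        rev = rec(revcomp(full[4:]), 30)
        p = MergeParams(min_overlap=8, max_overlap=300, max_mismatch_ratio=0.2)
        merged = merge_pair(fwd, rev, p)
        assert merged.seq[8] == alt  # forward kept on equal Phred

    def test_random_reads_reject(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=100))
        b = "".join(rng.choice(list("ACGT"), size=100))
        p = MergeParams(min_overlap=50, max_overlap=300, max_mismatch_ratio=0.2)
        assert brute_force_overlap(a, revcomp(rec(b).seq), p) is None
        assert merge_pair(rec(a), rec(b), p) is None

    def test_agrees_with_bruteforce_on_noisy_overlaps(self, rng):
        p = MergeParams(min_overlap=10, max_overlap=300, max_mismatch_ratio=0.2)
        for _ in range(30):
            full = "".join(rng.choice(list("ACGT"), size=60))
            cut = int(rng.integers(20, 40))
            fseq = full[:cut + 15]
            rseq = full[cut:]
            # sprinkle errors on the reverse template
            r = list(rseq)
            for pos in rng.choice(len(r), size=2, replace=False):
                r[pos] = "ACGT"[int(rng.integers(4))]
            rseq = "".join(r)
            oracle = brute_force_overlap(fseq, rseq, p)
            merged = merge_pair(rec(fseq), rec(revcomp(rseq)), p)
            if oracle is None:
                assert merged is None
            else:
                assert merged is not None
                assert len(merged.seq) == len(fseq) + len(rseq) - oracle

    def test_symmetric_under_error_side_when_qualities_equal(self):
        # same mismatch placed on either mate gives the same merged length
        full = "GTATCGGCTACCGCAAAAAT"  # unique overlap 8 for [:14] vs [6:]
        alt = "A" if full[9] != "A" else "C"
        p = MergeParams(min_overlap=8, max_overlap=300, max_mismatch_ratio=0.2)
        f1 = rec(full[:9] + alt + full[10:14], 30)
        r1 = rec(revcomp(full[6:]), 30)
        m1 = merge_pair(f1, r1, p)
        f2 = rec(full[:14], 30)
        seq2 = full[6:]
        r2 = rec(revcomp(seq2[:3] + alt + seq2[4:]), 30)
        m2 = merge_pair(f2, r2, p)
        assert m1 is not None and m2 is not None
        assert len(m1.seq) == len(m2.seq) == len(full)

    def test_requires_qualities(self):
        with pytest.raises(ValueError):
            merge_pair(SequenceRecord("a", "ACGT" * 20),
                       SequenceRecord("b", "ACGT" * 20))


class TestTrimPrimers:
    primers = PrimerPair()

    def _amplicon(self, insert, rng):
        fwd_site = realize_primer(self.primers.fwd, rng)
        rev_site = realize_primer(self.primers.rev, rng)
        return build_amplicon(insert, fwd_site, rev_site)

    def test_exact_construction_recovers_insert(self, rng):
        insert = "".join(rng.choice(list("ACGT"), size=321))
        read = rec(self._amplicon(insert, rng))
        trimmed = trim_primers(read, self.primers)
        assert trimmed.seq == insert

    def test_iupac_degenerate_match(self):
        # primer GWGG: W matches A in the read prefix GAGG
        p = PrimerPair(fwd="GWGGAATTCCGGAATT", rev="ACGTACGTACGTACGT",
                       max_error_rate=0.0, min_match=10)
        read = rec("GAGGAATTCCGGAATT" + "T" * 30 + revcomp("ACGTACGTACGTACGT"))
        trimmed = trim_primers(read, p, min_length=10)
        assert trimmed.seq == "T" * 30

    def test_missing_forward_primer_rejected(self, rng):
        read = rec("".join(rng.choice(list("ACGT"), size=360)))
        trimmed, reason = trim_primers_verbose(read, self.primers)
        assert trimmed is None and reason == "no_fwd_primer"

    def test_missing_reverse_primer_rejected(self, rng):
        fwd_site = realize_primer(self.primers.fwd, rng)
        read = rec(fwd_site + "".join(rng.choice(list("ACGT"), size=340)))
        trimmed, reason = trim_primers_verbose(read, self.primers)
        assert trimmed is None and reason == "no_rev_primer"

    def test_primer_with_errors_still_found(self, rng):
        insert = "".join(rng.choice(list("ACGT"), size=321))
        amp = self._amplicon(insert, rng)
        # two substitutions inside the 22-base forward primer site
        mangled = "T" + amp[1] + "C" + amp[3:] if amp[0] != "T" else \
            "A" + amp[1] + "C" + amp[3:]
        trimmed = trim_primers(rec(mangled), self.primers)
        assert trimmed is not None and trimmed.seq == insert

    def test_too_short_after_trim(self, rng):
        read = rec(self._amplicon("ACGTA", rng))
        trimmed, reason = trim_primers_verbose(read, self.primers, min_length=10)
        assert trimmed is None and reason == "too_short_after_trim"


class TestQualityTruncate:
    @pytest.mark.parametrize("quals,expect_len", [
        ((30, 30, 30), 3),       # untouched
        ((30, 30, 15, 30), 2),   # cut before first Q<20
        ((20, 20, 20), 3),       # Q20 itself survives ('< 20' semantics)
    ])
    def test_truncation_point(self, quals, expect_len):
        out = quality_truncate(rec("ACGT"[: len(quals)], quals))
        assert len(out.seq) == expect_len

    def test_leading_low_quality_gives_none(self):
        assert quality_truncate(rec("ACG", (10, 30, 30))) is None


class TestLengthFilter:
    @pytest.mark.parametrize("n,ok", [
        (314, False), (315, True), (321, True), (325, True), (326, False)])
    def test_inclusive_bounds(self, n, ok):
        assert length_filter(rec("A" * n)) is ok


class TestPreprocess:
    def test_error_free_reads_are_lossless_and_reconciled(self, rng):
        primers = PrimerPair()
        inserts = ["".join(rng.choice(list("ACGT"), size=322)) for _ in range(3)]
        fwd_reads, rev_reads, expected = [], [], []
        for i, insert in enumerate(inserts):
            amp = build_amplicon(insert, realize_primer(primers.fwd, rng),
                                 realize_primer(primers.rev, rng))
            for j in range(5):
                rid = f"a{i}_{j}"
                fwd_reads.append(rec(amp[:300], 38, rid))
                rev_reads.append(rec(revcomp(amp)[:300], 38, rid))
                expected.append(insert)
        res = preprocess(fwd_reads, rev_reads)
        assert sorted(r.seq for r in res.records) == sorted(expected)
        assert res.reconciles()

    def test_rejects_attributed_to_one_stage(self, rng):
        primers = PrimerPair()
        insert = "".join(rng.choice(list("ACGT"), size=322))
        amp = build_amplicon(insert, realize_primer(primers.fwd, rng),
                             realize_primer(primers.rev, rng))
        good_f = rec(amp[:300], 38, "good")
        good_r = rec(revcomp(amp)[:300], 38, "good")
        junk = "".join(rng.choice(list("ACGT"), size=300))
        bad_f = rec(junk, 38, "bad")
        bad_r = rec("".join(rng.choice(list("ACGT"), size=300)), 38, "bad")
        res = preprocess([good_f, bad_f], [good_r, bad_r])
        assert len(res.records) == 1
        assert res.counts["merge_rejected"] == 1
        assert res.reconciles()

    def test_low_quality_tail_truncated_then_length_filtered(self, rng):
        primers = PrimerPair()
        insert = "".join(rng.choice(list("ACGT"), size=322))
        amp = build_amplicon(insert, realize_primer(primers.fwd, rng),
                             realize_primer(primers.rev, rng))
        # poison one forward-only position (outside the mate overlap) with a
        # low-quality miscall: truncation shortens the read below 315
        fq = [38] * 300
        fq[30] = 16
        f_seq = amp[:300]
        f_seq = f_seq[:30] + ("A" if f_seq[30] != "A" else "C") + f_seq[31:]
        res = preprocess([rec(f_seq, fq, "x")], [rec(revcomp(amp)[:300], 38, "x")])
        assert res.records == []
        assert res.counts["length_rejected"] == 1
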