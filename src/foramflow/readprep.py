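"""Read preprocessing: pair merging, primer trimming, quality truncation,
length filtering.

The chain mirrors a standard amplicon workflow: FLASH-style overlap merging
(minimum overlap 50, maximum 300, mismatch ratio 0.2), cutadapt-style
IUPAC-aware primer removal (error rate 0.2, at least 10 matching bases),
truncation before the first base under Q20, and an inclusive 315-325 bp
length filter.  Each rejected read is attributed to exactly one stage so the
stage counts reconcile with input minus output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .alignment import IUPAC, iupac_match_prefix
from .io_formats import SequenceRecord, reverse_complement, revcomp

FWD_PRIMER = "GWGGWGTTAATGCTGGTYGAAC"
REV_PRIMER = "RWRCTTCWGGATGWCTAAGARATC"


@dataclass(frozen=True)
class MergeParams:
    min_overlap: int = 50
    max_overlap: int = 300
    max_mismatch_ratio: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.min_overlap <= self.max_overlap:
            raise ValueError("need 0 < min_overlap <= max_overlap")
        if not 0.0 <= self.max_mismatch_ratio <= 1.0:
            raise ValueError("max_mismatch_ratio must be in [0, 1]")


@dataclass(frozen=True)
class PrimerPair:
    fwd: str = FWD_PRIMER
    rev: str = REV_PRIMER
    max_error_rate: float = 0.2
    min_match: int = 10

    def __post_init__(self) -> None:
        for p in (self.fwd, self.rev):
            bad = set(p) - set(IUPAC)
            if bad:
                raise ValueError(f"non-IUPAC codes in primer {p!r}: {sorted(bad)}")
        if self.min_match > min(len(self.fwd), len(self.rev)):
            raise ValueError("min_match exceeds primer length")


# ---------------------------------------------------------------------------
# Merging
# ---------------------------------------------------------------------------

def _best_overlap(f: np.ndarray, r: np.ndarray, p: MergeParams
                  ) -> Optional[tuple[int, float]]:
    """Overlap length minimising mismatch ratio (ties -> longest overlap).

    ``f`` is the forward read, ``r`` the reverse-complemented reverse read,
    both uint8.  Returns (overlap, ratio) or None when no candidate overlap
    satisfies the ratio bound.
    """
    max_o = min(p.max_overlap, len(f), len(r))
    best: Optional[tuple[float, int]] = None
    for o in range(p.min_overlap, max_o + 1):
        mism = int(np.count_nonzero(f[len(f) - o:] != r[:o]))
        ratio = mism / o
        if ratio > p.max_mismatch_ratio:
            continue
        if best is None or (ratio, -o) < best:
            best = (ratio, -o)
    if best is None:
        return None
    return -best[1], best[0]


def _merge_at(fwd: SequenceRecord, rc: SequenceRecord, o: int
              ) -> SequenceRecord:
    """Join a pair at a fixed overlap; higher-Phred base wins disagreements
    (ties to the forward base), consensus quality = max of the two."""
    f = np.frombuffer(fwd.seq.encode(), dtype=np.uint8)
    r = np.frombuffer(rc.seq.encode(), dtype=np.uint8)
    fq = np.asarray(fwd.qual, dtype=np.int64)
    rq = np.asarray(rc.qual, dtype=np.int64)
    f_tail, r_head = f[len(f) - o:], r[:o]
    fq_tail, rq_head = fq[len(f) - o:], rq[:o]
    take_rev = (f_tail != r_head) & (rq_head > fq_tail)
    cons = np.where(take_rev, r_head, f_tail)
    cons_q = np.maximum(fq_tail, rq_head)
    seq = fwd.seq[: len(f) - o] + cons.tobytes().decode() + rc.seq[o:]
    qual = tuple(int(q) for q in np.concatenate([fq[: len(f) - o], cons_q, rq[o:]]))
    return SequenceRecord(fwd.id, seq, qual)


def merge_pair(fwd: SequenceRecord, rev: SequenceRecord,
               p: MergeParams = MergeParams()) -> Optional[SequenceRecord]:
    """Merge a read pair into one amplicon sequence, or None on rejection.

    The reverse read is reverse-complemented and slid against the forward
    read's 3' end; over candidate overlaps in [min_overlap, max_overlap] the
    one minimising the mismatch ratio wins (ties to the longest overlap) and
    is accepted when the ratio is at most ``max_mismatch_ratio``.
    """
    if fwd.qual is None or rev.qual is None:
        raise ValueError("merge_pair requires qualities on both reads")
    rc = reverse_complement(rev)
    f = np.frombuffer(fwd.seq.encode(), dtype=np.uint8)
    r = np.frombuffer(rc.seq.encode(), dtype=np.uint8)
    hit = _best_overlap(f, r, p)
    if hit is None:
        return None
    return _merge_at(fwd, rc, hit[0])


# ---------------------------------------------------------------------------
# Primer trimming
# ---------------------------------------------------------------------------

def _trim_span(seq: str, primers: PrimerPair, min_length: int
               ) -> tuple[Optional[tuple[int, int]], Optional[str]]:
    """Insert span after removing both primers, or (None, reason)."""
    start = _find_primer(primers.fwd, seq, primers)
    if start is None:
        return None, "no_fwd_primer"
    # reverse primer: its reverse-complement sits at the 3' end; reversing
    # both pattern and text turns this into a prefix match
    rc_rev = revcomp(primers.rev)
    back = _find_primer(rc_rev[::-1], seq[::-1], primers)
    if back is None:
        return None, "no_rev_primer"
    end = len(seq) - back
    if end - start < min_length:
        return None, "too_short_after_trim"
    return (start, end), None


def trim_primers_verbose(rec: SequenceRecord,
                         primers: PrimerPair = PrimerPair(),
                         min_length: int = 10
                         ) -> tuple[Optional[SequenceRecord], Optional[str]]:
    """Like :func:`trim_primers` but also returns the rejection reason
    ("no_fwd_primer", "no_rev_primer", "too_short_after_trim" or None)."""
    span, reason = _trim_span(rec.seq, primers, min_length)
    if span is None:
        return None, reason
    start, end = span
    qual = rec.qual[start:end] if rec.qual is not None else None
    return SequenceRecord(rec.id, rec.seq[start:end], qual), None


def trim_primers(rec: SequenceRecord, primers: PrimerPair = PrimerPair(),
                 min_length: int = 10) -> Optional[SequenceRecord]:
    """Remove the forward primer at the 5' end and the reverse-complemented
    reverse primer at the 3' end; None when either primer is not found.

    Matching is IUPAC-aware (a degenerate primer code matches any base in
    its set) and tolerates up to ``ceil(max_error_rate * primer_length)``
    unit-cost edits while requiring at least ``min_match`` matched primer
    bases.  Trimmed reads shorter than ``min_length`` are rejected.
    """
    trimmed, _reason = trim_primers_verbose(rec, primers, min_length)
    return trimmed


def _find_primer(pattern: str, text: str, primers: PrimerPair) -> Optional[int]:
    max_err = math.ceil(primers.max_error_rate * len(pattern))
    hit = iupac_match_prefix(pattern, text, max_err)
    if hit is None:
        return None
    errs, end = hit
    if len(pattern) - errs < primers.min_match:
        return None
    return end


# ---------------------------------------------------------------------------
# Quality truncation and length filter
# ---------------------------------------------------------------------------

def quality_truncate(rec: SequenceRecord, trunc_qual: int = 20
                     ) -> Optional[SequenceRecord]:
    """Truncate immediately before the first base with Phred < trunc_qual.

    Returns None when nothing survives (a zero-length record is not
    representable); such reads fall to the length filter's reject count.
    """
    if rec.qual is None:
        raise ValueError("quality_truncate requires qualities")
    low = np.asarray(rec.qual) < trunc_qual
    cut = int(np.argmax(low)) if low.any() else len(rec.seq)
    if cut == 0:
        return None
    return SequenceRecord(rec.id, rec.seq[:cut], rec.qual[:cut])


def length_filter(rec: SequenceRecord, len_min: int = 315,
                  len_max: int = 325) -> bool:
    """True iff len_min <= len(rec) <= len_max (bounds inclusive)."""
    return len_min <= len(rec) <= len_max


# ---------------------------------------------------------------------------
# Stage driver
# ---------------------------------------------------------------------------

@dataclass
class PrepResult:
    """Clean amplicons plus per-stage rejection counts for one sample."""

    records: list[SequenceRecord]
    counts: dict = field(default_factory=dict)

    def reconciles(self) -> bool:
        c = self.counts
        rejects = (c["merge_rejected"] + c["fwd_primer_rejected"]
                   + c["rev_primer_rejected"] + c["trim_too_short"]
                   + c["length_rejected"])
        return c["input_pairs"] == len(self.records) + rejects


_REASON_KEY = {"no_fwd_primer": "fwd_primer_rejected",
               "no_rev_primer": "rev_primer_rejected",
               "too_short_after_trim": "trim_too_short"}


def preprocess(fwd_reads: Sequence[SequenceRecord],
               rev_reads: Sequence[SequenceRecord],
               merge_params: MergeParams = MergeParams(),
               primers: PrimerPair = PrimerPair(),
               trunc_qual: int = 20, len_min: int = 315, len_max: int = 325,
               min_length_after_trim: int = 10) -> PrepResult:
    """Run merge -> trim -> quality-truncate -> length-filter on one sample.

    The overlap decision in merging depends only on the two sequences and is
    cached across the (heavily repeated) read pairs of deep amplicon data;
    the quality-dependent consensus is still computed per read.
    """
    if len(fwd_reads) != len(rev_reads):
        raise ValueError("forward/reverse read counts differ")
    counts = {"input_pairs": len(fwd_reads), "merge_rejected": 0,
              "fwd_primer_rejected": 0, "rev_primer_rejected": 0,
              "trim_too_short": 0, "length_rejected": 0}
    out: list[SequenceRecord] = []
    overlap_cache: dict[tuple[str, str], Optional[tuple[int, float]]] = {}
    trim_cache: dict[str, tuple[Optional[tuple[int, int]], Optional[str]]] = {}
    for fr, rr in zip(fwd_reads, rev_reads):
        rc = reverse_complement(rr)
        key = (fr.seq, rc.seq)
        if key not in overlap_cache:
            f = np.frombuffer(fr.seq.encode(), dtype=np.uint8)
            r = np.frombuffer(rc.seq.encode(), dtype=np.uint8)
            overlap_cache[key] = _best_overlap(f, r, merge_params)
        hit = overlap_cache[key]
        if hit is None:
            counts["merge_rejected"] += 1
            continue
        merged = _merge_at(fr, rc, hit[0])
        if merged.seq not in trim_cache:
            trim_cache[merged.seq] = _trim_span(
                merged.seq, primers, min_length_after_trim)
        span, reason = trim_cache[merged.seq]
        if span is None:
            counts[_REASON_KEY[reason]] += 1
            continue
        trimmed = SequenceRecord(merged.id, merged.seq[span[0]:span[1]],
                                 merged.qual[span[0]:span[1]])
        truncated = quality_truncate(trimmed, trunc_qual)
        if truncated is None or not length_filter(truncated, len_min, len_max):
            counts["length_rejected"] += 1
            continue
        out.append(truncated)
    return PrepResult(out, counts)
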