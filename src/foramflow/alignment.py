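"""Pairwise nucleotide alignment primitives shared across the pipeline.

All alignments run through edlib (unit-cost edit distance).  Three flavours
are used:

* global (NW) identity — reference-database pairwise identity matrices;
* global (NW) edit distance — the UNOISE skew rule's d;
* semi-global (HW: free end gaps on the reference) — database search.

Identity is defined as matched columns / total alignment columns of a
minimum-edit-distance alignment; gap columns count in the denominator.
"""

from __future__ import annotations

import re
import edlib
import numpy as np

# IUPAC degenerate codes -> base sets, used for primer matching.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

# Equality pairs so that a degenerate primer code matches any base in its set
# (plus N in the read matching anything).
IUPAC_EQUALITIES = tuple(
    (code, base)
    for code, bases in IUPAC.items()
    for base in bases
    if code != base
) + tuple(("N", b) for b in "ACGT") + tuple((b, "N") for b in "ACGT")

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def edit_distance(a: str, b: str) -> int:
    """Unit-cost global edit distance (substitutions and indels cost 1)."""
    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


_BIG = 1 << 20  # dominates any match count for sequences up to ~1 Mb


def global_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns (gaps count).

    Minimum-edit alignments are not unique and different co-optimal paths
    can carry different match counts, so the identity is pinned down as the
    maximum match count over all minimum-edit-distance global alignments.
    With unit costs every non-match column is one edit, so columns = matches
    + edits and identity = M / (M + d).  The combined objective d*BIG - M is
    minimised by a single banded-free dynamic programme (vectorised per
    row); the value is symmetric in its arguments by construction.
    """
    if not a or not b:
        raise ValueError("global_identity requires non-empty sequences")
    d, m = _min_edit_max_matches(a, b)
    return m / (m + d)


def _min_edit_max_matches(a: str, b: str) -> tuple[int, int]:
    """(edit distance, max matches among minimum-edit global alignments)."""
    av = np.frombuffer(a.encode(), dtype=np.uint8)
    bv = np.frombuffer(b.encode(), dtype=np.uint8)
    n, m = len(av), len(bv)
    drift = np.arange(m + 1, dtype=np.int64) * _BIG
    prev = drift.copy()
    for i in range(n):
        subcost = np.where(bv == av[i], -1, _BIG)
        base = np.minimum(prev[1:] + _BIG, prev[:-1] + subcost)
        seed = np.empty(m + 1, dtype=np.int64)
        seed[0] = (i + 1) * _BIG
        seed[1:] = base
        prev = np.minimum.accumulate(seed - drift) + drift
    c = int(prev[m])
    d = -(-c // _BIG)
    matches = d * _BIG - c
    return d, matches


def semiglobal_hit(query: str, ref: str) -> tuple[float, float]:
    """Align the full query inside a reference with free reference end gaps.

    Returns ``(identity, query_coverage)`` where identity is matches over
    alignment columns of the aligned span and coverage is the fraction of
    query bases aligned against a reference base (matches + mismatches).
    """
    res = edlib.align(query, ref, mode="HW", task="path")
    matches = 0
    columns = 0
    q_aligned = 0
    for n, op in _cigar_ops(res["cigar"]):
        columns += n
        if op == "=":
            matches += n
            q_aligned += n
        elif op == "X":
            q_aligned += n
    return matches / columns, q_aligned / len(query)


def iupac_match_prefix(pattern: str, text: str, max_errors: int
                       ) -> tuple[int, int] | None:
    """Best IUPAC-aware match of ``pattern`` against a prefix of ``text``.

    Returns ``(errors, end)`` — the edit distance and the end position of the
    match in ``text`` — or None if no alignment with ``errors <= max_errors``
    exists.  Ties in error count resolve to the longest match.
    """
    if len(text) == 0:
        return None
    res = edlib.align(pattern, text, mode="SHW", task="locations",
                      additionalEqualities=list(IUPAC_EQUALITIES))
    errs = res["editDistance"]
    if errs < 0 or errs > max_errors:
        return None
    end = max(loc[1] for loc in res["locations"]) + 1
    return errs, end
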