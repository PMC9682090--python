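"""Dereplication, UNOISE-style ASV denoising, and the relative-abundance
cutoff.

Denoising is the greedy abundance-skew rule: uniques are visited in
descending abundance; a unique u merges into the first already-accepted
centroid c whose skew size(u)/size(c) is at most beta(d) = 1 / 2**(alpha*d + 1),
d being the unit-cost edit distance between u and c.  Uniques below the
minimum abundance are dropped before clustering.  Clustering is pooled
across samples (one ASV space) with per-sample counts retained.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd



@dataclass
class UniqueSequence:
    """An exact sequence with its total and per-sample read counts."""

    seq: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return sum(self.counts.values())


@dataclass
class AsvTable:
    """ASV count matrix [asv x sample] carrying the ASV sequences.

    ``counts`` is a DataFrame with ASV ids as the index, sample ids as
    columns; ``sequences`` maps ASV id -> sequence.  ``params`` records the
    provenance (denoising settings).
    """

    counts: pd.DataFrame
    sequences: dict[str, str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("ASV counts must be non-negative")
        seqs = list(self.sequences.values())
        if len(seqs) != len(set(seqs)):
            raise ValueError("duplicate ASV sequences")

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


def beta(d: int, alpha: float = 4.0) -> float:
    """Maximum abundance skew at edit distance d: 1 / 2**(alpha*d + 1)."""
    return 1.0 / 2.0 ** (alpha * d + 1.0)


def dereplicate(seqs: Iterable[tuple[str, str]]) -> list[UniqueSequence]:
    """Collapse (sample_id, sequence) pairs into unique sequences.

    Output is ordered by total size descending, ties broken by
    lexicographically smaller sequence first.
    """
    counts: dict[str, dict[str, int]] = defaultdict(lambda: defaultdict(int))
    for sample_id, seq in seqs:
        counts[seq][sample_id] += 1
    uniques = [UniqueSequence(seq, dict(per_sample))
               for seq, per_sample in counts.items()]
    uniques.sort(key=lambda u: (-u.size, u.seq))
    return uniques


def unoise(uniques: Sequence[UniqueSequence], alpha: float = 4.0,
           minsize: int = 8, max_dist: Optional[int] = None
           ) -> tuple[list[UniqueSequence], dict[str, str]]:
    """Greedy abundance-skew denoising.

    Returns the centroid list (with merged per-sample counts) and a mapping
    unique sequence -> centroid sequence.  Uniques with size < ``minsize``
    are excluded before clustering and do not appear in the mapping.

    ``max_dist`` caps the edit-distance computation: at a skew s the merge
    needs beta(d) >= s, i.e. d <= (log2(1/s) - 1)/alpha, so distances beyond
    that bound need not be resolved exactly.  Behaviour equals the uncapped
    rule.
    """
    kept = [u for u in uniques if u.size >= minsize]
    kept.sort(key=lambda u: (-u.size, u.seq))
    centroids: list[UniqueSequence] = []
    mapping: dict[str, str] = {}
    for u in kept:
        target = None
        for c in centroids:
            skew = u.size / c.size
            # d must satisfy beta(d) >= skew, i.e. d <= (log2(1/skew)-1)/alpha;
            # +1 guards against float rounding, the exact check decides below
            d_cap = int(np.floor((np.log2(1.0 / skew) - 1.0) / alpha)) + 1
            if d_cap < 0:
                continue
            bound = d_cap if max_dist is None else min(d_cap, max_dist)
            d = _bounded_distance(u.seq, c.seq, bound)
            if d is not None and skew <= beta(d, alpha):
                target = c
                break
        if target is None:
            centroid = UniqueSequence(u.seq, dict(u.counts))
            centroids.append(centroid)
            mapping[u.seq] = u.seq
        else:
            for s, n in u.counts.items():
                target.counts[s] = target.counts.get(s, 0) + n
            mapping[u.seq] = target.seq
    # centroid sizes changed by merging; order is the acceptance order
    return centroids, mapping


def _bounded_distance(a: str, b: str, bound: int) -> Optional[int]:
    """Edit distance if it is <= bound, else None."""
    res = edlib.align(a, b, mode="NW", task="distance", k=bound)
    d = res["editDistance"]
    return None if d < 0 else d


def table_from_centroids(centroids: Sequence[UniqueSequence],
                         sample_ids: Sequence[str],
                         params: Optional[dict] = None) -> AsvTable:
    """Build an AsvTable (ids asv1, asv2, ... in centroid order)."""
    ids = [f"asv{i + 1}" for i in range(len(centroids))]
    data = {s: [c.counts.get(s, 0) for c in centroids] for s in sample_ids}
    counts = pd.DataFrame(data, index=ids).astype(int)
    sequences = dict(zip(ids, (c.seq for c in centroids)))
    return AsvTable(counts, sequences, params or {})


def denoise_samples(per_sample_seqs: Iterable[tuple[str, str]],
                    sample_ids: Sequence[str], alpha: float = 4.0,
                    minsize: int = 8) -> AsvTable:
    """Dereplicate + unoise across pooled samples, returning an AsvTable."""
    uniques = dereplicate(per_sample_seqs)
    centroids, _ = unoise(uniques, alpha=alpha, minsize=minsize)
    return table_from_centroids(
        centroids, sample_ids,
        {"alpha": alpha, "minsize": minsize})


def abundance_cutoff(table: AsvTable, frac: float = 1e-4) -> AsvTable:
    """Zero out ASV counts at or below ``frac`` of the sample's total.

    Totals are the pre-filter per-sample totals: an ASV with 1 read in a
    sample of 10,000 (exactly 0.01%) is removed; 2 reads are kept.  ASVs
    left with all-zero rows are dropped.
    """
    counts = table.counts.copy()
    totals = counts.sum(axis=0)
    for s in counts.columns:
        t = totals[s]
        if t == 0:
            continue
        col = counts[s]
        counts.loc[col / t <= frac, s] = 0
    keep = counts.sum(axis=1) > 0
    counts = counts.loc[keep]
    sequences = {a: table.sequences[a] for a in counts.index}
    params = dict(table.params)
    params["abundance_cutoff"] = frac
    return AsvTable(counts, sequences, params)
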