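"""Reference-database construction and per-rank identity-threshold calibration.

A barcoding reference is built from single-specimen sequencing runs: for each
morphospecies, the single most abundant ASV shared by at least two specimens
becomes that species' reference barcode.  Species whose chosen barcodes are
identical are merged into one composite entry ("SpA/SpB") carrying the deepest
taxonomy the members share.

Taxonomic identity thresholds (one per rank, no genus threshold) are then
calibrated from the all-pairs global identity matrix of the database: for each
rank the threshold minimising misclassified pairs is chosen, placed at the
midpoint of the widest error-free identity gap, and the per-rank thresholds
are made monotone with depth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import global_identity
from .io_formats import RANKS

# Ranks that get a calibrated threshold; genus is deliberately absent: a
# sparse database rarely holds several species of one genus, so no genus
# cutoff can be supported.
THRESHOLD_RANKS = ("phylum", "class", "order", "family", "species")


@dataclass(frozen=True)
class TaxonPath:
    """Six-rank taxonomy path; an empty rank implies all deeper ranks empty."""

    phylum: str = ""
    class_: str = ""
    order: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        seen_empty = False
        for v in vals:
            if v == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(f"taxonomy path has a gap: {vals}")

    def as_tuple(self) -> tuple[str, ...]:
        return (self.phylum, self.class_, self.order,
                self.family, self.genus, self.species)

    def rank(self, name: str) -> str:
        return self.as_tuple()[RANKS.index(name)]

    def truncate(self, rank: Optional[str]) -> "TaxonPath":
        """Path truncated to ``rank`` (inclusive); None -> empty path."""
        if rank is None:
            return TaxonPath()
        depth = RANKS.index(rank) + 1
        vals = self.as_tuple()[:depth] + ("",) * (6 - depth)
        return TaxonPath(*vals)

    def common_prefix(self, other: "TaxonPath") -> "TaxonPath":
        vals = []
        for a, b in zip(self.as_tuple(), other.as_tuple()):
            if a == b and a != "":
                vals.append(a)
            else:
                break
        return TaxonPath(*(tuple(vals) + ("",) * (6 - len(vals))))

    @classmethod
    def from_row(cls, row: Mapping[str, str]) -> "TaxonPath":
        return cls(row.get("phylum", ""), row.get("class", ""),
                   row.get("order", ""), row.get("family", ""),
                   row.get("genus", ""), row.get("species", ""))


@dataclass(frozen=True)
class ReferenceEntry:
    """One reference barcode: a label, its taxonomy, and its sequence."""

    label: str
    path: TaxonPath
    seq: str


@dataclass(frozen=True)
class ThresholdSet:
    """Identity fraction per rank (phylum..species, no genus)."""

    phylum: float = 0.75
    class_: float = 0.80
    order: float = 0.84
    family: float = 0.96
    species: float = 0.994

    def __post_init__(self) -> None:
        vals = self.as_tuple()
        if any(not 0 <= v <= 1 for v in vals):
            raise ValueError("thresholds must be fractions in [0, 1]")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"thresholds must strictly increase with depth: {vals}")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.phylum, self.class_, self.order, self.family, self.species)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(THRESHOLD_RANKS, self.as_tuple()))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ThresholdSet":
        return cls(d["phylum"], d["class"], d["order"], d["family"], d["species"])


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity of two sequences (gap columns count)."""
    return global_identity(a, b)


def identity_matrix(entries: Sequence[ReferenceEntry]) -> pd.DataFrame:
    """Square all-pairs identity matrix over the database entries."""
    n = len(entries)
    m = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = pairwise_identity(entries[i].seq, entries[j].seq)
    labels = [e.label for e in entries]
    return pd.DataFrame(m, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def build_reference(
    specimen_asvs: Mapping[str, Sequence[tuple[str, int]]],
    specimen_species: Mapping[str, str],
    species_paths: Mapping[str, TaxonPath],
) -> tuple[list[ReferenceEntry], pd.DataFrame]:
    """Choose one reference barcode per species from specimen-level ASVs.

    Parameters
    ----------
    specimen_asvs
        specimen id -> list of ``(asv_sequence, size)``.
    specimen_species
        specimen id -> species name.
    species_paths
        species name -> full TaxonPath.

    Returns
    -------
    entries, exclusions
        Reference entries (composites merged) and a DataFrame of excluded
        species with the reason.

    A species' candidates are ASVs seen in at least two of its specimens; the
    candidate with the largest summed size wins (ties to the lexicographically
    smallest sequence).  A shared-by-two candidate beats any larger
    single-specimen ASV.  Species with no candidate are excluded and reported.
    """
    if not specimen_asvs:
        raise ValueError("no specimens supplied")
    unknown = sorted(set(specimen_asvs) - set(specimen_species))
    if unknown:
        raise ValueError(f"specimens without a species assignment: {unknown}")

    by_species: dict[str, dict[str, dict[str, int]]] = defaultdict(dict)
    # species -> seq -> {specimen: size}
    for spec_id in sorted(specimen_asvs):
        sp = specimen_species[spec_id]
        for seq, size in specimen_asvs[spec_id]:
            by_species[sp].setdefault(seq, {})
            prev = by_species[sp][seq].get(spec_id, 0)
            by_species[sp][seq][spec_id] = prev + int(size)

    chosen: dict[str, str] = {}
    excluded: list[dict] = []
    for sp in sorted(by_species):
        candidates = {seq: sum(sizes.values())
                      for seq, sizes in by_species[sp].items()
                      if len(sizes) >= 2}
        if not candidates:
            n_spec = len({s for sizes in by_species[sp].values() for s in sizes})
            reason = ("single specimen" if n_spec < 2
                      else "no ASV shared by two specimens")
            excluded.append({"species": sp, "reason": reason})
            continue
        chosen[sp] = min(candidates, key=lambda s: (-candidates[s], s))

    # Merge species whose chosen barcodes are identical into composites.
    seq_to_species: dict[str, list[str]] = defaultdict(list)
    for sp, seq in chosen.items():
        seq_to_species[seq].append(sp)

    entries: list[ReferenceEntry] = []
    for seq in sorted(seq_to_species, key=lambda s: sorted(seq_to_species[s])[0]):
        members = sorted(seq_to_species[seq])
        if len(members) == 1:
            entries.append(ReferenceEntry(members[0], species_paths[members[0]], seq))
        else:
            path = species_paths[members[0]]
            for sp in members[1:]:
                path = path.common_prefix(species_paths[sp])
            entries.append(ReferenceEntry("/".join(members), path, seq))
    exclusions = pd.DataFrame(excluded, columns=["species", "reason"])
    return entries, exclusions


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

@dataclass
class RankCalibration:
    rank: str
    threshold: Optional[float]
    n_within: int
    n_between: int
    n_violations: int
    gap_lo: Optional[float]      # widest error-minimising interval
    gap_hi: Optional[float]
    violators: list[tuple[str, str, float]] = field(default_factory=list)
    within_identities: list[float] = field(default_factory=list)
    between_identities: list[float] = field(default_factory=list)


@dataclass
class CalibrationResult:
    thresholds: dict[str, Optional[float]]
    per_rank: dict[str, RankCalibration]

    @property
    def threshold_set(self) -> ThresholdSet:
        if any(v is None for v in self.thresholds.values()):
            missing = [r for r, v in self.thresholds.items() if v is None]
            raise ValueError(f"thresholds undefined for ranks: {missing}")
        return ThresholdSet.from_dict(self.thresholds)

    def report(self) -> pd.DataFrame:
        rows = []
        for r in THRESHOLD_RANKS:
            c = self.per_rank[r]
            rows.append({"rank": r, "threshold": self.thresholds[r],
                         "raw_threshold": c.threshold,
                         "n_within": c.n_within, "n_between": c.n_between,
                         "n_violations": c.n_violations,
                         "gap_lo": c.gap_lo, "gap_hi": c.gap_hi})
        return pd.DataFrame(rows)


def _best_cut(within: np.ndarray, between: np.ndarray
              ) -> tuple[float, int, float, float]:
    """Error-minimising cut point for one rank.

    A pair violates a threshold t when it is within-rank with identity <= t or
    between-rank with identity > t.  The violation count is constant on open
    intervals between observed identities; among minimising intervals the
    widest is chosen and its midpoint returned.

    Returns (threshold, n_violations, interval_lo, interval_hi).
    """
    values = np.unique(np.concatenate([within, between]))
    # candidate intervals: (0, v0), (v0, v1), ..., (v_last, 1)
    bounds = np.concatenate([[0.0], values, [1.0]])
    best_key: tuple[int, float] | None = None  # (violations, -width)
    best = (0.5, 0, 0.0, 1.0)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        t = (lo + hi) / 2.0
        viol = int(np.sum(within <= t) + np.sum(between > t))
        key = (viol, -(hi - lo))
        if best_key is None or key < best_key:
            best_key = key
            best = (t, viol, lo, hi)
    return best


def calibrate_thresholds(entries: Sequence[ReferenceEntry]
                         ) -> CalibrationResult:
    """Calibrate per-rank identity thresholds from a reference database.

    For each rank, entry pairs are split into within (sharing the rank's
    taxon) and between; the threshold minimising violating pairs is taken at
    the midpoint of the widest error-free gap, then thresholds are made
    non-decreasing with depth by pooled-adjacent-violators averaging (strict
    increase restored by a 1e-9 nudge on exact ties).

    A rank with no between-pairs (or no within-pairs) gets threshold None and
    is reported as undefined.
    """
    if len(entries) < 2:
        raise ValueError("calibration needs at least two reference entries")

    ident: dict[tuple[int, int], float] = {}
    n = len(entries)
    for i in range(n):
        for j in range(i + 1, n):
            ident[(i, j)] = pairwise_identity(entries[i].seq, entries[j].seq)

    per_rank: dict[str, RankCalibration] = {}
    for rank in THRESHOLD_RANKS:
        within, between = [], []
        wpairs, bpairs = [], []
        for (i, j), idv in ident.items():
            a = entries[i].path.rank(rank)
            b = entries[j].path.rank(rank)
            if a == "" or b == "":
                continue
            if a == b:
                within.append(idv)
                wpairs.append((i, j))
            else:
                between.append(idv)
                bpairs.append((i, j))
        if not between:
            # nothing to separate from: no upper anchor for this rank
            per_rank[rank] = RankCalibration(rank, None, len(within),
                                             len(between), 0, None, None,
                                             [], within, between)
            continue
        w = np.asarray(within, dtype=float)
        b = np.asarray(between, dtype=float)
        t, viol, lo, hi = _best_cut(w, b)
        violators = [(entries[i].label, entries[j].label, ident[(i, j)])
                     for (i, j) in wpairs if ident[(i, j)] <= t]
        violators += [(entries[i].label, entries[j].label, ident[(i, j)])
                      for (i, j) in bpairs if ident[(i, j)] > t]
        per_rank[rank] = RankCalibration(rank, t, len(within), len(between),
                                         viol, lo, hi, violators,
                                         within, between)

    # Isotonic (PAVA) adjustment over the defined thresholds, in depth order.
    defined = [r for r in THRESHOLD_RANKS if per_rank[r].threshold is not None]
    vals = [per_rank[r].threshold for r in defined]
    adjusted = _pava(vals)
    thresholds: dict[str, Optional[float]] = {r: None for r in THRESHOLD_RANKS}
    eps = 1e-9
    prev = -np.inf
    for r, v in zip(defined, adjusted):
        if v <= prev:
            v = prev + eps
        thresholds[r] = v
        prev = v
    return CalibrationResult(thresholds, per_rank)


def _pava(values: Sequence[float]) -> list[float]:
    """Pooled adjacent violators: least-squares non-decreasing fit."""
    blocks = [[v, 1] for v in values]  # [mean, weight]
    out: list[list[float]] = []
    for blk in blocks:
        out.append(blk)
        while len(out) > 1 and out[-2][0] > out[-1][0]:
            m2, w2 = out.pop()
            m1, w1 = out.pop()
            out.append([(m1 * w1 + m2 * w2) / (w1 + w2), w1 + w2])
    result: list[float] = []
    for mean, weight in out:
        result.extend([mean] * weight)
    return result
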