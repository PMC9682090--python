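"""Identity-threshold taxonomic assignment of ASVs against a barcode
reference database.

Every ASV is aligned to every reference (exhaustive semi-global search with
free end gaps on the reference side — with databases of at most a few
hundred barcodes exactness beats heuristic seeding).  A hit needs query
coverage >= 90% and identity > 75%; the best (max-identity) hit assigns the
taxonomy truncated at the deepest rank whose calibrated threshold the
identity strictly exceeds.  Ties at the maximum identity resolve to the
deepest common taxon of the tied references.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import semiglobal_hit
from .denoise import AsvTable
from .refdb import ReferenceEntry, TaxonPath, ThresholdSet

RANK_ORDER = ("phylum", "class", "order", "family", "species")


@dataclass(frozen=True)
class Hit:
    """Best database match of one query: labels, identity, query coverage."""

    labels: tuple[str, ...]          # >1 label on an identity tie
    identity: float
    query_coverage: float
    path: TaxonPath                  # deepest common path of tied references

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= 1 or not 0 <= self.query_coverage <= 1:
            raise ValueError("identity and coverage must be fractions")

    @property
    def label(self) -> str:
        return "/".join(self.labels)


@dataclass(frozen=True)
class Assignment:
    """An ASV's assigned rank and truncated taxonomy path."""

    asv_id: str
    hit: Optional[Hit]
    rank: Optional[str]              # None = unassigned
    path: TaxonPath

    @property
    def species_label(self) -> Optional[str]:
        """Species-level taxon name: the reference label (composite labels
        such as "SpA/SpB" are first-class taxa), overridable by the path's
        species when a grouping map rewrote it."""
        if self.rank != "species":
            return None
        if self.path.species:
            return self.path.species
        return self.hit.label if self.hit else None


def search_best_hit(query: str, refs: Sequence[ReferenceEntry],
                    min_coverage: float = 0.90, min_identity: float = 0.75
                    ) -> Optional[Hit]:
    """Exhaustive best-hit search; None when no reference passes the floors.

    Passing means coverage >= min_coverage and identity > min_identity.
    References tying at the maximum identity are all retained; the hit's
    path is their deepest common taxon.
    """
    if not refs:
        raise ValueError("reference database is empty")
    best: list[ReferenceEntry] = []
    best_ident = -1.0
    best_cov = 0.0
    for ref in refs:
        ident, cov = semiglobal_hit(query, ref.seq)
        if cov < min_coverage or ident <= min_identity:
            continue
        if ident > best_ident + 1e-12:
            best, best_ident, best_cov = [ref], ident, cov
        elif abs(ident - best_ident) <= 1e-12:
            best.append(ref)
    if not best:
        return None
    path = best[0].path
    for ref in best[1:]:
        path = path.common_prefix(ref.path)
    return Hit(tuple(r.label for r in best), best_ident, best_cov, path)


def assign_rank(hit: Optional[Hit], thresholds: ThresholdSet, asv_id: str = ""
                ) -> Assignment:
    """Truncate the hit's taxonomy at the deepest rank whose threshold the
    identity strictly exceeds; genus is kept only for species-rank calls."""
    if hit is None:
        return Assignment(asv_id, None, None, TaxonPath())
    tdict = thresholds.as_dict()
    rank: Optional[str] = None
    for r in RANK_ORDER:
        if hit.identity > tdict[r]:
            rank = r
        else:
            break
    if rank is None:
        return Assignment(asv_id, hit, None, TaxonPath())
    # genus carries no threshold of its own: it survives only inside a
    # species-level call; a composite/tied path may legitimately be
    # shallower than the awarded rank (the label then carries the taxon)
    path = hit.path.truncate("species" if rank == "species" else rank)
    return Assignment(asv_id, hit, rank, path)


def assign_all(table: AsvTable, refs: Sequence[ReferenceEntry],
               thresholds: ThresholdSet, min_coverage: float = 0.90,
               min_identity: float = 0.75) -> list[Assignment]:
    """Assign every ASV in a table; order follows the table."""
    out = []
    for asv_id in table.asv_ids:
        hit = search_best_hit(table.sequences[asv_id], refs,
                              min_coverage, min_identity)
        out.append(assign_rank(hit, thresholds, asv_id))
    return out


# ---------------------------------------------------------------------------
# Summary tallies
# ---------------------------------------------------------------------------

def tally_assignments(assignments: Sequence[Assignment], table: AsvTable,
                      groups: Optional[dict[str, Sequence[str]]] = None
                      ) -> pd.DataFrame:
    """Cumulative per-level tallies of ASVs and read percentages.

    For each sample group (default: one group with all samples) the table
    reports, nested by depth, the number of ASVs assigned at or below each
    level and the percentage of reads they carry — an ASV called at species
    level counts at every shallower level too — plus the number of distinct
    species among species-level calls.
    """
    if groups is None:
        groups = {"all": table.sample_ids}
    by_id = {a.asv_id: a for a in assignments}
    rows = []
    for gname, samples in groups.items():
        counts = table.counts[list(samples)].sum(axis=1)
        total_reads = counts.sum()
        total_asvs = int((counts > 0).sum())
        present = [a for a in counts.index if counts[a] > 0]

        def depth_of(asv: str) -> int:
            a = by_id.get(asv)
            if a is None or a.rank is None:
                return -1
            return RANK_ORDER.index(a.rank if a.rank != "species" else "species")

        rows.append(_row(gname, "total", total_asvs,
                         100.0 if total_reads else 0.0))
        unassigned = [a for a in present if depth_of(a) < 0]
        rows.append(_row(gname, "unassigned", len(unassigned),
                         _pct(counts, unassigned, total_reads)))
        for i, level in enumerate(RANK_ORDER):
            at = [a for a in present if depth_of(a) >= i]
            rows.append(_row(gname, level, len(at), _pct(counts, at, total_reads)))
        species = {by_id[a].species_label for a in present
                   if a in by_id and by_id[a].rank == "species"
                   and by_id[a].species_label}
        rows.append(_row(gname, "distinct_species", len(species), np.nan))
    return pd.DataFrame(rows)


def _pct(counts: pd.Series, ids: Sequence[str], total) -> float:
    if total == 0:
        return 0.0
    return 100.0 * counts[list(ids)].sum() / total if len(ids) else 0.0


def _row(group: str, level: str, n_asvs: int, reads_pct: float) -> dict:
    return {"group": group, "level": level, "n_asvs": n_asvs,
            "reads_pct": reads_pct}


def group_labels(assignments: Sequence[Assignment],
                 mapping: dict[str, str]) -> list[Assignment]:
    """Rename species labels via a one-step many-to-one map.

    Unmatched labels pass through.  Downstream community matrices sum the
    counts of labels merged onto one target.
    """
    out = []
    for a in assignments:
        sp = a.species_label
        if sp and sp in mapping:
            target = mapping[sp]
            vals = list(a.path.as_tuple())
            vals[5] = target
            # fill any empty intermediate ranks (e.g. the genus of a
            # composite path) so the path stays gap-free
            for i in range(5):
                if vals[i] == "":
                    vals[i] = target
            out.append(Assignment(a.asv_id, a.hit, a.rank, TaxonPath(*vals)))
        else:
            out.append(a)
    return out
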