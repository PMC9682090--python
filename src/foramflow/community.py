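"""Community matrices, replicate-majority species detection, mock-community
validation and rarefaction.

Species-level community analyses keep only ASVs whose best hit exceeded the
species identity threshold; a species counts as detected at a site when it
is present in strictly more than half of the site's (successfully amplified)
replicates.  Mock communities are scored with four detection metrics
(expected species in all replicates / in the majority, replicates finding
every expected species, replicates containing erroneous species).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .denoise import AsvTable
from .taxassign import Assignment


@dataclass
class CommunityMatrix:
    """Samples x taxa counts at a given taxon level ("asv" or "species")."""

    counts: pd.DataFrame              # rows samples, columns taxa
    level: str

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("community counts must be non-negative")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate taxa in community matrix")

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def restrict(self, samples: Sequence[str]) -> "CommunityMatrix":
        missing = [s for s in samples if s not in self.counts.index]
        if missing:
            raise KeyError(f"unknown samples: {missing}")
        return CommunityMatrix(self.counts.loc[list(samples)], self.level)


@dataclass(frozen=True)
class MockSpec:
    """A mock community: its expected species and its replicate samples."""

    mock_id: str
    expected: frozenset
    replicates: tuple

    def __post_init__(self) -> None:
        if not self.expected:
            raise ValueError(f"mock {self.mock_id}: empty expected species set")
        if len(self.replicates) < 1:
            raise ValueError(f"mock {self.mock_id}: needs at least one replicate")


def build_community(assignments: Sequence[Assignment], table: AsvTable,
                    level: str = "species",
                    samples: Optional[Sequence[str]] = None) -> CommunityMatrix:
    """Aggregate ASV counts into a samples x taxa matrix.

    level="species" keeps only species-rank assignments, one column per
    species label (composites are one taxon); level="asv" keeps every ASV
    with any assignment (i.e. everything confidently in-phylum), one column
    per ASV id.
    """
    if level not in ("asv", "species"):
        raise ValueError("level must be 'asv' or 'species'")
    samples = list(samples) if samples is not None else table.sample_ids
    missing = [s for s in samples if s not in table.sample_ids]
    if missing:
        raise KeyError(f"unknown samples: {missing}")
    cols: dict[str, pd.Series] = {}
    for a in assignments:
        if a.asv_id not in table.counts.index:
            continue
        row = table.counts.loc[a.asv_id, samples]
        if level == "asv":
            if a.rank is None:
                continue
            cols[a.asv_id] = row
        else:
            label = a.species_label
            if label is None:
                continue
            if label in cols:
                cols[label] = cols[label] + row
            else:
                cols[label] = row.copy()
    counts = pd.DataFrame(cols, index=samples).fillna(0).astype(int)
    return CommunityMatrix(counts, level)


def detect_species(matrix: CommunityMatrix) -> set[str]:
    """Species present in strictly more than half of the given replicates.

    The matrix should already be restricted to one site's (or one mock's)
    replicate samples; replicates that did not amplify must be excluded
    before the call so the majority denominator is the amplified count.
    """
    pres = matrix.presence()
    n = len(pres.index)
    if n < 1:
        raise ValueError("need at least one replicate")
    hits = pres.sum(axis=0)
    return set(hits.index[hits > n / 2.0])


@dataclass(frozen=True)
class MockValidation:
    """Detection metrics for one mock community (numerator, denominator)."""

    mock_id: str
    n_expected_all_replicates: tuple[int, int]
    n_expected_majority: tuple[int, int]
    n_replicates_all_expected: tuple[int, int]
    n_replicates_with_erroneous: tuple[int, int]
    erroneous_species: frozenset = frozenset()

    def perfect(self) -> bool:
        return (self.n_expected_all_replicates[0] == self.n_expected_all_replicates[1]
                and self.n_replicates_all_expected[0] == self.n_replicates_all_expected[1]
                and self.n_replicates_with_erroneous[0] == 0)


def validate_mock(mock: MockSpec, matrix: CommunityMatrix) -> MockValidation:
    """Score one mock community against its expected species set.

    An erroneous species is any species-level taxon present in a replicate
    but outside the expected set; both the per-replicate count and the
    distinct erroneous species are reported.
    """
    sub = matrix.restrict(mock.replicates)
    pres = sub.presence()
    n_rep = len(mock.replicates)
    n_exp = len(mock.expected)
    present_sets = {r: set(pres.columns[pres.loc[r]]) for r in mock.replicates}

    in_all = sum(1 for sp in mock.expected
                 if all(sp in present_sets[r] for r in mock.replicates))
    majority = detect_species(sub)
    in_majority = len(mock.expected & majority)
    reps_all = sum(1 for r in mock.replicates
                   if mock.expected <= present_sets[r])
    erroneous = {r: present_sets[r] - mock.expected for r in mock.replicates}
    reps_err = sum(1 for r in mock.replicates if erroneous[r])
    distinct_err = frozenset().union(*erroneous.values()) if erroneous else frozenset()
    return MockValidation(
        mock.mock_id,
        (in_all, n_exp),
        (in_majority, n_exp),
        (reps_all, n_rep),
        (reps_err, n_rep),
        frozenset(distinct_err),
    )


def validation_report(validations: Sequence[MockValidation]) -> pd.DataFrame:
    """Detection metrics, one mock per column (numerator/denominator text)."""
    rows = {
        "expected_in_all_replicates": {},
        "expected_in_majority": {},
        "replicates_with_all_expected": {},
        "replicates_with_erroneous": {},
    }
    for v in validations:
        rows["expected_in_all_replicates"][v.mock_id] = \
            f"{v.n_expected_all_replicates[0]}/{v.n_expected_all_replicates[1]}"
        rows["expected_in_majority"][v.mock_id] = \
            f"{v.n_expected_majority[0]}/{v.n_expected_majority[1]}"
        rows["replicates_with_all_expected"][v.mock_id] = \
            f"{v.n_replicates_all_expected[0]}/{v.n_replicates_all_expected[1]}"
        rows["replicates_with_erroneous"][v.mock_id] = \
            f"{v.n_replicates_with_erroneous[0]}/{v.n_replicates_with_erroneous[1]}"
    return pd.DataFrame(rows).T


# ---------------------------------------------------------------------------
# Richness
# ---------------------------------------------------------------------------

def rarefaction_curve(counts: Sequence[int], depths: Sequence[int]
                      ) -> np.ndarray:
    """Expected species richness of random subsamples (hypergeometric).

    E[S_n] = sum_i (1 - C(N - N_i, n) / C(N, n)), computed in log space.
    """
    c = np.asarray([x for x in counts if x > 0], dtype=np.int64)
    n_total = int(c.sum())
    out = []
    for n in depths:
        if n > n_total:
            raise ValueError(f"rarefaction depth {n} exceeds total count {n_total}")
        if n == 0:
            out.append(0.0)
            continue
        # log C(N - Ni, n) - log C(N, n); terms with N - Ni < n contribute 1
        keep = (n_total - c) >= n
        miss = np.zeros(len(c))
        if keep.any():
            a = n_total - c[keep]
            miss[keep] = np.exp(
                _log_comb(a, n) - _log_comb(n_total, n))
        out.append(float(np.sum(1.0 - miss)))
    return np.asarray(out)


def _log_comb(a, k):
    a = np.asarray(a, dtype=float)
    return gammaln(a + 1) - gammaln(a - k + 1) - gammaln(k + 1)


def shared_species(set_a: set, set_b: set) -> tuple[int, int, int]:
    """(shared, only in A, only in B) counts — Venn-diagram partition."""
    return (len(set_a & set_b), len(set_a - set_b), len(set_b - set_a))
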