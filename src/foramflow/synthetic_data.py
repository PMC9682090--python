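"""Synthetic reference databases, communities and paired-end reads.

The generator plants the statistical structure the analysis assumes, so that
every downstream stage (merging, trimming, denoising, assignment, detection,
statistics) can be exercised and its parameter recovery checked without any
sequencing download.

Reference sequences evolve from one random ancestor down the 6-rank taxonomy
tree by substitutions only, with every edge mutating a set of positions that
is globally disjoint from every other edge's.  Pairwise Hamming distances are
then exactly the sum of per-edge substitution counts along the connecting
path, so the identity of every sequence pair lands deterministically inside
the band of its lowest common rank, and those bands bracket the published
per-rank thresholds (75/80/84/96/99.4%).  The price of exactness is that all
sequences in one database share a single length drawn from the amplicon
range, and that at most two sequences per species can be emitted (a third
would push within-species identity below the 99.4% species band at ~322 bp).

Amplicons are the reference barcode flanked by a concrete realisation of the
degenerate PCR primers; paired 2x300 bp reads carry independent substitution
errors with low Phred (15-25) at error sites and high Phred (30-40)
elsewhere, so quality truncation is exercised while the length filter stays
deterministic.  Chimeras are off by default; a two-parent breakpoint model is
available for stress tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import DEFAULT_RANK_THRESHOLDS, SequenceRecord, revcomp
from .readprep import PrimerPair
from .refdb import ReferenceEntry, TaxonPath

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: substitutions planted on each edge entering a node of the given rank;
#: chosen so that at ~322 bp every lowest-common-rank identity band falls
#: between the published thresholds with margin for the slight identity
#: inflation a minimum-edit alignment shows over Hamming at large distances
DEFAULT_EDGE_SUBS = {
    "phylum": 13, "class": 7, "order": 17, "family": 8, "genus": 2, "species": 3,
}

_LEVELS = ("phylum", "class", "order", "family", "genus", "species")


@dataclass
class TaxonomySpec:
    """Shape of the simulated taxonomy and its planted identity structure.

    ``counts`` gives the branching factor per level: number of phyla, then
    classes per phylum, orders per class, families per order, genera per
    family, and species per genus (the last may be a sequence, cycled over
    genera).  ``populations_per_species`` (1 or 2) controls within-species
    pairs; two populations differ by exactly one substitution.
    """

    counts: tuple = (2, (2, 1), (2, 1, 1), (2, 1, 1, 1), (2, 1, 1, 1, 1), (4, 3))
    populations_per_species: int = 2
    edge_subs: dict = field(default_factory=lambda: dict(DEFAULT_EDGE_SUBS))

    def __post_init__(self) -> None:
        if self.populations_per_species not in (1, 2):
            raise ValueError("populations_per_species must be 1 or 2")
        if len(self.counts) != 6:
            raise ValueError("counts must give 6 branching factors")

    # -- planted distance structure -------------------------------------

    def _cum_below(self, level: str) -> int:
        """Substitutions per lineage on edges strictly deeper than ``level``."""
        idx = _LEVELS.index(level)
        return sum(self.edge_subs[l] for l in _LEVELS[idx + 1:])

    def distance_range(self, lca_level: str) -> tuple[int, int]:
        """Hamming distance range for a pair whose lowest common rank is given.

        ``lca_level`` is a rank name ("species" = two populations of one
        species) or "root" (different phyla).  The distance is the sum of
        per-edge substitution counts below the LCA on both sides, plus 0-2
        population-edge substitutions.
        """
        if lca_level == "species":
            return (1, 1)
        pop = 2 if self.populations_per_species == 2 else 0
        if lca_level == "root":
            per_side = sum(self.edge_subs.values())
        else:
            per_side = self._cum_below(lca_level)
        return (2 * per_side, 2 * per_side + pop)

    def identity_band(self, lca_level: str, length: int) -> tuple[float, float]:
        lo_d, hi_d = self.distance_range(lca_level)
        return (1 - hi_d / length, 1 - lo_d / length)

    def validate_bands(self, length: int,
                       thresholds: Mapping[str, float] = DEFAULT_RANK_THRESHOLDS
                       ) -> None:
        """Check bands are disjoint, ordered, and bracket the thresholds."""
        order = ["species", "genus", "family", "order", "class", "phylum", "root"]
        bands = {l: self.identity_band(l, length) for l in order}
        for shallow, deep in zip(order[1:], order[:-1]):
            if bands[shallow][1] >= bands[deep][0]:
                raise ValueError(
                    f"identity bands overlap: {shallow} {bands[shallow]} vs "
                    f"{deep} {bands[deep]} at length {length}")
        # The threshold at rank r separates pairs sharing rank r (lowest band:
        # LCA exactly at r) from pairs not sharing it (highest band: LCA at
        # the parent of r).
        outside = {"species": "genus", "family": "order", "order": "class",
                   "class": "phylum", "phylum": "root"}
        for rank, thr in thresholds.items():
            if bands[rank][0] <= thr:
                raise ValueError(f"within-{rank} band {bands[rank]} does "
                                 f"not stay above threshold {thr}")
            if bands[outside[rank]][1] > thr:
                raise ValueError(f"between-{rank} band {bands[outside[rank]]} does "
                                 f"not stay below threshold {thr}")

    def substitution_budget(self) -> int:
        """Total distinct positions needed for globally disjoint edges."""
        n = [1]
        for i, lev in enumerate(_LEVELS):
            c = self.counts[i]
            if isinstance(c, (tuple, list)):
                total = 0
                k = 0
                for _ in range(n[-1]):
                    total += c[k % len(c)]
                    k += 1
                n.append(total)
            else:
                n.append(n[-1] * c)
        budget = sum(n[i + 1] * self.edge_subs[lev]
                     for i, lev in enumerate(_LEVELS))
        if self.populations_per_species == 2:
            budget += n[-1]  # one 1-substitution population edge per species
        return budget


@dataclass
class CommunitySpec:
    """One community: species, abundances, replication, depth and noise."""

    name: str
    species: Sequence[str]
    abundances: Optional[Sequence[float]] = None  # None -> equal (mock-style)
    n_replicates: int = 5
    noise_sd: float = 0.15           # lognormal sigma on replicate abundances
    reads_per_replicate: int = 2000
    error_rate: float = 0.001        # per-base substitution rate in reads
    chimera_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.abundances is not None:
            a = np.asarray(self.abundances, float)
            if len(a) != len(self.species):
                raise ValueError("abundances must match species list")
            if not np.isclose(a.sum(), 1.0):
                raise ValueError("abundances must sum to 1")
        if not 0 <= self.error_rate <= 1 or not 0 <= self.chimera_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")

    def abundance_vector(self) -> np.ndarray:
        if self.abundances is None:
            return np.full(len(self.species), 1.0 / len(self.species))
        return np.asarray(self.abundances, float)


# ---------------------------------------------------------------------------
# Reference database simulation
# ---------------------------------------------------------------------------

def simulate_refdb(tax: TaxonomySpec,
                   amplicon_len_range: tuple[int, int] = (321, 323),
                   seed: int | np.random.Generator = 0,
                   verify: bool = True,
                   ) -> tuple[list[SequenceRecord], pd.DataFrame]:
    """Generate reference barcodes with planted per-rank identity bands.

    Returns records (one or two per species, ids ``<species>_p<k>``) and a
    taxonomy table with columns id, phylum..species, population.
    Raises ValueError before generation when the substitution budget exceeds
    the amplicon length (bands infeasible).
    """
    rng = np.random.default_rng(seed)
    length = int(rng.integers(amplicon_len_range[0], amplicon_len_range[1] + 1))
    budget = tax.substitution_budget()
    if budget > length:
        raise ValueError(
            f"identity bands infeasible: {budget} disjoint substitution "
            f"positions needed but amplicons are only {length} bp")
    tax.validate_bands(length)

    positions = rng.permutation(length)
    pos_cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal pos_cursor
        out = positions[pos_cursor:pos_cursor + k]
        pos_cursor += k
        return out

    def mutate(seq: np.ndarray, k: int) -> np.ndarray:
        child = seq.copy()
        for p in take(k):
            old = child[p]
            choices = _BASES[_BASES != old]
            child[p] = rng.choice(choices)
        return child

    ancestor = rng.choice(_BASES, size=length)

    records: list[SequenceRecord] = []
    rows: list[dict] = []

    cycle_counters = [0] * 6  # one per level, for list-valued branching

    def expand(level_idx: int, node_seq: np.ndarray, path: list[str]) -> None:
        level = _LEVELS[level_idx]
        c = tax.counts[level_idx]
        if isinstance(c, (tuple, list)):
            n_children = c[cycle_counters[level_idx] % len(c)]
            cycle_counters[level_idx] += 1
        else:
            n_children = c
        for i in range(n_children):
            child_seq = mutate(node_seq, tax.edge_subs[level])
            name = _node_name(level, path, i)
            if level == "species":
                _emit_species(child_seq, path + [name])
            else:
                expand(level_idx + 1, child_seq, path + [name])

    def _emit_species(seq: np.ndarray, path: list[str]) -> None:
        pops = [seq]
        if tax.populations_per_species == 2:
            pops.append(mutate(seq, 1))
        for k, pseq in enumerate(pops):
            rid = f"{path[-1]}_p{k}"
            records.append(SequenceRecord(rid, pseq.tobytes().decode()))
            rows.append({"id": rid, "phylum": path[0], "class": path[1],
                         "order": path[2], "family": path[3],
                         "genus": path[4], "species": path[5],
                         "population": k})

    expand(0, ancestor, [])
    taxonomy = pd.DataFrame(rows)
    if verify:
        verify_observed_bands(records, taxonomy)
    return records, taxonomy


def observed_bands(records: Sequence[SequenceRecord], taxonomy: pd.DataFrame
                   ) -> dict[str, tuple[float, float]]:
    """Measured (min, max) pairwise alignment identity per lowest-common-rank.

    The generator plants Hamming distances exactly; a minimum-edit global
    alignment can report slightly higher identities at large distances, so
    the realised bands are what threshold calibration actually sees.
    """
    from .refdb import pairwise_identity
    levels = ["root"] + list(_LEVELS)
    paths = {row["id"]: (row["phylum"], row["class"], row["order"],
                         row["family"], row["genus"], row["species"])
             for _, row in taxonomy.iterrows()}
    bands: dict[str, list[float]] = {}
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            depth = 0
            for x, y in zip(paths[a.id], paths[b.id]):
                if x == y:
                    depth += 1
                else:
                    break
            lca = levels[depth]
            bands.setdefault(lca, []).append(pairwise_identity(a.seq, b.seq))
    return {l: (min(v), max(v)) for l, v in bands.items()}


def verify_observed_bands(records: Sequence[SequenceRecord],
                          taxonomy: pd.DataFrame,
                          thresholds: Mapping[str, float] = DEFAULT_RANK_THRESHOLDS
                          ) -> dict[str, tuple[float, float]]:
    """Check realised identity bands are disjoint, ordered with rank depth,
    and bracket the assignment thresholds; raise on violation."""
    bands = observed_bands(records, taxonomy)
    order = [l for l in
             ("species", "genus", "family", "order", "class", "phylum", "root")
             if l in bands]
    for shallow, deep in zip(order[1:], order[:-1]):
        if bands[shallow][1] >= bands[deep][0]:
            raise ValueError(
                f"realised identity bands overlap: {shallow} "
                f"{bands[shallow]} vs {deep} {bands[deep]}")
    outside = {"species": "genus", "family": "order", "order": "class",
               "class": "phylum", "phylum": "root"}
    for rank, thr in thresholds.items():
        if rank in bands and bands[rank][0] <= thr:
            raise ValueError(f"realised within-{rank} band {bands[rank]} "
                             f"does not stay above threshold {thr}")
        if outside[rank] in bands and bands[outside[rank]][1] > thr:
            raise ValueError(f"realised between-{rank} band "
                             f"{bands[outside[rank]]} does not stay below "
                             f"threshold {thr}")
    return bands


_PREFIX = {"phylum": "Phy", "class": "Cla", "order": "Ord",
           "family": "Fam", "genus": "Gen", "species": "Sp"}


def _node_name(level: str, path: list[str], i: int) -> str:
    suffix = path[-1].split("-", 1)[1] if path else ""
    tag = f"{suffix}{i + 1}" if suffix else f"{i + 1}"
    return f"{_PREFIX[level]}-{tag}"


def refdb_entries(records: Sequence[SequenceRecord], taxonomy: pd.DataFrame
                  ) -> list[ReferenceEntry]:
    """Reference entries (one per record) for assignment and calibration."""
    paths = {row["id"]: TaxonPath(row["phylum"], row["class"], row["order"],
                                  row["family"], row["genus"], row["species"])
             for _, row in taxonomy.iterrows()}
    return [ReferenceEntry(r.id, paths[r.id], r.seq) for r in records]


# ---------------------------------------------------------------------------
# Communities
# ---------------------------------------------------------------------------

def simulate_community(spec: CommunitySpec, species_available: Sequence[str],
                       seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Per-replicate true relative abundances (rows: replicate sample ids).

    Replicate abundances are the spec abundances perturbed by multiplicative
    lognormal noise (sigma = ``noise_sd``) and renormalised.
    """
    unknown = sorted(set(spec.species) - set(species_available))
    if unknown:
        raise ValueError(f"species not in reference database: {unknown}")
    rng = np.random.default_rng(seed)
    base = spec.abundance_vector()
    rows = {}
    for r in range(1, spec.n_replicates + 1):
        if spec.noise_sd > 0:
            noisy = base * rng.lognormal(0.0, spec.noise_sd, size=len(base))
        else:
            noisy = base.copy()
        rows[f"{spec.name}-r{r}"] = noisy / noisy.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(spec.species))


def lognormal_abundances(n_species: int, sigma: float = 1.0,
                         seed: int | np.random.Generator = 0) -> np.ndarray:
    """Log-skewed relative abundances (lognormal, normalised)."""
    rng = np.random.default_rng(seed)
    a = rng.lognormal(0.0, sigma, size=n_species)
    return a / a.sum()


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def realize_primer(primer: str, rng: np.random.Generator) -> str:
    """Concrete binding-site realisation of a degenerate primer."""
    from .alignment import IUPAC
    return "".join(c if c in "ACGT" else rng.choice(list(IUPAC[c]))
                   for c in primer)


def build_amplicon(barcode: str, fwd_site: str, rev_site: str) -> str:
    """Amplicon as sequenced: forward site + barcode + revcomp(reverse site)."""
    return fwd_site + barcode + revcomp(rev_site)


def simulate_reads(truth: pd.DataFrame, species_seqs: Mapping[str, str],
                   primers: Optional[PrimerPair] = None, read_len: int = 300,
                   error_rate: float = 0.001, min_overlap: int = 50,
                   chimera_rate: float = 0.0,
                   reads_per_replicate: int | Mapping[str, int] = 2000,
                   seed: int | np.random.Generator = 0,
                   ) -> dict[str, tuple[list[SequenceRecord], list[SequenceRecord]]]:
    """Paired 2x``read_len`` reads for every replicate row of a truth table.

    Returns ``{sample_id: (forward_records, reverse_records)}``.  Read counts
    are multinomial on the replicate's abundances; errors are independent
    per-mate substitutions; error-site Phred is drawn in [15, 25], all other
    bases in [30, 40].
    """
    primers = primers or PrimerPair()
    rng = np.random.default_rng(seed)
    fwd_sites = {}
    rev_sites = {}
    amplicons = {}
    for sp in truth.columns:
        if sp not in species_seqs:
            raise ValueError(f"no reference sequence for species {sp!r}")
        fwd_sites[sp] = realize_primer(primers.fwd, rng)
        rev_sites[sp] = realize_primer(primers.rev, rng)
        amp = build_amplicon(species_seqs[sp], fwd_sites[sp], rev_sites[sp])
        if len(amp) > 2 * read_len - min_overlap:
            raise ValueError(
                f"amplicon for {sp!r} ({len(amp)} bp) too long for "
                f"2x{read_len} reads with overlap >= {min_overlap}")
        if len(amp) < read_len:
            raise ValueError(f"amplicon for {sp!r} shorter than read length")
        amplicons[sp] = np.frombuffer(amp.encode(), dtype=np.uint8)

    species = list(truth.columns)
    out: dict[str, tuple[list, list]] = {}
    for sample_id, row in truth.iterrows():
        if isinstance(reads_per_replicate, Mapping):
            depth = int(reads_per_replicate[sample_id])
        else:
            depth = int(reads_per_replicate)
        counts = rng.multinomial(depth, np.asarray(row, float))
        fwd_recs: list[SequenceRecord] = []
        rev_recs: list[SequenceRecord] = []
        i = 0
        for sp, c in zip(species, counts):
            for _ in range(c):
                i += 1
                amp = amplicons[sp]
                if chimera_rate > 0 and rng.random() < chimera_rate:
                    other = species[rng.integers(len(species))]
                    amp = _chimera(amp, amplicons[other], rng)
                rid = f"{sample_id}_read{i}"
                f_rec = _read_with_errors(rid, amp[:read_len], error_rate, rng)
                rc = _revcomp_arr(amp)
                r_rec = _read_with_errors(rid, rc[:read_len], error_rate, rng)
                fwd_recs.append(f_rec)
                rev_recs.append(r_rec)
        out[sample_id] = (fwd_recs, rev_recs)
    return out


_RC = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _RC[_a] = _b


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    return _RC[arr][::-1]


def _read_with_errors(rid: str, template: np.ndarray, error_rate: float,
                      rng: np.random.Generator) -> SequenceRecord:
    seq = template.copy()
    qual = rng.integers(30, 41, size=len(seq))
    if error_rate > 0:
        err = rng.random(len(seq)) < error_rate
        for p in np.nonzero(err)[0]:
            choices = _BASES[_BASES != seq[p]]
            seq[p] = rng.choice(choices)
        qual[err] = rng.integers(15, 26, size=int(err.sum()))
    return SequenceRecord(rid, seq.tobytes().decode(), tuple(int(q) for q in qual))


def _chimera(a: np.ndarray, b: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cut = int(rng.integers(1, min(len(a), len(b))))
    return np.concatenate([a[:cut], b[cut:]])
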