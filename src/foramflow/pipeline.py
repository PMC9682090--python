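"""End-to-end orchestration: prep -> denoise -> assign -> community ->
validate -> stats, with a run manifest, plus the bundled demo design that
mirrors the study layout (6 mock communities x 5 technical replicates and
10 bulk-sediment sites) on synthetic data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .community import (CommunityMatrix, MockSpec, build_community,
                        validate_mock, validation_report)
from .denoise import AsvTable, abundance_cutoff, denoise_samples
from .ecostats import anosim, bray_curtis, nmds, permanova
from .io_formats import Config, SampleMetadata, SequenceRecord, write_fasta, write_table
from .readprep import MergeParams, PrepResult, PrimerPair, preprocess
from .refdb import ReferenceEntry, ThresholdSet
from .synthetic_data import (CommunitySpec, TaxonomySpec, lognormal_abundances,
                             refdb_entries, simulate_community, simulate_reads,
                             simulate_refdb)
from .taxassign import assign_all, tally_assignments


@dataclass
class DemoData:
    """Everything one synthetic study run needs, generated from one seed."""

    refdb_records: list
    taxonomy: pd.DataFrame
    entries: list
    metadata: list
    mocks: list
    truth: pd.DataFrame
    sample_reads: dict


@dataclass
class PipelineResult:
    prep: dict
    asv_table: AsvTable
    assignments: list
    species_matrix: CommunityMatrix
    validations: list
    tally: pd.DataFrame
    stats: dict
    manifest: dict


def simulate_demo(seed: int = 1, error_rate: float = 0.001,
                  reads_per_replicate: int = 1000,
                  n_bulk_sites: int = 10, replicate_noise_sd: float = 0.15,
                  tax: Optional[TaxonomySpec] = None) -> DemoData:
    """Synthetic study: reference database, 6 mocks x 5 replicates, and
    bulk-sediment communities for ``n_bulk_sites`` sites x 5 replicates.

    Mock communities hold 8 or 9 species at equal nominal abundance (one
    specimen each); bulk sites hold log-normally skewed abundances over a
    site-specific species subset.  All randomness flows from ``seed``.
    """
    rng = np.random.default_rng(seed)
    tax = tax or TaxonomySpec()
    records, taxonomy = simulate_refdb(tax, seed=rng)
    entries = refdb_entries(records, taxonomy)
    species = sorted(taxonomy["species"].unique())
    # reads amplify from the population-0 barcode of each species
    species_seqs = {row["species"]: rec.seq
                    for rec, (_, row) in zip(records, taxonomy.iterrows())
                    if row["population"] == 0}

    metadata: list[SampleMetadata] = []
    mocks: list[MockSpec] = []
    truths = []
    mock_sizes = [9, 8, 9, 9, 8, 9]
    for m, size in enumerate(mock_sizes, start=1):
        chosen = sorted(rng.choice(species, size=size, replace=False))
        spec = CommunitySpec(name=f"M{m}", species=chosen,
                             n_replicates=5, noise_sd=replicate_noise_sd,
                             reads_per_replicate=reads_per_replicate,
                             error_rate=error_rate)
        t = simulate_community(spec, species, seed=rng)
        truths.append(t)
        reps = tuple(t.index)
        mocks.append(MockSpec(f"M{m}", frozenset(chosen), reps))
        for r, sid in enumerate(reps, start=1):
            metadata.append(SampleMetadata(sid, f"M{m}", "lab", "reef_flat",
                                           "mock", r))

    locations = {}
    for s in range(1, n_bulk_sites + 1):
        locations[f"S{s:02d}"] = f"L{(s - 1) * 3 // n_bulk_sites + 1}"
    for s in range(1, n_bulk_sites + 1):
        site = f"S{s:02d}"
        subset = sorted(rng.choice(species, size=min(12, len(species)),
                                   replace=False))
        ab = lognormal_abundances(len(subset), sigma=1.0, seed=rng)
        spec = CommunitySpec(name=site, species=subset, abundances=ab,
                             n_replicates=5, noise_sd=replicate_noise_sd,
                             reads_per_replicate=reads_per_replicate,
                             error_rate=error_rate)
        t = simulate_community(spec, species, seed=rng)
        truths.append(t)
        habitat = "reef_flat" if s % 2 else "reef_slope"
        for r, sid in enumerate(t.index, start=1):
            metadata.append(SampleMetadata(sid, site, locations[site],
                                           habitat, "bulk", r))

    truth = pd.concat(truths).fillna(0.0)
    sample_reads = simulate_reads(
        truth, species_seqs, read_len=300, error_rate=error_rate,
        reads_per_replicate=reads_per_replicate, seed=rng)
    return DemoData(records, taxonomy, entries, metadata, mocks, truth,
                    sample_reads)


def run_all(config: Config,
            entries: Sequence[ReferenceEntry],
            sample_reads: Mapping[str, tuple[Sequence[SequenceRecord],
                                             Sequence[SequenceRecord]]],
            metadata: Sequence[SampleMetadata],
            mocks: Sequence[MockSpec] = (),
            thresholds: Optional[ThresholdSet] = None,
            outdir: Optional[Path] = None,
            run_stats: bool = True) -> PipelineResult:
    """Run the full analysis chain on preprocessed inputs.

    Deterministic for a fixed config seed; stage read counts reconcile
    (input pairs = clean reads + per-stage rejects) in the manifest.
    """
    if not entries:
        raise ValueError("reference database is empty")
    meta_ids = {m.sample_id for m in metadata}
    unknown = sorted(set(sample_reads) - meta_ids)
    if unknown:
        raise ValueError(f"samples without metadata: {unknown}")
    thresholds = thresholds or ThresholdSet.from_dict(config.rank_thresholds)

    merge_params = MergeParams(config.min_overlap, config.max_overlap,
                               config.mismatch_ratio)
    primers = PrimerPair(config.fwd_primer, config.rev_primer,
                         config.primer_error_rate, config.primer_min_match)

    prep: dict[str, PrepResult] = {}
    pooled: list[tuple[str, str]] = []
    for sid in sorted(sample_reads):
        fwd, rev = sample_reads[sid]
        res = preprocess(fwd, rev, merge_params, primers, config.trunc_qual,
                         config.len_min, config.len_max,
                         config.min_length_after_trim)
        prep[sid] = res
        pooled.extend((sid, r.seq) for r in res.records)

    sample_ids = sorted(sample_reads)
    table = denoise_samples(pooled, sample_ids, config.alpha, config.minsize)
    table = abundance_cutoff(table, config.abundance_cutoff)

    assignments = assign_all(table, list(entries), thresholds,
                             config.min_coverage, config.min_identity)

    groups = _sample_groups(metadata, sample_ids)
    tally = tally_assignments(assignments, table, groups)
    species_matrix = build_community(assignments, table, level="species")

    validations = []
    for mock in mocks:
        amplified = [r for r in mock.replicates
                     if species_matrix.counts.loc[r].sum() > 0]
        validations.append(validate_mock(
            MockSpec(mock.mock_id, mock.expected, tuple(amplified)),
            species_matrix))

    stats = _run_stats(species_matrix, metadata, config) if run_stats else {}

    manifest = _manifest(config, prep, table)
    result = PipelineResult(prep, table, assignments, species_matrix,
                            validations, tally, stats, manifest)
    if outdir is not None:
        _write_outputs(result, Path(outdir))
    return result


def _sample_groups(metadata: Sequence[SampleMetadata],
                   sample_ids: Sequence[str]) -> dict[str, list[str]]:
    by_type: dict[str, list[str]] = {}
    for m in metadata:
        if m.sample_id in set(sample_ids):
            by_type.setdefault(m.sample_type, []).append(m.sample_id)
    return by_type


def _run_stats(matrix: CommunityMatrix, metadata: Sequence[SampleMetadata],
               config: Config) -> dict:
    """ANOSIM on mock replicates, one-way PermANOVA on bulk sites, NMDS."""
    meta = {m.sample_id: m for m in metadata}
    stats: dict = {}
    nonzero = matrix.counts.index[matrix.counts.sum(axis=1) > 0]

    def usable(sample_type: str) -> list[str]:
        return [s for s in nonzero if meta[s].sample_type == sample_type]

    mock_samples = usable("mock")
    if mock_samples:
        groups = [meta[s].site for s in mock_samples]
        if len(set(groups)) >= 2 and min(
                pd.Series(groups).value_counts()) >= 2:
            dm = bray_curtis(matrix.restrict(mock_samples))
            stats["anosim_mocks"] = anosim(dm, groups, config.n_permutations,
                                           config.seed)
            stats["nmds_mocks"] = nmds(dm, seed=config.seed)

    bulk_samples = usable("bulk")
    if bulk_samples:
        sites = [meta[s].site for s in bulk_samples]
        if len(set(sites)) >= 2:
            dm = bray_curtis(matrix.restrict(bulk_samples))
            stats["permanova_bulk_site"] = permanova(
                dm, np.asarray(sites), n_perm=config.n_permutations,
                seed=config.seed)["factor"]
            design = pd.DataFrame({
                "habitat": [meta[s].habitat for s in bulk_samples],
                "location": [meta[s].location for s in bulk_samples],
                "site": sites}, index=bulk_samples)
            stats["permanova_bulk_multifactor"] = permanova(
                dm, design, terms=["habitat", "location", "site"],
                nested_in={"site": "location"},
                n_perm=config.n_permutations, seed=config.seed)
            stats["nmds_bulk"] = nmds(dm, seed=config.seed)
    return stats


def _manifest(config: Config, prep: Mapping[str, PrepResult],
              table: AsvTable) -> dict:
    stage_counts = {sid: dict(res.counts, clean_reads=len(res.records))
                    for sid, res in prep.items()}
    reconciled = all(res.reconciles() for res in prep.values())
    return {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_counts": stage_counts,
        "reads_reconciled": reconciled,
        "n_asvs": len(table.asv_ids),
        "reads_in_asv_table": int(table.counts.values.sum()),
    }


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    asv = result.asv_table
    write_fasta(outdir / "asvs.fasta",
                [SequenceRecord(a, asv.sequences[a]) for a in asv.asv_ids])
    asv.counts.rename_axis("asv_id").reset_index().to_csv(
        outdir / "asv_table.tsv", sep="\t", index=False)
    rows = []
    for a in result.assignments:
        hit = a.hit
        rows.append({
            "asv_id": a.asv_id,
            "best_ref": hit.label if hit else "",
            "identity": hit.identity if hit else "",
            "coverage": hit.query_coverage if hit else "",
            "rank": a.rank or "unassigned",
            "path": ";".join(a.path.as_tuple()),
        })
    write_table(outdir / "assignments.tsv", pd.DataFrame(rows))
    write_table(outdir / "assignment_tally.tsv", result.tally)
    result.species_matrix.counts.rename_axis("sample_id").reset_index().to_csv(
        outdir / "species_matrix.tsv", sep="\t", index=False)
    if result.validations:
        validation_report(result.validations).rename_axis("metric") \
            .reset_index().to_csv(outdir / "mock_validation.tsv", sep="\t",
                                  index=False)
    stat_rows = []
    for name, res in result.stats.items():
        if hasattr(res, "statistic"):
            stat_rows.append({"test": name, "statistic": res.statistic,
                              "r_squared": res.r_squared, "p": res.p_value})
        elif isinstance(res, dict):
            for term, r in res.items():
                stat_rows.append({"test": f"{name}:{term}",
                                  "statistic": r.statistic,
                                  "r_squared": r.r_squared, "p": r.p_value})
    if stat_rows:
        write_table(outdir / "stats.tsv", pd.DataFrame(stat_rows))
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
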