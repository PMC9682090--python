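"""Readers and writers for the plain-text formats the pipeline touches.

Sequence data travel as :class:`SequenceRecord` (FASTA/FASTQ, Phred+33),
tabular data (sample metadata, taxonomy, mock expectations, ASV tables) as
tab-separated files read into pandas DataFrames, and pipeline parameters as
a flat YAML config mapped onto :class:`Config`.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("foramflow")

_VALID = set("ACGTN")

HABITATS = ("reef_flat", "reef_slope")
SAMPLE_TYPES = ("mock", "bulk", "eDNA", "morphology")
RANKS = ("phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """Raised on malformed input files (bad FASTQ record, duplicate ids...)."""


class SchemaError(ValueError):
    """Raised when a table is missing a mandatory column."""


def _clean_seq(seq: str) -> str:
    """Uppercase, map U->T, and replace any non-ACGTN letter with N."""
    s = seq.upper().replace("U", "T")
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence with optional Phred quality scores."""

    id: str
    seq: str
    qual: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def reverse_complement(rec: SequenceRecord) -> SequenceRecord:
    qual = rec.qual[::-1] if rec.qual is not None else None
    return SequenceRecord(rec.id, revcomp(rec.seq), qual)


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path) -> list[SequenceRecord]:
    """Read a Phred+33 FASTQ file.

    Raises :class:`FormatError` on malformed records (missing '+' separator,
    seq/qual length mismatch) naming the offending line, and on quality
    characters outside the Phred+33 printable range.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if not header:
                break
            lineno += 1
            header = header.rstrip("\n")
            if not header:
                continue
            if not header.startswith("@"):
                raise FormatError(f"{path}:{lineno}: expected '@' header, got {header[:20]!r}")
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise FormatError(f"{path}:{lineno}: truncated record")
            lineno += 3
            if not plus.startswith("+"):
                raise FormatError(f"{path}:{lineno - 1}: missing '+' separator line")
            if len(qual) != len(seq):
                raise FormatError(
                    f"{path}:{lineno}: quality length {len(qual)} != sequence length {len(seq)}"
                )
            phred = tuple(ord(c) - 33 for c in qual)
            if any(q < 0 or q > 62 for q in phred):
                raise FormatError(
                    f"{path}:{lineno}: quality characters outside Phred+33 range "
                    "(Phred+64 input is not supported)"
                )
            rid = header[1:].split()[0]
            if rid in seen:
                raise FormatError(f"{path}:{lineno - 3}: duplicate record id {rid!r}")
            seen.add(rid)
            records.append(SequenceRecord(rid, _clean_seq(seq), phred))
    return records


def write_fastq(path, records: Iterable[SequenceRecord]) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.qual is None:
                raise FormatError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            qual = "".join(chr(q + 33) for q in rec.qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qual}\n")


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA (wrapped lines allowed); duplicate ids are an error."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    dupes: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            dupes.append(rec.id)
            continue
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, _clean_seq(str(rec.seq))))
    if dupes:
        raise FormatError(f"{path}: duplicate record ids: {sorted(set(dupes))}")
    return records


def write_fasta(path, records: Iterable[SequenceRecord], width: int = 70) -> None:
    bio = (SeqRecord(Seq(r.seq), id=r.id, description="") for r in records)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def read_table(path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a UTF-8 TSV with a header row; '#'-prefixed lines are comments.

    Unknown columns are preserved.  Missing mandatory columns raise
    :class:`SchemaError` naming them.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s): {missing}")
    return df


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SampleMetadata:
    """One sample's grouping factors: site, location, habitat, type, replicate."""

    sample_id: str
    site: str
    location: str
    habitat: str
    sample_type: str
    replicate: int

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise SchemaError(f"sample {self.sample_id!r}: habitat {self.habitat!r} "
                              f"not in {HABITATS}")
        if self.sample_type not in SAMPLE_TYPES:
            raise SchemaError(f"sample {self.sample_id!r}: sample_type "
                              f"{self.sample_type!r} not in {SAMPLE_TYPES}")
        if self.replicate < 1:
            raise SchemaError(f"sample {self.sample_id!r}: replicate must be >= 1")


def read_metadata(path) -> list[SampleMetadata]:
    df = read_table(path, required=("sample_id", "site", "location", "habitat",
                                    "sample_type", "replicate"))
    out = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.sample_id in seen:
            raise SchemaError(f"{path}: duplicate sample_id {row.sample_id!r}")
        seen.add(row.sample_id)
        out.append(SampleMetadata(row.sample_id, row.site, row.location,
                                  row.habitat, row.sample_type, int(row.replicate)))
    return out


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

DEFAULT_RANK_THRESHOLDS = {
    "phylum": 0.75,
    "class": 0.80,
    "order": 0.84,
    "family": 0.96,
    "species": 0.994,
}


@dataclass
class Config:
    """All pipeline parameters; defaults are the study's published settings."""

    # read merging (FLASH-style)
    min_overlap: int = 50
    max_overlap: int = 300
    mismatch_ratio: float = 0.2
    # primer trimming (cutadapt-style)
    fwd_primer: str = "GWGGWGTTAATGCTGGTYGAAC"
    rev_primer: str = "RWRCTTCWGGATGWCTAAGARATC"
    primer_error_rate: float = 0.2
    primer_min_match: int = 10
    min_length_after_trim: int = 10
    # quality truncation and length filter
    trunc_qual: int = 20
    len_min: int = 315
    len_max: int = 325
    # denoising
    alpha: float = 4.0
    minsize: int = 8
    abundance_cutoff: float = 1e-4
    # taxonomic assignment
    min_coverage: float = 0.90
    min_identity: float = 0.75
    rank_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_RANK_THRESHOLDS))
    # statistics
    n_permutations: int = 999
    seed: int = 1

    def __post_init__(self) -> None:
        order = ["phylum", "class", "order", "family", "species"]
        vals = [self.rank_thresholds[r] for r in order]
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("rank thresholds must strictly increase with depth")
        for name in ("mismatch_ratio", "primer_error_rate", "abundance_cutoff",
                     "min_coverage", "min_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("rank thresholds must be fractions in [0, 1]")
        if not 0 < self.min_overlap <= self.max_overlap:
            raise ValueError("need 0 < min_overlap <= max_overlap")

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
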