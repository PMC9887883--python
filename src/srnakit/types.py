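"""Core data containers shared across the toolkit.

Coordinates are 0-based half-open everywhere inside the package; the
standard 1-based dialects (GFF3, SAM POS) are converted at the I/O
boundary.  Alignment collections are carried as pandas DataFrames with
the canonical columns in :data:`RECORD_COLUMNS`; the scalar
:class:`AlignmentRecord` exists for single-read inspection and tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

BIOTYPES = ("mRNA", "piRNA", "miRNA", "other")
TARGET_CLASSES = ("WAGO", "CSR1", "both", "none")
STRANDS = ("+", "-")

#: canonical column order of an alignment table (pos0 is 0-based leftmost)
RECORD_COLUMNS = ["read_id", "chrom", "pos0", "strand", "length", "seq", "n_hits"]


@dataclass(frozen=True)
class GeneModel:
    """An annotated locus: coordinates, strand, biotype and Argonaute target class."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "mRNA"
    target_class: str = "none"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: need 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.gene_id}: bad biotype {self.biotype!r}")
        if self.target_class not in TARGET_CLASSES:
            raise ValueError(f"{self.gene_id}: bad target_class {self.target_class!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AlignmentRecord:
    """One aligned read.

    ``seq`` is the read as sequenced (its own 5'->3'), not the
    reference-forward SAM orientation.  ``pos`` is the 0-based leftmost
    reference coordinate of the alignment.
    """

    read_id: str
    chrom: str
    pos: int
    strand: str
    seq: str = ""
    length: int = 0
    n_hits: int = 1

    def __post_init__(self) -> None:
        if self.seq and not self.length:
            self.length = len(self.seq)
        if self.seq and self.length != len(self.seq):
            raise ValueError(f"{self.read_id}: length {self.length} != |seq| {len(self.seq)}")
        if self.n_hits < 1:
            raise ValueError(f"{self.read_id}: n_hits must be >= 1")
        if self.strand not in STRANDS:
            raise ValueError(f"{self.read_id}: bad strand {self.strand!r}")


def records_to_frame(records: Iterable[AlignmentRecord]) -> pd.DataFrame:
    rows = [
        (r.read_id, r.chrom, r.pos, r.strand, r.length, r.seq, r.n_hits) for r in records
    ]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def frame_to_records(frame: pd.DataFrame) -> list[AlignmentRecord]:
    return [
        AlignmentRecord(
            read_id=str(t.read_id),
            chrom=str(t.chrom),
            pos=int(t.pos0),
            strand=str(t.strand),
            seq=str(t.seq) if isinstance(t.seq, str) else "",
            length=int(t.length),
            n_hits=int(t.n_hits),
        )
        for t in frame.itertuples(index=False)
    ]


def _json_header(path: Path) -> dict:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        return json.loads(first[1:])
    return {}


@dataclass
class CountTable:
    """Per-gene raw counts and RPM for one sample.

    RPM[g] = count[g] / total * 1e6 (all zero when total == 0).  The
    normalization total and the class filter that produced the counts
    travel with the table so every downstream call is auditable.
    """

    sample_id: str
    counts: pd.Series
    total: int
    class_filter: str = "all"
    norm_mode: str = "total"

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.counts.index.name = "gene_id"
        if self.total < 0:
            raise ValueError("normalization total must be nonnegative")

    @property
    def rpm(self) -> pd.Series:
        if self.total == 0:
            return pd.Series(0.0, index=self.counts.index, name="rpm")
        return (self.counts / self.total * 1e6).rename("rpm")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def to_tsv(self, path: str | Path) -> None:
        header = {
            "sample_id": self.sample_id,
            "total": int(self.total),
            "class_filter": self.class_filter,
            "norm_mode": self.norm_mode,
        }
        df = pd.DataFrame({"count": self.counts, "rpm": self.rpm})
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
            df.to_csv(fh, sep="\t", float_format="%.6f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        header = _json_header(Path(path))
        df = pd.read_csv(path, sep="\t", comment="#", index_col="gene_id")
        return cls(
            sample_id=header.get("sample_id", Path(path).stem),
            counts=df["count"],
            total=int(header.get("total", df["count"].sum())),
            class_filter=header.get("class_filter", "all"),
            norm_mode=header.get("norm_mode", "total"),
        )


@dataclass
class EnrichedSet:
    """Genes passing a fold-over-reference rule, with the rule recorded.

    ``members`` maps gene_id -> fold; fold is +inf exactly when the
    reference RPM was 0 and the IP RPM cleared the floor.
    """

    ip_sample: str
    ref_sample: str
    fold_threshold: float
    strict: bool
    min_rpm: float
    members: dict[str, float] = field(default_factory=dict)

    @property
    def genes(self) -> set[str]:
        return set(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def to_tsv(self, path: str | Path) -> None:
        header = {
            "ip_sample": self.ip_sample,
            "ref_sample": self.ref_sample,
            "fold_threshold": self.fold_threshold,
            "strict": self.strict,
            "min_rpm": self.min_rpm,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
            fh.write("gene_id\tfold\n")
            for g in sorted(self.members):
                f = self.members[g]
                fh.write(f"{g}\t{'inf' if np.isinf(f) else format(f, '.6f')}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EnrichedSet":
        header = _json_header(Path(path))
        df = pd.read_csv(path, sep="\t", comment="#")
        members = dict(zip(df["gene_id"], df["fold"].astype(float)))
        return cls(
            ip_sample=header["ip_sample"],
            ref_sample=header["ref_sample"],
            fold_threshold=float(header["fold_threshold"]),
            strict=bool(header["strict"]),
            min_rpm=float(header["min_rpm"]),
            members=members,
        )


DIFF_CATEGORIES = ("up", "down", "unchanged", "below_floor")


@dataclass
class DifferentialResult:
    """Per-gene fold-change categories between two samples.

    ``table`` is indexed by gene_id with columns category, fold,
    test_rpm, ref_rpm.  Categories are exhaustive and mutually
    exclusive.
    """

    test_sample: str
    ref_sample: str
    fold_threshold: float
    floor_rpm: float
    table: pd.DataFrame

    def genes(self, category: str) -> set[str]:
        if category not in DIFF_CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return set(self.table.index[self.table["category"] == category])

    @property
    def up(self) -> set[str]:
        return self.genes("up")

    @property
    def down(self) -> set[str]:
        return self.genes("down")

    def to_tsv(self, path: str | Path) -> None:
        header = {
            "test_sample": self.test_sample,
            "ref_sample": self.ref_sample,
            "fold_threshold": self.fold_threshold,
            "floor_rpm": self.floor_rpm,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
            self.table.to_csv(fh, sep="\t", float_format="%.6f")


@dataclass
class MetageneProfile:
    """Aggregate positional coverage over a gene set in 100 transcript-relative bins (5'->3')."""

    set_id: str
    sample_id: str
    values: np.ndarray
    mode: str = "mean"
    n_genes: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (100,):
            raise ValueError("a metagene profile has exactly 100 bins")
        if (self.values < 0).any():
            raise ValueError("bin values must be nonnegative")

    @property
    def center_of_mass(self) -> float:
        """Mean bin index (1..100) weighted by bin value; 50.5 for a flat profile."""
        total = self.values.sum()
        if total == 0:
            return float("nan")
        return float(np.arange(1, 101) @ self.values / total)

    def to_tsv(self, path: str | Path) -> None:
        header = {
            "set_id": self.set_id,
            "sample_id": self.sample_id,
            "mode": self.mode,
            "n_genes": self.n_genes,
        }
        with open(path, "w") as fh:
            fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
            fh.write("bin\tvalue\n")
            for i, v in enumerate(self.values, start=1):
                fh.write(f"{i}\t{v:.6f}\n")


@dataclass
class CoverageTrack:
    """Per-base read density over one gene span, in RPM units, genome orientation."""

    gene_id: str
    values: np.ndarray
    strand: str = "+"
    start: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("coverage must be nonnegative")

    def to_bedgraph(self, path: str | Path, chrom: str) -> None:
        with open(path, "w") as fh:
            for i, v in enumerate(self.values):
                if v:
                    fh.write(f"{chrom}\t{self.start + i}\t{self.start + i + 1}\t{v:.6f}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-column (or first-column) gene list from TSV; '#' lines ignored."""
    genes: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            genes.add(line.split("\t")[0])
    return genes


def write_gene_list(genes: Iterable[str], path: str | Path, header: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write("#" + json.dumps(dict(header), sort_keys=True) + "\n")
        for g in sorted(genes):
            fh.write(f"{g}\n")
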