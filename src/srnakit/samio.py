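"""Alignment I/O: SAM (via pysam) and the canonical tabular dialect.

Internally reads are stored with ``seq`` in read orientation (the
molecule as sequenced, 5'->3') and ``pos0`` as the 0-based leftmost
reference coordinate.  SAM stores minus-strand alignments with the
sequence reverse-complemented onto the reference forward strand and a
1-based POS; both conversions happen here and nowhere else.  Mapping
multiplicity round-trips through the NH tag.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd
import pysam

from .seqtools import revcomp
from .types import RECORD_COLUMNS, GeneModel


def write_alignment_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame[RECORD_COLUMNS].to_csv(path, sep="\t", index=False)


def read_alignment_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"read_id": str, "chrom": str, "strand": str, "seq": str},
        keep_default_na=False,
    )
    df["pos0"] = df["pos0"].astype(int)
    df["length"] = df["length"].astype(int)
    df["n_hits"] = df["n_hits"].astype(int)
    return df[RECORD_COLUMNS]


def _sam_header(chrom_sizes: dict[str, int]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": name, "LN": size} for name, size in chrom_sizes.items()],
        }
    )


def chrom_sizes_from_genes(genes: Sequence[GeneModel], pad: int = 1000) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for g in genes:
        sizes[g.chrom] = max(sizes.get(g.chrom, 0), g.end + pad)
    return sizes


def write_sam(frame: pd.DataFrame, path: str | Path, chrom_sizes: dict[str, int]) -> None:
    header = _sam_header(chrom_sizes)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        tids = {name: i for i, name in enumerate(chrom_sizes)}
        for t in frame.itertuples(index=False):
            a = pysam.AlignedSegment(header)
            a.query_name = t.read_id
            a.reference_id = tids[t.chrom]
            a.reference_start = int(t.pos0)
            a.flag = 16 if t.strand == "-" else 0
            seq = t.seq if isinstance(t.seq, str) else ""
            if seq:
                # SAM carries the reference-forward orientation
                a.query_sequence = revcomp(seq) if t.strand == "-" else seq
                a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.cigarstring = f"{int(t.length)}M"
            a.mapping_quality = 255
            a.set_tag("NH", int(t.n_hits))
            out.write(a)


def read_sam(path: str | Path) -> pd.DataFrame:
    rows = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            strand = "-" if a.is_reverse else "+"
            seq = a.query_sequence or ""
            if seq and a.is_reverse:
                seq = revcomp(seq)
            length = a.query_length or (a.reference_length or 0)
            n_hits = a.get_tag("NH") if a.has_tag("NH") else 1
            rows.append(
                (a.query_name, a.reference_name, a.reference_start, strand, length, seq, int(n_hits))
            )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def read_alignments(path: str | Path) -> pd.DataFrame:
    """Dispatch on extension: .sam -> SAM, anything else -> canonical TSV."""
    p = Path(path)
    if p.suffix == ".sam":
        return read_sam(p)
    return read_alignment_tsv(p)
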