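"""Read classification and per-gene RPM quantification.

A 22G-RNA call requires a uniquely mapped 22-nt read antisense to an
mRNA locus; an optional 5'-G check is off by default because the
length/strand/uniqueness rule is what defines the class operationally.
piRNA calls require sense overlap of a piRNA locus (optional 21-nt and
5'-U checks); miRNA calls go by miRNA-locus overlap.  When loci of
several biotypes overlap a read the precedence is
piRNA > miRNA > mRNA > other.  Every record receives exactly one label
from {22G, piRNA, miRNA, other, unassigned}.

Quantification sums per-gene reads of a requested class and normalizes
to reads per million: RPM[g] = count[g] / total * 1e6, where the
default total is every mapped read in the sample (class-independent),
matching normalization "by total read counts of each sample".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import GeneIndex, index_from_any
from .types import AlignmentRecord, CountTable, records_to_frame

LABELS = ("22G", "piRNA", "miRNA", "other", "unassigned")


@dataclass(frozen=True)
class ClassifyRules:
    """Classification configuration; defaults follow the operational 22G definition."""

    g22_length: int = 22
    require_unique: bool = True
    check_5p_g: bool = False
    pirna_length: int | None = None  # set to 21 to enforce
    check_5p_u: bool = False
    min_overlap: int = 1


DEFAULT_RULES = ClassifyRules()


def _first_base(seqs: pd.Series) -> np.ndarray:
    return np.array([s[0] if isinstance(s, str) and s else "" for s in seqs])


def classify_frame(
    frame: pd.DataFrame,
    annotation,
    rules: ClassifyRules = DEFAULT_RULES,
) -> pd.DataFrame:
    """Label every record and assign it a gene.

    Returns a copy of ``frame`` with ``label`` and ``gene_id`` columns
    (gene_id is "" when no locus is assigned).  Records on chromosomes
    absent from the annotation come back unassigned, not as errors.
    """
    index = index_from_any(annotation)
    out = frame.reset_index(drop=True).copy()
    n = len(out)
    label = np.full(n, "unassigned", dtype=object)
    gene = np.full(n, "", dtype=object)
    if n == 0:
        out["label"] = label
        out["gene_id"] = gene
        return out

    pos = out["pos0"].to_numpy(dtype=np.int64)
    length = out["length"].to_numpy(dtype=np.int64)
    ends = pos + length
    minus = (out["strand"] == "-").to_numpy()
    nh = out["n_hits"].to_numpy(dtype=np.int64)
    first = _first_base(out["seq"]) if (rules.check_5p_g or rules.check_5p_u) else None

    unresolved = np.ones(n, dtype=bool)
    for chrom, rows in out.groupby("chrom", sort=False).groups.items():
        rows = np.asarray(rows, dtype=np.int64)
        rs, re = pos[rows], ends[rows]
        rminus = minus[rows]
        open_mask = np.ones(len(rows), dtype=bool)

        for biotype in ("piRNA", "miRNA", "mRNA", "other"):
            if not open_mask.any():
                break
            layer = index.layer(str(chrom), biotype)
            if layer is None:
                continue
            row_best, ov = layer.assign(rs, re)
            hit = open_mask & (row_best >= 0) & (ov >= rules.min_overlap)
            if biotype == "piRNA":
                # piRNA assignment requires sense overlap
                hit &= layer.strands[np.maximum(row_best, 0)] == rminus
            if not hit.any():
                continue
            g_local = np.maximum(row_best, 0)
            gids = layer.ids[g_local]
            gminus = layer.strands[g_local]
            sub = rows[hit]
            gene[sub] = gids[hit]
            if biotype == "piRNA":
                lab = np.full(hit.sum(), "piRNA", dtype=object)
                ok = np.ones(hit.sum(), dtype=bool)
                if rules.pirna_length is not None:
                    ok &= length[sub] == rules.pirna_length
                if rules.check_5p_u:
                    ok &= np.isin(first[sub], ("U", "T"))
                lab[~ok] = "other"
                label[sub] = lab
            elif biotype == "miRNA":
                label[sub] = "miRNA"
            elif biotype == "mRNA":
                anti = rminus[hit] != gminus[hit]
                is22 = (
                    anti
                    & (length[sub] == rules.g22_length)
                    & ((nh[sub] == 1) if rules.require_unique else True)
                )
                if rules.check_5p_g:
                    is22 &= first[sub] == "G"
                label[sub] = np.where(is22, "22G", "other")
            else:
                label[sub] = "other"
            open_mask &= ~hit
    out["label"] = label
    out["gene_id"] = gene
    return out


def classify_read(
    rec: AlignmentRecord,
    annotation,
    rules: ClassifyRules = DEFAULT_RULES,
) -> tuple[str, str | None]:
    """Classify a single record; returns (label, gene_id or None)."""
    df = classify_frame(records_to_frame([rec]), annotation, rules)
    gene = df["gene_id"].iloc[0]
    return df["label"].iloc[0], (gene if gene else None)


def _norm_total(frame: pd.DataFrame, counted: pd.DataFrame, mode: str) -> int:
    if mode == "total":
        return len(frame)
    if mode == "unique":
        return int((frame["n_hits"] == 1).sum())
    if mode == "counted":
        return len(counted)
    raise ValueError(f"unknown normalization mode {mode!r}")


def quantify(
    records: "pd.DataFrame | Iterable[AlignmentRecord]",
    annotation,
    class_filter: str = "22G",
    norm: str = "total",
    sample_id: str = "sample",
    rules: ClassifyRules = DEFAULT_RULES,
) -> CountTable:
    """Per-gene counts and RPM for one sample and one read class.

    ``class_filter``: one of the labels ('22G', 'piRNA', 'miRNA'),
    'mRNA' (any read assigned to an mRNA locus, as used for CLIP), or
    'all' (any assigned read).  ``norm``: 'total' (all mapped records in
    the stream, the default denominator), 'unique' (n_hits == 1 records)
    or 'counted' (only the counted class).  An empty stream yields an
    all-zero table with total 0.
    """
    index = index_from_any(annotation)
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(list(records))
    labeled = classify_frame(frame, index, rules)

    if class_filter in ("22G", "piRNA", "miRNA"):
        counted = labeled[labeled["label"] == class_filter]
    elif class_filter == "mRNA":
        mrna = {g.gene_id for g in index.of_biotype("mRNA")}
        counted = labeled[labeled["gene_id"].isin(mrna)]
    elif class_filter == "all":
        counted = labeled[labeled["gene_id"] != ""]
    else:
        raise ValueError(f"unknown class filter {class_filter!r}")

    universe = pd.Index(sorted(index.gene_ids), name="gene_id")
    counts = (
        counted["gene_id"].value_counts().reindex(universe, fill_value=0).astype(np.int64)
    )
    total = _norm_total(labeled, counted, norm)
    return CountTable(
        sample_id=sample_id,
        counts=counts,
        total=total,
        class_filter=class_filter,
        norm_mode=norm,
    )
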