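"""Gene-annotation I/O and interval indexing.

Annotations move through two dialects: GFF3 (1-based inclusive, read
via gffutils) and a canonical TSV (0-based half-open).  Internally a
:class:`GeneIndex` groups loci per chromosome into biotype layers with
the overlap precedence piRNA > miRNA > mRNA > other, and answers
overlap queries either through a vectorized sorted-array fast path
(when genes within a layer do not overlap, as in simulated data) or
through an interval tree for arbitrary annotations.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .types import GeneModel

#: overlap precedence when a read touches loci of several biotypes
LAYER_ORDER = ("piRNA", "miRNA", "mRNA", "other")

ANNOTATION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype", "target_class"]


# ---------------------------------------------------------------------------
# I/O

def write_annotation_tsv(genes: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.chrom, g.start, g.end, g.strand, g.biotype, g.target_class) for g in genes],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: str | Path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        GeneModel(
            gene_id=str(t.gene_id),
            chrom=str(t.chrom),
            start=int(t.start),
            end=int(t.end),
            strand=str(t.strand),
            biotype=str(t.biotype),
            target_class=str(t.target_class),
        )
        for t in df.itertuples(index=False)
    ]


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write genes as GFF3 `gene` features (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id};biotype={g.biotype};target_class={g.target_class}"
            fh.write(
                f"{g.chrom}\tsrnakit\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for feat in db.all_features():
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                biotype=feat.attributes.get("biotype", ["mRNA"])[0],
                target_class=feat.attributes.get("target_class", ["none"])[0],
            )
        )
    return genes


def write_fasta(genome: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Index

class _Layer:
    """Sorted per-chromosome gene arrays for one biotype; vectorized when non-overlapping."""

    def __init__(self, genes: list[tuple[int, GeneModel]]):
        genes = sorted(genes, key=lambda t: (t[1].start, t[1].end, t[1].gene_id))
        self.idx = np.array([i for i, _ in genes], dtype=np.int64)
        self.starts = np.array([g.start for _, g in genes], dtype=np.int64)
        self.ends = np.array([g.end for _, g in genes], dtype=np.int64)
        self.strands = np.array([g.strand == "-" for _, g in genes], dtype=bool)
        self.ids = np.array([g.gene_id for _, g in genes])
        self.nonoverlapping = bool(np.all(self.ends[:-1] <= self.starts[1:]))
        self.tree: IntervalTree | None = None
        if not self.nonoverlapping:
            self.tree = IntervalTree()
            for j in range(len(self.idx)):
                self.tree.addi(int(self.starts[j]), int(self.ends[j]), j)

    def assign(self, rs: np.ndarray, re: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Best gene (layer-local row, -1 if none) and overlap length per read interval.

        Best = largest overlap; ties break to the lexicographically
        smallest gene_id.
        """
        n = len(rs)
        if len(self.idx) == 0:
            return np.full(n, -1, dtype=np.int64), np.zeros(n, dtype=np.int64)
        if self.nonoverlapping:
            # candidate: predecessor by start, and its successor
            j = np.searchsorted(self.starts, rs, side="right") - 1
            best_row = np.full(n, -1, dtype=np.int64)
            best_ov = np.zeros(n, dtype=np.int64)
            for cand in (j, j + 1):
                ok = (cand >= 0) & (cand < len(self.idx))
                c = np.where(ok, cand, 0)
                ov = np.minimum(re, self.ends[c]) - np.maximum(rs, self.starts[c])
                ov = np.where(ok, np.maximum(ov, 0), 0)
                better = ov > best_ov
                # tie -> smaller gene_id
                tie = (ov == best_ov) & (ov > 0) & (best_row >= 0)
                if tie.any():
                    better |= tie & (self.ids[c] < self.ids[np.maximum(best_row, 0)])
                best_row = np.where(better, c, best_row)
                best_ov = np.where(better, ov, best_ov)
            return best_row, best_ov
        # general path
        best_row = np.full(n, -1, dtype=np.int64)
        best_ov = np.zeros(n, dtype=np.int64)
        for k in range(n):
            hits = self.tree.overlap(int(rs[k]), int(re[k]))
            top = None
            for iv in hits:
                ov = min(re[k], iv.end) - max(rs[k], iv.begin)
                key = (-ov, self.ids[iv.data])
                if top is None or key < top[0]:
                    top = (key, iv.data, ov)
            if top is not None:
                best_row[k] = top[1]
                best_ov[k] = top[2]
        return best_row, best_ov


class GeneIndex:
    """Overlap index over a gene annotation with biotype precedence."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene_id values must be unique within an annotation")
        self.gene_ids = np.array(ids)
        self._layers: dict[tuple[str, str], _Layer] = {}
        by_key: dict[tuple[str, str], list[tuple[int, GeneModel]]] = {}
        for i, g in enumerate(self.genes):
            by_key.setdefault((g.chrom, g.biotype), []).append((i, g))
        for key, lst in by_key.items():
            self._layers[key] = _Layer(lst)
        self._by_id = {g.gene_id: g for g in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def chroms(self) -> set[str]:
        return {g.chrom for g in self.genes}

    def layer(self, chrom: str, biotype: str) -> _Layer | None:
        return self._layers.get((chrom, biotype))

    def of_biotype(self, biotype: str) -> list[GeneModel]:
        return [g for g in self.genes if g.biotype == biotype]

    def of_target_class(self, target_class: str) -> set[str]:
        """Gene ids of the class; 'WAGO'/'CSR1' include 'both'."""
        out = set()
        for g in self.genes:
            if g.target_class == target_class or (
                target_class in ("WAGO", "CSR1") and g.target_class == "both"
            ):
                out.add(g.gene_id)
        return out

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[GeneModel, int]]:
        """All genes overlapping [start, end) with overlap lengths (any biotype)."""
        hits: list[tuple[GeneModel, int]] = []
        for bt in LAYER_ORDER:
            layer = self._layers.get((chrom, bt))
            if layer is None:
                continue
            for j in range(len(layer.idx)):
                ov = min(end, int(layer.ends[j])) - max(start, int(layer.starts[j]))
                if ov > 0:
                    hits.append((self.genes[int(layer.idx[j])], ov))
        return hits


def index_from_any(source: "GeneIndex | Sequence[GeneModel] | str | Path") -> GeneIndex:
    """Accept an index, a gene list, or a GFF3/TSV path."""
    if isinstance(source, GeneIndex):
        return source
    if isinstance(source, (str, Path)):
        p = Path(source)
        if p.suffix in (".gff", ".gff3"):
            return GeneIndex(read_gff3(p))
        return GeneIndex(read_annotation_tsv(p))
    return GeneIndex(list(source))
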