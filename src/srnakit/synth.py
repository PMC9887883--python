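"""Synthetic small-RNA / CLIP library generator with planted ground truth.

The generator emulates the structure of a germline Argonaute study:

* a genome of non-overlapping loci -- mRNAs, discrete 21-nt piRNA loci
  and ~22-nt miRNA loci -- with WAGO / CSR-1 target-class labels;
* per-gene baseline abundances (log-normal) and named *planted sets*
  whose abundance is multiplied in chosen conditions (e.g. an ectopic
  set that gains 22G-RNAs in a helicase-null background);
* immunoprecipitation baits that multiply a target set's sampling
  weight by an enrichment factor ``e`` in IP libraries only;
* CLIP libraries whose fragment start positions carry a configurable
  3' positional bias (``beta``; 0 = uniform along the transcript).

Reads are drawn multinomially (class mixture first, then genes within a
class) so the truth sidecar counts always sum to the requested depth.
22G-class reads are 22 nt, antisense to their source mRNA and begin
with G on the read strand (start positions are sampled among genome
positions that yield a G start, so read sequences are genuine genome
slices); piRNA reads are the 21-nt locus read sense, starting with U.
Per-sample random streams derive reproducibly from
(master seed, sample_id).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import AlignmentRecord, GeneModel, RECORD_COLUMNS

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGT", b"TGCA"):
    _COMP[x] = y


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class PlantedSet:
    """A named gene set drawn from a pool: a target class, a biotype, or another set."""

    name: str
    source: str  # 'mRNA', 'WAGO', 'CSR1', 'none', or the name of an earlier set
    size: int


@dataclass(frozen=True)
class BaitSpec:
    """An IP bait: enrichment factor e applied to a target set, optionally per condition."""

    name: str
    e: float
    targets: tuple[str, ...]  # planted-set / class names, unioned
    targets_by_condition: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def target_names(self, condition: str) -> tuple[str, ...]:
        return tuple(self.targets_by_condition.get(condition, self.targets))


@dataclass(frozen=True)
class SimConfig:
    """Study design: gene counts, planted structure, mixtures, and library anatomy."""

    n_mrna: int = 1000
    n_pirna: int = 60
    n_mirna: int = 20
    n_chrom: int = 3
    mrna_len: tuple[int, int] = (500, 2000)
    pirna_len: int = 21
    mirna_len: int = 22
    gap: tuple[int, int] = (50, 200)
    n_wago: int = 150
    n_csr1: int = 300
    n_both: int = 30
    abundance_sigma: float = 0.25
    planted_sets: tuple[PlantedSet, ...] = ()
    conditions: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"wt": {}}
    )
    baits: tuple[BaitSpec, ...] = ()
    # class mixture of small-RNA libraries (22G, piRNA, miRNA, other)
    mixture: tuple[float, float, float, float] = (0.80, 0.12, 0.04, 0.04)
    # class mixture of CLIP libraries (mRNA fragments, piRNA, other)
    clip_mixture: tuple[float, float, float] = (0.85, 0.10, 0.05)
    clip_frag_len: tuple[int, int] = (15, 40)
    clip_beta: float = 0.0
    multimap_fraction: float = 0.0
    read_len_other: tuple[int, int] = (18, 26)

    def validate(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")
        if abs(sum(self.clip_mixture) - 1.0) > 1e-9:
            raise ValueError("clip_mixture proportions must sum to 1")
        if self.n_wago + self.n_csr1 + self.n_both > self.n_mrna:
            raise ValueError("target classes exceed available mRNA genes")
        if not 0.0 <= self.multimap_fraction <= 1.0:
            raise ValueError("multimap_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SampleSpec:
    """One library to simulate."""

    sample_id: str
    condition: str = "wt"
    fraction: str = "input"  # input | IP | CLIP | CLIP-control
    bait: str | None = None
    depth: int = 100_000
    beta: float | None = None  # CLIP positional bias override

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.fraction not in ("input", "IP", "CLIP", "CLIP-control"):
            raise ValueError(f"unknown fraction {self.fraction!r}")
        if self.fraction == "IP" and self.bait is None:
            raise ValueError("IP libraries require a bait")


@dataclass
class GroundTruth:
    """Planted per-gene structure the analysis is expected to recover."""

    config: SimConfig
    master_seed: int
    abundance: pd.Series  # baseline rate per mRNA gene
    pirna_abundance: pd.Series
    mirna_abundance: pd.Series
    sets: dict[str, set[str]]  # planted sets plus WAGO/CSR1 class sets
    genome: dict[str, np.ndarray]  # chrom -> uint8 ASCII array

    def genome_str(self) -> dict[str, str]:
        return {c: a.tobytes().decode() for c, a in self.genome.items()}

    def bait(self, name: str) -> BaitSpec:
        for b in self.config.baits:
            if b.name == name:
                return b
        raise ValueError(f"unknown bait {name!r}")

    def condition_multipliers(self, condition: str) -> pd.Series:
        if condition not in self.config.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        mult = pd.Series(1.0, index=self.abundance.index)
        for set_name, m in self.config.conditions[condition].items():
            genes = sorted(self.sets[set_name] & set(mult.index))
            mult.loc[genes] = float(m)
        return mult

    def resolve_targets(self, names: Sequence[str]) -> set[str]:
        """Union of the named sets; a leading '-' subtracts a set instead."""
        out: set[str] = set()
        for name in names:
            if not name.startswith("-"):
                out |= self.sets[name]
        for name in names:
            if name.startswith("-"):
                out -= self.sets[name[1:]]
        return out


def sample_seed(master_seed: int, sample_id: str) -> np.random.SeedSequence:
    """Stable per-sample stream: CRC32 of the sample id spliced with the master seed."""
    return np.random.SeedSequence([int(master_seed) % (2**31), zlib.crc32(sample_id.encode())])


# ---------------------------------------------------------------------------
# truth construction

def build_truth(config: SimConfig, seed: int) -> tuple[list[GeneModel], GroundTruth]:
    """Lay out the genome, draw abundances, and resolve all planted sets.

    Deterministic in (config, seed): the same pair reproduces the
    annotation, genome sequence and truth byte-for-byte.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 0xA110C]))

    # gene layout round-robin over chromosomes
    genes: list[GeneModel] = []
    cursors = np.zeros(config.n_chrom, dtype=np.int64)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chrom)]

    def place(gene_id: str, length: int, strand: str, biotype: str) -> GeneModel:
        c = len(genes) % config.n_chrom
        start = int(cursors[c] + rng.integers(config.gap[0], config.gap[1] + 1))
        g = GeneModel(gene_id, chrom_names[c], start, start + length, strand, biotype)
        cursors[c] = g.end
        return g

    widths = {"mRNA": 5, "piRNA": 4, "miRNA": 4}
    for i in range(config.n_mrna):
        length = int(rng.integers(config.mrna_len[0], config.mrna_len[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(place(f"g{i:0{widths['mRNA']}d}", length, strand, "mRNA"))
    for i in range(config.n_pirna):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(place(f"pi{i:0{widths['piRNA']}d}", config.pirna_len, strand, "piRNA"))
    for i in range(config.n_mirna):
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(place(f"mi{i:0{widths['miRNA']}d}", config.mirna_len, strand, "miRNA"))

    # target classes over mRNA genes
    mrna_ids = [g.gene_id for g in genes if g.biotype == "mRNA"]
    shuffled = list(mrna_ids)
    rng.shuffle(shuffled)
    wago = set(shuffled[: config.n_wago])
    csr1 = set(shuffled[config.n_wago : config.n_wago + config.n_csr1])
    both = set(shuffled[config.n_wago + config.n_csr1 : config.n_wago + config.n_csr1 + config.n_both])
    cls = {}
    for gid in mrna_ids:
        cls[gid] = "WAGO" if gid in wago else "CSR1" if gid in csr1 else "both" if gid in both else "none"
    genes = [
        replace(g, target_class=cls[g.gene_id]) if g.biotype == "mRNA" else g for g in genes
    ]

    # genome sequence: i.i.d. uniform ACGT, then force piRNA 5' U and miRNA 5' G
    genome: dict[str, np.ndarray] = {}
    for c, name in enumerate(chrom_names):
        size = int(cursors[c] + config.gap[1])
        genome[name] = _BASES[rng.integers(0, 4, size=size)]
    for g in genes:
        if g.biotype == "piRNA":
            # sense read starts with U: first sense base is T on its own strand
            if g.strand == "+":
                genome[g.chrom][g.start] = ord("T")
            else:
                genome[g.chrom][g.end - 1] = ord("A")  # revcomp -> U
        elif g.biotype == "miRNA":
            if g.strand == "+":
                genome[g.chrom][g.start] = ord("G")
            else:
                genome[g.chrom][g.end - 1] = ord("C")

    # abundances
    mrna_index = pd.Index(mrna_ids, name="gene_id")
    abundance = pd.Series(
        rng.lognormal(0.0, config.abundance_sigma, size=len(mrna_ids)), index=mrna_index
    )
    pirna_ids = pd.Index([g.gene_id for g in genes if g.biotype == "piRNA"], name="gene_id")
    mirna_ids = pd.Index([g.gene_id for g in genes if g.biotype == "miRNA"], name="gene_id")
    pirna_abundance = pd.Series(
        rng.lognormal(0.0, config.abundance_sigma, size=len(pirna_ids)), index=pirna_ids
    )
    mirna_abundance = pd.Series(
        rng.lognormal(0.0, config.abundance_sigma, size=len(mirna_ids)), index=mirna_ids
    )

    # planted sets
    sets: dict[str, set[str]] = {
        "mRNA": set(mrna_ids),
        "WAGO": wago | both,
        "CSR1": csr1 | both,
        "both": set(both),
        "none": {g for g, c in cls.items() if c == "none"},
    }
    for ps in config.planted_sets:
        if ps.source not in sets:
            raise ValueError(f"planted set {ps.name!r}: unknown source {ps.source!r}")
        pool = sorted(sets[ps.source])
        if ps.size > len(pool):
            raise ValueError(
                f"planted set {ps.name!r}: requested {ps.size} genes but only "
                f"{len(pool)} available in {ps.source!r}"
            )
        sets[ps.name] = set(rng.choice(pool, size=ps.size, replace=False))

    for cond, mults in config.conditions.items():
        for set_name in mults:
            if set_name not in sets:
                raise ValueError(f"condition {cond!r} references unknown set {set_name!r}")
    for b in config.baits:
        for names in [b.targets, *b.targets_by_condition.values()]:
            for name in names:
                if name.lstrip("-") not in sets:
                    raise ValueError(f"bait {b.name!r} references unknown set {name!r}")

    truth = GroundTruth(
        config=config,
        master_seed=int(seed),
        abundance=abundance,
        pirna_abundance=pirna_abundance,
        mirna_abundance=mirna_abundance,
        sets=sets,
        genome=genome,
    )
    return genes, truth


# ---------------------------------------------------------------------------
# library simulation

def _extract_seqs(
    genome: np.ndarray, starts: np.ndarray, length: int, antisense: np.ndarray
) -> list[str]:
    """Genome slices as strings; rows flagged antisense are reverse-complemented."""
    if len(starts) == 0:
        return []
    mat = genome[starts[:, None] + np.arange(length)[None, :]]
    if antisense.any():
        rc = _COMP[mat[antisense][:, ::-1]]
        mat = mat.copy()
        mat[antisense] = rc
    raw = mat.tobytes()
    return [raw[i * length : (i + 1) * length].decode() for i in range(len(starts))]


def _gene_arrays(genes: Sequence[GeneModel], biotype: str):
    sub = [g for g in genes if g.biotype == biotype]
    return sub


def _valid_g_starts(genome: np.ndarray, g: GeneModel, read_len: int) -> np.ndarray:
    """Start positions within the gene whose antisense read begins with G.

    For a plus-strand gene the antisense read's 5' base sits at the
    rightmost genomic coordinate of the slice and must be C there; for a
    minus-strand gene (antisense read on genome +) the 5' base is the
    leftmost coordinate and must be G.
    """
    lo, hi = g.start, g.end - read_len
    if hi < lo:
        return np.array([g.start], dtype=np.int64)
    window = genome[lo : hi + read_len]
    if g.strand == "+":
        ok = window[read_len - 1 : read_len - 1 + (hi - lo + 1)] == ord("C")
    else:
        ok = window[: hi - lo + 1] == ord("G")
    starts = np.arange(lo, hi + 1, dtype=np.int64)[ok]
    if len(starts) == 0:
        starts = np.arange(lo, hi + 1, dtype=np.int64)
    return starts


def simulate_library(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    spec: SampleSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one library; returns (alignment frame, truth sidecar).

    The sidecar has columns (gene_id, cls, count); its counts sum to
    ``spec.depth`` exactly.  Gene-level counts are multinomial with
    probabilities proportional to abundance x condition multiplier x
    (bait enrichment e for IP/tagged-CLIP target genes).
    """
    cfg = truth.config
    rng = np.random.default_rng(sample_seed(truth.master_seed, spec.sample_id))
    mult = truth.condition_multipliers(spec.condition)

    bait_targets: set[str] = set()
    e = 1.0
    if spec.fraction == "IP" or (spec.fraction == "CLIP" and spec.bait is not None):
        bait = truth.bait(spec.bait)
        e = bait.e
        bait_targets = truth.resolve_targets(bait.target_names(spec.condition))

    by_id = {g.gene_id: g for g in genes}
    mrna = _gene_arrays(genes, "mRNA")
    pirna = _gene_arrays(genes, "piRNA")
    mirna = _gene_arrays(genes, "miRNA")

    frames: list[pd.DataFrame] = []
    sidecar_rows: list[tuple[str, str, int]] = []
    genome = truth.genome

    def gene_weights(ab: pd.Series, enriched: bool) -> np.ndarray:
        w = ab.to_numpy() * mult.reindex(ab.index, fill_value=1.0).to_numpy()
        if enriched and bait_targets:
            boost = np.fromiter(
                (e if gid in bait_targets else 1.0 for gid in ab.index), float, len(ab)
            )
            w = w * boost
        return w

    def emit_fixed_locus(gene_list, ab, n_reads, cls):
        """Classes read as the whole locus, sense strand (piRNA / miRNA)."""
        if n_reads == 0 or not gene_list:
            return
        w = ab.to_numpy()
        counts = rng.multinomial(n_reads, w / w.sum())
        rows = []
        for g, c in zip(gene_list, counts):
            if c == 0:
                continue
            sidecar_rows.append((g.gene_id, cls, int(c)))
            seq_arr = genome[g.chrom][g.start : g.end]
            if g.strand == "-":
                seq_arr = _COMP[seq_arr[::-1]]
            seq = seq_arr.tobytes().decode()
            rows.append((g.chrom, g.start, g.strand, g.length, seq, c))
        recs = []
        for chrom, start, strand, length, seq, c in rows:
            recs.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos0": np.full(c, start, dtype=np.int64),
                        "strand": strand,
                        "length": length,
                        "seq": seq,
                        "n_hits": 1,
                    }
                )
            )
        if recs:
            frames.append(pd.concat(recs, ignore_index=True))

    if spec.fraction in ("input", "IP"):
        n_by_class = rng.multinomial(spec.depth, cfg.mixture)
        n22, npi, nmi, noth = (int(x) for x in n_by_class)

        # --- 22G: antisense 22-mers over mRNAs
        if n22 and mrna:
            w = gene_weights(truth.abundance, enriched=spec.fraction == "IP")
            counts = rng.multinomial(n22, w / w.sum())
            sub_frames = []
            for g, c in zip(mrna, counts):
                if c == 0:
                    continue
                sidecar_rows.append((g.gene_id, "22G", int(c)))
                valid = _valid_g_starts(genome[g.chrom], g, 22)
                starts = rng.choice(valid, size=c)
                anti_strand = "-" if g.strand == "+" else "+"
                seqs = _extract_seqs(
                    genome[g.chrom], starts, 22, np.full(c, g.strand == "+", dtype=bool)
                )
                sub_frames.append(
                    pd.DataFrame(
                        {
                            "chrom": g.chrom,
                            "pos0": starts,
                            "strand": anti_strand,
                            "length": 22,
                            "seq": seqs,
                            "n_hits": 1,
                        }
                    )
                )
            if sub_frames:
                f22 = pd.concat(sub_frames, ignore_index=True)
                if cfg.multimap_fraction > 0:
                    mm = rng.random(len(f22)) < cfg.multimap_fraction
                    f22.loc[mm, "n_hits"] = 2
                frames.append(f22)

        emit_fixed_locus(pirna, truth.pirna_abundance, npi, "piRNA")
        emit_fixed_locus(mirna, truth.mirna_abundance, nmi, "miRNA")

        # --- background: random genomic fragments
        if noth:
            sidecar_rows.append(("*", "other", int(noth)))
            frames.append(_random_background(rng, genome, noth, cfg.read_len_other))

    elif spec.fraction in ("CLIP", "CLIP-control"):
        beta = spec.beta if spec.beta is not None else cfg.clip_beta
        n_by_class = rng.multinomial(spec.depth, cfg.clip_mixture)
        nm, npi, noth = (int(x) for x in n_by_class)

        if nm and mrna:
            w = gene_weights(truth.abundance, enriched=spec.fraction == "CLIP" and bool(bait_targets))
            counts = rng.multinomial(nm, w / w.sum())
            sub_frames = []
            lo, hi = cfg.clip_frag_len
            for g, c in zip(mrna, counts):
                if c == 0:
                    continue
                sidecar_rows.append((g.gene_id, "mRNA", int(c)))
                frag = rng.integers(lo, hi + 1, size=c)
                frag = np.minimum(frag, g.length)
                # transcript-relative start with 3' skew: u ~ 1 - Beta(1, 1+beta)
                u = 1.0 - rng.beta(1.0, 1.0 + beta, size=c)
                slots = (g.length - frag + 1).astype(np.int64)
                t_start = np.minimum((u * slots).astype(np.int64), slots - 1)
                if g.strand == "+":
                    gstart = g.start + t_start
                else:
                    gstart = g.end - t_start - frag
                for L in np.unique(frag):
                    m = frag == L
                    seqs = _extract_seqs(
                        genome[g.chrom], gstart[m], int(L),
                        np.full(int(m.sum()), g.strand == "-", dtype=bool),
                    )
                    sub_frames.append(
                        pd.DataFrame(
                            {
                                "chrom": g.chrom,
                                "pos0": gstart[m],
                                "strand": g.strand,
                                "length": int(L),
                                "seq": seqs,
                                "n_hits": 1,
                            }
                        )
                    )
            if sub_frames:
                frames.append(pd.concat(sub_frames, ignore_index=True))

        emit_fixed_locus(pirna, truth.pirna_abundance, npi, "piRNA")
        if noth:
            sidecar_rows.append(("*", "other", int(noth)))
            frames.append(_random_background(rng, genome, noth, cfg.clip_frag_len))
    else:  # pragma: no cover - SampleSpec already validates
        raise ValueError(f"unknown fraction {spec.fraction!r}")

    if frames:
        frame = pd.concat(frames, ignore_index=True)
    else:
        frame = pd.DataFrame(columns=RECORD_COLUMNS[1:])
    frame.insert(0, "read_id", [f"{spec.sample_id}:{i:08d}" for i in range(len(frame))])
    frame = frame[RECORD_COLUMNS]

    sidecar = pd.DataFrame(sidecar_rows, columns=["gene_id", "cls", "count"])
    sidecar = (
        sidecar.groupby(["gene_id", "cls"], as_index=False)["count"].sum()
        .sort_values(["cls", "gene_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    assert int(sidecar["count"].sum()) == spec.depth
    return frame, sidecar


def _random_background(
    rng: np.random.Generator,
    genome: dict[str, np.ndarray],
    n: int,
    len_range: tuple[int, int],
) -> pd.DataFrame:
    chroms = sorted(genome)
    sizes = np.array([len(genome[c]) for c in chroms], dtype=float)
    pick = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    lengths = rng.integers(len_range[0], len_range[1] + 1, size=n)
    frames = []
    for ci in np.unique(pick):
        m = pick == ci
        chrom = chroms[int(ci)]
        garr = genome[chrom]
        ls = lengths[m]
        starts = (rng.random(int(m.sum())) * (len(garr) - ls)).astype(np.int64)
        minus = rng.random(int(m.sum())) < 0.5
        for L in np.unique(ls):
            sel = ls == L
            seqs = _extract_seqs(garr, starts[sel], int(L), minus[sel])
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos0": starts[sel],
                        "strand": np.where(minus[sel], "-", "+"),
                        "length": int(L),
                        "seq": seqs,
                        "n_hits": 1,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# sidecar I/O

def write_sidecar(sidecar: pd.DataFrame, path: str | Path) -> None:
    sidecar.to_csv(path, sep="\t", index=False)


def read_sidecar(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
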