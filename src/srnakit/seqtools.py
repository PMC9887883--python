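"""Sequence utilities: reverse complement, duplex annealing geometry, adaptor trimming.

The annealing routine scores every ungapped antiparallel register of two
oligos by Watson-Crick matches (U and T are interchangeable; G*U wobble
is off by default) and reports the geometry of the best register -- the
duplex length and the single-stranded overhangs left on each strand.
This is the arithmetic behind designing an unwinding-assay substrate
such as an 11-bp duplex carrying a 3' single-strand extension.
"""

from __future__ import annotations

from dataclasses import dataclass

_ALPHABET = set("ACGUT")

_DNA_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "U": "A"}
_RNA_COMP = {"A": "U", "C": "G", "G": "C", "T": "A", "U": "A"}


@dataclass(frozen=True)
class Oligo:
    """A short single-stranded nucleic acid, written 5'->3'."""

    seq: str
    label: str = ""

    def __post_init__(self) -> None:
        validate_alphabet(self.seq)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DuplexReport:
    """Geometry of the best ungapped antiparallel register of two strands.

    ``offset`` is the register index (see :func:`anneal`); ``duplex_length``
    counts the Watson-Crick paired positions; overhangs are the unpaired
    terminal lengths outside the paired span of each strand.
    """

    offset: int
    duplex_length: int
    paired_fraction: float
    a_overhang_5p: int
    a_overhang_3p: int
    b_overhang_5p: int
    b_overhang_3p: int


def validate_alphabet(seq: str) -> None:
    for i, c in enumerate(seq):
        if c.upper() not in _ALPHABET:
            raise ValueError(f"invalid nucleotide {c!r} at position {i}")


def _seq_of(x: "str | Oligo") -> str:
    return x.seq if isinstance(x, Oligo) else x


def revcomp(seq: "str | Oligo", rna: bool | None = None) -> str:
    """Reverse complement, preserving the input alphabet (RNA in -> RNA out).

    With ``rna=None`` the alphabet is inferred: a sequence containing U
    (and no T) complements into RNA, anything else into DNA.  Pass
    ``rna`` explicitly for sequences that do not pin the alphabet down
    themselves (e.g. "ACG").
    """
    s = _seq_of(seq)
    validate_alphabet(s)
    up = s.upper()
    if rna is None:
        rna = "U" in up and "T" not in up
    comp = _RNA_COMP if rna else _DNA_COMP
    return "".join(comp[c] for c in reversed(up))


def _pairs(x: str, y: str, wobble: bool) -> bool:
    """True when bases x and y can pair in an antiparallel duplex (U==T)."""
    x = "U" if x == "T" else x
    y = "U" if y == "T" else y
    if {x, y} in ({"A", "U"}, {"G", "C"}):
        return True
    return wobble and {x, y} == {"G", "U"}


def anneal(a: "str | Oligo", b: "str | Oligo", wobble: bool = False) -> DuplexReport:
    """Find the maximal-match ungapped antiparallel register of two oligos.

    Register ``offset`` o aligns base i of strand a (5'->3') against base
    ``len(b) - 1 - (i + o)`` of strand b, i.e. a is slid along the reverse
    of b.  All registers with at least one aligned position are scored by
    the number of Watson-Crick pairs; ties break toward the smallest
    offset.  Overhangs are measured outside the *paired span* (first to
    last matched position), so a register with zero matches reports
    duplex length 0.
    """
    sa, sb = _seq_of(a).upper(), _seq_of(b).upper()
    if not sa or not sb:
        raise ValueError("both strands must be non-empty for annealing")
    validate_alphabet(sa)
    validate_alphabet(sb)
    la, lb = len(sa), len(sb)

    best: tuple[int, int] | None = None  # (-matches, offset)
    best_hits: list[int] = []
    for off in range(-(la - 1), lb):
        lo = max(0, -off)
        hi = min(la, lb - off)
        hits = [i for i in range(lo, hi) if _pairs(sa[i], sb[lb - 1 - (i + off)], wobble)]
        key = (-len(hits), off)
        if best is None or key < best:
            best = key
            best_hits = hits
    matches = -best[0]
    off = best[1]

    if matches == 0:
        return DuplexReport(off, 0, 0.0, 0, 0, 0, 0)

    # paired span in a coordinates
    i0, i1 = best_hits[0], best_hits[-1]
    span = i1 - i0 + 1
    # partner coordinates in b (antiparallel: i0 pairs with the larger b index)
    j_hi = lb - 1 - (i0 + off)
    j_lo = lb - 1 - (i1 + off)
    return DuplexReport(
        offset=off,
        duplex_length=matches,
        paired_fraction=matches / span,
        a_overhang_5p=i0,
        a_overhang_3p=la - 1 - i1,
        b_overhang_5p=j_lo,
        b_overhang_3p=lb - 1 - j_hi,
    )


def trim_filter(read: str, adaptor: str, min_len: int = 15) -> tuple[str, bool]:
    """Trim a 3' adaptor and apply the minimum-length filter.

    Everything from the first exact occurrence of the adaptor onward is
    removed; if the full adaptor is absent, the longest adaptor prefix of
    at least 6 nt sitting flush at the read's 3' end is removed instead.
    Reads lacking any adaptor match are returned unmodified.  Returns
    ``(trimmed, kept)`` where ``kept`` is True iff the trimmed length is
    at least ``min_len``.
    """
    if not adaptor:
        raise ValueError("adaptor must be non-empty")
    cut = read.find(adaptor)
    if cut == -1:
        for k in range(min(len(adaptor) - 1, len(read)), 5, -1):
            if read.endswith(adaptor[:k]):
                cut = len(read) - k
                break
    trimmed = read[:cut] if cut != -1 else read
    return trimmed, len(trimmed) >= min_len
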