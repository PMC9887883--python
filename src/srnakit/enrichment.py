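"""Threshold-based set procedures.

IP-enrichment calling (strictly more than ``fold`` over the matched
input, with a minimum-RPM floor on the IP side), differential
categories (at-least ``fold`` in either direction, floor applied to the
higher side), set cross-tabulations, ectopic-target detection,
suppression counting, composite unions across mutants, and IP-MS
protein enrichment.  Zero-reference folds are reported as +inf rather
than pseudocounted so the recorded thresholds mean what they say; an
optional pseudocount is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .types import CountTable, DifferentialResult, EnrichedSet


def _check_universe(a: CountTable, b: CountTable) -> pd.Index:
    ia, ib = a.genes, b.genes
    if not ia.equals(ib):
        diff = sorted(set(ia).symmetric_difference(set(ib)))
        shown = ", ".join(diff[:10]) + ("..." if len(diff) > 10 else "")
        raise ValueError(
            f"gene universes differ between {a.sample_id!r} and {b.sample_id!r} "
            f"({len(diff)} genes): {shown}"
        )
    return ia


def _folds(num: pd.Series, den: pd.Series, pseudocount: float) -> pd.Series:
    if pseudocount > 0:
        return (num + pseudocount) / (den + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / den
    return f  # inf where den==0, num>0; nan for 0/0


def ip_enrichment(
    ip: CountTable,
    input_table: CountTable,
    fold: float = 2.0,
    min_rpm: float = 1.0,
    strict: bool = True,
    pseudocount: float = 0.0,
) -> EnrichedSet:
    """Genes whose IP RPM clears the floor and exceeds ``fold`` x input RPM.

    ``strict`` uses ">" ("more than 2-fold"); non-strict uses ">=" ("at
    least 2-fold", the CLIP wording).  A gene with zero input RPM and an
    IP RPM at or above the floor is enriched with fold +inf; 0/0 genes
    are excluded.
    """
    genes = _check_universe(ip, input_table)
    f = _folds(ip.rpm, input_table.rpm, pseudocount)
    passes = ip.rpm >= min_rpm
    passes &= (f > fold) if strict else (f >= fold)
    passes &= ~f.isna()
    members = {g: float(f[g]) for g in genes[passes]}
    return EnrichedSet(
        ip_sample=ip.sample_id,
        ref_sample=input_table.sample_id,
        fold_threshold=fold,
        strict=strict,
        min_rpm=min_rpm,
        members=members,
    )


def differential(
    test: CountTable,
    ref: CountTable,
    fold: float = 2.0,
    floor_rpm: float = 0.0,
    pseudocount: float = 0.0,
) -> DifferentialResult:
    """Categorize genes as up / down / unchanged / below_floor between two samples.

    up: test >= fold x ref and test RPM > floor; down: ref >= fold x
    test and ref RPM > floor (the floor sits on the higher side, so a
    "2-fold reduction and >5 RPM" call floors the reference).  Genes at
    or below the floor in both samples are below_floor.
    """
    if floor_rpm < 0:
        raise ValueError("floor_rpm must be nonnegative")
    genes = _check_universe(test, ref)
    t, r = test.rpm, ref.rpm
    up = (t >= fold * r) & (t > floor_rpm)
    down = (r >= fold * t) & (r > floor_rpm) & ~up
    below = ~up & ~down & (t <= floor_rpm) & (r <= floor_rpm)
    category = np.select(
        [up, down, below], ["up", "down", "below_floor"], default="unchanged"
    )
    f = _folds(t, r, pseudocount)
    table = pd.DataFrame(
        {"category": category, "fold": f, "test_rpm": t, "ref_rpm": r}, index=genes
    )
    return DifferentialResult(
        test_sample=test.sample_id,
        ref_sample=ref.sample_id,
        fold_threshold=fold,
        floor_rpm=floor_rpm,
        table=table,
    )


@dataclass(frozen=True)
class CrossTab:
    """Overlap bookkeeping for two gene sets within a universe."""

    n_a: int
    n_b: int
    n_intersection: int
    n_union: int

    @property
    def jaccard(self) -> float:
        return self.n_intersection / self.n_union if self.n_union else 0.0

    @property
    def shared_fraction_a(self) -> float:
        return self.n_intersection / self.n_a if self.n_a else 0.0

    @property
    def shared_fraction_b(self) -> float:
        return self.n_intersection / self.n_b if self.n_b else 0.0


def set_crosstab(a: Iterable[str], b: Iterable[str], universe: Iterable[str]) -> CrossTab:
    """Overlap counts and fractions for two gene sets inside a shared universe."""
    sa, sb, su = set(a), set(b), set(universe)
    stray = (sa | sb) - su
    if stray:
        shown = ", ".join(sorted(stray)[:10])
        raise ValueError(f"{len(stray)} set members outside the universe: {shown}")
    return CrossTab(
        n_a=len(sa), n_b=len(sb), n_intersection=len(sa & sb), n_union=len(sa | sb)
    )


def ectopic_targets(
    diff: DifferentialResult,
    csr1_list: Iterable[str],
    ip_sets: Mapping[str, EnrichedSet],
    wago_keys: Sequence[str] | None = None,
    csr1_key: str = "CSR1",
) -> set[str]:
    """CSR-1 targets gaining small RNAs that relocate into the WAGO branch.

    A gene qualifies iff it (a) is on the CSR-1 target list, (b) is
    category 'up' in ``diff``, (c) is enriched in at least one
    WAGO-family IP, and (d) is NOT enriched in the CSR-1 IP.  WAGO keys
    default to every ip_sets key starting with "WAGO".
    """
    if wago_keys is None:
        wago_keys = [k for k in ip_sets if k.upper().startswith("WAGO")]
    if not wago_keys:
        raise ValueError("no WAGO-family IP set provided")
    missing = [k for k in [*wago_keys, csr1_key] if k not in ip_sets]
    if missing:
        raise ValueError(f"missing IP sets: {missing}")
    csr1 = set(csr1_list)
    up = diff.up
    wago_any = set().union(*(ip_sets[k].genes for k in wago_keys))
    return (csr1 & up & wago_any) - ip_sets[csr1_key].genes


def suppression(
    ectopic: Iterable[str],
    mutant: CountTable,
    double: CountTable,
    fold: float = 2.0,
    criterion: str = "halved",
    wt: CountTable | None = None,
) -> tuple[set[str], tuple[int, int]]:
    """Which ectopic genes lose their extra small RNAs in the double mutant.

    'halved' (default): double RPM <= mutant RPM / fold.  'restored':
    double RPM within ``fold`` of the wild-type level (requires ``wt``).
    Returns (suppressed subset, (n_suppressed, n_total)).
    """
    genes = sorted(set(ectopic))
    if not genes:
        return set(), (0, 0)
    _check_universe(mutant, double)
    missing = [g for g in genes if g not in mutant.genes]
    if missing:
        raise ValueError(f"ectopic genes outside the count universe: {missing[:10]}")
    m, d = mutant.rpm, double.rpm
    if criterion == "halved":
        ok = {g for g in genes if d[g] <= m[g] / fold}
    elif criterion == "restored":
        if wt is None:
            raise ValueError("criterion 'restored' requires the wild-type table")
        w = wt.rpm
        ok = {g for g in genes if d[g] <= fold * w[g]}
    else:
        raise ValueError(f"unknown suppression criterion {criterion!r}")
    return ok, (len(ok), len(genes))


def composite_union(
    diffs: Sequence[DifferentialResult], category: str = "down"
) -> set[str]:
    """Union of one category across several differential results (e.g. all
    genes depleted in at least one double mutant)."""
    out: set[str] = set()
    for d in diffs:
        out |= d.genes(category)
    return out


def overlap_fraction(composite: Iterable[str], reference: Iterable[str]) -> float:
    """|composite n reference| / |composite| (0 for an empty composite)."""
    c, r = set(composite), set(reference)
    return len(c & r) / len(c) if c else 0.0


def protein_enrichment(
    ip: pd.Series,
    background: pd.Series,
    fold: float = 2.0,
) -> dict[str, float]:
    """Proteins with at-least ``fold`` enrichment of relative peptide level
    in the IP over the background IP.

    Missing proteins count as level 0 on the side they are absent from;
    a protein detected in the IP but absent from background is enriched
    with fold +inf.  Returns protein_id -> fold for the enriched set.
    """
    universe = ip.index.union(background.index)
    i = ip.reindex(universe, fill_value=0.0).astype(float)
    b = background.reindex(universe, fill_value=0.0).astype(float)
    if (i < 0).any() or (b < 0).any():
        raise ValueError("peptide levels must be nonnegative")
    out: dict[str, float] = {}
    for p in universe:
        if i[p] <= 0:
            continue
        f = math.inf if b[p] == 0 else i[p] / b[p]
        if f >= fold:
            out[p] = f
    return out


def read_protein_table(path) -> pd.Series:
    """Two-column TSV (protein_id, level) -> Series."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return pd.Series(df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str))
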