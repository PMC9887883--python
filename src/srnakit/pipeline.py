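"""End-to-end orchestration: simulation -> classification -> quantification
-> enrichment -> CLIP analysis, with an auditable manifest.

The bundled demo design mirrors a germline Argonaute study: wild type
and a helicase-null mutant with a planted 50-gene ectopic set (CSR-1
targets that gain 22G-RNAs and relocate into the WAGO branch), two
"double mutant" conditions in which overlapping subsets of the ectopic
genes are suppressed, a separate hypomorphic condition depleting a
planted WAGO-dependent set, and a pair of CLIP libraries (tagged bait
with 3'-biased binding vs untagged control).  Every output table
carries the thresholds that produced it in a JSON header line, and the
whole run is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import GeneIndex, write_annotation_tsv, write_gff3
from .clip import class_composition, clip_targets, metagene_profile
from .enrichment import (
    composite_union,
    differential,
    ectopic_targets,
    ip_enrichment,
    overlap_fraction,
    set_crosstab,
    suppression,
)
from .smallrna import quantify
from .synth import BaitSpec, PlantedSet, SampleSpec, SimConfig, build_truth, simulate_library
from .types import write_gene_list

log = logging.getLogger("srnakit")


@dataclass(frozen=True)
class Thresholds:
    """Every fold / floor the pipeline applies; defaults follow the study conventions."""

    ip_fold: float = 2.0          # strictly more than 2-fold over input
    ip_min_rpm: float = 1.0
    diff_fold: float = 2.0        # at least 2-fold either direction
    diff_floor_rpm: float = 0.0
    depleted_floor_rpm: float = 5.0   # "2-fold reduction and >5 RPM"
    clip_fold: float = 2.0        # at least 2-fold over untagged
    clip_min_rpm: float = 5.0
    clip_min_len: int = 15
    suppress_fold: float = 2.0
    protein_fold: float = 2.0
    g22_length: int = 22
    metagene_bins: int = 100


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    outdir: str
    seed: int = 0
    depth: int = 100_000
    thresholds: Thresholds = field(default_factory=Thresholds)
    sim: SimConfig = field(default_factory=SimConfig)
    samples: list[SampleSpec] = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thr = Thresholds(**raw.get("thresholds", {}))
        simraw = dict(raw.get("sim", {}))
        simraw["planted_sets"] = tuple(
            PlantedSet(**p) for p in simraw.get("planted_sets", [])
        )
        simraw["baits"] = tuple(
            BaitSpec(
                name=b["name"],
                e=b["e"],
                targets=tuple(b.get("targets", [])),
                targets_by_condition={
                    k: tuple(v) for k, v in b.get("targets_by_condition", {}).items()
                },
            )
            for b in simraw.get("baits", [])
        )
        for key in ("mrna_len", "gap", "mixture", "clip_mixture", "clip_frag_len", "read_len_other"):
            if key in simraw:
                simraw[key] = tuple(simraw[key])
        samples = [SampleSpec(**s) for s in raw.get("samples", [])]
        return cls(
            outdir=raw["outdir"],
            seed=int(raw.get("seed", 0)),
            depth=int(raw.get("depth", 100_000)),
            thresholds=thr,
            sim=SimConfig(**simraw),
            samples=samples,
        )


def demo_config(outdir: str, seed: int = 0, depth: int = 100_000) -> RunConfig:
    """The bundled demo study design (see module docstring)."""
    sim = SimConfig(
        n_mrna=1000,
        n_pirna=60,
        n_mirna=20,
        n_wago=80,
        n_csr1=300,
        n_both=20,
        planted_sets=(
            PlantedSet("ectopic", "CSR1", 50),
            PlantedSet("ectopic_retained_a", "ectopic", 15),
            PlantedSet("ectopic_retained_b", "ectopic", 25),
            PlantedSet("wago_dep", "WAGO", 60),
        ),
        conditions={
            "wt": {},
            "mut": {"ectopic": 4.0},
            "double_a": {"ectopic_retained_a": 4.0},
            "double_b": {"ectopic_retained_b": 4.0},
            "k391a": {"wago_dep": 0.25},
        },
        baits=(
            BaitSpec(
                "WAGO1",
                e=6.0,
                targets=("WAGO",),
                targets_by_condition={"mut": ("WAGO", "ectopic")},
            ),
            BaitSpec(
                "CSR1",
                e=6.0,
                targets=("CSR1",),
                targets_by_condition={"mut": ("CSR1", "-ectopic")},
            ),
            BaitSpec("GLH1", e=6.0, targets=("WAGO",)),
        ),
        clip_beta=3.0,
    )
    samples = [
        SampleSpec("wt_input", "wt", "input", None, depth),
        SampleSpec("mut_input", "mut", "input", None, depth),
        SampleSpec("k391a_input", "k391a", "input", None, depth),
        SampleSpec("double_a_input", "double_a", "input", None, depth),
        SampleSpec("double_b_input", "double_b", "input", None, depth),
        SampleSpec("wt_WAGO1_IP", "wt", "IP", "WAGO1", depth),
        SampleSpec("wt_CSR1_IP", "wt", "IP", "CSR1", depth),
        SampleSpec("mut_WAGO1_IP", "mut", "IP", "WAGO1", depth),
        SampleSpec("mut_CSR1_IP", "mut", "IP", "CSR1", depth),
        SampleSpec("clip_GLH1", "wt", "CLIP", "GLH1", depth),
        SampleSpec("clip_untagged", "wt", "CLIP-control", None, depth),
    ]
    return RunConfig(outdir=outdir, seed=seed, depth=depth, sim=sim, samples=samples)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run simulation and the full analysis; returns the manifest dict.

    Per-stage failures are recorded in the manifest and downstream
    stages that depend on a failed stage are skipped with explicit
    status rather than aborting the run.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))

    thr = config.thresholds
    manifest: dict = {
        "srnakit_version": __version__,
        "seed": config.seed,
        "depth": config.depth,
        "thresholds": dataclasses.asdict(thr),
        "stages": {},
        "outputs": {},
        "results": {},
    }

    def stage(name: str):
        def deco(fn):
            def run(*args, **kw):
                try:
                    res = fn(*args, **kw)
                    manifest["stages"][name] = "ok"
                    return res
                except Exception as exc:  # noqa: BLE001 - per-stage reporting
                    log.error("stage %s failed: %s", name, exc)
                    manifest["stages"][name] = f"failed: {exc}"
                    return None
            return run
        return deco

    # --- simulate
    genes, truth = build_truth(config.sim, config.seed)
    index = GeneIndex(genes)
    write_annotation_tsv(genes, out / "annotation.tsv")
    write_gff3(genes, out / "annotation.gff3")
    manifest["stages"]["simulate"] = "ok"

    libs: dict[str, pd.DataFrame] = {}
    specs = {s.sample_id: s for s in config.samples}
    for s in config.samples:
        frame, sidecar = simulate_library(genes, truth, s)
        libs[s.sample_id] = frame
        sidecar.to_csv(out / f"{s.sample_id}.truth.tsv", sep="\t", index=False)
        log.info("simulated %s (%d reads)", s.sample_id, len(frame))

    # --- quantify
    tables: dict[str, object] = {}

    @stage("quantify")
    def _quantify():
        for sid, frame in libs.items():
            cls = "mRNA" if specs[sid].fraction.startswith("CLIP") else "22G"
            ct = quantify(frame, index, class_filter=cls, norm="total", sample_id=sid)
            ct.to_tsv(out / f"{sid}.counts.tsv")
            tables[sid] = ct
        return tables

    _quantify()

    def input_of(condition: str) -> str:
        for s in config.samples:
            if s.condition == condition and s.fraction == "input":
                return s.sample_id
        raise ValueError(f"no input library for condition {condition!r}")

    # --- IP enrichment
    ip_sets: dict[tuple[str, str], object] = {}

    @stage("ip_enrichment")
    def _enrich():
        for s in config.samples:
            if s.fraction != "IP":
                continue
            ref = tables[input_of(s.condition)]
            es = ip_enrichment(
                tables[s.sample_id], ref, fold=thr.ip_fold, min_rpm=thr.ip_min_rpm, strict=True
            )
            es.to_tsv(out / f"{s.sample_id}.enriched.tsv")
            ip_sets[(s.condition, s.bait)] = es
            manifest["results"][f"n_enriched.{s.sample_id}"] = len(es)
        return ip_sets

    _enrich()

    # --- crosstabs of WAGO vs CSR-1 enrichment per condition
    @stage("crosstab")
    def _crosstab():
        universe = set(index.gene_ids)
        for cond in ("wt", "mut"):
            a = ip_sets.get((cond, "WAGO1"))
            b = ip_sets.get((cond, "CSR1"))
            if a is None or b is None:
                continue
            ct = set_crosstab(a.genes, b.genes, universe)
            manifest["results"][f"crosstab.{cond}"] = {
                "n_wago": ct.n_a,
                "n_csr1": ct.n_b,
                "n_both": ct.n_intersection,
                "jaccard": round(ct.jaccard, 4),
            }

    if ip_sets:
        _crosstab()

    # --- differential calls
    diffs: dict[str, object] = {}

    @stage("differential")
    def _diff():
        wt = tables[input_of("wt")]
        for cond in config.sim.conditions:
            if cond == "wt":
                continue
            try:
                test = tables[input_of(cond)]
            except ValueError:
                continue
            d = differential(test, wt, fold=thr.diff_fold, floor_rpm=thr.diff_floor_rpm)
            d.to_tsv(out / f"diff.{cond}_vs_wt.tsv")
            diffs[cond] = d
            manifest["results"][f"n_up.{cond}"] = len(d.up)
            manifest["results"][f"n_down.{cond}"] = len(d.down)
        return diffs

    _diff()

    # --- ectopic targets and suppression
    ectopic: set[str] | None = None

    @stage("ectopic")
    def _ectopic():
        nonlocal ectopic
        if "mut" not in diffs:
            raise ValueError("no mutant-vs-wt differential available")
        sets = {
            "WAGO1": ip_sets[("mut", "WAGO1")],
            "CSR1": ip_sets[("mut", "CSR1")],
        }
        ectopic = ectopic_targets(diffs["mut"], index.of_target_class("CSR1"), sets)
        write_gene_list(
            ectopic,
            out / "ectopic_targets.tsv",
            header={
                "rule": "CSR1-list & up(mut vs wt) & WAGO-IP-enriched & not CSR1-IP-enriched",
                "diff_fold": thr.diff_fold,
                "ip_fold": thr.ip_fold,
            },
        )
        manifest["results"]["n_ectopic"] = len(ectopic)
        return ectopic

    if ("mut", "WAGO1") in ip_sets and ("mut", "CSR1") in ip_sets and "mut" in diffs:
        _ectopic()
    else:
        manifest["stages"]["ectopic"] = "skipped: missing mutant IP sets or differential"

    @stage("suppression")
    def _suppress():
        mut = tables[input_of("mut")]
        for cond in config.sim.conditions:
            if not cond.startswith("double"):
                continue
            dbl = tables[input_of(cond)]
            sup, (n_sup, n_tot) = suppression(ectopic, mut, dbl, fold=thr.suppress_fold)
            write_gene_list(
                sup,
                out / f"suppressed.{cond}.tsv",
                header={"criterion": "halved", "fold": thr.suppress_fold},
            )
            manifest["results"][f"suppressed.{cond}"] = [n_sup, n_tot]

    if ectopic is not None:
        _suppress()
    else:
        manifest["stages"]["suppression"] = "skipped: no ectopic set"

    # --- composite union across double mutants
    @stage("composite")
    def _composite():
        wt = tables[input_of("wt")]
        dd = []
        for cond in config.sim.conditions:
            if not cond.startswith("double"):
                continue
            mutd = differential(
                tables[input_of(cond)],
                tables[input_of("mut")],
                fold=thr.diff_fold,
                floor_rpm=thr.diff_floor_rpm,
            )
            dd.append(mutd)
        if not dd:
            return
        comp = composite_union(dd, category="down")
        frac = overlap_fraction(comp, ectopic or set())
        write_gene_list(comp, out / "composite_down.tsv", header={"category": "down"})
        manifest["results"]["n_composite_down"] = len(comp)
        manifest["results"]["composite_overlap_with_ectopic"] = round(frac, 4)

    _composite()

    # --- CLIP: targets, composition, metagene
    @stage("clip")
    def _clip():
        tagged = [s for s in config.samples if s.fraction == "CLIP"]
        control = [s for s in config.samples if s.fraction == "CLIP-control"]
        if not tagged or not control:
            return
        tag, ctl = tagged[0], control[0]
        es = clip_targets(
            tables[tag.sample_id],
            tables[ctl.sample_id],
            fold=thr.clip_fold,
            min_rpm=thr.clip_min_rpm,
        )
        es.to_tsv(out / f"{tag.sample_id}.clip_targets.tsv")
        manifest["results"]["n_clip_targets"] = len(es)

        comp = class_composition(libs[tag.sample_id], index)
        manifest["results"]["clip_composition"] = {
            k: round(v, 2) for k, v in comp["percent"].items()
        }

        if "k391a" in diffs:
            d = differential(
                tables[input_of("k391a")],
                tables[input_of("wt")],
                fold=thr.diff_fold,
                floor_rpm=thr.depleted_floor_rpm,
            )
            dep = d.down
            ctrl_set = d.genes("unchanged")
            for name, gene_set in (("depleted", dep), ("control", ctrl_set)):
                if not gene_set:
                    continue
                prof = metagene_profile(
                    libs[tag.sample_id],
                    gene_set,
                    index,
                    mode="mean",
                    sample_id=tag.sample_id,
                    set_id=name,
                )
                prof.to_tsv(out / f"metagene.{name}.{tag.sample_id}.tsv")
                manifest["results"][f"metagene_com.{name}"] = round(prof.center_of_mass, 2)

    _clip()

    # --- manifest
    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.removeHandler(handler)
    handler.close()
    return manifest
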