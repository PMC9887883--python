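# Methods

This note documents the models and procedures srnakit implements, the
parameters that matter, what the simulator does and does not emulate,
and the design choices made where the design was genuinely open.

## Read classification

Reads are classified against an annotation of loci with biotypes
{mRNA, piRNA, miRNA, other}. Assignment resolves overlap with biotype
precedence piRNA > miRNA > mRNA > other; within a biotype the gene with
the larger overlap wins and ties break to the lexicographically
smallest `gene_id`, so assignment is deterministic and independent of
input order. The minimum overlap to assign is 1 nt. A read on a
chromosome absent from the annotation is `unassigned`, not an error.

A **22G-RNA** call requires a uniquely mapped read (`n_hits == 1`),
length exactly 22 nt, antisense to its assigned mRNA locus. The 5′-G
check is off by default: operationally the class is defined by
length + strand + uniqueness, and real libraries contain a minority of
non-G starts; the check can be enabled (`ClassifyRules(check_5p_g=True)`).
**piRNA** calls require sense overlap of a piRNA locus; 21-nt length
and 5′-U checks are optional for the same reason. Every record receives
exactly one label, so class percentages always total 100%.

Sense/antisense bookkeeping: internally `seq` is the read as sequenced
(5′→3′ of the molecule); SAM's reference-forward orientation is
converted at I/O. Coordinates are 0-based half-open internally, with
GFF3 (1-based inclusive) and SAM POS converted at the boundary.

## Quantification

RPM(g) = count(g) / N × 10⁶. The default denominator N is every mapped
record in the sample (class-independent), matching normalization by
total read counts; `norm="unique"` restricts N to unique mappers and
`norm="counted"` to the counted class, because published pipelines are
ambiguous on whether multimappers enter the denominator. An empty
stream yields an all-zero table with N = 0 rather than a division
error. When every counted read maps to exactly one gene and N equals
the counted reads, ΣRPM = 10⁶ exactly (a property test enforces this).

## Threshold rules

The wording of the source procedures distinguishes "more than" from
"at least", and the package preserves that distinction:

| procedure | rule | strictness | floor |
|---|---|---|---|
| IP enrichment | IP/input fold > 2 | strict | IP RPM ≥ 1 |
| differential | fold ≥ 2 either direction | non-strict | higher side > floor (default 0) |
| depleted-set definition | down ≥ 2-fold | non-strict | reference > 5 RPM |
| CLIP targets | tagged/untagged ≥ 2 | non-strict | tagged RPM ≥ 5 |
| IP-MS proteins | IP/background ≥ 2 | non-strict | — |

Zero-denominator folds are reported as +∞ rather than pseudocounted,
so the recorded thresholds are applied to unmodified RPM values; a
pseudocount option exists for plotting-style use. 0/0 genes are
excluded from enriched sets. The differential floor sits on the
*higher* side of the comparison because a "2-fold reduction and
> 5 RPM" rule is only meaningful on the sample that still has signal.

**Suppression** of an ectopic gene in a paralog-depletion double mutant
is not given an explicit criterion in the source analyses; the default
here is `double RPM ≤ mutant RPM / 2`, with a second variant
("restored": double within 2-fold of wild type) selectable. Both are
reported with the criterion recorded in the output header.

**Ectopic targets** = (CSR-1 list) ∩ (up in mutant vs wild type) ∩
(≥ 1 WAGO-family IP enriched set) − (CSR-1 IP enriched set). The
differential step uses the plain ≥ 2-fold rule with no extra floor,
the same rule as the general differential scatter.

## Metagene profiles

Each gene's per-base RPM coverage over its annotated span (the span is
the transcript proxy; no splicing model) is oriented 5′→3′ and rebinned
into exactly 100 bins of 1% transcript length by fractional overlap,
implemented as linear interpolation of the cumulative coverage, so
Σbins = Σcoverage to float precision for any gene length. Aggregation
across genes is mean (default; every gene weighted equally — whether
published metagenes weight genes equally or by coverage is usually
unstated, and sum mode is retained both for conservation tests and as
the coverage-weighted alternative). Profiles are summarized by centre
of mass Σi·vᵢ/Σvᵢ over bins i = 1..100; a flat profile gives 50.5.

## The simulator

`build_truth` lays out non-overlapping loci round-robin across
chromosomes (defaults: 1000 mRNAs of 500–2000 nt, 60 piRNA loci of
21 nt, 20 miRNA loci of 22 nt on 3 chromosomes), assigns WAGO/CSR-1/
both/none target classes, draws log-normal baseline abundances
(σ = 0.25 — modest spread so that depth-10⁵ libraries give usable
per-gene counts while still exercising abundance-dependent noise), and
materializes an i.i.d.-uniform ACGT genome. piRNA loci get a forced
sense-strand 5′ T (read as U) and miRNA loci a 5′ G.

`simulate_library` draws the class mixture multinomially (defaults for
small-RNA libraries: 80% 22G, 12% piRNA, 4% miRNA, 4% background;
CLIP: 85% mRNA fragments, 10% piRNA, 5% background — the true
first-nucleotide and class distributions of real libraries are not
published, so these are explicit configuration, not claims), then
per-gene counts multinomially with weights
abundance × condition multiplier × (e for bait targets in IP/tagged
CLIP). The truth sidecar therefore sums to the requested depth exactly.
22G read sequences are genuine genome slices: start positions are
sampled among positions whose antisense read begins with G, so the
classifier's optional 5′-G check can be exercised honestly. CLIP
fragment lengths are uniform on 15–40 nt and transcript-relative start
positions follow u = 1 − Beta(1, 1+β): β = 0 is uniform over the valid
start range, larger β piles starts toward the 3′ end, and E[u] =
1 − 1/(2+β) makes the bias analytically checkable. Per-sample RNG
streams derive from `SeedSequence([master_seed, crc32(sample_id)])`, so
samples are independent but the whole study is reproducible from one
seed. Mapping multiplicity is simulated by flagging a configurable
fraction of 22G reads with `n_hits = 2` (default 0) to exercise the
unique-mapper filter.

What the simulator does **not** emulate: sequencing errors, adapter
chimeras, transcript structure (introns/UTRs), ping-pong piRNA
biogenesis, motif composition, or mapping ambiguity beyond the NH flag.
Passing recovery tests therefore demonstrate that the *procedures*
recover planted structure under idealized sampling noise; they do not
certify performance on real libraries with alignment artifacts.

## Study-condition sizing

An IP library's observed fold is diluted by its own normalization:
with target weight fraction small, observed fold ≈ e × Σw_input/Σw_IP.
The recovery conditions (e = 4, 100 planted genes among 1000 mRNAs,
depth 10⁵) give an expected observed fold ≈ 3.1 with a per-gene
coefficient of variation ≈ 12%, hence ≥ 95% recall at the fold > 2
rule with essentially no false positives; the same arithmetic applies
to the 4× differential multiplier. The bundled demo design uses e = 6
and smaller bait sets for the ectopic scenario, because the WAGO bait
set there contains 150 genes including the 50 ectopic ones at 4×
abundance, which dilutes folds more strongly. These are power
considerations applied at design time, not fits to data.

Desk-scale problem sizes used by the test suite: unit fixtures of
60 genes / 8000 reads; recovery tests at depth 10⁵ over 20 master
seeds; metagene bias over a β ∈ {0, 2, 5} grid with 10 seeds each;
the pipeline demo at depth 2×10⁴ in unit tests and 10⁵ in the
recovery suite.

## Numerical and degenerate-input choices

- Annealing scores all ungapped antiparallel registers; duplex length
  is the count of Watson–Crick matches (U ≡ T; G·U wobble opt-in),
  ties break to the smallest register offset, and overhangs are
  measured outside the first-to-last matched span.
- Adaptor trimming is exact substring plus a ≥ 6-nt adaptor prefix
  flush at the 3′ terminus; reads without a match are kept unmodified
  (the procedure specifies only a length floor). No error tolerance:
  synthetic reads are error-free and full trimmer fidelity is out of
  scope.
- `revcomp` infers RNA vs DNA output from the input (U and no T → RNA)
  and takes an explicit `rna=` flag for sequences that do not pin the
  alphabet down; with the explicit flag it is an involution.
- Gene-overlap queries use a sorted-array vectorized path when loci
  within a biotype layer are non-overlapping (always true for
  simulated annotations) and fall back to an interval tree otherwise.
- Enriched sets, differential tables, counts and profiles serialize as
  TSV with a single JSON header line carrying every threshold that
  produced them; the pipeline manifest additionally records seed,
  version and SHA-256 digests of all outputs, and two runs with the
  same config and seed are byte-identical.

## Known limitations

- The metagene uses annotated spans, not spliced transcripts; an
  exon-aware mode would be required for real GFF3 annotations with
  introns.
- CLIP crosslink-site (deletion/truncation) calling and peak calling
  are out of scope; target calling is gene-level.
- No statistical testing is attached to the threshold rules (the
  procedures they reproduce use none); counts are small-sample noisy
  near the thresholds, and the recovery guarantees quantify that only
  under the simulator's assumptions.
- The external-data path (SAM in, tables out) is exercised on
  simulated SAM; scaling to full published depositions is supported in
  principle but untested here.
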