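"""CLIP target calling and 3'-biased metagene profiles.

Simulates tagged and untagged CLIP libraries where fragment starts are
skewed toward the 3' end (beta = 3), calls targets with the at-least
2-fold / >= 5 RPM rule, and builds 100-bin metagene profiles whose
centre of mass reports the positional bias.
"""

from srnakit import SampleSpec, SimConfig, BaitSpec, PlantedSet, build_truth, quantify, simulate_library
from srnakit.clip import class_composition, clip_targets, metagene_profile

config = SimConfig(
    n_mrna=120, n_pirna=20, n_mirna=5, n_wago=20, n_csr1=20, n_both=0,
    planted_sets=(PlantedSet("bound", "mRNA", 30),),
    baits=(BaitSpec("GLH1", e=6.0, targets=("bound",)),),
    clip_beta=3.0,
)
genes, truth = build_truth(config, seed=13)

libs = {}
for sid, frac, bait in (("tagged", "CLIP", "GLH1"), ("untagged", "CLIP-control", None)):
    frame, _ = simulate_library(genes, truth, SampleSpec(sid, "wt", frac, bait, 40_000))
    libs[sid] = frame

tables = {
    sid: quantify(frame, genes, class_filter="mRNA", sample_id=sid)
    for sid, frame in libs.items()
}
es = clip_targets(tables["tagged"], tables["untagged"], fold=2.0, min_rpm=5.0)
planted = truth.sets["bound"]
print(f"planted bound genes: {len(planted)}; called CLIP targets: {len(es)}; "
      f"recovered: {len(es.genes & planted)}")

comp = class_composition(libs["tagged"], genes)
print("tagged-library class composition (%):",
      {k: round(v, 1) for k, v in comp["percent"].items()})

for beta_label, frame in libs.items():
    prof = metagene_profile(frame, sorted(planted), genes, sample_id=beta_label)
    print(f"{beta_label:9s} metagene centre of mass: bin {prof.center_of_mass:.1f} / 100")
print()
print("With beta = 3 the fragment starts pile up near the 3' end, so the")
print("centre of mass sits well beyond bin 50 (the uniform expectation).")
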