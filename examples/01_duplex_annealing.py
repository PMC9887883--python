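"""Annealing geometry of an unwinding-assay substrate.

Anneals the 11-nt labeled RNA oligo to its 22-nt partner strand and
reports the duplex register: how many base pairs form and what
single-stranded overhangs remain.  This is the substrate design check
for a helicase unwinding assay -- the enzyme needs a 3' single-strand
extension to load onto.
"""

from srnakit import anneal, revcomp

short = "AGCGCAGUACC"              # 5'-labeled 11-mer
long_ = "GGUACUGCGCUUUUAUGACAUC"   # 22-mer partner

rep = anneal(short, long_)
print(f"strands: {short} (11 nt) x {long_} (22 nt)")
print(f"duplex length:        {rep.duplex_length} bp")
print(f"paired fraction:      {rep.paired_fraction:.2f}")
print(f"long-strand 3' tail:  {rep.b_overhang_3p} nt single-stranded")
print(f"long-strand 5' tail:  {rep.b_overhang_5p} nt")
print()
print("The 11-mer is the exact reverse complement of the long strand's")
print(f"5' end ({revcomp(short)}...), so the duplex spans 11 bp and leaves")
print(f"an {rep.b_overhang_3p}-nt 3' extension for helicase loading.")
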